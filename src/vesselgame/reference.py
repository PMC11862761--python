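"""Published summary statistics from the original 25-participant study.

These printed per-level summaries (mean, sample SD, n = 25) are the
anchor for the simulator's default calibration and for reproducing the
reported confidence intervals and level-pair comparisons without access
to the raw data.
"""

from __future__ import annotations

N_PARTICIPANTS = 25

#: level_id -> (mean, sd) completion time in seconds.
TIME_SUMMARY: dict[int, tuple[float, float]] = {
    1: (5.7, 3.6),
    2: (3.3, 2.6),
    3: (7.2, 2.8),
    4: (6.4, 3.3),
    5: (12.5, 5.7),
    6: (9.8, 4.8),
    7: (16.4, 11.0),
}

#: level_id -> (mean, sd) attempts to complete.
ATTEMPTS_SUMMARY: dict[int, tuple[float, float]] = {
    1: (1.3, 2.0),
    2: (1.2, 0.7),
    3: (1.4, 1.1),
    4: (1.6, 1.1),
    5: (1.4, 0.7),
    6: (1.8, 0.9),
    7: (1.6, 1.2),
}

#: Matched level pairs identical except for the field of view: (full, limited).
FOV_PAIRS: tuple[tuple[int, int], ...] = ((4, 5), (6, 7))
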