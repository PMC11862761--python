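"""Statistical pipeline for trial data.

Per-level summaries with t-based 95% confidence intervals, Welch
two-sample comparisons with Satterthwaite degrees of freedom, Cohen's d
(equal-n pooled form), percent increases between matched level pairs,
questionnaire arithmetic, and noncentral-t sample-size planning.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DataError, DegenerateComparisonError, InsufficientDataError

CONF_LEVEL = 0.95


@dataclass(frozen=True)
class SummaryStats:
    """n, mean, sample SD (n-1 denominator) and t-based 95% CI."""

    n: int
    mean: float
    sd: float
    ci_low: float
    ci_high: float

    def formatted(self, decimals: int = 1) -> dict[str, str]:
        return {
            "mean_sd": f"{self.mean:.{decimals}f} ({self.sd:.{decimals}f})",
            "ci": format_ci(self.ci_low, self.ci_high, decimals),
        }


@dataclass(frozen=True)
class ComparisonResult:
    """Welch comparison of two levels plus effect-size measures."""

    t_stat: float
    df: float
    p_two_sided: float
    d: float
    pct_increase: float
    n1: int
    n2: int
    mean1: float
    mean2: float


class WelchResult(NamedTuple):
    t_stat: float
    df: float
    p_two_sided: float


def summarize(values: Sequence[float]) -> SummaryStats:
    """Mean, sample SD and t-based 95% CI: mean +/- t(0.975, n-1) * sd/sqrt(n)."""
    x = np.asarray(list(values), dtype=float)
    n = x.size
    if n < 2:
        raise InsufficientDataError(f"need at least 2 values, got {n}")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    half = float(sps.t.ppf(0.5 + CONF_LEVEL / 2, n - 1)) * sd / math.sqrt(n)
    return SummaryStats(n=n, mean=mean, sd=sd, ci_low=mean - half, ci_high=mean + half)


def summary_from_moments(mean: float, sd: float, n: int) -> SummaryStats:
    """Build the same t-based CI directly from printed (mean, SD, n)."""
    if n < 2:
        raise InsufficientDataError(f"need n >= 2, got {n}")
    if sd < 0:
        raise ValueError("sd must be non-negative")
    half = float(sps.t.ppf(0.5 + CONF_LEVEL / 2, n - 1)) * sd / math.sqrt(n)
    return SummaryStats(n=n, mean=mean, sd=sd, ci_low=mean - half, ci_high=mean + half)


def welch(m1: float, s1: float, n1: int, m2: float, s2: float, n2: int) -> WelchResult:
    """Welch two-sample t test from summary statistics.

    t = (m2 - m1) / sqrt(s1^2/n1 + s2^2/n2), Satterthwaite df, two-sided p.
    """
    if n1 < 2 or n2 < 2:
        raise InsufficientDataError("both groups need n >= 2")
    if s1 == 0 and s2 == 0:
        raise DegenerateComparisonError("both variances are zero")
    v1, v2 = s1 * s1 / n1, s2 * s2 / n2
    se = math.sqrt(v1 + v2)
    t = (m2 - m1) / se
    df = (v1 + v2) ** 2 / (v1 * v1 / (n1 - 1) + v2 * v2 / (n2 - 1))
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return WelchResult(t_stat=t, df=df, p_two_sided=min(p, 1.0))


def cohen_d(m1: float, s1: float, m2: float, s2: float) -> float:
    """Absolute standardized mean difference, |m2-m1| / sqrt((s1^2+s2^2)/2).

    The equal-n pooled form; appropriate here because compared groups
    always have the same size."""
    if s1 == 0 and s2 == 0:
        raise DegenerateComparisonError("both variances are zero")
    return abs(m2 - m1) / math.sqrt((s1 * s1 + s2 * s2) / 2.0)


def percent_increase(m_ref: float, m_new: float) -> float:
    """100 * (m_new - m_ref) / m_ref."""
    if m_ref <= 0:
        raise ValueError(f"reference mean must be positive, got {m_ref}")
    return 100.0 * (m_new - m_ref) / m_ref


def _metric_values(trials: Iterable, level: int, metric: str) -> np.ndarray:
    col = {"time": "time_s", "attempts": "attempts"}
    if metric not in col:
        raise ValueError(f"metric must be 'time' or 'attempts', got {metric!r}")
    if isinstance(trials, pd.DataFrame):
        df = trials
    else:
        rows = getattr(trials, "trials", trials)
        df = pd.DataFrame([vars(t) if not isinstance(t, dict) else t for t in rows])
    if df.empty or "level_id" not in df.columns:
        raise DataError("no trial rows")
    sub = df[df["level_id"] == level]
    if len(sub) < 2:
        raise DataError(f"level {level} has fewer than 2 trials")
    return sub[col[metric]].to_numpy(dtype=float)


def compare_levels(trials, level_a: int, level_b: int, metric: str = "time") -> ComparisonResult:
    """Welch comparison of two levels on time or attempts.

    Accepts a cohort dataset, an iterable of trial records, or a trials
    DataFrame.  Direction: level_a is the reference (percent increase is of
    level_b over level_a)."""
    xa = _metric_values(trials, level_a, metric)
    xb = _metric_values(trials, level_b, metric)
    m1, s1 = float(xa.mean()), float(xa.std(ddof=1))
    m2, s2 = float(xb.mean()), float(xb.std(ddof=1))
    w = welch(m1, s1, len(xa), m2, s2, len(xb))
    return ComparisonResult(
        t_stat=w.t_stat,
        df=w.df,
        p_two_sided=w.p_two_sided,
        d=cohen_d(m1, s1, m2, s2),
        pct_increase=percent_increase(m1, m2),
        n1=len(xa),
        n2=len(xb),
        mean1=m1,
        mean2=m2,
    )


def power_two_sample_t(d: float, n_per_group: int, alpha: float = 0.05) -> float:
    """Power of the two-sided two-sample t test at effect size d (noncentral t)."""
    if n_per_group < 2:
        return 0.0
    df = 2 * n_per_group - 2
    ncp = d * math.sqrt(n_per_group / 2.0)
    tcrit = float(sps.t.ppf(1 - alpha / 2, df))
    return float(sps.nct.sf(tcrit, df, ncp) + sps.nct.cdf(-tcrit, df, ncp))


def required_n(d: float, alpha: float = 0.05, power: float = 0.80) -> int:
    """Smallest n per group giving the requested power for effect size d.

    Exact noncentral-t search from the n=2 floor upward (doubling then
    bisection), not the normal approximation."""
    if d <= 0:
        raise ValueError("d must be positive")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power must lie in (0, 1)")
    lo = 2
    if power_two_sample_t(d, lo, alpha) >= power:
        return lo
    hi = 4
    while power_two_sample_t(d, hi, alpha) < power:
        hi *= 2
        if hi > 10_000_000:
            raise ValueError("required sample size exceeds search bound")
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if power_two_sample_t(d, mid, alpha) >= power:
            hi = mid
        else:
            lo = mid
    return hi


def fov_effect_estimate(trials, conf: float = 0.95) -> tuple[float, float, float]:
    """Estimate the multiplicative FOV effect on log completion time.

    Uses the matched pairs (4, 5) and (6, 7): per participant, the average
    of log(t5) - log(t4) and log(t7) - log(t6); returns the mean and its
    t-based confidence interval.
    """
    rows = getattr(trials, "trials", trials)
    if isinstance(trials, pd.DataFrame):
        df = trials
    else:
        df = pd.DataFrame([vars(t) if not isinstance(t, dict) else t for t in rows])
    need = {4, 5, 6, 7}
    if not need.issubset(set(df["level_id"].unique())):
        raise DataError("levels 4-7 required for FOV effect estimation")
    wide = df.pivot_table(index="participant_id", columns="level_id", values="time_s")
    diffs = 0.5 * (
        (np.log(wide[5]) - np.log(wide[4])) + (np.log(wide[7]) - np.log(wide[6]))
    ).dropna()
    if len(diffs) < 2:
        raise DataError("need at least 2 complete participants")
    s = summarize(diffs.to_numpy())
    return s.mean, s.ci_low, s.ci_high


def questionnaire_summary(data: dict) -> dict:
    """Summarize questionnaire responses.

    Values that are (yes, n) pairs become integer yes-percentages; values
    that are sequences of item scores become 1-decimal means."""
    out: dict = {}
    for key, val in data.items():
        if isinstance(val, tuple) and len(val) == 2 and all(
            isinstance(v, int) for v in val
        ):
            yes, n = val
            if n <= 0:
                raise ValueError(f"{key}: n must be positive")
            out[key] = int(round(100.0 * yes / n))
        else:
            scores = np.asarray(list(val), dtype=float)
            if scores.size == 0:
                raise ValueError(f"{key}: empty score list")
            out[key] = round(float(scores.mean()), 1)
    return out


def moment_matched_sample(
    mean: float, sd: float, n: int, rng: np.random.Generator | int | None = None
) -> np.ndarray:
    """A sample of size n whose mean and sample SD match exactly.

    Draws Normal noise, standardizes it (n-1 denominator) and rescales, so
    printed summary statistics can be pushed back through the raw-data
    pipeline."""
    if n < 2:
        raise InsufficientDataError("need n >= 2")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    z = rng.normal(size=n)
    z = z - z.mean()
    s = z.std(ddof=1)
    if s == 0:  # pragma: no cover - measure-zero draw
        z = np.linspace(-1, 1, n)
        z = z - z.mean()
        s = z.std(ddof=1)
    return mean + sd * z / s


def format_ci(lo: float, hi: float, decimals: int = 1) -> str:
    return f"{lo:.{decimals}f}-{hi:.{decimals}f}"


def format_p(p: float, decimals: int = 3, floor: float = 0.001) -> str:
    """Report p to 3 decimals, '<.001' below the floor, no leading zero."""
    if p < floor:
        return "<.001"
    s = f"{p:.{decimals}f}"
    return s[1:] if s.startswith("0.") else s
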