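"""Synthetic cohorts of simulated players.

Two layers of fidelity:

* :func:`simulate_trial` / :func:`simulate_cohort` draw trial outcomes
  from a transparent generative model — lognormal completion times with
  additive level, FOV and participant effects on the log scale, and
  1 + Poisson failed attempts.  The FOV effect multiplies time but leaves
  attempts untouched, matching the qualitative structure of the observed
  data (limited view lengthens completion time, not attempt counts).

* :func:`agent_play` drives the actual game engine with a mechanistic
  agent that scans the scene (a boustrophedon spotlight sweep when the
  view is limited), locates the two black markers, traces the target
  vessel and cuts it, emitting a replayable pointer-event stream.

Every source of randomness flows from an explicit seed or generator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .config import RunConfig
from .engine import CutLine, PointerEvent, TrialRecord, is_cut
from .errors import GenerationError
from .reference import FOV_PAIRS, TIME_SUMMARY
from .scene import FOV_LIMITED, LevelSpec, Point, Scene, make_level_spec


def _default_alpha() -> dict[int, float]:
    beta = default_beta_fov()
    alpha = {}
    for level, (mean, _sd) in TIME_SUMMARY.items():
        spec = make_level_spec(level)
        alpha[level] = math.log(mean) - (beta if spec.fov_mode == FOV_LIMITED else 0.0)
    return alpha


def default_beta_fov() -> float:
    """Default FOV effect on log time, anchored to the 4-vs-5 mean ratio."""
    full, limited = FOV_PAIRS[0]
    return math.log(TIME_SUMMARY[limited][0] / TIME_SUMMARY[full][0])


@dataclass(frozen=True)
class PlayerParams:
    """Generative model parameters (all time effects in log-seconds).

    ``alpha_level`` is calibrated so that noiseless level means reproduce
    the published per-level mean times; ``gamma_*`` default to zero because
    the level intercepts already absorb vessel-count and intertwining
    effects.
    """

    alpha_level: dict[int, float] = field(default_factory=_default_alpha)
    beta_fov: float = field(default_factory=default_beta_fov)
    gamma_vessels: float = 0.0
    gamma_intertwined: float = 0.0
    sigma: float = 0.35
    lambda_err: float = 0.5
    participant_sd: float = 0.2

    def __post_init__(self):
        if self.sigma < 0 or self.lambda_err < 0 or self.participant_sd < 0:
            raise ValueError("sigma, lambda_err and participant_sd must be >= 0")

    @classmethod
    def pair_balanced(cls, beta_fov: float, **kwargs) -> "PlayerParams":
        """Calibration where matched-pair members share their level intercept.

        The limited member of each FOV pair inherits the full member's
        alpha, so the entire limited-vs-full log-time contrast equals
        ``beta_fov`` exactly — the calibration to use for effect-recovery
        studies.  (The default calibration instead pins every level's
        noiseless mean to its published value, which leaves a residual in
        the 6-vs-7 contrast.)
        """
        alpha = {
            level: math.log(mean) for level, (mean, _sd) in TIME_SUMMARY.items()
        }
        for full, limited in FOV_PAIRS:
            alpha[limited] = alpha[full]
        return cls(alpha_level=alpha, beta_fov=beta_fov, **kwargs)

    def to_dict(self) -> dict:
        return {
            "alpha_level": {str(k): v for k, v in self.alpha_level.items()},
            "beta_fov": self.beta_fov,
            "gamma_vessels": self.gamma_vessels,
            "gamma_intertwined": self.gamma_intertwined,
            "sigma": self.sigma,
            "lambda_err": self.lambda_err,
            "participant_sd": self.participant_sd,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PlayerParams":
        d = dict(d)
        if "alpha_level" in d:
            d["alpha_level"] = {int(k): float(v) for k, v in d["alpha_level"].items()}
        return cls(**d)


@dataclass
class CohortDataset:
    trials: list[TrialRecord]
    params: PlayerParams
    seed: int

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame([vars(t) for t in self.trials])


def simulate_trial(
    spec: LevelSpec,
    params: PlayerParams,
    participant_effect: float,
    rng: np.random.Generator,
    participant_id: str = "",
    seed: int = 0,
) -> TrialRecord:
    """Draw one trial outcome.

    time = exp(alpha_level + beta_fov * 1[limited] + gamma terms
               + participant_effect + Normal(0, sigma^2));
    attempts = 1 + Poisson(lambda_err); the trial always completes.
    """
    limited = spec.fov_mode == FOV_LIMITED
    mu = (
        params.alpha_level[spec.level_id]
        + (params.beta_fov if limited else 0.0)
        + params.gamma_vessels * (spec.n_vessels - 1)
        + (params.gamma_intertwined if spec.intertwined else 0.0)
        + participant_effect
    )
    eps = rng.normal(0.0, params.sigma) if params.sigma > 0 else 0.0
    time_s = math.exp(mu + eps)
    extra = int(rng.poisson(params.lambda_err)) if params.lambda_err > 0 else 0
    return TrialRecord(
        participant_id=participant_id,
        level_id=spec.level_id,
        fov_mode=spec.fov_mode,
        time_s=time_s,
        attempts=1 + extra,
        success=True,
        seed=seed,
    )


def simulate_cohort(
    n_participants: int, params: PlayerParams | None = None, seed: int = 0
) -> CohortDataset:
    """Simulate a cohort playing all 7 levels in order.

    One participant effect ~ Normal(0, participant_sd^2) per participant;
    everything is reproducible from (params, seed)."""
    if n_participants < 2:
        raise ValueError("need at least 2 participants")
    params = params or PlayerParams()
    rng = np.random.default_rng(seed)
    trials: list[TrialRecord] = []
    for i in range(n_participants):
        pid = f"p{i:03d}"
        pe = rng.normal(0.0, params.participant_sd) if params.participant_sd > 0 else 0.0
        for level in range(1, 8):
            spec = make_level_spec(level)
            trials.append(
                simulate_trial(spec, params, pe, rng, participant_id=pid, seed=seed)
            )
    return CohortDataset(trials=trials, params=params, seed=seed)


# ---------------------------------------------------------------------------
# Mechanistic agent
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AgentPolicy:
    """Timing and accuracy knobs for the mechanistic agent (not science)."""

    move_speed: float = 900.0  # cursor units per second while scanning
    draw_speed: float = 300.0  # units per second while drawing the cut
    reaction_s: float = 0.2  # pause before pressing
    sweep_stride_frac: float = 0.9  # sweep row spacing as fraction of FOV radius
    motor_noise: float = 0.0  # SD of the perpendicular cut jitter (units)
    max_retries: int = 20


def _find_cut_line(scene: Scene, config: RunConfig) -> tuple[int, CutLine]:
    """Deterministically pick a centerline index and a valid transecting cut."""
    target = scene.target
    pts = target.centerline
    n = len(pts)
    half = min(config.l_max / 2.0 - 0.5, target.width / 2.0 + 13.0)
    mid = n // 2
    # search outward from the middle of the vessel
    for off in range(0, n // 2):
        for idx in ({mid + off, mid - off} if off else {mid}):
            if not (1 <= idx < n - 1):
                continue
            tx = pts[idx + 1].x - pts[idx - 1].x
            ty = pts[idx + 1].y - pts[idx - 1].y
            norm = math.hypot(tx, ty)
            if norm == 0:
                continue
            px, py = -ty / norm, tx / norm
            line = CutLine(
                Point(pts[idx].x - px * half, pts[idx].y - py * half),
                Point(pts[idx].x + px * half, pts[idx].y + py * half),
            )
            if line.length <= config.l_max and is_cut(line, target, config.strict_sides):
                return idx, line
    raise GenerationError("agent found no valid cut on the target vessel")


def _path_moves(events, t, pos, targets, speed):
    for q in targets:
        d = math.hypot(q[0] - pos[0], q[1] - pos[1])
        t += d / speed
        events.append(PointerEvent(t, "move", Point(q[0], q[1])))
        pos = q
    return t, pos


def agent_play(
    scene: Scene,
    fov_mode: str,
    fov_radius: float | None = None,
    policy: AgentPolicy | None = None,
    rng: np.random.Generator | int | None = None,
    config: RunConfig | None = None,
) -> list[PointerEvent]:
    """Produce a pointer-event stream that completes the level.

    With a full view the agent moves straight to the target and cuts it.
    With a limited view it first sweeps the scene in a boustrophedon
    pattern (row spacing <= the FOV radius) until both black markers have
    fallen inside the spotlight, then traces the target vessel to the cut
    point — so locate time scales with scene area over spotlight area.

    With ``motor_noise`` zero the first attempt always succeeds; with noise
    the agent retries until it does (noise-free fallback on the last try).
    """
    cfg = config or RunConfig()
    pol = policy or AgentPolicy()
    radius = cfg.fov_radius if fov_radius is None else fov_radius
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    idx, clean_line = _find_cut_line(scene, cfg)
    target = scene.target
    events: list[PointerEvent] = []
    t = 0.0
    pos = (scene.width / 2.0, scene.height / 2.0)

    if fov_mode == FOV_LIMITED:
        stride = pol.sweep_stride_frac * radius
        marker_pts = [tuple(m.center) for m in scene.markers if m.is_black]
        seen = [False] * len(marker_pts)
        y = stride / 2.0
        direction = 1
        done = False
        while y < scene.height and not done:
            xs = np.arange(0.0, scene.width + 1e-9, stride / 2.0)
            if direction < 0:
                xs = xs[::-1]
            for x in xs:
                t, pos = _path_moves(events, t, pos, [(float(x), float(y))], pol.move_speed)
                for k, mp in enumerate(marker_pts):
                    if math.hypot(mp[0] - pos[0], mp[1] - pos[1]) <= radius:
                        seen[k] = True
                if all(seen):
                    done = True
                    break
            direction *= -1
            y += stride
        # trace the vessel from the nearest end to the cut point
        ends = [0, len(target.centerline) - 1]
        nearest = min(
            ends,
            key=lambda e: math.hypot(
                target.centerline[e].x - pos[0], target.centerline[e].y - pos[1]
            ),
        )
        step = 5 if nearest < idx else -5
        trace = [
            tuple(target.centerline[i])
            for i in range(nearest, idx, step)
        ]
        t, pos = _path_moves(events, t, pos, trace, pol.move_speed)

    cut_mid = target.centerline[idx]
    t, pos = _path_moves(events, t, pos, [tuple(cut_mid)], pol.move_speed)

    for attempt in range(pol.max_retries + 1):
        noise_free = pol.motor_noise == 0.0 or attempt == pol.max_retries
        if noise_free:
            line = clean_line
        else:
            jx = rng.normal(0.0, pol.motor_noise)
            jy = rng.normal(0.0, pol.motor_noise)
            line = CutLine(
                Point(clean_line.start.x + jx, clean_line.start.y + jy),
                Point(clean_line.end.x + jx, clean_line.end.y + jy),
            )
            if line.length > cfg.l_max:
                line = clean_line
        t += pol.reaction_s
        events.append(PointerEvent(t, "press", line.start))
        t += line.length / pol.draw_speed
        events.append(PointerEvent(t, "drag", line.end))
        t += 0.05
        events.append(PointerEvent(t, "release", line.end))
        pos = tuple(line.end)
        if is_cut(line, target, cfg.strict_sides):
            break
    return events
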