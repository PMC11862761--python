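"""Run configuration shared by scene generation, the engine and the CLI.

All lengths are in scene units (real-valued pixels, origin top-left,
y pointing down).  ``l_max`` is the one constant fixed by the original
game design: a drawn cut line may never exceed 45 units.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass

from .errors import ConfigError

#: Maximum cut-line length (scene units).
L_MAX_DEFAULT = 45.0


@dataclass(frozen=True)
class RunConfig:
    """Geometry, interaction and reporting parameters for a run.

    Defaults are chosen so a 45-unit cut comfortably transects a single
    vessel and the limited-FOV spotlight covers a small fraction of the
    scene.
    """

    scene_width: float = 800.0
    scene_height: float = 600.0
    vessel_width: float = 14.0
    marker_radius: float = 8.0
    fov_radius: float = 100.0
    l_max: float = L_MAX_DEFAULT
    k_min_crossings: int = 2
    retry_cap: int = 200
    n_waypoints: int = 6
    #: (background, vessel) RGB; low contrast by design.
    palette: tuple[tuple[int, int, int], tuple[int, int, int]] = (
        (205, 92, 92),
        (178, 34, 34),
    )
    strict_sides: bool = False
    paint_mode: bool = False
    seed: int = 0
    time_decimals: int = 3
    report_decimals: int = 1

    def __post_init__(self) -> None:
        for name in ("scene_width", "scene_height", "vessel_width",
                     "marker_radius", "fov_radius", "l_max"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive, got {getattr(self, name)}")
        if self.k_min_crossings < 1:
            raise ConfigError("k_min_crossings must be >= 1")
        if self.retry_cap < 1:
            raise ConfigError("retry_cap must be >= 1")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["palette"] = [list(c) for c in self.palette]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "palette" in d:
            d["palette"] = tuple(tuple(c) for c in d["palette"])
        return cls(**d)

    def fingerprint(self) -> str:
        """Stable hash of the configuration, embedded in every report."""
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]
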