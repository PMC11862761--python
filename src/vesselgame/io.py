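"""File formats and reporting.

Plain-text artifacts only, all designed to round-trip losslessly:

* scene JSON  — the full generated playfield;
* events JSONL — one pointer event per line ``{"t", "kind", "x", "y"}``;
* trials CSV  — one row per participant x level;
* report JSON / text — per-level summaries plus matched-pair comparisons,
  stamped with the configuration fingerprint and seeds.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .config import RunConfig
from .engine import PointerEvent, TrialRecord
from .errors import DataError, SchemaError
from .scene import Marker, Point, Scene, VesselPath
from . import stats as vstats

TRIAL_COLUMNS = [
    "participant_id",
    "level_id",
    "fov_mode",
    "time_s",
    "attempts",
    "success",
    "seed",
]


# ---------------------------------------------------------------------------
# Scene JSON
# ---------------------------------------------------------------------------


def scene_to_dict(scene: Scene) -> dict:
    return {
        "width": scene.width,
        "height": scene.height,
        "seed": scene.seed,
        "level_id": scene.level_id,
        "target_index": scene.target_index,
        "palette": [list(c) for c in scene.palette],
        "vessels": [
            {
                "centerline": [[p.x, p.y] for p in v.centerline],
                "width": v.width,
                "polygon": [[p.x, p.y] for p in v.polygon],
                "is_target": v.is_target,
            }
            for v in scene.vessels
        ],
        "markers": [
            {"x": m.center.x, "y": m.center.y, "r": m.radius, "black": m.is_black}
            for m in scene.markers
        ],
    }


def scene_from_dict(d: dict) -> Scene:
    try:
        vessels = [
            VesselPath(
                centerline=[Point(*p) for p in v["centerline"]],
                width=v["width"],
                polygon=[Point(*p) for p in v["polygon"]],
                is_target=v["is_target"],
            )
            for v in d["vessels"]
        ]
        markers = [
            Marker(center=Point(m["x"], m["y"]), radius=m["r"], is_black=m["black"])
            for m in d["markers"]
        ]
        return Scene(
            width=d["width"],
            height=d["height"],
            level_id=d["level_id"],
            seed=d["seed"],
            vessels=vessels,
            markers=markers,
            target_index=d["target_index"],
            palette=tuple(tuple(c) for c in d["palette"]),
        )
    except KeyError as e:
        raise SchemaError(f"scene JSON missing key {e}") from e


def write_scene(scene: Scene, path: str | Path) -> None:
    Path(path).write_text(json.dumps(scene_to_dict(scene), sort_keys=True))


def read_scene(path: str | Path) -> Scene:
    return scene_from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# Event JSONL
# ---------------------------------------------------------------------------


def write_events(events: Sequence[PointerEvent], path: str | Path) -> None:
    with open(path, "w") as fh:
        for e in events:
            fh.write(
                json.dumps(
                    {"t": e.t, "kind": e.kind, "x": e.position.x, "y": e.position.y}
                )
                + "\n"
            )


def read_events(path: str | Path) -> list[PointerEvent]:
    events = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            try:
                d = json.loads(line)
                events.append(
                    PointerEvent(t=d["t"], kind=d["kind"], position=Point(d["x"], d["y"]))
                )
            except (KeyError, json.JSONDecodeError) as e:
                raise SchemaError(f"bad event at line {lineno}: {e}") from e
    return events


# ---------------------------------------------------------------------------
# Trials CSV
# ---------------------------------------------------------------------------


def write_trials(trials: Iterable[TrialRecord], path: str | Path) -> None:
    df = pd.DataFrame([vars(t) for t in trials], columns=TRIAL_COLUMNS)
    # times are stored at millisecond resolution
    df["time_s"] = df["time_s"].round(3)
    df.to_csv(path, index=False)


def read_trials(path: str | Path) -> list[TrialRecord]:
    """Read a trial CSV; malformed rows are reported with line numbers."""
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as e:
        raise SchemaError(f"{path}: empty file") from e
    missing = set(TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    trials = []
    for i, row in df.iterrows():
        lineno = i + 2  # header is line 1
        try:
            rec = TrialRecord(
                participant_id=str(row["participant_id"]),
                level_id=int(row["level_id"]),
                fov_mode=str(row["fov_mode"]),
                time_s=float(row["time_s"]),
                attempts=int(row["attempts"]),
                success=bool(row["success"]),
                seed=int(row["seed"]),
            )
        except (TypeError, ValueError) as e:
            raise SchemaError(f"{path}: malformed row at line {lineno}: {e}") from e
        if rec.success and rec.attempts < 1:
            raise SchemaError(
                f"{path}: line {lineno}: completed trial must have attempts >= 1"
            )
        trials.append(rec)
    return trials


# ---------------------------------------------------------------------------
# Report
# ---------------------------------------------------------------------------


def run_report(
    config: RunConfig,
    trials: Sequence[TrialRecord],
    pairs: Sequence[tuple[int, int]] = ((4, 5), (6, 7)),
    metrics: Sequence[str] = ("time", "attempts"),
) -> dict:
    """Per-level summaries and per-pair Welch comparisons as a JSON-able dict."""
    trials = list(trials)
    if not trials:
        raise DataError("no trials to report on")
    df = pd.DataFrame([vars(t) for t in trials])
    dec = config.report_decimals
    levels: dict[str, dict] = {}
    for level in sorted(df["level_id"].unique()):
        entry = {}
        for metric, col in (("time", "time_s"), ("attempts", "attempts")):
            if metric not in metrics:
                continue
            vals = df.loc[df["level_id"] == level, col].to_numpy(dtype=float)
            if len(vals) < 2:
                continue
            s = vstats.summarize(vals)
            entry[metric] = {
                "n": s.n,
                "mean": s.mean,
                "sd": s.sd,
                "ci_low": s.ci_low,
                "ci_high": s.ci_high,
                **s.formatted(dec),
            }
        levels[str(int(level))] = entry
    comparisons = []
    for a, b in pairs:
        for metric in metrics:
            c = vstats.compare_levels(df, a, b, metric)
            comparisons.append(
                {
                    "pair": [a, b],
                    "metric": metric,
                    "t_stat": c.t_stat,
                    "df": c.df,
                    "p_two_sided": c.p_two_sided,
                    "p_formatted": vstats.format_p(c.p_two_sided),
                    "cohen_d": c.d,
                    "pct_increase": c.pct_increase,
                    "n": [c.n1, c.n2],
                }
            )
    return {
        "config": {**config.to_dict(), "fingerprint": config.fingerprint()},
        "seeds": sorted({t.seed for t in trials}),
        "n_trials": len(trials),
        "levels": levels,
        "comparisons": comparisons,
    }


def report_to_json(report: dict) -> str:
    return json.dumps(report, sort_keys=True, indent=2)


def report_to_text(report: dict) -> str:
    lines = [
        f"config fingerprint: {report['config']['fingerprint']}",
        f"trials: {report['n_trials']}  seeds: {report['seeds']}",
        "",
        "level  time mean (SD)   95% CI       attempts mean (SD)  95% CI",
    ]
    for level, entry in sorted(report["levels"].items(), key=lambda kv: int(kv[0])):
        tt = entry.get("time", {})
        aa = entry.get("attempts", {})
        lines.append(
            f"{level:>5}  {tt.get('mean_sd', '-'):<15}{tt.get('ci', '-'):<13}"
            f"{aa.get('mean_sd', '-'):<19} {aa.get('ci', '-')}"
        )
    lines.append("")
    for c in report["comparisons"]:
        a, b = c["pair"]
        lines.append(
            f"levels {a} vs {b} ({c['metric']}): t={c['t_stat']:.2f}, "
            f"df={c['df']:.1f}, p={c['p_formatted']}, d={c['cohen_d']:.2f}, "
            f"+{c['pct_increase']:.1f}%"
        )
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Optional raster export (documentation only)
# ---------------------------------------------------------------------------


def render_scene_png(scene: Scene, path: str | Path) -> None:
    """Render the scene to PNG with matplotlib (not a test surface)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Circle, Polygon as MplPolygon

    bg, fg = (tuple(c / 255 for c in col) for col in scene.palette)
    fig, ax = plt.subplots(figsize=(scene.width / 100, scene.height / 100))
    ax.set_facecolor(bg)
    for v in scene.vessels:
        ax.add_patch(MplPolygon([(p.x, p.y) for p in v.polygon], color=fg))
    for m in scene.markers:
        ax.add_patch(
            Circle(
                (m.center.x, m.center.y),
                m.radius,
                color="black" if m.is_black else "dimgray",
            )
        )
    ax.set_xlim(0, scene.width)
    ax.set_ylim(scene.height, 0)
    ax.set_aspect("equal")
    ax.axis("off")
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)
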