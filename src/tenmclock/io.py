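"""Writers and configuration loading for simulation results.

CSV outputs round-trip doubles losslessly (17 significant digits).  Segment
maps additionally export as BED-like 3-column interval text (0-based,
half-open) so segment calls can be piped into genomic interval tooling.
Every run directory gets a RunRecord JSON with the resolved configuration,
seed and software version.
"""

from __future__ import annotations

import dataclasses
import json
import sys
import tomllib
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .dynamics import PeriodProfile, Trajectory
from .growth import SegmentMap
from .spatial import Field1D

__all__ = [
    "load_config",
    "write_trajectory_csv",
    "read_trajectory_csv",
    "write_period_profile_csv",
    "write_field_csv",
    "write_segment_map_csv",
    "write_segment_map_bed",
    "write_run_record",
]

_FLOAT_FMT = "%.17g"


def load_config(path: str | Path) -> dict:
    """Read a TOML (primary) or JSON parameter file into a plain dict."""
    path = Path(path)
    data = path.read_bytes()
    if path.suffix.lower() == ".json":
        return json.loads(data)
    try:
        return tomllib.loads(data.decode())
    except tomllib.TOMLDecodeError:
        # accept JSON content regardless of extension
        return json.loads(data)


def write_trajectory_csv(traj: Trajectory, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        {"time": traj.times, "x": traj.x_series, "y": traj.y_series}
    )
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)
    return path


def read_trajectory_csv(path: str | Path) -> Trajectory:
    df = pd.read_csv(path, float_precision="round_trip")
    return Trajectory(
        times=df["time"].to_numpy(),
        x_series=df["x"].to_numpy(),
        y_series=df["y"].to_numpy(),
        params_used=None,
    )


def write_period_profile_csv(profile: PeriodProfile, path: str | Path) -> Path:
    path = Path(path)
    n = len(profile.periods)
    df = pd.DataFrame(
        {"peak_time": profile.peak_times[1 : n + 1], "period": profile.periods}
    )
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)
    return path


def write_field_csv(field: Field1D, path: str | Path) -> Path:
    """Long-format kymograph: one row per (time, position) pair."""
    path = Path(path)
    z = field.grid.positions
    t = field.times
    tt, zz = np.meshgrid(t, z, indexing="ij")
    df = pd.DataFrame(
        {
            "time": tt.ravel(),
            "position": zz.ravel(),
            "x": field.x_field.T.ravel(),
            "y": field.y_field.T.ravel(),
        }
    )
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)
    return path


def write_field_png(field: Field1D, path: str | Path) -> Path:
    """Kymograph heatmap (y field; space vertical, time horizontal)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 4))
    im = ax.imshow(
        field.y_field,
        aspect="auto",
        origin="lower",
        extent=(field.times[0], field.times[-1], 0, field.grid.length),
        cmap="viridis",
    )
    ax.set_xlabel("time (model units)")
    ax.set_ylabel("position (model units)")
    fig.colorbar(im, ax=ax, label="membrane dimer y")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def write_segment_map_csv(seg: SegmentMap, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        {"position": seg.positions, "frozen_phase": seg.frozen_phase}
    )
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)
    return path


def write_segment_map_bed(
    seg: SegmentMap, path: str | Path, chrom: str = "axis"
) -> Path:
    """Segments as BED3 intervals (0-based half-open, lattice units)."""
    path = Path(path)
    with open(path, "w") as fh:
        for start, end in zip(seg.boundaries[:-1], seg.boundaries[1:]):
            fh.write(f"{chrom}\t{int(round(start))}\t{int(round(end))}\n")
    return path


def write_run_record(
    path: str | Path,
    command: str,
    config: dict,
    seed: int | None,
) -> Path:
    """JSON provenance record accompanying every output directory."""
    path = Path(path)

    def _default(o):
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if callable(o):
            return f"<function {getattr(o, '__name__', repr(o))}>"
        return str(o)

    record = {
        "command": command,
        "argv": sys.argv,
        "config": config,
        "seed": seed,
        "version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    path.write_text(json.dumps(record, indent=2, default=_default) + "\n")
    return path
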