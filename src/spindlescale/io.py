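"""CSV/YAML dialects for atlases, trajectories, traces and configurations.

Atlas tables are plain CSV with one row per cell (embryo_id, cell_id,
lineage, stage, volume_um3, size_um plus any fitted trait columns);
trajectories and simulation traces are per-frame CSVs (t_s, d_pp_um,
d_cc_um); model configurations round-trip through YAML mirroring the
global-parameter and per-stage tables field for field.
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .dynamics import CellTrajectory
from .model import ChromosomeProgram, SimulationParams, StageConfig

__all__ = [
    "write_atlas",
    "read_atlas",
    "write_trajectory",
    "read_trajectory",
    "write_trace",
    "save_config",
    "load_config",
]

ATLAS_REQUIRED = ["embryo_id", "cell_id", "lineage", "stage", "volume_um3", "size_um"]


def write_atlas(atlas: pd.DataFrame, path: str | Path) -> None:
    missing = [c for c in ATLAS_REQUIRED if c not in atlas.columns]
    if missing:
        raise ValueError(f"atlas missing required columns: {missing}")
    atlas.to_csv(path, index=False)


def read_atlas(path: str | Path) -> pd.DataFrame:
    atlas = pd.read_csv(path)
    missing = [c for c in ATLAS_REQUIRED if c not in atlas.columns]
    if missing:
        raise ValueError(f"atlas missing required columns: {missing}")
    return atlas


def write_trajectory(traj: CellTrajectory, path: str | Path) -> None:
    df = pd.DataFrame({"t_s": traj.times, "d_pp_um": traj.d_pp, "d_cc_um": traj.d_cc})
    df.to_csv(path, index=False)


def read_trajectory(path: str | Path, ao_index: int | None = None) -> CellTrajectory:
    """Load a per-frame CSV; the onset frame defaults to the last t <= 0."""
    df = pd.read_csv(path)
    t = df["t_s"].to_numpy()
    if ao_index is None:
        pre = np.nonzero(t <= 0)[0]
        ao_index = int(pre[-1]) if len(pre) else 0
    return CellTrajectory(
        times=t, d_pp=df["d_pp_um"].to_numpy(), d_cc=df["d_cc_um"].to_numpy(), ao_index=ao_index
    )


def write_trace(times, d_pp, d_cc, path: str | Path) -> None:
    pd.DataFrame({"t_s": times, "d_pp_um": d_pp, "d_cc_um": d_cc}).to_csv(path, index=False)


def save_config(
    path: str | Path,
    params: SimulationParams,
    stages: dict[int, StageConfig],
    program: ChromosomeProgram,
) -> None:
    payload = {
        "global": asdict(params),
        "stages": {int(s): asdict(cfg) for s, cfg in stages.items()},
        "chromosome_program": asdict(program),
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def load_config(path: str | Path):
    payload = yaml.safe_load(Path(path).read_text())
    params = SimulationParams(**payload["global"])
    stages = {int(s): StageConfig(**cfg) for s, cfg in payload["stages"].items()}
    program = ChromosomeProgram(**payload["chromosome_program"])
    return params, stages, program
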