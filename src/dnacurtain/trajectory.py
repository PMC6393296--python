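"""The trajectory container and its tab-separated interchange format.

A trajectory is the time-ordered sequence of sub-pixel positions of one
tracked molecule along the DNA axis. The table dialect
(``molecule_id, frame, time_s, position_um, position_bp``) is the
interchange format between tracking and all downstream stages, so
trajectories from other trackers can be imported as long as they provide
these columns (``position_bp`` may be reconstructed from ``position_um``
and vice versa).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .config import BP_PER_UM

TRAJECTORY_COLUMNS = ["molecule_id", "frame", "time_s", "position_um", "position_bp"]

#: tolerated relative spread of the frame interval in an imported table
_DT_RTOL = 0.01


@dataclass
class Trajectory:
    """Positions of one molecule along the DNA axis over time.

    ``times`` must be strictly increasing with uniform spacing equal to
    ``frame_interval``; positions are in micrometres.
    """

    molecule_id: int
    frames: np.ndarray
    times: np.ndarray
    positions: np.ndarray
    frame_interval: float
    source: str = "simulated"
    transverse: np.ndarray | None = None  # QC only, um

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if not (len(self.frames) == len(self.times) == len(self.positions)):
            raise ValueError("frames, times and positions must have equal length")
        if len(self.times) > 1:
            dts = np.diff(self.times)
            if np.any(dts <= 0):
                raise ValueError("times must be strictly increasing")
            if np.any(np.abs(dts - self.frame_interval) > _DT_RTOL * self.frame_interval):
                raise ValueError(
                    "times must be uniformly spaced at frame_interval "
                    f"({self.frame_interval} s)"
                )
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")

    def __len__(self) -> int:
        return len(self.positions)

    def to_frame(self, bp_per_um: float = BP_PER_UM) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "molecule_id": self.molecule_id,
                "frame": self.frames,
                "time_s": self.times,
                "position_um": self.positions,
                "position_bp": self.positions * bp_per_um,
            }
        )


def write_trajectories(
    trajectories: Iterable[Trajectory],
    path: str | Path,
    bp_per_um: float = BP_PER_UM,
) -> None:
    """Write trajectories as a tab-separated table in the interchange dialect."""
    frames = [t.to_frame(bp_per_um) for t in trajectories]
    table = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=TRAJECTORY_COLUMNS)
    )
    table.to_csv(path, sep="\t", index=False, float_format="%.9g")


def read_trajectories(
    path: str | Path, bp_per_um: float = BP_PER_UM
) -> list[Trajectory]:
    """Read a trajectory table, validating columns, spacing and finiteness.

    Rows are sorted by (molecule_id, frame) on read. A missing
    ``position_um`` column is reconstructed from ``position_bp`` via
    ``bp_per_um``. Non-uniform time steps (relative spread above 1%) or
    NaN positions raise a named validation error.
    """
    table = pd.read_csv(path, sep="\t")
    have = set(table.columns)
    if "position_um" not in have and "position_bp" in have:
        table["position_um"] = table["position_bp"] / bp_per_um
    missing = {"molecule_id", "frame", "time_s", "position_um"} - set(table.columns)
    if missing:
        raise ValueError(f"trajectory table is missing columns: {sorted(missing)}")
    if table["position_um"].isna().any():
        raise ValueError("trajectory table contains NaN positions")
    table = table.sort_values(["molecule_id", "frame"], kind="mergesort")

    out: list[Trajectory] = []
    for mol_id, grp in table.groupby("molecule_id", sort=True):
        times = grp["time_s"].to_numpy(dtype=float)
        if len(times) > 1:
            dts = np.diff(times)
            dt = float(np.median(dts))
            if np.any(np.abs(dts - dt) > _DT_RTOL * dt):
                raise ValueError(
                    f"molecule {mol_id}: non-uniform frame interval (>1% spread)"
                )
        else:
            dt = float("nan")
        out.append(
            Trajectory(
                molecule_id=int(mol_id),
                frames=grp["frame"].to_numpy(dtype=int),
                times=times,
                positions=grp["position_um"].to_numpy(dtype=float),
                frame_interval=dt,
                source="imported",
            )
        )
    return out
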