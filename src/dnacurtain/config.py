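"""Configuration objects shared across the pipeline.

Positions are expressed in micrometres along the DNA axis, with 0 at one
tether point. Conversion to base pairs uses a constant extension factor
(``bp_per_um``); the default 3750 bp/um corresponds to the printed
equivalence of 0.08 um with roughly 300 bp for a doubly tethered lambda
substrate.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

#: default micrometre -> base-pair calibration (48.5 kb extended to ~12.9 um)
BP_PER_UM = 3750.0

#: half-width of the nucleosome collision zone, um (three s.d. of the
#: nucleosome-position resolution)
COLLISION_ZONE_HALF_WIDTH_UM = 0.08


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the 1D diffusion simulation on a doubly tethered DNA.

    Parameters
    ----------
    diffusion_coefficient : float
        1D diffusion coefficient D in um^2/s. The default of 0.4 um^2/s is
        typical of MLH-family complexes sliding on naked DNA.
    frame_interval : float
        Camera frame interval in seconds (50-100 ms in the imaging regime
        this emulates).
    n_frames : int
        Number of frames to emit.
    dna_length : float
        Extended DNA length in um; reflecting boundaries at 0 and
        ``dna_length``. Default 12.9 um ~ 48.5 kb at 3750 bp/um.
    localization_sigma : float
        Standard deviation of i.i.d. Gaussian localization noise added to
        the emitted positions, um. Default 0.08/3 um, one third of the
        collision-zone half-width (the zone spans three s.d.).
    obstacle_positions : sequence of float
        Nucleosome positions along the DNA, um.
    obstacle_bypass_prob : float
        Probability that an attempted crossing of an obstacle succeeds;
        otherwise the particle is reflected back to its pre-step side.
    start_position : float or None
        Initial true position, um; None draws uniformly on the DNA.
    seed : int
        Seed for the pseudo-random generator; identical seed and config
        give identical output.
    """

    diffusion_coefficient: float = 0.4
    frame_interval: float = 0.05
    n_frames: int = 2000
    dna_length: float = 12.9
    localization_sigma: float = COLLISION_ZONE_HALF_WIDTH_UM / 3.0
    obstacle_positions: tuple[float, ...] = ()
    obstacle_bypass_prob: float = 1.0
    start_position: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "obstacle_positions", tuple(float(p) for p in self.obstacle_positions)
        )
        vals = [
            self.diffusion_coefficient,
            self.frame_interval,
            self.dna_length,
            self.localization_sigma,
            self.obstacle_bypass_prob,
            *self.obstacle_positions,
        ]
        _require(all(np.isfinite(v) for v in vals), "all parameters must be finite")
        _require(self.diffusion_coefficient >= 0, "diffusion_coefficient must be >= 0")
        _require(self.frame_interval > 0, "frame_interval must be > 0")
        _require(self.n_frames >= 1, "n_frames must be >= 1")
        _require(self.dna_length > 0, "dna_length must be > 0")
        _require(self.localization_sigma >= 0, "localization_sigma must be >= 0")
        _require(
            0.0 <= self.obstacle_bypass_prob <= 1.0,
            "obstacle_bypass_prob must be in [0, 1]",
        )
        _require(
            all(0.0 <= p <= self.dna_length for p in self.obstacle_positions),
            "obstacle_positions must lie within [0, dna_length]",
        )
        if self.start_position is not None:
            _require(
                0.0 <= self.start_position <= self.dna_length,
                "start_position must lie within [0, dna_length]",
            )

    def step_sigma(self) -> float:
        """RMS per-frame displacement sqrt(2 D dt), um."""
        return float(np.sqrt(2.0 * self.diffusion_coefficient * self.frame_interval))


@dataclass
class PipelineConfig:
    """Umbrella configuration echoed into every output's metadata."""

    frame_interval_s: float = 0.05
    pixel_size_um: float = 0.08
    bp_per_um: float = BP_PER_UM
    collision_zone_half_width_um: float = COLLISION_ZONE_HALF_WIDTH_UM
    n_max_lags: int = 10
    n_bootstrap: int = 1000
    seed: int = 0
    paths: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        _require(self.frame_interval_s > 0, "frame_interval_s must be > 0")
        _require(self.pixel_size_um > 0, "pixel_size_um must be > 0")
        _require(self.bp_per_um > 0, "bp_per_um must be > 0")
        _require(
            self.collision_zone_half_width_um > 0,
            "collision_zone_half_width_um must be > 0",
        )
        _require(self.n_max_lags >= 3, "n_max_lags must be >= 3")
        _require(self.n_bootstrap >= 1, "n_bootstrap must be >= 1")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def um_to_bp(position_um: float | np.ndarray, bp_per_um: float = BP_PER_UM):
    """Convert a position along the DNA axis from um to base pairs (0-based)."""
    return np.asarray(position_um, dtype=float) * bp_per_um


def bp_to_um(position_bp: float | np.ndarray, bp_per_um: float = BP_PER_UM):
    """Convert a position along the DNA axis from base pairs to um."""
    return np.asarray(position_bp, dtype=float) / bp_per_um
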