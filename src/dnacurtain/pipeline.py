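"""Pipeline orchestration: run stages in order with a reproducible manifest.

Stages communicate through files in a working directory using conventional
names, so any stage can also be fed externally produced inputs:

* ``trajectories.tsv``          - simulated (emitted) trajectories
* ``stack.tif`` (+ ``.yaml``)   - simulated image stack
* ``tracked_trajectories.tsv``  - trajectories recovered by tracking
* ``diffusion_per_molecule.csv`` / ``diffusion_summary.csv``
* ``collision_records.csv`` / ``bypass_summary.json``
* ``manifest.json``             - config hash, input hashes, stage log

Given a fixed seed the stage outputs are byte-identical between runs (the
manifest's timestamps are the only exception).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .bypass import CollisionZone, segment_collisions, summarize_bypass
from .config import PipelineConfig, SimulationConfig
from .diffusion import (
    classify_mobile,
    compute_msd,
    fit_diffusion_coefficient,
    summarize_condition,
)
from .localize import track_stack
from .simulate import simulate_ensemble, simulate_image_stack
from .trajectory import read_trajectories, write_trajectories

STAGES = ("simulate", "track", "diffusion", "bypass")


@dataclass
class RunManifest:
    """Provenance record for one pipeline run."""

    tool_version: str
    config_hash: str
    config: dict
    input_hashes: dict = field(default_factory=dict)
    started: str = ""
    finished: str = ""
    stages: list = field(default_factory=list)

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def run_pipeline(
    config: PipelineConfig,
    stages: Sequence[str],
    workdir: str | Path,
    sim_config: SimulationConfig | None = None,
    n_molecules: int = 20,
    zones: Sequence[CollisionZone] | None = None,
    image_psf_sigma_um: float = 0.125,
    image_amplitude: float = 300.0,
    image_background: float = 20.0,
) -> RunManifest:
    """Execute the requested stages in dependency order.

    Raises before any stage runs if a requested stage's input can neither
    be produced by an earlier requested stage nor found in ``workdir``.
    """
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    requested = [s for s in STAGES if s in stages]
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}; valid: {list(STAGES)}")

    # resolve dependencies up front
    def available(name: str, producer: str) -> bool:
        return producer in requested or (workdir / name).exists()

    if "track" in requested and not available("stack.tif", "simulate"):
        raise ValueError("stage 'track' needs stack.tif (run 'simulate' or provide it)")
    for s in ("diffusion", "bypass"):
        if s in requested and not (
            available("tracked_trajectories.tsv", "track")
            or available("trajectories.tsv", "simulate")
        ):
            raise ValueError(f"stage '{s}' needs a trajectory table")

    manifest = RunManifest(
        tool_version=__version__,
        config_hash=config.config_hash(),
        config=config.to_dict(),
        started=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )

    def log(stage: str, **info) -> None:
        manifest.stages.append({"stage": stage, **info})

    if "simulate" in requested:
        sim = sim_config or SimulationConfig(
            frame_interval=config.frame_interval_s, seed=config.seed
        )
        trajectories, truths = simulate_ensemble(sim, n_molecules)
        write_trajectories(trajectories, workdir / "trajectories.tsv", config.bp_per_um)
        stack = simulate_image_stack(
            trajectories,
            psf_sigma=image_psf_sigma_um,
            amplitude=image_amplitude,
            background=image_background,
            pixel_size=config.pixel_size_um,
            seed=sim.seed,
        )
        stack.write(workdir / "stack.tif")
        log("simulate", n_molecules=n_molecules, n_frames=sim.n_frames)

    if "track" in requested:
        from .images import ImageStack

        stack = ImageStack.read(workdir / "stack.tif")
        tracked = track_stack(stack)
        write_trajectories(tracked, workdir / "tracked_trajectories.tsv", config.bp_per_um)
        log("track", n_trajectories=len(tracked))

    def load_trajectories():
        for name in ("tracked_trajectories.tsv", "trajectories.tsv"):
            p = workdir / name
            if p.exists():
                manifest.input_hashes[name] = _sha256(p)
                return read_trajectories(p, config.bp_per_um)
        raise ValueError("no trajectory table found")  # pragma: no cover

    if "diffusion" in requested:
        trajectories = [
            t for t in load_trajectories() if len(t) > config.n_max_lags
        ]
        rows, estimates, flags = [], [], []
        for t in trajectories:
            msd = compute_msd(t, config.n_max_lags)
            est = fit_diffusion_coefficient(msd)
            mob = classify_mobile(est, msd, noise_sigma=config.pixel_size_um / 3.0)
            estimates.append(est)
            flags.append(mob)
            rows.append(
                {
                    "molecule_id": t.molecule_id,
                    "slope_um2_per_s": est.slope,
                    "intercept_um2": est.intercept,
                    "diffusion_coefficient_um2_per_s": est.diffusion_coefficient,
                    "r_squared": est.r_squared,
                    "mobile": mob,
                    "non_physical": est.non_physical,
                }
            )
        pd.DataFrame(rows).to_csv(workdir / "diffusion_per_molecule.csv", index=False)
        summary = summarize_condition(estimates, condition="run", mobile_flags=flags)
        pd.DataFrame(
            [
                {
                    "condition": summary.condition,
                    "n_molecules": summary.n_molecules,
                    "mean_D_um2_per_s": summary.mean,
                    "sem_D_um2_per_s": summary.sem,
                    "percent_mobile": summary.percent_mobile,
                    "reportable": summary.reportable,
                }
            ]
        ).to_csv(workdir / "diffusion_summary.csv", index=False)
        log("diffusion", n_molecules=summary.n_molecules)

    if "bypass" in requested:
        trajectories = load_trajectories()
        zs = list(zones) if zones else [
            CollisionZone(
                nucleosome_id=0,
                center=float(np.median(np.concatenate([t.positions for t in trajectories]))),
                half_width=config.collision_zone_half_width_um,
            )
        ]
        records = []
        for t in trajectories:
            records.extend(segment_collisions(t, zs))
        pd.DataFrame([dataclasses.asdict(r) for r in records]).to_csv(
            workdir / "collision_records.csv", index=False
        )
        summary = summarize_bypass(
            records, n_bootstrap=config.n_bootstrap, seed=config.seed, condition="run"
        )
        with open(workdir / "bypass_summary.json", "w") as fh:
            json.dump(
                {
                    "condition": summary.condition,
                    "n_collisions": summary.n_collisions,
                    "n_bypass": summary.n_bypass,
                    "n_censored": summary.n_censored,
                    "p_bypass": summary.p_bypass,
                    "ci_low": summary.ci_low,
                    "ci_high": summary.ci_high,
                },
                fh,
                indent=2,
                sort_keys=True,
            )
        log("bypass", n_collisions=summary.n_collisions)

    manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
    manifest.write(workdir / "manifest.json")
    return manifest
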