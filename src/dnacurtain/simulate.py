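"""Synthetic single-molecule data with known ground truth.

Every input the analysis pipeline consumes can be generated here:

* 1D reflected Brownian trajectories on a doubly tethered DNA, with
  partially permeable nucleosome obstacles and Gaussian localization
  noise (:func:`simulate_trajectory`);
* TIRF-like image stacks of diffraction-limited 2D Gaussian spots on a
  noisy background (:func:`simulate_image_stack`);
* stepwise photobleaching intensity traces (:func:`simulate_bleach_trace`);
* Luria-Delbruck fluctuation-assay cultures
  (:func:`simulate_fluctuation_cultures`).

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .config import SimulationConfig
from .fluctuation import FluctuationAssay
from .images import ImageStack
from .stoichiometry import IntensityTrace
from .trajectory import Trajectory

__all__ = [
    "GroundTruth",
    "simulate_trajectory",
    "simulate_ensemble",
    "simulate_image_stack",
    "simulate_bleach_trace",
    "simulate_fluctuation_cultures",
]


@dataclass
class GroundTruth:
    """Noise-free positions and obstacle-crossing log of one simulation.

    ``obstacle_crossings`` holds one ``(frame, obstacle_index, crossed)``
    entry per attempted crossing: ``crossed`` is True when the Bernoulli
    bypass draw succeeded and the particle ended the step on the far side.
    """

    true_positions: np.ndarray
    obstacle_crossings: list[tuple[int, int, bool]] = field(default_factory=list)


def _reflect_domain(x: float, length: float) -> float:
    # fold into [0, 2L) then mirror; equivalent to iterated wall reflection
    x = x % (2.0 * length)
    return 2.0 * length - x if x > length else x


def simulate_trajectory(config: SimulationConfig) -> tuple[Trajectory, GroundTruth]:
    """Simulate one molecule diffusing on a doubly tethered DNA.

    Each frame-to-frame displacement is drawn from a zero-mean Gaussian of
    variance ``2 D dt``; the DNA ends reflect. A step whose straight path
    would carry the particle across an obstacle succeeds with probability
    ``obstacle_bypass_prob`` and is otherwise reflected about the obstacle,
    leaving the particle on its pre-step side. Independent Gaussian
    localization noise of s.d. ``localization_sigma`` is added to the
    emitted positions only; the returned :class:`GroundTruth` keeps the
    noise-free path and the log of attempted crossings.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_frames
    L = config.dna_length
    obstacles = np.asarray(config.obstacle_positions, dtype=float)

    if config.start_position is not None:
        x0 = float(config.start_position)
    else:
        x0 = float(rng.uniform(0.0, L))

    steps = rng.normal(0.0, config.step_sigma(), size=n - 1) if n > 1 else np.empty(0)

    true = np.empty(n)
    true[0] = x0
    crossings: list[tuple[int, int, bool]] = []

    if obstacles.size == 0:
        # vectorized path: cumulative sum folded into the domain
        raw = x0 + np.concatenate(([0.0], np.cumsum(steps)))
        folded = raw % (2.0 * L)
        true = np.where(folded > L, 2.0 * L - folded, folded)
    else:
        for i in range(1, n):
            x = true[i - 1]
            disp = steps[i - 1]
            # walk the step, resolving wall and obstacle reflections in the
            # order they are encountered along the straight path
            for _ in range(64):  # reflections per step are few in practice
                target = x + disp
                # first event along the path: wall or obstacle
                lo, hi = (x, target) if target >= x else (target, x)
                hit_obs = obstacles[(obstacles > lo) & (obstacles < hi)]
                events: list[tuple[float, str, int]] = []
                if target < 0.0:
                    events.append((x - 0.0, "wall", -1))
                if target > L:
                    events.append((L - x, "wall", -1))
                for j, ob in enumerate(obstacles):
                    if lo < ob < hi:
                        events.append((abs(ob - x), "obstacle", j))
                if not events:
                    x = target
                    break
                events.sort(key=lambda e: e[0])
                dist, kind, j = events[0]
                direction = 1.0 if disp > 0 else -1.0
                if kind == "wall":
                    wall = 0.0 if direction < 0 else L
                    x = wall
                    disp = -(disp - direction * dist)
                else:
                    ob = obstacles[j]
                    if rng.random() < config.obstacle_bypass_prob:
                        crossings.append((i, int(j), True))
                        remaining = disp - direction * dist
                        x = ob
                        disp = remaining
                        # nudge past the obstacle so it is not re-hit
                        if remaining == 0.0:
                            disp = direction * 1e-12
                    else:
                        crossings.append((i, int(j), False))
                        x = ob
                        disp = -(disp - direction * dist)
                        if disp == 0.0:
                            disp = -direction * 1e-12
            else:  # pragma: no cover - pathological step count
                x = min(max(x, 0.0), L)
            true[i] = min(max(x, 0.0), L)

    noise = (
        rng.normal(0.0, config.localization_sigma, size=n)
        if config.localization_sigma > 0
        else np.zeros(n)
    )
    emitted = true + noise

    frames = np.arange(n)
    traj = Trajectory(
        molecule_id=0,
        frames=frames,
        times=frames * config.frame_interval,
        positions=emitted,
        frame_interval=config.frame_interval,
        source="simulated",
    )
    return traj, GroundTruth(true_positions=true, obstacle_crossings=crossings)


def simulate_ensemble(
    config: SimulationConfig, n_molecules: int
) -> tuple[list[Trajectory], list[GroundTruth]]:
    """Simulate ``n_molecules`` independent trajectories.

    Molecule ``k`` uses an independent child seed derived from
    ``config.seed`` and receives ``molecule_id = k``.
    """
    seeds = np.random.SeedSequence(config.seed).spawn(n_molecules)
    trajectories, truths = [], []
    for k, ss in enumerate(seeds):
        sub = SimulationConfig(
            **{
                **{f: getattr(config, f) for f in (
                    "diffusion_coefficient",
                    "frame_interval",
                    "n_frames",
                    "dna_length",
                    "localization_sigma",
                    "obstacle_positions",
                    "obstacle_bypass_prob",
                    "start_position",
                )},
                "seed": int(ss.generate_state(1)[0] % (2**31)),
            }
        )
        traj, truth = simulate_trajectory(sub)
        traj.molecule_id = k
        trajectories.append(traj)
        truths.append(truth)
    return trajectories, truths


def simulate_image_stack(
    trajectories: Sequence[Trajectory],
    psf_sigma: float,
    amplitude: float,
    background: float,
    noise_model: str = "poisson",
    pixel_size: float = 0.08,
    image_height_px: int = 16,
    seed: int = 0,
    dna_axis_offset_um: float | None = None,
) -> ImageStack:
    """Render trajectories as a TIRF-like multi-frame image stack.

    Each frame holds one symmetric 2D Gaussian of s.d. ``psf_sigma`` (um)
    and peak ``amplitude`` (photons) per molecule, centred at the
    molecule's position along the x (DNA) axis and at a fixed transverse
    coordinate, on a constant ``background``. Noise is per-pixel Poisson
    (photon shot noise) or additive Gaussian of s.d. sqrt(background).
    """
    if psf_sigma <= 0 or pixel_size <= 0:
        raise ValueError("psf_sigma and pixel_size must be > 0")
    if noise_model not in ("poisson", "gaussian", "none"):
        raise ValueError("noise_model must be 'poisson', 'gaussian' or 'none'")
    n_frames = {len(t) for t in trajectories}
    if len(n_frames) > 1:
        raise ValueError("all trajectories must share the same frame count")
    n = n_frames.pop() if n_frames else 0

    max_x = max((float(np.max(t.positions)) for t in trajectories), default=1.0)
    nx = int(np.ceil(max_x / pixel_size)) + 8
    ny = int(image_height_px)
    y_center = (ny / 2.0) * pixel_size if dna_axis_offset_um is None else dna_axis_offset_um

    rng = np.random.default_rng(seed)
    xs = (np.arange(nx) + 0.5) * pixel_size
    ys = (np.arange(ny) + 0.5) * pixel_size
    X, Y = np.meshgrid(xs, ys)

    data = np.empty((n, ny, nx))
    for i in range(n):
        frame = np.full((ny, nx), float(background))
        for t in trajectories:
            x0 = float(t.positions[i])
            frame += amplitude * np.exp(
                -((X - x0) ** 2 + (Y - y_center) ** 2) / (2.0 * psf_sigma**2)
            )
        if noise_model == "poisson":
            frame = rng.poisson(np.clip(frame, 0.0, None)).astype(float)
        elif noise_model == "gaussian":
            frame = frame + rng.normal(0.0, np.sqrt(max(background, 1.0)), frame.shape)
        data[i] = frame

    dt = trajectories[0].frame_interval if trajectories else float("nan")
    return ImageStack(
        data=data,
        pixel_size_um=pixel_size,
        frame_interval_s=dt,
        metadata={
            "psf_sigma_um": psf_sigma,
            "amplitude": amplitude,
            "background": background,
            "noise_model": noise_model,
            "dna_axis_y_um": y_center,
            "seed": seed,
        },
    )


def simulate_bleach_trace(
    n_fluorophores: int,
    unit_intensity: float,
    bleach_prob_per_frame: float,
    noise_sd: float,
    n_frames: int,
    seed: int = 0,
    background: float = 0.0,
    frame_interval: float = 0.25,
) -> IntensityTrace:
    """Simulate a stepwise photobleaching intensity trace.

    The punctum starts at ``background + n_fluorophores * unit_intensity``
    (plus noise); each fluorophore bleaches independently at a geometric
    time with per-frame probability ``bleach_prob_per_frame``, dropping the
    trace by ``unit_intensity``. Values below the background are clipped
    and the clipping is flagged in the trace metadata.
    """
    if n_fluorophores < 0:
        raise ValueError("n_fluorophores must be >= 0")
    if not 0.0 <= bleach_prob_per_frame <= 1.0:
        raise ValueError("bleach_prob_per_frame must be in [0, 1]")
    rng = np.random.default_rng(seed)
    if n_fluorophores > 0 and bleach_prob_per_frame > 0:
        bleach_frames = rng.geometric(bleach_prob_per_frame, size=n_fluorophores)
    else:
        bleach_frames = np.full(n_fluorophores, np.iinfo(np.int64).max)
    frames = np.arange(n_frames)
    n_alive = (bleach_frames[None, :] > frames[:, None]).sum(axis=1)
    clean = background + n_alive * unit_intensity
    noisy = clean + (rng.normal(0.0, noise_sd, n_frames) if noise_sd > 0 else 0.0)
    clipped = noisy < background
    noisy = np.where(clipped, background, noisy)
    return IntensityTrace(
        punctum_id=0,
        times=frames * frame_interval,
        intensities=noisy,
        acquisition_mode="continuous",
        metadata={
            "true_n_fluorophores": int(n_fluorophores),
            "true_unit_intensity": float(unit_intensity),
            "true_bleach_frames": bleach_frames.tolist(),
            "n_clipped": int(clipped.sum()),
        },
    )


def simulate_fluctuation_cultures(
    n_cultures: int,
    final_population: int,
    mutation_rate: float,
    seed: int = 0,
    strain: str = "synthetic",
) -> FluctuationAssay:
    """Draw per-culture revertant counts from a Luria-Delbruck process.

    Each culture grows from one cell by discrete doublings to
    ``final_population`` (rounded to the nearest power of two). The number
    of mutation events is Poisson with mean ``mutation_rate *
    final_population``; each event is assigned to a division drawn with
    probability proportional to the number of divisions in that
    generation, and its mutant clone doubles until harvest. Jackpot
    cultures arise from early events exactly as in the classical
    fluctuation experiment.
    """
    if final_population < 1:
        raise ValueError("final_population must be >= 1")
    if not 0.0 <= mutation_rate < 1.0:
        raise ValueError("mutation_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    generations = max(1, int(round(np.log2(final_population))))
    pop = 2**generations
    m = mutation_rate * pop
    # divisions during step g -> g+1 number 2^g, g = 0..G-1
    weights = 2.0 ** np.arange(generations)
    weights /= weights.sum()
    counts = np.empty(n_cultures, dtype=int)
    for c in range(n_cultures):
        k = rng.poisson(m)
        if k == 0:
            counts[c] = 0
            continue
        gs = rng.choice(generations, size=k, p=weights)
        clones = 2 ** (generations - 1 - gs)
        counts[c] = min(int(clones.sum()), pop)
    return FluctuationAssay(
        strain=strain,
        mutant_counts=counts,
        total_cells=np.full(n_cultures, pop, dtype=float),
    )
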