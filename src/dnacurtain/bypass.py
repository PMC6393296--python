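"""Nucleosome collision and bypass scoring.

A collision zone is an interval around each nucleosome position, by
default of half-width 0.08 um (three standard deviations of the
nucleosome-position resolution, ~300 bp). A collision is a maximal
contiguous excursion of a trajectory inside a zone; the entry side is the
side of the last sampled position outside the zone before the excursion
and the exit side that of the first outside position after it. An
excursion that exits on the opposite side is a bypass; same side is a
non-bypass; excursions truncated by the start or end of the trajectory
are censored and never enter the denominator.

Bypass events are coded 1 and non-bypass 0; the pooled bypass probability
is the binomial fraction with a percentile-bootstrap 95% CI, and
conditions are compared by logistic (binary) regression at alpha = 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .config import COLLISION_ZONE_HALF_WIDTH_UM, SimulationConfig
from .trajectory import Trajectory

__all__ = [
    "CollisionZone",
    "CollisionRecord",
    "BypassSummary",
    "segment_collisions",
    "summarize_bypass",
    "compare_bypass",
    "free_walk_bypass_reference",
]


@dataclass(frozen=True)
class CollisionZone:
    """Interval around one nucleosome position."""

    nucleosome_id: int
    center: float  # um
    half_width: float = COLLISION_ZONE_HALF_WIDTH_UM  # um

    def __post_init__(self) -> None:
        if not self.half_width > 0:
            raise ValueError("half_width must be > 0")

    @property
    def low(self) -> float:
        return self.center - self.half_width

    @property
    def high(self) -> float:
        return self.center + self.half_width


@dataclass
class CollisionRecord:
    """One excursion of one molecule inside one collision zone."""

    molecule_id: int
    nucleosome_id: int
    entry_frame: int
    exit_frame: int
    entry_side: str  # "left" | "right" | "censored"
    exit_side: str  # "left" | "right" | "censored"
    outcome: str  # "bypass" | "no_bypass" | "censored"


@dataclass
class BypassSummary:
    """Pooled bypass probability for one condition."""

    condition: str
    n_collisions: int
    n_bypass: int
    p_bypass: float
    ci_low: float
    ci_high: float
    binary_codes: np.ndarray = field(repr=False, default_factory=lambda: np.empty(0))
    n_censored: int = 0


def _check_zones(zones: Sequence[CollisionZone]) -> list[CollisionZone]:
    zs = sorted(zones, key=lambda z: z.center)
    for a, b in zip(zs, zs[1:]):
        if a.high > b.low:
            raise ValueError(
                f"collision zones {a.nucleosome_id} and {b.nucleosome_id} overlap "
                "after width expansion; merge or narrow them"
            )
    return zs


def segment_collisions(
    trajectory: Trajectory, zones: Sequence[CollisionZone]
) -> list[CollisionRecord]:
    """Split a trajectory into per-zone collision records.

    One record per maximal contiguous run of sampled positions inside a
    zone. Excursions that begin at the first frame or are still inside the
    zone at the last frame have no outside reference position on that end
    and are censored.
    """
    zs = _check_zones(zones)
    y = trajectory.positions
    N = len(y)
    records: list[CollisionRecord] = []
    for zone in zs:
        inside = (y >= zone.low) & (y <= zone.high)
        i = 0
        while i < N:
            if not inside[i]:
                i += 1
                continue
            j = i
            while j < N and inside[j]:
                j += 1
            # excursion spans frames [i, j-1]
            if i == 0:
                entry = "censored"
            else:
                entry = "left" if y[i - 1] < zone.center else "right"
            if j == N:
                exit_ = "censored"
            else:
                exit_ = "left" if y[j] < zone.center else "right"
            if entry == "censored" or exit_ == "censored":
                outcome = "censored"
            elif entry != exit_:
                outcome = "bypass"
            else:
                outcome = "no_bypass"
            records.append(
                CollisionRecord(
                    molecule_id=trajectory.molecule_id,
                    nucleosome_id=zone.nucleosome_id,
                    entry_frame=int(trajectory.frames[i]),
                    exit_frame=int(trajectory.frames[j - 1]),
                    entry_side=entry,
                    exit_side=exit_,
                    outcome=outcome,
                )
            )
            i = j
    return records


def summarize_bypass(
    records: Sequence[CollisionRecord],
    n_bootstrap: int = 1000,
    seed: int = 0,
    condition: str = "",
    resample_by: str = "event",
) -> BypassSummary:
    """Pool collision records into a bypass probability with bootstrap CI.

    Bypass events are coded 1 and non-bypass 0; censored records are
    excluded from the denominator. The 95% CI is the 2.5/97.5 percentile
    interval of the bypass fraction over ``n_bootstrap`` resamples drawn
    with replacement, by individual event (default) or by molecule
    (``resample_by="molecule"``, robust to within-molecule correlation).
    """
    scored = [r for r in records if r.outcome != "censored"]
    n_censored = len(records) - len(scored)
    if not scored:
        raise ValueError("all collision records are censored; nothing to score")
    codes = np.array([1 if r.outcome == "bypass" else 0 for r in scored], dtype=int)
    p = float(codes.mean())
    rng = np.random.default_rng(seed)
    if resample_by == "event":
        idx = rng.integers(0, len(codes), size=(n_bootstrap, len(codes)))
        reps = codes[idx].mean(axis=1)
    elif resample_by == "molecule":
        mols = np.array([r.molecule_id for r in scored])
        unique = np.unique(mols)
        groups = [codes[mols == m] for m in unique]
        reps = np.empty(n_bootstrap)
        for b in range(n_bootstrap):
            pick = rng.integers(0, len(groups), size=len(groups))
            sel = np.concatenate([groups[k] for k in pick])
            reps[b] = sel.mean()
    else:
        raise ValueError("resample_by must be 'event' or 'molecule'")
    lo, hi = np.percentile(reps, [2.5, 97.5])
    return BypassSummary(
        condition=condition,
        n_collisions=len(codes),
        n_bypass=int(codes.sum()),
        p_bypass=p,
        ci_low=float(lo),
        ci_high=float(hi),
        binary_codes=codes,
        n_censored=n_censored,
    )


def compare_bypass(a: BypassSummary, b: BypassSummary) -> dict:
    """Logistic regression of bypass outcome on condition.

    Fits ``P(bypass) = logistic(b0 + b1 * condition)`` over the pooled
    binary codes and returns the Wald p-value for the condition
    coefficient. Complete separation (a group with all-0 or all-1 codes)
    makes the Wald test degenerate, so the result is flagged and the
    p-value replaced by Fisher's exact test on the 2x2 table.
    """
    import statsmodels.api as sm

    ya = np.asarray(a.binary_codes, dtype=float)
    yb = np.asarray(b.binary_codes, dtype=float)
    if len(ya) == 0 or len(yb) == 0:
        raise ValueError("both groups must contain scored collisions")
    y = np.concatenate([ya, yb])
    group = np.concatenate([np.zeros(len(ya)), np.ones(len(yb))])
    X = sm.add_constant(group)
    separated = ya.min() == ya.max() or yb.min() == yb.max()
    if not separated:
        fit = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        return {
            "coef": float(fit.params[1]),
            "p_value": float(fit.pvalues[1]),
            "method": "logistic_wald",
            "separated": False,
        }
    table = np.array(
        [
            [a.n_bypass, a.n_collisions - a.n_bypass],
            [b.n_bypass, b.n_collisions - b.n_bypass],
        ]
    )
    _, p = stats.fisher_exact(table)
    return {"coef": float("nan"), "p_value": float(p), "method": "fisher_exact",
            "separated": True}


def free_walk_bypass_reference(
    config: SimulationConfig,
    zone: CollisionZone | None = None,
    n_trajectories: int = 200,
    n_bootstrap: int = 1000,
) -> BypassSummary:
    """Measure the bypass ceiling of an unobstructed 1D random walk.

    Simulates ``n_trajectories`` obstacle-free trajectories under
    ``config``, scores collisions at a single mid-DNA zone (or the zone
    given), and pools them. For a free walk the microscopic step is
    unbiased, so the bypass probability approaches the theoretical 50%
    ceiling; this reference bounds any obstructed measurement from above.
    """
    from .simulate import simulate_ensemble

    if config.obstacle_positions:
        raise ValueError("free-walk reference requires a config with no obstacles")
    if zone is None:
        zone = CollisionZone(nucleosome_id=0, center=config.dna_length / 2.0)
    trajectories, _ = simulate_ensemble(config, n_trajectories)
    records: list[CollisionRecord] = []
    for traj in trajectories:
        records.extend(segment_collisions(traj, [zone]))
    return summarize_bypass(
        records, n_bootstrap=n_bootstrap, seed=config.seed,
        condition="free_walk_reference",
    )
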