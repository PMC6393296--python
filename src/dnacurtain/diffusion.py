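"""MSD curves, diffusion coefficients, mobility, and condition comparison.

For a trajectory of N positions y_i sampled every dt seconds, the mean
squared displacement at lag n is the average over all N - n overlapping
pairs,

    MSD(n dt) = 1/(N - n) * sum_{i=1..N-n} (y_{i+n} - y_i)^2 ,

computed for the first ``n_max`` lags (default 10). An ordinary
least-squares line through (lag, MSD) gives the slope; in one dimension
MSD = 2 D t, so D = slope / 2 and the intercept estimates the
localization-noise floor (2 sigma^2 for static noise of s.d. sigma).
Per-condition coefficients are reported as mean +/- s.e.m. over molecules,
with a minimum of 30 molecules for a reportable mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .trajectory import Trajectory

__all__ = [
    "MsdCurve",
    "DiffusionEstimate",
    "ConditionSummary",
    "compute_msd",
    "fit_diffusion_coefficient",
    "classify_mobile",
    "summarize_condition",
    "compare_diffusion",
]

DEFAULT_N_MAX_LAGS = 10
MIN_MOLECULES_REPORTABLE = 30
#: mobile iff MSD at the largest fitted lag exceeds this multiple of the
#: static-noise floor 2 sigma^2
MOBILITY_FLOOR_FACTOR = 3.0


@dataclass
class MsdCurve:
    """MSD values over the first ``n_max`` time lags of one trajectory."""

    lags: np.ndarray  # seconds, n * dt for n = 1..n_max
    msd_values: np.ndarray  # um^2
    n_pairs_per_lag: np.ndarray
    molecule_id: int = 0


@dataclass
class DiffusionEstimate:
    """Line fit of an MSD curve and the implied diffusion coefficient."""

    molecule_id: int
    slope: float  # um^2/s
    intercept: float  # um^2
    diffusion_coefficient: float  # um^2/s, slope/2 clamped at 0
    r_squared: float
    mobile: bool | None = None
    non_physical: bool = False  # negative fitted slope


@dataclass
class ConditionSummary:
    """Per-condition collection of diffusion coefficients."""

    condition: str
    diffusion_coefficients: np.ndarray
    mean: float
    sem: float
    n_molecules: int
    percent_mobile: float | None = None
    reportable: bool = True


def compute_msd(trajectory: Trajectory, n_max: int = DEFAULT_N_MAX_LAGS) -> MsdCurve:
    """Compute the MSD of one trajectory over lags 1..n_max frames."""
    y = trajectory.positions
    N = len(y)
    if N <= n_max:
        raise ValueError(
            f"trajectory has {N} frames; MSD over {n_max} lags requires at least "
            f"{n_max + 1}"
        )
    dt = trajectory.frame_interval
    lags = np.arange(1, n_max + 1) * dt
    msd = np.empty(n_max)
    npairs = np.empty(n_max, dtype=int)
    for n in range(1, n_max + 1):
        diffs = y[n:] - y[:-n]
        msd[n - 1] = np.mean(diffs**2)
        npairs[n - 1] = N - n
    return MsdCurve(
        lags=lags, msd_values=msd, n_pairs_per_lag=npairs,
        molecule_id=trajectory.molecule_id,
    )


def fit_diffusion_coefficient(msd: MsdCurve) -> DiffusionEstimate:
    """Fit MSD vs lag to a line; D = slope / 2 (1D convention).

    A negative slope is reported as D = 0 with the ``non_physical`` flag
    rather than dropping the molecule, keeping denominators auditable.
    The intercept is retained as a localization-noise estimate.
    """
    if len(msd.lags) < 3:
        raise ValueError("diffusion fit requires at least 3 lags")
    slope, intercept = np.polyfit(msd.lags, msd.msd_values, 1)
    fitted = slope * msd.lags + intercept
    ss_res = float(np.sum((msd.msd_values - fitted) ** 2))
    ss_tot = float(np.sum((msd.msd_values - np.mean(msd.msd_values)) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    non_physical = slope < 0
    return DiffusionEstimate(
        molecule_id=msd.molecule_id,
        slope=float(slope),
        intercept=float(intercept),
        diffusion_coefficient=float(max(slope, 0.0) / 2.0),
        r_squared=r2,
        non_physical=bool(non_physical),
    )


def classify_mobile(
    estimate: DiffusionEstimate, msd: MsdCurve, noise_sigma: float
) -> bool:
    """Flag a molecule as mobile when its MSD clears the static-noise floor.

    A stationary molecule localized with noise of s.d. sigma shows a flat
    MSD of 2 sigma^2; a molecule is called mobile when the MSD at the
    largest fitted lag exceeds that floor by at least
    ``MOBILITY_FLOOR_FACTOR``.
    """
    floor = 2.0 * noise_sigma**2
    if floor == 0.0:
        return bool(msd.msd_values[-1] > 0.0 and not estimate.non_physical)
    return bool(msd.msd_values[-1] >= MOBILITY_FLOOR_FACTOR * floor)


def summarize_condition(
    estimates: Sequence[DiffusionEstimate],
    condition: str = "",
    mobile_flags: Sequence[bool] | None = None,
) -> ConditionSummary:
    """Aggregate per-molecule coefficients into a condition summary.

    Means over fewer than 30 molecules are flagged as not reportable.
    """
    ds = np.asarray([e.diffusion_coefficient for e in estimates], dtype=float)
    if len(ds) == 0:
        raise ValueError("at least one estimate is required")
    pct = None
    if mobile_flags is not None:
        flags = np.asarray(mobile_flags, dtype=bool)
        if len(flags) != len(ds):
            raise ValueError("mobile_flags must match estimates")
        pct = percent_mobile(int(flags.sum()), len(flags))
    return ConditionSummary(
        condition=condition,
        diffusion_coefficients=ds,
        mean=float(np.mean(ds)),
        sem=float(np.std(ds, ddof=1) / np.sqrt(len(ds))) if len(ds) > 1 else 0.0,
        n_molecules=len(ds),
        percent_mobile=pct,
        reportable=len(ds) >= MIN_MOLECULES_REPORTABLE,
    )


def percent_mobile(n_mobile: int, n_total: int) -> float:
    """Percent of molecules classified mobile, rounded to whole percent."""
    if n_total < 1:
        raise ValueError("n_total must be >= 1")
    if not 0 <= n_mobile <= n_total:
        raise ValueError("n_mobile must be in [0, n_total]")
    return round(100.0 * n_mobile / n_total)


def compare_diffusion(
    a: ConditionSummary | Sequence[float], b: ConditionSummary | Sequence[float]
) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test between per-molecule coefficients.

    Returns ``(D_KS, p_value)`` with the exact sup-distance statistic and
    the asymptotic p-value; the significance threshold used throughout is
    alpha = 0.05.
    """
    xs = np.asarray(
        a.diffusion_coefficients if isinstance(a, ConditionSummary) else a, float
    )
    ys = np.asarray(
        b.diffusion_coefficients if isinstance(b, ConditionSummary) else b, float
    )
    if len(xs) < 2 or len(ys) < 2:
        raise ValueError("each group needs at least 2 values")
    res = stats.ks_2samp(xs, ys, method="asymp")
    return float(res.statistic), float(res.pvalue)
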