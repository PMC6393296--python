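"""Mutation-rate estimation from fluctuation assays.

Parallel cultures grown from small inocula accumulate mutants according to
the Luria-Delbruck distribution; the mutation rate mu (mutations per cell
per generation) is recovered from the observed mutant frequency f and the
final cell number N through the Drake median-frequency equation

    mu = f / ln(N * mu),

solved for mu on the branch N*mu > e where the equation has a unique
root. Confidence intervals come from a nonparametric bootstrap over
cultures, re-solving the equation for every resample.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

__all__ = [
    "FluctuationAssay",
    "RateEstimate",
    "solve_drake",
    "estimate_rate",
    "compare_rates",
    "read_fluctuation_csv",
    "write_fluctuation_csv",
]

#: solver relative tolerance on the residual mu*ln(N*mu) - f
SOLVER_RTOL = 1e-12


@dataclass
class FluctuationAssay:
    """Per-culture revertant counts and total cell numbers for one strain."""

    strain: str
    mutant_counts: np.ndarray
    total_cells: np.ndarray

    def __post_init__(self) -> None:
        self.mutant_counts = np.asarray(self.mutant_counts, dtype=float)
        self.total_cells = np.asarray(self.total_cells, dtype=float)
        if len(self.mutant_counts) != len(self.total_cells):
            raise ValueError("mutant_counts and total_cells must have equal length")
        if len(self.mutant_counts) < 1:
            raise ValueError("at least one culture is required")
        if np.any(self.mutant_counts < 0) or np.any(self.total_cells < 1):
            raise ValueError("counts must be >= 0 and total_cells >= 1")
        if np.any(self.mutant_counts > self.total_cells):
            raise ValueError("mutant_count cannot exceed total_cells")

    @property
    def n_cultures(self) -> int:
        return len(self.mutant_counts)

    @property
    def frequencies(self) -> np.ndarray:
        return self.mutant_counts / self.total_cells


@dataclass
class RateEstimate:
    """A solved mutation rate with 95% confidence bounds."""

    strain: str
    mu: float
    ci_low: float
    ci_high: float
    f_used: float
    n_used: float
    solver_residual: float
    below_detection: bool = False
    bootstrap_mus: np.ndarray | None = field(default=None, repr=False)


def solve_drake(f: float, n: float) -> float:
    """Solve mu = f / ln(N mu) for the mutation rate.

    Equivalent to finding the root of g(mu) = mu ln(N mu) - f, which is
    strictly increasing for N mu > 1/e; the physically meaningful branch
    requires N mu > e (so that ln(N mu) > 1 and mu < f). The root is
    bracketed on [e/N, f] and refined to relative tolerance 1e-12.

    Raises a ValueError naming the f = e/N boundary when the frequency is
    too small for a root on this branch.
    """
    if not (f > 0 and n > 0):
        raise ValueError("f and n must be > 0")
    boundary = np.e / n
    if f < boundary:
        raise ValueError(
            f"no root with N*mu > e: f={f:g} is below the boundary e/N={boundary:g}"
        )
    if f == boundary:
        return boundary  # fixed point: ln(N mu) = 1 exactly at mu = f

    def g(mu: float) -> float:
        return mu * np.log(n * mu) - f

    mu = brentq(g, boundary, f, xtol=1e-300, rtol=1e-15, maxiter=200)
    # Newton polish to drive the residual to the stated tolerance
    for _ in range(3):
        r = mu * np.log(n * mu) - f
        if abs(r) <= SOLVER_RTOL * f:
            break
        mu -= r / (np.log(n * mu) + 1.0)
    return float(mu)


def _below_detection(assay: FluctuationAssay) -> RateEstimate:
    n_med = float(np.median(assay.total_cells))
    return RateEstimate(
        strain=assay.strain,
        mu=0.0,
        ci_low=0.0,
        ci_high=1.0 / n_med,
        f_used=0.0,
        n_used=n_med,
        solver_residual=0.0,
        below_detection=True,
    )


def estimate_rate(
    assay: FluctuationAssay,
    ci_method: str = "bootstrap",
    n_bootstrap: int = 1000,
    seed: int = 0,
) -> RateEstimate:
    """Estimate the mutation rate of one strain from its cultures.

    The frequency f is the median per-culture mutant frequency (robust to
    jackpot cultures) and N the median final cell number; mu solves the
    Drake equation. The 95% CI is the 2.5/97.5 percentile interval of the
    estimate over bootstrap resamples of the cultures (resamples whose
    median frequency falls below the solvable branch contribute the e/N
    boundary value). An assay with all-zero mutant counts is reported as
    below detection with upper bound 1/N.
    """
    if assay.n_cultures < 5:
        raise ValueError("rate estimation requires >= 5 cultures")
    if ci_method != "bootstrap":
        raise ValueError("only the bootstrap CI method is implemented")
    freqs = assay.frequencies
    f = float(np.median(freqs))
    n = float(np.median(assay.total_cells))
    if f <= 0:
        return _below_detection(assay)

    def point(fs: np.ndarray, ns: np.ndarray) -> float:
        fm = float(np.median(fs))
        nm = float(np.median(ns))
        if fm <= 0:
            return 0.0
        if fm <= np.e / nm:
            return np.e / nm
        return solve_drake(fm, nm)

    mu = solve_drake(f, n) if f > np.e / n else np.e / n
    rng = np.random.default_rng(seed)
    reps = np.empty(n_bootstrap)
    k = assay.n_cultures
    for b in range(n_bootstrap):
        idx = rng.integers(0, k, size=k)
        reps[b] = point(freqs[idx], assay.total_cells[idx])
    lo, hi = np.percentile(reps, [2.5, 97.5])
    residual = abs(mu * np.log(n * mu) - f) if mu > 0 else 0.0
    return RateEstimate(
        strain=assay.strain,
        mu=mu,
        ci_low=float(min(lo, mu)),
        ci_high=float(max(hi, mu)),
        f_used=f,
        n_used=n,
        solver_residual=float(residual),
        bootstrap_mus=reps,
    )


@dataclass
class FoldChange:
    """Ratio of two mutation rates with a bootstrap CI."""

    fold: float
    ci_low: float
    ci_high: float
    is_lower_bound: bool = False


def compare_rates(a: RateEstimate, b: RateEstimate) -> FoldChange:
    """Fold difference mu_a / mu_b with a paired-bootstrap 95% CI.

    When the reference rate is below detection the fold change is reported
    as a lower bound using the reference's CI upper limit.
    """
    if b.below_detection or b.mu <= 0:
        if b.ci_high <= 0:
            raise ValueError("reference rate and its upper bound are both zero")
        return FoldChange(
            fold=a.mu / b.ci_high, ci_low=a.mu / b.ci_high, ci_high=np.inf,
            is_lower_bound=True,
        )
    fold = a.mu / b.mu
    if a.bootstrap_mus is not None and b.bootstrap_mus is not None:
        nb = min(len(a.bootstrap_mus), len(b.bootstrap_mus))
        ra = a.bootstrap_mus[:nb]
        rb = b.bootstrap_mus[:nb]
        ok = rb > 0
        ratios = ra[ok] / rb[ok]
        lo, hi = np.percentile(ratios, [2.5, 97.5])
        return FoldChange(fold=fold, ci_low=float(lo), ci_high=float(hi))
    return FoldChange(fold=fold, ci_low=float("nan"), ci_high=float("nan"))


def write_fluctuation_csv(assay: FluctuationAssay, path: str | Path) -> None:
    """Write cultures as CSV (culture_id, mutant_count, total_cells)."""
    pd.DataFrame(
        {
            "culture_id": np.arange(assay.n_cultures),
            "mutant_count": assay.mutant_counts.astype(int),
            "total_cells": assay.total_cells,
        }
    ).to_csv(path, index=False)


def read_fluctuation_csv(path: str | Path, strain: str = "") -> FluctuationAssay:
    """Read a culture CSV (culture_id, mutant_count, total_cells)."""
    table = pd.read_csv(path)
    missing = {"mutant_count", "total_cells"} - set(table.columns)
    if missing:
        raise ValueError(f"fluctuation CSV is missing columns: {sorted(missing)}")
    return FluctuationAssay(
        strain=strain or str(Path(path).stem),
        mutant_counts=table["mutant_count"].to_numpy(dtype=float),
        total_cells=table["total_cells"].to_numpy(dtype=float),
    )
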