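# Methods

This note records the models behind each stage, the defaults and why they
were chosen, and what the synthetic-data generator does and does not
emulate.

## Coordinate system and calibration

Positions are micrometres along the DNA axis, 0 at one tether. The
µm↔bp calibration defaults to 3750 bp/µm, fixed by the equivalence of
0.08 µm with ~300 bp on the doubly tethered 48.5 kb substrate (which is
also where the default DNA length of 12.9 µm comes from). The true
end-to-end extension of a curtain substrate varies with buffer and tether
geometry; the calibration is config-overridable and is echoed into every
output.

## Synthetic trajectories

1D Brownian motion with per-frame Gaussian steps of variance 2DΔt,
reflecting walls at both DNA ends (a doubly tethered substrate cannot be
exited; reflection preserves the equilibrium occupancy). Defaults:

- `diffusion_coefficient = 0.4 µm²/s` — typical of MLH-family complexes
  sliding on naked DNA in single-molecule measurements; chosen as the
  wild-type-like study condition.
- `frame_interval = 0.05 s` — the 50–100 ms camera regime; 50 ms default.
- `localization_sigma = 0.08/3 µm ≈ 27 nm` — one third of the collision
  zone half-width, consistent with reading the 0.08 µm zone as three s.d.
  of the position resolution. Localization noise is applied post hoc as
  i.i.d. Gaussian on the emitted positions only; the ground-truth record
  keeps the noise-free path.

Obstacles (nucleosomes) are instantaneous Bernoulli barriers: a step whose
straight path crosses an obstacle succeeds with probability
`obstacle_bypass_prob`, otherwise the remaining displacement is reflected
about the obstacle, leaving the particle on its entry side. Multiple
wall/obstacle events within one step are resolved in path order. Every
attempted crossing is logged in the ground truth, so the microscopic
pass probability is directly testable (it is, binomially, in the suite).

Not emulated: 2D/3D excursions off the DNA, flow-stretched geometries,
ATP-state switching within a trajectory, and quantum-dot blinking.
Passing round-trip tests therefore show the estimators are correct for an
ideal 1D diffuser, not that real data are free of these artifacts.

## Image model and localization

Each frame is a constant background plus one symmetric 2D Gaussian per
molecule (default PSF σ = 0.125 µm, pixel 0.08 µm), with Poisson shot
noise. Detection is robust local-maxima thresholding
(median/MAD background, non-maximum suppression within one PSF width);
fits are nonlinear least squares of a 6-parameter Gaussian initialized
from centroid moments, with non-convergence reported rather than
discarded. Linking is greedy nearest-neighbour with gap closing
(default `max_jump = 0.5 µm`, `max_gap = 2` frames, gaps filled by linear
interpolation so trajectory time bases stay uniform); ties are broken by
smallest displacement, then lower track id, making tracking fully
deterministic. The transverse coordinate is retained for QC only. The
round-trip tests compare tracking error against the Thompson-style
theoretical localization s.d. (including pixelation and background
terms). Drift correction and multi-colour registration are out of scope.

## MSD and diffusion coefficients

`MSD(nΔt)` averages all N−n overlapping pairs, n = 1..10 by default; the
overlapping-pair covariance is ignored (unweighted OLS), matching common
practice. `D = slope/2` is the 1D convention forced by `MSD = 2Dt` — a
choice recorded prominently because it rescales every coefficient. The
intercept is kept as a localization-noise estimate (static noise of s.d.
σ contributes 2σ²). A negative fitted slope yields D = 0 with a
`non_physical` flag instead of silently dropping the molecule. Mobility
is an invented operational criterion (the underlying experiments report
percent-moving without defining it): a molecule is mobile when its MSD at
the largest fitted lag exceeds the static-noise floor 2σ² at least
3-fold. Condition means over fewer than 30 molecules are flagged
unreportable. Between-condition comparison is the exact two-sample K–S
statistic with asymptotic p-value, α = 0.05.

## Collision-zone bypass scoring

The zone half-width defaults to 0.08 µm. The wording "encompasses three
standard deviations of the spatial resolution (0.08 µm)" is ambiguous
between σ = 0.08/3 and σ = 0.08; the half-width is read as 0.08 µm (three
s.d. with σ ≈ 27 nm) and is config-overridable. Excursions are maximal
runs of sampled positions inside a zone; entry/exit sides come from the
last/first sampled positions outside; excursions truncated by the
trajectory ends are censored and never enter the denominator. Zones that
would overlap raise an error (dense arrays are out of scope; sparse 1–7
nucleosome substrates motivate the design). The bootstrap unit is the
individual collision event, matching the 1/0 coding; resampling by
molecule is offered for correlation robustness. `n_bootstrap = 1000` by
default. Complete separation in the logistic comparison falls back to
Fisher's exact test, flagged.

**Discretization bias of the free-walk ceiling.** A symmetric walk
crossing a finite zone is scored from sampled positions, so the measured
free-walk bypass approaches the theoretical 50% ceiling only from below,
as the per-frame rms step grows past the zone width: ~41% at
σ_step/zone-width ≈ 0.6 (D = 0.1 µm²/s at 50 ms), ~47% at D = 0.4, ~49%
at D = 1.6. (Counting single-frame jump-overs as bypasses would overshoot
the ceiling without bound and is therefore wrong.) The ceiling is
accordingly measured in the fast-diffusion regime (D = 1.6 µm²/s,
rms step 0.4 µm, no localization noise — the ceiling is a property of the
walk, not of the microscope), where the estimate is statistically
indistinguishable from 50%. At imaging-realistic parameters the same
classifier reads ~47%, which is the relevant empirical ceiling when
comparing measured nucleosome-bypass values.

## Photobleaching stoichiometry

Step detection is an exact O(n²) dynamic program for penalized
piecewise-constant least squares; the per-change-point penalty is
`(penalty·σ̂)²·2·ln n` with σ̂ a robust (successive-difference MAD) noise
estimate. The default `penalty = 2.0` was chosen from the detector's
operating curve on synthetic traces: false positives on SNR-matched flat
traces ~1% (< 5% by design), with dwell resolution of ~2 frames at SNR 5.
Heights of segments shorter than ~5 frames are noticeably biased, so the
step-count molecule estimator derives the unit intensity from drops
flanked by ≥5-frame segments (minimum of those, falling back to their
median when the minimum looks like an outlier) and reports
`round(total intensity lost / unit)` — robust to two fluorophores
bleaching within the same frame, which no step counter can resolve as
separate events. The intensity-ratio estimator uses the median of the
first 5 frames minus background as the plateau (the pre-normalization
punctum-intensity protocol is not otherwise specified); both the rounded
count and the raw ratio are emitted, since condition-level reports
average non-integer ratios (e.g. "2.6 ± 1.2 molecules per punctum").
Battery conditions in the tests — unit/noise SNR 5, bleach probability
0.01 per 250 ms frame (a ~25 s bleaching time constant), 600 frames so
that all fluorophores bleach with probability > 99.7% — emulate
continuous-illumination imaging of RPA-RFP puncta. RPA counts map to
ssDNA bounds via the 10 nt minimal / 30 nt preferred footprint:
n molecules → [10 + 30(n−1), 30n] nt.

## Fluctuation assays

Cultures grow by discrete doublings from one cell; mutation events are
Poisson with mean µ·N, each assigned to a division with probability
proportional to that generation's division count, and clones double until
harvest — the classical jackpot mechanism (clone-size tail ∝ 1/k). The
rate solves µ = f/ln(N·µ) on the branch N·µ > e (the equation's other
branch is spurious), by bracketed root-finding polished to a relative
residual ≤ 1e-12. The text this formula comes from defines N as "the
total number of revertants"; that is an evident erratum for total cells,
and N = total cells is used. f is the median per-culture frequency
(robust, standard for fluctuation analysis; mean frequencies diverge with
the jackpot tail), N the median cell count. CIs are a nonparametric
bootstrap over cultures, re-solving per resample; zero-mutant assays are
reported below detection with upper bound 1/N.

**Known bias.** The median-frequency equation implies a median mutant
count of m·ln m (m = N·µ), whereas the Luria–Delbrück median is closer to
m(ln m + 1.24); the point estimate is therefore systematically high —
about +16% at m ≈ 13, the regime of a 1e-7 rate at ~1.3e8 cells per
culture — while remaining comfortably within the 2-fold accuracy the
method is used for. Because the culture-level bootstrap quantifies
sampling variability only, nominal 95% CIs cover the true rate at well
below nominal frequency (~60–70% in simulation); CIs from this method
should be read as precision of the estimate, not calibrated coverage of
the truth. Ma–Sandri–Sarkar maximum likelihood and plating-efficiency
corrections are deliberately out of scope.

## Determinism and problem sizes

Every stochastic routine takes a seed; ensembles derive independent child
seeds via `SeedSequence.spawn`, and fixed seeds give byte-identical
outputs end to end (verified in the suite). Test and acceptance problem
sizes — e.g. 100–250 trajectories of 400–2000 frames, 50-trace bleaching
batteries, 60-assay fluctuation batteries — were chosen so each check's
statistical tolerance is comfortably resolved at desk scale.
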