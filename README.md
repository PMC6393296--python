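# dnacurtain

Analysis toolkit for single-molecule DNA-curtain experiments in which a
fluorescently labeled protein (e.g. the Mlh1–Pms1 mismatch-repair complex)
diffuses along doubly tethered ~48.5 kb DNA molecules imaged by TIRF
microscopy. The package covers the full quantitative chain of such a study:

- **Particle tracking** — detect diffraction-limited puncta in TIFF stacks,
  fit each to a 2D Gaussian for sub-pixel localization, and link detections
  into trajectories.
- **Diffusion analysis** — per-molecule mean squared displacement
  `MSD(nΔt) = 1/(N−n) Σᵢ (yᵢ₊ₙ − yᵢ)²` over the first ten lags, fitted to a
  line; in 1D `MSD = 2Dt`, so `D = slope/2`. Conditions are summarized as
  mean ± s.e.m. over ≥30 molecules and compared with a two-sample
  Kolmogorov–Smirnov test (α = 0.05).
- **Nucleosome bypass** — a collision zone of half-width 0.08 µm (~300 bp,
  three s.d. of the nucleosome-position resolution) around each nucleosome;
  each excursion into a zone is scored bypass (exits the far side) or
  non-bypass (returns to the entry side). Events are coded 1/0, pooled into
  a binomial bypass probability with a bootstrap 95% CI, and compared
  between conditions by logistic (binary) regression. An unobstructed
  random walk sets the ceiling: at most 50% of collisions can be bypasses.
- **Photobleaching stoichiometry** — penalized change-point detection of
  discrete bleaching steps; single-step traces calibrate the
  single-fluorophore unit intensity; molecules per punctum from step counts
  or plateau/unit ratios; RPA counts map to exposed ssDNA lengths via the
  10–30 nt footprint.
- **Fluctuation-assay mutation rates** — the rate µ (mutations per cell per
  generation) solves the Drake median-frequency equation `µ = f / ln(N·µ)`
  with f the median mutant frequency and N the cells per culture;
  bootstrap CIs over cultures and fold-change comparisons between strains.
- **Synthetic data** — every input above can be generated with known ground
  truth: reflected Brownian motion with partially permeable obstacles,
  camera-model image stacks, stepwise bleaching traces, and
  Luria–Delbrück-distributed mutant counts. This makes the entire pipeline
  testable end to end without laboratory data.

## Worked example

Score nucleosome bypass against the free-walk ceiling
(`examples/nucleosome_bypass.py`):

```
nucleosome p0=0.3    bypass = 23.7% [21.5, 25.8]% (338/1428 collisions)
free_walk_reference  bypass = 50.5% [48.5, 52.6]% (1115/2210 collisions)
binary regression: p = 5.19e-56 -> the obstacle significantly reduces bypass
```

One hundred simulated molecules diffused across a nucleosome that lets
30% of attempted crossings through; the classifier measures 23.7%
macroscopic bypass — below the microscopic permeability, because a
molecule can make several blocked attempts within one zone visit — while
the unobstructed walk sits at the 50% ceiling. The regression confirms the
obstacle effect at α = 0.05.

Estimate mutation rates from fluctuation assays
(`examples/mutation_rate.py`):

```
wild-type-like  mu = 1.21e-07 [1.00e-07, 1.28e-07] (truth 1e-07)
mutator-like    mu = 9.32e-06 [8.21e-06, 1.03e-05] (truth 1e-05)
fold difference: 77x [66, 98] (simulated: 100x)
```

Each line is a 30-culture assay: the solved rate with its bootstrap 95% CI
recovers the simulated truth well within the ~2-fold accuracy expected of
the median-frequency method.

The other examples (`simulate_and_track.py`, `diffusion_analysis.py`,
`photobleaching_stoichiometry.py`) demonstrate tracking precision (~2 nm
median error at 80 nm pixels), diffusion-coefficient recovery, and
fluorophore counting.

A thin CLI mirrors the library (`dnacurtain simulate | track | diffusion |
bypass | stoichiometry | flucrate | run`); see `dnacurtain --help`.

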