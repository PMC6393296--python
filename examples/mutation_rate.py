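"""Estimate mutation rates from simulated fluctuation assays.

Parallel cultures accumulate mutants with the characteristic jackpot-heavy
Luria-Delbruck distribution. The rate mu (mutations per cell per
generation) solves mu = f / ln(N mu), with f the median mutant frequency
and N the cell number per culture; CIs come from a bootstrap over
cultures. A wild-type-like and a 100-fold mutator strain are compared;
expect point estimates within ~2-fold of the simulated truths and a fold
change near 100.
"""

from dnacurtain import compare_rates, estimate_rate, simulate_fluctuation_cultures

POP = 2**27  # ~1.3e8 cells per culture

wt_assay = simulate_fluctuation_cultures(30, POP, 1e-7, seed=1, strain="wild-type-like")
mut_assay = simulate_fluctuation_cultures(30, POP, 1e-5, seed=2, strain="mutator-like")

wt = estimate_rate(wt_assay, seed=1)
mut = estimate_rate(mut_assay, seed=2)

for est, truth in ((wt, 1e-7), (mut, 1e-5)):
    print(f"{est.strain:15s} mu = {est.mu:.2e} "
          f"[{est.ci_low:.2e}, {est.ci_high:.2e}] (truth {truth:.0e})")

fc = compare_rates(mut, wt)
print(f"fold difference: {fc.fold:.0f}x [{fc.ci_low:.0f}, {fc.ci_high:.0f}] "
      f"(simulated: 100x)")
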