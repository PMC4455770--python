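"""Mapping power of a BSA-seq design for three characterized mutants.

Builds the mapping design actually used for these strains (10^7
segregants, 2% phenotype tails so 2x10^5 cells per bulk, 10 generations
of growth before and after sorting, 75x sequencing depth, alpha = 0.001)
and, for each mutant, prints the deterministic expected mutant-allele
frequencies in the two bulks and the Monte-Carlo probability that the
causal site is detected as a significant bulk difference.
"""

import numpy as np

from bsapower import (
    ExperimentalDesign,
    MutationEffects,
    estimate_power,
    expected_bulk_frequencies,
)

design = ExperimentalDesign(
    population_size=10_000_000,
    cutoff_fraction=0.02,
    generations_pre=10,
    generations_post=10,
    depth=75,
    alpha=0.001,
    wild_type_cv=0.07572,
)

mutants = {
    "YPW89": MutationEffects(10.45, 0.9467, 0.127),
    "YPW94": MutationEffects(7.21, 0.862, 0.130),
    "YPW102": MutationEffects(-3.25, 0.9251, 0.009),
}

print(f"bulks of {design.bulk_size} cells, depth {design.depth}x, "
      f"alpha {design.alpha}")
print(f"{'mutant':8s} {'p_low':>8s} {'p_high':>8s} {'power':>7s} {'+/-':>7s}")
for i, (name, eff) in enumerate(mutants.items()):
    exp = expected_bulk_frequencies(design, eff)
    est = estimate_power(design, eff, n_sims=4000,
                         rng=np.random.default_rng([0, i]))
    print(f"{name:8s} {exp.p_low:8.4f} {exp.p_high:8.4f} "
          f"{est.power:7.3f} {est.mc_stderr:7.3f}")

print()
print("p_low/p_high: expected causal-allele frequency in the low/high bulk")
print("at sequencing time; power: fraction of simulated experiments whose")
print("bulk-difference G-test is significant at alpha.")
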