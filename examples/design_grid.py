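"""How sequencing depth trades off against mapping power.

Sweeps sequencing depth for a small-effect mutation (5% mean shift,
selection coefficient 0.03) under the 2%-tails design, then asks for the
cheapest depth on the grid that reaches 90% power.
"""

import numpy as np

from bsapower import (
    ExperimentalDesign,
    MutationEffects,
    min_coverage_search,
    power_curve,
)

design = ExperimentalDesign(
    population_size=10_000_000,
    cutoff_fraction=0.02,
    generations_pre=10,
    generations_post=10,
    depth=100,
    alpha=0.001,
    wild_type_cv=0.07572,
)
effects = MutationEffects(mean_effect_pct=5.0, sd_ratio=1.0,
                          selection_coefficient=0.03)

depths = [5, 10, 15, 25, 50, 100]
curve = power_curve(design, effects, "depth", depths,
                    n_sims=2000, rng=np.random.default_rng(1))
print("depth    power  (mc stderr)")
for d, est in zip(curve.values, curve.estimates):
    print(f"{d:5d}  {est.power:7.3f}  ({est.mc_stderr:.3f})")

best = min_coverage_search(design, effects, power_target=0.9,
                           coverage_grid=depths, n_sims=2000,
                           rng=np.random.default_rng(2))
print()
print(f"smallest depth on the grid with power >= 0.90: {best}x")
print("Power rises monotonically with depth; a 5% mean-effect mutation is")
print("already reliably mapped at modest coverage with 2% tails.")
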