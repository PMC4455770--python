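"""End-to-end mapping on a synthetic experiment.

Generates a synthetic two-bulk sync file — 60 neutral EMS-style sites
segregating at frequency 0.5 plus one spiked causal site — then runs the
scan pipeline (coverage filters, per-site G-tests) and checks that the
top-ranked site is the spiked one.
"""

import tempfile
from pathlib import Path

from bsapower import (
    ExperimentalDesign,
    MutationEffects,
    SyntheticExperimentSpec,
    filter_sites,
    generate_sync,
    read_sync,
    scan,
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
spec = SyntheticExperimentSpec(
    design=design,
    n_null_sites=60,
    causal_effects=MutationEffects(7.21, 0.862, 0.130),
)

workdir = Path(tempfile.mkdtemp())
sync_path = workdir / "experiment.sync"
truth = generate_sync(spec, rng=42, path=sync_path)
causal_pos = int(truth.loc[truth.is_causal, "pos"].iloc[0])

sites = filter_sites(read_sync(sync_path))
records = scan(sites, alpha=0.001)
records.sort(key=lambda r: r.p_value)

print(f"{len(truth)} sites generated; {len(records)} pass filters and are variable")
print(f"true causal site: chrI:{causal_pos}")
print()
print("top five sites by p-value:")
print(f"{'pos':>8s} {'freq_low':>9s} {'freq_high':>9s} {'G':>8s} {'p':>10s}")
for r in records[:5]:
    mark = "  <- causal" if r.pos == causal_pos else ""
    print(f"{r.pos:8d} {r.freq_low:9.3f} {r.freq_high:9.3f} "
          f"{r.G:8.2f} {r.p_value:10.2e}{mark}")
print()
print("Neutral sites sit near frequency 0.5 in both bulks; the causal site")
print("is depleted from one tail and enriched in the other, which the")
print("G-test flags far below alpha = 0.001.")
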