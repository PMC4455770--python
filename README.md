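# bsapower

Design, power analysis and allele-frequency scanning for **bulk
segregant analysis with pooled sequencing (BSA-seq)**.

BSA-seq maps the genetic basis of a quantitative trait by crossing a
mutant to a reference strain, pooling recombinant progeny (segregants)
from the two extreme tails of the phenotype distribution, sequencing
each pool, and looking for sites whose allele frequencies differ between
the pools. In microbes the experiment necessarily includes phases of
competitive growth, so a causal mutation's effect on *fitness* — not
just on the phenotype's mean and standard deviation — shapes whether it
can be mapped. `bsapower` is for experimentalists planning such a screen
(how many segregants? how extreme a cutoff? how much coverage?) and for
analyzing the resulting pooled allele counts.

## The model

Phenotypes are a two-component Gaussian mixture on the wild-type-SD
scale: wild-type cells ~ N(0, 1), mutant cells ~ N(μ_m, r), where μ_m
is the mutation's mean effect in wild-type SDs (a percent effect *m*
converts as μ_m = (m/100)/CV with CV the wild-type coefficient of
variation) and *r* the mutant/wild-type SD ratio. The causal allele
starts at frequency p₀ = 0.5 and evolves under haploid selection with
coefficient *s*,

    p_g = p₀(1−s)^g / (p₀(1−s)^g + 1 − p₀),

through *g* generations of growth. Sorting the tail mass *c* from each
side of the mixture enriches the mutant allele by Bayes' rule
(p·T_m / (p·T_m + (1−p)·T_w), with T the component tail probabilities
beyond the cutoff), and each bulk then grows again before sequencing.
Around this deterministic expectation, each simulated replicate draws
binomial sorting noise (bulk size n) and binomial read sampling (depth
D), and tests the resulting 2×2 table with a likelihood-ratio G-test
(G = 2ΣO·ln(O/E), χ²₁). Power is the fraction of replicates with
p < α. The same G-test drives the empirical per-site scan of
Popoolation2-style sync files, and a companion module estimates *s*
from two-marker competition assays, s = [ln(YFP₁/GFP₁) −
ln(YFP₀/GFP₀)]/g.

## Worked example

`examples/power_analysis.py` evaluates the mapping design used for
three EMS mutants of a fluorescent-reporter phenotype (10⁷ segregants,
2% tails → 2×10⁵ cells per bulk, 10+10 generations, 75× depth):

```
bulks of 200000 cells, depth 75x, alpha 0.001
mutant      p_low   p_high   power     +/-
YPW89      0.0006   0.6055   1.000   0.000
YPW94      0.0009   0.2537   0.998   0.001
YPW102     0.6255   0.1512   0.999   0.000
```

`p_low`/`p_high` are the expected causal-allele frequencies in the two
bulks at sequencing time — note how strong selection (s ≈ 0.13 for the
first two mutants) pushes both well below the naive 0/1 separation —
and `power` is the Monte-Carlo probability that the bulk difference is
significant at α = 0.001: all three mutants are mapped essentially
every time. The other examples sweep sequencing depth
(`design_grid.py`: 25× suffices for a 5% mean effect), run the scan
end-to-end on a synthetic experiment (`scan_bulks.py`) and recover
selection coefficients from simulated competitions
(`fitness_assay.py`).

The same machinery is scriptable from a shell:

```sh
bsapower power --mean-effect 5 --sel-coef 0.03 --cutoff 2 --depth 100 \
    --generations 10,10 --n-sims 1000 --seed 1
bsapower scan --sync bulks.sync --snps high_confidence.tsv --out scan.tsv
```

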