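# Methods

## Model and assumptions

`bsapower` models a BSA-seq experiment on a haploid cross with a single
causal site. The assumptions are:

- exactly one segregating site affects the phenotype; all other
  segregating sites are unlinked to it and fitness-neutral (the
  low-density mutation load of a mild mutagenesis screen);
- the causal allele starts at frequency 0.5 among spores (Mendelian
  segregation);
- phenotypes are Gaussian within genotype: wild type ~ N(0, 1) and
  mutant ~ N(μ_m, r) on the wild-type-SD scale. Working in SD units
  makes the sorting cutoffs independent of the phenotype's absolute
  scale; percent mean effects are converted via the wild-type
  coefficient of variation (CV);
- fitness acts as discrete-generation haploid selection with constant
  coefficient s (mutant relative fitness 1 − s per generation), giving
  the closed form p_g = p(1−s)^g / (p(1−s)^g + 1 − p). Continuous
  (exponential) selection would differ only in the time scaling of s;
  the discrete recursion is used throughout;
- the population is effectively infinite during growth (no drift): the
  deterministic expectation chain is exact up to the two sampling
  stages below.

The expectation chain is: pre-selection growth of p₀ = 0.5 → truncation
selection of both phenotype tails at the design cutoff (mixture
quantile by bracketed root finding; Bayes tail fractions) →
post-selection growth of each bulk's frequency.

## Stochastic layer and power

Each simulated replicate injects noise at exactly two points:

1. bulk composition at sorting: mutant cells ~ Binomial(n_bulk,
   sorted fraction);
2. read sampling at sequencing: mutant reads ~ Binomial(depth, grown
   realized frequency).

Post-selection growth is applied deterministically to the *realized*
sorted frequency between the two draws. The read-frequency variance at
a null site is therefore p(1−p)[1/D + (1 − 1/D)/n_bulk] (law of total
variance), which produces the characteristic failure mode of
small-bulk designs: when n_bulk ≪ D the sorting term dominates, the
G-test (which models only read sampling) is anti-conservative, and the
false-positive rate inflates far above α. The test suite checks this
variance law to 5% and the >5α inflation at n_bulk = D/10.

Power is the fraction of replicates whose 2×2 G-test falls below α;
replicates with a zero table margin count as non-significant (dropping
them would bias power upward at low depth). Depth is a fixed per-bulk
constant (a Poisson-depth mode could be added, but "average coverage"
is modeled as its mean). Simulation is vectorized over replicates;
1000 replicates — the default, and the problem size all shipped
analyses use — take milliseconds, so the acceptance script and tests
use 2000–20000 replicates where tighter Monte-Carlo error is useful.

## Statistical tests

G = 2ΣO·ln(O/E) with the 0·ln 0 ≡ 0 convention, df = 1, p from the χ²₁
upper tail; no Williams or continuity correction (corrections would
change significance calls relative to the plain likelihood-ratio test;
the implementation is cross-checked against scipy's log-likelihood-
ratio `chi2_contingency` in the tests). "Two-sided" is realized as the
direction-free chi-square tail. A 2×2 table with a zero margin is
undefined for the scalar API (error) and non-significant (G = 0, p = 1)
in the vectorized path used by the simulator and the scan. The
goodness-of-fit variant tests one pool against a null frequency
(default 0.5), for tetrad-pool style designs.

Calibration caveat: with discrete counts the χ² approximation is not
exact — measured null rejection rates at α = 0.01 range from ~0.9α
(large bulks, conservative discreteness) to ~1.3α (bulks only 10× the
depth, where the second sampling stage inflates variance by
1 + (D−1)/n_bulk). The calibration tests therefore assert agreement
with α within a factor of two, plus the strict inflation contrast
above.

## Scan pipeline

Sync input (tab-separated chrom, 1-based position, reference base, and
one A:T:C:G:N:del count field per pool; low bulk then high bulk) is
parsed strictly, with line numbers in parse errors. Filtering keeps
sites whose per-bulk base coverage (A+T+C+G) lies within
[min_coverage, max_coverage] inclusive and whose best non-reference
allele has at least min_count reads summed over both pools (defaults
10/10/500); min_count is interpreted as the cross-pool minor-allele
sum, the documented semantics of the pooled-sequencing toolchain the
format comes from. The high-confidence intersection keeps sites whose
(chrom, pos) and alt allele appear in an independently called variant
list (plain TSV or VCF); if >90% of listed positions are missing from
the sync sites a coordinate-convention warning is raised. Multiallelic
sites collapse to the single best alt allele (warning lists the
discarded ones). Significance is a fixed α = 0.001 with no
multiple-testing correction — the scan is a candidate-ranking step over
a few dozen sites, not a genome-wide discovery screen. Strand-bias
filtering belongs to the upstream variant caller and is deliberately
not re-implemented.

## Fitness assays

s is the per-generation slope of ln(YFP/GFP); g = log₂(d₁/d₀) doublings
from culture densities. The marker-background correction is the
multiplicative form s_mut = (1 + s)/(1 + s_YFP) − 1 (compounding the
marker's per-generation cost out of the measured coefficient), with the
first-order additive form s − s_YFP available behind a flag; the two
differ by ~2% of the coefficient at typical magnitudes. Correction is
applied per replicate before averaging. A convenience accessor negates
the raw slope so a deleterious focal strain reports a positive deficit.

## Synthetic data

The generator emulates the *statistical* structure of a mapped
experiment, not reads: per-site pooled counts for 30–80 point mutations
(the observed range for mildly mutagenized strains), 85% of them
G:C→A:T transitions (the EMS spectrum), neutral sites drawn through the
same two-stage chain at frequency 0.5, and an optional causal site
drawn through the full expectation chain. Truth tables record the exact
frequencies each read-count draw used. What it does *not* emulate —
alignment artifacts, strand bias, mapping errors, linkage blocks,
overdispersed coverage — means passing recovery tests demonstrate the
statistical pipeline, not robustness to upstream noise in real data.
Competition assays are simulated as binomial sampling of 2×10⁴
flow-cytometry events per time point around a deterministic log-ratio
shift.

## Numerical and design choices

- Default wild-type CV = 0.07572, the value implied by a +10.45% mean
  shift equalling +1.38 wild-type SDs for this reporter phenotype;
  always configurable.
- Mixture quantile inversion: Brent's method on
  [min(0, μ_m) − 10·max(1, r), max(0, μ_m) + 10·max(1, r)], xtol 1e−12;
  the mixture CDF is strictly increasing so the bracket is safe for any
  realistic effect size.
- Generations default to 10 pre- + 10 post-selection; a single total on
  the CLI is split evenly.
- Default α = 0.001 and n_sims = 1000.
- Two cutoff conventions are in common use (2% tails for maximum
  enrichment, 5% for gentler sorting); neither is hard-coded — the
  mapping-design examples use 2%, the design-survey baseline 5%.
- Seeded `numpy.random.Generator`s everywhere; fixed seed ⇒
  byte-identical outputs, including generated files.

## Limitations

Haploid, single-locus, drift-free, Gaussian-within-genotype. No
dominance (an F₂ diploid design is approximated by the haploid chain
with zero growth generations), no linked-site aggregation, no
sequencing-error model, no cost optimization beyond the minimum-depth
grid search. Boundary designs can sit exactly at a stated power target
(e.g. the no-growth 10⁴-individual, 5%-cutoff, 25× design measures
power 0.900 ± 0.001 against a ">0.9" goal); such knife-edge cases are
reported with their Monte-Carlo error rather than rounded up.
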