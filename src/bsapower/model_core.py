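"""Deterministic expectation model for bulk segregant analysis (BSA-seq).

The model follows a causal mutation's allele frequency through a mapping
experiment on a quantitative phenotype in a haploid cross:

1. segregants start at an initial mutant-allele frequency (0.5 under
   Mendelian segregation of a single causal site);
2. mitotic growth before bulk selection shifts the frequency if the mutant
   carries a fitness cost (haploid selection recursion);
3. the population is phenotyped and the two tails of the phenotype
   distribution are sorted into a "low" and a "high" bulk.  Phenotypes are
   modeled as a two-component Gaussian mixture: wild-type cells ~ N(0, 1)
   and mutant cells ~ N(mu_m, r) on the wild-type-SD scale, where mu_m is
   the mutation's mean effect in wild-type SD units and r the ratio of
   mutant to wild-type phenotypic SD;
4. growth after sorting again shifts each bulk's frequency;
5. the resulting expected mutant-allele frequency in each bulk is what
   pooled sequencing will sample from.

Everything in this module is deterministic (infinite-population
expectations); sampling noise is layered on top by :mod:`bsapower.power_sim`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.stats import norm

__all__ = [
    "MutationEffects",
    "ExperimentalDesign",
    "BulkExpectation",
    "pct_to_sd_units",
    "grow_frequency",
    "mixture_quantile",
    "bulk_mutant_fraction",
    "expected_bulk_frequencies",
]

#: Wild-type coefficient of variation of the fluorescence phenotype implied
#: by expressing a +10.45% mean shift as +1.38 wild-type SD.
DEFAULT_WILD_TYPE_CV = 0.07572


@dataclass(frozen=True)
class MutationEffects:
    """Effects of a single causal mutation.

    Parameters
    ----------
    mean_effect_pct
        Change of the mean phenotype relative to wild type, in percent
        (signed; +5 means the mutant mean is 5% above wild type).
    sd_ratio
        Mutant phenotypic SD divided by wild-type SD (> 0).  A mutation
        reported as changing the SD by -5.33% has ``sd_ratio = 0.9467``.
    selection_coefficient
        Per-generation fitness deficit ``s`` of the mutant during
        competitive growth; positive for deleterious mutants, must be < 1.
    initial_frequency
        Mutant-allele frequency at spore isolation (0.5 for a single
        segregating site).
    """

    mean_effect_pct: float = 0.0
    sd_ratio: float = 1.0
    selection_coefficient: float = 0.0
    initial_frequency: float = 0.5

    def __post_init__(self) -> None:
        if not self.sd_ratio > 0:
            raise ValueError(f"sd_ratio must be > 0, got {self.sd_ratio}")
        if not 0.0 <= self.initial_frequency <= 1.0:
            raise ValueError(
                f"initial_frequency must be in [0, 1], got {self.initial_frequency}"
            )
        if not self.selection_coefficient < 1:
            raise ValueError(
                f"selection_coefficient must be < 1, got {self.selection_coefficient}"
            )


@dataclass(frozen=True)
class ExperimentalDesign:
    """Controllable parameters of a BSA-seq mapping experiment.

    Parameters
    ----------
    population_size
        Number of segregants phenotyped before bulk selection.
    cutoff_fraction
        Tail mass of the phenotype distribution sorted into each bulk
        (0.02 for "2% tails"); must lie in (0, 0.5).
    generations_pre
        Mitotic generations between spore isolation and bulk selection.
    generations_post
        Generations between bulk selection and DNA extraction.
    depth
        Mean sequencing read depth per bulk at the causal site.
    alpha
        Significance level for declaring a site mapped.
    wild_type_cv
        Wild-type phenotypic SD as a fraction of the wild-type mean; used
        to convert percent mean effects into SD units.
    """

    population_size: int = 10_000_000
    cutoff_fraction: float = 0.02
    generations_pre: int = 10
    generations_post: int = 10
    depth: int = 100
    alpha: float = 0.001
    wild_type_cv: float = DEFAULT_WILD_TYPE_CV

    def __post_init__(self) -> None:
        if not 0 < self.cutoff_fraction < 0.5:
            raise ValueError(
                f"cutoff_fraction must be in (0, 0.5), got {self.cutoff_fraction}"
            )
        if self.population_size < 1:
            raise ValueError("population_size must be >= 1")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.generations_pre < 0 or self.generations_post < 0:
            raise ValueError("generations must be >= 0")
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if not self.wild_type_cv > 0:
            raise ValueError(f"wild_type_cv must be > 0, got {self.wild_type_cv}")
        if self.bulk_size < 1:
            raise ValueError(
                "cutoff_fraction x population_size must select at least one cell"
            )

    @property
    def bulk_size(self) -> int:
        """Number of cells sorted into each bulk."""
        return int(round(self.cutoff_fraction * self.population_size))


@dataclass(frozen=True)
class BulkExpectation:
    """Deterministic expected state of the two bulks.

    ``p_low`` / ``p_high`` are the expected mutant-allele frequencies at
    sequencing time (after post-selection growth); ``p_low_sorted`` /
    ``p_high_sorted`` are the frequencies in the freshly sorted bulks.
    ``t_low`` / ``t_high`` are the phenotype thresholds (wild-type SD
    units) defining the bulks and ``p_preselection`` the population
    frequency just before sorting.  The selection coefficient and
    post-selection generation count used by the chain are recorded so the
    stochastic sampler can re-apply growth to realized frequencies.
    """

    p_low: float
    p_high: float
    t_low: float
    t_high: float
    p_preselection: float
    p_low_sorted: float = field(default=float("nan"))
    p_high_sorted: float = field(default=float("nan"))
    selection_coefficient: float = 0.0
    generations_post: int = 0

    def __post_init__(self) -> None:
        for name in ("p_low", "p_high", "p_preselection"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not self.t_low < self.t_high:
            raise ValueError("t_low must be < t_high")


def pct_to_sd_units(mean_effect_pct: float, wild_type_cv: float) -> float:
    """Convert a percent mean effect into wild-type standard-deviation units.

    A mutation shifting the mean by ``m`` percent of the wild-type mean
    corresponds to ``(m/100) / cv`` wild-type SDs, where ``cv`` is the
    wild-type coefficient of variation.  Sign is preserved.
    """
    if not wild_type_cv > 0:
        raise ValueError(f"wild_type_cv must be > 0, got {wild_type_cv}")
    return (mean_effect_pct / 100.0) / wild_type_cv


def grow_frequency(p: float, s: float, g: float) -> float:
    """Mutant-allele frequency after ``g`` generations of haploid selection.

    The mutant genotype has relative fitness ``1 - s`` per generation; the
    per-generation recursion p' = p(1-s) / (1 - p s) has the closed form

        p_g = p (1-s)^g / (p (1-s)^g + (1-p)).

    ``s = 0`` or ``g = 0`` leaves ``p`` unchanged; 0 and 1 are fixed points.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must be in [0, 1], got {p}")
    if s >= 1:
        raise ValueError(f"selection coefficient must be < 1, got {s}")
    if g < 0:
        raise ValueError(f"generations must be >= 0, got {g}")
    if p in (0.0, 1.0) or s == 0 or g == 0:
        return p
    w = (1.0 - s) ** g
    return p * w / (p * w + (1.0 - p))


def _mixture_cdf(t, p: float, mu_m: float, r: float):
    """CDF of the phenotype mixture (1-p)·N(0,1) + p·N(mu_m, r) at t."""
    return (1.0 - p) * norm.cdf(t) + p * norm.cdf((t - mu_m) / r)


def mixture_quantile(
    p: float, mu_m: float, r: float, tail_mass: float, side: str
) -> float:
    """Phenotype threshold capturing ``tail_mass`` of the mixture on one side.

    Solves F(t) = tail_mass (side="low") or F(t) = 1 - tail_mass
    (side="high") for the mixture CDF F by bracketed root finding; the
    mixture CDF is strictly increasing so the root is unique.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must be in [0, 1], got {p}")
    if not 0.0 < tail_mass <= 0.5:
        raise ValueError(f"tail_mass must be in (0, 0.5], got {tail_mass}")
    if side not in ("low", "high"):
        raise ValueError(f"side must be 'low' or 'high', got {side!r}")
    target = tail_mass if side == "low" else 1.0 - tail_mass
    lo = min(0.0, mu_m) - 10.0 * max(1.0, r)
    hi = max(0.0, mu_m) + 10.0 * max(1.0, r)
    return float(
        brentq(lambda t: _mixture_cdf(t, p, mu_m, r) - target, lo, hi, xtol=1e-12)
    )


def bulk_mutant_fraction(
    p: float, mu_m: float, r: float, t: float, side: str
) -> float:
    """Mutant-allele fraction among cells sorted beyond threshold ``t``.

    By Bayes' rule the fraction of mutant cells in the selected tail is
    p·T_m / (p·T_m + (1-p)·T_w) where T_m and T_w are the mutant and
    wild-type tail probabilities beyond ``t`` on the given side.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must be in [0, 1], got {p}")
    if side == "low":
        tail_w = norm.cdf(t)
        tail_m = norm.cdf((t - mu_m) / r)
    elif side == "high":
        tail_w = norm.sf(t)
        tail_m = norm.sf((t - mu_m) / r)
    else:
        raise ValueError(f"side must be 'low' or 'high', got {side!r}")
    total = p * tail_m + (1.0 - p) * tail_w
    if total <= 0.0:
        raise ValueError("degenerate bulk: zero tail mass beyond threshold")
    return float(np.clip(p * tail_m / total, 0.0, 1.0))


def expected_bulk_frequencies(
    design: ExperimentalDesign, effects: MutationEffects
) -> BulkExpectation:
    """Expected mutant-allele frequencies in the low and high bulks.

    Chains the deterministic steps of the experiment: pre-selection growth
    of the initial frequency, truncation selection of both phenotype tails
    at the design's cutoff, and post-selection growth of each bulk.
    """
    s = effects.selection_coefficient
    mu_m = pct_to_sd_units(effects.mean_effect_pct, design.wild_type_cv)
    r = effects.sd_ratio

    p_pre = grow_frequency(effects.initial_frequency, s, design.generations_pre)
    t_low = mixture_quantile(p_pre, mu_m, r, design.cutoff_fraction, "low")
    t_high = mixture_quantile(p_pre, mu_m, r, design.cutoff_fraction, "high")
    p_low_sorted = bulk_mutant_fraction(p_pre, mu_m, r, t_low, "low")
    p_high_sorted = bulk_mutant_fraction(p_pre, mu_m, r, t_high, "high")
    p_low = grow_frequency(p_low_sorted, s, design.generations_post)
    p_high = grow_frequency(p_high_sorted, s, design.generations_post)

    return BulkExpectation(
        p_low=p_low,
        p_high=p_high,
        t_low=t_low,
        t_high=t_high,
        p_preselection=p_pre,
        p_low_sorted=p_low_sorted,
        p_high_sorted=p_high_sorted,
        selection_coefficient=s,
        generations_post=design.generations_post,
    )
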