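"""Selection-coefficient estimation from two-marker competition assays.

A strain of interest carrying a YFP marker is mixed ~1:1 with a GFP
reference strain, grown competitively, and the two populations are
counted by flow cytometry at the start (T0) and end (T1) of the assay.
The per-generation selection coefficient is the slope of the log marker
ratio per generation:

    s = ( ln(YFP1/GFP1) - ln(YFP0/GFP0) ) / g

with g = log2(final density / starting density) doublings elapsed.
Negative s means the YFP strain gained ground.  Because the YFP marker
itself can carry a cost, the mutant background's own coefficient is
obtained by factoring out the marker-only coefficient measured on the
unmutagenized parental strain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "CompetitionCounts",
    "generations_from_density",
    "selection_coefficient",
    "mutant_fitness_deficit",
    "background_selection_coefficient",
]


@dataclass(frozen=True)
class CompetitionCounts:
    """Flow-cytometry cell counts of a two-marker competition replicate."""

    yfp0: int
    gfp0: int
    yfp1: int
    gfp1: int
    generations: float

    def __post_init__(self) -> None:
        if min(self.yfp0, self.gfp0, self.yfp1, self.gfp1) <= 0:
            raise ValueError(
                "all four counts must be > 0 for a finite estimate"
            )
        if not self.generations > 0:
            raise ValueError("generations must be > 0")


def generations_from_density(d0: float, d1: float) -> float:
    """Number of doublings between two culture densities: log2(d1/d0)."""
    if d0 <= 0 or d1 < d0:
        raise ValueError("densities must satisfy d1 >= d0 > 0")
    return math.log2(d1 / d0)


def selection_coefficient(counts: CompetitionCounts) -> float:
    """Per-generation selection coefficient from one competition replicate."""
    return (
        math.log(counts.yfp1 / counts.gfp1) - math.log(counts.yfp0 / counts.gfp0)
    ) / counts.generations


def mutant_fitness_deficit(counts: CompetitionCounts) -> float:
    """Fitness deficit of the focal (YFP) strain as a positive number.

    Convenience accessor: the raw log-ratio slope is negative when the
    YFP strain loses ground; this returns its negation so that a
    deleterious mutant gets a positive selection coefficient, matching
    the usual reporting convention.
    """
    return -selection_coefficient(counts)


def background_selection_coefficient(
    s: float, s_yfp: float, additive: bool = False
) -> float:
    """Selection coefficient of the mutant background, marker cost removed.

    The default multiplicative correction is (1 + s)/(1 + s_yfp) - 1,
    compounding the marker's per-generation cost out of the measured
    coefficient.  ``additive=True`` uses the simple difference s - s_yfp
    instead; the two agree to first order in small coefficients.
    """
    if additive:
        return s - s_yfp
    if s_yfp <= -1:
        raise ValueError("s_yfp must be > -1")
    return (1.0 + s) / (1.0 + s_yfp) - 1.0
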