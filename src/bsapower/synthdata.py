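"""Synthetic fixtures: sync files with a spiked causal site, and
simulated competition assays.

The sync generator emulates the data a BSA-seq mapping experiment
produces after alignment and pooled allele counting: a set of unlinked
neutral mutations segregating at frequency 0.5 in both bulks (their read
counts reflecting only the two-stage sorting + sequencing noise), plus
optionally one causal site whose bulk frequencies follow the
deterministic expectation chain of :mod:`bsapower.model_core`.  The
substitution spectrum is biased toward G:C -> A:T transitions as expected
after EMS mutagenesis (default 85% of sites).

Every generated file comes with a truth table recording, per site, the
exact allele frequencies that the read-count draws used, so recovery can
be checked end to end.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .model_core import ExperimentalDesign, MutationEffects, expected_bulk_frequencies
from .power_sim import _grow_array
from .bsa_scan import SiteCounts, write_sync

__all__ = [
    "SyntheticExperimentSpec",
    "generate_sync",
    "generate_competition",
]

#: EMS produces predominantly G:C -> A:T transitions.
DEFAULT_EMS_TRANSITION_FRACTION = 0.85

_SYNC_INDEX = {"A": 0, "T": 1, "C": 2, "G": 3}
# non-EMS substitution types (anything that is not G->A or C->T)
_OTHER_SUBS = [
    (r, a)
    for r in "ATCG"
    for a in "ATCG"
    if r != a and (r, a) not in {("G", "A"), ("C", "T")}
]


@dataclass(frozen=True)
class SyntheticExperimentSpec:
    """Recipe for one synthetic two-bulk sequencing experiment.

    ``n_null_sites=None`` draws the site count uniformly from [30, 80],
    the range observed for EMS mutant strains with tens of induced point
    mutations.  ``depth_per_site`` overrides the design's depth, either as
    one integer or one value per site (null sites first, causal last).
    """

    design: ExperimentalDesign
    n_null_sites: int | None = None
    causal_effects: MutationEffects | None = None
    depth_per_site: int | list[int] | None = None
    ems_transition_fraction: float = DEFAULT_EMS_TRANSITION_FRACTION

    def __post_init__(self) -> None:
        if self.n_null_sites is not None and self.n_null_sites < 0:
            raise ValueError("n_null_sites must be >= 0")
        if not 0.0 <= self.ems_transition_fraction <= 1.0:
            raise ValueError("ems_transition_fraction must be in [0, 1]")


def _draw_substitution(rng: np.random.Generator, ems_fraction: float):
    if rng.random() < ems_fraction:
        return ("G", "A") if rng.random() < 0.5 else ("C", "T")
    return _OTHER_SUBS[rng.integers(len(_OTHER_SUBS))]


def _counts_field(ref: str, alt: str, mut_reads: int, depth: int) -> tuple[int, ...]:
    counts = [0, 0, 0, 0, 0, 0]
    counts[_SYNC_INDEX[ref]] = depth - mut_reads
    counts[_SYNC_INDEX[alt]] = mut_reads
    return tuple(counts)


def generate_sync(
    spec: SyntheticExperimentSpec,
    rng: np.random.Generator | int | None,
    path: str | Path,
    truth_path: str | Path | None = None,
) -> pd.DataFrame:
    """Write a synthetic sync file and return its truth table.

    Null sites are drawn through the same two-stage chain the power
    simulation uses (sorting binomial at frequency 0.5, then a read-count
    binomial); the causal site, if any, uses its full expectation chain
    including selection.  Sites are placed at distinct positions on one
    chromosome, the causal site at a random rank.  The truth table (one
    row per site: chrom, pos, ref, alt, is_causal, and the frequencies
    actually used to draw the low/high read counts) is returned and, if
    ``truth_path`` is given, also written as TSV.
    """
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(rng)
    design = spec.design
    n_null = (
        int(rng.integers(30, 81)) if spec.n_null_sites is None else spec.n_null_sites
    )
    n_sites = n_null + (1 if spec.causal_effects is not None else 0)

    if spec.depth_per_site is None:
        depths = [design.depth] * n_sites
    elif isinstance(spec.depth_per_site, (int, np.integer)):
        depths = [int(spec.depth_per_site)] * n_sites
    else:
        depths = [int(d) for d in spec.depth_per_site]
        if len(depths) != n_sites:
            raise ValueError(f"depth_per_site must have {n_sites} entries")

    positions = np.sort(rng.choice(np.arange(1, 1_000_001), size=n_sites, replace=False))
    causal_rank = int(rng.integers(n_sites)) if spec.causal_effects is not None else -1

    bulk = design.bulk_size
    sites: list[SiteCounts] = []
    truth_rows = []
    null_i = 0
    for rank, pos in enumerate(positions):
        ref, alt = _draw_substitution(rng, spec.ems_transition_fraction)
        depth = depths[null_i] if rank != causal_rank else depths[-1]
        if rank == causal_rank:
            effects = spec.causal_effects
            exp = expected_bulk_frequencies(design, effects)
            p_sorted = (exp.p_low_sorted, exp.p_high_sorted)
            s, g_post = exp.selection_coefficient, exp.generations_post
        else:
            p_sorted = (0.5, 0.5)
            s, g_post = 0.0, 0
            null_i += 1
        f_used = []
        counts_fields = []
        for p in p_sorted:
            k = rng.binomial(bulk, p)
            f = float(_grow_array(np.array(k / bulk), s, g_post))
            mut_reads = int(rng.binomial(depth, f))
            counts_fields.append(_counts_field(ref, alt, mut_reads, depth))
            f_used.append(f)
        sites.append(
            SiteCounts(
                chrom="chrI",
                pos=int(pos),
                ref_base=ref,
                counts_low=counts_fields[0],
                counts_high=counts_fields[1],
            )
        )
        truth_rows.append(
            {
                "chrom": "chrI",
                "pos": int(pos),
                "ref": ref,
                "alt": alt,
                "is_causal": rank == causal_rank,
                "freq_low_used": f_used[0],
                "freq_high_used": f_used[1],
            }
        )

    write_sync(sites, path)
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "chrom",
            "pos",
            "ref",
            "alt",
            "is_causal",
            "freq_low_used",
            "freq_high_used",
        ],
    )
    if truth_path is not None:
        truth.to_csv(truth_path, sep="\t", index=False)
    return truth


def generate_competition(
    true_s: float,
    generations: float = 12.55,
    events_per_timepoint: int = 20_000,
    n_replicates: int = 1,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Simulate two-marker competition replicates with a known true s.

    ``true_s`` is the per-generation slope of the log marker ratio
    ln(YFP/GFP): the underlying ratio starts at 1:1 and its log shifts by
    ``true_s * generations`` over the assay, so
    :func:`bsapower.fitness.selection_coefficient` recovers ``true_s`` up
    to sampling noise.  Both time points are sampled binomially with
    ``events_per_timepoint`` flow-cytometry events.  Returns one row per
    replicate with columns yfp0, gfp0, yfp1, gfp1, generations.
    """
    if events_per_timepoint < 1:
        raise ValueError("events_per_timepoint must be >= 1")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(rng)
    p1 = 1.0 / (1.0 + np.exp(-true_s * generations))  # YFP fraction at T1
    yfp0 = rng.binomial(events_per_timepoint, 0.5, size=n_replicates)
    yfp1 = rng.binomial(events_per_timepoint, p1, size=n_replicates)
    return pd.DataFrame(
        {
            "yfp0": yfp0,
            "gfp0": events_per_timepoint - yfp0,
            "yfp1": yfp1,
            "gfp1": events_per_timepoint - yfp1,
            "generations": generations,
        }
    )
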