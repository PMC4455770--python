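"""Per-site allele-frequency comparison between two sequenced bulks.

Works on Popoolation2-style "sync" tables: one line per genomic site with
tab-separated chromosome, 1-based position, reference base, and one
colon-separated ``A:T:C:G:N:del`` count field per pool (here two pools,
low bulk then high bulk).  The pipeline is

    read_sync -> filter_sites -> intersect_high_confidence -> scan

mirroring a pooled-sequencing mapping analysis: coverage/allele-count
filters, restriction to an independently called set of high-confidence
variants, then a two-sided G-test per site with a fixed significance
threshold (default alpha = 0.001, no multiple-testing correction).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .stats import g_test_tables

__all__ = [
    "SiteCounts",
    "ScanRecord",
    "read_sync",
    "write_sync",
    "read_variant_list",
    "filter_sites",
    "intersect_high_confidence",
    "scan",
    "scan_to_dataframe",
]

NUCLEOTIDES = "ATCG"
#: Order of the colon-separated count fields in a sync file.
SYNC_FIELDS = ("A", "T", "C", "G", "N", "del")


@dataclass(frozen=True)
class SiteCounts:
    """Per-nucleotide read counts for one site in the two bulks.

    ``counts_low`` and ``counts_high`` follow the sync field order
    (A, T, C, G, N, deletion).
    """

    chrom: str
    pos: int
    ref_base: str
    counts_low: tuple[int, ...]
    counts_high: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        for counts in (self.counts_low, self.counts_high):
            if len(counts) != 6 or any(c < 0 for c in counts):
                raise ValueError("counts must be 6 non-negative integers")

    def coverage(self, bulk: str) -> int:
        """Base coverage (A+T+C+G) in one bulk ('low' or 'high')."""
        counts = self.counts_low if bulk == "low" else self.counts_high
        return sum(counts[:4])

    def allele_count(self, base: str, bulk: str) -> int:
        counts = self.counts_low if bulk == "low" else self.counts_high
        return counts[SYNC_FIELDS.index(base)]

    def best_alt(self) -> tuple[str, int]:
        """Non-reference nucleotide with the highest count summed over bulks."""
        best, best_n = "N", 0
        for base in NUCLEOTIDES:
            if base == self.ref_base:
                continue
            n = self.allele_count(base, "low") + self.allele_count(base, "high")
            if n > best_n:
                best, best_n = base, n
        return best, best_n


@dataclass(frozen=True)
class ScanRecord:
    """G-test result for one site of the bulk comparison."""

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    mut_low: int
    ref_low: int
    mut_high: int
    ref_high: int
    freq_low: float
    freq_high: float
    G: float
    p_value: float
    significant: bool


class SyncParseError(ValueError):
    """Raised for malformed sync lines, naming the offending line number."""


def _parse_count_field(field: str, lineno: int) -> tuple[int, ...]:
    parts = field.split(":")
    if len(parts) != 6:
        raise SyncParseError(
            f"line {lineno}: expected 6 colon-separated counts, got {field!r}"
        )
    try:
        counts = tuple(int(x) for x in parts)
    except ValueError:
        raise SyncParseError(f"line {lineno}: non-integer count in {field!r}") from None
    return counts


def read_sync(path: str | Path) -> list[SiteCounts]:
    """Parse a two-pool sync file into a list of :class:`SiteCounts`.

    Lines must contain chrom, pos, reference base and exactly two count
    fields (low bulk, high bulk).  Blank lines are skipped; any malformed
    line raises :class:`SyncParseError` with its line number.
    """
    sites: list[SiteCounts] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 5:
                raise SyncParseError(
                    f"line {lineno}: expected 5 tab-separated columns, "
                    f"got {len(fields)}"
                )
            chrom, pos_s, ref = fields[0], fields[1], fields[2]
            try:
                pos = int(pos_s)
            except ValueError:
                raise SyncParseError(
                    f"line {lineno}: non-integer position {pos_s!r}"
                ) from None
            sites.append(
                SiteCounts(
                    chrom=chrom,
                    pos=pos,
                    ref_base=ref,
                    counts_low=_parse_count_field(fields[3], lineno),
                    counts_high=_parse_count_field(fields[4], lineno),
                )
            )
    return sites


def write_sync(sites: Iterable[SiteCounts], path: str | Path) -> None:
    """Write sites in two-pool sync format (inverse of :func:`read_sync`)."""
    with open(path, "w") as fh:
        for s in sites:
            low = ":".join(str(c) for c in s.counts_low)
            high = ":".join(str(c) for c in s.counts_high)
            fh.write(f"{s.chrom}\t{s.pos}\t{s.ref_base}\t{low}\t{high}\n")


def read_variant_list(path: str | Path) -> list[tuple[str, int, str, str]]:
    """Read a high-confidence variant list as (chrom, pos, ref, alt) tuples.

    Accepts either a plain tab-separated table with columns chrom, pos,
    ref, alt (a header line starting with '#' is skipped), or a VCF file
    (detected by its ``##fileformat=VCF`` first line and read with pysam).
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("##fileformat=VCF"):
        import pysam

        variants = []
        with pysam.VariantFile(str(path)) as vcf:
            for rec in vcf:
                for alt in rec.alts or ():
                    variants.append((rec.chrom, rec.pos, rec.ref, alt))
        return variants
    variants = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise SyncParseError(
                    f"line {lineno}: expected chrom, pos, ref, alt columns"
                )
            variants.append((fields[0], int(fields[1]), fields[2], fields[3]))
    return variants


def filter_sites(
    sites: Sequence[SiteCounts],
    min_count: int = 10,
    min_coverage: int = 10,
    max_coverage: int = 500,
) -> list[SiteCounts]:
    """Coverage and minor-allele-count filter on sync sites.

    Keeps sites where each bulk's coverage lies in
    [``min_coverage``, ``max_coverage``] (inclusive) and the best
    non-reference allele's count summed across the two bulks is at least
    ``min_count``.  Defaults follow common pooled-sequencing practice
    (10 / 10 / 500).  Idempotent.
    """
    if min_count < 1 or min_coverage < 1:
        raise ValueError("min_count and min_coverage must be positive")
    if min_coverage > max_coverage:
        raise ValueError("min_coverage must be <= max_coverage")
    kept = []
    for s in sites:
        cov_low, cov_high = s.coverage("low"), s.coverage("high")
        if not (min_coverage <= cov_low <= max_coverage):
            continue
        if not (min_coverage <= cov_high <= max_coverage):
            continue
        _, alt_n = s.best_alt()
        if alt_n < min_count:
            continue
        kept.append(s)
    return kept


def intersect_high_confidence(
    sites: Sequence[SiteCounts],
    variant_list: Sequence[tuple[str, int, str, str]],
) -> list[SiteCounts]:
    """Keep only sites confirmed by an independent high-confidence call set.

    A site passes if its (chrom, pos) appears in ``variant_list`` and its
    best alternate allele matches the listed alt allele.  If more than 90%
    of the list's positions are absent from ``sites``, a warning about a
    possible coordinate-convention mismatch is emitted.
    """
    wanted = {(c, p): alt for c, p, _ref, alt in variant_list}
    site_positions = {(s.chrom, s.pos) for s in sites}
    if wanted:
        missing = sum(1 for key in wanted if key not in site_positions)
        if missing / len(wanted) > 0.9:
            warnings.warn(
                f"{missing}/{len(wanted)} high-confidence positions are absent "
                "from the sync sites; check coordinate conventions (1-based "
                "positions expected)",
                stacklevel=2,
            )
    kept = []
    for s in sites:
        alt = wanted.get((s.chrom, s.pos))
        if alt is not None and s.best_alt()[0] == alt:
            kept.append(s)
    return kept


def scan(sites: Sequence[SiteCounts], alpha: float = 0.001) -> list[ScanRecord]:
    """Two-sided G-test of the alt-allele frequency difference per site.

    For each site the alternate allele is the non-reference nucleotide
    with the highest count summed over bulks; the 2x2 table (alt, ref) x
    (low, high) is tested.  Sites with no alt reads in either bulk are
    dropped.  Tertiary alleles at multiallelic sites are discarded with a
    warning.  Output is ordered by (chrom, pos).
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    rows = []
    multiallelic = []
    for s in sorted(sites, key=lambda x: (x.chrom, x.pos)):
        alt, alt_n = s.best_alt()
        if alt_n == 0:
            continue
        extra = [
            b
            for b in NUCLEOTIDES
            if b not in (s.ref_base, alt)
            and s.allele_count(b, "low") + s.allele_count(b, "high") > 0
        ]
        if extra:
            multiallelic.append(f"{s.chrom}:{s.pos} ({','.join(extra)})")
        rows.append(
            (
                s,
                alt,
                s.allele_count(alt, "low"),
                s.allele_count(s.ref_base, "low"),
                s.allele_count(alt, "high"),
                s.allele_count(s.ref_base, "high"),
            )
        )
    if multiallelic:
        warnings.warn(
            "discarded tertiary alleles at multiallelic sites: "
            + "; ".join(multiallelic),
            stacklevel=2,
        )
    if not rows:
        return []
    ml = np.array([r[2] for r in rows])
    rl = np.array([r[3] for r in rows])
    mh = np.array([r[4] for r in rows])
    rh = np.array([r[5] for r in rows])
    g, p = g_test_tables(ml, rl, mh, rh)

    def freq(mut, ref):
        return mut / (mut + ref) if mut + ref > 0 else float("nan")

    return [
        ScanRecord(
            chrom=s.chrom,
            pos=s.pos,
            ref_allele=s.ref_base,
            alt_allele=alt,
            mut_low=int(a),
            ref_low=int(b),
            mut_high=int(c),
            ref_high=int(d),
            freq_low=freq(a, b),
            freq_high=freq(c, d),
            G=float(gi),
            p_value=float(pi),
            significant=bool(pi < alpha),
        )
        for (s, alt, a, b, c, d), gi, pi in zip(rows, g, p)
    ]


def scan_to_dataframe(records: Sequence[ScanRecord]) -> pd.DataFrame:
    """Scan records as a DataFrame with a -log10(p) column, for TSV output."""
    df = pd.DataFrame([r.__dict__ for r in records])
    if not df.empty:
        with np.errstate(divide="ignore"):
            df["neg_log10_p"] = -np.log10(df["p_value"])
    return df
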