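"""Shared domain types.

All genomic intervals are 0-based half-open ``[start, end)`` internally.
GFF3 coordinates (1-based, inclusive) are converted at the I/O boundary.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

#: Gene-relative regions into which a TE insertion can fall.
REGIONS: Tuple[str, ...] = (
    "CDS",
    "UP2000",
    "INTRON",
    "DOWN2000",
    "DOWN200",
    "DOWN200_2000",
)

#: Closed set of TE classes.
TE_TYPES: Tuple[str, ...] = ("DNA", "RC", "LTR", "LINE", "SINE")

#: Length of the full downstream/upstream flank in bp.
FLANK_BP = 2000
#: Length of the short (possible 3'UTR) downstream window in bp.
SHORT_DOWN_BP = 200

Interval = Tuple[int, int]


def merge_intervals(intervals: Sequence[Interval]) -> list[Interval]:
    """Merge overlapping/touching intervals into a sorted disjoint list."""
    if not intervals:
        return []
    ivs = sorted(intervals)
    out = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def total_length(intervals: Sequence[Interval]) -> int:
    """Total number of bases covered by the union of ``intervals``."""
    return sum(e - s for s, e in merge_intervals(intervals))


def intervals_overlap(a: Interval, b: Interval) -> bool:
    return a[0] < b[1] and b[0] < a[1]


@dataclass(frozen=True)
class GeneModel:
    """A strand-aware gene defined by its CDS (and exon) intervals.

    The *gene region* spans from the first CDS base to the last CDS base;
    flanking windows are measured from this region in transcriptional
    orientation.
    """

    gene_id: str
    chrom: str
    strand: str
    cds_intervals: Tuple[Interval, ...]
    exon_intervals: Tuple[Interval, ...] = ()
    chrom_length: Optional[int] = None

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r} for {self.gene_id}")
        if not self.cds_intervals:
            raise ValueError(f"gene {self.gene_id} has no CDS intervals")
        ivs = tuple(sorted(tuple(i) for i in self.cds_intervals))
        object.__setattr__(self, "cds_intervals", ivs)
        exons = tuple(sorted(tuple(i) for i in self.exon_intervals)) or ivs
        object.__setattr__(self, "exon_intervals", exons)
        for s, e in ivs:
            if e <= s:
                raise ValueError(f"empty CDS interval in {self.gene_id}")

    @property
    def gene_region(self) -> Interval:
        return (self.cds_intervals[0][0], self.cds_intervals[-1][1])

    @property
    def exonic_length(self) -> int:
        return total_length(self.exon_intervals)


@dataclass(frozen=True)
class TEAnnotation:
    """A typed transposable-element interval on a genome."""

    te_id: str
    chrom: str
    start: int
    end: int
    te_type: str
    strand: str = "+"

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(f"TE {self.te_id}: end <= start")
        if self.te_type not in TE_TYPES:
            raise ValueError(f"TE {self.te_id}: unknown type {self.te_type!r}")

    @property
    def interval(self) -> Interval:
        return (self.start, self.end)


@dataclass(frozen=True)
class OrthologPair:
    """A one-to-one ortholog pair with per-species total exonic lengths."""

    gene_a: str
    gene_b: str
    len_a: int
    len_b: int

    def __post_init__(self):
        if self.len_a <= 0 or self.len_b <= 0:
            raise ValueError(
                f"pair ({self.gene_a},{self.gene_b}): non-positive exonic length"
            )

    @property
    def mean_len(self) -> float:
        return (self.len_a + self.len_b) / 2.0


@dataclass(frozen=True)
class InsertionRecord:
    """One (gene, TE, region) hit; a TE may hit several regions and genes."""

    gene_id: str
    te_id: str
    te_type: str
    region: str
    species: str = ""

    def __post_init__(self):
        if self.region not in REGIONS:
            raise ValueError(f"unknown region {self.region!r}")
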