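"""Classification of TE insertions into six strand-aware gene-relative regions.

Regions are measured from the gene region (first CDS base to last CDS base):
2,000-bp upstream and downstream flanks, a 200-bp possible-3'UTR downstream
window and its 200-2,000-bp complement, introns (gaps between CDS intervals),
and the CDS itself.  Any >= 1 bp overlap between a TE and a region interval
yields a record; a TE straddling a boundary counts in every region it touches.
"""
from __future__ import annotations

import logging
from collections import defaultdict
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

from .models import (
    FLANK_BP,
    REGIONS,
    SHORT_DOWN_BP,
    GeneModel,
    InsertionRecord,
    Interval,
    TEAnnotation,
    intervals_overlap,
)

log = logging.getLogger(__name__)


def build_regions(gene: GeneModel) -> Dict[str, List[Interval]]:
    """Map region label -> interval list for one gene, strand-aware.

    Flanks are truncated at chromosome bounds only, never at neighboring
    genes.  Empty (fully truncated) intervals are omitted.
    """
    start, end = gene.gene_region
    lo = 0
    hi = gene.chrom_length if gene.chrom_length is not None else None

    def clip(s: int, e: int) -> Optional[Interval]:
        s = max(s, lo)
        if hi is not None:
            e = min(e, hi)
        return (s, e) if e > s else None

    if gene.strand == "+":
        up = clip(start - FLANK_BP, start)
        down = clip(end, end + FLANK_BP)
        down_short = clip(end, end + SHORT_DOWN_BP)
        down_rest = clip(end + SHORT_DOWN_BP, end + FLANK_BP)
    else:
        up = clip(end, end + FLANK_BP)
        down = clip(start - FLANK_BP, start)
        down_short = clip(start - SHORT_DOWN_BP, start)
        down_rest = clip(start - FLANK_BP, start - SHORT_DOWN_BP)

    introns = [
        (a_end, b_start)
        for (_, a_end), (b_start, _) in zip(
            gene.cds_intervals, gene.cds_intervals[1:]
        )
        if b_start > a_end
    ]

    regions: Dict[str, List[Interval]] = {
        "CDS": list(gene.cds_intervals),
        "UP2000": [up] if up else [],
        "INTRON": introns,
        "DOWN2000": [down] if down else [],
        "DOWN200": [down_short] if down_short else [],
        "DOWN200_2000": [down_rest] if down_rest else [],
    }
    return regions


def classify_te_insertions(
    genes: Iterable[GeneModel],
    tes: Iterable[TEAnnotation],
    species: str = "",
) -> List[InsertionRecord]:
    """Emit one record per (gene, te, region) with >= 1 bp overlap."""
    tes_by_chrom: Dict[str, List[TEAnnotation]] = defaultdict(list)
    for te in tes:
        tes_by_chrom[te.chrom].append(te)
    for lst in tes_by_chrom.values():
        lst.sort(key=lambda t: t.start)

    records: List[InsertionRecord] = []
    for gene in genes:
        chrom_tes = tes_by_chrom.get(gene.chrom)
        if not chrom_tes:
            continue
        regions = build_regions(gene)
        # search window covering every region interval of this gene
        g_lo = min(s for ivs in regions.values() for s, _ in ivs)
        g_hi = max(e for ivs in regions.values() for _, e in ivs)
        for te in chrom_tes:
            if te.end <= g_lo:
                continue
            if te.start >= g_hi:
                break
            for region in REGIONS:
                if any(
                    intervals_overlap(te.interval, iv) for iv in regions[region]
                ):
                    records.append(
                        InsertionRecord(
                            gene_id=gene.gene_id,
                            te_id=te.te_id,
                            te_type=te.te_type,
                            region=region,
                            species=species,
                        )
                    )
    return records


def species_specific_insertions(
    records_a: Sequence[InsertionRecord],
    records_b: Sequence[InsertionRecord],
    pairs: Sequence,
    region: str,
    te_type: str,
    conserved_filter: Optional[Set[str]] = None,
) -> Dict[str, Set[str]]:
    """Partition ortholog pairs by qualifying-insertion status.

    Returns ``{"only_A": ..., "only_B": ..., "both": ..., "neither": ...}``
    of pair ids (keyed by the species-A gene id).  A record qualifies when it
    matches ``region`` and ``te_type``; on the A side, when
    ``conserved_filter`` is given, only TE ids in that set qualify.
    """
    if region not in REGIONS:
        raise ValueError(f"unknown region {region!r}")

    has_a: Set[str] = set()
    for r in records_a:
        if r.region == region and r.te_type == te_type:
            if conserved_filter is not None and r.te_id not in conserved_filter:
                continue
            has_a.add(r.gene_id)
    has_b: Set[str] = {
        r.gene_id
        for r in records_b
        if r.region == region and r.te_type == te_type
    }

    out = {"only_A": set(), "only_B": set(), "both": set(), "neither": set()}
    for p in pairs:
        a, b = p.gene_a, p.gene_b
        in_a, in_b = a in has_a, b in has_b
        if in_a and in_b:
            out["both"].add(a)
        elif in_a:
            out["only_A"].add(a)
        elif in_b:
            out["only_B"].add(a)
        else:
            out["neither"].add(a)
    return out


def insertion_summary(
    records: Sequence[InsertionRecord],
) -> Dict[Tuple[str, str], int]:
    """Per (region, te_type) count of distinct genes with an insertion."""
    genes: Dict[Tuple[str, str], Set[str]] = defaultdict(set)
    for r in records:
        genes[(r.region, r.te_type)].add(r.gene_id)
    return {key: len(v) for key, v in sorted(genes.items())}
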