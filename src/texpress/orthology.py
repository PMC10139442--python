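"""One-to-one ortholog determination from pairwise similarity scores.

Pairs are reciprocal best hits by bitscore; a gene that is the best hit of
two or more genes of the other species is excluded as a putative duplicate.
Ties for a gene's best hit make that gene ambiguous and drop any pair it
would form.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

from .models import GeneModel, OrthologPair, total_length

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SimilarityRecord:
    gene_a: str
    gene_b: str
    bitscore: float

    def __post_init__(self):
        if self.bitscore < 0:
            raise ValueError("bitscore must be >= 0")


def aggregate_max(records: Iterable[SimilarityRecord]) -> List[SimilarityRecord]:
    """Collapse multiple HSPs per (gene_a, gene_b) to the maximum bitscore."""
    best: Dict[Tuple[str, str], float] = {}
    for r in records:
        key = (r.gene_a, r.gene_b)
        if key not in best or r.bitscore > best[key]:
            best[key] = r.bitscore
    return [SimilarityRecord(a, b, s) for (a, b), s in best.items()]


def _best_hits(records: Sequence[SimilarityRecord], side: str) -> Dict[str, str]:
    """Unique best hit per gene on ``side`` ('a' or 'b'); ties -> no best hit."""
    score: Dict[str, float] = {}
    hit: Dict[str, str] = {}
    tied: set[str] = set()
    for r in records:
        g, other = (r.gene_a, r.gene_b) if side == "a" else (r.gene_b, r.gene_a)
        if g not in score or r.bitscore > score[g]:
            score[g] = r.bitscore
            hit[g] = other
            tied.discard(g)
        elif r.bitscore == score[g] and hit.get(g) != other:
            tied.add(g)
    for g in tied:
        del hit[g]
    return hit


def reciprocal_best_pairs(
    records: Sequence[SimilarityRecord],
) -> List[Tuple[str, str]]:
    """Reciprocal-best pairs after multi-best exclusion, sorted by gene_a.

    Input records must be pre-aggregated (one row per gene pair); use
    :func:`aggregate_max` otherwise.
    """
    if not records:
        return []
    best_a = _best_hits(records, "a")
    best_b = _best_hits(records, "b")
    pairs = [
        (a, b) for a, b in best_a.items() if best_b.get(b) == a
    ]
    pairs = exclude_multi_best(pairs, records)
    return sorted(pairs)


def exclude_multi_best(
    pairs: Sequence[Tuple[str, str]], records: Sequence[SimilarityRecord]
) -> List[Tuple[str, str]]:
    """Drop pairs containing a gene that is the best hit of >= 2 genes.

    A gene popular among many genes of the other species likely has
    duplicated counterparts, so any pair involving it is removed.
    """
    best_a = _best_hits(records, "a")
    best_b = _best_hits(records, "b")
    hit_count_b: Dict[str, int] = {}
    for b in best_a.values():
        hit_count_b[b] = hit_count_b.get(b, 0) + 1
    hit_count_a: Dict[str, int] = {}
    for a in best_b.values():
        hit_count_a[a] = hit_count_a.get(a, 0) + 1
    kept = [
        (a, b)
        for a, b in pairs
        if hit_count_a.get(a, 0) < 2 and hit_count_b.get(b, 0) < 2
    ]
    dropped = len(pairs) - len(kept)
    if dropped:
        log.info("multi-best exclusion removed %d pair(s)", dropped)
    return kept


def attach_lengths(
    pairs: Sequence[Tuple[str, str]],
    genes_a: Mapping[str, GeneModel],
    genes_b: Mapping[str, GeneModel],
) -> List[OrthologPair]:
    """Attach per-species total exonic lengths (union of exon intervals)."""
    out = []
    for a, b in pairs:
        ga, gb = genes_a[a], genes_b[b]
        la = total_length(ga.exon_intervals)
        lb = total_length(gb.exon_intervals)
        for gid, length in ((a, la), (b, lb)):
            if length <= 0:
                raise ValueError(f"gene {gid} has zero exonic length")
        out.append(OrthologPair(a, b, la, lb))
    return out
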