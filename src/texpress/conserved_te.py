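"""Conserved-TE calling from boundary-spanning read evidence.

A reference-genome TE is present in a population when at least one read
alignment from a line of that population continuously covers >= 10 bp inside
and >= 10 bp outside one TE boundary, with fewer than 5 uncovered bases in
the 20-bp window.  A TE present in every population is conserved.
"""
from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from .models import Interval, TEAnnotation, merge_intervals

log = logging.getLogger(__name__)

#: Bases required on each side of a boundary.
WINDOW_HALF = 10
#: Maximum uncovered bases tolerated in the 20-bp window ("gap below 5 bp").
MAX_GAP = 4


@dataclass(frozen=True)
class MateAlignment:
    """One mate's aligned blocks (0-based half-open), or unmapped."""

    chrom: Optional[str]
    blocks: Tuple[Interval, ...] = ()

    @property
    def mapped(self) -> bool:
        return self.chrom is not None and len(self.blocks) > 0

    @property
    def extent(self) -> Interval:
        return (self.blocks[0][0], self.blocks[-1][1])


@dataclass(frozen=True)
class ReadPairAlignment:
    read_id: str
    line_id: str
    population: str
    mates: Tuple[MateAlignment, MateAlignment]
    proper_pair: bool = True
    unique: bool = True


@dataclass(frozen=True)
class BoundarySupport:
    te_id: str
    boundary: str  # "left" | "right"
    supported: bool
    uncovered_bp: int
    truncated: bool = False


@dataclass(frozen=True)
class ConservedCall:
    te_id: str
    presence: Dict[str, bool] = field(default_factory=dict)

    @property
    def conserved(self) -> bool:
        return bool(self.presence) and all(self.presence.values())


def _mate_in_repeats(mate: MateAlignment, merged: Sequence[Interval]) -> bool:
    """True when every aligned base of the mate lies inside repeat intervals."""
    for bs, be in mate.blocks:
        if not any(s <= bs and be <= e for s, e in merged):
            return False
    return True


def filter_read_pairs(
    pairs: Iterable[ReadPairAlignment],
    repeat_intervals: Mapping[str, Sequence[Interval]],
) -> List[ReadPairAlignment]:
    """Keep properly/uniquely mapped pairs with at least one mate outside repeats.

    Drops pairs with an unmapped mate and pairs whose both mates lie
    entirely within annotated repeat intervals.
    """
    merged = {c: merge_intervals(ivs) for c, ivs in repeat_intervals.items()}
    kept = []
    for p in pairs:
        if not (p.proper_pair and p.unique):
            continue
        if not all(m.mapped for m in p.mates):
            continue
        if all(
            _mate_in_repeats(m, merged.get(m.chrom, ())) for m in p.mates
        ):
            continue
        kept.append(p)
    return kept


def boundary_support(
    te: TEAnnotation, blocks: Sequence[Interval], boundary: str
) -> BoundarySupport:
    """Evaluate one mate alignment against one TE boundary.

    The window spans ``WINDOW_HALF`` bp on each side of the boundary; for TEs
    shorter than ``WINDOW_HALF`` the inside half is truncated to the TE
    extent (and the result flagged).  Supported iff the number of window
    positions not covered by the blocks is <= ``MAX_GAP``.
    """
    if boundary not in ("left", "right"):
        raise ValueError(f"boundary must be left|right, got {boundary!r}")
    te_len = te.end - te.start
    inside = min(WINDOW_HALF, te_len)
    truncated = inside < WINDOW_HALF
    if boundary == "left":
        win = (te.start - WINDOW_HALF, te.start + inside)
    else:
        win = (te.end - inside, te.end + WINDOW_HALF)

    covered = 0
    for bs, be in merge_intervals(blocks):
        covered += max(0, min(be, win[1]) - max(bs, win[0]))
    uncovered = (win[1] - win[0]) - covered
    return BoundarySupport(
        te_id=te.te_id,
        boundary=boundary,
        supported=uncovered <= MAX_GAP,
        uncovered_bp=uncovered,
        truncated=truncated,
    )


def call_population_presence(
    te: TEAnnotation,
    filtered_pairs: Sequence[ReadPairAlignment],
    min_lines: int = 1,
) -> bool:
    """Present iff >= ``min_lines`` lines contribute a mate supporting either boundary."""
    supporting_lines = set()
    for p in filtered_pairs:
        for mate in p.mates:
            if not mate.mapped or mate.chrom != te.chrom:
                continue
            for boundary in ("left", "right"):
                if boundary_support(te, mate.blocks, boundary).supported:
                    supporting_lines.add(p.line_id)
                    break
    return len(supporting_lines) >= min_lines


def conserved_set(
    tes: Sequence[TEAnnotation],
    alignments_by_population: Mapping[str, Sequence[ReadPairAlignment]],
    repeat_intervals: Optional[Mapping[str, Sequence[Interval]]] = None,
    min_lines: int = 1,
    prefiltered: bool = False,
) -> List[ConservedCall]:
    """Per-TE population-presence matrix and conserved calls.

    ``repeat_intervals`` defaults to the TE intervals themselves (the
    both-mates-inside-repeats filter).  Pass ``prefiltered=True`` to skip
    read-pair filtering.
    """
    if not alignments_by_population:
        raise ValueError("at least one population is required")
    if repeat_intervals is None:
        by_chrom: Dict[str, List[Interval]] = defaultdict(list)
        for te in tes:
            by_chrom[te.chrom].append(te.interval)
        repeat_intervals = by_chrom

    filtered: Dict[str, List[ReadPairAlignment]] = {}
    for pop, pairs in alignments_by_population.items():
        if not pairs:
            log.warning("population %s has zero reads; all TEs absent", pop)
            filtered[pop] = []
        else:
            filtered[pop] = (
                list(pairs)
                if prefiltered
                else filter_read_pairs(pairs, repeat_intervals)
            )

    # index TE boundaries per chromosome so each mate only visits nearby TEs
    by_chrom: Dict[str, List[int]] = defaultdict(list)
    for i, te in enumerate(tes):
        by_chrom[te.chrom].append(i)
    def _sorted_index(values: List[int], idx: List[int]):
        arr = np.array(values)
        order = np.argsort(arr, kind="stable")
        return arr[order], [idx[j] for j in order]

    starts = {
        c: _sorted_index([tes[i].start for i in idx], idx)
        for c, idx in by_chrom.items()
    }
    ends = {
        c: _sorted_index([tes[i].end for i in idx], idx)
        for c, idx in by_chrom.items()
    }

    support_lines: Dict[int, Dict[str, set]] = defaultdict(
        lambda: defaultdict(set)
    )
    for pop, pairs in filtered.items():
        for p in pairs:
            for mate in p.mates:
                if not mate.mapped or mate.chrom not in by_chrom:
                    continue
                ext_s, ext_e = mate.extent
                cand: set[int] = set()
                for arr, idx in (starts[mate.chrom], ends[mate.chrom]):
                    lo = np.searchsorted(arr, ext_s - WINDOW_HALF, side="left")
                    hi = np.searchsorted(arr, ext_e + WINDOW_HALF, side="right")
                    cand.update(idx[lo:hi])
                for i in cand:
                    te = tes[i]
                    if any(
                        boundary_support(te, mate.blocks, b).supported
                        for b in ("left", "right")
                    ):
                        support_lines[i][pop].add(p.line_id)

    calls = []
    for i, te in enumerate(tes):
        presence = {
            pop: len(support_lines[i][pop]) >= min_lines for pop in filtered
        }
        calls.append(ConservedCall(te_id=te.te_id, presence=presence))
    return calls


def conserved_te_ids(calls: Sequence[ConservedCall]) -> set[str]:
    return {c.te_id for c in calls if c.conserved}
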