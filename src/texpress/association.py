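"""TE-insertion x expression association: 2x2 tables, Fisher tests, BH.

Tables contrast ortholog pairs carrying a qualifying TE insertion only in
the focal species against pairs without the insertion in either species
(pairs with the insertion in both species, or only in the other species,
are excluded).  P-values are BH-corrected within a condition: one family
per (stage, focal species, direction), across region x TE-type tests.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
from scipy.stats import hypergeom

from .models import REGIONS, TE_TYPES
from .te_annotation import species_specific_insertions

log = logging.getLogger(__name__)

#: Relative tolerance when comparing table probabilities to the observed one.
_P_REL_TOL = 1e-7

# Regions whose universes require CDS cleanliness in both species.
_CDS_CLEAN_REGIONS = ("UP2000", "INTRON", "DOWN2000", "DOWN200")


@dataclass(frozen=True)
class ContingencyTable:
    n11: int
    n12: int
    n21: int
    n22: int

    def __post_init__(self):
        if min(self.n11, self.n12, self.n21, self.n22) < 0:
            raise ValueError("negative cell")

    @property
    def total(self) -> int:
        return self.n11 + self.n12 + self.n21 + self.n22

    def odds_ratio(self) -> float:
        a, b, c, d = self.n11, self.n12, self.n21, self.n22
        if 0 in (a, b, c, d):
            a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        return (a * d) / (b * c)


@dataclass
class ContingencyResult:
    table: ContingencyTable
    odds_ratio: float
    p: float
    q: float = math.nan
    stage: str = ""
    direction: str = ""
    focal_species: str = ""
    region: str = ""
    te_type: str = ""
    cluster: Optional[int] = None
    degenerate: bool = False


def fisher_exact(table: ContingencyTable) -> Tuple[float, float, bool]:
    """Two-sided Fisher's exact test on a 2x2 table.

    Fixing all margins, sums hypergeometric probabilities of every table at
    least as extreme (probability <= observed, with a small relative
    tolerance).  Returns ``(p, odds_ratio, degenerate)``; a zero margin makes
    the table degenerate with ``p = 1`` and ``odds_ratio = 1``.
    """
    a, b, c, d = table.n11, table.n12, table.n21, table.n22
    n = table.total
    r1 = a + b
    c1 = a + c
    if r1 == 0 or c1 == 0 or (c + d) == 0 or (b + d) == 0:
        return 1.0, 1.0, True
    lo = max(0, r1 + c1 - n)
    hi = min(r1, c1)
    support = np.arange(lo, hi + 1)
    probs = hypergeom.pmf(support, n, c1, r1)
    p_obs = probs[a - lo]
    p = float(probs[probs <= p_obs * (1 + _P_REL_TOL)].sum())
    return min(p, 1.0), table.odds_ratio(), False


def bh_adjust(pvalues: Sequence[float]) -> List[float]:
    """Benjamini-Hochberg adjusted p-values (NaN entries pass through)."""
    p = np.asarray(pvalues, dtype=float)
    q = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    m = pv.size
    if m == 0:
        return q.tolist()
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    q[ok] = out
    return q.tolist()


def build_universe(
    region: str,
    records_a: Sequence,
    records_b: Sequence,
    pairs: Sequence,
) -> Set[str]:
    """Pair-id universe for testing insertions in ``region``.

    CDS tests use all pairs.  Other regions require that neither species has
    any TE (of any type) overlapping the CDS; the 200-2,000-bp downstream
    region additionally excludes pairs where either species has any TE in
    the 0-200-bp downstream window.
    """
    if region not in REGIONS:
        raise ValueError(f"unknown region {region!r}")
    all_ids = {p.gene_a for p in pairs}
    if region == "CDS":
        return all_ids

    def genes_with(records, target_region):
        return {r.gene_id for r in records if r.region == target_region}

    cds_a = genes_with(records_a, "CDS")
    cds_b = genes_with(records_b, "CDS")
    b_to_a = {p.gene_b: p.gene_a for p in pairs}
    excluded = {a for a in all_ids if a in cds_a}
    excluded |= {b_to_a[b] for b in cds_b if b in b_to_a}
    if region == "DOWN200_2000":
        d200_a = genes_with(records_a, "DOWN200")
        d200_b = genes_with(records_b, "DOWN200")
        excluded |= {a for a in all_ids if a in d200_a}
        excluded |= {b_to_a[b] for b in d200_b if b in b_to_a}
    return all_ids - excluded


def build_te_deg_table(
    universe: Set[str],
    only_focal: Set[str],
    neither: Set[str],
    direction_set: Set[str],
) -> ContingencyTable:
    """Assemble the 2x2 table from pair-id sets.

    Rows: with-TE-only-in-focal vs without-TE-in-both (both restricted to
    the universe); columns: DEG-in-stated-direction vs other.
    """
    only_focal = only_focal & universe
    neither = neither & universe
    if only_focal & neither:
        raise ValueError("only_focal and neither overlap")
    if only_focal and not neither:
        raise ValueError("no comparison group: 'neither' set is empty")
    direction = direction_set
    return ContingencyTable(
        n11=len(only_focal & direction),
        n12=len(only_focal - direction),
        n21=len(neither & direction),
        n22=len(neither - direction),
    )


def _direction_sets(
    deg_results: Sequence, focal_species: str
) -> Dict[Tuple[str, str], Set[str]]:
    """(stage, higher|lower) -> pair ids DE in that direction for the focal species."""
    out: Dict[Tuple[str, str], Set[str]] = {}
    for r in deg_results:
        if r.direction == "ns":
            continue
        if focal_species == "A":
            word = "higher" if r.direction == "higher_in_A" else "lower"
        else:
            word = "higher" if r.direction == "higher_in_B" else "lower"
        out.setdefault((r.stage, word), set()).add(r.pair_id)
    return out


def run_te_deg_scan(
    deg_results: Sequence,
    records_a: Sequence,
    records_b: Sequence,
    pairs: Sequence,
    conserved_filter: Optional[Set[str]] = None,
    stages: Sequence[str] = ("L4", "YA"),
    directions: Sequence[str] = ("higher", "lower"),
    regions: Sequence[str] = REGIONS,
    te_types: Sequence[str] = TE_TYPES,
    focal_species: Sequence[str] = ("A", "B"),
) -> List[ContingencyResult]:
    """One Fisher test per (stage x direction x focal x region x te_type).

    BH correction is applied within each (stage, focal species, direction)
    family across the region x te_type tests.
    """
    results: List[ContingencyResult] = []
    universes = {
        region: build_universe(region, records_a, records_b, pairs)
        for region in regions
    }
    for focal in focal_species:
        dir_sets = _direction_sets(deg_results, focal)
        for region in regions:
            universe = universes[region]
            for te_type in te_types:
                parts = species_specific_insertions(
                    records_a,
                    records_b,
                    pairs,
                    region,
                    te_type,
                    conserved_filter=conserved_filter if focal == "A" else None,
                )
                only_focal = parts["only_A"] if focal == "A" else parts["only_B"]
                neither = parts["neither"]
                for stage in stages:
                    for direction in directions:
                        dset = dir_sets.get((stage, direction), set())
                        try:
                            table = build_te_deg_table(
                                universe, only_focal, neither, dset
                            )
                        except ValueError as exc:
                            log.warning(
                                "skipping %s/%s/%s/%s/%s: %s",
                                stage, direction, focal, region, te_type, exc,
                            )
                            table = ContingencyTable(0, 0, 0, 0)
                        if table.total == 0:
                            p, orat, degenerate = math.nan, math.nan, True
                            if not universe:
                                log.warning(
                                    "empty universe for region %s", region
                                )
                        else:
                            p, orat, degenerate = fisher_exact(table)
                        results.append(
                            ContingencyResult(
                                table=table,
                                odds_ratio=orat,
                                p=p,
                                stage=stage,
                                direction=direction,
                                focal_species=focal,
                                region=region,
                                te_type=te_type,
                                degenerate=degenerate,
                            )
                        )
    _apply_bh(results, key=lambda r: (r.stage, r.focal_species, r.direction))
    results.sort(
        key=lambda r: (r.stage, r.focal_species, r.direction, r.region, r.te_type)
    )
    return results


def _apply_bh(results: List[ContingencyResult], key) -> None:
    groups: Dict[Tuple, List[ContingencyResult]] = {}
    for r in results:
        groups.setdefault(key(r), []).append(r)
    for members in groups.values():
        qs = bh_adjust([r.p for r in members])
        for r, q in zip(members, qs):
            r.q = q


def run_cluster_te_scan(
    assignments: Mapping[str, int],
    records_a: Sequence,
    records_b: Sequence,
    pairs: Sequence,
    clusterable: Set[str],
    conserved_filter: Optional[Set[str]] = None,
    regions: Sequence[str] = REGIONS,
    te_types: Sequence[str] = TE_TYPES,
    focal_species: Sequence[str] = ("A", "B"),
) -> List[ContingencyResult]:
    """Cluster-membership x TE-insertion Fisher scan.

    For each (cluster, region, te_type, focal): rows = in-cluster vs
    out-of-cluster genes of the clusterable universe, columns =
    TE-only-in-focal vs without-TE-in-both; genes with the TE in both
    species (or only the other species) are excluded.  BH per focal species
    across the whole scan.
    """
    cluster_ids = sorted(set(assignments.values()))
    results: List[ContingencyResult] = []
    for focal in focal_species:
        for region in regions:
            universe = (
                build_universe(region, records_a, records_b, pairs) & clusterable
            )
            for te_type in te_types:
                parts = species_specific_insertions(
                    records_a,
                    records_b,
                    pairs,
                    region,
                    te_type,
                    conserved_filter=conserved_filter if focal == "A" else None,
                )
                only_focal = (
                    parts["only_A"] if focal == "A" else parts["only_B"]
                ) & universe
                neither = parts["neither"] & universe
                eligible = only_focal | neither
                for cid in cluster_ids:
                    in_cluster = {
                        g for g in eligible if assignments.get(g) == cid
                    }
                    table = ContingencyTable(
                        n11=len(in_cluster & only_focal),
                        n12=len(in_cluster & neither),
                        n21=len((eligible - in_cluster) & only_focal),
                        n22=len((eligible - in_cluster) & neither),
                    )
                    p, orat, degenerate = fisher_exact(table)
                    results.append(
                        ContingencyResult(
                            table=table,
                            odds_ratio=orat,
                            p=p,
                            focal_species=focal,
                            region=region,
                            te_type=te_type,
                            cluster=cid,
                            degenerate=degenerate,
                        )
                    )
    _apply_bh(results, key=lambda r: (r.focal_species,))
    results.sort(
        key=lambda r: (r.focal_species, r.cluster, r.region, r.te_type)
    )
    return results
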