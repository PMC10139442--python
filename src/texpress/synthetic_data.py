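"""Synthetic inputs with known ground truth for every pipeline stage.

Simulates a pair of genomes with one-to-one orthologous gene models (plus
decoy duplicates to exercise multi-best exclusion), TE insertions of five
types in six gene-relative regions with configurable species-specificity
and population conservation, negative-binomial counts with species/stage
effects, and read alignments that do or do not span TE boundaries.  Only
post-mapping structures are emulated; no nucleotide sequences.

All randomness flows from ``SimConfig.seed``: identical configs produce
byte-identical outputs.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .conserved_te import MateAlignment, ReadPairAlignment
from .models import REGIONS, TE_TYPES, GeneModel, TEAnnotation
from .orthology import SimilarityRecord
from .te_annotation import build_regions

log = logging.getLogger(__name__)

_GENES_PER_CHROM = 100
_GENE_SPACING = 1_000_000  # 1-Mb grid keeps default flanks collision-free


@dataclass
class SimConfig:
    seed: int = 0
    n_genes: int = 100
    n_samples_per_group: int = 4
    stages: Tuple[str, str] = ("L4", "YA")
    species: Tuple[str, str] = ("A", "B")
    nb_mean_log_range: Tuple[float, float] = (math.log(20), math.log(200))
    nb_dispersion: float = 0.05
    frac_deg: float = 0.2
    logfc_effect: float = 2.0
    stage_lfc_sd: float = 0.5
    te_rates: Dict[Tuple[str, str], Tuple[float, float]] = field(
        default_factory=dict
    )
    te_effect_beta: float = 1.0
    te_effect_target: Optional[Tuple[str, str]] = None
    n_populations: int = 8
    lines_per_population: int = 2
    read_length: int = 150
    conserved_fraction: float = 1.0
    decoy_fraction: float = 0.05
    crowding: bool = False
    length_asymmetry: float = 1.0
    lib_factor_sd: float = 0.1
    lib_factors: Optional[Dict[str, float]] = None
    te_deg_odds_ratio: Optional[float] = None
    te_deg_direction: str = "higher_in_A"

    def __post_init__(self):
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        if not 0 <= self.frac_deg <= 1:
            raise ValueError("frac_deg must be in [0, 1]")
        if not 0 <= self.conserved_fraction <= 1:
            raise ValueError("conserved_fraction must be in [0, 1]")
        for (region, te_type), rates in self.te_rates.items():
            if region not in REGIONS or te_type not in TE_TYPES:
                raise ValueError(f"bad te_rates key {(region, te_type)}")
            for r in rates:
                if not 0 <= r <= 1:
                    raise ValueError("insertion probabilities must be in [0,1]")


@dataclass
class GroundTruth:
    ortholog_map: Dict[str, str] = field(default_factory=dict)
    true_deg: Dict[str, Dict[str, str]] = field(default_factory=dict)
    te_placements_a: List[Tuple[str, str, str, str]] = field(
        default_factory=list
    )  # (gene_id, te_id, te_type, region)
    te_placements_b: List[Tuple[str, str, str, str]] = field(
        default_factory=list
    )
    conservation_map: Dict[str, Set[str]] = field(default_factory=dict)
    conserved_te_ids: Set[str] = field(default_factory=set)
    te_boost_genes: Set[str] = field(default_factory=set)


def _chrom_for(index: int, prefix: str) -> Tuple[str, int]:
    chrom = f"{prefix}chr{index // _GENES_PER_CHROM + 1}"
    base = (index % _GENES_PER_CHROM) * _GENE_SPACING + 10_000
    return chrom, base


def _make_gene(
    gene_id: str,
    chrom: str,
    base: int,
    strand: str,
    cds_lens: Sequence[int],
    intron_lens: Sequence[int],
    chrom_length: int,
) -> GeneModel:
    cds = []
    pos = base
    for i, length in enumerate(cds_lens):
        cds.append((pos, pos + length))
        pos += length
        if i < len(intron_lens):
            pos += intron_lens[i]
    return GeneModel(
        gene_id=gene_id,
        chrom=chrom,
        strand=strand,
        cds_intervals=tuple(cds),
        chrom_length=chrom_length,
    )


def simulate_genome_pair(
    config: SimConfig,
) -> Tuple[Dict[str, GeneModel], Dict[str, GeneModel], Dict[str, str]]:
    """Two gene sets on synthetic chromosomes plus the true ortholog map.

    ``n_genes`` true one-to-one pairs; decoy genes (two species-A genes
    sharing one species-B best hit) are appended to exercise multi-best
    exclusion.  Without crowding, adjacent gene regions sit on a 1-Mb grid
    so 2,000-bp flanks can never overlap a neighboring gene.
    """
    rng = np.random.default_rng(config.seed)
    spacing = 6000 if config.crowding else _GENE_SPACING
    chrom_length = _GENES_PER_CHROM * spacing + 200_000

    genes_a: Dict[str, GeneModel] = {}
    genes_b: Dict[str, GeneModel] = {}
    truth: Dict[str, str] = {}
    for i in range(config.n_genes):
        a_id = f"gA{i:05d}"
        b_id = f"gB{i:05d}"
        n_cds = int(rng.integers(2, 6))
        cds_lens = rng.integers(100, 300, size=n_cds)
        intron_lens = rng.integers(300, 800, size=n_cds - 1)
        strand = "+" if rng.random() < 0.5 else "-"
        chrom_a = f"Achr{i // _GENES_PER_CHROM + 1}"
        chrom_b = f"Bchr{i // _GENES_PER_CHROM + 1}"
        base = (i % _GENES_PER_CHROM) * spacing + 10_000
        genes_a[a_id] = _make_gene(
            a_id, chrom_a, base, strand, cds_lens, intron_lens, chrom_length
        )
        b_lens = np.maximum(
            30, np.rint(cds_lens * config.length_asymmetry).astype(int)
        )
        b_introns = rng.integers(300, 800, size=n_cds - 1)
        genes_b[b_id] = _make_gene(
            b_id, chrom_b, base, strand, b_lens, b_introns, chrom_length
        )
        truth[a_id] = b_id

    n_decoys = int(config.n_genes * config.decoy_fraction)
    for j in range(n_decoys):
        i = config.n_genes + j
        n_cds = int(rng.integers(2, 4))
        cds_lens = rng.integers(100, 300, size=n_cds)
        chrom_a = f"Achr{i // _GENES_PER_CHROM + 1}"
        chrom_b = f"Bchr{i // _GENES_PER_CHROM + 1}"
        base = (i % _GENES_PER_CHROM) * spacing + 10_000
        for copy in (1, 2):
            gid = f"gAdup{j:04d}_{copy}"
            genes_a[gid] = _make_gene(
                gid,
                chrom_a,
                base + (copy - 1) * (spacing // 2),
                "+",
                cds_lens,
                rng.integers(300, 800, size=n_cds - 1),
                chrom_length,
            )
        gid = f"gBdup{j:04d}"
        genes_b[gid] = _make_gene(
            gid,
            chrom_b,
            base,
            "+",
            cds_lens,
            rng.integers(300, 800, size=n_cds - 1),
            chrom_length,
        )
    return genes_a, genes_b, truth


def simulate_similarity_scores(
    config: SimConfig,
    genes_a: Mapping[str, GeneModel],
    genes_b: Mapping[str, GeneModel],
    ortholog_truth: Mapping[str, str],
) -> List[SimilarityRecord]:
    """Bitscore table whose reciprocal-best structure matches the truth.

    True pairs score highest mutually; decoy species-B genes are the best
    hit of both of their species-A duplicates, so the exclusion rule must
    remove them.  Low-score background hits are sprinkled in.
    """
    rng = np.random.default_rng(config.seed + 1)
    records: List[SimilarityRecord] = []
    b_ids = sorted(genes_b)
    for a_id, b_id in sorted(ortholog_truth.items()):
        records.append(SimilarityRecord(a_id, b_id, float(rng.uniform(800, 1500))))
        # background off-target hit
        other = b_ids[int(rng.integers(len(b_ids)))]
        if other != b_id:
            records.append(
                SimilarityRecord(a_id, other, float(rng.uniform(50, 300)))
            )
    dup_bs = sorted(g for g in genes_b if g.startswith("gBdup"))
    for b_id in dup_bs:
        j = b_id[len("gBdup"):]
        records.append(SimilarityRecord(f"gAdup{j}_1", b_id, 1000.0))
        records.append(SimilarityRecord(f"gAdup{j}_2", b_id, 990.0))
    return records


def _placement_probability(
    config: SimConfig,
    species_idx: int,
    region: str,
    te_type: str,
    base_rate: float,
    gene_is_target_deg: bool,
) -> float:
    if (
        config.te_deg_odds_ratio is None
        or species_idx != 0
        or not gene_is_target_deg
    ):
        return base_rate
    odds = config.te_deg_odds_ratio * base_rate / (1 - base_rate)
    return odds / (1 + odds)


def simulate_te_landscape(
    config: SimConfig,
    genes_a: Mapping[str, GeneModel],
    genes_b: Mapping[str, GeneModel],
    deg_truth: Optional[Mapping[str, str]] = None,
) -> Tuple[
    List[TEAnnotation],
    List[TEAnnotation],
    Dict[str, Set[str]],
    GroundTruth,
]:
    """Place TEs per ``te_rates`` and assign per-population conservation.

    Each planted TE lies strictly inside one interval of its intended
    region.  Region labels impossible for a gene (intron of a single-CDS
    gene, fully truncated flank) are skipped with a log entry.  When
    ``te_deg_odds_ratio`` is set, species-A insertions of the target
    region/type are enriched in genes whose true DEG direction matches
    ``te_deg_direction``.
    """
    rng = np.random.default_rng(config.seed + 2)
    populations = [f"pop{i+1}" for i in range(config.n_populations)]
    truth = GroundTruth()
    tes: Dict[str, List[TEAnnotation]] = {"A": [], "B": []}

    for sp_idx, (sp, genes) in enumerate((("A", genes_a), ("B", genes_b))):
        counter = 0
        for gene_id in sorted(genes):
            gene = genes[gene_id]
            regions = build_regions(gene)
            is_target = bool(
                deg_truth is not None
                and deg_truth.get(gene_id) == config.te_deg_direction
            )
            for (region, te_type), rates in sorted(config.te_rates.items()):
                p = _placement_probability(
                    config, sp_idx, region, te_type,
                    rates[sp_idx], is_target,
                )
                if rng.random() >= p:
                    continue
                ivs = [
                    iv for iv in regions.get(region, []) if iv[1] - iv[0] >= 30
                ]
                if not ivs:
                    log.info(
                        "cannot place %s TE in %s of %s: no interval",
                        te_type, region, gene_id,
                    )
                    continue
                iv = ivs[int(rng.integers(len(ivs)))]
                max_len = min(200, iv[1] - iv[0])
                te_len = int(rng.integers(30, max_len + 1))
                start = int(rng.integers(iv[0], iv[1] - te_len + 1))
                te_id = f"TE{sp}{counter:06d}"
                counter += 1
                te = TEAnnotation(
                    te_id=te_id,
                    chrom=gene.chrom,
                    start=start,
                    end=start + te_len,
                    te_type=te_type,
                )
                tes[sp].append(te)
                placement = (gene_id, te_id, te_type, region)
                if sp == "A":
                    truth.te_placements_a.append(placement)
                else:
                    truth.te_placements_b.append(placement)

    conservation: Dict[str, Set[str]] = {}
    for te in tes["A"]:
        if rng.random() < config.conserved_fraction:
            conservation[te.te_id] = set(populations)
        else:
            present = {p for p in populations if rng.random() < 0.5}
            if len(present) == len(populations) and populations:
                present.discard(
                    populations[int(rng.integers(len(populations)))]
                )
            conservation[te.te_id] = present
    truth.conservation_map = conservation
    truth.conserved_te_ids = {
        t for t, pops in conservation.items() if pops == set(populations)
    }

    if config.te_effect_beta != 1.0:
        target = config.te_effect_target
        truth.te_boost_genes = {
            g
            for g, _, tt, region in truth.te_placements_a
            if target is None or (region, tt) == target
        }
    return tes["A"], tes["B"], conservation, truth


def simulate_counts(
    config: SimConfig,
    ortholog_truth: Mapping[str, str],
    te_boost_genes: Optional[Set[str]] = None,
) -> Tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Negative-binomial counts with species/stage effects and library factors.

    Rows are pair ids (species-A gene ids); columns cover
    ``2 species x len(stages) x n_samples_per_group`` samples.  True DEGs
    (fraction ``frac_deg``, both stages, random direction) receive a
    ``2^logfc_effect`` species effect; TE-boosted genes are multiplied by
    ``te_effect_beta`` in species A.
    """
    if config.nb_dispersion < 0:
        raise ValueError("nb_dispersion must be >= 0")
    rng = np.random.default_rng(config.seed + 3)
    pair_ids = sorted(ortholog_truth)
    n = len(pair_ids)

    samples = []
    for sp in config.species:
        for stage in config.stages:
            for r in range(1, config.n_samples_per_group + 1):
                samples.append((f"{sp}_{stage}_r{r}", sp, stage, r))
    meta = pd.DataFrame(
        [(sp, st, r) for _, sp, st, r in samples],
        index=[s for s, *_ in samples],
        columns=["species", "stage", "replicate"],
    )

    base = np.exp(rng.uniform(*config.nb_mean_log_range, size=n))
    stage_lfc = rng.normal(0, config.stage_lfc_sd, size=n)

    truth = GroundTruth(ortholog_map=dict(ortholog_truth))
    deg_dir = np.zeros(n)
    if config.logfc_effect != 0 and config.frac_deg > 0:
        n_deg = int(round(config.frac_deg * n))
        idx = rng.choice(n, size=n_deg, replace=False)
        deg_dir[idx] = rng.choice([-1.0, 1.0], size=n_deg)
    for stage in config.stages:
        truth.true_deg[stage] = {
            pair_ids[i]: ("higher_in_A" if deg_dir[i] > 0 else "higher_in_B")
            for i in np.flatnonzero(deg_dir)
        }
    boost = np.array(
        [
            config.te_effect_beta
            if te_boost_genes and pair_ids[i] in te_boost_genes
            else 1.0
            for i in range(n)
        ]
    )
    truth.te_boost_genes = set(te_boost_genes or set())

    lib = {}
    for s, *_ in samples:
        if config.lib_factors and s in config.lib_factors:
            lib[s] = config.lib_factors[s]
        else:
            lib[s] = float(rng.lognormal(0, config.lib_factor_sd))

    counts = np.empty((n, len(samples)), dtype=np.int64)
    for j, (s, sp, stage, _) in enumerate(samples):
        mean = base.copy()
        if stage == config.stages[1]:
            mean = mean * 2.0**stage_lfc
        sp_sign = 1.0 if sp == "A" else -1.0
        mean = mean * 2.0 ** (sp_sign * deg_dir * config.logfc_effect / 2.0)
        if sp == "A":
            mean = mean * boost
        mean = mean * lib[s]
        if config.nb_dispersion == 0:
            counts[:, j] = rng.poisson(mean)
        else:
            r = 1.0 / config.nb_dispersion
            lam = rng.gamma(shape=r, scale=mean / r)
            counts[:, j] = rng.poisson(lam)
    df = pd.DataFrame(counts, index=pair_ids, columns=meta.index)
    return df, meta, truth


def simulate_population_reads(
    config: SimConfig,
    tes_a: Sequence[TEAnnotation],
    conservation_map: Mapping[str, Set[str]],
) -> Dict[str, List[ReadPairAlignment]]:
    """Boundary-evidence read pairs per population.

    Where a TE is present, one line contributes a properly-paired read whose
    mate continuously spans 20 bp across the left boundary.  Where absent,
    reads stop 5 bp short inside each boundary window (uncovered = 5, below
    the support threshold).  Decoy pairs (one unmapped mate; both mates
    inside a repeat) exercise the read-pair filter.
    """
    if config.read_length < 20:
        raise ValueError("read_length must be >= 20")
    populations = [f"pop{i+1}" for i in range(config.n_populations)]
    out: Dict[str, List[ReadPairAlignment]] = {p: [] for p in populations}
    counter = 0
    for te in tes_a:
        present_in = conservation_map.get(te.te_id, set())
        for pop in populations:
            line = f"{pop}_line1"
            if pop in present_in:
                mates = (
                    MateAlignment(te.chrom, ((te.start - 20, te.start + 20),)),
                    MateAlignment(te.chrom, ((te.end + 100, te.end + 160),)),
                )
            else:
                mates = (
                    MateAlignment(te.chrom, ((te.start - 60, te.start + 5),)),
                    MateAlignment(te.chrom, ((te.end - 5, te.end + 60),)),
                )
            out[pop].append(
                ReadPairAlignment(
                    read_id=f"rd{counter:08d}",
                    line_id=line,
                    population=pop,
                    mates=mates,
                )
            )
            counter += 1
    # decoys: filtered out before any boundary evaluation
    for pop in populations:
        line = f"{pop}_line1"
        if tes_a:
            te = tes_a[0]
            out[pop].append(
                ReadPairAlignment(
                    read_id=f"rd{counter:08d}",
                    line_id=line,
                    population=pop,
                    mates=(
                        MateAlignment(te.chrom, ((te.start - 500, te.start - 440),)),
                        MateAlignment(None),
                    ),
                )
            )
            counter += 1
            if te.end - te.start >= 60:
                out[pop].append(
                    ReadPairAlignment(
                        read_id=f"rd{counter:08d}",
                        line_id=line,
                        population=pop,
                        mates=(
                            MateAlignment(te.chrom, ((te.start + 5, te.start + 30),)),
                            MateAlignment(te.chrom, ((te.start + 10, te.start + 35),)),
                        ),
                    )
                )
                counter += 1
    return out


@dataclass
class SimBundle:
    config: SimConfig
    genes_a: Dict[str, GeneModel]
    genes_b: Dict[str, GeneModel]
    similarity: List[SimilarityRecord]
    tes_a: List[TEAnnotation]
    tes_b: List[TEAnnotation]
    counts: pd.DataFrame
    meta: pd.DataFrame
    reads: Dict[str, List[ReadPairAlignment]]
    truth: GroundTruth


def simulate_all(config: SimConfig) -> SimBundle:
    """Run every simulator stage in dependency order and merge the truth."""
    genes_a, genes_b, ortho = simulate_genome_pair(config)
    similarity = simulate_similarity_scores(config, genes_a, genes_b, ortho)

    # counts first: TE placement may depend on true DEG direction
    counts, meta, truth_counts = simulate_counts(config, ortho)
    deg_truth = truth_counts.true_deg.get(config.stages[0], {})
    tes_a, tes_b, conservation, truth_te = simulate_te_landscape(
        config, genes_a, genes_b, deg_truth=deg_truth
    )
    if truth_te.te_boost_genes:
        counts, meta, truth_counts = simulate_counts(
            config, ortho, te_boost_genes=truth_te.te_boost_genes
        )
    reads = simulate_population_reads(config, tes_a, conservation)

    truth = GroundTruth(
        ortholog_map=dict(ortho),
        true_deg=truth_counts.true_deg,
        te_placements_a=truth_te.te_placements_a,
        te_placements_b=truth_te.te_placements_b,
        conservation_map=conservation,
        conserved_te_ids=truth_te.conserved_te_ids,
        te_boost_genes=truth_te.te_boost_genes,
    )
    return SimBundle(
        config=config,
        genes_a=genes_a,
        genes_b=genes_b,
        similarity=similarity,
        tes_a=tes_a,
        tes_b=tes_b,
        counts=counts,
        meta=meta,
        reads=reads,
        truth=truth,
    )
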