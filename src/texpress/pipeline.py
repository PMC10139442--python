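"""End-to-end orchestration: simulate (or load) inputs, then run
orthology -> expression -> clustering -> TE annotation -> conserved-TE ->
association, writing fixed-name TSV outputs and a machine-readable run
report.  Idempotent for a fixed config and seed.
"""
from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import __version__
from . import association, clustering, conserved_te, expression, io, orthology
from . import synthetic_data, te_annotation

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    outdir: str = "texpress_run"
    seed: int = 0
    simulate: bool = True
    sim: synthetic_data.SimConfig = field(
        default_factory=lambda: synthetic_data.SimConfig(
            n_genes=2000,
            te_rates={("INTRON", "DNA"): (0.10, 0.10), ("UP2000", "LINE"): (0.05, 0.05)},
        )
    )
    # input paths when simulate is False
    counts_path: Optional[str] = None
    meta_path: Optional[str] = None
    similarity_path: Optional[str] = None
    genes_a_path: Optional[str] = None
    genes_b_path: Optional[str] = None
    tes_a_path: Optional[str] = None
    tes_b_path: Optional[str] = None
    alignments_path: Optional[str] = None
    alpha_deg: float = 1e-5
    alpha_assoc_report: float = 0.1
    kmax: int = 10
    gap_b: int = 30
    fixed_k: Optional[int] = None
    use_conserved_filter: bool = True
    min_lines: int = 1

    def __post_init__(self):
        if not (0 < self.alpha_deg < 1 and 0 < self.alpha_assoc_report < 1):
            raise ValueError("thresholds must lie in (0, 1)")
        if self.kmax < 1:
            raise ValueError("kmax must be >= 1")


def _write_truth(truth: synthetic_data.GroundTruth, path: Path) -> None:
    lines = ["kind\tkey\tvalue"]
    for stage in sorted(truth.true_deg):
        for g in sorted(truth.true_deg[stage]):
            lines.append(f"deg_{stage}\t{g}\t{truth.true_deg[stage][g]}")
    for g, te, tt, region in truth.te_placements_a:
        lines.append(f"te_A\t{te}\t{g}|{tt}|{region}")
    for g, te, tt, region in truth.te_placements_b:
        lines.append(f"te_B\t{te}\t{g}|{tt}|{region}")
    for te in sorted(truth.conserved_te_ids):
        lines.append(f"conserved\t{te}\t1")
    path.write_text("\n".join(lines) + "\n")


def run_all(config: PipelineConfig) -> Dict:
    """Execute every stage; returns the run report dict."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: Dict = {
        "version": __version__,
        "seed": config.seed,
        "counts": {},
    }

    # ------------------------------------------------------------ inputs
    if config.simulate:
        sim = dataclasses.replace(config.sim, seed=config.seed)
        bundle = synthetic_data.simulate_all(sim)
        io.write_gff3(bundle.genes_a, out / "genes_a.gff3")
        io.write_gff3(bundle.genes_b, out / "genes_b.gff3")
        io.write_bed6(bundle.tes_a, out / "tes_a.bed")
        io.write_bed6(bundle.tes_b, out / "tes_b.bed")
        io.write_repeatmasker_out(bundle.tes_a, out / "tes_a.out")
        io.write_similarity_tsv(bundle.similarity, out / "similarity.tsv")
        io.write_counts_tsv(bundle.counts, out / "counts.tsv")
        io.write_meta_tsv(bundle.meta, out / "sample_meta.tsv")
        io.write_alignment_tsv(bundle.reads, out / "alignments.tsv")
        _write_truth(bundle.truth, out / "ground_truth.tsv")
        genes_a, genes_b = bundle.genes_a, bundle.genes_b
        tes_a, tes_b = bundle.tes_a, bundle.tes_b
        similarity = bundle.similarity
        counts, meta = bundle.counts, bundle.meta
        reads = bundle.reads
    else:
        genes_a = io.read_gff3(config.genes_a_path)
        genes_b = io.read_gff3(config.genes_b_path)
        tes_a = io.read_bed6(config.tes_a_path)
        tes_b = io.read_bed6(config.tes_b_path)
        similarity = io.read_similarity_tsv(config.similarity_path)
        counts = io.read_counts_tsv(config.counts_path)
        meta = io.read_meta_tsv(config.meta_path)
        reads = (
            io.read_alignment_tsv(config.alignments_path)
            if config.alignments_path
            else {}
        )

    # ---------------------------------------------------------- orthology
    agg = orthology.aggregate_max(similarity)
    raw_pairs = orthology.reciprocal_best_pairs(agg)
    pairs = orthology.attach_lengths(raw_pairs, genes_a, genes_b)
    io.write_ortholog_tsv(pairs, out / "orthologs.tsv")
    report["counts"]["ortholog_pairs"] = len(pairs)

    pair_ids = [p.gene_a for p in pairs]
    counts = counts.loc[[g for g in counts.index if g in set(pair_ids)]]
    report["counts"]["count_genes"] = len(counts)

    # --------------------------------------------------------- expression
    stages = sorted(set(meta["stage"]))
    de_results: List[expression.DEResult] = []
    for stage in stages:
        de_results.extend(
            expression.call_degs(
                counts, meta, pairs, stage, alpha=config.alpha_deg
            )
        )
    de_df = pd.DataFrame(
        [
            (r.pair_id, r.stage, r.logFC, r.logCPM, r.p, r.q, r.direction)
            for r in de_results
        ],
        columns=["pair_id", "stage", "logFC", "logCPM", "p", "q", "direction"],
    )
    de_df.to_csv(out / "de_results.tsv", sep="\t", index=False, float_format="%.6g")
    report["counts"]["degs"] = int((de_df["direction"] != "ns").sum())
    report["counts"]["filtered_genes"] = int(de_df[de_df.stage == stages[0]]["p"].notna().sum())

    tpm = expression.compute_tpm(counts, pairs, meta)
    tpm.to_csv(out / "tpm.tsv", sep="\t", index_label="gene_id", float_format="%.6g")

    corrected = expression.length_correct(counts, pairs)
    cpm = expression.corrected_cpm(corrected)
    fractions, scores = expression.pca_variance_explained(np.log2(cpm + 1))
    pca_df = scores.copy()
    pca_df.to_csv(out / "pca_scores.tsv", sep="\t", index_label="sample_id", float_format="%.6g")
    (out / "pca_variance.tsv").write_text(
        "component\tfraction\n"
        + "\n".join(f"PC{i+1}\t{f:.6g}" for i, f in enumerate(fractions))
        + "\n"
    )

    # --------------------------------------------------------- clustering
    clusterable = clustering.select_clusterable_genes(tpm, de_results)
    report["counts"]["clusterable_genes"] = len(clusterable)
    assignments: Dict[str, int] = {}
    if len(clusterable) >= 2:
        profiles = clustering.zscore_profiles(tpm, clusterable, meta)
        kmax = min(config.kmax, len(profiles))
        assignments, gap = clustering.cluster_degs(
            profiles,
            kmax=kmax,
            b=config.gap_b,
            seed=config.seed,
            k=config.fixed_k,
        )
        pd.DataFrame(
            sorted(assignments.items()), columns=["pair_id", "cluster_id"]
        ).to_csv(out / "clusters.tsv", sep="\t", index=False)
        gap_df = pd.DataFrame(
            {
                "k": gap.k_values,
                "logW": gap.log_w,
                "E_logW": gap.e_log_w,
                "gap": gap.gap,
                "se": gap.se,
            }
        )
        gap_df["k_chosen"] = gap.k_chosen
        gap_df.to_csv(out / "gap_statistic.tsv", sep="\t", index=False, float_format="%.6g")
        report["counts"]["k_chosen"] = gap.k_chosen
    else:
        log.warning("fewer than 2 clusterable genes; skipping clustering")

    # ------------------------------------------------------ TE annotation
    records_a = te_annotation.classify_te_insertions(
        genes_a.values(), tes_a, species="A"
    )
    records_b = te_annotation.classify_te_insertions(
        genes_b.values(), tes_b, species="B"
    )
    for name, recs in (("insertions_a.tsv", records_a), ("insertions_b.tsv", records_b)):
        pd.DataFrame(
            [(r.gene_id, r.te_id, r.te_type, r.region) for r in recs],
            columns=["gene_id", "te_id", "te_type", "region"],
        ).to_csv(out / name, sep="\t", index=False)
    summary = te_annotation.insertion_summary(records_a)
    pd.DataFrame(
        [(reg, tt, n) for (reg, tt), n in summary.items()],
        columns=["region", "te_type", "n_genes"],
    ).to_csv(out / "insertion_summary.tsv", sep="\t", index=False)
    report["counts"]["insertion_records_a"] = len(records_a)
    report["counts"]["insertion_records_b"] = len(records_b)

    # ------------------------------------------------------- conserved TE
    conserved_filter = None
    if reads:
        calls = conserved_te.conserved_set(tes_a, reads, min_lines=config.min_lines)
        pops = sorted(reads)
        pd.DataFrame(
            [
                [c.te_id] + [int(c.presence.get(p, False)) for p in pops]
                for c in calls
            ],
            columns=["te_id"] + pops,
        ).to_csv(out / "presence_matrix.tsv", sep="\t", index=False)
        conserved_ids = conserved_te.conserved_te_ids(calls)
        io.write_bed6(
            [t for t in tes_a if t.te_id in conserved_ids],
            out / "conserved_tes.bed",
        )
        report["counts"]["conserved_tes"] = len(conserved_ids)
        if config.use_conserved_filter:
            conserved_filter = conserved_ids

    # -------------------------------------------------------- association
    scan = association.run_te_deg_scan(
        de_results,
        records_a,
        records_b,
        pairs,
        conserved_filter=conserved_filter,
        stages=stages,
    )
    scan_df = pd.DataFrame(
        [
            (
                r.stage, r.direction, r.focal_species, r.region, r.te_type,
                r.table.n11, r.table.n12, r.table.n21, r.table.n22,
                f"{r.table.n11}/{r.table.n11 + r.table.n12}",
                r.odds_ratio, r.p, r.q,
                bool(not math.isnan(r.q) and r.q < config.alpha_assoc_report),
            )
            for r in scan
        ],
        columns=[
            "stage", "direction", "focal_species", "region", "te_type",
            "n11", "n12", "n21", "n22", "deg_over_te", "odds_ratio", "p", "q",
            "reported",
        ],
    )
    scan_df.to_csv(out / "associations.tsv", sep="\t", index=False, float_format="%.6g")
    report["counts"]["association_tests"] = len(scan_df)

    if assignments:
        cscan = association.run_cluster_te_scan(
            assignments,
            records_a,
            records_b,
            pairs,
            clusterable,
            conserved_filter=conserved_filter,
        )
        pd.DataFrame(
            [
                (
                    r.cluster, r.focal_species, r.region, r.te_type,
                    r.table.n11, r.table.n12, r.table.n21, r.table.n22,
                    r.odds_ratio, r.p, r.q,
                )
                for r in cscan
            ],
            columns=[
                "cluster", "focal_species", "region", "te_type",
                "n11", "n12", "n21", "n22", "odds_ratio", "p", "q",
            ],
        ).to_csv(out / "cluster_associations.tsv", sep="\t", index=False, float_format="%.6g")
        report["counts"]["cluster_association_tests"] = len(cscan)

    report_path = out / "report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return report
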