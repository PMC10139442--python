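"""Readers and writers for the pipeline's on-disk formats.

GFF3 is 1-based inclusive on disk and converted to 0-based half-open on
read.  BED6 is native 0-based half-open.  The RepeatMasker ``.out`` reader
handles the 15-column whitespace dialect with its two header lines.  All
writers emit deterministic, byte-stable output.
"""
from __future__ import annotations

import logging
from collections import defaultdict
from pathlib import Path
from typing import Dict, List, Mapping, Sequence, Tuple

import pandas as pd

from .conserved_te import MateAlignment, ReadPairAlignment
from .models import GeneModel, OrthologPair, TEAnnotation
from .orthology import SimilarityRecord

log = logging.getLogger(__name__)

_RM_CLASS_MAP = {
    "DNA": "DNA",
    "RC": "RC",
    "LTR": "LTR",
    "LINE": "LINE",
    "SINE": "SINE",
}


# ---------------------------------------------------------------------- GFF3

def write_gff3(genes: Mapping[str, GeneModel], path: str | Path) -> None:
    lines = ["##gff-version 3"]
    for gene_id in sorted(genes):
        g = genes[gene_id]
        start, end = g.gene_region
        lines.append(
            "\t".join(
                [
                    g.chrom, "texpress", "gene", str(start + 1), str(end),
                    ".", g.strand, ".", f"ID={gene_id}",
                ]
            )
        )
        mrna_id = f"{gene_id}.t1"
        lines.append(
            "\t".join(
                [
                    g.chrom, "texpress", "mRNA", str(start + 1), str(end),
                    ".", g.strand, ".", f"ID={mrna_id};Parent={gene_id}",
                ]
            )
        )
        for kind, ivs in (("exon", g.exon_intervals), ("CDS", g.cds_intervals)):
            for i, (s, e) in enumerate(ivs, 1):
                frame = "0" if kind == "CDS" else "."
                lines.append(
                    "\t".join(
                        [
                            g.chrom, "texpress", kind, str(s + 1), str(e),
                            ".", g.strand, frame,
                            f"ID={mrna_id}.{kind.lower()}{i};Parent={mrna_id}",
                        ]
                    )
                )
    Path(path).write_text("\n".join(lines) + "\n")


def _parse_attrs(field: str) -> Dict[str, str]:
    out = {}
    for item in field.strip().split(";"):
        if "=" in item:
            k, v = item.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_gff3(path: str | Path) -> Dict[str, GeneModel]:
    """Parse gene models (gene/mRNA/exon/CDS with ID/Parent attributes)."""
    gene_meta: Dict[str, Tuple[str, str]] = {}
    mrna_parent: Dict[str, str] = {}
    cds: Dict[str, List[Tuple[int, int]]] = defaultdict(list)
    exons: Dict[str, List[Tuple[int, int]]] = defaultdict(list)
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        f = line.split("\t")
        if len(f) != 9:
            continue
        chrom, _, kind, start, end, _, strand, _, attrs = f
        a = _parse_attrs(attrs)
        iv = (int(start) - 1, int(end))
        if kind == "gene":
            gene_meta[a["ID"]] = (chrom, strand)
        elif kind == "mRNA":
            mrna_parent[a["ID"]] = a["Parent"]
        elif kind in ("CDS", "exon"):
            parent = a.get("Parent", "")
            gene_id = mrna_parent.get(parent, parent)
            (cds if kind == "CDS" else exons)[gene_id].append(iv)
    genes = {}
    for gene_id, (chrom, strand) in gene_meta.items():
        if not cds.get(gene_id):
            log.warning("gene %s has no CDS features; skipped", gene_id)
            continue
        genes[gene_id] = GeneModel(
            gene_id=gene_id,
            chrom=chrom,
            strand=strand,
            cds_intervals=tuple(sorted(cds[gene_id])),
            exon_intervals=tuple(sorted(exons.get(gene_id, []))),
        )
    return genes


# ----------------------------------------------------------------------- TEs

def write_bed6(tes: Sequence[TEAnnotation], path: str | Path) -> None:
    rows = [
        f"{t.chrom}\t{t.start}\t{t.end}\t{t.te_id}|{t.te_type}\t0\t{t.strand}"
        for t in sorted(tes, key=lambda t: (t.chrom, t.start, t.te_id))
    ]
    Path(path).write_text("\n".join(rows) + ("\n" if rows else ""))


def read_bed6(path: str | Path) -> List[TEAnnotation]:
    tes = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith(("#", "track", "browser")):
            continue
        f = line.split("\t")
        name = f[3]
        te_id, _, te_type = name.partition("|")
        tes.append(
            TEAnnotation(
                te_id=te_id,
                chrom=f[0],
                start=int(f[1]),
                end=int(f[2]),
                te_type=te_type or "DNA",
                strand=f[5] if len(f) > 5 else "+",
            )
        )
    return tes


def write_repeatmasker_out(
    tes: Sequence[TEAnnotation], path: str | Path
) -> None:
    """Emit the classic 15-column whitespace ``.out`` dialect."""
    header = (
        "   SW  perc perc perc  query      position in query           matching"
        "       repeat              position in  repeat\n"
        "score  div. del. ins.  sequence    begin     end    (left)    repeat"
        "         class/family         begin  end (left)   ID\n\n"
    )
    rows = []
    for i, t in enumerate(
        sorted(tes, key=lambda t: (t.chrom, t.start, t.te_id)), 1
    ):
        strand = "+" if t.strand == "+" else "C"
        rows.append(
            f"  500  10.0  1.0  1.0  {t.chrom}  {t.start + 1}  {t.end}  (0)  "
            f"{strand}  {t.te_id}  {_RM_CLASS_MAP[t.te_type]}/synthetic  "
            f"1  {t.end - t.start}  (0)  {i}"
        )
    Path(path).write_text(header + "\n".join(rows) + ("\n" if rows else ""))


def read_repeatmasker_out(path: str | Path) -> List[TEAnnotation]:
    """Parse RepeatMasker ``.out`` (15/16 whitespace-separated columns).

    The TE type is the class before the first ``/`` of the class/family
    column; unknown classes are skipped with a log entry.
    """
    tes = []
    for line in Path(path).read_text().splitlines():
        f = line.split()
        if len(f) < 15 or not f[0].lstrip("-").isdigit():
            continue
        chrom, begin, end = f[4], int(f[5]), int(f[6])
        strand = "+" if f[8] == "+" else "-"
        repeat_name = f[9]
        te_class = f[10].split("/")[0]
        if te_class not in _RM_CLASS_MAP:
            log.info("skipping non-TE repeat class %s", te_class)
            continue
        tes.append(
            TEAnnotation(
                te_id=repeat_name,
                chrom=chrom,
                start=begin - 1,
                end=end,
                te_type=te_class,
                strand=strand,
            )
        )
    return tes


# ----------------------------------------------------------------------- TSV

def write_similarity_tsv(
    records: Sequence[SimilarityRecord], path: str | Path
) -> None:
    lines = ["gene_a\tgene_b\tbitscore"]
    for r in sorted(records, key=lambda r: (r.gene_a, r.gene_b, -r.bitscore)):
        lines.append(f"{r.gene_a}\t{r.gene_b}\t{r.bitscore:.6g}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_similarity_tsv(path: str | Path) -> List[SimilarityRecord]:
    df = pd.read_csv(path, sep="\t")
    return [
        SimilarityRecord(r.gene_a, r.gene_b, float(r.bitscore))
        for r in df.itertuples()
    ]


def write_ortholog_tsv(pairs: Sequence[OrthologPair], path: str | Path) -> None:
    lines = ["gene_a\tgene_b\tlen_a\tlen_b\tmean_len"]
    for p in sorted(pairs, key=lambda p: p.gene_a):
        lines.append(
            f"{p.gene_a}\t{p.gene_b}\t{p.len_a}\t{p.len_b}\t{p.mean_len:g}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_ortholog_tsv(path: str | Path) -> List[OrthologPair]:
    df = pd.read_csv(path, sep="\t")
    return [
        OrthologPair(r.gene_a, r.gene_b, int(r.len_a), int(r.len_b))
        for r in df.itertuples()
    ]


def write_counts_tsv(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")


def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")


def write_meta_tsv(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", index_label="sample_id")


def read_meta_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample_id")


# ------------------------------------------------------------- read pairs

def write_alignment_tsv(
    reads: Mapping[str, Sequence[ReadPairAlignment]], path: str | Path
) -> None:
    """One row per mate: blocks as comma-separated ``start-end`` spans."""
    lines = [
        "read_id\tmate\tline_id\tpopulation\tchrom\tblocks\tproper_pair\tunique"
    ]
    for pop in sorted(reads):
        for pair in reads[pop]:
            for mate_no, mate in enumerate(pair.mates, 1):
                if mate.mapped:
                    chrom = mate.chrom
                    blocks = ",".join(f"{s}-{e}" for s, e in mate.blocks)
                else:
                    chrom, blocks = ".", "."
                lines.append(
                    "\t".join(
                        [
                            pair.read_id, str(mate_no), pair.line_id, pop,
                            chrom, blocks,
                            "1" if pair.proper_pair else "0",
                            "1" if pair.unique else "0",
                        ]
                    )
                )
    Path(path).write_text("\n".join(lines) + "\n")


def read_alignment_tsv(
    path: str | Path,
) -> Dict[str, List[ReadPairAlignment]]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    out: Dict[str, List[ReadPairAlignment]] = defaultdict(list)
    for (read_id, pop), grp in df.groupby(["read_id", "population"], sort=False):
        mates: List[MateAlignment] = []
        for _, row in grp.sort_values("mate").iterrows():
            if row["chrom"] == "." or row["blocks"] == ".":
                mates.append(MateAlignment(None))
            else:
                blocks = tuple(
                    tuple(map(int, b.split("-")))
                    for b in row["blocks"].split(",")
                )
                mates.append(MateAlignment(row["chrom"], blocks))
        while len(mates) < 2:
            mates.append(MateAlignment(None))
        first = grp.iloc[0]
        out[pop].append(
            ReadPairAlignment(
                read_id=read_id,
                line_id=first["line_id"],
                population=pop,
                mates=(mates[0], mates[1]),
                proper_pair=first["proper_pair"] == "1",
                unique=first["unique"] == "1",
            )
        )
    return dict(out)
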