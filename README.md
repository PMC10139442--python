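# texpress

A tested, reusable pipeline linking transposable-element (TE) insertions to
interspecific gene-expression differences between two closely related
species.  It covers:

- **orthology** — one-to-one ortholog pairs from pairwise bitscores
  (reciprocal best hits, with genes that are the best hit of several genes
  excluded as putative duplicates), plus per-species total exonic lengths;
- **expression** — counts corrected by each pair's mean exonic length, a
  1-corrected-CPM-in-all-samples low-expression filter, TMM library
  scaling, a common-dispersion negative-binomial exact test per
  developmental stage with BH correction (default threshold q < 1e-5),
  TPM computation, and sample PCA;
- **clustering** — k-means on per-gene Z-scored condition-mean TPM
  profiles, with the number of clusters chosen by the gap statistic
  (uniform-box reference, one-standard-error rule);
- **te_annotation** — classification of TE insertions (DNA / RC / LTR /
  LINE / SINE) into six strand-aware gene-relative regions: CDS, 2,000-bp
  upstream, intron, 2,000-bp downstream, 0–200-bp downstream, and
  200–2,000-bp downstream of the CDS-delimited gene region;
- **conserved_te** — calling a reference TE present in a population when a
  single read continuously covers ≥ 10 bp inside and ≥ 10 bp outside a TE
  boundary with < 5 uncovered bases in the 20-bp window, after dropping
  read pairs with an unmapped mate or with both mates inside repeats;
  a TE present in every population is conserved;
- **association** — 2×2 Fisher's exact tests contrasting genes with a TE
  insertion only in the focal species against genes without it in either
  species, per (stage × direction × region × TE type), with BH correction
  per condition; plus cluster-membership × TE scans;
- **synthetic_data** — a simulator that generates every pipeline input
  (GFF3 gene models, BED/RepeatMasker TE annotations, NB count matrices,
  boundary-spanning read alignments) with known ground truth, so each
  stage is testable offline.

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the oracle-agreement and
simulation-recovery criteria (exact-integer Fisher enumeration, per-base
interval labeling, per-position boundary counting, exhaustive 2^8
conservation patterns, NB-exact-test convolution oracle, null/power
simulations, gap-statistic recovery).

## Run

One-command synthetic demo:

```sh
texpress run-all --simulate --seed 7 --n-genes 2000 --outdir demo_run
```

Stage-by-stage on files:

```sh
texpress simulate --seed 7 --n-genes 500 --outdir inputs
texpress orthologs --similarity inputs/similarity.tsv \
    --genes-a inputs/genes_a.gff3 --genes-b inputs/genes_b.gff3 --out orth.tsv
texpress de --counts inputs/counts.tsv --meta inputs/sample_meta.tsv \
    --orthologs orth.tsv --stage L4 --alpha 1e-5 --out de.tsv
texpress annotate --genes inputs/genes_a.gff3 --tes inputs/tes_a.bed --out ins_a.tsv
texpress conserved --tes inputs/tes_a.bed --alignments inputs/alignments.tsv --out cons.tsv
texpress cluster --tpm demo_run/tpm.tsv --de demo_run/de_results.tsv \
    --meta inputs/sample_meta.tsv --kmax 20 --b 100 --out clusters.tsv
texpress associate --de demo_run/de_results.tsv \
    --insertions-a demo_run/insertions_a.tsv --insertions-b demo_run/insertions_b.tsv \
    --orthologs orth.tsv --out assoc.tsv
```

All outputs are plain TSV/BED/GFF3; the run directory also contains a
`report.json` with per-stage row counts.  Identical config + seed give
byte-identical outputs.

## Coordinates and conventions

- Internally all intervals are 0-based half-open; GFF3 is converted at the
  I/O boundary, BED is native.
- Flanks are strand-aware (upstream = 5′ of the first CDS) and truncated
  only at chromosome ends.
- A TE overlapping a region by ≥ 1 bp counts as inserted there; a TE may
  hit several regions and genes.
- Odds ratios are sample cross-product ratios with a Haldane–Anscombe
  +0.5 correction only when a cell is zero.
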