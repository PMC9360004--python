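# ribostress

Analysis of paired mRNA-seq and Ribo-seq count data from an acute-to-chronic
ER-stress time course in insulin-secreting β cells, together with a synthetic
data generator that plants a known ground truth for every stage.

Cells stressed briefly (condition `CPA1`) or repeatedly over days (`CPA18`)
reprogram both their transcriptome and their translatome relative to control
(`CON`). Given transcript-level counts from the two assays, the package:

1. normalizes counts to RPKM and applies a strict detection filter
   (RPKM > 0 in every replicate of every condition, in both assays);
2. computes per-condition **ribosome occupancy** (mean Ribo-seq RPKM divided
   by mean mRNA-seq RPKM), a proxy for translation efficiency;
3. computes **L2DE** (log2 ratio of replicate-mean RPKM) for the acute
   (`CPA1/CON`), chronic (`CPA18/CPA1`) and overall (`CPA18/CON`) contrasts;
4. classifies transcripts into temporal classes **G1–G6** (mRNA abundance)
   and **G7–G12** (occupancy) at a 0.32 log2 cutoff, and into four
   **regulation modes** (`up_both`, `up_occ_only`, `down_both`,
   `down_occ_only`) at a 0.6 log2 cutoff (2^0.6 ≈ 1.52-fold);
5. derives gene sets: a cell-type-specific **regulome** (changed genes minus
   genes changing the same way in a reference cell type) and a pathway
   **adaptome** (abundance- or translation-upregulated pathway genes, split
   by overlap with the reference), with hypergeometric enrichment and a
   Mann–Whitney + Benjamini–Hochberg cohort comparison;
6. runs Ribo-seq frame QC: P-site offsetting of footprint 5′ ends, reading
   frame distribution relative to the CDS, and a CDS enrichment ratio.

## Worked example

Generate a synthetic dataset with planted truth and run the full pipeline:

```sh
ribostress simulate --outdir demo/fx --n-genes 500 --seed 3
cat > demo/config.yaml <<EOF
mrna_counts: demo/fx/mrna_counts.tsv
mrna_meta: demo/fx/mrna_meta.tsv
ribo_counts: demo/fx/ribo_counts.tsv
ribo_meta: demo/fx/ribo_meta.tsv
gene_model: demo/fx/gene_model.tsv
footprints: demo/fx/footprints.tsv
pathways: demo/fx/pathways.gmt
outdir: demo/out
EOF
ribostress run --config demo/config.yaml
```

The run prints, among other stages:

```
ribostress INFO stage genesets: adaptome of 43 genes from pathway 'ER_PROTEIN_PROCESSING_SYNTHETIC'
ribostress INFO stage qc: 10000 reads counted, frame0 fraction 0.849
pipeline outputs in demo/out
```

and `demo/out/summary.tsv` begins:

```
channel	label	n
abundance_group	G1	19
abundance_group	G2	28
abundance_group	G3	37
...
mode[overall]	up_both	32
```

Other outputs: per-sample RPKM tables, the occupancy table, long-format
L2DE values, per-transcript assignments and modes, the regulome/adaptome
tables, enrichment p-values, frame QC metrics, and `provenance.json` with
the configuration hash. Re-running the same config reproduces every file
byte-for-byte. Stage subcommands (`normalize`, `classify`, `genesets`,
`qc`) run prefixes of the pipeline.

Python API equivalents live in `ribostress` (see `ribostress.pipeline.run_pipeline`
and the module docstrings).

## Synthetic data and ground truth

`ribostress simulate` (or `ribostress.synthetic.write_fixture`) writes count
tables, sample metadata, a gene model, footprints, pathway sets and a
`truth.tsv` with every planted label and effect size. Counts are negative
binomial (variance μ + αμ²; α = 0 gives exact rounded means, so the pipeline
recovers 100% of planted labels noise-free). Because RPKM is compositional,
the generator plants effects mass-neutrally — classes in mirror pairs plus a
small set of dominant insulin-like transcripts that absorb the residual mass
imbalance exactly — so realized log2 contrasts equal the planted effects;
see `docs/methods.md`.

## Reproducing results

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

reports, for the generated 2000-transcript dataset at dispersion 0.05:
abundance-class recovery 0.928 (n = 472 planted), occupancy-class recovery
0.777 (n = 485), regulation-mode recovery 0.933, noise-free recovery 1.0 in
both channels, recovered frame-0 fraction 0.8532 against a planted 0.85,
zero significant genes in a null cohort at FDR ≤ 10⁻³ and full recall of a
planted −1 log2 cohort shift. All quantities derive from `--seed`; nothing
is read from outside the repository.
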