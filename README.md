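# funcprior

Prioritize GWAS variants by combining functional-annotation evidence with
association evidence in a Bayesian framework.

A class-weighted elastic-net logistic regression is trained to predict
GWAS-hit status from functional annotations (transcription-factor binding,
DNase hypersensitivity, histone marks, eQTLs, conservation scores, ...).
Because hits and non-hits are weighted to equal total mass, the fitted odds
of a variant — score / (1 − score) — serve directly as an annotation Bayes
factor (BF_annot).  Multiplying BF_annot with a Wakefield approximate Bayes
factor computed from association summary statistics (BF_assoc) re-ranks
variants using both sources of evidence.

## What is in the package

| module                  | role |
|-------------------------|------|
| `funcprior.annotation`  | variant universe (MHC / sex-chromosome exclusion), hit/non-hit labelling at two significance tiers, annotation matrix from BED / score tracks, LD-proxy max-propagation, clumped vs separated feature collapsing |
| `funcprior.enrichment`  | per-feature Fisher exact tests, odds ratios with Woolf CIs, feature correlation matrices, mean annotation scores, LD pruning |
| `funcprior.model`       | class weights, stratified 60/40 and nested 70/30 splits, (alpha, lambda) tuning by cross-validated weighted deviance, elastic-net fitting by IRLS + coordinate descent, probability prediction |
| `funcprior.bayes`       | BF_annot from scores, Wakefield BF_assoc (log-space safe), evidence combination, rank computation, rank-improvement evaluation with p-value-matched random control sets |
| `funcprior.evaluation`  | ROC/AUC (Mann–Whitney form), PPV at score thresholds with a minimum-hit rule, class score histograms, score-stratified QQ statistics |
| `funcprior.synthetic`   | generators with known ground truth: correlated binary/quantitative annotations (latent-Gaussian threshold model), logistic hit labels, LD-proxy graphs, GWAS summary statistics |

## Command-line usage

```bash
# generate a synthetic universe with known truth
funcprior simulate --config sim.json --out simdata/

# or build the matrix from real-format inputs
funcprior annotate --manifest manifest.tsv --ld ld.tsv --tracks tracks/ \
    --clump clumped --out matrix.tsv
funcprior label --manifest manifest.tsv --catalog catalog.tsv --ld ld.tsv \
    --tier strong --out labels.tsv

# enrichment statistics (hits vs non-hits)
funcprior enrich --matrix matrix.tsv --labels labels.tsv --out enrichment.tsv

# train, predict, combine with association evidence
funcprior fit --matrix matrix.tsv --labels labels.tsv --scheme simple_60_40 \
    --folds 10 --seed 1 --out model/
funcprior predict --model model/ --matrix matrix.tsv --out scores.tsv
funcprior bayes --scores scores.tsv --sumstats gwas.tsv --prior-sd 0.2 --out bf.tsv

# evaluation
funcprior evaluate --scores scores.tsv --labels labels.tsv --out eval/
funcprior qq --scores scores.tsv --sumstats gwas.tsv --bins 5 --out qq/
funcprior rankcheck --bf bf.tsv --hits hits.txt --sumstats gwas.tsv \
    --ld ld.tsv --n-sets 12 --seed 1
```

Input formats are plain TSV: array manifest (`id, chrom, pos`), hit catalog
(`id, p_value[, phenotype]`), LD table (`id_a, id_b, r2`; PLINK `.ld`
headers accepted), summary statistics (`id, beta, se[, p]`), binary tracks
as BED, quantitative tracks as `chrom, start, end, score` blocks or
per-SNP `id, score` tables.

## Conventions

- Coordinates are 1-based inclusive internally; BED input is converted on
  read.  The MHC region (chr6:29,624,809–33,160,245, build 37) and the sex
  chromosomes are excluded by default.
- Hit tiers: `weak` = p < 1e-5, `strong` = p < 5e-8; LD proxies use
  r² ≥ 0.8 (inclusive).
- All randomness flows from explicit seeds; identical seeds give
  byte-identical TSV outputs.
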