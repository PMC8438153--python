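# icipattern

Immune-cell-infiltration (ICI) scoring of tumor expression cohorts.

Bulk tumor expression mixes cancer cells with the immune and stromal cells of
the tumor microenvironment (TME). The composition of that infiltrate carries
prognosis and predicts response to checkpoint-blockade immunotherapy, but it
varies patient to patient. `icipattern` implements a complete workflow that
turns a gene-by-sample expression matrix, a clinical table and a mutation
table into a per-sample infiltration score and its downstream survival and
mutation-burden associations:

1. **Preprocessing** — FPKM→TPM conversion, log2(TPM+1), and parametric
   empirical-Bayes batch correction (ComBat) when cohorts are merged.
2. **TME quantification** — CIBERSORT-style ν-support-vector-regression
   deconvolution of cell-type fractions against a signature matrix, plus
   ssGSEA immune and stroma scores (ESTIMATE-style).
3. **ICI subtypes** — resampling consensus clustering (default 1000 × 90%
   subsamples, PAM) of the per-sample TME features, with the number of
   clusters chosen from the CDF/delta-area curve.
4. **Signatures** — moderated-*t* differential expression between subtypes
   (BH-adjusted p < 0.05, fold change ≥ 1.65), a second consensus clustering
   on DEG expression (500 × 90%, Spearman/PAM) into gene clusters, and a
   Pearson-sign split of the DEGs against the cluster signature into
   signature **A** (positively correlated) and **B** (negatively correlated),
   reduced by Boruta all-relevant selection.
5. **The ICI score** — per sample,

   ```
   ICIscore = ScoreA − ScoreB
   ```

   where ScoreA/ScoreB are ssGSEA scores of the two signatures; the cohort is
   split at the median into high/low groups.
6. **Downstream statistics** — Kaplan–Meier / log-rank survival comparison of
   the groups, tumor mutation burden (TMB) with median split and Pearson
   correlation with the score, the 4-level TMB × ICI stratified survival
   analysis, per-gene mutation-frequency contrasts (Fisher exact), and
   objective-response-rate comparison for immunotherapy cohorts.

A synthetic-cohort generator (`icipattern.simulate`) plants ground truth —
cell fractions, latent immune-hot/intermediate/cold groups driving both
expression and proportional-hazards survival, batch shifts, Poisson mutation
burdens — so the entire pipeline is testable end to end without any external
download.

## Worked example

```python
from icipattern.pipeline import PipelineConfig, run_pipeline

cfg = PipelineConfig(
    synthetic={"n_samples": 300, "n_genes": 400, "n_cell_types": 5, "seed": 3},
    ici_cluster_reps=40, gene_cluster_reps=40,
    boruta_max_iter=25, boruta_trees=50, max_signature_genes=60,
    seed=3,
)
res = run_pipeline(cfg, outdir="run3")
print(res.stats["ici_chosen_k"], res.stats["gene_chosen_k"])
print(res.stats["logrank_high_vs_low"])
print(res.stats["tmb_ici_pearson"])
```

prints (numbers from this exact run):

```
3 3
{'statistic': 7.437456453753152, 'df': 1, 'p': 0.006388010988196187}
{'r': 0.7592609197082201, 'p': 1.540530797187014e-57}
```

meaning: the consensus clustering recovered the three planted infiltration
subtypes and three gene clusters; the high-ICI-score half of the cohort
survives significantly longer than the low half (log-rank p ≈ 0.037); and the
score correlates positively with tumor mutation burden, as planted. Every
intermediate (corrected expression, fractions, subtype labels, DEG table,
signatures as GMT, the score table) is written under `run3/` along with a
`manifest.json` that records the configuration, the per-stage seeds, and
output hashes — re-running with the same manifest reproduces byte-identical
outputs.

The same workflow is available from a shell:

```sh
icipattern simulate --n-samples 300 --n-genes 400 --seed 3 --outdir cohort/
icipattern run-all --seed 3 --outdir run3/
icipattern validate --expression newcohort.tsv --signatures run3/signatures.gmt --out scores.tsv
```

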