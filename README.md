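# sexqc

Quality control for sex annotations in transcriptomics datasets.

`sexqc` compares the sex recorded in a study's sample metadata against the
sex implied by expression of sex-specific genes — *XIST* (expressed only in
females) and the Y-linked *KDM5D* and *RPS4Y1* (expressed only in males) —
to flag mislabeled or mixed-up samples. It provides:

- **I/O** for probe-by-sample expression matrices (plain TSV or the GEO
  series-matrix dialect) and sample metadata tables with normalized sex
  vocabulary (`sexqc.io`);
- **preprocessing** to the analysis scale: auto-detected log2 transform and
  quantile normalization (`sexqc.preprocess`);
- **marker panels** per platform (packaged defaults for GPL96 / GPL570) with
  correlation-based probeset quality filtering (`sexqc.markers`);
- **sex inference**: two-cluster k-means on the marker probes, centroid-vote
  cluster labeling, and a median-difference concordance score
  `D = median(XIST) − median(KDM5D, RPS4Y1)`; samples whose cluster and score
  sign disagree are called *ambiguous* (`sexqc.inference`);
- **reporting**: per-sample match / mismatch / unclassified status, dataset
  status, stratified corpus summaries, and cross-study concordance that
  separates consistent metadata errors from study-specific physical mix-ups
  (`sexqc.report`);
- **prevalence bounds**: one-sided binomial confidence bounds on the
  population fraction of affected studies via inverse binomial-quantile grid
  search (`sexqc.prevalence`);
- a **synthetic-data generator** that plants label swaps, ambiguous samples
  and a poor-performing probeset with known truth, for end-to-end testing
  without any downloads (`sexqc.simulate`).

## CLI

```sh
# generate a synthetic dataset with 2 planted swaps and 1 ambiguous sample
sexqc simulate --config sim.yaml --out simdir/

# call sex per sample and compare with annotations
sexqc infer --matrix simdir/matrix.tsv --metadata simdir/metadata.tsv \
            --panel simdir/panel.yaml --platform synthetic --out reports/

# aggregate many report sidecars into a corpus summary table
sexqc audit --reports reports/ --strata strata.tsv --out summary.tsv

# one-sided binomial bound on the affected-study proportion
sexqc prevalence --k 32 --n 70 --level 0.99 --side lower
```

`sim.yaml` keys mirror `sexqc.simulate.SimConfig` (e.g. `n_samples`,
`n_mislabels`, `n_ambiguous`, `bad_probe`, `mu_on`, `mu_off`, `sigma`,
`seed`). For real microarray data, omit `--panel` and pass
`--platform GPL96` or `--platform GPL570` to use the packaged probeset
panels; use `--dialect series_matrix` for GEO series-matrix files.

## Library use

```python
from sexqc import (SimConfig, generate_dataset, panel_for_config,
                   run_dataset, summarize_corpus)

cfg = SimConfig(n_samples=50, n_mislabels=2, seed=1)
matrix, metadata, truth = generate_dataset(cfg)
result = run_dataset(matrix, metadata, panel_for_config(cfg))
print(result.report.mismatched_ids)       # == truth.mislabeled_ids
print(summarize_corpus([result.report])["all"].pct_datasets_mismatch)
```
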