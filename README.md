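# mbnoise

Background-noise correction and evaluation for multi-study microbiome
feature tables.

When taxonomic or k-mer abundance tables from several studies are pooled —
to gain power for biomarker discovery or to train phenotype predictors —
study-specific technical variation (DNA extraction, primers, sequencing
platform, bioinformatic pipeline) acts as a confounder. Because each
study's protocol multiplies taxon abundances by feature-specific factors,
samples cluster by study rather than by biology, and case–control
comparisons across studies produce false-positive associations. `mbnoise`
implements the standard tool-kit for detecting and removing this noise on
compositional data, together with the benchmarks used to judge whether a
correction actually works.

## What is in the box

**Transforms** (`mbnoise.transforms`). Closure to relative abundance;
zero replacement with a pseudocount equal to 0.65 × the smallest non-zero
relative abundance; the centered log-ratio transform
`clr(x)_i = ln x_i − ln G(x)` with `G(x)` the row geometric mean; its
softmax inverse; log₂ counts-per-million.

**Corrections** (`mbnoise.corrections`).

- *BMC* — batch mean centering: per feature, subtract each study's mean.
- *DCC* — direct covariate correction: per-feature OLS on a covariate
  design `X ~ βC + ε`; the residual matrix ε is the corrected data.
- *limma-style removal* — the batch term of a joint linear model is
  subtracted while an optional protected phenotype term is retained.
- *ComBat* — the parametric empirical-Bayes location–scale model: batch
  locations get a normal prior, batch scales an inverse-gamma prior,
  hyperparameters by method of moments, solved by the standard iterative
  update.
- *Percentile normalization* — each value becomes its percentile within
  the study's control distribution (midrank ties).
- *PCA correction* — the unsupervised option: multiplicative study bias is
  additive in CLR space and concentrates in the top principal components,
  so removing the projection onto the first *p* PCs strips study structure
  without ever reading the study label. *p* is either fixed (default 3) or
  tuned on a validation split by phenotype-prediction performance.

**Diagnostics** (`mbnoise.diagnostics`). Canonical correlations between
the top PCs and sample covariates (|Pearson| for continuous covariates,
√R² of scores-on-dummies OLS for categorical ones) with significance, and
a paired one-sided Wilcoxon signed-rank comparison of correlation
distributions before/after a transform.

**Benchmarks** (`mbnoise.evaluation`). The control-titration experiment —
replace 0–100 % of one study's controls with another study's controls and
count significant features (Wilcoxon rank-sum, Benjamini–Hochberg q < 0.05)
that were absent at 0 % — and leave-one-dataset-out (LODO) phenotype
prediction with a grid-tuned random forest (AUC) or linear regression
(Pearson r), with every correction parameter fitted on training samples
only.

**Ground-truth simulator** (`mbnoise.synthetic_data`). Multi-study
multinomial count tables with per-feature log-normal study bias, planted
differential features, tunable phenotype–study confounding ρ, and
dispersed library sizes.

## Worked example

Simulate two studies with strong per-feature study bias and *no* true
case–control differences, look at the diagnostic, then run the titration
benchmark:

```python
import numpy as np
import mbnoise as m

cfg = m.SimulationConfig(n_studies=2, samples_per_study=60, n_features=200,
                         bias_sd=1.0, n_differential=0, sample_noise_sd=0.5)
table, meta, truth = m.simulate_dataset(cfg, seed=11)

clr = m.clr_transform(m.add_pseudocount(m.closure(table)))
model = m.fit_pca(clr, K=10)
cm = m.pc_covariate_correlation(model, meta, covariates=["study"], n_pcs=5)
print("PC-study correlations:", np.round(cm.correlations[:, 0], 3))

for name, spec in [("uncorrected", m.PipelineSpec(correction="none")),
                   ("bmc", m.PipelineSpec(correction="bmc")),
                   ("pca_fixed(p=2)", m.PipelineSpec(correction="pca_fixed", n_pcs=2))]:
    res = m.run_titration(table, meta, "study0", "study1", pipeline=spec,
                          proportions=[0.0, 0.5, 1.0], replicates=5, seed=5)
    print(f"{name:16s} mean new associations at 0/50/100%:",
          res.mean_new_associations)
```

Output:

```
PC-study correlations: [0.997 0.002 0.011 0.003 0.001]
uncorrected      mean new associations at 0/50/100%: [  0.   99.6 161.4]
bmc              mean new associations at 0/50/100%: [0. 0. 0.]
pca_fixed(p=2)   mean new associations at 0/50/100%: [0. 0. 0.]
```

PC1 is essentially the study label (canonical correlation 0.997). With no
real effects planted, the uncorrected pipeline reports ~160 of 200
features as "disease-associated" once all controls come from the second
study — every one a false positive driven by study bias. Batch mean
centering or removing two principal components eliminates them.

## Command line

```sh
mbnoise simulate --out-dir sim/ --seed 7
mbnoise transform --table sim/counts.tsv --method clr --out-dir out/
mbnoise correct  --table sim/counts.tsv --metadata sim/metadata.tsv \
                 --method combat --batch-col study --out-dir out/
mbnoise diagnose --table sim/counts.tsv --metadata sim/metadata.tsv --out-dir out/
mbnoise titrate  --table sim/counts.tsv --metadata sim/metadata.tsv \
                 --study1 study0 --study2 study1 --out-dir out/
mbnoise predict  --table sim/counts.tsv --metadata sim/metadata.tsv \
                 --scheme lodo --out-dir out/
```

Every subcommand records its parameters, seed and library versions in
`run.json` inside `--out-dir`.

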