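# icpair

Immune-cell-pair prognostic indices from bulk tumor transcriptomes.

Tumor immune infiltration carries prognostic information, but enrichment
scores computed on different expression platforms are not directly
comparable across cohorts. `icpair` implements a pipeline that sidesteps
cross-platform normalization by reducing each sample to *within-sample
orderings* of immune-cell infiltration: it scores 28 immune-cell
subpopulations per sample by single-sample gene set enrichment (ssGSEA),
converts them into binary cell-pair indicators, selects prognostic pairs
with survival statistics, and composes them into a weighted risk index
with a classification cutoff. It is aimed at researchers building or
stress-testing rank-based prognostic signatures on pooled survival
cohorts (hepatocellular carcinoma being the motivating disease setting).

## The method

1. **Infiltration scoring.** For each sample, each of 28 immune-cell
   metagene sets *S* is scored by a rank-weighted running sum over the
   sample's genes ranked by expression (weight `(N - rank + 1)^alpha`,
   `alpha = 0.25`). Scores depend only on within-sample ranks.
2. **Cell pairs (ICPs).** For cell types A, B the indicator
   `ICP(A|B, s) = 1` iff infiltration(A, s) > infiltration(B, s). All
   C(28, 2) = 378 pairs are formed; constant pairs are removed. The pair
   matrix is invariant to any per-sample monotone distortion of the
   scores — the property that makes multi-platform pooling safe.
3. **Signature training.** Pairs are screened by per-pair log-rank tests
   on the full cohort (p < 0.05); the cohort is split 1:1; LASSO-Cox
   (penalty by cross-validated partial-likelihood deviance, minimum
   rule) followed by an unpenalized multivariate Cox fit on the training
   half gives the signature coefficients. The per-sample risk score is

       ICRPI(s) = sum_i coef_i * ICP_i(s)

4. **Cutoff.** The 5-year (60-month) time-dependent ROC of the training
   scores is computed with Kaplan–Meier correction; the cutoff
   minimizing the distance to the (FPR 0, TPR 1) corner splits samples
   into high- and low-risk groups (high iff score > cutoff).
5. **Composite index.** A multivariable Cox fit of the score with age,
   gender and TNM stage retains covariates at Wald p < 0.05 and yields
   the composite linear index `ICPI(s) = sum retained coef * covariate`.

Evaluation utilities cover Kaplan–Meier/RMS curves, log-rank, Harrell's
C with paired-bootstrap comparison, Wilcoxon/Kruskal–Wallis/Fisher
tests, correlation sweeps with BH adjustment, the cytolytic-activity
(CYT) score, and response-prediction ROC/AUC.

Because real multi-cohort tumor data is not shipped, the package
includes a first-class synthetic-cohort generator with planted cell-pair
signal (see `docs/methods.md`) so every stage is testable and parameter
recovery is measurable.

## Worked example

```python
import icpair

bundle = icpair.generate_cohort(icpair.SimulationConfig(n_samples=600, seed=1))
scores = icpair.ssgsea_scores(bundle.expression, bundle.gene_sets)
pairs  = icpair.build_pairs(scores)            # 378 pairs x 600 samples

res = icpair.train_signature(pairs, bundle.clinical, seed=1)
print(res)
print(res.heldout_evaluation())
```

prints

```
<SignatureResults: 27 pairs, cutoff=-2.4652, train AUC=0.850>
{'c_index': 0.687..., 'auc': 0.816..., 'logrank_statistic': 54.56..., 'logrank_p': 1.50...e-13}
```

i.e. the trained signature keeps 27 pairs (including all 5 planted
ones), the training-half 5-year AUC is 0.85, and on the untouched
held-out half the score reaches concordance 0.69 and separates the
high/low risk groups at log-rank p ≈ 1e-13. `res.summary()` tabulates
per-pair hazard ratios, Wald p-values and screening p-values;
`res.signature.to_json(path)` saves the model for later `score` calls.

The same pipeline is exposed on the command line:

```bash
icpair simulate --n-samples 600 --seed 1 --out cohort/
icpair score-cells --expr cohort/expression.tsv --gmt cohort/gene_sets.gmt --out infiltration.tsv
icpair build-pairs --infiltration infiltration.tsv --out pairs.tsv
icpair train --pairs pairs.tsv --clinical cohort/clinical.csv --seed 1 --out model.json
icpair score --model model.json --pairs pairs.tsv --out risk.csv
icpair evaluate --risk risk.csv --clinical cohort/clinical.csv --out report/
```

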