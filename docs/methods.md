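# Methods

## Infiltration scoring (ssGSEA)

Each sample is scored independently against each metagene set. With N
genes ranked by expression in the sample (rank 1 = highest; ties share
average ranks) and a set S, the score is the summed difference of two
running distributions while walking the ranked list: the in-set
distribution weighted by `w_i = (N - rank_i + 1)^alpha` (normalized by
the total in-set weight) and the uniform out-of-set distribution
(normalized by `N - |S|`). The walk order is expression-descending with
stable tie-breaking on input gene order. `alpha` defaults to 0.25, the
conventional ssGSEA exponent; `alpha = 0` reduces the score to a plain
step-CDF (Kolmogorov–Smirnov-style) accumulation. Optional
normalization divides the whole score matrix by its global max − min;
it rescales all samples by one constant and therefore never changes any
within-sample ordering, so pair features are identical either way.
Genes missing from the expression matrix are dropped from sets with a
logged count; a set losing all genes, or covering every gene, is an
error.

Because the score depends only on within-sample ranks, any strictly
increasing per-sample transform of expression leaves it unchanged to
machine precision. This is the foundation of the pipeline's
cross-platform claim and is asserted exactly in the tests.

## Pair features

`build_pairs` forms all C(n, 2) ordered indicators, direction fixed by
the input cell-type order (serializable, reproducible). Ties score 0 —
they have measure zero for continuous enrichment scores — and are
counted per pair so silent distortion is detectable. The default filter
removes exactly the pairs constant across all samples; a symmetric
prevalence band `[q, 1 - q]` is available because antecedent
relative-ordering methods used one.

## Signature training

The training sequence is: log-rank screen of every non-constant pair on
the **full** cohort at raw p < 0.05 (Benjamini–Hochberg optional,
default off); a seeded 1:1 split; LASSO-penalized Cox on the training
half over a descending penalty grid with the penalty chosen by K-fold
(default 5) cross-validated partial-likelihood deviance, minimum rule,
computed as `-2 [pl_all(beta) - pl_train(beta)]` so risk sets are
handled consistently; an unpenalized multivariate Cox refit of the
selected pairs provides the coefficients. An optional `prune_alpha`
drops refit pairs above a Wald threshold and refits; it is off by
default so the reported selection is the penalized one.

The Cox fitter maximizes the Breslow partial likelihood by damped
Newton iteration (relative tolerance 1e-9, max 100 iterations) with
Wald inference from the inverse information matrix. Divergence
(|coef| > 50, typically separation) and non-convergence are flagged via
warnings, never silently returned. On tie-free data it agrees with the
Efron-based reference implementation in lifelines to 1e-5, which the
tests assert.

## Cutoff selection

The time-dependent ROC at horizon t (default 60 months) uses the
cumulative-case / dynamic-control estimator with Kaplan–Meier
correction inside the two score strata defined by each candidate
cutoff. Candidates are midpoints between consecutive sorted unique
scores; the curve is anchored at (0,0) and (1,1) and integrated by
trapezoid in descending-cutoff order (re-sorting by FPR would scramble
vertical runs that differ only by float noise). Without censoring the
estimator reduces to the plain binary ROC, which the tests check to
1e-10. The grouping cutoff minimizes the Euclidean distance to the
(FPR 0, TPR 1) corner; ties break toward higher sensitivity, then the
lower cutoff. Samples are high-risk iff score strictly exceeds the
cutoff (boundary convention: the boundary sample is low-risk).

## Composite index

`CompositeIndexModel` fits a multivariable Cox model on the signature
score plus age, gender (encoded male = 1) and ordinal TNM stage,
retains covariates at Wald p < 0.05, refits on the retained set, and
exposes the linear index. If nothing is significant it warns and falls
back to the signature score alone.

## C-index comparison

The paired-bootstrap comparison of two scores' Harrell's C (resample
samples with replacement, compute both C's per replicate, two-sided
fraction-based p on the difference distribution, degenerate resamples
skipped and logged) is this package's own convention — the result
object records the method explicitly.

## Synthetic cohorts

The generator emulates the structure the pipeline assumes, not real
RNA-seq marginals:

- 28 latent per-sample abundances `a(c, s) ~ LogNormal(0, spread)`,
  independent across cells and samples (`infiltration_spread = 1`).
- latent risk `r(s) = sum_k beta_k 1[a(A_k, s) > a(B_k, s)]` over the
  planted pairs; event time `T ~ Exp(h0 * exp(r))` with
  `h0 = 0.02`/month; censoring `U ~ Uniform(0, 120)` months
  (non-informative); observed time `min(T, U)`, event `1[T <= U]`.
  These rates give roughly 60–70% events.
- metagene expression `mu_g + gain * a(c, s) + batch(cohort, g) +
  N(0, noise_sd^2)` with `mu_g ~ N(5, 1)`, `noise_sd = 1`, additive
  per-cohort per-gene offsets `~ N(0, 0.5^2)` across 2 cohorts, and 360
  background genes carrying batch and noise only. `monotone_distort`
  additionally applies a per-cohort strictly increasing cubic
  (`b + a x + c x^3`, a > 0, c >= 0) to exercise the platform-invariance
  claim end to end.
- TNM stage is a quartile cut of `r + N(0, 0.5^2)`; the binary response
  label is `Bernoulli(logistic(-slope * r))` with slope 1, so low-risk
  samples are enriched for responders.

Reference conditions: 600 samples, 30 genes per set, five planted pairs
over ten distinct cell types with weights (1.0, 1.0, 0.9, −1.0, −0.9).
The weights sit at the upper end of the unit log-hazard scale and the
abundance-to-expression coupling is `signal_gain = 2` so that 30-gene
metagene sets determine the latent orderings almost unambiguously
(pair-indicator disagreement with the latent ordering ≈ 5%): the
generator's purpose is measurable parameter recovery, and under these
conditions the trained signature reproducibly recovers ≥ 4/5 planted
pairs with held-out concordance ≈ 0.66–0.72 against a latent-risk
ceiling of ≈ 0.70–0.74. Weaker coupling degrades the enrichment step
gracefully (the tests check the ordering-agreement trend at two gain
levels) but leaves less headroom for studying the selection stages.

What passing these simulations does **not** show: robustness to
negative-binomial count noise, correlated immune lineages,
informative censoring, or missing clinical data — none of which the
generator emulates.

## Numerical and degenerate-input conventions

- Exponential/uniform survival sampling clips observed times at 1e-3
  months to keep them strictly positive.
- The log-rank screen is vectorized over all pairs via risk-set count
  matrices; it matches the per-pair reference test (lifelines) to 1e-9
  relative and raises on constant groupings.
- Wilcoxon uses the exact permutation distribution of the rank sum for
  pooled n ≤ 10 (ties handled by conditioning on observed average
  ranks) and a tie-corrected normal approximation above; identical
  multisets give p = 1 under the exact convention.
- Kruskal–Wallis returns H = 0, p = 1 for all-identical pooled values.
- Fisher's two-sided p follows the probability-mass rule; the statistic
  is the sample odds ratio.
- LASSO folds are redrawn (up to 100 times) until every fold contains
  at least one event; the 1:1 split likewise requires ≥ 2 events per
  half. All randomness flows through `numpy.random.default_rng` seeds.

## Known limitations

- Hazards are proportional by construction in the generator; the
  pipeline never tests the proportional-hazards assumption.
- The time-dependent ROC estimator can be locally non-monotone under
  heavy censoring (a known property of stratified-KM correction); the
  cutoff search scans candidates exhaustively, so it is unaffected.
- The screen-on-full-cohort-then-split sequence reuses the test half
  during screening; held-out metrics are therefore mildly optimistic
  for the screening stage, a deliberate mirror of the published
  procedure rather than a recommendation.
- With ~20–30 pairs surviving CV-minimum selection, coefficients are
  noisy at n = 300 training samples; the 1-SE rule is not implemented.
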