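# Methods

This note documents the models, conventions and numerical choices behind
`immunosig`, in the spirit of a statistical software methods appendix.

## Synthetic cohort model

The generator (`immunosig.datasets`) emulates the structure of a
two-group expression study of early colorectal carcinoma on the
variance-stabilized (log-like) scale the downstream analysis assumes:

- **Cohort.** 33 non-recurrent and 12 metachronous-metastasis samples by
  default, ~44,000 probes.  Probe baselines are drawn from a broad normal
  distribution, N(8, 2²) in transformed units, with i.i.d. Gaussian
  within-group noise (default SD 1.0 — an upper-mid range value for
  between-tumor variability on a log2-like scale, chosen once for the
  package's study conditions).
- **Planted signature.** 14 immune-related genes (the MHC-class-II /
  chemokine / immunoglobulin set of the published signature), one probe per
  gene by default, each down-shifted by the effect size δ (default 2.0) in a
  metastatic sample only with probability `penetrance` (default 0.7), drawn
  independently per sample and gene.  This heterogeneity — different genes
  affected in different patients — is the statistical reason a univariate
  screen stays silent while a multivariate selector recovers the set, and it
  is asserted as a testable property rather than assumed.
- **Survival.** Non-recurrent follow-up is uniform on 41–115 months and
  censored; metastatic disease-free times are log-normal with median 13
  months and log-SD √(2·log(17/13)) ≈ 0.73, so the implied mean is 17
  months, and all are events.  Censoring therefore occurs only in the
  non-recurrent group.
- **Annotations.** 70% of background probes carry synthetic gene symbols;
  one immune gene set holds the signature genes plus ~7% of the annotated
  background (mirroring a term covering roughly 7% of an array universe),
  and 40 random background terms with log-normal sizes complete the
  annotation.
- **qPCR.** Ct tables contain a reference gene (ACTB, baseline 18 cycles), a
  per-gene target baseline in 22–27 cycles, Gaussian cycle noise (SD 0.5 for
  targets, 0.3 for the reference), a calibrator cell-line sample (HT29), and
  an upward Ct shift (default 2 cycles = 4-fold down-regulation) in the
  metastatic group.

All randomness flows from a single integer seed through
`numpy.random.default_rng`; identical configuration and seed give
byte-identical outputs.

What the generator does **not** model: probe-probe correlation, batch and
dye effects, scanner artifacts, annotation errors, and the strongly
structured noise of real arrays.  Passing tests therefore demonstrate the
correctness and calibration of the algorithms under the stated model, not
performance on real cohorts.  One visible consequence: with i.i.d.
background noise the union of probes saved across 100 bootstrap steps is
much larger than the 44 probes seen on real data, where correlated
informative probes recur step after step.

## Normalization

Arrays are first affine-calibrated (per-array median and MAD matched to the
dataset medians), then transformed by the generalized log
glog(x) = arsinh(x/c).  The crossover c is estimated as
σ_additive / cv_multiplicative, with σ_additive the median per-probe SD in
the lowest intensity quintile and cv the median SD/mean in the highest;
this equalizes the asymptotic variance of the additive and multiplicative
noise regimes.  A degenerate estimate falls back to the overall MAD.  The
transform is strictly increasing, so within-array ranks are preserved.  This
is a deliberately reduced variance-stabilization: a full maximum-likelihood
fit of array-specific affine parameters is a project of its own, and every
downstream stage here depends only on a monotone, roughly
variance-stabilized scale.

## Differential screen

Per-probe Welch two-sample t on the transformed scale, Benjamini-Hochberg
step-up q-values (q_(i) = min_{j≥i} m·p_(j)/j, capped at 1), and the double
threshold |FC| beyond 2 with q < 0.05.  Fold change is the ratio of
anti-transformed group means, reading the transformed scale as log2; the
threshold is applied symmetrically (FC > 2 or FC < 0.5).  Probes with zero
variance in both groups get p = 1 with a warning.  The screen's role in
this pipeline is a null check — on heterogeneous cohorts it is expected to
come up (nearly) empty.

A calibration caveat, measured by the package's own tests: across
effect-free synthetic cohorts the fraction of runs with zero flagged probes
is slightly **below** 95%.  Two arithmetic facts cause this: under the
global null the probability of at least one BH rejection at q < 0.05 equals
α (Simes' equality), so even ideal p-values give only ≈95% flag-free runs;
and the plain Welch t at 33-vs-12 is anticonservative in the far tail that
BH consults at array-scale multiplicity, pushing the flag-free rate to
≈92%.  A moderated-variance test would behave better in the far tail but is
deliberately out of scope.

## Bootstrap recursive-SVM selection

- **Scoring.** f_j = w_j (m_j⁺ − m_j⁻) from a linear SVM (fixed cost,
  default C = 1; no per-step tuning).  The score is invariant to negating a
  feature and zero for a feature with equal class means.
- **Ladder.** Geometric halving from all features down to the reporting
  level, with the reporting level (default 42) inserted as an explicit
  rung.  At each rung the SVM is refit on the retained features, held-out
  error recorded, and the next rung's features taken as the top scorers of
  the current fit.  Ties in f_j break by feature order for determinism.
- **Bootstrap.** 100 stratified resamples (sampling with replacement within
  each class preserves the 33:12 imbalance); out-of-bag samples form the
  held-out set, and a step with an empty out-of-bag set is redrawn (logged).
  Features saved at the reporting level are counted; every feature saved at
  least once enters the signature.
- **Estimator surface.** `BootstrapRSVM` follows the scikit-learn selector
  API (`fit`, `get_support`, `transform`), with `selection_count_`,
  `signature_mask_` and `cv_error_by_level_` as fitted attributes.

## Gene-set over-representation

Unconditional hypergeometric upper tail P(X ≥ a) per term, with the
universe defined as all gene symbols carrying at least one annotation term;
zero-overlap rows are omitted (their p is identically 1), no multiple-testing
correction is applied to enrichment p-values (matching the published table's
raw p column), and a saturated odds ratio (empty off-diagonal cell) is
reported as +∞, never NaN.  Probe sets are collapsed to unique non-empty
gene symbols (stable order) before testing.

`reconstruct_table_params` recovers the selection size n and universe size N
that a printed table used but omitted: a grid search over n ∈ [max a, 100]
and N ∈ [1000, 50000] keeps the pairs for which every row's recomputed
expected count and odds ratio round to the printed 2-decimal values, and
demands exactly one survivor (no pair and multiple pairs are distinct
errors).  On the published anchor rows the unique survivor is
(n, N) = (21, 12464), from either of the two anchor triplets, and with that
pair the four printed p-values are reproduced to their printed precision.

## Below-median count classifier

"Median ... in all other samples" is read literally as a leave-one-out
median (default); a pooled-median mode is provided for sensitivity
analysis.  A value strictly below the reference median counts; equality does
not, which makes the constant-matrix case well defined (all counts zero).
Counts are integers in [0, signature size].  The decision rule is
metastatic ⇔ count > θ with θ half-integer (equivalently count ≥ ⌈θ⌉).
The ROC sweeps all half-integer thresholds bracketing the observed counts;
AUC uses the pairwise Mann-Whitney identity with ties counted ½; the
selected cutoff maximizes Youden's J with ties broken toward the higher
threshold (higher specificity).  The published operating point (θ = 8.5)
can be fixed via configuration instead.  The sklearn wrapper scores new
samples against pooled training medians.

## Survival

Product-limit estimation and the Mantel-Cox log-rank test are delegated to
`lifelines`; the module surface validates inputs (positive finite times,
0/1 event flags, at least one event for the test) and returns plain arrays.
Events precede censorings at tied times (standard convention); the log-rank
p is the two-sided χ²(1) tail.  Hand-computed product-limit and O/E/Var
examples serve as the test oracle.

## qPCR relative quantification

ΔCt = Ct(target) − Ct(reference), ΔΔCt subtracts the calibrator sample's
ΔCt, RQ = 2^−ΔΔCt with 100% amplification efficiency assumed (exactly
factor 2 per cycle).  RQ is invariant to shifting both Cts of a sample by a
constant.  The Mann-Whitney comparison uses midranks; for combined n ≤ 20
the two-sided p is exact by full enumeration of group assignments (counting
assignments at least as extreme in |U − n₁n₂/2|), larger samples use the
tie-corrected normal approximation.

## Pipeline and reproducibility

The `run` pipeline executes screen → selection → gene collapse → enrichment
→ signature extraction → classification → survival, writing every stage
output with a provenance header (package version, seed, configuration
hash).  The classifier's signature defaults to the selected genes annotated
to the configured immune term (one designated probe per gene,
lexicographically smallest selected probe), overridable by an explicit probe
list.  Per-stage seeds are spawned hierarchically from the single run seed,
so stages are individually re-runnable; reruns with identical inputs and
seed are byte-identical.

## Problem sizes used in tests

The shipped tests and demonstrations run the generator at reduced probe
counts — typically 150–1,000 probes for selection and null-calibration
studies, 20,000 for the array-scale screen property, and 800 for the
end-to-end pipeline — which preserve every statistical property being
asserted while keeping the default suite fast.  The generator's own
defaults remain the full study conditions (44,000 probes, 33 + 12 samples).

## Known limitations

- The background noise model is i.i.d.; correlated probe blocks, batch
  effects and real annotation structure are not simulated.
- The exact 44-probe identity, AUC 0.817 and log-rank p = 0.002 of the
  original cohort require the deposited array data and are outside the
  test scope (`scripts/gse31905_workflow.py` supports that workflow on a
  locally provided series-matrix file).
- The Welch-based screen is slightly anticonservative in the extreme tail
  (see above); conditional (GO-graph-decorrelated) enrichment testing and
  moderated-variance statistics are intentionally not implemented.
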