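# immunosig

Prognostic marker discovery for early colorectal carcinoma, built around a
concertedly down-regulated immune-gene signature that predicts metachronous
metastasis.  The package reimplements, as a tested and reusable pipeline, a
microarray analysis in which no single gene separates the outcome groups but
a multivariate signature does: bootstrap recursive-SVM feature selection,
hypergeometric GO over-representation, a below-median-count classifier with
ROC cutoff selection, Kaplan-Meier / log-rank survival stratification, and
ΔΔCt qPCR validation.  A first-class synthetic-cohort generator emulates the
study structure (33 non-recurrent vs 12 metastatic tumors, ~44k probes, a
heterogeneously down-shifted 14-gene immune signature), so every stage is
testable without any array download.

## The methods in brief

**Recursive SVM (R-SVM).**  A linear SVM is fit on the current feature set;
each feature is scored by its contribution to class separation,
f_j = w_j (m_j⁺ − m_j⁻), where w is the fitted weight vector and m_j± are
the class means of feature j.  The top-scoring features are retained along a
geometrically shrinking ladder.  A bootstrap wrapper repeats this on 100
stratified resamples (out-of-bag samples held out), saves the best 42 probes
of each step, and keeps every probe selected at least once as the candidate
signature.

**GO over-representation.**  For a selection of n genes from a universe of
N, a term with K members and overlap a is scored by the upper hypergeometric
tail P(X ≥ a), with expected count nK/N and odds ratio (a·d)/(b·c) of the
2×2 membership table.  A companion utility reconstructs the (n, N) that a
published table used but did not print, by integer grid search against its
Expected and Odds-ratio columns.

**Below-median count classifier.**  A sample's score c_i is the number of
signature probes whose value lies strictly below the probe's median over all
*other* samples; the sample is called metastatic when c_i > θ.  θ is chosen
on the ROC curve by Youden's J (the published operating point, θ = 8.5,
i.e. at least 9 of 14 probes below median, can be fixed explicitly).  AUC
uses the Mann-Whitney identity with ties counted ½.

**Survival and validation.**  Predicted strata are compared on disease-free
survival with the product-limit estimator and the Mantel-Cox log-rank test.
qPCR validation uses ΔΔCt relative quantification (β-actin reference, HT29
calibrator, RQ = 2^−ΔΔCt) with an exact Mann-Whitney group comparison.

## Worked example

Reconstructing the published enrichment statistics from the printed table
columns alone (no data download):

```python
>>> import immunosig as im
>>> rows = [(1.47, 26.94, 14, 874),   # expected, odds ratio, count, size
...         (1.04, 31.69, 13, 620),
...         (0.10, 73.05,  5,  58)]
>>> im.reconstruct_table_params(rows)
(21, 12464)
>>> im.hypergeom_pvalue(14, 874, 21, 12464)
4.599692758706333e-12
```

The grid search pins the unprinted selection size (21 annotated genes) and
gene universe (12,464 genes); with them, the recomputed p-value for the
immune-system-process term reproduces the published 4.6E-12, and the other
printed rows follow the same way (1.4E-12, 1.8E-08, 3.5E-08).

Running the full pipeline on a synthetic cohort (800 probes keeps the demo
quick; the generator defaults to the full 44,000):

```python
import immunosig as im

cohort = im.generate_cohort(im.CohortConfig(n_probes=800, seed=3))
paths = im.write_cohort(cohort, "demo_data")
summary = im.run_pipeline(im.PipelineConfig(out_dir="demo_run", seed=3, **paths))
```

Selected fields of the printed `summary.json`:

```
"de_flagged": 6,              # univariate screen finds almost nothing
"n_selected_probes": 448,     # probes saved at least once by bootstrap R-SVM
"auc": 0.919192,              # below-median counts on the immune signature
"cutoff": 21.5,               # Youden-optimal half-integer threshold
"logrank_chi2": 27.822281,
"logrank_p": 1.32986e-07      # predicted strata separate disease-free survival
```

The planted 14 immune probes are all contained in the extracted signature,
the univariate screen stays essentially silent (the heterogeneous
down-regulation defeats per-probe t-tests), and the classifier's predicted
strata split the survival curves decisively — the qualitative fingerprint of
the original analysis.

The same stages are available from the shell:

```sh
immunosig simulate --out demo_data --seed 3
immunosig run --config pipeline.yaml --seed 3
immunosig qpcr --ct ct_table.tsv --ref ACTB --calibrator HT29 --out rq.tsv
```

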