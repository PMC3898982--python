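# ccpmeta

Cross-cohort meta-analysis of prognostic gene-expression signatures, built
around the cell-cycle proliferation (CCP) score.

## The problem

Most published prognostic expression signatures fail to validate in
independent cohorts. One explanation is that the signatures that *do*
validate all tap the same underlying biology — cell-cycle / proliferation
activity — so that (i) a simple proliferation score is prognostic across
cohorts and platforms, (ii) other signatures lose their prognostic value
once their genes are adjusted for the proliferation score, and (iii) a small
subset of proliferation genes performs as well as the full set. `ccpmeta`
packages the statistical machinery needed to ask these questions on any
collection of expression + outcome cohorts, together with a synthetic-cohort
generator with full ground truth so every analysis can be validated against
known effect sizes.

It is aimed at computational biologists evaluating prognostic biomarkers
across public cohorts (microarray or RNA-seq), and at methodologists who
want a controlled sandbox for signature-robustness experiments.

## The model

- **Score.** For a gene matrix collapsed to one row per symbol (multi-probe
  genes keep the probe with the highest mean) and z-normalized per gene,
  the signature score of sample *j* is `s_j = mean_{g in S∩platform} z_gj`.
- **Survival endpoints.** Cox proportional hazards with the score as sole
  continuous covariate: `h(t|s) = h0(t)·exp(β·s)`; the reported p-value is
  the partial-likelihood **score test at β=0** (the continuous-covariate
  generalization of the log-rank test, Efron tie handling); the hazard
  ratio per 1-unit score and its Wald CI come from the fitted model.
  Endpoints follow the hierarchy DSS > OS > RFS.
- **Binary endpoints** (progressor vs non-progressor, node status) use the
  AUC with a Mann–Whitney p-value and DeLong CI.
- **Enrichment.** Per-cohort gene lists (P<0.01 screen) are tested for
  module over-representation with the one-sided hypergeometric tail and
  Benjamini–Hochberg FDR; modules are ranked across cohorts by the number
  of cohorts significant at FDR<20%, then mean p.
- **Adjustment.** Each signature gene row is replaced by its residuals from
  least squares on the CCP score (negative control: subtract a constant);
  a signature prognostic (p<0.05) before but not after adjustment is
  **lost**, prognostic in both is **retained**.
- **Signature size.** Up to 10,000 distinct random subsets of the signature
  per size are scored and tested; the plateau size is the smallest size
  whose proportion-significant reaches 95% of the full signature's. Refined
  CCP-k signatures take the top-k genes by cross-cohort univariate
  consistency, and a nested likelihood-ratio test asks whether the full
  score still adds value over (refined score + clinical risk covariate).

## Worked example

```python
import ccpmeta as cm

spec = cm.CohortSpec(n_samples=150, n_genes=500, beta_prolif=1.0,
                     baseline_hazard=0.1, censor_max=20.0, seed=42)
cohort = cm.generate_cohort(spec)
matrix = cm.znormalize(cm.collapse_probes(cohort.expression))
score = cm.signature_score(matrix, cm.ccp_signature(spec))
result = cm.test_continuous(score, cohort.clinical)
```

Running `python examples/simulate_and_score.py` (the same code) prints:

```
cohort: cohort_seed42, n=150, events=82
CCP score coverage: 31/31 genes
HR per 1-unit CCP score = 2.86 (95% CI 2.06-3.97), p = 8.9e-10
tertile thresholds: -0.208, 0.315; group sizes {'lower': 50, 'middle': 50, 'upper': 50}
```

The cohort was generated with log-hazard 1.0 per unit latent proliferation;
the score is a noisy but highly correlated proxy for that factor, so a
1-unit increase in the score carries a hazard ratio of ~2.9 and the
continuous-score (log-rank family) p-value is tiny. `km_tertiles` returns
the three Kaplan–Meier curves (lower/middle/upper 33% of the score) ready
for plotting.

The other scripts in `examples/` each demonstrate one capability:
`enrichment_ranking.py` (cross-cohort module ranking and per-cohort top
hits), `adjustment_analysis.py` (lost/retained classification and loss
percentages), `signature_size.py` (size curves, plateau, refined CCP-k and
the nested test), `run_full_study.py` (the whole pipeline from files on
disk). A thin CLI mirrors the pipeline:
`ccpmeta simulate|preprocess|score|prognosis|screen|run-study`.

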