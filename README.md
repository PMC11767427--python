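# osteowarn

Early-warning analysis of bone loss from metabolomic cohorts.

Osteoporosis is usually silent until fracture risk is already high, and the
intermediate low-bone-mass stage — osteopenia — is where intervention pays
off most. This package implements a network-based early-warning analysis for
three-stage bone-mineral-density (BMD) cohorts
(control → osteopenia → osteoporosis): it asks whether the middle stage
behaves like the *critical state* of a dynamic system approaching a
transition, and which metabolites flag it.

## The method

Samples are staged by DXA T-scores
(T = (measured BMD − young-adult mean)/young-adult SD; osteoporosis if
T < −2.5 at any site, control if T ≥ −1.0 at all sites, osteopenia between).
After a 20% missingness filter, the pipeline runs:

1. **Differential metabolite analysis** — Jonckheere–Terpstra ordered trend
   test across the three stages, Wilcoxon rank-sum for each stage pair
   (p < 0.05), PCA and PLS-DA ordination.
2. **Individual edge-network analysis (iENA)** — every quantity is anchored
   to control-group reference statistics (μₓ, σₓ). For one sample *s*,

   - `sPCC_s(x,y) = z_x(s)·z_y(s)` with `z_x(s) = (x(s) − μ_x)/σ_x`
     (the sample's contribution to the reference Pearson correlation),
   - `shPCC_s(e₁,e₂) = Z_{e₁}(s)·Z_{e₂}(s)`, the fourth-order score between
     two edges, standardized by the reference edge-score distribution,
   - the composite warning index over a candidate "domain" module *D*

     ```
     sCI(s) = mean_{x,y∈D} |sPCC_s(x,y)|
              ───────────────────────────── × mean_{x∈D} |x(s) − μ_x|
              mean_{x∈D, y∉D} |sPCC_s(x,y)|
     ```

   which is large when a tightly coupled module deviates strongly from the
   reference while decoupling from the rest of the network — the
   dynamic-network-biomarker signature of a tipping point. The stage where
   the best module's mean sCI peaks is the predicted critical stage.
3. **Random-forest biomarkers** — 70/30 stratified split on
   control vs osteopenia, 500-tree forest, features with ≥ 5% normalized
   importance retained, retrained, evaluated by test-set ROC/AUC with a
   DeLong 95% CI and a DeLong-paired comparison against a bone-turnover-marker
   (osteocalcin, PINP, β-CTX) baseline.
4. **Module–trait association** — WGCNA-style soft-threshold adjacency
   (|cor|^β), topological overlap, static tree cut, eigen-metabolite per
   module, Pearson correlation with clinical covariates.
5. **Mediation** — exposure → metabolite → binary outcome via a linear
   mediator model plus a logistic outcome model, with quasi-Bayesian
   ACME/ADE/total-effect estimates (risk-difference scale) and percentile CIs.

Because matched clinical cohorts are rarely shareable, the package ships a
synthetic-cohort generator with planted ground truth (a domain block whose
correlation and variance surge at the middle stage, monotone trend
metabolites, missing cells, and a mediation-structured covariate), so every
stage is testable end to end.

## Worked example

```bash
python analysis/01_simulate_cohort.py      # writes results/cohort/
python analysis/03_iena_warning_index.py   # the core early-warning analysis
```

prints (seed 1):

```
top edges selected: 18
stage-mean sCI: control=0.190, osteopenia=1.408, osteoporosis=0.320
critical stage: osteopenia
domain module (10 metabolites) overlaps planted domain in 10/10
```

The sCI trajectory peaks sharply at the osteopenia-analog stage — a 7-fold
rise over the control mean and a relaxation at the overt-disease stage — and
the recovered domain module is exactly the planted one. The remaining
drivers (`analysis/02…06`) run the differential, forest, module–trait and
mediation stages; for example `analysis/04_rf_biomarkers.py` reports a
metabolite-panel AUC of 0.749 (95% CI 0.558–0.940) against a 0.398 baseline
from bone turnover markers (DeLong p = 0.011) on the same test split.

The full pipeline, from one config, is also available as a CLI:

```bash
osteowarn synth --seed 1 --out cohort/
osteowarn run --config cfg.yaml --out run1/
```

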