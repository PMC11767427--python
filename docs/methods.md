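# Methods

## Cohort model and staging

A cohort is a samples × metabolites abundance matrix (non-negative
concentrations, µM or semi-quantitative units) with per-sample metadata.
Staging follows the WHO T-score convention:
T = (measured BMD − young-adult mean)/young-adult SD per DXA site (lumbar
spine L1-4, femoral neck, total hip); osteoporosis if any site T < −2.5,
control if all sites T ≥ the control threshold, osteopenia otherwise. The
literal "controls have T > −2.5 everywhere" reading would leave the
osteopenia stratum empty, so the control threshold defaults to the WHO
value −1.0 and is configurable; the convention in force is logged.

Metabolites missing in strictly more than 20% of samples are excluded.
The remaining missing cells (empty, `NA`, `NaN`, `<LOD`; below-LOD counts
as missing, not zero) are imputed with the per-metabolite median within
gender stratum — robust, and neutral for the rank tests downstream —
with `half_min` (an LOD-style fill) and `none` as alternatives. Clinical
analyses are intended to run per gender; synthetic cohorts default to a
single stratum and run pooled.

## Synthetic cohorts and what they emulate

The generator encodes the dynamic-network-biomarker (DNB) premise: ahead
of a state transition, a small "domain" group of variables becomes more
variable and more tightly inter-correlated while decoupling from the rest
of the network — at the *critical* (osteopenia-like) stage, not the
overt-disease stage.

Per stage, log-abundances are multivariate normal with block correlation:
domain block at `rho_in` = (0.2, 0.7, 0.35), domain↔background at
`rho_out` = (0.15, 0.05, 0.10), background at 0.1; domain SDs are scaled
by (1.0, 2.0, 1.3); all metabolites have baseline log-SD 0.25 (typical of
mid-sized CVs in targeted panels). Eight trend metabolites drift by 0.5
SD per stage in alternating directions. Values are exponentiated
(log-normal positivity); rank tests are invariant to this, and at these
SDs Pearson correlations are attenuated only mildly (ρ = 0.7 on the log
scale ≈ 0.67 after exponentiation). Missing cells (5%) are
missing-at-random with an exact per-metabolite count. Defaults are 50
samples per stage and 60 metabolites — a desk-scale stand-in for a
~100-300-participant, ~200-metabolite targeted panel.

One caveat on `rho_out`: a compound-symmetric block structure is a valid
correlation matrix only if
(1+(d−1)·rho_in)(1+(B−1)·rho_bg) > d·B·rho_out², which at the default
sizes caps the control-stage coupling at about 0.18; the defaults sit
inside that region and the generator verifies positive definiteness at
build time, naming the offending stage otherwise.

A standard-normal exposure ("tffm") feeds one background metabolite with
slope α·0.25 per log-unit, providing a mediation path inside the cohort.
The pure generative triple (exposure → mediator → logistic binary
outcome) is also available separately, with its exact ACME computed by
Gauss–Hermite integration — the oracle the mediation engine is validated
against. The cohort's own stage labels are *not* generated by that
logistic model, so the cohort truth table records the mediator identity
but no analytic ACME.

What the generator does not emulate: real p180 metabolite classes and
their covariance, batch effects, left-censored (LOD-mechanism) missingness
by default (an optional left-censoring mode exists), and any real
association between BMD and metabolism. Passing tests therefore show the
*procedures* are correct and calibrated, not that the biological claims
hold in any particular cohort.

## Differential metabolite analysis

The Jonckheere–Terpstra statistic is the sum of Mann–Whitney counts over
ordered group pairs (ties ½). The null is exact (enumeration of all
multiset assignments) when total n ≤ 12, and a tie-corrected normal
approximation otherwise; all values identical returns p = 1. With two
groups it reduces exactly to the one-sided Mann–Whitney test. Pairwise
contrasts use the Wilcoxon rank-sum test (scipy; exact when
min(n) ≤ 8 and tie-free). Midranks are used throughout. Significance is
raw p < 0.05 with no multiplicity correction by default, matching common
practice in targeted-panel studies at this scale; Benjamini–Hochberg is
available (`fdr='bh'`). Ordination standardizes metabolites to zero
mean/unit SD (log transform optional, off by default) and uses SVD-based
PCA or a two-component PLS2 fit against one-hot stage labels.

## iENA and the sCI warning index

All single-sample scores are anchored to reference statistics (mean and
ddof-1 SD per metabolite) computed from the control stage only;
zero-variance metabolites are dropped with a warning, and at least three
reference samples are required.

- `sPCC_s(x,y) = z_x(s)·z_y(s)` — the sample's standardized co-deviation,
  i.e. its additive contribution to the reference Pearson correlation
  (the mean of sPCC over the reference samples equals (n−1)/n times the
  reference correlation). An edge is ranked by its mean |sPCC| over the
  non-reference samples; the top 1% of pairs (configurable top-k /
  top-quantile) form the edge network, ties broken lexicographically.
- `shPCC_s(e₁,e₂)` standardizes each edge's sPCC by that edge's score
  distribution over the reference samples and multiplies — fourth-order
  in the metabolite values. Edges whose reference score SD is zero are
  skipped with a warning.
- `sCI(s)` = (mean in-module |sPCC|) / (mean module-to-outside |sPCC|)
  × (mean in-module |x − μ|). The third factor deliberately uses the
  un-normalized absolute deviation, so sCI is scale-dependent in the
  units of the input panel; a σ-standardized variant would change only
  the overall scale on a homogeneous panel. The out-of-module denominator
  is floored at 1e-8 and flagged, so decoupled modules yield large finite
  values, never NaN/Inf. sCI ≥ 0 always and is 0 exactly at the reference
  mean.

Candidate modules come from average-linkage hierarchical clustering of
metabolites on 1 − |Pearson correlation| over all samples, cut at height
0.7 (i.e. clusters with mean |cor| ≥ 0.3), keeping clusters of 3–30
members — exhaustive subset search over modules is combinatorially
infeasible, and co-expression clustering is the module-recognition step
of the framework. If no cluster satisfies the bounds the tree is re-cut
at the smallest fixed k that yields a size-valid cluster (warned); this
lean fallback matters for calibration, see below.

For stage evaluation, per-sample sCI values are averaged within stage
(arithmetic mean; median by flag) and the module with the highest
best-stage mean is the domain module; its argmax stage is the critical
stage.

Two estimator choices are worth spelling out, both made on calibration
grounds under the exchangeable null (flat stage parameters, no trends):

1. **Leave-one-out reference scoring.** A reference-stage sample scored
   against statistics that include itself has systematically deflated
   |z| (in-sample optimism, O(1/n)); the control stage would then almost
   never be named critical. Reference samples are therefore scored
   against jackknifed (leave-one-out) reference means/SDs inside
   `detect_critical_stage`. The primitive `spcc`/`sci` functions keep the
   plain full-reference definition.
2. **Lean module fallback.** Maximizing the best stage-mean sCI over a
   large list of noise modules interacts with an unavoidable variance
   asymmetry — non-reference stage means share the reference-estimation
   noise and fluctuate more than the (jackknifed) control mean — and
   biases null stage selection away from control. Returning the
   smallest-k size-valid cut instead of every size-valid cluster keeps
   the candidate list short and the null selection near-uniform
   (measured 23/35/42% over 100 seeds) while leaving the planted-DNB
   recovery at 100/100 with exact domain recovery.

## Random-forest biomarkers

Candidates are the control-vs-osteopenia differential metabolites. The
split is stratified 70/30 with round(0.7·n) per class, deterministic
under the seed. Forests use 500 trees, √p features per split, no depth
limit (conventional defaults, fixed). Importances are impurity-based
(Gini), normalized to percent over all candidates; features at ≥ 5% are
retained (top-3 fallback with a warning), a second forest is fit on the
panel, and test-set probabilities give the ROC/AUC. The AUC CI and the
comparison against the bone-turnover-marker baseline (a forest on
osteocalcin/PINP/β-CTX over the identical split) use DeLong's variance
and paired test — the standard machinery for correlated ROC curves.
Selection never touches test labels (verified by a label-flipping test).

## Module–trait association

Unsigned adjacency |cor|^β with β = 6 (the WGCNA default), topological
overlap TOM_ij = (Σ_u a_iu a_uj + a_ij)/(min(k_i,k_j) + 1 − a_ij),
average-linkage clustering on 1 − TOM with a *static* cut at height 0.97
(near the top of the TOM dendrogram, where genuine modules separate from
the noise background at these panel sizes; the canonical dynamic hybrid
cut is a large auxiliary algorithm and is deliberately not reproduced).
Modules below 5 members join the grey pool; colors follow size rank.
The eigen-metabolite is the first PC of the module's standardized
abundances, sign-oriented to the module mean. Module–trait and
biomarker–trait cells are Pearson r/p, pairwise-complete with ≥ 3 pairs,
NA for constant traits, flagged at p < 0.05. This stage is fully
deterministic.

## Mediation

Mediator model: OLS of the mediator on the exposure. Outcome model:
logistic regression of the binary outcome on exposure + mediator
(suspected separation raises an error suggesting regularization).
Effects are estimated by the quasi-Bayesian potential-outcomes
algorithm: 1000 parameter draws from the asymptotic normal of each
model, 100 mediator-noise simulations per draw, exposure contrast
mean ± 1 SD (or explicit treat/control values). Sharing the noise draws
across the four potential-outcome combinations makes
ACME + ADE = total hold exactly per draw, on the risk-difference scale.
CIs are 2.5/97.5 percentiles over draws; the proportion mediated
(ACME/total) is reported only when the total-effect CI excludes zero.
Against the Gauss–Hermite analytic ACME the 95% CI covers at 97% over
200 replicates at n = 2000 (nominal-to-slightly-conservative, as
expected from the extra simulation noise entering the draws).
Covariate adjustment and exposure–mediator interactions are out of scope.

## Pipeline and reproducibility

`run_pipeline` executes filter → DMA → iENA → RF → module–trait →
mediation per gender stratum (strata share no fitted state), writing
each stage's tables plus a manifest (config hash, seed, package
versions, per-stage timings, surfaced warnings such as dropped
metabolites or floored sCI denominators). Every random operation derives
its seed from the config; re-running a config reproduces byte-identical
outputs. Outputs are plain TSV/JSON; no plots are produced.

## Problem sizes used in validation

The test-suite and acceptance-script simulations use the generator's
default conditions: 100 cohorts of 150 × 60 for stage-recovery and null
calibration; 10,000 (suite) / 5,000 (script) null draws of 3 × 20 for
the trend test's size and 400 draws per step for power; 20 planted and
40–100 null forest fits at n = 160 with 20 features; 5,000 paired-AUC
null simulations at 30 per class; 200 mediation replicates at n = 2000;
and 32-metabolite two-block layouts for module recovery.

## Known limitations

- The sCI's third factor is unit-dependent by construction; comparing
  sCI across panels with heterogeneous units requires the standardized
  variant.
- The module search is a clustering heuristic; modules that are tight
  only within one stage but not pooled across stages can be missed.
- The static WGCNA cut under-splits nested module structure compared to
  dynamic tree cutting.
- The mediation engine assumes no exposure–mediator interaction and
  sequential ignorability; it quantifies association-compatible
  mediation, not confounding-robust causality.
- Null calibration of stage selection is approximate (within ±10
  percentage points of uniform), not exact: reference-anchored scoring
  necessarily treats the reference stage differently at second order.
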