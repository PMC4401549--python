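# Methods

This note documents the models, parameter choices, and numerical
conventions behind `scnp`, and what the synthetic-data experiments do and
do not demonstrate.

## The assay and its metrics

Single-cell network profiling (SCNP) measures intracellular signaling per
cell by phospho-flow cytometry. A *signaling node* is a (modulator,
exposure time, proteomic readout) triple — e.g. AraC+daunorubicin / 24 h /
cleaved PARP. Each patient sample is split across wells: an
autofluorescence well `a` (no antibody against the readout), an
unmodulated reference well `u`, and modulated wells `m`; 24 h drug nodes
use an untreated 24 h well as their `u` reference, since a 24 h culture is
its own baseline.

Raw intensities are mapped to Equivalent Reference Fluorophore (ERF)
units per plate by regressing the log10 median intensities of an 8-peak
rainbow-bead well on the manufacturer-assigned log10 reference values and
inverting the fitted line (log10 on both axes; any fixed base would do).
A positive slope makes the map strictly monotone, so all rank-based
metrics are unaffected by calibration; the ratio metrics are not, which
is why they are always computed on the ERF scale. Bead peaks at the
detector ceiling (default 2^18) are excluded; at least 3 resolvable peaks
are required.

Five per-node metrics are computed on gated populations:

- `Basal = log2(ERF_u / ERF_a)` and `log2Fold = log2(ERF_m / ERF_u)`,
  with "ERF" operationalized as the population **median** of calibrated
  values (mean available via the `location` argument). A nonpositive
  median makes the record non-evaluable rather than raising mid-pipeline.
- `Uu` and `Ua`: the Mann-Whitney U statistic of the modulated well
  against the unmodulated (resp. autofluorescence) well, scaled by
  `n_m * n_ref` so it lies in [0, 1]. Ties get half credit (midranks);
  this is the only convention under which two identical wells give
  exactly 0.5. `U/(n_m * n_ref)` is likewise the only scaling consistent
  with a (0, 1) range — a sum-based denominator `n_1 + n_2` is sometimes
  written for this statistic but is incompatible with U's maximum of
  `n_1 * n_2` and is not used anywhere in this package.
- `PhIntact`: the percentage of blast cells at or below the 98th
  percentile of the autofluorescence well's cPARP values. Percentiles use
  linear interpolation between order statistics (NumPy's default,
  type 7); this matters because the split point is quantitatively
  consequential. An empty autofluorescence well is an error — there is no
  fallback threshold.

Evaluability: any well whose gated population is below `min_cells`
(default 200) flags the record non-evaluable; non-evaluable values
propagate as missing, and patients missing a classifier's inputs are
excluded from scoring rather than imputed.

## Gating

Four nested populations: intact (scatter) ⊇ viable (Amine Aqua below a
threshold) ⊇ blast (CD45-dim / SSC-low) ⊇ cPARP-negative "healthy"
blast. Design choices:

- The scatter and CD45 gates default to **absolute rectangles** on the
  documented intensity scale of the simulator (debris near 10^1.8,
  blasts near 10^2.6 on FSC). Within-well quantile bounds are available
  (`GateParams.quantile_defaults()`), but quantile bounds only trim
  tails and cannot exclude a debris subpopulation, and they cap
  pure-population recall well below what a fixed gate achieves; absolute
  defaults are therefore primary.
- The viability threshold is the 98th percentile of the reference
  (autofluorescence) well's Amine Aqua values — deliberately the same
  rule as the cPARP split, for internal consistency.
- Gating runs on ERF-calibrated fluorescence channels, so fixed gate
  boundaries transfer across plates after gain removal; scatter channels
  are never calibrated (beads calibrate fluorescence only).
- Short-term signaling metrics use cPARP-negative blasts (apoptotic
  cells distort phospho readouts); the 24 h apoptosis nodes use **all
  viable blasts** — restricting to cPARP-negative cells there would gate
  away the very shift the nodes measure.

## The locked DX_SCNP classifier

Two node metrics after 24 h in-vitro AraC + daunorubicin: N1 = Uu(cPARP),
N2 = Uu(CD34). Transforms and coefficients are locked:

    C1 = (N1 - 0.5)^2 if N1 > 0.5 else 0
    C2 = (0.5 - N2)^2 if N2 < 0.5 else 0
    score = expit(-1.26004 + 95.60133*C1 + 34.94358*C2)

The hinge-squared transforms make the score flat at chance inputs and
steeply increasing once apoptosis induction (cPARP up) or blast depletion
(CD34 down) appears; the score is nondecreasing in N1, nonincreasing in
N2, and continuous at both hinges. The coefficients ship in
`src/scnp/data/locked_dxscnp.json`; a checksum test guards the artifact
against drift. The refinement procedure that produced the piecewise
transforms is not reconstructed — the training pipeline fits plain linear
logistic models and is used for structure-recovery experiments, not to
re-derive the printed coefficients.

## Training pipeline

Prescreening unions three screens with provenance tags: a univariate
exact rank test at level alpha (default 0.05), the top-15 random-forest
permutation importances (500 trees), and the nonzero coefficients of an
all-node L1 logistic fit. Patient order is canonicalized internally so
selection is order-invariant. `min_keep` back-fills by univariate p when
the screens select fewer than a usable minimum.

Combination models: every subset of 2–4 candidate node metrics is fit by
unpenalized logistic regression (an internal Newton/IRLS solver with a
1e-6 ridge for numerical stability; quasi-separation is detected and
flagged, not "fixed" by an unpenalized fallback) on its complete cases
and ranked by optimism-adjusted AUROC.

Optimism adjustment is Harrell's bootstrap: adjusted = apparent − mean
over B resamples of (AUROC of the resample-fit model on the resample −
its AUROC on the original data). Measured property worth knowing: under
the null at n≈90 with 2 predictors the estimator retains a small residual
optimism (mean adjusted AUROC ≈ 0.53, not 0.50), because the "original
data" evaluation still contains the in-bag patients; stratified
resampling does not remove it. Out-of-bag AUROC averages each patient's
linear predictor over the bootstrap fits that excluded them; under the
null it is mildly *pessimistic* (mean ≈ 0.42 at n=80) — OOB never
flatters a null model, which is the property the pipeline relies on.

Penalized fits use LASSO logistic regression (liblinear) with the penalty
chosen by 10-fold cross-validated deviance and the one-standard-error
rule; features are standardized internally and coefficients returned on
the original scale. Clinical classifiers: level 1 uses only covariates
available at diagnosis; level 2 adds cytogenetic risk, %CD34+ (from the
assay's phenotyping, passed in explicitly), FLT3-ITD (continuous and
binary) and NPM1. When every coefficient shrinks to zero the model is
flagged *not constructible* and refuses to score. Note that this outcome
is data-dependent: on outcome-independent cohorts of n≈80–200 with 13
inputs, chance correlations let CV-selected LASSO return a nonzero model
on roughly half of random cohorts; such models have no transferable skill
(validation AUROC ≈ 0.5), which is what the tests assert in aggregate.

## Validation statistics

- AUROC is computed as the scaled Mann-Whitney U (midrank ties), and a
  property test keeps it exactly equal to the brute-force pairwise
  win/half-tie count.
- The one-sided exact test of AUROC = 0.5 uses the exact null
  distribution of U, computed by dynamic programming over rank
  assignments (cached per class-size pair) and verified against full
  enumeration for all n1+n2 ≤ 10. With ties the DP null is invalid, so a
  10^4-draw permutation null is used instead.
- BCa intervals use a class-stratified bootstrap, bias correction z0 from
  the bootstrap fraction below the estimate (half credit at ties,
  clamped away from 0/1), and acceleration from jackknife skewness; a
  degenerate bootstrap distribution falls back to the percentile
  interval with a warning. DeLong intervals use the structural-component
  variance with a Wald interval truncated to [0, 1]; perfect separation
  yields a flagged degenerate interval.
- Power simulation draws binormal scores (responders N(mu, 1), others
  N(0, 1), mu = sqrt(2) Phi^-1(AUROC)); because the scores are
  continuous the exact null critical region depends only on the class
  sizes, so the null SF is computed once and 2,000 replicates cost
  milliseconds. The default design — n=50 at the 72% response rate of
  the emulated training set, true AUROC 0.75, alpha 0.05 — yields ~89%
  power, comfortably above the 80% design requirement.
- The combined redundancy test fits an unpenalized logistic model on the
  SCNP and clinical scores together and reports the Wald p for the SCNP
  term (likelihood-ratio optional); collinear score columns are rejected
  loudly rather than producing a meaningless p.
- Median splits send values equal to the median to the "≤ median" side.

## Cohort operations

Pocock-Simon minimization with range imbalance, unit factor weights, and
deterministic-assignment probability 0.8 (all config-exposed; the
balancing factors are induction response, sample types, cytogenetic risk,
parent trial arm, FLT3-ITD, readout availability). Measured behavior at
p=1.0, 200 patients, 6 two-level factors: worst per-factor-level arm
difference averages ≈ 2.4 and is ≤ 3 in ≈ 88% of runs — minimizing the
*total* marginal imbalance lets single factors drift a little; the
distribution is nonetheless stochastically far below simple
randomization's. Analysis sets exclude treatment-related mortality (the
assay measures blast chemosensitivity, not comorbidities) and
non-assessable samples, with a per-patient exclusion log; a patient with
both tissues appears once in each tissue's set. Imputation: unknown
cytogenetic risk becomes intermediate (the clinical convention); other
missing values take the training-set median (numeric) or mode
(categorical) to avoid leakage; every imputed field carries provenance.

## The synthetic cohort generator

What it emulates: elderly-AML induction cohorts with CR/CRi/RD/TRM
outcomes (~72% response among non-TRM at defaults), BM and/or PB samples,
plates of 28 samples with multiplicative per-channel gains plus a bead
well per plate, and per-well events from a debris / dead / lymphocyte /
blast mixture with log-normal channel intensities (documented in
`POPULATIONS`; blast share of live cells follows the tissue's blast
percentage). Ground truth is a latent chemosensitivity score s ~ U(0, 1)
per patient, linked to outcome by a logistic law (intercept −0.4, slope
3.0 at defaults) and hidden from all classifiers; TRM is drawn
independently of s.

The planted 24 h AraC+Dauno effect shifts blast cPARP up (0.5 log10 units
at s=1), CD34 down (0.4), and Amine Aqua up (0.35), each scaled by an
effective per-readout score s_r = clip(s + eps_r, 0, 1). The eps_r are
per-patient readout-specific decoupling noises (sd 0.05 for cPARP, 0.35
for CD34, 0.25 for Aqua): without them all three readouts are monotone
transforms of the same scalar and therefore statistically
interchangeable, which no real assay panel is; with them cPARP is the
cleanest chemosensitivity readout, CD34 and viability informative but
noisier — the structure the locked classifier presumes. Short-term
signaling nodes (FLT3L→pAKT/pERK/pS6, IL-27→pSTAT1/3/5, PMA→pCREB)
respond with fixed shifts plus outcome-independent per-patient
responsiveness noise; they are realistic decoys for the training
pipeline. Secondary-AML PB samples mix s with an independent draw
(weight 0.8 by default), reproducing the qualitative BM/PB discordance of
secondary disease.

Defaults worth restating: 10,000 mean events/well (Poisson); the
recovery and null experiments in the test suite run at 1,000–2,000
events/well and n ≤ 100 patients per cohort, sizes at which every metric
is estimated to well under its biological spread. At generator defaults
the responder-vs-RD mean Uu(cPARP) gap is ≈ 0.09 and the locked
classifier reaches AUROC ≈ 0.70 on a 100-patient cohort; with a sharp
outcome link (slope 8, intercept −2.5) the gap is ≈ 0.18–0.2 and the
locked AUROC ≈ 0.90. The autofluorescence well carries the surface
stains (CD45, CD34, Amine Aqua) and omits only the readout antibodies,
so it can be gated like any other well.

What passing tests do **not** show about real data: the generator has no
spectral spillover, doublets, acquisition drift, non-log-normal
heavy tails, or inter-antibody correlation structure, and its gate
boundaries are matched to its own intensity scale; recovery results are
statements about the pipeline's correctness under the assumed structure,
not about clinical performance.

## File formats

Event tables round-trip as CSV (header `event_index,FSC,...`, UTF-8, '.'
decimal, JSON metadata sidecar; lossless) or as minimal FCS 3.1
(list-mode float32 little-endian single dataset, metadata in custom TEXT
keywords; exact at float32 precision). The FCS reader/writer covers only
this profile and reports malformed input with byte offsets. The node
panel is a YAML list of (modulator, time, readout, population, reference,
metrics); the shipped default covers the apoptosis nodes plus three
signaling pathways. The locked model is a JSON artifact; calibrations
serialize to JSON with plate id and fit diagnostics.
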