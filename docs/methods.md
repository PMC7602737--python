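# Methods

This note documents the models, the statistical procedures, the
synthetic-data generator, and the numerical and design choices behind
`lactoflow`. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Two-compartment water-turnover model

### Model and assumptions

A lactating dam receives an intravenous D2O bolus at t = 0. Two
well-mixed pools are modelled: the dam's total body water `W_d` (g) and
the pooled body water of her whole litter `W_l` (g). Tracer amounts
follow

    dQ_d/dt = −(k_dl + k_de) Q_d
    dQ_l/dt = k_dl Q_d − k_le Q_l,      Q_d(0) = dose, Q_l(0) = 0

with first-order constants (h⁻¹): `k_dl` dam→litter transfer through
milk, `k_de` dam elimination to the environment, `k_le` litter
elimination. Measured enrichments are the concentrations
`C_d = Q_d/W_d`, `C_l = Q_l/W_l` above background, carried in dose units
per unit body water (g D2O per g water; the defining arithmetic is
`W_d = dose / C_d(0)`, so the absolute unit cancels).

Assumptions: no litter→dam return flow (pups' water intake is essentially
milk-derived); pool sizes constant over the sampling week; milk water
flow equals total dam→litter water flow; a single pooled litter
compartment (litter urine is pooled across pups). Milk flow in g/day is
`W_d · k_dl · 24`.

The closed forms are

    C_d(t) = (dose/W_d) e^(−k_d t),                         k_d = k_dl + k_de
    C_l(t) = (dose·k_dl/W_l) (e^(−k_d t) − e^(−k_le t)) / (k_le − k_d)

with the analytic limit `(dose·k_dl/W_l) · t · e^(−k_d t)` substituted
when `|k_le − k_d|` falls below 1e−10 (relative). The litter curve rises
to a single peak at `t* = ln(k_le/k_d)/(k_le − k_d)` and decays; the test
suite checks the closed forms against an independent ODE integration and
a mass-balance quadrature.

### Estimation

1. `fit_tbw`: ordinary least squares of ln(C_d) on time;
   `W_d = dose/e^intercept`, `k_d = −slope`. Requires ≥ 3 points with
   positive enrichment.
2. `fit_turnover`: bounded nonlinear least squares (scipy `dogbox`,
   ftol = xtol = gtol = 1e−14, parameters scaled by their starting
   values). The objective sums **log**-residuals for the dam curve
   (multiplicative error on an exponential) and linear residuals scaled
   by 1/max(C_l) for the litter curve, so both series contribute at
   comparable magnitude. Starting values: `W_d` and `k_d` from
   `fit_tbw`, split `k_dl = k_de = k_d/2`; `W_l` from 0.7 × litter weight
   when supplied, else 0.75 × W_d.

**Identifiability — why W_l is fixed.** The litter curve depends on
(`k_dl/W_l`, `k_d`, `k_le`) only: the amplitude confounds `k_dl` with
`W_l`, and the dam curve fixes only the sum `k_dl + k_de`. A free
5-parameter fit therefore sits on a ridge and returns arbitrary points
along it. `fit_turnover` consequently holds `W_l` fixed at its starting
value by default — in practice litters are weighed daily, and body water
is ~70% of body mass, so `W_l = 0.7 ×` measured litter weight is an
externally measured quantity, not a fitted one. `fix_W_l=False` frees it
for users who accept the ridge.

**Bounds.** Rate constants are bounded above by 1 h⁻¹: a body-water pool
turning over completely within an hour is physiologically impossible, and
the bound removes a degenerate solution in which `k_le → ∞` flattens the
litter curve instead of `k_dl → 0` when litter enrichment is absent.
Non-convergence is flagged (`converged=False`), never silently returned,
and parameters landing on a bound are recorded as warnings on the fit.

## Relative expression (2^−ΔΔCq)

Technical replicates are averaged on the Cq scale. ΔCq is the gene's Cq
minus the arithmetic mean Cq of the housekeeping set (mammary:
Actb/Uxt/Rps9; pituitary: Actb/Vcp/Rps9); any sample missing a
housekeeping gene is dropped (logged), while a missing target gene only
leaves that one cell empty. ΔΔCq subtracts the **mean ΔCq of the
reference group** (CTL diet at L12) per gene, so each reference sample
keeps its own deviation and the reference-group mean of −ΔΔCq is exactly
0 with a nonzero SEM — matching how such tables print a 0.00 ± SEM
reference cell. −ΔΔCq is reported as log2 fold change; per-day diet fold
changes are `2^(mean −ΔΔCq_treated − mean −ΔΔCq_reference)` within the
period, which cancels the global reference and any per-sample additive Cq
offset.

Primer efficiency is validated (`E = (2^(−1/slope) − 1)·100` from the
Cq-vs-log2(dilution) regression; pass when E > 90 and ΔCq(RT−) > 10 with
absent RT− amplifications set to the sentinel Cq 50) but **not** used to
correct fold changes: the method assumes near-100% efficiencies, and an
efficiency-corrected mode is out of scope.

## Univariate statistics

Two-way ANOVA with diet and period factors uses type-II sums of squares:
the involution cells are larger (n ≈ 11 vs 6) and type-II requires no
a-priori factor ordering. A response with zero variance is flagged
degenerate and returns p = 1 throughout. Post-hoc conventions:

- **Periods within each diet:** Tukey HSD with Tukey–Kramer standard
  errors, studentized-range reference with k = 3 and the residual df of
  the full model.
- **Diets within each period:** pooled-MSE t contrasts, Šidák-adjusted
  with family size m = number of periods: `p' = 1 − (1 − p)^m`.
- Both families share the full model's pooled MSE. Letters (a/b) mark
  diet differences within period, digits (1/2/3) mark period groups
  within diet via a compact letter display built from maximal cliques of
  the non-significance graph.

Alpha is 0.05 throughout, and no correction is applied **across** genes —
a deliberate fidelity choice to the analysis style this pipeline mirrors,
documented rather than endorsed. Diagnostics are Shapiro–Wilk on pooled
residuals and Brown–Forsythe (median-centered Levene) across cells.
The `sidak_null_fwer` helper re-runs the balanced ANOVA + Šidák chain
vectorized over thousands of null datasets to measure the realized
family-wise error; the tests cross-check it against the
statsmodels-backed path and hold it to the nominal 5%.

## Multivariate models

PCA operates on the column-centered, unit-variance-scaled (ddof = 1)
matrix with a deterministic sign convention (largest-|loading| positive).
PLS-DA is NIPALS on the centered one-hot class dummy: per component, the
unit-norm X-weight maximizing covariance with the class scores, with
deflation of both X and Y; R2X/R2Y accumulate the deflated sums of
squares. Scores are orthogonal across components (tested to 1e−8), and
the implementation is cross-checked against an independent PLS fit of the
centered class indicator.

- **Per-period normalization** ("masking the time effect"): each gene is
  centered and scaled to unit variance within each lactation point
  (ddof = 1), annihilating every gene × period mean difference while
  preserving within-period diet contrasts. Genes with zero variance
  inside any period are dropped with a warning.
- **Q2**: stratified, seeded 7-fold CV; `Q2 = 1 − PRESS/SS` with PRESS
  the squared error of held-out dummy predictions from models refit on
  each training fold and SS the corrected total of the dummy. A fold draw
  that leaves a training set without some class is re-drawn (logged).
- **VIP**: `VIP_j = sqrt(p · Σ_a SSY_a w_aj² / Σ_a SSY_a)` with unit-norm
  weights; mean squared VIP is identically 1.
- **CV-ANOVA**: two modes. `method="f"` is the F-ratio
  `((SS − PRESS)/A) / (PRESS/(n − A − 1))` on the CV predictive
  residuals — an approximation to the bookkeeping of commercial PLS
  software. It is conservative by construction: whenever PRESS ≥ SS
  (i.e. Q2 ≤ 0, the typical no-signal outcome) the p saturates at 1, so
  its null distribution has a point mass at 1 rather than being uniform.
  `method="permutation"` ranks the model's PRESS within the PRESS
  distribution under random relabelings, giving an exactly calibrated
  finite-sample p (uniform under the null); it is the mode to use when a
  calibrated significance level matters.
- **Kinetic clusters**: the loading-plot cluster reading is re-cast as a
  testable rule — each gene joins the seed gene (cluster barycenter,
  defaults *Prlr*/*Insr*/*Cpt1a*) with which its Pearson correlation
  across samples is maximal, if that correlation exceeds the threshold
  (default 0.7); ties break toward larger |r|, then lexicographic symbol.

## Synthetic-data generator

The generator emulates the study conditions that the pipeline is meant to
analyze, from explicit ground truth and a single seed (all streams are
derived, reproducible, and independent per dyad/table):

- **Design**: diets CTL/FEN; periods L12, L18, Inv1; 6 samples per
  diet × period cell during lactation and 11 at involution; 16 tracer
  dyads per diet by default. Dose 4.92 g/kg on a 300 g dam. Dam plasma
  sampled at {4, 24, 48, 72, 96} h post-dose (daily L11–L15, first
  sample a few hours after the bolus), litter urine at {24 … 168} h
  (daily L12–L18).
- **Kinetic ground truth**: per-diet base parameters (W_d = 200 g,
  W_l = 150 g, k_de = 0.004 h⁻¹, k_le = 0.010 h⁻¹) with k_dl set so that
  the group-mean milk flows equal the published 55.90 (CTL) and 64.45
  (FEN) g/day; per-dyad lognormal inter-animal jitter, CV 10%.
- **Enrichment noise**: mean-one multiplicative lognormal, CV 1%
  (instrument-repeatability scale; the source study reports no error
  model).
- **Cq model**: `Cq = baseline(gene) − effect(gene, diet, period) +
  sample offset + noise`, housekeeping genes receiving no effect. The
  offset (SD 0.5 cycles, shared by all genes of a sample) emulates
  loading/RT differences that housekeeping normalization absorbs; the
  per-cell noise (SD 0.5 cycles) lumps technical and biological
  variation. The default effect table is the study's full printed set of
  42 mammary target-gene group means (−ΔΔCq vs CTL at L12), so a
  zero-noise simulation reproduces the published tables exactly and the
  three temporal kinetics (lactation peak / late peak / involution rise)
  are present by construction.
- **Hormones**: period means follow the published decline-then-rise
  profiles (insulin, IGF-1, leptin), the prolactin drop, and the
  involution estrogen rise; diet multipliers are 1 except insulin at L12
  (×1.771) and estrogens at Inv1 (×1.355); mean-one lognormal noise,
  CV 30%.

What the generator does **not** emulate: amplification/melting curves,
correlated biological co-regulation beyond the group-mean structure
(genes fluctuate independently around their cell means), litter-size
variation, repeated measures on the same animal across periods, or
missing data. Passing tests therefore demonstrate the correctness and
calibration of the computational chain under the study's design and
realistic noise — not robustness to artifacts these omissions would
introduce in real data.

## Numerical choices and degenerate inputs

- Closed-form/ODE agreement tolerance 1e−8; degenerate `k_le = k_d`
  handled analytically; optimizer tolerances 1e−14 with dogbox and
  parameter scaling (residuals are numerically tiny in enrichment units).
- Cq values are validated into (0, 50]; 50 is the no-amplification
  sentinel. A non-negative dilution slope is flagged invalid rather than
  producing a complex efficiency.
- Constant responses, empty design cells, missing reference groups,
  single classes, zero-variance correlation inputs and unknown config
  keys all raise explicit errors before any computation runs.
- All stochastic procedures (simulation, CV folds, permutations) consume
  explicit seeds; identical config + seed yields byte-identical pipeline
  outputs (tested).

## Known limitations

- Equivalence with the original study's proprietary compartmental fits
  and PLS software cannot be asserted — only internal consistency and
  recovery of known ground truth.
- The F-mode CV-ANOVA df bookkeeping is an approximation (the commercial
  algorithm is unpublished); use the permutation mode for calibrated
  significance.
- The per-gene p-values and VIP gene lists of any particular animal
  dataset depend on raw data; the pipeline reproduces procedures, not
  those lists, when raw data are unavailable.
- No mixed-effects modelling of repeated litters, no efficiency-corrected
  fold changes, no isotope-fractionation corrections.
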