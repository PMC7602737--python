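# lactoflow

Analysis pipeline for rodent lactation studies that quantify milk
production with the deuterium-oxide (D2O) water-turnover method and
profile mammary/pituitary gene expression by RT-qPCR across lactation and
early involution, under a two-diet design (control vs a galactagogue
supplement such as fenugreek).

It is written for physiologists and biostatisticians who have: tracer
enrichment time courses (dam plasma, pooled litter urine), quantification
cycle (Cq) tables, primer-validation dilution series, and plasma hormone
concentrations — and who want the complete, reproducible computational
chain from those raw tables to the summary statistics a paper reports.

## What it computes

**Milk flow from tracer kinetics.** A two-compartment model: the dam's
body-water pool `W_d` receives a D2O bolus; tracer transfers to the pooled
litter pool `W_l` through milk at rate `k_dl` (h⁻¹) and is eliminated from
each pool (`k_de`, `k_le`):

    C_d(t) = (dose / W_d) · e^(−(k_dl + k_de) t)
    C_l(t) = (dose · k_dl / W_l) · (e^(−k_d t) − e^(−k_le t)) / (k_le − k_d)

`W_d` comes from the intercept of the log-linear plasma decay
(`W_d = dose / e^intercept`); the rate constants from nonlinear least
squares over both curves; and milk (water) flow is `W_d · k_dl · 24`
g/day. The litter pool size is pinned from measured litter weight
(~70% body water) because enrichment data alone determine only the ratio
`k_dl / W_l`.

**Relative expression by the 2^−ΔΔCq method.** ΔCq against the arithmetic
mean of three housekeeping genes (mammary: *Actb*, *Uxt*, *Rps9*;
pituitary: *Actb*, *Vcp*, *Rps9*), ΔΔCq against a reference group (CTL
diet at lactation day 12), reported as −ΔΔCq = log2 fold change, plus
per-day diet fold changes `2^(mean −ΔΔCq_FEN − mean −ΔΔCq_CTL)`. Primer
QC: efficiency `E(%) = (2^(−1/slope) − 1) × 100` from a 2-fold dilution
ladder, and ΔCq(RT−) checks with the no-amplification sentinel Cq = 50
(valid when E > 90% and ΔCq(RT−) > 10).

**Univariate statistics.** Diet × period two-way ANOVA (type-II sums of
squares for the unbalanced involution cells), Tukey HSD across the three
periods within each diet and Šidák-adjusted pooled-MSE contrasts between
diets within each period, significance letters/digits, Shapiro–Wilk and
Brown–Forsythe diagnostics, Student's t (including from published
mean ± SEM summaries), Pearson correlation, percent change.

**Multivariate models.** PCA and NIPALS PLS-DA on the expression matrix;
"masking" of the dominant longitudinal signal by centering and
unit-variance scaling each gene within each lactation point; R2X/R2Y from
deflation, Q2 by stratified 7-fold cross-validation, CV-ANOVA significance
(F approximation and an exact permutation calibration), VIP scores (mean
squared VIP = 1), and correlation-based assignment of genes to temporal
"kinetic" clusters around seed genes (*Prlr*, *Insr*, *Cpt1a*).

**Synthetic data.** A seeded generator produces every input from explicit
ground truth — the study's dose (4.92 g/kg), sampling schedules, group
sizes (6 per diet×period cell during lactation, 11 at involution) and the
published expression/hormone group means — so the whole pipeline is
testable end to end without animal data.

## Worked example

```python
import lactoflow as lf

# simulate one dyad under the study design and recover its milk flow
cfg = lf.SimConfig(seed=1)
dam, litter = lf.simulate_enrichment(cfg, "CTL01")
truth = cfg.true_params["CTL01"]
fit = lf.fit_turnover(dam, litter, litter_weight=truth.W_l / 0.7)
print(f"k_dl = {fit.params.k_dl:.5f} /h   milk flow = {fit.milk_flow:.1f} g/day")

# expression chain on a zero-noise simulation carrying the published means
cfg0 = lf.SimConfig(seed=1, cq_noise_sd=0, sample_effect_sd=0,
                    enrichment_noise_cv=0, inter_animal_cv=0, hormone_noise_cv=0)
cq = lf.synthetic.simulate_cq(cfg0)
expr = lf.neg_ddcq(lf.delta_cq(cq, ["Actb", "Uxt", "Rps9"]), ("CTL", "L12"))
print(f"Cpt1a fold change at L12: {lf.fold_change_by_day(expr, 'Cpt1a', 'L12'):.2f}")
print(f"milk-flow gain from published means: "
      f"{lf.percent_change(55.90, 64.45):.1f}%")
```

prints

```
k_dl = 0.00980 /h   milk flow = 46.6 g/day
Cpt1a fold change at L12: 3.84
milk-flow gain from published means: 15.3%
```

The fitted `k_dl` is this dyad's transfer constant (its dam-to-litter
water turnover per hour); multiplied by the dam's fitted body water and
24 h it gives the milk flow in g/day (this particular simulated dam has a
smaller-than-average body-water pool, hence a flow below the 55.9 g/day
group mean). The fold change of 3.84 is the
within-day FEN/CTL expression ratio of the β-oxidation gene *Cpt1a*
implied by the group means, and 15.3% is the relative milk-flow gain of
the supplemented group.

The same stages run from a shell:

```sh
lactoflow run --seed 1 --outdir out/        # full pipeline on simulated inputs
lactoflow simulate --seed 1 --outdir out/   # just write the input CSVs
lactoflow mva --config run.yaml             # PCA + PLS-DA stage only
```

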