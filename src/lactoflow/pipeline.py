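"""End-to-end orchestration: schema-validated CSV I/O and staged analysis.

Stages run in order tracer -> qpcr -> univariate -> multivariate, each
reading/writing long-format CSVs with documented headers, so every stage
is independently re-runnable.  Identical config + seed produces
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import multivariate as mva
from . import qpcr, stats, synthetic, tracer

__all__ = [
    "RunConfig",
    "read_enrichment_csv",
    "write_enrichment_csv",
    "read_cq_csv",
    "read_hormone_csv",
    "run_simulate",
    "run_milkflow",
    "run_qpcr",
    "run_stats",
    "run_mva",
    "run_full_analysis",
]

logger = logging.getLogger(__name__)

ENRICHMENT_COLUMNS = [
    "dyad_id", "compartment", "time_h", "enrichment", "dose", "dam_body_weight",
]
# optional extra column: litter_weight (g) — pins the litter body-water pool
HORMONE_COLUMNS = ["animal_id", "diet", "period", "hormone", "concentration"]

#: default seed genes (cluster barycenters) for the three temporal kinetics
KINETIC_SEEDS = ("Prlr", "Insr", "Cpt1a")


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    seed: int = 0
    outdir: Path = Path("lactoflow_out")
    simulate: dict = field(default_factory=dict)  # SimConfig overrides; {} = defaults
    enrichment_csv: Path | None = None  # read instead of simulating when set
    cq_csv: Path | None = None
    hormone_csv: Path | None = None
    hkg: dict = field(default_factory=lambda: {k: list(v) for k, v in synthetic.HKG.items()})
    reference_group: tuple[str, str] = ("CTL", "L12")
    alpha: float = 0.05
    plsda_components: int = 2
    plsda_folds: int = 7
    cluster_seed_genes: tuple[str, ...] = KINETIC_SEEDS
    cluster_r_threshold: float = 0.7

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.outdir = Path(cfg.outdir)
        cfg.reference_group = tuple(cfg.reference_group)
        cfg.cluster_seed_genes = tuple(cfg.cluster_seed_genes)
        for key in ("enrichment_csv", "cq_csv", "hormone_csv"):
            if getattr(cfg, key) is not None:
                setattr(cfg, key, Path(getattr(cfg, key)))
        return cfg

    def sim_config(self) -> synthetic.SimConfig:
        return synthetic.SimConfig(seed=self.seed, **self.simulate)


def _require_columns(df: pd.DataFrame, columns: list[str], what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{what} is missing required column(s): {missing}")


def write_enrichment_csv(series_list, path: str | Path,
                         litter_weights: dict[str, float] | None = None) -> None:
    recs = []
    for s in series_list:
        for t, e in zip(s.times, s.enrichment):
            rec = {"dyad_id": s.dyad_id, "compartment": s.compartment, "time_h": t,
                   "enrichment": e, "dose": s.dose, "dam_body_weight": s.dam_body_weight}
            if litter_weights is not None:
                rec["litter_weight"] = litter_weights.get(s.dyad_id, np.nan)
            recs.append(rec)
    cols = ENRICHMENT_COLUMNS + (["litter_weight"] if litter_weights is not None else [])
    pd.DataFrame(recs, columns=cols).to_csv(path, index=False)


def read_enrichment_csv(
    path: str | Path,
) -> tuple[dict[str, dict[str, tracer.EnrichmentSeries]], dict[str, float]]:
    """Returns ({dyad_id: {compartment: EnrichmentSeries}}, {dyad_id: litter_weight})."""
    df = pd.read_csv(path)
    _require_columns(df, ENRICHMENT_COLUMNS, "enrichment table")
    out: dict[str, dict[str, tracer.EnrichmentSeries]] = {}
    weights: dict[str, float] = {}
    for (dyad, comp), sub in df.groupby(["dyad_id", "compartment"], sort=True):
        sub = sub.sort_values("time_h")
        out.setdefault(dyad, {})[comp] = tracer.EnrichmentSeries(
            dyad_id=dyad,
            compartment=comp,
            times=sub["time_h"].to_numpy(),
            enrichment=sub["enrichment"].to_numpy(),
            dose=float(sub["dose"].iloc[0]),
            dam_body_weight=float(sub["dam_body_weight"].iloc[0]),
        )
        if "litter_weight" in sub.columns and np.isfinite(sub["litter_weight"].iloc[0]):
            weights[dyad] = float(sub["litter_weight"].iloc[0])
    return out, weights


def read_cq_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, qpcr.CQ_COLUMNS, "Cq table")
    bad = df[(df["cq"] <= 0) | (df["cq"] > qpcr.NO_AMPLIFICATION_CQ)]
    if not bad.empty:
        raise ValueError(f"Cq values outside (0, 50] in {len(bad)} row(s)")
    return df


def read_hormone_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, HORMONE_COLUMNS, "hormone table")
    return df


# ---------------------------------------------------------------- stages

def run_simulate(config: RunConfig, outdir: Path) -> dict[str, Path]:
    """Generate and write every synthetic input CSV."""
    sim = config.sim_config()
    series = []
    for dyad in sim.dyad_ids():
        dam, litter = synthetic.simulate_enrichment(sim, dyad)
        series.extend([dam, litter])
    # litter body water is ~70% of the (measured) litter weight
    litter_weights = {d: p.W_l / 0.7 for d, p in sim.true_params.items()}
    paths = {
        "enrichment": outdir / "enrichment.csv",
        "cq": outdir / "cq.csv",
        "hormones": outdir / "hormones.csv",
    }
    write_enrichment_csv(series, paths["enrichment"], litter_weights)
    synthetic.simulate_cq(sim).to_csv(paths["cq"], index=False)
    synthetic.simulate_hormones(sim).to_csv(paths["hormones"], index=False)
    return paths


def run_milkflow(enrichment_path: Path, outdir: Path) -> pd.DataFrame:
    """Fit the two-pool model per dyad; write per-dyad fits and a diet summary."""
    dyads, litter_weights = read_enrichment_csv(enrichment_path)
    recs = []
    for dyad_id, comps in sorted(dyads.items()):
        if "dam_plasma" not in comps or "litter_urine" not in comps:
            raise ValueError(f"dyad {dyad_id!r} lacks one of the two compartments")
        fit = tracer.fit_turnover(comps["dam_plasma"], comps["litter_urine"],
                                  litter_weight=litter_weights.get(dyad_id))
        p = fit.params
        recs.append(
            {"dyad_id": dyad_id, "W_d": p.W_d, "W_l": p.W_l, "k_dl": p.k_dl,
             "k_de": p.k_de, "k_le": p.k_le, "milk_flow": fit.milk_flow,
             "sse": fit.sse, "n_obs": fit.n_obs, "converged": fit.converged}
        )
    fits = pd.DataFrame(recs)
    fits.to_csv(outdir / "turnover_fits.csv", index=False)

    fits["diet"] = fits["dyad_id"].str[:3]
    ok = fits[fits["converged"]]
    summary = ok.groupby("diet")["milk_flow"].agg(["mean", "sem", "count"])
    if {"CTL", "FEN"} <= set(summary.index):
        t, p_val = stats.students_t(
            ok.loc[ok["diet"] == "CTL", "milk_flow"],
            ok.loc[ok["diet"] == "FEN", "milk_flow"],
        )
        summary.attrs["t"] = t
        summary.attrs["p"] = p_val
        summary.attrs["percent_change"] = stats.percent_change(
            summary.loc["CTL", "mean"], summary.loc["FEN", "mean"]
        )
    summary.to_csv(outdir / "milkflow_summary.csv")
    return fits


def run_qpcr(config: RunConfig, cq_path: Path, outdir: Path) -> dict[str, qpcr.ExpressionMatrix]:
    """Relative expression per tissue; writes wide and long -ddCq tables."""
    table = read_cq_csv(cq_path)
    out: dict[str, qpcr.ExpressionMatrix] = {}
    for tissue, sub in table.groupby("tissue", sort=True):
        hkg = config.hkg.get(tissue)
        if hkg is None:
            raise ValueError(f"no housekeeping genes configured for tissue {tissue!r}")
        dcq = qpcr.delta_cq(sub, hkg)
        ref_diet, ref_period = config.reference_group
        present = (dcq["diet"] == ref_diet) & (dcq["period"] == ref_period)
        if not present.any():
            raise ValueError(
                f"reference group {config.reference_group} absent from {tissue} data"
            )
        expr = qpcr.neg_ddcq(dcq, tuple(config.reference_group), hkg_set=hkg)
        expr.values.to_csv(outdir / f"expression_{tissue}_wide.csv")
        expr.long().to_csv(outdir / f"expression_{tissue}_long.csv", index=False)
        out[tissue] = expr
    return out


def run_stats(
    config: RunConfig,
    expression: dict[str, qpcr.ExpressionMatrix],
    hormone_path: Path | None,
    outdir: Path,
) -> pd.DataFrame:
    """Per-gene (and per-hormone) two-way ANOVA with post-hocs and fold changes.

    Emits one row per gene x period shaped like the study tables: cell
    means +/- SEM per diet, per-day fold change, effect p-values and
    significance symbols.
    """
    recs = []

    def analyze(name: str, kind: str, values, diets, periods, fold_fn=None):
        anova = stats.two_way_anova(values, diets, periods)
        post = stats.posthoc_tests(values, diets, periods, alpha=config.alpha)
        df = pd.DataFrame({"value": values, "diet": diets, "period": periods})
        for period in sorted(df["period"].unique()):
            row = {"variable": name, "kind": kind, "period": period,
                   "p_interaction": anova.p_interaction, "p_period": anova.p_period,
                   "p_diet": anova.p_diet}
            for diet in ("CTL", "FEN"):
                cell = df[(df["diet"] == diet) & (df["period"] == period)]["value"]
                row[f"{diet}_mean"] = cell.mean()
                row[f"{diet}_sem"] = cell.sem()
                row[f"{diet}_n"] = len(cell)
                row[f"{diet}_letters"] = (
                    post.diet_letters[(diet, period)] + post.period_digits[(diet, period)]
                )
            row["fold_change"] = (
                fold_fn(period) if fold_fn is not None
                else row["FEN_mean"] / row["CTL_mean"] if row["CTL_mean"] else np.nan
            )
            sh_p, bf_p = stats.diagnostics(
                anova.residuals, (df["diet"] + ":" + df["period"]).to_numpy()
            )
            row["shapiro_p"], row["brown_forsythe_p"] = sh_p, bf_p
            recs.append(row)

    for tissue, expr in sorted(expression.items()):
        long = expr.long().dropna(subset=["neg_ddcq"])
        for gene, sub in long.groupby("gene", sort=True):
            analyze(
                f"{tissue}:{gene}", "gene",
                sub["neg_ddcq"].to_numpy(), sub["diet"].to_numpy(), sub["period"].to_numpy(),
                fold_fn=lambda period, g=gene, e=expr: qpcr.fold_change_by_day(e, g, period),
            )

    if hormone_path is not None:
        hormones = read_hormone_csv(hormone_path)
        for hormone, sub in hormones.groupby("hormone", sort=True):
            analyze(
                f"plasma:{hormone}", "hormone",
                sub["concentration"].to_numpy(), sub["diet"].to_numpy(), sub["period"].to_numpy(),
            )

    results = pd.DataFrame(recs)
    results.to_csv(outdir / "univariate_results.csv", index=False)
    return results


def run_mva(
    config: RunConfig,
    expression: dict[str, qpcr.ExpressionMatrix],
    outdir: Path,
) -> dict:
    """PCA (longitudinal structure) and PLS-DA for diet (per-period normalized)."""
    out: dict = {}
    for tissue, expr in sorted(expression.items()):
        values = expr.values.dropna(axis=1)
        meta = expr.meta
        n_comp = min(config.plsda_components, values.shape[0] - 1, values.shape[1])

        pca = mva.fit_pca(values, n_comp)
        pd.DataFrame(
            pca.scores, index=values.index,
            columns=[f"PC{i + 1}" for i in range(n_comp)],
        ).to_csv(outdir / f"pca_scores_{tissue}.csv")

        norm = mva.normalize_by_period(values, meta["period"])
        model = mva.fit_plsda(norm, meta["diet"].to_numpy(), n_comp)
        mva.q2_cv(norm, meta["diet"].to_numpy(), n_comp,
                  n_folds=min(config.plsda_folds, norm.values.shape[0]),
                  seed=config.seed, model=model)
        model.cv_anova_p = mva.cv_anova(model, class_labels=meta["diet"].to_numpy())

        vip = pd.Series(model.vip, index=norm.values.columns, name="vip")
        vip.sort_values(ascending=False).to_csv(outdir / f"vip_{tissue}.csv")

        seeds = [g for g in config.cluster_seed_genes if g in values.columns]
        clusters = (
            mva.correlation_clusters(values, seeds, config.cluster_r_threshold)
            if len(seeds) >= 2 else pd.Series(dtype=object)
        )
        clusters.to_csv(outdir / f"kinetic_clusters_{tissue}.csv", header=["cluster"])

        out[tissue] = {
            "pca_explained_2comp": float(pca.explained_variance_ratio[:2].sum()),
            "r2x_cum": model.r2x_cum,
            "r2y_cum": model.r2y_cum,
            "q2_cum": model.q2_cum,
            "cv_anova_p": model.cv_anova_p,
            "model": model,
            "clusters": clusters,
        }
        pd.DataFrame(
            [{k: v for k, v in out[tissue].items() if k not in ("model", "clusters")}]
        ).to_csv(outdir / f"mva_summary_{tissue}.csv", index=False)
    return out


def run_full_analysis(config: RunConfig) -> dict:
    """Execute every stage; returns a run report dict (also written to disk)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if config.cq_csv is None or config.enrichment_csv is None or config.hormone_csv is None:
        sim_paths = run_simulate(config, outdir)
    else:
        sim_paths = {}
    enrichment_path = config.enrichment_csv or sim_paths["enrichment"]
    cq_path = config.cq_csv or sim_paths["cq"]
    hormone_path = config.hormone_csv or sim_paths["hormones"]

    fits = run_milkflow(enrichment_path, outdir)
    expression = run_qpcr(config, cq_path, outdir)
    results = run_stats(config, expression, hormone_path, outdir)
    models = run_mva(config, expression, outdir)

    fits_diet = fits[fits["converged"]].copy()
    fits_diet["diet"] = fits_diet["dyad_id"].str[:3]
    means = fits_diet.groupby("diet")["milk_flow"].mean()
    report = {
        "seed": config.seed,
        "n_dyads_fit": int(len(fits)),
        "n_dyads_converged": int(fits["converged"].sum()),
        "milk_flow_mean": {k: float(v) for k, v in means.items()},
        "milk_flow_percent_change": (
            float(stats.percent_change(means["CTL"], means["FEN"]))
            if {"CTL", "FEN"} <= set(means.index) else None
        ),
        "n_univariate_rows": int(len(results)),
        "multivariate": {
            t: {k: float(v) for k, v in d.items() if k not in ("model", "clusters")}
            for t, d in models.items()
        },
    }
    (outdir / "run_report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    logger.info("pipeline complete; outputs in %s", outdir)
    return report
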