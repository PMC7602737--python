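"""Primer validation and relative gene-expression analysis (2^-ddCq method).

The quantification cycle (Cq) of each gene is normalized to the arithmetic
mean Cq of a set of housekeeping genes (dCq), then to the mean dCq of a
reference group (ddCq).  The negated value, -ddCq, reads as a log2 fold
change; per-period fold changes between diets are 2 to the difference of
group mean -ddCq values.

Primer quality control covers amplification efficiency from a 2-fold
dilution ladder and genomic-DNA / non-specific amplification checks
against no-reverse-transcriptase (RT-) controls, with the conventional
sentinel Cq of 50 standing for "no amplification".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "NO_AMPLIFICATION_CQ",
    "DilutionSeries",
    "PrimerQC",
    "ExpressionMatrix",
    "efficiency_from_slope",
    "primer_efficiency",
    "rt_minus_delta",
    "delta_cq",
    "neg_ddcq",
    "fold_change_by_day",
]

logger = logging.getLogger(__name__)

#: Sentinel Cq assigned when a reaction shows no amplification.
NO_AMPLIFICATION_CQ = 50.0

#: Validity thresholds: efficiency > 90% and dCq(RT-) > 10 cycles.
MIN_EFFICIENCY = 90.0
MIN_DCQ_RT_MINUS = 10.0

CQ_COLUMNS = ["sample_id", "tissue", "diet", "period", "gene", "cq"]


@dataclass(frozen=True)
class DilutionSeries:
    """Cq measurements of one primer pair over a serial 2-fold dilution ladder."""

    gene: str
    log2_dilution: np.ndarray  # 0, -1, -2, ... for 1:1, 1:2, 1:4 ...
    cq: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "log2_dilution", np.asarray(self.log2_dilution, float))
        object.__setattr__(self, "cq", np.asarray(self.cq, float))
        if self.log2_dilution.shape != self.cq.shape:
            raise ValueError("log2_dilution and cq must have equal length")
        if np.unique(self.log2_dilution).size < 3:
            raise ValueError("need >= 3 distinct dilution levels")


@dataclass
class PrimerQC:
    gene: str
    slope: float  # cycles per log2-dilution step
    efficiency: float  # percent
    dcq_rt_minus: float | None = None  # cycles; None if no RT- data
    valid_slope: bool = True

    @property
    def pass_flag(self) -> bool:
        ok = self.valid_slope and self.efficiency > MIN_EFFICIENCY
        if self.dcq_rt_minus is not None:
            ok = ok and self.dcq_rt_minus > MIN_DCQ_RT_MINUS
        return ok


@dataclass
class ExpressionMatrix:
    """Per-sample -ddCq (log2 fold change) values against a reference group.

    ``values`` is wide, samples x genes; ``meta`` is indexed like ``values``
    and carries tissue/diet/period per sample.  Housekeeping genes are not
    part of the matrix.
    """

    values: pd.DataFrame
    meta: pd.DataFrame  # columns: tissue, diet, period
    reference_group: tuple[str, str]  # (diet, period)
    hkg_set: tuple[str, ...] = field(default_factory=tuple)

    @property
    def genes(self) -> list[str]:
        return list(self.values.columns)

    def long(self) -> pd.DataFrame:
        """Long-format view: sample_id, tissue, diet, period, gene, neg_ddcq."""
        out = self.values.join(self.meta).reset_index(names="sample_id")
        return out.melt(
            id_vars=["sample_id", *self.meta.columns],
            value_vars=self.genes,
            var_name="gene",
            value_name="neg_ddcq",
        )


def efficiency_from_slope(slope: float) -> float:
    """PCR efficiency in percent from a Cq-vs-log2(dilution) slope:
    E = (2^(-1/slope) - 1) * 100; slope -1 gives exactly 100%."""
    if slope >= 0:
        raise ValueError("amplification requires a negative slope")
    return (2.0 ** (-1.0 / slope) - 1.0) * 100.0


def primer_efficiency(series: DilutionSeries) -> PrimerQC:
    """Amplification efficiency from a dilution ladder.

    Cq is regressed on log2(dilution); efficiency in percent is
    E = (2^(-1/slope) - 1) * 100.  A perfect assay loses one cycle per
    2-fold dilution (slope -1, E = 100%).  A non-negative slope is
    physically impossible for real amplification and is flagged invalid.
    """
    slope = float(np.polyfit(series.log2_dilution, series.cq, 1)[0])
    if slope >= 0:
        return PrimerQC(series.gene, slope, float("nan"), valid_slope=False)
    return PrimerQC(series.gene, slope, efficiency_from_slope(slope))


def rt_minus_delta(
    sample_cqs: Sequence[float],
    rtminus_cqs: Sequence[float | None],
) -> float:
    """dCq(RT-) = mean Cq(RT-) - mean Cq(sample).

    Absent RT- amplifications (None/NaN) are replaced by the sentinel Cq
    of 50 before averaging.  Large values mean negligible genomic-DNA or
    non-specific signal.
    """
    sample = np.asarray(sample_cqs, dtype=float)
    if sample.size == 0:
        raise ValueError("sample_cqs must be non-empty")
    rtminus = np.array(
        [NO_AMPLIFICATION_CQ if (c is None or np.isnan(c)) else float(c) for c in rtminus_cqs],
        dtype=float,
    )
    if rtminus.size == 0:
        rtminus = np.array([NO_AMPLIFICATION_CQ])
    return float(rtminus.mean() - sample.mean())


def _validate_cq_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in CQ_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"Cq table missing required columns: {missing}")
    return table


def delta_cq(table: pd.DataFrame, hkg: Iterable[str]) -> pd.DataFrame:
    """Per-sample dCq for every non-housekeeping gene.

    Technical replicates are averaged on the Cq scale first; then
    dCq(sample, gene) = Cq(gene) - arithmetic mean Cq of the housekeeping
    genes.  Samples missing any housekeeping gene are dropped with a
    logged warning; a missing target gene only leaves that single cell
    empty.

    Returns a long DataFrame: sample_id, tissue, diet, period, gene, dcq.
    """
    table = _validate_cq_table(table)
    hkg = sorted(set(hkg))
    if not hkg:
        raise ValueError("hkg set must be non-empty")
    meta_cols = ["sample_id", "tissue", "diet", "period"]
    mean_cq = (
        table.groupby(meta_cols + ["gene"], as_index=False, observed=True)["cq"].mean()
    )
    wide = mean_cq.pivot(index=meta_cols, columns="gene", values="cq")
    present_hkg = [g for g in hkg if g in wide.columns]
    if len(present_hkg) < len(hkg):
        raise ValueError(f"housekeeping genes absent from table: {sorted(set(hkg) - set(present_hkg))}")
    ok = wide[hkg].notna().all(axis=1)
    if not ok.all():
        dropped = [idx[0] for idx in wide.index[~ok]]
        logger.warning("dropping %d sample(s) missing a housekeeping gene: %s", len(dropped), dropped)
        wide = wide[ok]
    hkg_mean = wide[hkg].mean(axis=1)
    targets = [g for g in wide.columns if g not in hkg]
    dcq = wide[targets].sub(hkg_mean, axis=0)
    out = dcq.reset_index().melt(id_vars=meta_cols, var_name="gene", value_name="dcq")
    return out.dropna(subset=["dcq"]).reset_index(drop=True)


def neg_ddcq(
    dcq: pd.DataFrame,
    reference_group: tuple[str, str],
    hkg_set: Iterable[str] = (),
) -> ExpressionMatrix:
    """-ddCq per sample and gene against the (diet, period) reference group.

    -ddCq(sample, gene) = -(dCq(sample, gene) - mean dCq over reference
    samples for that gene), so the reference-group mean is exactly zero for
    every gene and positive values read as up-regulation (log2 scale).
    """
    ref_diet, ref_period = reference_group
    ref = dcq[(dcq["diet"] == ref_diet) & (dcq["period"] == ref_period)]
    if ref.empty:
        raise ValueError(f"reference group {reference_group} has no samples")
    ref_means = ref.groupby("gene", observed=True)["dcq"].mean()
    missing_ref = set(dcq["gene"]) - set(ref_means.index)
    if missing_ref:
        raise ValueError(f"reference group empty for gene(s): {sorted(missing_ref)}")

    work = dcq.copy()
    work["neg_ddcq"] = -(work["dcq"] - work["gene"].map(ref_means))
    values = work.pivot(index="sample_id", columns="gene", values="neg_ddcq")
    meta = (
        work[["sample_id", "tissue", "diet", "period"]]
        .drop_duplicates("sample_id")
        .set_index("sample_id")
        .loc[values.index]
    )
    return ExpressionMatrix(values=values, meta=meta, reference_group=reference_group,
                            hkg_set=tuple(sorted(set(hkg_set))))


def fold_change_by_day(
    expr: ExpressionMatrix,
    gene: str,
    period: str,
    reference_diet: str = "CTL",
    treated_diet: str = "FEN",
) -> float:
    """Fold change of ``treated_diet`` vs ``reference_diet`` at one period.

    Computed as 2^(mean -ddCq treated - mean -ddCq reference) within the
    period, i.e. the within-day 2^-ddCq fold change.  Invariant to any
    per-sample additive Cq shift and to the choice of global reference
    group.
    """
    if gene not in expr.values.columns:
        raise KeyError(f"gene {gene!r} not in expression matrix")
    at_period = expr.meta["period"] == period
    means = {}
    for diet in (reference_diet, treated_diet):
        sel = at_period & (expr.meta["diet"] == diet)
        vals = expr.values.loc[sel, gene].dropna()
        if vals.empty:
            raise ValueError(f"no {diet} samples at period {period!r} for gene {gene!r}")
        means[diet] = vals.mean()
    return float(2.0 ** (means[treated_diet] - means[reference_diet]))
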