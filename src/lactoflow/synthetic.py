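"""Seeded synthetic-data generator emulating the lactation-study design.

Generates every input the analysis pipeline consumes, from explicit
ground-truth parameters: tracer-enrichment time courses from the
two-compartment water-turnover model, Cq tables with stable housekeeping
genes and gene-specific diet x period effects, and hormone concentration
tables with a decline-then-rise period profile.

Defaults mirror the study conditions: two diets (CTL, FEN), three
sampling points (lactation days 12 and 18, first involution day), 6 dams
per diet x period cell at L12/L18 and 11 at Inv1, a D2O dose of
4.92 g/kg body weight, dam plasma sampled daily over the four days after
dosing and pooled litter urine daily for a week, and ground-truth
log2-expression effects taken from the study's printed group means, which
follow three temporal kinetics (peak during lactation, peak near L18,
rise at involution).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .tracer import EnrichmentSeries, TurnoverParams, forward_enrichment

__all__ = [
    "GeneSpec",
    "SimConfig",
    "simulate_enrichment",
    "simulate_cq",
    "simulate_hormones",
    "default_gene_panel",
    "default_effect_table",
    "default_hormone_means",
]

DIETS = ("CTL", "FEN")
PERIODS = ("L12", "L18", "Inv1")

#: housekeeping genes per tissue
HKG = {"mammary": ("Actb", "Uxt", "Rps9"), "pituitary": ("Actb", "Vcp", "Rps9")}


@dataclass(frozen=True)
class GeneSpec:
    symbol: str
    baseline_cq: float  # expected Cq of an average reference sample
    hkg: bool = False


#: mean log2 expression effect (-ddCq vs CTL at L12) per gene:
#: (CTL L12, CTL L18, CTL Inv1, FEN L12, FEN L18, FEN Inv1)
_MAMMARY_EFFECTS: dict[str, tuple[float, ...]] = {
    # milk lipid synthesis
    "Lpl": (0.00, 0.52, -2.63, 0.97, 0.90, -2.83),
    "Fasn": (0.00, 0.21, -5.10, 1.10, 0.25, -4.84),
    "Acaca": (0.00, -0.18, -4.24, 1.08, 0.16, -4.19),
    "Acacb": (0.00, 0.52, -2.12, 0.31, 0.43, -2.37),
    "Fabp3": (0.00, 0.51, -4.37, 1.84, 0.67, -3.95),
    "Fabp4": (0.00, -1.73, -0.30, -0.03, -1.75, -0.44),
    "Scd1": (0.00, 1.10, 0.04, 1.19, 2.10, -0.03),
    "Dgat1": (0.00, 1.04, -0.50, 0.21, 0.85, -0.33),
    "Dgat2": (0.00, -0.33, 0.65, -0.74, -0.25, 0.12),
    "Plin2": (0.00, 1.51, -0.37, 0.50, 1.43, 0.16),
    # milk lactose synthesis
    "Glut1": (0.00, -0.52, -2.08, 0.49, -0.06, -2.04),
    "Pgm1": (0.00, -0.61, -0.05, 0.33, -0.60, -0.26),
    "Ugp2": (0.00, -0.67, -2.49, 1.03, -0.48, -2.56),
    "B4galt1": (0.00, 0.74, -3.22, 1.23, 0.88, -3.06),
    "Lalba": (0.00, 1.65, -1.44, 1.28, 1.64, -0.86),
    # milk protein synthesis and water inflow
    "Slc7a5": (0.00, 1.12, -1.73, 0.83, 0.74, -1.31),
    "Csn2": (0.00, 1.48, -2.13, 1.18, 1.36, -1.37),
    "Wap": (0.00, 1.58, -2.29, 1.47, 1.48, -1.91),
    "Aqp1": (0.00, 1.24, -0.39, 0.58, 0.57, 0.05),
    "Aqp3": (0.00, 1.64, -0.91, 0.63, 1.82, -0.75),
    # energy metabolism and antioxidant enzymes
    "Cpt1a": (0.00, -0.26, 3.28, 1.94, 0.29, 3.22),
    "Acads": (0.00, 0.19, 1.28, 1.47, 0.39, 1.41),
    "Pdha1": (0.00, 0.32, -1.46, 0.53, 0.59, -1.39),
    "Cs": (0.00, 0.10, -1.20, 0.70, 0.32, -1.03),
    "Mtco1": (0.00, 0.52, -0.90, 0.74, 0.35, -0.61),
    "Atp5f1a": (0.00, -0.24, -0.61, 0.55, 0.07, -0.64),
    "Sod1": (0.00, -0.55, -0.22, -0.24, -0.48, -0.48),
    "Cat": (0.00, -0.85, -0.51, -0.18, -0.85, -0.11),
    "Gpx1": (0.00, 0.14, -0.47, 0.20, 0.38, -0.71),
    # milk-synthesis regulatory factors
    "Srebf1": (0.00, -2.11, -3.03, 0.40, -1.76, -3.24),
    "Pparg": (0.00, -0.07, -0.93, 0.77, -0.12, -1.19),
    "Spot14": (0.00, -0.03, -1.28, 0.55, 0.23, -1.28),
    "Lxra": (0.00, 0.52, 1.08, 1.24, 0.44, 1.00),
    "Akt1": (0.00, -0.02, -0.81, 0.59, -0.10, -0.65),
    "Mtor": (0.00, 0.34, 0.06, 0.88, 0.09, 0.06),
    "Stat5": (0.00, 0.17, -0.36, 0.78, 0.09, -0.35),
    # lactogenic hormone receptors
    "Prlr": (0.00, -0.32, -1.84, 0.40, -0.11, -2.09),
    "Insr": (0.00, 2.29, -0.85, 0.84, 2.35, -0.67),
    "Oxtr": (0.00, -0.52, 0.75, 0.79, -0.58, 0.73),
    "Ghr": (0.00, -0.14, 0.07, 0.89, 0.34, 0.01),
    "Igf1r": (0.00, 0.89, 1.87, 1.37, 0.96, 1.97),
    "Esr1": (0.00, 1.57, -2.02, 0.34, 1.09, -1.44),
}

#: typical Cq of a reference (CTL, L12) sample; housekeeping mean is ~19.7,
#: so highly expressed milk-protein genes sit far below it and the weakly
#: expressed regulatory/receptor genes far above
_MAMMARY_BASELINES: dict[str, float] = {
    "Csn2": 13.0, "Wap": 13.2, "Mtco1": 13.5, "Lalba": 14.0, "Plin2": 17.5,
    "Fasn": 18.0, "Lpl": 19.0, "Aqp1": 20.5, "Aqp3": 21.0, "Glut1": 21.0,
    "B4galt1": 21.5, "Ugp2": 21.0, "Acaca": 21.5, "Acacb": 22.0, "Fabp3": 20.0,
    "Fabp4": 21.5, "Dgat1": 22.0, "Slc7a5": 22.0, "Srebf1": 22.0, "Spot14": 21.5,
    "Akt1": 22.5, "Stat5": 22.5, "Pdha1": 22.0, "Cs": 22.5, "Atp5f1a": 21.0,
    "Sod1": 20.5, "Cat": 22.0, "Gpx1": 21.0, "Prlr": 23.0, "Oxtr": 24.5,
    "Ghr": 23.5, "Cpt1a": 26.0, "Acads": 25.0, "Mtor": 25.0, "Igf1r": 25.0,
    "Esr1": 24.5, "Insr": 24.0, "Lxra": 25.0, "Scd1": 24.5, "Pgm1": 24.0,
    "Dgat2": 24.5, "Pparg": 23.0,
}


def default_gene_panel() -> tuple[GeneSpec, ...]:
    """Mammary panel: three housekeeping genes plus the 42 studied targets."""
    hkgs = (
        GeneSpec("Actb", 18.0, hkg=True),
        GeneSpec("Uxt", 22.0, hkg=True),
        GeneSpec("Rps9", 19.0, hkg=True),
    )
    return hkgs + tuple(
        GeneSpec(g, _MAMMARY_BASELINES[g]) for g in _MAMMARY_EFFECTS
    )


def default_effect_table() -> pd.DataFrame:
    """Ground-truth mean -ddCq per (gene, diet, period), CTL at L12 = 0.

    Values are the study's printed group means, so zero-noise simulation
    reproduces its tables exactly: e.g. the Cpt1a FEN-CTL contrast at L12
    is 1.94 (fold change 2^1.94 = 3.84).  Kinetic-1 genes (e.g. Ugp2,
    Fasn, Prlr, Pgm1) peak during lactation and collapse at involution,
    kinetic-2 genes (e.g. Insr, Lalba, Csn2) peak near L18, kinetic-3
    genes (e.g. Cpt1a, Acads, Igf1r, Lxra) rise at involution.
    """
    recs = []
    for gene, v in _MAMMARY_EFFECTS.items():
        for i, (diet, period) in enumerate(
            [(d, p) for d in DIETS for p in PERIODS]
        ):
            recs.append({"gene": gene, "diet": diet, "period": period, "effect": v[i]})
    return pd.DataFrame(recs)


def default_hormone_means() -> pd.DataFrame:
    """Plasma hormone period means (ng/mL) with the study's time course:
    decline from L12 to L18 then a sharp rise at involution (insulin
    -65.9% then +392.5%; IGF-1 -48.5% then +156.9%; leptin -79.7% then
    +325%), a prolactin drop, and an estrogen rise at involution.  The
    only non-unit diet multipliers are insulin at L12 (+77.1% in FEN) and
    estrogens at Inv1 (+35.5%)."""
    means = {
        "insulin": {"L12": 2.00, "L18": 0.682, "Inv1": 3.359},
        "igf1": {"L12": 800.0, "L18": 412.0, "Inv1": 1058.4},
        "leptin": {"L12": 4.00, "L18": 0.812, "Inv1": 3.451},
        "prolactin": {"L12": 100.0, "L18": 36.0, "Inv1": 36.0},
        "estrogens": {"L12": 20.0, "L18": 20.0, "Inv1": 27.4},
    }
    mult = {("insulin", "L12"): 1.771, ("estrogens", "Inv1"): 1.355}
    recs = []
    for hormone, per in means.items():
        for period, mean in per.items():
            recs.append(
                {
                    "hormone": hormone,
                    "period": period,
                    "mean": mean,
                    "fen_multiplier": mult.get((hormone, period), 1.0),
                }
            )
    return pd.DataFrame(recs)


def _base_params(diet: str) -> TurnoverParams:
    # mean milk flow targets: CTL 55.90 g/day, FEN 64.45 g/day at W_d = 200 g
    k_dl = {"CTL": 55.90, "FEN": 64.45}[diet] / (24.0 * 200.0)
    return TurnoverParams(W_d=200.0, W_l=150.0, k_dl=k_dl, k_de=0.004, k_le=0.010)


@dataclass
class SimConfig:
    """Ground-truth parameters and design of one simulated study."""

    seed: int = 0
    n_dams_per_group: int = 16  # tracer dyads per diet
    dose_per_kg: float = 4.92  # g D2O per kg body weight
    dam_body_weight: float = 300.0  # g
    dam_schedule: np.ndarray = field(
        default_factory=lambda: np.array([4.0, 24.0, 48.0, 72.0, 96.0])
    )  # h post-dose, daily L11-L15
    litter_schedule: np.ndarray = field(
        default_factory=lambda: np.array([24.0, 48.0, 72.0, 96.0, 120.0, 144.0, 168.0])
    )  # h post-dose, daily L12-L18
    enrichment_noise_cv: float = 0.01
    inter_animal_cv: float = 0.10  # lognormal CV on per-dyad kinetic parameters
    true_params: Mapping[str, TurnoverParams] | None = None  # per dyad; built from seed if None

    tissue: str = "mammary"
    gene_panel: tuple[GeneSpec, ...] = field(default_factory=default_gene_panel)
    effect_table: pd.DataFrame = field(default_factory=default_effect_table)
    n_per_cell: Mapping[str, int] = field(
        default_factory=lambda: {"L12": 6, "L18": 6, "Inv1": 11}
    )
    cq_noise_sd: float = 0.5  # cycles, per (sample, gene)
    sample_effect_sd: float = 0.5  # cycles, shared by all genes of a sample

    hormone_means: pd.DataFrame = field(default_factory=default_hormone_means)
    hormone_noise_cv: float = 0.30

    def __post_init__(self) -> None:
        self.dam_schedule = np.asarray(self.dam_schedule, dtype=float)
        self.litter_schedule = np.asarray(self.litter_schedule, dtype=float)
        for name in ("dose_per_kg", "dam_body_weight"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("enrichment_noise_cv", "inter_animal_cv", "cq_noise_sd",
                     "sample_effect_sd", "hormone_noise_cv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for sched in (self.dam_schedule, self.litter_schedule):
            if np.any(sched <= 0) or np.any(np.diff(sched) <= 0):
                raise ValueError("schedules must be strictly increasing with times > 0")
        hkg_syms = {g.symbol for g in self.gene_panel if g.hkg}
        bad = self.effect_table[
            self.effect_table["gene"].isin(hkg_syms) & (self.effect_table["effect"] != 0)
        ]
        if not bad.empty:
            raise ValueError("housekeeping genes must have zero effect entries")
        if self.true_params is None:
            self.true_params = self._draw_dyad_params()

    @property
    def dose(self) -> float:
        """Administered D2O dose, g."""
        return self.dose_per_kg * self.dam_body_weight / 1000.0

    def dyad_ids(self) -> list[str]:
        return [f"{d}{i + 1:02d}" for d in DIETS for i in range(self.n_dams_per_group)]

    def _draw_dyad_params(self) -> dict[str, TurnoverParams]:
        rng = np.random.default_rng([int(self.seed), 0x7261])
        sigma = np.sqrt(np.log1p(self.inter_animal_cv**2))
        out = {}
        for dyad in self.dyad_ids():
            base = _base_params(dyad[:3])
            jitter = np.exp(rng.normal(-sigma**2 / 2, sigma, size=5))
            out[dyad] = TurnoverParams(
                W_d=base.W_d * jitter[0],
                W_l=base.W_l * jitter[1],
                k_dl=base.k_dl * jitter[2],
                k_de=base.k_de * jitter[3],
                k_le=base.k_le * jitter[4],
            )
        return out


def _dyad_rng(config: SimConfig, dyad_id: str, stream: int) -> np.random.Generator:
    return np.random.default_rng(
        [int(config.seed), stream, zlib.crc32(dyad_id.encode()) & 0x7FFFFFFF]
    )


def _lognormal_factor(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative lognormal noise with mean exactly 1 and the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return np.exp(rng.normal(-sigma**2 / 2.0, sigma, size=size))


def simulate_enrichment(
    config: SimConfig, dyad_id: str
) -> tuple[EnrichmentSeries, EnrichmentSeries]:
    """Dam-plasma and litter-urine enrichment series for one dyad.

    Noiseless two-pool forward-model values at the configured schedules,
    times mean-one multiplicative lognormal noise with the configured CV.
    Reproducible for a given (config seed, dyad_id).
    """
    if dyad_id not in config.true_params:
        raise KeyError(f"unknown dyad_id {dyad_id!r}")
    params = config.true_params[dyad_id]
    rng = _dyad_rng(config, dyad_id, stream=1)
    dose = config.dose
    out = []
    for compartment, times in (
        ("dam_plasma", config.dam_schedule),
        ("litter_urine", config.litter_schedule),
    ):
        clean = forward_enrichment(params, dose, times, compartment)
        noisy = clean * _lognormal_factor(rng, config.enrichment_noise_cv, times.size)
        out.append(
            EnrichmentSeries(
                dyad_id=dyad_id,
                compartment=compartment,
                times=times,
                enrichment=noisy,
                dose=dose,
                dam_body_weight=config.dam_body_weight,
            )
        )
    return out[0], out[1]


def simulate_cq(config: SimConfig) -> pd.DataFrame:
    """Long-format Cq table for the configured diet x period design.

    Cq(sample, gene) = baseline(gene) - effect(gene, diet, period)
    + sample offset + technical noise; housekeeping genes receive no
    effect.  The per-sample offset, shared by all genes of a sample,
    emulates loading/RT differences that housekeeping normalization
    absorbs.
    """
    eff = config.effect_table.set_index(["gene", "diet", "period"])["effect"]
    targets = [g for g in config.gene_panel if not g.hkg]
    missing = [
        (g.symbol, d, p)
        for g in targets
        for d in DIETS
        for p in config.n_per_cell
        if (g.symbol, d, p) not in eff.index
    ]
    if missing:
        raise ValueError(f"effect_table missing cell(s): {missing}")

    rng = np.random.default_rng([int(config.seed), 2])
    recs = []
    for diet in DIETS:
        for period, n in config.n_per_cell.items():
            for i in range(n):
                sample_id = f"{config.tissue[0].upper()}_{diet}_{period}_{i + 1:02d}"
                offset = rng.normal(0.0, config.sample_effect_sd) if config.sample_effect_sd else 0.0
                for gene in config.gene_panel:
                    effect = 0.0 if gene.hkg else float(eff[(gene.symbol, diet, period)])
                    noise = rng.normal(0.0, config.cq_noise_sd) if config.cq_noise_sd else 0.0
                    recs.append(
                        {
                            "sample_id": sample_id,
                            "tissue": config.tissue,
                            "diet": diet,
                            "period": period,
                            "gene": gene.symbol,
                            "cq": gene.baseline_cq - effect + offset + noise,
                            "replicate": 1,
                        }
                    )
    return pd.DataFrame(recs)


def simulate_hormones(config: SimConfig) -> pd.DataFrame:
    """Per-animal plasma hormone concentrations.

    concentration = period mean x diet multiplier x mean-one lognormal
    noise with the configured CV; FEN multipliers apply only where the
    configured table says so.
    """
    hm = config.hormone_means
    if (hm["mean"] <= 0).any():
        bad = hm.loc[hm["mean"] <= 0, ["hormone", "period"]].to_records(index=False)
        raise ValueError(f"non-positive hormone mean(s): {list(bad)}")
    needed = {(h, p) for h in hm["hormone"].unique() for p in config.n_per_cell}
    have = set(zip(hm["hormone"], hm["period"]))
    if needed - have:
        raise ValueError(f"hormone_means missing cell(s): {sorted(needed - have)}")

    rng = np.random.default_rng([int(config.seed), 3])
    recs = []
    for _, row in hm.sort_values(["hormone", "period"]).iterrows():
        if row["period"] not in config.n_per_cell:
            continue
        n = config.n_per_cell[row["period"]]
        for diet in DIETS:
            mult = row["fen_multiplier"] if diet == "FEN" else 1.0
            noise = _lognormal_factor(rng, config.hormone_noise_cv, n)
            for i in range(n):
                recs.append(
                    {
                        "animal_id": f"H_{diet}_{row['period']}_{i + 1:02d}",
                        "diet": diet,
                        "period": row["period"],
                        "hormone": row["hormone"],
                        "concentration": row["mean"] * mult * noise[i],
                    }
                )
    return pd.DataFrame(recs)
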