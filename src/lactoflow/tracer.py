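"""Two-compartment deuterium-oxide water-turnover model.

A lactating dam receives a bolus of D2O at time zero.  Tracer distributes
instantly in the dam's body-water pool (``W_d``), is transferred to the
pooled litter body-water pool (``W_l``) through milk at first-order rate
``k_dl``, and is eliminated to the environment from each pool (``k_de``,
``k_le``).  There is no return flow from litter to dam: the pups' water
intake is essentially milk-derived.

Tracer amounts follow

    dQ_d/dt = -(k_dl + k_de) Q_d
    dQ_l/dt = k_dl Q_d - k_le Q_l,     Q_d(0) = dose, Q_l(0) = 0

and measured enrichments are concentrations C_d = Q_d / W_d,
C_l = Q_l / W_l (tracer mass per unit body water).  Milk (water) flow is
``W_d * k_dl`` (g/h), reported in g/day.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "TurnoverParams",
    "EnrichmentSeries",
    "TurnoverFit",
    "forward_enrichment",
    "fit_tbw",
    "fit_turnover",
    "milk_flow",
    "UnconvergedFitError",
]

# closed form degenerates when k_le == k_dl + k_de; switch to the limit form
_DEGENERATE_TOL = 1e-10

Compartment = Literal["dam_plasma", "litter_urine"]


class UnconvergedFitError(RuntimeError):
    """Raised when a derived quantity is requested from a fit that did not converge."""


@dataclass(frozen=True)
class TurnoverParams:
    """Rate constants (h^-1) and pool sizes (g) of the two-pool model."""

    W_d: float  # dam total body water, g
    W_l: float  # litter (pooled) total body water, g
    k_dl: float  # dam -> litter transfer, h^-1
    k_de: float  # dam -> environment elimination, h^-1
    k_le: float  # litter -> environment elimination, h^-1

    def __post_init__(self) -> None:
        for name in ("W_d", "W_l", "k_de", "k_le"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.k_dl < 0:
            raise ValueError(f"k_dl must be >= 0, got {self.k_dl}")

    @property
    def k_d(self) -> float:
        """Total fractional turnover of the dam pool, h^-1."""
        return self.k_dl + self.k_de


@dataclass
class EnrichmentSeries:
    """One compartment's tracer-enrichment time course for a dam-litter dyad.

    ``enrichment`` is tracer concentration above background, in dose units
    per unit body water (g D2O per g body water).
    """

    dyad_id: str
    compartment: Compartment
    times: np.ndarray  # hours since dose, strictly increasing, > 0
    enrichment: np.ndarray
    dose: float  # g D2O administered
    dam_body_weight: float = float("nan")  # g, optional metadata

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.enrichment = np.asarray(self.enrichment, dtype=float)
        if self.times.shape != self.enrichment.shape:
            raise ValueError("times and enrichment must have the same length")
        if self.times.size and (np.any(self.times <= 0) or np.any(np.diff(self.times) <= 0)):
            raise ValueError("times must be strictly increasing and > 0")
        if self.dose <= 0:
            raise ValueError("dose must be > 0")

    def __len__(self) -> int:
        return self.times.size


@dataclass
class TurnoverFit:
    """Fitted model parameters plus the derived milk flow for one dyad."""

    dyad_id: str
    params: TurnoverParams
    sse: float
    n_obs: int
    converged: bool
    message: str = ""
    warnings: list[str] = field(default_factory=list)

    @property
    def milk_flow(self) -> float:
        """Dam-to-litter water flow, g/day = W_d * k_dl * 24."""
        return self.params.W_d * self.params.k_dl * 24.0


def forward_enrichment(
    params: TurnoverParams,
    dose: float,
    times: Sequence[float] | np.ndarray,
    compartment: Compartment,
) -> np.ndarray:
    """Noiseless enrichment of one compartment at the given times (hours).

    dam_plasma:   C_d(t) = (dose / W_d) * exp(-k_d t)
    litter_urine: C_l(t) = (dose * k_dl / W_l) * (exp(-k_d t) - exp(-k_le t)) / (k_le - k_d)
    with k_d = k_dl + k_de; the analytic limit t*exp(-k_d t) is used when
    k_le is numerically equal to k_d.
    """
    if dose <= 0:
        raise ValueError("dose must be > 0")
    t = np.asarray(times, dtype=float)
    if np.any(t < 0):
        raise ValueError("times must be >= 0")
    k_d = params.k_d
    if compartment == "dam_plasma":
        return (dose / params.W_d) * np.exp(-k_d * t)
    if compartment == "litter_urine":
        a = dose * params.k_dl / params.W_l
        if abs(params.k_le - k_d) < _DEGENERATE_TOL * max(params.k_le, k_d, 1.0):
            return a * t * np.exp(-k_d * t)
        return a * (np.exp(-k_d * t) - np.exp(-params.k_le * t)) / (params.k_le - k_d)
    raise ValueError(f"unknown compartment {compartment!r}")


def fit_tbw(dam_series: EnrichmentSeries, dose: float | None = None) -> tuple[float, float]:
    """Dam total body water and turnover from the log-linear plasma decay.

    Ordinary least squares of ln(enrichment) on time; the zero-time
    intercept gives the dilution space: W_d = dose / exp(intercept), and
    the slope gives k_d = -slope.

    Returns ``(W_d, k_d)``.
    """
    if dam_series.compartment != "dam_plasma":
        raise ValueError("fit_tbw requires a dam_plasma series")
    if len(dam_series) < 3:
        raise ValueError("need at least 3 dam plasma points")
    if np.any(dam_series.enrichment <= 0):
        raise ValueError("enrichment must be > 0 for log-linear fitting")
    dose = dam_series.dose if dose is None else dose
    slope, intercept = np.polyfit(dam_series.times, np.log(dam_series.enrichment), 1)
    return dose / math.exp(intercept), -slope


def fit_turnover(
    dam_series: EnrichmentSeries,
    litter_series: EnrichmentSeries,
    dose: float | None = None,
    init: TurnoverParams | None = None,
    litter_weight: float | None = None,
    fix_W_l: bool = True,
    max_nfev: int = 2000,
) -> TurnoverFit:
    """Nonlinear least-squares fit of the two-pool model to one dyad.

    The objective sums squared residuals of log-enrichment for the dam
    plasma series (multiplicative error on an exponential decay) and
    squared enrichment residuals scaled by 1/max(C_l) for the litter urine
    series, minimized over (W_d, k_dl, k_de, k_le) and, optionally, W_l.

    When ``init`` is absent, starting values come from :func:`fit_tbw`
    (W_d and k_d, the latter split evenly between k_dl and k_de) and the
    litter pool from 0.7 x ``litter_weight`` when given, else 0.75 x W_d.

    The litter pool size W_l is held fixed at its starting value by
    default: the enrichment data constrain only the amplitude
    dose*k_dl/W_l, so W_l and k_dl are not jointly identifiable and W_l
    must come from the measured litter weight (body water ~ 70% of body
    mass).  Pass ``fix_W_l=False`` to free it regardless, accepting that
    k_dl is then determined only up to that ratio.
    """
    if dam_series.dyad_id != litter_series.dyad_id:
        raise ValueError("dam and litter series must come from the same dyad")
    if len(dam_series) < 3 or len(litter_series) < 3:
        raise ValueError("need at least 3 points in each series")
    dose = dam_series.dose if dose is None else dose

    if init is None:
        W_d0, k_d0 = fit_tbw(dam_series, dose)
        k_d0 = max(k_d0, 1e-6)
        W_l0 = 0.7 * litter_weight if litter_weight is not None else 0.75 * W_d0
        x0 = np.array([W_d0, W_l0, k_d0 / 2, k_d0 / 2, k_d0])
    else:
        x0 = np.array([init.W_d, init.W_l, init.k_dl, init.k_de, init.k_le])

    cl_obs = litter_series.enrichment
    cl_scale = float(np.max(np.abs(cl_obs))) or 1.0
    log_cd_obs = np.log(dam_series.enrichment)

    # rate constants above 1 h^-1 (full pool turnover within the hour) are
    # physiologically impossible for body water and would otherwise offer a
    # degenerate escape (k_le -> inf flattens the litter curve)
    lower = np.array([1e-3, 1e-3, 0.0, 1e-8, 1e-8])
    upper = np.array([np.inf, np.inf, 1.0, 1.0, 1.0])
    x0 = np.clip(x0, lower * 1.001 + 1e-12, None)
    free = np.array([True, not fix_W_l, True, True, True])
    W_l_fixed = x0[1]

    def expand(x: np.ndarray) -> TurnoverParams:
        full = np.empty(5)
        full[free] = x
        if fix_W_l:
            full[1] = W_l_fixed
        return TurnoverParams(*full)

    def residuals(x: np.ndarray) -> np.ndarray:
        p = expand(x)
        cd = forward_enrichment(p, dose, dam_series.times, "dam_plasma")
        cl = forward_enrichment(p, dose, litter_series.times, "litter_urine")
        return np.concatenate([np.log(np.maximum(cd, 1e-300)) - log_cd_obs,
                               (cl - cl_obs) / cl_scale])

    res = least_squares(residuals, x0[free], bounds=(lower[free], upper[free]),
                        method="dogbox", x_scale=np.maximum(np.abs(x0[free]), 1e-6),
                        ftol=1e-14, xtol=1e-14, gtol=1e-14, max_nfev=max_nfev)
    params = expand(res.x)
    full_x = np.array([params.W_d, params.W_l, params.k_dl, params.k_de, params.k_le])
    fit = TurnoverFit(
        dyad_id=dam_series.dyad_id,
        params=params,
        sse=float(2 * res.cost),
        n_obs=len(dam_series) + len(litter_series),
        converged=bool(res.success),
        message=res.message,
    )
    at_bound = np.isclose(full_x, lower) | np.isclose(full_x, upper)
    if np.any(at_bound[1:]):
        names = np.array(["W_d", "W_l", "k_dl", "k_de", "k_le"])[1:][at_bound[1:]]
        msg = f"parameter(s) at bound: {', '.join(names)}"
        fit.warnings.append(msg)
        warnings.warn(msg, stacklevel=2)
    return fit


def milk_flow(fit: TurnoverFit) -> float:
    """Milk (water) flow in g/day from a converged fit: W_d * k_dl * 24."""
    if not fit.converged:
        raise UnconvergedFitError(
            f"fit for dyad {fit.dyad_id!r} did not converge: {fit.message}"
        )
    return fit.milk_flow
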