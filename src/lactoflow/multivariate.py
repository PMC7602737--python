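"""PCA and PLS-DA with per-period normalization, VIP, cross-validated Q2,
CV-ANOVA, and correlation-based kinetic clustering.

PLS-DA is fitted by the NIPALS algorithm on a one-hot class dummy matrix:
each component extracts the direction of predictor space with maximal
covariance with class membership, deflating X and Y in turn.  Model
quality is summarized by R2X / R2Y (explained predictor / class variance),
Q2 from stratified k-fold cross-validation (predictive fraction of class
variance), a CV-ANOVA significance test on the cross-validated predictive
residuals, and per-variable VIP scores (variable importance in the
projection; mean squared VIP equals 1 by construction).

The "mask the time effect" device used for diet-specific models is
per-period normalization: each variable is centered and scaled to unit
variance within each lactation point, which removes every gene x period
mean difference while preserving within-period (diet) contrasts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.decomposition import PCA as _SkPCA
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "NormalizedMatrix",
    "PcaModel",
    "PlsdaModel",
    "normalize_by_period",
    "fit_pca",
    "fit_plsda",
    "q2_cv",
    "cv_anova",
    "vip_scores",
    "correlation_clusters",
]

logger = logging.getLogger(__name__)

_NIPALS_TOL = 1e-12
_NIPALS_MAX_ITER = 1000


@dataclass
class NormalizedMatrix:
    """Samples x variables matrix with its normalization provenance."""

    values: pd.DataFrame
    normalization: str  # "uv_global" or "uv_by_period"
    period_labels: pd.Series | None = None


@dataclass
class PcaModel:
    scores: np.ndarray  # n x A
    loadings: np.ndarray  # p x A
    explained_variance: np.ndarray  # per component
    explained_variance_ratio: np.ndarray
    mean_: np.ndarray = field(repr=False, default=None)
    scale_: np.ndarray = field(repr=False, default=None)


@dataclass
class PlsdaModel:
    """NIPALS PLS-DA fit on a class dummy matrix."""

    n_components: int
    classes_: np.ndarray
    x_weights: np.ndarray  # p x A, unit norm per component
    x_loadings: np.ndarray  # p x A
    x_scores: np.ndarray  # n x A
    y_loadings: np.ndarray  # g x A
    coef: np.ndarray  # p x g regression coefficients (centered spaces)
    x_mean: np.ndarray
    y_mean: np.ndarray
    r2x: np.ndarray  # per component
    r2y: np.ndarray
    r2x_cum: float = 0.0
    r2y_cum: float = 0.0
    q2_cum: float | None = None
    cv_press: float | None = None
    cv_residuals: np.ndarray | None = field(repr=False, default=None)
    cv_anova_p: float | None = None

    @property
    def vip(self) -> np.ndarray:
        return vip_scores(self)


def _dummy(labels: Sequence) -> tuple[np.ndarray, np.ndarray]:
    classes, idx = np.unique(np.asarray(labels), return_inverse=True)
    Y = np.zeros((len(idx), classes.size))
    Y[np.arange(len(idx)), idx] = 1.0
    return Y, classes


def _matrix(X) -> pd.DataFrame:
    if isinstance(X, NormalizedMatrix):
        return X.values
    if isinstance(X, pd.DataFrame):
        return X
    return pd.DataFrame(np.asarray(X, dtype=float))


def normalize_by_period(X, period_labels, ddof: int = 1) -> NormalizedMatrix:
    """Center and unit-variance scale every variable within each period.

    Removes all between-period mean structure (the dominant longitudinal
    signal) so that subsequent models resolve within-period effects such
    as diet.  Variables with zero variance inside any period cannot be
    scaled there and are dropped with a warning.
    """
    df = _matrix(X)
    periods = pd.Series(np.asarray(period_labels), index=df.index, name="period")
    counts = periods.value_counts()
    if (counts < 2).any():
        raise ValueError(f"every period needs >= 2 samples; got {counts.to_dict()}")

    bad: list = []
    for per, sub in df.groupby(periods, observed=True):
        sd = sub.std(ddof=ddof)
        bad.extend(sd.index[(sd == 0) | sd.isna()])
    if bad:
        bad = sorted(set(bad))
        logger.warning("dropping %d zero-within-period-variance variable(s): %s", len(bad), bad)
        df = df.drop(columns=bad)

    out = df.copy()
    for per, sub in df.groupby(periods, observed=True):
        out.loc[sub.index] = (sub - sub.mean()) / sub.std(ddof=ddof)
    return NormalizedMatrix(values=out, normalization="uv_by_period", period_labels=periods)


def fit_pca(X, n_components: int, scale: bool = True) -> PcaModel:
    """PCA of the column-centered (and unit-variance scaled) matrix.

    Components are ordered by explained variance with a deterministic sign
    convention: the largest-magnitude loading of each component is
    positive.  If the matrix rank is below ``n_components`` the extra
    components are returned with ~zero variance and a log message.
    """
    df = _matrix(X)
    n, p = df.shape
    if n_components > min(n - 1, p):
        raise ValueError(f"n_components must be <= min(n-1, p) = {min(n - 1, p)}")
    mean = df.mean().to_numpy()
    sd = df.std(ddof=1).to_numpy() if scale else np.ones(p)
    if np.any(sd == 0):
        raise ValueError("zero-variance variable; drop it before PCA")
    Z = (df.to_numpy() - mean) / sd
    pca = _SkPCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(Z)
    loadings = pca.components_.T  # p x A
    rank = np.linalg.matrix_rank(Z)
    if rank < n_components:
        logger.info("matrix rank %d below requested %d components", rank, n_components)
    # sign convention: largest |loading| positive per component
    for a in range(loadings.shape[1]):
        j = np.argmax(np.abs(loadings[:, a]))
        if loadings[j, a] < 0:
            loadings[:, a] *= -1
            scores[:, a] *= -1
    return PcaModel(
        scores=scores,
        loadings=loadings,
        explained_variance=pca.explained_variance_,
        explained_variance_ratio=pca.explained_variance_ratio_,
        mean_=mean,
        scale_=sd,
    )


def fit_plsda(X, class_labels, n_components: int) -> PlsdaModel:
    """NIPALS PLS-DA of X against one-hot class membership.

    X should already be normalized (globally or per period); columns are
    re-centered here, and the class dummy is centered.  Per-component
    R2X / R2Y come from the deflation residuals.
    """
    df = _matrix(X)
    labels = np.asarray(class_labels)
    if labels.shape[0] != df.shape[0]:
        raise ValueError("class_labels length must match the number of rows")
    Y0, classes = _dummy(labels)
    if classes.size < 2:
        raise ValueError("need >= 2 classes for PLS-DA")
    n, p = df.shape
    if n_components < 1 or n_components > min(n - 1, p):
        raise ValueError(f"n_components must be in [1, {min(n - 1, p)}]")

    x_mean = df.mean().to_numpy()
    y_mean = Y0.mean(axis=0)
    Xc = df.to_numpy() - x_mean
    Yc = Y0 - y_mean
    ssx0 = float(np.sum(Xc**2))
    ssy0 = float(np.sum(Yc**2))

    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    T = np.zeros((n, n_components))
    C = np.zeros((Y0.shape[1], n_components))
    r2x = np.zeros(n_components)
    r2y = np.zeros(n_components)

    Xa, Ya = Xc.copy(), Yc.copy()
    for a in range(n_components):
        u = Ya[:, np.argmax(Ya.var(axis=0))].copy()
        if not np.any(u):
            u = np.ones(n)
        t = np.zeros(n)
        for _ in range(_NIPALS_MAX_ITER):
            w = Xa.T @ u
            nw = np.linalg.norm(w)
            if nw == 0:
                raise ValueError("X residual exhausted; reduce n_components")
            w /= nw
            t_new = Xa @ w
            c = Ya.T @ t_new / (t_new @ t_new)
            u = Ya @ c / (c @ c) if c @ c > 0 else t_new
            if np.linalg.norm(t_new - t) <= _NIPALS_TOL * np.linalg.norm(t_new):
                t = t_new
                break
            t = t_new
        tt = t @ t
        pvec = Xa.T @ t / tt
        Xa = Xa - np.outer(t, pvec)
        Ya = Ya - np.outer(t, c)
        W[:, a], P[:, a], T[:, a], C[:, a] = w, pvec, t, c
        r2x[a] = tt * (pvec @ pvec) / ssx0
        r2y[a] = tt * (c @ c) / ssy0

    coef = W @ np.linalg.solve(P.T @ W, C.T)
    return PlsdaModel(
        n_components=n_components,
        classes_=classes,
        x_weights=W,
        x_loadings=P,
        x_scores=T,
        y_loadings=C,
        coef=coef,
        x_mean=x_mean,
        y_mean=y_mean,
        r2x=r2x,
        r2y=r2y,
        r2x_cum=float(r2x.sum()),
        r2y_cum=float(r2y.sum()),
    )


def _predict_dummy(model: PlsdaModel, Xnew: np.ndarray) -> np.ndarray:
    return (Xnew - model.x_mean) @ model.coef + model.y_mean


def q2_cv(
    X,
    class_labels,
    n_components: int,
    n_folds: int = 7,
    seed: int = 0,
    model: PlsdaModel | None = None,
) -> float:
    """Cumulative Q2 from stratified k-fold cross-validation.

    Q2 = 1 - PRESS/SS, with PRESS the squared error of held-out class-dummy
    predictions and SS the corrected total sum of squares of the dummy.
    Fold assignment is stratified by class and seeded; a draw that leaves
    any training fold without every class is re-drawn with an incremented
    seed (logged).  When ``model`` is given, the CV residuals and Q2 are
    stored on it for a subsequent CV-ANOVA.
    """
    df = _matrix(X)
    labels = np.asarray(class_labels)
    n = df.shape[0]
    if n_folds > n:
        raise ValueError("n_folds must be <= number of samples")
    Y0, classes = _dummy(labels)
    Xn = df.to_numpy()

    for attempt in range(20):
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed + attempt)
        folds = list(skf.split(Xn, labels))
        if all(np.unique(labels[tr]).size == classes.size for tr, _ in folds):
            if attempt:
                logger.info("re-drew CV folds %d time(s) to cover all classes", attempt)
            break
    else:
        raise ValueError("could not build folds containing every class")

    resid = np.zeros_like(Y0)
    for tr, te in folds:
        sub = fit_plsda(df.iloc[tr], labels[tr], n_components)
        resid[te] = Y0[te] - _predict_dummy(sub, Xn[te])
    press = float(np.sum(resid**2))
    ss = float(np.sum((Y0 - Y0.mean(axis=0)) ** 2))
    q2 = 1.0 - press / ss
    if model is not None:
        model.q2_cum = q2
        model.cv_press = press
        model.cv_residuals = resid
    return q2


def cv_anova(
    model: PlsdaModel,
    X=None,
    class_labels=None,
    method: str = "f",
    n_permutations: int = 199,
    n_folds: int = 7,
    seed: int = 0,
) -> float:
    """Significance of a PLS-DA model from its CV predictive residuals.

    ``method="f"``: F-ratio of the variance explained by the
    cross-validated predictions against the residual predictive variance,
    with df1 = number of model components and df2 = n - components - 1;
    returns the upper-tail p.  This approximates the CV-ANOVA bookkeeping
    of commercial PLS software and is conservative for models with no
    predictive power (PRESS above the total SS pins the p at 1), so its
    null distribution piles up at 1 rather than being uniform.

    ``method="permutation"``: exact finite-sample calibration — the PRESS
    of the model is ranked within the PRESS distribution obtained by
    refitting under ``n_permutations`` random relabelings (requires ``X``
    and ``class_labels``); the null distribution of this p is uniform by
    construction.
    """
    if method == "permutation":
        if X is None or class_labels is None:
            raise ValueError("permutation CV-ANOVA needs X and class_labels")
        return _cv_anova_permutation(
            model, X, class_labels, n_permutations=n_permutations,
            n_folds=n_folds, seed=seed,
        )
    if method != "f":
        raise ValueError(f"unknown method {method!r}")
    if model.cv_residuals is None or model.cv_press is None:
        raise ValueError("model has no CV residuals; run q2_cv(..., model=model) first")
    n = model.cv_residuals.shape[0]
    press = model.cv_press
    if class_labels is not None:
        Y0, _ = _dummy(np.asarray(class_labels))
        ss_tot = float(np.sum((Y0 - Y0.mean(axis=0)) ** 2))
    else:
        ss_tot = press / (1.0 - model.q2_cum) if model.q2_cum is not None and model.q2_cum < 1 else press
    df1 = model.n_components
    df2 = n - model.n_components - 1
    if df2 <= 0:
        raise ValueError("not enough samples for CV-ANOVA degrees of freedom")
    explained = max(ss_tot - press, 0.0)
    if press <= 0:
        return 0.0
    f = (explained / df1) / (press / df2)
    return float(sps.f.sf(f, df1, df2))


def _cv_anova_permutation(
    model: PlsdaModel, X, class_labels, n_permutations: int, n_folds: int, seed: int
) -> float:
    labels = np.asarray(class_labels)
    if model.cv_press is None:
        q2_cv(X, labels, model.n_components, n_folds=n_folds, seed=seed, model=model)
    rng = np.random.default_rng(seed)
    hits = 0
    for b in range(n_permutations):
        perm = rng.permutation(labels)
        press_b = _press(X, perm, model.n_components, n_folds, seed=seed + b + 1)
        if press_b <= model.cv_press:
            hits += 1
    return (1 + hits) / (n_permutations + 1)


def _press(X, labels, n_components: int, n_folds: int, seed: int) -> float:
    """PRESS of held-out class-dummy predictions under stratified CV."""
    tmp = PlsdaModel(
        n_components=n_components, classes_=np.unique(labels),
        x_weights=None, x_loadings=None, x_scores=None, y_loadings=None,
        coef=None, x_mean=None, y_mean=None,
        r2x=np.zeros(n_components), r2y=np.zeros(n_components),
    )
    q2_cv(X, labels, n_components, n_folds=n_folds, seed=seed, model=tmp)
    return tmp.cv_press


def vip_scores(model: PlsdaModel) -> np.ndarray:
    """Variable importance in the projection.

    VIP_j = sqrt( p * sum_a SSY_a w_aj^2 / sum_a SSY_a ) with unit-norm
    component weights w_a and SSY_a the class variance explained by
    component a; mean squared VIP over variables equals 1.
    """
    if model.r2y.sum() <= 0:
        raise ValueError("model explains no class variance; VIP undefined")
    p = model.x_weights.shape[0]
    w2 = model.x_weights**2  # columns already unit norm
    return np.sqrt(p * (w2 @ model.r2y) / model.r2y.sum())


def correlation_clusters(
    expr,
    seed_genes: Sequence[str],
    r_threshold: float = 0.7,
) -> pd.Series:
    """Assign each gene to the temporal-kinetic cluster of its nearest seed.

    Every gene goes to the seed gene with which its Pearson correlation
    across samples is maximal, provided that correlation exceeds
    ``r_threshold``; otherwise it stays unassigned (NaN).  Ties break
    toward the larger correlation magnitude, then the lexicographically
    smaller seed symbol.  Seed genes are their own barycenters.
    """
    from .qpcr import ExpressionMatrix  # local import to avoid cycle

    df = expr.values if isinstance(expr, ExpressionMatrix) else _matrix(expr)
    if not 0 < r_threshold < 1:
        raise ValueError("r_threshold must be in (0, 1)")
    missing = [g for g in seed_genes if g not in df.columns]
    if missing:
        raise ValueError(f"seed gene(s) absent from matrix: {missing}")
    seeds = sorted(seed_genes)
    corr = df.corr(method="pearson").loc[:, seeds]
    out = {}
    for gene in df.columns:
        if gene in seeds:
            out[gene] = gene
            continue
        r = corr.loc[gene]
        best = r.sort_values(ascending=False)
        top = best.index[0]
        ties = best.index[best == best.iloc[0]]
        if len(ties) > 1:
            top = sorted(ties, key=lambda s: (-abs(r[s]), s))[0]
        out[gene] = top if r[top] > r_threshold else np.nan
    return pd.Series(out, name="cluster")
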