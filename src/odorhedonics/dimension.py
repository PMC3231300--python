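"""Extraction of the hedonic dimension from an odor-profile matrix.

When a wide range of odors is profiled, the first principal component of
the (autoscaled) profile matrix often separates pleasant from unpleasant
odorants.  This module implements the decision workflow: optional
per-variable normalizing transforms, autoscaling, PCA, component-retention
criteria (eigenvalue > 1 and cross-validated Q^2), the no-intercept
quadratic relation between PC1 loadings and descriptor hedonic tones, and
the final is-PC1-hedonic verdict combining those criteria with the
correlation between PC1 scores and weighted-average hedonic estimates.

Q^2 uses an element-wise deletion scheme: random cells are held out in K
folds, the deleted entries are predicted by an iterative SVD (EM)
reconstruction fitted without them, and

    Q^2_k = 1 - PRESS_k / SS_{k-1}

where PRESS_k is the prediction error sum of squares of the k-component
model over held-out cells and SS_{k-1} the residual sum of squares of the
(k-1)-component model on the full data (SS_0 = total sum of squares).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from statsmodels.stats.outliers_influence import OLSInfluence

from .errors import (
    CollinearityError,
    DimensionError,
    ScalingError,
    TransformError,
)

# ---------------------------------------------------------------- transforms


def autoscale(m: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Mean-center and scale each column to unit variance (divisor n-1).

    Returns (scaled matrix, centers, scales).  A zero-variance column
    cannot be scaled and raises :class:`ScalingError` naming it.
    """
    center = m.mean(axis=0)
    scale = m.std(axis=0, ddof=1)
    dead = scale.index[(scale == 0) | scale.isna()]
    if len(dead):
        raise ScalingError(f"zero-variance column(s): {list(dead)}")
    return (m - center) / scale, center, scale


def transform_for_normality(
    m: pd.DataFrame,
    overrides: Optional[Mapping[str, str]] = None,
    log_offset: float = 1.0,
    skew_log_threshold: float = 1.5,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Apply per-variable normalizing transforms ("log", "sqrt" or "none").

    Explicit per-column overrides always win.  Otherwise the choice is
    automatic from the sample skewness: above `skew_log_threshold` ->
    log(x + offset); positive but moderate -> sqrt; else none.  Negative
    values are incompatible with both transforms.
    """
    overrides = {k: v for k, v in (overrides or {}).items()}
    unknown = set(overrides) - set(m.columns)
    if unknown:
        raise TransformError(f"override for absent column(s): {sorted(unknown)}")
    out = m.copy().astype(float)
    log: dict[str, str] = {}
    for col in m.columns:
        x = out[col].to_numpy()
        choice = overrides.get(col)
        if choice is None:
            skew = scipy.stats.skew(x, bias=False) if np.ptp(x) > 0 else 0.0
            choice = "log" if skew > skew_log_threshold else ("sqrt" if skew > 0 else "none")
        if choice not in ("log", "sqrt", "none"):
            raise TransformError(f"unknown transform {choice!r} for column {col!r}")
        if choice in ("log", "sqrt") and (x < 0).any():
            raise TransformError(f"negative values in column {col!r} under {choice}")
        if choice == "log":
            out[col] = np.log(x + log_offset)
        elif choice == "sqrt":
            out[col] = np.sqrt(x)
        log[col] = choice
    return out, log


# ----------------------------------------------------------------------- PCA


@dataclass
class PCAResult:
    """Loadings, scores, eigenvalues and bookkeeping of one PCA run.

    Loadings are orthonormal columns over descriptors; the score variance
    of component k (divisor n-1) equals the eigenvalue lambda_k.  Sign
    convention: when tones are supplied at orientation time, PC1 points so
    that corr(p1, tones) >= 0 and larger t1 means more pleasant; otherwise
    each component's largest-magnitude loading is positive.
    """

    loadings: pd.DataFrame  # descriptors x components
    scores: pd.DataFrame  # odorants x components
    eigenvalues: np.ndarray
    explained_variance_ratio: np.ndarray
    transform_log: dict[str, str] = field(default_factory=dict)
    center: Optional[pd.Series] = None
    scale: Optional[pd.Series] = None

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    def orient(self, tones: Optional[Sequence[float]] = None) -> "PCAResult":
        """Return a copy with the sign convention applied (see class doc)."""
        L = self.loadings.to_numpy().copy()
        S = self.scores.to_numpy().copy()
        for k in range(L.shape[1]):
            if k == 0 and tones is not None:
                t = np.asarray(tones, dtype=float)
                flip = np.corrcoef(L[:, 0], t)[0, 1] < 0
            else:
                flip = L[np.argmax(np.abs(L[:, k])), k] < 0
            if flip:
                L[:, k] = -L[:, k]
                S[:, k] = -S[:, k]
        return PCAResult(
            pd.DataFrame(L, index=self.loadings.index, columns=self.loadings.columns),
            pd.DataFrame(S, index=self.scores.index, columns=self.scores.columns),
            self.eigenvalues.copy(),
            self.explained_variance_ratio.copy(),
            dict(self.transform_log),
            self.center,
            self.scale,
        )

    def hedonic_scores(self) -> pd.DataFrame:
        """t1 scores packaged as hedonic estimates (method "pc1").

        Flagged "asymmetric-scale": PC1 scores typically span a wider range
        on the unpleasant side than the pleasant side, so they are not on
        the symmetric -4..+4 scale and downstream regressions default to
        the weighted-average estimates instead.
        """
        return pd.DataFrame(
            {
                "hedonic_score": self.scores.iloc[:, 0],
                "method": "pc1",
                "flags": "asymmetric-scale",
            },
            index=self.scores.index.rename("id"),
        )


def run_pca(m: pd.DataFrame, n_components: Optional[int] = None) -> PCAResult:
    """PCA of a (typically autoscaled) matrix via SVD.

    Components come out ordered by decreasing eigenvalue
    lambda_k = s_k^2/(n-1); with autoscaled input the eigenvalues sum to
    the number of variables when all components are kept.
    """
    X = m.to_numpy(dtype=float)
    n, p = X.shape
    max_comp = min(n - 1, p)
    if n_components is None:
        n_components = max_comp
    if not 1 <= n_components <= max_comp:
        raise DimensionError(
            f"n_components={n_components} outside 1..min(rows-1, cols)={max_comp}"
        )
    Xc = X - X.mean(axis=0)  # harmless if already centered
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    eig = s**2 / (n - 1)
    ratio = eig / eig.sum() if eig.sum() > 0 else eig
    k = n_components
    cols = [f"pc{i + 1}" for i in range(k)]
    loadings = pd.DataFrame(Vt[:k].T, index=m.columns, columns=cols)
    scores = pd.DataFrame(U[:, :k] * s[:k], index=m.index, columns=cols)
    return PCAResult(loadings, scores, eig[:k], ratio[:k]).orient()


# ------------------------------------------------------- Q^2 cross-validation


def _em_reconstruct(
    X: np.ndarray, mask: np.ndarray, rank: int, n_iter: int = 200, tol: float = 1e-9
) -> np.ndarray:
    """Rank-`rank` SVD reconstruction with entries under `mask` treated as
    missing, imputed by iterating fill -> SVD -> refill to convergence."""
    Xi = X.copy()
    Xi[mask] = 0.0  # columns of an autoscaled matrix have mean ~0
    prev = np.inf
    approx = Xi
    for _ in range(n_iter):
        U, s, Vt = np.linalg.svd(Xi, full_matrices=False)
        approx = (U[:, :rank] * s[:rank]) @ Vt[:rank]
        delta = float(np.abs(Xi[mask] - approx[mask]).max(initial=0.0))
        Xi[mask] = approx[mask]
        if delta < tol or abs(prev - delta) < tol:
            break
        prev = delta
    return approx


def q2_cross_validation(
    m: Union[pd.DataFrame, np.ndarray],
    n_components: int,
    folds: int = 7,
    seed: int = 0,
) -> np.ndarray:
    """Per-component cross-validated Q^2 by element-wise deletion.

    Cells are randomly partitioned into `folds` groups; each group is held
    out in turn and predicted by an EM/SVD model of the remaining cells.
    Returns Q^2_k = 1 - PRESS_k/SS_{k-1} for k = 1..n_components; values
    never exceed 1.
    """
    X = np.asarray(m, dtype=float)
    n, p = X.shape
    if folds < 2:
        raise DimensionError("need at least 2 folds")
    if folds > n * p:
        raise DimensionError(f"{folds} folds exceed the {n * p} matrix cells")
    if not 1 <= n_components <= min(n - 1, p):
        raise DimensionError(f"n_components={n_components} outside 1..{min(n - 1, p)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n * p)
    fold_of = np.empty(n * p, dtype=int)
    fold_of[order] = np.arange(n * p) % folds

    press = np.zeros(n_components)
    for f in range(folds):
        mask = (fold_of == f).reshape(n, p)
        for k in range(1, n_components + 1):
            approx = _em_reconstruct(X, mask, k)
            press[k - 1] += float(((X[mask] - approx[mask]) ** 2).sum())

    # residual SS of the full-data k-component model, k = 0..n_components-1
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    ss_prev = np.empty(n_components)
    ss_prev[0] = float((X**2).sum())
    for k in range(1, n_components):
        approx = (U[:, :k] * s[:k]) @ Vt[:k]
        ss_prev[k] = float(((X - approx) ** 2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        q2 = 1.0 - press / ss_prev
    return q2


# ------------------------------------------------- loading-tone relationship


@dataclass(frozen=True)
class LoadingToneModel:
    """No-intercept quadratic fit of PC1 loadings on hedonic tones.

    p1 = a*HT + b*HT^2 passes through the origin by construction, so a
    descriptor with positive loading maps to positive fitted tone over the
    increasing branch of the parabola.
    """

    linear: float
    quadratic: float
    rsquared: float  # R^2 through the origin (uncentered)
    residuals: pd.Series
    outliers: pd.Series  # |studentized residual| > 2

    def predict(self, tones) -> np.ndarray:
        t = np.asarray(tones, dtype=float)
        return self.linear * t + self.quadratic * t**2


def fit_loading_tone_quadratic(p1, tones) -> LoadingToneModel:
    """Fit p1 ~ HT + HT^2 without intercept; flag moderate outliers."""
    p1 = pd.Series(p1, dtype=float)
    t = np.asarray(tones, dtype=float)
    if len(p1) < 3:
        raise ValueError("need at least 3 loading/tone pairs")
    X = np.column_stack([t, t**2])
    if np.linalg.matrix_rank(X) < 2:
        raise CollinearityError("tones give a singular no-intercept quadratic design")
    res = sm.OLS(p1.to_numpy(), X).fit()
    student = OLSInfluence(res).resid_studentized_external
    return LoadingToneModel(
        linear=float(res.params[0]),
        quadratic=float(res.params[1]),
        rsquared=float(res.rsquared),
        residuals=pd.Series(res.resid, index=p1.index),
        outliers=pd.Series(np.abs(student) > 2.0, index=p1.index),
    )


# ------------------------------------------------------------------ decision


@dataclass(frozen=True)
class HedonicDecision:
    """Report on whether PC1 of a profile matrix is the hedonic dimension."""

    r_loading_tone: float
    p_loading_tone: float
    r_score_eq1: Optional[float]
    p_score_eq1: Optional[float]
    eigenvalue_pc1: float
    eigenvalue_ok: bool
    q2_pc1: float
    q2_ok: bool
    is_hedonic: bool

    def summary(self) -> str:
        lines = [
            "Hedonic-dimension decision",
            f"  corr(p1 loadings, tones): r={self.r_loading_tone:.3f} "
            f"p={self.p_loading_tone:.3g}",
        ]
        if self.r_score_eq1 is not None:
            lines.append(
                f"  corr(t1 scores, eq1 scores): r={self.r_score_eq1:.3f} "
                f"p={self.p_score_eq1:.3g}"
            )
        lines += [
            f"  eigenvalue PC1: {self.eigenvalue_pc1:.3f} "
            f"({'passes' if self.eigenvalue_ok else 'fails'} lambda > 1)",
            f"  Q^2 PC1: {self.q2_pc1:.3f} ({'passes' if self.q2_ok else 'fails'} threshold)",
            f"  verdict: PC1 {'IS' if self.is_hedonic else 'is NOT'} the hedonic dimension",
        ]
        return "\n".join(lines)


def hedonic_decision(
    pca: PCAResult,
    tones,
    data: Optional[pd.DataFrame] = None,
    eq1_scores=None,
    eigenvalue_threshold: float = 1.0,
    q2_threshold: float = 0.13,
    folds: int = 7,
    seed: int = 0,
    alpha: float = 0.05,
) -> HedonicDecision:
    """Decide whether PC1 is the hedonic dimension.

    Combines (a) the Pearson correlation between p1 loadings and descriptor
    tones, (b) optionally the correlation between t1 scores and
    weighted-average hedonic estimates, (c) the eigenvalue and Q^2
    retention criteria (Q^2 computed on `data`, the matrix the PCA ran on,
    when supplied).  Default rule: PC1 is hedonic iff the loading-tone
    correlation is positive and significant at `alpha` and at least one
    retention criterion passes.  P-values use the t-transform with n-2
    degrees of freedom, two-sided.
    """
    oriented = pca.orient(tones)
    t = np.asarray(tones, dtype=float)
    r_lt, p_lt = scipy.stats.pearsonr(oriented.loadings.iloc[:, 0].to_numpy(), t)
    r_se = p_se = None
    if eq1_scores is not None:
        if isinstance(eq1_scores, pd.DataFrame):
            eq1_scores = eq1_scores["hedonic_score"]
        e = np.asarray(eq1_scores, dtype=float)
        s1 = oriented.scores.iloc[:, 0].to_numpy()
        keep = np.isfinite(e)
        r_se, p_se = scipy.stats.pearsonr(s1[keep], e[keep])
        r_se, p_se = float(r_se), float(p_se)
    lam1 = float(pca.eigenvalues[0])
    eig_ok = lam1 > eigenvalue_threshold
    if data is not None:
        q2 = float(q2_cross_validation(data, 1, folds=folds, seed=seed)[0])
    else:
        q2 = float("nan")
    q2_ok = bool(q2 > q2_threshold) if np.isfinite(q2) else False
    verdict = bool(r_lt > 0 and p_lt < alpha and (eig_ok or q2_ok))
    return HedonicDecision(
        r_loading_tone=float(r_lt),
        p_loading_tone=float(p_lt),
        r_score_eq1=r_se,
        p_score_eq1=p_se,
        eigenvalue_pc1=lam1,
        eigenvalue_ok=bool(eig_ok),
        q2_pc1=q2,
        q2_ok=q2_ok,
        is_hedonic=verdict,
    )


# ------------------------------------------------------- model-object facade


class HedonicPCA:
    """Model object: profile matrix -> transformed, autoscaled PCA.

    Parameters
    ----------
    profile : odorant x descriptor matrix (non-negative applicabilities).
    transform : "auto" for skewness-based per-variable transforms, a
        per-column override map, or None for no transform.
    standardize : whether to autoscale (mean-center, unit variance; default).
    """

    def __init__(
        self,
        profile: pd.DataFrame,
        transform: Union[str, Mapping[str, str], None] = None,
        standardize: bool = True,
    ):
        self.profile = profile
        work = profile
        self.transform_log: dict[str, str] = {}
        if transform is not None:
            overrides = None if transform == "auto" else dict(transform)
            work, self.transform_log = transform_for_normality(work, overrides)
        self.center = self.scale = None
        if standardize:
            work, self.center, self.scale = autoscale(work)
        self.data = work

    def fit(self, n_components: Optional[int] = None) -> "HedonicPCAResults":
        res = run_pca(self.data, n_components)
        res.transform_log = dict(self.transform_log)
        res.center, res.scale = self.center, self.scale
        return HedonicPCAResults(self, res)


class HedonicPCAResults:
    """Fitted PCA with the decision workflow attached."""

    def __init__(self, model: HedonicPCA, result: PCAResult):
        self.model = model
        self.result = result

    @property
    def loadings(self) -> pd.DataFrame:
        return self.result.loadings

    @property
    def scores(self) -> pd.DataFrame:
        return self.result.scores

    @property
    def eigenvalues(self) -> np.ndarray:
        return self.result.eigenvalues

    def q2(self, n_components: Optional[int] = None, folds: int = 7, seed: int = 0):
        k = n_components or self.result.n_components
        return q2_cross_validation(self.model.data, k, folds=folds, seed=seed)

    def loading_tone_fit(self, tones) -> LoadingToneModel:
        oriented = self.result.orient(tones)
        return fit_loading_tone_quadratic(oriented.loadings.iloc[:, 0], tones)

    def decide(self, tones, eq1_scores=None, **kwargs) -> HedonicDecision:
        return hedonic_decision(
            self.result, tones, data=self.model.data, eq1_scores=eq1_scores, **kwargs
        )

    def plot_loading_tone(self, tones, ax=None):
        """Scatter of PC1 loadings vs tones with the fitted origin parabola."""
        import matplotlib.pyplot as plt

        fit = self.loading_tone_fit(tones)
        oriented = self.result.orient(tones)
        if ax is None:
            _, ax = plt.subplots()
        t = np.asarray(tones, dtype=float)
        ax.scatter(t, oriented.loadings.iloc[:, 0], s=18)
        grid = np.linspace(min(t.min(), -4), max(t.max(), 4), 200)
        ax.plot(grid, fit.predict(grid), lw=1.2)
        ax.axhline(0, lw=0.5, color="grey")
        ax.axvline(0, lw=0.5, color="grey")
        ax.set_xlabel("descriptor hedonic tone")
        ax.set_ylabel("PC1 loading")
        return ax

    def summary(self) -> str:
        lam = ", ".join(f"{v:.3f}" for v in self.eigenvalues)
        evr = ", ".join(f"{v:.1%}" for v in self.result.explained_variance_ratio)
        return (
            f"PCA of {self.model.data.shape[0]} odorants x "
            f"{self.model.data.shape[1]} descriptors\n"
            f"  eigenvalues: {lam}\n  explained variance: {evr}\n"
            f"  transforms: {self.result.transform_log or 'none'}"
        )
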