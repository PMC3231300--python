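"""Hedonic-score regression on molecular features, with analytics.

The model class follows the statsmodels convention: build a
:class:`HedonicRegression` from data, call :meth:`~HedonicRegression.fit`,
get a :class:`HedonicRegressionResults` carrying coefficients, standard
errors, p-values, R^2 and the diagnostics the workflow requires (residual
normality, influential points).  The published equations are available as
immutable presets (see :mod:`odorhedonics.presets`); the analytic helpers
(`null_crossing`, `optimum_nat`) answer the scientific questions those
equations pose: at what molecular size does predicted pleasantness cross
zero, and where does a quadratic model reach its hedonic optimum.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from statsmodels.stats.outliers_influence import OLSInfluence

from .errors import CollinearityError, UndeterminedFeatureError
from .presets import INDICATOR_TERMS, PRESETS, PresetEquation, term_columns

ModelLike = Union["HedonicRegressionResults", PresetEquation, str]


def _coerce_model(model: ModelLike) -> Tuple[Mapping[str, float], Optional[str]]:
    """Return (term->coefficient map, advisory) for a results object,
    preset, or preset id."""
    if isinstance(model, str):
        if model not in PRESETS:
            raise KeyError(f"unknown preset {model!r}; choose from {sorted(PRESETS)}")
        model = PRESETS[model]
    if isinstance(model, PresetEquation):
        return dict(model.coefficients), model.advisory
    return dict(model.params), None


def _check_determined(features: pd.DataFrame, terms: Sequence[str]) -> None:
    needed = [t for t in ("i_acid", "i_amine") if t in terms]
    for t in needed:
        if features[t].isna().any():
            bad = list(features.index[features[t].isna()])
            raise UndeterminedFeatureError(
                f"term {t!r} required but undetermined for molecules {bad[:10]}"
                + ("..." if len(bad) > 10 else "")
            )


def _design(features: pd.DataFrame, terms: Tuple[str, ...]) -> pd.DataFrame:
    _check_determined(features, terms)
    X = term_columns(features, terms)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < len(terms):
        # name the dependent columns via near-zero singular directions
        _, s, vt = np.linalg.svd(X.to_numpy(), full_matrices=False)
        dep = vt[rank:]
        involved = [
            terms[j] for j in range(len(terms)) if np.abs(dep[:, j]).max() > 1e-8
        ]
        raise CollinearityError(f"singular design; linearly dependent terms: {involved}")
    return X


class HedonicRegression:
    """OLS model of hedonic scores on molecular-feature terms.

    Parameters
    ----------
    scores : Series or array of hedonic scores (response), indexed by
        molecule id when a Series.
    features : DataFrame with columns n_at, i_ox, i_sul, i_acid, i_amine
        (as required by `terms`), same index as `scores`.
    terms : regression terms from
        {"const","n_at","n_at2","i_ox","i_sul","i_acid","i_amine","i_ox:n_at"}.
    """

    def __init__(self, scores, features: pd.DataFrame, terms: Sequence[str]):
        if isinstance(scores, pd.DataFrame):
            scores = scores["hedonic_score"]
        y = pd.Series(np.asarray(scores, dtype=float), index=features.index)
        keep = y.notna()
        self.endog = y[keep]
        self.features = features.loc[keep]
        self.terms: Tuple[str, ...] = tuple(terms)
        if len(self.endog) <= len(self.terms):
            raise ValueError(
                f"need more observations ({len(self.endog)}) than terms ({len(self.terms)})"
            )

    @classmethod
    def from_dataframe(
        cls, data: pd.DataFrame, terms: Sequence[str], response: str = "hedonic_score"
    ) -> "HedonicRegression":
        return cls(data[response], data, terms)

    def fit(self) -> "HedonicRegressionResults":
        X = _design(self.features, self.terms)
        res = sm.OLS(self.endog.to_numpy(), X.to_numpy()).fit()
        return HedonicRegressionResults(self, res, X)


class HedonicRegressionResults:
    """Fitted hedonic regression with diagnostics.

    Exposes ``params``, ``bse``, ``pvalues`` (Series by term), ``rsquared``,
    ``nobs``, residual-normality omnibus test, and an influential-point
    report (Cook's distance > 1 or leverage > 3*p/n).  Exclusion of
    influential points is explicit via :meth:`refit_without_influential`,
    never silent.
    """

    provenance = "fitted"

    def __init__(self, model: HedonicRegression, sm_results, design: pd.DataFrame):
        self.model = model
        self._sm = sm_results
        self._design = design
        terms = model.terms
        self.params = pd.Series(sm_results.params, index=terms)
        self.bse = pd.Series(sm_results.bse, index=terms)
        self.pvalues = pd.Series(sm_results.pvalues, index=terms)
        self.rsquared = float(sm_results.rsquared)
        self.nobs = int(sm_results.nobs)
        self.resid = pd.Series(sm_results.resid, index=design.index)
        stat, p = scipy.stats.normaltest(sm_results.resid)
        self.residual_normality = {"statistic": float(stat), "pvalue": float(p)}

    @property
    def influential(self) -> pd.DataFrame:
        infl = OLSInfluence(self._sm)
        cooks = infl.cooks_distance[0]
        lev = infl.hat_matrix_diag
        p = len(self.model.terms)
        n = self.nobs
        flagged = (cooks > 1.0) | (lev > 3.0 * p / n)
        return pd.DataFrame(
            {"cooks_distance": cooks, "leverage": lev, "influential": flagged},
            index=self._design.index,
        )

    def refit_without_influential(self) -> "HedonicRegressionResults":
        """Refit excluding flagged influential points (auditable opt-in)."""
        flagged = self.influential["influential"]
        if not flagged.any():
            return self
        keep = ~flagged
        sub = HedonicRegression(
            self.model.endog[keep], self.model.features.loc[keep], self.model.terms
        )
        return sub.fit()

    def predict(self, features: pd.DataFrame) -> pd.Series:
        _check_determined(features, self.model.terms)
        X = term_columns(features, self.model.terms)
        return pd.Series(X.to_numpy() @ self.params.to_numpy(), index=features.index)

    def summary(self) -> str:
        lines = [
            f"Hedonic regression  n={self.nobs}  R^2={self.rsquared:.4f}",
            f"residual normality: stat={self.residual_normality['statistic']:.3f} "
            f"p={self.residual_normality['pvalue']:.3g}",
            f"{'term':>10} {'coef':>10} {'se':>9} {'p':>10}",
        ]
        for t in self.model.terms:
            lines.append(
                f"{t:>10} {self.params[t]:>10.4f} {self.bse[t]:>9.4f} {self.pvalues[t]:>10.3g}"
            )
        n_infl = int(self.influential["influential"].sum())
        lines.append(f"influential points flagged: {n_infl}")
        return "\n".join(lines)


def fit_hedonic_model(
    features: pd.DataFrame,
    scores,
    terms: Sequence[str],
    exclude_influential: bool = False,
) -> HedonicRegressionResults:
    """Convenience wrapper: build and fit a :class:`HedonicRegression`."""
    res = HedonicRegression(scores, features, terms).fit()
    if exclude_influential:
        res = res.refit_without_influential()
    return res


def predict(model: ModelLike, features: pd.DataFrame) -> pd.DataFrame:
    """Evaluate a fitted model or preset on a feature table."""
    coeffs, _ = _coerce_model(model)
    terms = tuple(coeffs)
    _check_determined(features, terms)
    X = term_columns(features, terms)
    vals = X.to_numpy() @ np.array([coeffs[t] for t in terms])
    return pd.DataFrame(
        {"hedonic_score": vals, "method": "regression", "flags": ""},
        index=features.index,
    )


def _polynomial_in_nat(
    coeffs: Mapping[str, float], fixed_indicators: Mapping[str, int]
) -> Tuple[float, float, float]:
    """Collapse a term map onto (c0, c1, c2) of c0 + c1*N + c2*N^2 given
    fixed indicator values (unspecified indicators default to 0)."""
    ind = {t: int(fixed_indicators.get(t, 0)) for t in INDICATOR_TERMS}
    c0 = coeffs.get("const", 0.0) + sum(coeffs.get(t, 0.0) * ind[t] for t in INDICATOR_TERMS)
    c1 = coeffs.get("n_at", 0.0) + coeffs.get("i_ox:n_at", 0.0) * ind["i_ox"]
    c2 = coeffs.get("n_at2", 0.0)
    return c0, c1, c2


@dataclass(frozen=True)
class NullCrossing:
    """Real roots in N_at of a hedonic prediction polynomial.

    ``threshold`` is the pleasantness threshold: the (smaller positive)
    N_at at which the predicted score crosses zero.  Roots beyond the
    typical fitted range are reported with an extrapolation flag.
    """

    roots: Tuple[float, ...]
    threshold: Optional[float]
    extrapolated: Tuple[float, ...]
    kind: str  # "linear" | "quadratic" | "none"

    @property
    def has_crossing(self) -> bool:
        return self.threshold is not None


#: Largest N_at regarded as within the fitted range of the study sets.
NAT_FITTED_MAX = 29.0


def null_crossing(
    model: ModelLike, fixed_indicators: Optional[Mapping[str, int]] = None
) -> NullCrossing:
    """N_at value(s) at which the predicted hedonic score equals zero.

    Indicators are held at `fixed_indicators` (default: oxygen present,
    all others absent).  Roots are returned ascending and restricted to
    (0, 100); an empty result is a no-crossing outcome, not an error.
    """
    coeffs, _ = _coerce_model(model)
    fixed = dict(fixed_indicators) if fixed_indicators is not None else {"i_ox": 1}
    c0, c1, c2 = _polynomial_in_nat(coeffs, fixed)
    if c2 == 0.0 and c1 == 0.0:
        return NullCrossing((), None, (), "none")
    if c2 == 0.0:
        root = -c0 / c1
        roots = (root,) if 0 < root < 100 else ()
        return NullCrossing(roots, roots[0] if roots else None, (), "linear")
    disc = c1 * c1 - 4.0 * c2 * c0
    if disc < 0:
        return NullCrossing((), None, (), "quadratic")
    sq = float(np.sqrt(disc))
    r = sorted(((-c1 - sq) / (2 * c2), (-c1 + sq) / (2 * c2)))
    roots = tuple(x for x in r if 0 < x < 100)
    extrapolated = tuple(x for x in roots if x > NAT_FITTED_MAX)
    threshold = roots[0] if roots else None
    return NullCrossing(roots, threshold, extrapolated, "quadratic")


@dataclass(frozen=True)
class Optimum:
    """Vertex analysis of a (possibly quadratic) hedonic model."""

    kind: str  # "maximum" | "monotone" | "unbounded"
    n_at: Optional[float] = None
    score: Optional[float] = None


def optimum_nat(
    model: ModelLike, fixed_indicators: Optional[Mapping[str, int]] = None
) -> Optimum:
    """Hedonically optimal molecular size under a quadratic model.

    For a negative quadratic coefficient the prediction peaks at the vertex
    -c1/(2*c2); a model without a quadratic term is "monotone" and a
    positive quadratic coefficient is "unbounded".
    """
    coeffs, _ = _coerce_model(model)
    fixed = dict(fixed_indicators) if fixed_indicators is not None else {"i_ox": 1}
    c0, c1, c2 = _polynomial_in_nat(coeffs, fixed)
    if c2 == 0.0:
        return Optimum("monotone")
    if c2 > 0.0:
        return Optimum("unbounded")
    vertex = -c1 / (2.0 * c2)
    return Optimum("maximum", vertex, c0 + c1 * vertex + c2 * vertex**2)


def classify_pleasant(scores) -> pd.DataFrame:
    """Classify each score as pleasant (strictly > 0) and report the fraction.

    Returns a frame with a boolean ``pleasant`` column; the pleasant
    fraction and n are stored in ``.attrs``.  A score of exactly zero is
    not pleasant.
    """
    if isinstance(scores, pd.DataFrame):
        scores = scores["hedonic_score"]
    s = pd.Series(scores, dtype=float)
    if s.isna().any():
        raise ValueError("scores must be finite; drop odorless/missing rows first")
    out = pd.DataFrame({"hedonic_score": s, "pleasant": s > 0})
    out.attrs["fraction_pleasant"] = float((s > 0).mean())
    out.attrs["n"] = int(len(s))
    return out


@dataclass(frozen=True)
class ScoreComparison:
    r: float
    pvalue: float
    slope: float
    intercept: float
    slope_ci: Tuple[float, float]
    intercept_ci: Tuple[float, float]
    nobs: int


def compare_scores(a, b) -> ScoreComparison:
    """Pearson correlation and calibration line between two score sets.

    Fits b ~ a by OLS and reports r, the two-sided p-value, and 95%
    confidence intervals for slope and intercept.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    keep = np.isfinite(a) & np.isfinite(b)
    a, b = a[keep], b[keep]
    if len(a) < 3:
        raise ValueError("need at least 3 paired finite scores")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("zero variance in one score vector; correlation undefined")
    r, p = scipy.stats.pearsonr(a, b)
    X = sm.add_constant(a)
    res = sm.OLS(b, X).fit()
    ci = res.conf_int(alpha=0.05)
    return ScoreComparison(
        r=float(r),
        pvalue=float(p),
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        slope_ci=(float(ci[1][0]), float(ci[1][1])),
        intercept_ci=(float(ci[0][0]), float(ci[0][1])),
        nobs=len(a),
    )
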