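"""Hedonic scoring of odorants from numerical odor-character profiles.

An odor profile is a non-negative odorant x descriptor matrix whose entries
(0-100 "percentage applicability") say how strongly each descriptor applies
to each odorant.  Given per-descriptor hedonic tones on a -4..+4 scale
(pleasantness of the descriptor itself, as rated by a panel), the hedonic
score of an odorant is estimated as the tone-weighted average over its
profile row:

    H_i = sum_j HT_j * x_ij / sum_j x_ij

which is a convex combination of the tones of the descriptors actually used
for that odorant.  This module houses the tone vocabulary, the 7-point
semantic coding of verbal hedonic labels, profile clean-up (noise threshold,
descriptor aliases), the weighted-average estimator, preference-ranking
conversion, and calibration fits between score variants.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from .errors import CollinearityError, VocabularyError

#: Symmetric 7-point coding of verbal hedonic labels onto the -4..+4 scale.
SEMANTIC_SCALE: Mapping[str, float] = {
    "very unpleasant": -4.0,
    "moderately unpleasant": -2.67,
    "slightly unpleasant": -1.33,
    "neutral": 0.0,
    "slightly pleasant": 1.33,
    "moderately pleasant": 2.67,
    "very pleasant": 4.0,
}

_WS = re.compile(r"\s+")


def canonical_descriptor(name: str) -> str:
    """Canonical descriptor key: case-folded, trimmed, whitespace collapsed.

    Comma-variants such as "sour, vinegar" are kept verbatim as names.
    """
    return _WS.sub(" ", name.strip().casefold())


def code_semantic_hedonic(label: str) -> float:
    """Map one of the seven verbal hedonic categories to its numeric value."""
    key = canonical_descriptor(label)
    try:
        return SEMANTIC_SCALE[key]
    except KeyError:
        raise VocabularyError(
            f"unknown semantic hedonic label {label!r}; expected one of "
            f"{sorted(SEMANTIC_SCALE)}"
        ) from None


class HedonicVocabulary:
    """Descriptor -> hedonic tone map on the -4..+4 scale."""

    def __init__(self, entries: Mapping[str, float], provenance: str = "user"):
        self.provenance = provenance
        canon: dict[str, float] = {}
        for name, tone in entries.items():
            key = canonical_descriptor(name)
            if key in canon:
                raise VocabularyError(f"duplicate descriptor after canonicalization: {key!r}")
            tone = float(tone)
            if not -4.0 <= tone <= 4.0:
                raise VocabularyError(f"tone {tone} for {key!r} outside [-4, 4]")
            canon[key] = tone
        self._entries = canon

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, name: str) -> bool:
        return canonical_descriptor(name) in self._entries

    def __iter__(self):
        return iter(self._entries)

    def tone(self, name: str) -> float:
        key = canonical_descriptor(name)
        try:
            return self._entries[key]
        except KeyError:
            raise VocabularyError(f"descriptor {name!r} has no hedonic tone") from None

    def tones_for(self, names: Sequence[str]) -> pd.Series:
        """Tones aligned to `names`; raises listing every missing descriptor."""
        missing = [n for n in names if n not in self]
        if missing:
            raise VocabularyError(f"descriptors without hedonic tone: {missing}")
        return pd.Series([self.tone(n) for n in names], index=list(names), dtype=float)

    def as_series(self) -> pd.Series:
        return pd.Series(self._entries, dtype=float)

    @classmethod
    def from_file(cls, path, sep: Optional[str] = None, provenance: Optional[str] = None):
        df = pd.read_csv(path, sep=sep, engine="python")
        if not {"descriptor", "hedonic_tone"} <= set(df.columns):
            raise VocabularyError(
                f"vocabulary file {path} must have columns 'descriptor', 'hedonic_tone'"
            )
        return cls(
            dict(zip(df["descriptor"], df["hedonic_tone"])),
            provenance=provenance or str(path),
        )

    @classmethod
    def published_subset(cls) -> "HedonicVocabulary":
        """The hedonic tones printed in the source study (8 descriptors).

        The full 146-descriptor panel vocabulary is not public; this subset
        ships as a fixture and user files supply the rest.
        """
        with resources.files("odorhedonics.data").joinpath("ht_d84_published.csv").open() as fh:
            df = pd.read_csv(fh)
        return cls(dict(zip(df["descriptor"], df["hedonic_tone"])), provenance="published-subset")


def validate_profile(m: pd.DataFrame) -> None:
    if m.empty:
        raise ValueError("empty profile matrix")
    if m.index.has_duplicates or m.columns.has_duplicates:
        raise ValueError("duplicate row or column labels in profile matrix")
    vals = m.to_numpy(dtype=float)
    if np.isnan(vals).any() or (vals < 0).any():
        raise ValueError("profile matrix must be non-negative and complete")


def clean_profile(
    m: pd.DataFrame, threshold: float = 4.0
) -> tuple[pd.DataFrame, list[str]]:
    """Zero out sub-threshold applicabilities and drop emptied descriptors.

    Values strictly below `threshold` (default 4, i.e. 4% of the maximum)
    are treated as panel noise and set to zero; descriptor columns that
    become all-zero are removed.  Returns (cleaned matrix, dropped column
    names).  Idempotent.
    """
    validate_profile(m)
    out = m.astype(float).where(m >= threshold, 0.0)
    dead = out.columns[(out == 0).all(axis=0)]
    return out.drop(columns=dead), list(dead)


def apply_descriptor_aliases(
    m: pd.DataFrame,
    aliases: Optional[Mapping[str, str]] = None,
    drop: Optional[Iterable[str]] = None,
    vocabulary: Optional[HedonicVocabulary] = None,
) -> pd.DataFrame:
    """Drop unusable descriptor columns and rename aliased ones.

    When an alias target column already exists the two columns merge by
    element-wise maximum, keeping applicability within 0-100.  If a
    vocabulary is supplied, alias targets must have a tone in it.
    """
    validate_profile(m)
    out = m.copy()
    for col in drop or []:
        if col not in out.columns:
            raise VocabularyError(f"cannot drop absent descriptor {col!r}")
        out = out.drop(columns=[col])
    for src, dst in (aliases or {}).items():
        if src not in out.columns:
            raise VocabularyError(f"alias source {src!r} not a column")
        if vocabulary is not None and dst not in vocabulary:
            raise VocabularyError(f"alias target {dst!r} has no hedonic tone")
        if dst in out.columns:
            out[dst] = np.maximum(out[dst].to_numpy(), out[src].to_numpy())
            out = out.drop(columns=[src])
        else:
            out = out.rename(columns={src: dst})
    return out


ODORLESS_FLAG = "odorless"


def estimate_hedonic_eq1(m: pd.DataFrame, v: HedonicVocabulary) -> pd.DataFrame:
    """Tone-weighted-average hedonic score for every odorant row.

    Returns a frame indexed by odorant id with columns ``hedonic_score``,
    ``method`` ("eq1") and ``flags``.  A row whose applicabilities sum to
    zero has no defined score: it is returned as NaN with the "odorless"
    flag, and downstream fits must exclude it.
    """
    validate_profile(m)
    tones = v.tones_for(list(m.columns))
    x = m.to_numpy(dtype=float)
    wsum = x.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        scores = x @ tones.to_numpy() / wsum
    scores = np.where(wsum > 0, scores, np.nan)
    return pd.DataFrame(
        {
            "hedonic_score": scores,
            "method": "eq1",
            "flags": np.where(wsum > 0, "", ODORLESS_FLAG),
        },
        index=m.index.rename("id"),
    )


def convert_preference_ranking(pr, intercept: float = 7.11, slope: float = -0.091):
    """Convert mean preference rankings (lower = preferred) to hedonic scores.

    Uses the published affine calibration H = 7.11 - 0.091 * PR obtained by
    regressing panel hedonic ratings on preference rankings for compounds
    common to both studies.
    """
    arr = np.asarray(pr, dtype=float)
    if (arr <= 0).any():
        raise ValueError("preference rankings must be positive")
    out = intercept + slope * arr
    if np.isscalar(pr) or arr.ndim == 0:
        return float(out)
    return pd.DataFrame(
        {
            "hedonic_score": out,
            "method": "converted-ranking",
            "flags": "",
        },
        index=pr.index.rename("id") if isinstance(pr, pd.Series) else None,
    )


@dataclass(frozen=True)
class CalibrationResult:
    """Least-squares calibration between two hedonic-score variants."""

    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    rsquared: float
    r: float
    nobs: int
    with_intercept: bool
    quadratic: bool

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        out = np.zeros_like(x)
        if self.with_intercept:
            out = out + self.params["const"]
        out = out + self.params["x"] * x
        if self.quadratic:
            out = out + self.params["x2"] * x**2
        return out

    def summary(self) -> str:
        lines = [
            f"Calibration fit (n={self.nobs}, R^2={self.rsquared:.4f}, r={self.r:.4f})",
            f"{'term':>6} {'coef':>12} {'se':>10} {'p':>10}",
        ]
        for t in self.params.index:
            lines.append(
                f"{t:>6} {self.params[t]:>12.4f} {self.bse[t]:>10.4f} {self.pvalues[t]:>10.4g}"
            )
        return "\n".join(lines)


def fit_score_calibration(
    x, y, with_intercept: bool = True, quadratic: bool = False
) -> CalibrationResult:
    """OLS calibration y ~ [1] + x [+ x^2] between paired score vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    names = (["const"] if with_intercept else []) + ["x"] + (["x2"] if quadratic else [])
    if len(x) < len(names) + 1:
        raise ValueError(f"need at least {len(names) + 1} paired finite values, got {len(x)}")
    if np.ptp(x) == 0:
        raise CollinearityError("predictor scores are constant; calibration fit is singular")
    cols = [x] + ([x**2] if quadratic else [])
    X = np.column_stack(([np.ones_like(x)] if with_intercept else []) + cols)
    res = sm.OLS(y, X).fit()
    r = float(scipy.stats.pearsonr(x, y)[0])
    return CalibrationResult(
        params=pd.Series(res.params, index=names),
        bse=pd.Series(res.bse, index=names),
        pvalues=pd.Series(res.pvalues, index=names),
        rsquared=float(res.rsquared),
        r=r,
        nobs=int(res.nobs),
        with_intercept=with_intercept,
        quadratic=quadratic,
    )
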