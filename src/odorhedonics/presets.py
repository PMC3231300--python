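"""Published hedonic prediction equations and score calibrations.

Five regression equations relate the hedonic score of an odorant to its
heavy-atom count N_at and functional-group indicators; they were obtained
on five independent chemical sets and ship here as immutable presets.  The
preference-ranking-scale variant (eq8) is retained only for round-trip
checks against its hedonic-scale equivalent (eq9).  The calibration
constants relating score variants (panel ratings vs weighted-average
estimates vs first-principal-component scores) are kept alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Mapping, Optional, Tuple

import numpy as np
import pandas as pd

#: Canonical regression-term names in display order.
TERM_ORDER: Tuple[str, ...] = (
    "const",
    "n_at",
    "n_at2",
    "i_ox",
    "i_sul",
    "i_acid",
    "i_amine",
    "i_ox:n_at",
)

INDICATOR_TERMS = ("i_ox", "i_sul", "i_acid", "i_amine")


def term_columns(features: pd.DataFrame, terms: Tuple[str, ...]) -> pd.DataFrame:
    """Build the design columns for `terms` from a feature table.

    `features` needs columns n_at, i_ox, i_sul, i_acid, i_amine as
    applicable.  NaN in a required indicator (undetermined tri-state) is a
    contract violation handled by the caller.
    """
    cols = {}
    for t in terms:
        if t == "const":
            cols[t] = np.ones(len(features))
        elif t == "n_at":
            cols[t] = features["n_at"].to_numpy(dtype=float)
        elif t == "n_at2":
            cols[t] = features["n_at"].to_numpy(dtype=float) ** 2
        elif t == "i_ox:n_at":
            cols[t] = features["i_ox"].to_numpy(dtype=float) * features["n_at"].to_numpy(
                dtype=float
            )
        elif t in INDICATOR_TERMS:
            cols[t] = features[t].to_numpy(dtype=float)
        else:
            raise ValueError(f"unknown regression term {t!r}")
    return pd.DataFrame(cols, index=features.index)


@dataclass(frozen=True)
class PresetEquation:
    """An immutable published prediction equation."""

    id: str
    response: str  # "hedonic" (-4..4 scale) or "preference" (ranking scale)
    coefficients: Mapping[str, float]
    advisory: Optional[str] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "coefficients", MappingProxyType(dict(self.coefficients)))

    @property
    def terms(self) -> Tuple[str, ...]:
        return tuple(self.coefficients)

    def predict(self, features: pd.DataFrame) -> pd.Series:
        X = term_columns(features, self.terms)
        beta = np.array([self.coefficients[t] for t in self.terms])
        return pd.Series(X.to_numpy() @ beta, index=features.index, name=self.id)


PRESETS: Mapping[str, PresetEquation] = MappingProxyType(
    {
        "eq7": PresetEquation(
            "eq7",
            "hedonic",
            {"const": -2.56, "n_at": 0.23, "i_ox": 1.26, "i_sul": -1.54},
        ),
        "eq8": PresetEquation(
            "eq8",
            "preference",
            {
                "const": 106.9,
                "n_at": -2.49,
                "i_ox": -17.33,
                "i_sul": 21.6,
                "i_acid": 28.32,
                "i_amine": 20.77,
            },
            advisory="preference-ranking scale; use eq9 for hedonic predictions",
        ),
        "eq9": PresetEquation(
            "eq9",
            "hedonic",
            {
                "const": -2.62,
                "n_at": 0.23,
                "i_ox": 1.58,
                "i_sul": -1.96,
                "i_acid": -2.58,
                "i_amine": -1.89,
            },
        ),
        "eq10": PresetEquation(
            "eq10",
            "hedonic",
            {
                "const": -1.87,
                "n_at": 0.22,
                "i_ox": 2.60,
                "i_sul": -2.23,
                "i_acid": -3.51,
            },
            advisory=(
                "not recommended for prediction: fitted on a set with no "
                "neutral odorants, inflating the oxygen coefficient"
            ),
        ),
        "eq11": PresetEquation(
            "eq11",
            "hedonic",
            {
                "const": -2.33,
                "n_at": 0.33,
                "n_at2": -0.0104,
                "i_ox:n_at": 0.057,
                "i_sul": -0.83,
                "i_acid": -1.62,
            },
        ),
        "eq12": PresetEquation(
            "eq12",
            "hedonic",
            {
                "const": -1.85,
                "n_at": 0.35,
                "n_at2": -0.014,
                "i_ox:n_at": 0.041,
            },
        ),
    }
)


@dataclass(frozen=True)
class CalibrationEquation:
    """Published affine/quadratic relation between two score variants."""

    id: str
    response: str
    predictor: str
    intercept: float
    linear: float
    quadratic: float = 0.0

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return self.intercept + self.linear * x + self.quadratic * x**2


CALIBRATIONS: Mapping[str, CalibrationEquation] = MappingProxyType(
    {
        "eq2": CalibrationEquation("eq2", "H_panel", "H_eq1", 0.26, 1.03),
        "eq3": CalibrationEquation("eq3", "H_panel", "PR", 7.11, -0.091),
        "eq5": CalibrationEquation("eq5", "H_t1", "H_eq1", -0.297, 3.365, -0.491),
        "eq6": CalibrationEquation("eq6", "H_panel", "H_eq1", 0.185, 1.228),
    }
)

#: Loading-tone quadratic through the origin: p1 = 0.0309*HT - 0.0046*HT^2.
LOADING_TONE_COEFFS: Tuple[float, float] = (0.0309, -0.0046)
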