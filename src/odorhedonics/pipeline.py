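"""End-to-end analysis workflows with run manifests.

Each workflow composes the library stages (clean -> alias -> score;
join -> fit/evaluate -> analytics; transform -> autoscale -> PCA ->
decision) and returns a report object carrying the results plus the
bookkeeping a reproducible run needs: what was dropped, joined, excluded,
and under which seed.  Warnings (dropped descriptors, clipped scores,
join mismatches) are recorded in the report, never silent.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from . import __version__
from .chem import MoleculeRecord, featurize, features_frame
from .dimension import HedonicDecision, HedonicPCA
from .errors import JoinError
from .regression import (
    HedonicRegressionResults,
    NullCrossing,
    Optimum,
    classify_pleasant,
    fit_hedonic_model,
    null_crossing,
    optimum_nat,
    predict,
)
from .scoring import HedonicVocabulary, apply_descriptor_aliases, clean_profile, estimate_hedonic_eq1


@dataclass
class RunManifest:
    """Reproducibility record for one pipeline run."""

    command: str
    config: dict
    input_digests: dict
    seed: Optional[int]
    package_version: str = __version__
    timestamp: float = field(default_factory=time.time)

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True, default=str)

    def write(self, path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(self.to_json() + "\n")
        return path


def digest_file(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


@dataclass
class ScoreReport:
    scores: pd.DataFrame
    dropped_descriptors: list[str]
    n_odorants: int
    n_odorless: int
    manifest: RunManifest

    def summary(self) -> str:
        return (
            f"Scored {self.n_odorants} odorants "
            f"({self.n_odorless} odorless/undefined); "
            f"dropped descriptors: {self.dropped_descriptors or 'none'}"
        )


def run_profile_to_hedonics(
    profile: pd.DataFrame,
    vocabulary: HedonicVocabulary,
    threshold: float = 4.0,
    aliases: Optional[Mapping[str, str]] = None,
    drop: Optional[Sequence[str]] = None,
    seed: Optional[int] = None,
) -> ScoreReport:
    """clean -> alias -> weighted-average scoring of a profile matrix."""
    if profile.empty:
        raise ValueError("empty profile matrix")
    work = apply_descriptor_aliases(profile, aliases, drop, vocabulary)
    work, dropped = clean_profile(work, threshold)
    dropped = list(drop or []) + dropped
    scores = estimate_hedonic_eq1(work, vocabulary)
    manifest = RunManifest(
        command="score",
        config={
            "threshold": threshold,
            "aliases": dict(aliases or {}),
            "drop": list(drop or []),
        },
        input_digests={},
        seed=seed,
    )
    return ScoreReport(
        scores=scores,
        dropped_descriptors=dropped,
        n_odorants=len(scores),
        n_odorless=int(scores["hedonic_score"].isna().sum()),
        manifest=manifest,
    )


@dataclass
class RegressionReport:
    model: object  # HedonicRegressionResults or preset id
    predictions: pd.DataFrame
    crossing: NullCrossing
    optimum: Optimum
    pleasant_fraction: float
    n_joined: int
    n_score_only: int
    n_molecule_only: int
    manifest: RunManifest

    def summary(self) -> str:
        lines = [f"n joined: {self.n_joined} (score-only {self.n_score_only}, "
                 f"molecule-only {self.n_molecule_only})"]
        if isinstance(self.model, HedonicRegressionResults):
            lines.append(self.model.summary())
        else:
            lines.append(f"preset model: {self.model}")
        if self.crossing.has_crossing:
            lines.append(f"pleasantness threshold N_at = {self.crossing.threshold:.2f}")
        if self.optimum.kind == "maximum":
            lines.append(
                f"hedonic optimum at N_at = {self.optimum.n_at:.2f} "
                f"(score {self.optimum.score:.2f})"
            )
        lines.append(f"pleasant fraction: {self.pleasant_fraction:.1%}")
        return "\n".join(lines)


def run_structure_regression(
    scores: pd.DataFrame,
    molecules: Sequence[MoleculeRecord],
    terms: Optional[Sequence[str]] = None,
    preset: Optional[str] = None,
    fixed_indicators: Optional[Mapping[str, int]] = None,
    exclude_influential: bool = False,
    seed: Optional[int] = None,
) -> RegressionReport:
    """Join scores to molecules, fit or evaluate, run the analytics.

    Inner join on id; mismatches are counted in the report, never silently
    absorbed.  Either `terms` (fit a new model) or `preset` (evaluate a
    published equation) must be given.
    """
    if (terms is None) == (preset is None):
        raise ValueError("give exactly one of terms=... or preset=...")
    feats = features_frame(featurize(m) for m in molecules)
    joined = feats.join(scores[["hedonic_score"]], how="inner").dropna(
        subset=["hedonic_score"]
    )
    if joined.empty:
        raise JoinError("no molecules share ids with the score table")
    n_score_only = len(scores.index.difference(feats.index))
    n_mol_only = len(feats.index.difference(scores.index))

    if terms is not None:
        model: object = fit_hedonic_model(
            joined, joined["hedonic_score"], terms, exclude_influential
        )
        preds = predict(model, joined)
    else:
        model = preset
        preds = predict(preset, joined)
    crossing = null_crossing(model, fixed_indicators)
    opt = optimum_nat(model, fixed_indicators)
    classified = classify_pleasant(preds)
    manifest = RunManifest(
        command="fit" if terms is not None else "predict",
        config={
            "terms": list(terms) if terms else None,
            "preset": preset,
            "fixed_indicators": dict(fixed_indicators or {"i_ox": 1}),
            "exclude_influential": exclude_influential,
        },
        input_digests={},
        seed=seed,
    )
    return RegressionReport(
        model=model,
        predictions=preds,
        crossing=crossing,
        optimum=opt,
        pleasant_fraction=classified.attrs["fraction_pleasant"],
        n_joined=len(joined),
        n_score_only=n_score_only,
        n_molecule_only=n_mol_only,
        manifest=manifest,
    )


@dataclass
class DimensionReport:
    decision: HedonicDecision
    eigenvalues: list[float]
    transform_log: dict[str, str]
    n_odorants: int
    manifest: RunManifest

    def summary(self) -> str:
        return (
            f"PCA on {self.n_odorants} odorants; eigenvalues "
            + ", ".join(f"{v:.2f}" for v in self.eigenvalues[:3])
            + "\n"
            + self.decision.summary()
        )


def run_hedonic_dimension(
    profile: pd.DataFrame,
    vocabulary: HedonicVocabulary,
    threshold: float = 4.0,
    transform: object = "auto",
    n_components: int = 2,
    q2_folds: int = 7,
    q2_threshold: float = 0.13,
    seed: int = 0,
) -> DimensionReport:
    """clean -> transform -> autoscale -> PCA -> hedonic verdict."""
    work, _dropped = clean_profile(profile, threshold)
    if isinstance(transform, Mapping):
        # overrides for descriptors removed by cleaning no longer apply
        transform = {k: v for k, v in transform.items() if k in work.columns}
    tones = vocabulary.tones_for(list(work.columns))
    eq1 = estimate_hedonic_eq1(work, vocabulary)
    model = HedonicPCA(work, transform=transform)
    res = model.fit(n_components)
    decision = res.decide(
        tones.to_numpy(),
        eq1_scores=eq1,
        q2_threshold=q2_threshold,
        folds=q2_folds,
        seed=seed,
    )
    manifest = RunManifest(
        command="pca",
        config={
            "threshold": threshold,
            "transform": transform if isinstance(transform, (str, type(None))) else dict(transform),
            "n_components": n_components,
            "q2.folds": q2_folds,
            "q2.threshold.pc1": q2_threshold,
        },
        input_digests={},
        seed=seed,
    )
    return DimensionReport(
        decision=decision,
        eigenvalues=[float(v) for v in res.eigenvalues],
        transform_log=res.result.transform_log,
        n_odorants=len(work),
        manifest=manifest,
    )
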