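"""Synthetic odorant sets and profile matrices with known ground truth.

The historical odor-profile datasets this methodology was developed on are
not freely redistributable, so every pipeline stage is exercised against
generated data whose hedonic truth is planted: molecular features are drawn
to match the composition statistics of the published chemical sets, hedonic
scores follow a chosen preset equation plus Gaussian noise, and profile
matrices concentrate descriptor applicability on descriptors whose hedonic
tone is close to the odorant's true score, so that the weighted-average
estimator can recover the planted scores.

Everything is driven by a mandatory seed and is byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .chem import MoleculeRecord, MolecularFeatures, features_frame
from .errors import ConfigError
from .presets import PRESETS


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic generator.

    Defaults emulate the composition of the largest published chemical set:
    heavy-atom counts uniform on 2..22, ~73% of molecules oxygenated, small
    sulfur/acid/amine rates, truth from the quadratic atlas-style equation
    with score noise sd 0.5 on the -4..+4 scale.
    """

    seed: int
    n_molecules: int = 143
    nat_min: int = 2
    nat_max: int = 22
    p_oxygen: float = 0.73
    p_sulfur: float = 0.08
    p_acid: float = 0.07  # conditional on the oxygen draw
    p_amine: float = 0.035
    truth_equation: str = "eq11"
    noise_sd: float = 0.5
    n_descriptors: int = 40
    sparsity: float = 0.35  # fraction of descriptor cells kept per odorant
    tau: float = 1.0  # kernel width in tone units
    applicability_scale: float = 80.0
    applicability_noise_sd: float = 2.0

    def __post_init__(self) -> None:
        for name in ("p_oxygen", "p_sulfur", "p_acid", "p_amine"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v} outside [0, 1]")
        if self.p_acid > 0 and self.p_oxygen == 0:
            raise ConfigError("acids require oxygen: p_acid > 0 with p_oxygen = 0")
        if self.noise_sd < 0 or self.applicability_noise_sd < 0:
            raise ConfigError("noise sd must be non-negative")
        if not 0.0 < self.sparsity <= 1.0:
            raise ConfigError(f"sparsity={self.sparsity} outside (0, 1]")
        if self.tau < 0:
            raise ConfigError("kernel width tau must be non-negative")
        if self.nat_min < 1 or self.nat_max < self.nat_min:
            raise ConfigError("need 1 <= nat_min <= nat_max")
        if self.truth_equation not in PRESETS:
            raise ConfigError(f"unknown truth equation {self.truth_equation!r}")


def _formula_string(c: int, h: int, o: int, s: int, n: int) -> str:
    parts = [("C", c), ("H", h), ("N", n), ("O", o), ("S", s)]  # Hill order
    return "".join(f"{el}{cnt if cnt > 1 else ''}" for el, cnt in parts if cnt > 0)


def _template_smiles(c: int, ox: int, acid: int, sul: int, amine: int) -> Optional[str]:
    """Linear-chain SMILES for simple group combinations, else None.

    Groups are placed at the two chain ends; molecules needing more than
    two terminal groups fall back to formula-only records (exercising the
    undetermined acid/amine path downstream).
    """
    groups = []
    if acid:
        groups.append("acid")
    if amine:
        groups.append("amine")
    if sul:
        groups.append("thiol")
    if ox and not acid:
        groups.append("hydroxyl")
    if len(groups) > 2:
        return None
    carbons = c - (1 if acid else 0)  # the carboxyl carbon is written explicitly
    if carbons < max(1, len(groups) - (1 if acid else 0)):
        return None
    prefix = ""
    suffix = ""
    for g in groups:
        piece = {"amine": "N", "thiol": "S", "hydroxyl": "O"}.get(g)
        if g == "acid":
            suffix = "C(=O)O"
        elif not prefix:
            prefix = piece
        else:
            suffix = suffix or piece
    if suffix and not suffix.startswith("C(") and carbons < 2 and prefix:
        return None  # two terminal heteroatoms need at least a 2-carbon chain
    return prefix + "C" * carbons + suffix


def generate_molecules(
    cfg: GeneratorConfig,
) -> tuple[list[MoleculeRecord], pd.DataFrame]:
    """Draw a synthetic molecule set with ground-truth features.

    Returns the molecule records (SMILES where a simple chain template can
    express the drawn groups, otherwise formula plus explicit flags) and
    the true feature table indexed by id.
    """
    rng = np.random.default_rng(cfg.seed)
    records: list[MoleculeRecord] = []
    feats: list[MolecularFeatures] = []
    for i in range(cfg.n_molecules):
        n_at = int(rng.integers(cfg.nat_min, cfg.nat_max + 1))
        i_ox = int(rng.random() < cfg.p_oxygen)
        i_acid = int(i_ox and n_at >= 3 and rng.random() < cfg.p_acid)
        i_sul = int(n_at >= 2 + 2 * i_acid and rng.random() < cfg.p_sulfur)
        i_amine = int(
            n_at >= 2 + 2 * i_acid + i_sul and rng.random() < cfg.p_amine
        )
        o = 2 if i_acid else i_ox
        s = i_sul
        nn = i_amine
        c = n_at - o - s - nn
        if c < 1:  # tiny molecule cannot host the drawn groups; keep it plain
            i_ox = i_acid = i_sul = i_amine = o = s = nn = 0
            c = n_at
        h = 2 * c + 2 - 2 * i_acid + i_amine
        mol_id = f"syn{i:04d}"
        formula = _formula_string(c, h, o, s, nn)
        smiles = _template_smiles(c, i_ox, i_acid, i_sul, i_amine)
        if smiles is not None:
            rec = MoleculeRecord(id=mol_id, smiles=smiles, formula=formula)
        else:
            rec = MoleculeRecord(
                id=mol_id,
                formula=formula,
                explicit_flags={"acid": bool(i_acid), "amine": bool(i_amine)},
            )
        records.append(rec)
        counts = {k: v for k, v in (("C", c), ("H", h), ("N", nn), ("O", o), ("S", s)) if v}
        feats.append(
            MolecularFeatures(
                id=mol_id,
                n_at=n_at,
                i_ox=i_ox,
                i_sul=i_sul,
                i_cl=0,
                i_acid=i_acid,
                i_amine=i_amine,
                atom_counts=counts,
            )
        )
    return records, features_frame(feats)


def generate_hedonic_truth(
    features: pd.DataFrame,
    equation_id: str = "eq11",
    noise_sd: float = 0.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Plant hedonic scores: preset prediction + Gaussian noise, clipped.

    Scores are clipped to the -4..+4 scale; clip events are flagged in the
    ``clipped`` column so tests can see the boundary behaviour.
    """
    preset = PRESETS[equation_id]
    pred = preset.predict(features).to_numpy()
    rng = np.random.default_rng(seed)
    noisy = pred + (rng.normal(0.0, noise_sd, len(pred)) if noise_sd > 0 else 0.0)
    clipped = (noisy < -4.0) | (noisy > 4.0)
    return pd.DataFrame(
        {
            "true_score": np.clip(noisy, -4.0, 4.0),
            "noiseless": pred,
            "clipped": clipped,
        },
        index=features.index,
    )


def generate_descriptor_tones(
    n_descriptors: int, seed: int, low: float = -4.0, high: float = 4.0
) -> pd.Series:
    """Uniform descriptor tones spanning the hedonic scale."""
    rng = np.random.default_rng(seed)
    tones = rng.uniform(low, high, n_descriptors)
    return pd.Series(tones, index=[f"desc{j:03d}" for j in range(n_descriptors)])


def generate_profile_matrix(
    scores, tones: pd.Series, cfg: GeneratorConfig
) -> pd.DataFrame:
    """Profile matrix whose weighted-average score tracks the planted truth.

    Each odorant's applicability mass sits on descriptors whose tone is
    close to its true score: weight proportional to a Gaussian kernel
    exp(-(tone - score)^2 / 2 tau^2) (normalized so the nearest descriptor
    gets the full applicability scale; tau -> 0 degenerates to the nearest
    descriptor alone), times a Bernoulli sparsity mask, plus Gaussian
    applicability noise truncated at zero.  Rows that end up all-zero are
    legitimate "odorless" cases for the scoring stage.
    """
    if isinstance(scores, pd.DataFrame):
        scores = scores["true_score"]
    s = pd.Series(scores, dtype=float)
    t = tones.to_numpy(dtype=float)
    if np.ptp(t) == 0:
        raise ConfigError("all descriptor tones equal: planted score unrecoverable")
    if not ((t > 0).any() and (t < 0).any()):
        raise ConfigError("descriptor tones must span both signs")
    rng = np.random.default_rng(cfg.seed + 1)
    d2 = (t[None, :] - s.to_numpy()[:, None]) ** 2
    d2min = d2.min(axis=1, keepdims=True)
    if cfg.tau > 0:
        kernel = np.exp(-(d2 - d2min) / (2.0 * cfg.tau**2))
    else:
        kernel = (d2 == d2min).astype(float)
    mask = rng.random(kernel.shape) < cfg.sparsity
    # the nearest descriptor is always kept so rows stay scoreable
    mask[np.arange(len(s)), d2.argmin(axis=1)] = True
    x = cfg.applicability_scale * kernel * mask
    if cfg.applicability_noise_sd > 0:
        x = x + rng.normal(0.0, cfg.applicability_noise_sd, x.shape)
    x = np.clip(x, 0.0, 100.0)
    return pd.DataFrame(x, index=s.index, columns=tones.index)


def simulate_study(cfg: GeneratorConfig) -> dict:
    """Full synthetic study: molecules, truth, tones, profile matrix."""
    records, features = generate_molecules(cfg)
    truth = generate_hedonic_truth(
        features, cfg.truth_equation, cfg.noise_sd, seed=cfg.seed + 2
    )
    tones = generate_descriptor_tones(cfg.n_descriptors, seed=cfg.seed + 3)
    profile = generate_profile_matrix(truth, tones, cfg)
    return {
        "records": records,
        "features": features,
        "truth": truth,
        "tones": tones,
        "profile": profile,
        "config": cfg,
    }
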