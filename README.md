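# odorhedonics

Hedonic valence of odorants — how pleasant a smell is, on a symmetric
−4…+4 scale — estimated from numerical odor-character profiles and from
simple molecular features.  For sensory scientists, perfumery/flavor
chemists and QSOR (quantitative structure–odor relationship) researchers
who need the classic profile-based scoring and size-based prediction
equations as tested, scriptable code.

## What it computes

**From an odor profile.**  Given an odorant × descriptor applicability
matrix X (values 0–100) and per-descriptor hedonic tones HT_j, the hedonic
score of odorant *i* is the tone-weighted average

    H_i = Σ_j HT_j · x_ij / Σ_j x_ij ,

a convex combination of the tones of the descriptors used for that
odorant.  Alternatively, PC1 of the cleaned, transformed, autoscaled
profile matrix is extracted and tested for being the hedonic dimension
(loading–tone correlation, eigenvalue > 1 and cross-validated Q²
criteria, correlation of t₁ scores with the weighted-average estimates).

**From molecular structure.**  OLS regressions of hedonic scores on
N_at (heavy-atom count) and functional-group indicators, with the five
published prediction equations as immutable presets, e.g.

    H = −2.33 + 0.33·N_at − 0.0104·N_at² + 0.057·I_ox·N_at − 0.83·I_sul − 1.62·I_acid

and their analytics: the pleasantness threshold (N_at at which the
prediction crosses zero) and the hedonic optimum (vertex of the quadratic
in N_at).  Featurization accepts SMILES (RDKit-based carboxyl/amine
detection) and/or molecular formulas; formula-only input leaves the
structural indicators explicitly undetermined.  A seeded synthetic-data
generator plants known hedonic structure so every stage is testable
without the (non-redistributable) historical datasets.

See `docs/methods.md` for the model details and design choices.

## Worked example

```python
import pandas as pd
import odorhedonics as oh

profile = pd.DataFrame(
    {"fruity": [36.0, 0.0], "sweet": [8.0, 3.0], "fishy": [0.0, 62.0]},
    index=["benzyl_acetate", "trimethylamine"],
)
vocab = oh.HedonicVocabulary.published_subset()
report = oh.run_profile_to_hedonics(profile, vocab)
print(report.scores)

feats = oh.features_frame([oh.featurize(oh.MoleculeRecord("decanal", smiles="CCCCCCCCCC=O"))])
print(oh.predict("eq11", feats))
cr, op = oh.null_crossing("eq11"), oh.optimum_nat("eq11")
print(f"threshold N_at = {cr.threshold:.2f}; optimum N_at = {op.n_at:.2f} (score {op.score:.2f})")
```

prints

```
                hedonic_score method flags
id
benzyl_acetate       2.193636    eq1
trimethylamine      -1.980000    eq1
         hedonic_score      method flags
id
decanal         0.6686  regression
threshold N_at = 7.55; optimum N_at = 18.61 (score 1.27)
```

Benzyl acetate scores 2.19: its profile mass sits on "fruity" (tone 2.23)
and "sweet" (2.03), so the weighted average lands between them — a clearly
pleasant odorant.  Trimethylamine's sub-threshold "sweet" value (3 < 4) is
cleaned away as panel noise, leaving only "fishy", so its score is that
descriptor's tone, −1.98.  Decanal (N_at = 11, oxygenated) is predicted
mildly pleasant (0.67) by the quadratic atlas-set equation; under that
equation an oxygenated, sulfur-free molecule needs about 8 heavy atoms to
cross into pleasantness, and pleasantness peaks near N_at ≈ 19.

The same workflows are available from the shell:

```sh
odorhedonics --seed 7 --out-dir sim simulate --n-molecules 150
odorhedonics --out-dir scores score sim/profile.csv --vocabulary sim/vocabulary.csv
odorhedonics --out-dir fit fit scores/scores.csv sim/molecules.csv --terms const,n_at,i_ox,i_sul
odorhedonics analyze --model eq12
```

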