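# Methods

## The problem

Pleasantness (hedonic valence) is the most salient perceptual dimension of
smell when odors are compared at matched intensity.  `odorhedonics` models
two complementary routes to a numeric hedonic score for an odorant, both on
a symmetric −4…+4 scale, and the regression layer that relates those scores
to simple molecular features.

**Route 1 — descriptor-weighted averaging.**  A numerical odor profile
gives, for odorant *i* and descriptor *j*, a non-negative applicability
x_ij (0–100).  Given per-descriptor hedonic tones HT_j (how pleasant the
descriptor itself is, panel-rated on −4…+4), the odorant's score is the
convex combination

    H_i = Σ_j HT_j · x_ij / Σ_j x_ij .

Because the weights normalize out, H_i is invariant to rescaling a profile
row and always lies between the minimum and maximum tone of the descriptors
actually used.  A row whose applicabilities sum to zero has no defined
score; it is returned as missing with an "odorless" flag and excluded from
every downstream fit.

**Route 2 — the first principal component.**  If profiles are cleaned
(values under a noise threshold of 4%-of-maximum set to zero; descriptor
columns emptied by this are dropped and logged), optionally transformed per
variable toward normality, autoscaled (mean 0, variance 1, divisor n−1) and
decomposed by PCA, PC1 frequently separates pleasant from unpleasant
odorants.  The package decides whether PC1 *is* the hedonic dimension by
combining: the Pearson correlation (t-transform p-value, n−2 df,
two-sided) between the p₁ loadings and the descriptor tones; optionally
the correlation between the t₁ scores and the Route-1 estimates; and two
component-retention criteria — eigenvalue λ₁ > 1 and cross-validated
Q² above a configurable threshold (defaults 0.13 for PC1, 0.15 for PC2,
matching the thresholds conventional chemometrics software applies to a
seven-variable problem).  The default verdict rule: PC1 is hedonic iff the
loading–tone correlation is positive and significant at α = 0.05 and at
least one retention criterion passes.

Components are sign-oriented so that corr(p₁, tones) ≥ 0 (larger t₁ =
more pleasant); without tones, the largest-magnitude loading is made
positive.  t₁ scores exported as hedonic estimates carry an
"asymmetric-scale" flag: their unpleasant range is typically about twice
the pleasant range, so regressions default to the Route-1 scores.

## Q² cross-validation

The Q² scheme is element-wise deletion: matrix cells are randomly
partitioned into K folds (default 7, seeded); each fold is held out and
predicted by an iterative SVD reconstruction (missing cells initialized at
0 — the column mean of autoscaled data — then alternately reconstructed at
rank k and re-imputed until the imputations converge).  With PRESS_k the
squared prediction error over held-out cells of the rank-k model and
SS_{k−1} the residual sum of squares of the (k−1)-component model on the
full data (SS_0 = total SS),

    Q²_k = 1 − PRESS_k / SS_{k−1} ,

so each component is judged on what it adds beyond the previous ones.
Q² ≤ 1 always; pure-noise matrices give Q² near or below zero, noiseless
low-rank matrices give Q² near 1.  Whether the historical software used
row-wise or element-wise deletion is not documented; element-wise was
chosen because it is well-posed for any matrix shape, and the thresholds
are configuration, not derived constants.

## The loading–tone quadratic

The relation between p₁ loadings and tones is fitted without an intercept
as p₁ = a·HT + b·HT², so the curve passes through the origin and a
descriptor with positive loading maps to a positive fitted tone on the
increasing branch.  R² is reported uncentered (through the origin);
residuals with |externally studentized residual| > 2 are flagged as
moderate outliers.  The canonical published fit is a = 0.0309,
b = −0.0046.

## Regression on molecular features

The feature vector is deliberately minimal: N_at (number of non-hydrogen
atoms, a molecular-size proxy), indicators I_ox, I_sul, I_cl for the
presence of oxygen/sulfur/chlorine, and structural indicators I_acid
(carboxyl group C(=O)OH; carboxylates excluded — odorants are neutral
volatiles) and I_amine.  "Amine" is defined as a neutral, non-aromatic
nitrogen with only C/H neighbours, single bonds only, and no neighbouring
(thio)carbonyl carbon: this captures the fishy-urinous aliphatic and aryl
amines while excluding amides, nitriles, nitro, azide and pyridine-type
ring nitrogens.  Whether aryl amines belong in the class is genuinely
open; they are included here and the choice is localized in
`detect_amine`.  From a bare molecular formula the structural indicators
are undetermined (tri-state `None`), never silently 0; fits and
predictions that need them reject undetermined values explicitly.

`HedonicRegression.fit()` is OLS (via statsmodels) with per-term standard
errors and two-sided p-values, an omnibus residual-normality statistic
(reported, never auto-rejected), and an influential-point report (Cook's
distance > 1 or leverage > 3·p/n).  Exclusion of influential points is an
explicit opt-in (`refit_without_influential`) so that any exclusion is
auditable.

Five published equations ship as immutable presets (hedonic scale unless
noted):

| id  | equation |
|-----|----------|
| eq7 | −2.56 + 0.23·N_at + 1.26·I_ox − 1.54·I_sul |
| eq8 | 106.9 − 2.49·N_at − 17.33·I_ox + 21.6·I_sul + 28.32·I_acid + 20.77·I_amine (preference-ranking scale) |
| eq9 | −2.62 + 0.23·N_at + 1.58·I_ox − 1.96·I_sul − 2.58·I_acid − 1.89·I_amine |
| eq10 | −1.87 + 0.22·N_at + 2.60·I_ox − 2.23·I_sul − 3.51·I_acid (advisory: not recommended for prediction) |
| eq11 | −2.33 + 0.33·N_at − 0.0104·N_at² + 0.057·I_ox·N_at − 0.83·I_sul − 1.62·I_acid |
| eq12 | −1.85 + 0.35·N_at − 0.014·N_at² + 0.041·I_ox·N_at |

plus the calibration constants between score variants (eq2: 0.26 + 1.03x;
eq3: 7.11 − 0.091·PR; eq5: −0.297 + 3.365x − 0.491x²; eq6:
0.185 + 1.228x).  eq8 exists only for round-trip checks against eq9
through eq3.

**Analytics.**  With indicators fixed (the canonical pattern is I_ox = 1,
others 0) the prediction is a polynomial in N_at.  `null_crossing` returns
its real roots in (0, 100) ascending; for quadratics the smaller positive
root is the "pleasantness threshold" and roots beyond N_at = 29 (the
largest molecule in the fitted sets) are flagged as extrapolation.
`optimum_nat` returns the vertex −c₁/(2c₂) for a concave quadratic, or a
monotone/unbounded flag.  From the printed coefficients: crossings 5.65
(eq7), 4.52 (eq9), 7.55 (eq11), 6.04 (eq12), mean 5.94; optima 18.6
(eq11) and 13.96 (eq12).  The published text rounds the eq12 crossing to
5.9 where the printed coefficients give ≈6.0; the ≈0.1 residue evidently
stems from unrounded internal coefficients and is documented rather than
chased — this package always evaluates the printed coefficients.

`classify_pleasant` uses the strict rule pleasant ⇔ score > 0 (a score of
exactly zero is not pleasant).

## Semantic coding and conversions

Verbal hedonic labels map onto the symmetric 7-point scale −4, −2.67,
−1.33, 0, 1.33, 2.67, 4 ("very unpleasant" … "very pleasant").  Mean
preference rankings (lower = preferred) convert to hedonic scores through
the affine calibration H = 7.11 − 0.091·PR.

## Profile clean-up conventions

"Under 4" is strict: x < 4 → 0; 4.0 is kept.  Descriptor aliases rename
columns (e.g. wintergreen → medicinal); when the target column already
exists the two merge by element-wise maximum, keeping applicability ≤ 100.
Descriptor names are canonicalized by case-folding, trimming and
collapsing internal whitespace; comma-variants ("sour, vinegar") are kept
verbatim.  Cleaning is idempotent.

## The synthetic generator

The literature profile datasets behind this methodology are not
redistributable, so the generator plants known structure and every claim
the test suite makes about recovery is a claim about these conditions:

- **Molecules** (`generate_molecules`): N_at uniform on 2…22; oxygen with
  probability 0.73 (the share of oxygenated molecules typical of the
  published sets); sulfur 0.08, acid 0.07 conditional on the oxygen draw
  (acid ⇒ oxygen by construction), amine 0.035 — approximately the rates
  in the largest published set.  Default set size 143, the size of that
  set.  Each molecule gets a consistent C/H/N/O/S formula; molecules whose
  groups fit a linear-chain template (at most two terminal groups) also
  get a SMILES string, the rest are emitted formula-only with explicit
  acid/amine flags, exercising the tri-state featurizer path.
- **Truth** (`generate_hedonic_truth`): score = preset prediction (default
  eq11) + N(0, 0.5), clipped to [−4, 4] with clip events flagged.
- **Profiles** (`generate_profile_matrix`): descriptor tones uniform on
  [−4, 4]; applicability weight ∝ exp(−(tone − score)²/2τ²), normalized so
  the nearest descriptor receives the full scale (80 by default; τ → 0
  degenerates to the nearest descriptor alone), times a Bernoulli(0.35)
  sparsity mask (the nearest descriptor always kept so rows stay
  scoreable), plus Gaussian applicability noise (sd 2) truncated at zero —
  which the downstream <4 threshold then removes, exercising
  `clean_profile` realistically.
- Kernel width τ = 1.0 tone units.  A narrower kernel concentrates each
  row on one or two descriptors; because eq11-planted scores top out near
  +1.5, descriptors with tones in [2, 4] are then used by almost no
  odorant and their PC1 loadings become noise-dominated, weakening the
  planted loading–tone association the generator is required to
  guarantee.  τ = 1.0 keeps that association strong (loading–tone r
  typically 0.83–0.92 at 200 odorants × 40 descriptors) while leaving
  realistic descriptor spread; it is configurable.

What the generator does **not** emulate: real descriptor semantics and
inter-descriptor correlation structure, panel psychophysics, intensity
effects, or any particular real compound list.  Passing recovery tests
therefore shows the estimators are consistent under the planted model, not
that real profile data satisfies that model.

## Problem sizes and numerics

Tests run at 200–500 molecules/odorants and 40 descriptors; end-to-end
coefficient recovery is checked at n = 300 against a 3-SE band (a
95%-style criterion under the generator's noise).  The EM reconstruction
in Q² iterates to an imputation tolerance of 1e−9 (cap 200 iterations).
Degenerate inputs fail loudly: zero-variance columns (autoscaling),
negative values (transforms), constant predictors and rank-deficient
designs (fits), all-equal tones (generator).  Ties in `null_crossing` and
the vertex formula follow the closed forms exactly; the numeric root-scan
used in tests is an independent oracle, not the implementation.

## Known limitations

- The shipped tone vocabulary contains only the eight published values;
  any real analysis needs a user-supplied tone table.
- The quadratic presets are valid inside the fitted N_at range (≈ 2–29);
  the larger eq11 root (≈ 29.7) is reported but flagged extrapolation.
- The amine definition is one defensible reading of an undefined class;
  steroid-like and polyfunctional molecules are known failure modes of
  size-based hedonic prediction generally.
- Q² thresholds are conventions, not derived limits; changing the deletion
  scheme or folds shifts Q² by a few hundredths near the threshold.
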