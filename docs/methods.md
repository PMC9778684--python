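# Methods

## Speciation model

Sulfonamides are treated as diprotic acids and tetracyclines as
triprotic amphoteric compounds undergoing sequential deprotonation.
For a ladder of constants pKa₁ < … < pKa_m at a given pH, the species
that has lost k protons has relative abundance
10^(k·pH − Σ_{i≤k} pKa_i); normalising over k = 0…m gives the species
fractions (computed with the maximum exponent factored out, so the
ladder is stable over the full pH 0–14 domain). Macro-classes: the
fully protonated species is the cation α⁺, the first deprotonation the
neutral/zwitterion α⁰, and everything beyond is pooled into the anion
α⁻ — for tetracyclines this pools the mono- and di-anion, because the
regression models use exactly three classes. Zwitterion and
true-neutral microspecies are not distinguished, activity corrections
and temperature dependence of pKa are out of scope. pH outside [0, 14]
is a hard error; the training data span only pH 2.75–9.40, so no
separate extrapolation handling is needed here.

## Isotherms and Kd re-fitting

Batch equilibrium couples the isotherm with the mass balance
Ci − Ce = SLR·Qe(Ce), where SLR is soil mass per solution volume in
kg L⁻¹ ("1:X" strings parse to 1/X). The residual is strictly
decreasing in Ce, so the root in (0, Ci] is found by bracketed Brent
iteration driven to machine precision (the mass-balance residual stays
below 1e−9·Ci; the linear case is verified against the closed form
Ce = Ci/(1 + Kd·SLR) at 1e−10 relative).

For studies reporting only (Kf, n), a linear Kd is recovered by
simulating a batch series and fitting Qe = Kd·Ce through the origin
(closed form Kd = ΣQeCe/ΣCe²; the model has no intercept because the
linear isotherm has none). Significance is a two-sided t-test on the
slope with N−1 degrees of freedom; re-fits with p ≥ 0.05 are flagged
"not significant" and left to the caller to exclude. For an exact fit
(n = 1, zero residuals) the p-value is floored at the smallest positive
float so it stays in (0, 1]. Source studies rarely state their
concentration grids or SLR, so the defaults are explicit: five
log-spaced Ci from 0.1 to 10 mg L⁻¹ (inside the 0.04–14,236 mg L⁻¹ span
of the literature) and SLR = 0.1 kg L⁻¹ (the common 1:10 convention);
both are overridable per call. Because n > 1 means saturating sorption,
the re-fitted Kd decreases when the concentration grid shifts upward —
re-fitted values are therefore grid-dependent, which is why the grid is
recorded with the result.

## Dataset conventions

Canonical units: OC in % mass (OM converted by %OM = 1.724 × %OC), CEC
in mmol kg⁻¹ (a cmol kg⁻¹ ingest flag multiplies by 10 — never
auto-guessed), SLR in kg L⁻¹, concentrations in mg L⁻¹. The Freundlich
exponent column may hold n or 1/n in source papers; only an explicit
ingest flag inverts it. Texture fractions must sum to 95–105 % (rounding
tolerance). Train/validation bookkeeping uses four pools: A/a for Kf
models, B/b for Kd models. The partition method behind the published
counts is not documented, so the splitter is a seeded, per-antibiotic
stratified random permutation with a configurable fraction
(default 0.75, which reproduces the published SMT Kf partition
107/35 of 142 via n_train = round(fraction·N)); records carrying both
parameter sets are labelled in the Kf pool only, so each record carries
at most one label per pool.

## Pedotransfer functions

A coefficient set is an intercept plus named linear terms over a closed
predictor vocabulary: OC, pH, CEC, Sand, Silt, Clay, SLR, Cimax, the
species fractions, and CEC_inv (reciprocal CEC, used by one published
comparator whose source reported CEC in cmol kg⁻¹; that set carries a
`cec_unit` annotation and `predict` converts from mmol kg⁻¹
automatically). Species fractions enter as fractions in [0, 1], not
percentages — the printed coefficient magnitudes (e.g. 183.089·α⁺)
remain interpretable with the tiny α⁺ at field pH, but the encoding in
the original regressions is not documented, so this choice is
deliberately explicit and configurable by rescaling coefficients.
SLR enters as the numeric kg L⁻¹ ratio. Predictions return the raw
affine value; negative values are flagged rather than clamped (a risk
assessor may floor at 0, a statistician may not), and predictors
outside the training ranges (pH 2.75–9.40, OC 0.1–21.3 %, CEC
3.40–740 mmol kg⁻¹) raise an extrapolation flag.

Fitting is ordinary least squares with intercept (statsmodels), with
adjusted r² = 1 − (1−R²)(N−1)/(N−k−1), coefficient t-test p-values and
95 % confidence intervals. Rank-deficient designs are rejected with the
collinear predictors named. The variable-selection procedure behind the
published models is not documented; `forward_select` is a deterministic
greedy forward pass (enter the candidate with the smallest p-value
while p < α_enter, default 0.05, ties broken by name order) and records
its selection trace.

## Evaluation metrics

NSE = 1 − SSE/SST (1 perfect, 0 no better than the measured mean),
RMSE, AE = |M−E|/|M| per observation, and RMSE as a percentage of the
measurements' standard deviation. The SD uses the sample (N−1) formula —
the convention is not stated in the source material, so it is fixed
here and noted. Observations with measured value 0 are excluded from
batch AE with a count rather than failing the run. Pearson screening
uses pairwise-complete observations and the conventional stars
(* p < 0.05, ** p < 0.01). AE-by-range reports default to interior bin
edges {1, 3, 5} % for OC and {5, 6.5, 8} for pH (half-open bins, last
closed; mean aggregation, median available).

## Synthetic data generator

The generator defines the study conditions used throughout the tests:
pH is a two-component uniform mixture calibrated to 75 % acidic soils
over 2.75–9.40; OC and CEC are log-uniform over 0.1–21.3 % and
3.40–740 mmol kg⁻¹ (right-skewed, medians below the arithmetic
mid-range, matching the reported medians below 3 % OC); texture is
Dirichlet-distributed around a clay-loam composition (sand/silt/clay
≈ 32/34/34, concentration 60) and sums to 100 %. No distributional
forms are reported for the source dataset — only ranges, medians and
the acidic share — so these forms are declared choices, not inferences.

Responses are truth-model predictions plus noise. `noise_scale` is the
ratio of the noise SD to the spread of the truth predictions across the
soils; the default 0.88 places the expected training RMSE/SD near 66 %,
the middle of the 56.2–77.2 % band reported for the built-in models
(s = ρ/√(1−ρ²)). Freundlich linearity indices are drawn near 1 for
sulfonamides and near 2 for tetracyclines, matching the reported class
means. Sorption coefficients must be positive, so negative draws are
redrawn up to 10 times and then floored at 1 % of the antibiotic's
smallest reported value, with a warning.

**Limitation — censoring vs. inference.** At the calibrated noise level
the truth spread (driven by log-uniform OC) is large relative to the
truth value of typical low-OC soils, so the positivity policy censors a
non-trivial share of records. Censored data violate the OLS error
model: fitted intercepts drift upward and nominal confidence intervals
lose coverage. The confidence-interval coverage check of the
generate → split → fit pipeline is therefore run in the low-noise
regime (noise_scale = 0.1, strictly positive truth model), where the
floor never engages and the OLS intervals are the thing being tested;
the calibrated default remains the generator's standard condition and
is exercised by the RMSE/SD-band test. Real literature data are
positive by construction rather than by censoring, so this artefact is
a property of the additive-Gaussian emulation, not of the method.

## Problem sizes

The test suite uses 50–200 soils per scenario and 200 replicates of
100 soils for the seeded coverage experiment; the whole suite runs in a
few seconds on one CPU. These sizes give binomial standard errors of
~1.5 % on the 95 % coverage estimate, comfortably resolving the ≥ 90 %
acceptance bound.
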