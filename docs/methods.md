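# Methods

## Models

Three morphometric body-condition indices are defined from straight-line
total length SL (m), umbilical girth UG (m) and body mass W (kg):
BCI1 = UG/SL^b1, BCI2 = W/SL^b2, BCI3 = W/(SL·UG^b3). Each index has an
allometric exponent *b* estimated from data. Under geometric similarity
(large animals are scaled-up copies of small ones) b1 = 1, b2 = 3,
b3 = 2; deviations mean shape changes with size, so every fit reports
the contrast (k − b) with k ∈ {1, 3, 2} as a t test against similarity,
sharing the standard error of b (the contrast is a linear
reparameterization of the exponent, so fitting b directly is
algebraically identical to fitting the contrast).

Habitat (coastal vs riverine) and sex (F vs M) enter the nonlinear model
as additive offsets on both the coefficient and the exponent, reference
cell female/coastal, no interaction term. Group-specific exponents
(reference plus applicable offsets) are used when scoring individuals,
and the score table records which exponent served each row so exponent
regimes are never silently mixed.

## Robust nonlinear estimation

The generative forms (UG = BCI1·SL^b1 etc.) are fitted by M-estimation
on raw-scale residuals via iteratively reweighted nonlinear least
squares:

1. **Initialization.** OLS on the log-linearised model — always
   well-defined for positive measurements. With factors, a per-stratum
   log-log fit per cell is combined into reference values and offsets by
   least squares over the cell design; for additively generated
   noise-free data this start is already the solution.
2. **Iteration.** Residuals on the raw scale; robust scale = median
   absolute deviation × 1.4826, recomputed each iteration (simultaneous
   scale); Huber weights with k = 1.345 (95% Gaussian efficiency; Tukey
   bisquare c = 4.685 available via `loss="bisquare"`); weighted
   nonlinear least-squares step (Levenberg–Marquardt with an analytic
   Jacobian).
3. **Convergence.** Relative parameter change < 1e-8, max 100
   iterations. Non-convergence returns a flagged fit with a warning,
   never a silent success.

Standard errors come from the asymptotic covariance of the final
weighted fit, `s² (JᵀWJ)⁻¹` with `s² = Σ w r² / (n − p)`.

Degenerate inputs: an exactly zero residual scale with uniformly tiny
residuals (noise-free data) short-circuits to one unweighted refinement;
zero MAD with large residuals remaining (majority-exact data plus
outliers) falls back to a mean-|r| scale so downweighting still
operates; all-identical predictor values or n < p + 3 refuse to fit; a
requested factor with a single observed level raises a model
specification error; a zero SE yields an undefined similarity test
rather than an infinite t.

## Robust linear factor model

Scores are analysed with
`BCI = a + c·Country + h·Habitat + s·Sex + f·FieldCondition` using an
MM-type estimator: a subsampling S-estimate (exact p-subset fits scored
by the 50%-breakdown bisquare M-scale, c = 1.5476, each refined by three
I-steps; 200 subsamples by default, seeded — default seed fixed for
reproducibility) provides a high-breakdown start and scale, followed by
bisquare IRLS (c = 4.685) at that fixed scale. Coefficient covariance
uses the standard M-estimation sandwich
`s²·(mean ψ²/mean ψ′²)·(XᵀX/n)⁻¹/n`. No installed Python library offers
S-initialised MM linear regression, so this estimator is implemented
here; on clean Gaussian data it agrees with OLS within sampling error
(checked in the tests). Treatment coding with explicit reference levels
(coastal, female, ideal condition, largest-sample country); since
reference choices affect only the parameterization, arithmetic cell
means are emitted alongside. Aliased terms (e.g. country ≡ habitat in a
two-country subset) raise a rank-deficiency error naming the aliased
columns. A zero S-scale (all scores identical) returns the exact-fit
coefficients with zero scale and undefined tests rather than dividing by
zero. The "two-way ANCOVA" usage is this model restricted to
habitat + sex, not a separate classical routine.

## Pairwise locality comparisons

All-pairs two-sided Wilcoxon rank-sum tests: the exact null distribution
when both groups have ≤ 10 observations and no ties, otherwise the
normal approximation with tie and continuity corrections. The
per-pair path is recorded in the result's metadata. Bonferroni
adjustment multiplies each raw p by the number of pairs, capped at 1.
Groups with fewer than two observations are excluded with a warning.

## Synthetic populations

The generator draws, per habitat×sex cell: SL from an age-class mixture
(adult/subadult/calf weights 0.486/0.331/0.183 matching the study's
census composition; uniform lengths within 2.25–3.30, 1.75–2.25 and
1.10–1.75 m), then UG = BCI1·SL^b1·exp(ε_ug) and
W = BCI3·SL·UG^b3·exp(ε_w) with independent Gaussian log-residuals.
Mass is generated through the three-measurement law so all three indices
are mutually consistent on one population; the weight-length law's
parameters are therefore emergent and only checked qualitatively.
Multiplicative lognormal noise (not additive) keeps measurements
positive, the standard assumption for power-law allometry.

Default cell parameters are the fitted population values for wild
Antillean manatees — coastal BCI1 0.76 (F) / 0.75 (M), riverine 0.69 /
0.66, sex-specific exponents 0.926/0.846 (coastal) and 0.934/0.854
(riverine), BCI3 levels 37.8–39.5 with b3 1.88–2.00 — and cell sizes
127/136/47/43, the study's girth-length sample sizes. Note the default
coefficient field is *not* exactly additive across cells (real
populations need not be), so the no-interaction factor model recovers
defaults only approximately; exact-recovery checks use additive
configurations.

Noise scales default to σ_ug = 0.065 and σ_w = 0.10, calibrated so the
simulated per-cell index SDs match the reported magnitudes (BCI1 SD
≈ 0.05 at level 0.76; BCI3 SD ≈ 4 at level 38); no residual variances
are published, so these are calibration choices of this package.
Outliers: with probability 0.03 one of UG or W is multiplied by a factor
uniform in [1.5, 2.5] (configurable, e.g. [0.4, 0.7] for low outliers).
W is set missing with probability 0.35 (mass was measured on roughly
two-thirds of animals). Field scores are tied to the combined
standardized log-residual (sum/√k of the available ε/σ components,
computed before outlier injection since a recording error should not
change the visual assessment): below the thin quantile → C1/C2, above
the obese quantile → C4/C5, else C3, with normal-quantile thresholds so
labels are deterministic per record; defaults 0.015/0.97 reproduce the
study's ~1.5% thin and ~3% obese fractions, and the quantile mapping
makes labels correlate with, not determine, the indices. Late pregnancy
is off by default (the analysis population excludes such females); when
enabled it flags adult females and inflates their girth by ×1.15 so the
exclusion is morphometrically meaningful. One global RNG stream per
call, seeded once: identical config + seed gives identical output.

What the generator does **not** emulate: capture locations beyond
country/locality labels (localities are sampled with weights matching
the study's per-country sample sizes, independent of morphometrics
within habitat), seasonal or growth dynamics, measurement correlation
between UG and W beyond their shared dependence on SL and UG, and
non-lognormal error shapes. Passing recovery tests therefore show the
estimators work under the assumed error model with stratified power-law
structure — not that real field data satisfy those assumptions.

## Filtering rules

The main analysis set keeps animals with ideal (C3) or unscored field
condition and excludes late-pregnancy females; the field-condition model
re-incorporates thin (C1/C2) and obese (C4/C5) animals. The five-point
scale collapses C1,C2 → thin and C4,C5 → obese. Age classes: calf
< 1.75 m, subadult 1.75–2.25 m (both boundaries inclusive — the printed
interval contains its endpoints and "< 175 cm" excludes the lower
boundary from calf), adult > 2.25 m; a missing length yields an explicit
"unavailable" sentinel, never a default class. Records of unknown sex
stay in pooled fits and are dropped (with a logged count) from models
with a sex factor. A missing pregnancy flag is assumed non-pregnant and
logged. Every input row lands exactly once in the retained set or the
exclusion ledger, including rows rejected at read time; ad-hoc
exclusions (single atypical animals) go through an explicit per-id list
reported under its own reason. Plausibility bounds (SL 0.3–4.5 m, UG
0.2–4.0 m, W 5–2000 kg) flag rows as invalid measurements rather than
silently dropping them. Canonical units are meters/kilograms; a
`cm_kg` flag converts centimeter input on read (field protocols quote
age classes in cm, while the weight-prediction law is stated in meters).

## Problem sizes and tolerances in validation

The validation suite uses 50-animal noise-free grids for the analytic
closure checks (tolerances 1e-4 on similarity exponents, 1e-3 on the
weight-law constants), 20 replicates of n = 300 for the
robust-vs-plain-least-squares comparison under 10% contamination, 100
replicates of n = 400 for 2-SE coverage of the habitat offset, and full
enumeration of rank assignments for every two-group shape up to 7 + 7
for the Wilcoxon oracle. These sizes keep the suite fast while leaving
the Monte-Carlo margins comfortable.

## Known limitations

- The nonlinear stage is M-estimation (≈10% breakdown under leverage),
  not the MM machinery used for the linear model; gross outliers in SL
  itself (leverage points) can still influence the nonlinear fits.
- Asymptotic standard errors only; no bootstrap intervals.
- Per-country summaries are arithmetic means ± SE of per-individual
  scores rather than per-country robust refits; with moderate n these
  agree closely, and the cell-mean output is parameterization-free.
- BCI2's generator truth is emergent, so its recovery is checked only
  qualitatively.
- Exact Wilcoxon p-values are limited to tie-free groups of ≤ 10; larger
  or tied groups use the corrected normal approximation (the per-pair
  choice is recorded).
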