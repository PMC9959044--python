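# Methods

`beadopt` reproduces the computational chain of a gastroretentive
floating-bead formulation study: a designed experiment over three
formulation factors, quadratic response-surface models, desirability
optimization, dissolution-kinetics classification, and non-compartmental
pharmacokinetics.  This note records the models, the defaults and why
they are set where they are, and the places where the design was
genuinely open.

## Experimental design

The design is a rotatable central composite design (CCD) in k = 3
factors: sodium alginate 2–6% w/v (X1), CaCl₂ cross-linker 5–15% (X2),
sesame oil 4–8% (X3).  A full 2³ factorial core at coded ±1, six axial
points at ±α on one axis at a time, and three center replicates give
17 runs.  Rotatability requires α = (2^k)^¼; for k = 3 this is
8^¼ = 1.6817928…, and the *unrounded* value is used internally — the
study's own axial actual levels (e.g. alginate 0.636414% at −α) are
consistent only with the unrounded α, not the commonly quoted 1.682.
Coded units are the canonical representation (`coded = (actual −
center)/half_range`); actual units appear only at I/O boundaries, and
the design CSV carries both with a 1e−6 cross-check at read time.

## Response-surface models

Each response (Y1 entrapment efficiency %, Y2 buoyancy h, Y3 release at
6 h %) is fitted with the full 10-term quadratic model on coded factors
by ordinary least squares (statsmodels OLS under the hood).  No term
pruning is ever applied: the study's published polynomials contain every
term, and a reduced model would change the diagnostics.

Diagnostics follow the conventions needed to reproduce Design-Expert
output (verified against the study's ANOVA table on all three
responses):

- SST is corrected about the mean; df_total = n − 1, df_error = n − p.
- PRESS uses the hat-diagonal shortcut Σ(eᵢ/(1−hᵢ))², with an
  independent explicit leave-one-out refit oracle (`press_by_loo`) that
  must agree to 1e−8 relative — the two routes are implemented
  separately and never collapsed.
- CV% = 100·√MSE / ȳ.
- Adequate precision = (max ŷ − min ŷ over design points) / √(p·MSE/n),
  the documented signal-to-noise form; the study prints the value but
  not the formula, and only this form reproduces it.

The fitted intercept (≈ 90.00 for Y1) equals the center-point mean,
confirming that the published polynomials are coded-unit models.

One reproduction limit: the model prediction for Y3 at the optimized
formulation computes to 66.018%, which the study printed as 66.0 (one
decimal).  Tests therefore compare Y3 at ±0.05 (printed precision) and
Y1/Y2 at ±0.01.

## Desirability optimization

Per-response desirabilities use the Derringer ramps (maximize, minimize,
two-sided target, in-range indicator) with curvature weight w and
importance r; the overall score is D = (Π dᵢ^rᵢ)^(1/Σrᵢ).  The optimizer
is a seeded multi-start: 32 Latin-hypercube starts over the region
(default: the coded cube [−1,1]³, which contains the study's optimum; a
spherical region of radius α is available), each polished by Nelder–Mead
with candidates projected back into the region, convergence tolerance
1e−8 on D.

The study's exact goal bounds/weights were not published.  The package's
documented default maps Y1 and Y2 to *maximize* over their observed
ranges and Y3 ("prolong" — no Derringer equivalent) to *in-range* over
its observed range.  Under these defaults the optimizer saturates at
D = 1 on a plateau roughly 0.5–0.9 coded units from the study's reported
optimum (the plateau is non-unique, so the located point varies with
seed while D does not).  Consequently the package validates the *model
predictions at the reported optimum* (which are determined by the design
table alone) and does not assert reproduction of the reported D = 0.978
or the optimum's location; `analysis/02_optimize_formulation.py` records
the discrepancy.

## Dissolution kinetics

Five release laws are fitted by their conventional linearizations (see
the `kinetics` module docstring for the table).  Choices worth stating:

- Korsmeyer–Peppas is fitted on log₁₀–log₁₀ axes, restricted to points
  with fractional release Mt/M∞ ≤ 0.60 (the power law's standard
  validity range; configurable).  The first-order rate is natural-log
  based (1/h).
- The zero-order/Higuchi/Hixson–Crowell regressions include an intercept
  but report only the slope constant, and R² is the regression R² —
  forcing through the origin is not assumed.
- A (0 h, 0%) point is prepended for integration (release starts at
  dosing) but never enters log-transformed fits.
- Decreasing release values are flagged as monotone violations and kept
  as measured, never re-sorted.

The mechanism classifier follows the exponent rule as published:
n ≤ 0.45 Fickian, 0.45 < n < 0.89 anomalous, 0.89 ≤ n ≤ 1 case II,
n > 1 super case II.  (The study labels its own n = 0.836 "super case
II", which contradicts the rule it states; the classifier follows the
rule, and 0.836 classifies as anomalous.)

Because the study's raw release curves exist only as figures, kinetic
validation is property-based: exact recovery (R² = 1, parameters to
1e−9) on noiseless self-generated data, and exponent recovery with mean
absolute error < 0.02 over 500 replicates at 1% noise.

## Non-compartmental pharmacokinetics

Cmax/Tmax are read directly off the observations (ties → earliest).  The
terminal slope is a log₁₀-linear regression with Kel = −slope·2.303 (the
rounded ln 10 conventional in PK, implied by the published formula).  No
terminal-window rule was stated, so the default considers every suffix
window of ≥ 3 positive-concentration points strictly after Tmax and
picks the best adjusted R² (ties → more points); a fixed "last k" rule
is available.  AUC is the linear trapezoid (log-linear is not used
because the study specifies "the trapezoidal method"), with tail
C_last/Kel; AUMC adds the analytic tail C_last(t_last/Kel + 1/Kel²) and
MRT = AUMC/AUC.  The study's printed MRT values are internally
inconsistent with this (or any standard) definition — e.g. MRT 1.86 h
for a drug with Tmax 3 h — so MRT is validated against closed forms
(MRT = 1/ke for an IV mono-exponential), not against printed values.
Zero concentrations are excluded from log fits; negative ones are input
errors.

Relative bioavailability is 100·(AUC_test/AUC_ref)·(dose_ref/dose_test);
applied to the published group-mean AUCs at equal doses it reproduces
the published 222.52% (oil beads) and 146.93% (oil-free beads).

## Synthetic data: what it emulates and what it does not

- **CCD responses**: the published polynomials are the default truth;
  noise is multiplicative Gaussian with σ = CV/100, anchored to the
  published per-response CV% (2.40 / 7.20 / 3.82).  This matches how the
  study reports dispersion but assumes independent homoscedastic-in-CV
  errors; real assay errors may correlate across runs.
- **Dissolution**: profiles follow a chosen law with multiplicative
  noise, clamped to [0,100] and made non-decreasing by cumulative max.
  The presets keep the published exponents (0.836 / 0.7297) but
  calibrate Km to the published 12-h cumulative release (92.68% /
  91.88%), because the published kinetic constants are not mutually
  consistent with the observed release magnitudes on any percent or
  fraction basis.
- **Plasma**: one-compartment Bateman curves stand in for the
  unpublished individual-animal data.  Presets fix ke to the published
  group value, solve ka so the analytic Tmax = ln(ka/ke)/(ka−ke) matches
  the published Tmax, and set the scale to the published Cmax
  (pure drug: ka 0.74, ke 0.114, scale 1.631; oil beads: 0.48/0.0585/
  1.513; oil-free beads: 0.37/0.093/1.685).  The published Cmax, AUC and
  ke triples are not jointly consistent with a one-compartment model, so
  the presets prioritize Cmax/Tmax/ke; their implied AUCs (S/ke) exceed
  the published ones, and a green synthetic-PK test establishes correct
  NCA arithmetic, not reproduction of the published AUC table.
- **Blood pressure**: baseline minus a gamma-shaped pulse peaking at
  t_peak, with the shape exponent set so the effect decays to 10% of
  peak at t = duration; additive Gaussian noise (BP dispersion is
  reported as absolute ± SD).  It emulates the drop–nadir–recovery shape
  of the oil-bead group, not circadian or measurement-protocol effects.

A green test on synthetic data establishes that the estimators recover
the generating parameters under the stated noise model — not that the
noise model is the biology.

## Numerical choices and degenerate inputs

- Fits raise on rank deficiency (fewer distinct points than terms) and
  on saturated leave-one-out refits; diagnostics raise on zero response
  mean (CV undefined) and leverage ≥ 1 (PRESS undefined).
- Desirability components are total functions on the reals; D = 0 as
  soon as any component is 0, and an all-zero optimization is returned
  flagged infeasible rather than raised.
- Cmax/argmin ties break to the earliest time everywhere.
- SD uses the n−1 denominator; a single observation reports SD 0 with an
  explicit flag.
- Reports round to 4 decimals by default (matching the study's
  presentation); internal computation is full precision.

## Known limitations

- The desirability goal settings behind the study's D = 0.978 are
  unrecoverable; only predictions at the reported optimum are validated.
- Kinetic and PK tables are validated by property, not by value, because
  their raw data were published only as figures.
- No lack-of-fit test against pure error (only three center replicates;
  the study does not report one), no Box–Cox transforms, no
  blocking/fractional designs, no compartmental PK, and no inferential
  group comparisons (descriptive summaries only).
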