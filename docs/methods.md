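# Methods

## Measurement model

A fast field-cycling (FFC) relaxometer polarizes the specimen at a high
field (25 MHz proton Larmor frequency), lets the magnetization relax at a
low *evolution* field ν for a variable delay τ, and reads the signal at a
detection field (14.5 MHz). Under the Bloch equations the longitudinal
magnetization follows a mono-exponential approach to the evolution-field
equilibrium:

    Mz(τ) = m_inf + (m0 − m_inf) · exp(−τ / T1),

with `m0` the polarization-level magnetization at τ = 0 and `m_inf` the
equilibrium value at ν. The package fits all three parameters
(`m0`, `m_inf`, `T1`) per curve; R₁ = 1/T₁ per field gives the NMRD
profile. A three-parameter form is used because a pre-polarized sequence
decays to a non-zero low-field equilibrium; whether the original analysis
fixed one parameter is unknown, and the three-parameter fit is the safer,
assumption-free choice.

## Acquisition layout (defaults)

| parameter | default | unit | rationale |
|---|---|---|---|
| evolution fields | 0.02, 0.037, 0.07, 0.15, 0.39, 1 | MHz PLF | the protocol's six-point profile |
| delays per field | 32, log-spaced | — | acquisition table of the reference instrument |
| delay span, 3 lowest fields | 0.01–2.8 | s | idem |
| delay span, 3 highest fields | 0.01–4 | s | idem |
| polarization / detection field | 25 / 14.5 | MHz | idem |
| switching time | 4 | ms | informational; not simulated |
| temperature | 10 | °C | informational |

The two quantifiers need only subsets of the fields: the Ratio uses 0.02
and 1 MHz, 2R₁ uses 0.39 and 1 MHz. Field matching is exact to 1e-6 MHz;
values are never interpolated to missing fields, because the protocol
measures exactly these fields — a profile lacking one raises a
`MissingFieldError`, and a borderline specimen lacking the 0.39 MHz point
raises `MissingMeasurementError`, mirroring the extra acquisition the
sequential protocol orders.

## Synthetic dispersion model

No public decay-curve or profile data exist, so cohorts are simulated. The
shape of R₁(ν) is not published analytically; the package adopts the
simplest two-parameter family with monotone dispersion, a power law
R₁(ν) = C·ν^(−α), because it can reproduce both quantifier anchors exactly:

    Ratio = 50^α          →  α = ln(Ratio)/ln(50)
    2R₁   = C(1+0.39^−α)  →  C = 2R₁/(1+0.39^−α)

Anchors: healthy (Ratio 1.83, 2R₁ 34.7 s⁻¹ → α ≈ 0.154, C ≈ 16.09 s⁻¹) and
tumour (Ratio 3.42, 2R₁ 12.2 s⁻¹ → α ≈ 0.314, C ≈ 5.20 s⁻¹). This is a
synthetic-data device only, not a claim about relaxation physics; a
Lorentzian pool model would be a natural extension.

Mixed specimens interpolate linearly in (α, ln C) with weight
w = f_tumour/0.70 clipped to [0, 1] — the simplest rule that makes
adipose-rich mixed specimens Ratio-borderline while leaving their 2R₁
relatively intact, the behaviour the borderline band exploits.

**Jitter.** Biological spread enters as Gaussian jitter on α
(SD 0.045) and log-normal jitter on C (SD 0.24 on the log scale). Raw
log-normal jitter would bias the quantifier means upward (Jensen), so both
draws are mean-corrected: the α-shift uses mean −σ_α²ln50/2 (making
E[Ratio] equal the anchor exactly) and the ln C shift absorbs the residual
factor so E[2R₁] equals its anchor too. The SDs were chosen once so the
simulated healthy-group spreads approximate the reference cohort SDs
(Ratio ≈ 0.33 vs 0.36; 2R₁ ≈ 8.5 vs 8.7 s⁻¹); the tumour-group Ratio
spread comes out somewhat wider (≈ 0.61 vs 0.53) — a single pair of jitter
SDs cannot match all six group SDs simultaneously and the means are what
downstream checks pin down.

**Cohort composition.** Healthy specimens have zero tumour fraction and
adipose fraction in [0.7, 1]; tumour specimens draw f_tumour in
[0.70, 0.95]; mixed specimens draw f_tumour in (0.02, 0.68) by default,
with adipose up to 0.85. The default mixed range intentionally includes
nearly-healthy specimens, so simulated cohorts are *harder* than the
original one, in which mixed specimens were sampled at visible lesions.
Pipeline users can narrow the range (`m_tumour_low/high`); with tumour
fractions ≥ 0.30 and zero noise/jitter the classes separate perfectly.

**Noise.** Acquisition noise is i.i.d. Gaussian on Mz with
SD = `noise_fraction` × M_pol, with M_pol ∝ 25 MHz and the evolution-field
equilibrium M_inf ∝ ν (Curie law; the actual detected-signal model is not
published). The default `noise_fraction = 0.007` was calibrated by
Monte-Carlo so that the instrument-repeatability protocol — 9 specimens,
triplicate acquisitions at 0.02 and 1 MHz, pooled relative SD of R₁ (the
root mean square of the per-specimen relative SDs) — stays within the ±2%
instrument specification on every seed tried, not merely on average.

What the generator does **not** emulate: multi-exponential or
exchange-coupled relaxation, field-switching transients, coil loading or
mass effects, inter-patient correlation between specimens, and the
composition-conditional biology that made real mixed specimens cluster
near lesions. Passing tests therefore show the pipeline's *arithmetic* is
right under a plausible physical model; they cannot certify performance on
real tissue.

## Fitting: numerical choices

* Initialization from data: m0 ≈ first point, m_inf ≈ last point, T1 from a
  log-linear regression of the centred early decay (fallback: a delay one
  third into the grid).
* `scipy.optimize.least_squares` (trust-region reflective), tolerances
  1e-12, T1 bounded to [1e-4, 100] s.
* Failures are flagged, never imputed: non-convergence, T1 pinned at a
  bound, or a fitted amplitude below 1e-8 of the data scale (a flat curve
  makes T1 unidentifiable) yield `converged=False` with `T1 = NaN`, and
  profile assembly drops them with a logged warning.

## Statistics

* **Pooled SD** (equal replicates): S_p = sqrt((S₁²+…+S_k²)/k).
* **Outlier fences**: the published fence definition, P75 ± 1.5·IQR, is the
  default (`as_published`); conventional Tukey fences
  [Q1 − 1.5·IQR, Q3 + 1.5·IQR] are selectable. The published form is
  asymmetric (its lower fence sits one IQR above Tukey's) and is plausibly
  a typo; both are implemented and neither is asserted as intended.
  Quantiles use linear interpolation. Reference profiles (healthy ≥ 90%
  adipose; tumour ≥ 70% tumour) drop any specimen fenced at one or more
  fields, then average fieldwise with the SD as uncertainty.
* **ROC**: threshold sweep over unique score values with thresholds at
  midpoints between adjacent unique scores (±∞ sentinels), so ties never
  sit on a threshold; AUC by trapezoid, which equals the Mann–Whitney
  concordance with ties counted ½ (property-tested against a pair-count
  oracle and `sklearn.metrics.roc_auc_score`). Ratio is scored high-is-
  positive, 2R₁ low-is-positive.
* **Cut-off selection**: criterion unspecified in the source protocol;
  Youden's J is the default, with closest-to-(0,1) and equal-error-rate
  selectable. Ties break toward higher sensitivity, then higher
  specificity. The shipped constants (2.19; 24.0 s⁻¹; band 1.95 / 26.5
  s⁻¹) are protocol constants derived on the original cohort: they are
  *not* re-derived from synthetic data, and selection is validated on
  synthetic data against an exhaustive threshold scan only.

## Decision rule conventions

Boundary conventions follow the printed protocol exactly: Ratio positive
strictly above 2.19; the borderline band is inclusive, [1.95, 2.19]; 2R₁
positive at ≤ 24.0 s⁻¹; the reversed-order band is (24.0, 26.5]. One
deliberate edge-case choice: a zero-width band (`ratio_band_low ==
ratio_cutoff`) disables deferral entirely, so the sequential rule collapses
exactly onto the Ratio-only rule — otherwise the single point
Ratio = cut-off would still defer, breaking the collapse equivalence.
Quadrants of the (2R₁, Ratio) plane use the same conventions: I = both
rules positive (tumour-like), III = both negative (healthy-like), II/IV
the mixed cases.

H is negative, M and T positive throughout evaluation; the protocol is
binary by design and never predicts the three-way H/M/T label.

## Problem sizes

Monte-Carlo checks use 2000 replicate Gaussian-model cohorts for the
headline AUC and sensitivity figures, 200 physics-simulated cohorts for
the group-mean anchoring check, 1000 random instances for the AUC/
concordance identity, and 50 seeds for the reproducibility protocol —
sizes chosen so each estimate's Monte-Carlo error is well below the
tolerance it is compared against while the whole suite runs in well under
a minute of simulation time.

## Known limitations

* The power-law dispersion and linear mixing rule are conveniences; real
  NMRD profiles of tissue are sums of relaxation contributions and need
  not follow either.
* Simulated cohort-level sensitivity/specificity depend strongly on the
  assumed tumour-fraction distribution of mixed specimens, which the
  source cohort does not report per specimen.
* The exact cut-offs and the real-cohort AUC cannot be re-derived without
  the unavailable specimen data; they are shipped constants.
* Acquisition timing (6 min two-field, 9 min full protocol, 17′48″ full
  profile) is reported as informational metadata and never asserted.
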