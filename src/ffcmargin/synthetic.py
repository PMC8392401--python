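"""Synthetic cohorts of labelled breast-tissue specimens with physically
plausible NMRD profiles and raw pre-polarized decay curves.

No public data accompany the margin-assessment protocol, so every downstream
stage is exercised on simulated specimens. Healthy (H) adipose-rich tissue
shows high R1 with weak dispersion; tumour-rich (T) tissue shows low R1 with
strong dispersion. Both behaviours are encoded by a two-parameter power law

    R1(nu) = C * nu**(-alpha)        (nu in MHz proton Larmor frequency)

anchored so that the two relaxometric quantifiers of the noiseless H and T
profiles reproduce the cohort group means:

    Ratio = R1(0.02 MHz) / R1(1 MHz) = 50**alpha
    2R1   = R1(0.39 MHz) + R1(1 MHz) = C * (1 + 0.39**(-alpha))

Mixed (M) specimens interpolate linearly in (alpha, ln C) with a weight
w = f_tumour / 0.70 clipped to [0, 1]; biological variability enters through
mean-corrected log-normal jitter on C and Gaussian jitter on alpha, so the
noiseless anchors remain the exact group means of the simulated quantifiers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidDispersionError
from .relaxometry import DecayCurve, NMRDProfile, decay_signal

#: Printed per-class statistics of the two quantifiers (mean, SD) and the
#: cohort group sizes used throughout: 40 H, 43 M, 21 T.
GROUP_SIZES = {"H": 40, "M": 43, "T": 21}
RATIO_GROUP_STATS = {"H": (1.83, 0.36), "M": (2.66, 0.48), "T": (3.42, 0.53)}
TWO_R1_GROUP_STATS = {"H": (34.7, 8.7), "M": (19.5, 5.7), "T": (12.2, 2.9)}

#: Tumour fraction at and above which a specimen counts as a tumour (T)
#: reference; mirrors the >= 70% tumour-content threshold.
TUMOUR_CLASS_THRESHOLD = 0.70

#: Default noise level of the simulated acquisition, as a fraction of the
#: polarization-level magnetization. Calibrated by Monte-Carlo so that the
#: triplicate reproducibility protocol yields a pooled relative SD of the
#: fitted R1 comfortably within the +/-2% instrument specification.
DEFAULT_NOISE_FRACTION = 0.007

#: Default jitter of the per-sample dispersion parameters (SD of ln C and of
#: alpha), chosen so cohort quantifier spreads approximate the printed group
#: SDs (relative SD ~0.25 for 2R1, ~0.18 for Ratio).
DEFAULT_JITTER_SD = 0.24
DEFAULT_ALPHA_JITTER_SD = 0.045

_LN50 = math.log(50.0)
_B039 = -math.log(0.39)  # 0.39**(-a) = exp(a * _B039)


def _default_delay_grid() -> dict[float, np.ndarray]:
    grids = {}
    for f in (0.02, 0.037, 0.07):
        grids[f] = np.geomspace(0.01, 2.8, 32)
    for f in (0.15, 0.39, 1.0):
        grids[f] = np.geomspace(0.01, 4.0, 32)
    return grids


@dataclass(frozen=True)
class AcquisitionScheme:
    """Field-cycling acquisition layout.

    Six evolution fields between 0.02 and 1 MHz, 32 log-spaced relaxation
    delays per field (0.01-2.8 s at the three lowest fields, 0.01-4 s at the
    three highest), polarization at 25 MHz, detection at 14.5 MHz, 4 ms field
    switching, 10 degC.
    """

    evolution_fields_mhz: tuple = (0.02, 0.037, 0.07, 0.15, 0.39, 1.0)
    delay_grid: dict = field(default_factory=_default_delay_grid)
    polarization_field_mhz: float = 25.0
    detection_field_mhz: float = 14.5
    switching_time_s: float = 0.004
    temperature_c: float = 10.0

    def delays_for(self, field_mhz: float) -> np.ndarray:
        for f, grid in self.delay_grid.items():
            if abs(f - field_mhz) <= 1e-6:
                return grid
        raise KeyError(f"no delay grid for field {field_mhz} MHz")


@dataclass(frozen=True)
class TissueSample:
    """Specimen metadata: mass, histological composition and H/M/T class.

    The class label follows the composition: H iff the specimen contains no
    tumour tissue, T iff the tumour fraction reaches 0.70, M otherwise.
    """

    sample_id: str
    mass_mg: float
    f_adipose: float
    f_stroma: float
    f_tumour: float

    def __post_init__(self):
        if self.mass_mg <= 0:
            raise ValueError("mass must be positive")
        total = self.f_adipose + self.f_stroma + self.f_tumour
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"composition fractions must sum to 1 (got {total})")
        for f in (self.f_adipose, self.f_stroma, self.f_tumour):
            if f < -1e-12 or f > 1 + 1e-12:
                raise ValueError("fractions must lie in [0, 1]")

    @property
    def true_class(self) -> str:
        if self.f_tumour == 0:
            return "H"
        if self.f_tumour >= TUMOUR_CLASS_THRESHOLD:
            return "T"
        return "M"


@dataclass(frozen=True)
class DispersionParams:
    """Power-law dispersion R1(nu) = C * nu**(-alpha), nu in MHz."""

    c: float
    alpha: float

    def __post_init__(self):
        if self.c <= 0:
            raise ValueError("C must be positive")
        if not 0 <= self.alpha < 1:
            raise ValueError("alpha must lie in [0, 1)")

    def r1(self, fields_mhz) -> np.ndarray:
        nu = np.asarray(fields_mhz, dtype=float)
        return self.c * nu ** (-self.alpha)


@dataclass(frozen=True)
class GaussianGroupModel:
    """Per-class normal model of one quantifier, with group sizes.

    ``stats`` maps class label -> (mean, SD); ``sizes`` maps class -> n.
    Used for classifier-level simulations only — it bypasses the relaxation
    physics entirely.
    """

    stats: dict
    sizes: dict

    def __post_init__(self):
        for cls, (mu, sd) in self.stats.items():
            if sd <= 0:
                raise ValueError(f"SD for class {cls} must be positive")
        for cls, n in self.sizes.items():
            if n <= 0:
                raise ValueError(f"size for class {cls} must be positive")

    @classmethod
    def ratio_reference(cls) -> "GaussianGroupModel":
        return cls(stats=dict(RATIO_GROUP_STATS), sizes=dict(GROUP_SIZES))

    @classmethod
    def two_r1_reference(cls) -> "GaussianGroupModel":
        return cls(stats=dict(TWO_R1_GROUP_STATS), sizes=dict(GROUP_SIZES))


def calibrate_power_law(ratio_mean: float, two_r1_mean: float) -> DispersionParams:
    """Solve the power law for the pair (Ratio, 2R1) it must reproduce.

    Closed form: ``alpha = ln(ratio) / ln(50)`` and
    ``C = two_r1 / (1 + 0.39**(-alpha))``.
    """
    if ratio_mean <= 1:
        raise InvalidDispersionError(
            f"Ratio must exceed 1 for a non-increasing profile (got {ratio_mean})"
        )
    if two_r1_mean <= 0:
        raise ValueError("2R1 must be positive")
    alpha = math.log(ratio_mean) / _LN50
    c = two_r1_mean / (1.0 + math.exp(alpha * _B039))
    return DispersionParams(c=c, alpha=alpha)


def default_calibration() -> tuple[DispersionParams, DispersionParams]:
    """(H anchor, T anchor) calibrated to the printed group means."""
    return (
        calibrate_power_law(*[RATIO_GROUP_STATS["H"][0], TWO_R1_GROUP_STATS["H"][0]]),
        calibrate_power_law(*[RATIO_GROUP_STATS["T"][0], TWO_R1_GROUP_STATS["T"][0]]),
    )


def make_cohort(
    n_h: int,
    n_m: int,
    n_t: int,
    seed: int | None = None,
    m_tumour_range: tuple[float, float] = (0.02, 0.68),
    rng: np.random.Generator | None = None,
) -> list[TissueSample]:
    """Draw a labelled cohort of specimens with plausible compositions.

    H specimens carry no tumour and are adipose-dominated (f_adipose in
    [0.7, 1]); T specimens have f_tumour in [0.70, 0.95]; M specimens draw
    f_tumour from ``m_tumour_range`` with adipose content up to 0.85, so a
    subset of M mimics the adipose-rich borderline specimens that defeat the
    Ratio criterion. Masses span the 16-114 mg specimen range. Deterministic
    under a fixed seed.
    """
    if min(n_h, n_m, n_t) < 0:
        raise ValueError("group sizes must be nonnegative")
    lo, hi = m_tumour_range
    if not (0 < lo <= hi < TUMOUR_CLASS_THRESHOLD):
        raise ValueError("m_tumour_range must lie strictly inside (0, 0.70)")
    rng = np.random.default_rng(seed) if rng is None else rng
    samples: list[TissueSample] = []

    def add(i, f_tumour, f_adipose):
        f_stroma = 1.0 - f_tumour - f_adipose
        samples.append(
            TissueSample(
                sample_id=f"S{i:03d}",
                mass_mg=float(rng.uniform(16.0, 114.0)),
                f_adipose=float(f_adipose),
                f_stroma=float(f_stroma),
                f_tumour=float(f_tumour),
            )
        )

    i = 0
    for _ in range(n_h):
        add(i, 0.0, rng.uniform(0.70, 1.0)); i += 1
    for _ in range(n_m):
        ft = rng.uniform(lo, hi)
        add(i, ft, rng.uniform(0.0, min(0.85, 1.0 - ft))); i += 1
    for _ in range(n_t):
        ft = rng.uniform(0.70, 0.95)
        add(i, ft, rng.uniform(0.0, 1.0 - ft)); i += 1
    return samples


def ground_truth_profile(
    sample: TissueSample,
    calibration: tuple[DispersionParams, DispersionParams] | None = None,
    jitter_sd: float = DEFAULT_JITTER_SD,
    alpha_jitter_sd: float = DEFAULT_ALPHA_JITTER_SD,
    seed: int | None = None,
    scheme: AcquisitionScheme | None = None,
    rng: np.random.Generator | None = None,
) -> NMRDProfile:
    """Noise-free per-sample NMRD profile from the composition-mixed power law.

    The per-sample dispersion interpolates linearly in (alpha, ln C) between
    the H and T anchors with weight w = f_tumour/0.70 clipped to [0, 1].
    Jitter is log-normal multiplicative on C (SD ``jitter_sd`` on the log
    scale) and additive Gaussian on alpha (SD ``alpha_jitter_sd``); both
    draws are mean-corrected so the expected Ratio and 2R1 of a jittered
    sample equal the noiseless anchor values — the cohort group means stay
    pinned to the calibration targets while the spreads approximate the
    printed group SDs. With zero jitter the anchors are reproduced exactly.
    """
    if calibration is None:
        calibration = default_calibration()
    h, t = calibration
    scheme = scheme or AcquisitionScheme()
    rng = np.random.default_rng(seed) if rng is None else rng

    w = min(max(sample.f_tumour / TUMOUR_CLASS_THRESHOLD, 0.0), 1.0)
    alpha_w = (1 - w) * h.alpha + w * t.alpha
    ln_c_w = (1 - w) * math.log(h.c) + w * math.log(t.c)

    # mean corrections: E[Ratio] = 50**alpha_w and E[2R1] = C_w (1+0.39**-alpha_w)
    mu_a = -0.5 * alpha_jitter_sd**2 * _LN50
    k_alpha = math.exp(_B039 * mu_a + 0.5 * _B039**2 * alpha_jitter_sd**2)
    e_ba = math.exp(_B039 * alpha_w)
    mu_c = math.log((e_ba + 1.0) / (e_ba * k_alpha + 1.0)) - 0.5 * jitter_sd**2

    alpha = alpha_w + mu_a + alpha_jitter_sd * float(rng.standard_normal())
    alpha = min(max(alpha, 0.0), 0.999)
    ln_c = ln_c_w + mu_c + jitter_sd * float(rng.standard_normal())
    params = DispersionParams(c=math.exp(ln_c), alpha=alpha)

    fields = np.asarray(scheme.evolution_fields_mhz, dtype=float)
    return NMRDProfile(sample_id=sample.sample_id, fields_mhz=fields, r1_s1=params.r1(fields))


def simulate_decay_curves(
    profile: NMRDProfile,
    scheme: AcquisitionScheme | None = None,
    noise_fraction: float = DEFAULT_NOISE_FRACTION,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> list[DecayCurve]:
    """Raw pre-polarized decay curves for every field of a profile.

    At each evolution field nu the magnetization relaxes from the
    polarization-level value (proportional to the 25 MHz polarization field)
    to the Curie-law equilibrium of the evolution field (proportional to nu)
    with time constant T1 = 1/R1(nu), sampled on the scheme's 32-delay grid.
    i.i.d. Gaussian noise with SD = ``noise_fraction`` * M_pol is added.
    """
    if noise_fraction < 0:
        raise ValueError("noise_fraction must be nonnegative")
    scheme = scheme or AcquisitionScheme()
    rng = np.random.default_rng(seed) if rng is None else rng
    m_pol = scheme.polarization_field_mhz
    curves = []
    for nu, r1 in zip(profile.fields_mhz, profile.r1_s1):
        tau = scheme.delays_for(float(nu))
        mz = decay_signal(tau, m_pol, float(nu), 1.0 / float(r1))
        if noise_fraction > 0:
            mz = mz + rng.normal(0.0, noise_fraction * m_pol, size=tau.size)
        curves.append(DecayCurve(profile.sample_id, float(nu), tau.copy(), mz))
    return curves


def sample_quantifiers_gaussian(
    model: GaussianGroupModel,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> list[tuple[str, float]]:
    """Draw one labelled cohort of quantifier values from the group model.

    Returns ``[(class_label, value), ...]`` in class order H, M, T (classes
    ordered as in the model's ``sizes``). Deterministic under a fixed seed.
    """
    rng = np.random.default_rng(seed) if rng is None else rng
    out: list[tuple[str, float]] = []
    for cls, n in model.sizes.items():
        mu, sd = model.stats[cls]
        vals = rng.normal(mu, sd, size=n)
        out.extend((cls, float(v)) for v in vals)
    return out
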