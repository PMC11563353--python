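"""Synthetic paired lesion/healthy multispectral autofluorescence cohorts.

The clinical acquisition this emulates images a suspicious oral lesion and a
clinically healthy-appearing contralateral site in each patient, collecting
fluorescence decay traces in three emission bands (390±20 nm, 452±22.5 nm,
>500 nm) that preferentially report collagen, NADH and FAD autofluorescence.
The generator reproduces the statistical structure the downstream analysis
relies on:

* class-dependent band composition — each histopathology grade has a mean
  triple of normalized band intensities; malignant/premalignant tissue shifts
  fluorescence away from the collagen band toward the NADH band and lowers
  the optical redox ratio (NADH band over FAD band);
* per-pixel compositional jitter, additive Gaussian (optionally Poisson)
  noise on every time sample, a constant background offset, and a
  configurable fraction of pixels driven into hard amplitude saturation;
* single-exponential decay per band after a short signal-free pre-pulse
  window, so offset and noise can be estimated from the leading samples.

Band amplitudes are scaled by the reciprocal of the unit decay's trapezoidal
integral on the simulation grid, so the numerically integrated band intensity
of a noise-free pixel equals ``amplitude_scale * fraction`` exactly and the
normalized intensities recover the configured class fractions.

Effect sizes are synthetic by construction: they make the classes separable
under the configured noise and must not be read as estimates of clinical
effect sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cube import MultispectralCube
from .errors import ConfigurationError

HISTOPATHOLOGY_GRADES = ("Benign", "MoD", "HiD", "SCC")
POSITIVE_GRADES = ("MoD", "HiD", "SCC")
BAND_LABELS = ("I390", "I452", "I500")

# Anatomical sites observed in oral screening cohorts; cycled for flavour only.
_SITES = (
    "Buccal mucosa", "Tongue", "Lip", "Gingiva", "Floor of mouth",
    "Mandible", "Maxilla", "Palate", "Retromolar",
)


def _default_class_fractions() -> dict[str, tuple[float, float, float]]:
    # Benign/healthy reference: collagen-dominated emission, redox ratio > 1.
    # Positive grades: less collagen (I390), more NADH (I452), and a lower
    # I452/I500 redox ratio, increasingly so with grade severity.
    return {
        "Benign": (0.40, 0.33, 0.27),
        "MoD": (0.30, 0.350, 0.350),
        "HiD": (0.27, 0.355, 0.375),
        "SCC": (0.24, 0.360, 0.400),
    }


def _default_grade_weights() -> dict[str, float]:
    # Positive-class composition of the emulated 67-lesion cohort:
    # 1 MoD, 3 HiD, 29 SCC out of 33 positives.
    return {"MoD": 1 / 33, "HiD": 3 / 33, "SCC": 29 / 33}


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic cohort generator.

    ``class_band_fractions`` maps each histopathology grade to its mean
    normalized band-intensity triple (must sum to 1).  Healthy contralateral
    cubes always use the Benign triple, whatever the lesion's grade.
    """

    n_patients: int = 40
    positive_fraction: float = 33 / 67
    image_shape: tuple[int, int] = (64, 64)
    n_time: int = 256
    dt: float = 0.1  # ns per sample
    band_labels: tuple[str, str, str] = BAND_LABELS
    class_band_fractions: dict[str, tuple[float, float, float]] = field(
        default_factory=_default_class_fractions
    )
    positive_grade_weights: dict[str, float] = field(default_factory=_default_grade_weights)
    fraction_jitter_sd: float = 0.05
    decay_constants: tuple[float, float, float] = (5.0, 4.0, 4.5)  # ns
    amplitude_scale: float = 1000.0
    pre_pulse_samples: int = 16
    noise_sd: float = 2.0
    poisson_noise: bool = False
    offset_level: float = 50.0
    saturation_level: float = 4000.0
    saturation_fraction: float = 0.01
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ConfigurationError("n_patients must be >= 1")
        if not 0.0 <= self.positive_fraction <= 1.0:
            raise ConfigurationError("positive_fraction must lie in [0, 1]")
        if len(self.band_labels) != 3:
            raise ConfigurationError("exactly three emission bands are required")
        for grade, frac in self.class_band_fractions.items():
            if grade not in HISTOPATHOLOGY_GRADES:
                raise ConfigurationError(f"unknown histopathology grade {grade!r}")
            frac = tuple(frac)
            if len(frac) != 3 or any(f < 0 for f in frac):
                raise ConfigurationError(f"band fractions for {grade!r} must be 3 non-negative values")
            if abs(sum(frac) - 1.0) > 1e-9:
                raise ConfigurationError(f"band fractions for {grade!r} must sum to 1, got {sum(frac)}")
        missing = set(HISTOPATHOLOGY_GRADES) - set(self.class_band_fractions)
        if missing:
            raise ConfigurationError(f"missing band fractions for grades {sorted(missing)}")
        if set(self.positive_grade_weights) - set(POSITIVE_GRADES):
            raise ConfigurationError("positive_grade_weights keys must be MoD/HiD/SCC")
        if sum(self.positive_grade_weights.values()) <= 0:
            raise ConfigurationError("positive_grade_weights must have positive total")
        if self.n_time < 2 or self.dt <= 0:
            raise ConfigurationError("need n_time >= 2 and dt > 0")
        if not 0 <= self.pre_pulse_samples < self.n_time - 1:
            raise ConfigurationError("pre_pulse_samples must leave room for the decay")
        if self.fraction_jitter_sd < 0 or self.noise_sd < 0:
            raise ConfigurationError("dispersion parameters must be non-negative")
        if self.amplitude_scale <= 0 or self.saturation_level <= 0:
            raise ConfigurationError("amplitude_scale and saturation_level must be positive")
        if not 0.0 <= self.saturation_fraction <= 1.0:
            raise ConfigurationError("saturation_fraction must lie in [0, 1]")
        # The time window must contain >= 99% of each exponential's area so
        # integrated intensities are not truncated.
        window = (self.n_time - 1 - self.pre_pulse_samples) * self.dt
        for tau in self.decay_constants:
            if tau <= 0:
                raise ConfigurationError("decay constants must be positive")
            if 1.0 - np.exp(-window / tau) < 0.99:
                raise ConfigurationError(
                    f"time window {window:.1f} ns covers <99% of a tau={tau} ns decay"
                )


@dataclass
class LesionSample:
    """One patient's paired acquisitions plus the biopsy ground truth."""

    patient_id: str
    lesion_cube: MultispectralCube
    healthy_cube: MultispectralCube
    histopathology: str
    site: str

    def __post_init__(self) -> None:
        if self.histopathology not in HISTOPATHOLOGY_GRADES:
            raise ConfigurationError(f"unknown histopathology {self.histopathology!r}")

    @property
    def is_positive(self) -> bool:
        """Binary screening label: dysplasia or carcinoma vs benign."""
        return self.histopathology in POSITIVE_GRADES


def default_effect_config(**overrides) -> SimulationConfig:
    """Config whose positive class follows the trends reported for oral
    malignancy: lower normalized collagen-band intensity (I390,n), higher
    normalized NADH-band intensity (I452,n), and a lower I452/I500 optical
    redox ratio than benign/healthy tissue, at separable effect sizes.
    """
    cfg = SimulationConfig(**overrides)
    cfg.validate()
    return cfg


def assign_labels(config: SimulationConfig) -> list[str]:
    """Deterministic histopathology grade per patient.

    ``round(n_patients * positive_fraction)`` patients are positive; the
    positive grades follow ``positive_grade_weights`` via largest-remainder
    apportionment.  Grade order is shuffled with a seed-derived RNG so
    positives are not clustered at one end of the cohort.
    """
    n = config.n_patients
    n_pos = int(round(n * config.positive_fraction))
    weights = {g: config.positive_grade_weights.get(g, 0.0) for g in POSITIVE_GRADES}
    total = sum(weights.values())
    quotas = {g: n_pos * w / total for g, w in weights.items()}
    counts = {g: int(np.floor(q)) for g, q in quotas.items()}
    short = n_pos - sum(counts.values())
    for g in sorted(POSITIVE_GRADES, key=lambda g: quotas[g] - counts[g], reverse=True)[:short]:
        counts[g] += 1
    labels = ["Benign"] * (n - n_pos)
    for g in POSITIVE_GRADES:
        labels.extend([g] * counts[g])
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xC0F]))
    rng.shuffle(labels)
    return labels


def _unit_decay(config: SimulationConfig, tau: float) -> tuple[np.ndarray, float]:
    """Unit-peak decay shape on the time grid and its trapezoidal integral."""
    t = np.arange(config.n_time) * config.dt
    t0 = config.pre_pulse_samples * config.dt
    shape = np.where(t >= t0, np.exp(-(np.maximum(t - t0, 0.0)) / tau), 0.0)
    return shape, float(np.trapezoid(shape, dx=config.dt))


def _simulate_cube(
    config: SimulationConfig, fractions: tuple[float, float, float], rng: np.random.Generator
) -> MultispectralCube:
    rows, cols = config.image_shape
    f = np.broadcast_to(np.asarray(fractions, dtype=np.float64), (rows, cols, 3)).copy()
    if config.fraction_jitter_sd > 0:
        f += rng.normal(0.0, config.fraction_jitter_sd, size=f.shape)
    f = np.clip(f, 1e-3, None)
    f /= f.sum(axis=2, keepdims=True)

    # Per-pixel amplitude; a chosen subset is boosted past the clipping ceiling.
    amplitude = np.full((rows, cols), config.amplitude_scale)
    n_sat = int(round(config.saturation_fraction * rows * cols))
    sat_idx = rng.choice(rows * cols, size=n_sat, replace=False) if n_sat else np.array([], int)

    shapes, integrals = zip(*(_unit_decay(config, tau) for tau in config.decay_constants))
    if n_sat:
        # Peak of band b at decay onset is amplitude * f_b / integral_b.
        peak_rate = np.max(f / np.asarray(integrals), axis=2).ravel()[sat_idx]
        amplitude.ravel()[sat_idx] = 2.0 * config.saturation_level / peak_rate

    bands: dict[str, np.ndarray] = {}
    for b, label in enumerate(config.band_labels):
        trace = (
            amplitude[:, :, None]
            * (f[:, :, b] / integrals[b])[:, :, None]
            * shapes[b][None, None, :]
        )
        trace += config.offset_level
        if config.poisson_noise:
            trace = rng.poisson(np.clip(trace, 0.0, None)).astype(np.float64)
        if config.noise_sd > 0:
            trace += rng.normal(0.0, config.noise_sd, size=trace.shape)
        np.minimum(trace, config.saturation_level, out=trace)
        bands[label] = trace

    return MultispectralCube(
        bands=bands,
        time_dt=config.dt,
        meta={
            "pre_pulse_samples": config.pre_pulse_samples,
            "saturation_level": config.saturation_level,
            "offset_level": config.offset_level,
        },
    )


def simulate_patient(config: SimulationConfig, index: int, histopathology: str) -> LesionSample:
    """Generate one patient's paired cubes; deterministic in (seed, index)."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1, index]))
    lesion = _simulate_cube(config, tuple(config.class_band_fractions[histopathology]), rng)
    # Contralateral healthy tissue always draws from the Benign reference.
    healthy = _simulate_cube(config, tuple(config.class_band_fractions["Benign"]), rng)
    site = _SITES[index % len(_SITES)]
    return LesionSample(
        patient_id=f"P{index:03d}",
        lesion_cube=lesion,
        healthy_cube=healthy,
        histopathology=histopathology,
        site=site,
    )


def iter_cohort(config: SimulationConfig):
    """Yield the cohort one patient at a time (constant memory)."""
    config.validate()
    for i, grade in enumerate(assign_labels(config)):
        yield simulate_patient(config, i, grade)


def simulate_cohort(config: SimulationConfig) -> list[LesionSample]:
    """Materialize the whole cohort; see :func:`iter_cohort` for streaming."""
    return list(iter_cohort(config))
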