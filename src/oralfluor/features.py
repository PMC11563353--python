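"""Per-pixel spectral intensity features of an oral lesion image.

From the cleaned decay cube, each pixel yields an integrated intensity per
emission band

    I_b(x, y) = ∫ y_b(x, y, t) dt        (composite trapezoid),

from which 18 features are derived, in a fixed canonical order:

* 3 normalized intensities I_b,n = I_b / Σ_b I_b (collagen, NADH and FAD
  band shares; they sum to 1);
* 6 spectral ratios I390/I452, I390/I500, I452/I500 (the optical redox
  ratio), (I452+I500)/I390, (I390+I500)/I452, (I390+I452)/I500;
* 9 relative counterparts Δf = f(x, y) − median(f over the paired healthy
  image), normalizing each lesion feature against the patient's own
  contralateral healthy tissue.

Pixels where any band integral is non-positive (noise can drive weak signals
negative after offset subtraction) are masked with a dedicated reason code:
every feature requires all three integrals strictly positive.  Masked pixels
carry NaN in every feature map.

The canonical feature order doubles as the deterministic tie-break order for
feature ranking downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cube import REASON_NONPOS_INTENSITY, MultispectralCube, PixelMask
from .errors import DataError, UnusableSampleError
from .simulate import BAND_LABELS

#: Canonical names and order of the 9 absolute features.
ABSOLUTE_FEATURES: tuple[str, ...] = (
    "I390n",
    "I452n",
    "I500n",
    "I390/I452",
    "I390/I500",
    "I452/I500",
    "(I452+I500)/I390",
    "(I390+I500)/I452",
    "(I390+I452)/I500",
)

RELATIVE_PREFIX = "delta_"

#: The 9 relative (lesion-minus-healthy-median) counterparts.
RELATIVE_FEATURES: tuple[str, ...] = tuple(RELATIVE_PREFIX + f for f in ABSOLUTE_FEATURES)

ALL_FEATURES: tuple[str, ...] = ABSOLUTE_FEATURES + RELATIVE_FEATURES

#: Single derived feature emulating a blue-excitation single-channel
#: autofluorescence viewer: the combined NADH+FAD band share.  Equals
#: 1 − I390n on every valid pixel by the normalization identity.
VELSCOPE_FEATURE = "I452n+I500n"


@dataclass
class FeatureStack:
    """Named per-pixel feature maps sharing one validity mask."""

    features: dict[str, np.ndarray]
    mask: PixelMask
    feature_names: tuple[str, ...]

    def __post_init__(self) -> None:
        if tuple(self.features) != tuple(self.feature_names):
            raise DataError("features dict must follow feature_names order")
        for name, arr in self.features.items():
            if arr.shape != self.mask.valid.shape:
                raise DataError(f"feature {name!r} shape mismatch")

    def get(self, name: str) -> np.ndarray:
        """Feature map by name; the single-channel viewer surrogate
        ``I452n+I500n`` is derived on the fly if not stored."""
        if name in self.features:
            return self.features[name]
        if name == VELSCOPE_FEATURE:
            return self.features["I452n"] + self.features["I500n"]
        raise KeyError(name)

    def matrix(self, names: tuple[str, ...]) -> np.ndarray:
        """(n_valid, len(names)) matrix of feature values at valid pixels,
        in row-major pixel order."""
        cols = [self.get(n)[self.mask.valid] for n in names]
        return np.column_stack(cols)


@dataclass
class HealthyReference:
    """Per-feature median over the valid pixels of the healthy image."""

    medians: dict[str, float]


def integrate_intensity(cube: MultispectralCube) -> dict[str, np.ndarray]:
    """Trapezoidal time integral of each band's decay trace, per pixel.

    Units: intensity x ns.  Assumes the offset has been subtracted.
    """
    return {
        b: np.trapezoid(arr, dx=cube.time_dt, axis=2) for b, arr in cube.bands.items()
    }


def mask_nonpositive(
    integrals: dict[str, np.ndarray], mask: PixelMask
) -> PixelMask:
    """Mask pixels where any band integral is <= 0 (undefined ratios)."""
    bad = np.zeros(mask.valid.shape, dtype=bool)
    for arr in integrals.values():
        bad |= ~(arr > 0)
    return mask.mask_where(bad, REASON_NONPOS_INTENSITY)


def normalize_intensity(
    integrals: dict[str, np.ndarray], mask: PixelMask
) -> tuple[dict[str, np.ndarray], PixelMask]:
    """Normalized band intensities I_b,n = I_b / Σ I_b.

    Returns the three maps (keyed ``I390n`` etc.) and a mask updated with the
    non-positive-integral rule; invalid pixels are NaN.
    """
    if set(integrals) != set(BAND_LABELS):
        raise DataError(f"expected bands {BAND_LABELS}, got {tuple(integrals)}")
    mask = mask_nonpositive(integrals, mask)
    total = sum(integrals[b] for b in BAND_LABELS)
    out = {}
    with np.errstate(invalid="ignore", divide="ignore"):
        for b in BAND_LABELS:
            m = integrals[b] / total
            m[~mask.valid] = np.nan
            out[b + "n"] = m
    return out, mask


def spectral_ratios(
    integrals: dict[str, np.ndarray], mask: PixelMask
) -> tuple[dict[str, np.ndarray], PixelMask]:
    """The six band-intensity ratios, in canonical order."""
    mask = mask_nonpositive(integrals, mask)
    i390, i452, i500 = (integrals[b] for b in BAND_LABELS)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratios = {
            "I390/I452": i390 / i452,
            "I390/I500": i390 / i500,
            "I452/I500": i452 / i500,
            "(I452+I500)/I390": (i452 + i500) / i390,
            "(I390+I500)/I452": (i390 + i500) / i452,
            "(I390+I452)/I500": (i390 + i452) / i500,
        }
    for m in ratios.values():
        m[~mask.valid] = np.nan
    return ratios, mask


def absolute_feature_stack(cube: MultispectralCube, mask: PixelMask) -> FeatureStack:
    """The 9 absolute features (3 normalized intensities + 6 ratios)."""
    integrals = integrate_intensity(cube)
    normed, mask = normalize_intensity(integrals, mask)
    ratios, mask = spectral_ratios(integrals, mask)
    feats = {**normed, **ratios}
    feats = {name: feats[name] for name in ABSOLUTE_FEATURES}
    return FeatureStack(feats, mask, ABSOLUTE_FEATURES)


def healthy_reference(healthy: FeatureStack) -> HealthyReference:
    """Median of each absolute feature over the healthy image's valid pixels."""
    if healthy.mask.n_valid < 1:
        raise UnusableSampleError("healthy image has no valid pixels for the reference")
    valid = healthy.mask.valid
    return HealthyReference(
        {name: float(np.median(healthy.features[name][valid])) for name in ABSOLUTE_FEATURES}
    )


def relative_features(
    lesion: FeatureStack, ref: HealthyReference
) -> dict[str, np.ndarray]:
    """Δf maps: lesion feature minus the healthy-image median, per pixel."""
    missing = [n for n in ABSOLUTE_FEATURES if n not in ref.medians]
    if missing:
        raise DataError(f"healthy reference missing features {missing}")
    return {
        RELATIVE_PREFIX + name: lesion.features[name] - ref.medians[name]
        for name in ABSOLUTE_FEATURES
    }


def build_feature_stacks(
    lesion_cube: MultispectralCube,
    lesion_mask: PixelMask,
    healthy_cube: MultispectralCube,
    healthy_mask: PixelMask,
) -> tuple[FeatureStack, FeatureStack]:
    """Full feature extraction for one preprocessed lesion/healthy pair.

    Returns the lesion stack with all 18 features (9 absolute + 9 relative to
    the healthy medians) and the healthy stack with the 9 absolute features.
    The healthy stack never receives relative features — it is its own
    baseline.
    """
    healthy = absolute_feature_stack(healthy_cube, healthy_mask)
    lesion_abs = absolute_feature_stack(lesion_cube, lesion_mask)
    ref = healthy_reference(healthy)
    rel = relative_features(lesion_abs, ref)
    feats = dict(lesion_abs.features)
    for name in RELATIVE_FEATURES:
        m = rel[name].copy()
        m[~lesion_abs.mask.valid] = np.nan
        feats[name] = m
    lesion = FeatureStack(feats, lesion_abs.mask, ALL_FEATURES)
    return lesion, healthy


def total_intensity(cube: MultispectralCube, mask: PixelMask) -> np.ndarray:
    """Summed band integrals per pixel — the grayscale backdrop for
    posterior-map overlays.  Masked pixels are NaN."""
    integrals = integrate_intensity(cube)
    tot = sum(integrals.values()).astype(np.float64)
    tot[~mask.valid] = np.nan
    return tot
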