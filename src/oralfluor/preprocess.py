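"""Five-step preprocessing of a multispectral decay cube.

The cleaning protocol, applied independently to the lesion and healthy cube
of each patient, in this fixed order:

1. subtract the per-pixel signal offset/background, estimated from the
   leading pre-pulse time samples;
2. mask pixels whose maximum amplitude reaches a saturation threshold in any
   band;
3. spatial boxcar smoothing (default 5x5) of every time sample, with the
   kernel renormalized over in-image, unmasked neighbours;
4. mask pixels whose post-smoothing SNR falls below a dB threshold in any
   band, with SNR = 20*log10(peak amplitude / baseline noise std);
5. apply an optional manual mask (e.g. teeth regions with strong
   autofluorescence), supplied as a boolean image.

Masking is monotone across steps and the recorded per-pixel reason is the
first cause encountered.  The "any band" rule reflects that every spectral
feature needs all three band intensities at a pixel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage

from .cube import (
    REASON_LOW_SNR,
    REASON_MANUAL,
    REASON_SATURATED,
    MultispectralCube,
    PixelMask,
)
from .errors import ConfigurationError, DataError, UnusableSampleError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PreprocessConfig:
    """Knobs of the cleaning protocol.

    ``saturation_threshold`` is an absolute amplitude if given; otherwise the
    threshold resolves to ``saturation_fraction_of_max`` times the cube's
    global maximum.  ``baseline_samples`` leading time samples are treated as
    signal-free and used for both offset and noise estimation.
    """

    saturation_threshold: Optional[float] = None
    saturation_fraction_of_max: float = 0.999
    smoothing_kernel: int = 5
    snr_threshold_db: float = 15.0
    baseline_samples: int = 16

    def validate(self) -> None:
        if self.smoothing_kernel < 1 or self.smoothing_kernel % 2 == 0:
            raise ConfigurationError("smoothing_kernel must be odd and >= 1")
        if not np.isfinite(self.snr_threshold_db):
            raise ConfigurationError("snr_threshold_db must be finite")
        if self.baseline_samples < 2:
            raise ConfigurationError("baseline_samples must be >= 2")
        if self.saturation_threshold is not None and self.saturation_threshold <= 0:
            raise ConfigurationError("saturation_threshold must be positive")
        if not 0 < self.saturation_fraction_of_max <= 1:
            raise ConfigurationError("saturation_fraction_of_max must be in (0, 1]")


def subtract_offset(cube: MultispectralCube, config: PreprocessConfig) -> MultispectralCube:
    """Remove the per-pixel baseline: the mean of the leading
    ``baseline_samples`` time samples of each trace."""
    config.validate()
    if config.baseline_samples >= cube.n_samples:
        raise ConfigurationError(
            f"baseline_samples={config.baseline_samples} must be < n_samples={cube.n_samples}"
        )
    out = {}
    for b, arr in cube.bands.items():
        baseline = arr[:, :, : config.baseline_samples].mean(axis=2, keepdims=True)
        out[b] = arr - baseline
    return MultispectralCube(out, cube.time_dt, dict(cube.meta))


def resolve_saturation_threshold(cube: MultispectralCube, config: PreprocessConfig) -> float:
    if config.saturation_threshold is not None:
        return float(config.saturation_threshold)
    global_max = max(float(a.max()) for a in cube.bands.values())
    return config.saturation_fraction_of_max * global_max


def mask_saturated(
    cube: MultispectralCube, config: PreprocessConfig, mask: Optional[PixelMask] = None
) -> PixelMask:
    """Mask pixels whose amplitude reaches the saturation ceiling in any band."""
    config.validate()
    threshold = resolve_saturation_threshold(cube, config)
    if threshold <= 0:
        raise ConfigurationError("resolved saturation threshold must be positive")
    if mask is None:
        mask = PixelMask.all_valid(cube.image_shape)
    saturated = np.zeros(cube.image_shape, dtype=bool)
    for arr in cube.bands.values():
        saturated |= arr.max(axis=2) >= threshold
    return mask.mask_where(saturated, REASON_SATURATED)


def spatial_smooth(
    cube: MultispectralCube, mask: PixelMask, config: PreprocessConfig
) -> MultispectralCube:
    """Boxcar-average each time sample over unmasked in-image neighbours.

    The kernel is renormalized over the available neighbours, so image borders
    and masked pixels contribute nothing and no synthetic values leak in.
    Masked pixels are zeroed in the output; they carry no signal downstream.
    """
    config.validate()
    k = config.smoothing_kernel
    if k == 1:
        out = {b: np.where(mask.valid[:, :, None], a, 0.0) for b, a in cube.bands.items()}
        return MultispectralCube(out, cube.time_dt, dict(cube.meta))
    weight = ndimage.uniform_filter(
        mask.valid.astype(np.float64), size=k, mode="constant", cval=0.0
    )
    out = {}
    with np.errstate(invalid="ignore", divide="ignore"):
        for b, arr in cube.bands.items():
            num = ndimage.uniform_filter(
                arr * mask.valid[:, :, None], size=(k, k, 1), mode="constant", cval=0.0
            )
            sm = np.where(weight[:, :, None] > 0, num / weight[:, :, None], 0.0)
            sm[~mask.valid] = 0.0
            out[b] = sm
    return MultispectralCube(out, cube.time_dt, dict(cube.meta))


def mask_low_snr(
    cube: MultispectralCube, mask: PixelMask, config: PreprocessConfig
) -> PixelMask:
    """Mask pixels with SNR below the dB threshold in any band.

    SNR(x, y, band) = 20*log10(peak of the smoothed trace / sigma), with sigma
    the standard deviation of the leading ``baseline_samples`` of the smoothed
    (offset-subtracted) trace.  Noise-free pixels (sigma == 0) are treated as
    infinite SNR and kept.
    """
    config.validate()
    if config.baseline_samples >= cube.n_samples:
        raise ConfigurationError("baseline_samples must be < n_samples")
    low = np.zeros(cube.image_shape, dtype=bool)
    n_sigma_zero = 0
    for arr in cube.bands.values():
        peak = arr.max(axis=2)
        sigma = arr[:, :, : config.baseline_samples].std(axis=2)
        zero = sigma == 0
        n_sigma_zero += int((zero & mask.valid).sum())
        with np.errstate(divide="ignore", invalid="ignore"):
            snr_db = 20.0 * np.log10(np.where(zero, np.inf, peak / sigma))
        # Non-positive peaks have undefined log amplitude ratio -> below any
        # finite threshold.
        snr_db = np.where((peak <= 0) & ~zero, -np.inf, snr_db)
        low |= snr_db < config.snr_threshold_db
    if n_sigma_zero:
        logger.info("mask_low_snr: %d pixel-bands with zero baseline noise kept", n_sigma_zero)
    return mask.mask_where(low, REASON_LOW_SNR)


def apply_manual_mask(mask: PixelMask, manual: np.ndarray) -> PixelMask:
    """Remove manually flagged pixels (reason MANUAL); never unmasks."""
    manual = np.asarray(manual, dtype=bool)
    if manual.shape != mask.valid.shape:
        raise DataError(
            f"manual mask shape {manual.shape} != image shape {mask.valid.shape}"
        )
    return mask.mask_where(manual, REASON_MANUAL)


def preprocess_cube(
    cube: MultispectralCube,
    config: PreprocessConfig,
    manual: Optional[np.ndarray] = None,
) -> tuple[MultispectralCube, PixelMask]:
    """Run steps 1-5 on a single cube."""
    config.validate()
    cube = subtract_offset(cube, config)
    mask = mask_saturated(cube, config)
    cube = spatial_smooth(cube, mask, config)
    mask = mask_low_snr(cube, mask, config)
    if manual is not None:
        mask = apply_manual_mask(mask, manual)
    return cube, mask


def preprocess(
    sample,
    config: PreprocessConfig,
    manual_lesion: Optional[np.ndarray] = None,
    manual_healthy: Optional[np.ndarray] = None,
) -> tuple[tuple[MultispectralCube, PixelMask], tuple[MultispectralCube, PixelMask]]:
    """Clean a lesion/healthy pair independently, in the fixed step order.

    Raises :class:`UnusableSampleError` if either image retains no valid pixel.
    """
    lesion = preprocess_cube(sample.lesion_cube, config, manual_lesion)
    healthy = preprocess_cube(sample.healthy_cube, config, manual_healthy)
    for name, (_, mask) in (("lesion", lesion), ("healthy", healthy)):
        if mask.n_valid < 1:
            raise UnusableSampleError(
                f"{getattr(sample, 'patient_id', '?')}: no valid {name} pixels after preprocessing"
            )
    return lesion, healthy
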