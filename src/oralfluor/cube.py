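"""Shared image containers for the pipeline.

A :class:`MultispectralCube` holds one endoscopic acquisition: per emission
band, a stack of fluorescence decay traces ``y(x, y, t)`` on a common uniform
time axis.  A :class:`PixelMask` tracks which pixels are usable and why the
others were discarded; masking is monotone — once a pixel is removed by one
processing step, no later step may restore it, and the recorded reason is the
first cause encountered.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DataError

# Mask reason codes, in pipeline step order.
REASON_OK = 0
REASON_SATURATED = 1
REASON_LOW_SNR = 2
REASON_MANUAL = 3
REASON_NONPOS_INTENSITY = 4

REASON_NAMES = {
    REASON_OK: "OK",
    REASON_SATURATED: "SATURATED",
    REASON_LOW_SNR: "LOW_SNR",
    REASON_MANUAL: "MANUAL",
    REASON_NONPOS_INTENSITY: "NONPOS_INTENSITY",
}


@dataclass
class MultispectralCube:
    """Per-band decay-resolved image stack with a shared time axis.

    Parameters
    ----------
    bands
        Ordered mapping ``band label -> float array (rows, cols, n_samples)``.
    time_dt
        Sampling interval of the decay traces, in nanoseconds.
    meta
        Free-form acquisition metadata.
    """

    bands: dict[str, np.ndarray]
    time_dt: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.bands:
            raise DataError("cube must contain at least one band")
        shapes = {b: np.asarray(a).shape for b, a in self.bands.items()}
        ref = next(iter(shapes.values()))
        if any(s != ref for s in shapes.values()):
            raise DataError(f"bands disagree on shape: {shapes}")
        if len(ref) != 3:
            raise DataError(f"band stacks must be (rows, cols, n_samples), got {ref}")
        if ref[2] < 2:
            raise DataError("decay traces need at least 2 time samples")
        if not self.time_dt > 0:
            raise DataError("time_dt must be positive")
        self.bands = {b: np.asarray(a, dtype=np.float64) for b, a in self.bands.items()}

    @property
    def band_labels(self) -> tuple[str, ...]:
        return tuple(self.bands)

    @property
    def image_shape(self) -> tuple[int, int]:
        r, c, _ = next(iter(self.bands.values())).shape
        return (r, c)

    @property
    def n_samples(self) -> int:
        return next(iter(self.bands.values())).shape[2]

    @property
    def time_axis(self) -> np.ndarray:
        """Time points in nanoseconds, starting at 0."""
        return np.arange(self.n_samples) * self.time_dt

    def copy(self) -> "MultispectralCube":
        return MultispectralCube(
            bands={b: a.copy() for b, a in self.bands.items()},
            time_dt=self.time_dt,
            meta=dict(self.meta),
        )


@dataclass
class PixelMask:
    """Boolean validity map plus a per-pixel reason code."""

    valid: np.ndarray
    reason: np.ndarray

    def __post_init__(self) -> None:
        self.valid = np.asarray(self.valid, dtype=bool)
        self.reason = np.asarray(self.reason, dtype=np.uint8)
        if self.valid.shape != self.reason.shape:
            raise DataError("valid and reason maps must share a shape")
        if not np.array_equal(self.valid, self.reason == REASON_OK):
            raise DataError("valid map must equal (reason == OK)")

    @classmethod
    def all_valid(cls, shape: tuple[int, int]) -> "PixelMask":
        return cls(np.ones(shape, dtype=bool), np.zeros(shape, dtype=np.uint8))

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())

    def mask_where(self, where: np.ndarray, reason: int) -> "PixelMask":
        """Return a new mask with currently-valid pixels under `where` removed.

        First-reason-wins: pixels already masked keep their original code.
        """
        where = np.asarray(where, dtype=bool)
        if where.shape != self.valid.shape:
            raise DataError("mask shape mismatch")
        newly = where & self.valid
        new_reason = self.reason.copy()
        new_reason[newly] = reason
        return PixelMask(self.valid & ~where, new_reason)

    def copy(self) -> "PixelMask":
        return PixelMask(self.valid.copy(), self.reason.copy())
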