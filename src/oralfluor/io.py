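"""Readers and writers for the on-disk pipeline formats.

* Cohorts: one HDF5 file per patient with ``/lesion/<band>`` and
  ``/healthy/<band>`` datasets of shape (rows, cols, n_samples) and the
  attributes ``time_dt_ns``, ``histopathology``, ``site``, ``patient_id``;
  plus a cohort ``manifest.csv`` (patient_id, histopathology, label, site,
  path).
* Cleaned cubes: same layout plus ``/mask/<side>/valid`` and
  ``/mask/<side>/reason`` datasets.
* Feature stacks: one multi-page 32-bit TIFF per image (page order = feature
  order, names in the TIFF metadata), the mask reason map as a companion
  TIFF, and a long-format CSV (patient_id, row, col, feature_name, value)
  restricted to valid pixels.
* Manual masks: single-page binary TIFF or PNG aligned to the image grid;
  any nonzero pixel is masked.

Coordinates are (row, col), 0-based, row-major everywhere.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Optional

import h5py
import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .cube import REASON_OK, MultispectralCube, PixelMask
from .errors import DataError
from .features import FeatureStack
from .simulate import LesionSample, POSITIVE_GRADES

MANIFEST_NAME = "manifest.csv"


# ---------------------------------------------------------------------------
# Cohort HDF5


def _write_cube(group: h5py.Group, cube: MultispectralCube) -> None:
    for band, arr in cube.bands.items():
        group.create_dataset(band, data=arr.astype(np.float32), compression="gzip", compression_opts=1)


def _read_cube(group: h5py.Group, time_dt: float) -> MultispectralCube:
    bands = {band: np.asarray(group[band], dtype=np.float64) for band in group}
    return MultispectralCube(bands=bands, time_dt=time_dt)


def write_cohort(samples: Iterable[LesionSample], out_dir) -> Path:
    """Write one HDF5 per patient plus the cohort manifest; returns the
    manifest path.  Accepts any iterable, so cohorts can be streamed."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for sample in samples:
        path = out_dir / f"{sample.patient_id}.h5"
        with h5py.File(path, "w") as f:
            f.attrs["patient_id"] = sample.patient_id
            f.attrs["histopathology"] = sample.histopathology
            f.attrs["site"] = sample.site
            f.attrs["time_dt_ns"] = sample.lesion_cube.time_dt
            _write_cube(f.create_group("lesion"), sample.lesion_cube)
            _write_cube(f.create_group("healthy"), sample.healthy_cube)
        rows.append(
            {
                "patient_id": sample.patient_id,
                "histopathology": sample.histopathology,
                "label": int(sample.histopathology in POSITIVE_GRADES),
                "site": sample.site,
                "path": path.name,
            }
        )
    manifest = out_dir / MANIFEST_NAME
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_manifest(in_dir) -> pd.DataFrame:
    path = Path(in_dir) / MANIFEST_NAME
    if not path.exists():
        raise DataError(f"no {MANIFEST_NAME} in {in_dir}")
    return pd.read_csv(path)


def read_patient(in_dir, patient_id: str) -> LesionSample:
    path = Path(in_dir) / f"{patient_id}.h5"
    with h5py.File(path, "r") as f:
        dt = float(f.attrs["time_dt_ns"])
        return LesionSample(
            patient_id=str(f.attrs["patient_id"]),
            lesion_cube=_read_cube(f["lesion"], dt),
            healthy_cube=_read_cube(f["healthy"], dt),
            histopathology=str(f.attrs["histopathology"]),
            site=str(f.attrs["site"]),
        )


def iter_cohort_files(in_dir):
    """Yield LesionSamples listed in the manifest, one at a time."""
    for pid in read_manifest(in_dir)["patient_id"]:
        yield read_patient(in_dir, pid)


# ---------------------------------------------------------------------------
# Cleaned cubes (cube + mask per side)


def write_clean(
    patient_id: str,
    lesion: tuple[MultispectralCube, PixelMask],
    healthy: tuple[MultispectralCube, PixelMask],
    out_dir,
    meta: Optional[dict] = None,
) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / f"{patient_id}.h5"
    with h5py.File(path, "w") as f:
        f.attrs["patient_id"] = patient_id
        f.attrs["time_dt_ns"] = lesion[0].time_dt
        for k, v in (meta or {}).items():
            f.attrs[k] = v
        for side, (cube, mask) in (("lesion", lesion), ("healthy", healthy)):
            _write_cube(f.create_group(side), cube)
            g = f.create_group(f"mask/{side}")
            g.create_dataset("valid", data=mask.valid)
            g.create_dataset("reason", data=mask.reason)
    return path


def read_clean(in_dir, patient_id: str):
    path = Path(in_dir) / f"{patient_id}.h5"
    with h5py.File(path, "r") as f:
        dt = float(f.attrs["time_dt_ns"])
        out = {}
        for side in ("lesion", "healthy"):
            cube = _read_cube(f[side], dt)
            mask = PixelMask(
                np.asarray(f[f"mask/{side}/valid"], dtype=bool),
                np.asarray(f[f"mask/{side}/reason"], dtype=np.uint8),
            )
            out[side] = (cube, mask)
        meta = dict(f.attrs)
    return out["lesion"], out["healthy"], meta


# ---------------------------------------------------------------------------
# Feature stacks (TIFF + long CSV)


def write_feature_stack(patient_id: str, tag: str, stack: FeatureStack, out_dir) -> Path:
    """Write one image's stack as a multi-page float32 TIFF plus the mask
    reason map; page order and names live in the TIFF metadata."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    arr = np.stack([stack.features[n] for n in stack.feature_names]).astype(np.float32)
    path = out_dir / f"{patient_id}_{tag}_features.tif"
    tifffile.imwrite(path, arr, metadata={"feature_names": list(stack.feature_names)})
    tifffile.imwrite(out_dir / f"{patient_id}_{tag}_mask.tif", stack.mask.reason)
    return path


def read_feature_stack(in_dir, patient_id: str, tag: str) -> FeatureStack:
    in_dir = Path(in_dir)
    path = in_dir / f"{patient_id}_{tag}_features.tif"
    with tifffile.TiffFile(path) as tf:
        arr = tf.asarray().astype(np.float64)
        meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
    names = meta.get("feature_names")
    if not names:
        raise DataError(f"{path} lacks feature_names metadata")
    reason = tifffile.imread(in_dir / f"{patient_id}_{tag}_mask.tif").astype(np.uint8)
    mask = PixelMask(reason == REASON_OK, reason)
    feats = {n: arr[i] for i, n in enumerate(names)}
    return FeatureStack(feats, mask, tuple(names))


def write_feature_csv(patient_id: str, stack: FeatureStack, out_path) -> Path:
    """Long-format CSV of valid-pixel feature values."""
    rows_idx, cols_idx = np.nonzero(stack.mask.valid)
    frames = [
        pd.DataFrame(
            {
                "patient_id": patient_id,
                "row": rows_idx,
                "col": cols_idx,
                "feature_name": name,
                "value": stack.features[name][rows_idx, cols_idx],
            }
        )
        for name in stack.feature_names
    ]
    out_path = Path(out_path)
    pd.concat(frames, ignore_index=True).to_csv(out_path, index=False)
    return out_path


def write_posterior_tiff(prob: np.ndarray, path) -> Path:
    path = Path(path)
    tifffile.imwrite(path, prob.astype(np.float32))
    return path


# ---------------------------------------------------------------------------
# Manual masks


def read_manual_mask(path, image_shape: tuple[int, int]) -> np.ndarray:
    """Load a binary TIFF/PNG manual mask; nonzero pixels are masked."""
    arr = np.asarray(iio.imread(Path(path)))
    if arr.ndim == 3:  # RGB(A): any nonzero channel counts
        arr = arr.max(axis=2)
    if arr.shape != tuple(image_shape):
        raise DataError(f"manual mask {path} shape {arr.shape} != image {tuple(image_shape)}")
    return arr != 0


def load_manual_masks(mask_dir, image_shape) -> dict[str, np.ndarray]:
    """Collect `<patient_id>.(tif|tiff|png)` files from a directory."""
    out = {}
    mask_dir = Path(mask_dir)
    for path in sorted(mask_dir.iterdir()):
        if path.suffix.lower() in {".tif", ".tiff", ".png"}:
            out[path.stem] = read_manual_mask(path, image_shape)
    return out
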