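"""Volume I/O: multipage TIFF and slice-image directories.

The on-disk contract is 8-bit grayscale, one page (or one file) per B-scan;
in memory everything is float in [0, 1].  Slice directories are read in
lexicographic filename order, so indices should be zero-padded.
"""

from __future__ import annotations

import os
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .phantom import GroundTruth
from .volume import OCTVolume

__all__ = ["read_volume", "write_volume", "write_ground_truth", "read_ground_truth"]

_SLICE_EXTS = (".tif", ".tiff", ".png")


def _rescale(arr: np.ndarray) -> np.ndarray:
    arr = np.asarray(arr)
    if np.issubdtype(arr.dtype, np.integer):
        return arr.astype(np.float64) / np.iinfo(arr.dtype).max
    return np.clip(arr.astype(np.float64), 0.0, 1.0)


def read_volume(path: str | os.PathLike, patient_id: str | None = None) -> OCTVolume:
    """Read an OCT volume from a multipage TIFF or a directory of slices.

    Directory slices must all share one shape; they are stacked along y in
    filename order.  Intensities are rescaled to [0, 1].
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(
            f for f in path.iterdir() if f.suffix.lower() in _SLICE_EXTS
        )
        if not files:
            raise IOError(f"no slice images (*.tif/*.png) found in {path}")
        slices = []
        for f in files:
            if f.stat().st_size == 0:
                raise IOError(f"empty slice file: {f}")
            img = iio.imread(f)
            if img.ndim == 3:  # RGB(A) -> first channel (grayscale exports)
                img = img[..., 0]
            slices.append(img)
        shapes = {s.shape for s in slices}
        if len(shapes) != 1:
            raise ValueError(f"mixed slice shapes in {path}: {sorted(shapes)}")
        vox = _rescale(np.stack(slices))
    else:
        if not path.exists():
            raise IOError(f"no such volume: {path}")
        if path.stat().st_size == 0:
            raise IOError(f"empty volume file: {path}")
        arr = tifffile.imread(path)
        if arr.ndim == 2:
            arr = arr[None]
        if arr.ndim != 3:
            raise ValueError(f"expected a grayscale volume in {path}, got {arr.shape}")
        vox = _rescale(arr)
    return OCTVolume(voxels=vox, patient_id=patient_id or path.stem)


def write_volume(volume: OCTVolume, path: str | os.PathLike) -> None:
    """Write a volume as an 8-bit grayscale multipage TIFF (one page per
    B-scan)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = np.rint(np.clip(volume.voxels, 0.0, 1.0) * 255).astype(np.uint8)
    tifffile.imwrite(path, data, photometric="minisblack")


def write_ground_truth(
    truths: list[GroundTruth], path: str | os.PathLike
) -> None:
    """Write phantom ground truth as a CSV sidecar: one row per slice with
    patient id, label and the RPE-curve coefficients (a, b, c)."""
    rows = []
    for t in truths:
        for y, (a, b, c) in enumerate(t.coeffs):
            rows.append(
                {
                    "patient_id": t.patient_id,
                    "label": t.label,
                    "slice": y,
                    "a": a,
                    "b": b,
                    "c": c,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_ground_truth(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path)
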