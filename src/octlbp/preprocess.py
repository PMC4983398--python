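"""B-scan preprocessing: speckle denoising, retina flattening, alignment.

Three steps, applied per B-scan:

1. **Non-local means (NLM) denoising** — patch-similarity weighted
   averaging, which attenuates multiplicative speckle while preserving
   layer boundaries and flat zones.
2. **Flattening** — the curvature of the retinal pigment epithelium (RPE),
   the bright lowest retinal layer, is estimated by Otsu thresholding,
   median filtering, morphological closing/opening, keeping the largest
   foreground component, and fitting a second-order polynomial
   ``z(x) = a x^2 + b x + c`` to the component's bottom boundary.  The
   B-scan is then warped column-wise so the fitted curve becomes a
   horizontal line.
3. **Alignment** — all flattened B-scans of a volume are warped to one
   shared reference altitude, removing inter-slice axial offsets.

Flatten-only mode warps each slice to its own curve's constant term, so the
curvature is removed but slices keep their individual altitudes; align mode
uses the shared ``reference_row``.  The two modes correspond to the "F" and
"F+A" preprocessing variants evaluated by the classification experiments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure, morphology
from skimage.filters import threshold_otsu
from skimage.restoration import denoise_nl_means

from .volume import OCTVolume

__all__ = [
    "NLMParams",
    "FlattenModel",
    "CurveEstimationError",
    "WarpOutOfRangeError",
    "denoise_nlm",
    "estimate_retina_curve",
    "estimate_flatten_model",
    "flatten_slice",
    "flatten_volume",
    "align_volume",
]


class CurveEstimationError(RuntimeError):
    """RPE curve could not be estimated from a B-scan."""


class WarpOutOfRangeError(RuntimeError):
    """A column shift exceeds the slice height."""


@dataclass
class NLMParams:
    """Non-local means configuration.

    ``patch_size`` and ``search_window`` are the side lengths (px) of the
    comparison patch and of the search neighbourhood; ``h`` is the filter
    strength in intensity units.  ``h=None`` selects ``0.8 * sigma_hat`` per
    slice, where ``sigma_hat`` is a robust (median-absolute-deviation) noise
    estimate over the *foreground* pixels: OCT speckle is multiplicative, so
    its absolute scale is set by the bright tissue, not by the dark
    background that dominates a global estimate.
    """

    patch_size: int = 7
    search_window: int = 21
    h: float | None = None

    def __post_init__(self) -> None:
        if self.patch_size >= self.search_window:
            raise ValueError("patch_size must be smaller than search_window")
        if self.h is not None and self.h <= 0:
            raise ValueError("filter strength h must be > 0")


@dataclass
class FlattenModel:
    """Per-slice quadratic RPE curves plus the shared reference altitude.

    ``coeffs[y] = (a, b, c)`` with fitted curve ``z(x) = a x^2 + b x + c``;
    ``reference_row`` is the z row every slice is aligned to.
    """

    coeffs: np.ndarray  # (d, 3)
    reference_row: int

    def __post_init__(self) -> None:
        self.coeffs = np.atleast_2d(np.asarray(self.coeffs, dtype=np.float64))
        if self.coeffs.shape[1] != 3:
            raise ValueError("coeffs must be (d, 3)")

    def curve(self, y: int, x: np.ndarray) -> np.ndarray:
        a, b, c = self.coeffs[y]
        return a * x**2 + b * x + c


def _foreground_noise_sigma(bscan: np.ndarray) -> float:
    """Robust speckle-scale estimate over tissue pixels.

    High-frequency residual (slice minus its 3x3 median) scaled by the MAD
    factor 1.4826, restricted to pixels above the Otsu threshold when that
    split is meaningful.
    """
    residual = bscan - ndimage.median_filter(bscan, size=3)
    fg = np.ones(bscan.shape, dtype=bool)
    if np.ptp(bscan) > 0:
        fg_try = bscan > threshold_otsu(bscan)
        if fg_try.sum() >= 100:
            fg = fg_try
    return 1.4826 * float(np.median(np.abs(residual[fg])))


def denoise_nlm(volume: OCTVolume, params: NLMParams | None = None) -> OCTVolume:
    """NLM-denoise every B-scan of a volume independently.

    Output intensities are clipped to [0, 1]; provenance gains ``"nlm"``.
    """
    params = params or NLMParams()
    if volume.voxels.size == 0:
        raise ValueError("cannot denoise an empty volume")
    patch_distance = (params.search_window - 1) // 2
    out = np.empty_like(volume.voxels)
    for y in range(volume.n_slices):
        sl = volume.voxels[y]
        h = params.h
        if h is None:
            h = max(0.8 * _foreground_noise_sigma(sl), 1e-8)
        out[y] = denoise_nl_means(
            sl,
            patch_size=params.patch_size,
            patch_distance=patch_distance,
            h=h,
            fast_mode=True,
        )
    np.clip(out, 0.0, 1.0, out=out)
    return volume.with_voxels(out, "nlm")


def estimate_retina_curve(
    bscan: np.ndarray,
    morph_radius: int = 3,
    median_size: int = 5,
    slice_index: int | None = None,
) -> tuple[float, float, float]:
    """Fit the quadratic RPE curve of one B-scan.

    Pipeline: Otsu binarization -> median filter -> morphological closing
    then opening (hole filling) -> keep the largest connected foreground
    component -> take the bottom-most foreground row per column -> least
    squares quadratic fit of those (x, z) points.

    Returns ``(a, b, c)`` such that the curve is ``z(x) = a x^2 + b x + c``.

    Raises
    ------
    CurveEstimationError
        If no foreground survives cleaning or fewer than 3 columns support
        the fit; the message names ``slice_index`` when given.
    """
    where = f" (slice {slice_index})" if slice_index is not None else ""
    bscan = np.asarray(bscan, dtype=np.float64)
    if bscan.ndim != 2:
        raise ValueError("bscan must be 2-D (z, x)")
    if np.ptp(bscan) == 0:
        raise CurveEstimationError(f"constant B-scan, no foreground{where}")
    mask = bscan > threshold_otsu(bscan)
    if not mask.any():
        raise CurveEstimationError(f"empty foreground after thresholding{where}")
    mask = ndimage.median_filter(mask, size=median_size)
    selem = morphology.disk(morph_radius)
    mask = morphology.closing(mask, selem)
    mask = morphology.opening(mask, selem)
    if not mask.any():
        raise CurveEstimationError(f"empty foreground after cleaning{where}")
    labels = measure.label(mask)
    largest = np.argmax(np.bincount(labels.ravel())[1:]) + 1
    mask = labels == largest

    has_fg = mask.any(axis=0)
    cols = np.flatnonzero(has_fg)
    if cols.size < 3:
        raise CurveEstimationError(
            f"only {cols.size} support columns after cleaning{where}"
        )
    H = bscan.shape[0]
    # Bottom-most foreground row per supported column (the RPE is the
    # lowest bright layer).
    bottom = H - 1 - np.argmax(mask[::-1, :], axis=0)
    a, b, c = np.polyfit(cols, bottom[cols], deg=2)
    return float(a), float(b), float(c)


def flatten_slice(
    bscan: np.ndarray, coeffs: tuple[float, float, float], reference_row: int
) -> np.ndarray:
    """Warp one B-scan so its fitted curve lands on ``reference_row``.

    Each column ``x`` is shifted vertically by
    ``dz(x) = reference_row - (a x^2 + b x + c)`` using 1-D linear
    interpolation along z; pixels shifted in from outside the slice are
    zero-filled.  Output shape equals input shape.
    """
    bscan = np.asarray(bscan, dtype=np.float64)
    H, W = bscan.shape
    a, b, c = coeffs
    if not np.all(np.isfinite([a, b, c])):
        raise ValueError("curve coefficients must be finite")
    x = np.arange(W)
    dz = reference_row - (a * x**2 + b * x + c)  # (W,)
    if np.any(np.abs(dz) >= H):
        raise WarpOutOfRangeError(
            f"column shift up to {np.abs(dz).max():.1f} px exceeds height {H}"
        )
    z = np.arange(H)[:, None]
    src_rows = z - dz[None, :]  # out[z, x] = in[z - dz(x), x]
    coords = np.stack([src_rows, np.broadcast_to(x[None, :], (H, W))])
    return ndimage.map_coordinates(bscan, coords, order=1, mode="constant", cval=0.0)


def estimate_flatten_model(
    volume: OCTVolume,
    reference_row: int | None = None,
    morph_radius: int = 3,
    median_size: int = 5,
) -> FlattenModel:
    """Estimate per-slice RPE curves for a whole volume.

    ``reference_row`` defaults to ``round(0.6 * H)``.
    """
    H = volume.shape[1]
    ref = int(round(0.6 * H)) if reference_row is None else int(reference_row)
    if not 0 <= ref < H:
        raise ValueError(f"reference_row {ref} outside [0, {H})")
    coeffs = np.empty((volume.n_slices, 3))
    for y in range(volume.n_slices):
        coeffs[y] = estimate_retina_curve(
            volume.voxels[y], morph_radius, median_size, slice_index=y
        )
    return FlattenModel(coeffs=coeffs, reference_row=ref)


def flatten_volume(volume: OCTVolume, model: FlattenModel) -> OCTVolume:
    """Remove curvature slice-by-slice without inter-slice alignment.

    Each slice is warped to its *own* constant term ``round(c_y)``, so the
    curve becomes a line but per-slice altitudes are preserved.
    """
    _check_model(volume, model)
    out = np.empty_like(volume.voxels)
    for y in range(volume.n_slices):
        ref = int(round(model.coeffs[y, 2]))
        out[y] = flatten_slice(volume.voxels[y], tuple(model.coeffs[y]), ref)
    return volume.with_voxels(out, "flatten")


def align_volume(volume: OCTVolume, model: FlattenModel) -> OCTVolume:
    """Flatten every slice to the shared ``model.reference_row``.

    After alignment the flattened RPE line sits at the same z altitude in
    every B-scan; provenance gains ``"flatten"`` and ``"align"``.
    """
    _check_model(volume, model)
    out = np.empty_like(volume.voxels)
    for y in range(volume.n_slices):
        out[y] = flatten_slice(
            volume.voxels[y], tuple(model.coeffs[y]), model.reference_row
        )
    vol = volume.with_voxels(out, "flatten")
    vol.provenance.append("align")
    return vol


def _check_model(volume: OCTVolume, model: FlattenModel) -> None:
    if model.coeffs.shape[0] != volume.n_slices:
        raise ValueError(
            f"model has {model.coeffs.shape[0]} coefficient triples for a "
            f"volume of {volume.n_slices} slices"
        )
    H = volume.shape[1]
    if not 0 <= model.reference_row < H:
        raise ValueError(f"reference_row {model.reference_row} outside [0, {H})")
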