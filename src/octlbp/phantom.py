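"""Synthetic OCT phantom generator with known ground truth.

The phantom emulates the structure of a macular SD-OCT cube: a curved,
layered bright retinal band over a dark background, corrupted by
multiplicative speckle noise.  The retinal pigment epithelium (RPE), the
bright lowest layer of the band, follows a per-slice quadratic curve

    z(x) = a * x**2 + b * x + c

whose coefficients vary smoothly from B-scan to B-scan, producing a coherent
3-D retina.  Volumes labelled ``"DME"`` additionally contain hypo-reflective
ellipsoidal lesions (cysts) inside the band and, optionally, small bright
exudate-like spots.  The exact per-slice coefficients, the class label and
the cyst voxel mask are recorded as ground truth, so every downstream stage
(flattening, texture extraction, classification) can be validated without
access to clinical data.

The defaults describe a cube of 32 B-scans of 128 x 256 pixels — the
package's standard working scale, a down-sampled analogue of a 128-slice
512 x 1024 clinical cube — with gamma speckle of shape 4 and a band of four
stacked layers roughly 30 px thick.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .volume import OCTVolume

__all__ = [
    "PhantomSpec",
    "LesionSpec",
    "GroundTruth",
    "generate_volume",
    "generate_dataset",
]

#: (thickness px, mean intensity) from the top of the band downwards; the
#: last entry is the bright RPE complex whose bottom edge is the fitted curve.
DEFAULT_LAYER_PROFILE: tuple[tuple[int, float], ...] = (
    (6, 0.55),   # inner retina (RNFL/GCL): moderately reflective
    (10, 0.35),  # middle retina: darker nuclear layers
    (6, 0.50),   # outer plexiform / photoreceptors
    (8, 0.90),   # RPE complex: the brightest band
)


class PhantomConfigError(ValueError):
    """Raised when a phantom specification is invalid."""


@dataclass
class LesionSpec:
    """Configuration of DME-like lesions.

    Cysts are dark (hypo-reflective) axis-aligned ellipsoids placed inside
    the retinal band; exudates are small bright spots.  ``contrast`` is the
    fractional intensity reduction inside a cyst (0 = invisible, 1 = black).
    """

    count_range: tuple[int, int] = (5, 9)
    radii_range: tuple[float, float] = (4.0, 10.0)
    contrast: float = 0.6
    exudate_count_range: tuple[int, int] = (0, 3)
    exudate_radii_range: tuple[float, float] = (1.0, 2.0)
    exudate_contrast: float = 0.35


@dataclass
class PhantomSpec:
    """Full specification of the phantom geometry and noise model.

    Parameters
    ----------
    shape:
        ``(d, H, W)`` — number of B-scans, depth rows, lateral columns.
    a_range, b_range, c_range:
        Sampling ranges for the quadratic RPE-curve coefficients
        ``z(x) = a x^2 + b x + c`` (``c`` in pixels; ``c_range=None`` defaults
        to ``(0.55 H, 0.68 H)``).
    layer_profile:
        ``(thickness_px, mean_intensity)`` pairs from the top of the retinal
        band downwards; the last layer's bottom edge is the RPE curve.
    background:
        Mean background intensity outside the band.
    speckle_shape:
        Shape parameter ``L`` of the multiplicative gamma speckle
        (mean 1, variance ``1/L``); ``None`` or ``inf`` disables noise.
    slice_wobble:
        Amplitude in pixels of the smooth sinusoidal variation of ``c``
        across slices (plus a +/-10% modulation of ``a``).
    lesion:
        Lesion configuration, applied only to ``"DME"`` volumes.
    seed:
        Default RNG seed used when :func:`generate_volume` is called
        without an explicit one.
    """

    shape: tuple[int, int, int] = (32, 128, 256)
    a_range: tuple[float, float] = (5e-5, 3e-4)
    b_range: tuple[float, float] = (-0.08, 0.0)
    c_range: tuple[float, float] | None = None
    layer_profile: tuple[tuple[int, float], ...] = DEFAULT_LAYER_PROFILE
    background: float = 0.03
    speckle_shape: float | None = 4.0
    slice_wobble: float = 2.0
    lesion: LesionSpec = field(default_factory=LesionSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        d, H, W = self.shape
        if d < 8 or H < 64 or W < 64:
            raise PhantomConfigError(
                f"shape must be at least (8, 64, 64); got {self.shape}"
            )
        if not self.layer_profile:
            raise PhantomConfigError("layer_profile must be non-empty")
        if any(t < 1 for t, _ in self.layer_profile):
            raise PhantomConfigError("layer thicknesses must be >= 1 px")

    @property
    def band_thickness(self) -> int:
        return int(sum(t for t, _ in self.layer_profile))

    def resolved_c_range(self) -> tuple[float, float]:
        if self.c_range is not None:
            return self.c_range
        H = self.shape[1]
        return (0.55 * H, 0.68 * H)


@dataclass
class GroundTruth:
    """Exact generative parameters of one phantom volume.

    ``coeffs[y] = (a, b, c)`` is the RPE curve of slice ``y`` (the curve of
    the *bottom* of the bright band, the quantity the flattening stage
    estimates).  ``lesion_mask`` marks cyst voxels; it is empty for normal
    volumes.
    """

    patient_id: str
    label: str
    coeffs: np.ndarray  # (d, 3)
    lesion_mask: np.ndarray  # bool, (d, H, W)

    def curve(self, y: int, x: np.ndarray) -> np.ndarray:
        a, b, c = self.coeffs[y]
        return a * x**2 + b * x + c


def _sample_slice_coeffs(
    spec: PhantomSpec, rng: np.random.Generator
) -> np.ndarray:
    """Sample per-slice (a, b, c), varying smoothly across slices."""
    d, H, _ = spec.shape
    a0 = rng.uniform(*spec.a_range)
    b0 = rng.uniform(*spec.b_range)
    c0 = rng.uniform(*spec.resolved_c_range())
    phase = rng.uniform(0.0, 2.0 * math.pi)
    y = np.arange(d)
    # One slow sinusoidal period across the cube: bounded first difference.
    wave = np.sin(2.0 * math.pi * y / d + phase)
    c = c0 + spec.slice_wobble * wave
    a = a0 * (1.0 + 0.1 * wave)
    b = np.full(d, b0)
    return np.column_stack([a, b, c])


def _paint_slice(spec: PhantomSpec, coeffs: np.ndarray, H: int, W: int) -> np.ndarray:
    """Render one noiseless B-scan from its curve coefficients.

    The band's bottom row at column x is exactly ``round(a x^2 + b x + c)``,
    with the layer profile stacked upwards from it.
    """
    a, b, c = coeffs
    x = np.arange(W)
    z_bot = np.rint(a * x**2 + b * x + c).astype(np.int64)  # (W,)
    z = np.arange(H)[:, None]  # (H, 1)
    img = np.full((H, W), spec.background)
    # Offsets of layer boundaries measured upwards from the band bottom.
    offset = 0
    for thickness, intensity in reversed(spec.layer_profile):
        lo = z_bot - offset - thickness + 1
        hi = z_bot - offset
        img[(z >= lo) & (z <= hi)] = intensity
        offset += thickness
    return img


def _place_ellipsoids(
    rng: np.random.Generator,
    n: int,
    radii_range: tuple[float, float],
    coeffs: np.ndarray,
    shape: tuple[int, int, int],
    band_thickness: int,
    bottom_clearance: int = 0,
    top_margin: float = 2.0,
    existing: list[tuple[np.ndarray, np.ndarray]] | None = None,
    max_tries: int = 200,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Sample ``n`` non-overlapping ellipsoids inside the retinal band.

    Returns a list of ``(center (y,z,x), radii (ry,rz,rx))``.  Rejection
    sampling keeps centers separated by more than the sum of the paired
    radii plus one voxel, so each lesion is its own connected component.
    ``bottom_clearance`` rows above the band bottom are kept lesion-free
    (cystoid spaces lie in the nuclear layers, above the RPE complex, and
    the bright RPE floor is the flattening landmark); ``top_margin`` absorbs
    the slice-to-slice curve wobble so an ellipsoid spanning several slices
    stays inside the band.  ``existing`` ellipsoids also repel new ones.
    """
    d, H, W = shape
    placed: list[tuple[np.ndarray, np.ndarray]] = []
    avoid = list(existing or [])
    # Radii are capped to what the geometry can hold: the axial radius by
    # the lesion-free band interior, the others by the cube extents.
    rz_cap = max(1.0, (band_thickness - bottom_clearance - 4) / 2.0)
    ry_cap = max(1.0, (d - 4) / 2.0)
    rx_cap = max(1.0, (W - 4) / 2.0)
    tries = 0
    while len(placed) < n and tries < max_tries * max(n, 1):
        tries += 1
        radii = rng.uniform(*radii_range, size=3)
        radii[0] = min(radii[0], ry_cap)
        radii[1] = min(radii[1], rz_cap)
        radii[2] = min(radii[2], rx_cap)
        ry, rz, rx = radii
        cy = rng.uniform(ry + 1, d - ry - 2)
        cx = rng.uniform(rx + 1, W - rx - 2)
        a, b, c = coeffs[int(round(cy))]
        z_bot = a * cx**2 + b * cx + c
        z_top = z_bot - band_thickness + 1
        lo, hi = z_top + rz + top_margin, z_bot - bottom_clearance - rz
        if hi <= lo:
            continue
        cz = rng.uniform(lo, hi)
        center = np.array([cy, cz, cx])
        # Axis-aligned ellipsoids cannot overlap (nor touch, given the 2 px
        # gap) if they are separated along at least one axis.
        ok = all(
            bool(np.any(np.abs(center - c2) > radii + r2 + 2.0))
            for c2, r2 in placed + avoid
        )
        if ok:
            placed.append((center, radii))
    if len(placed) < n:
        raise PhantomConfigError(
            f"could not place {n} non-overlapping lesions "
            f"(placed {len(placed)}); reduce count or radii"
        )
    return placed


def _ellipsoid_mask(
    center: np.ndarray, radii: np.ndarray, shape: tuple[int, int, int]
) -> np.ndarray:
    d, H, W = shape
    y = np.arange(d)[:, None, None]
    z = np.arange(H)[None, :, None]
    x = np.arange(W)[None, None, :]
    cy, cz, cx = center
    ry, rz, rx = radii
    return ((y - cy) / ry) ** 2 + ((z - cz) / rz) ** 2 + ((x - cx) / rx) ** 2 <= 1.0


def generate_volume(
    spec: PhantomSpec, label: str, seed: int | None = None
) -> tuple[OCTVolume, GroundTruth]:
    """Generate one phantom OCT volume and its ground-truth record.

    Parameters
    ----------
    spec:
        Phantom configuration.
    label:
        ``"normal"`` or ``"DME"``; lesions are only added for DME.
    seed:
        RNG seed; falls back to ``spec.seed``.  Identical ``(spec, label,
        seed)`` produce bit-identical volumes.
    """
    if label not in ("normal", "DME"):
        raise PhantomConfigError(f"label must be 'normal' or 'DME', got {label!r}")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    d, H, W = spec.shape
    coeffs = _sample_slice_coeffs(spec, rng)

    vox = np.empty((d, H, W))
    for y in range(d):
        vox[y] = _paint_slice(spec, coeffs[y], H, W)

    lesion_mask = np.zeros((d, H, W), dtype=bool)
    if label == "DME":
        les = spec.lesion
        n_cysts = int(rng.integers(les.count_range[0], les.count_range[1] + 1))
        rpe_thickness = spec.layer_profile[-1][0]
        margin = 2.0 + spec.slice_wobble
        cysts = _place_ellipsoids(
            rng, n_cysts, les.radii_range, coeffs, spec.shape,
            spec.band_thickness, bottom_clearance=rpe_thickness,
            top_margin=margin,
        )
        for center, radii in cysts:
            lesion_mask |= _ellipsoid_mask(center, radii, spec.shape)
        # Cysts are serous-fluid pockets: they backscatter little, so both
        # the mean signal and the speckle amplitude drop by the contrast
        # factor (a fully anechoic cyst at contrast 1 is dark and smooth).
        vox[lesion_mask] *= 1.0 - les.contrast
        n_exu = int(
            rng.integers(les.exudate_count_range[0], les.exudate_count_range[1] + 1)
        )
        if n_exu:
            for center, radii in _place_ellipsoids(
                rng, n_exu, les.exudate_radii_range, coeffs, spec.shape,
                spec.band_thickness, bottom_clearance=rpe_thickness,
                top_margin=margin, existing=cysts,
            ):
                vox[_ellipsoid_mask(center, radii, spec.shape)] += les.exudate_contrast

    if spec.speckle_shape is not None and math.isfinite(spec.speckle_shape):
        L = float(spec.speckle_shape)
        noise = rng.gamma(L, 1.0 / L, size=vox.shape) - 1.0
        if lesion_mask.any():
            noise[lesion_mask] *= 1.0 - spec.lesion.contrast
        vox *= 1.0 + noise

    np.clip(vox, 0.0, 1.0, out=vox)
    volume = OCTVolume(voxels=vox, label=label, provenance=["phantom"])
    truth = GroundTruth(
        patient_id="", label=label, coeffs=coeffs, lesion_mask=lesion_mask
    )
    return volume, truth


def generate_dataset(
    spec: PhantomSpec, n_per_class: int, seed: int = 0
) -> list[tuple[OCTVolume, GroundTruth]]:
    """Generate a balanced phantom cohort of ``2 * n_per_class`` patients.

    Each volume gets a distinct patient id and a per-volume seed derived
    deterministically from the master ``seed``.  The first ``n_per_class``
    patients are DME, the rest normal; the patient ids encode the class, so
    any downstream shuffling is explicit and seeded.
    """
    if n_per_class < 1:
        raise PhantomConfigError(f"n_per_class must be >= 1, got {n_per_class}")
    rng = np.random.default_rng(seed)
    sub_seeds = rng.integers(0, 2**31 - 1, size=2 * n_per_class)
    out: list[tuple[OCTVolume, GroundTruth]] = []
    for i in range(2 * n_per_class):
        label = "DME" if i < n_per_class else "normal"
        pid = f"{'dme' if label == 'DME' else 'nrm'}{i % n_per_class:03d}"
        vol, truth = generate_volume(spec, label, seed=int(sub_seeds[i]))
        vol.patient_id = pid
        truth.patient_id = pid
        out.append((vol, truth))
    return out
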