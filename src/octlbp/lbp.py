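"""Rotation-invariant uniform local binary patterns (LBP) in 2-D and on
three orthogonal planes (LBP-TOP).

The raw LBP code of a pixel compares the ``P`` bilinearly interpolated
intensities on the circle of radius ``R`` around it with the center value:

    LBP_{P,R} = sum_{p=0}^{P-1} s(g_p - g_c) 2^p,   s(x) = 1 iff x >= 0

(the sign function sets the bit on *equality*).  The rotation-invariant
uniform ("riu2") relabelling maps a raw code with at most two circular
0/1 transitions to its number of set bits (0..P), and every non-uniform
code to the single label ``P + 1``, giving ``P + 2`` distinct labels.

For a volume indexed ``(y, z, x)``, LBP-TOP computes independent 2-D riu2
maps on every (x-z) slice, every (x-y) slice and every (y-z) slice.  Code
maps are undefined within ``R`` pixels of each image border (no padding);
the accompanying validity masks exclude that margin.

Sampling-point / radius presets follow the standard pairs
``{(8, 1), (16, 2), (24, 3)}``; other combinations work but emit a warning.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LBPParams",
    "LBPMapSet",
    "STANDARD_PRESETS",
    "n_patterns",
    "sample_circle",
    "lbp_code",
    "riu2_label",
    "lbp_map_2d",
    "lbp_top_maps",
]

STANDARD_PRESETS: tuple[tuple[int, int], ...] = ((8, 1), (16, 2), (24, 3))

#: Plane order used everywhere a per-plane quantity is concatenated.
PLANES: tuple[str, str, str] = ("xz", "xy", "yz")


@dataclass
class LBPParams:
    """Descriptor configuration: ``P`` sampling points on a circle of
    radius ``R`` px, riu2 relabelling."""

    P: int = 8
    R: int = 1
    interpolation: str = "bilinear"  # or "nearest"

    def __post_init__(self) -> None:
        if self.P < 2 or self.R < 1:
            raise ValueError("need P >= 2 and R >= 1")
        if self.interpolation not in ("bilinear", "nearest"):
            raise ValueError("interpolation must be 'bilinear' or 'nearest'")
        if (self.P, self.R) not in STANDARD_PRESETS:
            warnings.warn(
                f"(P, R) = ({self.P}, {self.R}) is not one of the standard "
                f"presets {STANDARD_PRESETS}",
                stacklevel=2,
            )

    @property
    def n_patterns(self) -> int:
        return n_patterns(self.P)


@dataclass
class LBPMapSet:
    """riu2 code maps plus validity masks for one image or volume.

    ``planes`` maps a plane name to a code array:

    * 2-D LBP: ``{"xz": (d, H, W)}`` — one map per B-scan (a single 2-D map
      is stored as shape ``(1, H, W)``).
    * LBP-TOP: ``{"xz", "xy", "yz"}``, each stored *in volume coordinates*
      ``(d, H, W)`` so a voxel's three plane codes are co-indexed.

    ``masks`` holds same-shaped boolean arrays; codes are only defined where
    the mask is True (outside the R-pixel border of each constituent plane).
    Invalid positions carry code 0 and must be ignored via the mask.
    """

    planes: dict[str, np.ndarray]
    masks: dict[str, np.ndarray]
    params: LBPParams = field(default_factory=LBPParams)

    @property
    def feature(self) -> str:
        return "lbptop" if len(self.planes) == 3 else "lbp"

    @property
    def n_slices(self) -> int:
        return next(iter(self.planes.values())).shape[0]


def n_patterns(P: int) -> int:
    """Number of distinct riu2 labels for ``P`` sampling points: ``P + 2``
    (the uniform labels 0..P plus one bucket for all non-uniform codes)."""
    if P < 2:
        raise ValueError("P must be >= 2")
    return P + 2


def _circle_offsets(P: int, R: float) -> np.ndarray:
    """(row, col) offsets of the P sampling points: p = 0 at angle 0 (to the
    right), counter-clockwise; rows grow downwards so row offset is -R sin.
    Offsets within 1e-9 of the lattice are snapped so lattice-aligned
    angles need no interpolation."""
    p = np.arange(P)
    theta = 2.0 * math.pi * p / P
    offs = np.stack([-R * np.sin(theta), R * np.cos(theta)], axis=1)
    near = np.rint(offs)
    snap = np.abs(offs - near) < 1e-9
    offs[snap] = near[snap]
    return offs


def sample_circle(
    image: np.ndarray,
    center: tuple[int, int],
    P: int,
    R: float,
    interpolation: str = "bilinear",
) -> np.ndarray:
    """Sample the ``P`` circle neighbours of one pixel.

    Returns ``g_p`` for ``p = 0..P-1`` at angles ``2 pi p / P``, bilinearly
    interpolated (or nearest-neighbour if requested).  The center must be at
    least ``R`` pixels from every border.
    """
    image = np.asarray(image, dtype=np.float64)
    H, W = image.shape
    r, c = center
    if not (R <= r <= H - 1 - R and R <= c <= W - 1 - R):
        raise ValueError(f"center {center} within {R} px of the border")
    out = np.empty(P)
    for p, (dr, dc) in enumerate(_circle_offsets(P, R)):
        rr, cc = r + dr, c + dc
        if interpolation == "nearest":
            out[p] = image[int(round(rr)), int(round(cc))]
            continue
        r0, c0 = int(math.floor(rr)), int(math.floor(cc))
        fr, fc = rr - r0, cc - c0
        val = 0.0
        for ro, wr in ((0, 1.0 - fr), (1, fr)):
            for co, wc in ((0, 1.0 - fc), (1, fc)):
                if wr * wc:
                    val += wr * wc * image[r0 + ro, c0 + co]
        out[p] = val
    return out


def lbp_code(g_c: float, neighbors: np.ndarray) -> int:
    """Raw LBP pattern: bit ``p`` is set iff ``neighbors[p] >= g_c``."""
    code = 0
    for p, g_p in enumerate(neighbors):
        if g_p >= g_c:
            code |= 1 << p
    return code


def riu2_label(pattern: int, P: int) -> int:
    """Map a raw pattern to its riu2 label.

    Uniform patterns (<= 2 circular 0/1 transitions) map to their ones
    count in ``0..P``; all others collapse to ``P + 1``.
    """
    if not 0 <= pattern < (1 << P):
        raise ValueError(f"pattern {pattern} out of range for P={P}")
    bits = [(pattern >> p) & 1 for p in range(P)]
    transitions = sum(bits[p] != bits[(p + 1) % P] for p in range(P))
    return sum(bits) if transitions <= 2 else P + 1


def _shifted_interior(img: np.ndarray, dr: float, dc: float, R: int) -> np.ndarray:
    """Bilinear sample of ``img`` at ``(r + dr, c + dc)`` for every interior
    pixel ``(r, c)`` with ``R <= r < H - R``, ``R <= c < W - R``.

    Implemented as a weighted sum of up to four integer-shifted views;
    valid because ``|dr|, |dc| <= R``.
    """
    H, W = img.shape
    r0, c0 = int(math.floor(dr)), int(math.floor(dc))
    fr, fc = dr - r0, dc - c0
    out: np.ndarray | float = 0.0
    for ro, wr in ((r0, 1.0 - fr), (r0 + 1, fr)):
        if wr == 0.0:
            continue
        for co, wc in ((c0, 1.0 - fc), (c0 + 1, fc)):
            if wc == 0.0:
                continue
            out = out + wr * wc * img[R + ro : H - R + ro, R + co : W - R + co]
    return np.asarray(out)


def lbp_map_2d(
    image: np.ndarray, params: LBPParams
) -> tuple[np.ndarray, np.ndarray]:
    """riu2 code map of a 2-D image.

    Returns ``(codes, valid)`` with the image's shape: ``codes`` holds riu2
    labels in ``[0, P + 1]`` wherever ``valid`` is True (the interior beyond
    the R-pixel border) and 0 elsewhere.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError("image must be 2-D")
    P, R = params.P, params.R
    H, W = image.shape
    if H <= 2 * R + 1 or W <= 2 * R + 1:
        raise ValueError(f"image {image.shape} too small for R={R}")
    g_c = image[R : H - R, R : W - R]
    offsets = _circle_offsets(P, R)
    if params.interpolation == "nearest":
        offsets = np.rint(offsets)
    signs = [
        _shifted_interior(image, dr, dc, R) >= g_c for dr, dc in offsets
    ]
    ones = np.zeros(g_c.shape, dtype=np.uint8)
    transitions = np.zeros(g_c.shape, dtype=np.uint8)
    for p in range(P):
        ones += signs[p]
        transitions += signs[p] ^ signs[(p + 1) % P]
    interior = np.where(transitions <= 2, ones, P + 1)
    codes = np.zeros((H, W), dtype=np.uint8)
    codes[R : H - R, R : W - R] = interior
    valid = np.zeros((H, W), dtype=bool)
    valid[R : H - R, R : W - R] = True
    return codes, valid


def lbp_maps_per_slice(volume_voxels: np.ndarray, params: LBPParams) -> LBPMapSet:
    """2-D LBP maps of every (x-z) B-scan of a volume (the 2-D feature)."""
    vox = np.asarray(volume_voxels, dtype=np.float64)
    d = vox.shape[0]
    codes = np.empty(vox.shape, dtype=np.uint8)
    masks = np.empty(vox.shape, dtype=bool)
    for y in range(d):
        codes[y], masks[y] = lbp_map_2d(vox[y], params)
    return LBPMapSet(planes={"xz": codes}, masks={"xz": masks}, params=params)


def lbp_top_maps(volume_voxels: np.ndarray, params: LBPParams) -> LBPMapSet:
    """riu2 LBP maps on the three orthogonal planes of a volume.

    Independent 2-D maps are computed on every (x-z) slice (fixed y), every
    (x-y) slice (fixed z) and every (y-z) slice (fixed x); each plane's map
    stack is returned re-assembled in volume coordinates ``(d, H, W)``.
    """
    vox = np.asarray(volume_voxels, dtype=np.float64)
    if vox.ndim != 3:
        raise ValueError("volume must be 3-D (y, z, x)")
    d, H, W = vox.shape
    R = params.R
    if min(d, H, W) <= 2 * R + 1:
        raise ValueError(f"volume {vox.shape} too small for R={R}")

    planes: dict[str, np.ndarray] = {}
    masks: dict[str, np.ndarray] = {}

    xz_c = np.empty((d, H, W), dtype=np.uint8)
    xz_m = np.empty((d, H, W), dtype=bool)
    for y in range(d):
        xz_c[y], xz_m[y] = lbp_map_2d(vox[y], params)
    planes["xz"], masks["xz"] = xz_c, xz_m

    xy_c = np.empty((H, d, W), dtype=np.uint8)
    xy_m = np.empty((H, d, W), dtype=bool)
    for z in range(H):
        xy_c[z], xy_m[z] = lbp_map_2d(vox[:, z, :], params)
    planes["xy"] = xy_c.transpose(1, 0, 2)  # (d, H, W)
    masks["xy"] = xy_m.transpose(1, 0, 2)

    yz_c = np.empty((W, d, H), dtype=np.uint8)
    yz_m = np.empty((W, d, H), dtype=bool)
    for x in range(W):
        yz_c[x], yz_m[x] = lbp_map_2d(vox[:, :, x], params)
    planes["yz"] = yz_c.transpose(1, 2, 0)  # (d, H, W)
    masks["yz"] = yz_m.transpose(1, 2, 0)

    return LBPMapSet(planes=planes, masks=masks, params=params)
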