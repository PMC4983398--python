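"""Independent brute-force LBP reference used by the oracle-equivalence
tests.  Deliberately naive: per-pixel loops, its own bilinear interpolation
and its own uniformity counting — it shares no code path with the package's
vectorized implementation."""

from __future__ import annotations

import math

import numpy as np


def naive_sample(img: np.ndarray, r: float, c: float) -> float:
    r0, c0 = math.floor(r), math.floor(c)
    fr, fc = r - r0, c - c0
    total = 0.0
    for dr, wr in ((0, 1 - fr), (1, fr)):
        for dc, wc in ((0, 1 - fc), (1, fc)):
            if wr * wc:
                total += wr * wc * img[r0 + dr, c0 + dc]
    return total


def naive_riu2_at(img: np.ndarray, r: int, c: int, P: int, R: int) -> int:
    bits = []
    for p in range(P):
        theta = 2 * math.pi * p / P
        dr, dc = -R * math.sin(theta), R * math.cos(theta)
        if abs(dr - round(dr)) < 1e-9:
            dr = round(dr)
        if abs(dc - round(dc)) < 1e-9:
            dc = round(dc)
        g = naive_sample(img, r + dr, c + dc)
        bits.append(1 if g >= img[r, c] else 0)
    transitions = sum(bits[p] != bits[(p + 1) % P] for p in range(P))
    return sum(bits) if transitions <= 2 else P + 1


def naive_map(img: np.ndarray, P: int, R: int) -> tuple[np.ndarray, np.ndarray]:
    H, W = img.shape
    codes = np.zeros((H, W), dtype=np.uint8)
    valid = np.zeros((H, W), dtype=bool)
    for r in range(R, H - R):
        for c in range(R, W - R):
            codes[r, c] = naive_riu2_at(img, r, c, P, R)
            valid[r, c] = True
    return codes, valid


def naive_top_maps(vol: np.ndarray, P: int, R: int) -> dict[str, np.ndarray]:
    """Plane code cubes in volume coordinates (d, H, W), slicewise."""
    d, H, W = vol.shape
    xz = np.stack([naive_map(vol[y], P, R)[0] for y in range(d)])
    xy = np.stack([naive_map(vol[:, z, :], P, R)[0] for z in range(H)])
    yz = np.stack([naive_map(vol[:, :, x], P, R)[0] for x in range(W)])
    return {
        "xz": xz,
        "xy": xy.transpose(1, 0, 2),
        "yz": yz.transpose(1, 2, 0),
    }
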