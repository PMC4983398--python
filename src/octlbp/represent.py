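"""Mapping and representation of LBP code maps.

Two mapping strategies partition a volume's code maps into *elements*
before histogramming:

* **global** — one element per B-scan for 2-D LBP (``d`` elements for a
  ``d``-slice volume), or the whole volume as a single element for LBP-TOP;
* **local** — non-overlapping ``m x m`` patches per B-scan for 2-D LBP
  (``N x d`` elements) or ``m x m x m`` subvolumes for LBP-TOP (``N'``
  elements).  Grids are laid over the valid (border-unmasked) region and
  incomplete border cells are dropped.

Each element becomes a histogram over the ``P + 2`` riu2 labels; LBP-TOP
elements concatenate the three plane histograms in the fixed order
(x-z, x-y, y-z), i.e. length ``3 (P + 2)``.

The *low-level* volume descriptor is the concatenation of the global
elements' histograms (``d (P + 2)`` for LBP, ``3 (P + 2)`` for LBP-TOP).
The *high-level* descriptor quantizes the elements against a k-word visual
codebook (bag of visual words): each element is replaced by its nearest
word in Euclidean distance and the volume is described by the k-bin word
occurrence histogram.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans, kmeans_plusplus

from .lbp import PLANES, LBPMapSet

__all__ = [
    "MappingSpec",
    "ElementHistogramSet",
    "Codebook",
    "partition",
    "lowlevel_descriptor",
    "build_codebook",
    "encode_bow",
    "descriptor_length",
]

#: Codebook sizes swept by the word-count experiment.
K_SWEEP: tuple[int, ...] = (*range(10, 101, 10), *range(200, 501, 100), 1000)


@dataclass
class MappingSpec:
    """``mode="global"`` (per-slice / whole-volume elements) or
    ``mode="local"`` with patch / subvolume edge ``m`` px."""

    mode: str = "local"
    m: int = 7

    def __post_init__(self) -> None:
        if self.mode not in ("global", "local"):
            raise ValueError("mode must be 'global' or 'local'")
        if self.mode == "local" and self.m < 2:
            raise ValueError("local element edge m must be >= 2")


@dataclass
class ElementHistogramSet:
    """Per-element LBP-label histograms of one volume.

    ``histograms`` has shape ``(n_elements, L)`` with ``L = P + 2`` for 2-D
    LBP and ``L = 3 (P + 2)`` for LBP-TOP (plane blocks in x-z, x-y, y-z
    order).  Raw counts; each 2-D LBP histogram sums to the number of valid
    coded pixels in its element, each LBP-TOP plane block likewise.
    """

    histograms: np.ndarray
    feature: str  # "lbp" | "lbptop"
    mapping: MappingSpec
    n_labels: int  # P + 2

    @property
    def n_elements(self) -> int:
        return self.histograms.shape[0]


@dataclass
class Codebook:
    """k visual words in element-histogram space."""

    words: np.ndarray  # (k, L)
    build: str  # "kmeans" | "kmeans_pp_init_only" | "random"
    seed: int

    def __post_init__(self) -> None:
        self.words = np.asarray(self.words, dtype=np.float64)
        if not np.all(np.isfinite(self.words)):
            raise ValueError("codebook words must be finite")
        if self.words.shape[0] < 2:
            raise ValueError("codebook needs k >= 2 words")

    @property
    def k(self) -> int:
        return self.words.shape[0]


def _hist(codes: np.ndarray, n_labels: int) -> np.ndarray:
    return np.bincount(codes.ravel(), minlength=n_labels).astype(np.float64)


def _grid_cells(extent: int, m: int) -> int:
    return extent // m


def partition(maps: LBPMapSet, spec: MappingSpec) -> ElementHistogramSet:
    """Partition code maps into elements and histogram each one.

    See the module docstring for the element layout per (feature, mode).
    """
    L = maps.params.n_patterns
    R = maps.params.R
    if maps.feature == "lbp":
        codes = maps.planes["xz"]  # (d, H, W)
        d, H, W = codes.shape
        if spec.mode == "global":
            hists = np.stack(
                [_hist(codes[y, R : H - R, R : W - R], L) for y in range(d)]
            )
        else:
            m = spec.m
            vh, vw = H - 2 * R, W - 2 * R
            nr, nc = _grid_cells(vh, m), _grid_cells(vw, m)
            if nr < 1 or nc < 1:
                raise ValueError(
                    f"local element edge m={m} exceeds the valid map extent "
                    f"({vh} x {vw})"
                )
            core = codes[:, R : R + nr * m, R : R + nc * m]
            # (d, nr, m, nc, m) -> flatten cells, histogram each.
            cells = core.reshape(d, nr, m, nc, m).transpose(0, 1, 3, 2, 4)
            cells = cells.reshape(d * nr * nc, m * m)
            hists = _batch_hist(cells, L)
        return ElementHistogramSet(hists, "lbp", spec, L)

    # LBP-TOP: three co-indexed (d, H, W) code cubes.
    d, H, W = maps.planes["xz"].shape
    if spec.mode == "global":
        blocks = [
            _hist(maps.planes[pl][maps.masks[pl]], L) for pl in PLANES
        ]
        hists = np.concatenate(blocks)[None, :]
        return ElementHistogramSet(hists, "lbptop", spec, L)

    m = spec.m
    # Valid in all three orientations: R-border excluded along every axis.
    vd, vh, vw = d - 2 * R, H - 2 * R, W - 2 * R
    ny, nr, nc = _grid_cells(vd, m), _grid_cells(vh, m), _grid_cells(vw, m)
    if min(ny, nr, nc) < 1:
        raise ValueError(
            f"local element edge m={m} exceeds the valid volume extent "
            f"({vd} x {vh} x {vw})"
        )
    per_plane = []
    for pl in PLANES:
        core = maps.planes[pl][
            R : R + ny * m, R : R + nr * m, R : R + nc * m
        ]
        cells = core.reshape(ny, m, nr, m, nc, m).transpose(0, 2, 4, 1, 3, 5)
        cells = cells.reshape(ny * nr * nc, m**3)
        per_plane.append(_batch_hist(cells, L))
    hists = np.concatenate(per_plane, axis=1)  # (N', 3L)
    return ElementHistogramSet(hists, "lbptop", spec, L)


def _batch_hist(cells: np.ndarray, n_labels: int) -> np.ndarray:
    """Histogram every row of ``cells`` over labels ``0..n_labels-1``."""
    n = cells.shape[0]
    offset = (np.arange(n, dtype=np.int64)[:, None] * n_labels)
    flat = (cells.astype(np.int64) + offset).ravel()
    counts = np.bincount(flat, minlength=n * n_labels)
    return counts.reshape(n, n_labels).astype(np.float64)


def lowlevel_descriptor(
    elements: ElementHistogramSet, normalize: bool = False
) -> np.ndarray:
    """Concatenated-histogram descriptor (global mapping only).

    2-D LBP: the ``d`` per-slice histograms concatenated in slice order,
    length ``d (P + 2)``.  LBP-TOP: the single three-plane element, length
    ``3 (P + 2)``.  With ``normalize=True`` each constituent ``P + 2``-bin
    block is L1-normalized.
    """
    if elements.mapping.mode != "global":
        raise ValueError("the low-level descriptor is defined for global mapping")
    hists = elements.histograms
    if normalize:
        L = elements.n_labels
        blocks = hists.reshape(-1, L)
        sums = blocks.sum(axis=1, keepdims=True)
        sums[sums == 0] = 1.0
        hists = (blocks / sums).reshape(hists.shape)
    return hists.ravel()


def build_codebook(
    train_histograms: np.ndarray,
    k: int,
    build: str = "kmeans",
    seed: int = 0,
) -> Codebook:
    """Learn a k-word visual codebook from training element histograms.

    ``build``:

    * ``"kmeans"`` — full k-means (k-means++ init, single restart, max 300
      iterations, tol 1e-4);
    * ``"kmeans_pp_init_only"`` — the k-means++ seeding points without any
      Lloyd iterations (the cheap randomized codebook used for word-count
      sweeps);
    * ``"random"`` — k training histograms sampled uniformly without
      replacement.
    """
    X = np.asarray(train_histograms, dtype=np.float64)
    if X.ndim != 2:
        raise ValueError("train_histograms must be 2-D (n, L)")
    if X.shape[0] < k:
        raise ValueError(f"need at least k={k} training histograms, got {X.shape[0]}")
    if build == "kmeans":
        km = KMeans(
            n_clusters=k, init="k-means++", n_init=1, max_iter=300, tol=1e-4,
            random_state=seed,
        ).fit(X)
        words = km.cluster_centers_
    elif build == "kmeans_pp_init_only":
        words, _ = kmeans_plusplus(X, n_clusters=k, random_state=seed)
    elif build == "random":
        rng = np.random.default_rng(seed)
        words = X[rng.choice(X.shape[0], size=k, replace=False)]
    else:
        raise ValueError(f"unknown codebook build method {build!r}")
    return Codebook(words=words, build=build, seed=seed)


def encode_bow(
    elements: ElementHistogramSet | np.ndarray,
    codebook: Codebook,
    normalize: bool = False,
) -> np.ndarray:
    """Bag-of-words descriptor: k-bin histogram of nearest-word assignments.

    Each element histogram is assigned to its nearest codebook word in
    Euclidean distance (ties broken towards the lowest word index).  The raw
    output sums to the number of elements; ``normalize=True`` L1-normalizes.
    """
    hists = (
        elements.histograms
        if isinstance(elements, ElementHistogramSet)
        else np.asarray(elements, dtype=np.float64)
    )
    if hists.shape[1] != codebook.words.shape[1]:
        raise ValueError(
            f"element length {hists.shape[1]} != word length "
            f"{codebook.words.shape[1]}"
        )
    assign = np.argmin(cdist(hists, codebook.words), axis=1)
    bow = np.bincount(assign, minlength=codebook.k).astype(np.float64)
    if normalize and bow.sum() > 0:
        bow = bow / bow.sum()
    return bow


def descriptor_length(
    feature: str, mode: str, P: int, d: int | None = None,
    n_elements: int | None = None,
) -> int:
    """Length of the concatenated low-level descriptor for a volume.

    ``d (P + 2)`` for global 2-D LBP, ``3 (P + 2)`` for global LBP-TOP,
    ``n_elements (P + 2)`` for local 2-D LBP and ``n_elements 3 (P + 2)``
    for local LBP-TOP.
    """
    L = P + 2
    if mode == "global":
        if feature == "lbp":
            if d is None:
                raise ValueError("global LBP length needs d")
            return d * L
        return 3 * L
    if n_elements is None:
        raise ValueError("local length needs n_elements")
    return n_elements * (L if feature == "lbp" else 3 * L)
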