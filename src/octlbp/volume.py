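"""Core volumetric container shared by every pipeline stage.

An SD-OCT volume is a stack of ``d`` B-scans.  The axis convention used
throughout the package is ``voxels[y, z, x]``:

* ``y`` — slice index (which B-scan), ``0 <= y < d``
* ``z`` — depth row within a B-scan, ``0 <= z < H`` (z grows downwards,
  towards the choroid)
* ``x`` — lateral column within a B-scan, ``0 <= x < W``

A single B-scan is therefore the 2-D ``(z, x)`` array ``voxels[y]``.
Intensities are floating point in ``[0, 1]``; on-disk 8-bit quantization is
handled by :mod:`octlbp.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["OCTVolume"]


@dataclass
class OCTVolume:
    """A 3-D OCT intensity volume with patient metadata.

    Parameters
    ----------
    voxels:
        Array of shape ``(d, H, W)`` indexed ``(y, z, x)`` with values in
        ``[0, 1]``.
    patient_id:
        Identifier of the patient this volume was acquired from (one volume
        per patient).
    label:
        Optional class label, ``"normal"`` or ``"DME"``.
    provenance:
        Ordered, append-only list of the preprocessing step names already
        applied to ``voxels`` (e.g. ``["nlm", "flatten", "align"]``).
    """

    voxels: np.ndarray
    patient_id: str = ""
    label: str | None = None
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 3:
            raise ValueError(
                f"voxels must be 3-D (y, z, x); got shape {self.voxels.shape}"
            )
        if self.label is not None and self.label not in ("normal", "DME"):
            raise ValueError(f"label must be 'normal' or 'DME', got {self.label!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        """``(d, H, W)`` = (number of slices, depth rows, lateral columns)."""
        return self.voxels.shape  # type: ignore[return-value]

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]

    def slice(self, y: int) -> np.ndarray:
        """Return B-scan ``y`` as a 2-D ``(z, x)`` array (a view)."""
        return self.voxels[y]

    def with_voxels(self, voxels: np.ndarray, step: str) -> "OCTVolume":
        """Return a new volume with replaced voxels and ``step`` appended to
        the provenance trail."""
        return OCTVolume(
            voxels=voxels,
            patient_id=self.patient_id,
            label=self.label,
            provenance=[*self.provenance, step],
        )
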