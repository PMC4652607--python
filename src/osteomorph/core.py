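"""Core containers for voxel volumes and region-of-interest specifications.

All imaging operations in this package act on :class:`VoxelVolume`: a 3D
scalar grid (greyscale attenuation or a binary bone mask) tagged with its
physical voxel edge length in micrometres.  Axis 0 is, by convention, the
proximodistal (long) axis of the bone after reorientation; slice 0 is the
most proximal slice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

__all__ = ["VoxelVolume", "RoiSpec"]


@dataclass
class VoxelVolume:
    """A 3D image grid with isotropic physical voxel size.

    Parameters
    ----------
    data
        3D array.  Greyscale volumes keep their native dtype; binary
        volumes contain only {0, 1} (any integer or bool dtype).
    voxel_size
        Isotropic voxel edge length in micrometres (μm).  Anisotropic
        voxels are not supported.
    is_binary
        Whether ``data`` is a segmented mask.
    meta
        Free-form provenance metadata (applied rotations, ROI records,
        conventions used).  Carried through operations when practical.
    """

    data: np.ndarray
    voxel_size: float
    is_binary: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.data.ndim}")
        if min(self.data.shape) < 1:
            raise ValueError(f"all dimensions must be >= 1, got {self.data.shape}")
        if not (np.isfinite(self.voxel_size) and self.voxel_size > 0):
            raise ValueError(f"voxel_size must be positive, got {self.voxel_size}")
        if self.is_binary:
            vals = np.unique(self.data)
            if not np.isin(vals, (0, 1)).all():
                raise ValueError("binary volume contains values outside {0, 1}")

    # -- convenience -------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_slices(self) -> int:
        return self.data.shape[0]

    @property
    def voxel_volume_um3(self) -> float:
        """Physical volume of one voxel in μm³."""
        return float(self.voxel_size) ** 3

    def mask(self) -> np.ndarray:
        """Boolean view of a binary volume."""
        if not self.is_binary:
            raise ValueError("volume is greyscale, not binary")
        return self.data.astype(bool)

    def with_data(self, data: np.ndarray, *, is_binary: bool | None = None,
                  **meta) -> "VoxelVolume":
        """New volume sharing physical metadata, with updated meta entries."""
        merged = dict(self.meta)
        merged.update(meta)
        return VoxelVolume(
            data=data,
            voxel_size=self.voxel_size,
            is_binary=self.is_binary if is_binary is None else is_binary,
            meta=merged,
        )


@dataclass(frozen=True)
class RoiSpec:
    """Axial region-of-interest along the bone length.

    Three addressing modes mirror how sites are reported for long-bone
    CT work:

    ``fraction_range``
        ``start`` and ``extent`` are fractions of total length, e.g.
        the 10–90% diaphyseal window is ``start=0.10, extent=0.80``.
    ``fraction_point_plus_extent``
        ``start`` is a fraction of total length; ``extent`` is a slice
        count, e.g. a 100-slice stack at 37% of length.
    ``slice_count``
        ``start`` is an absolute reference slice index supplied by the
        user (anatomical landmarks are inputs, never detected) and
        ``extent`` a slice count, e.g. 300 slices from the
        tibia–fibula junction.

    Fraction-to-index conversion uses ``floor(start * total_length)``
    and half-open intervals ``[begin, begin + extent)``; slice 0 is the
    most proximal slice.  The convention is recorded so downstream
    reports can state exactly which slices were analysed.
    """

    mode: Literal["fraction_range", "fraction_point_plus_extent", "slice_count"]
    start: float
    extent: float
    reference: str = ""

    def __post_init__(self) -> None:
        if self.mode not in ("fraction_range", "fraction_point_plus_extent",
                             "slice_count"):
            raise ValueError(f"unknown ROI mode: {self.mode!r}")
        if self.mode == "fraction_range":
            if not (0.0 <= self.start <= self.start + self.extent <= 1.0):
                raise ValueError(
                    f"fraction range [{self.start}, {self.start + self.extent}] "
                    "must lie within [0, 1]")
        elif self.mode == "fraction_point_plus_extent":
            if not 0.0 <= self.start <= 1.0:
                raise ValueError(f"start fraction {self.start} outside [0, 1]")
            if self.extent < 1 or self.extent != int(self.extent):
                raise ValueError("extent must be a positive slice count")
        else:  # slice_count
            if self.start < 0 or self.start != int(self.start):
                raise ValueError("start must be a non-negative slice index")
            if self.extent < 1 or self.extent != int(self.extent):
                raise ValueError("extent must be a positive slice count")

    def to_slice_interval(self, total_length_slices: int) -> tuple[int, int]:
        """Resolve to a half-open slice interval ``[begin, end)``."""
        if total_length_slices < 1:
            raise ValueError("total_length_slices must be >= 1")
        if self.mode == "fraction_range":
            begin = int(np.floor(self.start * total_length_slices))
            end = int(np.floor((self.start + self.extent) * total_length_slices))
        elif self.mode == "fraction_point_plus_extent":
            begin = int(np.floor(self.start * total_length_slices))
            end = begin + int(self.extent)
        else:
            begin = int(self.start)
            end = begin + int(self.extent)
        return begin, end
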