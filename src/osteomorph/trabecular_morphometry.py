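"""Metaphyseal trabecular bone morphometry on a binary ROI."""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from skimage.measure import euler_number

from .core import VoxelVolume
from .cortical_geometry import local_thickness_map

__all__ = ["TrabecularIndices", "trabecular_indices", "trabecular_roi"]

_MM3_PER_UM3 = 1e-9
_MM_PER_UM = 1e-3


@dataclass
class TrabecularIndices:
    """Standard trabecular index vector.

    ``TV`` total ROI volume and ``BV`` bone volume (mm³), ``BV/TV`` in
    percent, ``Tb.Th``/``Tb.Sp`` mean 3D sphere-fitting local thickness
    of bone and marrow (mm), ``Tb.N = (BV/TV)/Tb.Th`` (mm⁻¹, the
    model-independent form), Euler characteristic χ of the bone phase
    and connectivity density ``Conn.Dn = (1 − χ)/TV`` (mm⁻³).
    """

    tv_mm3: float
    bv_mm3: float
    bv_tv_pct: float
    tb_th_mm: float
    tb_sp_mm: float
    tb_n_per_mm: float
    euler_chi: int
    conn_dn_per_mm3: float

    def to_series(self) -> pd.Series:
        names = {"tv_mm3": "TV", "bv_mm3": "BV", "bv_tv_pct": "BV/TV",
                 "tb_th_mm": "Tb.Th", "tb_sp_mm": "Tb.Sp",
                 "tb_n_per_mm": "Tb.N", "euler_chi": "Euler.chi",
                 "conn_dn_per_mm3": "Conn.Dn"}
        d = asdict(self)
        return pd.Series({v: d[k] for k, v in names.items()})


def trabecular_indices(roi: VoxelVolume,
                       roi_mask: VoxelVolume | None = None) -> TrabecularIndices:
    """Morphometric indices of a binary trabecular ROI.

    ``roi`` holds the bone voxels; ``roi_mask`` is the analysed
    envelope (endocortical contour supplied by the user, or the whole
    grid when omitted).  Bone must lie inside the mask.  χ is computed
    on the bone phase with 26-connectivity, without edge correction at
    the open slab faces.
    """
    bone = roi.mask()
    if roi_mask is None:
        mask = np.ones_like(bone)
    else:
        mask = roi_mask.mask()
        if roi_mask.voxel_size != roi.voxel_size or mask.shape != bone.shape:
            raise ValueError("roi and roi_mask must share grid and voxel size")
    if not mask.any():
        raise ValueError("empty ROI mask")
    if (bone & ~mask).any():
        raise ValueError("bone voxels outside the ROI mask")

    vs = roi.voxel_size
    tv = float(mask.sum()) * vs**3 * _MM3_PER_UM3
    bv = float(bone.sum()) * vs**3 * _MM3_PER_UM3
    bvtv = bv / tv

    if bone.any():
        th_map = local_thickness_map(bone)
        tb_th = float(th_map[bone].mean()) * vs * _MM_PER_UM
        marrow = mask & ~bone
        if marrow.any():
            sp_map = local_thickness_map(marrow)
            tb_sp = float(sp_map[marrow].mean()) * vs * _MM_PER_UM
        else:
            tb_sp = 0.0
        chi = int(euler_number(bone, connectivity=3))
        tb_n = bvtv / tb_th if tb_th > 0 else 0.0
    else:
        tb_th = tb_sp = tb_n = 0.0
        chi = 0
    return TrabecularIndices(
        tv_mm3=tv, bv_mm3=bv, bv_tv_pct=100.0 * bvtv,
        tb_th_mm=tb_th, tb_sp_mm=tb_sp, tb_n_per_mm=tb_n,
        euler_chi=chi, conn_dn_per_mm3=(1.0 - chi) / tv,
    )


def trabecular_roi(vol: VoxelVolume, bridge_slice: int,
                   total_length_slices: int | None = None) -> VoxelVolume:
    """Trabecular analysis slab below the metaphyseal reference slice.

    The reference (the trabecular "bridge" connecting the primary
    spongiosa islands) is supplied by the user; the slab spans 5% of
    total bone length from it toward the diaphysis:
    ``[bridge, bridge + round(0.05 · total_length))``.
    """
    total = vol.n_slices if total_length_slices is None else int(total_length_slices)
    extent = int(round(0.05 * total))
    end = bridge_slice + extent
    if bridge_slice < 0 or end > vol.n_slices:
        raise IndexError(
            f"trabecular ROI [{bridge_slice}, {end}) outside volume of "
            f"{vol.n_slices} slices")
    return vol.with_data(vol.data[bridge_slice:end],
                         roi={"mode": "trabecular_5pct",
                              "slices": [bridge_slice, end]})
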