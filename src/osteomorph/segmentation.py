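"""Thresholding, despeckling, component labeling and pore extraction.

Digital-topology conventions: bone (foreground) uses 26-connectivity,
pores/background use 6-connectivity — the standard dual pair that avoids
connectivity paradoxes on a cubic grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu

from .core import VoxelVolume

__all__ = [
    "ParticleSet",
    "threshold_global",
    "despeckle",
    "label_components",
    "extract_pores",
]

_STRUCT_26 = ndimage.generate_binary_structure(3, 3)
_STRUCT_6 = ndimage.generate_binary_structure(3, 1)


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 26:
        return _STRUCT_26
    if connectivity == 6:
        return _STRUCT_6
    raise ValueError(f"connectivity must be 6 or 26, got {connectivity}")


# ---------------------------------------------------------------------------
# thresholding
# ---------------------------------------------------------------------------

def threshold_global(vol: VoxelVolume, threshold: float | str) -> VoxelVolume:
    """Binarize a greyscale volume: foreground iff intensity >= threshold.

    ``threshold="otsu"`` derives the cut from the intensity histogram
    (between-class variance maximisation); a constant image raises
    ``ValueError``.
    """
    data = vol.data
    if isinstance(threshold, str):
        if threshold.lower() != "otsu":
            raise ValueError(f"unknown threshold mode {threshold!r}")
        if np.ptp(data) == 0:
            raise ValueError("cannot compute Otsu threshold of a constant image")
        # threshold_otsu returns t with foreground = (I > t); our convention
        # is >=, which coincides for any t strictly between histogram levels
        t = float(threshold_otsu(data))
        mask = data > t
    else:
        t = float(threshold)
        mask = data >= t
    return vol.with_data(mask.astype(np.uint8), is_binary=True, threshold=t)


# ---------------------------------------------------------------------------
# despeckling
# ---------------------------------------------------------------------------

def despeckle(vol: VoxelVolume, min_size: int, phase: str = "foreground") -> VoxelVolume:
    """Remove connected components strictly smaller than ``min_size`` voxels.

    ``phase`` selects which phase is cleaned: ``"foreground"`` removes
    small islands (26-connectivity); ``"background"`` fills small
    enclosed holes (6-connectivity).  The other phase is untouched, and
    the operation is idempotent.
    """
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    mask = vol.mask()
    if phase == "foreground":
        work, struct, fill_value = mask, _STRUCT_26, False
    elif phase == "background":
        work, struct, fill_value = ~mask, _STRUCT_6, True
    else:
        raise ValueError(f"phase must be 'foreground' or 'background', got {phase!r}")
    labels, n = ndimage.label(work, structure=struct)
    if n:
        counts = np.bincount(labels.ravel())
        small = counts < min_size
        small[0] = False
        mask = mask.copy()
        mask[small[labels]] = fill_value
    return vol.with_data(mask.astype(np.uint8),
                         despeckle={"min_size": min_size, "phase": phase})


# ---------------------------------------------------------------------------
# connected-component particle analysis
# ---------------------------------------------------------------------------

@dataclass
class ParticleSet:
    """Labeled connected components with per-particle statistics.

    ``labels`` is the 3D integer label grid (0 = background; labels are
    assigned in raster order of each component's first voxel, so the
    decomposition is deterministic).  ``particles`` has one row per
    component: ``voxel_count``, ``volume_um3``, centroid (voxel
    coordinates), bounding box, ``touches_boundary``.
    ``second_moments`` holds each particle's central second-moment
    matrix (3x3, μm², per unit mass) including the voxel self-moment
    ``voxel_size²/12 · I`` — symmetric positive definite.
    """

    labels: np.ndarray
    voxel_size: float
    particles: pd.DataFrame
    second_moments: np.ndarray  # (n, 3, 3), μm²
    connectivity: int

    def __len__(self) -> int:
        return len(self.particles)

    @property
    def n_particles(self) -> int:
        return len(self.particles)

    def mask(self) -> np.ndarray:
        return self.labels > 0

    def select(self, keep: np.ndarray) -> "ParticleSet":
        """Subset to particles where ``keep`` is True (re-labeled 1..k)."""
        keep = np.asarray(keep, dtype=bool)
        old_ids = self.particles.index.to_numpy()[keep]
        lut = np.zeros(int(self.labels.max()) + 1, dtype=self.labels.dtype)
        lut[old_ids] = np.arange(1, keep.sum() + 1)
        new_particles = self.particles.loc[old_ids].reset_index(drop=True)
        new_particles.index = pd.RangeIndex(1, len(new_particles) + 1)
        return ParticleSet(
            labels=lut[self.labels],
            voxel_size=self.voxel_size,
            particles=new_particles,
            second_moments=self.second_moments[keep],
            connectivity=self.connectivity,
        )


def label_components(vol: VoxelVolume, connectivity: int = 26) -> ParticleSet:
    """Label maximal connected components and compute particle statistics."""
    mask = vol.mask()
    labels, n = ndimage.label(mask, structure=_structure(connectivity))
    vs = float(vol.voxel_size)
    if n == 0:
        empty = pd.DataFrame(columns=[
            "voxel_count", "volume_um3", "centroid_z", "centroid_y", "centroid_x",
            "bbox_z0", "bbox_y0", "bbox_x0", "bbox_z1", "bbox_y1", "bbox_x1",
            "touches_boundary"])
        return ParticleSet(labels, vs, empty, np.empty((0, 3, 3)), connectivity)

    idx = np.arange(1, n + 1)
    counts = ndimage.sum_labels(np.ones_like(labels, dtype=np.float64), labels, idx)
    zz, yy, xx = np.meshgrid(*(np.arange(s, dtype=np.float64) for s in mask.shape),
                             indexing="ij")
    sums = {}
    for name, arr in (("z", zz), ("y", yy), ("x", xx)):
        sums[name] = ndimage.sum_labels(arr, labels, idx)
    cz, cy, cx = (sums[k] / counts for k in ("z", "y", "x"))
    # raw second moments, then central
    prod = {}
    for (a, arr_a), (b, arr_b) in (
            (("z", zz), ("z", zz)), (("y", yy), ("y", yy)), (("x", xx), ("x", xx)),
            (("z", zz), ("y", yy)), (("z", zz), ("x", xx)), (("y", yy), ("x", xx))):
        prod[a + b] = ndimage.sum_labels(arr_a * arr_b, labels, idx)
    c = {"z": cz, "y": cy, "x": cx}
    moments = np.empty((n, 3, 3))
    names = ("z", "y", "x")
    for i, a in enumerate(names):
        for j, b in enumerate(names):
            key = a + b if a + b in prod else b + a
            cov = prod[key] / counts - c[a] * c[b]
            if i == j:
                cov = cov + 1.0 / 12.0  # voxel self-moment
            moments[:, i, j] = cov * vs * vs

    objs = ndimage.find_objects(labels)
    bbox = np.array([[s[0].start, s[1].start, s[2].start,
                      s[0].stop, s[1].stop, s[2].stop] for s in objs])
    shape = np.asarray(mask.shape)
    touches = (bbox[:, :3] == 0).any(axis=1) | (bbox[:, 3:] == shape).any(axis=1)

    particles = pd.DataFrame({
        "voxel_count": counts.astype(int),
        "volume_um3": counts * vs**3,
        "centroid_z": cz, "centroid_y": cy, "centroid_x": cx,
        "bbox_z0": bbox[:, 0], "bbox_y0": bbox[:, 1], "bbox_x0": bbox[:, 2],
        "bbox_z1": bbox[:, 3], "bbox_y1": bbox[:, 4], "bbox_x1": bbox[:, 5],
        "touches_boundary": touches,
    }, index=pd.RangeIndex(1, n + 1))
    return ParticleSet(labels, vs, particles, moments, connectivity)


# ---------------------------------------------------------------------------
# pore extraction
# ---------------------------------------------------------------------------

def extract_pores(cortex_bone: VoxelVolume) -> tuple[VoxelVolume, dict]:
    """Enclosed intracortical void space of a binarized cortical slab.

    The complement of the bone is partitioned into 6-connected
    components; components reaching the slab's in-plane outer faces are
    the exterior, and components spanning both axial end faces are the
    marrow cavity (the slab ends are open).  Components touching exactly
    one axial face are pores censored by the analysis window: they are
    excluded from the mask and counted.  What remains — void fully
    enclosed by bone — is the pore space.

    Returns the binary pore volume and an info dict with
    ``n_excluded_axial`` (censored pores), ``n_pore_components`` and
    ``excluded_voxels``.
    """
    bone = cortex_bone.mask()
    if not bone.any():
        raise ValueError("empty bone mask")
    void = ~bone
    labels, n = ndimage.label(void, structure=_STRUCT_6)

    def face_labels(sl) -> set[int]:
        return set(np.unique(labels[sl])) - {0}

    in_plane = (face_labels(np.s_[:, 0, :]) | face_labels(np.s_[:, -1, :])
                | face_labels(np.s_[:, :, 0]) | face_labels(np.s_[:, :, -1]))
    top, bottom = face_labels(np.s_[0]), face_labels(np.s_[-1])
    marrow = (top & bottom) - in_plane
    censored = ((top | bottom) - (top & bottom)) - in_plane

    keep = np.ones(n + 1, dtype=bool)
    keep[0] = False
    for s in (in_plane, marrow, censored):
        for lab in s:
            keep[lab] = False
    pores = keep[labels]
    excluded_voxels = int(sum(np.count_nonzero(labels == lab) for lab in censored))
    info = {
        "n_excluded_axial": len(censored),
        "n_pore_components": int(keep.sum()),
        "excluded_voxels": excluded_voxels,
    }
    return cortex_bone.with_data(pores.astype(np.uint8), pore_extraction=info), info
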