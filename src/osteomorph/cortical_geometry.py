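"""Cross-sectional slice geometry, 3D local thickness, anisotropy and TMD.

Per-slice indices follow the conventions of cross-sectional bone
geometry: CSA and B.Ar are the bone area of the section, Imin/Imax the
second moments of area about the principal centroidal axes (each voxel
treated as a unit square with its 1/12 self-moment), and the polar
moment their sum.  Whole-bone profiles evaluate these at percent-length
stations over the 10-90% diaphyseal window.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import VoxelVolume

__all__ = [
    "SliceGeometry",
    "CalibrationLine",
    "slice_geometry",
    "whole_bone_profile",
    "local_thickness_map",
    "local_thickness_3d",
    "degree_of_anisotropy",
    "tmd_calibrate",
    "tmd_apply",
]

_UM_PER_MM = 1000.0


# ---------------------------------------------------------------------------
# local thickness (Hildebrand–Rüegsegger sphere fitting)
# ---------------------------------------------------------------------------

def local_thickness_map(mask: np.ndarray, *, bin_width: float = 0.5) -> np.ndarray:
    """Sphere-fitting local thickness of a binary structure, in voxels.

    The thickness at a foreground point is the diameter of the largest
    inscribed sphere (fully inside the structure) that contains the
    point.  Computed by the classic two-step construction: the Euclidean
    distance transform gives the largest centred sphere at every voxel,
    and spheres are then propagated outward — voxels covered by a sphere
    inherit its diameter if larger.

    Sphere radii are processed in descending bins of ``bin_width``
    voxels; coverage per bin is resolved with one distance transform, so
    the result is exact to within one bin (default half a voxel).
    Works for 2D or 3D masks.
    """
    mask = np.asarray(mask, dtype=bool)
    out = np.zeros(mask.shape, dtype=np.float64)
    if not mask.any():
        return out
    dt = ndimage.distance_transform_edt(mask)
    r_max = float(dt.max())
    edges = np.arange(0.0, r_max + bin_width, bin_width)[::-1]
    unassigned = mask.copy()
    for r_hi in edges[:-1]:
        r_lo = r_hi - bin_width
        sources = (dt > r_lo) & (dt <= r_hi)
        if not sources.any():
            continue
        reach = ndimage.distance_transform_edt(~sources) <= r_hi
        newly = reach & unassigned
        out[newly] = 2.0 * r_hi
        unassigned &= ~newly
        if not unassigned.any():
            break
    return out


def local_thickness_3d(vol: VoxelVolume | np.ndarray,
                       voxel_size: float | None = None) -> tuple[np.ndarray, float]:
    """3D local-thickness map and its foreground mean, in μm.

    Accepts a binary :class:`VoxelVolume` (voxel size taken from it) or
    a bare mask plus ``voxel_size``.
    """
    if isinstance(vol, VoxelVolume):
        mask, vs = vol.mask(), vol.voxel_size
    else:
        mask = np.asarray(vol, dtype=bool)
        vs = 1.0 if voxel_size is None else float(voxel_size)
    th = local_thickness_map(mask) * vs
    mean = float(th[mask].mean()) if mask.any() else 0.0
    return th, mean


# ---------------------------------------------------------------------------
# slice geometry
# ---------------------------------------------------------------------------

@dataclass
class SliceGeometry:
    """Cross-sectional geometry of one transverse section.

    Physical fields are in mm / mm² / mm⁴; ``position`` is percent of
    bone length when produced by :func:`whole_bone_profile`.
    """

    csa_mm2: float          # bone cross-sectional area
    bone_area_mm2: float    # B.Ar (== CSA for a binary bone section)
    centroid_mm: tuple[float, float]
    imin_mm4: float
    imax_mm4: float
    polar_mmi_mm4: float    # Imin + Imax
    ct_th_2d_mm: float      # mean 2D local thickness
    eccentricity: float     # sqrt(1 - Imin/Imax) of the inertia ellipse
    total_porosity_pct: float
    envelope_area_mm2: float
    position: float | None = None

    def as_dict(self) -> dict:
        return asdict(self)


def _section_moments(section: np.ndarray) -> tuple[float, float, np.ndarray, int]:
    """(Imin, Imax, centroid, n) in voxel units about principal centroidal axes."""
    ys, xs = np.nonzero(section)
    n = len(ys)
    cy, cx = ys.mean(), xs.mean()
    dy, dx = ys - cy, xs - cx
    ix = float(dy @ dy) + n / 12.0   # ∫ y² dA
    iy = float(dx @ dx) + n / 12.0   # ∫ x² dA
    ixy = float(dx @ dy)
    tensor = np.array([[ix, -ixy], [-ixy, iy]])
    imin, imax = np.linalg.eigvalsh(tensor)
    return float(imin), float(imax), np.array([cy, cx]), n


def _envelope_and_porosity(section: np.ndarray) -> tuple[int, float]:
    """(envelope area voxels, total porosity %) of a 2D section.

    The cortical envelope is the filled periosteal contour minus the
    marrow cavity, taken as the largest enclosed void; intracortical
    voids (pores) stay inside the envelope, so
    Tot.Po = 100 · (1 − B.Ar / envelope).
    """
    fill = ndimage.binary_fill_holes(section)
    voids = fill & ~section
    labels, n = ndimage.label(voids, structure=ndimage.generate_binary_structure(2, 1))
    if n:
        counts = np.bincount(labels.ravel())[1:]
        marrow_label = int(np.argmax(counts)) + 1
        envelope = fill & (labels != marrow_label)
    else:
        envelope = fill
    env_area = int(envelope.sum())
    bone_area = int(section.sum())
    tot_po = 100.0 * (1.0 - bone_area / env_area) if env_area else 0.0
    return env_area, tot_po


def slice_geometry(section: np.ndarray, voxel_size: float,
                   position: float | None = None) -> SliceGeometry:
    """Geometry of a single 2D binary section (voxel size in μm)."""
    section = np.asarray(section).astype(bool)
    if section.ndim != 2:
        raise ValueError("section must be 2D")
    if not section.any():
        raise ValueError("empty section")
    imin, imax, centroid, n = _section_moments(section)
    th2d = local_thickness_map(section)
    mean_th = float(th2d[section].mean())
    env_area, tot_po = _envelope_and_porosity(section)
    ecc = float(np.sqrt(max(0.0, 1.0 - imin / imax))) if imax > 0 else 0.0

    mm = voxel_size / _UM_PER_MM
    return SliceGeometry(
        csa_mm2=n * mm**2,
        bone_area_mm2=n * mm**2,
        centroid_mm=(centroid[0] * mm, centroid[1] * mm),
        imin_mm4=imin * mm**4,
        imax_mm4=imax * mm**4,
        polar_mmi_mm4=(imin + imax) * mm**4,
        ct_th_2d_mm=mean_th * mm,
        eccentricity=ecc,
        total_porosity_pct=tot_po,
        envelope_area_mm2=env_area * mm**2,
        position=position,
    )


def whole_bone_profile(vol: VoxelVolume,
                       stations: Sequence[float] | None = None,
                       *,
                       total_length_slices: int | None = None) -> pd.DataFrame:
    """Per-station slice geometry along the diaphysis.

    ``stations`` are percent-of-length positions in [10, 90] (default
    1% steps); each is mapped to the nearest slice of the full bone
    length (no averaging window).  Returns one row per station with the
    :class:`SliceGeometry` fields.
    """
    if stations is None:
        stations = np.arange(10.0, 90.0 + 1e-9, 1.0)
    stations = np.asarray(stations, dtype=float)
    if stations.min() < 10.0 - 1e-9 or stations.max() > 90.0 + 1e-9:
        raise ValueError("stations must lie within [10, 90] percent of length")
    total = vol.n_slices if total_length_slices is None else total_length_slices
    rows = []
    for p in stations:
        k = int(round(p / 100.0 * (total - 1)))
        if not 0 <= k < vol.n_slices:
            raise IndexError(f"station {p}% maps to slice {k} outside the volume")
        geo = slice_geometry(vol.data[k].astype(bool), vol.voxel_size, position=p)
        row = geo.as_dict()
        row["slice_index"] = k
        del row["centroid_mm"]
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# degree of anisotropy (mean intercept length)
# ---------------------------------------------------------------------------

def _fibonacci_hemisphere(n: int) -> np.ndarray:
    """Quasi-uniform directions on the upper hemisphere (antipodes merged)."""
    i = np.arange(n) + 0.5
    phi = np.pi * (1 + 5**0.5) * i
    z = i / n  # upper hemisphere only: MIL is antipodally symmetric
    r = np.sqrt(1 - z**2)
    return np.stack([z, r * np.cos(phi), r * np.sin(phi)], axis=1)


def degree_of_anisotropy(vol: VoxelVolume, n_directions: int = 128,
                         seed: int | np.random.Generator = 0,
                         n_lines: int = 64, step: float = 0.5) -> float:
    """Degree of anisotropy from the mean-intercept-length (MIL) ellipsoid.

    For each of ``n_directions`` quasi-uniform (Fibonacci-sphere)
    directions, parallel test lines with seeded random offsets are
    traced through the volume; MIL(n) = bone length / number of
    bone-void intercepts.  The MIL ellipsoid is fitted as the quadric
    ``nᵀ H n = 1 / MIL(n)²`` and

        DA = 1 − MIL_min / MIL_max ∈ [0, 1)

    with MIL extremes from the ellipsoid's principal semi-axes
    ``1/√(eig H)``.  Deterministic for a fixed seed.
    """
    if n_directions < 3:
        raise ValueError("need at least 3 directions")
    rng = np.random.default_rng(seed)
    mask = vol.mask()
    shape = np.asarray(mask.shape, dtype=float)
    center = (shape - 1) / 2.0
    radius = float(np.linalg.norm(shape)) / 2.0
    n_steps = int(2 * radius / step) + 1
    t = (np.arange(n_steps) - n_steps / 2) * step

    dirs = _fibonacci_hemisphere(n_directions)
    mils = []
    used_dirs = []
    for d in dirs:
        # orthonormal frame (d, u, v); lines offset within the section plane
        u = np.cross(d, [1.0, 0.0, 0.0])
        if np.linalg.norm(u) < 1e-8:
            u = np.cross(d, [0.0, 1.0, 0.0])
        u /= np.linalg.norm(u)
        v = np.cross(d, u)
        off = rng.uniform(-radius, radius, size=(n_lines, 2))
        origins = center + off[:, :1] * u + off[:, 1:] * v     # (L, 3)
        pts = origins[:, None, :] + t[None, :, None] * d        # (L, S, 3)
        idx = np.round(pts).astype(int)
        inside = np.all((idx >= 0) & (idx < np.asarray(mask.shape)), axis=-1)
        vals = np.zeros(inside.shape, dtype=bool)
        ii = idx[inside]
        vals[inside] = mask[ii[:, 0], ii[:, 1], ii[:, 2]]
        bone_len = vals.sum() * step
        intercepts = np.count_nonzero(vals[:, 1:] & ~vals[:, :-1])
        if intercepts > 0:
            mils.append(bone_len / intercepts)
            used_dirs.append(d)
    if len(mils) < 6:
        raise ValueError("too few intercepts to fit a MIL ellipsoid")
    mils = np.asarray(mils)
    D = np.asarray(used_dirs)
    # design matrix for symmetric quadric n'Hn = 1/MIL²
    z, y, x = D[:, 0], D[:, 1], D[:, 2]
    A = np.stack([z * z, y * y, x * x, 2 * z * y, 2 * z * x, 2 * y * x], axis=1)
    coef, *_ = np.linalg.lstsq(A, 1.0 / mils**2, rcond=None)
    H = np.array([[coef[0], coef[3], coef[4]],
                  [coef[3], coef[1], coef[5]],
                  [coef[4], coef[5], coef[2]]])
    evals = np.linalg.eigvalsh(H)
    evals = np.clip(evals, 1e-12, None)
    mil_axes = 1.0 / np.sqrt(evals)  # descending MIL for ascending eigenvalue
    return float(1.0 - mil_axes.min() / mil_axes.max())


# ---------------------------------------------------------------------------
# tissue mineral density calibration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CalibrationLine:
    """Affine attenuation → mineral density map from two HA phantoms."""

    slope: float
    intercept: float

    def density(self, attenuation: float) -> float:
        return self.slope * attenuation + self.intercept


def tmd_calibrate(phantom_means: tuple[float, float],
                  densities: tuple[float, float] = (0.25, 0.75)) -> CalibrationLine:
    """Two-point calibration line through the phantom measurements.

    ``phantom_means`` are the mean interior attenuations of the two
    hydroxyapatite rods of known density (default 0.25 and 0.75 g/cm³).
    The line reproduces both points exactly; equal attenuations (or a
    non-positive slope, which is physically meaningless) raise
    ``ValueError``.
    """
    (a1, a2), (d1, d2) = phantom_means, densities
    if a1 == a2:
        raise ValueError("phantom attenuations must be distinct")
    slope = (d2 - d1) / (a2 - a1)
    if slope <= 0:
        raise ValueError("calibration slope must be positive "
                         "(denser phantom must attenuate more)")
    return CalibrationLine(slope=slope, intercept=d1 - slope * a1)


def tmd_apply(line: CalibrationLine, roi_mean_attenuation: float) -> float:
    """Tissue mineral density (g/cm³) of an ROI's mean bone attenuation."""
    return line.density(roi_mean_attenuation)
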