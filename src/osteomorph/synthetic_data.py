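"""Synthetic bone volumes with analytic ground truth.

Every stage of the morphometry pipeline is exercised against volumes
generated here: hollow cortical shells with known cross-sectional
geometry, planted ellipsoidal lacunae and tubular canals, trabecular rod
lattices of known volume fraction and topology, density-calibration
phantom cylinders, and simulated genotype x age cohort tables.

Rasterization uses center-of-voxel inclusion throughout: a voxel is
solid iff its center lies inside the analytic body.  Defaults mirror the
two imaging scales of murine tibial CT work: 5 μm voxels for whole-bone
microCT and 0.6 μm voxels for nanoCT of the lacunar-canal network, so
the physical 13/1500 μm³ pore-class thresholds are exercised at
realistic scales.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import VoxelVolume

__all__ = [
    "PlantedPoreSpec",
    "CohortSpec",
    "make_cortical_shell",
    "plant_pores",
    "random_pore_specs",
    "make_porous_shell",
    "make_trabecular_lattice",
    "make_solid_torus",
    "make_ball",
    "make_slab",
    "make_hollow_cylinder",
    "rasterize_ellipsoid",
    "make_phantoms",
    "simulate_cohort",
]

#: physical pore-class thresholds, μm³ (noise < 13 <= lacuna <= 1500 < canal)
NOISE_MAX_UM3 = 13.0
CANAL_MIN_UM3 = 1500.0


# ---------------------------------------------------------------------------
# planted pore specifications
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedPoreSpec:
    """One pore to carve out of a cortical shell.

    ``kind`` selects the geometry: ``"lacuna"`` is an ellipsoid with
    semi-axes ``radii_um`` (μm, sorted or not); ``"canal"`` a finite
    cylinder of ``radius_um`` x ``length_um`` along unit ``direction``;
    ``"noise"`` a tiny ball of ``radius_um`` (sub-voxel radii carve a
    single voxel).  ``center`` is in voxel coordinates of the host
    volume.
    """

    kind: str  # lacuna | canal | noise
    center: tuple[float, float, float]
    radii_um: tuple[float, float, float] | None = None
    radius_um: float | None = None
    length_um: float | None = None
    direction: tuple[float, float, float] = (1.0, 0.0, 0.0)

    def analytic_volume_um3(self) -> float:
        if self.kind == "lacuna":
            a, b, c = self.radii_um
            return 4.0 / 3.0 * np.pi * a * b * c
        if self.kind == "canal":
            return float(np.pi * self.radius_um**2 * self.length_um)
        if self.kind == "noise":
            return 4.0 / 3.0 * np.pi * self.radius_um**3
        raise ValueError(f"unknown pore kind {self.kind!r}")

    def target_class(self) -> str:
        """Pore class implied by the analytic volume (13/1500 μm³ rule)."""
        v = self.analytic_volume_um3()
        if v < NOISE_MAX_UM3:
            return "noise"
        if v > CANAL_MIN_UM3:
            return "canal"
        return "lacuna"

    def validate(self) -> None:
        cls = self.target_class()
        if cls != self.kind and not (self.kind == "noise" and cls == "noise"):
            raise ValueError(
                f"{self.kind} spec has analytic volume "
                f"{self.analytic_volume_um3():.1f} μm³, which classifies as {cls}")


# ---------------------------------------------------------------------------
# rasterization primitives (center-of-voxel)
# ---------------------------------------------------------------------------

def _grid(shape: tuple[int, int, int]):
    return np.meshgrid(*(np.arange(n, dtype=float) for n in shape), indexing="ij")


def rasterize_ellipsoid(semi_axes_vox: Sequence[float],
                        shape: tuple[int, int, int] | None = None,
                        center: Sequence[float] | None = None,
                        orientation: np.ndarray | None = None) -> np.ndarray:
    """Boolean mask of an ellipsoid; semi-axes in voxels.

    ``orientation`` columns are the ellipsoid's principal directions
    (defaults to grid-aligned axes).
    """
    a = np.asarray(semi_axes_vox, dtype=float)
    if shape is None:
        ext = int(np.ceil(a.max())) + 2
        shape = (2 * ext + 1,) * 3
    if center is None:
        center = (np.asarray(shape) - 1) / 2.0
    zz, yy, xx = _grid(shape)
    pts = np.stack([zz - center[0], yy - center[1], xx - center[2]], axis=-1)
    if orientation is not None:
        pts = pts @ orientation  # project onto principal directions
    return (np.square(pts / a).sum(axis=-1)) <= 1.0


def make_ball(radius_vox: float, shape: tuple[int, int, int] | None = None,
              center: Sequence[float] | None = None) -> np.ndarray:
    return rasterize_ellipsoid([radius_vox] * 3, shape=shape, center=center)


def make_slab(thickness_vox: int, lateral: int = 40,
              pad: int = 6) -> np.ndarray:
    """Flat slab of given thickness along axis 0, padded with background."""
    vol = np.zeros((thickness_vox + 2 * pad, lateral, lateral), dtype=bool)
    vol[pad:pad + thickness_vox] = True
    return vol


def make_hollow_cylinder(outer_radius_vox: float, inner_radius_vox: float,
                         length: int, pad: int = 3) -> np.ndarray:
    """Axis-0-aligned hollow cylinder (annular cross-section)."""
    n = int(np.ceil(2 * outer_radius_vox)) + 2 * pad + 1
    c = (n - 1) / 2.0
    yy, xx = np.meshgrid(np.arange(n, dtype=float), np.arange(n, dtype=float),
                         indexing="ij")
    d2 = (yy - c) ** 2 + (xx - c) ** 2
    ring = (d2 <= outer_radius_vox**2) & (d2 > inner_radius_vox**2)
    return np.broadcast_to(ring, (length,) + ring.shape).copy()


def make_solid_torus(major_radius_vox: float, minor_radius_vox: float,
                     pad: int = 3) -> np.ndarray:
    """Solid torus about axis 0 (χ = 0, one loop)."""
    r_out = major_radius_vox + minor_radius_vox
    n = int(np.ceil(2 * r_out)) + 2 * pad + 1
    h = int(np.ceil(2 * minor_radius_vox)) + 2 * pad + 1
    cz, cy = (h - 1) / 2.0, (n - 1) / 2.0
    zz, yy, xx = _grid((h, n, n))
    rho = np.sqrt((yy - cy) ** 2 + (xx - cy) ** 2)
    return (zz - cz) ** 2 + (rho - major_radius_vox) ** 2 <= minor_radius_vox**2


# ---------------------------------------------------------------------------
# cortical shell
# ---------------------------------------------------------------------------

def make_cortical_shell(
    length: int,
    outer_radius: float | Sequence[float],
    inner_radius: float | Sequence[float],
    *,
    voxel_size: float = 0.6,
    curvature: Sequence[Sequence[float]] | None = None,
    pad: int = 3,
) -> tuple[VoxelVolume, pd.DataFrame]:
    """Hollow tube emulating a tibial diaphysis, with analytic ground truth.

    Parameters
    ----------
    length
        Number of slices along axis 0.
    outer_radius, inner_radius
        Scalars or per-slice arrays, in voxels.  ``outer > inner > 0``
        everywhere.
    curvature
        Optional per-slice in-plane centroid drift ``(dy, dz)`` in
        voxels, emulating the bone's natural curvature.
    pad
        Background margin around the largest cross-section.

    Returns
    -------
    vol, truth
        Binary volume and a per-slice DataFrame with analytic
        cross-sectional area (``csa_vox2``), principal second moments of
        area (``imin_vox4``/``imax_vox4``), polar moment, wall thickness
        (voxels), and centroid, for the ideal annulus of each slice.
    """
    R = np.broadcast_to(np.asarray(outer_radius, dtype=float), (length,))
    r = np.broadcast_to(np.asarray(inner_radius, dtype=float), (length,))
    if np.any(r <= 0) or np.any(R <= r):
        raise ValueError("radius profiles must satisfy outer > inner > 0")
    drift = np.zeros((length, 2)) if curvature is None else np.asarray(curvature, float)
    if drift.shape != (length, 2):
        raise ValueError(f"curvature must have shape ({length}, 2)")

    half = R.max() + np.abs(drift).max() + pad
    n = int(np.ceil(2 * half)) + 1
    c = (n - 1) / 2.0
    yy, xx = np.meshgrid(np.arange(n, dtype=float), np.arange(n, dtype=float),
                         indexing="ij")
    data = np.zeros((length, n, n), dtype=np.uint8)
    for k in range(length):
        cy, cx = c + drift[k, 0], c + drift[k, 1]
        d2 = (yy - cy) ** 2 + (xx - cx) ** 2
        data[k] = ((d2 <= R[k] ** 2) & (d2 > r[k] ** 2)).astype(np.uint8)

    i_annulus = np.pi * (R**4 - r**4) / 4.0
    truth = pd.DataFrame({
        "slice": np.arange(length),
        "outer_radius_vox": R,
        "inner_radius_vox": r,
        "csa_vox2": np.pi * (R**2 - r**2),
        "imin_vox4": i_annulus,
        "imax_vox4": i_annulus,
        "polar_vox4": 2 * i_annulus,
        "wall_thickness_vox": R - r,
        "centroid_y_vox": c + drift[:, 0],
        "centroid_x_vox": c + drift[:, 1],
    })
    vol = VoxelVolume(data=data, voxel_size=voxel_size, is_binary=True,
                      meta={"generator": "cortical_shell"})
    return vol, truth


# ---------------------------------------------------------------------------
# pore planting
# ---------------------------------------------------------------------------

def _rasterize_pore_local(spec: PlantedPoreSpec, voxel_size: float,
                          shape: tuple[int, int, int]):
    """Rasterize one pore into a local bounding box.

    Returns (box slices, local boolean mask) or None if the box leaves
    the volume.
    """
    if spec.kind == "lacuna":
        ext_um = np.asarray(spec.radii_um, dtype=float)  # λ1->z, λ2->y, λ3->x
    elif spec.kind == "canal":
        d = np.abs(np.asarray(spec.direction, float))
        d = d / np.linalg.norm(d)
        ext_um = d * spec.length_um / 2.0 + spec.radius_um
    else:
        ext_um = np.full(3, max(spec.radius_um or 0.0, 0.0))
    ext = np.ceil(ext_um / voxel_size).astype(int) + 1
    c = np.asarray(spec.center, dtype=float)
    lo = np.floor(c).astype(int) - ext
    hi = np.floor(c).astype(int) + ext + 1
    if np.any(lo < 0) or np.any(hi > np.asarray(shape)):
        return None
    box = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
    local_shape = tuple(int(b - a) for a, b in zip(lo, hi))
    local_center = c - lo

    if spec.kind == "lacuna":
        a = np.asarray(spec.radii_um, float) / voxel_size
        mask = rasterize_ellipsoid(a, shape=local_shape, center=local_center)
    elif spec.kind == "canal":
        d = np.asarray(spec.direction, float)
        d = d / np.linalg.norm(d)
        zz, yy, xx = _grid(local_shape)
        pts = np.stack([zz - local_center[0], yy - local_center[1],
                        xx - local_center[2]], axis=-1)
        t = pts @ d
        perp2 = np.square(pts).sum(axis=-1) - t**2
        r_vox = spec.radius_um / voxel_size
        mask = (np.abs(t) <= spec.length_um / (2 * voxel_size)) & (perp2 <= r_vox**2)
    else:  # noise
        r_vox = (spec.radius_um or 0.0) / voxel_size
        if r_vox < 0.5:  # sub-voxel: carve the single voxel holding the center
            mask = np.zeros(local_shape, dtype=bool)
            idx = np.floor(local_center + 0.5).astype(int)
            idx = np.clip(idx, 0, np.asarray(local_shape) - 1)
            mask[tuple(idx)] = True
        else:
            mask = make_ball(r_vox, shape=local_shape, center=local_center)
    if not mask.any():  # guarantee at least the center voxel
        mask = np.zeros(local_shape, dtype=bool)
        idx = np.clip(np.round(local_center).astype(int), 0,
                      np.asarray(local_shape) - 1)
        mask[tuple(idx)] = True
    return box, mask


_CLEARANCE_STRUCT = ndimage.generate_binary_structure(3, 3)


def _pore_fits(spec: PlantedPoreSpec, bone: np.ndarray, occupied: np.ndarray,
               voxel_size: float, clearance: int):
    """Check containment and clearance; return (box, mask) or a reason string."""
    loc = _rasterize_pore_local(spec, voxel_size, bone.shape)
    if loc is None:
        return "outside volume"
    box, mask = loc
    grown = ndimage.binary_dilation(mask, _CLEARANCE_STRUCT, iterations=clearance) \
        if clearance else mask
    if not bone[box][grown].all():
        return "breaches the cortical wall"
    if occupied[box][grown].any():
        return "overlaps another pore"
    return box, mask


def plant_pores(
    shell: VoxelVolume,
    specs: Sequence[PlantedPoreSpec],
    *,
    clearance: int = 2,
) -> tuple[VoxelVolume, pd.DataFrame]:
    """Carve the given pores out of a binary shell.

    Pores must lie entirely within the bone wall with ``clearance``
    voxels of bone (or unplanted space) around them, and must not
    overlap each other; violations raise ``ValueError`` naming the
    offending spec index.

    Returns the porous volume and a manifest with one row per pore:
    analytic volume (μm³), target class under the 13/1500 μm³ rule,
    rasterized voxel count, and center.
    """
    bone = shell.mask()
    occupied = np.zeros_like(bone)
    rows = []
    for i, spec in enumerate(specs):
        spec.validate()
        res = _pore_fits(spec, bone, occupied, shell.voxel_size, clearance)
        if isinstance(res, str):
            raise ValueError(f"pore spec {i} ({spec.kind}) {res}")
        box, mask = res
        occupied[box] |= mask
        rows.append({
            "pore_id": i,
            "kind": spec.kind,
            "target_class": spec.target_class(),
            "analytic_volume_um3": spec.analytic_volume_um3(),
            "n_voxels": int(mask.sum()),
            "rasterized_volume_um3": float(mask.sum()) * shell.voxel_volume_um3,
            "center_z": spec.center[0], "center_y": spec.center[1],
            "center_x": spec.center[2],
        })
    carved = bone & ~occupied
    manifest = pd.DataFrame(rows)
    vol = shell.with_data(carved.astype(np.uint8), planted_pores=len(specs))
    return vol, manifest


def random_pore_specs(
    shell: VoxelVolume,
    *,
    n_lacunae: int = 50,
    n_canals: int = 4,
    n_noise: int = 15,
    seed: int | np.random.Generator = 0,
    clearance: int = 2,
    lacuna_minor_um: tuple[float, float] = (1.5, 2.8),
    lacuna_mid_ratio: tuple[float, float] = (1.3, 2.2),
    lacuna_major_ratio: tuple[float, float] = (1.2, 2.5),
    canal_radius_um: tuple[float, float] = (3.5, 4.5),
    canal_length_um: tuple[float, float] = (45.0, 60.0),
    canal_min_volume_um3: float = 2200.0,
    max_tries: int = 20000,
) -> list[PlantedPoreSpec]:
    """Draw non-overlapping pore specs inside a shell by rejection sampling.

    Lacunae are tri-axial ellipsoids with minor semi-axis λ3 of
    1.5-2.8 μm, λ2/λ3 of 1.3-2.2 and λ1/λ2 of 1.2-2.5, the long axis
    along the bone — typical murine osteocyte lacunae, whose volumes
    (≈50-800 μm³) sit safely inside the 13-1500 μm³ class window so
    rasterization never flips the class.  Canals are near-axial
    cylinders of at least ``canal_min_volume_um3`` (margin above the
    1500 μm³ cut); noise is single-voxel speckle.
    """
    rng = np.random.default_rng(seed)
    bone = shell.mask()
    occupied = np.zeros_like(bone)
    # candidate centers: bone voxels comfortably inside the wall
    depth = ndimage.distance_transform_edt(bone)
    specs: list[PlantedPoreSpec] = []

    def try_place(make_spec, min_depth_vox: float) -> bool:
        cand = np.argwhere(depth >= min_depth_vox)
        if len(cand) == 0:
            return False
        for _ in range(max_tries):
            center = cand[rng.integers(len(cand))] + rng.uniform(-0.5, 0.5, 3)
            spec = make_spec(tuple(center))
            res = _pore_fits(spec, bone, occupied, shell.voxel_size, clearance)
            if not isinstance(res, str):
                box, mask = res
                occupied[box] |= mask
                specs.append(spec)
                return True
        return False

    vs = shell.voxel_size
    for _ in range(n_canals):
        r = rng.uniform(*canal_radius_um)
        length = rng.uniform(*canal_length_um)
        if np.pi * r * r * length < canal_min_volume_um3:
            length = canal_min_volume_um3 / (np.pi * r * r)
        tilt = rng.normal(scale=0.06, size=2)
        direction = np.array([1.0, tilt[0], tilt[1]])
        direction /= np.linalg.norm(direction)
        md = r / vs + clearance + 1  # radial requirement; axial fit is checked

        def mk(c, r=r, length=length, direction=tuple(direction)):
            return PlantedPoreSpec("canal", c, radius_um=r, length_um=length,
                                   direction=direction)
        if not try_place(mk, md):
            raise RuntimeError("could not place canal; shell too small/full")
    for _ in range(n_lacunae):
        l3 = rng.uniform(*lacuna_minor_um)
        l2 = l3 * rng.uniform(*lacuna_mid_ratio)
        l1 = l2 * rng.uniform(*lacuna_major_ratio)
        radii = (l1, l2, l3)
        md = l2 / vs + clearance + 1  # in-plane requirement; λ1 runs axially

        def mk(cen, radii=radii):
            return PlantedPoreSpec("lacuna", cen, radii_um=radii)
        if not try_place(mk, md):
            raise RuntimeError("could not place lacuna; shell too small/full")
    for _ in range(n_noise):
        def mk(cen):
            return PlantedPoreSpec("noise", cen, radius_um=0.25 * vs)
        if not try_place(mk, clearance + 1.5):
            raise RuntimeError("could not place speckle")
    return specs


def make_porous_shell(
    *,
    length: int = 160,
    outer_radius_vox: float = 52.0,
    inner_radius_vox: float = 22.0,
    voxel_size: float = 0.6,
    n_lacunae: int = 50,
    n_canals: int = 4,
    n_noise: int = 15,
    seed: int | np.random.Generator = 0,
) -> tuple[VoxelVolume, pd.DataFrame, list[PlantedPoreSpec]]:
    """One-call porous cortical slab: shell + planted pores + manifest.

    Defaults emulate a nanoCT cortical window at 0.6 μm voxels with a
    30-voxel (18 μm) wall — thick enough to hold murine-scale lacunae
    and near-axial canals without wall breach.
    """
    shell, _ = make_cortical_shell(length, outer_radius_vox, inner_radius_vox,
                                   voxel_size=voxel_size)
    specs = random_pore_specs(shell, n_lacunae=n_lacunae, n_canals=n_canals,
                              n_noise=n_noise, seed=seed)
    vol, manifest = plant_pores(shell, specs)
    return vol, manifest, specs


# ---------------------------------------------------------------------------
# trabecular lattice
# ---------------------------------------------------------------------------

def make_trabecular_lattice(
    spacing_um: float = 250.0,
    rod_thickness_um: float = 50.0,
    n_cells: tuple[int, int, int] = (3, 3, 3),
    *,
    voxel_size: float = 5.0,
) -> tuple[VoxelVolume, dict]:
    """Cubic rod lattice of known volume fraction and topology.

    Square-cross-section rods (edge ``rod_thickness_um``) run along all
    three axes through a grid of ``(n+1)`` node planes per axis, spaced
    ``spacing_um`` apart, emulating an idealised trabecular network.

    Ground truth (returned dict):

    - ``bvtv``: analytic volume fraction by inclusion-exclusion over the
      rod union (each node cube counted once);
    - ``euler`` = V − E of the lattice graph (nodes, rod segments) and
      ``beta1`` = E − V + 1, the graph cycle rank, which equal the
      Euler characteristic and loop count of the thickened solid as
      long as ``rod_thickness < spacing``;
    - ``n_nodes``, ``n_edges``, ``tv_mm3``.
    """
    s, t = float(spacing_um), float(rod_thickness_um)
    if not (0 < t < s):
        raise ValueError("need 0 < rod_thickness < spacing")
    n1, n2, n3 = n_cells
    if min(n_cells) < 1:
        raise ValueError("need at least one cell per axis")

    dims_um = np.array([n1 * s + t, n2 * s + t, n3 * s + t])
    shape = tuple(int(np.ceil(d / voxel_size)) for d in dims_um)
    node_pos = [t / 2 + s * np.arange(nk + 1) for nk in (n1, n2, n3)]

    # proximity of each coordinate to its nearest node plane
    prox = []
    for ax, n_ax in enumerate(shape):
        coords = (np.arange(n_ax) + 0.5) * voxel_size  # voxel centers, μm
        d = np.min(np.abs(coords[:, None] - node_pos[ax][None, :]), axis=1)
        prox.append(d <= t / 2)
    pz = prox[0][:, None, None]
    py = prox[1][None, :, None]
    px = prox[2][None, None, :]
    solid = (py & px) | (pz & px) | (pz & py)  # x-, y-, z-rods

    n_nodes = (n1 + 1) * (n2 + 1) * (n3 + 1)
    n_edges = (n1 * (n2 + 1) * (n3 + 1) + n2 * (n1 + 1) * (n3 + 1)
               + n3 * (n1 + 1) * (n2 + 1))
    rod_vol = t * t * (dims_um[0] * (n2 + 1) * (n3 + 1)
                       + dims_um[1] * (n1 + 1) * (n3 + 1)
                       + dims_um[2] * (n1 + 1) * (n2 + 1))
    union_vol = rod_vol - 2 * n_nodes * t**3
    tv_um3 = float(np.prod(dims_um))
    truth = {
        "bvtv": union_vol / tv_um3,
        "bv_um3": union_vol,
        "tv_um3": tv_um3,
        "tv_mm3": tv_um3 * 1e-9,
        "n_nodes": n_nodes,
        "n_edges": n_edges,
        "beta1": n_edges - n_nodes + 1,
        "euler": n_nodes - n_edges,
        "rod_thickness_um": t,
        "spacing_um": s,
    }
    vol = VoxelVolume(solid.astype(np.uint8), voxel_size=voxel_size,
                      is_binary=True, meta={"generator": "trabecular_lattice"})
    return vol, truth


# ---------------------------------------------------------------------------
# density phantoms
# ---------------------------------------------------------------------------

def make_phantoms(
    densities: Sequence[float],
    *,
    attenuation_slope: float = 400.0,
    attenuation_intercept: float = 20.0,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator = 0,
    radius_vox: float = 12.0,
    length: int = 30,
    voxel_size: float = 5.0,
) -> tuple[list[VoxelVolume], dict]:
    """Greyscale calibration cylinders of known hydroxyapatite density.

    Each phantom's interior intensity is
    ``attenuation_intercept + attenuation_slope * density`` plus optional
    Gaussian noise — an affine attenuation-density law like the
    manufacturer HA rods (0.25 and 0.75 g/cm³) used to calibrate tissue
    mineral density.

    Returns the volumes (``meta["interior_mask"]`` marks voxels at least
    one voxel inside the rod) and a truth dict recording the affine and
    the per-phantom noiseless means.
    """
    densities = list(densities)
    if not densities:
        raise ValueError("need at least one phantom density")
    rng = np.random.default_rng(seed)
    n = int(np.ceil(2 * radius_vox)) + 7
    c = (n - 1) / 2.0
    yy, xx = np.meshgrid(np.arange(n, dtype=float), np.arange(n, dtype=float),
                         indexing="ij")
    d2 = (yy - c) ** 2 + (xx - c) ** 2
    cyl = np.broadcast_to(d2 <= radius_vox**2, (length, n, n)).copy()
    core = np.broadcast_to(d2 <= (radius_vox - 1.0) ** 2, (length, n, n)).copy()
    vols = []
    for d in densities:
        mean = attenuation_intercept + attenuation_slope * d
        data = np.zeros(cyl.shape, dtype=np.float32)
        data[cyl] = mean
        if noise_sd > 0:
            data[cyl] += rng.normal(scale=noise_sd, size=int(cyl.sum())).astype(
                np.float32)
        vols.append(VoxelVolume(data, voxel_size=voxel_size, is_binary=False,
                                meta={"density_g_cm3": d,
                                      "interior_mask": core.copy()}))
    truth = {
        "densities": densities,
        "slope": attenuation_slope,
        "intercept": attenuation_intercept,
        "true_means": [attenuation_intercept + attenuation_slope * d
                       for d in densities],
        "noise_sd": noise_sd,
    }
    return vols, truth


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSpec:
    """Two-genotype, multi-age cohort with additive effects.

    The response for animal k in cell (genotype i, age j) is

        y = mu + g·[i = KO] + a_j + d_j·[i = KO] + eps,   eps ~ N(0, sigma²)

    i.e. ``genotype_effect`` is the KO−WT contrast, ``age_effects`` are
    shared across genotypes, and ``interaction_effects`` are the
    KO-specific per-age departures (zero vector → no interaction).
    Defaults mirror a murine ageing study: ages 5, 7, 16 and 34 weeks
    with 6 animals per cell except 5 at 34 weeks.
    """

    genotypes: tuple[str, str] = ("WT", "KO")
    ages: tuple[int, ...] = (5, 7, 16, 34)
    n_per_group: int = 6
    mu: float = 0.0
    genotype_effect: float = 0.0
    age_effects: tuple[float, ...] | None = None
    interaction_effects: tuple[float, ...] | None = None
    sigma: float = 1.0
    seed: int = 0
    n_overrides: tuple[tuple[tuple[str, int], int], ...] = ()

    def __post_init__(self):
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        for eff, name in ((self.age_effects, "age_effects"),
                          (self.interaction_effects, "interaction_effects")):
            if eff is not None and len(eff) != len(self.ages):
                raise ValueError(f"{name} must have one entry per age")


def simulate_cohort(spec: CohortSpec, *, response: str = "value") -> pd.DataFrame:
    """Simulate one measurement table under a :class:`CohortSpec`.

    Bit-reproducible under the spec's seed.  Columns: ``specimen``,
    ``genotype``, ``age``, and the response.
    """
    rng = np.random.default_rng(spec.seed)
    a = spec.age_effects or (0.0,) * len(spec.ages)
    d = spec.interaction_effects or (0.0,) * len(spec.ages)
    overrides = dict(spec.n_overrides)
    rows = []
    for gi, g in enumerate(spec.genotypes):
        for j, age in enumerate(spec.ages):
            n = overrides.get((g, age), spec.n_per_group)
            mean = spec.mu + a[j]
            if gi == 1:
                mean += spec.genotype_effect + d[j]
            y = mean + rng.normal(scale=spec.sigma, size=n)
            for k in range(n):
                rows.append({"specimen": f"{g}{age}w-{k + 1}", "genotype": g,
                             "age": age, response: y[k]})
    return pd.DataFrame(rows)
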