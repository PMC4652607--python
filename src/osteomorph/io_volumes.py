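"""Reading, writing, reorienting and slicing CT image stacks.

Volumes are multi-page TIFF files or directories of equally sized 2D
TIFF/PNG slices in lexicographic order; axis 0 is the stack (long) axis.
Greyscale data are preserved bit-exactly on a read/write round trip.
"""

from __future__ import annotations

import os
import warnings
from pathlib import Path

import numpy as np
import tifffile
from scipy import ndimage

from .core import RoiSpec, VoxelVolume

__all__ = [
    "read_stack",
    "write_stack",
    "reorient_to_long_axis",
    "select_roi",
]

_SLICE_EXTS = {".tif", ".tiff", ".png"}


def read_stack(path: str | os.PathLike, voxel_size: float) -> VoxelVolume:
    """Read a multi-page TIFF or a directory of 2D slices into a volume.

    Parameters
    ----------
    path
        Multi-page TIFF file, or a directory whose TIFF/PNG members are
        taken in lexicographic order as consecutive slices.
    voxel_size
        Isotropic voxel edge length, μm.

    Raises
    ------
    ValueError
        Empty stack, or slices of inconsistent shape.
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(p for p in path.iterdir() if p.suffix.lower() in _SLICE_EXTS)
        if not files:
            raise ValueError(f"no TIFF/PNG slices found in directory {path}")
        slices = []
        for f in files:
            if f.suffix.lower() == ".png":
                from imageio.v3 import imread
                arr = imread(f)
            else:
                arr = tifffile.imread(f)
            if arr.ndim != 2:
                raise ValueError(f"slice {f.name} is not a 2D image (ndim={arr.ndim})")
            if slices and arr.shape != slices[0].shape:
                raise ValueError(
                    f"inconsistent slice shape: {f.name} has {arr.shape}, "
                    f"expected {slices[0].shape}")
            slices.append(arr)
        data = np.stack(slices, axis=0)
    else:
        data = tifffile.imread(path)
        if data.ndim == 2:
            data = data[None]
        if data.ndim != 3:
            raise ValueError(f"expected a 3D stack in {path}, got ndim={data.ndim}")
        if data.shape[0] == 0:
            raise ValueError(f"empty stack: {path}")
    is_binary = bool(np.isin(np.unique(data), (0, 1)).all())
    return VoxelVolume(data=data, voxel_size=float(voxel_size), is_binary=is_binary,
                       meta={"source": str(path)})


def write_stack(vol: VoxelVolume, path: str | os.PathLike) -> None:
    """Write a volume as a multi-page TIFF (bit-exact for integer dtypes)."""
    data = vol.data
    if data.dtype == bool:
        data = data.astype(np.uint8)
    tifffile.imwrite(Path(path), data)


def _principal_axes(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Eigenvalues (desc) and eigenvectors of the voxel-coordinate covariance."""
    coords = np.argwhere(mask)
    centroid = coords.mean(axis=0)
    centered = coords - centroid
    cov = centered.T @ centered / len(coords)
    evals, evecs = np.linalg.eigh(cov)  # ascending
    order = np.argsort(evals)[::-1]
    return evals[order], evecs[:, order], centroid


def reorient_to_long_axis(
    vol: VoxelVolume,
    mask: VoxelVolume,
    *,
    degeneracy_rtol: float = 0.05,
) -> VoxelVolume:
    """Rigidly rotate ``vol`` so the mask's dominant principal axis is axis 0.

    The dominant axis of the binary mask's voxel distribution (leading
    eigenvector of the coordinate covariance) is aligned with the stack
    axis, so transverse slices are perpendicular to the bone's long
    axis.  Binary volumes are resampled nearest-neighbour (preserving
    binarity); greyscale volumes trilinearly.

    If the mask's inertia is degenerate (leading two eigenvalues within
    ``degeneracy_rtol`` relative difference — e.g. a sphere) a warning is
    issued and the input is returned unrotated.

    The applied rotation matrix and angle (degrees) are recorded in the
    output's ``meta`` under ``"rotation_matrix"`` and
    ``"rotation_angle_deg"``.
    """
    m = mask.mask()
    if not m.any():
        raise ValueError("mask is empty")
    evals, evecs, _ = _principal_axes(m)
    if evals[0] <= 0 or (evals[0] - evals[1]) / evals[0] < degeneracy_rtol:
        warnings.warn("degenerate mask inertia; returning volume unrotated",
                      stacklevel=2)
        return vol.with_data(vol.data.copy(), rotation_matrix=np.eye(3),
                             rotation_angle_deg=0.0)

    long_axis = evecs[:, 0]
    if long_axis[0] < 0:  # keep proximal->distal sense
        long_axis = -long_axis
    target = np.array([1.0, 0.0, 0.0])

    # rotation taking long_axis -> target (Rodrigues)
    v = np.cross(long_axis, target)
    c = float(np.dot(long_axis, target))
    angle = float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))
    if np.linalg.norm(v) < 1e-12:
        rot = np.eye(3)
    else:
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        rot = np.eye(3) + vx + vx @ vx * (1.0 / (1.0 + c))

    center = (np.array(vol.data.shape) - 1) / 2.0
    # affine_transform maps output coords -> input coords: x_in = A x_out + b
    inv = rot.T
    offset = center - inv @ center
    order = 0 if vol.is_binary else 1
    rotated = ndimage.affine_transform(
        vol.data, inv, offset=offset, order=order, mode="constant", cval=0,
        output=vol.data.dtype)
    return vol.with_data(rotated, rotation_matrix=rot, rotation_angle_deg=angle)


def rotation_angle_applied(vol: VoxelVolume) -> float:
    """Rotation angle (degrees) recorded by :func:`reorient_to_long_axis`."""
    return float(vol.meta.get("rotation_angle_deg", 0.0))


def select_roi(vol: VoxelVolume, roi: RoiSpec,
               total_length_slices: int | None = None) -> VoxelVolume:
    """Extract an axial slab addressed by an :class:`RoiSpec`.

    ``total_length_slices`` is the slice count of the whole bone, which
    may exceed the loaded volume when a pre-cropped stack is supplied;
    it defaults to the volume's own slice count.

    Raises
    ------
    IndexError
        If the resolved interval falls outside the volume.
    """
    if total_length_slices is None:
        total_length_slices = vol.n_slices
    begin, end = roi.to_slice_interval(total_length_slices)
    if begin < 0 or end > vol.n_slices or begin >= end:
        raise IndexError(
            f"ROI slices [{begin}, {end}) outside volume of {vol.n_slices} slices")
    return vol.with_data(
        vol.data[begin:end],
        roi={"mode": roi.mode, "start": roi.start, "extent": roi.extent,
             "reference": roi.reference, "slices": [begin, end],
             "convention": "floor, half-open, slice 0 = proximal"},
    )
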