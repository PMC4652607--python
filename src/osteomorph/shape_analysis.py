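"""Best-fit ellipsoids and lacunar shape descriptors.

Each lacunar particle is summarised by the ellipsoid with the same
central second moments as the voxelised solid.  For a uniform solid
ellipsoid the principal moments of inertia per unit mass are
``m_i = (λ_j² + λ_k²)/5``, so the semi-axes follow from the inertia
eigenvalues as ``λ_i = sqrt(5/2 · (m_j + m_k − m_i))``.  Shape is then
described by equancy, elongation and flatness of the sorted semi-axes
``λ1 ≥ λ2 ≥ λ3``:

    Eq = λ3/λ1,  El = 1 − λ2/λ1,  Fl = 1 − λ3/λ2,  Eq = (1−El)(1−Fl)

with Flinn-diagram coordinates (x, y) = (λ2/λ3, λ1/λ2): prolate
(elongated) shapes plot above the diagonal, oblate (flattened) below.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .segmentation import ParticleSet

__all__ = [
    "Ellipsoid",
    "ShapeMetrics",
    "fit_ellipsoid",
    "fit_ellipsoids",
    "shape_metrics",
    "particle_shape_table",
    "group_shape_summary",
]

MIN_FIT_VOXELS = 10


@dataclass(frozen=True)
class Ellipsoid:
    """Best-fit ellipsoid: center (μm), semi-axes λ1 ≥ λ2 ≥ λ3 (μm),
    and the orthonormal principal-axis triad (columns)."""

    center_um: tuple[float, float, float]
    radii_um: tuple[float, float, float]
    axes: np.ndarray

    def __post_init__(self):
        l1, l2, l3 = self.radii_um
        if not (l1 >= l2 >= l3 > 0):
            raise ValueError(f"semi-axes must satisfy λ1 ≥ λ2 ≥ λ3 > 0, "
                             f"got {self.radii_um}")

    def volume_um3(self) -> float:
        return 4.0 / 3.0 * np.pi * float(np.prod(self.radii_um))


@dataclass(frozen=True)
class ShapeMetrics:
    equancy: float      # λ3/λ1 ∈ (0, 1]
    elongation: float   # 1 − λ2/λ1 ∈ [0, 1)
    flatness: float     # 1 − λ3/λ2 ∈ [0, 1)
    flinn_x: float      # λ2/λ3 ≥ 1
    flinn_y: float      # λ1/λ2 ≥ 1


def fit_ellipsoid(second_moment_um2: np.ndarray,
                  centroid_um: tuple[float, float, float]) -> Ellipsoid | None:
    """Ellipsoid matching a particle's central second-moment matrix.

    The 3x3 matrix (μm², per unit mass) is eigen-decomposed; the
    inertia eigenvalues ``m_i = trace − μ_i`` (with μ_i the
    second-moment eigenvalues) are converted to semi-axes by the
    uniform-solid relation above.  Returns ``None`` (flagged, excluded
    from shape statistics) if a radicand is non-positive — a
    pathological moment matrix no solid ellipsoid can produce.
    """
    C = np.asarray(second_moment_um2, dtype=float)
    mu, vecs = np.linalg.eigh(C)  # ascending
    tr = mu.sum()
    m = tr - mu  # principal inertia moments, descending
    # λ_i² = (5/2)(m_j + m_k − m_i); with m = tr − μ this is 5 μ_i
    rad2 = 2.5 * (m.sum() - 2 * m)
    if np.any(rad2 <= 0):
        return None
    radii = np.sqrt(rad2)  # ascending with μ
    order = np.argsort(radii)[::-1]
    return Ellipsoid(center_um=tuple(centroid_um),
                     radii_um=tuple(radii[order]),
                     axes=vecs[:, order])


def fit_ellipsoids(particles: ParticleSet,
                   min_voxels: int = MIN_FIT_VOXELS) -> list[Ellipsoid | None]:
    """Fit every particle; entries are None for skipped/degenerate ones.

    Particles below ``min_voxels`` are skipped with a warning — their
    moment matrices are dominated by discretisation.
    """
    out: list[Ellipsoid | None] = []
    n_small = 0
    vs = particles.voxel_size
    counts = particles.particles["voxel_count"].to_numpy()
    cents = particles.particles[["centroid_z", "centroid_y", "centroid_x"]].to_numpy()
    for i in range(len(particles)):
        if counts[i] < min_voxels:
            out.append(None)
            n_small += 1
            continue
        out.append(fit_ellipsoid(particles.second_moments[i], tuple(cents[i] * vs)))
    if n_small:
        warnings.warn(f"skipped {n_small} particles below {min_voxels} voxels",
                      stacklevel=2)
    return out


def shape_metrics(e: Ellipsoid) -> ShapeMetrics:
    """Equancy/elongation/flatness and Flinn coordinates of an ellipsoid."""
    l1, l2, l3 = e.radii_um
    return ShapeMetrics(
        equancy=l3 / l1,
        elongation=1.0 - l2 / l1,
        flatness=1.0 - l3 / l2,
        flinn_x=l2 / l3,
        flinn_y=l1 / l2,
    )


def particle_shape_table(particles: ParticleSet,
                         min_voxels: int = MIN_FIT_VOXELS) -> pd.DataFrame:
    """Per-particle shape table (fitted particles only).

    Columns: particle id, center, λ1..λ3 (μm), Eq, El, Fl, Flinn x/y,
    fitted-ellipsoid volume (μm³) and the particle's voxel volume.
    """
    fits = fit_ellipsoids(particles, min_voxels=min_voxels)
    rows = []
    for pid, e in zip(particles.particles.index, fits):
        if e is None:
            continue
        m = shape_metrics(e)
        rows.append({
            "particle": pid,
            "center_z_um": e.center_um[0], "center_y_um": e.center_um[1],
            "center_x_um": e.center_um[2],
            "lambda1_um": e.radii_um[0], "lambda2_um": e.radii_um[1],
            "lambda3_um": e.radii_um[2],
            "Lc.Eq": m.equancy, "Lc.El": m.elongation, "Lc.Fl": m.flatness,
            "flinn_x": m.flinn_x, "flinn_y": m.flinn_y,
            "ellipsoid_volume_um3": e.volume_um3(),
            "particle_volume_um3":
                particles.particles.loc[pid, "volume_um3"],
        })
    return pd.DataFrame(rows)


def group_shape_summary(table: pd.DataFrame,
                        by: list[str] = ("genotype", "age")) -> pd.DataFrame:
    """Per-group mean ± SEM of Eq/El/Fl and mean Flinn coordinates.

    ``table`` is a per-particle shape table with grouping columns
    attached; particles are weighted equally (per-lacuna averages).
    Empty groups are omitted with a warning.
    """
    by = list(by)
    metrics = ["Lc.Eq", "Lc.El", "Lc.Fl", "flinn_x", "flinn_y"]
    if table.empty:
        warnings.warn("no particles to summarise", stacklevel=2)
        return pd.DataFrame(columns=by + ["n"])
    rows = []
    for key, grp in table.groupby(by, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        row = dict(zip(by, key))
        row["n"] = len(grp)
        for mname in metrics:
            vals = grp[mname].to_numpy(dtype=float)
            row[f"{mname} mean"] = vals.mean()
            row[f"{mname} sem"] = (vals.std(ddof=1) / np.sqrt(len(vals))
                                   if len(vals) > 1 else 0.0)
        rows.append(row)
    return pd.DataFrame(rows)
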