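"""Lacunar and vascular-canal porosity indices of a cortical window.

Pore particles are classified purely by physical volume: below 13 μm³
noise, above 1500 μm³ vascular canals, the inclusive band between them
osteocyte lacunae.  The thresholds are physical (μm³), so the rule is
independent of voxel size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from skimage.measure import euler_number

from .core import VoxelVolume
from .cortical_geometry import local_thickness_map
from .segmentation import ParticleSet, extract_pores, label_components
from .synthetic_data import CANAL_MIN_UM3, NOISE_MAX_UM3

__all__ = [
    "PorosityReport",
    "classify_pores",
    "porosity_indices",
    "analyze_cortical_porosity",
]

_MM3_PER_UM3 = 1e-9
_MM_PER_UM = 1e-3


def classify_pores(particles: ParticleSet,
                   noise_max_um3: float = NOISE_MAX_UM3,
                   canal_min_um3: float = CANAL_MIN_UM3) -> pd.Series:
    """Assign each pore particle to {noise, lacuna, canal} by volume.

    volume < 13 μm³ → noise; volume > 1500 μm³ → canal; the inclusive
    band [13, 1500] μm³ → lacuna.  Total on non-negative volumes.
    """
    if not 0 < noise_max_um3 < canal_min_um3:
        raise ValueError("thresholds must satisfy 0 < noise_max < canal_min")
    v = particles.particles["volume_um3"]
    cls = pd.Series("lacuna", index=v.index, name="pore_class")
    cls[v < noise_max_um3] = "noise"
    cls[v > canal_min_um3] = "canal"
    return cls


@dataclass
class PorosityReport:
    """Osteocyte-lacunar and vascular-canal index vector of a cortical ROI.

    Naming follows standard bone-morphometry nomenclature: ``Ct.TV``
    cortical tissue volume (bone + enclosed pores, mm³), ``N.Lc``/
    ``N.Ca`` counts, ``/Ct.TV`` densities (mm⁻³), ``Lc.V``/``Ca.V``
    mean particle volume (μm³), ``.V/Ct.TV`` volume fractions (%),
    ``.Th``/``.Sp`` mean sphere-fitting local thickness and separation
    (μm), ``Con.Dnn`` connectivity density (1 − χ)/Ct.TV (mm⁻³).
    """

    ct_tv_mm3: float
    ct_th_mm: float
    n_lc: int
    n_lc_per_ct_tv: float
    lc_v_um3: float
    lc_v_per_ct_tv_pct: float
    lc_th_um: float
    lc_sp_um: float
    lc_con_dnn_per_mm3: float
    n_ca: int
    n_ca_per_ct_tv: float
    ca_v_um3: float
    ca_v_per_ct_tv_pct: float
    ca_th_um: float
    ca_sp_um: float
    ca_con_dnn_per_mm3: float
    n_noise: int = 0
    n_excluded: int = 0

    _COLUMNS = {
        "ct_tv_mm3": "Ct.TV (mm^3)",
        "ct_th_mm": "Ct.Th (mm)",
        "n_lc": "N.Lc",
        "n_lc_per_ct_tv": "N.Lc/Ct.TV (mm^-3)",
        "lc_v_um3": "Lc.V (um^3)",
        "lc_v_per_ct_tv_pct": "Lc.V/Ct.TV (%)",
        "lc_th_um": "Lc.Th (um)",
        "lc_sp_um": "Lc.Sp (um)",
        "lc_con_dnn_per_mm3": "Lc.Con.Dnn (mm^-3)",
        "n_ca": "N.Ca",
        "n_ca_per_ct_tv": "N.Ca/Ct.TV (mm^-3)",
        "ca_v_um3": "Ca.V (um^3)",
        "ca_v_per_ct_tv_pct": "Ca.V/Ct.TV (%)",
        "ca_th_um": "Ca.Th (um)",
        "ca_sp_um": "Ca.Sp (um)",
        "ca_con_dnn_per_mm3": "Ca.Con.Dnn (mm^-3)",
        "n_noise": "n_noise",
        "n_excluded": "n_excluded",
    }

    def to_series(self) -> pd.Series:
        d = asdict(self)
        return pd.Series({self._COLUMNS[k]: d[k] for k in self._COLUMNS})


def _class_stats(pset: ParticleSet | None, tissue: np.ndarray, ct_tv_mm3: float,
                 voxel_size: float, label: str) -> dict:
    """Count/volume/thickness/separation/connectivity block for one class."""
    if pset is None or pset.n_particles == 0:
        warnings.warn(f"no {label} particles; indices reported as zero",
                      stacklevel=3)
        return {"n": 0, "n_per_tv": 0.0, "v": 0.0, "v_frac": 0.0,
                "th": 0.0, "sp": 0.0, "con": 0.0}
    mask = pset.mask()
    n = pset.n_particles
    vols = pset.particles["volume_um3"].to_numpy()
    th_map = local_thickness_map(mask)
    th = float(th_map[mask].mean()) * voxel_size
    sp_mask = tissue & ~mask
    sp_map = local_thickness_map(sp_mask)
    sp = float(sp_map[sp_mask].mean()) * voxel_size if sp_mask.any() else 0.0
    chi = euler_number(mask, connectivity=3)
    return {
        "n": n,
        "n_per_tv": n / ct_tv_mm3,
        "v": float(vols.mean()),
        "v_frac": 100.0 * float(vols.sum()) * _MM3_PER_UM3 / ct_tv_mm3,
        "th": th,
        "sp": sp,
        "con": (1.0 - chi) / ct_tv_mm3,
    }


def porosity_indices(lacunae: ParticleSet | None, canals: ParticleSet | None,
                     cortex: VoxelVolume, *, n_noise: int = 0,
                     n_excluded: int = 0) -> PorosityReport:
    """Compute the porosity index vector from classified particle sets.

    ``cortex`` is the binarized cortical bone slab; Ct.TV is the tissue
    volume (bone plus the pore space of both classes), Ct.Th the mean
    3D local thickness of the bone phase.  Separations are local
    thicknesses of the non-pore tissue within the cortex (the choice of
    restricting to the cortex mask is recorded here rather than left
    implicit).  Connectivity density per class is (1 − χ)/Ct.TV with χ
    from the 26-connectivity 3D Euler characteristic.
    """
    bone = cortex.mask()
    if not bone.any():
        raise ValueError("empty cortex mask")
    vs = cortex.voxel_size
    lc_mask = lacunae.mask() if lacunae is not None and len(lacunae) else \
        np.zeros_like(bone)
    ca_mask = canals.mask() if canals is not None and len(canals) else \
        np.zeros_like(bone)
    tissue = bone | lc_mask | ca_mask
    ct_tv_mm3 = float(tissue.sum()) * vs**3 * _MM3_PER_UM3
    th_map = local_thickness_map(bone)
    ct_th_mm = float(th_map[bone].mean()) * vs * _MM_PER_UM

    lc = _class_stats(lacunae, tissue, ct_tv_mm3, vs, "lacuna")
    ca = _class_stats(canals, tissue, ct_tv_mm3, vs, "canal")
    return PorosityReport(
        ct_tv_mm3=ct_tv_mm3, ct_th_mm=ct_th_mm,
        n_lc=lc["n"], n_lc_per_ct_tv=lc["n_per_tv"], lc_v_um3=lc["v"],
        lc_v_per_ct_tv_pct=lc["v_frac"], lc_th_um=lc["th"], lc_sp_um=lc["sp"],
        lc_con_dnn_per_mm3=lc["con"],
        n_ca=ca["n"], n_ca_per_ct_tv=ca["n_per_tv"], ca_v_um3=ca["v"],
        ca_v_per_ct_tv_pct=ca["v_frac"], ca_th_um=ca["th"], ca_sp_um=ca["sp"],
        ca_con_dnn_per_mm3=ca["con"],
        n_noise=n_noise, n_excluded=n_excluded,
    )


def analyze_cortical_porosity(cortex_bone: VoxelVolume, *,
                              connectivity: int = 6
                              ) -> tuple[PorosityReport, ParticleSet, pd.Series]:
    """Full pore chain on a binarized cortical slab.

    extract enclosed pores → label (6-connectivity, the background/pore
    convention) → classify by volume → porosity indices.  Returns the
    report, the labeled pore particle set and the per-particle class
    series.
    """
    pores, info = extract_pores(cortex_bone)
    pset = label_components(pores, connectivity=connectivity)
    classes = classify_pores(pset)
    lacunae = pset.select((classes == "lacuna").to_numpy()) if len(pset) else None
    canals = pset.select((classes == "canal").to_numpy()) if len(pset) else None
    n_noise = int((classes == "noise").sum())
    report = porosity_indices(lacunae, canals, cortex_bone, n_noise=n_noise,
                              n_excluded=info["n_excluded_axial"])
    return report, pset, classes
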