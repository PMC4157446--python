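"""Refinement quality metrics: r.m.s.d. to a reference and real-space CC."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import gemmi
import numpy as np

from . import geometry as geom
from .model_io import AtomicModel, MapGrid, ReflectionSet
from .scattering import calc_structure_factors
from .map_synthesis import synthesize_map
from .scattering import StructureFactorSet

__all__ = ["ComparisonReport", "rmsd", "real_space_cc", "simulated_map", "compare_models"]


@dataclass
class ComparisonReport:
    all_heavy_rmsd: float
    backbone_rmsd: float
    per_residue_rmsd: dict
    map_cc: Optional[float]
    superposed: bool


def _matched_coords(model_a: AtomicModel, model_b: AtomicModel, selection: str):
    """Coordinates of atoms matched by (chain, res_num, icode, atom name)."""
    def keyed(m, mask):
        return {
            (m.chain[i], int(m.res_num[i]), m.icode[i], m.name[i]): i
            for i in np.flatnonzero(mask)
        }

    if selection == "backbone":
        mask_a, mask_b = model_a.backbone_mask(), model_b.backbone_mask()
    elif selection == "all-heavy":
        mask_a, mask_b = model_a.heavy_mask(), model_b.heavy_mask()
    else:
        raise ValueError(f"unknown selection {selection!r}")
    ka = keyed(model_a, mask_a)
    kb = keyed(model_b, mask_b)
    common = sorted(set(ka) & set(kb))
    unmatched = len(set(ka) ^ set(kb)) // 1
    if len(common) < 3:
        raise ValueError("fewer than 3 matched atoms")
    ia = [ka[c] for c in common]
    ib = [kb[c] for c in common]
    return model_a.xyz[ia], model_b.xyz[ib], common, unmatched


def rmsd(model_a: AtomicModel, model_b: AtomicModel,
         selection: str = "backbone", superpose: bool = False) -> float:
    """Root-mean-square deviation over matched atoms, in angstroms.

    ``superpose=True`` removes the best rigid-body transform first (needed
    when the two models sit in different crystal frames).
    """
    xa, xb, _, _ = _matched_coords(model_a, model_b, selection)
    if superpose:
        xa = geom.superpose(xa, xb)
    return float(np.sqrt(np.mean(np.sum((xa - xb) ** 2, axis=1))))


def per_residue_rmsd(model_a: AtomicModel, model_b: AtomicModel,
                     selection: str = "backbone", superpose: bool = False) -> dict:
    xa, xb, keys, _ = _matched_coords(model_a, model_b, selection)
    if superpose:
        xa = geom.superpose(xa, xb)
    d2 = np.sum((xa - xb) ** 2, axis=1)
    out = {}
    for (chain, num, icode, _name), val in zip(keys, d2):
        out.setdefault((chain, num, icode), []).append(val)
    return {k: float(np.sqrt(np.mean(v))) for k, v in out.items()}


def real_space_cc(map_a: MapGrid, map_b: MapGrid,
                  mask_atoms: Optional[AtomicModel] = None,
                  mask_radius: float = 3.0) -> float:
    """Pearson correlation between two maps on the same grid.

    With ``mask_atoms`` the correlation is restricted to voxels within
    ``mask_radius`` A of any selected atom (local CC).
    """
    if map_a.shape != map_b.shape:
        raise ValueError("maps must share grid geometry (resample first)")
    a = np.asarray(map_a.values, float).ravel()
    b = np.asarray(map_b.values, float).ravel()
    if mask_atoms is not None:
        mask = _sphere_mask(map_a, mask_atoms, mask_radius).ravel()
        a, b = a[mask], b[mask]
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero-variance map region; CC undefined")
    return float(np.corrcoef(a, b)[0, 1])


def _sphere_mask(mapgrid: MapGrid, model: AtomicModel, radius: float) -> np.ndarray:
    dims = np.array(mapgrid.shape)
    F = np.array(mapgrid.cell.frac.mat.tolist())
    O = np.array(mapgrid.cell.orth.mat.tolist())
    mask = np.zeros(mapgrid.shape, dtype=bool)
    spacing = np.array(mapgrid.cell.parameters[:3]) / dims
    n_off = np.ceil(radius / spacing).astype(int)
    for pos in model.xyz:
        frac = (F @ pos) % 1.0
        u = frac * dims
        i0 = np.floor(u).astype(int)
        ranges = [np.arange(i0[d] - n_off[d], i0[d] + n_off[d] + 1) for d in range(3)]
        gi, gj, gk = np.meshgrid(*ranges, indexing="ij")
        dfrac = np.stack([gi / dims[0] - frac[0], gj / dims[1] - frac[1],
                          gk / dims[2] - frac[2]], axis=-1)
        dfrac -= np.round(dfrac)
        dxyz = dfrac @ O.T
        within = np.sum(dxyz**2, axis=-1) <= radius**2
        mask[gi[within] % dims[0], gj[within] % dims[1], gk[within] % dims[2]] = True
    return mask


def simulated_map(model: AtomicModel, resolution: float,
                  grid_spacing: Optional[float] = None) -> MapGrid:
    """Resolution-limited model density: F_calc to d_min, Fourier synthesis."""
    if grid_spacing is None:
        grid_spacing = resolution / 3.0
    from .model_io import full_sphere_hkl
    hkl = full_sphere_hkl(model.cell, resolution)
    refl = ReflectionSet(hkl=hkl, f_obs=np.zeros(len(hkl)), cell=model.cell,
                         spacegroup=model.spacegroup)
    fc = calc_structure_factors(model, refl)
    return synthesize_map(fc, model.cell, grid_spacing)


def compare_models(model: AtomicModel, reference: AtomicModel,
                   superpose: bool = True,
                   map_cc: Optional[float] = None) -> ComparisonReport:
    return ComparisonReport(
        all_heavy_rmsd=rmsd(model, reference, "all-heavy", superpose),
        backbone_rmsd=rmsd(model, reference, "backbone", superpose),
        per_residue_rmsd=per_residue_rmsd(model, reference, "backbone", superpose),
        map_cc=map_cc,
        superposed=superpose,
    )
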