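"""Desk-scale ground-truth systems for refinement experiments.

A "target" conformation generates error-free diffraction amplitudes at a
chosen resolution limit (optionally smoothed with an applied B factor and/or
noised); a conformationally displaced "search" model — one arm rigidly
rotated about a hinge plus small coordinate jitter — plays the role of the
mismatched phasing model.  Cells are P1 so that the refinement path is not
masked by crystallographic symmetry.

Models are ideal-geometry polyalanine with backbone + C-beta atoms: at the
low resolutions of interest the claim under test is backbone placement, and
side chains beyond C-beta only slow the experiment down.
"""

from __future__ import annotations

from dataclasses import dataclass

import gemmi
import numpy as np

from . import geometry as geom
from .model_io import AtomicModel, ReflectionSet, full_sphere_hkl
from .scattering import assign_free_flags, calc_structure_factors

__all__ = ["ToySystemSpec", "make_target", "make_search_model", "simulate_reflections"]

def _ala_internal_coords():
    """Backbone internal coordinates measured from the idealized alanine
    template, so generated models sit exactly at the force field's
    equilibrium geometry.  Inter-residue values match the peptide-link
    constants used by the topology builder."""
    from .forcefield import _template
    coords, _ = _template("ALA")
    d = lambda a, b: float(np.linalg.norm(coords[a] - coords[b]))
    ang = lambda a, b, c: float(np.rad2deg(geom.angle(coords[a], coords[b], coords[c])))
    dih = lambda a, b, c, e: float(np.rad2deg(geom.dihedral(coords[a], coords[b],
                                                            coords[c], coords[e])))
    return {
        "N-CA": d("N", "CA"), "CA-C": d("CA", "C"), "C-O": d("C", "O"),
        "CA-CB": d("CA", "CB"),
        "N-CA-C": ang("N", "CA", "C"), "CA-C-O": ang("CA", "C", "O"),
        "N-CA-CB": ang("N", "CA", "CB"),
        # dihedral (C, N, CA, CB): places C-beta with L chirality
        "C-N-CA-CB": dih("C", "N", "CA", "CB"),
    }


_IC = _ala_internal_coords()
_B_N_CA, _B_CA_C, _B_C_N = _IC["N-CA"], _IC["CA-C"], 1.329
_B_C_O, _B_CA_CB = _IC["C-O"], _IC["CA-CB"]
_A_C_N_CA, _A_N_CA_C, _A_CA_C_N = 121.7, _IC["N-CA-C"], 116.2
_A_CA_C_O, _A_N_CA_CB = _IC["CA-C-O"], _IC["N-CA-CB"]
_D_C_N_CA_CB = _IC["C-N-CA-CB"]

HELIX = (-57.0, -47.0)
EXTENDED = (-139.0, 135.0)
# four-residue reverse-turn torsions connecting the two helical arms,
# chosen so the packed arms stay clash-free (>4.5 A closest approach)
_TURN = ((-135.0, 75.0), (-75.0, 160.0), (55.0, 45.0), (-120.0, 130.0))


@dataclass
class ToySystemSpec:
    """Study conditions for one synthetic refinement experiment."""

    n_residues: int = 15          # per helical segment
    architecture: str = "helix-hairpin"
    padding: float = 10.0         # A of empty cell on every side
    hinge_deg: float = 30.0
    seed: int = 0
    d_min: float = 4.0
    smoothing_b: float = 0.0      # A^2; 0 = off
    noise_frac: float = 0.0       # multiplicative log-normal sigma
    jitter_rms: float = 0.3       # A, applied to the search model
    free_fraction: float = 0.05
    b_iso: float = 20.0

    def __post_init__(self):
        if self.n_residues < 5:
            raise ValueError("need at least 5 residues per segment")
        if self.d_min <= 1.0:
            raise ValueError("d_min must exceed 1 A")
        if not (0.0 <= self.hinge_deg <= 90.0):
            raise ValueError("hinge angle must be within [0, 90] deg")

    def phi_psi_sequence(self):
        """Per-residue (phi, psi) and the hinge residue index (0-based)."""
        n = self.n_residues
        if self.architecture == "helix-hairpin":
            seq = [HELIX] * n + list(_TURN) + [HELIX] * n
            hinge = n + len(_TURN) // 2
        elif self.architecture == "two-domain-hinge":
            seq = [HELIX] * n + [EXTENDED] * 3 + list(_TURN) + [HELIX] * n
            hinge = n + 3 + len(_TURN) // 2
        elif self.architecture == "extended":
            seq = [EXTENDED] * (2 * n)
            hinge = n
        else:
            raise ValueError(f"unknown architecture {self.architecture!r}")
        return seq, hinge


def _build_chain(phi_psi: list) -> dict:
    """Backbone + CB + O coordinates for a polyalanine chain.

    Returns per-residue dicts of atom name -> xyz, built by natural-extension
    (NeRF) placement with ideal bond lengths/angles, trans peptide bonds and
    the requested (phi, psi).
    """
    deg = np.deg2rad
    res_atoms = []
    n_res = len(phi_psi)
    # seed residue frame
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([_B_N_CA, 0.0, 0.0])
    th = deg(_A_N_CA_C)
    c0 = ca0 + _B_CA_C * np.array([-np.cos(th), np.sin(th), 0.0])
    prev = {"N": n0, "CA": ca0, "C": c0}
    for i in range(n_res):
        phi, psi = phi_psi[i]
        cur = dict(prev) if i == 0 else {}
        if i > 0:
            cur["N"] = geom.place_atom(prev["N"], prev["CA"], prev["C"],
                                       _B_C_N, deg(_A_CA_C_N), deg(phi_psi[i - 1][1]))
            cur["CA"] = geom.place_atom(prev["CA"], prev["C"], cur["N"],
                                        _B_N_CA, deg(_A_C_N_CA), deg(180.0))
            cur["C"] = geom.place_atom(prev["C"], cur["N"], cur["CA"],
                                       _B_CA_C, deg(_A_N_CA_C), deg(phi))
        cur["O"] = geom.place_atom(cur["N"], cur["CA"], cur["C"],
                                   _B_C_O, deg(_A_CA_C_O), deg(psi + 180.0))
        cur["CB"] = geom.place_atom(cur["C"], cur["N"], cur["CA"],
                                    _B_CA_CB, deg(_A_N_CA_CB), deg(_D_C_N_CA_CB))
        res_atoms.append(cur)
        prev = cur
    return res_atoms


_ATOM_ORDER = (("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O"), ("CB", "C"))


def make_target(spec: ToySystemSpec) -> AtomicModel:
    """Ideal-geometry polyalanine target in a padded P1 cell."""
    seq, _hinge = spec.phi_psi_sequence()
    residues = _build_chain(seq)
    names, elements, res_num, xyz = [], [], [], []
    for i, atoms in enumerate(residues, start=1):
        for name, el in _ATOM_ORDER:
            names.append(name)
            elements.append(el)
            res_num.append(i)
            xyz.append(atoms[name])
    xyz = np.array(xyz)
    lo = xyz.min(axis=0)
    xyz = xyz - lo + spec.padding
    extent = xyz.max(axis=0) + spec.padding
    cell = gemmi.UnitCell(*extent, 90.0, 90.0, 90.0)
    n = len(xyz)
    return AtomicModel(
        serial=np.arange(1, n + 1),
        name=names,
        element=elements,
        res_name=["ALA"] * n,
        res_num=np.array(res_num),
        chain=["A"] * n,
        icode=[""] * n,
        altloc=[""] * n,
        xyz=xyz,
        occ=np.ones(n),
        b_iso=np.full(n, spec.b_iso),
        cell=cell,
        spacegroup="P 1",
    )


def make_search_model(target: AtomicModel, spec: ToySystemSpec):
    """Hinge-rotated, jittered copy of the target.

    One arm (all residues past the hinge) is rigidly rotated about an axis
    through the hinge CA, perpendicular to the two arm directions, by
    ``spec.hinge_deg``; every atom then receives seeded Gaussian jitter of
    r.m.s. magnitude ``spec.jitter_rms``.  Returns (model, backbone_rmsd).
    """
    _seq, hinge = spec.phi_psi_sequence()
    hinge_res = hinge + 1          # residues are 1-based
    model = target.copy()
    res_num = model.res_num
    arm2 = res_num > hinge_res
    arm1 = res_num < hinge_res
    ca_hinge = model.xyz[(res_num == hinge_res)
                         & (np.array(model.name) == "CA")][0]
    v1 = model.xyz[arm1].mean(axis=0) - ca_hinge
    v2 = model.xyz[arm2].mean(axis=0) - ca_hinge
    axis = np.cross(v1, v2)
    if np.linalg.norm(axis) < 1e-8:
        axis = np.array([0.0, 0.0, 1.0])
    R = geom.rotation_about_axis(axis, np.deg2rad(spec.hinge_deg))
    moved = model.xyz.copy()
    moved[arm2] = (moved[arm2] - ca_hinge) @ R.T + ca_hinge
    rng = np.random.default_rng(spec.seed)
    if spec.jitter_rms > 0:
        moved += rng.normal(0.0, spec.jitter_rms / np.sqrt(3.0), moved.shape)
    model.xyz = moved
    from .evaluate import rmsd
    return model, rmsd(model, target, "backbone", superpose=False)


def simulate_reflections(target: AtomicModel, spec: ToySystemSpec) -> ReflectionSet:
    """Error-free amplitudes |F_calc(target)| to d_min, optionally smoothed
    (amplitude x exp(-B_smooth stol^2)) and noised; free flags assigned."""
    hkl = full_sphere_hkl(target.cell, spec.d_min)
    refl = ReflectionSet(hkl=hkl, f_obs=np.zeros(len(hkl)), cell=target.cell,
                         spacegroup=target.spacegroup)
    fc = calc_structure_factors(target, refl)
    f = fc.amplitude
    if spec.smoothing_b > 0:
        f = f * np.exp(-spec.smoothing_b * refl.stol**2)
    if spec.noise_frac > 0:
        rng = np.random.default_rng(spec.seed + 7)
        f = f * np.exp(rng.normal(0.0, spec.noise_frac, len(f)))
    refl.f_obs = f
    return assign_free_flags(refl, spec.free_fraction, seed=spec.seed + 13)
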