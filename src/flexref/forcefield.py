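"""Simplified restrained molecular-mechanics potential with analytic gradients.

The potential is deliberately minimal: harmonic bonds and angles, harmonic
(wrapped) torsion and improper restraints, and a soft-core repulsion between
nonbonded pairs — no electrostatics, no dispersion, vacuum.  Refinement
balances these stereochemical restraints against the density-derived forces,
so the essential requirement is correct equilibrium geometry and exact
gradients, not a calibrated thermodynamic force field.  The module interface
isolates this choice so a full force field could be swapped in.

Equilibrium bond lengths and angles are measured from idealized residue
templates (CCD ideal coordinates via biotite); inter-residue peptide-link
values are standard Engh-Huber-like numbers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import geometry as geom
from .model_io import AtomicModel

__all__ = [
    "Topology",
    "RestraintSet",
    "build_topology",
    "assign_secondary_structure",
    "compute_energy_forces",
    "ncs_restraint_forces",
]

# default force constants (kcal/mol/A^2, kcal/mol/rad^2)
K_BOND = 300.0
K_ANGLE = 60.0
K_OMEGA = 40.0
K_IMPROPER = 40.0
K_PHIPSI = 150.0
K_HBOND = 30.0
EPS_REPULSION = 25.0
REPULSION_SCALE = 0.75  # soft-core cutoff as a fraction of summed radii

_VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
              "H": 1.10, "FE": 1.60, "ZN": 1.40, "MG": 1.50}

# inter-residue (peptide link) ideal values, degrees.  O-C-N closes the
# planar carbonyl exactly against the template's intra-residue CA-C-O
# (120.03 deg), so an ideally built chain is strain-free.
_LINK_BOND = ("C", "N", 1.329)
_LINK_ANGLES = (("CA", "C", "N", 116.2), ("O", "C", "N", 123.769),
                ("C", "N", "CA", 121.7))

# idealized (phi, psi) targets for restrained secondary structure, degrees
HELIX_PHI_PSI = (-57.0, -47.0)
SHEET_PHI_PSI = (-119.0, 113.0)


@dataclass
class Topology:
    """Bonded terms, impropers, nonbonded parameters and masses."""

    n_atoms: int
    bonds: np.ndarray          # (nb, 2) int
    bond_r0: np.ndarray
    bond_k: np.ndarray
    angles: np.ndarray         # (na, 3) int, vertex at column 1
    angle_theta0: np.ndarray   # radians
    angle_k: np.ndarray
    torsions: np.ndarray       # (nt, 4) int  (omega restraints live here)
    torsion_target: np.ndarray  # radians
    torsion_k: np.ndarray
    impropers: np.ndarray      # (ni, 4) int  (chirality + planarity)
    improper_target: np.ndarray
    improper_k: np.ndarray
    radii: np.ndarray          # per atom, A
    eps: np.ndarray            # per atom soft-core strength
    masses: np.ndarray         # amu
    exclusions: set = field(default_factory=set)   # frozenset pairs (1-2, 1-3)


@dataclass
class RestraintSet:
    """Secondary-structure and symmetry restraints (the U_SS term)."""

    ss_dihedrals: np.ndarray = None        # (n, 4) int
    ss_targets: np.ndarray = None          # radians
    ss_k: np.ndarray = None
    hbond_pairs: np.ndarray = None         # (n, 2) int (O_i, N_i+4)
    hbond_r0: np.ndarray = None
    hbond_k: np.ndarray = None
    assignments: dict = field(default_factory=dict)  # residue key -> 'H'/'E'
    ncs_groups: list = field(default_factory=list)   # lists of index arrays
    ncs_k: float = 1.0

    def __post_init__(self):
        if self.ss_dihedrals is None:
            self.ss_dihedrals = np.zeros((0, 4), int)
            self.ss_targets = np.zeros(0)
            self.ss_k = np.zeros(0)
        if self.hbond_pairs is None:
            self.hbond_pairs = np.zeros((0, 2), int)
            self.hbond_r0 = np.zeros(0)
            self.hbond_k = np.zeros(0)


def _template(res_name: str):
    """Idealized residue template (heavy atoms): name -> xyz, plus bond pairs."""
    import biotite.structure.info as info
    try:
        res = info.residue(res_name)
    except KeyError:
        return None
    if res is None:
        return None
    heavy = res.element != "H"
    names = list(res.atom_name[heavy])
    coords = {n: c for n, c in zip(names, res.coord[heavy])}
    bonds = []
    idx_name = list(res.atom_name)
    for i, j, _ in res.bonds.as_array():
        ni, nj = idx_name[i], idx_name[j]
        if ni in coords and nj in coords:
            bonds.append((ni, nj))
    return coords, bonds


def _residue_groups(model: AtomicModel):
    """Consecutive groups of atom indices per residue, in file order."""
    groups = []
    keys = model.residue_keys()
    start = 0
    for i in range(1, model.n_atoms + 1):
        if i == model.n_atoms or keys[i] != keys[start]:
            groups.append((keys[start], model.res_name[start], list(range(start, i))))
            start = i
    return groups


def build_topology(model: AtomicModel) -> Topology:
    """Bonded topology from residue templates plus peptide links.

    Unknown residues fall back to distance restraints on their initial
    geometry (rigid-body-like), with a warning.  Hydrogens, if present,
    receive only bonds to their template parent and are excluded from
    repulsion.
    """
    n = model.n_atoms
    bonds, bond_r0, bond_k = [], [], []
    impropers, imp_t, imp_k = [], [], []
    torsions, tor_t, tor_k = [], [], []

    name_of = model.name
    groups = _residue_groups(model)

    res_maps = []
    for key, rname, idxs in groups:
        amap = {}
        for i in idxs:
            amap.setdefault(name_of[i], i)
        res_maps.append((key, rname, amap))
        tmpl = _template(rname)
        matched = []
        if tmpl is not None:
            coords, tbonds = tmpl
            for ni, nj in tbonds:
                ii, jj = amap.get(ni), amap.get(nj)
                if ii is None or jj is None:
                    continue
                matched.append((ii, jj, float(np.linalg.norm(coords[ni] - coords[nj]))))
        if tmpl is None or (len(idxs) > 1 and not matched):
            # unknown residue (or known name whose atoms do not match the
            # template): restrain its initial geometry instead
            warnings.warn(f"unknown residue {rname} {key}: restraining initial geometry")
            xyz = model.xyz
            for a_i, ii in enumerate(idxs):
                for jj in idxs[a_i + 1:]:
                    r = np.linalg.norm(xyz[ii] - xyz[jj])
                    if r < 5.0:
                        bonds.append((ii, jj))
                        bond_r0.append(r)
                        bond_k.append(K_BOND if r < 2.0 else K_BOND / 10)
            continue
        coords, _ = tmpl
        for ii, jj, r0 in matched:
            bonds.append((ii, jj))
            bond_r0.append(r0)
            bond_k.append(K_BOND)
        # chirality improper at CA for residues with a CB (glycine has none)
        quad = [amap.get(x) for x in ("CA", "N", "C", "CB")]
        if all(q is not None for q in quad) and all(x in coords for x in ("CA", "N", "C", "CB")):
            target = float(geom.dihedral(coords["CA"], coords["N"], coords["C"], coords["CB"]))
            impropers.append(quad)
            imp_t.append(target)
            imp_k.append(K_IMPROPER)

    # peptide links between consecutive residues of the same chain
    link_angles = []
    for (k1, r1, m1), (k2, r2, m2) in zip(res_maps, res_maps[1:]):
        c_i, n_j = m1.get("C"), m2.get("N")
        if c_i is None or n_j is None or k1[0] != k2[0]:
            continue
        gap = np.linalg.norm(model.xyz[c_i] - model.xyz[n_j])
        if gap > 2.5:        # chain break: no link terms
            continue
        bonds.append((c_i, n_j))
        bond_r0.append(_LINK_BOND[2])
        bond_k.append(K_BOND)
        # the three angles that straddle the link: CA-C-N, O-C-N, C-N-CA
        link_atoms = {"CA1": m1.get("CA"), "C": c_i, "O": m1.get("O"),
                      "N": n_j, "CA2": m2.get("CA")}
        for an1, an2, an3, deg in ((("CA1", "C", "N") + (116.2,)),
                                   (("O", "C", "N") + (123.0,)),
                                   (("C", "N", "CA2") + (121.7,))):
            ii, jj, kk = link_atoms[an1], link_atoms[an2], link_atoms[an3]
            if None in (ii, jj, kk):
                continue
            link_angles.append((ii, jj, kk, np.deg2rad(deg)))
        # omega torsion restrained trans; planarity improper on the carbonyl O
        ca_i, ca_j, o_i = m1.get("CA"), m2.get("CA"), m1.get("O")
        if None not in (ca_i, c_i, n_j, ca_j):
            torsions.append((ca_i, c_i, n_j, ca_j))
            tor_t.append(np.pi)
            tor_k.append(K_OMEGA)
        if None not in (o_i, ca_i, c_i, n_j):
            impropers.append((o_i, ca_i, c_i, n_j))
            imp_t.append(np.pi)
            imp_k.append(K_IMPROPER)

    # angles: every pair of bonds sharing an atom; theta0 from current
    # templates when both arms are intra-residue, else from link table above
    bonds_arr = np.array(bonds, int).reshape(-1, 2)
    adj = [[] for _ in range(n)]
    for bi, (i, j) in enumerate(bonds_arr):
        adj[i].append(j)
        adj[j].append(i)

    angle_list, angle_t0, angle_kk = [], [], []
    seen = set()
    tmpl_cache = {}

    def template_angle(center, i, j, k):
        """theta0 from the residue template if all three atoms share a residue."""
        keys = model.residue_keys()
        if keys[i] == keys[j] == keys[k]:
            rn = model.res_name[j]
            if rn not in tmpl_cache:
                tmpl_cache[rn] = _template(rn)
            tmpl = tmpl_cache[rn]
            if tmpl is not None:
                coords = tmpl[0]
                ni, nj, nk = name_of[i], name_of[j], name_of[k]
                if ni in coords and nj in coords and nk in coords:
                    return float(geom.angle(coords[ni], coords[nj], coords[nk]))
        return None

    for j in range(n):
        nb = adj[j]
        for x in range(len(nb)):
            for y in range(x + 1, len(nb)):
                i, k = nb[x], nb[y]
                key = (min(i, k), j, max(i, k))
                if key in seen:
                    continue
                seen.add(key)
                t0 = template_angle(j, i, j, k)
                if t0 is None:
                    t0 = float(geom.angle(model.xyz[i], model.xyz[j], model.xyz[k]))
                angle_list.append((i, j, k))
                angle_t0.append(t0)
                angle_kk.append(K_ANGLE)

    for ii, jj, kk, t0 in link_angles:
        key = (min(ii, kk), jj, max(ii, kk))
        if key not in seen:
            seen.add(key)
            angle_list.append((ii, jj, kk))
            angle_t0.append(t0)
            angle_kk.append(K_ANGLE)

    # 1-2 and 1-3 exclusions for the soft repulsion
    exclusions = set()
    for i, j in bonds_arr:
        exclusions.add((min(i, j), max(i, j)))
    for i, j, k in angle_list:
        exclusions.add((min(i, k), max(i, k)))

    radii = np.array([_VDW_RADII.get(e.upper(), 1.7) for e in model.element])
    eps = np.full(n, EPS_REPULSION)
    is_h = np.array([e.upper() == "H" for e in model.element])
    eps[is_h] = 0.0

    import gemmi
    masses = np.array([gemmi.Element(e).weight for e in model.element])

    return Topology(
        n_atoms=n,
        bonds=bonds_arr,
        bond_r0=np.array(bond_r0),
        bond_k=np.array(bond_k),
        angles=np.array(angle_list, int).reshape(-1, 3),
        angle_theta0=np.array(angle_t0),
        angle_k=np.array(angle_kk),
        torsions=np.array(torsions, int).reshape(-1, 4),
        torsion_target=np.array(tor_t),
        torsion_k=np.array(tor_k),
        impropers=np.array(impropers, int).reshape(-1, 4),
        improper_target=np.array(imp_t),
        improper_k=np.array(imp_k),
        radii=radii,
        eps=eps,
        masses=masses,
        exclusions=exclusions,
    )


# ---------------------------------------------------------------------------
# Secondary-structure assignment


def backbone_indices(model: AtomicModel):
    """Per-residue dict of backbone atom indices, ordered as in the file."""
    out = []
    for key, rname, idxs in _residue_groups(model):
        amap = {}
        for i in idxs:
            amap.setdefault(model.name[i], i)
        out.append((key, {k: amap.get(k) for k in ("N", "CA", "C", "O")}))
    return out


def phi_psi(model: AtomicModel):
    """(phi, psi) in degrees per residue; NaN where undefined."""
    res = backbone_indices(model)
    nres = len(res)
    phi = np.full(nres, np.nan)
    psi = np.full(nres, np.nan)
    xyz = model.xyz
    for i in range(nres):
        key, bb = res[i]
        if None in (bb["N"], bb["CA"], bb["C"]):
            continue
        if i > 0:
            prev = res[i - 1][1]
            if prev["C"] is not None and res[i - 1][0][0] == key[0]:
                phi[i] = np.rad2deg(geom.dihedral(
                    xyz[prev["C"]], xyz[bb["N"]], xyz[bb["CA"]], xyz[bb["C"]]))
        if i < nres - 1:
            nxt = res[i + 1][1]
            if nxt["N"] is not None and res[i + 1][0][0] == key[0]:
                psi[i] = np.rad2deg(geom.dihedral(
                    xyz[bb["N"]], xyz[bb["CA"]], xyz[bb["C"]], xyz[nxt["N"]]))
    return phi, psi


def assign_secondary_structure(model: AtomicModel, mode: str = "geometric",
                               annotation: Optional[dict] = None,
                               k_dihedral: float = K_PHIPSI,
                               k_hbond: float = K_HBOND) -> RestraintSet:
    """Helix/sheet phi-psi restraints plus helical i -> i+4 H-bond restraints.

    ``geometric`` mode assigns from the initial backbone dihedrals (windows
    around the canonical helix and sheet regions, runs of >= 3 residues);
    ``from-annotation`` takes a {(chain, res_num, icode): 'H'|'E'} dict.
    The assignment is made once, from the input model, and stays fixed for
    the whole refinement.
    """
    res = backbone_indices(model)
    nres = len(res)
    if mode == "from-annotation":
        if annotation is None:
            raise ValueError("annotation dict required in from-annotation mode")
        keys = [key for key, _ in res]
        missing = [k for k in annotation if k not in keys]
        if missing:
            raise ValueError(f"annotation references absent residues: {missing[:3]}")
        types = np.array([annotation.get(key, "-") for key, _ in res])
    elif mode == "geometric":
        phi, psi = phi_psi(model)
        types = np.full(nres, "-", dtype=object)
        helix = (phi > -100) & (phi < -30) & (psi > -80) & (psi < -5)
        sheet = (phi > -170) & (phi < -70) & (psi > 90) & (psi < 180)
        types[helix] = "H"
        types[sheet] = "E"
        types = _smooth_runs(types, min_run=3)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    ss_d, ss_t, ss_kk = [], [], []
    hb_pairs, hb_r0, hb_kk = [], [], []
    xyz_ok = lambda bb: None not in (bb["N"], bb["CA"], bb["C"])
    for i in range(nres):
        t = types[i]
        if t not in ("H", "E"):
            continue
        key, bb = res[i]
        if not xyz_ok(bb):
            raise ValueError(f"incomplete backbone for assigned residue {key}")
        tgt = HELIX_PHI_PSI if t == "H" else SHEET_PHI_PSI
        if i > 0 and res[i - 1][0][0] == key[0] and res[i - 1][1]["C"] is not None:
            ss_d.append((res[i - 1][1]["C"], bb["N"], bb["CA"], bb["C"]))
            ss_t.append(np.deg2rad(tgt[0]))
            ss_kk.append(k_dihedral)
        if i < nres - 1 and res[i + 1][0][0] == key[0] and res[i + 1][1]["N"] is not None:
            ss_d.append((bb["N"], bb["CA"], bb["C"], res[i + 1][1]["N"]))
            ss_t.append(np.deg2rad(tgt[1]))
            ss_kk.append(k_dihedral)
        # helical H-bond O(i) ... N(i+4) inside a continuous helix run
        if t == "H" and i + 4 < nres and all(types[i:i + 5] == "H"):
            o_i = bb["O"]
            n_j = res[i + 4][1]["N"]
            if o_i is not None and n_j is not None and res[i + 4][0][0] == key[0]:
                hb_pairs.append((o_i, n_j))
                hb_r0.append(2.9)
                hb_kk.append(k_hbond)

    assignments = {key: t for (key, _), t in zip(res, types) if t in ("H", "E")}
    return RestraintSet(
        ss_dihedrals=np.array(ss_d, int).reshape(-1, 4),
        ss_targets=np.array(ss_t),
        ss_k=np.array(ss_kk),
        hbond_pairs=np.array(hb_pairs, int).reshape(-1, 2),
        hbond_r0=np.array(hb_r0),
        hbond_k=np.array(hb_kk),
        assignments=assignments,
    )


def _smooth_runs(types, min_run=3):
    out = types.copy()
    i = 0
    n = len(types)
    while i < n:
        j = i
        while j < n and types[j] == types[i]:
            j += 1
        if types[i] in ("H", "E") and (j - i) < min_run:
            out[i:j] = "-"
        i = j
    return out


# ---------------------------------------------------------------------------
# Energy and forces


def _wrap_angle(x):
    """Wrap to (-pi, pi]."""
    return np.remainder(x + np.pi, 2 * np.pi) - np.pi


def _bond_terms(xyz, idx, r0, k, forces):
    if len(idx) == 0:
        return 0.0
    d = xyz[idx[:, 0]] - xyz[idx[:, 1]]
    r = np.linalg.norm(d, axis=1)
    delta = r - r0
    e = np.sum(k * delta**2)
    # dU/dr = 2 k delta; f = -dU/dr * dhat
    fmag = (2 * k * delta / np.maximum(r, 1e-12))[:, None] * d
    np.subtract.at(forces, idx[:, 0], fmag)
    np.add.at(forces, idx[:, 1], fmag)
    return float(e)


def _angle_terms(xyz, idx, t0, k, forces):
    if len(idx) == 0:
        return 0.0
    a, b, c = xyz[idx[:, 0]], xyz[idx[:, 1]], xyz[idx[:, 2]]
    u = a - b
    v = c - b
    ru = np.linalg.norm(u, axis=1)
    rv = np.linalg.norm(v, axis=1)
    uh = u / ru[:, None]
    vh = v / rv[:, None]
    cosang = np.clip(np.sum(uh * vh, axis=1), -1.0, 1.0)
    theta = np.arccos(cosang)
    sin = np.sqrt(np.clip(1 - cosang**2, 1e-12, None))
    delta = theta - t0
    e = np.sum(k * delta**2)
    dEdt = 2 * k * delta
    ga = (cosang[:, None] * uh - vh) / (ru * sin)[:, None]
    gc = (cosang[:, None] * vh - uh) / (rv * sin)[:, None]
    gb = -ga - gc
    np.subtract.at(forces, idx[:, 0], dEdt[:, None] * ga)
    np.subtract.at(forces, idx[:, 1], dEdt[:, None] * gb)
    np.subtract.at(forces, idx[:, 2], dEdt[:, None] * gc)
    return float(e)


def _dihedral_grads(xyz, idx):
    """Dihedral values and gradients d(phi)/d(p0..p3), vectorized."""
    p0, p1, p2, p3 = (xyz[idx[:, i]] for i in range(4))
    b1 = p1 - p0
    b2 = p2 - p1
    b3 = p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = np.linalg.norm(b2, axis=1)
    n1sq = np.sum(n1 * n1, axis=1)
    n2sq = np.sum(n2 * n2, axis=1)
    m1 = np.cross(n1, b2 / b2n[:, None])
    x = np.sum(n1 * n2, axis=1)
    y = np.sum(m1 * n2, axis=1)
    phi = np.arctan2(y, x)
    g0 = (b2n / np.maximum(n1sq, 1e-12))[:, None] * n1
    g3 = (-b2n / np.maximum(n2sq, 1e-12))[:, None] * n2
    s12 = (np.sum(b1 * b2, axis=1) / b2n**2)[:, None]
    s32 = (np.sum(b3 * b2, axis=1) / b2n**2)[:, None]
    g1 = -(1 + s12) * g0 + s32 * g3
    g2 = s12 * g0 - (1 + s32) * g3
    return phi, (g0, g1, g2, g3)


def _torsion_terms(xyz, idx, target, k, forces):
    if len(idx) == 0:
        return 0.0
    phi, grads = _dihedral_grads(xyz, idx)
    delta = _wrap_angle(phi - target)
    e = np.sum(k * delta**2)
    dEdphi = 2 * k * delta
    for col, g in enumerate(grads):
        np.subtract.at(forces, idx[:, col], dEdphi[:, None] * g)
    return float(e)


def _repulsion_terms(xyz, topo: Topology, forces):
    n = len(xyz)
    if n < 2:
        return 0.0
    radii, eps = topo.radii, topo.eps
    if n <= 600:
        ii, jj = np.triu_indices(n, k=1)
    else:
        from scipy.spatial import cKDTree
        tree = cKDTree(xyz)
        pairs = tree.query_pairs(r=float(2 * radii.max() * REPULSION_SCALE),
                                 output_type="ndarray")
        if len(pairs) == 0:
            return 0.0
        ii, jj = pairs[:, 0], pairs[:, 1]
    if topo.exclusions:
        excl = np.array(sorted(topo.exclusions), int).reshape(-1, 2)
        pair_id = ii.astype(np.int64) * n + jj
        excl_id = excl[:, 0].astype(np.int64) * n + excl[:, 1]
        keep = ~np.isin(pair_id, excl_id)
        ii, jj = ii[keep], jj[keep]
    d = xyz[ii] - xyz[jj]
    r = np.linalg.norm(d, axis=1)
    rc = REPULSION_SCALE * (radii[ii] + radii[jj])
    e_pair = np.sqrt(eps[ii] * eps[jj])
    act = (r < rc) & (e_pair > 0)
    if not np.any(act):
        return 0.0
    ii, jj, d, r, rc, e_pair = ii[act], jj[act], d[act], r[act], rc[act], e_pair[act]
    r_safe = np.maximum(r, 0.1)   # capped repulsion for overlapping atoms
    t = 1 - r_safe / rc
    e = np.sum(e_pair * t**2)
    dUdr = -2 * e_pair * t / rc
    fvec = (-dUdr / np.maximum(r, 0.1))[:, None] * d
    np.add.at(forces, ii, fvec)
    np.subtract.at(forces, jj, fvec)
    return float(e)


def compute_energy_forces(coords: np.ndarray, topo: Topology,
                          restraints: Optional[RestraintSet] = None,
                          detail: bool = False):
    """Total restrained-MM energy (kcal/mol) and per-atom forces (-grad U)."""
    xyz = np.asarray(coords, float).reshape(-1, 3)
    if not np.all(np.isfinite(xyz)):
        raise ValueError("non-finite coordinates")
    forces = np.zeros_like(xyz)
    comps = {}
    comps["bond"] = _bond_terms(xyz, topo.bonds, topo.bond_r0, topo.bond_k, forces)
    comps["angle"] = _angle_terms(xyz, topo.angles, topo.angle_theta0, topo.angle_k, forces)
    comps["torsion"] = _torsion_terms(xyz, topo.torsions, topo.torsion_target,
                                      topo.torsion_k, forces)
    comps["improper"] = _torsion_terms(xyz, topo.impropers, topo.improper_target,
                                       topo.improper_k, forces)
    comps["repulsion"] = _repulsion_terms(xyz, topo, forces)
    if restraints is not None:
        comps["ss_dihedral"] = _torsion_terms(xyz, restraints.ss_dihedrals,
                                              restraints.ss_targets, restraints.ss_k,
                                              forces)
        comps["hbond"] = _bond_terms(xyz, restraints.hbond_pairs, restraints.hbond_r0,
                                     restraints.hbond_k, forces)
        if restraints.ncs_groups:
            e_ncs, f_ncs = ncs_restraint_forces(xyz, restraints.ncs_groups,
                                                restraints.ncs_k)
            comps["ncs"] = e_ncs
            forces += f_ncs
    energy = float(sum(comps.values()))
    if detail:
        return energy, forces, comps
    return energy, forces


def ncs_restraint_forces(coords: np.ndarray, ncs_groups, k_ncs: float):
    """Harmonic restraint of each symmetry copy toward the group consensus.

    Copies are least-squares superposed before the consensus (mean) is taken,
    so rigid-body differences between copies cost nothing.  Gradients treat
    the superposition transforms as fixed at their least-squares values.
    """
    xyz = np.asarray(coords, float).reshape(-1, 3)
    energy = 0.0
    forces = np.zeros_like(xyz)
    for group in ncs_groups:
        group = [np.asarray(g, int) for g in group]
        if len(group) < 2:
            continue
        sizes = {len(g) for g in group}
        if len(sizes) != 1:
            raise ValueError("NCS copies must have equal atom counts")
        # iterate: align copies to the running mean
        ref = xyz[group[0]]
        transforms = []
        for _ in range(3):
            aligned = []
            transforms = []
            for g in group:
                R, t = geom.kabsch(xyz[g], ref)
                aligned.append(xyz[g] @ R.T + t)
                transforms.append((R, t))
            ref = np.mean(aligned, axis=0)
        mean = ref
        for g, (R, t), y in zip(group, transforms, aligned):
            dev = y - mean
            energy += k_ncs * np.sum(dev**2)
            # dE/dx = 2 k R^T (y - mean)   (transform held fixed)
            forces[g] -= 2 * k_ncs * dev @ R
    return float(energy), forces
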