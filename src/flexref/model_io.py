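"""Atomic models, reflection data and density maps in standard formats.

Internally coordinates are Cartesian angstroms; fractional coordinates appear
only at the scattering/map boundary.  PDB, MTZ and CCP4/MRC parsing is
delegated to gemmi; the plain-text reflection dialect (whitespace-delimited
``h k l F [sigF] [free]`` with ``#`` comments) is handled here.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import gemmi
import numpy as np

__all__ = [
    "AtomicModel",
    "ReflectionSet",
    "MapGrid",
    "read_model",
    "write_model",
    "read_reflections",
    "write_reflections",
    "write_map",
    "read_map",
]

BACKBONE_NAMES = ("N", "CA", "C", "O")

#: gemmi symmetry operators use 24ths of a cell edge for translations
_OP_DEN = 24


def _identity_ops():
    return [(np.eye(3), np.zeros(3))]


@dataclass
class AtomicModel:
    """A single-conformer atomic model with unit cell and symmetry.

    Parallel arrays over atoms; ``xyz`` is (n, 3) Cartesian angstroms.
    ``symmetry`` is a list of ``(R, t)`` pairs acting on fractional
    coordinates; the default is the identity (space group P1).
    """

    serial: np.ndarray
    name: list
    element: list
    res_name: list
    res_num: np.ndarray
    chain: list
    icode: list
    altloc: list
    xyz: np.ndarray
    occ: np.ndarray
    b_iso: np.ndarray
    cell: gemmi.UnitCell
    symmetry: list = field(default_factory=_identity_ops)
    spacegroup: str = "P 1"

    # -- basic queries -------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.xyz)

    def copy(self) -> "AtomicModel":
        return AtomicModel(
            serial=self.serial.copy(),
            name=list(self.name),
            element=list(self.element),
            res_name=list(self.res_name),
            res_num=self.res_num.copy(),
            chain=list(self.chain),
            icode=list(self.icode),
            altloc=list(self.altloc),
            xyz=self.xyz.copy(),
            occ=self.occ.copy(),
            b_iso=self.b_iso.copy(),
            cell=gemmi.UnitCell(*self.cell.parameters),
            symmetry=[(R.copy(), t.copy()) for R, t in self.symmetry],
            spacegroup=self.spacegroup,
        )

    def with_xyz(self, xyz: np.ndarray) -> "AtomicModel":
        out = self.copy()
        out.xyz = np.asarray(xyz, float).reshape(-1, 3).copy()
        if len(out.xyz) != self.n_atoms:
            raise ValueError("coordinate array size mismatch")
        return out

    def backbone_mask(self) -> np.ndarray:
        return np.array([n in BACKBONE_NAMES for n in self.name])

    def heavy_mask(self) -> np.ndarray:
        return np.array([e.upper() != "H" for e in self.element])

    def frac_coords(self, xyz: Optional[np.ndarray] = None) -> np.ndarray:
        """Fractional coordinates (n, 3) via the cell fractionalization matrix."""
        if xyz is None:
            xyz = self.xyz
        F = np.array(self.cell.frac.mat.tolist())
        return np.asarray(xyz, float) @ F.T

    def masses(self) -> np.ndarray:
        return np.array([gemmi.Element(e).weight for e in self.element])

    def residue_keys(self) -> list:
        """(chain, res_num, icode) per atom — the residue identity used for matching."""
        return [
            (c, int(n), i)
            for c, n, i in zip(self.chain, self.res_num, self.icode)
        ]


def _validate_cell(cell: gemmi.UnitCell, context: str = "") -> None:
    a, b, c, al, be, ga = cell.parameters
    if min(a, b, c) <= 0:
        raise ValueError(f"non-positive cell edge {context}")
    for ang in (al, be, ga):
        if not (0.0 < ang < 180.0):
            raise ValueError(f"cell angle outside (0, 180) deg {context}")


def _is_dummy_cell(cell: gemmi.UnitCell) -> bool:
    a, b, c, *_ = cell.parameters
    return max(a, b, c) <= 1.0


# ---------------------------------------------------------------------------
# PDB I/O


def read_model(path, dialect: str = "pdb", require_cell: bool = True) -> AtomicModel:
    """Read an atomic model from a PDB file.

    Alternate locations are resolved to the highest-occupancy conformer.
    ``require_cell=True`` (the refinement default) rejects files without a
    usable CRYST1 record, because scattering needs the unit cell.
    """
    if dialect != "pdb":
        raise ValueError(f"unsupported model dialect: {dialect}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"malformed PDB file {path}: {exc}") from exc
    if len(st) == 0:
        raise ValueError(f"{path}: no models found")
    if require_cell and _is_dummy_cell(st.cell):
        raise ValueError(
            f"{path}: missing or dummy CRYST1 record; a unit cell is required"
        )
    _validate_cell(st.cell, f"in {path}")

    rows = []
    model = st[0]
    for chain in model:
        for res in chain:
            # resolve altlocs: keep the highest-occupancy conformer per atom name
            best = {}
            for atom in res:
                key = atom.name
                if key not in best or atom.occ > best[key].occ:
                    best[key] = atom
            n_alt = sum(1 for a in res if a.altloc not in ("", "\0"))
            for atom in best.values():
                el = atom.element.name
                if el == "X" or el == "":
                    raise ValueError(
                        f"{path}: unknown element for atom {atom.name} in "
                        f"{chain.name} {res.seqid.num} {res.name}"
                    )
                rows.append((
                    atom.serial, atom.name, el, res.name, res.seqid.num,
                    chain.name, res.seqid.icode.strip(), atom.altloc.strip("\0"),
                    (atom.pos.x, atom.pos.y, atom.pos.z), atom.occ, atom.b_iso,
                ))
    if not rows:
        raise ValueError(f"{path}: no ATOM/HETATM records")

    sg = st.spacegroup_hm or "P 1"
    ops = _ops_from_spacegroup(sg)
    return AtomicModel(
        serial=np.array([r[0] for r in rows], dtype=int),
        name=[r[1] for r in rows],
        element=[r[2] for r in rows],
        res_name=[r[3] for r in rows],
        res_num=np.array([r[4] for r in rows], dtype=int),
        chain=[r[5] for r in rows],
        icode=[r[6] for r in rows],
        altloc=[r[7] for r in rows],
        xyz=np.array([r[8] for r in rows], dtype=float),
        occ=np.array([r[9] for r in rows], dtype=float),
        b_iso=np.array([r[10] for r in rows], dtype=float),
        cell=gemmi.UnitCell(*st.cell.parameters),
        symmetry=ops,
        spacegroup=sg,
    )


def _ops_from_spacegroup(hm: str) -> list:
    sg = gemmi.find_spacegroup_by_name(hm)
    if sg is None:
        return _identity_ops()
    ops = []
    for op in sg.operations():
        R = np.array(op.rot, dtype=float) / _OP_DEN
        t = np.array(op.tran, dtype=float) / _OP_DEN
        ops.append((R, t))
    return ops


def write_model(model: AtomicModel, path) -> None:
    """Write a model as a standards-conformant PDB with CRYST1."""
    if np.any(np.abs(model.xyz) >= 10000) or not np.all(np.isfinite(model.xyz)):
        raise ValueError("coordinates overflow fixed PDB columns")
    st = gemmi.Structure()
    st.cell = gemmi.UnitCell(*model.cell.parameters)
    st.spacegroup_hm = model.spacegroup
    gm = gemmi.Model("1")
    chain_obj = None
    res_obj = None
    prev_chain = object()
    prev_res = object()
    for i in range(model.n_atoms):
        ckey = model.chain[i]
        rkey = (model.chain[i], int(model.res_num[i]), model.icode[i], model.res_name[i])
        if ckey != prev_chain:
            chain_obj = gemmi.Chain(ckey)
            gm.add_chain(chain_obj)
            chain_obj = gm[-1]
            prev_chain = ckey
            prev_res = object()
        if rkey != prev_res:
            res = gemmi.Residue()
            res.name = model.res_name[i]
            res.seqid = gemmi.SeqId(int(model.res_num[i]), model.icode[i] or " ")
            res.het_flag = "A"
            chain_obj.add_residue(res)
            res_obj = chain_obj[-1]
            prev_res = rkey
        a = gemmi.Atom()
        a.name = model.name[i]
        a.element = gemmi.Element(model.element[i])
        a.pos = gemmi.Position(*model.xyz[i])
        a.occ = float(model.occ[i])
        a.b_iso = float(model.b_iso[i])
        a.serial = int(model.serial[i])
        if model.altloc[i]:
            a.altloc = model.altloc[i]
        res_obj.add_atom(a)
    st.add_model(gm)
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# Reflection data


@dataclass
class ReflectionSet:
    """Unique reflections with observed amplitudes and optional free flags.

    Reduced to one hemisphere of reciprocal space (Friedel mates merged);
    d-spacings are computed from the cell on construction.
    """

    hkl: np.ndarray                 # (n, 3) int
    f_obs: np.ndarray               # (n,) amplitudes
    cell: gemmi.UnitCell
    sigma: Optional[np.ndarray] = None
    free: Optional[np.ndarray] = None   # bool; True = cross-validation set
    d: np.ndarray = None            # computed if not given
    spacegroup: str = "P 1"

    def __post_init__(self):
        self.hkl = np.asarray(self.hkl, dtype=int).reshape(-1, 3)
        self.f_obs = np.asarray(self.f_obs, dtype=float)
        if self.d is None:
            self.d = d_spacings(self.cell, self.hkl)
        if self.free is not None:
            self.free = np.asarray(self.free, dtype=bool)

    @property
    def n(self) -> int:
        return len(self.f_obs)

    @property
    def d_min(self) -> float:
        return float(self.d.min())

    @property
    def d_max(self) -> float:
        return float(self.d.max())

    @property
    def stol(self) -> np.ndarray:
        """sin(theta)/lambda = 1/(2 d) per reflection."""
        return 1.0 / (2.0 * self.d)

    def work_mask(self) -> np.ndarray:
        if self.free is None:
            return np.ones(self.n, dtype=bool)
        return ~self.free

    def copy(self) -> "ReflectionSet":
        return ReflectionSet(
            hkl=self.hkl.copy(),
            f_obs=self.f_obs.copy(),
            cell=gemmi.UnitCell(*self.cell.parameters),
            sigma=None if self.sigma is None else self.sigma.copy(),
            free=None if self.free is None else self.free.copy(),
            d=self.d.copy(),
            spacegroup=self.spacegroup,
        )

    def select(self, mask: np.ndarray) -> "ReflectionSet":
        return ReflectionSet(
            hkl=self.hkl[mask],
            f_obs=self.f_obs[mask],
            cell=gemmi.UnitCell(*self.cell.parameters),
            sigma=None if self.sigma is None else self.sigma[mask],
            free=None if self.free is None else self.free[mask],
            d=self.d[mask],
            spacegroup=self.spacegroup,
        )


def d_spacings(cell: gemmi.UnitCell, hkl: np.ndarray) -> np.ndarray:
    hkl = np.asarray(hkl, dtype=int).reshape(-1, 3)
    return np.array([cell.calculate_d(tuple(int(x) for x in h)) for h in hkl])


def canonical_hemisphere(hkl: np.ndarray) -> np.ndarray:
    """Map each (h,k,l) to its Friedel-canonical representative.

    The representative is the member of {h, -h} that is lexicographically
    positive: h > 0, or h = 0 and k > 0, or h = k = 0 and l >= 0.
    """
    hkl = np.asarray(hkl, dtype=int).reshape(-1, 3)
    out = hkl.copy()
    h, k, l = hkl[:, 0], hkl[:, 1], hkl[:, 2]
    flip = (h < 0) | ((h == 0) & (k < 0)) | ((h == 0) & (k == 0) & (l < 0))
    out[flip] *= -1
    return out


def reduce_reflections(hkl, f_obs, sigma=None, free=None, tol: float = 1e-3):
    """Merge duplicate/Friedel-equivalent rows to unique reflections.

    Raises if duplicate amplitudes disagree by more than ``tol`` (relative).
    """
    hkl = canonical_hemisphere(hkl)
    f_obs = np.asarray(f_obs, float)
    order = np.lexsort((hkl[:, 2], hkl[:, 1], hkl[:, 0]))
    hkl, f_obs = hkl[order], f_obs[order]
    sigma = None if sigma is None else np.asarray(sigma, float)[order]
    free = None if free is None else np.asarray(free, bool)[order]
    uniq, first, inv, counts = np.unique(
        hkl, axis=0, return_index=True, return_inverse=True, return_counts=True
    )
    if np.any(counts > 1):
        sums = np.zeros(len(uniq))
        np.add.at(sums, inv, f_obs)
        means = sums / counts
        spread = np.zeros(len(uniq))
        np.maximum.at(spread, inv, np.abs(f_obs - means[inv]))
        scale = np.maximum(np.abs(means), 1e-30)
        bad = spread / scale > tol
        if np.any(bad):
            h = uniq[np.argmax(bad)]
            raise ValueError(
                f"duplicate reflection {tuple(h)} with inconsistent amplitudes"
            )
        f_out = means
    else:
        f_out = f_obs[first]
    sig_out = None if sigma is None else sigma[first]
    free_out = None if free is None else free[first]
    return uniq, f_out, sig_out, free_out


def full_sphere_hkl(cell: gemmi.UnitCell, d_min: float) -> np.ndarray:
    """All unique (Friedel-hemisphere) Miller indices with d >= d_min."""
    a, b, c = cell.parameters[:3]
    hmax = int(np.floor(a / d_min)) + 1
    kmax = int(np.floor(b / d_min)) + 1
    lmax = int(np.floor(c / d_min)) + 1
    h, k, l = np.meshgrid(np.arange(-hmax, hmax + 1),
                          np.arange(-kmax, kmax + 1),
                          np.arange(-lmax, lmax + 1), indexing="ij")
    hkl = np.column_stack([h.ravel(), k.ravel(), l.ravel()])
    hkl = np.unique(canonical_hemisphere(hkl), axis=0)
    hkl = hkl[np.any(hkl != 0, axis=1)]
    d = d_spacings(cell, hkl)
    return hkl[d >= d_min]


def read_reflections(path, dialect: Optional[str] = None,
                     convert_intensities: bool = False) -> ReflectionSet:
    """Read reflection amplitudes from MTZ or plain hkl text.

    The text dialect is whitespace-delimited ``h k l F [sigF] [free]``
    with ``#`` comments; the first non-comment line may be a header giving
    the cell as ``# CELL a b c alpha beta gamma`` (required for text files).
    """
    path = Path(path)
    if dialect is None:
        dialect = "mtz" if path.suffix.lower() == ".mtz" else "hkl-text"
    if dialect == "mtz":
        return _read_mtz(path, convert_intensities)
    if dialect == "hkl-text":
        return _read_hkl_text(path)
    raise ValueError(f"unsupported reflection dialect: {dialect}")


def _read_mtz(path, convert_intensities: bool) -> ReflectionSet:
    mtz = gemmi.read_mtz_file(str(path))
    labels = [c.label for c in mtz.columns]
    amp_col = next((l for l in ("F", "FP", "FOBS", "F-obs", "FOBS_X") if l in labels), None)
    data = np.array(mtz, copy=True)

    def col(label):
        return data[:, labels.index(label)]

    if amp_col is None:
        i_col = next((l for l in ("I", "IMEAN", "IOBS", "I-obs") if l in labels), None)
        if i_col is None:
            raise ValueError(f"{path}: no amplitude column (F/FP) found")
        if not convert_intensities:
            raise ValueError(
                f"{path}: intensity-only data; pass convert_intensities=True "
                "to use |F| = sqrt(max(I, 0)) (no French-Wilson treatment)"
            )
        f = np.sqrt(np.clip(col(i_col), 0.0, None))
    else:
        f = col(amp_col)
    hkl = np.column_stack([col("H"), col("K"), col("L")]).astype(int)
    sig_col = next((l for l in ("SIGF", "SIGFP", "SIGFOBS") if l in labels), None)
    sigma = col(sig_col) if sig_col else None
    free_col = next(
        (l for l in ("FreeR_flag", "FREE", "R-free-flags", "FreeRflag") if l in labels),
        None,
    )
    free = None
    if free_col:
        flags = col(free_col)
        # CCP4/PHENIX convention: the flag value held by the smallest class
        # marks the test set; most commonly 0.
        vals, counts = np.unique(flags[np.isfinite(flags)], return_counts=True)
        free_val = vals[np.argmin(counts)] if len(vals) > 1 else None
        free = flags == free_val if free_val is not None else None
    keep = np.isfinite(f)
    hkl, f = hkl[keep], f[keep]
    sigma = None if sigma is None else sigma[keep]
    free = None if free is None else free[keep]
    uhkl, uf, usig, ufree = reduce_reflections(hkl, f, sigma, free)
    return ReflectionSet(
        hkl=uhkl, f_obs=uf, sigma=usig, free=ufree,
        cell=gemmi.UnitCell(*mtz.cell.parameters),
        spacegroup=mtz.spacegroup.hm if mtz.spacegroup else "P 1",
    )


def _read_hkl_text(path) -> ReflectionSet:
    cell = None
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith("#"):
                parts = stripped[1:].split()
                if parts and parts[0].upper() == "CELL":
                    cell = gemmi.UnitCell(*[float(x) for x in parts[1:7]])
                continue
            parts = stripped.split()
            if len(parts) < 4:
                raise ValueError(f"{path}:{ln}: expected 'h k l F [sigF] [free]'")
            try:
                h, k, l = int(parts[0]), int(parts[1]), int(parts[2])
                f = float(parts[3])
                sig = float(parts[4]) if len(parts) > 4 else np.nan
                fr = bool(int(parts[5])) if len(parts) > 5 else False
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: unparseable field ({exc})") from exc
            rows.append((h, k, l, f, sig, fr))
    if cell is None:
        raise ValueError(f"{path}: no '# CELL a b c alpha beta gamma' header")
    if not rows:
        raise ValueError(f"{path}: no reflections")
    hkl = np.array([r[:3] for r in rows], dtype=int)
    f = np.array([r[3] for r in rows])
    sig = np.array([r[4] for r in rows])
    free = np.array([r[5] for r in rows], dtype=bool)
    has_sig = np.any(np.isfinite(sig))
    has_free = np.any(free)
    uhkl, uf, usig, ufree = reduce_reflections(
        hkl, f, sig if has_sig else None, free if (has_free or True) else None
    )
    return ReflectionSet(hkl=uhkl, f_obs=uf, sigma=usig if has_sig else None,
                         free=ufree, cell=cell)


def write_reflections(refl: ReflectionSet, path) -> None:
    """Write the plain hkl-text dialect (with cell header and free flags)."""
    with open(path, "w") as fh:
        a, b, c, al, be, ga = refl.cell.parameters
        fh.write(f"# CELL {a:.4f} {b:.4f} {c:.4f} {al:.3f} {be:.3f} {ga:.3f}\n")
        fh.write("# h k l F sigF free\n")
        sig = refl.sigma if refl.sigma is not None else np.zeros(refl.n)
        free = refl.free if refl.free is not None else np.zeros(refl.n, bool)
        for (h, k, l), f, s, fr in zip(refl.hkl, refl.f_obs, sig, free):
            fh.write(f"{h:5d} {k:5d} {l:5d} {f:14.6g} {s:12.6g} {int(fr)}\n")


# ---------------------------------------------------------------------------
# Density maps


@dataclass
class MapGrid:
    """Periodic density sampled on an n_a x n_b x n_c unit-cell grid."""

    values: np.ndarray
    cell: gemmi.UnitCell
    origin: tuple = (0.0, 0.0, 0.0)   # fractional coordinate of voxel (0,0,0)

    @property
    def shape(self):
        return self.values.shape

    def copy(self) -> "MapGrid":
        return MapGrid(self.values.copy(), gemmi.UnitCell(*self.cell.parameters),
                       tuple(self.origin))


def write_map(mapgrid: MapGrid, path) -> None:
    """Write a CCP4/MRC-2014 map readable by standard viewers."""
    vals = np.asarray(mapgrid.values, dtype=np.float32)
    if vals.ndim != 3:
        raise ValueError("map values must be a 3-D array")
    _validate_cell(mapgrid.cell)
    grid = gemmi.FloatGrid(*vals.shape)
    grid.set_unit_cell(gemmi.UnitCell(*mapgrid.cell.parameters))
    grid.spacegroup = gemmi.SpaceGroup("P1")
    np.asarray(grid.array)[...] = vals
    ccp4 = gemmi.Ccp4Map()
    ccp4.grid = grid
    ccp4.update_ccp4_header()
    ccp4.write_ccp4_map(str(path))


def read_map(path) -> MapGrid:
    ccp4 = gemmi.read_ccp4_map(str(path))
    grid = ccp4.grid
    return MapGrid(
        values=np.array(grid.array, dtype=float),
        cell=gemmi.UnitCell(*grid.unit_cell.parameters),
    )
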