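"""Coupling atoms to the grid potential and restrained dynamics under it.

The steering energy is U_EM = sum_j w_j V(r_j) with V trilinearly
interpolated on the periodic potential grid and w_j the per-atom coupling
weight (atomic mass by default; zero for uncoupled atoms).  Forces are the
analytic gradient of the trilinear interpolant, equivalent to finite
differences of neighbouring grid values.

Dynamics is Langevin (BAOAB splitting), which reduces exactly to velocity
Verlet when the friction is zero, in vacuum at constant volume and
temperature.  Units: kcal/mol, angstrom, amu, femtosecond.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import minimize as _scipy_minimize

from .forcefield import RestraintSet, Topology, compute_energy_forces
from .map_synthesis import GridPotential
from .model_io import AtomicModel

__all__ = [
    "CouplingSpec",
    "DynamicsParams",
    "map_energy_forces",
    "run_dynamics",
    "minimize",
    "anneal",
]

KB = 0.0019872041                 # kcal/mol/K
ACC = 4.184e-4                    # (amu A^2/fs^2) per (kcal/mol)


@dataclass
class CouplingSpec:
    """Which atoms feel the map, and with what weight (default atomic mass)."""

    coupled: np.ndarray            # bool per atom
    weights: np.ndarray            # per atom; ignored where not coupled

    def __post_init__(self):
        self.coupled = np.asarray(self.coupled, bool)
        self.weights = np.asarray(self.weights, float)
        if np.any(self.weights[self.coupled] <= 0):
            raise ValueError("coupling weights must be positive for coupled atoms")

    @classmethod
    def backbone(cls, model: AtomicModel) -> "CouplingSpec":
        return cls(coupled=model.backbone_mask(), weights=model.masses())

    @classmethod
    def all_heavy(cls, model: AtomicModel) -> "CouplingSpec":
        return cls(coupled=model.heavy_mask(), weights=model.masses())

    @classmethod
    def none(cls, n_atoms: int) -> "CouplingSpec":
        return cls(coupled=np.zeros(n_atoms, bool), weights=np.ones(n_atoms))


@dataclass
class DynamicsParams:
    timestep: float = 1.0          # fs
    temperature: float = 300.0     # K
    friction: float = 5.0          # 1/ps
    n_steps: int = 500
    seed: int = 0
    record_every: int = 0          # 0: record only the final frame

    def __post_init__(self):
        if not (0.0 < self.timestep <= 2.0):
            raise ValueError("timestep must be in (0, 2] fs")
        if self.temperature < 0:
            raise ValueError("temperature must be >= 0")


def map_energy_forces(coords: np.ndarray, potential: GridPotential,
                      coupling: CouplingSpec):
    """(U_EM, forces): trilinear interpolation of V and its analytic gradient.

    Positions are wrapped periodically into the cell for the lookup only.
    Uncoupled atoms contribute nothing and feel nothing.
    """
    xyz = np.asarray(coords, float).reshape(-1, 3)
    forces = np.zeros_like(xyz)
    sel = np.flatnonzero(coupling.coupled)
    if len(sel) == 0:
        return 0.0, forces
    V = potential.values
    na, nb, nc = V.shape
    dims = np.array([na, nb, nc], float)
    F = np.array(potential.cell.frac.mat.tolist())
    frac = (xyz[sel] @ F.T) % 1.0
    u = frac * dims
    i0 = np.floor(u).astype(int)
    t = u - i0
    i0 %= V.shape
    i1 = (i0 + 1) % np.array(V.shape)

    c = np.empty((len(sel), 2, 2, 2))
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                ix = i1[:, 0] if dx else i0[:, 0]
                iy = i1[:, 1] if dy else i0[:, 1]
                iz = i1[:, 2] if dz else i0[:, 2]
                c[:, dx, dy, dz] = V[ix, iy, iz]

    tx, ty, tz = t[:, 0], t[:, 1], t[:, 2]
    wx = np.stack([1 - tx, tx], axis=1)
    wy = np.stack([1 - ty, ty], axis=1)
    wz = np.stack([1 - tz, tz], axis=1)
    dwx = np.stack([-np.ones_like(tx), np.ones_like(tx)], axis=1)

    val = np.einsum("nxyz,nx,ny,nz->n", c, wx, wy, wz)
    ddx = np.einsum("nxyz,nx,ny,nz->n", c, dwx, wy, wz)
    ddy = np.einsum("nxyz,nx,ny,nz->n", c, wx, dwx, wz)
    ddz = np.einsum("nxyz,nx,ny,nz->n", c, wx, wy, dwx)

    w = coupling.weights[sel]
    energy = float(np.sum(w * val))
    # chain rule: d/dx = (dV/dt) * diag(n) * Fmat
    grad_t = np.stack([ddx, ddy, ddz], axis=1) * dims[None, :]
    grad_xyz = grad_t @ F
    forces[sel] = -w[:, None] * grad_xyz
    return energy, forces


def _total_energy_forces(xyz, topo, restraints, potential, coupling):
    e_md, f_md = compute_energy_forces(xyz, topo, restraints)
    if potential is not None and coupling is not None:
        e_em, f_em = map_energy_forces(xyz, potential, coupling)
    else:
        e_em, f_em = 0.0, 0.0
    return e_md + e_em, f_md + f_em


@dataclass
class Trajectory:
    frames: list = field(default_factory=list)
    energies: list = field(default_factory=list)

    @property
    def final(self) -> np.ndarray:
        return self.frames[-1]


def run_dynamics(model: AtomicModel, topo: Topology,
                 restraints: Optional[RestraintSet],
                 potential: Optional[GridPotential],
                 coupling: Optional[CouplingSpec],
                 params: DynamicsParams,
                 velocities: Optional[np.ndarray] = None):
    """Langevin (BAOAB) integration under U_MD + U_SS + U_EM.

    Returns (Trajectory, final_velocities).  With friction 0 the O-step is
    the identity and the scheme is plain velocity Verlet (NVE).  Velocities
    default to a seeded Maxwell-Boltzmann draw at the stage temperature.
    """
    xyz = model.xyz.copy()
    n = len(xyz)
    m = topo.masses[:, None]
    dt = params.timestep
    gamma = params.friction * 1e-3          # 1/ps -> 1/fs
    rng = np.random.default_rng(params.seed)
    if velocities is None:
        if params.temperature > 0:
            sigma_v = np.sqrt(KB * params.temperature * ACC / topo.masses)
            velocities = rng.normal(size=(n, 3)) * sigma_v[:, None]
        else:
            velocities = np.zeros((n, 3))
    v = velocities.copy()

    e, f = _total_energy_forces(xyz, topo, restraints, potential, coupling)
    traj = Trajectory()
    c1 = np.exp(-gamma * dt) if gamma > 0 else 1.0
    if gamma > 0 and params.temperature > 0:
        c2 = np.sqrt((1 - c1**2) * KB * params.temperature * ACC / topo.masses)[:, None]
    else:
        c2 = 0.0

    for step in range(params.n_steps):
        v += 0.5 * dt * (f * ACC) / m
        xyz += 0.5 * dt * v
        if gamma > 0:
            v = c1 * v + c2 * rng.normal(size=(n, 3))
        xyz += 0.5 * dt * v
        e, f = _total_energy_forces(xyz, topo, restraints, potential, coupling)
        v += 0.5 * dt * (f * ACC) / m
        if e > 1e6:
            _, _, comps = compute_energy_forces(xyz, topo, restraints, detail=True)
            worst = max(comps, key=comps.get)
            raise RuntimeError(
                f"energy diverged at step {step} ({e:.3g} kcal/mol); "
                f"worst term: {worst} = {comps[worst]:.3g}"
            )
        if params.record_every and (step + 1) % params.record_every == 0:
            traj.frames.append(xyz.copy())
            traj.energies.append(e)
    if not traj.frames or not np.array_equal(traj.frames[-1], xyz):
        traj.frames.append(xyz.copy())
        traj.energies.append(e)
    return traj, v


def kinetic_energy(velocities: np.ndarray, masses: np.ndarray) -> float:
    """Kinetic energy in kcal/mol from velocities in A/fs."""
    return float(0.5 * np.sum(masses[:, None] * velocities**2) / ACC)


def minimize(model: AtomicModel, topo: Topology,
             restraints: Optional[RestraintSet],
             potential: Optional[GridPotential],
             coupling: Optional[CouplingSpec],
             max_steps: int = 200, gtol: float = 1e-3) -> np.ndarray:
    """L-BFGS energy minimization; returns the relaxed coordinates."""
    shape = model.xyz.shape

    def fun(x):
        e, f = _total_energy_forces(x.reshape(shape), topo, restraints,
                                    potential, coupling)
        return e, -f.ravel()

    res = _scipy_minimize(fun, model.xyz.ravel(), jac=True, method="L-BFGS-B",
                          options={"maxiter": max_steps, "gtol": gtol})
    return res.x.reshape(shape)


def anneal(model: AtomicModel, topo: Topology,
           restraints: Optional[RestraintSet],
           potential: Optional[GridPotential],
           coupling: Optional[CouplingSpec],
           schedule, base_params: Optional[DynamicsParams] = None,
           seed: int = 0):
    """Sequential dynamics segments at the scheduled temperatures.

    ``schedule`` is a list of (temperature_K, n_steps); velocities carry over
    between segments, rescaled to the new temperature.  A temperature of 0
    runs gradient minimization instead of dynamics.
    Returns (final coordinates, segment log).
    """
    if not schedule:
        raise ValueError("empty annealing schedule")
    if base_params is None:
        base_params = DynamicsParams()
    current = model.copy()
    v = None
    log = []
    t_prev = None
    for seg_idx, (temp, n_steps) in enumerate(schedule):
        if temp <= 0:
            current.xyz = minimize(current, topo, restraints, potential,
                                   coupling, max_steps=max(50, n_steps))
            v = None
            log.append({"segment": seg_idx, "T": 0.0, "mode": "minimize"})
            t_prev = None
            continue
        if v is not None and t_prev and t_prev > 0:
            v = v * np.sqrt(temp / t_prev)
        params = DynamicsParams(
            timestep=base_params.timestep, temperature=temp,
            friction=base_params.friction, n_steps=n_steps,
            seed=seed + seg_idx,
        )
        traj, v = run_dynamics(current, topo, restraints, potential, coupling,
                               params, velocities=v)
        current.xyz = traj.final
        log.append({"segment": seg_idx, "T": temp, "mode": "dynamics",
                    "steps": n_steps})
        t_prev = temp
    return current.xyz, log
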