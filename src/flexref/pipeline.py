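"""The iterative real-space refinement loop.

Each iteration: compute F_calc and phases from the current model, scale to
F_obs and record R_work/R_free, build the sigma-A weighted 2mFo-DFc map
(free reflections excluded; optional sharpening or kicked averaging), turn
it into a steering potential, and run a segment of restrained dynamics (or
minimization) with atoms coupled to the potential.  The freshly fitted
model re-phases the next map.  The loop runs through a staged schedule —
backbone-only coupling at low xi first when the starting model is far from
the target, then all heavy atoms at higher xi, finally cooling to 0 K —
and stops when the cross-validation R factor stops improving.  The
best-R_free model seen is the one returned.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .evaluate import rmsd
from .fitting_engine import (CouplingSpec, DynamicsParams, anneal, minimize,
                             run_dynamics)
from .forcefield import assign_secondary_structure, build_topology
from .map_synthesis import density_to_potential, kicked_map, model_phased_map
from .model_io import AtomicModel, ReflectionSet
from .scattering import assign_free_flags, calc_structure_factors, fit_scale, r_factors

__all__ = ["Stage", "RefineSchedule", "RefinementRecord", "refine", "default_schedule"]


@dataclass
class Stage:
    """One leg of the staged protocol."""

    coupling: str = "all-heavy"        # 'backbone' | 'all-heavy'
    xi: float = 0.3                    # kcal/mol steering scale
    temperature: float = 300.0         # K; 0 -> gradient minimization
    md_steps: int = 500                # dynamics steps per map iteration
    map_iters: int = 6                 # map regenerations in this stage
    kick: Optional[tuple] = None       # (kick_rms A, n_kicks) or None
    sharpen_b: float = 0.0             # A^2 map sharpening
    blur_b: float = 0.0                # A^2 map blurring (cascade fitting)
    pre_minimize: int = 200            # L-BFGS steps before each dynamics leg
    anneal_schedule: Optional[list] = None  # [(T, steps), ...] overrides T

    def __post_init__(self):
        if self.xi < 0:
            raise ValueError("xi must be >= 0")
        if self.coupling not in ("backbone", "all-heavy"):
            raise ValueError(f"unknown coupling {self.coupling!r}")


@dataclass
class RefineSchedule:
    stages: list
    convergence_tol: float = 0.002     # min R_free gain per patience window
    patience: int = 3                  # map iterations
    r_free_floor: float = 0.0          # stop outright below this
    divergence_guard: float = 0.05     # stop if R_free > best + guard for patience
    grid_spacing: Optional[float] = None   # default d_min / 3
    free_fraction: float = 0.05

    def __post_init__(self):
        if not self.stages:
            raise ValueError("schedule needs at least one stage")


@dataclass
class RefinementRecord:
    """Per-iteration metrics and the refined model."""

    history: list = field(default_factory=list)
    final_model: AtomicModel = None    # best-R_free model
    last_model: AtomicModel = None     # model after the final iteration
    best_r_free: float = np.inf
    best_iteration: int = -1
    seed: int = 0
    stopped_early: bool = False
    stop_reason: str = ""

    def as_dataframe(self):
        import pandas as pd
        return pd.DataFrame(self.history)


def default_schedule(resolution: float, large_displacement: bool = True,
                     md_steps: int = 500, temperature: float = 150.0) -> RefineSchedule:
    """The staged protocol: backbone-only at xi ~ 0.1 for far-off starting
    models, all-heavy at xi 0.3 then 0.5, annealing at very low resolution,
    ending with cooling to 0 K.

    Early large-displacement stages additionally steer against blurred
    (resolution-lowered) maps whose long-range gradients capture regions that
    would otherwise sit on the flat clamped plateau (cascade fitting).  The
    fitting temperature default (150 K) trades sampling for stability of the
    simplified vacuum force field.
    """
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    T = temperature
    stages = []
    if large_displacement:
        stages.append(Stage(coupling="backbone", xi=0.1, temperature=T,
                            blur_b=200.0, md_steps=md_steps, map_iters=3))
        stages.append(Stage(coupling="backbone", xi=0.3, temperature=T,
                            blur_b=100.0, md_steps=md_steps, map_iters=3))
        stages.append(Stage(coupling="all-heavy", xi=0.3, temperature=T,
                            blur_b=40.0, md_steps=md_steps, map_iters=3))
    stages.append(Stage(coupling="all-heavy", xi=0.3, temperature=T,
                        md_steps=md_steps, map_iters=5))
    if resolution > 4.0:
        # simulated annealing leg: heat then cool to escape local minima
        stages.append(Stage(coupling="all-heavy", xi=0.3, temperature=T,
                            md_steps=md_steps, map_iters=2,
                            anneal_schedule=[(450.0, md_steps // 2),
                                             (300.0, md_steps // 2),
                                             (T, md_steps)]))
    stages.append(Stage(coupling="all-heavy", xi=0.5, temperature=T,
                        md_steps=md_steps, map_iters=4))
    stages.append(Stage(coupling="all-heavy", xi=0.5, temperature=0.0,
                        md_steps=md_steps, map_iters=2))
    return RefineSchedule(stages=stages, grid_spacing=resolution / 3.0,
                          patience=6)


def refine(model: AtomicModel, refl: ReflectionSet,
           schedule: Optional[RefineSchedule] = None,
           seed: int = 0,
           reference: Optional[AtomicModel] = None,
           verbose: bool = False) -> RefinementRecord:
    """Iteratively re-phase and flexibly fit `model` against `refl`.

    Free flags are auto-assigned (seeded) when absent.  ``reference``, if
    given, adds backbone r.m.s.d.-to-reference tracking to the history.
    One master seed fans out to flag assignment, velocities and kicks.
    """
    if schedule is None:
        schedule = default_schedule(refl.d_min)
    if refl.free is None:
        refl = assign_free_flags(refl, schedule.free_fraction, seed=seed)
    if not np.allclose(model.cell.parameters, refl.cell.parameters, atol=1e-2):
        raise ValueError("model and data unit cells disagree")
    grid_spacing = schedule.grid_spacing or refl.d_min / 3.0

    topo = build_topology(model)
    restraints = assign_secondary_structure(model, mode="geometric")
    current = model.copy()
    record = RefinementRecord(seed=seed)
    r_free_history = []
    iteration = 0
    stop = False
    fitted_since_eval = False

    for stage_idx, stage in enumerate(schedule.stages):
        if stop:
            break
        coupling = (CouplingSpec.backbone(current) if stage.coupling == "backbone"
                    else CouplingSpec.all_heavy(current))
        for map_iter in range(stage.map_iters):
            fc = calc_structure_factors(current, refl)
            scale = fit_scale(refl, fc)
            r_work, r_free = r_factors(refl, fc, scale)
            entry = {
                "iteration": iteration, "stage": stage_idx,
                "coupling": stage.coupling, "xi": stage.xi,
                "temperature": stage.temperature,
                "r_work": r_work, "r_free": r_free,
                "scale_k": scale.k, "scale_b": scale.b_overall,
            }
            if reference is not None:
                entry["backbone_rmsd"] = rmsd(current, reference, "backbone",
                                              superpose=False)
                entry["backbone_rmsd_superposed"] = rmsd(
                    current, reference, "backbone", superpose=True)
            record.history.append(entry)
            fitted_since_eval = False
            if verbose:
                print(f"[{iteration:3d}] stage {stage_idx} "
                      f"Rwork {r_work:.4f} Rfree {r_free:.4f}"
                      + (f" rmsd {entry.get('backbone_rmsd', float('nan')):.2f}"
                         if reference is not None else ""))

            if r_free is not None and r_free < record.best_r_free:
                record.best_r_free = r_free
                record.best_iteration = iteration
                record.final_model = current.copy()
            r_free_history.append(r_free)

            # convergence / divergence checks on the R_free trace; only in
            # full-detail stages — the R trace legitimately wanders while the
            # steering map is blurred
            if r_free is not None and r_free <= schedule.r_free_floor:
                record.stop_reason = "reached R_free floor"
                stop = True
                break
            window = schedule.patience
            if stage.blur_b == 0 and len(r_free_history) > window:
                prev_best = np.nanmin(r_free_history[:-window])
                recent_best = np.nanmin(r_free_history[-window:])
                if recent_best > prev_best - schedule.convergence_tol:
                    record.stop_reason = "R_free converged"
                    stop = True
                    break
                if recent_best > record.best_r_free + schedule.divergence_guard:
                    record.stop_reason = "R_free diverging"
                    record.stopped_early = True
                    stop = True
                    break

            # build the steering potential from the model-phased map
            if stage.kick is not None:
                kick_rms, n_kicks = stage.kick
                density = kicked_map(current, refl, kick_rms, n_kicks,
                                     seed=seed + 1000 + iteration,
                                     grid_spacing=grid_spacing,
                                     b_sharp=stage.sharpen_b)
            else:
                density = model_phased_map(current, refl, grid_spacing,
                                           b_sharp=stage.sharpen_b,
                                           b_blur=stage.blur_b, fc=fc)
            potential = density_to_potential(density, xi=stage.xi)

            seg_seed = seed + 7919 * (iteration + 1)
            if stage.pre_minimize and stage.temperature > 0:
                current.xyz = minimize(current, topo, restraints, potential,
                                       coupling, max_steps=stage.pre_minimize)
            if stage.anneal_schedule:
                new_xyz, _ = anneal(current, topo, restraints, potential,
                                    coupling, stage.anneal_schedule,
                                    seed=seg_seed)
            elif stage.temperature > 0:
                params = DynamicsParams(temperature=stage.temperature,
                                        n_steps=stage.md_steps, seed=seg_seed)
                traj, _ = run_dynamics(current, topo, restraints, potential,
                                       coupling, params)
                new_xyz = traj.final
            else:
                new_xyz = minimize(current, topo, restraints, potential,
                                   coupling, max_steps=stage.md_steps)
            current.xyz = new_xyz
            fitted_since_eval = True
            iteration += 1

    # evaluate the model produced by the last fitting segment (skip when the
    # loop stopped right after an evaluation: nothing moved since)
    if not fitted_since_eval:
        record.last_model = current
        if record.final_model is None:
            record.final_model = current.copy()
        if not record.stop_reason:
            record.stop_reason = "schedule exhausted"
        return record
    fc = calc_structure_factors(current, refl)
    scale = fit_scale(refl, fc)
    r_work, r_free = r_factors(refl, fc, scale)
    entry = {"iteration": iteration, "stage": len(schedule.stages) - 1,
             "coupling": "final", "xi": 0.0, "temperature": 0.0,
             "r_work": r_work, "r_free": r_free,
             "scale_k": scale.k, "scale_b": scale.b_overall}
    if reference is not None:
        entry["backbone_rmsd"] = rmsd(current, reference, "backbone", superpose=False)
        entry["backbone_rmsd_superposed"] = rmsd(current, reference, "backbone",
                                                 superpose=True)
    record.history.append(entry)
    if r_free is not None and r_free < record.best_r_free:
        record.best_r_free = r_free
        record.best_iteration = iteration
        record.final_model = current.copy()
    record.last_model = current
    if record.final_model is None:
        record.final_model = current.copy()
    if not record.stop_reason:
        record.stop_reason = "schedule exhausted"
    return record
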