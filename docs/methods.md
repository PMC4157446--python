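# Methods

## Model and procedure

`flexref` performs real-space crystallographic refinement by molecular
dynamics flexible fitting against model-phased maps. One refinement
iteration does the following, starting from the current model:

1. **Structure factors.** `F_calc(h) = sum_sym sum_j occ_j f_j(s)
   exp(-B_j s_tol^2) exp(2 pi i h.x_j)` by direct summation over atoms with
   Cromer-Mann 4-Gaussian form factors (International Tables vol. C
   coefficients, via gemmi), symmetry expanded to P1 in real space. An
   FFT-gridding path (atoms splatted as the analytic real-space transform of
   the Cromer-Mann Gaussians, with an anti-aliasing blur that is removed in
   reciprocal space) is available for large models and agrees with the
   direct sum to better than 1e-3 relative amplitude error on d_min/4 grids.
2. **Scaling and R factors.** A two-parameter scale
   `|F_obs| ~ k exp(-B_overall s_tol^2) |F_calc|` is least-squares fitted on
   the working set (bounded 1-D search over `B_overall`, closed-form `k`).
   `R = sum||Fo| - k'|Fc|| / sum|Fo|` over the work and free sets separately.
   No bulk-solvent model is included; the overall scale absorbs gross
   effects, so absolute R values on measured data run somewhat higher than a
   full-pipeline refinement would give. For the synthetic suite this is
   irrelevant (no solvent in the data generator).
3. **Sigma-A weighting.** Per resolution shell (equal-count shells in s^2,
   at least 30 working reflections each), normalized amplitudes
   `E_o, E_c` are formed from shell means. The moment estimator
   `sigma_A = clip(corr(E_o^2, E_c^2), 0, 1)^(1/4)` is used — for acentric
   data the correlation of normalized intensities equals `sigma_A^4` — with
   a shrinkage floor at `2/sqrt(n_shell)` so sampling noise in an
   uninformative shell maps to `sigma_A = 0` rather than to
   `noise^(1/4)`. `D = sigma_A sqrt(<|Fo|^2>/<|Fc|^2>)` restores scale;
   the figure of merit is `m = I1(X)/I0(X)` (acentric) or `tanh(X/2)`
   (centric) with `X = 2 sigma_A E_o E_c / (1 - sigma_A^2)`. This is a
   deliberately simple estimator with the correct perfect-model and
   uncorrelated-model limits; a maximum-likelihood estimator would be a
   drop-in replacement.
4. **Map.** Coefficients `(2m|Fo| - D|Fc|) exp(i phi_calc)` per working
   reflection; free reflections contribute nothing to any steering map;
   missing amplitudes fall back to `D|Fc|`. Optional B-factor sharpening
   (`exp(+B s_tol^2)`), blurring (see cascade below), or kicked averaging
   (mean map over several randomly perturbed copies of the model, reducing
   model bias). Real-space synthesis by inverse FFT with Friedel completion
   on a grid of spacing d_min/3 (FFT-friendly dimensions).
5. **Steering potential.** The map is converted voxel-wise to
   `V = xi (1 - (Phi' - Phi_thr)/(Phi_max - Phi_thr))`, `Phi' = max(Phi,
   Phi_thr)`, so `V` spans `[0, xi]`, is zero at the density maximum and
   clamps flat below the threshold. The default `Phi_thr = 0` treats the
   negative and noise regions of the difference-style map as the solvent
   floor; an absolute value or quantile can be supplied instead.
6. **Fitting.** Coupled atoms (backbone-only or all heavy atoms; weights =
   atomic masses) feel `-w grad V` with trilinear interpolation and the
   analytic gradient of the interpolant. A short L-BFGS minimization
   precedes each dynamics leg; Langevin dynamics (BAOAB splitting, velocity
   Verlet at zero friction) then samples under `U_MD + U_SS + U_EM`.
   The fitted model re-phases the next map.

The loop runs through a staged schedule and keeps the best-`R_free` model.
Convergence: stop when the best `R_free` fails to improve by 0.002 over 6
consecutive full-detail map iterations, or worsens by more than 0.05 over
that window (divergence guard). Blurred-map stages are exempt from the test
because their R trace legitimately wanders.

## Force field

`U_MD` is intentionally minimal: harmonic bonds `k(r-r0)^2` and angles
`k(theta-theta0)^2` with equilibria measured from idealized CCD residue
templates (biotite) plus standard peptide-link values; harmonic wrapped
impropers for C-alpha chirality (template-derived target) and carbonyl
planarity; omega torsions restrained to trans (180°, cis only by flag); and
a soft-core repulsion `eps (1 - r/r_c)^2` for `r < r_c = 0.75 (R_i + R_j)`
between pairs beyond 1-3 exclusions, `eps = 25` kcal/mol. No electrostatics,
no dispersion, vacuum. The strong short-range repulsion matters: the map
term rewards piling atoms into density, and without a firm excluded-volume
wall a model collapses into its own blobs. Residues without a usable
template fall back to harmonic distance restraints on their initial
geometry (rigid-body-like), with a warning.

`U_SS` holds phi/psi of helix/sheet residues at (-57°, -47°)/(-119°, 113°)
with k = 150 kcal/mol/rad^2 and helical O(i)-N(i+4) hydrogen-bond distances
at 2.9 Å with k = 30 kcal/mol/Å^2 — NAMD-ssrestraints-class stiffness.
Softer values let helix ends register-shift into adjacent density at low
resolution. The assignment (geometric, from initial phi/psi windows, runs of
three or more; or from an annotation) is made once from the input model and
never updated, so secondary-structure changes cannot occur during
refinement — a known limitation shared with the approach this implements.
Optional NCS restraints pull each symmetry copy toward the group consensus
after least-squares superposition; gradients hold the transforms fixed at
their least-squares values (envelope approximation, verified against finite
differences at 1e-3).

All analytic gradients are verified against central finite differences to
1e-4 relative; every internal term obeys Newton's third law to 1e-8 and is
invariant under rigid motion.

## Default schedule and its parameters

| stage | coupling | xi (kcal/mol) | map blur B (Å^2) | T (K) | map iters |
|-------|----------|----|-----|-----|----|
| 1 | backbone | 0.1 | 200 | 150 | 3 |
| 2 | backbone | 0.3 | 100 | 150 | 3 |
| 3 | all-heavy | 0.3 | 40 | 150 | 3 |
| 4 | all-heavy | 0.3 | 0 | 150 | 5 |
| (d_min > 4 Å) | all-heavy | 0.3 | 0 | anneal 450→300→150 | 2 |
| 5 | all-heavy | 0.5 | 0 | 150 | 4 |
| 6 | all-heavy | 0.5 | 0 | 0 (minimize) | 2 |

Stages 1–3 appear only when the starting model is flagged as far from the
target (> ~2 Å r.m.s.d.); 500 dynamics steps of 1 fs per map iteration,
friction 5 ps^-1, Maxwell-Boltzmann velocities re-drawn each leg from the
stage seed.

Two choices deserve comment. **Cascade blurring**: the clamped potential is
flat outside the molecular envelope, so a region displaced by ~10 Å feels no
force from a full-detail map; steering first against strongly blurred maps
(B = 200 → 100 → 40 Å^2) gives those regions a long-range gradient, and
detail is restored once they are captured. Multi-resolution cascades are
established practice in density-guided fitting. **Fitting temperature
150 K**: with the minimal vacuum force field, 300 K thermal motion degrades
a well-placed model faster than weak early maps can correct it; at 150 K the
same schedule recovers hinge-bent models to sub-Å backbone accuracy. The
temperature is a schedule parameter, and the annealing leg still heats to
450 K where barrier crossing is needed.

Integration units: kcal/mol, Å, amu, fs; `k_B = 0.0019872` kcal/mol/K;
1 kcal/mol = 4.184e-4 amu Å^2/fs^2.

## Synthetic study conditions

The generator emulates a controlled refinement experiment with a known
answer. The target is an ideal-geometry polyalanine (backbone + C-beta)
helix hairpin — two 15-residue arms joined by a 4-residue turn chosen so the
packed arms are clash-free — in a P1 cell padded by 10 Å, B = 20 Å^2
throughout. Data are `|F_calc(target)|` for all unique reflections to
d_min = 4 Å by default (error-free; optional B = 35 Å^2 amplitude smoothing
and multiplicative log-normal noise), with 5% of reflections flagged free
(seeded). The search model rotates the second arm 30° about the hinge
C-alpha (axis perpendicular to both arm directions) and adds 0.3 Å r.m.s.
jitter, giving ~3.5 Å backbone r.m.s.d. (superposed) from the target.

What the toys deliberately omit: solvent (and hence bulk-solvent scaling),
measurement noise by default, side chains beyond C-beta, crystallographic
symmetry (exercised separately in scattering tests), and B-factor
heterogeneity. Passing the recovery suite therefore demonstrates that the
iterative map/fit machinery converges across a large hinge motion at low
resolution under clean conditions; it does not certify performance on
measured data, where solvent modelling, data quality and side-chain fitting
dominate the attainable R values.

**P1 origin note.** Amplitudes are invariant under global translation, so in
P1 nothing pins the refined model to the target's origin: over many
re-phasing iterations the model (with its self-consistent maps) drifts as a
rigid body. All recovery metrics are therefore computed after least-squares
superposition, and map-vs-map correlations superpose the model before
re-phasing. In space groups with symmetry the origin is (partly) fixed and
this freedom largely disappears.

## Numerical choices and degenerate inputs

- Grid spacing d_min/3 for maps (Shannon-safe); FFT dimensions rounded to
  fast sizes and large enough to hold every Miller index without aliasing.
- Duplicate reflections are merged after mapping to a canonical Friedel
  hemisphere; amplitudes disagreeing beyond 1e-3 relative raise an error.
- Intensity-only data are refused unless conversion is requested
  (`|F| = sqrt(max(I, 0))`; no French-Wilson treatment).
- Alternate locations: highest-occupancy conformer kept at read time.
  Hydrogens are ignored by the scattering model and carry no repulsion.
- `fit_scale` requires ≥ 20 working reflections; sigma-A estimation ≥ 50,
  with thin shells merged automatically.
- Flat maps (max = threshold) are rejected when building the potential.
- Overlapping atoms (r < 0.1 Å) get a capped repulsive force; dynamics
  aborts with a per-term diagnostic if the energy exceeds 1e6 kcal/mol.
- Seeds: one master seed fans out deterministically to free-flag assignment,
  per-leg velocities and map kicks; a full refinement run is bit-reproducible
  for a fixed seed.

## Problem sizes

The recovery suite and the acceptance script use the 34-residue hairpin
(170 atoms, ~2,450 reflections at 4 Å), five seeds, ~17 map iterations and
~10^4 dynamics steps per run — about one minute per seed on one CPU. These
sizes were chosen so the full ground-truth experiment, not a cut-down proxy,
runs comfortably at a desk; the machinery itself is size-agnostic and the
FFT structure-factor path exists for models where direct summation becomes
the bottleneck.

## Known limitations

- The simplified force field cannot reproduce the packing quality of a full
  force field; side-chain placement (beyond C-beta) is untested.
- No bulk-solvent correction and no individual B-factor refinement: absolute
  R factors on measured data will sit above those from a full crystallographic
  pipeline, by a roughly resolution-independent offset.
- Secondary-structure assignments are frozen at iteration 0.
- The sigma-A moment estimator is conservative (shrinkage) and per-shell;
  anisotropy and twinning are out of scope, as are mmCIF models and
  anomalous data.
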