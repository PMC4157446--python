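"""Sigma-A weighted 2mFo-DFc maps and their conversion to a steering potential.

The map coefficients are (2 m |F_obs| - D |F_calc|) exp(i phi_calc) per
working reflection; cross-validation (free) reflections are excluded from
every map used to steer the fit.  The density is turned into a grid
potential

    V(r) = xi * [1 - (max(Phi(r), Phi_thr) - Phi_thr) / (Phi_max - Phi_thr)]

which is 0 at the density maximum, rises as density falls, and is clamped
flat at xi wherever the density is at or below the threshold (solvent/noise
floor), so atoms there feel no gradient.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import gemmi
import numpy as np
from scipy import fft as sfft
from scipy.special import i0e, i1e

from .model_io import AtomicModel, MapGrid, ReflectionSet
from .scattering import StructureFactorSet, calc_structure_factors

__all__ = [
    "SigmaAModel",
    "GridPotential",
    "estimate_sigmaA",
    "map_coefficients",
    "sharpen",
    "synthesize_map",
    "kicked_map",
    "density_to_potential",
    "centric_flags",
    "model_phased_map",
]


def centric_flags(refl: ReflectionSet, symmetry=None) -> np.ndarray:
    """True where a symmetry rotation maps h to -h (centric reflection).

    In P1 (identity only) every reflection is acentric.
    """
    hkl = refl.hkl
    out = np.zeros(len(hkl), dtype=bool)
    if symmetry is None:
        return out
    for R, _t in symmetry:
        Rt = np.rint(R).astype(int) if np.allclose(R, np.rint(R)) else None
        if Rt is None:
            continue
        mapped = hkl @ Rt   # row vector h times R (acts on fractional coords)
        out |= np.all(mapped == -hkl, axis=1)
    return out


@dataclass
class SigmaAModel:
    """Per-resolution-shell model-quality parameters.

    ``shells`` rows: (stol2_lo, stol2_hi, D, sigmaA, mean_fom). D maps
    |F_calc| onto the F_obs scale; sigmaA in [0, 1) measures phase quality.
    """

    shells: np.ndarray   # (n_shells, 5)

    def shell_of(self, stol: np.ndarray) -> np.ndarray:
        s2 = np.asarray(stol) ** 2
        edges = self.shells[:, 1]
        idx = np.searchsorted(edges[:-1], s2, side="right")
        return np.clip(idx, 0, len(self.shells) - 1)

    def params_for(self, stol: np.ndarray):
        """(sigmaA, D) per reflection."""
        idx = self.shell_of(stol)
        return self.shells[idx, 3], self.shells[idx, 2]


def figure_of_merit(sigma_a, e_obs, e_calc, centric) -> np.ndarray:
    """m = <cos(phase error)>: I1/I0(X) acentric, tanh(X/2) centric,
    with X = 2 sigmaA Eo Ec / (1 - sigmaA^2)."""
    sa = np.clip(sigma_a, 0.0, 0.999)
    x = 2.0 * sa * e_obs * e_calc / (1.0 - sa**2)
    m = np.where(centric, np.tanh(x / 2.0), i1e(x) / i0e(x))
    return np.clip(m, 0.0, 1.0)


def estimate_sigmaA(refl: ReflectionSet, fc: StructureFactorSet,
                    n_shells: int = 10, centric: Optional[np.ndarray] = None,
                    min_per_shell: int = 30) -> SigmaAModel:
    """Moment estimator of sigma_A and D per resolution shell.

    Uses working reflections only.  Per shell the amplitudes are normalized
    by their shell means (E_o, E_c); for acentric data the correlation of
    E_o^2 with E_c^2 equals sigma_A^4, giving the moment estimate
    sigma_A = corr^(1/4) (clamped to [0, 0.999]).
    D = sigma_A * sqrt(<|F_obs|^2> / <|F_calc|^2>) restores the scale.
    """
    work = refl.work_mask()
    if work.sum() < 50:
        raise ValueError("need at least 50 working reflections")
    n_shells = max(1, min(n_shells, work.sum() // min_per_shell))
    s2 = refl.stol**2
    order = np.argsort(s2[work])
    widx = np.flatnonzero(work)[order]
    splits = np.array_split(widx, n_shells)

    fo_all = refl.f_obs
    fc_all = fc.amplitude
    shells = []
    for shell_idx in splits:
        lo = s2[shell_idx].min()
        hi = s2[shell_idx].max()
        fo = fo_all[shell_idx]
        fcs = fc_all[shell_idx]
        mo2 = np.mean(fo**2)
        mc2 = np.mean(fcs**2)
        if mo2 <= 0 or mc2 <= 0:
            shells.append((lo, hi, 0.0, 0.0, 0.0))
            continue
        eo2 = fo**2 / mo2
        ec2 = fcs**2 / mc2
        if np.std(eo2) < 1e-12 or np.std(ec2) < 1e-12:
            cc = 1.0 if np.allclose(fo, fcs) else 0.0
        else:
            cc = float(np.corrcoef(eo2, ec2)[0, 1])
        # shrink toward zero below the sampling-noise floor of the
        # correlation (~2/sqrt(n)); corr^(1/4) would otherwise turn pure
        # noise into a sizeable sigma_A
        floor = 2.0 / np.sqrt(len(shell_idx))
        cc_adj = max((cc - floor) / max(1.0 - floor, 1e-6), 0.0)
        sigma_a = float(np.clip(cc_adj ** 0.25, 0.0, 0.999))
        d_val = sigma_a * np.sqrt(mo2 / mc2)
        cen = np.zeros(len(shell_idx), bool) if centric is None else centric[shell_idx]
        m = figure_of_merit(sigma_a, np.sqrt(eo2), np.sqrt(ec2), cen)
        shells.append((lo, hi, d_val, sigma_a, float(np.mean(m))))
    arr = np.array(shells)
    # make shell edges contiguous over the full resolution range
    arr[0, 0] = 0.0
    for i in range(1, len(arr)):
        arr[i, 0] = arr[i - 1, 1]
    arr[-1, 1] = np.inf
    return SigmaAModel(shells=arr)


def map_coefficients(refl: ReflectionSet, fc: StructureFactorSet,
                     sa: SigmaAModel, exclude_free: bool = True,
                     centric: Optional[np.ndarray] = None) -> StructureFactorSet:
    """2mFo-DFc coefficients with model phases.

    Free reflections get coefficient 0 when ``exclude_free`` (the default for
    any map that steers fitting); reflections with missing F_obs fall back to
    D|F_calc| (pure model term).
    """
    sigma_a, d_vals = sa.params_for(fc.stol)
    # normalized amplitudes from shell means of the working set
    shell_idx = sa.shell_of(fc.stol)
    work = refl.work_mask()
    n_sh = len(sa.shells)
    mo2 = np.ones(n_sh)
    mc2 = np.ones(n_sh)
    for s in range(n_sh):
        sel = (shell_idx == s) & work
        if sel.sum() > 0:
            mo2[s] = max(np.mean(refl.f_obs[sel] ** 2), 1e-30)
            mc2[s] = max(np.mean(fc.amplitude[sel] ** 2), 1e-30)
    e_obs = refl.f_obs / np.sqrt(mo2[shell_idx])
    e_calc = fc.amplitude / np.sqrt(mc2[shell_idx])
    cen = np.zeros(refl.n, bool) if centric is None else centric
    m = figure_of_merit(sigma_a, e_obs, e_calc, cen)

    phase = np.exp(1j * fc.phase)
    missing = ~np.isfinite(refl.f_obs)
    amp = 2.0 * m * refl.f_obs - d_vals * fc.amplitude
    amp = np.where(missing, d_vals * fc.amplitude, amp)
    coeff = amp * phase
    if exclude_free and refl.free is not None:
        coeff = np.where(refl.free, 0.0 + 0.0j, coeff)
    return StructureFactorSet(hkl=refl.hkl.copy(), f=coeff, stol=fc.stol.copy())


def sharpen(coeffs: StructureFactorSet, b_sharp: float) -> StructureFactorSet:
    """Scale amplitudes by exp(+B_sharp stol^2); phases untouched."""
    if b_sharp < 0:
        raise ValueError("B_sharp must be >= 0 (use a negative exponent to blur)")
    out = coeffs.copy()
    out.f = out.f * np.exp(b_sharp * out.stol**2)
    return out


def _choose_dims(cell: gemmi.UnitCell, grid_spacing: float, hkl: np.ndarray):
    dims = []
    for axis, length in enumerate(cell.parameters[:3]):
        n = sfft.next_fast_len(max(4, int(np.ceil(length / grid_spacing))))
        h_max = int(np.abs(hkl[:, axis]).max()) if len(hkl) else 0
        while n < 2 * h_max + 2:
            n = sfft.next_fast_len(n + 1)
        dims.append(n)
    return tuple(dims)


def synthesize_map(coeffs: StructureFactorSet, cell: gemmi.UnitCell,
                   grid_spacing: float, dims: Optional[tuple] = None) -> MapGrid:
    """Inverse Fourier synthesis Phi(x) = (1/V) sum_h c_h exp(-2 pi i h.x).

    Friedel completion (conjugate at -h) makes the output real; grid
    dimensions are rounded up to FFT-friendly sizes.
    """
    hkl = coeffs.hkl
    if dims is None:
        dims = _choose_dims(cell, grid_spacing, hkl)
    na, nb, nc = dims
    C = np.zeros(dims, dtype=complex)
    h = hkl[:, 0] % na
    k = hkl[:, 1] % nb
    l = hkl[:, 2] % nc
    C[h, k, l] = coeffs.f
    hm = (-hkl[:, 0]) % na
    km = (-hkl[:, 1]) % nb
    lm = (-hkl[:, 2]) % nc
    # Friedel mate; (0,0,0) and self-conjugate points must not be doubled
    self_conj = (h == hm) & (k == km) & (l == lm)
    C[hm[~self_conj], km[~self_conj], lm[~self_conj]] = np.conj(coeffs.f[~self_conj])
    rho = sfft.fftn(C).real / cell.volume
    return MapGrid(values=rho, cell=gemmi.UnitCell(*cell.parameters))


@dataclass
class GridPotential:
    """Density-derived steering potential on the unit-cell grid.

    values in [0, xi] kcal/mol (per unit atom weight): 0 at the density
    maximum, xi in clamped (below-threshold) regions.
    """

    values: np.ndarray
    cell: gemmi.UnitCell
    xi: float
    phi_thr: float
    phi_max: float

    @property
    def shape(self):
        return self.values.shape


def density_to_potential(mapgrid: MapGrid, xi: float,
                         phi_thr: float = 0.0,
                         thr_quantile: Optional[float] = None) -> GridPotential:
    """Convert density to the clamped linear steering potential.

    ``phi_thr`` is an absolute density threshold (default 0: the natural
    solvent/noise floor of a difference-style map); alternatively
    ``thr_quantile`` picks the threshold as a voxel-value quantile.
    """
    phi = np.asarray(mapgrid.values, float)
    if thr_quantile is not None:
        phi_thr = float(np.quantile(phi, thr_quantile))
    phi_max = float(phi.max())
    if not (phi_max > phi_thr):
        raise ValueError("flat map: Phi_max must exceed Phi_thr")
    clamped = np.maximum(phi, phi_thr)
    values = xi * (1.0 - (clamped - phi_thr) / (phi_max - phi_thr))
    return GridPotential(values=values, cell=gemmi.UnitCell(*mapgrid.cell.parameters),
                         xi=xi, phi_thr=phi_thr, phi_max=phi_max)


# ---------------------------------------------------------------------------
# Full model-phased map pipeline (used by the refinement loop and kicked maps)


def model_phased_map(model: AtomicModel, refl: ReflectionSet,
                     grid_spacing: Optional[float] = None,
                     b_sharp: float = 0.0,
                     b_blur: float = 0.0,
                     exclude_free: bool = True,
                     n_shells: int = 10,
                     dims: Optional[tuple] = None,
                     fc: Optional[StructureFactorSet] = None) -> MapGrid:
    """F_calc -> sigma_A -> 2mFo-DFc (-> sharpen/blur) -> real-space map.

    ``b_blur`` applies exp(-B stol^2) to the coefficients, lowering the
    effective resolution of the steering map.  Early fitting stages use a
    strongly blurred map whose long-range gradients capture far-displaced
    regions (cascade fitting); later stages restore full detail.
    """
    if grid_spacing is None:
        grid_spacing = refl.d_min / 3.0
    if fc is None:
        fc = calc_structure_factors(model, refl)
    cen = centric_flags(refl, model.symmetry)
    sa = estimate_sigmaA(refl, fc, n_shells=n_shells, centric=cen)
    coeffs = map_coefficients(refl, fc, sa, exclude_free=exclude_free, centric=cen)
    if b_sharp > 0:
        coeffs = sharpen(coeffs, b_sharp)
    if b_blur > 0:
        coeffs = coeffs.copy()
        coeffs.f = coeffs.f * np.exp(-b_blur * coeffs.stol**2)
    return synthesize_map(coeffs, model.cell, grid_spacing, dims=dims)


def kicked_map(model: AtomicModel, refl: ReflectionSet, kick_rms: float,
               n_kicks: int, seed: int, grid_spacing: Optional[float] = None,
               b_sharp: float = 0.0, exclude_free: bool = True,
               n_shells: int = 10) -> MapGrid:
    """Average of maps phased by randomly perturbed copies of the model.

    Each kick displaces every atom by zero-mean Gaussian noise of r.m.s.
    magnitude ``kick_rms`` (A), reruns the full map pipeline with the new
    phases (same F_obs), and the voxel-wise mean map is returned.
    """
    if kick_rms <= 0:
        raise ValueError("kick_rms must be positive")
    if n_kicks < 2:
        raise ValueError("need at least 2 kicks")
    if grid_spacing is None:
        grid_spacing = refl.d_min / 3.0
    dims = _choose_dims(model.cell, grid_spacing, refl.hkl)
    rng = np.random.default_rng(seed)
    acc = np.zeros(dims)
    sigma = kick_rms / np.sqrt(3.0)
    for _ in range(n_kicks):
        kicked = model.with_xyz(model.xyz + rng.normal(0.0, sigma, model.xyz.shape))
        m = model_phased_map(kicked, refl, grid_spacing, b_sharp=b_sharp,
                             exclude_free=exclude_free, n_shells=n_shells, dims=dims)
        acc += m.values
    return MapGrid(values=acc / n_kicks, cell=gemmi.UnitCell(*model.cell.parameters))
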