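"""Structure factors, least-squares objective, normal equations, covariance.

Intensities are modelled as I_calc = scale * |F|^2 with F the multipolar
structure factor summed over all symmetry images of the asymmetric unit.
The normal matrix A_ij = sum_H W_H (dI/dx_i)(dI/dx_j) is the Gauss-Newton
approximation; its inverse B is the parameter variance-covariance matrix,
with e.s.d.'s scaled by the goodness of fit when the weights are not exact
inverse variances.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import factorial

import numpy as np
from scipy.special import spherical_jn

from .elements import DEFORMATION_POWERS
from .harmonics import HARMONIC_TERMS, NORMALIZATION
from .model import (
    CrystalModel,
    ParameterVector,
    pack_parameters,
    unpack_parameters,
)

# central finite-difference steps for nonlinear parameters
FD_STEPS = {"xyz": 1e-5, "uij": 1e-5, "kappa": 1e-4, "kappa_prime": 1e-4}


# ---------------------------------------------------------------------------
# reflection data


@dataclass
class ReflectionSet:
    """Observed reflection list with weights W_H (default c / sigma_I^2)."""

    hkl: np.ndarray       # (n, 3) int
    i_obs: np.ndarray
    sigma_i: np.ndarray
    weight: np.ndarray

    def __post_init__(self):
        self.hkl = np.asarray(self.hkl, int)
        self.i_obs = np.asarray(self.i_obs, float)
        self.sigma_i = np.asarray(self.sigma_i, float)
        self.weight = np.asarray(self.weight, float)
        if np.any(self.sigma_i <= 0):
            raise ValueError("sigma_I must be > 0")
        if np.any(self.weight <= 0):
            raise ValueError("weights must be > 0")

    @classmethod
    def from_intensities(cls, hkl, i_obs, sigma_i, weight_c=1.0):
        sigma_i = np.asarray(sigma_i, float)
        return cls(hkl=np.asarray(hkl, int), i_obs=np.asarray(i_obs, float),
                   sigma_i=sigma_i, weight=weight_c / sigma_i**2)

    def __len__(self):
        return len(self.i_obs)

    def resolution_s(self, cell):
        return cell.resolution_s(self.hkl)

    def filter_i_over_sigma(self, cutoff=0.35):
        """Keep reflections with I/sigma > cutoff; returns (subset, n_removed)."""
        keep = self.i_obs / self.sigma_i > cutoff
        sub = ReflectionSet(hkl=self.hkl[keep], i_obs=self.i_obs[keep],
                            sigma_i=self.sigma_i[keep], weight=self.weight[keep])
        return sub, int(np.sum(~keep))


# ---------------------------------------------------------------------------
# scattering factors


def _radial_fourier(n, zeta, l, k, nodes=240):
    """J_l(n, zeta; k) = zeta^(n+3)/(n+2)! * int r^(n+2) e^(-zeta r) j_l(kr) dr.

    Numeric Gauss-Legendre quadrature, vectorized over the k array.
    J_0(n, zeta; 0) = 1 (one electron).
    """
    rmax = (n + 30.0) / zeta
    x, w = np.polynomial.legendre.leggauss(nodes)
    r = 0.5 * rmax * (x + 1.0)
    wr = 0.5 * rmax * w
    radial = r ** (n + 2) * np.exp(-zeta * r) * wr
    k = np.atleast_1d(np.asarray(k, float))
    jl = spherical_jn(l, np.outer(k, r))
    return zeta ** (n + 3) / factorial(n + 2) * (jl @ radial)


class ScatteringEngine:
    """Structure-factor evaluator bound to one (cell, hkl) batch.

    Radial Fourier integrals depend only on (shell power, effective zeta,
    l) and the resolution grid, so they are cached across model
    re-evaluations; this is what makes finite-difference derivatives and
    iterated refinement cycles affordable.
    """

    def __init__(self, cell, hkl):
        self.cell = cell
        self.hkl = np.atleast_2d(np.asarray(hkl, int))
        self.q_cart = self.hkl @ cell.fractionalization   # 1/A
        self.k = 2.0 * np.pi * np.linalg.norm(self.q_cart, axis=1)
        self._radial_cache = {}
        self._op_cache = {}

    def _radial(self, n, zeta, l):
        key = (n, round(float(zeta), 12), l)
        if key not in self._radial_cache:
            self._radial_cache[key] = _radial_fourier(n, zeta, l, self.k)
        return self._radial_cache[key]

    def _op_data(self, op):
        key = op.to_string()
        if key not in self._op_cache:
            rot_c = op.cartesian_rotation(self.cell)
            h_loc = self.hkl @ op.rot
            q_loc = self.q_cart @ rot_c
            qn = np.linalg.norm(q_loc, axis=1)
            u_loc = np.where(qn[:, None] > 0,
                             q_loc / np.maximum(qn, 1e-300)[:, None],
                             np.array([0.0, 0.0, 1.0]))
            astar = self.cell.reciprocal_lengths
            hh = (h_loc[:, :, None] * h_loc[:, None, :]
                  * (astar[None, :, None] * astar[None, None, :]))
            self._op_cache[key] = (h_loc, u_loc, hh)
        return self._op_cache[key]

    def atom_contribution(self, model, atom, collect_pop_derivs=None):
        """Sum over symmetry images of one pseudoatom's contribution to F."""
        data = atom.data
        n = len(self.hkl)
        contrib = np.zeros(n, complex)
        for op in model.symmetry:
            h_loc, u_loc, hh = self._op_data(op)
            t_factor = np.exp(-2 * np.pi**2 * np.einsum(
                "nij,ij->n", hh, atom.u))
            phase = np.exp(2j * np.pi * (op.apply(atom.frac) @ self.hkl.T))
            site_w = t_factor * phase
            j_val = self._radial(data.n_val_pow, data.zeta_val * atom.kappa, 0)
            f_sph = atom.p_val * j_val
            if data.n_core:
                f_sph = f_sph + data.n_core * self._radial(
                    data.n_core_pow, data.zeta_core, 0)
            if collect_pop_derivs is not None:
                key = (atom.label, "pval", None)
                collect_pop_derivs.setdefault(key, np.zeros(n, complex))
                collect_pop_derivs[key] += j_val * site_w
            f_multi = np.zeros(n, complex)
            lms = (atom.plm_order() if collect_pop_derivs is not None
                   else sorted(atom.p_lm, key=lambda t: (t[0], -t[1])))
            for lm in lms:
                pop = atom.p_lm.get(lm, 0.0)
                l = lm[0]
                jl = self._radial(DEFORMATION_POWERS[l],
                                  data.zeta_l[l] * atom.kappa_prime, l)
                ang = NORMALIZATION[lm] * HARMONIC_TERMS[lm].value(u_loc)
                basis = 4 * np.pi * (1j**l) * jl * ang
                f_multi = f_multi + pop * basis
                if collect_pop_derivs is not None:
                    key = (atom.label, "plm", lm)
                    collect_pop_derivs.setdefault(key, np.zeros(n, complex))
                    collect_pop_derivs[key] += basis * site_w
            contrib += (f_sph + f_multi) * site_w
        return contrib

    def structure_factors(self, model, return_pop_derivs=False):
        pop_derivs = {} if return_pop_derivs else None
        f_total = np.zeros(len(self.hkl), complex)
        for atom in model.atoms:
            f_total += self.atom_contribution(model, atom, pop_derivs)
        if return_pop_derivs:
            return f_total, pop_derivs
        return f_total

    def intensities(self, model):
        return model.scale_factor * np.abs(self.structure_factors(model)) ** 2


def structure_factors(model: CrystalModel, hkl, return_pop_derivs=False):
    """Complex structure factors F(H) for an array of reflections."""
    engine = ScatteringEngine(model.cell, hkl)
    return engine.structure_factors(model, return_pop_derivs)


def structure_factor(model: CrystalModel, hkl):
    """Single complex structure factor."""
    return complex(structure_factors(model, [hkl])[0])


def calculated_intensities(model: CrystalModel, hkl, engine=None):
    if engine is None:
        engine = ScatteringEngine(model.cell, hkl)
    return engine.intensities(model)


def objective_value(model: CrystalModel, reflections: ReflectionSet) -> float:
    """Weighted least-squares objective E = sum_H W_H (I_calc - I_obs)^2."""
    if len(reflections) == 0:
        raise ValueError("empty reflection set")
    resid = calculated_intensities(model, reflections.hkl) - reflections.i_obs
    return float(np.sum(reflections.weight * resid**2))


def weighted_r2(model: CrystalModel, reflections: ReflectionSet) -> float:
    """wR^2(I) = sqrt(sum W (Io-Ic)^2 / sum W Io^2)."""
    resid = calculated_intensities(model, reflections.hkl) - reflections.i_obs
    return float(np.sqrt(np.sum(reflections.weight * resid**2)
                         / np.sum(reflections.weight * reflections.i_obs**2)))


# ---------------------------------------------------------------------------
# normal equations and covariance


@dataclass
class NormalEquations:
    a: np.ndarray            # n x n symmetric
    v: np.ndarray            # gradient-side vector
    n_obs: int
    n_par: int
    index_map: list
    e_value: float = 0.0
    singular_labels: list = field(default_factory=list)


@dataclass
class CovarianceModel:
    b: np.ndarray
    gof: float
    esd: np.ndarray
    scaled: bool
    index_map: list


def intensity_derivatives(model: CrystalModel, reflections: ReflectionSet,
                          selection=None, engine=None, fixed=()):
    """Matrix dI/dx (n_refl x n_par): analytic for the scale factor and the
    population parameters (linear in F), central finite differences for the
    nonlinear parameter kinds.

    Finite differences perturb one atom at a time, so only that atom's
    contribution to F is recomputed.
    """
    if engine is None:
        engine = ScatteringEngine(model.cell, reflections.hkl)
    pv = pack_parameters(model, selection, fixed)
    f, pop_derivs = engine.structure_factors(model, return_pop_derivs=True)
    contribs = {a.label: engine.atom_contribution(model, a)
                for a in model.atoms}
    n_refl, n_par = len(reflections), len(pv)
    d = np.empty((n_refl, n_par))
    scale = model.scale_factor

    def perturbed_intensity(label, kind, comp, delta):
        atom = model.atom(label).copy()
        if kind == "xyz":
            atom.frac[comp] += delta
        elif kind == "uij":
            i, j = comp
            atom.u[i, j] += delta
            if i != j:
                atom.u[j, i] += delta
        elif kind == "kappa":
            atom.kappa += delta
        else:
            atom.kappa_prime += delta
        f_pert = f - contribs[label] + engine.atom_contribution(model, atom)
        return scale * np.abs(f_pert) ** 2

    for j, key in enumerate(pv.index_map):
        label, kind, comp = key
        if kind == "scale":
            d[:, j] = np.abs(f) ** 2
        elif kind in ("pval", "plm"):
            d[:, j] = 2 * scale * np.real(np.conj(f) * pop_derivs[key])
        else:
            step = FD_STEPS[kind]
            d[:, j] = (perturbed_intensity(label, kind, comp, step)
                       - perturbed_intensity(label, kind, comp, -step)) / (2 * step)
    return d, pv, f


def normal_matrix(model: CrystalModel, reflections: ReflectionSet,
                  selection=None, engine=None, fixed=()) -> NormalEquations:
    """Gauss-Newton normal equations A dX = V at the current model."""
    d, pv, f = intensity_derivatives(model, reflections, selection, engine, fixed)
    w = reflections.weight
    a = (d * w[:, None]).T @ d
    resid = reflections.i_obs - model.scale_factor * np.abs(f) ** 2
    v = d.T @ (w * resid)
    singular = [lbl for j, lbl in enumerate(pv.labels())
                if np.all(d[:, j] == 0.0)]
    return NormalEquations(a=a, v=v, n_obs=len(reflections), n_par=len(pv),
                           index_map=pv.index_map,
                           e_value=float(np.sum(w * resid**2)),
                           singular_labels=singular)


def covariance_from_normal(ne: NormalEquations, e_value=None,
                           scaled=True, eigen_floor=1e-10) -> CovarianceModel:
    """B = A^-1 with e.s.d._i = GOF * sqrt(B_ii) (GOF scaling optional)."""
    if ne.n_obs <= ne.n_par:
        raise ValueError(
            f"degrees of freedom <= 0 (n_obs={ne.n_obs}, n_par={ne.n_par})")
    e = ne.e_value if e_value is None else float(e_value)
    gof = float(np.sqrt(e / (ne.n_obs - ne.n_par)))
    evals, q = np.linalg.eigh(ne.a)
    floor = eigen_floor * np.max(evals)
    evals_c = np.maximum(evals, floor)
    b = (q / evals_c) @ q.T
    b = 0.5 * (b + b.T)
    esd = (gof if scaled else 1.0) * np.sqrt(np.diag(b))
    return CovarianceModel(b=b, gof=gof, esd=esd, scaled=scaled,
                           index_map=ne.index_map)


def correlation_coefficient(cov: CovarianceModel, i: int, j: int) -> float:
    """corr_ij = B_ij / sqrt(B_ii B_jj), in [-1, 1]."""
    bii, bjj = cov.b[i, i], cov.b[j, j]
    if bii <= 0 or bjj <= 0:
        raise ValueError("undefined correlation: zero variance")
    return float(np.clip(cov.b[i, j] / np.sqrt(bii * bjj), -1.0, 1.0))


def reduced_normal_matrix(ne: NormalEquations, excluded) -> NormalEquations:
    """Principal submatrix of A excluding the given parameter kinds (e.g.
    {'uij'}), as used to probe the effect of thermal parameters on derived
    SSDs."""
    excluded = set(excluded)
    keep = [i for i, (_, kind, _) in enumerate(ne.index_map)
            if kind not in excluded]
    if not keep:
        raise ValueError("cannot exclude every parameter")
    idx = np.array(keep)
    return NormalEquations(
        a=ne.a[np.ix_(idx, idx)], v=ne.v[idx], n_obs=ne.n_obs,
        n_par=len(keep), index_map=[ne.index_map[i] for i in keep],
        e_value=ne.e_value,
        singular_labels=list(ne.singular_labels))


# ---------------------------------------------------------------------------
# Gauss-Newton refinement


@dataclass
class RefinementResult:
    model: CrystalModel
    covariance: CovarianceModel
    normal: NormalEquations
    history: list
    converged: bool
    n_cycles: int


class RefinementError(RuntimeError):
    pass


def _block_diagonal(a, index_map):
    """Zero inter-atom blocks of A (scale couples to everything)."""
    groups = [lbl for (lbl, _, _) in index_map]
    out = np.zeros_like(a)
    for i in range(len(groups)):
        for j in range(len(groups)):
            if groups[i] == groups[j] or groups[i] is None or groups[j] is None:
                out[i, j] = a[i, j]
    return out


def gauss_newton_refine(model: CrystalModel, reflections: ReflectionSet,
                        selection=None, fixed=(), max_cycles=50, shift_tol=0.01,
                        block_diagonal_cycles=0,
                        scaled_esd=True) -> RefinementResult:
    """Iterative Gauss-Newton least squares with step halving.

    Converges when every shift falls below ``shift_tol`` times its e.s.d.;
    raises :class:`RefinementError` if the objective rises on three
    consecutive cycles despite step halving.
    """
    current = model.copy()
    engine = ScatteringEngine(current.cell, reflections.hkl)
    history = []

    def _objective(m):
        resid = engine.intensities(m) - reflections.i_obs
        return float(np.sum(reflections.weight * resid**2))

    wnorm = float(np.sum(reflections.weight * reflections.i_obs**2))
    e_prev = _objective(current)
    rises = 0
    converged = False
    cycle = 0
    for cycle in range(1, max_cycles + 1):
        ne = normal_matrix(current, reflections, selection, engine, fixed)
        a = ne.a
        if cycle <= block_diagonal_cycles:
            a = _block_diagonal(a, ne.index_map)
        try:
            dx = np.linalg.solve(a, ne.v)
        except np.linalg.LinAlgError:
            dx = np.linalg.lstsq(a, ne.v, rcond=None)[0]
        pv = pack_parameters(current, selection, fixed)
        # step halving keeps E non-increasing on well-posed fixtures
        step = 1.0
        for _ in range(10):
            trial = unpack_parameters(
                current, ParameterVector(pv.values + step * dx, pv.index_map))
            e_trial = _objective(trial)
            if e_trial <= e_prev or step < 1e-3:
                break
            step *= 0.5
        cov = covariance_from_normal(ne, e_value=e_trial, scaled=scaled_esd)
        # with exact data the GOF-scaled e.s.d.'s collapse to zero; fall back
        # to unscaled variances for the relative-shift convergence test
        esd_ref = cov.esd if cov.gof > 1e-10 else np.sqrt(np.diag(cov.b))
        rel_shift = np.max(np.abs(step * dx) / np.maximum(esd_ref, 1e-300))
        current = trial
        history.append({
            "cycle": cycle, "e": e_trial, "gof": cov.gof,
            "wr2": float(np.sqrt(e_trial / wnorm)),
            "max_shift_over_esd": float(rel_shift), "step": step,
        })
        if e_trial > e_prev:
            rises += 1
            if rises >= 3:
                raise RefinementError(
                    f"objective increased on 3 consecutive cycles "
                    f"(trace: {[h['e'] for h in history]})")
        else:
            rises = 0
        e_prev = e_trial
        if rel_shift < shift_tol and cycle > block_diagonal_cycles:
            converged = True
            break
    # final full-matrix covariance at the converged point
    ne = normal_matrix(current, reflections, selection, engine, fixed)
    cov = covariance_from_normal(ne, scaled=scaled_esd)
    return RefinementResult(model=current, covariance=cov, normal=ne,
                            history=history, converged=converged,
                            n_cycles=cycle)
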