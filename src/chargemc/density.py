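"""Analytic evaluation of the Hansen-Coppens pseudoatom electron density.

Each pseudoatom contributes

    rho_a(r) = rho_core(r) + P_val kappa^3 rho_val(kappa r)
             + sum_{l<=lmax} kappa'^3 R_l(kappa' r) sum_m P_lm y_lm(theta, phi)

with single-zeta Slater radial functions.  Values, gradients and Hessians
are analytic; symmetry-related images rotate the local multipole frame with
the Cartesian rotation of the operator.  Evaluation is vectorized over
points.
"""

from __future__ import annotations

from math import factorial

import numpy as np

from .elements import DEFORMATION_POWERS
from .harmonics import HARMONIC_TERMS, NORMALIZATION
from .model import CrystalModel, MultipoleAtom

R_CAP = 1e-6  # Angstrom; nuclear-cusp evaluation cap


# ---------------------------------------------------------------------------
# per-atom analytic terms


class _SphericalShell:
    """f(r) = C r^n exp(-zeta r); normalized densities times populations."""

    __slots__ = ("c", "n", "zeta")

    def __init__(self, electrons, n, zeta, scale=1.0):
        # normalized shell: zeta^(n+3)/(4 pi (n+2)!) r^n e^(-zeta r);
        # kappa-scaling scale^3 f(scale*r) is equivalent to zeta -> zeta*scale
        z = zeta * scale
        self.n = n
        self.zeta = z
        self.c = electrons * z ** (n + 3) / (4.0 * np.pi * factorial(n + 2))

    def f(self, r):
        return self.c * r**self.n * np.exp(-self.zeta * r)

    def df(self, r):
        e = np.exp(-self.zeta * r)
        if self.n == 0:
            return -self.c * self.zeta * e
        return self.c * e * (self.n * r ** (self.n - 1) - self.zeta * r**self.n)

    def d2f(self, r):
        e = np.exp(-self.zeta * r)
        n, z = self.n, self.zeta
        if n == 0:
            return self.c * z * z * e
        if n == 1:
            return self.c * e * (-2 * z + z * z * r)
        return self.c * e * (n * (n - 1) * r ** (n - 2)
                             - 2 * z * n * r ** (n - 1) + z * z * r**n)


class _MultipoleTerm:
    """G(r) * S_lm(v) with G = C r^(n_l - l) exp(-alpha r)."""

    __slots__ = ("c", "n", "alpha", "lm")

    def __init__(self, population, lm, zeta, kappa_prime):
        l = lm[0]
        n_l = DEFORMATION_POWERS[l]
        n_rad = (zeta * kappa_prime) ** (n_l + 3) / factorial(n_l + 2) \
            / kappa_prime ** (n_l + 3)  # R_l normalization at unit kappa'
        # kappa'^3 R_l(kappa' r) = N_l kappa'^(n_l+3) r^n_l exp(-zeta kappa' r)
        self.c = population * NORMALIZATION[lm] * n_rad * kappa_prime ** (n_l + 3)
        self.n = n_l - l
        self.alpha = zeta * kappa_prime
        self.lm = lm

    # radial factor and derivatives
    def g(self, r):
        return self.c * r**self.n * np.exp(-self.alpha * r)

    def dg(self, r):
        e = np.exp(-self.alpha * r)
        if self.n == 0:
            return -self.c * self.alpha * e
        return self.c * e * (self.n * r ** (self.n - 1) - self.alpha * r**self.n)

    def d2g(self, r):
        e = np.exp(-self.alpha * r)
        n, a = self.n, self.alpha
        if n == 0:
            return self.c * a * a * e
        if n == 1:
            return self.c * e * (-2 * a + a * a * r)
        return self.c * e * (n * (n - 1) * r ** (n - 2)
                             - 2 * a * n * r ** (n - 1) + a * a * r**n)


def atom_terms(atom: MultipoleAtom, promolecule: bool = False):
    """Spherical shells and multipole terms of one pseudoatom."""
    data = atom.data
    shells = []
    if data.n_core > 0:
        shells.append(_SphericalShell(data.n_core, data.n_core_pow, data.zeta_core))
    if promolecule:
        shells.append(_SphericalShell(data.n_val, data.n_val_pow, data.zeta_val))
        return shells, []
    kappa = atom.kappa
    shells.append(
        _SphericalShell(atom.p_val, data.n_val_pow, data.zeta_val, scale=kappa))
    # note: kappa scaling of the valence shell: kappa^3 f(kappa r) means
    # zeta -> zeta kappa and prefactor -> prefactor * kappa^(n+3); handled
    # by passing scale=kappa to the shell constructor.
    terms = []
    for lm, pop in sorted(atom.p_lm.items(), key=lambda t: (t[0][0], -t[0][1])):
        if pop == 0.0:
            continue
        terms.append(_MultipoleTerm(pop, lm, data.zeta_l[lm[0]], atom.kappa_prime))
    return shells, terms


# ---------------------------------------------------------------------------
# site enumeration


class _Site:
    __slots__ = ("cart", "rot", "shells", "terms", "label")

    def __init__(self, cart, rot, shells, terms, label=None):
        self.cart = cart
        self.rot = rot        # Cartesian rotation, local -> global
        self.shells = shells
        self.terms = terms
        self.label = label


def _sites_for_region(model: CrystalModel, bbox_min, bbox_max, cutoff,
                      promolecule=False):
    """All symmetry/lattice images whose atom lies within *cutoff* of the
    evaluation bounding box."""
    cell = model.cell
    frac_rows = np.linalg.norm(cell.fractionalization, axis=1)
    corners = np.array([[bbox_min[i] if b & (1 << i) == 0 else bbox_max[i]
                         for i in range(3)] for b in range(8)])
    fcorners = cell.fractionalize(corners)
    fmin = fcorners.min(axis=0) - cutoff * frac_rows
    fmax = fcorners.max(axis=0) + cutoff * frac_rows
    term_cache = {a.label: atom_terms(a, promolecule) for a in model.atoms}
    sites = []
    for op in model.symmetry:
        rot = op.cartesian_rotation(cell)
        for atom in model.atoms:
            f0 = op.apply(atom.frac)
            f0 -= np.floor(f0)
            lo = np.ceil(fmin - f0).astype(int)
            hi = np.floor(fmax - f0).astype(int)
            shells, terms = term_cache[atom.label]
            for n1 in range(lo[0], hi[0] + 1):
                for n2 in range(lo[1], hi[1] + 1):
                    for n3 in range(lo[2], hi[2] + 1):
                        cart = cell.orthogonalize(f0 + (n1, n2, n3))
                        # distance from site to the evaluation box
                        d = np.linalg.norm(
                            np.maximum(0.0, np.maximum(bbox_min - cart,
                                                       cart - bbox_max)))
                        if d <= cutoff:
                            sites.append(_Site(cart, rot, shells, terms,
                                               atom.label))
    return sites


def _asymmetric_sites(model: CrystalModel, promolecule=False):
    sites = []
    eye = np.eye(3)
    for atom in model.atoms:
        shells, terms = atom_terms(atom, promolecule)
        sites.append(_Site(model.cell.orthogonalize(atom.frac), eye,
                           shells, terms, atom.label))
    return sites


def build_sites(model, points, mode="crystal", cutoff=10.0, promolecule=False):
    pts = np.atleast_2d(np.asarray(points, float))
    if mode == "asymmetric":
        return _asymmetric_sites(model, promolecule)
    if mode != "crystal":
        raise ValueError(f"unknown mode {mode!r}")
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    return _sites_for_region(model, pts.min(axis=0), pts.max(axis=0),
                             cutoff, promolecule)


# ---------------------------------------------------------------------------
# evaluation


def _eval_sites(points, sites, derivatives=False):
    pts = np.atleast_2d(np.asarray(points, float))
    m = pts.shape[0]
    rho = np.zeros(m)
    grad = np.zeros((m, 3)) if derivatives else None
    hess = np.zeros((m, 3, 3)) if derivatives else None
    eye = np.eye(3)
    for site in sites:
        v = pts - site.cart
        vl = v @ site.rot  # local-frame displacement
        r = np.linalg.norm(vl, axis=1)
        r = np.maximum(r, R_CAP)
        u = vl / r[:, None]
        if not derivatives:
            for sh in site.shells:
                rho += sh.f(r)
            for t in site.terms:
                rho += t.g(r) * HARMONIC_TERMS[t.lm].value(vl)
            continue
        gl = np.zeros((m, 3))
        hl = np.zeros((m, 3, 3))
        uu = u[:, :, None] * u[:, None, :]
        perp = (eye[None] - uu) / r[:, None, None]
        for sh in site.shells:
            rho += sh.f(r)
            d1, d2 = sh.df(r), sh.d2f(r)
            gl += d1[:, None] * u
            hl += d2[:, None, None] * uu + d1[:, None, None] * perp
        for t in site.terms:
            term = HARMONIC_TERMS[t.lm]
            s = term.value(vl)
            ds = term.gradient(vl)
            hs = term.hessian(vl)
            g0, g1, g2 = t.g(r), t.dg(r), t.d2g(r)
            rho += g0 * s
            gl += g1[:, None] * u * s[:, None] + g0[:, None] * ds
            cross = u[:, :, None] * ds[:, None, :]
            hl += (s[:, None, None] * (g2[:, None, None] * uu
                                       + g1[:, None, None] * perp)
                   + g1[:, None, None] * (cross + cross.transpose(0, 2, 1))
                   + g0[:, None, None] * hs)
        grad += gl @ site.rot.T
        hess += np.einsum("ab,mbc,dc->mad", site.rot, hl, site.rot)
    if derivatives:
        return rho, grad, hess
    return rho


def density_at(model, points, mode="crystal", cutoff=10.0):
    """Total model electron density rho(r) in e/A^3 at Cartesian point(s)."""
    pts = np.asarray(points, float)
    single = pts.ndim == 1
    sites = build_sites(model, pts, mode, cutoff)
    rho = _eval_sites(pts, sites)
    return float(rho[0]) if single else rho


def promolecule_density_at(model, points, mode="crystal", cutoff=10.0):
    """Superposition of spherical neutral atoms (IAM promolecule)."""
    pts = np.asarray(points, float)
    single = pts.ndim == 1
    sites = build_sites(model, pts, mode, cutoff, promolecule=True)
    rho = _eval_sites(pts, sites)
    return float(rho[0]) if single else rho


def density_gradient_hessian(model, points, mode="crystal", cutoff=10.0):
    """rho, grad rho (e/A^4) and Hessian (e/A^5) at Cartesian point(s)."""
    pts = np.asarray(points, float)
    single = pts.ndim == 1
    sites = build_sites(model, pts, mode, cutoff)
    rho, grad, hess = _eval_sites(pts, sites, derivatives=True)
    if single:
        return float(rho[0]), grad[0], hess[0]
    return rho, grad, hess


# ---------------------------------------------------------------------------
# grids


def plane_grid(model, anchors, extent=3.0, step=0.05):
    """Orthonormal grid in the plane of three anchor atoms (by label).

    Returns (points (ny, nx, 3), origin, e1, e2).  Raises on collinear
    anchors.
    """
    p = np.array([model.cell.orthogonalize(model.atom(lbl).frac)
                  for lbl in anchors])
    e1 = p[1] - p[0]
    n1 = np.linalg.norm(e1)
    e1 = e1 / n1
    w = p[2] - p[0]
    w_perp = w - (w @ e1) * e1
    if np.linalg.norm(w_perp) < 1e-8:
        raise ValueError("collinear plane anchors")
    e2 = w_perp / np.linalg.norm(w_perp)
    center = p.mean(axis=0)
    n = int(round(2 * extent / step)) + 1
    t = np.linspace(-extent, extent, n)
    pts = (center[None, None, :] + t[:, None, None] * e2[None, None, :]
           + t[None, :, None] * e1[None, None, :])
    return pts, center, e1, e2


def deformation_density_grid(model, anchors=None, points=None,
                             extent=3.0, step=0.05, mode="crystal",
                             cutoff=10.0):
    """Deformation density (multipolar minus promolecule) on a plane or at
    given points, in e/A^3."""
    if step <= 0:
        raise ValueError("step must be > 0")
    if points is None:
        pts, *_ = plane_grid(model, anchors, extent, step)
        shape = pts.shape[:-1]
        flat = pts.reshape(-1, 3)
    else:
        flat = np.atleast_2d(np.asarray(points, float))
        shape = flat.shape[:-1]
    rho = density_at(model, flat, mode, cutoff)
    pro = promolecule_density_at(model, flat, mode, cutoff)
    return (rho - pro).reshape(shape)
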