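"""Density-normalized real spherical harmonics for l <= 3.

The multipole formalism uses real harmonics y_lm normalized such that the
integral of |y_lm| over the sphere equals 2 for l > 0 (one electron moved
from the negative to the positive lobe per unit population) and y_00 =
1/(4 pi).  We represent each y_lm as N_lm * S_lm(x, y, z) / r^l with S_lm a
real harmonic (traceless) polynomial; the normalization constants N_lm are
fixed numerically once at import by spherical quadrature of |S_lm|.

Cartesian polynomials, their gradients and Hessians are generated
symbolically and lambdified, which keeps the derivative code free of
hand-transcription errors.
"""

from __future__ import annotations

import numpy as np
import sympy as sp

_x, _y, _z = sp.symbols("x y z")
_r2 = _x**2 + _y**2 + _z**2

# real harmonic polynomials S_lm, keyed (l, m); m > 0 cosine-type, m < 0 sine
SOLID_HARMONIC_POLYNOMIALS = {
    (0, 0): sp.Integer(1),
    (1, 0): _z,
    (1, 1): _x,
    (1, -1): _y,
    (2, 0): _z**2 - (_x**2 + _y**2) / 2,
    (2, 1): _x * _z,
    (2, -1): _y * _z,
    (2, 2): _x**2 - _y**2,
    (2, -2): _x * _y,
    (3, 0): _z * (2 * _z**2 - 3 * _x**2 - 3 * _y**2),
    (3, 1): _x * (4 * _z**2 - _x**2 - _y**2),
    (3, -1): _y * (4 * _z**2 - _x**2 - _y**2),
    (3, 2): _z * (_x**2 - _y**2),
    (3, -2): _x * _y * _z,
    (3, 3): _x * (_x**2 - 3 * _y**2),
    (3, -3): _y * (3 * _x**2 - _y**2),
}


def _lambdify(expr):
    return sp.lambdify((_x, _y, _z), expr, modules="numpy")


class _HarmonicTerm:
    """Callable bundle: S_lm, grad S_lm, Hess S_lm as numpy functions."""

    def __init__(self, l, m, expr):
        self.l, self.m = l, m
        self.func = _lambdify(expr)
        grads = [sp.diff(expr, v) for v in (_x, _y, _z)]
        self.grad_funcs = [_lambdify(g) for g in grads]
        self.hess_funcs = [[_lambdify(sp.diff(g, v)) for v in (_x, _y, _z)]
                           for g in grads]

    def value(self, v):
        x, y, z = v[..., 0], v[..., 1], v[..., 2]
        return np.broadcast_to(np.asarray(self.func(x, y, z), float), x.shape).copy()

    def gradient(self, v):
        x, y, z = v[..., 0], v[..., 1], v[..., 2]
        out = np.empty(v.shape, float)
        for k, g in enumerate(self.grad_funcs):
            out[..., k] = np.broadcast_to(np.asarray(g(x, y, z), float), x.shape)
        return out

    def hessian(self, v):
        x, y, z = v[..., 0], v[..., 1], v[..., 2]
        out = np.empty(v.shape[:-1] + (3, 3), float)
        for i in range(3):
            for j in range(3):
                out[..., i, j] = np.broadcast_to(
                    np.asarray(self.hess_funcs[i][j](x, y, z), float), x.shape)
        return out


HARMONIC_TERMS = {lm: _HarmonicTerm(lm[0], lm[1], expr)
                  for lm, expr in SOLID_HARMONIC_POLYNOMIALS.items()}


def _normalization_constants():
    """N_lm with int |N_lm S_lm(u)| dOmega = 2 (l>0); y_00 = 1/4pi."""
    # Gauss-Legendre in cos(theta) x uniform in phi; |y| has kinks on the
    # nodal lines, so the grid is kept fine (error ~1e-6 relative)
    nt, nphi = 800, 800
    ct, wt = np.polynomial.legendre.leggauss(nt)
    phi = (np.arange(nphi) + 0.5) * (2 * np.pi / nphi)
    wphi = 2 * np.pi / nphi
    st = np.sqrt(1 - ct**2)
    u = np.empty((nt, nphi, 3))
    u[..., 0] = st[:, None] * np.cos(phi)[None, :]
    u[..., 1] = st[:, None] * np.sin(phi)[None, :]
    u[..., 2] = ct[:, None] * np.ones_like(phi)[None, :]
    out = {}
    for lm, term in HARMONIC_TERMS.items():
        if lm == (0, 0):
            out[lm] = 1.0 / (4 * np.pi)
            continue
        vals = np.abs(term.value(u))
        integral = float(np.sum(vals * wt[:, None]) * wphi)
        out[lm] = 2.0 / integral
    return out


NORMALIZATION = _normalization_constants()


def y_lm(lm, unit_vectors):
    """Density-normalized real harmonic evaluated on unit direction(s)."""
    u = np.asarray(unit_vectors, float)
    return NORMALIZATION[lm] * HARMONIC_TERMS[lm].value(u)
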