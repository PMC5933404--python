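"""Synthetic toy crystals and simulated diffraction data.

These generators define the desk-scale study conditions for the whole
pipeline: small periodic structures with known ground-truth multipolar
parameters (every refinable kind has leverage: nonzero P_lm, kappa != 1)
and simulated noisy intensities with Gaussian errors matching the
least-squares weighting model.  Nothing is downloaded; every test input is
produced here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import (
    CrystalModel,
    MultipoleAtom,
    ParameterVector,
    SymmetryOperator,
    UnitCell,
    pack_parameters,
    unpack_parameters,
)
from .refine import ReflectionSet, structure_factors


@dataclass
class ToySpec:
    """Study conditions for one synthetic data set."""

    recipe: str = "diatomic_p1"
    noise_level: float = 0.02   # sigma_I = sqrt(max(I, floor)) * noise_level
    s_max: float = 0.8          # resolution limit sin(theta)/lambda, 1/A
    completeness: float = 1.0
    seed: int = 0
    intensity_floor: float = 0.1
    weight_c: float = 1.0


def make_toy_crystal(recipe="diatomic_p1") -> CrystalModel:
    """Build a small crystal with known ground-truth parameters.

    Recipes
    -------
    diatomic_p1
        Two C pseudoatoms 1.40 A apart in a P1 cell, bond along z, with
        antisymmetric dipoles and equal quadrupoles so the total density has
        the symmetry of a homonuclear diatomic.
    bent_triatomic_pminus1
        A bent O-H2 molecule in a P-1 cell; the inversion (an involutional
        operator) creates a second molecule for dimer tests.
    hbond_chain_p1
        A water-like molecule in a short-axis P1 cell forming an
        O-H...O contact shorter than 3 A with its +x lattice neighbour.
    """
    if recipe == "diatomic_p1":
        cell = UnitCell(6.0, 6.0, 7.0)
        dz = 0.70 / 7.0  # half bond 0.70 A
        a1 = MultipoleAtom(
            label="C1", element="C", frac=np.array([0.5, 0.5, 0.5 - dz]),
            u=np.diag([0.010, 0.012, 0.008]), p_val=4.0,
            p_lm={(1, 0): 0.12, (2, 0): 0.10}, kappa=1.05, kappa_prime=0.95,
            lmax=2)
        a2 = MultipoleAtom(
            label="C2", element="C", frac=np.array([0.5, 0.5, 0.5 + dz]),
            u=np.diag([0.010, 0.012, 0.008]), p_val=4.0,
            p_lm={(1, 0): -0.12, (2, 0): 0.10}, kappa=1.05, kappa_prime=0.95,
            lmax=2)
        return CrystalModel(cell=cell, symmetry=[SymmetryOperator.identity()],
                            atoms=[a1, a2], scale_factor=0.9)

    if recipe == "bent_triatomic_pminus1":
        cell = UnitCell(7.0, 8.0, 9.0)
        # O-H 0.97 A, H-O-H 104.5 deg, molecule centred off the inversion
        o_cart = np.array([1.6, 1.8, 2.0])
        ang = np.radians(104.5) / 2
        h1_cart = o_cart + 0.97 * np.array([np.sin(ang), 0.0, np.cos(ang)])
        h2_cart = o_cart + 0.97 * np.array([-np.sin(ang), 0.0, np.cos(ang)])
        frac = cell.fractionalize
        atoms = [
            MultipoleAtom(label="O1", element="O", frac=frac(o_cart),
                          u=np.diag([0.008, 0.009, 0.010]), p_val=6.3,
                          p_lm={(1, 0): -0.10, (2, 0): 0.08}, kappa=0.98,
                          kappa_prime=1.05, lmax=2),
            MultipoleAtom(label="H1", element="H", frac=frac(h1_cart),
                          u=np.eye(3) * 0.02, p_val=0.85,
                          p_lm={(1, 1): 0.10}, kappa=1.15, kappa_prime=1.2,
                          lmax=1),
            MultipoleAtom(label="H2", element="H", frac=frac(h2_cart),
                          u=np.eye(3) * 0.02, p_val=0.85,
                          p_lm={(1, 1): -0.10}, kappa=1.15, kappa_prime=1.2,
                          lmax=1),
        ]
        symmetry = [SymmetryOperator.identity(),
                    SymmetryOperator.from_string("-x, -y, -z")]
        return CrystalModel(cell=cell, symmetry=symmetry, atoms=atoms,
                            scale_factor=1.1)

    if recipe == "hbond_chain_p1":
        cell = UnitCell(3.0, 8.0, 8.5)
        o_cart = np.array([0.0, 4.0, 4.25])
        h1_cart = o_cart + np.array([0.97, 0.0, 0.0])   # donor along +x
        h2_cart = o_cart + 0.97 * np.array([-np.cos(np.radians(75.5)),
                                            np.sin(np.radians(75.5)), 0.0])
        frac = cell.fractionalize
        atoms = [
            MultipoleAtom(label="O1", element="O", frac=frac(o_cart),
                          u=np.diag([0.008, 0.009, 0.010]), p_val=6.3,
                          p_lm={(1, 1): -0.12, (2, 0): 0.06}, kappa=0.98,
                          kappa_prime=1.05, lmax=2),
            MultipoleAtom(label="H1", element="H", frac=frac(h1_cart),
                          u=np.eye(3) * 0.02, p_val=0.8,
                          p_lm={(1, 1): 0.12}, kappa=1.2, kappa_prime=1.2,
                          lmax=1),
            MultipoleAtom(label="H2", element="H", frac=frac(h2_cart),
                          u=np.eye(3) * 0.02, p_val=0.9,
                          p_lm={(1, -1): 0.10}, kappa=1.15, kappa_prime=1.2,
                          lmax=1),
        ]
        return CrystalModel(cell=cell, symmetry=[SymmetryOperator.identity()],
                            atoms=atoms, scale_factor=1.0)

    raise ValueError(f"unknown toy recipe {recipe!r}")


def unique_hkl(cell: UnitCell, s_max: float) -> np.ndarray:
    """Friedel-unique reflection indices with resolution s <= s_max."""
    if s_max <= 0:
        raise ValueError("s_max must be > 0")
    hmax = np.ceil(2 * s_max / cell.reciprocal_lengths).astype(int)
    h, k, l = np.meshgrid(*(np.arange(-m, m + 1) for m in hmax), indexing="ij")
    hkl = np.stack([h.ravel(), k.ravel(), l.ravel()], axis=1)
    # one hemisphere: h > 0, or h = 0 and k > 0, or h = k = 0 and l > 0
    keep = ((hkl[:, 0] > 0)
            | ((hkl[:, 0] == 0) & (hkl[:, 1] > 0))
            | ((hkl[:, 0] == 0) & (hkl[:, 1] == 0) & (hkl[:, 2] > 0)))
    hkl = hkl[keep]
    s = cell.resolution_s(hkl)
    return hkl[s <= s_max]


def simulate_intensities(model: CrystalModel, spec: ToySpec) -> ReflectionSet:
    """Simulated observed intensities I_obs = scale|F|^2 + Gaussian noise.

    sigma_I = sqrt(max(I_true, floor)) * noise_level; with noise_level = 0
    the observations equal the true intensities exactly and a nominal
    sigma (same functional form, level 1e-3) is kept so weights stay finite.
    """
    hkl = unique_hkl(model.cell, spec.s_max)
    if spec.completeness < 1.0:
        rng_sel = np.random.default_rng(spec.seed + 1)
        keep = rng_sel.random(len(hkl)) < spec.completeness
        hkl = hkl[keep]
    i_true = model.scale_factor * np.abs(structure_factors(model, hkl)) ** 2
    level = spec.noise_level if spec.noise_level > 0 else 1e-3
    sigma = np.sqrt(np.maximum(i_true, spec.intensity_floor)) * level
    if spec.noise_level > 0:
        rng = np.random.default_rng(spec.seed)
        i_obs = i_true + rng.normal(scale=sigma)
    else:
        i_obs = i_true.copy()
    refl = ReflectionSet.from_intensities(hkl, i_obs, sigma,
                                          weight_c=spec.weight_c)
    if len(refl) == 0:
        raise ValueError("no reflections generated")
    return refl


def perturb_model(model: CrystalModel, seed=0, scale=1.0,
                  selection=None) -> CrystalModel:
    """Random small perturbation of every selected parameter kind; used to
    start refinements inside the basin of attraction."""
    rng = np.random.default_rng(seed)
    amplitudes = {"scale": 0.01, "xyz": 1.5e-3, "uij": 4e-4, "pval": 0.04,
                  "plm": 0.02, "kappa": 0.015, "kappa_prime": 0.03}
    pv = pack_parameters(model, selection)
    vals = pv.values.copy()
    for i, (_, kind, comp) in enumerate(pv.index_map):
        amp = amplitudes[kind] * scale
        if kind == "uij" and comp[0] != comp[1]:
            amp *= 0.5
        vals[i] += rng.normal(scale=amp)
    return unpack_parameters(model, ParameterVector(vals, pv.index_map))
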