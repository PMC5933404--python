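"""Potential, significance surfaces, dimers, energies, basin charges."""

import numpy as np
import pytest

from chargemc import electrostatics as es
from chargemc import ensemble as en
from chargemc import refine as rf
from chargemc.constants import BOHR_ANGSTROM, COULOMB_KJMOL_ANG
from chargemc.model import (
    CrystalModel,
    MultipoleAtom,
    SymmetryOperator,
    UnitCell,
)


def _single_atom(element="C", p_val=None, **kw):
    cell = UnitCell(20, 20, 20)
    atom = MultipoleAtom.neutral("A1", element, [0.5, 0.5, 0.5], **kw)
    if p_val is not None:
        atom.p_val = p_val
    model = CrystalModel(cell=cell, symmetry=[SymmetryOperator.identity()],
                        atoms=[atom])
    return model, cell.orthogonalize(atom.frac)


class TestPotential:
    def test_neutral_atom_decays_faster_than_coulomb(self):
        model, c0 = _single_atom("C")
        r_phi = [r * es.electrostatic_potential(model, c0 + [r, 0, 0])
                 for r in (2.0, 4.0, 6.0)]
        assert r_phi[0] > 10 * r_phi[1] > 100 * r_phi[2]

    def test_cation_approaches_point_charge(self):
        model, c0 = _single_atom("C", p_val=3.0)   # net +1
        for r in (4.0, 8.0):
            phi = es.electrostatic_potential(model, c0 + [0, r, 0])
            assert abs(r * phi - 1.0) < 1e-4

    def test_hydrogen_atom_closed_form(self):
        """Phi(R) = exp(-zeta R)(zeta/2 + 1/R) for a single-zeta 1s atom."""
        model, c0 = _single_atom("H")
        zeta = 2.0 / BOHR_ANGSTROM
        for r in (0.3, 1.0, 2.5):
            phi = es.electrostatic_potential(model, c0 + [r, 0, 0])
            ref = np.exp(-zeta * r) * (zeta / 2 + 1 / r)
            assert np.isclose(phi, ref, rtol=1e-10)

    def test_multipole_terms_against_numeric_integration(self):
        """The closed-form dipole/quadrupole potentials match a brute-force
        grid integral of the corresponding density."""
        from chargemc.density import density_at

        base, c0 = _single_atom("H")
        pt = c0 + np.array([1.7, 0.9, 1.1])
        phi_off = es.electrostatic_potential(base, pt)
        step, half = 0.05, 6.0
        ax = np.arange(-half, half + step / 2, step)
        gx, gy, gz = np.meshgrid(ax, ax, ax, indexing="ij")
        gp = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1) + c0
        r = np.maximum(np.linalg.norm(gp - pt, axis=1), step / 2)
        rho_off = density_at(base, gp, mode="asymmetric")
        for lm, pop in (((1, 0), 0.2), ((2, 2), 0.15)):
            model, _ = _single_atom("H", lmax=2)
            model.atoms[0].p_lm = {lm: pop}
            d_exact = es.electrostatic_potential(model, pt) - phi_off
            rho_on = density_at(model, gp, mode="asymmetric")
            d_num = -np.sum((rho_on - rho_off) / r) * step**3
            assert np.isclose(d_exact, d_num, atol=5e-6), lm

    def test_grid_method_agrees_for_gentle_density(self):
        """Numeric grid integration (oracle path) matches the closed form
        for an H atom, whose cusp a 0.04 A grid can resolve."""
        model, c0 = _single_atom("H")
        pt = c0 + np.array([2.0, 0.5, 0.0])
        exact = es.electrostatic_potential(model, pt)
        grid = es.electrostatic_potential(model, pt, method="grid",
                                          grid_step=0.04, margin=6.0)
        assert abs(exact - grid) < 1e-3


class TestIsoSurface:
    def test_single_atom_surface_is_a_sphere(self):
        """Area within 2% of the analytic sphere at the radius where the
        radial density crosses the level."""
        from scipy.optimize import brentq
        from chargemc.density import density_at

        model, c0 = _single_atom("C")
        level = es.AU_DENSITY_LEVEL
        r_star = brentq(
            lambda r: density_at(model, c0 + [r, 0, 0],
                                 mode="asymmetric") - level, 1.0, 8.0)
        surf = es.isodensity_surface_map(model, grid_step=0.08)
        assert abs(surf.area - 4 * np.pi * r_star**2) \
            / (4 * np.pi * r_star**2) < 0.02
        radii = np.linalg.norm(surf.vertices - c0, axis=1)
        assert np.max(np.abs(radii - r_star)) < 0.05

    def test_vertices_lie_on_the_level(self, hbond_model):
        from chargemc.density import density_at

        surf = es.isodensity_surface_map(hbond_model, grid_step=0.1)
        rho = density_at(hbond_model, surf.vertices, mode="asymmetric")
        # marching-cubes linear interpolation: within a few % of the level
        assert np.median(np.abs(rho / surf.level - 1)) < 0.02

    def test_zero_spread_ensemble_gives_capped_ratio(self, hbond_model):
        surf = es.isodensity_surface_map(hbond_model,
                                         member_models=[hbond_model] * 4,
                                         grid_step=0.15)
        assert np.allclose(surf.ssd_phi, 0.0)
        assert np.all(surf.ratio == es.RATIO_CAP)

    def test_absurd_level_rejected(self, hbond_model):
        with pytest.raises(ValueError):
            es.isodensity_surface_map(hbond_model, level=1e6)

    def test_significance_map_over_refined_ensemble(self, hbond_model):
        """SSD(Phi) on the isodensity surface of a refined polar molecule:
        positive everywhere, finite ratios, and the insignificant stripe
        (|Phi|/SSD < 1) concentrated where the potential is small."""
        from chargemc import fixtures as fx

        refl = fx.simulate_intensities(
            hbond_model, fx.ToySpec(noise_level=0.02, s_max=0.8, seed=21))
        start = fx.perturb_model(hbond_model, seed=22, scale=0.3)
        start.atom("O1").frac[:] = hbond_model.atom("O1").frac
        fit = rf.gauss_newton_refine(start, refl, fixed=(("O1", "xyz"),),
                                     max_cycles=40)
        sq = en.covariance_sqrt(fit.normal, fit.covariance)
        x_min = rf.pack_parameters(fit.model, fixed=(("O1", "xyz"),))
        devs = en.generate_ensemble(x_min, sq, 10, seed=11)
        surf = es.isodensity_surface_map(
            fit.model, devs.member_models(fit.model), grid_step=0.15)
        assert np.all(surf.ssd_phi > 0)
        assert np.all(np.isfinite(surf.ratio))
        sig = surf.significant()
        assert 0 < np.mean(sig) < 1
        assert np.mean(np.abs(surf.phi[~sig])) \
            < np.mean(np.abs(surf.phi[sig]))


class TestDimers:
    def test_inversion_dimer_is_involutional(self, bent_model):
        dims = es.enumerate_contact_dimers(bent_model, cutoff=6.0)
        inv = [d for d in dims if d.op.rot.trace() == -3]
        assert inv
        assert all(d.involutional and d.weight == 0.5 for d in inv)

    def test_translation_dimer_has_full_weight(self, hbond_model):
        dims = es.enumerate_contact_dimers(hbond_model, cutoff=3.0)
        assert len(dims) == 1
        dm = dims[0]
        assert not dm.involutional and dm.weight == 1.0

    def test_plus_minus_translations_deduplicated(self, hbond_model):
        """x-1 and x+1 images generate the same dimer: exactly one
        survives."""
        dims = es.enumerate_contact_dimers(hbond_model, cutoff=3.0)
        assert len(dims) == 1
        assert dims[0].min_distance < 3.0

    def test_contacts_listed_below_cutoff(self, hbond_model):
        dm = es.enumerate_contact_dimers(hbond_model, cutoff=3.0)[0]
        assert all(d < 3.0 for (_, _, d) in dm.contacts)


class TestInteractionEnergy:
    def test_point_charge_oracle(self):
        """Two +1 pseudoion images 8 A apart reproduce Coulomb's law."""
        cell = UnitCell(8.0, 14.0, 14.0)
        atom = MultipoleAtom.neutral("C1", "C", [0.0, 0.5, 0.5])
        atom.p_val = 3.0
        model = CrystalModel(cell=cell,
                             symmetry=[SymmetryOperator.identity()],
                             atoms=[atom])
        dm = [d for d in es.enumerate_contact_dimers(model, cutoff=8.5)
              if abs(d.min_distance - 8.0) < 1e-9][0]
        e = es.interaction_energy(model, dm)
        assert abs(e - COULOMB_KJMOL_ANG / 8) / (COULOMB_KJMOL_ANG / 8) \
            < 0.01

    def test_neutral_atoms_interact_negligibly(self):
        cell = UnitCell(8.0, 14.0, 14.0)
        atom = MultipoleAtom.neutral("C1", "C", [0.0, 0.5, 0.5])
        model = CrystalModel(cell=cell,
                             symmetry=[SymmetryOperator.identity()],
                             atoms=[atom])
        dm = [d for d in es.enumerate_contact_dimers(model, cutoff=8.5)
              if abs(d.min_distance - 8.0) < 1e-9][0]
        assert abs(es.interaction_energy(model, dm)) < 0.1

    def test_symmetric_under_molecule_swap(self, hbond_model):
        dm = es.enumerate_contact_dimers(hbond_model, cutoff=3.0)[0]
        e_f = es.interaction_energy(hbond_model, dm)
        swapped = es.DimerInteraction(
            op=dm.op.inverse(), lattice=tuple(-np.array(dm.lattice)),
            involutional=dm.involutional, weight=dm.weight,
            contacts=dm.contacts)
        e_b = es.interaction_energy(hbond_model, swapped)
        assert abs(e_f - e_b) / abs(e_f) < 0.01

    def test_packing_sum_applies_weights(self):
        dims = [es.DimerInteraction(op=SymmetryOperator.identity(),
                                    lattice=(0, 0, 0), involutional=inv,
                                    weight=0.5 if inv else 1.0,
                                    contacts=[("a", "b", 1.0)],
                                    e_elec=e)
                for inv, e in ((True, -10.0), (False, -5.0))]
        assert es.packing_energy_sum(dims) == -10.0


class TestBasinCharges:
    def test_single_neutral_atom_is_neutral(self):
        model, _ = _single_atom("C")
        tab = es.bader_basin_charges(model, grid_step=0.1, margin=3.0)
        assert abs(tab.charges["A1"]) < 1e-3
        assert abs(tab.deficit) < 0.05

    def test_homonuclear_charges_split_symmetrically(self, diatomic_truth):
        tab = es.bader_basin_charges(diatomic_truth, grid_step=0.1,
                                     margin=3.0)
        q = list(tab.charges.values())
        assert abs(q[0] - q[1]) < 1e-3
        assert abs(q[0] + q[1]) < 1e-9   # redistribution conserves charge

    def test_conservation_identity_without_redistribution(
            self, diatomic_truth):
        tab = es.bader_basin_charges(diatomic_truth, grid_step=0.12,
                                     margin=2.5, redistribute=False)
        total_e = sum(a.n_electrons for a in diatomic_truth.atoms)
        assert np.isclose(sum(tab.electrons.values()) + tab.deficit,
                          total_e, atol=1e-9)

    def test_even_redistribution_arithmetic(self, diatomic_truth):
        raw = es.bader_basin_charges(diatomic_truth, grid_step=0.12,
                                     margin=2.5, redistribute=False)
        adj = es.bader_basin_charges(diatomic_truth, grid_step=0.12,
                                     margin=2.5, redistribute=True)
        corr = raw.deficit / len(diatomic_truth.atoms)
        for lbl in raw.electrons:
            assert np.isclose(adj.electrons[lbl],
                              raw.electrons[lbl] + corr, atol=1e-12)
        assert abs(adj.total_charge()
                   - sum(a.data.z - a.n_electrons
                         for a in diatomic_truth.atoms)) < 1e-9

    def test_heteronuclear_promolecule_charges_nonzero(self):
        """Spherical-neutral-atom (promolecule) basins of a B-O pair still
        carry charge: the B basin is positive."""
        cell = UnitCell(14, 14, 15)
        atoms = [MultipoleAtom.neutral("B1", "B", [0.5, 0.5, 0.45]),
                 MultipoleAtom.neutral("O1", "O", [0.5, 0.5, 0.45 + 1.37 / 15])]
        model = CrystalModel(cell=cell,
                             symmetry=[SymmetryOperator.identity()],
                             atoms=atoms)
        tab = es.bader_basin_charges(model, grid_step=0.08, margin=2.5,
                                     promolecule=True)
        assert tab.charges["B1"] > 0.2
        assert tab.charges["O1"] < -0.2


class TestPopulationCharges:
    def test_neutral_population_gives_zero(self):
        model, _ = _single_atom("C")
        assert es.charges_from_pval(model) == {"A1": 0.0}

    def test_arithmetic(self):
        model, _ = _single_atom("C", p_val=4.2)
        assert np.isclose(es.charges_from_pval(model)["A1"], -0.2)

    def test_pval_ssd_matches_esd_over_ensemble(self, refined,
                                                parameter_ensemble_200):
        """Ensemble SSD of a valence population agrees with its e.s.d."""
        idx = [i for i, (lbl, kind, _) in
               enumerate(refined.covariance.index_map)
               if kind == "pval"][0]
        vals = parameter_ensemble_200.member_values()[:, idx]
        ssd = vals.std(ddof=1)
        band = 4 * en.expected_relative_sd_of_ssd(200)
        assert abs(ssd / refined.covariance.esd[idx] - 1) < band
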