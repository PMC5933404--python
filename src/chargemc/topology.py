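"""QTAIM analysis of the multipolar density: critical points, bond paths,
ellipticity, energy densities, and their ensemble statistics.

Critical points are stationary points of the static electron density,
located by Newton iteration on the analytic gradient with the analytic
Hessian, seeded from atom-pair midpoints (optionally plus a coarse grid).
A (3,-1) point has two negative curvatures (lambda_1 <= lambda_2 < 0) and
one positive; its ellipticity epsilon = lambda_1/lambda_2 - 1 measures the
departure from cylindrical bond symmetry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import A3_TO_AU, A5_TO_AU, HARTREE_KJMOL
from .density import _eval_sites, build_sites
from .ensemble import DeviatingEnsemble, sample_standard_deviation
from .model import CrystalModel

GRAD_TOL = 1e-7          # e/A^4 convergence threshold on |grad rho|
EIGEN_ZERO = 1e-6        # e/A^5 threshold for a "zero" curvature
MERGE_RADIUS = 0.05      # A, duplicate CP merging
MATCH_RADIUS = 0.3       # A, CP identification across ensemble members
PATH_STEP = 0.01         # A, bond-path integration step
NUCLEUS_RADIUS = 0.3     # A, bond-path termination distance


@dataclass
class CriticalPoint:
    position: np.ndarray
    rho: float
    laplacian: float
    eigenvalues: np.ndarray          # ascending, e/A^5
    eigenvectors: np.ndarray         # columns match eigenvalues
    kind: tuple                      # (rank, signature)
    linked_atoms: tuple = None       # (label_A, label_B) from the bond path
    linked_positions: np.ndarray = None
    path_length: float = None
    unterminated: bool = False

    @property
    def is_bond_cp(self):
        return self.kind == (3, -1)

    @property
    def ellipticity(self):
        return ellipticity(self)

    def distances(self):
        """d(A, CP) for the two linked nuclei, in A."""
        if self.linked_positions is None:
            return None
        return np.linalg.norm(self.linked_positions - self.position, axis=1)


def ellipticity(cp: CriticalPoint) -> float:
    """epsilon = lambda_1/lambda_2 - 1 >= 0 at a (3,-1) critical point."""
    l1, l2 = cp.eigenvalues[0], cp.eigenvalues[1]
    if cp.kind != (3, -1) or l2 >= 0:
        raise ValueError("ellipticity is defined for (3,-1) points only")
    return float(l1 / l2 - 1.0)


class _FieldEvaluator:
    """rho / grad / Hessian closure over a frozen site list."""

    def __init__(self, model, region_points, mode="crystal", cutoff=8.0,
                 margin=3.0):
        pts = np.atleast_2d(np.asarray(region_points, float))
        pad = np.array([margin] * 3)
        box = np.vstack([pts.min(axis=0) - pad, pts.max(axis=0) + pad])
        self.sites = build_sites(model, box, mode, cutoff)
        self.nuclei = np.array([s.cart for s in self.sites])
        self.nucleus_labels = [s.label for s in self.sites]

    def rho(self, points):
        return _eval_sites(points, self.sites)

    def rho_grad_hess(self, points):
        return _eval_sites(points, self.sites, derivatives=True)


def _pair_midpoint_seeds(model, evaluator: _FieldEvaluator, pair_cutoff=3.5):
    """Midpoints of (reference atom, any image) pairs closer than the
    cutoff; the reference molecule is the asymmetric unit as given."""
    ref = np.array([model.cell.orthogonalize(a.frac) for a in model.atoms])
    nuc = evaluator.nuclei
    seeds = []
    for r in ref:
        d = np.linalg.norm(nuc - r, axis=1)
        for j in np.nonzero((d < pair_cutoff) & (d > 1e-6))[0]:
            seeds.append(0.5 * (r + nuc[j]))
    return np.array(seeds) if seeds else np.empty((0, 3))


def _canonical_key(model, position, decimals=2):
    """Canonical identifier of a CP position modulo lattice translations
    and space-group symmetry."""
    frac = model.cell.fractionalize(position)
    best = None
    for op in model.symmetry:
        f = op.apply(frac)
        f -= np.floor(f + 1e-6)
        key = tuple(np.round(f, decimals) % 1.0)
        if best is None or key < best:
            best = key
    return best


def _newton_polish(evaluator, seeds, max_steps=100, gtol=GRAD_TOL,
                   step_cap=0.3, wander=2.5):
    """Batched Newton iteration on grad rho; returns converged points."""
    pts = np.atleast_2d(np.asarray(seeds, float)).copy()
    start = pts.copy()
    active = np.arange(len(pts))
    out = []
    rng = np.random.default_rng(12345)   # perturb-and-retry fallback
    for _ in range(max_steps):
        if len(active) == 0:
            break
        _, g, h = evaluator.rho_grad_hess(pts[active])
        gn = np.linalg.norm(g, axis=1)
        done = gn < gtol
        for idx in active[done]:
            out.append(pts[idx])
        active = active[~done]
        if len(active) == 0:
            break
        g, h = g[~done], h[~done]
        try:
            step = -np.linalg.solve(h, g[..., None])[..., 0]
        except np.linalg.LinAlgError:
            step = np.empty_like(g)
            for i in range(len(g)):
                try:
                    step[i] = -np.linalg.solve(h[i], g[i])
                except np.linalg.LinAlgError:
                    step[i] = rng.normal(scale=0.01, size=3)
        norms = np.linalg.norm(step, axis=1)
        big = norms > step_cap
        step[big] *= (step_cap / norms[big])[:, None]
        pts[active] += step
        # drop walkers that wandered far from their seed
        stay = np.linalg.norm(pts[active] - start[active], axis=1) < wander
        active = active[stay]
    return np.array(out) if out else np.empty((0, 3))


def _merge_points(points, radius=MERGE_RADIUS):
    merged = []
    for p in points:
        if not any(np.linalg.norm(p - q) < radius for q in merged):
            merged.append(p)
    return merged


def find_critical_points(model: CrystalModel, region_points=None, seeds=None,
                         grid_step=None, mode="crystal", cutoff=8.0,
                         pair_cutoff=3.5, max_steps=100, gtol=GRAD_TOL,
                         kinds=None, trace_paths=True,
                         deduplicate_symmetry=True, min_rho=1e-4) -> list:
    """Locate critical points of the model density.

    Seeds default to midpoints of pairs (reference atom, any nucleus image)
    closer than ``pair_cutoff``; a coarse grid with ``grid_step`` over the
    region bounding box can be added for completeness searches.  Converged
    points are merged within 0.05 A, reduced to one representative per
    symmetry/lattice orbit (the one nearest the reference molecule), and
    classified by Hessian signature with a curvature-zero threshold of
    1e-6 e/A^5.
    """
    ref_atoms = np.array([model.cell.orthogonalize(a.frac)
                          for a in model.atoms])
    if region_points is None:
        region_points = ref_atoms
    evaluator = _FieldEvaluator(model, region_points, mode, cutoff)
    seed_list = []
    if seeds is not None:
        seed_list.append(np.atleast_2d(np.asarray(seeds, float)))
    else:
        seed_list.append(_pair_midpoint_seeds(model, evaluator, pair_cutoff))
        if grid_step:
            pts = np.atleast_2d(np.asarray(region_points, float))
            lo, hi = pts.min(axis=0), pts.max(axis=0)
            axes = [np.arange(lo[k], hi[k] + grid_step / 2, grid_step)
                    for k in range(3)]
            gx, gy, gz = np.meshgrid(*axes, indexing="ij")
            seed_list.append(
                np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1))
    all_seeds = np.vstack([s for s in seed_list if len(s)])
    if len(all_seeds) == 0:
        return []
    converged = _newton_polish(evaluator, all_seeds, max_steps, gtol)
    merged = _merge_points(converged)
    if deduplicate_symmetry:
        centroid = ref_atoms.mean(axis=0)
        orbit = {}
        for p in merged:
            key = _canonical_key(model, p)
            d = np.linalg.norm(p - centroid)
            if key not in orbit or d < orbit[key][0]:
                orbit[key] = (d, p)
        merged = [p for _, p in orbit.values()]
    cps = []
    for p in merged:
        # skip points that collapsed onto a nucleus
        if np.min(np.linalg.norm(evaluator.nuclei - p, axis=1)) < 0.2:
            continue
        rho, g, h = evaluator.rho_grad_hess(p[None, :])
        evals, evecs = np.linalg.eigh(h[0])
        signature = int(np.sum(np.sign(evals[np.abs(evals) > EIGEN_ZERO])))
        rank = int(np.sum(np.abs(evals) > EIGEN_ZERO))
        cp = CriticalPoint(position=p, rho=float(rho[0]),
                           laplacian=float(np.trace(h[0])),
                           eigenvalues=evals, eigenvectors=evecs,
                           kind=(rank, signature))
        if cp.rho < min_rho:
            continue    # stationary point of the exponentially flat tail
        if kinds is not None and cp.kind not in kinds:
            continue
        cps.append(cp)
    if trace_paths:
        trace_bond_paths(model, [c for c in cps if c.is_bond_cp],
                         evaluator=evaluator)
    return cps


def trace_bond_paths(model, cps, step=PATH_STEP, max_steps=10_000,
                     mode="crystal", cutoff=10.0, evaluator=None):
    """Trace the two gradient-ascent trajectories of each (3,-1) CP.

    Launched along +/- the lambda_3 eigenvector with fixed-step 4th-order
    (RK4) integration of the normalized gradient field; a trajectory
    terminates within 0.3 A of a nucleus.  Sets linked_atoms /
    linked_positions / path_length on each CP in place (unterminated paths
    are flagged and leave the linkage empty).  All trajectories advance in
    one vectorized batch.
    """
    cps = [cp for cp in cps if cp.is_bond_cp]
    if not cps:
        return []
    if evaluator is None:
        pts = np.array([cp.position for cp in cps])
        evaluator = _FieldEvaluator(model, pts, mode, cutoff,
                                    margin=3.0)
    nuclei, labels = evaluator.nuclei, evaluator.nucleus_labels

    def unit_grad(points):
        _, g, _ = evaluator.rho_grad_hess(points)
        n = np.linalg.norm(g, axis=1, keepdims=True)
        return g / np.maximum(n, 1e-300)

    starts, dirs = [], []
    for cp in cps:
        v3 = cp.eigenvectors[:, 2]
        for sign in (+1.0, -1.0):
            starts.append(cp.position + sign * step * v3)
            dirs.append(sign)
    pts = np.array(starts)
    lengths = np.full(len(pts), step)
    terminus = np.full(len(pts), -1, int)
    active = np.arange(len(pts))
    for _ in range(max_steps):
        if len(active) == 0:
            break
        p = pts[active]
        k1 = unit_grad(p)
        # terminate on the nearest nucleus only when ascending towards it,
        # so a path starting right next to one nucleus can still leave for
        # the attractor on the other side
        d = np.linalg.norm(p[:, None, :] - nuclei[None], axis=2)
        nearest = d.argmin(axis=1)
        dmin = d[np.arange(len(p)), nearest]
        to_nuc = nuclei[nearest] - p
        cosang = np.einsum("ij,ij->i", k1, to_nuc) / np.maximum(dmin, 1e-12)
        hit = (dmin < NUCLEUS_RADIUS) & (cosang > 0.7)
        terminus[active[hit]] = nearest[hit]
        lengths[active[hit]] += dmin[hit]   # close onto the nucleus
        active = active[~hit]
        if len(active) == 0:
            break
        keep = ~hit
        p, k1 = p[keep], k1[keep]
        k2 = unit_grad(p + 0.5 * step * k1)
        k3 = unit_grad(p + 0.5 * step * k2)
        k4 = unit_grad(p + step * k3)
        pts[active] += (step / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        lengths[active] += step
    for i, cp in enumerate(cps):
        t1, t2 = terminus[2 * i], terminus[2 * i + 1]
        if t1 < 0 or t2 < 0:
            cp.unterminated = True
            cp.linked_atoms = None
            continue
        # close the last segment onto the nuclei
        ends = nuclei[[t1, t2]]
        cp.linked_atoms = (labels[t1], labels[t2])
        cp.linked_positions = ends
        cp.path_length = float(lengths[2 * i] + lengths[2 * i + 1])
    return cps


# ---------------------------------------------------------------------------
# energy densities


@dataclass
class EnergyDensities:
    """Kinetic (G) and potential (V) energy densities at a CP, plus the
    hydrogen-bond dissociation energy estimate."""

    g_au: float
    v_au: float
    e_hb_kjmol: float              # headline value, default convention
    e_hb_half_v: float             # -V/2 (Espinosa's calibration)
    e_hb_full_v: float             # -V
    convention: str


def energy_densities_and_ehb(rho, laplacian, convention="half_v"):
    """Abramov kinetic energy density and local-virial potential energy
    density from rho (e/A^3) and the Laplacian (e/A^5) at a critical point.

    G = (3/10)(3 pi^2)^(2/3) rho^(5/3) + lap/6   (atomic units)
    V = lap/4 - 2 G

    The hydrogen-bond dissociation energy is reported under both the -V/2
    (default) and -V conventions, converted to kJ/mol.
    """
    if rho <= 0:
        raise ValueError("rho must be > 0 at a critical point")
    if convention not in ("half_v", "full_v"):
        raise ValueError("convention must be 'half_v' or 'full_v'")
    rho_au = rho * A3_TO_AU
    lap_au = laplacian * A5_TO_AU
    g = 0.3 * (3.0 * np.pi**2) ** (2.0 / 3.0) * rho_au ** (5.0 / 3.0) \
        + lap_au / 6.0
    v = 0.25 * lap_au - 2.0 * g
    half_v = -0.5 * v * HARTREE_KJMOL
    full_v = -v * HARTREE_KJMOL
    return EnergyDensities(
        g_au=float(g), v_au=float(v),
        e_hb_kjmol=float(half_v if convention == "half_v" else full_v),
        e_hb_half_v=float(half_v), e_hb_full_v=float(full_v),
        convention=convention)


# ---------------------------------------------------------------------------
# ensemble statistics


@dataclass
class CPEnsembleEntry:
    """Per-CP occurrence and SSD statistics over a deviating ensemble."""

    reference: CriticalPoint
    occurrence: int
    n: int
    reports: dict = field(default_factory=dict)   # property -> SSDReport
    linked_atom_counts: dict = field(default_factory=dict)

    @property
    def ambiguous_path(self):
        return len(self.linked_atom_counts) > 1


def _relocate_cp(model, reference: CriticalPoint, mode="crystal",
                 match_radius=MATCH_RADIUS):
    """Find the CP of *model* matching a reference CP: Newton from the
    reference position, then a fresh local seed cloud if that fails."""
    ref = reference.position
    evaluator = _FieldEvaluator(model, ref[None, :], mode, margin=2.0)
    for attempt in range(2):
        if attempt == 0:
            seeds = ref[None, :]
        else:
            offs = np.array([[i, j, k] for i in (-1, 0, 1)
                             for j in (-1, 0, 1) for k in (-1, 0, 1)], float)
            seeds = ref[None, :] + 0.15 * offs
        conv = _newton_polish(evaluator, seeds)
        if len(conv) == 0:
            continue
        d = np.linalg.norm(conv - ref, axis=1)
        if d.min() > match_radius:
            continue
        p = conv[np.argmin(d)]
        rho, g, h = evaluator.rho_grad_hess(p[None, :])
        evals, evecs = np.linalg.eigh(h[0])
        signature = int(np.sum(np.sign(evals[np.abs(evals) > EIGEN_ZERO])))
        rank = int(np.sum(np.abs(evals) > EIGEN_ZERO))
        if (rank, signature) != reference.kind:
            continue
        return CriticalPoint(position=p, rho=float(rho[0]),
                             laplacian=float(np.trace(h[0])),
                             eigenvalues=evals, eigenvectors=evecs,
                             kind=(rank, signature))
    return None


def _nearest_image(model, label, point):
    """Cartesian position of the symmetry/lattice image of atom *label*
    closest to *point*."""
    cell = model.cell
    frac_pt = cell.fractionalize(point)
    atom = model.atom(label)
    best, best_d = None, np.inf
    for op in model.symmetry:
        f = op.apply(atom.frac)
        base = np.round(frac_pt - f)
        for dn_ in np.array([[i, j, k] for i in (-1, 0, 1)
                             for j in (-1, 0, 1) for k in (-1, 0, 1)]):
            cart = cell.orthogonalize(f + base + dn_)
            d = np.linalg.norm(cart - point)
            if d < best_d:
                best, best_d = cart, d
    return best


def cp_ensemble_statistics(ensemble: DeviatingEnsemble, model: CrystalModel,
                           reference_cps, mode="crystal",
                           match_radius=MATCH_RADIUS,
                           trace_linked_atoms=False) -> list:
    """Re-locate every reference CP in each deviating model and reduce to
    per-CP SSD reports (rho, Laplacian, eigenvalues, ellipticity, and
    nucleus-CP distances when the reference CP carries a bond path).

    A CP absent from a member (no stationary point of the right signature
    within ``match_radius``) simply lowers that CP's occurrence count; with
    fewer than two occurrences no SSD is reported.
    """
    return cp_statistics_over_models(
        ensemble.member_models(model), reference_cps, mode=mode,
        match_radius=match_radius, trace_linked_atoms=trace_linked_atoms)


def cp_statistics_over_models(member_models, reference_cps, mode="crystal",
                              match_radius=MATCH_RADIUS,
                              trace_linked_atoms=False) -> list:
    """Same as :func:`cp_ensemble_statistics` but over explicit member
    models (e.g. an ensemble reloaded from disk)."""
    entries = []
    for ref in reference_cps:
        found = []
        linked_counts = {}
        for mm in member_models:
            cp = _relocate_cp(mm, ref, mode, match_radius)
            if cp is None:
                continue
            if trace_linked_atoms and ref.is_bond_cp:
                trace_bond_paths(mm, [cp], mode=mode)
                if cp.linked_atoms is not None:
                    key = tuple(sorted(cp.linked_atoms))
                    linked_counts[key] = linked_counts.get(key, 0) + 1
            elif ref.linked_positions is not None:
                # the member's own nuclei (nearest symmetry image of each
                # linked atom), so d(X, CP) sees both CP and atom shifts
                cp.linked_atoms = ref.linked_atoms
                cp.linked_positions = np.array([
                    _nearest_image(mm, lbl, ref_pos)
                    for lbl, ref_pos in zip(ref.linked_atoms,
                                            ref.linked_positions)])
            found.append(cp)
        entry = CPEnsembleEntry(reference=ref, occurrence=len(found),
                                n=len(member_models),
                                linked_atom_counts=linked_counts)
        if len(found) >= 2:
            props = {
                "rho": [c.rho for c in found],
                "laplacian": [c.laplacian for c in found],
                "lambda1": [c.eigenvalues[0] for c in found],
                "lambda2": [c.eigenvalues[1] for c in found],
                "lambda3": [c.eigenvalues[2] for c in found],
            }
            if ref.is_bond_cp:
                try:
                    props["ellipticity"] = [c.ellipticity for c in found]
                except ValueError:
                    pass
            if all(c.linked_positions is not None for c in found):
                props["d_a1_cp"] = [c.distances()[0] for c in found]
                props["d_a2_cp"] = [c.distances()[1] for c in found]
            units = {"rho": "e/A^3", "laplacian": "e/A^5",
                     "lambda1": "e/A^5", "lambda2": "e/A^5",
                     "lambda3": "e/A^5", "ellipticity": "",
                     "d_a1_cp": "A", "d_a2_cp": "A"}
            for name, vals in props.items():
                entry.reports[name] = sample_standard_deviation(
                    vals, label=name, units=units.get(name, ""))
                entry.reports[name].n = len(member_models)
                entry.reports[name].occurrence = len(found)
        entries.append(entry)
    return entries
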