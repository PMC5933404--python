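"""Crystal model containers: unit cell, symmetry, multipolar pseudoatoms.

The refinable state is a :class:`CrystalModel`; :func:`pack_parameters` /
:func:`unpack_parameters` map it to and from a flat real vector with a
documented deterministic ordering (scale factor first, then per atom:
fractional coordinates, U tensor components, valence population, multipole
populations, kappa, kappa').
"""

from __future__ import annotations

import copy as _copy
import re
from dataclasses import dataclass, field

import numpy as np

from .elements import ElementData, element

PARAMETER_KINDS = ("scale", "xyz", "uij", "pval", "plm", "kappa", "kappa_prime")

# storage order of the symmetric U tensor components
UIJ_COMPONENTS = ((0, 0), (1, 1), (2, 2), (0, 1), (0, 2), (1, 2))


def multipole_index_order(lmax: int):
    """Canonical (l, m) ordering of multipole populations: l ascending,
    within each l the order 0, +1, -1, +2, -2, ..."""
    order = []
    for l in range(1, lmax + 1):
        order.append((l, 0))
        for m in range(1, l + 1):
            order.append((l, m))
            order.append((l, -m))
    return order


class UnitCell:
    """Triclinic unit cell with metric and orthogonalization transforms.

    Cartesian convention: a along x, b in the xy plane.
    """

    def __init__(self, a, b, c, alpha=90.0, beta=90.0, gamma=90.0):
        self.a, self.b, self.c = float(a), float(b), float(c)
        self.alpha, self.beta, self.gamma = float(alpha), float(beta), float(gamma)
        al, be, ga = np.radians([self.alpha, self.beta, self.gamma])
        ca, cb, cg = np.cos([al, be, ga])
        sg = np.sin(ga)
        v_arg = 1 - ca**2 - cb**2 - cg**2 + 2 * ca * cb * cg
        if not v_arg > 0:
            raise ValueError("degenerate unit cell (volume <= 0)")
        v_factor = np.sqrt(v_arg)
        self.volume = self.a * self.b * self.c * v_factor
        # orthogonalization matrix: cartesian = M @ fractional
        self.orthogonalization = np.array([
            [self.a, self.b * cg, self.c * cb],
            [0.0, self.b * sg, self.c * (ca - cb * cg) / sg],
            [0.0, 0.0, self.c * v_factor / sg],
        ])
        self.fractionalization = np.linalg.inv(self.orthogonalization)
        # direct and reciprocal metric tensors
        self.metric = self.orthogonalization.T @ self.orthogonalization
        self.reciprocal_metric = np.linalg.inv(self.metric)
        self.reciprocal_lengths = np.sqrt(np.diag(self.reciprocal_metric))

    def orthogonalize(self, frac):
        return np.asarray(frac, float) @ self.orthogonalization.T

    def fractionalize(self, cart):
        return np.asarray(cart, float) @ self.fractionalization.T

    def resolution_s(self, hkl):
        """sin(theta)/lambda = |h*|/2 in 1/A for integer hkl (array ok)."""
        hkl = np.atleast_2d(np.asarray(hkl, float))
        d2inv = np.einsum("ni,ij,nj->n", hkl, self.reciprocal_metric, hkl)
        return 0.5 * np.sqrt(d2inv)

    def __repr__(self):
        return (f"UnitCell(a={self.a}, b={self.b}, c={self.c}, "
                f"alpha={self.alpha}, beta={self.beta}, gamma={self.gamma})")


_AXES = {"x": 0, "y": 1, "z": 2}


@dataclass(frozen=True)
class SymmetryOperator:
    """Space-group operator in the fractional basis: x' = R x + t."""

    rotation: tuple    # 3x3 nested tuple of ints
    translation: tuple  # 3 floats (fractions)

    @property
    def rot(self) -> np.ndarray:
        return np.array(self.rotation, float)

    @property
    def trans(self) -> np.ndarray:
        return np.array(self.translation, float)

    def __post_init__(self):
        det = round(np.linalg.det(np.array(self.rotation, float)))
        if det not in (-1, 1):
            raise ValueError("symmetry rotation must have determinant +/-1")

    @classmethod
    def identity(cls):
        return cls.from_string("x, y, z")

    @classmethod
    def from_string(cls, triplet: str) -> "SymmetryOperator":
        """Parse an 'x, y, z'-style triplet, e.g. '-x+1/2, y, -z'."""
        rows, trans = [], []
        parts = triplet.lower().replace(" ", "").split(",")
        if len(parts) != 3:
            raise ValueError(f"bad symmetry triplet: {triplet!r}")
        for part in parts:
            row = [0, 0, 0]
            t = 0.0
            for sign, term in re.findall(r"([+-]?)([^+-]+)", part):
                s = -1 if sign == "-" else 1
                if term in _AXES:
                    row[_AXES[term]] += s
                elif "/" in term:
                    num, den = term.split("/")
                    t += s * float(num) / float(den)
                else:
                    t += s * float(term)
            rows.append(tuple(row))
            trans.append(t)
        return cls(rotation=tuple(rows), translation=tuple(trans))

    def to_string(self) -> str:
        out = []
        for row, t in zip(self.rotation, self.translation):
            terms = []
            for coeff, axis in zip(row, "xyz"):
                if coeff == 1:
                    terms.append(f"+{axis}")
                elif coeff == -1:
                    terms.append(f"-{axis}")
                elif coeff != 0:
                    terms.append(f"{coeff:+d}{axis}")
            if abs(t) > 1e-9:
                terms.append(f"{t:+g}")
            out.append("".join(terms).lstrip("+"))
        return ", ".join(out)

    def apply(self, frac):
        return np.asarray(frac, float) @ self.rot.T + self.trans

    def compose(self, other: "SymmetryOperator") -> "SymmetryOperator":
        """self o other (apply other first)."""
        r = self.rot @ other.rot
        t = self.rot @ other.trans + self.trans
        return SymmetryOperator(
            rotation=tuple(tuple(int(round(v)) for v in row) for row in r),
            translation=tuple(float(v) for v in t),
        )

    def inverse(self) -> "SymmetryOperator":
        rinv = np.linalg.inv(self.rot)
        t = -rinv @ self.trans
        return SymmetryOperator(
            rotation=tuple(tuple(int(round(v)) for v in row) for row in rinv),
            translation=tuple(float(v) for v in t),
        )

    def equals_mod_lattice(self, other: "SymmetryOperator", tol=1e-8) -> bool:
        if self.rotation != other.rotation:
            return False
        dt = self.trans - other.trans
        return bool(np.all(np.abs(dt - np.round(dt)) < tol))

    def is_involution(self) -> bool:
        """True when the operator composed with itself is the exact
        identity (zero residual translation), i.e. the two molecules of
        the dimer it generates map onto each other mutually.  Inversions
        and in-place two-folds qualify; screws, glides and pure
        translations (whose square is a nonzero lattice translation) do
        not."""
        sq = self.compose(self)
        return (sq.rotation == SymmetryOperator.identity().rotation
                and bool(np.all(np.abs(sq.trans) < 1e-8)))

    def cartesian_rotation(self, cell: UnitCell) -> np.ndarray:
        return cell.orthogonalization @ self.rot @ cell.fractionalization


@dataclass
class MultipoleAtom:
    """One Hansen-Coppens pseudoatom of the asymmetric unit."""

    label: str
    element: str
    frac: np.ndarray                 # fractional coordinates
    u: np.ndarray                    # 3x3 symmetric ADP tensor, A^2
    p_val: float                     # valence population, electrons
    p_lm: dict = field(default_factory=dict)   # {(l, m): population}
    kappa: float = 1.0
    kappa_prime: float = 1.0
    lmax: int = None                 # type: ignore[assignment]

    def __post_init__(self):
        self.frac = np.asarray(self.frac, float).copy()
        self.u = np.asarray(self.u, float).copy()
        if self.lmax is None:
            self.lmax = self.data.lmax
        if self.kappa <= 0 or self.kappa_prime <= 0:
            raise ValueError(f"atom {self.label}: kappa values must be > 0")
        if self.p_val < 0:
            raise ValueError(f"atom {self.label}: P_val must be >= 0")

    @property
    def data(self) -> ElementData:
        return element(self.element)

    @property
    def n_electrons(self) -> float:
        return self.data.n_core + self.p_val

    @classmethod
    def neutral(cls, label, elem, frac, u_iso=0.01, **kw):
        data = element(elem)
        return cls(label=label, element=elem, frac=np.asarray(frac, float),
                   u=np.eye(3) * u_iso, p_val=float(data.n_val), **kw)

    def plm_order(self):
        return multipole_index_order(self.lmax)

    def copy(self) -> "MultipoleAtom":
        return _copy.deepcopy(self)


@dataclass
class CrystalModel:
    """A crystal: cell + space-group operators + asymmetric-unit pseudoatoms."""

    cell: UnitCell
    symmetry: list
    atoms: list
    scale_factor: float = 1.0

    def __post_init__(self):
        labels = [a.label for a in self.atoms]
        if len(set(labels)) != len(labels):
            raise ValueError("atom labels must be unique")

    def atom(self, label: str) -> MultipoleAtom:
        for a in self.atoms:
            if a.label == label:
                return a
        raise KeyError(label)

    @property
    def n_symmetry(self) -> int:
        return len(self.symmetry)

    def electrons_per_cell(self) -> float:
        return self.n_symmetry * sum(a.n_electrons for a in self.atoms)

    def copy(self) -> "CrystalModel":
        return CrystalModel(
            cell=self.cell,
            symmetry=list(self.symmetry),
            atoms=[a.copy() for a in self.atoms],
            scale_factor=self.scale_factor,
        )


@dataclass
class ParameterVector:
    """Flat view of the refinable state with a bijective index map."""

    values: np.ndarray
    index_map: list   # entries (atom_label_or_None, kind, component_key)

    def __len__(self):
        return len(self.values)

    def position(self, label, kind, component=None):
        key = (label, kind, component)
        for i, entry in enumerate(self.index_map):
            if entry == key:
                return i
        raise KeyError(key)

    def labels(self):
        out = []
        for label, kind, comp in self.index_map:
            base = kind if label is None else f"{label}.{kind}"
            out.append(base if comp is None else f"{base}[{comp}]")
        return out


def pack_parameters(model: CrystalModel, selection=None,
                    fixed=()) -> ParameterVector:
    """Flatten the selected parameter kinds of *model* into a vector.

    Ordering: scale factor, then for each atom in model order: x, y, z,
    U11, U22, U33, U12, U13, U23, P_val, P_lm (l ascending; m = 0, +1, -1,
    ...), kappa, kappa'.

    ``fixed`` holds keys excluded from the free set, given as
    (label, kind, component) or (label, kind); e.g. [("C1", "xyz")] pins
    the first atom to fix a floating P1 origin.
    """
    if selection is None:
        selection = set(PARAMETER_KINDS)
    selection = set(selection)
    unknown = selection - set(PARAMETER_KINDS)
    if unknown:
        raise ValueError(f"unknown parameter kind(s): {sorted(unknown)}")
    if not selection:
        raise ValueError("empty parameter selection")
    fixed = {tuple(f) for f in fixed}

    def is_free(label, kind, comp):
        return ((label, kind, comp) not in fixed
                and (label, kind) not in fixed)

    values, index_map = [], []
    if "scale" in selection and is_free(None, "scale", None):
        values.append(model.scale_factor)
        index_map.append((None, "scale", None))
    for atom in model.atoms:
        if "xyz" in selection:
            for k in range(3):
                if is_free(atom.label, "xyz", k):
                    values.append(atom.frac[k])
                    index_map.append((atom.label, "xyz", k))
        if "uij" in selection:
            for (i, j) in UIJ_COMPONENTS:
                if is_free(atom.label, "uij", (i, j)):
                    values.append(atom.u[i, j])
                    index_map.append((atom.label, "uij", (i, j)))
        if "pval" in selection and is_free(atom.label, "pval", None):
            values.append(atom.p_val)
            index_map.append((atom.label, "pval", None))
        if "plm" in selection:
            for lm in atom.plm_order():
                if is_free(atom.label, "plm", lm):
                    values.append(atom.p_lm.get(lm, 0.0))
                    index_map.append((atom.label, "plm", lm))
        if "kappa" in selection and is_free(atom.label, "kappa", None):
            values.append(atom.kappa)
            index_map.append((atom.label, "kappa", None))
        if "kappa_prime" in selection and is_free(atom.label, "kappa_prime", None):
            values.append(atom.kappa_prime)
            index_map.append((atom.label, "kappa_prime", None))
    return ParameterVector(values=np.array(values, float), index_map=index_map)


def unpack_parameters(model: CrystalModel, pv: ParameterVector) -> CrystalModel:
    """Return a copy of *model* with the vector written back."""
    out = model.copy()
    atoms = {a.label: a for a in out.atoms}
    for value, (label, kind, comp) in zip(pv.values, pv.index_map):
        if kind == "scale":
            out.scale_factor = float(value)
            continue
        atom = atoms[label]
        if kind == "xyz":
            atom.frac[comp] = value
        elif kind == "uij":
            i, j = comp
            atom.u[i, j] = value
            atom.u[j, i] = value
        elif kind == "pval":
            atom.p_val = float(value)
        elif kind == "plm":
            atom.p_lm[comp] = float(value)
        elif kind == "kappa":
            atom.kappa = float(value)
        elif kind == "kappa_prime":
            atom.kappa_prime = float(value)
        else:  # pragma: no cover
            raise ValueError(f"unknown kind {kind}")
    return out


def parameter_count(model: CrystalModel, selection=None) -> int:
    return len(pack_parameters(model, selection))
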