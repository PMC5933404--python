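"""File formats: plain-text model blocks, reflection lists, Gaussian cube
volumes, run configuration, ensemble manifests, and the crystallographic
parenthesized-uncertainty notation.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .constants import BOHR_ANGSTROM
from .elements import element
from .model import (
    CrystalModel,
    MultipoleAtom,
    SymmetryOperator,
    UnitCell,
)

_FMT = "%.17g"   # shortest-exact float round-trip


# ---------------------------------------------------------------------------
# model files


def write_model(model: CrystalModel, path):
    """Write the plain-text model block format (canonical form)."""
    lines = []
    c = model.cell
    lines.append("CELL " + " ".join(
        _FMT % v for v in (c.a, c.b, c.c, c.alpha, c.beta, c.gamma)))
    lines.append("SCALE " + _FMT % model.scale_factor)
    for op in model.symmetry:
        lines.append("SYMM " + op.to_string())
    for a in model.atoms:
        lines.append(f"ATOM {a.label} {a.element}")
        lines.append("  XYZ " + " ".join(_FMT % v for v in a.frac))
        u = a.u
        lines.append("  UIJ " + " ".join(
            _FMT % u[i, j] for (i, j) in
            ((0, 0), (1, 1), (2, 2), (0, 1), (0, 2), (1, 2))))
        lines.append("  PVAL " + _FMT % a.p_val)
        for (l, m) in sorted(a.p_lm, key=lambda lm: (lm[0], -lm[1])):
            lines.append(f"  PLM {l} {m} " + _FMT % a.p_lm[(l, m)])
        lines.append("  KAPPA " + _FMT % a.kappa + " " + _FMT % a.kappa_prime)
        lines.append(f"  LMAX {a.lmax}")
        lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def read_model(path) -> CrystalModel:
    cell = None
    scale = 1.0
    symmetry = []
    atoms = []
    current = None

    def close(cur):
        if cur is None:
            return
        atoms.append(MultipoleAtom(
            label=cur["label"], element=cur["element"],
            frac=np.array(cur["xyz"]), u=np.array(cur["u"]),
            p_val=cur["pval"], p_lm=cur["plm"], kappa=cur["kappa"],
            kappa_prime=cur["kappa_prime"], lmax=cur.get("lmax")))

    for ln, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        tok = line.split()
        key = tok[0].upper()
        try:
            if key == "CELL":
                cell = UnitCell(*map(float, tok[1:7]))
            elif key == "SCALE":
                scale = float(tok[1])
            elif key == "SYMM":
                symmetry.append(
                    SymmetryOperator.from_string(line[4:].strip()))
            elif key == "ATOM":
                close(current)
                current = {"label": tok[1], "element": tok[2], "plm": {},
                           "kappa": 1.0, "kappa_prime": 1.0, "pval": 0.0,
                           "u": np.zeros((3, 3)), "xyz": [0, 0, 0],
                           "lmax": None}
            elif key == "XYZ":
                current["xyz"] = [float(v) for v in tok[1:4]]
            elif key == "UIJ":
                u = np.zeros((3, 3))
                vals = [float(v) for v in tok[1:7]]
                for (i, j), v in zip(
                        ((0, 0), (1, 1), (2, 2), (0, 1), (0, 2), (1, 2)),
                        vals):
                    u[i, j] = u[j, i] = v
                current["u"] = u
            elif key == "PVAL":
                current["pval"] = float(tok[1])
            elif key == "PLM":
                current["plm"][(int(tok[1]), int(tok[2]))] = float(tok[3])
            elif key == "KAPPA":
                current["kappa"] = float(tok[1])
                current["kappa_prime"] = float(tok[2])
            elif key == "LMAX":
                current["lmax"] = int(tok[1])
            elif key == "END":
                close(current)
                current = None
            else:
                raise ValueError(f"unknown record {key!r}")
        except (IndexError, ValueError) as exc:
            raise ValueError(f"{path}:{ln}: cannot parse {raw!r} ({exc})") \
                from exc
    close(current)
    if cell is None:
        raise ValueError(f"{path}: missing CELL record")
    if not symmetry:
        symmetry = [SymmetryOperator.identity()]
    return CrystalModel(cell=cell, symmetry=symmetry, atoms=atoms,
                        scale_factor=scale)


# ---------------------------------------------------------------------------
# reflection files (free whitespace format: h k l I sigma)


def write_reflections(reflections, path):
    lines = ["# h k l I_obs sigma_I"]
    for (h, k, l), i, s in zip(reflections.hkl, reflections.i_obs,
                               reflections.sigma_i):
        lines.append(f"{h:d} {k:d} {l:d} {_FMT % i} {_FMT % s}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_reflections(path, weight_c=1.0):
    from .refine import ReflectionSet

    hkl, i_obs, sig = [], [], []
    for ln, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith(("#", "!")):
            continue
        tok = line.split()
        if len(tok) < 5:
            raise ValueError(f"{path}:{ln}: expected 'h k l I sigma'")
        hkl.append([int(tok[0]), int(tok[1]), int(tok[2])])
        i_obs.append(float(tok[3]))
        sig.append(float(tok[4]))
    return ReflectionSet.from_intensities(np.array(hkl), np.array(i_obs),
                                          np.array(sig), weight_c=weight_c)


# ---------------------------------------------------------------------------
# Gaussian cube files


def write_cube(path, grid, origin, step, model: CrystalModel = None,
               comment="chargemc density grid"):
    """Write a scalar grid as a Gaussian cube file (lengths in bohr in the
    header per the cube convention; the grid must be axis-aligned)."""
    grid = np.asarray(grid, float)
    if grid.ndim != 3:
        raise ValueError("cube grid must be 3-dimensional")
    origin_b = np.asarray(origin, float) / BOHR_ANGSTROM
    step_b = (np.eye(3) * step / BOHR_ANGSTROM if np.isscalar(step)
              else np.asarray(step, float) / BOHR_ANGSTROM)
    atoms = model.atoms if model is not None else []
    lines = [comment, "OUTER LOOP: X, MIDDLE: Y, INNER: Z"]
    lines.append("%5d %11.6f %11.6f %11.6f" % (len(atoms), *origin_b))
    for k in range(3):
        lines.append("%5d %11.6f %11.6f %11.6f"
                     % (grid.shape[k], *step_b[k]))
    for a in atoms:
        z = element(a.element).z
        cart = model.cell.orthogonalize(a.frac) / BOHR_ANGSTROM
        lines.append("%5d %11.6f %11.6f %11.6f %11.6f" % (z, float(z), *cart))
    flat = grid.reshape(grid.shape[0] * grid.shape[1], grid.shape[2])
    for row in flat:
        for start in range(0, len(row), 6):
            lines.append(" ".join("%13.5E" % v
                                  for v in row[start:start + 6]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_cube(path):
    """Read a Gaussian cube file -> (grid, origin A, axes (3,3) A, atom
    records [(Z, x, y, z) in A])."""
    text = Path(path).read_text().splitlines()
    try:
        natoms_tok = text[2].split()
        natoms = int(natoms_tok[0])
        origin = np.array([float(v) for v in natoms_tok[1:4]]) * BOHR_ANGSTROM
        shape, axes = [], []
        for k in range(3):
            tok = text[3 + k].split()
            shape.append(int(tok[0]))
            axes.append([float(v) * BOHR_ANGSTROM for v in tok[1:4]])
        atoms = []
        for i in range(abs(natoms)):
            tok = text[6 + i].split()
            atoms.append((int(tok[0]),
                          *(float(v) * BOHR_ANGSTROM for v in tok[2:5])))
        data = []
        for line in text[6 + abs(natoms):]:
            data.extend(float(v) for v in line.split())
        grid = np.array(data).reshape(shape)
    except (IndexError, ValueError) as exc:
        raise ValueError(f"{path}: malformed cube header or data "
                         f"({exc})") from exc
    return grid, origin, np.array(axes), atoms


# ---------------------------------------------------------------------------
# parenthesized uncertainties ("1.3711 (2)" style)


def format_value_with_uncertainty(value, uncertainty, sig=1):
    """Crystallographic notation: uncertainty in parentheses scaled to the
    last printed digit(s), e.g. (1.3711, 0.0002) -> '1.3711 (2)' and
    (41.0, 2.0) -> '41 (2)'."""
    if not math.isfinite(value):
        return str(value)
    if uncertainty is None or not math.isfinite(uncertainty) \
            or uncertainty <= 0:
        return _FMT % value
    exponent = math.floor(math.log10(uncertainty)) - (sig - 1)
    scaled = round(uncertainty / 10**exponent)
    if scaled >= 10**sig:   # e.g. 0.098 -> '10' at sig=1; carry the decade
        scaled //= 10
        exponent += 1
    decimals = max(0, -exponent)
    if exponent > 0:
        scaled *= 10**exponent
    return f"{value:.{decimals}f} ({scaled:d})"


def parse_value_with_uncertainty(text):
    """Inverse of :func:`format_value_with_uncertainty`; returns
    (value, uncertainty) with uncertainty None when absent."""
    m = re.match(r"\s*([-+]?[\d.]+(?:[eE][-+]?\d+)?)"
                 r"(?:\s*\((\d+)\))?\s*$", text)
    if not m:
        raise ValueError(f"cannot parse {text!r}")
    value = float(m.group(1))
    if m.group(2) is None:
        return value, None
    digits = m.group(2)
    main = m.group(1)
    decimals = len(main.split(".")[1]) if "." in main else 0
    return value, int(digits) * 10.0 ** (-decimals)


# ---------------------------------------------------------------------------
# run configuration and ensemble manifests


@dataclass
class RunConfig:
    """Pipeline configuration; every step, cutoff and margin is > 0."""

    seed: int = 0
    n_models: int = 20
    truncation_bound: float = 4.0
    eigen_floor: float = 1e-10
    density_grid_step: float = 0.05
    surface_grid_step: float = 0.1
    basin_margin: float = 3.0
    contact_cutoff: float = 3.0
    i_over_sigma_cutoff: float = None   # optional filter, e.g. 0.35
    weight_c: float = 1.0
    output_dir: str = "chargemc_out"

    def __post_init__(self):
        for name in ("density_grid_step", "surface_grid_step",
                     "basin_margin", "contact_cutoff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    def save(self, path):
        Path(path).write_text(json.dumps(asdict(self), indent=1) + "\n")

    @classmethod
    def load(cls, path):
        return cls(**json.loads(Path(path).read_text()))


def save_ensemble(ensemble, model, directory):
    """One model file per deviating member plus a manifest with the seed,
    N, truncation and square-root metadata."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    members = ensemble.member_models(model)
    for i, mm in enumerate(members):
        write_model(mm, directory / f"member_{i:03d}.mod")
    write_model(model, directory / "reference.mod")
    manifest = {
        "n": ensemble.n,
        "seed": ensemble.seed,
        "truncation_bound": ensemble.truncation_bound,
        "renormalization": ensemble.renormalization,
    }
    if ensemble.sqrt_factor is not None:
        manifest["eigen_floor_applied"] = ensemble.sqrt_factor.floor_applied
        manifest["gof_scaled"] = ensemble.sqrt_factor.gof_scaled
    (directory / "manifest.json").write_text(
        json.dumps(manifest, indent=1) + "\n")


def load_ensemble_models(directory):
    """Read back the member models and the manifest of a saved ensemble."""
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    members = [read_model(p)
               for p in sorted(directory.glob("member_*.mod"))]
    reference = read_model(directory / "reference.mod")
    return reference, members, manifest
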