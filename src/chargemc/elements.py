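"""Per-element Slater-type radial data for the pseudoatom model.

Every spherical shell is a normalized density f(r) = C r^n exp(-zeta r) with
C = zeta^(n+3) / (4 pi (n+2)!) so that the shell integrates to one electron.
Orbital exponents follow Slater's screening rules; the density exponent is
twice the orbital exponent converted to 1/Angstrom.  These single-zeta forms
are a self-contained desk-scale radial model: absolute densities differ from
multi-zeta Hartree-Fock atomic wavefunction tables, and no claim is made of
reproducing literature absolute values for real compounds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .constants import BOHR_ANGSTROM

# powers r^n_l of the deformation radial functions for l = 0..3
DEFORMATION_POWERS = (2, 2, 3, 4)


@dataclass(frozen=True)
class ElementData:
    symbol: str
    z: int                    # atomic number
    n_core: int               # core electrons (frozen)
    n_val: int                # neutral valence electrons
    zeta_core: float          # core density exponent, 1/A (0 if no core)
    zeta_val: float           # valence density exponent, 1/A
    n_core_pow: int = 0       # r-power of the core shell
    n_val_pow: int = 0        # r-power of the valence shell
    lmax: int = 1             # default multipole truncation
    # deformation radial exponents per l, default to the valence exponent
    zeta_l: tuple = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.zeta_l is None:
            object.__setattr__(
                self, "zeta_l", tuple(self.zeta_val for _ in range(4))
            )


def _second_row(symbol: str, z: int, lmax: int = 3) -> ElementData:
    """Slater single-zeta data for a 1s^2 core + 2s2p valence element."""
    n_val = z - 2
    zeta_orb_val = (z - 2 * 0.85 - (n_val - 1) * 0.35) / 2.0
    zeta_orb_core = z - 0.3
    return ElementData(
        symbol=symbol,
        z=z,
        n_core=2,
        n_val=n_val,
        zeta_core=2.0 * zeta_orb_core / BOHR_ANGSTROM,
        zeta_val=2.0 * zeta_orb_val / BOHR_ANGSTROM,
        n_core_pow=0,
        n_val_pow=2,
        lmax=lmax,
    )


ELEMENTS = {
    "H": ElementData(
        symbol="H", z=1, n_core=0, n_val=1,
        zeta_core=0.0, zeta_val=2.0 / BOHR_ANGSTROM,
        n_core_pow=0, n_val_pow=0, lmax=1,
    ),
    "B": _second_row("B", 5),
    "C": _second_row("C", 6),
    "N": _second_row("N", 7),
    "O": _second_row("O", 8),
}


def element(symbol: str) -> ElementData:
    try:
        return ELEMENTS[symbol]
    except KeyError:
        raise KeyError(
            f"element {symbol!r} not tabulated (available: {sorted(ELEMENTS)})"
        ) from None
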