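"""Chemical species and electronic-structure method descriptions.

A :class:`Species` is one SCF problem: a set of nuclei, a net charge and a
spin multiplicity.  A :class:`MethodSpec` fixes how its energy is computed:
the functional family (HF, pure/hybrid/double-hybrid DFT), the fraction of
Hartree-Fock exchange ``a_x``, the MP2 mixing coefficient ``a_c`` (nonzero
only for double hybrids), the dispersion model and the basis set.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

ELEMENTS = [
    "X", "H", "He", "Li", "Be", "B", "C", "N", "O", "F", "Ne",
    "Na", "Mg", "Al", "Si", "P", "S", "Cl", "Ar",
]
Z_BY_SYMBOL = {s.lower(): z for z, s in enumerate(ELEMENTS)}


def symbol_to_z(symbol: str) -> int:
    try:
        return Z_BY_SYMBOL[symbol.strip().lower()]
    except KeyError:
        raise ValueError(f"unknown element symbol: {symbol!r}") from None


@dataclass(frozen=True)
class Species:
    """A molecule or fragment: nuclei, charge and multiplicity.

    Parameters
    ----------
    numbers : tuple of int
        Atomic numbers Z.
    coords_bohr : ndarray, shape (natom, 3)
        Nuclear positions in Bohr.
    charge : int
        Net charge.
    multiplicity : int
        Spin multiplicity 2S+1.
    """

    numbers: tuple
    coords_bohr: np.ndarray
    charge: int = 0
    multiplicity: int = 1

    def __post_init__(self):
        coords = np.asarray(self.coords_bohr, dtype=float).reshape(-1, 3)
        object.__setattr__(self, "coords_bohr", coords)
        object.__setattr__(self, "numbers", tuple(int(z) for z in self.numbers))
        if len(self.numbers) != coords.shape[0]:
            raise ValueError("numbers and coordinates disagree in length")
        if not np.all(np.isfinite(coords)):
            raise ValueError("non-finite coordinates")
        if self.n_electrons < 0:
            raise ValueError("negative electron count")
        if self.multiplicity < 1:
            raise ValueError("multiplicity must be >= 1")
        n_unpaired = self.multiplicity - 1
        if n_unpaired > self.n_electrons:
            raise ValueError("multiplicity inconsistent with electron count")
        if (self.n_electrons - n_unpaired) % 2 != 0:
            raise ValueError(
                f"multiplicity {self.multiplicity} impossible for "
                f"{self.n_electrons} electrons"
            )

    @property
    def natom(self) -> int:
        return len(self.numbers)

    @property
    def n_electrons(self) -> int:
        return int(sum(self.numbers)) - self.charge

    @property
    def n_alpha(self) -> int:
        return (self.n_electrons + self.multiplicity - 1) // 2

    @property
    def n_beta(self) -> int:
        return self.n_electrons - self.n_alpha

    @property
    def is_closed_shell(self) -> bool:
        return self.multiplicity == 1

    def nuclear_repulsion(self) -> float:
        e = 0.0
        for i in range(self.natom):
            for j in range(i + 1, self.natom):
                r = np.linalg.norm(self.coords_bohr[i] - self.coords_bohr[j])
                e += self.numbers[i] * self.numbers[j] / r
        return e

    def subset(self, indices, charge: int, multiplicity: int) -> "Species":
        """Species built from a subset of atoms at frozen coordinates."""
        idx = list(indices)
        return Species(
            numbers=tuple(self.numbers[i] for i in idx),
            coords_bohr=self.coords_bohr[idx],
            charge=charge,
            multiplicity=multiplicity,
        )


# exchange/correlation recipe per functional: list of (name, weight) pairs
# consumed by etsnocv.functionals, plus the HF-exchange fraction.
_FUNCTIONALS = {
    # name: (family, a_x, a_c, xc_terms)
    "hf": ("hf", 1.0, 0.0, ()),
    "lda": ("pure", 0.0, 0.0, (("slater_x", 1.0), ("vwn5_c", 1.0))),
    "svwn": ("pure", 0.0, 0.0, (("slater_x", 1.0), ("vwn5_c", 1.0))),
    "blyp": ("pure", 0.0, 0.0,
             (("slater_x", 1.0), ("b88_x", 1.0), ("lyp_c", 1.0))),
    # B3LYP with the VWN5 local-correlation variant
    "b3lyp": ("hybrid", 0.20, 0.0,
              (("slater_x", 0.80), ("b88_x", 0.72),
               ("vwn5_c", 0.19), ("lyp_c", 0.81))),
    "b2plyp": ("double-hybrid", 0.53, 0.27,
               (("slater_x", 0.47), ("b88_x", 0.47), ("lyp_c", 0.73))),
    "mp2": ("double-hybrid", 1.0, 1.0, ()),  # plain MP2 for testing
}


@dataclass(frozen=True)
class MethodSpec:
    """Electronic-structure method: functional, mixing fractions, basis.

    ``hf_exchange_fraction`` is the coefficient *a* multiplying exact
    exchange; ``mp2_coefficient`` is the *a_C* scaling of the MP2
    correlation term (nonzero only for double hybrids, where the DFT
    correlation carries weight 1 - a_C inside ``xc_terms``).
    """

    functional: str = "hf"
    basis: str = "sto-3g"
    dispersion: str = "none"
    family: str = field(default="", compare=False)
    hf_exchange_fraction: float = field(default=None, compare=False)
    mp2_coefficient: float = field(default=None, compare=False)
    xc_terms: tuple = field(default=(), compare=False)
    force_unrestricted: bool = False
    relaxed_mp2_density: bool = False

    def __post_init__(self):
        key = self.functional.strip().lower()
        if key not in _FUNCTIONALS:
            raise ValueError(
                f"unknown functional {self.functional!r}; "
                f"available: {sorted(_FUNCTIONALS)}"
            )
        family, a_x, a_c, xc = _FUNCTIONALS[key]
        object.__setattr__(self, "functional", key)
        if not self.family:
            object.__setattr__(self, "family", family)
        if self.hf_exchange_fraction is None:
            object.__setattr__(self, "hf_exchange_fraction", a_x)
        if self.mp2_coefficient is None:
            object.__setattr__(self, "mp2_coefficient", a_c)
        object.__setattr__(self, "xc_terms", xc)
        if not 0.0 <= self.hf_exchange_fraction <= 1.0:
            raise ValueError("hf_exchange_fraction outside [0, 1]")
        if self.mp2_coefficient and self.family != "double-hybrid":
            raise ValueError("mp2_coefficient > 0 requires a double hybrid")
        if self.family == "hf" and self.hf_exchange_fraction != 1.0:
            raise ValueError("HF requires hf_exchange_fraction = 1")

    @property
    def is_double_hybrid(self) -> bool:
        return self.family == "double-hybrid"

    @property
    def has_dft_xc(self) -> bool:
        return bool(self.xc_terms)

    def with_(self, **kw) -> "MethodSpec":
        return replace(self, **kw)


def available_functionals():
    return sorted(_FUNCTIONALS)
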