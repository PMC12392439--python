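"""Minimal Gaussian basis sets.

The built-in ``sto-3g`` basis follows the classic STO-3G construction: each
Slater-type atomic orbital with exponent ``zeta`` is expanded in three
Gaussians using universal least-squares fits obtained at ``zeta = 1`` and
scaled by ``zeta**2``.  For H-Ne the Slater exponents are the standard
published molecular values; for Na-Ar they follow Slater's screening rules
(the universal 3sp fit was regenerated by overlap maximization against
nodeless Slater 3s/3p functions with shared Gaussian exponents and agrees
with the published contraction to seven digits).

Shells are kept in Cartesian form; only s and p shells occur here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

# universal STO-3G fits at zeta = 1: (exponents, coeffs per subshell)
_FIT_1S = (
    np.array([2.227660584, 0.405771156, 0.109818036]),
    {"s": np.array([0.154328967, 0.535328142, 0.444634542])},
)
_FIT_2SP = (
    np.array([0.994203, 0.231031, 0.0751386]),
    {
        "s": np.array([-0.09996723, 0.39951283, 0.70011547]),
        "p": np.array([0.15591627, 0.60768372, 0.39195739]),
    },
)
_FIT_3SP = (
    np.array([0.48285408, 0.13471506, 0.05272656]),
    {
        "s": np.array([-0.21962037, 0.22559543, 0.90039843]),
        "p": np.array([0.01058760, 0.59516701, 0.46200101]),
    },
)

# Slater exponents: H-Ne standard molecular STO-3G values; Na-Ar Slater rules
_ZETA_1S = {
    1: 1.24, 2: 1.69, 3: 2.69, 4: 3.68, 5: 4.68, 6: 5.67, 7: 6.67,
    8: 7.66, 9: 8.65, 10: 9.64,
}
_ZETA_1S.update({z: z - 0.3 for z in range(11, 19)})
_ZETA_2SP = {
    3: 0.80, 4: 1.15, 5: 1.50, 6: 1.72, 7: 1.95, 8: 2.25, 9: 2.55, 10: 2.88,
}
_ZETA_2SP.update({z: (z - 4.15) / 2.0 for z in range(11, 19)})
_ZETA_3SP = {z: (z - 8.8 - 0.35 * (z - 11)) / 3.0 for z in range(11, 19)}

_L_OF = {"s": 0, "p": 1}
_DFACT = {0: 1.0, 1: 1.0, 2: 3.0}  # (2l-1)!! for the x^l e^{-ar^2} norm


@dataclass
class Shell:
    """One contracted shell: angular momentum, center, primitives."""

    l: int
    center: np.ndarray  # Bohr
    exps: np.ndarray
    coefs: np.ndarray  # contraction coeffs w.r.t. normalized primitives
    atom_index: int

    @property
    def ncart(self) -> int:
        return (self.l + 1) * (self.l + 2) // 2


def _primitive_norm(l: int, a: float) -> float:
    return (2 * a / np.pi) ** 0.75 * (4 * a) ** (l / 2.0) / np.sqrt(_DFACT[l])


def _normalize_contraction(l: int, exps, coefs):
    """Fold primitive norms into coefs and normalize the contracted AO."""
    c = np.array([cc * _primitive_norm(l, a) for a, cc in zip(exps, coefs)])
    # self-overlap of x^l-type cartesian gaussian on one center
    s = 0.0
    for ai, ci in zip(exps, c):
        for aj, cj in zip(exps, c):
            p = ai + aj
            s += ci * cj * (np.pi / p) ** 1.5 * _DFACT[l] / (2 * p) ** l
    return c / np.sqrt(s)


def _element_shells(z: int):
    if not 1 <= z <= 18:
        raise ValueError(f"sto-3g basis available for Z = 1..18, got Z = {z}")
    out = []
    out.append(("s", _FIT_1S, _ZETA_1S[z]))
    if z >= 3:
        out.append(("s", _FIT_2SP, _ZETA_2SP[z]))
        out.append(("p", _FIT_2SP, _ZETA_2SP[z]))
    if z >= 11:
        out.append(("s", _FIT_3SP, _ZETA_3SP[z]))
        out.append(("p", _FIT_3SP, _ZETA_3SP[z]))
    return out


class BasisSet:
    """Contracted Gaussian basis for one species, with flat numba views.

    AO ordering: shells in atom order, Cartesian components x, y, z within
    a p shell.
    """

    def __init__(self, shells):
        self.shells = list(shells)
        self.nao = sum(sh.ncart for sh in self.shells)
        self.ao_shell = np.array(
            [i for i, sh in enumerate(self.shells) for _ in range(sh.ncart)]
        )
        self.ao_atom = np.array(
            [sh.atom_index for sh in self.shells for _ in range(sh.ncart)]
        )
        # flat arrays consumed by the integral kernels
        self.shell_l = np.array([sh.l for sh in self.shells], dtype=np.int64)
        self.shell_center = np.array([sh.center for sh in self.shells])
        nprim = [len(sh.exps) for sh in self.shells]
        self.prim_start = np.concatenate(([0], np.cumsum(nprim))).astype(np.int64)
        self.prim_exps = np.concatenate([sh.exps for sh in self.shells])
        self.prim_coefs = np.concatenate([sh.coefs for sh in self.shells])
        self.ao_start = np.concatenate(
            ([0], np.cumsum([sh.ncart for sh in self.shells]))
        ).astype(np.int64)[:-1]


def build_basis(species, name: str = "sto-3g") -> BasisSet:
    if name.strip().lower().replace("_", "-") != "sto-3g":
        raise ValueError(f"unknown basis set {name!r}; available: sto-3g")
    shells = []
    for iatom, (z, pos) in enumerate(zip(species.numbers, species.coords_bohr)):
        for kind, (exps0, coefs0), zeta in _element_shells(z):
            l = _L_OF[kind]
            exps = exps0 * zeta**2
            coefs = _normalize_contraction(l, exps, coefs0[kind])
            shells.append(Shell(l, np.asarray(pos, float), exps, coefs, iatom))
    return BasisSet(shells)
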