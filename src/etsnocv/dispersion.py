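"""Dispersion-energy providers.

Dispersion enters the decomposition as an additive, geometry-only term
(Eq.-2-style bookkeeping): the provider maps a species to an energy and the
EDA forms E_disp(AB) - E_disp(A) - E_disp(B).  Two providers ship:

* ``none``        - null provider, returns 0 for any geometry.
* ``pairwise-bj`` - a lightweight atom-pairwise -C6/R^6 model with
  Becke-Johnson-style rational damping, free-atom C6 coefficients and
  van der Waals radii.  This is a generic damped London term, not Grimme's
  D3 parameterization (no coordination-number dependence, no C8 term);
  it reproduces the qualitative long-range behavior the decomposition
  needs and vanishes exactly for single atoms.

Additional providers (e.g. an external D3 binding) can be registered via
:func:`register_dispersion_provider`.
"""

from __future__ import annotations

import numpy as np

# free-atom C6 coefficients, Hartree * Bohr^6
_C6_FREE = {
    1: 6.5, 2: 1.46, 3: 1387.0, 4: 214.0, 5: 99.5, 6: 46.6, 7: 24.2,
    8: 15.6, 9: 9.5, 10: 6.38, 11: 1556.0, 12: 627.0, 13: 528.0,
    14: 305.0, 15: 185.0, 16: 134.0, 17: 94.6, 18: 64.3,
}
# van der Waals radii (Angstrom, Bondi/Alvarez)
_RVDW_ANG = {
    1: 1.10, 2: 1.40, 3: 1.81, 4: 1.53, 5: 1.92, 6: 1.70, 7: 1.55,
    8: 1.52, 9: 1.47, 10: 1.54, 11: 2.27, 12: 1.73, 13: 1.84, 14: 2.10,
    15: 1.80, 16: 1.80, 17: 1.75, 18: 1.88,
}
_ANG2BOHR = 1.0 / 0.529177210903


def _null_provider(species) -> float:
    return 0.0


def _pairwise_bj(species, a1: float = 0.40, a2: float = 1.80) -> float:
    """-sum_{i<j} C6_ij / (R_ij^6 + R0_ij^6), R0 = a1 (rvdw_i + rvdw_j) + a2."""
    coords = species.coords_bohr
    numbers = species.numbers
    e = 0.0
    for i in range(len(numbers)):
        zi = numbers[i]
        if zi not in _C6_FREE:
            raise ValueError(f"no dispersion parameters for Z = {zi}")
        for j in range(i + 1, len(numbers)):
            zj = numbers[j]
            c6i, c6j = _C6_FREE[zi], _C6_FREE[zj]
            c6 = 2.0 * c6i * c6j / (c6i + c6j)
            r0 = (a1 * (_RVDW_ANG[zi] + _RVDW_ANG[zj]) * _ANG2BOHR + a2)
            r = float(np.linalg.norm(coords[i] - coords[j]))
            e -= c6 / (r**6 + r0**6)
    return e


_PROVIDERS = {
    "none": _null_provider,
    "pairwise-bj": _pairwise_bj,
}


def register_dispersion_provider(name: str, fn):
    _PROVIDERS[name.lower()] = fn


def get_dispersion_provider(name: str):
    key = (name or "none").strip().lower()
    if key not in _PROVIDERS:
        raise ValueError(
            f"unknown dispersion model {name!r}; available: {sorted(_PROVIDERS)}"
        )
    return _PROVIDERS[key]
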