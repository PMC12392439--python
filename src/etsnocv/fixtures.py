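"""Parameterized toy systems for testing and demonstration.

Each fixture builds an :class:`~etsnocv.system.AdductSystem` at a tunable
separation, spanning the qualitatively distinct bonding regimes the
decomposition distinguishes: closed-shell repulsion (he2), a charged
donor-acceptor pair (heh+, arli+), covalent electron sharing from open-shell
fragments (h2_from_atoms), dispersion-bound rare-gas dimers (he2, ar2), a
metallic-covalent borderline case (be2) and hydrogen bonds (hf2, water2).

Default separations are realistic near-equilibrium values for property
tests; they are not tuned to reproduce any published numbers, and users may
substitute their own coordinates to study specific geometries.
"""

from __future__ import annotations

import numpy as np

from .species import Species
from .system import AdductSystem
from .units import angstrom_to_bohr

DEFAULT_SEPARATIONS = {
    "he2": 2.0,
    "heh+": 0.93,
    "h2_from_atoms": 0.7408,  # 1.4 bohr
    "ar2": 3.76,
    "arli+": 2.40,
    "be2": 2.45,
    "hf2": 1.83,  # F...H hydrogen-bond distance
    "water2": 1.95,  # O...H hydrogen-bond distance
}


def _diatomic(z1, z2, r_ang, charges, mults, orientation=("alpha", "beta"),
              name=""):
    r = angstrom_to_bohr(r_ang)
    s = sum(
        (m - 1) * (1 if o == "alpha" else -1)
        for m, o in zip(mults, orientation)
    )
    adduct_mult = abs(s) + 1
    adduct = Species((z1, z2), [[0, 0, 0], [0, 0, r]],
                     charge=charges[0] + charges[1],
                     multiplicity=adduct_mult)
    frag_a = adduct.subset([0], charges[0], mults[0])
    frag_b = adduct.subset([1], charges[1], mults[1])
    return AdductSystem(adduct=adduct, fragment_a=frag_a, fragment_b=frag_b,
                        indices_a=(0,), indices_b=(1,),
                        spin_orientation=tuple(orientation), name=name)


def _hf_dimer(r_hb_ang):
    """(HF)2 in the bent hydrogen-bonded motif: F1-H1...F2-H2."""
    r_fh = 0.92  # Angstrom
    f1 = np.array([0.0, 0.0, 0.0])
    h1 = np.array([0.0, 0.0, r_fh])
    f2 = np.array([0.0, 0.0, r_fh + r_hb_ang])
    ang = np.deg2rad(110.0)
    h2 = f2 + r_fh * np.array([np.sin(ang), 0.0, np.cos(ang)])
    coords = angstrom_to_bohr(np.array([f1, h1, f2, h2]))
    adduct = Species((9, 1, 9, 1), coords)
    frag_a = adduct.subset([0, 1], 0, 1)  # donor HF
    frag_b = adduct.subset([2, 3], 0, 1)  # acceptor HF
    return AdductSystem(adduct=adduct, fragment_a=frag_a, fragment_b=frag_b,
                        indices_a=(0, 1), indices_b=(2, 3), name="hf2")


def _water_dimer(r_hb_ang):
    """Hydrogen-bonded water dimer: donor O-H points at the acceptor O."""
    r_oh, theta = 0.9572, np.deg2rad(104.52)
    # donor: one O-H along +z (the hydrogen bond axis)
    od = np.array([0.0, 0.0, 0.0])
    hd1 = np.array([0.0, 0.0, r_oh])
    hd2 = r_oh * np.array([np.sin(theta), 0.0, np.cos(theta)])
    # acceptor O beyond the donor hydrogen, its hydrogens pointing away
    oa = np.array([0.0, 0.0, r_oh + r_hb_ang])
    half = theta / 2.0
    ha1 = oa + r_oh * np.array([np.sin(half), 0.0, np.cos(half)])
    ha2 = oa + r_oh * np.array([-np.sin(half) * 0.5,
                                np.sin(half) * np.sqrt(3) / 2,
                                np.cos(half)])
    coords = angstrom_to_bohr(np.array([od, hd1, hd2, oa, ha1, ha2]))
    adduct = Species((8, 1, 1, 8, 1, 1), coords)
    frag_a = adduct.subset([0, 1, 2], 0, 1)
    frag_b = adduct.subset([3, 4, 5], 0, 1)
    return AdductSystem(adduct=adduct, fragment_a=frag_a, fragment_b=frag_b,
                        indices_a=(0, 1, 2), indices_b=(3, 4, 5),
                        name="water2")


def make_fixture(name: str, separation_ang: float = None) -> AdductSystem:
    """Build a named toy system; ``separation_ang`` overrides the default
    interfragment distance (Angstrom)."""
    key = name.strip().lower()
    if key not in DEFAULT_SEPARATIONS:
        raise ValueError(
            f"unknown fixture {name!r}; available: {sorted(DEFAULT_SEPARATIONS)}"
        )
    r = DEFAULT_SEPARATIONS[key] if separation_ang is None else separation_ang
    if r <= 0:
        raise ValueError("separation must be positive")
    if key == "he2":
        sys = _diatomic(2, 2, r, (0, 0), (1, 1), name="he2")
    elif key == "heh+":
        sys = _diatomic(2, 1, r, (0, 1), (1, 1), name="heh+")
    elif key == "h2_from_atoms":
        sys = _diatomic(1, 1, r, (0, 0), (2, 2),
                        orientation=("alpha", "beta"), name="h2_from_atoms")
    elif key == "ar2":
        sys = _diatomic(18, 18, r, (0, 0), (1, 1), name="ar2")
    elif key == "arli+":
        sys = _diatomic(18, 3, r, (0, 1), (1, 1), name="arli+")
    elif key == "be2":
        sys = _diatomic(4, 4, r, (0, 0), (1, 1), name="be2")
    elif key == "hf2":
        sys = _hf_dimer(r)
    else:
        sys = _water_dimer(r)
    return sys
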