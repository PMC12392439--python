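"""Adduct + fragment partition handling.

Parses XYZ geometries and a two-fragment partition ("1-3;4-6", 1-based
inclusive atom ranges separated by a semicolon), validates charge and spin
bookkeeping, and manages the embedding of fragment-dimension matrices into
supermolecule AO dimensions.

Fragment geometries are verbatim slices of the adduct geometry (the
fragments are kept frozen in the geometry they adopt in the complex);
relaxed fragment geometries may be attached separately for the preparation
term.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .basis import build_basis
from .species import Species, symbol_to_z, ELEMENTS
from .units import angstrom_to_bohr, bohr_to_angstrom


def parse_xyz(source) -> tuple:
    """Read an XYZ file or string -> (numbers, coords in Bohr, comment)."""
    if isinstance(source, (str, Path)) and "\n" not in str(source):
        text = Path(source).read_text()
    else:
        text = str(source)
    lines = text.strip().splitlines()
    try:
        natom = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise ValueError("XYZ: first line must be the atom count") from None
    comment = lines[1] if len(lines) > 1 else ""
    rows = lines[2 : 2 + natom]
    if len(rows) != natom:
        raise ValueError(f"XYZ: expected {natom} atom lines, got {len(rows)}")
    numbers, coords = [], []
    for row in rows:
        parts = row.split()
        numbers.append(symbol_to_z(parts[0]))
        coords.append([float(x) for x in parts[1:4]])
    return tuple(numbers), angstrom_to_bohr(np.array(coords)), comment


def write_xyz(species: Species, path, comment: str = "") -> None:
    lines = [str(species.natom), comment]
    for z, pos in zip(species.numbers, bohr_to_angstrom(species.coords_bohr)):
        lines.append(
            f"{ELEMENTS[z]:<2s} {pos[0]:18.10f} {pos[1]:18.10f} {pos[2]:18.10f}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def parse_fragment_spec(spec: str, natom: int) -> tuple:
    """Parse "1-3;4-6" into two disjoint, exhaustive 0-based index lists."""
    parts = [p for p in spec.split(";") if p.strip()]
    if len(parts) != 2:
        raise ValueError("fragment spec must contain exactly two fragments "
                         "separated by ';'")
    groups = []
    for part in parts:
        idx = []
        for chunk in part.split(","):
            chunk = chunk.strip()
            if "-" in chunk[1:]:
                lo, hi = chunk.split("-")
                idx.extend(range(int(lo) - 1, int(hi)))
            else:
                idx.append(int(chunk) - 1)
        groups.append(idx)
    flat = groups[0] + groups[1]
    if any(i < 0 or i >= natom for i in flat):
        raise ValueError("fragment spec references atoms outside 1..natom")
    if len(set(flat)) != len(flat):
        dup = sorted({i + 1 for i in flat if flat.count(i) > 1})
        raise ValueError(f"atoms assigned to both fragments: {dup}")
    if len(flat) != natom:
        missing = sorted(set(range(natom)) - set(flat))
        raise ValueError(f"atoms missing from partition: "
                         f"{[i + 1 for i in missing]}")
    return tuple(groups[0]), tuple(groups[1])


@dataclass
class IndexEmbedding:
    """AO-index maps from each fragment basis into the supermolecule basis."""

    ao_map_a: np.ndarray  # fragment-A AO index -> supermolecule AO index
    ao_map_b: np.ndarray
    nao_a: int
    nao_b: int
    nao_super: int

    def __post_init__(self):
        maps = np.concatenate([self.ao_map_a, self.ao_map_b])
        if len(set(maps.tolist())) != len(maps):
            raise ValueError("embedding maps overlap")
        if len(maps) != self.nao_super:
            raise ValueError("embedding does not cover the supermolecule AOs")

    def map_for(self, fragment: str) -> np.ndarray:
        return self.ao_map_a if fragment == "A" else self.ao_map_b


def embed_matrix(M: np.ndarray, ao_map: np.ndarray, nao_super: int) -> np.ndarray:
    """Zero-pad a fragment-dimension square matrix to supermolecule shape."""
    M = np.asarray(M)
    n = len(ao_map)
    if M.shape != (n, n):
        raise ValueError(
            f"matrix dimension {M.shape} does not match embedding size {n}"
        )
    out = np.zeros((nao_super, nao_super), dtype=M.dtype)
    out[np.ix_(ao_map, ao_map)] = M
    return out


def embed_vectors(C: np.ndarray, ao_map: np.ndarray, nao_super: int) -> np.ndarray:
    """Zero-pad fragment orbital coefficient columns to supermolecule rows."""
    out = np.zeros((nao_super, C.shape[1]), dtype=C.dtype)
    out[ao_map, :] = C
    return out


@dataclass
class AdductSystem:
    """Adduct plus two-fragment partition, all geometries frozen.

    ``spin_orientation`` fixes how open-shell fragments couple: each entry is
    "alpha" or "beta", stating which spin channel carries that fragment's
    excess electrons (default: A excess alpha, B excess beta).
    """

    adduct: Species
    fragment_a: Species
    fragment_b: Species
    indices_a: tuple
    indices_b: tuple
    relaxed_a: Species = None
    relaxed_b: Species = None
    spin_orientation: tuple = ("alpha", "beta")
    labels: tuple = ("A", "B")
    name: str = ""

    def __post_init__(self):
        if self.fragment_a.charge + self.fragment_b.charge != self.adduct.charge:
            raise ValueError("fragment charges do not sum to the adduct charge")
        for frag, idx in ((self.fragment_a, self.indices_a),
                          (self.fragment_b, self.indices_b)):
            if tuple(frag.numbers) != tuple(self.adduct.numbers[i] for i in idx):
                raise ValueError("fragment elements do not match the partition")
            if not np.array_equal(frag.coords_bohr, self.adduct.coords_bohr[list(idx)]):
                raise ValueError("fragment coordinates are not frozen slices "
                                 "of the adduct geometry")
        # spin bookkeeping under the configured coupling orientation
        na = nb = 0
        for frag, orient in ((self.fragment_a, self.spin_orientation[0]),
                             (self.fragment_b, self.spin_orientation[1])):
            fa, fb = frag.n_alpha, frag.n_beta
            if orient == "beta":
                fa, fb = fb, fa
            na += fa
            nb += fb
        if (na, nb) != (self.adduct.n_alpha, self.adduct.n_beta):
            raise ValueError(
                f"fragment spin channels ({na}a,{nb}b) inconsistent with the "
                f"adduct ({self.adduct.n_alpha}a,{self.adduct.n_beta}b) under "
                f"orientation {self.spin_orientation}"
            )

    @property
    def is_closed_shell(self) -> bool:
        return (self.adduct.is_closed_shell
                and self.fragment_a.is_closed_shell
                and self.fragment_b.is_closed_shell)

    def fragment_spins(self, fragment: str):
        """(n_alpha, n_beta) of a fragment in the adduct's spin frame."""
        frag, orient = ((self.fragment_a, self.spin_orientation[0])
                        if fragment == "A"
                        else (self.fragment_b, self.spin_orientation[1]))
        fa, fb = frag.n_alpha, frag.n_beta
        return (fb, fa) if orient == "beta" else (fa, fb)

    def build_embedding(self, basis_name: str = "sto-3g") -> IndexEmbedding:
        """AO index maps for the configured basis (atom-blocked AO order)."""
        sup_basis = build_basis(self.adduct, basis_name)
        # AO index ranges per adduct atom
        ao_of_atom = [[] for _ in range(self.adduct.natom)]
        for iao, iatom in enumerate(sup_basis.ao_atom):
            ao_of_atom[iatom].append(iao)
        map_a = np.array([iao for i in self.indices_a for iao in ao_of_atom[i]])
        map_b = np.array([iao for i in self.indices_b for iao in ao_of_atom[i]])
        return IndexEmbedding(map_a, map_b, len(map_a), len(map_b),
                              sup_basis.nao)


def build_system(
    xyz_source,
    fragment_spec: str,
    charges=(0, 0),
    multiplicities=(1, 1),
    adduct_charge=None,
    adduct_multiplicity=None,
    relaxed_xyz=(None, None),
    spin_orientation=("alpha", "beta"),
    name: str = "",
) -> AdductSystem:
    """Assemble a validated :class:`AdductSystem` from XYZ input.

    ``fragment_spec`` uses 1-based inclusive atom ranges, two fragments
    separated by ';'.  Fragment geometries are verbatim slices of the adduct
    geometry; ``relaxed_xyz`` optionally supplies relaxed monomer geometries
    for the preparation energy.
    """
    numbers, coords, _ = parse_xyz(xyz_source)
    idx_a, idx_b = parse_fragment_spec(fragment_spec, len(numbers))
    charges = tuple(int(c) for c in charges)
    mults = tuple(int(m) for m in multiplicities)
    if adduct_charge is None:
        adduct_charge = charges[0] + charges[1]
    if adduct_multiplicity is None:
        # spin frame: A excess up, B excess down unless oriented otherwise
        s = 0
        for m, orient in zip(mults, spin_orientation):
            s += (m - 1) if orient == "alpha" else -(m - 1)
        adduct_multiplicity = abs(s) + 1
    adduct = Species(numbers, coords, adduct_charge, adduct_multiplicity)
    frag_a = adduct.subset(idx_a, charges[0], mults[0])
    frag_b = adduct.subset(idx_b, charges[1], mults[1])
    relaxed = []
    for src, frozen in zip(relaxed_xyz, (frag_a, frag_b)):
        if src is None:
            relaxed.append(None)
            continue
        rn, rc, _ = parse_xyz(src)
        if rn != frozen.numbers:
            raise ValueError("relaxed geometry elements do not match fragment")
        relaxed.append(Species(rn, rc, frozen.charge, frozen.multiplicity))
    return AdductSystem(
        adduct=adduct, fragment_a=frag_a, fragment_b=frag_b,
        indices_a=idx_a, indices_b=idx_b,
        relaxed_a=relaxed[0], relaxed_b=relaxed[1],
        spin_orientation=tuple(spin_orientation), name=name,
    )
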