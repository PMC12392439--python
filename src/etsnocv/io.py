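"""Reports and volumetric export.

Gaussian cube files (Bohr units, z-fastest value order) carry deformation
densities and NOCV orbitals; density cubes use the plain positive-atom-count
header, orbital cubes the negative-count MO-block dialect.  Reports come in
two forms: a human-readable kcal/mol table mirroring the conventional EDA
row order, and a machine-readable JSON document with full-precision Hartree
values.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .fields import GridSpec
from .units import hartree_to_kcalmol


def write_cube(values, grid: GridSpec, species, path, comment="",
               orbital_index=None) -> None:
    """Write one scalar field as a Gaussian cube file.

    ``orbital_index`` switches to the MO-block dialect (negative atom count,
    one-orbital index record) used for orbital cubes.
    """
    values = np.asarray(values, float).ravel()
    if values.size != grid.npoints:
        raise ValueError("field size does not match grid")
    nx, ny, nz = grid.counts
    natom = species.natom
    lines = ["etsnocv cube file", comment or "scalar field"]
    sign = -1 if orbital_index is not None else 1
    o = grid.origin
    lines.append(f"{sign * natom:5d} {o[0]:13.6f} {o[1]:13.6f} {o[2]:13.6f}")
    for n, ax in zip(grid.counts, grid.axes):
        lines.append(f"{n:5d} {ax[0]:13.6f} {ax[1]:13.6f} {ax[2]:13.6f}")
    for z, pos in zip(species.numbers, species.coords_bohr):
        lines.append(
            f"{z:5d} {float(z):13.6f} {pos[0]:13.6f} {pos[1]:13.6f} {pos[2]:13.6f}"
        )
    if orbital_index is not None:
        lines.append(f"{1:5d} {int(orbital_index):5d}")
    vals = values.reshape(nx * ny, nz)
    for row in vals:
        for start in range(0, nz, 6):
            chunk = row[start:start + 6]
            lines.append(" ".join(f"{v:13.5e}" for v in chunk))
    Path(path).write_text("\n".join(lines) + "\n")


def read_cube(path):
    """Read a cube file -> (values, GridSpec, numbers, coords_bohr)."""
    lines = Path(path).read_text().splitlines()
    parts = lines[2].split()
    natom = int(parts[0])
    mo_dialect = natom < 0
    natom = abs(natom)
    origin = [float(x) for x in parts[1:4]]
    counts, axes = [], []
    for i in range(3):
        p = lines[3 + i].split()
        counts.append(int(p[0]))
        axes.append([float(x) for x in p[1:4]])
    numbers, coords = [], []
    for i in range(natom):
        p = lines[6 + i].split()
        numbers.append(int(p[0]))
        coords.append([float(x) for x in p[2:5]])
    start = 6 + natom + (1 if mo_dialect else 0)
    values = np.array(
        [float(x) for line in lines[start:] for x in line.split()]
    )
    grid = GridSpec(origin, axes, counts)
    return values, grid, tuple(numbers), np.array(coords)


_REPORT_ROWS = (
    ("e_int", "dE_int"),
    ("e_orb_exact", "dE_orb"),
    ("e_pauli", "dE_Pauli"),
    ("e_elstat", "dE_elstat"),
    ("e_disp", "dE_disp"),
    ("e_mp2", "dE_C(MP2)"),
    ("e_corrections", "dE_corrections"),
)


def _fmt_kcal(x: float) -> str:
    v = hartree_to_kcalmol(x)
    if abs(v) < 0.005:
        v = 0.0  # suppress negative zero in the printed table
    return f"{v:10.2f}"


def format_report(terms, nocv_result=None, system=None, method=None) -> str:
    """Human-readable decomposition table (kcal/mol, 2 decimals)."""
    lines = []
    if system is not None and system.name:
        lines.append(f"System: {system.name}")
    if method is not None:
        lines.append(f"Method: {method.functional.upper()}/{method.basis}"
                     f"  dispersion={method.dispersion}")
    lines.append("")
    lines.append("ETS energy decomposition (kcal/mol)")
    lines.append("-" * 37)
    for attr, label in _REPORT_ROWS:
        lines.append(f"{label:<18s}{_fmt_kcal(getattr(terms, attr))}")
    lines.append("-" * 37)
    lines.append(f"{'dE_steric':<18s}{_fmt_kcal(terms.e_steric)}")
    lines.append(f"{'dE_orb (TS est.)':<18s}{_fmt_kcal(terms.e_orb_ets2)}")
    lines.append(f"{'dE_prep':<18s}{_fmt_kcal(terms.e_prep)}")
    lines.append(f"{'dE_binding':<18s}{_fmt_kcal(terms.e_binding)}")
    lines.append(f"closure residual  {terms.closure_residual: .3e} Ha")
    if nocv_result is not None:
        lines.append("")
        lines.append("NOCV channels")
        lines.append(f"{'k':>3s} {'spin':>10s} {'v_k':>10s} "
                     f"{'dE_orb,k (kcal/mol)':>20s}")
        for ch in nocv_result["total_channels"]:
            lines.append(
                f"{ch.k:3d} {ch.spin:>10s} {ch.eigenvalue:10.5f} "
                f"{hartree_to_kcalmol(ch.energy):20.2f}"
            )
        lines.append(f"channel-sum vs Tr(F~ dP) residual: "
                     f"{_total_residual(nocv_result): .3e} Ha")
    return "\n".join(lines) + "\n"


def _total_residual(nocv_result):
    blocks = [v for k, v in nocv_result.items()
              if k in ("restricted", "alpha", "beta")]
    return sum(b.residual for b in blocks)


def report_payload(terms, nocv_result=None, system=None, method=None,
                   version="0.1.0") -> dict:
    """Machine-readable report: full-precision Hartree values."""
    payload = {
        "program": "etsnocv",
        "version": version,
        "units": "hartree",
        "terms": terms.as_dict(),
        "fragment_energies": terms.fragment_energies,
        "flags": terms.flags,
    }
    if method is not None:
        payload["method"] = {
            "functional": method.functional,
            "family": method.family,
            "basis": method.basis,
            "dispersion": method.dispersion,
            "hf_exchange_fraction": method.hf_exchange_fraction,
            "mp2_coefficient": method.mp2_coefficient,
        }
    if system is not None:
        payload["system"] = {
            "name": system.name,
            "natom": system.adduct.natom,
            "charge": system.adduct.charge,
            "multiplicity": system.adduct.multiplicity,
            "fragment_atoms": [list(i + 1 for i in system.indices_a),
                               list(i + 1 for i in system.indices_b)],
        }
    if nocv_result is not None:
        payload["nocv"] = {
            "total_ets2": nocv_result["total_ets2"],
            "channels": [
                {"k": ch.k, "spin": ch.spin, "eigenvalue": ch.eigenvalue,
                 "energy": ch.energy}
                for ch in nocv_result["total_channels"]
            ],
            "residual": _total_residual(nocv_result),
        }
    return payload


def write_report(terms, nocv_result, system, method, text_path=None,
                 json_path=None) -> str:
    """Write the text table and/or JSON document; returns the text."""
    text = format_report(terms, nocv_result, system, method)
    if text_path is not None:
        Path(text_path).write_text(text)
    if json_path is not None:
        payload = report_payload(terms, nocv_result, system, method)
        Path(json_path).write_text(json.dumps(payload, indent=2, sort_keys=True))
    return text
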