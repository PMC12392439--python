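"""Shared fixtures: decomposition runs are expensive (three SCFs plus grid
work each), so each study system/method combination is computed once per
session and reused across test modules."""

import warnings

import pytest

from etsnocv import MethodSpec, decompose, make_fixture


def _run(name, functional, dispersion="none", separation=None, **kw):
    system = make_fixture(name, separation)
    method = MethodSpec(functional, dispersion=dispersion, **kw)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # missing relaxed geometries
        return decompose(system, method)


@pytest.fixture(scope="session")
def decomp_he2_hf():
    """Overlapping closed shells, HF: pure Pauli repulsion, no virtuals."""
    return _run("he2", "hf", dispersion="pairwise-bj")


@pytest.fixture(scope="session")
def decomp_he2_far_lda():
    """Non-interacting limit: He pair at 100 Angstrom, local DFT."""
    return _run("he2", "lda", separation=100.0)


@pytest.fixture(scope="session")
def decomp_heh_hf():
    """Charged donor-acceptor pair with one clean sigma channel."""
    return _run("heh+", "hf")


@pytest.fixture(scope="session")
def decomp_heh_hf_unrestricted():
    """Same closed-shell system forced through the spin-resolved path."""
    return _run("heh+", "hf", force_unrestricted=True)


@pytest.fixture(scope="session")
def decomp_h2_atoms_hf():
    """Covalent bond from two doublet hydrogen atoms (open-shell path)."""
    return _run("h2_from_atoms", "hf")


@pytest.fixture(scope="session")
def decomp_be2_lda():
    """Homodimer with weak covalent character, local DFT + dispersion."""
    return _run("be2", "lda", dispersion="pairwise-bj")


@pytest.fixture(scope="session")
def decomp_hf2_b3lyp():
    """Hydrogen-bonded HF dimer with a hybrid functional."""
    return _run("hf2", "b3lyp", dispersion="pairwise-bj")


@pytest.fixture(scope="session")
def decomp_water2_blyp():
    """Hydrogen-bonded water dimer, GGA functional."""
    return _run("water2", "blyp", dispersion="pairwise-bj")


@pytest.fixture(scope="session")
def decomp_water2_b2plyp():
    """Water dimer with a double hybrid (MP2 correlation line)."""
    return _run("water2", "b2plyp", dispersion="pairwise-bj")


@pytest.fixture(scope="session")
def closed_shell_decomps(decomp_he2_hf, decomp_heh_hf, decomp_be2_lda,
                         decomp_hf2_b3lyp, decomp_water2_blyp,
                         decomp_water2_b2plyp):
    return {
        "he2/hf": decomp_he2_hf,
        "heh+/hf": decomp_heh_hf,
        "be2/lda": decomp_be2_lda,
        "hf2/b3lyp": decomp_hf2_b3lyp,
        "water2/blyp": decomp_water2_blyp,
        "water2/b2plyp": decomp_water2_b2plyp,
    }


@pytest.fixture(scope="session")
def all_decomps(closed_shell_decomps, decomp_h2_atoms_hf, decomp_he2_far_lda):
    out = dict(closed_shell_decomps)
    out["h2_from_atoms/hf"] = decomp_h2_atoms_hf
    out["he2_far/lda"] = decomp_he2_far_lda
    return out
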