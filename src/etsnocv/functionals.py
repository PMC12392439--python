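"""Exchange-correlation functionals on a quadrature grid.

Each functional is an energy density e(rho_a, rho_b, sigma_aa, sigma_ab,
sigma_bb) per unit volume (sigma are gradient invariants grad(rho_i) .
grad(rho_j)).  Implemented forms:

* ``slater_x``  - Dirac/Slater local exchange (spin-resolved).
* ``b88_x``     - Becke 1988 gradient correction to exchange (beta 0.0042).
* ``vwn5_c``    - Vosko-Wilk-Nusair parameterization V of the local
                  correlation energy of the uniform electron gas.
* ``lyp_c``     - Lee-Yang-Parr correlation in the Miehlich form.

Potentials (the functional derivatives entering the Kohn-Sham matrix) are
obtained by pointwise central finite differences of the energy density with
respect to its five arguments; this keeps a single, uniformly tested code
path for all functionals.  Correctness of the resulting Fock contribution
is enforced by a directional-derivative property test on the total energy.
"""

from __future__ import annotations

import numpy as np

_TINY_RHO = 1e-11


def _slater_x(ra, rb, saa, sab, sbb):
    cx = (3.0 / 4.0) * (3.0 / np.pi) ** (1.0 / 3.0) * 2.0 ** (1.0 / 3.0)
    return -cx * (ra ** (4.0 / 3.0) + rb ** (4.0 / 3.0))


def _b88_x(ra, rb, saa, sab, sbb):
    beta = 0.0042
    out = np.zeros_like(ra)
    for r, s in ((ra, saa), (rb, sbb)):
        r43 = r ** (4.0 / 3.0)
        x = np.sqrt(np.maximum(s, 0.0)) / np.maximum(r43, 1e-300)
        out -= beta * r43 * x * x / (1.0 + 6.0 * beta * x * np.arcsinh(x))
    return out


def _vwn_eps(rs, A, x0, b, c):
    x = np.sqrt(rs)
    X = x * x + b * x + c
    X0 = x0 * x0 + b * x0 + c
    Q = np.sqrt(4 * c - b * b)
    atn = np.arctan(Q / (2 * x + b))
    return A * (
        np.log(x * x / X)
        + 2 * b / Q * atn
        - b * x0 / X0 * (np.log((x - x0) ** 2 / X) + 2 * (b + 2 * x0) / Q * atn)
    )


def _vwn5_c(ra, rb, saa, sab, sbb):
    rho = ra + rb
    rho = np.maximum(rho, 1e-300)
    rs = (3.0 / (4.0 * np.pi * rho)) ** (1.0 / 3.0)
    zeta = np.clip((ra - rb) / rho, -1.0, 1.0)
    eps_p = _vwn_eps(rs, 0.0310907, -0.10498, 3.72744, 12.9352)
    eps_f = _vwn_eps(rs, 0.01554535, -0.32500, 7.06042, 18.0578)
    alpha = _vwn_eps(rs, -1.0 / (6.0 * np.pi**2), -0.00475840, 1.13107, 13.0045)
    fz = ((1 + zeta) ** (4.0 / 3.0) + (1 - zeta) ** (4.0 / 3.0) - 2.0) / (
        2.0 ** (4.0 / 3.0) - 2.0
    )
    fpp0 = 8.0 / (9.0 * (2.0 ** (4.0 / 3.0) - 2.0))
    z4 = zeta**4
    eps = eps_p + alpha * fz / fpp0 * (1 - z4) + (eps_f - eps_p) * fz * z4
    return rho * eps


def _lyp_c(ra, rb, saa, sab, sbb):
    a, b, c, d = 0.04918, 0.132, 0.2533, 0.349
    cf = 0.3 * (3.0 * np.pi**2) ** (2.0 / 3.0)
    rho = np.maximum(ra + rb, 1e-300)
    rm13 = rho ** (-1.0 / 3.0)
    denom = 1.0 + d * rm13
    omega = np.exp(-c * rm13) / denom * rho ** (-11.0 / 3.0)
    delta = c * rm13 + d * rm13 / denom
    sig = saa + 2.0 * sab + sbb  # |grad rho_total|^2
    rab = ra * rb
    term_lda = -4.0 * a / denom * rab / rho
    inner = (
        2.0 ** (11.0 / 3.0) * cf * (ra ** (8.0 / 3.0) + rb ** (8.0 / 3.0))
        + (47.0 / 18.0 - 7.0 * delta / 18.0) * sig
        - (5.0 / 2.0 - delta / 18.0) * (saa + sbb)
        - (delta - 11.0) / 9.0 * (ra / rho * saa + rb / rho * sbb)
    )
    term_grad = -a * b * omega * (
        rab * inner
        - 2.0 / 3.0 * rho * rho * sig
        + (2.0 / 3.0 * rho * rho - ra * ra) * sbb
        + (2.0 / 3.0 * rho * rho - rb * rb) * saa
    )
    return term_lda + term_grad


_FUNCS = {
    "slater_x": _slater_x,
    "b88_x": _b88_x,
    "vwn5_c": _vwn5_c,
    "lyp_c": _lyp_c,
}

_NEEDS_GRADIENT = {"b88_x", "lyp_c"}


def needs_gradient(xc_terms) -> bool:
    return any(name in _NEEDS_GRADIENT for name, _ in xc_terms)


def energy_density(xc_terms, ra, rb, saa, sab, sbb):
    """Total XC energy density for a weighted list of functional terms."""
    mask = (ra + rb) > _TINY_RHO
    out = np.zeros_like(ra)
    if not np.any(mask):
        return out
    args = [np.maximum(v[mask], 0.0) if i < 2 else v[mask]
            for i, v in enumerate((ra, rb, saa, sab, sbb))]
    acc = np.zeros_like(args[0])
    for name, weight in xc_terms:
        acc += weight * _FUNCS[name](*args)
    out[mask] = acc
    return out


def energy_density_per_term(xc_terms, ra, rb, saa, sab, sbb):
    mask = (ra + rb) > _TINY_RHO
    vals = {}
    args = [np.maximum(v[mask], 0.0) if i < 2 else v[mask]
            for i, v in enumerate((ra, rb, saa, sab, sbb))]
    for name, weight in xc_terms:
        e = np.zeros_like(ra)
        if np.any(mask):
            e[mask] = weight * _FUNCS[name](*args)
        vals[name] = e
    return vals


def potentials(xc_terms, ra, rb, saa, sab, sbb):
    """Pointwise partial derivatives of the energy density.

    Returns (v_ra, v_rb, v_saa, v_sab, v_sbb) by central finite differences;
    one-sided stencils keep density and gradient invariants in their
    physical domain near the boundary.
    """
    variables = [ra, rb, saa, sab, sbb]
    # characteristic scales: densities scale as rho, invariants as rho^(8/3)
    rho = ra + rb
    rho_scale = np.maximum(rho, _TINY_RHO)
    sig_scale = rho_scale ** (8.0 / 3.0)
    scales = [rho_scale, rho_scale, sig_scale, sig_scale, sig_scale]
    nonneg = [True, True, True, False, True]
    outs = []
    rel = 1e-6
    for i, (x, sc, nn) in enumerate(zip(variables, scales, nonneg)):
        h = rel * np.maximum(np.abs(x), sc)
        lo = x - h
        if nn:
            shift = np.where(lo < 0.0, -lo, 0.0)  # slide stencil up to stay >= 0
            lo = lo + shift
        hi = lo + 2 * h
        args_hi = list(variables)
        args_lo = list(variables)
        args_hi[i] = hi
        args_lo[i] = lo
        e_hi = energy_density(xc_terms, *args_hi)
        e_lo = energy_density(xc_terms, *args_lo)
        outs.append((e_hi - e_lo) / (2 * h))
    return tuple(outs)
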