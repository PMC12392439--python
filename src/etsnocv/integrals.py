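"""Molecular integrals over contracted Cartesian Gaussians.

McMurchie-Davidson scheme: products of Gaussians are expanded in Hermite
Gaussians (coefficients ``E``), Coulomb-type integrals reduce to Hermite
Coulomb integrals ``R`` built on the Boys function.  Kernels are
numba-compiled; angular momenta up to d are supported (the built-in basis
uses s and p only).

Public entry points take a :class:`~etsnocv.basis.BasisSet` and return dense
NumPy arrays in the AO basis: :func:`overlap`, :func:`kinetic`,
:func:`nuclear_attraction` (optionally for a subset of nuclei, which is what
the per-fragment electrostatic operators need), and :func:`eri` (full
permutational symmetry, chemists' notation (munu|lambdasigma)).
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

# Cartesian component exponents per shell angular momentum, ordered
# s; p: x,y,z; d: xx,yy,zz,xy,xz,yz
_CART = {
    0: [(0, 0, 0)],
    1: [(1, 0, 0), (0, 1, 0), (0, 0, 1)],
    2: [(2, 0, 0), (0, 2, 0), (0, 0, 2), (1, 1, 0), (1, 0, 1), (0, 1, 1)],
}
_MAXL = 2
# flat lookup tables usable inside numba
_CART_LX = np.zeros((_MAXL + 1, 6), dtype=np.int64)
_CART_LY = np.zeros((_MAXL + 1, 6), dtype=np.int64)
_CART_LZ = np.zeros((_MAXL + 1, 6), dtype=np.int64)
for _l, comps in _CART.items():
    for _i, (lx, ly, lz) in enumerate(comps):
        _CART_LX[_l, _i] = lx
        _CART_LY[_l, _i] = ly
        _CART_LZ[_l, _i] = lz


@njit
def _boys(mmax, T, out):
    """Boys function F_m(T) for m = 0..mmax, downward recursion."""
    if T < 1e-14:
        for m in range(mmax + 1):
            out[m] = 1.0 / (2 * m + 1) - T / (2 * m + 3)
        return
    if T > 35.0:
        out[0] = 0.5 * math.sqrt(math.pi / T) * math.erf(math.sqrt(T))
        expT = math.exp(-T)
        for m in range(1, mmax + 1):
            out[m] = ((2 * m - 1) * out[m - 1] - expT) / (2 * T)
        return
    # series for the highest order, then downward recursion (stable)
    m = mmax
    term = 1.0 / (2 * m + 1)
    acc = term
    i = 1
    while True:
        term *= 2 * T / (2 * m + 2 * i + 1)
        acc += term
        if term < 1e-17 * acc:
            break
        i += 1
    expT = math.exp(-T)
    out[mmax] = acc * expT
    for mm in range(mmax, 0, -1):
        out[mm - 1] = (2 * T * out[mm] + expT) / (2 * mm - 1)


@njit
def _E(i, j, t, Q, a, b):
    """Hermite expansion coefficient E_t^{ij} for a 1-D Gaussian product."""
    p = a + b
    q = a * b / p
    if t < 0 or t > i + j:
        return 0.0
    if i == 0 and j == 0 and t == 0:
        return math.exp(-q * Q * Q)
    if j == 0:
        return (
            _E(i - 1, j, t - 1, Q, a, b) / (2 * p)
            - q * Q / a * _E(i - 1, j, t, Q, a, b)
            + (t + 1) * _E(i - 1, j, t + 1, Q, a, b)
        )
    return (
        _E(i, j - 1, t - 1, Q, a, b) / (2 * p)
        + q * Q / b * _E(i, j - 1, t, Q, a, b)
        + (t + 1) * _E(i, j - 1, t + 1, Q, a, b)
    )


@njit
def _R(t, u, v, n, p, X, Y, Z, F):
    """Hermite Coulomb integral R_{tuv}^n."""
    if t == 0 and u == 0 and v == 0:
        return (-2.0 * p) ** n * F[n]
    if t > 0:
        val = X * _R(t - 1, u, v, n + 1, p, X, Y, Z, F)
        if t > 1:
            val += (t - 1) * _R(t - 2, u, v, n + 1, p, X, Y, Z, F)
        return val
    if u > 0:
        val = Y * _R(t, u - 1, v, n + 1, p, X, Y, Z, F)
        if u > 1:
            val += (u - 1) * _R(t, u - 2, v, n + 1, p, X, Y, Z, F)
        return val
    val = Z * _R(t, u, v - 1, n + 1, p, X, Y, Z, F)
    if v > 1:
        val += (v - 1) * _R(t, u, v - 2, n + 1, p, X, Y, Z, F)
    return val


@njit
def _overlap_kinetic_kernel(
    shell_l, centers, prim_start, pexp, pcoef, ao_start, lx, ly, lz, nao
):
    S = np.zeros((nao, nao))
    T = np.zeros((nao, nao))
    nsh = shell_l.shape[0]
    for ish in range(nsh):
        la = shell_l[ish]
        na = (la + 1) * (la + 2) // 2
        A = centers[ish]
        for jsh in range(ish + 1):
            lb = shell_l[jsh]
            nb = (lb + 1) * (lb + 2) // 2
            B = centers[jsh]
            ABx = A[0] - B[0]
            ABy = A[1] - B[1]
            ABz = A[2] - B[2]
            for ipr in range(prim_start[ish], prim_start[ish + 1]):
                a = pexp[ipr]
                ca = pcoef[ipr]
                for jpr in range(prim_start[jsh], prim_start[jsh + 1]):
                    b = pexp[jpr]
                    cb = pcoef[jpr]
                    p = a + b
                    pref = ca * cb * (math.pi / p) ** 1.5
                    for ia in range(na):
                        i1, j1, k1 = lx[la, ia], ly[la, ia], lz[la, ia]
                        for ib in range(nb):
                            i2, j2, k2 = lx[lb, ib], ly[lb, ib], lz[lb, ib]
                            sx = _E(i1, i2, 0, ABx, a, b)
                            sy = _E(j1, j2, 0, ABy, a, b)
                            sz = _E(k1, k2, 0, ABz, a, b)
                            # 1-D kinetic pieces
                            tx = (
                                -2.0 * b * b * _E(i1, i2 + 2, 0, ABx, a, b)
                                + b * (2 * i2 + 1) * sx
                            )
                            if i2 >= 2:
                                tx -= 0.5 * i2 * (i2 - 1) * _E(i1, i2 - 2, 0, ABx, a, b)
                            ty = (
                                -2.0 * b * b * _E(j1, j2 + 2, 0, ABy, a, b)
                                + b * (2 * j2 + 1) * sy
                            )
                            if j2 >= 2:
                                ty -= 0.5 * j2 * (j2 - 1) * _E(j1, j2 - 2, 0, ABy, a, b)
                            tz = (
                                -2.0 * b * b * _E(k1, k2 + 2, 0, ABz, a, b)
                                + b * (2 * k2 + 1) * sz
                            )
                            if k2 >= 2:
                                tz -= 0.5 * k2 * (k2 - 1) * _E(k1, k2 - 2, 0, ABz, a, b)
                            mu = ao_start[ish] + ia
                            nu = ao_start[jsh] + ib
                            S[mu, nu] += pref * sx * sy * sz
                            T[mu, nu] += pref * (tx * sy * sz + sx * ty * sz + sx * sy * tz)
    for mu in range(nao):
        for nu in range(mu):
            S[nu, mu] = S[mu, nu]
            T[nu, mu] = T[mu, nu]
    return S, T


@njit
def _nuclear_kernel(
    shell_l, centers, prim_start, pexp, pcoef, ao_start,
    lx, ly, lz, nao, nuc_coords, nuc_charges,
):
    V = np.zeros((nao, nao))
    nsh = shell_l.shape[0]
    nnuc = nuc_charges.shape[0]
    F = np.zeros(4 * _MAXL + 1)
    for ish in range(nsh):
        la = shell_l[ish]
        na = (la + 1) * (la + 2) // 2
        A = centers[ish]
        for jsh in range(ish + 1):
            lb = shell_l[jsh]
            nb = (lb + 1) * (lb + 2) // 2
            B = centers[jsh]
            ABx, ABy, ABz = A[0] - B[0], A[1] - B[1], A[2] - B[2]
            ltot = la + lb
            for ipr in range(prim_start[ish], prim_start[ish + 1]):
                a = pexp[ipr]
                ca = pcoef[ipr]
                for jpr in range(prim_start[jsh], prim_start[jsh + 1]):
                    b = pexp[jpr]
                    cb = pcoef[jpr]
                    p = a + b
                    Px = (a * A[0] + b * B[0]) / p
                    Py = (a * A[1] + b * B[1]) / p
                    Pz = (a * A[2] + b * B[2]) / p
                    pref = ca * cb * 2.0 * math.pi / p
                    # Hermite coefficient tables for this primitive pair
                    Ex = np.zeros((na, ltot + 1))
                    Ey = np.zeros((na, ltot + 1))
                    Ez = np.zeros((na, ltot + 1))
                    for inuc in range(nnuc):
                        PCx = Px - nuc_coords[inuc, 0]
                        PCy = Py - nuc_coords[inuc, 1]
                        PCz = Pz - nuc_coords[inuc, 2]
                        T = p * (PCx * PCx + PCy * PCy + PCz * PCz)
                        _boys(ltot, T, F)
                        Zq = nuc_charges[inuc]
                        for ia in range(na):
                            i1, j1, k1 = lx[la, ia], ly[la, ia], lz[la, ia]
                            for ib in range(nb):
                                i2, j2, k2 = lx[lb, ib], ly[lb, ib], lz[lb, ib]
                                val = 0.0
                                for t in range(i1 + i2 + 1):
                                    ex = _E(i1, i2, t, ABx, a, b)
                                    for u in range(j1 + j2 + 1):
                                        ey = _E(j1, j2, u, ABy, a, b)
                                        for v in range(k1 + k2 + 1):
                                            ez = _E(k1, k2, v, ABz, a, b)
                                            val += ex * ey * ez * _R(
                                                t, u, v, 0, p, PCx, PCy, PCz, F
                                            )
                                mu = ao_start[ish] + ia
                                nu = ao_start[jsh] + ib
                                V[mu, nu] -= Zq * pref * val
    for mu in range(nao):
        for nu in range(mu):
            V[nu, mu] = V[mu, nu]
    return V


@njit
def _eri_kernel(
    shell_l, centers, prim_start, pexp, pcoef, ao_start, lx, ly, lz, nao
):
    G = np.zeros((nao, nao, nao, nao))
    nsh = shell_l.shape[0]
    F = np.zeros(8 * _MAXL + 1)
    for ish in range(nsh):
        la = shell_l[ish]
        na = (la + 1) * (la + 2) // 2
        A = centers[ish]
        for jsh in range(ish + 1):
            lb = shell_l[jsh]
            nb = (lb + 1) * (lb + 2) // 2
            B = centers[jsh]
            ABx, ABy, ABz = A[0] - B[0], A[1] - B[1], A[2] - B[2]
            for ksh in range(ish + 1):
                lc = shell_l[ksh]
                nc = (lc + 1) * (lc + 2) // 2
                C = centers[ksh]
                lsh_max = jsh if ksh == ish else ksh
                for lsh in range(lsh_max + 1):
                    ld = shell_l[lsh]
                    nd = (ld + 1) * (ld + 2) // 2
                    D = centers[lsh]
                    CDx, CDy, CDz = C[0] - D[0], C[1] - D[1], C[2] - D[2]
                    lab = la + lb
                    lcd = lc + ld
                    block = np.zeros((na, nb, nc, nd))
                    for ipr in range(prim_start[ish], prim_start[ish + 1]):
                        a = pexp[ipr]
                        ca = pcoef[ipr]
                        for jpr in range(prim_start[jsh], prim_start[jsh + 1]):
                            b = pexp[jpr]
                            cb = pcoef[jpr]
                            p = a + b
                            Px = (a * A[0] + b * B[0]) / p
                            Py = (a * A[1] + b * B[1]) / p
                            Pz = (a * A[2] + b * B[2]) / p
                            for kpr in range(prim_start[ksh], prim_start[ksh + 1]):
                                c = pexp[kpr]
                                cc = pcoef[kpr]
                                for lpr in range(prim_start[lsh], prim_start[lsh + 1]):
                                    d = pexp[lpr]
                                    cd = pcoef[lpr]
                                    q = c + d
                                    Qx = (c * C[0] + d * D[0]) / q
                                    Qy = (c * C[1] + d * D[1]) / q
                                    Qz = (c * C[2] + d * D[2]) / q
                                    alpha = p * q / (p + q)
                                    PQx, PQy, PQz = Px - Qx, Py - Qy, Pz - Qz
                                    T = alpha * (PQx**2 + PQy**2 + PQz**2)
                                    _boys(lab + lcd, T, F)
                                    pref = (
                                        ca * cb * cc * cd
                                        * 2.0 * math.pi**2.5
                                        / (p * q * math.sqrt(p + q))
                                    )
                                    for ia in range(na):
                                        i1 = lx[la, ia]
                                        j1 = ly[la, ia]
                                        k1 = lz[la, ia]
                                        for ib in range(nb):
                                            i2 = lx[lb, ib]
                                            j2 = ly[lb, ib]
                                            k2 = lz[lb, ib]
                                            for ic in range(nc):
                                                i3 = lx[lc, ic]
                                                j3 = ly[lc, ic]
                                                k3 = lz[lc, ic]
                                                for id_ in range(nd):
                                                    i4 = lx[ld, id_]
                                                    j4 = ly[ld, id_]
                                                    k4 = lz[ld, id_]
                                                    val = 0.0
                                                    for t in range(i1 + i2 + 1):
                                                        ex1 = _E(i1, i2, t, ABx, a, b)
                                                        for u in range(j1 + j2 + 1):
                                                            ey1 = _E(j1, j2, u, ABy, a, b)
                                                            for v in range(k1 + k2 + 1):
                                                                ez1 = _E(k1, k2, v, ABz, a, b)
                                                                e1 = ex1 * ey1 * ez1
                                                                if e1 == 0.0:
                                                                    continue
                                                                for t2 in range(i3 + i4 + 1):
                                                                    ex2 = _E(i3, i4, t2, CDx, c, d)
                                                                    for u2 in range(j3 + j4 + 1):
                                                                        ey2 = _E(j3, j4, u2, CDy, c, d)
                                                                        for v2 in range(k3 + k4 + 1):
                                                                            ez2 = _E(k3, k4, v2, CDz, c, d)
                                                                            e2 = ex2 * ey2 * ez2
                                                                            if e2 == 0.0:
                                                                                continue
                                                                            sgn = 1.0 if (t2 + u2 + v2) % 2 == 0 else -1.0
                                                                            val += e1 * e2 * sgn * _R(
                                                                                t + t2, u + u2, v + v2, 0,
                                                                                alpha, PQx, PQy, PQz, F,
                                                                            )
                                                    block[ia, ib, ic, id_] += pref * val
                    # scatter with 8-fold symmetry
                    for ia in range(na):
                        mu = ao_start[ish] + ia
                        for ib in range(nb):
                            nu = ao_start[jsh] + ib
                            for ic in range(nc):
                                lam = ao_start[ksh] + ic
                                for id_ in range(nd):
                                    sig = ao_start[lsh] + id_
                                    v = block[ia, ib, ic, id_]
                                    G[mu, nu, lam, sig] = v
                                    G[nu, mu, lam, sig] = v
                                    G[mu, nu, sig, lam] = v
                                    G[nu, mu, sig, lam] = v
                                    G[lam, sig, mu, nu] = v
                                    G[sig, lam, mu, nu] = v
                                    G[lam, sig, nu, mu] = v
                                    G[sig, lam, nu, mu] = v
    return G


def _flat(basis):
    return (
        basis.shell_l, basis.shell_center, basis.prim_start,
        basis.prim_exps, basis.prim_coefs, basis.ao_start,
        _CART_LX, _CART_LY, _CART_LZ, basis.nao,
    )


def overlap(basis) -> np.ndarray:
    return _overlap_kinetic_kernel(*_flat(basis))[0]


def kinetic(basis) -> np.ndarray:
    return _overlap_kinetic_kernel(*_flat(basis))[1]


def overlap_and_kinetic(basis):
    return _overlap_kinetic_kernel(*_flat(basis))


def nuclear_attraction(basis, coords, charges) -> np.ndarray:
    """Electron-nuclear attraction operator for the given nuclei.

    ``coords``/``charges`` may cover any subset of nuclei, which yields the
    per-fragment external potential operators V_A, V_B.
    """
    coords = np.asarray(coords, float).reshape(-1, 3)
    charges = np.asarray(charges, float)
    return _nuclear_kernel(*_flat(basis), coords, charges)


def eri(basis) -> np.ndarray:
    """Full two-electron integral tensor (mu nu | lambda sigma)."""
    return _eri_kernel(*_flat(basis))


def ao_values(basis, points, derivatives: bool = False):
    """AO values (and optionally Cartesian gradients) on grid points.

    Returns ``(npts, nao)`` or ``(ao, grad)`` with grad ``(npts, nao, 3)``.
    Pure NumPy; used by the DFT quadrature and cube export.
    """
    pts = np.asarray(points, float).reshape(-1, 3)
    npts = pts.shape[0]
    ao = np.zeros((npts, basis.nao))
    grad = np.zeros((npts, basis.nao, 3)) if derivatives else None
    for ish, sh in enumerate(basis.shells):
        d = pts - sh.center  # (npts, 3)
        r2 = np.einsum("pi,pi->p", d, d)
        rad = np.zeros(npts)
        drad = np.zeros(npts)  # d(radial)/d(r^2)
        for a, c in zip(sh.exps, sh.coefs):
            e = c * np.exp(-a * r2)
            rad += e
            drad += -a * e
        for comp, (lx_, ly_, lz_) in enumerate(_CART[sh.l]):
            mu = basis.ao_start[ish] + comp
            poly = d[:, 0] ** lx_ * d[:, 1] ** ly_ * d[:, 2] ** lz_
            ao[:, mu] = poly * rad
            if derivatives:
                for ax, lax in enumerate((lx_, ly_, lz_)):
                    dpoly = np.zeros(npts)
                    if lax > 0:
                        ll = [lx_, ly_, lz_]
                        ll[ax] -= 1
                        dpoly = (
                            lax * d[:, 0] ** ll[0] * d[:, 1] ** ll[1] * d[:, 2] ** ll[2]
                        )
                    grad[:, mu, ax] = dpoly * rad + poly * 2.0 * d[:, ax] * drad
    if derivatives:
        return ao, grad
    return ao
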