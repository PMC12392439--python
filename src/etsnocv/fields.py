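"""Scalar fields (deformation densities, orbitals) on rectilinear grids."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .integrals import ao_values


@dataclass
class GridSpec:
    """Rectilinear grid: origin, three axis step vectors, point counts.

    All lengths in Bohr.  ``from_species`` builds the conventional bounding
    box + padding grid.
    """

    origin: np.ndarray
    axes: np.ndarray  # (3, 3) rows are step vectors
    counts: tuple

    def __post_init__(self):
        self.origin = np.asarray(self.origin, float).reshape(3)
        self.axes = np.asarray(self.axes, float).reshape(3, 3)
        self.counts = tuple(int(c) for c in self.counts)
        if any(c < 2 for c in self.counts):
            raise ValueError("grid needs at least 2 points per axis")
        if abs(np.linalg.det(self.axes)) < 1e-12:
            raise ValueError("grid axes are linearly dependent")

    @classmethod
    def from_species(cls, species, spacing: float = 0.2, padding: float = 4.0):
        lo = species.coords_bohr.min(axis=0) - padding
        hi = species.coords_bohr.max(axis=0) + padding
        counts = np.maximum(np.ceil((hi - lo) / spacing).astype(int) + 1, 2)
        axes = np.diag([spacing] * 3)
        return cls(lo, axes, tuple(counts))

    @property
    def npoints(self) -> int:
        nx, ny, nz = self.counts
        return nx * ny * nz

    def points(self) -> np.ndarray:
        """All grid points, z fastest (cube-file ordering), shape (N, 3)."""
        nx, ny, nz = self.counts
        ii, jj, kk = np.meshgrid(
            np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
        )
        idx = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1)
        return self.origin + idx @ self.axes

    @property
    def voxel_volume(self) -> float:
        return abs(np.linalg.det(self.axes))


@dataclass
class DeformationField:
    """Total and per-channel deformation densities on a grid.

    Values are flat arrays in cube (z-fastest) order.  The grid integral of
    every channel field vanishes within quadrature tolerance - each channel
    moves charge, it does not create it.
    """

    grid: GridSpec
    total: np.ndarray
    channels: dict = field(default_factory=dict)  # (spin, k) -> values
    mp2_correction: np.ndarray = None

    def integral(self, values=None) -> float:
        v = self.total if values is None else values
        return float(v.sum() * self.grid.voxel_volume)


def density_on_grid(P, basis, points, chunk: int = 20000) -> np.ndarray:
    """rho(r) = sum_mn P_mn phi_m(r) phi_n(r), evaluated in chunks."""
    pts = np.asarray(points, float).reshape(-1, 3)
    out = np.empty(pts.shape[0])
    for start in range(0, pts.shape[0], chunk):
        ao = ao_values(basis, pts[start:start + chunk])
        out[start:start + chunk] = np.einsum(
            "pi,ij,pj->p", ao, P, ao, optimize=True
        )
    return out


def orbital_on_grid(c, basis, points, chunk: int = 20000) -> np.ndarray:
    pts = np.asarray(points, float).reshape(-1, 3)
    out = np.empty(pts.shape[0])
    for start in range(0, pts.shape[0], chunk):
        ao = ao_values(basis, pts[start:start + chunk])
        out[start:start + chunk] = ao @ c
    return out


def channel_density(channels, grid: GridSpec, basis,
                    dP_total=None, mp2_matrix=None) -> DeformationField:
    """Per-channel deformation densities v_k (psi_k^2 - psi_-k^2) plus the
    total deformation density.

    ``dP_total`` (the full density-difference matrix, summed over spins if
    open-shell) defines the total field; when omitted, the channel sum is
    used.  ``mp2_matrix`` optionally adds the MP2 difference-density field.
    """
    pts = grid.points()
    per_channel = {}
    total = np.zeros(pts.shape[0])
    for ch in channels:
        psi_p = orbital_on_grid(ch.c_plus, basis, pts)
        psi_m = orbital_on_grid(ch.c_minus, basis, pts)
        vals = ch.eigenvalue * (psi_p**2 - psi_m**2)
        per_channel[(ch.spin, ch.k)] = vals
        total += vals
    if dP_total is not None:
        total = density_on_grid(dP_total, basis, pts)
    mp2_vals = None
    if mp2_matrix is not None and np.any(mp2_matrix):
        mp2_vals = density_on_grid(mp2_matrix, basis, pts)
    return DeformationField(grid=grid, total=total, channels=per_channel,
                            mp2_correction=mp2_vals)
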