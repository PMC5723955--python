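"""Focal-plane system matrix assembly and its cost accounting.

The expected image F^{(m)} differs between blurry pixels m, so the per-pixel
Born sums cannot be stacked into one linear system directly.  The fix:
anchor every equation to the reference pixel's expected image F^{(1)} via a
proportional relation, and approximate the unknown yield-dependent weight
ratios by assuming all fluorescent signal originates from one chosen
constant-depth plane — the *focal plane* at depth DFP, depth index k.  The
resulting square system matrix is

    R_mn = ΔV · C_n^{(1)} · C_{n,k}^{(m)} / C_{n,k}^{(1)},

mapping the expected image to the blurry image, B = R F^{(1)}.  Only the
reference row of each depth-conversion matrix and its focal column are ever
evaluated: Npix·Nx + Npix·(Npix − 1) Green's-function products per DFP.

Because detector pixels and lateral grid nodes share one lattice and the
slab Green's function depends only on depth and lateral offset, the focal
column for all (m, n) pairs reduces to a (2Ny−1)×(2Nz−1) lateral-offset
table — assembly is O(Npix²) table lookups, not Green evaluations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .forward import ImagingSetup
from .optics import VoxelGrid, green_slab

__all__ = [
    "FocalPlane",
    "SystemMatrix",
    "depth_to_focal_index",
    "assemble_system_matrix",
    "count_green_evaluations",
    "storage_requirements",
    "system_matrix_error",
]


@dataclass(frozen=True)
class FocalPlane:
    """Chosen depth of focal plane (DFP) and its nearest grid node index."""

    depth: float
    index: int

    @classmethod
    def at_depth(cls, dfp: float, grid: VoxelGrid) -> "FocalPlane":
        return cls(depth=float(dfp), index=depth_to_focal_index(dfp, grid))


def depth_to_focal_index(dfp: float, grid: VoxelGrid) -> int:
    """Nearest depth-node index to the DFP; midpoint ties round toward the detector."""
    x0 = grid.origin[0]
    extent = (grid.counts[0] - 1) * grid.spacing[0]
    if not x0 - 1e-12 <= dfp <= x0 + extent + 1e-12:
        raise ValueError("depth of focal plane outside the slab")
    ratio = (dfp - x0) / grid.spacing[0]
    k = int(np.floor(ratio))
    frac = ratio - k
    if frac > 0.5:  # strict: exact midpoints stay with the shallower node
        k += 1
    return min(max(k, 0), grid.counts[0] - 1)


@dataclass
class SystemMatrix:
    """Dense Npix×Npix operator R with B = R·F^{(ref)} (ΔV absorbed).

    ``provenance`` records the configuration the matrix was assembled from
    (grid shape/spacing, optics, source, reference pixel, DFP).
    """

    values: np.ndarray
    focal: FocalPlane
    grid: VoxelGrid
    provenance: dict

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("system matrix must be square")
        self._alpha: float | None = None

    @property
    def npix(self) -> int:
        return self.values.shape[0]

    @property
    def alpha(self) -> float:
        """trace(RᵀR) = ‖R‖_F², cached; the regularization scale of the solver."""
        if self._alpha is None:
            self._alpha = float(np.sum(self.values**2))
        return self._alpha


def assemble_system_matrix(setup: ImagingSetup, focal: FocalPlane) -> SystemMatrix:
    """Assemble R_mn = ΔV · C_n^{(1)} · C_{n,k}^{(m)} / C_{n,k}^{(1)}.

    Evaluates only the reference row (all depths) and the focal column of
    each depth-conversion matrix; the focal column over all pixel pairs is
    built from a lateral-offset Green's table.
    """
    grid = setup.grid
    nx, ny, nz = grid.counts
    k = focal.index
    if not 0 <= k < nx:
        raise ValueError("focal index outside the depth axis")

    phi = setup.phi_ex  # (Nx, Ny, Nz)
    g_ref = setup.emission_green_field(setup.reference_pixel)  # (Nx, Ny, Nz)

    # reference row: C_n^{(1)} = Σ_i C_{n,i}^{(1)}
    c_ref_sum = np.sum(g_ref * phi, axis=0)  # (Ny, Nz)

    # lateral-offset table of G_em between a detector pixel and a focal node
    dy = grid.spacing[1] * (np.arange(2 * ny - 1) - (ny - 1))
    dz = grid.spacing[2] * (np.arange(2 * nz - 1) - (nz - 1))
    dyg, dzg = np.meshgrid(dy, dz, indexing="ij")
    a = np.zeros(dyg.shape + (3,))
    a[..., 1] = dyg
    a[..., 2] = dzg
    b = np.zeros(3)
    b[0] = grid.x_coords[k]
    table = green_slab(
        a, b, setup.optics, setup.slab, tol=setup.tol, rho_min=setup.rho_min
    )  # (2Ny-1, 2Nz-1)

    m = np.arange(grid.npix)
    iy_m, iz_m = grid.pixel_multi_index(m)
    # offsets pixel m -> lateral node n; y fastest linearization on both axes
    dyi = iy_m[None, :] - iy_m[:, None] + (ny - 1)
    dzi = iz_m[None, :] - iz_m[:, None] + (nz - 1)
    g_k = table[dyi, dzi]  # (Npix, Npix): G_em(r_dm, focal node at lateral n)

    c_ref_sum_v = grid.image_to_vector(c_ref_sum)
    # focal entry of the reference row, taken from the same table so the
    # ratio cancels identically at m = reference (row-1 invariant is exact)
    g_ref_k_v = g_k[setup.reference_pixel, :]
    # C_{n,k}^{(m)} / C_{n,k}^{(1)} = g_k[m, n] / g_ref_k[n] (Φ_ex cancels)
    r = grid.delta_v * c_ref_sum_v[None, :] * g_k / g_ref_k_v[None, :]

    provenance = {
        "grid_counts": grid.counts,
        "grid_spacing": grid.spacing,
        "mu_a": setup.optics.mu_a,
        "mu_s_prime": setup.optics.mu_s_prime,
        "q": setup.optics.q,
        "slab_thickness": setup.slab.thickness,
        "source_position": tuple(setup.source.position),
        "source_strength": setup.source.strength,
        "reference_pixel": setup.reference_pixel,
        "dfp": focal.depth,
        "focal_index": focal.index,
        "delta_v_absorbed": True,
    }
    return SystemMatrix(values=r, focal=focal, grid=grid, provenance=provenance)


def count_green_evaluations(grid: VoxelGrid) -> int:
    """Green's-function product evaluations needed for one DFP.

    Full depth rows for the reference pixel (Npix·Nx) plus a single focal
    entry for every other blurry pixel (Npix·(Npix − 1)).
    """
    npix, nx = grid.npix, grid.counts[0]
    return npix * nx + npix * (npix - 1)


def storage_requirements(grid: VoxelGrid, bytes_per_value: int = 8) -> dict:
    """Memory footprint of the dense operators at double precision.

    Returns the system matrix (MB), one depth conversion matrix (MB), and
    the total of all depth conversion matrices plus the system matrix (GB).
    """
    npix, nx = grid.npix, grid.counts[0]
    mb = 1024.0**2
    gb = 1024.0**3
    return {
        "system_matrix_MB": npix * npix * bytes_per_value / mb,
        "depth_matrix_MB": npix * nx * bytes_per_value / mb,
        "total_all_GB": (npix * npix * nx + npix * npix) * bytes_per_value / gb,
    }


def system_matrix_error(r: SystemMatrix, r_ref: SystemMatrix, norm: str = "fro") -> float:
    """Squared norm of R − R_ref; ``norm`` is "fro" (default) or "spectral".

    Used to quantify how far a system matrix assembled at a trial DFP is
    from the one at the true target depth.
    """
    if r.values.shape != r_ref.values.shape:
        raise ValueError("system matrices must have identical shapes")
    diff = r.values - r_ref.values
    if norm == "fro":
        return float(np.sum(diff**2))
    if norm == "spectral":
        return float(np.linalg.norm(diff, ord=2) ** 2)
    raise ValueError(f"unknown norm: {norm!r}")
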