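"""Born-approximation forward model for transillumination planar fluorescence.

Under the Born approximation the fluorescence photon density detected at
pixel m is a weighted sum of the fluorescent yield f over all voxels,

    B_m = ΔV Σ_n Σ_i C_{n,i}^{(m)} f(x_i, y_n, z_n),
    C_{n,i}^{(m)} = G_em(r_dm, x_i, y_n, z_n) · Φ_ex(x_i, y_n, z_n, r_s),

where n runs over the (y, z) pixel lattice and i over depth.  The
restoration target is not the 3-D yield but the *expected image*: by the
first mean value theorem, the depth integral at each lateral position can
be replaced by the yield at some intermediate depth, giving per-pixel
values F_n that are convex (weighted-average) combinations of f along x,

    F_n^{(m)} = Σ_i C_{n,i}^{(m)} f(x_i, y_n, z_n) / Σ_i C_{n,i}^{(m)}.

F depends on which blurry pixel m supplies the weights — the expected
image is not unique, which is exactly what the focal-plane system matrix
(see :mod:`fpirestore.sysmat`) works around.

The full weight tensor (Npix² · Nx entries) is never materialized; weights
are evaluated lazily from the two cached factor fields (the excitation
field and per-pixel emission Green's fields).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .optics import (
    OpticalProperties,
    PointSource,
    SlabGeometry,
    VoxelGrid,
    excitation_field,
    green_slab,
)

__all__ = [
    "ImagingSetup",
    "YieldMap",
    "BlurryImage",
    "ExpectedImage",
    "DepthConversionMatrix",
    "voxel_weight",
    "depth_conversion_matrix",
    "expected_image_from_yield",
    "simulate_blurry_image",
    "add_noise",
]


@dataclass
class ImagingSetup:
    """Complete imaging configuration: medium, grid, and excitation source.

    ``reference_pixel`` is the blurry pixel whose depth-conversion weights
    anchor the system matrix.  Which pixel is "first" is a free convention;
    the default is the central detector pixel, which preserves the lateral
    symmetries of the physical setup in the assembled operator (a corner
    reference skews the column scaling of the system matrix and drags the
    restored target toward the far corner).  Pass an integer pixel index to
    override.
    """

    optics: OpticalProperties
    slab: SlabGeometry
    grid: VoxelGrid
    source: PointSource
    reference_pixel: int | None = None
    tol: float = 1e-14  # image-series truncation: tight enough that scalar
    # and vectorized evaluations of the same weight agree to ~1e-13 relative

    def __post_init__(self) -> None:
        if self.reference_pixel is None:
            self.reference_pixel = self.grid.pixel_index(
                self.grid.counts[1] // 2, self.grid.counts[2] // 2
            )
        if not 0 <= self.reference_pixel < self.grid.npix:
            raise ValueError("reference pixel out of range")
        x0 = self.source.position[0]
        if not 0.0 < x0 < self.slab.thickness:
            raise ValueError("source must lie strictly inside the slab")
        self._phi_ex: np.ndarray | None = None
        self._gem_cache: dict[int, np.ndarray] = {}

    @property
    def rho_min(self) -> float:
        """Singular-kernel clamp distance: half a depth voxel."""
        return self.grid.spacing[0] / 2.0

    @property
    def phi_ex(self) -> np.ndarray:
        """Cached excitation field Φ_ex on the voxel grid, shape (Nx, Ny, Nz)."""
        if self._phi_ex is None:
            self._phi_ex = excitation_field(
                self.grid, self.source, self.optics, self.slab, tol=self.tol
            )
        return self._phi_ex

    def emission_green_field(self, m: int) -> np.ndarray:
        """G_em from detector pixel m to every voxel node, shape (Nx, Ny, Nz).

        Cached per pixel; only a handful of pixels (the reference pixel,
        any pixel used for an expected image) are ever requested.
        """
        if m not in self._gem_cache:
            pixel = self.grid.pixel_position(m)
            nodes = self.grid.node_positions()
            self._gem_cache[m] = green_slab(
                nodes, pixel, self.optics, self.slab, tol=self.tol, rho_min=self.rho_min
            )
        return self._gem_cache[m]

    def with_source_strength(self, strength: float) -> "ImagingSetup":
        src = PointSource(self.source.position, strength)
        return ImagingSetup(
            self.optics, self.slab, self.grid, src, self.reference_pixel, self.tol
        )


@dataclass
class YieldMap:
    """Fluorescent yield f on the voxel grid, shape (Nx, Ny, Nz), values >= 0."""

    values: np.ndarray
    grid: VoxelGrid

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.counts:
            raise ValueError(
                f"yield shape {self.values.shape} does not match grid {self.grid.counts}"
            )
        if np.any(self.values < 0):
            raise ValueError("fluorescent yield must be non-negative")


@dataclass
class BlurryImage:
    """Detected (diffusion-blurred) image on the (Ny, Nz) pixel lattice."""

    pixels: np.ndarray
    grid: VoxelGrid

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.shape != (self.grid.counts[1], self.grid.counts[2]):
            raise ValueError("image shape does not match the detector lattice")

    @property
    def vector(self) -> np.ndarray:
        return self.grid.image_to_vector(self.pixels)


@dataclass
class ExpectedImage:
    """Sharp projection F on the (Ny, Nz) lattice, in yield units.

    ``reference_pixel`` records which blurry pixel's weights define the
    depth averaging (the superscript of F^{(m)}).
    """

    pixels: np.ndarray
    grid: VoxelGrid
    reference_pixel: int = 0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.shape != (self.grid.counts[1], self.grid.counts[2]):
            raise ValueError("image shape does not match the detector lattice")

    @property
    def vector(self) -> np.ndarray:
        return self.grid.image_to_vector(self.pixels)


@dataclass
class DepthConversionMatrix:
    """All weights tied to one expected pixel n: entries[m, i] = C_{n,i}^{(m)}.

    Rows run over blurry pixels m, columns over depth indices i; row sums
    are the per-pixel totals C_n^{(m)}.
    """

    entries: np.ndarray
    pixel_index: int

    @property
    def row_sums(self) -> np.ndarray:
        return self.entries.sum(axis=1)


def voxel_weight(m: int, n: int, i: int, setup: ImagingSetup) -> float:
    """Single Born weight C_{n,i}^{(m)} = G_em(r_dm, node) · Φ_ex(node, r_s)."""
    grid = setup.grid
    if not (0 <= m < grid.npix and 0 <= n < grid.npix and 0 <= i < grid.counts[0]):
        raise IndexError("weight index out of range")
    iy, iz = grid.pixel_multi_index(n)
    node = grid.node_position(i, int(iy), int(iz))
    g_em = green_slab(
        node,
        grid.pixel_position(m),
        setup.optics,
        setup.slab,
        tol=setup.tol,
        rho_min=setup.rho_min,
    )
    return float(g_em * setup.phi_ex[i, int(iy), int(iz)])


def depth_conversion_matrix(n: int, setup: ImagingSetup) -> DepthConversionMatrix:
    """Assemble the (Npix, Nx) depth conversion matrix of expected pixel n."""
    grid = setup.grid
    if not 0 <= n < grid.npix:
        raise IndexError("expected-pixel index out of range")
    iy, iz = grid.pixel_multi_index(n)
    iy, iz = int(iy), int(iz)
    # nodes along depth at the lateral position of pixel n: (Nx, 3)
    depths = grid.x_coords
    nodes = np.column_stack(
        [
            depths,
            np.full_like(depths, grid.origin[1] + iy * grid.spacing[1]),
            np.full_like(depths, grid.origin[2] + iz * grid.spacing[2]),
        ]
    )
    pixels = grid.pixel_position(np.arange(grid.npix))  # (Npix, 3)
    g_em = green_slab(
        nodes[None, :, :],
        pixels[:, None, :],
        setup.optics,
        setup.slab,
        tol=setup.tol,
        rho_min=setup.rho_min,
    )
    entries = g_em * setup.phi_ex[:, iy, iz][None, :]
    return DepthConversionMatrix(entries=entries, pixel_index=n)


def expected_image_from_yield(
    f: YieldMap, m: int, setup: ImagingSetup
) -> ExpectedImage:
    """Depth-average the yield with the weights of blurry pixel m.

    F_n = Σ_i C_{n,i}^{(m)} f(x_i, y_n, z_n) / Σ_i C_{n,i}^{(m)} — a convex
    combination of the yield along depth at each lateral position.
    """
    if f.grid is not setup.grid and f.grid != setup.grid:
        raise ValueError("yield map grid does not match the setup grid")
    w = setup.emission_green_field(m) * setup.phi_ex  # (Nx, Ny, Nz)
    num = np.sum(w * f.values, axis=0)
    den = np.sum(w, axis=0)
    return ExpectedImage(pixels=num / den, grid=setup.grid, reference_pixel=m)


def simulate_blurry_image(f: YieldMap, setup: ImagingSetup) -> BlurryImage:
    """Forward-project a yield map to the blurred detector image.

    B_m = ΔV Σ_voxels G_em(r_dm, v) Φ_ex(v, r_s) f(v); the sum runs only
    over the voxels where f is nonzero, so sparse targets (the usual case)
    are cheap even on fine grids.
    """
    if np.any(f.values < 0):
        raise ValueError("fluorescent yield must be non-negative")
    grid = setup.grid
    idx = np.nonzero(f.values)
    if idx[0].size == 0:
        return BlurryImage(
            pixels=np.zeros((grid.counts[1], grid.counts[2])), grid=grid
        )
    vox = np.column_stack(
        [
            grid.origin[0] + idx[0] * grid.spacing[0],
            grid.origin[1] + idx[1] * grid.spacing[1],
            grid.origin[2] + idx[2] * grid.spacing[2],
        ]
    )  # (nv, 3)
    weights = f.values[idx] * setup.phi_ex[idx]  # (nv,)
    pixels = grid.pixel_position(np.arange(grid.npix))  # (Npix, 3)
    g_em = green_slab(
        vox[None, :, :],
        pixels[:, None, :],
        setup.optics,
        setup.slab,
        tol=setup.tol,
        rho_min=setup.rho_min,
    )  # (Npix, nv)
    b = grid.delta_v * g_em @ weights
    return BlurryImage(pixels=grid.vector_to_image(b), grid=grid)


def add_noise(
    b: BlurryImage, model: str = "gaussian", level: float = 0.01, seed: int | None = None
) -> BlurryImage:
    """Corrupt a blurry image with measurement noise (reproducible per seed).

    gaussian: adds zero-mean noise with σ = level · max(B).
    poisson: rescales B so its maximum equals ``level`` expected photon
    counts, resamples, and scales back.
    """
    if level < 0:
        raise ValueError("noise level must be non-negative")
    if level == 0:
        return BlurryImage(pixels=b.pixels.copy(), grid=b.grid)
    rng = np.random.default_rng(seed)
    peak = float(b.pixels.max())
    if model == "gaussian":
        noisy = b.pixels + rng.normal(0.0, level * peak, size=b.pixels.shape)
    elif model == "poisson":
        if peak <= 0:
            raise ValueError("poisson noise requires a positive image")
        scale = level / peak
        noisy = rng.poisson(b.pixels * scale).astype(float) / scale
    else:
        raise ValueError(f"unknown noise model: {model!r}")
    return BlurryImage(pixels=noisy, grid=b.grid)
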