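"""Diffusion-theory photon propagation in homogeneous turbid slabs.

Photon transport in a highly scattering medium is modelled by the steady-state
diffusion equation with a Robin (partial-current) boundary condition,

    -D ∇²Φ(r) + μa Φ(r) = Q(r),      2 q D ∂Φ/∂n + Φ = 0 on the boundary,

with diffusion coefficient D = 1/[3(μa + μs′)] and effective attenuation
μeff = sqrt(μa / D).  The free-space Green's function of this operator is the
screened Poisson kernel exp(-μeff ρ)/(4π D ρ); planar boundaries are handled
with the extrapolated-boundary method of image sources, the zero-density
planes sitting a distance z_b = 2 q D outside the physical surfaces.

Coordinate convention used throughout the package: x is the depth (detection)
axis with x = 0 on the detector-side surface and x = thickness on the
illuminated surface; images are indexed over (y, z); all lengths in cm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np

__all__ = [
    "OpticalProperties",
    "SlabGeometry",
    "VoxelGrid",
    "PointSource",
    "derive_diffusion_coefficient",
    "green_infinite",
    "green_slab",
    "place_collimated_source",
    "excitation_field",
]

_4PI = 4.0 * np.pi


@dataclass(frozen=True)
class OpticalProperties:
    """Homogeneous optical coefficients of the diffusive medium.

    Parameters
    ----------
    mu_a : float
        Absorption coefficient, cm^-1.
    mu_s_prime : float
        Reduced scattering coefficient, cm^-1.
    q : float, optional
        Boundary refractive-index-mismatch coefficient of the Robin
        condition ``2 q D dΦ/dn + Φ = 0`` (dimensionless, 1 = index
        matched).
    """

    mu_a: float
    mu_s_prime: float
    q: float = 1.0

    def __post_init__(self) -> None:
        if self.mu_a < 0:
            raise ValueError("mu_a must be non-negative")
        if self.mu_s_prime <= 0:
            raise ValueError("mu_s_prime must be positive")
        if self.mu_a + self.mu_s_prime <= 0:
            raise ValueError("mu_a + mu_s_prime must be positive")
        if self.q <= 0:
            raise ValueError("q must be positive")

    @property
    def diffusion_coefficient(self) -> float:
        """D = 1 / [3 (μa + μs′)], cm."""
        return 1.0 / (3.0 * (self.mu_a + self.mu_s_prime))

    @property
    def mu_eff(self) -> float:
        """Effective attenuation sqrt(μa / D), cm^-1."""
        return float(np.sqrt(self.mu_a / self.diffusion_coefficient))


def derive_diffusion_coefficient(props: OpticalProperties) -> float:
    """Return the diffusion coefficient D = 1/[3(μa + μs′)] in cm."""
    return props.diffusion_coefficient


@dataclass(frozen=True)
class SlabGeometry:
    """Slab bounded by the detector plane x = 0 and the source plane x = thickness.

    Only the two planes normal to the detection axis are treated as
    boundaries; lateral walls are ignored (valid whenever sources, targets
    and detectors are many transport lengths away from them).
    """

    thickness: float

    def __post_init__(self) -> None:
        if self.thickness <= 0:
            raise ValueError("slab thickness must be positive")

    @property
    def detector_plane(self) -> float:
        return 0.0

    @property
    def source_plane(self) -> float:
        return self.thickness

    def extrapolation_distance(self, props: OpticalProperties) -> float:
        """z_b = 2 q D, the distance of the zero-density planes outside the slab."""
        return 2.0 * props.q * props.diffusion_coefficient


@dataclass(frozen=True)
class VoxelGrid:
    """Node-centered cartesian grid with nodes on both boundaries.

    A 3 cm axis sampled at 0.05 cm spacing has exactly 61 nodes; the extent
    per axis is (count - 1) * spacing.  The (y, z) node lattice doubles as
    the detector pixel lattice, so the number of image pixels is
    Npix = Ny * Nz.  Pixel linearization is y-fastest:
    ``m = iz * Ny + iy`` (0-based).
    """

    spacing: tuple[float, float, float]
    counts: tuple[int, int, int]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacings must be positive")
        if any(c < 1 for c in self.counts):
            raise ValueError("counts must be >= 1")

    @classmethod
    def from_extent(
        cls,
        extent: tuple[float, float, float],
        spacing: float | tuple[float, float, float],
        origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
    ) -> "VoxelGrid":
        if np.isscalar(spacing):
            spacing = (float(spacing),) * 3  # type: ignore[assignment]
        counts = tuple(int(round(e / s)) + 1 for e, s in zip(extent, spacing))
        return cls(tuple(float(s) for s in spacing), counts, tuple(map(float, origin)))

    @property
    def delta_v(self) -> float:
        """Voxel volume ΔV = Δx Δy Δz, cm^3."""
        dx, dy, dz = self.spacing
        return dx * dy * dz

    @property
    def npix(self) -> int:
        return self.counts[1] * self.counts[2]

    @property
    def n_nodes(self) -> int:
        return self.counts[0] * self.counts[1] * self.counts[2]

    @property
    def extent(self) -> tuple[float, float, float]:
        return tuple((c - 1) * s for c, s in zip(self.counts, self.spacing))

    def axis_coords(self, axis: int) -> np.ndarray:
        return self.origin[axis] + self.spacing[axis] * np.arange(self.counts[axis])

    @property
    def x_coords(self) -> np.ndarray:
        return self.axis_coords(0)

    @property
    def y_coords(self) -> np.ndarray:
        return self.axis_coords(1)

    @property
    def z_coords(self) -> np.ndarray:
        return self.axis_coords(2)

    def node_position(self, i: int, iy: int, iz: int) -> np.ndarray:
        return np.array(
            [
                self.origin[0] + i * self.spacing[0],
                self.origin[1] + iy * self.spacing[1],
                self.origin[2] + iz * self.spacing[2],
            ]
        )

    # --- pixel linearization (y fastest) -------------------------------
    def pixel_index(self, iy: int, iz: int) -> int:
        return iz * self.counts[1] + iy

    def pixel_multi_index(self, m: int | np.ndarray):
        ny = self.counts[1]
        return np.asarray(m) % ny, np.asarray(m) // ny

    def pixel_position(self, m: int | np.ndarray) -> np.ndarray:
        """Detector pixel position(s) on the x = 0 plane, shape (..., 3)."""
        iy, iz = self.pixel_multi_index(m)
        pos = np.empty(np.shape(iy) + (3,), dtype=float)
        pos[..., 0] = self.origin[0]
        pos[..., 1] = self.origin[1] + iy * self.spacing[1]
        pos[..., 2] = self.origin[2] + iz * self.spacing[2]
        return pos

    def node_positions(self) -> np.ndarray:
        """All node coordinates, shape (Nx, Ny, Nz, 3)."""
        x, y, z = np.meshgrid(self.x_coords, self.y_coords, self.z_coords, indexing="ij")
        return np.stack([x, y, z], axis=-1)

    def image_to_vector(self, image: np.ndarray) -> np.ndarray:
        """Flatten a (Ny, Nz) image to a length-Npix vector (y fastest)."""
        return np.asarray(image).reshape(-1, order="F")

    def vector_to_image(self, vec: np.ndarray) -> np.ndarray:
        return np.asarray(vec).reshape((self.counts[1], self.counts[2]), order="F")


@dataclass(frozen=True)
class PointSource:
    """Isotropic point source inside the medium."""

    position: tuple[float, float, float]
    strength: float = 1.0

    def __post_init__(self) -> None:
        if self.strength <= 0:
            raise ValueError("source strength must be positive")


def _kernel(rho: np.ndarray, props: OpticalProperties) -> np.ndarray:
    d = props.diffusion_coefficient
    return np.exp(-props.mu_eff * rho) / (_4PI * d * rho)


def green_infinite(r_a, r_b, props: OpticalProperties, rho_min: float = 0.0):
    """Infinite-medium diffusion Green's function exp(-μeff ρ)/(4π D ρ).

    ``r_a`` and ``r_b`` are broadcastable arrays of shape (..., 3); the
    result has the broadcast shape.  ``rho_min`` regularizes the 1/ρ
    singularity (voxelized-kernel practice: clamp to half a voxel).
    """
    r_a = np.asarray(r_a, dtype=float)
    r_b = np.asarray(r_b, dtype=float)
    rho = np.sqrt(np.sum((r_a - r_b) ** 2, axis=-1))
    if rho_min > 0:
        rho = np.maximum(rho, rho_min)
    if np.any(rho == 0):
        raise ValueError("coincident points: Green's function is singular")
    out = _kernel(rho, props)
    return out if out.ndim else float(out)


def green_slab(
    r_a,
    r_b,
    props: OpticalProperties,
    slab: SlabGeometry,
    tol: float = 1e-9,
    rho_min: float = 0.0,
    max_order: int = 200,
):
    """Slab Green's function via extrapolated-boundary image sources.

    Zero-density planes sit at x = -z_b and x = thickness + z_b with
    z_b = 2 q D.  The alternating-sign image series is summed in shells of
    increasing order and truncated once a shell's relative contribution
    falls below ``tol``.  Both points must lie within [0, thickness] along
    x (boundary points allowed — detector pixels live on x = 0).
    """
    r_a = np.asarray(r_a, dtype=float)
    r_b = np.asarray(r_b, dtype=float)
    L = slab.thickness
    for r in (r_a, r_b):
        x = r[..., 0]
        if np.any(x < -1e-12) or np.any(x > L + 1e-12):
            raise ValueError("point outside the slab")
    zb = slab.extrapolation_distance(props)
    width = L + 2.0 * zb  # distance between the extrapolated planes
    lat2 = (r_a[..., 1] - r_b[..., 1]) ** 2 + (r_a[..., 2] - r_b[..., 2]) ** 2
    x_f = r_a[..., 0]
    x_s = r_b[..., 0]

    def term(x_img: np.ndarray) -> np.ndarray:
        rho = np.sqrt((x_f - x_img) ** 2 + lat2)
        if rho_min > 0:
            rho = np.maximum(rho, rho_min)
        if np.any(rho == 0):
            raise ValueError("coincident points: Green's function is singular")
        return _kernel(rho, props)

    total = np.zeros(np.broadcast_shapes(x_f.shape, x_s.shape, lat2.shape))
    for k in range(max_order + 1):
        shell = np.zeros_like(total)
        for kk in ((0,) if k == 0 else (k, -k)):
            off = 2.0 * kk * width
            shell += term(x_s + off)  # positive image
            shell -= term(-2.0 * zb - x_s + off)  # mirror across x = -z_b
        total += shell
        if k >= 1:
            with np.errstate(divide="ignore", invalid="ignore"):
                rel = np.abs(shell) / np.where(total == 0, 1.0, np.abs(total))
            if np.max(rel) < tol:
                break
    else:
        raise RuntimeError("image-source series did not converge")
    return total if total.ndim else float(total)


def place_collimated_source(
    entry_point,
    props: OpticalProperties,
    slab: SlabGeometry,
    strength: float = 1.0,
) -> PointSource:
    """Model a collimated beam entering at the source plane as a point source.

    The beam is replaced by an isotropic point source one transport
    scattering length 1/μs′ below the illuminated surface, along the inward
    normal (toward the detector).
    """
    entry = np.asarray(entry_point, dtype=float)
    if abs(entry[0] - slab.source_plane) > 1e-9:
        raise ValueError("entry point must lie on the source-side boundary plane")
    depth = 1.0 / props.mu_s_prime
    if depth >= slab.thickness:
        raise ValueError("one transport length exceeds the slab thickness")
    pos = (slab.source_plane - depth, float(entry[1]), float(entry[2]))
    return PointSource(position=pos, strength=strength)


def excitation_field(
    grid: VoxelGrid,
    source: PointSource,
    props: OpticalProperties,
    slab: SlabGeometry,
    tol: float = 1e-9,
) -> np.ndarray:
    """Excitation photon density Φ_ex at every voxel node, shape (Nx, Ny, Nz).

    The node containing the source is regularized by clamping the
    source-node distance to Δx/2.
    """
    nodes = grid.node_positions()
    src = np.asarray(source.position, dtype=float)
    field = green_slab(nodes, src, props, slab, tol=tol, rho_min=grid.spacing[0] / 2.0)
    return source.strength * field
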