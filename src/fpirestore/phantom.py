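"""Synthetic cylindrical-tube phantom for end-to-end exercises.

Emulates the classic validation phantom for deep-fluorochrome imaging: a
3×3×3 cm diffusive cube (5% Intralipid-like optics, μa = 0.02 cm⁻¹,
μs′ = 10 cm⁻¹) containing a thin fluorescent capillary tube of 0.3 cm
diameter at 2 cm depth from the detector surface, trans-illuminated by a
collimated point source entering the opposite face.  The tube runs along
the z axis at a lateral offset of 1 cm from one wall; its dye amplitude is
proportional to concentration (the proportionality constant is folded into
``yield_amplitude``).

The true lateral cross-section of the tube projects to the chord profile
g(h) = sqrt(r² − h²), whose FWHM is r·√3 — the resolution reference the
restored images are judged against.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .forward import (
    BlurryImage,
    ImagingSetup,
    YieldMap,
    add_noise,
    expected_image_from_yield,
    simulate_blurry_image,
)
from .optics import (
    OpticalProperties,
    PointSource,
    SlabGeometry,
    VoxelGrid,
    place_collimated_source,
)

__all__ = ["PhantomSpec", "build_phantom_yield", "true_profile", "make_fixture", "setup_for_phantom"]


@dataclass(frozen=True)
class PhantomSpec:
    """Parametric description of the tube-in-tank phantom.

    Lengths in cm; ``tube_depth`` is measured from the detector-side
    surface (x = 0).  ``tube_axis`` is "z" (default) or "y"; the tube spans
    the full tank along its axis unless ``tube_span`` narrows it.
    ``tube_y``/``tube_z`` locate the axis in the lateral plane (for a
    z-axis tube only ``tube_y`` matters, and vice versa).
    """

    tank: tuple[float, float, float] = (3.0, 3.0, 3.0)
    mu_a: float = 0.02
    mu_s_prime: float = 10.0
    q: float = 1.0
    tube_radius: float = 0.15
    tube_depth: float = 2.0
    tube_y: float = 1.0
    tube_z: float = 1.5
    tube_axis: str = "z"
    tube_span: tuple[float, float] | None = None
    yield_amplitude: float = 1.0
    source_entry: tuple[float, float] = (1.5, 1.5)
    source_strength: float = 1.0

    def __post_init__(self) -> None:
        if self.tube_radius <= 0:
            raise ValueError("tube radius must be positive")
        if self.yield_amplitude < 0:
            raise ValueError("yield amplitude must be non-negative")
        if self.tube_axis not in ("y", "z"):
            raise ValueError("tube axis must be 'y' or 'z'")
        r = self.tube_radius
        lateral = self.tube_y if self.tube_axis == "z" else self.tube_z
        lat_extent = self.tank[1] if self.tube_axis == "z" else self.tank[2]
        if not (
            r <= self.tube_depth <= self.tank[0] - r
            and r <= lateral <= lat_extent - r
        ):
            raise ValueError("tube does not fit inside the tank")

    @property
    def true_center(self) -> tuple[float, float]:
        """Lateral (y, z) center of the tube's projection."""
        if self.tube_axis == "z":
            span = self.tube_span or (0.0, self.tank[2])
            return (self.tube_y, 0.5 * (span[0] + span[1]))
        span = self.tube_span or (0.0, self.tank[1])
        return (0.5 * (span[0] + span[1]), self.tube_z)


def build_phantom_yield(spec: PhantomSpec, grid: VoxelGrid) -> YieldMap:
    """Voxelize the tube: amplitude where the node center lies inside the cylinder.

    Nodes exactly on the tube surface count as inside (the squared-radius
    comparison carries a 1e-9 relative tolerance so lattice points at
    exactly r are not lost to roundoff).
    """
    x, y, z = np.meshgrid(grid.x_coords, grid.y_coords, grid.z_coords, indexing="ij")
    if spec.tube_axis == "z":
        d2 = (x - spec.tube_depth) ** 2 + (y - spec.tube_y) ** 2
        along = z
    else:
        d2 = (x - spec.tube_depth) ** 2 + (z - spec.tube_z) ** 2
        along = y
    inside = d2 <= spec.tube_radius**2 * (1.0 + 1e-9)
    if spec.tube_span is not None:
        lo, hi = spec.tube_span
        inside &= (along >= lo) & (along <= hi)
    return YieldMap(values=spec.yield_amplitude * inside.astype(float), grid=grid)


def true_profile(h, r: float):
    """Chord length profile g(h) = sqrt(r² − h²) of a cylinder of radius r.

    Zero outside |h| > r; FWHM of this profile is r·√3.
    """
    if r <= 0:
        raise ValueError("radius must be positive")
    h = np.asarray(h, dtype=float)
    out = np.sqrt(np.maximum(r**2 - h**2, 0.0))
    return out if out.ndim else float(out)


def setup_for_phantom(spec: PhantomSpec, spacing: float = 0.05) -> ImagingSetup:
    """Imaging configuration matching the phantom: slab, grid, collimated source."""
    optics = OpticalProperties(mu_a=spec.mu_a, mu_s_prime=spec.mu_s_prime, q=spec.q)
    slab = SlabGeometry(thickness=spec.tank[0])
    grid = VoxelGrid.from_extent(spec.tank, spacing)
    entry = (slab.source_plane, spec.source_entry[0], spec.source_entry[1])
    source = place_collimated_source(entry, optics, slab, strength=spec.source_strength)
    return ImagingSetup(optics=optics, slab=slab, grid=grid, source=source)


def make_fixture(
    spec: PhantomSpec,
    spacing: float = 0.05,
    noise_model: str | None = None,
    noise_level: float = 0.0,
    seed: int | None = None,
) -> dict:
    """Generate everything an end-to-end run needs, deterministically.

    Returns a dict with the imaging ``setup``, the true ``yield_map``, the
    noise-free and (optionally) noisy blurry images, the reference expected
    image, and a JSON-serializable ``manifest`` of all parameters.
    """
    setup = setup_for_phantom(spec, spacing)
    yield_map = build_phantom_yield(spec, setup.grid)
    clean = simulate_blurry_image(yield_map, setup)
    if noise_model is not None and noise_level > 0:
        blurry = add_noise(clean, model=noise_model, level=noise_level, seed=seed)
    else:
        blurry = clean
    expected = expected_image_from_yield(yield_map, setup.reference_pixel, setup)
    manifest = {
        "phantom": asdict(spec),
        "spacing_cm": spacing,
        "grid_counts": setup.grid.counts,
        "noise_model": noise_model,
        "noise_level": noise_level,
        "seed": seed,
        "source_position": tuple(setup.source.position),
        "true_center_yz_cm": spec.true_center,
    }
    # round-trip through JSON so the manifest is guaranteed serializable
    manifest = json.loads(json.dumps(manifest))
    return {
        "setup": setup,
        "yield_map": yield_map,
        "blurry": blurry,
        "blurry_clean": clean,
        "expected": expected,
        "manifest": manifest,
    }
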