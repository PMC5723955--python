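"""Shared fixtures: a toy 3x3x3-node configuration and the desk-scale phantom.

The heavy objects (phantom forward simulation at 0.1 cm voxels, the
system matrices of the depth-of-focal-plane sweep, the Levenberg-Marquardt
fits) are session-scoped so the module tests and the acceptance suite share
one computation.
"""

import numpy as np
import pytest

from fpirestore import (
    FocalPlane,
    ImagingSetup,
    OpticalProperties,
    PhantomSpec,
    PointSource,
    SlabGeometry,
    VoxelGrid,
    assemble_system_matrix,
    lm_restore,
    make_fixture,
)
from fpirestore.restore import RestorationConfig

# restoration settings used for the phantom pipeline throughout:
# the values of the reference study (lambda 1e-4, 200 iterations) with the
# physical nonnegativity projection enabled
PIPELINE_CFG = RestorationConfig(lam=1e-4, iterations=200, nonnegativity_clamp=True)
PLAIN_CFG = RestorationConfig(lam=1e-4, iterations=200, nonnegativity_clamp=False)

DESK_SPACING = 0.1  # cm; desk-scale voxel size for the simulated phantom


@pytest.fixture(scope="session")
def toy_setup() -> ImagingSetup:
    """3x3x3-node slab small enough for brute-force enumeration."""
    optics = OpticalProperties(mu_a=0.02, mu_s_prime=10.0)
    slab = SlabGeometry(thickness=0.3)
    grid = VoxelGrid.from_extent((0.3, 0.3, 0.3), 0.15)
    source = PointSource(position=(0.2, 0.15, 0.15))
    return ImagingSetup(optics=optics, slab=slab, grid=grid, source=source)


@pytest.fixture(scope="session")
def phantom():
    """Noise-free tube phantom at 0.1 cm voxels with its forward simulation."""
    spec = PhantomSpec()
    fx = make_fixture(spec, spacing=DESK_SPACING)
    return {"spec": spec, **fx}


@pytest.fixture(scope="session")
def phantom_lattice(phantom):
    grid = phantom["setup"].grid
    return (grid.spacing[1], grid.spacing[2]), (grid.origin[1], grid.origin[2])


@pytest.fixture(scope="session")
def dfp_matrices(phantom):
    """System matrices of the DFP sweep {1, 1.5, 2, 2.5, 3} cm."""
    setup = phantom["setup"]
    return {
        dfp: assemble_system_matrix(setup, FocalPlane.at_depth(dfp, setup.grid))
        for dfp in (1.0, 1.5, 2.0, 2.5, 3.0)
    }


@pytest.fixture(scope="session")
def matched_restoration(phantom, dfp_matrices):
    """Inverse-crime restoration at the true depth (DFP = 2 cm)."""
    return lm_restore(dfp_matrices[2.0], phantom["blurry"], PIPELINE_CFG)


@pytest.fixture(scope="session")
def dfp_restorations(phantom, dfp_matrices):
    """Pipeline restorations of the same blurry image across the DFP sweep."""
    return {
        dfp: lm_restore(r, phantom["blurry"], PIPELINE_CFG)
        for dfp, r in dfp_matrices.items()
    }
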