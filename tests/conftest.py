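"""Shared fixtures: small analytic tube phantoms and a reusable Stokes solve."""

import numpy as np
import pytest

from vwerp.core import FluidProperties, VoxelGrid
from vwerp.phantom import TubeGeometry, poiseuille_field, tube_labels
from vwerp.virtual_field import StokesSolverConfig, solve_stokes

SPACING = 1e-3


@pytest.fixture(scope="session")
def fluid():
    return FluidProperties()  # blood defaults


@pytest.fixture(scope="session")
def small_tube(fluid):
    """R = 4 mm, L = 24 mm straight tube at 1 mm voxels with labels and planes."""
    geom = TubeGeometry(radius=4e-3, length=24e-3)
    grid = VoxelGrid((14, 14, 28), (SPACING,) * 3)
    labels, inlet, outlet = tube_labels(geom, grid)
    field, truth = poiseuille_field(geom, 0.3, grid, frames=3, fluid=fluid)
    return {
        "geom": geom,
        "grid": grid,
        "labels": labels,
        "inlet": inlet,
        "outlet": outlet,
        "field": field,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def small_tube_vf(small_tube):
    """Image-resolution Stokes solve on the small tube (fast, reused widely)."""
    cfg = StokesSolverConfig(subsample_spacing=None, tolerance=1e-10)
    return solve_stokes(
        small_tube["labels"], cfg, inlet_normal=small_tube["inlet"].normal
    )


@pytest.fixture(scope="session")
def medium_tube(fluid):
    """R = 8 mm, L = 32 mm tube: resolved enough for profile-shape checks."""
    geom = TubeGeometry(radius=8e-3, length=32e-3)
    grid = VoxelGrid((22, 22, 36), (SPACING,) * 3)
    labels, inlet, outlet = tube_labels(geom, grid)
    return {"geom": geom, "grid": grid, "labels": labels, "inlet": inlet,
            "outlet": outlet}


@pytest.fixture(scope="session")
def medium_tube_vf(medium_tube):
    cfg = StokesSolverConfig(subsample_spacing=None, tolerance=1e-10)
    return solve_stokes(
        medium_tube["labels"], cfg, inlet_normal=medium_tube["inlet"].normal
    )


def axis_distance(grid, shape):
    """Radial distance of each voxel from the grid-center z-axis."""
    ax = grid.axes()
    cx = grid.origin[0] + (shape[0] - 1) / 2 * grid.spacing[0]
    cy = grid.origin[1] + (shape[1] - 1) / 2 * grid.spacing[1]
    ii, jj = np.meshgrid(ax[0], ax[1], indexing="ij")
    return np.sqrt((ii - cx) ** 2 + (jj - cy) ** 2)
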