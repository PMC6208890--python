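"""Shared fixtures: expensive meshes, distance tables and simulations.

Session-scoped so the travelling-bump runs and geodesic tables are computed
once and reused by both the unit tests and the acceptance checks.
"""

import numpy as np
import pytest
from hypothesis import settings

import neuralfield as nf
from neuralfield.geodesics import all_pairs_distances
from neuralfield.solvers import assemble_collocation_operator, integrate_time

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


PARAMS = nf.NeuralFieldParams()
TORUS = nf.TorusDomain(4.5, 2.0)


@pytest.fixture(scope="session")
def plane65():
    """4225-vertex regular periodic Cartesian mesh (stage m = 3) with distances."""
    mesh = nf.build_cartesian_plane_mesh(7.5, 65)
    return mesh, all_pairs_distances(mesh)


@pytest.fixture(scope="session")
def torus_fine():
    """48 x 96 torus grid with its symmetry-assembled geodesic distance table."""
    mesh = nf.build_torus_mesh(TORUS, 48, 96)
    return mesh, all_pairs_distances(mesh)


@pytest.fixture(scope="session")
def plane_bump():
    """Travelling bump on the reduced 33^2 regular plane grid, T = 250."""
    mesh = nf.build_cartesian_plane_mesh(7.5, 33)
    dm = all_pairs_distances(mesh)
    op = assemble_collocation_operator(mesh, dm, PARAMS)
    init = nf.make_initial_condition(mesh, nf.PatchSpec.plane_default())
    series = integrate_time(op, PARAMS, init, T=250.0)
    return mesh, series


@pytest.fixture(scope="session")
def torus_bump(torus_fine):
    """Travelling bump launched along the torus outer equator, T = 400."""
    mesh, dm = torus_fine
    op = assemble_collocation_operator(mesh, dm, PARAMS)
    init = nf.make_initial_condition(mesh, nf.PatchSpec.torus_default(TORUS))
    series = integrate_time(op, PARAMS, init, T=400.0)
    return mesh, series


@pytest.fixture(scope="session")
def torus_reference_cache():
    """Shared cache for the torus convergence reference distance field."""
    return {}


@pytest.fixture(scope="session")
def bumpy_torus(tmp_path_factory):
    """Synthetic bumpy closed surface (perturbed torus), round-tripped via OFF.

    A stand-in constructed in-package for irregular folded geometries; the
    tube radius is modulated so Gaussian curvature varies non-trivially.
    """
    base = nf.build_torus_mesh(TORUS, 32, 64)
    theta, phi = TORUS.angles(base.vertices)
    pert = 1.0 + 0.12 * np.sin(2 * theta) * np.cos(3 * phi)
    centerline = np.column_stack(
        [
            TORUS.major_radius * np.cos(phi),
            TORUS.major_radius * np.sin(phi),
            np.zeros(len(phi)),
        ]
    )
    verts = centerline + (base.vertices - centerline) * pert[:, None]
    bumpy = nf.TriMesh(verts, base.triangles)
    path = tmp_path_factory.mktemp("meshes") / "bumpy_torus_synthetic.off"
    nf.save_mesh(bumpy, path)
    mesh = nf.load_mesh(path)
    return mesh, all_pairs_distances(mesh)
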