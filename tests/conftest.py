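"""Shared fixtures: phantoms are built and solved once per session."""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pytest

import spinefe as sf

warnings.filterwarnings("ignore", message="non-physical")

GENERATING_E_DISC = 1.92  # MPa, disc modulus used to generate phantom targets


def _build(spec: sf.PhantomSpec):
    grid, mesh, bcs, markers = sf.make_phantom(spec)
    sf.map_materials(mesh, grid)
    disc = mesh.disc_mask()
    mesh.E[disc] = GENERATING_E_DISC
    mesh.nu[disc] = 0.1
    sol = sf.apply_bcs_and_solve(mesh, bcs)
    return {"spec": spec, "grid": grid, "mesh": mesh, "bcs": bcs,
            "markers": markers, "sol": sol}


@pytest.fixture(scope="session")
def phantom_default():
    """Default-resolution phantom (2 mm tet10) solved at the generating modulus."""
    return _build(sf.PhantomSpec())


@pytest.fixture(scope="session")
def phantom_coarse():
    """Coarse (3.5 mm tet10) phantom for tests where resolution is irrelevant."""
    return _build(dataclasses.replace(sf.PhantomSpec(), mesh_edge=3.5))


@pytest.fixture(scope="session")
def cube10():
    """10 mm cube, E=100 MPa, nu=0: the rod-formula verification problem."""
    mesh = sf.box_mesh((10.0, 10.0, 10.0), edge=2.5, order=10)
    mesh.E = np.full(mesh.n_elements, 100.0)
    mesh.nu = np.zeros(mesh.n_elements)
    return mesh


def cube_bcs(mesh, dz=-0.1):
    z = mesh.nodes[:, 2]
    pilot = np.array([5.0, 5.0, 12.0])
    return sf.BoundaryConditions(
        fixed_nodes=np.where(z < 1e-9)[0],
        tied_nodes=np.where(z > 10 - 1e-9)[0],
        pilot=pilot,
        pilot_motion=sf.RigidTransform(np.eye(3), [0.0, 0.0, dz], about=pilot),
    )
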