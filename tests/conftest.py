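"""Shared fixtures: phantoms, solved pairs, and the 61-channel lead field.

The expensive objects (the 61-electrode lead field, the homogeneous
validation sphere) are session-scoped so that all tests share one build.
"""

from __future__ import annotations

import numpy as np
import pytest

import phasortacs as pt
from phasortacs.fem_forward import assemble_system, solve_pair


@pytest.fixture(scope="session")
def tissue() -> pt.TissueTable:
    return pt.TissueTable()


@pytest.fixture(scope="session")
def sphere4() -> pt.TetrahedralMesh:
    """Default 4-layer phantom (92/88/83/80 mm), 8 mm edge."""
    return pt.build_layered_sphere(seed=7, target_edge_length=8.0)


@pytest.fixture(scope="session")
def phantom61(sphere4) -> pt.TetrahedralMesh:
    """Phantom with the 61-channel 10-10 montage attached."""
    return pt.place_electrodes(sphere4, pt.standard_10_10())


@pytest.fixture(scope="session")
def surface61(phantom61) -> pt.CorticalSurface:
    return pt.extract_cortical_surface(phantom61, "brain")


@pytest.fixture(scope="session")
def leadfield61(phantom61, surface61, tissue) -> pt.LeadField:
    """Full 60-column lead field of the 61-channel phantom (slow)."""
    return pt.build_leadfield(phantom61, tissue, surface61, active="Fpz")


@pytest.fixture(scope="session")
def parietal_rois(surface61) -> tuple[pt.RoiPatch, pt.RoiPatch]:
    """Two 15-degree lateral parietal caps (left and right)."""
    left = pt.define_roi_patch(surface61, [-0.6, -0.5, 0.62], 15.0, "lIPS")
    right = pt.define_roi_patch(surface61, [0.6, -0.5, 0.62], 15.0, "rIPS")
    return left, right


@pytest.fixture(scope="session")
def homog_pair(tissue):
    """Homogeneous 80 mm sphere with antipodal electrodes, solved pair.

    Returns (mesh, system, solution); ~47k tetrahedra.
    """
    mesh = pt.build_layered_sphere([80.0], ["brain"], target_edge_length=7.0, seed=3)
    layout = pt.ElectrodeLayout(
        ["A", "B"],
        np.array([[0.0, 0.0, 1.0], [0.0, 0.0, -1.0]]),
        [5.0, 5.0],
        [25.0, 25.0],
    )
    mesh = pt.place_electrodes(mesh, layout)
    system = assemble_system(mesh, tissue)
    sol = solve_pair(system, "A", "B")
    return mesh, system, sol


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def synthetic_leadfield(rng: np.random.Generator, n_elem=40, n_ret=6):
    """Small random lead field for optimizer/metric unit tests."""
    return pt.LeadField(
        rng.normal(size=(n_elem, n_ret)),
        active="Fpz",
        returns=[f"R{i}" for i in range(n_ret)],
        element_areas=np.ones(n_elem),
    )


@pytest.fixture()
def small_leadfield(rng):
    return synthetic_leadfield(rng)
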