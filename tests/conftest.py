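"""Shared fixtures: small deterministic scenes and seeded randomness."""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import settings

from osteorom.synthetic_joints import (
    FemurSpec, SocketSpec, make_femur, make_joint_scene, make_socket,
)

# Deterministic hypothesis profile: fixed examples, no flaky deadlines.
settings.register_profile(
    "ci", derandomize=True, max_examples=50, deadline=None, print_blob=False
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def coarse_specs():
    """Demo-geometry specs at the coarsest mesh resolution (fast sweeps)."""
    return (replace(SocketSpec(), mesh_resolution=1),
            replace(FemurSpec(), mesh_resolution=1))


@pytest.fixture(scope="session")
def coarse_scene(coarse_specs):
    socket, femur = coarse_specs
    return make_joint_scene(socket, femur)


@pytest.fixture(scope="session")
def medium_scene():
    """Demo geometry at mesh resolution 2 (structure-faithful, ~1500 tris)."""
    return make_joint_scene(replace(SocketSpec(), mesh_resolution=2),
                            replace(FemurSpec(), mesh_resolution=2))


@pytest.fixture(scope="session")
def coarse_socket(coarse_specs):
    return make_socket(coarse_specs[0])


@pytest.fixture(scope="session")
def coarse_femur(coarse_specs):
    return make_femur(coarse_specs[1])


@pytest.fixture()
def rng():
    return np.random.default_rng(20261002)
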