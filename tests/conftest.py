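"""Shared fixtures.

Heavy end-to-end runs (full simulation + model) are session-scoped and
shared between the analysis tests and the acceptance suite; cheap scene
tests use a coarse 5-degree lattice so renders stay small.
"""

import numpy as np
import pytest

import emdflow as ef
from emdflow.depth import estimate_depth_map
from emdflow.pipeline import TRACK_CENTER_INDEX, default_scene_spec, \
    depth_analysis_stack
from emdflow.scenes import build_scene, ground_truth_feature_maps, \
    make_trajectory

FIXTURE_SEED = 0


@pytest.fixture(scope="session")
def lattice():
    return ef.PhotoreceptorLattice()


@pytest.fixture(scope="session")
def coarse_lattice():
    """5-degree lattice (72 x 22) for cheap rendering tests."""
    return ef.PhotoreceptorLattice(spacing=5.0, elevation_min=-55.0,
                                   elevation_max=50.0)


@pytest.fixture(scope="session")
def fixture_scene():
    return build_scene(default_scene_spec(FIXTURE_SEED))


@pytest.fixture(scope="session")
def full_depth_run():
    return ef.run_condition(FIXTURE_SEED, "full_depth")


@pytest.fixture(scope="session")
def de1_run():
    return ef.run_condition(FIXTURE_SEED, "de_1m")


@pytest.fixture(scope="session")
def rotation_run():
    return ef.run_condition(FIXTURE_SEED, "rotation")


@pytest.fixture(scope="session")
def depth_estimation(lattice, fixture_scene):
    """Motion-parallax depth estimate at the track center + ground truth."""
    spec = default_scene_spec(FIXTURE_SEED)
    traj = make_trajectory("straight")
    c = TRACK_CENTER_INDEX
    stack, el, az = depth_analysis_stack(fixture_scene, traj.poses[c - 2: c + 3])
    est = estimate_depth_map(stack, el, az, lattice,
                             depth_cap_cm=fixture_scene.backdrop_radius * 200.0)
    gt_depth, gt_near = ground_truth_feature_maps(fixture_scene, traj.poses[c],
                                                  lattice)
    return {"est": est, "gt_depth": gt_depth, "gt_nearness": gt_near,
            "spec": spec, "el": el, "az": az}
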