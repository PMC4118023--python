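"""Scene simulator: geometry, textures, trajectories, depth equalization."""

import numpy as np
import pytest

import emdflow as ef
from emdflow.pipeline import default_scene_spec
from emdflow.scenes import CylinderSpec, GroundPlane, Cylinder, SceneSpec, \
    TextureParams

CYL_TEX = TextureParams(corr_length=0.05, rms_contrast=0.35)


# --------------------------------------------------------------------------
# trajectories
# --------------------------------------------------------------------------

def test_straight_track_matches_study_conditions():
    """1 m path of 10 mm steps at 1 m/s: 100 poses, 10 ms apart."""
    traj = ef.make_trajectory("straight")
    assert len(traj) == 100
    xs = np.array([p.position[0] for p in traj.poses])
    ts = np.array([p.timestamp for p in traj.poses])
    assert xs[0] == 0.0 and np.isclose(xs[-1], 0.99)
    assert np.allclose(np.diff(xs), 0.010)
    assert np.allclose(np.diff(ts), 10.0)
    assert all(label == "translation" for label in traj.phase_labels)
    assert len({p.yaw for p in traj.poses}) == 1  # constant yaw while translating


def test_saccade_total_amplitude_and_smooth_endpoints():
    traj = ef.make_trajectory("saccade", amplitude=180.0, duration_ms=70.0)
    yaw = np.array([p.yaw for p in traj.poses])
    assert np.isclose(yaw[-1] - yaw[0], 180.0)
    vel = np.diff(yaw)
    # raised-cosine profile: vanishing angular velocity at both ends
    assert vel[0] < 0.1 and vel[-1] < 0.1
    assert vel.max() > 180.0 / 70.0  # peaks above the mean rate


def test_zero_duration_saccade_rejected():
    with pytest.raises(ValueError):
        ef.make_trajectory("saccade", duration_ms=0.0)
    with pytest.raises(ValueError):
        ef.make_trajectory("straight", step_mm=0.0)


def test_loop_phase_sequence():
    traj = ef.make_trajectory("loop")
    phases = [traj.phase_labels[0]]
    for lab in traj.phase_labels[1:]:
        if lab != phases[-1]:
            phases.append(lab)
    assert phases == ["saccade", "translation", "saccade", "translation"]
    ts = np.array([p.timestamp for p in traj.poses])
    assert np.all(np.diff(ts) > 0)


# --------------------------------------------------------------------------
# scene construction and determinism
# --------------------------------------------------------------------------

def test_identical_seed_identical_scene(coarse_lattice):
    spec = default_scene_spec(3, n_objects=2)
    el, az = coarse_lattice.supersampled_grid(3)
    panos = [ef.render_panorama(ef.build_scene(spec), ef.Pose((0, 0, 0.5)), el, az)
             for _ in range(2)]
    assert np.array_equal(panos[0].brightness, panos[1].brightness)
    assert np.array_equal(panos[0].depth_cm, panos[1].depth_cm)


def test_empty_clutter_scene_is_ground_plus_backdrop(coarse_lattice):
    scene = ef.build_scene(SceneSpec(rng_seed=1))
    el, az = coarse_lattice.supersampled_grid(3)
    pano = ef.render_panorama(scene, ef.Pose((0, 0, 0.5)), el, az)
    # above the horizon everything is backdrop, below it ground
    assert np.allclose(pano.depth_cm[el > 1.0], 100.0 * 100.0, rtol=0.01)
    # ground-plane law: depth = h / sin(|el|) below the horizon
    rows = np.nonzero(el < -5.0)[0]
    expected = 0.5 / np.sin(np.deg2rad(np.abs(el[rows])))
    got = pano.depth_cm[rows] / 100.0
    assert np.allclose(got, expected[:, None], rtol=0.01)


def test_backdrop_must_enclose_objects():
    with pytest.raises(ValueError):
        SceneSpec(rng_seed=0, backdrop_radius=2.0,
                  objects=(CylinderSpec(3.0, 0.0, 0.2, 2.0, CYL_TEX),))


def test_cylinder_analytic_distance(coarse_lattice):
    """Cylinder at (1 m, 0) with r = 0.2 m: nearest surface at 0.8 m."""
    spec = SceneSpec(rng_seed=0,
                     objects=(CylinderSpec(1.0, 0.0, 0.2, 2.0, CYL_TEX),))
    scene = ef.build_scene(spec)
    el, az = coarse_lattice.supersampled_grid(3)
    pano = ef.render_panorama(scene, ef.Pose((0, 0, 0.5)), el, az)
    i = int(np.argmin(np.abs(el)))       # horizontal ray
    assert np.isclose(pano.depth_cm[i, 0], 80.0, rtol=1e-3)


def _ray_march_depth(scene, origin, d, t_max=120.0):
    """Brute-force reference: march along the ray, bisect the first hit."""
    def occupied(p):
        for g in scene.geoms:
            if isinstance(g, Cylinder):
                if (np.hypot(p[0] - g.x, p[1] - g.y) <= g.radius
                        and g.z0 <= p[2] <= g.z0 + g.height):
                    return True
            elif isinstance(g, GroundPlane):
                if p[2] <= g.height:
                    return True
            else:  # backdrop sphere
                if np.linalg.norm(p - g.center) >= g.radius:
                    return True
        return False
    step = 2e-3
    t = step
    while t < t_max:
        if occupied(origin + t * d):
            lo, hi = t - step, t
            for _ in range(40):
                mid = 0.5 * (lo + hi)
                (lo, hi) = (lo, mid) if occupied(origin + mid * d) else (mid, hi)
            return 0.5 * (lo + hi)
        t += step
        if t > 6.0:
            step = 0.1
    return np.nan


def test_renderer_depth_agrees_with_ray_marcher():
    """Analytic intersections vs a brute-force marcher on random rays."""
    scene = ef.build_scene(default_scene_spec(5, n_objects=4))
    rng = np.random.default_rng(11)
    origin = np.array([0.3, 0.1, 0.5])
    n_checked = 0
    while n_checked < 100:
        v = rng.standard_normal(3)
        v /= np.linalg.norm(v)
        t_true = _ray_march_depth(scene, origin, v)
        t_fast, _ = scene.trace(origin, v[None, :])
        assert np.isfinite(t_fast[0])
        assert abs(t_fast[0] - t_true) / t_true < 0.005
        n_checked += 1


def test_azimuth_wrap_yaw_360(coarse_lattice, fixture_scene):
    el, az = coarse_lattice.supersampled_grid(3)
    p1 = ef.render_panorama(fixture_scene, ef.Pose((0, 0, 0.5), yaw=30.0), el, az)
    p2 = ef.render_panorama(fixture_scene, ef.Pose((0, 0, 0.5), yaw=390.0), el, az)
    assert np.allclose(p1.brightness, p2.brightness, rtol=1e-10)


def test_invalid_poses_rejected(fixture_scene, coarse_lattice):
    el, az = coarse_lattice.supersampled_grid(3)
    with pytest.raises(ValueError):
        ef.render_panorama(fixture_scene, ef.Pose((0, 0, -0.1)), el, az)
    spec = default_scene_spec(0)
    ob = spec.objects[0]
    inside = ef.Pose((ob.x, ob.y, 0.5))
    with pytest.raises(ValueError):
        ef.render_panorama(fixture_scene, inside, el, az)


def test_uniform_texture_gives_constant_frame(coarse_lattice):
    flat = TextureParams(corr_length=0.2, rms_contrast=0.0)
    spec = SceneSpec(rng_seed=0, ground_texture=flat, backdrop_texture=flat)
    scene = ef.build_scene(spec)
    el, az = coarse_lattice.supersampled_grid(3)
    pano = ef.render_panorama(scene, ef.Pose((0, 0, 0.5)), el, az)
    assert np.allclose(pano.brightness, 1.0)


# --------------------------------------------------------------------------
# depth equalization
# --------------------------------------------------------------------------

def test_depth_equalized_center_reproduces_source(coarse_lattice, fixture_scene):
    el, az = coarse_lattice.supersampled_grid(3)
    center = ef.Pose((0.495, 0.0, 0.5))
    src = ef.render_panorama(fixture_scene, center, el, az)
    de = ef.depth_equalize(fixture_scene, center, 1.0,
                           res_deg=coarse_lattice.spacing / 3)
    rep = ef.render_panorama(de, center, el, az)
    rel = np.abs(rep.brightness - src.brightness) / src.brightness.mean()
    assert np.median(rel) < 0.01
    assert np.allclose(rep.depth_cm, 100.0, rtol=1e-6)


def test_depth_equalized_camera_bounds(coarse_lattice, fixture_scene):
    center = ef.Pose((0.495, 0.0, 0.5))
    de = ef.depth_equalize(fixture_scene, center, 0.5,
                           res_deg=coarse_lattice.spacing / 3)
    el, az = coarse_lattice.supersampled_grid(3)
    # displaced but still inside: valid render, however distorted
    inside = ef.Pose((0.495 + 0.49, 0.0, 0.5))
    pano = ef.render_panorama(de, inside, el, az)
    assert np.all(pano.brightness >= 0)
    with pytest.raises(ValueError):
        ef.render_panorama(de, ef.Pose((0.495 + 0.6, 0.0, 0.5)), el, az)


# --------------------------------------------------------------------------
# ground-truth feature maps
# --------------------------------------------------------------------------

def test_sphere_scene_nearness_constant(coarse_lattice, fixture_scene):
    center = ef.Pose((0.495, 0.0, 0.5))
    de = ef.depth_equalize(fixture_scene, center, 2.0,
                           res_deg=coarse_lattice.spacing / 3)
    depth, near = ef.ground_truth_feature_maps(de, center, coarse_lattice,
                                               factor=3)
    assert np.allclose(near, 0.005, rtol=1e-6)


def test_ground_truth_maps_positive_and_ordered(coarse_lattice, fixture_scene):
    center = ef.Pose((0.495, 0.0, 0.5))
    depth, near = ef.ground_truth_feature_maps(fixture_scene, center,
                                               coarse_lattice, factor=3)
    assert np.all(depth > 0)
    # the dominant trunk at azimuth 90 deg is nearer than the backdrop band
    cols = coarse_lattice.azimuths
    row = int(np.argmin(np.abs(coarse_lattice.elevations - 10.0)))
    trunk = near[row, int(np.argmin(np.abs(cols - 90.0)))]
    backdrop = near[row, int(np.argmin(np.abs(cols - 270.0)))]
    assert trunk > backdrop
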