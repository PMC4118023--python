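"""Depth-from-parallax: flow, geometry, triangulation, correction."""

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

import emdflow as ef
from emdflow.depth import DepthCorrectionParams, LKParams, correct_depth, \
    fit_depth_correction, finalize_depth, geometric_flow, lucas_kanade, \
    median_filter_invalid_aware, project_and_triangulate
from emdflow.panorama import equirect_grid


# --------------------------------------------------------------------------
# quadratic depth correction
# --------------------------------------------------------------------------

def test_correction_fixes_origin():
    assert correct_depth(np.array([0.0]))[0] == pytest.approx(0.0)


def test_correction_inverts_forward_model_exactly():
    p = DepthCorrectionParams()
    true = np.logspace(1, 4, 200)                     # 10 cm .. 100 m
    measured = p.p1 * true ** 2 + p.p2 * true
    back = correct_depth(measured, p)
    assert np.max(np.abs(back - true) / true) < 1e-9


def test_correction_known_point():
    # forward model at 100 cm: 2.778e-3 * 1e4 + 0.456 * 100 = 73.38 cm
    assert correct_depth(np.array([73.38]))[0] == pytest.approx(100.0, abs=1e-6)


def test_correction_monotone_and_invalid_for_negative():
    d = correct_depth(np.linspace(0, 500, 100))
    assert np.all(np.diff(d) > 0)
    assert np.isnan(correct_depth(np.array([-1.0]))[0])


def test_fit_recovers_planted_parameters():
    rng = np.random.default_rng(0)
    true = rng.uniform(30, 3000, 500)
    planted = DepthCorrectionParams(p1=4e-3, p2=0.61)
    measured = planted.p1 * true ** 2 + planted.p2 * true
    fit = fit_depth_correction(measured, true)
    assert np.isclose(fit.p1, planted.p1, rtol=1e-9)
    assert np.isclose(fit.p2, planted.p2, rtol=1e-9)


# --------------------------------------------------------------------------
# Lucas-Kanade
# --------------------------------------------------------------------------

def _smooth_texture(shape, seed=0, sigma=2.0):
    rng = np.random.default_rng(seed)
    img = gaussian_filter(rng.random(shape), sigma, mode="wrap")
    img -= img.min()
    return img / img.max()


def test_static_sequence_has_zero_flow():
    img = _smooth_texture((60, 120))
    stack = np.repeat(img[None], 5, axis=0)
    flow, valid = lucas_kanade(stack, LKParams(n_cols=120, n_rows=60))
    assert valid.mean() > 0.5
    assert np.nanmax(np.abs(flow[valid])) < 1e-6


def test_rigid_shift_recovered():
    img = _smooth_texture((60, 120), seed=1)
    stack = np.stack([np.roll(img, k, axis=1) for k in range(5)])
    flow, valid = lucas_kanade(stack, LKParams(n_cols=120, n_rows=60))
    interior = valid.copy()
    interior[:5] = interior[-5:] = False
    mean_flow = np.nanmean(flow[interior], axis=0)
    assert abs(mean_flow[0] - 1.0) < 0.1
    assert abs(mean_flow[1]) < 0.1


def test_textureless_region_is_invalid():
    img = _smooth_texture((60, 120), seed=2)
    img[20:40, 40:80] = 0.5                            # flat patch
    stack = np.stack([np.roll(img, k, axis=1) for k in range(5)])
    _, valid = lucas_kanade(stack, LKParams(n_cols=120, n_rows=60))
    assert valid[28:32, 55:65].mean() < 0.1


def test_too_few_frames_rejected():
    with pytest.raises(ValueError):
        lucas_kanade(np.zeros((3, 10, 10)), LKParams())


# --------------------------------------------------------------------------
# flow geometry
# --------------------------------------------------------------------------

def test_geometric_flow_singularities_and_lateral_direction():
    el, az = equirect_grid(360, 121, el_max=60.0, el_min=-60.0)
    unit, sin_theta = geometric_flow(el, az, np.array([1.0, 0.0, 0.0]))
    r0 = int(np.argmin(np.abs(el)))
    # FOE at azimuth 0 on the horizon: no flow
    assert sin_theta[r0, 0] < 1e-6
    assert np.allclose(unit[r0, 0], 0.0)
    # lateral view: full-speed flow pointing opposite to self-motion (+az)
    c90 = int(np.argmin(np.abs(az - 90.0)))
    assert sin_theta[r0, c90] == pytest.approx(1.0, abs=1e-6)
    assert unit[r0, c90, 0] == pytest.approx(1.0, abs=1e-6)


def test_flow_magnitude_symmetric_about_heading_axis():
    el, az = equirect_grid(360, 121, el_max=60.0, el_min=-60.0)
    _, sin_theta = geometric_flow(el, az, np.array([1.0, 0.0, 0.0]))
    mirrored = np.roll(sin_theta[:, ::-1], 1, axis=1)  # az -> -az
    assert np.allclose(sin_theta, mirrored, atol=1e-12)
    assert np.allclose(sin_theta, sin_theta[::-1], atol=1e-9)  # el -> -el


def test_geometric_flow_requires_unit_heading():
    el, az = equirect_grid(36, 13, el_max=30.0, el_min=-30.0)
    with pytest.raises(ValueError):
        geometric_flow(el, az, np.array([2.0, 0.0, 0.0]))


# --------------------------------------------------------------------------
# triangulation
# --------------------------------------------------------------------------

def _lateral_setup():
    el, az = equirect_grid(360, 121, el_max=60.0, el_min=-60.0)
    unit, sin_theta = geometric_flow(el, az, np.array([1.0, 0.0, 0.0]))
    return el, az, unit, sin_theta


def test_lateral_triangulation_example():
    """theta = 90 deg, baseline 1 cm, 0.01 rad displacement -> 100 cm."""
    el, az, unit, sin_theta = _lateral_setup()
    rad_per_col = np.deg2rad(az[1] - az[0])
    flow = np.zeros(sin_theta.shape + (2,))
    r0, c90 = int(np.argmin(np.abs(el))), int(np.argmin(np.abs(az - 90.0)))
    flow[r0, c90, 0] = 0.01 / rad_per_col              # pure azimuthal flow
    depth = project_and_triangulate(flow, unit, sin_theta, el, az, 1.0)
    assert depth[r0, c90] == pytest.approx(100.0, rel=1e-6)


def _angular_to_pixel(dphi, el, az):
    """Convert a tangent-plane angular flow field (rad) to pixel flow."""
    cos_el = np.cos(np.deg2rad(el))[:, None]
    rad_col = np.deg2rad(az[1] - az[0]) * cos_el
    rad_row = np.deg2rad(el[0] - el[1])
    return np.stack([dphi[..., 0] / rad_col, -dphi[..., 1] / rad_row], axis=-1)


def test_reversed_flow_is_invalid_everywhere():
    """Displacement against the expansion geometry carries no depth."""
    el, az, unit, sin_theta = _lateral_setup()
    flow = _angular_to_pixel(-0.005 * unit, el, az)
    depth = project_and_triangulate(flow, unit, sin_theta, el, az, 1.0)
    assert np.all(np.isnan(depth))


def test_orthogonal_flow_noise_leaves_depth_unchanged():
    el, az, unit, sin_theta = _lateral_setup()
    rng = np.random.default_rng(3)
    d0 = project_and_triangulate(_angular_to_pixel(0.005 * unit, el, az),
                                 unit, sin_theta, el, az, 1.0)
    orth = np.stack([-unit[..., 1], unit[..., 0]], axis=-1)
    noise = rng.standard_normal(sin_theta.shape)[..., None] * 0.01
    noisy = _angular_to_pixel(0.005 * unit + noise * orth, el, az)
    d1 = project_and_triangulate(noisy, unit, sin_theta, el, az, 1.0)
    ok = np.isfinite(d0)
    assert np.allclose(d0[ok], d1[ok], rtol=1e-6)


# --------------------------------------------------------------------------
# finalization
# --------------------------------------------------------------------------

def test_median_filter_removes_single_outlier():
    img = np.full((20, 30), 100.0)
    img[10, 15] = 1e6
    out = median_filter_invalid_aware(img)
    assert np.allclose(out, 100.0)


def test_median_filter_drops_sparse_pixels():
    img = np.full((10, 10), np.nan)
    img[5, 5] = 100.0                                  # lone valid pixel
    out = median_filter_invalid_aware(img)
    assert np.all(np.isnan(out))


def test_finalize_constant_map(lattice):
    el, az = equirect_grid(927, 251)
    depth, nearness = finalize_depth(np.full((251, 927), 150.0), el, az, lattice)
    assert np.allclose(depth[np.isfinite(depth)], 150.0)
    assert np.allclose(nearness[np.isfinite(nearness)], 1.0 / 150.0)
    with pytest.raises(ValueError):
        finalize_depth(np.full((251, 927), np.nan), el, az, lattice)


# --------------------------------------------------------------------------
# end-to-end on the fixture
# --------------------------------------------------------------------------

def test_foe_foc_regions_mostly_invalid(depth_estimation):
    """Flow singularities leave no parallax: validity collapses there.

    Compared over the textured ground band, where distance is finite in
    every direction, so invalidity reflects the flow geometry rather
    than the unmeasurable parallax of the distant backdrop.
    """
    raw = depth_estimation["est"]["raw_depth"]
    el, az = depth_estimation["el"], depth_estimation["az"]
    _, sin_theta = geometric_flow(el, az, np.array([1.0, 0.0, 0.0]))
    band = ((el < -5.0) & (el > -20.0))[:, None] & np.ones_like(sin_theta, bool)
    near_foci = (sin_theta < np.sin(np.deg2rad(10.0))) & band
    lateral = (sin_theta > np.sin(np.deg2rad(60.0))) & band
    inv_foci = np.isnan(raw[near_foci]).mean()
    inv_lateral = np.isnan(raw[lateral]).mean()
    assert inv_foci >= 2 * inv_lateral


def test_estimated_nearness_tracks_ground_truth(depth_estimation):
    est = depth_estimation["est"]["nearness"]
    gt = depth_estimation["gt_nearness"]
    ok = np.isfinite(est)
    assert ok.mean() > 0.5
    r = np.corrcoef(est[ok], gt[ok])[0, 1]
    assert r > 0.8
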