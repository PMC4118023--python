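"""Depth and nearness estimation from translational motion parallax.

Pipeline (per intersaccadic frame): Lucas-Kanade optical flow on the
high-resolution equirectangular sequence; projection of the measured
flow onto the geometrically correct pure-translation flow direction;
small-angle triangulation against the known per-frame baseline; an
empirical quadratic depth correction; invalid-aware median smoothing;
and Gaussian-acceptance downsampling to receptor resolution, where
nearness is the reciprocal of depth (1/cm).

Invalidity is data, not an error: pixels fail the structure-tensor
eigenvalue test, sit near the flow-field singularities (FOE/FOC), have
non-positive projected displacement, or exceed the depth cap; they are
carried as NaN with a boolean validity mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d, generic_filter, uniform_filter, map_coordinates

from .optics import LOG2x4, PhotoreceptorLattice
from .panorama import directions_from_angles, tangent_basis


@dataclass(frozen=True)
class LKParams:
    """Lucas-Kanade smoothing and validity parameters.

    The eigenvalue threshold applies to the smaller eigenvalue of the
    5x5-window structure tensor of brightness normalized to [0, 1]; the
    sigmas parameterize Gaussian pre-smoothing in space (pixels) and
    time (frames) over an odd temporal support.
    """

    spatial_sigma: float = 0.2       # px
    temporal_sigma: float = 1.5      # frames
    temporal_support: int = 5        # frames, odd
    eig_threshold: float = 0.0039
    window: int = 5                  # px, least-squares window
    n_cols: int = 927                # analysis resolution
    n_rows: int = 251

    def __post_init__(self) -> None:
        if self.temporal_support % 2 == 0 or self.temporal_support < 3:
            raise ValueError("temporal support must be odd and >= 3")
        if min(self.spatial_sigma, self.temporal_sigma, self.eig_threshold) <= 0:
            raise ValueError("smoothing and threshold parameters must be positive")


@dataclass(frozen=True)
class DepthCorrectionParams:
    """Quadratic error-model parameters: D = p1*Dc**2 + p2*Dc."""

    p1: float = 2.778e-3   # 1/cm
    p2: float = 0.456      # dimensionless

    def __post_init__(self) -> None:
        if self.p1 <= 0 or self.p2 <= 0:
            raise ValueError("correction parameters must be positive")


def lucas_kanade(stack: np.ndarray, params: LKParams | None = None
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel optical flow at the central frame of a short stack.

    ``stack`` is (T, H, W) brightness normalized to [0, 1] with
    T >= temporal_support; azimuth (columns) wraps.  Returns
    (flow, valid): flow is (H, W, 2) in pixels/frame, components
    (d_col, d_row); pixels whose smaller structure-tensor eigenvalue
    falls below the noise threshold are invalid (NaN flow).
    """
    if params is None:
        params = LKParams()
    stack = np.asarray(stack, dtype=np.float64)
    if stack.ndim != 3 or stack.shape[0] < params.temporal_support:
        raise ValueError("need at least temporal_support frames")
    mid = stack.shape[0] // 2
    half = params.temporal_support // 2
    sub = stack[mid - half: mid + half + 1]
    # spatio-temporal Gaussian pre-smoothing; columns wrap, rows clamp
    sm = gaussian_filter1d(sub, params.spatial_sigma, axis=2, mode="wrap")
    sm = gaussian_filter1d(sm, params.spatial_sigma, axis=1, mode="nearest")
    sm = gaussian_filter1d(sm, params.temporal_sigma, axis=0, mode="nearest")
    c = half
    ix = (np.roll(sm[c], -1, axis=1) - np.roll(sm[c], 1, axis=1)) / 2.0
    iy = np.empty_like(sm[c])
    iy[1:-1] = (sm[c][2:] - sm[c][:-2]) / 2.0
    iy[0] = sm[c][1] - sm[c][0]
    iy[-1] = sm[c][-1] - sm[c][-2]
    it = (sm[c + 1] - sm[c - 1]) / 2.0

    def wsum(img):
        return uniform_filter(img, size=params.window,
                              mode=("nearest", "wrap")) * params.window ** 2

    sxx, syy, sxy = wsum(ix * ix), wsum(iy * iy), wsum(ix * iy)
    sxt, syt = wsum(ix * it), wsum(iy * it)
    trace = sxx + syy
    det = sxx * syy - sxy * sxy
    disc = np.sqrt(np.maximum((trace / 2) ** 2 - det, 0.0))
    lam_min = trace / 2 - disc
    valid = lam_min >= params.eig_threshold
    with np.errstate(divide="ignore", invalid="ignore"):
        u = (-sxt * syy + syt * sxy) / det
        v = (-syt * sxx + sxt * sxy) / det
    flow = np.stack([u, v], axis=-1)
    flow[~valid] = np.nan
    flow[~np.isfinite(flow).all(axis=-1)] = np.nan
    valid &= np.isfinite(flow).all(axis=-1)
    return flow, valid


def geometric_flow(el_deg: np.ndarray, az_deg: np.ndarray,
                   heading: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pure-translation flow geometry on the viewing sphere.

    For forward self-motion along the unit vector ``heading`` (camera
    frame), the image of a feature in viewing direction d drifts along
    the tangent direction of -heading projected on the local tangent
    plane, with angular speed proportional to sin(theta), theta the
    angle between d and the heading.  Returns (unit_dir, sin_theta):
    unit_dir is (H, W, 2) in the local (e_az, e_el) tangent basis, the
    zero vector at the FOE and FOC where sin_theta = 0.
    """
    t = np.asarray(heading, dtype=np.float64)
    if abs(np.linalg.norm(t) - 1.0) > 1e-9:
        raise ValueError("heading must be a unit vector")
    d = directions_from_angles(el_deg, az_deg)
    e_az, e_el = tangent_basis(el_deg, az_deg)
    td = d @ t
    perp = -(t[None, None, :] - td[..., None] * d)   # tangent component of -t
    comp_az = np.einsum("hwc,hwc->hw", perp, e_az)
    comp_el = np.einsum("hwc,hwc->hw", perp, e_el)
    sin_theta = np.hypot(comp_az, comp_el)
    with np.errstate(divide="ignore", invalid="ignore"):
        unit = np.stack([comp_az / sin_theta, comp_el / sin_theta], axis=-1)
    unit[sin_theta < 1e-12] = 0.0
    return unit, sin_theta


def project_and_triangulate(flow: np.ndarray, unit_dir: np.ndarray,
                            sin_theta: np.ndarray,
                            el_deg: np.ndarray, az_deg: np.ndarray,
                            baseline_cm: float = 1.0,
                            depth_cap_cm: float | None = None) -> np.ndarray:
    """Depth (cm) from flow projected on the geometric flow direction.

    Pixel flow (d_col, d_row) is converted to local angular displacement
    (azimuth foreshortened by cos(el); row index runs against
    elevation), projected onto the geometric unit direction, and
    triangulated: D = baseline * sin(theta) / delta_phi.  Non-positive
    or near-singular projections, and depths beyond ``depth_cap_cm``,
    come out NaN.
    """
    if baseline_cm <= 0:
        raise ValueError("baseline must be positive")
    el = np.asarray(el_deg, float)
    az = np.asarray(az_deg, float)
    rad_per_col = np.deg2rad(az[1] - az[0])
    rad_per_row = np.deg2rad(el[0] - el[1])          # rows descend in elevation
    cos_el = np.cos(np.deg2rad(el))[:, None]
    dphi_az = flow[..., 0] * rad_per_col * cos_el
    dphi_el = -flow[..., 1] * rad_per_row            # +row displacement = downward
    dphi = dphi_az * unit_dir[..., 0] + dphi_el * unit_dir[..., 1]
    with np.errstate(divide="ignore", invalid="ignore"):
        depth = baseline_cm * sin_theta / dphi
    depth = np.where(dphi > 1e-12, depth, np.nan)
    if depth_cap_cm is not None:
        depth = np.where(depth <= depth_cap_cm, depth, np.nan)
    return depth


def correct_depth(depth_cm: np.ndarray,
                  params: DepthCorrectionParams | None = None) -> np.ndarray:
    """Invert the quadratic systematic-error model of the raw estimate.

    Solves D = p1*Dc**2 + p2*Dc for Dc:

        Dc = -p2/(2 p1) + sqrt((p2/(2 p1))**2 + D/p1)

    strictly increasing in D with Dc(0) = 0; negative inputs map to NaN.
    """
    if params is None:
        params = DepthCorrectionParams()
    d = np.asarray(depth_cm, dtype=np.float64)
    k = params.p2 / (2.0 * params.p1)
    with np.errstate(invalid="ignore"):
        out = -k + np.sqrt(k * k + d / params.p1)
    return np.where(d >= 0, out, np.nan)


def fit_depth_correction(measured_cm: np.ndarray, true_cm: np.ndarray
                         ) -> DepthCorrectionParams:
    """Calibrate p1, p2 by least squares on a known-depth synthetic movie.

    Fits the forward model measured = p1*true**2 + p2*true over finite
    pairs (the same procedure that produced the default parameters on a
    rendered calibration sequence).
    """
    m = np.ravel(measured_cm)
    t = np.ravel(true_cm)
    ok = np.isfinite(m) & np.isfinite(t) & (t > 0)
    if ok.sum() < 2:
        raise ValueError("need at least two valid (measured, true) pairs")
    A = np.column_stack([t[ok] ** 2, t[ok]])
    p, *_ = np.linalg.lstsq(A, m[ok], rcond=None)
    return DepthCorrectionParams(p1=float(p[0]), p2=float(p[1]))


def median_filter_invalid_aware(img: np.ndarray, min_valid: int = 3) -> np.ndarray:
    """3x3 median over valid neighbors; pixels with < min_valid dropped."""
    def med(win):
        w = win[np.isfinite(win)]
        return np.median(w) if w.size >= min_valid else np.nan
    padded = np.pad(img, ((0, 0), (1, 1)), mode="wrap")
    out = generic_filter(padded, med, size=3, mode="constant", cval=np.nan)
    return out[:, 1:-1]


def _ordered_grid_downsample(img: np.ndarray, el_deg: np.ndarray,
                             az_deg: np.ndarray, lattice: PhotoreceptorLattice,
                             grid: int = 10) -> np.ndarray:
    """Gaussian-acceptance aggregation via a grid x grid ordered sample.

    For each receptor, an ordered grid of directions spanning the
    truncated acceptance window (+-2 acceptance angles, azimuth
    foreshortened) samples the source image (nearest pixel); samples are
    combined with acceptance weights, ignoring invalid (NaN) samples.
    """
    rho = lattice.acceptance_angle
    off = np.linspace(-2 * rho, 2 * rho, grid)
    d_el, d_az = np.meshgrid(off, off, indexing="ij")
    w = np.exp(-LOG2x4 * (d_el ** 2 + d_az ** 2) / rho ** 2).ravel()
    el0 = el_deg[0]
    del_px = el_deg[0] - el_deg[1]
    daz_px = az_deg[1] - az_deg[0]
    n_rows, n_cols = lattice.n_rows, lattice.n_cols
    rec_el = lattice.elevations[:, None, None]
    rec_az = lattice.azimuths[None, :, None]
    cos_el = np.maximum(np.cos(np.deg2rad(lattice.elevations)), 1e-6)[:, None, None]
    el_s = rec_el + d_el.ravel()[None, None, :]
    az_s = rec_az + d_az.ravel()[None, None, :] / cos_el
    rows = np.clip(np.round((el0 - el_s) / del_px), 0, img.shape[0] - 1)
    cols = np.round(az_s / daz_px) % img.shape[1]
    samples = img[rows.astype(int), cols.astype(int)]   # (R, C, grid**2)
    wv = np.where(np.isfinite(samples), w[None, None, :], 0.0)
    num = np.nansum(samples * wv, axis=-1)
    den = wv.sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    out[den < 0.25 * w.sum()] = np.nan   # window mostly invalid
    return out


def finalize_depth(depth_cm: np.ndarray, el_deg: np.ndarray, az_deg: np.ndarray,
                   lattice: PhotoreceptorLattice
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Receptor-resolution depth and nearness from a corrected depth map.

    Applies the invalid-aware 3x3 median, the 10x10 ordered-grid
    Gaussian-acceptance downsampling to the photoreceptor lattice, and
    takes the reciprocal for nearness.
    """
    if not np.any(np.isfinite(depth_cm)):
        raise ValueError("no valid depth pixels to finalize")
    sm = median_filter_invalid_aware(depth_cm)
    depth = _ordered_grid_downsample(sm, el_deg, az_deg, lattice)
    with np.errstate(invalid="ignore", divide="ignore"):
        nearness = 1.0 / depth
    return depth, nearness


def estimate_depth_map(stack: np.ndarray, el_deg: np.ndarray, az_deg: np.ndarray,
                       lattice: PhotoreceptorLattice,
                       heading: np.ndarray = (1.0, 0.0, 0.0),
                       baseline_cm: float = 1.0,
                       lk_params: LKParams | None = None,
                       correction: DepthCorrectionParams | None = None,
                       depth_cap_cm: float | None = None
                       ) -> dict[str, np.ndarray]:
    """Full pipeline: flow -> projection -> triangulation -> correction
    -> receptor-resolution depth and nearness maps.

    ``stack`` is a short high-resolution brightness sequence (odd length
    >= the temporal support, centered on the frame of interest) in
    arbitrary linear units; it is normalized to [0, 1] internally.
    """
    stack = np.asarray(stack, dtype=np.float64)
    stack = stack / stack.max()
    flow, _ = lucas_kanade(stack, lk_params)
    unit, sin_theta = geometric_flow(el_deg, az_deg, np.asarray(heading, float))
    raw = project_and_triangulate(flow, unit, sin_theta, el_deg, az_deg,
                                  baseline_cm, depth_cap_cm)
    corrected = correct_depth(raw, correction)
    depth, nearness = finalize_depth(corrected, el_deg, az_deg, lattice)
    return {"flow": flow, "raw_depth": raw, "corrected_depth": corrected,
            "depth": depth, "nearness": nearness}
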