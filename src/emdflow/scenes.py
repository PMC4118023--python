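"""Procedural 3-D scenes with ground-truth depth, and simulated trajectories.

Scenes emulate cluttered outdoor environments: textured vertical
cylinders ("tree trunks") standing on a textured ground plane, enclosed
by a distant textured backdrop sphere.  A panoramic camera moves along
straight tracks (10 mm steps on a 1 m path, 0.5 m above ground) and
performs rapid saccade-like yaw turns.  Depth-equalized variants project
a single panorama onto a sphere of configurable radius so that every
viewing direction shares one distance.

World frame: z up, ground plane at z = ground_height, camera 0.5 m above
it by default.  Azimuth is measured counter-clockwise from the camera
heading; elevation is positive above the horizon.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates

from .optics import PhotoreceptorLattice, acceptance_downsample
from .panorama import HighResPanorama, directions_from_angles

M_TO_CM = 100.0
_EPS_T = 1e-6  # minimum ray parameter (m) accepted as a hit


# --------------------------------------------------------------------------
# textures
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TextureParams:
    """Band-limited noise texture: correlation length in the units of the
    surface parameterization (meters for ground/cylinders, degrees for
    the backdrop), target RMS contrast, and mean brightness (linear,
    arbitrary units)."""

    corr_length: float
    rms_contrast: float = 0.3
    mean: float = 1.0

    def __post_init__(self) -> None:
        if self.corr_length <= 0 or self.mean <= 0 or self.rms_contrast < 0:
            raise ValueError("texture parameters must be positive")


_FLOOR = 1e-3        # brightness floor as a fraction of the mean
_OUTER_CELLS = 32.0  # grid cells per outer (correlation) scale
_MAX_N = 4096        # cap on grid cells per axis


class NoiseTexture:
    """Periodic 1/f-shaped noise evaluated on a surface parameterization.

    A white-noise grid is spectrally shaped to a natural-image-like 1/f
    amplitude spectrum, flat below the outer scale ``corr_length`` (the
    texture's correlation scale) and scale-free down to the grid
    resolution, then standardized to zero mean and unit variance.
    Lookups are bilinear with wrap-around, so the texture is continuous
    and tiles seamlessly.  ``period_u`` (if given) forces the u-axis
    tile period, which closed surfaces (cylinder angle, backdrop
    azimuth) use to wrap exactly.
    """

    def __init__(self, params: TextureParams, seed, n: int = 512,
                 period_u: float | None = None):
        self.params = params
        rng = np.random.default_rng(seed)
        cell = params.corr_length / _OUTER_CELLS
        if period_u is not None:
            n_u = min(_MAX_N, max(16, int(round(period_u / cell))))
            self.cell_u = period_u / n_u
        else:
            n_u = n
            self.cell_u = cell
        n_v = n
        self.cell_v = cell
        noise = rng.standard_normal((n_u, n_v))
        spec = np.fft.rfft2(noise)
        fu = np.fft.fftfreq(n_u)[:, None]          # cycles per cell
        fv = np.fft.rfftfreq(n_v)[None, :]
        f = np.hypot(fu, fv)
        f0 = 1.0 / _OUTER_CELLS                    # outer-scale cutoff
        amp = 1.0 / np.maximum(f, f0)
        amp[0, 0] = 0.0                            # remove the DC term
        grid = np.fft.irfft2(spec * amp, s=(n_u, n_v))
        grid /= max(grid.std(), 1e-12)
        self._grid = grid

    def sample(self, u: np.ndarray, v: np.ndarray) -> np.ndarray:
        coords = np.vstack([np.ravel(u) / self.cell_u, np.ravel(v) / self.cell_v])
        noise = map_coordinates(self._grid, coords, order=1, mode="grid-wrap")
        p = self.params
        out = p.mean * (1.0 + p.rms_contrast * noise)
        np.maximum(out, _FLOOR * p.mean, out=out)
        return out.reshape(np.shape(u))


# --------------------------------------------------------------------------
# geometry
# --------------------------------------------------------------------------

class Cylinder:
    """Finite vertical cylinder standing on the ground plane (no caps)."""

    def __init__(self, x: float, y: float, radius: float, height: float,
                 texture: NoiseTexture, z0: float = 0.0):
        if radius <= 0 or height <= 0:
            raise ValueError("cylinder radius and height must be positive")
        self.x, self.y, self.radius, self.height, self.z0 = x, y, radius, height, z0
        self.texture = texture

    def contains(self, p: np.ndarray) -> bool:
        dx, dy = p[0] - self.x, p[1] - self.y
        return bool(dx * dx + dy * dy < self.radius ** 2
                    and self.z0 <= p[2] <= self.z0 + self.height)

    def azimuth_window(self, o: np.ndarray) -> tuple[float, float] | None:
        """World-azimuth silhouette (center, half-width), radians.

        Lets the renderer restrict the intersection test to the columns
        that can possibly hit this cylinder; None when the camera is so
        close that the window would span the whole circle.
        """
        dx, dy = self.x - o[0], self.y - o[1]
        d = np.hypot(dx, dy)
        if d <= self.radius * 1.05:
            return None
        half = np.arcsin(min(1.0, self.radius / d)) + 0.01
        return float(np.arctan2(dy, dx)), float(half)

    def intersect(self, o: np.ndarray, d: np.ndarray) -> np.ndarray:
        ox, oy = o[0] - self.x, o[1] - self.y
        dx, dy, dz = d[:, 0], d[:, 1], d[:, 2]
        a = dx * dx + dy * dy
        b = 2.0 * (ox * dx + oy * dy)
        c = ox * ox + oy * oy - self.radius ** 2
        disc = b * b - 4.0 * a * c
        t = np.full(len(d), np.inf)
        ok = (disc > 0) & (a > 1e-30)
        sq = np.sqrt(np.where(ok, disc, 0.0))
        with np.errstate(invalid="ignore"):
            for sign in (-1.0, 1.0):  # near root first; fall back to far root
                tc = np.where(ok, (-b + sign * sq) / (2.0 * a), np.inf)
                z = o[2] + tc * dz
                valid = ok & (tc > _EPS_T) & (z >= self.z0) & (z <= self.z0 + self.height)
                t = np.where(valid & (tc < t), tc, t)
        return t

    def shade(self, o: np.ndarray, d: np.ndarray, t: np.ndarray) -> np.ndarray:
        p = o[None, :] + t[:, None] * d
        ang = np.arctan2(p[:, 1] - self.y, p[:, 0] - self.x)
        return self.texture.sample(ang * self.radius, p[:, 2])


class GroundPlane:
    """Horizontal textured plane at z = height."""

    def __init__(self, height: float, texture: NoiseTexture):
        self.height = height
        self.texture = texture

    def intersect(self, o: np.ndarray, d: np.ndarray) -> np.ndarray:
        dz = d[:, 2]
        with np.errstate(divide="ignore", invalid="ignore"):
            t = (self.height - o[2]) / dz
        t = np.where((dz < 0) & (t > _EPS_T), t, np.inf)
        return t

    def shade(self, o: np.ndarray, d: np.ndarray, t: np.ndarray) -> np.ndarray:
        p = o[None, :] + t[:, None] * d
        return self.texture.sample(p[:, 0], p[:, 1])


class BackdropSphere:
    """Distant enclosing sphere textured in (azimuth, elevation)."""

    def __init__(self, radius: float, texture: NoiseTexture,
                 center: np.ndarray | None = None):
        if radius <= 0:
            raise ValueError("backdrop radius must be positive")
        self.radius = radius
        self.center = np.zeros(3) if center is None else np.asarray(center, float)
        self.texture = texture

    def intersect(self, o: np.ndarray, d: np.ndarray) -> np.ndarray:
        oc = o - self.center
        b = 2.0 * (d @ oc)
        c = oc @ oc - self.radius ** 2
        disc = b * b - 4.0 * c
        t = (-b + np.sqrt(np.maximum(disc, 0.0))) / 2.0
        return np.where(t > _EPS_T, t, np.inf)

    def shade(self, o: np.ndarray, d: np.ndarray, t: np.ndarray) -> np.ndarray:
        p = o[None, :] + t[:, None] * d - self.center[None, :]
        az = np.rad2deg(np.arctan2(p[:, 1], p[:, 0]))
        el = np.rad2deg(np.arcsin(np.clip(p[:, 2] / np.linalg.norm(p, axis=1), -1, 1)))
        return self.texture.sample(az, el)


class TexturedSphere:
    """Sphere carrying a source panorama as texture (depth equalization).

    Brightness in a world direction is looked up in the panorama that
    was rendered at the sphere center with yaw ``yaw_deg``; rendering
    from the exact center therefore reproduces the source panorama up to
    resampling.
    """

    def __init__(self, center: np.ndarray, radius: float, pano: HighResPanorama,
                 yaw_deg: float = 0.0):
        if radius <= 0:
            raise ValueError("sphere radius must be positive")
        self.center = np.asarray(center, float)
        self.radius = radius
        self.yaw_deg = yaw_deg
        # augment one wrapped column so bilinear lookup crosses the seam
        self._bright = np.concatenate([pano.brightness, pano.brightness[:, :1]], axis=1)
        self._el0 = pano.el_deg[0]
        self._del = pano.el_deg[0] - pano.el_deg[1]   # > 0, rows descend
        self._daz = pano.az_deg[1] - pano.az_deg[0]

    def intersect(self, o: np.ndarray, d: np.ndarray) -> np.ndarray:
        oc = o - self.center
        if oc @ oc >= self.radius ** 2:
            raise ValueError("camera displaced outside the depth-equalized sphere")
        b = 2.0 * (d @ oc)
        c = oc @ oc - self.radius ** 2
        disc = b * b - 4.0 * c
        return (-b + np.sqrt(np.maximum(disc, 0.0))) / 2.0

    def shade(self, o: np.ndarray, d: np.ndarray, t: np.ndarray) -> np.ndarray:
        p = o[None, :] + t[:, None] * d - self.center[None, :]
        az = np.rad2deg(np.arctan2(p[:, 1], p[:, 0])) - self.yaw_deg
        el = np.rad2deg(np.arcsin(np.clip(p[:, 2] / np.linalg.norm(p, axis=1), -1, 1)))
        rows = np.clip((self._el0 - el) / self._del, 0, self._bright.shape[0] - 1)
        cols = (az % 360.0) / self._daz
        return map_coordinates(self._bright, np.vstack([rows, cols]),
                               order=1, mode="nearest")


# --------------------------------------------------------------------------
# scene specification and construction
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CylinderSpec:
    x: float
    y: float
    radius: float
    height: float
    texture: TextureParams


@dataclass(frozen=True)
class SceneSpec:
    """Declarative description of a cluttered scene (deterministic in seed)."""

    rng_seed: int = 0
    ground_height: float = 0.0
    backdrop_radius: float = 100.0
    objects: tuple[CylinderSpec, ...] = ()
    ground_texture: TextureParams = field(
        default_factory=lambda: TextureParams(corr_length=0.15, rms_contrast=0.30))
    backdrop_texture: TextureParams = field(
        default_factory=lambda: TextureParams(corr_length=3.0, rms_contrast=0.25))

    def __post_init__(self) -> None:
        for ob in self.objects:
            dist = np.hypot(ob.x, ob.y) + ob.radius
            if dist >= self.backdrop_radius:
                raise ValueError("backdrop must lie beyond every object")


class Scene:
    """Ray-intersectable geometry with evaluable surface textures."""

    def __init__(self, geoms: list, backdrop_radius: float = np.inf,
                 ground_height: float | None = None):
        self.geoms = geoms
        self.backdrop_radius = backdrop_radius
        self.ground_height = ground_height

    def trace(self, origin: np.ndarray, dirs: np.ndarray,
              col_az_world: np.ndarray | None = None
              ) -> tuple[np.ndarray, np.ndarray]:
        """Nearest-hit distance (m) and brightness for a ray bundle.

        ``dirs`` is (N, 3) or (H, W, 3); with the latter plus
        ``col_az_world`` (per-column world azimuth, radians) the
        cylinder tests are culled to the columns inside each cylinder's
        azimuthal silhouette.
        """
        origin = np.asarray(origin, float)
        grid_shape = dirs.shape[:2] if dirs.ndim == 3 else None
        flat = dirs.reshape(-1, 3)
        n = len(flat)
        best_t = np.full(n, np.inf)
        best_g = np.full(n, -1, dtype=np.int8)
        for gi, geom in enumerate(self.geoms):
            cols = None
            if (grid_shape is not None and col_az_world is not None
                    and isinstance(geom, Cylinder)):
                win = geom.azimuth_window(origin)
                if win is not None:
                    ctr, half = win
                    daz = (col_az_world - ctr + np.pi) % (2 * np.pi) - np.pi
                    cols = np.abs(daz) <= half
                    if not cols.any():
                        continue
            if cols is None:
                t = geom.intersect(origin, flat)
                closer = t < best_t
                best_t[closer] = t[closer]
                best_g[closer] = gi
            else:
                sub = dirs[:, cols].reshape(-1, 3)
                t = geom.intersect(origin, sub)
                tb = best_t.reshape(grid_shape)[:, cols].ravel()
                closer = t < tb
                tb[closer] = t[closer]
                best_t.reshape(grid_shape)[:, cols] = tb.reshape(grid_shape[0], -1)
                gb = best_g.reshape(grid_shape)[:, cols].ravel()
                gb[closer] = gi
                best_g.reshape(grid_shape)[:, cols] = gb.reshape(grid_shape[0], -1)
        dirs = flat
        bright = np.zeros(n)
        for gi, geom in enumerate(self.geoms):
            sel = best_g == gi
            if np.any(sel):
                bright[sel] = geom.shade(origin, dirs[sel], best_t[sel])
        if np.any(best_g < 0):
            raise RuntimeError("ray escaped the scene (no enclosing backdrop?)")
        return best_t, bright

    def validate_pose(self, pose: "Pose") -> None:
        p = np.asarray(pose.position, float)
        if self.ground_height is not None and p[2] <= self.ground_height:
            raise ValueError("camera pose is at or below the ground plane")
        for geom in self.geoms:
            if isinstance(geom, Cylinder) and geom.contains(p):
                raise ValueError("camera pose lies inside a scene object")


def build_scene(spec: SceneSpec) -> Scene:
    """Instantiate geometry and seeded textures from a scene spec."""
    ss = np.random.SeedSequence(spec.rng_seed)
    seeds = ss.spawn(2 + len(spec.objects))
    geoms: list = []
    for i, ob in enumerate(spec.objects):
        tex = NoiseTexture(ob.texture, seeds[2 + i],
                           period_u=2 * np.pi * ob.radius)
        geoms.append(Cylinder(ob.x, ob.y, ob.radius, ob.height, tex,
                              z0=spec.ground_height))
    geoms.append(GroundPlane(spec.ground_height, NoiseTexture(spec.ground_texture, seeds[0])))
    geoms.append(BackdropSphere(spec.backdrop_radius,
                                NoiseTexture(spec.backdrop_texture, seeds[1], period_u=360.0),
                                center=np.array([0.0, 0.0, 0.0])))
    return Scene(geoms, backdrop_radius=spec.backdrop_radius,
                 ground_height=spec.ground_height)


# --------------------------------------------------------------------------
# poses and trajectories
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Pose:
    position: tuple[float, float, float]   # meters
    yaw: float = 0.0                       # degrees, CCW about z
    timestamp: float = 0.0                 # ms


@dataclass
class Trajectory:
    poses: list[Pose]
    phase_labels: list[str]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ts = np.array([p.timestamp for p in self.poses])
        if np.any(np.diff(ts) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if len(self.phase_labels) != len(self.poses):
            raise ValueError("one phase label per pose required")

    def __len__(self) -> int:
        return len(self.poses)


def _straight(length_m: float, step_mm: float, speed: float, height: float,
              start: tuple[float, float], yaw: float, t0: float,
              reverse: bool = False) -> tuple[list[Pose], list[str]]:
    if step_mm <= 0 or length_m <= 0:
        raise ValueError("step and path length must be positive")
    n = int(round(length_m * 1000.0 / step_mm))
    dt = step_mm / speed  # ms, for speed in m/s and step in mm
    heading = np.deg2rad(yaw)
    ux, uy = np.cos(heading), np.sin(heading)
    sgn = -1.0 if reverse else 1.0
    poses = []
    for i in range(n):
        s = sgn * i * step_mm / 1000.0
        poses.append(Pose((start[0] + s * ux, start[1] + s * uy, height),
                          yaw=yaw, timestamp=t0 + i * dt))
    return poses, ["translation"] * n


def _saccade(amplitude: float, duration_ms: float, position, yaw0: float,
             t0: float, dt: float = 1.0) -> tuple[list[Pose], list[str]]:
    """Yaw turn with a raised-cosine (Hann) angular-velocity profile."""
    if duration_ms <= 0:
        raise ValueError("saccade duration must be positive")
    n = int(round(duration_ms / dt)) + 1
    t = np.arange(n) * dt
    # integral of (A/T)(1 - cos(2 pi t / T)) -> smooth, zero-velocity endpoints
    yaw = yaw0 + amplitude * (t / duration_ms
                              - np.sin(2 * np.pi * t / duration_ms) / (2 * np.pi))
    yaw[-1] = yaw0 + amplitude
    poses = [Pose(tuple(position), yaw=float(y), timestamp=t0 + ti)
             for y, ti in zip(yaw, t)]
    return poses, ["saccade"] * n


def make_trajectory(kind: str, **params) -> Trajectory:
    """Build a simulated flight trajectory.

    kind="straight": 1 m path of 10 mm steps at 1 m/s by default, i.e.
    100 poses at 0, 10, ..., 990 mm with 10 ms timestamps.
    kind="saccade": in-place yaw turn, raised-cosine velocity profile
    (default 180 deg in 70 ms) sampled at 1 ms.
    kind="loop": saccade, forward translation, saccade, backward
    translation with contiguous timestamps.
    """
    height = params.pop("height", 0.5)
    if kind == "straight":
        poses, labels = _straight(params.pop("length_m", 1.0),
                                  params.pop("step_mm", 10.0),
                                  params.pop("speed", 1.0), height,
                                  params.pop("start", (0.0, 0.0)),
                                  params.pop("yaw", 0.0),
                                  params.pop("t0", 0.0))
        meta = {"speed": 1.0, "step_mm": 10.0}
    elif kind == "saccade":
        poses, labels = _saccade(params.pop("amplitude", 180.0),
                                 params.pop("duration_ms", 70.0),
                                 params.pop("position", (0.0, 0.0, height)),
                                 params.pop("yaw0", 0.0),
                                 params.pop("t0", 0.0),
                                 params.pop("dt", 1.0))
        meta = {}
    elif kind == "loop":
        length = params.pop("length_m", 1.0)
        step = params.pop("step_mm", 10.0)
        speed = params.pop("speed", 1.0)
        dur = params.pop("saccade_ms", 70.0)
        start = params.pop("start", (0.0, 0.0))
        dt_tr = step / speed
        p1, l1 = _saccade(180.0, dur, (start[0], start[1], height), -180.0, 0.0)
        t = p1[-1].timestamp + 1.0
        p2, l2 = _straight(length, step, speed, height, start, 0.0, t)
        t = p2[-1].timestamp + dt_tr
        end_xy = (p2[-1].position[0], p2[-1].position[1])
        p3, l3 = _saccade(180.0, dur, (end_xy[0], end_xy[1], height), 0.0, t)
        t = p3[-1].timestamp + 1.0
        p4, l4 = _straight(length, step, speed, height, end_xy, 180.0, t,
                           reverse=False)
        poses, labels = p1 + p2 + p3 + p4, l1 + l2 + l3 + l4
        meta = {"speed": speed, "step_mm": step}
    else:
        raise ValueError(f"unknown trajectory kind: {kind}")
    if params:
        raise TypeError(f"unknown trajectory parameters: {sorted(params)}")
    meta["kind"] = kind
    return Trajectory(poses, labels, meta)


# --------------------------------------------------------------------------
# rendering
# --------------------------------------------------------------------------

_DIR_CACHE: dict = {}  # single-entry cache of the last ray-direction grid


def render_panorama(scene: Scene, pose: Pose,
                    el_deg: np.ndarray, az_deg: np.ndarray,
                    with_depth: bool = True) -> HighResPanorama:
    """Ray-cast a panoramic brightness frame (and central-ray depth map).

    ``az_deg`` is azimuth in the camera frame (0 = heading); the camera
    yaw rotates the ray bundle into the world frame.
    """
    scene.validate_pose(pose)
    H, W = len(el_deg), len(az_deg)
    key = (H, W, float(el_deg[0]), float(el_deg[-1]), float(az_deg[0]), pose.yaw)
    cached = _DIR_CACHE.get(key)
    if cached is None:
        dirs = directions_from_angles(el_deg, az_deg)
        yaw = np.deg2rad(pose.yaw)
        if yaw != 0.0:
            cy, sy = np.cos(yaw), np.sin(yaw)
            rot = np.array([[cy, -sy, 0.0], [sy, cy, 0.0], [0.0, 0.0, 1.0]])
            dirs = dirs @ rot.T
        col_az = np.deg2rad(az_deg) + yaw
        _DIR_CACHE.clear()
        _DIR_CACHE[key] = (dirs, col_az)
    else:
        dirs, col_az = cached
    t, bright = scene.trace(np.asarray(pose.position, float), dirs, col_az)
    depth = (t.reshape(H, W) * M_TO_CM) if with_depth else None
    return HighResPanorama(bright.reshape(H, W), depth,
                           np.asarray(el_deg, float), np.asarray(az_deg, float))


def depth_equalize(scene: Scene, center_pose: Pose, sphere_radius: float,
                   res_deg: float | None = None) -> Scene:
    """Project the panorama seen at ``center_pose`` onto a sphere.

    The resulting scene reproduces the source imagery from the center
    (up to resampling) while every direction shares the distance
    ``sphere_radius`` -- the depth-equalized control condition.
    """
    if res_deg is None:
        res_deg = 1.25 / 9.0
    el = 90.0 - res_deg * np.arange(int(round(180.0 / res_deg)) + 1)
    az = res_deg * np.arange(int(round(360.0 / res_deg)))
    pano = render_panorama(scene, center_pose, el, az, with_depth=False)
    sphere = TexturedSphere(np.asarray(center_pose.position, float),
                            sphere_radius, pano, yaw_deg=center_pose.yaw)
    return Scene([sphere], backdrop_radius=sphere_radius)


def ground_truth_feature_maps(scene: Scene, pose: Pose,
                              lattice: PhotoreceptorLattice,
                              factor: int = 9,
                              harmonic: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Ground-truth per-receptor depth (cm) and nearness (1/cm) maps.

    Depth is aggregated to receptor resolution with the same Gaussian
    acceptance weighting used for brightness (arithmetic mean by
    default; ``harmonic=True`` averages nearness instead).
    """
    el, az = lattice.supersampled_grid(factor)
    pano = render_panorama(scene, pose, el, az)
    depth = acceptance_downsample(pano, lattice, field="depth_cm", harmonic=harmonic)
    return depth, 1.0 / depth
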