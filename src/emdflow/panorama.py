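"""Equirectangular panorama containers and grid helpers.

All image-like arrays in this package share one orientation convention:
row 0 is the highest elevation, rows run top-to-bottom with decreasing
elevation; columns run left-to-right with azimuth increasing from 0
toward 360 degrees (counter-clockwise, i.e. toward world +y when the
camera yaw is zero).  Azimuth wraps; elevation does not.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class HighResPanorama:
    """A rendered panoramic brightness frame with co-registered depth.

    Attributes
    ----------
    brightness : (H, W) float array
        Linear brightness, arbitrary units, >= 0.
    depth_cm : (H, W) float array
        Central-ray distance to the first surface hit, in centimeters.
    el_deg : (H,) float array
        Elevation of each row center (degrees, strictly decreasing).
    az_deg : (W,) float array
        Azimuth of each column center (degrees in [0, 360), increasing).
    """

    brightness: np.ndarray
    depth_cm: np.ndarray
    el_deg: np.ndarray
    az_deg: np.ndarray

    def __post_init__(self) -> None:
        if self.brightness.shape != (self.el_deg.size, self.az_deg.size):
            raise ValueError("brightness shape does not match angular grids")
        if self.depth_cm is not None and self.depth_cm.shape != self.brightness.shape:
            raise ValueError("depth grid not co-registered with brightness")

    @property
    def res_deg(self) -> float:
        """Angular resolution (degrees per pixel, assumed isotropic)."""
        return float(self.az_deg[1] - self.az_deg[0])


def directions_from_angles(el_deg: np.ndarray, az_deg: np.ndarray) -> np.ndarray:
    """Unit viewing directions for an (el, az) grid, camera frame.

    Returns an (H, W, 3) array with x toward azimuth 0, y toward azimuth
    90 deg, z up.
    """
    el = np.deg2rad(np.asarray(el_deg, dtype=np.float64))[:, None]
    az = np.deg2rad(np.asarray(az_deg, dtype=np.float64))[None, :]
    cos_el = np.cos(el)
    d = np.empty(np.broadcast_shapes(el.shape, az.shape) + (3,))
    d[..., 0] = cos_el * np.cos(az)
    d[..., 1] = cos_el * np.sin(az)
    d[..., 2] = np.broadcast_to(np.sin(el), d.shape[:2])
    return d


def equirect_grid(
    n_cols: int,
    n_rows: int,
    el_max: float = 47.0,
    el_min: float = -58.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Plain equirectangular grid (used by the depth-estimation pipeline).

    Columns span the full azimuth circle; rows span [el_min, el_max]
    inclusive, top row at el_max.
    """
    az = np.arange(n_cols) * (360.0 / n_cols)
    el = np.linspace(el_max, el_min, n_rows)
    return el, az


def tangent_basis(el_deg: np.ndarray, az_deg: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Local tangent unit vectors (e_az, e_el) on the viewing sphere.

    e_az points toward increasing azimuth, e_el toward increasing
    elevation.  Shapes follow ``directions_from_angles``.
    """
    el = np.deg2rad(np.asarray(el_deg, dtype=np.float64))[:, None]
    az = np.deg2rad(np.asarray(az_deg, dtype=np.float64))[None, :]
    H, W = el.shape[0], az.shape[1]
    e_az = np.zeros((H, W, 3))
    e_az[..., 0] = -np.sin(az)
    e_az[..., 1] = np.cos(az)
    e_el = np.empty((H, W, 3))
    e_el[..., 0] = -np.sin(el) * np.cos(az)
    e_el[..., 1] = -np.sin(el) * np.sin(az)
    e_el[..., 2] = np.broadcast_to(np.cos(el), (H, W))
    return e_az, e_el
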