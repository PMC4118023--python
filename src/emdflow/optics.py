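"""Photoreceptor lattice, Gaussian acceptance sampling, temporal interpolation.

The compound-eye front end is modeled as an equirectangular lattice of
photoreceptors with 1.25 deg spacing and a Gaussian angular sensitivity
(acceptance function) of half-width ``acceptance_angle`` = 1.64 deg:

    F(phi) = exp(-2.77 * phi**2 / acceptance_angle**2)

with phi the angular distance from the receptor axis (2.77 ~ 4 ln 2, so
the acceptance angle is the full width at half maximum).  Receptor
values are the F-weighted mean of the supersampled panorama within a
truncation radius of two acceptance angles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.ndimage import correlate1d

from .panorama import HighResPanorama

LOG2x4 = 2.77  # Gaussian exponent constant; ~4 ln 2


@dataclass(frozen=True)
class PhotoreceptorLattice:
    """Equirectangular receptor grid.

    Defaults give 288 azimuth columns and 85 elevation rows with row
    centers at +47, +45.75, ..., -58 degrees.
    """

    spacing: float = 1.25
    acceptance_angle: float = 1.64
    elevation_min: float = -58.0
    elevation_max: float = 47.0

    def __post_init__(self) -> None:
        n = 360.0 / self.spacing
        if abs(n - round(n)) > 1e-9:
            raise ValueError("360 deg must be divisible by the lattice spacing")
        if self.elevation_max <= self.elevation_min:
            raise ValueError("elevation_max must exceed elevation_min")

    @property
    def n_cols(self) -> int:
        return int(round(360.0 / self.spacing))

    @property
    def n_rows(self) -> int:
        span = self.elevation_max - self.elevation_min
        return int(round(span / self.spacing)) + 1

    @property
    def elevations(self) -> np.ndarray:
        """Row-center elevations, degrees, descending (row 0 on top)."""
        return self.elevation_max - self.spacing * np.arange(self.n_rows)

    @property
    def azimuths(self) -> np.ndarray:
        """Column-center azimuths, degrees in [0, 360)."""
        return self.spacing * np.arange(self.n_cols)

    def supersampled_grid(self, factor: int = 9) -> tuple[np.ndarray, np.ndarray]:
        """Angular grid for rendering at ``spacing / factor`` resolution.

        Receptor centers coincide with grid pixel centers.  The
        elevation range is padded by the acceptance-window truncation
        radius (2 * acceptance_angle) so edge receptors see a complete
        window.
        """
        res = self.spacing / factor
        pad_px = int(np.ceil(2.0 * self.acceptance_angle / res))
        n_el = (self.n_rows - 1) * factor + 1 + 2 * pad_px
        el = (self.elevation_max + pad_px * res) - res * np.arange(n_el)
        az = res * np.arange(int(round(360.0 / res)))
        return el, az


@dataclass
class FrameSequence:
    """Time-stamped stack of receptor-resolution brightness frames."""

    values: np.ndarray            # (T, rows, cols), linear brightness >= 0
    dt: float                     # ms
    t0: float = 0.0               # ms, timestamp of the first frame
    phase_labels: list[str] | None = None

    def __post_init__(self) -> None:
        if self.values.ndim != 3:
            raise ValueError("expected a (time, rows, cols) stack")
        if self.phase_labels is not None and len(self.phase_labels) != len(self.values):
            raise ValueError("one phase label per frame required")

    @property
    def timestamps(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.values.shape[0])

    def __len__(self) -> int:
        return self.values.shape[0]


def _acceptance_kernels(lattice: PhotoreceptorLattice, res: float, el_pano: np.ndarray):
    """Per-receptor-row separable acceptance weights.

    The angular distance near a receptor at elevation ``el`` decomposes
    (small-angle) into the elevation offset and the azimuth offset
    foreshortened by cos(el); the Gaussian then factorizes into an
    elevation vector and an azimuth vector per row.
    """
    rho = lattice.acceptance_angle
    trunc = 2.0 * rho
    kernels = []
    for el_c in lattice.elevations:
        d_el = el_pano - el_c
        rows = np.nonzero(np.abs(d_el) <= trunc + 1e-9)[0]
        w_el = np.exp(-LOG2x4 * (d_el[rows] / rho) ** 2)
        cos_el = max(np.cos(np.deg2rad(el_c)), 1e-6)
        half = int(np.floor(trunc / (res * cos_el) + 1e-9))
        d_az = res * cos_el * np.arange(-half, half + 1)
        w_az = np.exp(-LOG2x4 * (d_az / rho) ** 2)
        kernels.append((rows, w_el, w_az))
    return kernels


def acceptance_downsample(
    pano: HighResPanorama,
    lattice: PhotoreceptorLattice,
    *,
    field: str = "brightness",
    harmonic: bool = False,
) -> np.ndarray:
    """Sample a high-resolution panorama down to receptor resolution.

    Each receptor value is the acceptance-weighted (normalized) mean of
    the panorama pixels within the truncated Gaussian window.  With
    ``field="depth_cm"`` the same window aggregates the ground-truth
    depth grid (optionally as a harmonic mean, i.e. averaging nearness).
    """
    values = getattr(pano, field)
    if values is None:
        raise ValueError(f"panorama has no '{field}' grid")
    res = pano.res_deg
    if res > lattice.spacing / 3 + 1e-9:
        raise ValueError("panorama must oversample the lattice at least 3x")
    if harmonic:
        values = 1.0 / values
    el_pano = pano.el_deg
    # receptor column -> panorama column index (centers must align)
    col_idx = lattice.azimuths / res
    cols = np.round(col_idx).astype(int)
    if np.max(np.abs(col_idx - cols)) > 1e-6:
        raise ValueError("lattice azimuths do not align with panorama columns")
    out = np.empty((lattice.n_rows, lattice.n_cols))
    for r, (rows, w_el, w_az) in enumerate(_acceptance_kernels(lattice, res, el_pano)):
        band = w_el @ values[rows]                     # (W,)
        smooth = correlate1d(band, w_az, mode="wrap")
        out[r] = smooth[cols] / (w_el.sum() * w_az.sum())
    if harmonic:
        out = 1.0 / out
    return out


def interpolate_sequence(seq: FrameSequence, factor: int = 10) -> FrameSequence:
    """Upsample a frame sequence in time with shape-preserving cubics.

    Uses monotone piecewise cubic Hermite interpolation per receptor, so
    the interpolant passes through every original sample and creates no
    overshoots between them.  A sequence of N frames becomes
    (N - 1) * factor + 1 frames at dt / factor.
    """
    if len(seq) < 2:
        raise ValueError("need at least two frames to interpolate")
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if factor == 1:
        return FrameSequence(seq.values.copy(), seq.dt, seq.t0, seq.phase_labels)
    t = seq.timestamps
    n_out = (len(seq) - 1) * factor + 1
    t_out = seq.t0 + (seq.dt / factor) * np.arange(n_out)
    t_out[-1] = t[-1]  # guard against float drift past the last knot
    flat = seq.values.reshape(len(seq), -1)
    interp = PchipInterpolator(t, flat, axis=0)
    out = interp(t_out).astype(seq.values.dtype)
    labels = None
    if seq.phase_labels is not None:
        idx = np.clip((t_out - seq.t0) // seq.dt, 0, len(seq) - 1).astype(int)
        labels = [seq.phase_labels[i] for i in idx]
    return FrameSequence(out.reshape((n_out,) + seq.values.shape[1:]),
                         seq.dt / factor, seq.t0, labels)
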