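"""Relating the motion-energy profile to environmental feature maps.

Pixelwise squared Pearson correlation (R^2) between the motion-energy
map and a feature map (typically contrast-weighted nearness), with:
delay compensation for the temporal-filter latency of the motion
pathway; masking of the optic-flow singularities (FOE/FOC); uniform
square spatial pooling; correlation time courses over a trajectory; and
comparisons across stimulus conditions (full-depth, depth-equalized,
rotation).  Correlations default to the log domain (the energy/feature
relation is roughly linear on double-logarithmic axes); a linear-domain
option is available.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .optics import PhotoreceptorLattice
from .panorama import directions_from_angles


@dataclass(frozen=True)
class AnalysisConfig:
    delay_ms: float = 22.0
    domain: str = "log"            # {"log", "linear"}
    log_eps_factor: float = 1e-3   # flooring: eps = factor * valid median
    foe_radius_deg: float = 0.0
    mask_mode: str = "none"        # {"exclude", "include", "none"}
    pooling_deg: float = 1.25

    def __post_init__(self) -> None:
        if self.delay_ms < 0:
            raise ValueError("delay must be non-negative")
        if self.domain not in ("log", "linear"):
            raise ValueError("domain must be 'log' or 'linear'")
        if self.mask_mode not in ("exclude", "include", "none"):
            raise ValueError("bad mask mode")


@dataclass(frozen=True)
class CorrelationResult:
    r2: float                     # in [0, 1]; NaN when undefined
    n_pixels: int
    condition: str = ""
    time_ms: float | None = None
    config: AnalysisConfig = field(default_factory=AnalysisConfig)

    @property
    def valid(self) -> bool:
        return np.isfinite(self.r2)


# --------------------------------------------------------------------------
# correlation primitives
# --------------------------------------------------------------------------

def pixel_correlation(a: np.ndarray, b: np.ndarray,
                      mask: np.ndarray | None = None,
                      domain: str = "log",
                      log_eps_factor: float = 1e-3,
                      **result_kw) -> CorrelationResult:
    """Squared Pearson correlation over valid (finite, masked) pixels.

    In the log domain both maps are floored at ``log_eps_factor`` times
    their own valid median before the log transform.  Zero variance in
    either map makes the correlation undefined (NaN R^2, flagged
    invalid) rather than raising.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("maps are not co-registered")
    ok = np.isfinite(a) & np.isfinite(b)
    if mask is not None:
        ok &= mask
    x, y = a[ok], b[ok]
    cfg = AnalysisConfig(domain=domain, log_eps_factor=log_eps_factor)
    if x.size < 3:
        return CorrelationResult(np.nan, int(x.size), config=cfg, **result_kw)
    if domain == "log":
        x = np.log(np.maximum(x, _log_eps(x, log_eps_factor)))
        y = np.log(np.maximum(y, _log_eps(y, log_eps_factor)))
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return CorrelationResult(np.nan, int(x.size), config=cfg, **result_kw)
    r = float(np.corrcoef(x, y)[0, 1])
    return CorrelationResult(r * r, int(x.size), config=cfg, **result_kw)


def _log_eps(x: np.ndarray, factor: float) -> float:
    pos = x[x > 0]
    med = np.median(pos) if pos.size else 1.0
    return factor * float(med)


# --------------------------------------------------------------------------
# delay compensation
# --------------------------------------------------------------------------

def compensate_delay(energy_seq: np.ndarray, feature_seq: np.ndarray,
                     delay_ms: float, dt: float = 1.0
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Pair energy(t) with feature(t - delay); edges are truncated."""
    shift = delay_ms / dt
    if abs(shift - round(shift)) > 1e-9:
        raise ValueError("delay must be a multiple of the frame interval")
    shift = int(round(shift))
    if shift >= len(energy_seq):
        raise ValueError("delay exceeds the sequence duration")
    if shift == 0:
        return energy_seq, feature_seq
    return energy_seq[shift:], feature_seq[:len(feature_seq) - shift]


def estimate_latency(energy_seq: np.ndarray, feature_seq: np.ndarray,
                     dt: float = 1.0,
                     search_ms: tuple[float, float] = (0.0, 60.0),
                     frame_idx: np.ndarray | None = None,
                     domain: str = "log") -> float:
    """Lag (ms) maximizing mean pixelwise R^2 of energy vs shifted feature.

    For each candidate lag on the dt grid, energy frames (by default all
    frames late enough to be paired at the largest lag) are correlated
    against the feature map lagged by that amount; the mean R^2 over
    frames is the objective.  A flat objective is an error.
    """
    lags = np.arange(int(round(search_ms[0] / dt)),
                     int(round(search_ms[1] / dt)) + 1)
    if lags[-1] >= len(energy_seq):
        raise ValueError("search range exceeds the sequence")
    if frame_idx is None:
        frame_idx = np.arange(lags[-1], len(energy_seq))
    frame_idx = np.asarray(frame_idx)
    if frame_idx.min() < lags[-1]:
        raise ValueError("frames too early for the largest candidate lag")
    scores = np.empty(len(lags))
    for i, lag in enumerate(lags):
        r2 = np.array([pixel_correlation(energy_seq[t], feature_seq[t - lag],
                                         domain=domain).r2 for t in frame_idx])
        scores[i] = r2[np.isfinite(r2)].mean() if np.isfinite(r2).any() else np.nan
    finite = scores[np.isfinite(scores)]
    if finite.size == 0 or (len(lags) > 1 and np.allclose(finite, finite[0])):
        raise ValueError("latency objective is flat; cannot locate a maximum")
    return float(lags[np.nanargmax(scores)] * dt)


# --------------------------------------------------------------------------
# FOE/FOC masking
# --------------------------------------------------------------------------

def foe_foc_mask(lattice_or_grids, heading: np.ndarray,
                 radius_deg: float, mode: str = "exclude") -> np.ndarray:
    """Boolean mask around the flow-field singularities.

    Pixels within ``radius_deg`` great-circle distance of the heading
    (FOE) or anti-heading (FOC) direction are excluded
    (mode="exclude") or exclusively kept (mode="include").  The two
    modes are exact complements for any radius.
    """
    if not 0.0 <= radius_deg <= 90.0:
        raise ValueError("radius must be within [0, 90] degrees")
    if isinstance(lattice_or_grids, PhotoreceptorLattice):
        el, az = lattice_or_grids.elevations, lattice_or_grids.azimuths
    else:
        el, az = lattice_or_grids
    d = directions_from_angles(el, az)
    t = np.asarray(heading, float)
    t = t / np.linalg.norm(t)
    ang = np.rad2deg(np.arccos(np.clip(np.abs(d @ t), -1.0, 1.0)))
    near = ang <= radius_deg      # near FOE or FOC (|dot| folds both)
    if mode == "exclude":
        return ~near
    if mode == "include":
        return near
    raise ValueError("mode must be 'exclude' or 'include'")


# --------------------------------------------------------------------------
# spatial pooling
# --------------------------------------------------------------------------

def pool(values: np.ndarray, range_deg: float,
         lattice: PhotoreceptorLattice | None = None,
         spacing: float = 1.25) -> np.ndarray:
    """Square uniform pooling of a retinotopic map.

    The kernel is k x k with k = range/spacing (odd); azimuth wraps,
    rows truncate with renormalization, and invalid (NaN) pixels are
    excluded from the local mean.
    """
    if lattice is not None:
        spacing = lattice.spacing
    k = range_deg / spacing
    if abs(k - round(k)) > 1e-6 or int(round(k)) % 2 == 0:
        raise ValueError("pooling range must be an odd multiple of the spacing")
    k = int(round(k))
    if k == 1:
        return values.copy()
    half = k // 2
    v = np.asarray(values, dtype=np.float64)
    w = np.isfinite(v).astype(np.float64)
    v = np.where(np.isfinite(v), v, 0.0)
    v = np.pad(np.pad(v, ((half, half), (0, 0))), ((0, 0), (half, half)), mode="wrap")
    w = np.pad(np.pad(w, ((half, half), (0, 0))), ((0, 0), (half, half)), mode="wrap")
    slide = np.lib.stride_tricks.sliding_window_view
    num = slide(v, (k, k)).sum(axis=(-2, -1))
    den = slide(w, (k, k)).sum(axis=(-2, -1))
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    return np.where(den > 0, out, np.nan)


def neighborhood_pooling_range(lattice: PhotoreceptorLattice,
                               rings: int = 1) -> float:
    """Pooling range (deg) covering a unit and its ``rings`` neighbor
    shells: (2*rings + 1) lattice spacings (3.75 deg at defaults)."""
    return (2 * rings + 1) * lattice.spacing


def pooling_curves(energy_map: np.ndarray, feature_map: np.ndarray,
                   ranges_deg, lattice: PhotoreceptorLattice | None = None,
                   mask: np.ndarray | None = None,
                   domain: str = "log") -> dict[str, np.ndarray]:
    """Reliability and localizability R^2 curves vs pooling range.

    "reliability": pooled energy against equally pooled feature map;
    "localizability": pooled energy against the unpooled feature map.
    """
    ranges_deg = list(ranges_deg)
    if len(ranges_deg) < 2:
        raise ValueError("need at least two pooling ranges")
    rel, loc = [], []
    for rng in ranges_deg:
        pe = pool(energy_map, rng, lattice)
        pf = pool(feature_map, rng, lattice)
        rel.append(pixel_correlation(pe, pf, mask=mask, domain=domain).r2)
        loc.append(pixel_correlation(pe, feature_map, mask=mask, domain=domain).r2)
    return {"range_deg": np.asarray(ranges_deg),
            "reliability": np.asarray(rel),
            "localizability": np.asarray(loc)}


# --------------------------------------------------------------------------
# time courses and condition comparison
# --------------------------------------------------------------------------

def correlation_timecourse(energy_seq: np.ndarray, feature_seq: np.ndarray,
                           dt: float = 1.0,
                           delay_ms: float = 22.0,
                           phase_labels=None,
                           mask: np.ndarray | None = None,
                           domain: str = "log",
                           stride: int = 1) -> dict[str, np.ndarray]:
    """Per-frame R^2 between energy and delay-compensated feature maps.

    Returns frame times (of the energy frame), R^2 values (NaN where
    undefined), and the phase label of each evaluated frame when
    trajectory labels are provided.
    """
    e, f = compensate_delay(energy_seq, feature_seq, delay_ms, dt)
    shift = len(energy_seq) - len(e)
    idx = np.arange(0, len(e), stride)
    r2 = np.array([pixel_correlation(e[i], f[i], mask=mask, domain=domain).r2
                   for i in idx])
    out = {"time_ms": (idx + shift) * dt, "r2": r2}
    if phase_labels is not None:
        out["phase"] = np.asarray([phase_labels[i + shift] for i in idx])
    return out


def condition_compare(results: dict[str, np.ndarray]) -> dict:
    """Summarize per-condition R^2 distributions at the track center.

    ``results`` maps a condition tag to an array of R^2 samples.
    Returns per-condition median/quartiles and the pairwise ordering of
    medians.
    """
    summary = {}
    for tag, vals in results.items():
        v = np.asarray(vals, dtype=np.float64)
        v = v[np.isfinite(v)]
        summary[tag] = {
            "n": int(v.size),
            "median": float(np.median(v)) if v.size else np.nan,
            "q25": float(np.percentile(v, 25)) if v.size else np.nan,
            "q75": float(np.percentile(v, 75)) if v.size else np.nan,
        }
    order = sorted(summary, key=lambda t: -summary[t]["median"])
    return {"conditions": summary, "ordering": order}
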