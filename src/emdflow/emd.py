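"""Correlation-type elementary motion detectors and the motion-energy map.

Each EMD multiplies the low-pass-delayed signal of one receptor with the
undelayed signal of its direct neighbor and subtracts the output of the
mirror-symmetric subunit:

    r(t) = LP_tau[s1](t) * s2(t) - s1(t) * LP_tau[s2](t)

with a first-order low-pass delay of tau_lp = 40 ms.  Horizontal arrays
pair azimuthal neighbors and wrap around the panorama; vertical arrays
pair elevation neighbors.  The motion energy at a retinotopic location
is the Euclidean norm of the co-located horizontal and vertical
responses.

Sign convention: with the definition above, a pattern drifting from the
delayed receptor s1 toward its undelayed neighbor s2 (increasing index:
toward larger azimuth for horizontal arrays, downward for vertical
arrays) yields a positive mean response.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .periphery import exp_lowpass


@dataclass(frozen=True)
class EMDParams:
    tau_lp: float = 40.0   # ms, delay low-pass
    dt: float = 1.0        # ms

    def __post_init__(self) -> None:
        if self.tau_lp <= 0 or self.dt <= 0:
            raise ValueError("tau_lp and dt must be positive")


def emd_array(signal: np.ndarray, params: EMDParams | None = None,
              orientation: str = "horizontal") -> np.ndarray:
    """Opponent correlator responses for a (T, rows, cols) signal stack.

    Horizontal: detector column c pairs receptor columns (c, c+1 mod
    n_cols); output has the same number of columns (azimuth wraps) and
    is registered to the left receptor.  Vertical: detector row r pairs
    receptor rows (r, r+1); output has n_rows - 1 rows, registered to
    the upper receptor.
    """
    if params is None:
        params = EMDParams()
    signal = np.asarray(signal)
    if signal.ndim != 3:
        raise ValueError("expected a (time, rows, cols) stack")
    T, R, C = signal.shape
    if orientation == "horizontal":
        if C < 2:
            raise ValueError("need at least two columns for horizontal EMDs")
        s1 = signal
        s2 = np.roll(signal, -1, axis=2)
    elif orientation == "vertical":
        if R < 2:
            raise ValueError("need at least two rows for vertical EMDs")
        s1 = signal[:, :-1, :]
        s2 = signal[:, 1:, :]
    else:
        raise ValueError("orientation must be 'horizontal' or 'vertical'")
    d1 = exp_lowpass(s1, params.tau_lp, params.dt)
    d2 = exp_lowpass(s2, params.tau_lp, params.dt)
    return (d1 * s2 - s1 * d2).astype(np.float32)


def motion_energy(h: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Motion-energy profile: pointwise norm of the (h, v) response pair.

    ``h`` covers all receptor rows while ``v`` covers one row fewer; the
    energy grid is their overlap (h cropped to the upper rows).  Equal
    whether the signed responses are full-wave rectified first or not.
    """
    h = np.asarray(h)
    v = np.asarray(v)
    if h.shape[0] != v.shape[0] or h.shape[-1] != v.shape[-1]:
        raise ValueError("h and v response stacks are not co-registered")
    if h.shape[1] == v.shape[1] + 1:
        h = h[:, :-1, :]
    elif h.shape[1] != v.shape[1]:
        raise ValueError("h and v row counts differ by more than one")
    return np.hypot(h, v)


def analytic_sine_response(delta_u: float, lambda_s: float, f: float,
                           tau_lp: float = 40.0, delta_phi: float = 1.25) -> float:
    """Closed-form time-averaged opponent-correlator response.

    For a brightness sinusoid of amplitude ``delta_u``, spatial
    wavelength ``lambda_s`` (degrees) and temporal frequency ``f`` (Hz)
    drifting toward increasing receptor index (the preferred direction,
    delayed receptor toward undelayed neighbor), fed directly into the
    correlator (periphery bypassed):

        mean r = delta_u**2 * (w*tau / (1 + (w*tau)**2))
                 * sin(2*pi*delta_phi/lambda_s),      w = 2*pi*f

    with ``tau_lp`` in ms and receptor spacing ``delta_phi`` in degrees.
    The magnitude peaks at f = 1/(2*pi*tau_lp) for any wavelength.
    """
    if lambda_s < 2 * delta_phi:
        raise ValueError("spatial wavelength under the aliasing limit (2 * spacing)")
    w_tau = 2 * np.pi * f * tau_lp * 1e-3
    return float(delta_u ** 2 * (w_tau / (1 + w_tau ** 2))
                 * np.sin(2 * np.pi * delta_phi / lambda_s))


def optimal_temporal_frequency(tau_lp: float = 40.0) -> float:
    """Temporal frequency (Hz) maximizing the mean sine response."""
    return 1.0 / (2 * np.pi * tau_lp * 1e-3)
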