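"""EGTA-iontophoresis analysis: counting Ca2+ channels at one active zone.

Local iontophoretic application of EGTA depletes extracellular Ca2+ at a
single active zone (AZ), suppressing its Ca2+ influx while the rest of the
cell keeps signaling.  Plotting the concurrent drop of the whole-cell Ca2+
current against the drop of the AZ's fluorescence yields a pA-per-dF/F0
conversion slope; multiplied by the AZ's maximal dF/F0 this gives the
synaptic Ca2+ current, and division by the single-channel current times
open probability gives the channel count.  Because the EGTA plume may
graze neighboring AZs, the whole-cell current change is first scaled by
the targeted AZ's fractional contribution r_target (the neighbor
correction).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from scipy.stats import linregress

__all__ = [
    "IontophoresisRecording",
    "DetrendResult",
    "NeighborCorrection",
    "SlopeFit",
    "SynapticCurrentEstimate",
    "detrend_double_exp",
    "neighbor_correction",
    "current_fluorescence_slope",
    "channels_from_current",
    "analyze_recording",
]


class InvalidRecordingError(ValueError):
    """Recording violates the assumptions of the analysis."""


@dataclass
class IontophoresisRecording:
    """One iontophoresis experiment's aligned time courses.

    dF/F0 of the targeted AZ, dF/F0 of any monitored neighbor AZs, and the
    whole-cell Ca2+ current magnitude, on a common time base, plus the
    iontophoresis window (seconds).
    """

    time_s: np.ndarray
    target_dff: np.ndarray
    neighbor_dffs: np.ndarray  # (n_neighbors, T); may be empty
    current_pA: np.ndarray
    ionto_window_s: tuple[float, float]

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.target_dff = np.asarray(self.target_dff, dtype=float)
        self.current_pA = np.asarray(self.current_pA, dtype=float)
        self.neighbor_dffs = np.atleast_2d(
            np.asarray(self.neighbor_dffs, dtype=float)
        ) if np.size(self.neighbor_dffs) else np.empty((0, self.time_s.size))
        t = self.time_s.size
        for arr in (self.target_dff, self.current_pA):
            if arr.size != t:
                raise InvalidRecordingError("traces must share the time base")
        if self.neighbor_dffs.shape[1] != t:
            raise InvalidRecordingError("traces must share the time base")
        w0, w1 = self.ionto_window_s
        if not (self.time_s[0] <= w0 < w1 <= self.time_s[-1]):
            raise InvalidRecordingError(
                "iontophoresis window outside the trace span")

    def window_mask(self) -> np.ndarray:
        w0, w1 = self.ionto_window_s
        return (self.time_s >= w0) & (self.time_s <= w1)


@dataclass
class DetrendResult:
    """Baseline fit and suppression time course.

    ``delta`` is baseline − data inside the iontophoresis window (zero
    outside), so suppression appears as a positive deflection.
    """

    delta: np.ndarray
    baseline: np.ndarray
    params: tuple
    single_exp_fallback: bool = False


def _dexp(t, a1, tau1, a2, tau2):
    return a1 * np.exp(-t / tau1) + a2 * np.exp(-t / tau2)


def detrend_double_exp(
    time_s: np.ndarray,
    trace: np.ndarray,
    ionto_window_s: tuple[float, float],
) -> DetrendResult:
    """Fit a double exponential to the segments before and after the
    iontophoresis window (bleaching/rundown envelope) and return the
    suppression ``delta(t) = fit(t) - data(t)`` inside the window.

    Falls back to a single exponential (flagged) if the four-parameter fit
    is ill-conditioned.
    """
    t = np.asarray(time_s, dtype=float)
    y = np.asarray(trace, dtype=float)
    w0, w1 = ionto_window_s
    outside = (t < w0) | (t > w1)
    if outside.sum() < 5:
        raise InvalidRecordingError(
            "too few points outside the iontophoresis window to constrain "
            "the baseline")
    t0 = t[outside] - t[0]
    y0 = y[outside]
    scale = max(abs(y0).max(), 1e-12)
    span = t[-1] - t[0]
    fallback = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p, _ = curve_fit(
                _dexp, t0, y0,
                p0=[0.7 * scale, 10 * span, 0.3 * scale, span],
                maxfev=20000,
            )
        if not np.isfinite(p).all():
            raise RuntimeError
    except (RuntimeError, ValueError):
        fallback = True
        p1, _ = curve_fit(
            lambda tt, a, tau: a * np.exp(-tt / tau), t0, y0,
            p0=[scale, 10 * span], maxfev=20000)
        p = (p1[0], p1[1], 0.0, np.inf)
    baseline = _dexp(t - t[0], *p)
    delta = np.where(outside, 0.0, baseline - y)
    return DetrendResult(delta=delta, baseline=baseline, params=tuple(p),
                         single_exp_fallback=fallback)


@dataclass
class NeighborCorrection:
    r_target: float
    target_final: float
    neighbor_finals: np.ndarray
    n_clipped: int = 0

    def corrected_current(self, delta_I_Ca: float | np.ndarray):
        """Eq.-style neighbor correction: dI'_Ca = dI_Ca * r_target."""
        return np.asarray(delta_I_Ca) * self.r_target


def neighbor_correction(
    target_final: float,
    neighbor_finals: np.ndarray | list[float],
) -> NeighborCorrection:
    """Fractional contribution of the targeted AZ to the total signal
    change: ``r_target = target / (target + sum(neighbors))``.

    Neighbor final values are the line-fit values at the end of the
    iontophoresis window (see :func:`neighbor_final_values`); small
    negative values (noise) are clipped to zero and counted.
    """
    if target_final <= 0:
        raise InvalidRecordingError("targeted AZ shows no suppression")
    nb = np.asarray(neighbor_finals, dtype=float).ravel()
    n_clipped = int((nb < 0).sum())
    nb = np.clip(nb, 0.0, None)
    r = target_final / (target_final + nb.sum())
    return NeighborCorrection(
        r_target=float(r),
        target_final=float(target_final),
        neighbor_finals=nb,
        n_clipped=n_clipped,
    )


def neighbor_final_values(
    time_s: np.ndarray,
    delta_traces: np.ndarray,
    ionto_window_s: tuple[float, float],
) -> np.ndarray:
    """Line fit to each suppression trace over the iontophoresis window,
    evaluated at the window end."""
    t = np.asarray(time_s, dtype=float)
    w0, w1 = ionto_window_s
    m = (t >= w0) & (t <= w1)
    finals = []
    for tr in np.atleast_2d(delta_traces):
        res = linregress(t[m], tr[m])
        finals.append(res.intercept + res.slope * w1)
    return np.asarray(finals)


@dataclass
class SlopeFit:
    slope_pA_per_dff: float
    intercept_pA: float
    r_squared: float


def current_fluorescence_slope(
    delta_I_pA: np.ndarray,
    delta_dff: np.ndarray,
) -> SlopeFit:
    """OLS slope of the whole-cell current change against the AZ
    fluorescence change during the EGTA ramp (free intercept).

    The convention is suppression magnitudes, both positive, so the slope
    is invariant to the recording's inward-current sign convention.
    """
    x = np.asarray(delta_dff, dtype=float)
    y = np.asarray(delta_I_pA, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired samples")
    if np.ptp(x) <= 0:
        raise ValueError("degenerate dF/F0 range")
    res = linregress(x, y)
    return SlopeFit(float(res.slope), float(res.intercept),
                    float(res.rvalue**2))


def channels_from_current(
    I_AZ_pA: float,
    i_single_pA: float = 0.29,
    p_open: float = 0.4,
) -> float:
    """Channel count from the synaptic Ca2+ current:
    ``N = I_AZ / (i_single * p_open)``.

    The default single-channel current (0.29 pA at −7 mV, 5 mM external
    Ca2+) and open probability 0.4 are the standard conversion constants;
    0.82 substitutes for p_open under the BayK8644 agonist.  Returned as a
    real number; round half-to-even for an integer display.
    """
    if i_single_pA <= 0 or not (0 < p_open <= 1):
        raise ValueError("need i_single > 0 and 0 < p_open <= 1")
    if I_AZ_pA < 0:
        raise ValueError("I_AZ must be >= 0")
    return I_AZ_pA / (i_single_pA * p_open)


@dataclass
class SynapticCurrentEstimate:
    """End-to-end result of one iontophoresis recording."""

    r_target: float
    slope_pA_per_dff: float
    dff_max: float
    I_AZ_pA: float
    N_channels: float
    i_single_pA: float
    p_open: float
    slope_r_squared: float


def analyze_recording(
    rec: IontophoresisRecording,
    i_single_pA: float = 0.29,
    p_open: float = 0.4,
) -> SynapticCurrentEstimate:
    """Full pipeline: detrend target and current traces, correct for
    neighbor bleed, fit the current-fluorescence slope, convert the
    maximal dF/F0 to a synaptic current and a channel count."""
    tgt = detrend_double_exp(rec.time_s, rec.target_dff, rec.ionto_window_s)
    cur = detrend_double_exp(rec.time_s, np.abs(rec.current_pA),
                             rec.ionto_window_s)
    m = rec.window_mask()
    if rec.neighbor_dffs.shape[0]:
        nb_deltas = np.stack([
            detrend_double_exp(rec.time_s, nb, rec.ionto_window_s).delta
            for nb in rec.neighbor_dffs
        ])
        nb_final = neighbor_final_values(rec.time_s, nb_deltas,
                                         rec.ionto_window_s)
    else:
        nb_final = np.empty(0)
    tgt_final = neighbor_final_values(rec.time_s, tgt.delta[None, :],
                                      rec.ionto_window_s)[0]
    corr = neighbor_correction(tgt_final, nb_final)
    d_current = corr.corrected_current(cur.delta[m])
    slope = current_fluorescence_slope(d_current, tgt.delta[m])
    pre = rec.time_s < rec.ionto_window_s[0]
    dff_max = float(rec.target_dff[pre].max())
    i_az = slope.slope_pA_per_dff * dff_max
    return SynapticCurrentEstimate(
        r_target=corr.r_target,
        slope_pA_per_dff=slope.slope_pA_per_dff,
        dff_max=dff_max,
        I_AZ_pA=i_az,
        N_channels=channels_from_current(i_az, i_single_pA, p_open),
        i_single_pA=i_single_pA,
        p_open=p_open,
        slope_r_squared=slope.r_squared,
    )
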