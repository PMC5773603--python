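"""Non-stationary fluctuation analysis for ion-channel counting.

Trial-to-trial fluctuations of an ensemble of fluorescence (or whole-cell
current) responses carry information about the unitary event underlying
them: for ``N`` independent two-state channels with open probability
``p(t)``, variance and mean obey the parabola

    var(t) = f_s * S_mean(t) - S_mean(t)**2 / N,

where ``f_s`` is the single-channel contribution (fluorescence increment
or unitary current) and ``S_mean`` the ensemble mean.  The variance is
estimated with the successive-trial-difference estimator, which suppresses
slow rundown/drift across the ensemble; baseline (shot + detector) noise
measured before the stimulus is subtracted, fluorescence curves are
block-subsampled against temporal correlation, and the parabola is fitted
by iteratively reweighted (estimated generalized) least squares.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np

__all__ = [
    "TrialEnsemble",
    "VarianceMeanCurve",
    "ParabolicFit",
    "RejectedFitError",
    "ensemble_variance",
    "subsample",
    "fit_variance_mean",
    "estimate_channels",
]


class RejectedFitError(RuntimeError):
    """The variance-mean fit produced unphysical parameters."""


@dataclass
class TrialEnsemble:
    """K repeated trials of a sampled signal (rows = trials).

    ``baseline`` is the (start, stop) index window before the stimulus
    used to estimate shot/detector noise.  ``kind`` selects the processing
    path: fluorescence ensembles are subsampled before fitting, current
    ensembles are not.  Deactivating (inward) tail currents may be stored
    with negative polarity; the sign is resolved globally during variance
    estimation so the mean signal comes out positive either way.
    """

    trials: np.ndarray
    rate_hz: float
    kind: Literal["fluorescence", "current"] = "fluorescence"
    baseline: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        self.trials = np.atleast_2d(np.asarray(self.trials, dtype=float))
        if self.trials.shape[0] < 2:
            raise ValueError("need at least K = 2 trials")
        if not np.isfinite(self.trials).all():
            raise ValueError("trials contain non-finite values")
        b0, b1 = self.baseline
        if not (0 <= b0 < b1 <= self.trials.shape[1]):
            raise ValueError("baseline window empty or out of range")

    @property
    def K(self) -> int:
        return self.trials.shape[0]


@dataclass
class VarianceMeanCurve:
    """Ensemble mean and successive-difference variance versus time."""

    S_mean: np.ndarray
    variance: np.ndarray
    K: int
    baseline_variance: float = 0.0
    baseline_mean: float = 0.0

    @property
    def excess_variance(self) -> np.ndarray:
        return self.variance - self.baseline_variance

    @property
    def signal(self) -> np.ndarray:
        """Mean above the pre-stimulus baseline."""
        return self.S_mean - self.baseline_mean


@dataclass
class ParabolicFit:
    """Estimated unitary contribution and channel count."""

    f_s: float
    N: float
    covariance: np.ndarray
    weighting: str
    iterations: int = 1
    low_K: bool = False

    @property
    def peak_signal(self) -> float:
        """Mean signal at which the gating variance peaks, f_s*N/2."""
        return self.f_s * self.N / 2.0


def ensemble_variance(ens: TrialEnsemble) -> VarianceMeanCurve:
    """Mean and successive-difference variance of the ensemble:

    ``sigma^2(t) = 1/(2(K-1)) * sum_i [x_i(t) - x_{i+1}(t)]^2``.

    Differencing consecutive trials removes components that drift slowly
    over the ensemble (bleaching, rundown) which would inflate the plain
    across-trial variance.  The pre-stimulus window provides the baseline
    variance and baseline mean.
    """
    x = ens.trials
    b0, b1 = ens.baseline
    # resolve polarity globally so deactivating inward (negative) currents
    # yield a positive mean signal; per-sample rectification would fold
    # the noise distribution
    mean0 = x.mean(axis=0)
    dev = mean0 - mean0[b0:b1].mean()
    if dev[np.argmax(np.abs(dev))] < 0:
        x = -x
    k = ens.K
    diff = np.diff(x, axis=0)
    var = (diff**2).sum(axis=0) / (2.0 * (k - 1))
    mean = x.mean(axis=0)
    return VarianceMeanCurve(
        S_mean=mean,
        variance=var,
        K=k,
        baseline_variance=float(var[b0:b1].mean()),
        baseline_mean=float(mean[b0:b1].mean()),
    )


def subsample(trace: np.ndarray, factor: int) -> np.ndarray:
    """Non-overlapping block means along the last axis (e.g. factor 3
    takes 2 kHz data to 667 Hz).  A trailing partial block is dropped."""
    if factor < 1 or int(factor) != factor:
        raise ValueError("factor must be a positive integer")
    trace = np.asarray(trace, dtype=float)
    n = trace.shape[-1]
    if factor > n:
        raise ValueError("factor exceeds trace length")
    m = n // factor
    shape = trace.shape[:-1] + (m, int(factor))
    return trace[..., : m * factor].reshape(shape).mean(axis=-1)


#: additive floor in the EGLS weight denominator, in units of the squared
#: predicted variance scale, guarding against infinite weights where the
#: predicted variance vanishes
EGLS_FLOOR_FRACTION = 1e-3


def fit_variance_mean(
    curve: VarianceMeanCurve,
    weighting: Literal["EGLS", "uniform"] = "EGLS",
    tol: float = 1e-6,
    max_iter: int = 20,
) -> ParabolicFit:
    """Fit ``var = f_s*S - S^2/N`` to baseline-subtracted variance.

    The model is linear in ``(f_s, 1/N)``.  EGLS mode iterates: ordinary
    least squares, then weights ``w = (K-1) / (2*sigma_pred^4 + floor)``
    from the normal-theory variance of a variance estimate, refitting
    until the parameters move less than ``tol`` (relative).
    """
    s = np.asarray(curve.signal, dtype=float)
    v = np.asarray(curve.excess_variance, dtype=float)
    use = s > 0
    s, v = s[use], v[use]
    if s.size < 5:
        raise ValueError("need at least 5 usable variance-mean points")
    if not (v > 0).any():
        raise RejectedFitError("no positive excess variance to fit")
    design = np.stack([s, -(s**2)], axis=1)
    w = np.ones_like(s)
    theta = None
    floor = None
    for it in range(1, max_iter + 1):
        a = design * np.sqrt(w)[:, None]
        y = v * np.sqrt(w)
        theta_new, *_ = np.linalg.lstsq(a, y, rcond=None)
        if theta is not None and np.all(
            np.abs(theta_new - theta) <= tol * np.maximum(np.abs(theta), 1e-12)
        ):
            theta = theta_new
            break
        theta = theta_new
        if weighting == "uniform":
            break
        pred = design @ theta
        if floor is None:
            floor = EGLS_FLOOR_FRACTION * float(np.max(pred**2, initial=0.0) + 1e-300)
        w = (curve.K - 1) / (2.0 * pred**2 + floor)
    f_s, inv_n = theta
    if f_s <= 0 or inv_n <= 0:
        raise RejectedFitError(
            f"unphysical parameters: f_s = {f_s:.3g}, 1/N = {inv_n:.3g}")
    a = design * np.sqrt(w)[:, None]
    try:
        cov = np.linalg.inv(a.T @ a)
    except np.linalg.LinAlgError as exc:
        raise RejectedFitError("singular design matrix") from exc
    resid = a @ theta - v * np.sqrt(w)
    s2 = float(resid @ resid) / max(s.size - 2, 1)
    return ParabolicFit(
        f_s=float(f_s),
        N=float(1.0 / inv_n),
        covariance=cov * s2,
        weighting=weighting,
        iterations=it,
    )


def estimate_channels(
    ens: TrialEnsemble,
    weighting: Literal["EGLS", "uniform"] = "EGLS",
    subsample_factor: int = 3,
) -> ParabolicFit:
    """Full pipeline: variance estimation, baseline subtraction,
    subsampling (fluorescence only) and the weighted parabolic fit.

    Fluorescence ensembles acquired at 2 kHz use ``subsample_factor=3``
    (to 667 Hz) against neighbor-sample correlation; current ensembles are
    fitted at full bandwidth.  A minimal K = 2 ensemble is processed but
    flagged unreliable.
    """
    curve = ensemble_variance(ens)
    s = curve.signal
    v = curve.excess_variance
    if ens.kind == "fluorescence" and subsample_factor > 1:
        s = subsample(s, subsample_factor)
        v = subsample(v, subsample_factor)
    sub = VarianceMeanCurve(
        S_mean=s, variance=v, K=curve.K, baseline_variance=0.0,
        baseline_mean=0.0)
    low_k = ens.K < 10
    if low_k:
        warnings.warn(f"K = {ens.K} trials: variance estimates are "
                      "unreliable at this ensemble size")
    fit = fit_variance_mean(sub, weighting=weighting)
    fit.low_K = low_k
    return fit
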