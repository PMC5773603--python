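"""Synthetic-data generators with serialized ground truth.

Every analysis stage in this package has a generative counterpart here
producing inputs with the statistical structure the analysis assumes:
photon-decay histograms (two indicator states convolved with a Gaussian
IRF under Poisson counting noise, with optional STED artifacts and a
Ca2+-insensitive dye fraction), binomially gating channel ensembles with
shot and detector noise, rotated Gaussian hotspot images, and
EGTA-iontophoresis time courses with bleaching envelopes and neighbor
bleed.  Each generator returns its ground truth alongside the data so
round-trip recovery tests close the loop without any experimental input.

All generators are deterministic for a given spec and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .flim import DecayHistogram, IRF, LifetimePair, gaussian_irf
from .fluctuation import TrialEnsemble
from .iontophoresis import IontophoresisRecording
from .morphometry import HotspotImage

__all__ = [
    "DecayGenSpec",
    "GatingGenSpec",
    "gen_decay_histogram",
    "gen_gating_ensemble",
    "gen_hotspot_image",
    "gen_iontophoresis_recording",
    "solution_free_calcium",
]


@dataclass(frozen=True)
class DecayGenSpec:
    """Generative model of a TCSPC histogram at a known [Ca2+].

    The responsive dye partitions between bound and free states by the
    binding isotherm at ``K_eff``; bound-state photons are upweighted by
    the brightness factor and, under STED, by the relative focal volume
    ``s`` (equivalently, free photons sampled from the larger free-dye
    volume are upweighted by 1/s).  An optional Ca2+-insensitive fraction
    contributes a fixed state mix regardless of [Ca2+]; under STED a fast
    depletion-quenching component (tau = 0.19 ns, confined to the STED
    pulse) is added.
    """

    ca_uM: float
    K_eff: float = 195.0
    photons: float = 1e5
    lifetimes: LifetimePair = field(default_factory=LifetimePair)
    brightness: float = 28.02
    sted: bool = False
    s: float = 0.491
    fast_fraction: float = 0.1
    fast_tau_ns: float = 0.19
    fast_window_ps: float = 300.0
    insensitive_fraction: float = 0.0
    insensitive_bound_mix: float = 0.05
    irf_fwhm_ps: float = 110.0
    irf_t0_ns: float = 12.2
    n_bins: int = 1024
    bin_ps: float = 25.0
    #: True: ``photons`` is the expected total of this histogram.
    #: False: ``photons`` is a fixed exposure scale, so brighter pixels
    #: (more bound dye) yield more photons — required for matched
    #: stimulated/resting pixel pairs.
    normalize_total: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.photons < 1:
            raise ValueError("need at least one photon")
        for frac in (self.insensitive_fraction, self.insensitive_bound_mix,
                     self.fast_fraction):
            if not (0 <= frac <= 1):
                raise ValueError("fractions must lie in [0, 1]")
        if self.ca_uM < 0 or self.K_eff <= 0:
            raise ValueError("need ca >= 0 and K_eff > 0")


def gen_decay_histogram(
    spec: DecayGenSpec,
) -> tuple[DecayHistogram, IRF, dict]:
    """Sample a photon-decay histogram; returns (histogram, matching IRF,
    ground truth).

    The truth record carries the expected per-state photon counts and the
    correction constants (including the implied in-cell r_min/r_max of the
    insensitive-fraction model) that make the estimate chain exact in
    expectation.
    """
    rng = np.random.default_rng(spec.seed)
    p = spec.ca_uM / (spec.ca_uM + spec.K_eff)
    f = spec.insensitive_fraction
    q = spec.insensitive_bound_mix
    occ_bound = (1 - f) * p + f * q
    occ_free = 1.0 - occ_bound
    vol_bound = spec.s if spec.sted else 1.0  # relative focal volume
    w_bound = occ_bound * spec.brightness * vol_bound
    w_free = occ_free * 1.0
    w_sum = (w_bound + w_free) if spec.normalize_total else 1.0
    n_main = spec.photons
    n_fast_exp = (spec.fast_fraction * n_main / (1 - spec.fast_fraction)
                  if spec.sted else 0.0)
    n_bound = rng.poisson(n_main * w_bound / w_sum)
    n_free = rng.poisson(n_main * w_free / w_sum)
    n_fast = rng.poisson(n_fast_exp) if n_fast_exp else 0

    sigma_ns = spec.irf_fwhm_ps * 1e-3 / (2 * math.sqrt(2 * math.log(2)))
    taus = spec.lifetimes

    def sample(n: int, tau: float, truncate_ns: float | None = None):
        if n == 0:
            return np.empty(0)
        if truncate_ns is None:
            emit = rng.exponential(tau, n)
        else:  # depletion-pulse component exists only during the pulse
            u = rng.uniform(0, 1 - math.exp(-truncate_ns / tau), n)
            emit = -tau * np.log1p(-u)
        return spec.irf_t0_ns + rng.normal(0.0, sigma_ns, n) + emit

    times = np.concatenate([
        sample(n_free, taus.tau_free_ns),
        sample(n_bound, taus.tau_bound_ns),
        sample(n_fast, spec.fast_tau_ns, truncate_ns=spec.fast_window_ps * 1e-3),
    ])
    span = spec.n_bins * spec.bin_ps * 1e-3
    counts, _ = np.histogram(times, bins=spec.n_bins, range=(0.0, span))
    hist = DecayHistogram(
        counts, spec.bin_ps,
        mode="sted" if spec.sted else "confocal",
    )
    irf = gaussian_irf(spec.irf_fwhm_ps, spec.irf_t0_ns, spec.n_bins,
                       spec.bin_ps)
    truth = {
        "ca_uM": spec.ca_uM,
        "bound_fraction_responsive": p,
        "occ_bound": occ_bound,
        "F_bound_expected": n_main * w_bound / w_sum,
        "F_free_expected": n_main * w_free / w_sum,
        "n_bound": int(n_bound),
        "n_free": int(n_free),
        "n_fast": int(n_fast),
        "b": spec.brightness,
        "s": spec.s if spec.sted else 1.0,
        "K_eff": spec.K_eff,
        # implied in-cell calibration of the insensitive-fraction model
        "r_min": f * q,
        "r_max": 1.0 - f + f * q,
        "seed": spec.seed,
    }
    return hist, irf, truth


@dataclass(frozen=True)
class GatingGenSpec:
    """Generative model of a channel-gating trial ensemble.

    ``N`` two-state channels gate as Markov chains whose stationary open
    probability tracks a deactivation-like target course (peak ``p_peak``
    decaying with ``deact_tau_ms``); the correlation time defaults to
    values long against the sampling interval (agonist-prolonged open
    times).  The fluorescence signal is ``f_s`` counts per open channel
    plus background, with Poisson shot noise and Gaussian detector noise;
    current ensembles carry inward (negative) polarity and Gaussian noise
    only.  Optional extras emulate indicator binding kinetics (first-order
    low pass) and uneven per-channel detection across the cluster
    (truncated-Gaussian PSF weights).
    """

    N: int = 100
    f_s: float = 5.0
    K: int = 200
    rate_hz: float = 2000.0
    p_peak: float = 0.4
    deact_tau_ms: float = 10.0
    n_baseline: int = 40
    n_samples: int = 160
    corr_time_ms: float = 5.0
    background: float = 50.0
    detector_sigma: float = 2.0
    kind: str = "fluorescence"
    indicator_tau_ms: float = 0.0
    psf_weights: bool = False
    psf_weight_cv: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.N < 1 or self.K < 2:
            raise ValueError("need N >= 1 and K >= 2")
        if not (0 <= self.p_peak <= 1):
            raise ValueError("p_peak must lie in [0, 1]")

    def p_course(self) -> np.ndarray:
        """Target open probability per sample: zero during the baseline,
        then an exponential deactivation from the peak."""
        dt_ms = 1e3 / self.rate_hz
        t = np.arange(self.n_samples - self.n_baseline) * dt_ms
        course = np.zeros(self.n_samples)
        course[self.n_baseline:] = self.p_peak * np.exp(-t / self.deact_tau_ms)
        return course


def gen_gating_ensemble(spec: GatingGenSpec) -> tuple[TrialEnsemble, dict]:
    """Simulate the trial ensemble; returns (ensemble, ground truth)."""
    rng = np.random.default_rng(spec.seed)
    p_t = spec.p_course()
    dt_ms = 1e3 / spec.rate_hz
    n_open = rng.binomial(spec.N, p_t[0], size=spec.K)

    if spec.psf_weights:
        w = 1.0 + spec.psf_weight_cv * rng.standard_normal(spec.N)
        w = np.clip(w, 0.0, None)
        track_channels = True
        open_state = np.zeros((spec.K, spec.N), dtype=bool)
        for kk in range(spec.K):
            open_state[kk, : n_open[kk]] = True
    else:
        w = None
        track_channels = False

    signal = np.empty((spec.K, spec.n_samples))
    relax = 1.0 - math.exp(-dt_ms / spec.corr_time_ms)
    for j, p in enumerate(p_t):
        # exact per-step transition probabilities of a two-state chain with
        # stationary open probability p and relaxation time corr_time_ms
        po = p * relax
        pc = (1.0 - p) * relax
        if track_channels:
            flip_open = rng.random((spec.K, spec.N)) < po
            flip_close = rng.random((spec.K, spec.N)) < pc
            open_state = np.where(open_state, ~flip_close, flip_open)
            contrib = (open_state * w).sum(axis=1)
        else:
            stay = rng.binomial(n_open, 1.0 - pc)
            recruit = rng.binomial(spec.N - n_open, po)
            n_open = stay + recruit
            contrib = n_open.astype(float)
        signal[:, j] = contrib

    if spec.indicator_tau_ms > 0:
        a = math.exp(-dt_ms / spec.indicator_tau_ms)
        for j in range(1, spec.n_samples):
            signal[:, j] = a * signal[:, j - 1] + (1 - a) * signal[:, j]

    if spec.kind == "fluorescence":
        rate = spec.f_s * signal + spec.background
        trials = rng.poisson(rate).astype(float)
        trials += rng.normal(0.0, spec.detector_sigma, trials.shape)
    else:
        trials = -(spec.f_s * signal)
        trials += rng.normal(0.0, spec.detector_sigma, trials.shape)

    ens = TrialEnsemble(
        trials=trials,
        rate_hz=spec.rate_hz,
        kind="fluorescence" if spec.kind == "fluorescence" else "current",
        baseline=(0, spec.n_baseline),
    )
    truth = {"N": spec.N, "f_s": spec.f_s, "seed": spec.seed,
             "p_peak": spec.p_peak}
    return ens, truth


def gen_hotspot_image(
    amplitude: float = 100.0,
    fwhm_nm: tuple[float, float] = (200.0, 400.0),
    angle_deg: float = 0.0,
    offset: float = 10.0,
    pixel_nm: float = 20.0,
    shape: tuple[int, int] = (48, 48),
    center_px: tuple[float, float] | None = None,
    noise: str = "poisson",
    seed: int = 0,
) -> tuple[HotspotImage, dict]:
    """Rotated 2D Gaussian hotspot plus offset and counting noise.

    ``noise`` is 'poisson', 'gaussian' (sigma = sqrt(offset)) or 'none'.
    """
    rng = np.random.default_rng(seed)
    ny, nx = shape
    cy, cx = center_px if center_px is not None else ((ny - 1) / 2, (nx - 1) / 2)
    yy, xx = np.mgrid[0:ny, 0:nx]
    th = math.radians(angle_deg)
    fw = 2 * math.sqrt(2 * math.log(2))
    s_long = max(fwhm_nm) / fw / pixel_nm
    s_short = min(fwhm_nm) / fw / pixel_nm
    xr = (xx - cx) * math.cos(th) + (yy - cy) * math.sin(th)
    yr = -(xx - cx) * math.sin(th) + (yy - cy) * math.cos(th)
    clean = offset + amplitude * np.exp(
        -0.5 * ((xr / s_long) ** 2 + (yr / s_short) ** 2))
    if noise == "poisson":
        img = rng.poisson(clean).astype(float)
    elif noise == "gaussian":
        img = clean + rng.normal(0.0, math.sqrt(max(offset, 1.0)), clean.shape)
    elif noise == "none":
        img = clean
    else:
        raise ValueError(f"unknown noise model {noise!r}")
    truth = {
        "amplitude": amplitude,
        "fwhm_short_nm": min(fwhm_nm),
        "fwhm_long_nm": max(fwhm_nm),
        "angle_deg": angle_deg % 180.0,
        "offset": offset,
        "center_px": (cx, cy),
        "seed": seed,
    }
    return HotspotImage(img, pixel_nm), truth


def gen_iontophoresis_recording(
    N_true: int = 100,
    dff_max: float = 1.0,
    i_single_pA: float = 0.29,
    p_open: float = 0.4,
    suppression_floor: float = 0.52,
    bleach_taus_s: tuple[float, float] = (60.0, 8.0),
    bleach_weights: tuple[float, float] = (0.85, 0.15),
    neighbor_bleed: tuple[float, ...] = (0.08, 0.04),
    other_current_pA: float = 150.0,
    noise_dff: float = 0.0,
    noise_pA: float = 0.0,
    rate_hz: float = 20.0,
    duration_s: float = 12.0,
    ionto_window_s: tuple[float, float] = (4.0, 8.0),
    seed: int = 0,
) -> tuple[IontophoresisRecording, dict]:
    """Synthetic EGTA-iontophoresis experiment.

    The targeted AZ's dF/F0 rides a double-exponential bleaching envelope
    and is suppressed ramp-wise during the window (down to
    ``suppression_floor``, the study-typical endpoint); each neighbor AZ
    is suppressed by its bleed fraction of the target's suppression.  The
    whole-cell current sums a constant remainder and all AZ currents with
    a common pA-per-dF/F0 slope fixed by the ground-truth channel count.
    """
    rng = np.random.default_rng(seed)
    n = int(duration_s * rate_hz) + 1
    t = np.arange(n) / rate_hz
    w0, w1 = ionto_window_s
    a1, a2 = bleach_weights
    env = (a1 * np.exp(-t / bleach_taus_s[0])
           + a2 * np.exp(-t / bleach_taus_s[1])) / (a1 + a2)
    ramp = np.clip((t - w0) / (w1 - w0), 0.0, 1.0)
    inside = (t >= w0) & (t <= w1)
    supp = np.where(inside, 1.0 - (1.0 - suppression_floor) * ramp[...], 1.0)
    supp = np.where(t > w1, 1.0, supp)

    I_AZ = N_true * i_single_pA * p_open
    slope = I_AZ / dff_max

    target = dff_max * env * supp
    neighbors = []
    for fb in neighbor_bleed:
        nb_supp = 1.0 - fb * (1.0 - supp)
        neighbors.append(dff_max * env * nb_supp)
    neighbors = np.array(neighbors) if neighbors else np.empty((0, n))

    total_drop = slope * (dff_max * env * (1.0 - supp)) * (
        1.0 + sum(neighbor_bleed))
    current = -(other_current_pA + I_AZ * env - total_drop)

    target = target + rng.normal(0.0, noise_dff, n)
    if len(neighbors):
        neighbors = neighbors + rng.normal(0.0, noise_dff, neighbors.shape)
    current = current + rng.normal(0.0, noise_pA, n)

    rec = IontophoresisRecording(
        time_s=t,
        target_dff=target,
        neighbor_dffs=neighbors,
        current_pA=current,
        ionto_window_s=ionto_window_s,
    )
    truth = {
        "N": N_true,
        "slope_pA_per_dff": slope,
        "I_AZ_pA": I_AZ,
        "r_target": 1.0 / (1.0 + sum(neighbor_bleed)),
        "dff_max": dff_max,
        "seed": seed,
    }
    return rec, truth


def solution_free_calcium(
    ca_total_uM: float,
    buffers: list[tuple[float, float]],
) -> float:
    """Free [Ca2+] of a solution with total Ca and a list of
    ``(total_concentration_uM, K_D_uM)`` buffers.

    Solves the conservation equation
    ``Ca_total = Ca_free + sum_i B_i * Ca_free / (Ca_free + K_D_i)``
    by bracketed root finding (relative tolerance 1e-9).
    """
    if ca_total_uM < 0:
        raise ValueError("total Ca must be >= 0")
    for btot, kd in buffers:
        if btot < 0 or kd <= 0:
            raise ValueError("buffer totals must be >= 0 and K_D > 0")
    if ca_total_uM == 0:
        return 0.0
    if not buffers:
        return ca_total_uM

    def residual(free: float) -> float:
        bound = sum(b * free / (free + kd) for b, kd in buffers)
        return free + bound - ca_total_uM

    lo = ca_total_uM * 1e-15
    if residual(lo) > 0:
        return ca_total_uM  # buffers negligible at this scale
    return brentq(residual, lo, ca_total_uM, rtol=1e-9)
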