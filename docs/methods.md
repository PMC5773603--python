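# Methods

`azcal` quantifies presynaptic Ca²⁺ signaling at single active zones (AZs)
of cochlear inner hair cells along four largely independent analysis
chains: a buffered reaction–diffusion model of the Ca²⁺ nanodomain with
imaging emulation, a TCSPC fluorescence-lifetime pipeline converting photon
decays into [Ca²⁺], non-stationary fluctuation analysis for channel
counting, and the EGTA-iontophoresis channel-counting analysis.  Every
chain has a generative counterpart in `azcal.synthetic`, so all claims the
test suite makes are closed generator→analysis round trips.

## Reaction–diffusion model (`azcal.rd`)

**Model.** Free Ca²⁺ (D = 0.223 µm²/ms) and six buffers — an immobile
fixed buffer, EGTA, BAPTA, the indicator OGB-5N, ATP (Mg²⁺-corrected
effective concentration) and gluconate — react and diffuse in a
rectangular box (default 800 × 800 × 300 nm) above a flat membrane.  Each
buffer is a single-site binder with mass-action kinetics
(`k_off = K_D · k_on`); free and bound forms share one diffusion
coefficient.  Ca²⁺ enters at a 430 × 67 nm cluster of 120 point channels
(single-channel current 0.137 pA at 1.3 mM external Ca²⁺, open
probability 0.4, mean-field flux `i/(2e) · p_open` deposited into the
nearest membrane-plane node).  Side and top faces clamp every species at
its resting equilibrium (50 nM free Ca²⁺); the membrane face is
reflective.  Channel positions come from seeded rejection sampling with a
10 nm minimum spacing; the layout beyond these constraints is not
prescribed, and the smooth indicator-ratio readout is insensitive to it.

**Readout.** The "reported" [Ca²⁺] map is
`K_D · [dye_bound]/[dye_free]` (K_D = 195 µM, the indicator's effective
in-cell dissociation constant), optionally after convolving both dye
fields with an anisotropic Gaussian PSF (64 × 64 × 542 nm STED,
243 × 243 × 542 nm confocal).  The convolution treats the simulated box
the way a microscope treats a specimen with dye only inside the cell:
zero padding on all faces.  Because bound and free dye are attenuated
identically by the padding, the ratio is unbiased wherever free dye
retains mass.  Domain size is measured as the FWHM of axis profiles
through the map maximum, half-max crossings interpolated linearly.

**Numerics.** Explicit operator-split forward Euler (diffusion by
7-point finite differences, reactions pointwise) in a numba kernel.
Because both forms of each buffer diffuse equally and start uniform, each
buffer's total stays spatially uniform for all time; only free Ca²⁺ and
the bound forms are stored, and `free = total − bound` exactly — this
also makes per-buffer mass conservation structural.  The automatic time
step respects the combined stability bound
`dt < 2/(12·D_max/h² + Σ k_on·B_total + max k_off)` with a 25% margin:
the classic diffusive criterion `h²/(6·D_max)` alone is insufficient here
because the high-concentration, fast-exchanging gluconate pool adds a
reaction rate of ~1.4 × 10⁴ ms⁻¹ (the pure-diffusion criterion is still
enforced as a hard error for user-specified steps).  A quarter-volume
mode exploits the centered cluster: channel positions fold into one
quadrant with flux/4 per mirror image, exactly equivalent to the
symmetrized full problem (bit-identical for symmetric layouts, ≲1% on
the smooth reported map for random ones).  Correctness anchors: the
buffer-free single channel matches the half-space point-source transient
`C = Φ/(2πDr)·erfc(r/√(4Dt))` within 5% from four node spacings; a fully
reflective box conserves total Ca²⁺ to < 10⁻⁶ relative (trapezoidal node
volumes); peak readouts change < 10% when the grid is halved.

**Problem sizes.** Routine analyses and the acceptance script run the
model at a 10-nm node spacing with quarter symmetry (≈52,000 nodes,
≈31,000 steps per ms); the package's native default is the 5-nm spacing,
and `scripts/confirm_fine_grid.py` repeats the baseline run there.  At
matched conditions the 10- and 5-nm reported-[Ca²⁺] peaks differ by
about 1%, while the single-voxel free-Ca²⁺ peak — a near-singular
point-source quantity — remains grid-sensitive by construction.

**A known discrepancy.** With the published parameter table implemented
verbatim, the model reproduces the published free-Ca²⁺ peak near the
channels (~100–150 µM, grid-dependent), the STED-convolved reported peak
(~10 µM) and both convolved domain FWHMs, but the *unconvolved*
reported-[Ca²⁺] peak converges to ~31–32 µM rather than the ~40–45 µM
published for these three buffer conditions.
Diagnostics ruled out grid resolution, the quarter-symmetry fold, and an
alternative indicator-kinetics reading (literature K_D in the kinetics
inflates the readout to ~76 µM and the free Ca²⁺ to values inconsistent
with the published range).  Removing gluconate raises the readout to ~66 µM but
also pushes free Ca²⁺ to ~220 µM, again outside the published range.  We therefore keep
the parameter table as written and report the computed values.
Relatedly, the *reported* peak keeps creeping after the free-Ca²⁺ field
has stabilized — indicator redistribution is slower than nanodomain
equilibration — reaching 95% of its 1-ms value only at ~0.55–0.6 ms
(plateau 32.2 µM by 3 ms); the conventional "steady by ~0.3 ms"
expectation holds for free Ca²⁺, not for the indicator-ratio readout.

## Fluorescence-lifetime [Ca²⁺] estimation (`azcal.flim`)

**Model.** OGB-5N has two states: free (τ_U = 0.23 ns) and Ca²⁺-bound
(τ_B = 3.24 ns), both fixed during fitting.  A decay histogram (25-ps
bins, 1024 bins) is fitted by the IRF-reconvolved bi-exponential with
only the two amplitudes (and optionally the IRF/data shift, bounded to
±125 ps) free.  The objective is weighted least squares with Neyman
(Poisson, floored at one count) weights; amplitudes are solved by
non-negative linear least squares inside a scalar shift search.
Per-state photon counts are `F_i = α_i · τ_i / Δ` with Δ the bin width —
the exact discrete sum of the fitted component, identical to the
conventional `α·τ` product up to the fixed 1/Δ factor that cancels in
every downstream ratio.

**Reconvolution grid.** The model is evaluated on a 4× oversampled
internal grid: the binned IRF is refined by monotone (PCHIP)
interpolation of its cumulative curve and convolved with bin-integrated
exponentials centered on the IRF masses, then re-binned.  Same-grid
discrete convolution of two bin-integrated curves effectively widens the
IRF by ~Δ/√12 and biased the minority amplitude by several percent
against continuous-time photon data; with oversampling, noiseless
analytic (exponentially-modified-Gaussian) curves are recovered to
< 0.1% for non-degenerate mixtures.

**STED blanking.** Under STED the depletion pulse adds a fast artifact
(τ ≈ 0.19 ns) during its first ~300 ps, so bins within 300 ps of the
decay onset (IRF peak + shift) are excluded; the shift is determined in a
first full-range pass and frozen (two-pass scheme), and the fitted
amplitudes remain extrapolations to the blanked onset.  On synthetic
confocal data the blanked and full-range per-channel photon counts agree
to ≤ 2.8% across 10 nM–40 µM.

**Correction chain.** Photon counts convert to fluorophore fractions via
the brightness factor b = 28.02 (bound dye is brighter; the analytic
amplitude-ratio route 1.99 × 3.24/0.23 gives 28.03, kept as a check
value) and the STED-efficiency factor s (1 confocal; presets 0.491 and
0.424 for the two standard beam powers — the power mapping is an assumed
labeling, exposed as configuration).  In-cell dynamic-range rescaling
uses r_min (0.02 confocal / 0.04 STED) and r_max = 0.6; slightly negative
rescaled fractions are clipped to zero and flagged, saturation yields
+inf with a flag.  `[Ca²⁺] = K_eff · r′_B/r′_U` (method of scaled
lifetime ratios) or the insensitive-fraction form
`K_eff · ΔF_B/(F_U,rest·b·s·R − ΔF_B)`; K_eff = 195 µM.  The two methods
agree within 20% on matched synthetic stimulated/resting pixel pairs
(the generator's insensitive fraction implies r_min = f·q and
r_max = 1 − f + f·q, making method A exact in expectation).  Hardware
time gating of the first 450 ps removes `1 − e^(−gate/τ)` of each state —
85.9% of free-dye and 13.0% of bound-dye signal in the pure-exponential
approximation; IRF broadening, which raises the measured bound-dye loss
somewhat, is deliberately not modeled.

## Fluctuation analysis (`azcal.fluctuation`)

Trial-to-trial variance uses the successive-difference estimator
`σ²(t) = Σ(x_i − x_{i+1})²/(2(K−1))`, which cancels slow drift across the
ensemble; it is unbiased for independent trials regardless of temporal
correlation within a trial.  Baseline variance (shot + detector noise,
mean over a configurable pre-stimulus window) is subtracted pointwise.
Fluorescence curves are block-averaged 3:1 (2 kHz → 667 Hz) before
fitting; block means rather than decimation are the conservative
anti-correlation choice, with the block averaging applied to the variance and mean
curves after the variance computation.  The parabola
`var = f_s·S − S²/N` is linear in (f_s, 1/N) and fitted by iteratively
reweighted least squares with normal-theory weights
`w ∝ (K−1)/(2σ⁴_pred + floor)` (floor = 10⁻³ of the squared peak
prediction, guarding against infinite weights), iterating to 10⁻⁶
relative parameter change, 20 iterations maximum — a documented stand-in
for the unavailable published error-covariance model, validated by
parameter recovery.  Inward-current ensembles are sign-normalized
globally from the ensemble mean (per-sample rectification folds the
noise distribution and destroys the parabola).  Shot noise proportional
to the mean is absorbed into f_s by the linear term and does not bias N.
Recovery under study-like conditions (K = 200; fluorescence N = 100,
f_s = 5 counts/channel, Poisson shot + Gaussian detector noise; current
N = 1900 with 10 pA amplifier noise at 100 kHz): medians within 15% of
truth over 100 seeds.

## Iontophoresis channel counting (`azcal.iontophoresis`)

The targeted AZ's dF/F₀ and the whole-cell current magnitude are each
detrended by a double exponential fitted to the segments before and after
the EGTA application window (single-exponential fallback, flagged), so
suppression appears as a positive deflection Δ.  Neighbor AZ suppressions
are line-fitted over the window and evaluated at its end;
`r_target = target/(target + Σ neighbors)` (negatives clipped and
counted) scales the whole-cell current change before the free-intercept
OLS slope of ΔI against Δ(ΔF/F₀).  The synaptic current is slope ×
maximal pre-application dF/F₀, and `N = I_AZ/(i_single · p_open)` with
defaults 0.29 pA and 0.4 (0.82 under the BayK8644 agonist preset).
End-to-end recovery on synthetic recordings (12 ± 4%-style neighbor
bleed, ramp suppression to 52%, double-exponential bleaching, noise):
median N within 10% over 100 seeds.

## Morphometry (`azcal.morphometry`)

dF/F₀ averages the central pixel and its eight neighbors of the
background-subtracted depolarization image over the same pixels of the
background (mean of pre-depolarization frames).  Hotspots are fitted by a
rotated 2D Gaussian plus offset: a seeded differential-evolution global
stage (replacing the genetic optimizers traditionally used for this) is
polished by local least squares; axes are sorted short ≤ long, the angle
reported in [0°, 180°) from the image x-axis to the long axis, FWHM =
2√(2 ln 2)·σ, integral = 2π·A·σₓσᵧ.  3D line profiles are trilinearly
interpolated; the FWHM baseline is the minimum of the two profile ends
(a convention choice — the source procedure does not state one), and
crossings are interpolated linearly.  Tests confirm the expected
projection artifact: a stripe tilted out of the plane is measurably
shorter in a 2D projection fit than along its 3D axis.

## Synthetic data (`azcal.synthetic`)

Generators emulate: photon decays (continuous emission times = Gaussian
IRF delay + exponential lifetime, binned, Poisson counts; brightness- and
volume-weighted state mix; optional Ca²⁺-insensitive fraction and
truncated STED fast component; optional fixed-exposure mode for matched
pixel pairs); gating ensembles (exact-transition two-state Markov
channels with deactivation-like drive, Poisson shot and Gaussian detector
noise, optional indicator low-pass with Fluo-4FF-like kinetics and
optional per-channel PSF weights, both off by default); hotspot images;
iontophoresis recordings; and buffered-solution equilibria (bracketed
root of the conservation equation, 10⁻⁹ relative tolerance).  They do not
emulate: detector afterpulsing/dead time, triplet states or bleaching
during STED, scanner timing artifacts, or electrode/access-resistance
effects — so passing round trips demonstrate estimator correctness under
the stated statistical model, not robustness to those instrument
non-idealities.  Every generator is bit-reproducible from (spec, seed)
and serializes its ground truth.

## Reproduction script

`python scripts/acceptance.py --seed <int> --out <json>` recomputes the
simulation-side headline numbers from scratch at the desk-scale grid
(three 1-ms runs: baseline, 400 µM indicator, 2 mM EGTA; then PSF
convolution, FWHM measurement and the steady-state timing readout),
writing one JSON object.  Runtime ≈ 3 minutes on one CPU.  The channel
seed equals the script's `--seed`.
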