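"""Buffered reaction-diffusion simulation of Ca2+ influx at an active zone.

Simulates diffusion of free Ca2+ and a set of mobile and immobile Ca2+
buffers (one of which may be a fluorescent indicator) over a rectangular
box above a flat membrane, with Ca2+ entering through a cluster of point
channels in the membrane plane.  The membrane face (z = 0) is reflective;
the remaining faces clamp every species to its resting-equilibrium value,
emulating the essentially infinite cytosolic reservoir around a single
active zone.

Units
-----
Internally all arithmetic uses µm, ms and µM.  Public constructors take
geometry in nm (the natural unit at this scale) and convert.  One µM
corresponds to 602.2 ions/µm³.

The "reported" [Ca2+] map is the concentration an indicator-based imaging
experiment would infer, K_D * [indicator_bound] / [indicator_free], and can
be computed either on the raw grid or after convolving both indicator
fields with a 3D Gaussian point-spread function.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numba import njit
from scipy.ndimage import gaussian_filter

__all__ = [
    "AVOGADRO_UM3",
    "BufferSpec",
    "ChannelCluster",
    "SimulationConfig",
    "ConcentrationFields",
    "PSFModel",
    "ReportedCalciumMap",
    "SimulationResult",
    "ihc_buffer_set",
    "equilibrate_buffers",
    "build_channel_cluster",
    "current_to_flux",
    "simulate",
    "reported_calcium",
    "convolve_psf",
    "measure_domain_fwhm",
    "total_calcium",
]

#: ions per µm³ at a concentration of 1 µM (Avogadro * 1e-21 L/µm³ * 1e-6 M)
AVOGADRO_UM3 = 602.2

_ELEMENTARY_CHARGE = 1.602176634e-19  # C

FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


class ParameterError(ValueError):
    """Invalid physical or numerical parameter."""


class GeometryError(ValueError):
    """Channel placement or grid geometry cannot be satisfied."""


class StabilityError(ValueError):
    """Explicit time step violates the diffusion stability criterion."""


class MeasurementError(RuntimeError):
    """A map does not support the requested measurement."""


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class BufferSpec:
    """Kinetics of one Ca2+ buffer species.

    Parameters
    ----------
    name : str
        Species label.
    D : float
        Diffusion coefficient of both free and Ca-bound forms, µm²/ms.
        ``D = 0`` encodes an immobile (fixed) buffer.
    K_D : float
        Dissociation constant, µM.
    k_on : float
        Association rate constant, µM⁻¹ ms⁻¹.  The dissociation rate is
        implied, ``k_off = K_D * k_on``.
    total : float
        Total concentration (free + bound), µM.
    fluorescent : bool
        True only for the indicator dye.
    """

    name: str
    D: float
    K_D: float
    k_on: float
    total: float
    fluorescent: bool = False

    def __post_init__(self) -> None:
        if self.K_D <= 0:
            raise ParameterError(f"{self.name}: K_D must be > 0")
        if self.k_on <= 0:
            raise ParameterError(f"{self.name}: k_on must be > 0")
        if self.D < 0:
            raise ParameterError(f"{self.name}: D must be >= 0")
        if self.total < 0:
            raise ParameterError(f"{self.name}: total must be >= 0")

    @property
    def k_off(self) -> float:
        """Dissociation rate, ms⁻¹."""
        return self.K_D * self.k_on

    def bound_at(self, ca: float) -> float:
        """Equilibrium Ca-bound concentration at free [Ca2+] = ``ca`` µM."""
        return self.total * ca / (ca + self.K_D)


def ihc_buffer_set(
    *,
    fixed=610.0,
    egta=800.0,
    bapta=400.0,
    ogb5n=25.0,
    atp=68.0,
    gluconate=130_000.0,
) -> tuple[BufferSpec, ...]:
    """The standard inner-hair-cell buffer mix (concentrations in µM).

    Kinetic constants are fixed; only total concentrations are adjustable
    (the quantities varied between imaging conditions).  ATP stands for the
    Mg-corrected effective ATP concentration; gluconate for the main anion
    of the pipette solution.
    """
    return (
        BufferSpec("fixed", 0.0, 4.859, 1.375, fixed),
        BufferSpec("EGTA", 0.14, 0.071, 0.0105, egta),
        BufferSpec("BAPTA", 0.14, 0.17, 0.45, bapta),
        BufferSpec("OGB-5N", 0.1, 195.0, 0.25, ogb5n, fluorescent=True),
        BufferSpec("ATP", 0.14, 2200.0, 0.013, atp),
        BufferSpec("gluconate", 0.2, 57_000.0, 0.1, gluconate),
    )


@dataclass(frozen=True)
class ChannelCluster:
    """A rectangular cluster of Ca2+ channels in the membrane plane.

    ``positions_nm`` holds (x, y) coordinates in nm relative to the cluster
    center; the rectangle extends ±length/2 in x and ±width/2 in y.
    """

    positions_nm: np.ndarray
    i_single_pA: float = 0.137
    p_open: float = 0.4
    length_nm: float = 430.0
    width_nm: float = 67.0

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions_nm, dtype=float).reshape(-1, 2)
        object.__setattr__(self, "positions_nm", pos)
        if not (0.0 <= self.p_open <= 1.0):
            raise ParameterError("p_open must lie in [0, 1]")
        if self.i_single_pA < 0:
            raise ParameterError("i_single must be >= 0")
        if (np.abs(pos[:, 0]) > self.length_nm / 2 + 1e-9).any() or (
            np.abs(pos[:, 1]) > self.width_nm / 2 + 1e-9
        ).any():
            raise GeometryError("channel positions outside cluster rectangle")

    @property
    def n_channels(self) -> int:
        return self.positions_nm.shape[0]

    def min_nn_distance(self) -> float:
        """Smallest pairwise distance between channels, nm."""
        p = self.positions_nm
        if len(p) < 2:
            return math.inf
        d = np.linalg.norm(p[:, None, :] - p[None, :, :], axis=-1)
        d[np.diag_indices(len(p))] = math.inf
        return float(d.min())


def build_channel_cluster(
    n: int,
    length_nm: float = 430.0,
    width_nm: float = 67.0,
    min_nn_nm: float = 10.0,
    seed: int = 0,
    i_single_pA: float = 0.137,
    p_open: float = 0.4,
    max_restarts: int = 200,
) -> ChannelCluster:
    """Place ``n`` channels in a centered rectangle by seeded rejection
    sampling with a minimum nearest-neighbor distance.

    Raises
    ------
    GeometryError
        If the packing cannot be realized within the retry budget (e.g.
        ``n`` exceeds the disk-packing capacity of the rectangle).
    """
    if n < 1:
        raise ParameterError("n must be >= 1")
    if length_nm <= 0 or width_nm <= 0 or min_nn_nm <= 0:
        raise ParameterError("length, width and min_nn must be > 0")
    if n == 1:
        return ChannelCluster(
            np.zeros((1, 2)), i_single_pA, p_open, length_nm, width_nm
        )
    # quick infeasibility screen: disks of radius min_nn/2 inside the
    # rectangle grown by that radius
    capacity = ((length_nm + min_nn_nm) * (width_nm + min_nn_nm)) / (
        math.pi * (min_nn_nm / 2) ** 2
    )
    rng = np.random.default_rng(seed)
    for _ in range(max_restarts):
        pts: list[tuple[float, float]] = []
        attempts = 0
        budget = 2000 * n
        while len(pts) < n and attempts < budget:
            attempts += 1
            x = rng.uniform(-length_nm / 2, length_nm / 2)
            y = rng.uniform(-width_nm / 2, width_nm / 2)
            if all(
                (x - px) ** 2 + (y - py) ** 2 >= min_nn_nm**2 for px, py in pts
            ):
                pts.append((x, y))
        if len(pts) == n:
            return ChannelCluster(
                np.array(pts), i_single_pA, p_open, length_nm, width_nm
            )
        if n > capacity:
            break
    raise GeometryError(
        f"cannot place {n} channels with min spacing {min_nn_nm} nm in "
        f"{length_nm} x {width_nm} nm (packing capacity ~{capacity:.0f})"
    )


def current_to_flux(i_pA: float) -> float:
    """Convert a single-channel Ca2+ current (pA) to an ion flux (ions/ms).

    Ca2+ carries two elementary charges, so ``flux = I / (2 e)``.
    """
    if i_pA < 0:
        raise ParameterError("current must be >= 0")
    # pA = 1e-12 C/s; per ms divide by 1000
    return i_pA * 1e-15 / (2.0 * _ELEMENTARY_CHARGE)


@dataclass(frozen=True)
class PSFModel:
    """Anisotropic Gaussian point-spread function (FWHMs in nm)."""

    fwhm_xy_nm: float
    fwhm_z_nm: float
    fwhm_y_nm: float | None = None
    z_offset_nm: float = 0.0

    def __post_init__(self) -> None:
        if self.fwhm_y_nm is None:
            object.__setattr__(self, "fwhm_y_nm", self.fwhm_xy_nm)
        if min(self.fwhm_xy_nm, self.fwhm_y_nm, self.fwhm_z_nm) <= 0:
            raise ParameterError("PSF FWHMs must be > 0")

    @property
    def sigmas_nm(self) -> tuple[float, float, float]:
        return (
            self.fwhm_xy_nm * FWHM_TO_SIGMA,
            self.fwhm_y_nm * FWHM_TO_SIGMA,
            self.fwhm_z_nm * FWHM_TO_SIGMA,
        )


#: PSF of the 2D-STED microscope emulated here
STED_PSF = PSFModel(64.0, 542.0)
#: matching confocal PSF
CONFOCAL_PSF = PSFModel(243.0, 542.0)


@dataclass
class SimulationConfig:
    """Full parameterization of one reaction-diffusion run.

    ``dt_ns=None`` selects the largest stable explicit step automatically
    (90% of the diffusive limit h²/(6·D_max)).  An explicit ``dt_ns`` that
    violates the limit raises :class:`StabilityError` naming the maximum
    admissible step.

    ``quarter=True`` simulates one x/y quadrant with mirror planes through
    the cluster center; channel positions are folded into the quadrant,
    which symmetrizes the (random) channel layout across the mirrors.
    """

    extent_nm: tuple[float, float, float] = (800.0, 800.0, 300.0)
    h_nm: float = 5.0
    dt_ns: float | None = None
    duration_ms: float = 1.0
    ca_rest_uM: float = 0.05
    buffers: tuple[BufferSpec, ...] = field(default_factory=ihc_buffer_set)
    cluster: ChannelCluster | None = None
    quarter: bool = False
    # per-face boundary condition: 'dirichlet' (clamp at rest) or 'reflect'
    bc: tuple[str, str, str, str, str, str] = (
        "dirichlet", "dirichlet",  # x low/high
        "dirichlet", "dirichlet",  # y low/high
        "reflect", "dirichlet",    # z low (membrane) / high
    )

    def __post_init__(self) -> None:
        if min(self.extent_nm) <= 0 or self.h_nm <= 0:
            raise ParameterError("extents and h must be > 0")
        for e in self.extent_nm:
            if abs(e / self.h_nm - round(e / self.h_nm)) > 1e-9:
                raise ParameterError("h must divide the domain extents")
        if self.ca_rest_uM <= 0:
            raise ParameterError("resting [Ca2+] must be > 0")
        for b in self.bc:
            if b not in ("dirichlet", "reflect"):
                raise ParameterError(f"unknown boundary condition {b!r}")

    @property
    def d_max(self) -> float:
        return max([0.223] + [b.D for b in self.buffers])

    @property
    def dt_limit_ns(self) -> float:
        """Maximal admissible explicit step, ns."""
        h_um = self.h_nm * 1e-3
        return h_um**2 / (6.0 * self.d_max) * 1e6

    @property
    def reaction_rate_scale(self) -> float:
        """Upper estimate of the fastest pointwise reaction rate, ms⁻¹."""
        if not self.buffers:
            return 0.0
        return (sum(b.k_on * b.total for b in self.buffers)
                + max(b.k_off for b in self.buffers))

    def resolve_dt_ms(self) -> float:
        if self.dt_ns is None:
            # von Neumann: the worst diffusive mode decays at 12 D/h^2 and
            # the stiffest pointwise reaction adds on top, so the explicit
            # step needs dt * (12 D/h^2 + lambda_react) < 2; a 25% safety
            # margin absorbs the nonlinear rate increase near channels
            lam = (12.0 * self.d_max / (self.h_nm * 1e-3) ** 2
                   + self.reaction_rate_scale)
            return 0.75 * 2.0 / lam
        if self.dt_ns > self.dt_limit_ns:
            raise StabilityError(
                f"dt = {self.dt_ns:g} ns violates the explicit stability "
                f"criterion; maximal admissible dt = {self.dt_limit_ns:.3g} ns "
                f"for h = {self.h_nm:g} nm and D_max = {self.d_max:g} um^2/ms"
            )
        return self.dt_ns * 1e-6


D_CA = 0.223  # free Ca2+ diffusion coefficient, µm²/ms


@dataclass
class ConcentrationFields:
    """Per-species concentration state on the simulation grid (µM).

    Only free Ca2+ and the Ca-bound form of each buffer are stored: free
    and bound forms of a buffer share one diffusion coefficient, so the
    buffer total stays spatially uniform for all time and the free form is
    ``total - bound``.
    """

    ca: np.ndarray
    bound: dict[str, np.ndarray]
    buffers: tuple[BufferSpec, ...]
    h_nm: float
    origin_nm: tuple[float, float, float]
    t_ms: float = 0.0
    quarter: bool = False

    def free(self, name: str) -> np.ndarray:
        spec = self.spec(name)
        return spec.total - self.bound[name]

    def spec(self, name: str) -> BufferSpec:
        for b in self.buffers:
            if b.name == name:
                return b
        raise KeyError(name)

    @property
    def indicator(self) -> BufferSpec:
        fluor = [b for b in self.buffers if b.fluorescent]
        if len(fluor) != 1:
            raise ParameterError(
                "exactly one fluorescent buffer (the indicator) is required"
            )
        return fluor[0]

    def mirror_full(self) -> "ConcentrationFields":
        """Unfold a quarter-symmetry state to the full domain."""
        if not self.quarter:
            return self

        def unfold(a: np.ndarray) -> np.ndarray:
            a = np.concatenate([a[:0:-1], a], axis=0)
            return np.concatenate([a[:, :0:-1], a], axis=1)

        ox, oy, oz = self.origin_nm
        nx, ny = self.ca.shape[0], self.ca.shape[1]
        return ConcentrationFields(
            ca=unfold(self.ca),
            bound={k: unfold(v) for k, v in self.bound.items()},
            buffers=self.buffers,
            h_nm=self.h_nm,
            origin_nm=(ox - (nx - 1) * self.h_nm, oy - (ny - 1) * self.h_nm, oz),
            t_ms=self.t_ms,
            quarter=False,
        )


@dataclass
class ReportedCalciumMap:
    """[Ca2+] inferred from the bound/free indicator ratio (µM)."""

    values: np.ndarray
    h_nm: float
    K_D: float
    convolved: bool = False

    def plane(self, z_nm: float = 0.0) -> np.ndarray:
        """Extract the xy-plane at depth ``z_nm`` (3D maps only)."""
        if self.values.ndim != 3:
            return self.values
        k = int(round(z_nm / self.h_nm))
        return self.values[:, :, k]


@dataclass
class SimulationResult:
    """Output of :func:`simulate`."""

    fields: list[ConcentrationFields]
    config: SimulationConfig
    peak_times_ms: np.ndarray
    peak_reported_uM: np.ndarray
    injected_ions: float

    @property
    def final(self) -> ConcentrationFields:
        return self.fields[-1]


# --------------------------------------------------------------------------
# operations
# --------------------------------------------------------------------------

def equilibrate_buffers(
    buffers: Sequence[BufferSpec],
    ca_rest: float,
    shape: tuple[int, int, int] = (1, 1, 1),
    h_nm: float = 5.0,
    origin_nm: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> ConcentrationFields:
    """Spatially uniform resting state: each buffer independently at its
    binding-isotherm equilibrium with free [Ca2+] = ``ca_rest`` (µM)."""
    if ca_rest <= 0:
        raise ParameterError("ca_rest must be > 0")
    bound = {
        b.name: np.full(shape, b.bound_at(ca_rest), dtype=np.float64)
        for b in buffers
    }
    return ConcentrationFields(
        ca=np.full(shape, ca_rest, dtype=np.float64),
        bound=bound,
        buffers=tuple(buffers),
        h_nm=h_nm,
        origin_nm=origin_nm,
    )


@njit(cache=True)
def _run_kernel(ca, bnd, ca2, bnd2, totals, Db, kon, koff, inj,
                dt, inv_h2, nsteps, lo, hi, nxyz):  # pragma: no cover
    nx, ny, nz = nxyz[0], nxyz[1], nxyz[2]
    nb = bnd.shape[0]
    for _ in range(nsteps):
        for i in range(lo[0], hi[0]):
            im = i - 1 if i > 0 else 1
            ip = i + 1 if i < nx - 1 else nx - 2
            for j in range(lo[1], hi[1]):
                jm = j - 1 if j > 0 else 1
                jp = j + 1 if j < ny - 1 else ny - 2
                for k in range(lo[2], hi[2]):
                    km = k - 1 if k > 0 else 1
                    kp = k + 1 if k < nz - 1 else nz - 2
                    c = ca[i, j, k]
                    lap = (ca[im, j, k] + ca[ip, j, k]
                           + ca[i, jm, k] + ca[i, jp, k]
                           + ca[i, j, km] + ca[i, j, kp] - 6.0 * c)
                    dca = 0.223 * inv_h2 * lap
                    for b in range(nb):
                        bb = bnd[b, i, j, k]
                        rate = kon[b] * c * (totals[b] - bb) - koff[b] * bb
                        dca -= rate
                        if Db[b] > 0.0:
                            lapb = (bnd[b, im, j, k] + bnd[b, ip, j, k]
                                    + bnd[b, i, jm, k] + bnd[b, i, jp, k]
                                    + bnd[b, i, j, km] + bnd[b, i, j, kp]
                                    - 6.0 * bb)
                            bnd2[b, i, j, k] = bb + dt * (
                                Db[b] * inv_h2 * lapb + rate)
                        else:
                            bnd2[b, i, j, k] = bb + dt * rate
                    if k == 0:
                        dca += inj[i, j]
                    ca2[i, j, k] = c + dt * dca
        # swap buffers
        for i in range(lo[0], hi[0]):
            for j in range(lo[1], hi[1]):
                for k in range(lo[2], hi[2]):
                    ca[i, j, k] = ca2[i, j, k]
                    for b in range(nb):
                        bnd[b, i, j, k] = bnd2[b, i, j, k]


def _source_map(config: SimulationConfig, shape, origin_nm, h_nm) -> np.ndarray:
    """Per-node Ca2+ injection rates (µM/ms) in the membrane plane."""
    inj = np.zeros(shape[:2])
    cluster = config.cluster
    if cluster is None or cluster.p_open == 0 or cluster.i_single_pA == 0:
        return inj
    if config.bc[4] != "reflect":
        raise ParameterError("channel influx requires a reflective membrane "
                             "face (z low)")
    flux = current_to_flux(cluster.i_single_pA) * cluster.p_open  # ions/ms
    if config.quarter:
        # the quadrant holds one of four mirror images of each channel
        flux /= 4.0
    h_um3 = (h_nm * 1e-3) ** 3
    nx, ny = shape[0], shape[1]
    for x, y in cluster.positions_nm:
        if config.quarter:
            x, y = abs(x), abs(y)
        ix = int(round((x - origin_nm[0]) / h_nm))
        iy = int(round((y - origin_nm[1]) / h_nm))
        if not (0 <= ix < nx and 0 <= iy < ny):
            raise GeometryError("channel outside simulation domain")
        # control-volume factor: 1/2 per domain face the node sits on
        vol = h_um3 / 2.0  # membrane face
        if ix in (0, nx - 1):
            vol /= 2.0
        if iy in (0, ny - 1):
            vol /= 2.0
        inj[ix, iy] += flux / (AVOGADRO_UM3 * vol)
    return inj


def simulate(
    config: SimulationConfig,
    output_times_ms: Sequence[float] | None = None,
    peak_every_ms: float | None = 0.05,
) -> SimulationResult:
    """Run the reaction-diffusion model.

    Diffusion is integrated by explicit finite differences on a node grid,
    reactions pointwise with the same explicit step (operator-split forward
    Euler).  Ca2+ is injected into the membrane-plane node nearest each
    channel.  Returns the fields at ``output_times_ms`` (default: end of the
    run only) plus a coarse time series of the peak reported [Ca2+] in the
    membrane plane, recorded every ``peak_every_ms``.
    """
    dt = config.resolve_dt_ms()
    h = config.h_nm
    ext = config.extent_nm
    if config.quarter:
        if config.bc[0] != "dirichlet" or config.bc[2] != "dirichlet":
            raise ParameterError("quarter symmetry expects Dirichlet side faces")
        nx = int(round(ext[0] / 2 / h)) + 1
        ny = int(round(ext[1] / 2 / h)) + 1
        origin = (0.0, 0.0, 0.0)
        bc = ("reflect", config.bc[1], "reflect", config.bc[3],
              config.bc[4], config.bc[5])
    else:
        nx = int(round(ext[0] / h)) + 1
        ny = int(round(ext[1] / h)) + 1
        origin = (-ext[0] / 2, -ext[1] / 2, 0.0)
        bc = config.bc
    nz = int(round(ext[2] / h)) + 1
    shape = (nx, ny, nz)

    state = equilibrate_buffers(config.buffers, config.ca_rest_uM, shape,
                                h, origin)
    state.quarter = config.quarter
    inj = _source_map(config, shape, origin, h)

    nb = len(config.buffers)
    if nb:
        bnd = np.stack([state.bound[b.name] for b in config.buffers])
    else:
        bnd = np.zeros((0,) + shape)
    ca = state.ca
    ca2 = ca.copy()
    bnd2 = bnd.copy()
    totals = np.array([b.total for b in config.buffers])
    Db = np.array([b.D for b in config.buffers])
    kon = np.array([b.k_on for b in config.buffers])
    koff = np.array([b.k_off for b in config.buffers])
    lo = np.array([0 if bc[2 * a] == "reflect" else 1 for a in range(3)],
                  dtype=np.int64)
    hi = np.array(
        [shape[a] if bc[2 * a + 1] == "reflect" else shape[a] - 1
         for a in range(3)], dtype=np.int64)
    inv_h2 = 1.0 / (h * 1e-3) ** 2

    if output_times_ms is None:
        output_times_ms = [config.duration_ms]
    checkpoints = sorted(set(float(t) for t in output_times_ms))
    if checkpoints and checkpoints[-1] > config.duration_ms + 1e-12:
        raise ParameterError("output time beyond simulation duration")

    marks = set(checkpoints)
    if peak_every_ms:
        k = 1
        while k * peak_every_ms < config.duration_ms - 1e-12:
            marks.add(round(k * peak_every_ms, 9))
            k += 1
        marks.add(config.duration_ms)
    marks = sorted(marks)

    indicator = None
    try:
        indicator = state.indicator
    except ParameterError:
        pass

    def snapshot(t: float) -> ConcentrationFields:
        return ConcentrationFields(
            ca=ca.copy(),
            bound={b.name: bnd[i].copy()
                   for i, b in enumerate(config.buffers)},
            buffers=config.buffers,
            h_nm=h,
            origin_nm=origin,
            t_ms=t,
            quarter=config.quarter,
        )

    fields: list[ConcentrationFields] = []
    peak_t: list[float] = []
    peak_v: list[float] = []
    nxyz = np.array(shape, dtype=np.int64)
    checkpoint_set = set(checkpoints)
    steps_done = 0
    for t_mark in marks:
        nsteps = int(round(t_mark / dt)) - steps_done
        if nsteps > 0:
            _run_kernel(ca, bnd, ca2, bnd2, totals, Db, kon, koff, inj,
                        dt, inv_h2, nsteps, lo, hi, nxyz)
            steps_done += nsteps
        t_now = t_mark
        if not np.isfinite(ca).all():
            raise FloatingPointError(
                f"solver diverged (NaN/inf in fields at t = {t_now:g} ms)")
        if indicator is not None:
            idx = [b.name for b in config.buffers].index(indicator.name)
            b0 = bnd[idx][:, :, 0]
            f0 = totals[idx] - b0
            peak_t.append(t_now)
            peak_v.append(float(np.max(indicator.K_D * b0 / f0)))
        if t_mark in checkpoint_set:
            fields.append(snapshot(t_now))
    if not fields:
        fields.append(snapshot(t_now))

    injected = 0.0
    if config.cluster is not None:
        n_eff = config.cluster.n_channels
        injected = (current_to_flux(config.cluster.i_single_pA)
                    * config.cluster.p_open * n_eff * config.duration_ms)
    return SimulationResult(
        fields=fields,
        config=config,
        peak_times_ms=np.array(peak_t),
        peak_reported_uM=np.array(peak_v),
        injected_ions=injected,
    )


def reported_calcium(
    fields: ConcentrationFields,
    K_D: float | None = None,
    z_nm: float | None = None,
) -> ReportedCalciumMap:
    """[Ca2+] from the bound/free indicator ratio, ``K_D * bound / free``.

    With ``z_nm`` given, returns the 2D map of that plane (``z_nm=0`` is the
    membrane); otherwise the full 3D map.  Nodes where the bound indicator
    is exactly zero report 0; a vanishing *free* indicator (saturation)
    raises, naming the first offending node.
    """
    ind = fields.indicator
    kd = ind.K_D if K_D is None else K_D
    bound = fields.bound[ind.name]
    free = fields.free(ind.name)
    if z_nm is not None:
        k = int(round(z_nm / fields.h_nm))
        bound, free = bound[:, :, k], free[:, :, k]
    if (free <= 0).any():
        node = np.unravel_index(np.argmin(free), free.shape)
        raise ZeroDivisionError(
            f"free indicator vanishes at grid node {tuple(int(x) for x in node)}")
    values = kd * bound / free
    values[bound == 0] = 0.0
    return ReportedCalciumMap(values=values, h_nm=fields.h_nm, K_D=kd)


def convolve_psf(
    fields: ConcentrationFields,
    psf: PSFModel,
    K_D: float | None = None,
) -> ReportedCalciumMap:
    """Imaging emulation: blur bound and free indicator with the PSF, then
    ratio.

    The simulated volume is convolved as acquired data would be: zero
    padding on every face (in particular no dye below the membrane, and
    nothing beyond the simulated box).  Because bound and free fields are
    attenuated identically by the padding, the ratio map is exact wherever
    the free field retains mass.  Returns the 3D convolved reported-[Ca2+]
    map on the original grid; use ``.plane(z)`` to read it at a PSF-center
    depth (depth profiles).
    """
    fields = fields.mirror_full()
    ind = fields.indicator
    kd = ind.K_D if K_D is None else K_D
    h = fields.h_nm
    sig = [s / h for s in psf.sigmas_nm]  # in grid units
    if any(4 * s > n for s, n in zip(sig[:2], fields.ca.shape[:2])):
        raise ParameterError("PSF wider than the (padded) domain in x/y")

    def blur(arr: np.ndarray) -> np.ndarray:
        return gaussian_filter(arr, sigma=sig, mode="constant", cval=0.0,
                               truncate=6.0)

    cb = blur(fields.bound[ind.name])
    cf = blur(fields.free(ind.name))
    values = np.where(cf > 0, kd * cb / np.maximum(cf, 1e-300), 0.0)
    return ReportedCalciumMap(values=values, h_nm=h, K_D=kd, convolved=True)


def _profile_fwhm(profile: np.ndarray, h_nm: float) -> float:
    """FWHM of a 1D profile via linear interpolation of half-max crossings."""
    i_max = int(np.argmax(profile))
    if i_max in (0, len(profile) - 1):
        raise MeasurementError("peak lies on the domain edge")
    base = float(profile.min())
    half = base + 0.5 * (profile[i_max] - base)
    left = right = None
    for i in range(i_max, 0, -1):
        if profile[i - 1] < half <= profile[i]:
            frac = (profile[i] - half) / (profile[i] - profile[i - 1])
            left = i - frac
            break
    for i in range(i_max, len(profile) - 1):
        if profile[i + 1] < half <= profile[i]:
            frac = (profile[i] - half) / (profile[i] - profile[i + 1])
            right = i + frac
            break
    if left is None or right is None:
        raise MeasurementError("half-maximum not crossed inside the domain")
    return (right - left) * h_nm


def measure_domain_fwhm(
    cmap: ReportedCalciumMap | np.ndarray,
    h_nm: float | None = None,
    z_nm: float = 0.0,
) -> tuple[float, float]:
    """FWHM of a single-peaked 2D map along its two principal (grid) axes.

    Returns ``(short_axis_nm, long_axis_nm)``.  Half-max crossings are
    located by linear interpolation between nodes; the profile minimum
    serves as the baseline.
    """
    if isinstance(cmap, ReportedCalciumMap):
        arr = cmap.plane(z_nm)
        h = cmap.h_nm
    else:
        arr = np.asarray(cmap)
        if h_nm is None:
            raise ParameterError("h_nm required for bare arrays")
        h = h_nm
    i, j = np.unravel_index(int(np.argmax(arr)), arr.shape)
    fw_x = _profile_fwhm(arr[:, j], h)
    fw_y = _profile_fwhm(arr[i, :], h)
    lo, hi_ = sorted((fw_x, fw_y))
    return lo, hi_


def total_calcium(fields: ConcentrationFields) -> float:
    """Total Ca2+ content (free + all bound forms) of the box, in ions.

    Uses trapezoidal volume weights (half weight on boundary-face nodes),
    under which the explicit scheme conserves mass exactly in a closed box.
    """
    total = fields.ca.copy()
    for b in fields.buffers:
        total = total + fields.bound[b.name]
    w = np.ones_like(total)
    for axis in range(3):
        sl = [slice(None)] * 3
        for edge in (0, -1):
            sl[axis] = edge
            w[tuple(sl)] *= 0.5
    h_um3 = (fields.h_nm * 1e-3) ** 3
    return float((total * w).sum() * h_um3 * AVOGADRO_UM3)
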