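"""Deterministic 1-d reaction-diffusion model of the MinDE membrane oscillator.

The model follows the classic five-species description of the Min system:
cytosolic MinD:ADP (``c_DD``), cytosolic MinD:ATP (``c_DT``), cytosolic MinE
(``c_E``), membrane-bound MinD (``m_d``) and the membrane-bound MinDE complex
(``m_de``).  MinD:ATP binds the membrane (basal rate plus cooperative
recruitment by membrane-bound MinD species), MinE is recruited onto membrane
MinD forming MinDE, and hydrolysis releases MinD:ADP and MinE back to the
cytosol, where nucleotide exchange regenerates MinD:ATP.  All species are
represented as linear densities (molecules/um) on a 1-d cell of length L with
no-flux boundaries; bulk (3-d) rate constants are converted to effective 1-d
rates with a surface-to-volume factor for a cylindrical cell of radius r.

In a wild-type-sized cell these reactions self-organize into pole-to-pole
oscillations on a ~40 s timescale, leaving the mid-cell membrane transiently
free of MinD (and hence of the division inhibitor MinC that rides on it).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "MinModelParams",
    "Grid1D",
    "MinFields",
    "SimOutput",
    "initialize_fields",
    "rhs",
    "simulate",
    "detect_period",
    "time_average_profile",
]

logger = logging.getLogger(__name__)

#: Default width (um) of the pole / mid-cell signal windows, shared with the
#: occupancy module.
DEFAULT_WINDOW_W = 0.5


class IntegrationError(RuntimeError):
    """Raised when the explicit integrator goes unstable (NaN/Inf or
    conservation drift beyond tolerance)."""


@dataclass(frozen=True)
class MinModelParams:
    """Kinetic constants of the 1-d Min model, in effective 1-d units.

    Diffusivities are in um^2/s.  ``sigma_D`` is the basal membrane-binding
    rate (1/s, already including the surface-to-volume conversion);
    ``sigma_dD`` and ``sigma_E`` are recruitment rates in um/s per
    (molecules/um); ``sigma_de`` and ``k_exchange`` are first-order rates
    (1/s).  ``dens_D`` and ``dens_E`` are total linear densities
    (molecules/um); their ratio is the MinE/MinD ratio that the induction
    experiments manipulate.  ``geometry_factor`` (= 2/r) records the
    surface-to-volume conversion used for ``sigma_D``.
    """

    D_D: float = 2.5
    D_E: float = 2.5
    D_m: float = 0.0
    sigma_D: float = 0.1
    sigma_dD: float = 0.0015 / (math.pi * 0.25)
    sigma_E: float = 0.093 / (math.pi * 0.25)
    sigma_de: float = 0.7
    k_exchange: float = 1.0
    dens_D: float = 785.0
    dens_E: float = 275.0
    geometry_factor: float = 4.0

    def __post_init__(self) -> None:
        for name in ("D_D", "D_E", "D_m", "sigma_D", "sigma_dD", "sigma_E",
                     "sigma_de", "k_exchange", "geometry_factor"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.dens_D <= 0:
            raise ValueError("dens_D must be > 0")
        if not (self.dens_E > 0 and math.isfinite(self.dens_E / self.dens_D)):
            raise ValueError("dens_E must be > 0 with finite dens_E/dens_D")

    @property
    def ratio_ED(self) -> float:
        """MinE/MinD total-density ratio."""
        return self.dens_E / self.dens_D

    def with_ratio_multiplier(self, multiplier: float) -> "MinModelParams":
        """Return params with ``dens_E`` scaled (MinD fixed), emulating
        *minE* overexpression."""
        return replace(self, dens_E=self.dens_E * multiplier)

    @classmethod
    def from_bulk_rates(cls, sigma_D_bulk: float = 0.025,
                        sigma_dD_bulk: float = 0.0015,
                        sigma_E_bulk: float = 0.093,
                        conc_D: float = 1000.0, conc_E: float = 350.0,
                        radius: float = 0.5, **kw) -> "MinModelParams":
        """Build effective 1-d parameters from bulk (3-d) rate constants.

        ``sigma_D_bulk`` is in um/s, the recruitment rates in um^3/s, and the
        concentrations in molecules/um^3; ``radius`` is the cylindrical cell
        radius in um.
        """
        area = math.pi * radius ** 2
        return cls(sigma_D=sigma_D_bulk * 2.0 / radius,
                   sigma_dD=sigma_dD_bulk / area,
                   sigma_E=sigma_E_bulk / area,
                   dens_D=conc_D * area, dens_E=conc_E * area,
                   geometry_factor=2.0 / radius, **kw)


@dataclass(frozen=True)
class Grid1D:
    """Cell-centred uniform grid on [0, L] with reflecting boundaries."""

    L: float
    n_x: int

    def __post_init__(self) -> None:
        if self.L <= 0 or self.n_x < 1:
            raise ValueError("need L > 0 and n_x >= 1")

    @property
    def dx(self) -> float:
        return self.L / self.n_x

    @property
    def x(self) -> np.ndarray:
        return (np.arange(self.n_x) + 0.5) * self.dx

    @classmethod
    def for_length(cls, L: float, dx: float = 0.05) -> "Grid1D":
        """Grid with spacing as close to ``dx`` as divides L evenly."""
        return cls(L=L, n_x=max(1, int(round(L / dx))))


@dataclass
class MinFields:
    """The five species density profiles (molecules/um) on a grid."""

    c_DD: np.ndarray
    c_DT: np.ndarray
    c_E: np.ndarray
    m_d: np.ndarray
    m_de: np.ndarray

    def stack(self) -> np.ndarray:
        return np.stack([self.c_DD, self.c_DT, self.c_E, self.m_d, self.m_de])

    @classmethod
    def from_stack(cls, y: np.ndarray) -> "MinFields":
        return cls(*(y[i] for i in range(5)))

    def total_D(self, dx: float) -> float:
        return float((self.c_DD + self.c_DT + self.m_d + self.m_de).sum() * dx)

    def total_E(self, dx: float) -> float:
        return float((self.c_E + self.m_de).sum() * dx)


@dataclass
class SimOutput:
    """Sampled trajectory of a single Min simulation."""

    sample_times: np.ndarray          # (n_t,) seconds
    membrane_occupancy: np.ndarray    # (n_t, n_x) m_d + m_de, molecules/um
    pole_signal: np.ndarray           # molecules in the left pole window
    midcell_signal: np.ndarray        # molecules in the mid-cell window
    conservation_drift: float
    grid: Grid1D
    params: MinModelParams
    final_fields: MinFields = field(repr=False, default=None)


def initialize_fields(params: MinModelParams, grid: Grid1D, seed: int = 0,
                      perturbation: float = 0.01) -> MinFields:
    """Uniform cytosolic start with a seeded asymmetric kick on MinD:ATP.

    Cytosolic MinD is split evenly between the ADP and ATP forms, MinE is
    fully cytosolic and the membrane starts empty.  A reproducible random
    multiplicative perturbation of relative magnitude ``perturbation`` is
    applied to ``c_DT`` and compensated in ``c_DD`` so both totals equal
    ``dens * L`` to machine precision; without it the mirror symmetry of the
    equations would never break and oscillations could not develop.
    """
    if not (0.0 <= perturbation < 1.0):
        raise ValueError("perturbation must be in [0, 1)")
    n = grid.n_x
    c_DT = np.full(n, 0.5 * params.dens_D)
    if perturbation > 0:
        rng = np.random.default_rng(seed)
        noise = perturbation * (2.0 * rng.random(n) - 1.0)
        # guarantee an odd (asymmetric) component even for unlucky draws
        noise += 0.5 * perturbation * np.linspace(-1.0, 1.0, n)
        c_DT = c_DT * (1.0 + noise)
    c_DD = params.dens_D - c_DT
    c_E = np.full(n, params.dens_E)
    zeros = np.zeros(n)
    return MinFields(c_DD=c_DD, c_DT=c_DT, c_E=c_E,
                     m_d=zeros.copy(), m_de=zeros.copy())


def _laplacian(u: np.ndarray, dx: float) -> np.ndarray:
    """Second-order central Laplacian with ghost-cell no-flux boundaries."""
    out = np.empty_like(u)
    out[1:-1] = u[:-2] - 2.0 * u[1:-1] + u[2:]
    if len(u) == 1:
        out[0] = 0.0
    else:
        out[0] = u[1] - u[0]
        out[-1] = u[-2] - u[-1]
    return out / (dx * dx)


def rhs(fields: MinFields, params: MinModelParams, grid: Grid1D) -> MinFields:
    """Time derivative of the five coupled species equations.

    Pure function; the reaction terms conserve total MinD
    (c_DD + c_DT + m_d + m_de) and total MinE (c_E + m_de) exactly, and the
    no-flux Laplacian conserves each species' spatial integral.
    """
    p, dx = params, grid.dx
    bind = (p.sigma_D + p.sigma_dD * (fields.m_d + fields.m_de)) * fields.c_DT
    hydrolyze = p.sigma_E * fields.m_d * fields.c_E
    release = p.sigma_de * fields.m_de
    exchange = p.k_exchange * fields.c_DD
    return MinFields(
        c_DD=p.D_D * _laplacian(fields.c_DD, dx) - exchange + release,
        c_DT=p.D_D * _laplacian(fields.c_DT, dx) + exchange - bind,
        c_E=p.D_E * _laplacian(fields.c_E, dx) - hydrolyze + release,
        m_d=p.D_m * _laplacian(fields.m_d, dx) + bind - hydrolyze,
        m_de=p.D_m * _laplacian(fields.m_de, dx) + hydrolyze - release,
    )


def _window_weights(grid: Grid1D, center: float, width: float) -> np.ndarray:
    """Overlap length of each grid interval with [center-w/2, center+w/2]."""
    edges = np.arange(grid.n_x + 1) * grid.dx
    lo, hi = center - width / 2.0, center + width / 2.0
    return np.clip(np.minimum(edges[1:], hi) - np.maximum(edges[:-1], lo),
                   0.0, None)


def _stable_dt(params: MinModelParams, dx: float,
               stability_factor: float = 0.4) -> float:
    p = params
    # conservative bound on the fastest linearized reaction rate, so the
    # step stays stable even when diffusion does not dominate (coarse grids)
    rate_max = max(p.k_exchange + p.sigma_de
                   + 2.0 * p.sigma_E * p.dens_E
                   + p.sigma_D + 4.0 * p.sigma_dD * p.dens_D, 1e-9)
    dt = stability_factor / rate_max
    d_max = max(p.D_D, p.D_E, p.D_m)
    if d_max > 0:
        dt = min(dt, stability_factor * dx * dx / d_max)
    return dt


def simulate(params: MinModelParams, grid: Grid1D, t_end: float = 600.0,
             sample_dt: float = 1.0, seed: int = 0,
             perturbation: float = 0.01, fields: MinFields | None = None,
             window_w: float = DEFAULT_WINDOW_W,
             conservation_tol: float = 1e-6,
             method: str = "auto") -> SimOutput:
    """Integrate the Min model and sample membrane occupancy.

    The integrator is an explicit RK4 method-of-lines scheme with time step
    0.4*dx^2/max(D) (``method='rk4'``, numba-accelerated when available and
    selected automatically by ``'auto'``); ``method='split'`` uses Strang
    splitting with Crank-Nicolson diffusion for stiff settings.  Negative
    densities larger than -1e-12*dens_D abort; smaller undershoots are
    clipped to zero and counted.
    """
    if t_end <= 0 or sample_dt <= 0:
        raise ValueError("t_end and sample_dt must be > 0")
    if fields is None:
        fields = initialize_fields(params, grid, seed=seed,
                                   perturbation=perturbation)
    y = np.ascontiguousarray(fields.stack(), dtype=np.float64)
    dx = grid.dx

    dt0 = _stable_dt(params, dx)
    n_sub = max(1, int(math.ceil(sample_dt / dt0)))
    dt = sample_dt / n_sub
    n_samples = int(round(t_end / sample_dt))

    total_D0 = (y[0] + y[1] + y[3] + y[4]).sum() * dx
    total_E0 = (y[2] + y[4]).sum() * dx
    floor = -1e-12 * params.dens_D

    stepper = _get_stepper(method)
    pars = (params.D_D, params.D_E, params.D_m, params.sigma_D,
            params.sigma_dD, params.sigma_E, params.sigma_de,
            params.k_exchange)

    occupancy = np.empty((n_samples, grid.n_x))
    times = np.empty(n_samples)
    drift = 0.0
    n_clipped = 0
    for s in range(n_samples):
        y = stepper(y, dt, dx, pars, n_sub)
        if not np.all(np.isfinite(y)):
            raise IntegrationError(
                f"non-finite state at t={times[s - 1] if s else 0:.1f}s "
                f"with step dt={dt:.3g}s; reduce the step size")
        y_min = y.min()
        if y_min < 0.0:
            if y_min < floor:
                raise IntegrationError(
                    f"negative density {y_min:.3e} below tolerance at "
                    f"t={(s + 1) * sample_dt:.1f}s (step dt={dt:.3g}s)")
            n_clipped += int((y < 0).sum())
            np.clip(y, 0.0, None, out=y)
        d_now = (y[0] + y[1] + y[3] + y[4]).sum() * dx
        e_now = (y[2] + y[4]).sum() * dx
        drift = max(drift, abs(d_now - total_D0) / total_D0,
                    abs(e_now - total_E0) / total_E0)
        if drift > conservation_tol:
            raise IntegrationError(
                f"conservation drift {drift:.2e} exceeds {conservation_tol:g} "
                f"at t={(s + 1) * sample_dt:.1f}s (step dt={dt:.3g}s)")
        occupancy[s] = y[3] + y[4]
        times[s] = (s + 1) * sample_dt
    if n_clipped:
        logger.warning("clipped %d tiny negative density values to 0", n_clipped)

    w_pole = _window_weights(grid, window_w / 2.0, window_w)
    w_mid = _window_weights(grid, grid.L / 2.0, window_w)
    return SimOutput(
        sample_times=times,
        membrane_occupancy=occupancy,
        pole_signal=occupancy @ w_pole,
        midcell_signal=occupancy @ w_mid,
        conservation_drift=drift,
        grid=grid,
        params=params,
        final_fields=MinFields.from_stack(y),
    )


# ---------------------------------------------------------------------------
# steppers

def _step_rk4_numpy(y: np.ndarray, dt: float, dx: float, pars: tuple,
                    n_sub: int) -> np.ndarray:
    D_D, D_E, D_m, sD, sdD, sE, sde, k = pars

    def f(u: np.ndarray) -> np.ndarray:
        bind = (sD + sdD * (u[3] + u[4])) * u[1]
        hyd = sE * u[3] * u[2]
        rel = sde * u[4]
        exch = k * u[0]
        return np.stack([
            D_D * _laplacian(u[0], dx) - exch + rel,
            D_D * _laplacian(u[1], dx) + exch - bind,
            D_E * _laplacian(u[2], dx) - hyd + rel,
            D_m * _laplacian(u[3], dx) + bind - hyd,
            D_m * _laplacian(u[4], dx) + hyd - rel,
        ])

    for _ in range(n_sub):
        k1 = f(y)
        k2 = f(y + 0.5 * dt * k1)
        k3 = f(y + 0.5 * dt * k2)
        k4 = f(y + dt * k3)
        y = y + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
    return y


def _step_split_numpy(y: np.ndarray, dt: float, dx: float, pars: tuple,
                      n_sub: int) -> np.ndarray:
    """Strang splitting: half-step Crank-Nicolson diffusion, full-step RK4
    reactions, half-step diffusion."""
    from scipy.linalg import solve_banded

    D_D, D_E, D_m, sD, sdD, sE, sde, k = pars
    n = y.shape[1]
    diffs = (D_D, D_D, D_E, D_m, D_m)

    solvers = {}
    for d in set(diffs):
        r = d * (dt / 2.0) / (dx * dx)
        ab = np.zeros((3, n))
        ab[0, 1:] = -0.5 * r
        ab[2, :-1] = -0.5 * r
        ab[1, :] = 1.0 + r
        ab[1, 0] = ab[1, -1] = 1.0 + 0.5 * r
        solvers[d] = (r, ab)

    def half_diffuse(u: np.ndarray) -> np.ndarray:
        out = np.empty_like(u)
        for i, d in enumerate(diffs):
            if d == 0.0 or n == 1:
                out[i] = u[i]
                continue
            r, ab = solvers[d]
            b = u[i].copy()
            b[1:-1] += 0.5 * r * (u[i][:-2] - 2 * u[i][1:-1] + u[i][2:])
            b[0] += 0.5 * r * (u[i][1] - u[i][0])
            b[-1] += 0.5 * r * (u[i][-2] - u[i][-1])
            out[i] = solve_banded((1, 1), ab, b)
        return out

    def react(u: np.ndarray) -> np.ndarray:
        bind = (sD + sdD * (u[3] + u[4])) * u[1]
        hyd = sE * u[3] * u[2]
        rel = sde * u[4]
        exch = k * u[0]
        return np.stack([rel - exch, exch - bind, rel - hyd,
                         bind - hyd, hyd - rel])

    for _ in range(n_sub):
        y = half_diffuse(y)
        k1 = react(y)
        k2 = react(y + 0.5 * dt * k1)
        k3 = react(y + 0.5 * dt * k2)
        k4 = react(y + dt * k3)
        y = y + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        y = half_diffuse(y)
    return y


_NUMBA_STEPPER = None


def _numba_stepper():
    global _NUMBA_STEPPER
    if _NUMBA_STEPPER is not None:
        return _NUMBA_STEPPER
    from ._kernels import step_rk4 as _step

    def wrapper(y, dt, dx, pars, n_sub):
        return _step(y, dt, dx, *pars, n_sub)

    _NUMBA_STEPPER = wrapper
    return wrapper


def _get_stepper(method: str):
    if method == "split":
        return _step_split_numpy
    if method == "numpy":
        return _step_rk4_numpy
    if method == "rk4" or method == "auto":
        try:
            return _numba_stepper()
        except ImportError:
            if method == "rk4":
                raise
            return _step_rk4_numpy
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# trajectory analysis

def detect_period(signal: np.ndarray, sample_dt: float,
                  burn_in: float = 200.0,
                  amplitude_floor: float = 0.05) -> float | None:
    """Dominant oscillation period from the signal autocorrelation.

    Returns the lag of the first autocorrelation peak above the significance
    floor (2/sqrt(N)), refined by parabolic interpolation; returns ``None``
    when the post-burn-in amplitude ratio (max-min)/mean falls below
    ``amplitude_floor``.
    """
    signal = np.asarray(signal, dtype=float)
    n_burn = int(round(burn_in / sample_dt))
    if n_burn >= len(signal):
        raise ValueError("burn_in must be shorter than the signal")
    s = signal[n_burn:]
    mean = s.mean()
    if mean <= 0 or (s.max() - s.min()) / mean < amplitude_floor:
        return None
    s = s - mean
    ac = np.correlate(s, s, mode="full")[len(s) - 1:]
    if ac[0] <= 0:
        return None
    ac = ac / ac[0]
    floor = max(2.0 / math.sqrt(len(s)), 0.1)
    from scipy.signal import find_peaks
    peaks, _ = find_peaks(ac, height=floor)
    if len(peaks) == 0:
        return None
    p = int(peaks[0])
    # parabolic refinement around the discrete peak
    if 0 < p < len(ac) - 1:
        a, b, c = ac[p - 1], ac[p], ac[p + 1]
        denom = a - 2 * b + c
        if denom < 0:
            p = p + 0.5 * (a - c) / denom
    return float(p * sample_dt)


def time_average_profile(out: SimOutput, burn_in: float = 200.0) -> np.ndarray:
    """Arithmetic time-average of the membrane occupancy after ``burn_in``."""
    mask = out.sample_times > burn_in
    if not mask.any():
        raise ValueError("burn_in must be shorter than the simulated duration")
    return out.membrane_occupancy[mask].mean(axis=0)
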