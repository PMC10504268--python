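"""Induction kinetics, dose-response, and the generational cell-size model.

Three pieces chain together:

1. A sigmoid describes the rise of MinE after induction of overexpression,
   ``MinE(t) = E0 + (E1 - E0) / (1 + exp(-(t - t_c)/t_s))``; with MinD
   constant the relative ratio R/R0(t) is just ``MinE(t)/E0``.
2. A four-parameter logistic maps inducer (arabinose) concentration to the
   measured MinE/MinD expression ratio.
3. A generational recursion: each cycle the cell grows exponentially at rate
   alpha from birth length L0(g) until it reaches the division-permissive
   length L_stable(g) set by the current MinE/MinD ratio (time T_z), then
   grows a further fixed time tau before dividing in half:

       T_z(g) = (1/alpha) * ln(L_stable(g) / L0(g))          (clamped at 0)
       L0(g+1) = 1/2 * L_stable(g) * exp(alpha*tau)
               = 1/2 * L0(g) * exp(alpha*(T_z(g) + tau))

   At constant ratio the recursion has the fixed point
   L0* = 1/2 * L_stable * exp(alpha*tau) with cycle time ln(2)/alpha, and it
   reaches that fixed point in a single generation because the first
   equality does not involve L0(g).  Under a sigmoid ratio rise, T_z shows a
   transient peak and returns to baseline while the birth length climbs
   monotonically to a higher plateau.

The sister-cell closed form: two sisters born at fractions f_A + f_B = 1 of
the mother length both divide at L_stable * exp(alpha*tau), so the added
lengths obey Delta_A - Delta_B = -(f_A - f_B) * L_mother exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "InductionParams",
    "DoseResponseParams",
    "GrowthParams",
    "GenerationTrajectory",
    "SisterPair",
    "minE_at",
    "ratio_trajectory",
    "dose_response",
    "fit_dose_response",
    "time_to_ring",
    "run_generations",
    "sister_delta",
]


class FitFailure(RuntimeError):
    """Nonlinear fit did not converge after the restart schedule."""


@dataclass(frozen=True)
class InductionParams:
    """Sigmoid rise of MinE following induction at t = 0.

    ``t_c`` is the half-rise time and ``t_s`` the rise timescale; the unit
    (minutes or generations) is recorded in ``time_unit`` and interpreted by
    the generational model.
    """

    minE_initial: float = 1.0
    minE_final: float = 3.0
    t_c: float = 4.0
    t_s: float = 1.5
    time_unit: str = "generations"

    def __post_init__(self) -> None:
        if self.minE_final < self.minE_initial:
            raise ValueError("minE_final must be >= minE_initial")
        if self.t_s <= 0:
            raise ValueError("t_s must be > 0")
        if self.time_unit not in ("generations", "minutes"):
            raise ValueError("time_unit must be 'generations' or 'minutes'")


@dataclass(frozen=True)
class DoseResponseParams:
    """Four-parameter logistic R(C) = offset + amplitude / (1 + exp(-(C - inflection)/scale))."""

    offset: float = 2.878
    amplitude: float = 179.63
    inflection: float = 0.182       # % w/v arabinose at half-rise
    scale: float = 0.158            # % w/v rise-rate constant

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale must be > 0")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")


@dataclass(frozen=True)
class GrowthParams:
    """Exponential growth rate alpha (1/min), fixed post-ring interval tau
    (min), and the linear map ratio -> L_stable (um):
    L_stable = lopt_a + lopt_b * (R/R0)."""

    alpha: float = math.log(2) / 25.0
    tau: float = 18.0
    lopt_a: float = 1.5
    lopt_b: float = 1.0

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if self.tau < 0:
            raise ValueError("tau must be >= 0")

    def L_stable(self, ratio_rel: float) -> float:
        L = self.lopt_a + self.lopt_b * ratio_rel
        if L <= 0:
            raise ValueError(f"L_stable({ratio_rel:g}) = {L:g} is not positive")
        return L


@dataclass
class GenerationTrajectory:
    """Per-generation output of the recursion (generation 0 = induction)."""

    generation: np.ndarray
    start_time_min: np.ndarray
    ratio_rel: np.ndarray
    L_stable: np.ndarray
    L_0: np.ndarray
    T_z: np.ndarray
    cycle_time: np.ndarray
    division_factor: float = 0.5

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame(dict(
            g=self.generation, start_time_min=self.start_time_min,
            ratio_rel=self.ratio_rel, L_stable_um=self.L_stable,
            L0_um=self.L_0, Tz_min=self.T_z, cycle_min=self.cycle_time))


@dataclass(frozen=True)
class SisterPair:
    L_mother: float
    f_A: float
    f_B: float
    delta_A: float
    delta_B: float

    def __post_init__(self) -> None:
        if not (0 < self.f_A < 1 and 0 < self.f_B < 1):
            raise ValueError("birth fractions must lie in (0, 1)")
        if abs(self.f_A + self.f_B - 1.0) > 1e-9:
            raise ValueError("f_A + f_B must equal 1")


# ---------------------------------------------------------------------------
# induction kinetics

def minE_at(t, p: InductionParams):
    """MinE amount at time ``t`` after induction (sigmoid, evaluated as
    written; note it does not pass exactly through minE_initial at t = 0)."""
    t = np.asarray(t, dtype=float)
    val = p.minE_initial + (p.minE_final - p.minE_initial) / (
        1.0 + np.exp(-(t - p.t_c) / p.t_s))
    return float(val) if val.ndim == 0 else val


def ratio_trajectory(p: InductionParams, minD_const: float, times):
    """Relative MinE/MinD ratio R/R0(t); the constant MinD cancels."""
    if minD_const <= 0:
        raise ValueError("minD_const must be > 0")
    if p.minE_initial <= 0:
        raise ValueError("minE_initial must be > 0 to define R/R0")
    return minE_at(times, p) / p.minE_initial


# ---------------------------------------------------------------------------
# dose-response

def dose_response(C, p: DoseResponseParams):
    """Relative MinE/MinD expression ratio at arabinose concentration C (% w/v)."""
    C = np.asarray(C, dtype=float)
    val = p.offset + p.amplitude / (1.0 + np.exp(-(C - p.inflection) / p.scale))
    return float(val) if val.ndim == 0 else val


def fit_dose_response(points, init: DoseResponseParams | None = None):
    """Nonlinear least-squares fit of the four-parameter logistic.

    ``points`` is a sequence of (concentration, ratio) pairs.  Initialization
    is data-driven (offset = min R, amplitude = range, inflection = median C,
    scale = C-range/4) with three documented restarts at perturbed
    inflection/scale; parameter standard errors come from the fit covariance.
    Returns ``(DoseResponseParams, diagnostics dict)``.
    """
    from scipy.optimize import curve_fit

    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 4:
        raise ValueError("need >= 4 (C, R) points")
    C, R = pts[:, 0], pts[:, 1]
    if len(np.unique(C)) < 3:
        raise ValueError("need >= 3 distinct concentrations")

    def model(c, offset, amplitude, inflection, scale):
        return offset + amplitude / (1.0 + np.exp(-(c - inflection) / scale))

    c_range = C.max() - C.min()
    r_range = R.max() - R.min()
    if init is not None:
        starts = [(init.offset, init.amplitude, init.inflection, init.scale)]
    else:
        base = (R.min(), max(r_range, 1e-12), float(np.median(C)),
                max(c_range / 4.0, 1e-6))
        starts = [base,
                  (base[0], base[1], base[2] * 0.5 + C.min() * 0.5, base[3] * 0.5),
                  (base[0], base[1], base[2] * 0.5 + C.max() * 0.5, base[3] * 2.0),
                  (base[0], base[1] * 2.0, base[2], base[3])]

    last_err = None
    for p0 in starts:
        try:
            popt, pcov = curve_fit(model, C, R, p0=p0, maxfev=20000)
        except RuntimeError as err:
            last_err = err
            continue
        if popt[3] < 0:                      # mirror-symmetric solution
            continue
        resid = R - model(C, *popt)
        dof = max(len(C) - 4, 1)
        se = np.sqrt(np.clip(np.diag(pcov), 0, None))
        flat = r_range < 1e-12 or abs(popt[1]) < 1e-9 * max(abs(R).max(), 1.0)
        params = DoseResponseParams(offset=float(popt[0]),
                                    amplitude=float(abs(popt[1])),
                                    inflection=float(popt[2]),
                                    scale=float(popt[3]))
        return params, dict(
            stderr=dict(zip(("offset", "amplitude", "inflection", "scale"), se)),
            rss=float((resid ** 2).sum()), dof=dof,
            unidentifiable=bool(flat),
        )
    raise FitFailure(f"4PL fit did not converge after {len(starts)} starts: {last_err}")


# ---------------------------------------------------------------------------
# generational recursion

def time_to_ring(L_0: float, L_stable: float, alpha: float) -> float:
    """Time (min) for a cell of birth length L_0 to grow to L_stable;
    clamped at 0 when the cell is already past the permissive length."""
    if L_0 <= 0 or L_stable <= 0 or alpha <= 0:
        raise ValueError("L_0, L_stable and alpha must be > 0")
    if L_0 >= L_stable:
        return 0.0
    return math.log(L_stable / L_0) / alpha


def run_generations(g_max: int, growth: GrowthParams,
                    induction: InductionParams | None = None,
                    L_0_init: float | None = None,
                    division_factor: float = 0.5) -> GenerationTrajectory:
    """Iterate the birth-length recursion for generations 0..g_max.

    The relative ratio is sampled once at each generation's start time (the
    cumulative sum of preceding cycle times) and held for the cycle;
    induction (t = 0) coincides with the start of generation 0, and a
    ``None`` induction means a constant ratio of 1.  When ``induction`` is
    expressed in minutes the start times are converted via the running
    trajectory's own cycle times; the default unit is generations.  When
    ``L_0_init`` is omitted the pre-induction fixed point
    ``division_factor * L_stable(1) * exp(alpha*tau)`` is used.
    """
    if g_max < 1:
        raise ValueError("g_max must be >= 1")
    if L_0_init is None:
        L_0_init = division_factor * growth.L_stable(1.0) * math.exp(
            growth.alpha * growth.tau)
    if L_0_init <= 0:
        raise ValueError("L_0_init must be > 0")

    n = g_max + 1
    gen = np.arange(n)
    start = np.zeros(n)
    ratio = np.ones(n)
    L_st = np.zeros(n)
    L_0 = np.zeros(n)
    T_z = np.zeros(n)
    cyc = np.zeros(n)

    L_0[0] = L_0_init
    t_now = 0.0               # minutes since induction
    g_now = 0.0               # generations since induction
    for g in range(n):
        start[g] = t_now
        if induction is not None:
            t_eval = g_now if induction.time_unit == "generations" else t_now
            ratio[g] = minE_at(t_eval, induction) / induction.minE_initial
        L_st[g] = growth.L_stable(ratio[g])
        T_z[g] = time_to_ring(L_0[g], L_st[g], growth.alpha)
        cyc[g] = T_z[g] + growth.tau
        if g + 1 < n:
            L_0[g + 1] = division_factor * L_0[g] * math.exp(
                growth.alpha * cyc[g])
        t_now += cyc[g]
        g_now += 1.0
    return GenerationTrajectory(generation=gen, start_time_min=start,
                                ratio_rel=ratio, L_stable=L_st, L_0=L_0,
                                T_z=T_z, cycle_time=cyc,
                                division_factor=division_factor)


def sister_delta(f_A: float, L_mother: float, growth: GrowthParams,
                 ratio_rel: float = 1.0) -> tuple[float, float]:
    """Added lengths (Delta_A, Delta_B) of two sisters born at fractions
    f_A and 1 - f_A of the mother length.

    Both sisters divide at L_stable * exp(alpha*tau), so
    Delta_i = L_stable * exp(alpha*tau) - f_i * L_mother and
    Delta_A - Delta_B = -(f_A - f_B) * L_mother exactly.  Sisters born at or
    beyond L_stable take the clamped path (T_z = 0) and still divide at the
    same size, so the identity is unaffected.
    """
    if not (0 < f_A < 1):
        raise ValueError("f_A must be in (0, 1)")
    if L_mother <= 0:
        raise ValueError("L_mother must be > 0")
    L_div = growth.L_stable(ratio_rel) * math.exp(growth.alpha * growth.tau)
    f_B = 1.0 - f_A
    return L_div - f_A * L_mother, L_div - f_B * L_mother
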