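"""Single-cell measurement pipeline for ring-formation timing and size
statistics.

Mirrors the mother-machine analysis workflow: background-correct each
cycle's septal-ring intensity trace, time the ring stabilization as the
first crossing of 65% of the cycle's maximal intensity (linear interpolation
between frames), read off the cell length at that moment by exponential
interpolation, aggregate the metrics per generation relative to the
induction point, and run the sister-pair and adder regressions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "RingTiming",
    "background_correct",
    "ring_formation_time",
    "analyze_cycles",
    "aggregate_by_generation",
    "sister_pair_stats",
    "adder_stats",
    "recover_growth_params",
]

logger = logging.getLogger(__name__)


class NoRingError(ValueError):
    """The corrected intensity trace never becomes positive."""


@dataclass
class RingTiming:
    """Per-cycle ring-formation measurements.

    ``t65`` is minutes from birth to the threshold crossing; ``S_z_est`` the
    interpolated length then; ``post_interval`` the remaining time to
    division and ``size_ratio`` the exponential size increase S_D/S_z over
    that interval.
    """

    t65: float
    S_z_est: float
    post_interval: float
    size_ratio: float


def background_correct(intensity, background_mean: float):
    """Subtract the mean background; negative values are kept, not clipped."""
    return np.asarray(intensity, dtype=float) - background_mean


def _first_crossing(times: np.ndarray, values: np.ndarray,
                    threshold: float) -> float:
    """Time of first crossing of ``threshold``, linearly interpolated."""
    above = values >= threshold
    i = int(np.argmax(above))
    if not above.any():
        raise ValueError("threshold never reached")
    if i == 0:
        return float(times[0])
    t0, t1 = times[i - 1], times[i]
    v0, v1 = values[i - 1], values[i]
    if v1 == v0:
        return float(t1)
    return float(t0 + (threshold - v0) / (v1 - v0) * (t1 - t0))


def ring_formation_time(intensity_times, intensity, birth_time: float,
                        division_time: float, S_0: float, S_D: float,
                        threshold_fraction: float = 0.65,
                        background_mean: float = 0.0) -> RingTiming:
    """Time the ring stabilization of one cycle by the threshold rule.

    The threshold is ``threshold_fraction`` of the cycle's own maximal
    corrected intensity.  The length at the crossing is interpolated
    exponentially between birth and division lengths (consistent with
    exponential growth).  Raises :class:`NoRingError` when the corrected
    maximum is not positive.
    """
    times = np.asarray(intensity_times, dtype=float)
    if times.size < 3:
        raise ValueError("need >= 3 intensity samples")
    corrected = background_correct(intensity, background_mean)
    peak = corrected.max()
    if peak <= 0:
        raise NoRingError("corrected intensity never positive; no ring")
    t65_abs = _first_crossing(times, corrected, threshold_fraction * peak)
    t65 = t65_abs - birth_time
    duration = division_time - birth_time
    alpha_cycle = math.log(S_D / S_0) / duration if duration > 0 else 0.0
    S_z = S_0 * math.exp(alpha_cycle * t65)
    return RingTiming(t65=float(t65), S_z_est=float(S_z),
                      post_interval=float(duration - t65),
                      size_ratio=float(S_D / S_z))


def analyze_cycles(cycles: pd.DataFrame, intensity: pd.DataFrame,
                   threshold_fraction: float = 0.65,
                   background_mean: float = 0.0) -> pd.DataFrame:
    """Apply the ring-timing measurement to every cycle of a lineage table.

    Cycles whose ring never reaches the threshold (non-positive corrected
    maximum) are excluded and counted; the exclusion count is attached to
    the result as ``result.attrs['n_excluded']``.
    """
    grouped = intensity.groupby(["lineage_id", "generation"])
    rows = []
    n_excluded = 0
    for rec in cycles.itertuples():
        try:
            tr = grouped.get_group((rec.lineage_id, rec.generation))
        except KeyError:
            n_excluded += 1
            continue
        try:
            timing = ring_formation_time(
                tr["time_min"].to_numpy(), tr["ring_intensity"].to_numpy(),
                birth_time=rec.birth_time, division_time=rec.division_time,
                S_0=rec.S_0, S_D=rec.S_D,
                threshold_fraction=threshold_fraction,
                background_mean=background_mean)
        except (NoRingError, ValueError) as err:
            logger.warning("cycle (%s, %s) excluded: %s",
                           rec.lineage_id, rec.generation, err)
            n_excluded += 1
            continue
        rows.append(dict(lineage_id=rec.lineage_id, generation=rec.generation,
                         t65=timing.t65, S_z=timing.S_z_est,
                         post_interval=timing.post_interval,
                         size_ratio=timing.size_ratio,
                         cycle_time=rec.division_time - rec.birth_time,
                         S_0=rec.S_0, S_D=rec.S_D))
    result = pd.DataFrame(rows)
    result.attrs["n_excluded"] = n_excluded
    if n_excluded:
        logger.warning("excluded %d cycles without a measurable ring",
                       n_excluded)
    return result


_METRICS = ("t65", "S_z", "post_interval", "size_ratio", "cycle_time", "S_0")


def aggregate_by_generation(timed: pd.DataFrame,
                            induction_gen: int = 0) -> pd.DataFrame:
    """Per-generation mean, SD, SEM and n of each ring/size metric.

    Generations are re-indexed relative to the induction generation
    (negative = pre-induction).  SEM = SD/sqrt(n); single-cycle bins report
    SEM = NaN (flagged, not zero).
    """
    if timed.empty:
        raise ValueError("no measured cycles to aggregate")
    df = timed.copy()
    df["generation_rel"] = df["generation"] - induction_gen
    out = []
    for g, grp in df.groupby("generation_rel"):
        row = {"generation_rel": g, "n": len(grp)}
        for m in _METRICS:
            vals = grp[m].to_numpy()
            row[f"{m}_mean"] = vals.mean()
            sd = vals.std(ddof=1) if len(vals) > 1 else float("nan")
            row[f"{m}_sd"] = sd
            row[f"{m}_sem"] = sd / math.sqrt(len(vals))
        out.append(row)
    return pd.DataFrame(out).sort_values("generation_rel",
                                         ignore_index=True)


def sister_pair_stats(pairs: pd.DataFrame, n_bins: int = 8):
    """Sister-cell asymmetry test: (Delta_A - Delta_B) vs (f_A - f_B).

    Returns ``(binned, fit)`` where ``binned`` holds equal-count bins with
    mean +/- SD and ``fit`` the OLS slope and its standard error.  Under the
    threshold-length model the slope equals -mean(L_mother).
    """
    if len(pairs) < 2:
        raise ValueError("need >= 2 sister pairs")
    x = (pairs["f_A"] - pairs["f_B"]).to_numpy()
    y = (pairs["delta_A"] - pairs["delta_B"]).to_numpy()
    if np.ptp(x) == 0:
        return None, dict(slope=float("nan"), slope_se=float("nan"),
                          degenerate=True)
    X = np.column_stack([np.ones_like(x), x])
    beta, res, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = max(len(x) - 2, 1)
    s2 = (resid ** 2).sum() / dof
    cov = s2 * np.linalg.inv(X.T @ X)
    n_bins = min(n_bins, len(pairs))
    order = np.argsort(x)
    bins = np.array_split(order, n_bins)
    binned = pd.DataFrame([dict(
        x_mean=x[b].mean(), y_mean=y[b].mean(),
        y_sd=y[b].std(ddof=1) if len(b) > 1 else 0.0, n=len(b))
        for b in bins])
    fit = dict(intercept=float(beta[0]), slope=float(beta[1]),
               slope_se=float(math.sqrt(cov[1, 1])), degenerate=False)
    return binned, fit


def adder_stats(timed: pd.DataFrame) -> dict:
    """OLS of added length (S_D - S_0) on birth length S_0.

    Slope 0 indicates adder behaviour, slope -1 a pure sizer (division at a
    fixed threshold length); the statistic is reported, not asserted.
    """
    if len(timed) < 3:
        raise ValueError("need >= 3 cycles")
    s0 = timed["S_0"].to_numpy()
    added = (timed["S_D"] - timed["S_0"]).to_numpy()
    if np.ptp(s0) == 0:
        return dict(slope=float("nan"), slope_se=float("nan"),
                    pearson_r=float("nan"), n=len(timed), degenerate=True)
    X = np.column_stack([np.ones_like(s0), s0])
    beta, *_ = np.linalg.lstsq(X, added, rcond=None)
    resid = added - X @ beta
    dof = max(len(s0) - 2, 1)
    s2 = (resid ** 2).sum() / dof
    cov = s2 * np.linalg.inv(X.T @ X)
    if np.ptp(added) == 0:
        r = 0.0
    else:
        r = float(np.corrcoef(s0, added)[0, 1])
    return dict(slope=float(beta[1]), slope_se=float(math.sqrt(cov[1, 1])),
                pearson_r=r, n=len(timed), degenerate=False)


def recover_growth_params(cycles: pd.DataFrame, intensity: pd.DataFrame,
                          timed: pd.DataFrame | None = None,
                          threshold_fraction: float = 0.65,
                          background_mean: float = 0.0) -> dict:
    """Estimate alpha, tau and the per-generation stable length from traces.

    alpha comes from per-cycle exponential fits of length vs time (each
    cycle contributes ln(S_D/S_0)/duration); tau is the mean post-threshold
    interval; L_stable(g) is the mean interpolated length at the threshold
    crossing per generation.  Confidence intervals use the normal
    approximation.  Cycles without a measurable ring are skipped and logged
    by :func:`analyze_cycles`.
    """
    if len(cycles) < 10:
        raise ValueError("need >= 10 cycles for parameter recovery")
    if timed is None:
        timed = analyze_cycles(cycles, intensity,
                               threshold_fraction=threshold_fraction,
                               background_mean=background_mean)
    if timed.empty:
        raise ValueError("no measurable cycles")
    ok = timed["cycle_time"] > 0
    alphas = (np.log(timed.loc[ok, "S_D"] / timed.loc[ok, "S_0"])
              / timed.loc[ok, "cycle_time"]).to_numpy()
    taus = timed["post_interval"].to_numpy()

    def _ci(v):
        n = len(v)
        se = v.std(ddof=1) / math.sqrt(n) if n > 1 else float("nan")
        return float(v.mean()), (float(v.mean() - 1.96 * se),
                                 float(v.mean() + 1.96 * se))

    alpha_hat, alpha_ci = _ci(alphas)
    tau_hat, tau_ci = _ci(taus)
    lstable = timed.groupby("generation")["S_z"].agg(["mean", "std", "count"])
    lstable["sem"] = lstable["std"] / np.sqrt(lstable["count"])
    return dict(alpha=alpha_hat, alpha_ci=alpha_ci, tau=tau_hat,
                tau_ci=tau_ci, L_stable_by_generation=lstable,
                n_cycles=int(len(timed)))
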