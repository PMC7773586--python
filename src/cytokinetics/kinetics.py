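"""Kinetic signatures, biphasic constriction fitting, condition comparisons.

The *kinetic signature* of a protein is the peak time (or times) of its mean
accumulation curve at the division site, together with arrival and departure
times defined by threshold crossings.  Ring constriction is modelled as a
continuous two-segment piecewise-linear decline (slow phase, then fast phase);
the breakpoint is estimated by exhaustive search over grid candidates with a
constrained least-squares fit at each.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.signal import find_peaks

from .align import MeanKinetics
from .panel import max_rising_slope

__all__ = [
    "KineticSignature",
    "BiphasicFit",
    "ConditionComparison",
    "extract_signature",
    "fit_biphasic",
    "summarize_constriction",
    "compare_conditions",
    "measure_step_drop",
    "max_rising_slope",
]

log = logging.getLogger(__name__)


@dataclass
class KineticSignature:
    """Arrival, peak time(s) and departure of one protein/condition."""

    protein_id: str
    condition: str
    peak_times: list[float]  # min, ascending
    peak_values: list[float]  # a.u., raw mean curve at each peak
    arrival_time: float
    departure_time: float

    @property
    def primary_peak_time(self) -> float:
        i = int(np.argmax(self.peak_values))
        return self.peak_times[i]

    @property
    def primary_peak_value(self) -> float:
        return max(self.peak_values)


@dataclass
class BiphasicFit:
    """Two-segment piecewise-linear constriction fit for one cell."""

    breakpoint: float        # t_b, min
    slow_rate: float         # μm/min (>= 0)
    fast_rate: float         # μm/min (>= 0)
    slow_drop: float         # μm, plateau level minus fitted diameter at t_b
    fast_drop: float         # μm, fitted drop from t_b to window end
    sse: float               # μm², over the fitted window
    onset: float             # min, where the slow segment meets the plateau
    end: float               # min, end of the fitted window
    plateau: float           # μm, pre-constriction diameter estimate
    window: tuple[float, float]  # fitted gridpoint range
    incomplete: bool = False  # ring did not reach the resolution floor

    @property
    def percent_fast(self) -> float:
        total = self.slow_drop + self.fast_drop
        return 100.0 * self.fast_drop / total if total > 0 else np.nan


@dataclass
class ConditionComparison:
    protein_id: str
    peak_ratio_pct: float
    peak_shift: float
    rate_ratio_pct: float
    magnitude_ratio_pct: float


def _moving_average3(y: np.ndarray) -> np.ndarray:
    """Centered window-3 moving average with shrinking windows at the edges."""
    out = y.copy()
    if y.size >= 3:
        out[1:-1] = (y[:-2] + y[1:-1] + y[2:]) / 3.0
        out[0] = (y[0] + y[1]) / 2.0
        out[-1] = (y[-2] + y[-1]) / 2.0
    return out


def _crossing_time(grid: np.ndarray, y: np.ndarray, level: float, first: bool) -> float:
    """First (or last) upward (downward) crossing of ``level``, interpolated."""
    above = y >= level
    if first:
        idx = np.flatnonzero(above)
        if idx.size == 0:
            return np.nan
        i = idx[0]
        if i == 0 or not np.isfinite(y[i - 1]):
            return float(grid[i])
        t0, t1, y0, y1 = grid[i - 1], grid[i], y[i - 1], y[i]
    else:
        idx = np.flatnonzero(above)
        if idx.size == 0:
            return np.nan
        i = idx[-1]
        if i == y.size - 1 or not np.isfinite(y[i + 1]):
            return float(grid[i])
        t0, t1, y0, y1 = grid[i], grid[i + 1], y[i], y[i + 1]
    if y1 == y0:
        return float(t0)
    return float(t0 + (level - y0) * (t1 - t0) / (y1 - y0))


def extract_signature(mk: MeanKinetics, prominence_frac: float = 0.10,
                      onset_frac: float = 0.15, min_separation: float = 3.0,
                      ) -> KineticSignature:
    """Extract peaks, arrival and departure from a mean kinetic curve.

    The curve is smoothed with a centered window-3 moving average; peaks are
    local maxima with prominence at least ``prominence_frac`` of the curve's
    range and mutual separation at least ``min_separation`` minutes, with each
    peak location refined to the local argmax of the unsmoothed curve.
    Arrival/departure are the first/last crossings of
    ``baseline + onset_frac * (primary peak - baseline)`` where the baseline is
    the mean of the first five unmasked gridpoints.
    """
    ok = mk.unmasked
    if ok.sum() < 10:
        raise ValueError(f"{mk.protein_id}: fewer than 10 unmasked gridpoints")
    grid = mk.grid[ok]
    y = mk.mean[ok]
    step = float(np.median(np.diff(grid)))
    smooth = _moving_average3(y)
    rng_ = smooth.max() - smooth.min()
    if rng_ <= 0:
        raise ValueError(f"{mk.protein_id}: flat curve, no signature")
    distance = max(1, int(round(min_separation / step)))
    idx, _ = find_peaks(smooth, prominence=prominence_frac * rng_, distance=distance)
    if idx.size == 0:
        idx = np.array([int(np.argmax(smooth))])
    # refine on the raw curve: local argmax within one gridpoint
    refined = []
    for i in idx:
        lo, hi = max(0, i - 1), min(y.size, i + 2)
        refined.append(lo + int(np.argmax(y[lo:hi])))
    refined = sorted(set(refined))
    peak_times = [float(grid[i]) for i in refined]
    peak_values = [float(y[i]) for i in refined]

    baseline = float(np.mean(y[:5]))
    primary = max(peak_values)
    level = baseline + onset_frac * (primary - baseline)
    arrival = _crossing_time(grid, y, level, first=True)
    departure = _crossing_time(grid, y, level, first=False)
    arrival = min(arrival, peak_times[0]) if np.isfinite(arrival) else peak_times[0]
    departure = max(departure, peak_times[-1]) if np.isfinite(departure) else peak_times[-1]
    return KineticSignature(mk.protein_id, mk.condition, peak_times, peak_values,
                            arrival, departure)


# -- biphasic constriction fit -------------------------------------------------


def _solve_nonpos(A: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Exact LSQ with the slope coordinates (columns 1..) constrained <= 0.

    Tiny active-set enumeration: the constrained optimum restricted to its
    free coordinates solves the unconstrained subproblem, so enumerating all
    clamp patterns of the slope coordinates and keeping the feasible minimum
    is exact.  Returns (sse, x).
    """
    nslope = A.shape[1] - 1
    best_sse, best_x = np.inf, None
    for clamp in range(1 << nslope):
        free = [0] + [j for j in range(1, nslope + 1) if not (clamp >> (j - 1)) & 1]
        xf, *_ = np.linalg.lstsq(A[:, free], y, rcond=None)
        if np.any(xf[1:] > 1e-12):
            continue
        x = np.zeros(A.shape[1])
        x[free] = xf
        resid = A @ x - y
        sse = float(resid @ resid)
        if sse < best_sse:
            best_sse, best_x = sse, x
    return best_sse, best_x


def _two_segment_lsq(t: np.ndarray, y: np.ndarray, t_b: float) -> tuple[float, np.ndarray]:
    """Constrained LSQ for a continuous two-segment line with slopes <= 0.

    Model: y = c + b1*min(t-t_b, 0) + b2*max(t-t_b, 0), b1 <= 0, b2 <= 0.
    Returns (sse, [c, b1, b2]).
    """
    A = np.column_stack([np.ones_like(t), np.minimum(t - t_b, 0.0),
                         np.maximum(t - t_b, 0.0)])
    return _solve_nonpos(A, y)


def detect_constriction_window(times: np.ndarray, diam: np.ndarray,
                               plateau_frac: float = 0.95,
                               floor: float = 0.05,
                               margin_sigmas: float = 2.5,
                               ) -> tuple[int, int, float, bool]:
    """Locate the constriction window of a diameter trace.

    The pre-constriction plateau is the median diameter over frames whose
    smoothed value stays at >= ``plateau_frac`` of the maximum; the window
    starts at the last gridpoint before the smoothed trace falls below the
    plateau by more than a noise margin (``margin_sigmas`` estimated noise
    SDs, at least 1% of the plateau) for two consecutive frames, and ends
    where the diameter first reaches the resolution ``floor`` (μm).  If the
    floor is never reached the window ends at the argmin and is flagged
    incomplete.  Returns ``(i_start, i_end, plateau, incomplete)``.
    """
    d = np.asarray(diam, dtype=float)
    smooth = _moving_average3(d)
    dmax = float(np.nanmax(smooth))
    plateau_mask = smooth >= plateau_frac * dmax
    plateau = float(np.median(d[plateau_mask]))
    sigma_sm = 1.4826 * float(np.median(np.abs(d[plateau_mask] - plateau))) / np.sqrt(3.0)
    thr = plateau - max(margin_sigmas * sigma_sm, 0.01 * plateau)
    below = smooth < thr
    sust = below[:-1] & below[1:]
    starts = np.flatnonzero(sust)
    if starts.size == 0:
        raise ValueError("no constriction: diameter never drops below plateau")
    i0 = max(int(starts[0]) - 1, 0)
    after = np.flatnonzero(d[i0:] <= floor)
    if after.size:
        i1 = i0 + int(after[0])
        incomplete = False
    else:
        i1 = i0 + int(np.argmin(d[i0:]))
        incomplete = True
    return i0, i1, plateau, incomplete


def fit_biphasic(times: np.ndarray, diam: np.ndarray,
                 plateau_frac: float = 0.95, floor: float = 0.05,
                 margin_sigmas: float = 2.5) -> BiphasicFit:
    """Fit the continuous two-segment constriction model to a diameter trace.

    The breakpoint is chosen by exhaustive search over interior gridpoints of
    the constriction window, minimizing the SSE of the constrained
    (continuous, non-increasing) least-squares fit; ties resolve to the
    earliest breakpoint.  Phase contributions are measured from the plateau
    level: the slow drop is ``plateau - fit(t_b)`` (the slow segment
    extrapolated back to the pre-constriction diameter), the fast drop is the
    fitted decline from the breakpoint to the window end, so that
    ``slow_drop + fast_drop = plateau - fit(end)`` exactly.
    """
    times = np.asarray(times, dtype=float)
    d = np.asarray(diam, dtype=float)
    ok = np.isfinite(d)
    times, d = times[ok], d[ok]
    i0, i1, plateau, incomplete = detect_constriction_window(
        times, d, plateau_frac, floor, margin_sigmas)
    t, y = times[i0:i1 + 1], d[i0:i1 + 1]
    if t.size < 4:
        raise ValueError("no constriction: window shorter than 4 gridpoints")

    best_sse, best_x, best_tb = np.inf, None, None
    for t_b in t[1:-1]:
        sse, x = _two_segment_lsq(t, y, float(t_b))
        if sse < best_sse - 1e-15:
            best_sse, best_x, best_tb = sse, x, float(t_b)
    c, b1, b2 = best_x
    slow_rate, fast_rate = -b1, -b2
    fit_tb = c
    fit_end = c + b2 * (t[-1] - best_tb)
    slow_drop = max(plateau - fit_tb, 0.0)
    fast_drop = max(fit_tb - fit_end, 0.0)
    if slow_rate > 1e-12:
        onset = best_tb - slow_drop / slow_rate
        onset = max(onset, float(times[0]))
    else:
        onset = float(t[0])
    return BiphasicFit(breakpoint=best_tb, slow_rate=slow_rate, fast_rate=fast_rate,
                       slow_drop=slow_drop, fast_drop=fast_drop, sse=best_sse,
                       onset=onset, end=float(t[-1]), plateau=plateau,
                       window=(float(t[0]), float(t[-1])), incomplete=incomplete)


def summarize_constriction(fits: Sequence[BiphasicFit]) -> dict:
    """Ensemble means ± SD of rates, drops, percent_fast, and the fold ratio.

    Incomplete fits (ring never reached the floor) are excluded, as are
    zero-slow-rate fits from the fold ratio; both exclusions are logged and
    counted in the summary.
    """
    usable = [f for f in fits if not f.incomplete]
    n_incomplete = len(fits) - len(usable)
    if n_incomplete:
        log.warning("summarize_constriction: excluded %d incomplete fits", n_incomplete)
    if len(usable) < 5:
        raise ValueError("need at least 5 complete fits to summarize")

    def stats(vals: list[float]) -> tuple[float, float]:
        arr = np.asarray(vals)
        return float(arr.mean()), float(arr.std(ddof=1)) if arr.size > 1 else np.nan

    slow = [f.slow_rate for f in usable]
    fast = [f.fast_rate for f in usable]
    pos = [f for f in usable if f.slow_rate > 0]
    n_zero_slow = len(usable) - len(pos)
    if n_zero_slow:
        log.warning("summarize_constriction: %d zero slow-rate fits excluded "
                    "from fold_ratio", n_zero_slow)
    out = {}
    for name, vals in (("slow_rate", slow), ("fast_rate", fast),
                       ("slow_drop", [f.slow_drop for f in usable]),
                       ("fast_drop", [f.fast_drop for f in usable]),
                       ("percent_fast", [f.percent_fast for f in usable])):
        m, s = stats(vals)
        out[f"{name}_mean"] = m
        out[f"{name}_sd"] = s
    out["fold_ratio"] = (float(np.mean([f.fast_rate for f in pos]))
                         / float(np.mean([f.slow_rate for f in pos]))) if pos else np.nan
    out["n_cells"] = len(usable)
    out["n_incomplete"] = n_incomplete
    out["n_zero_slow_excluded"] = n_zero_slow
    return out


# -- condition comparison ------------------------------------------------------


def compare_conditions(mk_treat: MeanKinetics, mk_ctrl: MeanKinetics,
                       slope_window: float = 5.0) -> ConditionComparison:
    """Compare a treated mean curve with its control.

    peak ratio on raw a.u.; peak shift of the primary (highest) peak; rate
    ratio of max ``slope_window``-min rising slopes; magnitude ratio of areas
    above baseline (baseline = mean of the first five unmasked points).
    """
    if mk_treat.protein_id != mk_ctrl.protein_id:
        raise ValueError("compare_conditions: different proteins")
    joint = mk_treat.unmasked & mk_ctrl.unmasked
    if joint.sum() < 15:
        raise ValueError("compare_conditions: fewer than 15 joint gridpoints")
    sig_t = extract_signature(mk_treat)
    sig_c = extract_signature(mk_ctrl)
    if sig_c.primary_peak_value <= 0:
        raise ValueError("compare_conditions: control peak is zero")

    grid = mk_treat.grid[joint]
    yt, yc = mk_treat.mean[joint], mk_ctrl.mean[joint]
    rate_t = max_rising_slope(grid, yt, slope_window)
    rate_c = max_rising_slope(grid, yc, slope_window)

    def auc(y: np.ndarray) -> float:
        base = float(np.mean(y[:5]))
        return float(np.trapezoid(np.maximum(y - base, 0.0), grid))

    auc_c = auc(yc)
    return ConditionComparison(
        protein_id=mk_treat.protein_id,
        peak_ratio_pct=100.0 * sig_t.primary_peak_value / sig_c.primary_peak_value,
        peak_shift=sig_t.primary_peak_time - sig_c.primary_peak_time,
        rate_ratio_pct=100.0 * rate_t / rate_c if rate_c > 0 else np.nan,
        magnitude_ratio_pct=100.0 * auc(yt) / auc_c if auc_c > 0 else np.nan,
    )


def measure_step_drop(mk: MeanKinetics, window_start: float, window_end: float) -> float:
    """Percent intensity drop of the mean curve between two gridpoints."""
    vals = []
    for t in (window_start, window_end):
        i = np.flatnonzero(np.isclose(mk.grid, t))
        if i.size == 0 or not np.isfinite(mk.mean[i[0]]):
            raise ValueError(f"gridpoint {t} min is masked or absent")
        vals.append(float(mk.mean[i[0]]))
    v0, v1 = vals
    if v0 == 0:
        raise ValueError("zero value at window start")
    return 100.0 * (v0 - v1) / v0
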