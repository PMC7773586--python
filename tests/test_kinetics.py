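"""Signature extraction, biphasic fit (with brute-force oracle), comparisons."""

import numpy as np
import pytest
from scipy.optimize import nnls

from cytokinetics.align import MeanKinetics, aggregate
from cytokinetics.kinetics import (compare_conditions, extract_signature,
                                   fit_biphasic, measure_step_drop,
                                   summarize_constriction)
from cytokinetics.panel import ConditionEffect, apply_condition
from cytokinetics.simulate import (ConstrictionParams, simulate_constriction,
                                   simulate_trace)

ZERO_VAR = ConstrictionParams(slow_rate_sd=0.0, fast_rate_sd=0.0,
                              slow_drop_sd=0.0, fast_drop_sd=0.0, noise_sd=0.0)


def _mk(grid, mean, protein="X"):
    mean = np.asarray(mean, dtype=float)
    return MeanKinetics(protein_id=protein, grid=np.asarray(grid, float),
                        mean=mean, sd=np.zeros_like(mean),
                        n=np.full(mean.shape, 30.0))


# -- signature extraction ------------------------------------------------------


def test_unimodal_noiseless_peak_is_exact_argmax(byid, grid):
    tpl = byid["Chs2"]
    mk = _mk(grid, tpl(grid))
    sig = extract_signature(mk)
    assert sig.peak_times == [2.0]
    assert sig.arrival_time <= 2.0 <= sig.departure_time


def test_flat_curve_raises(grid):
    with pytest.raises(ValueError, match="flat"):
        extract_signature(_mk(grid, np.full(grid.shape, 4.0)))


def test_too_few_points_raises(grid):
    mean = np.full(grid.shape, np.nan)
    mean[:5] = 1.0
    with pytest.raises(ValueError, match="unmasked"):
        extract_signature(_mk(grid, mean))


def test_arrival_departure_threshold_crossings(grid):
    # symmetric triangle: baseline 0, peak 100 at t=0, support [-10, 10]
    mean = np.clip(100 - 10 * np.abs(grid), 0, None)
    sig = extract_signature(_mk(grid, mean))
    # 15% crossing of a 10-min linear rise: at +-8.5 min
    assert sig.arrival_time == pytest.approx(-8.5, abs=0.2)
    assert sig.departure_time == pytest.approx(8.5, abs=0.2)


# -- biphasic fit ---------------------------------------------------------------


def test_noiseless_piecewise_recovery_exact():
    t = np.arange(-6.0, 4.5, 1.0)
    d0 = 0.02 * 4 + 0.18 * 6
    d = np.where(t <= -2.0, d0 - 0.02 * (t + 6), 1.08 - 0.18 * (t + 2))
    fit = fit_biphasic(t, d)
    assert fit.breakpoint == pytest.approx(-2.0)
    assert fit.slow_rate == pytest.approx(0.02, abs=1e-9)
    assert fit.fast_rate == pytest.approx(0.18, abs=1e-9)
    assert fit.sse == pytest.approx(0.0, abs=1e-18)


def test_single_slope_line_ties_to_earliest_breakpoint():
    t = np.arange(0.0, 12.0)
    d = 1.2 - 0.1 * t
    fit = fit_biphasic(t, d, floor=0.0)
    assert fit.slow_rate == pytest.approx(0.1, abs=1e-9)
    assert fit.fast_rate == pytest.approx(0.1, abs=1e-9)
    assert fit.breakpoint == fit.window[0] + 1.0  # earliest interior candidate


def test_no_constriction_raises():
    t = np.arange(-10.0, 10.0)
    with pytest.raises(ValueError, match="no constriction"):
        fit_biphasic(t, np.full(t.shape, 1.0))


def _oracle(t, y):
    """Breakpoint enumeration with an independent NNLS solve per candidate.

    Slopes b <= 0 are written as b = -r with r >= 0 and the free intercept as
    c+ - c-, giving a pure nonnegative least-squares problem.
    """
    best = (np.inf, None)
    for tb in t[1:-1]:
        s1 = np.minimum(t - tb, 0.0)
        s2 = np.maximum(t - tb, 0.0)
        M = np.column_stack([np.ones_like(t), -np.ones_like(t), -s1, -s2])
        x, _ = nnls(M, y)
        resid = M @ x - y
        sse = float(resid @ resid)
        if sse < best[0] - 1e-15:
            best = (sse, float(tb))
    return best


def test_fit_equals_bruteforce_oracle_on_100_instances(grid):
    rng = np.random.default_rng(12345)
    checked = 0
    seed = 0
    while checked < 100:
        seed += 1
        params = ConstrictionParams(
            slow_rate_mean=float(rng.uniform(0.01, 0.05)),
            fast_rate_mean=float(rng.uniform(0.1, 0.3)),
            slow_drop_mean=float(rng.uniform(0.05, 0.2)),
            fast_drop_mean=float(rng.uniform(0.6, 1.1)),
            noise_sd=float(rng.uniform(0.005, 0.03)))
        d, _ = simulate_constriction(params, seed=seed)
        try:
            fit = fit_biphasic(grid, d)
        except ValueError:
            continue
        sel = (grid >= fit.window[0]) & (grid <= fit.window[1])
        sse_o, tb_o = _oracle(grid[sel], d[sel])
        assert fit.sse == pytest.approx(sse_o, abs=1e-9)
        assert fit.breakpoint == tb_o
        checked += 1


def test_drops_conservation_exact(grid):
    for seed in range(10):
        d, _ = simulate_constriction(ConstrictionParams(), seed=seed)
        try:
            f = fit_biphasic(grid, d)
        except ValueError:
            continue
        fit_end = f.plateau - f.slow_drop - f.fast_drop
        # slow_drop + fast_drop equals plateau minus the fitted end level
        assert f.slow_drop + f.fast_drop == pytest.approx(f.plateau - fit_end, abs=1e-9)
        assert f.slow_rate >= 0 and f.fast_rate >= 0


def test_breakpoint_error_monotone_in_noise(grid):
    """More diameter noise never improves median breakpoint accuracy."""
    med_err = []
    for noise in (0.005, 0.02, 0.05):
        errs = []
        for seed in range(50):
            params = ConstrictionParams(noise_sd=noise)
            d, truth = simulate_constriction(params, seed=seed)
            try:
                f = fit_biphasic(grid, d)
            except ValueError:
                continue
            if f.incomplete:
                continue
            errs.append(abs(f.breakpoint - truth["breakpoint_min"]))
        med_err.append(np.median(errs))
    assert med_err[0] <= med_err[1] + 1.0  # tolerance: one grid step
    assert med_err[1] <= med_err[2] + 1.0


def test_summarize_zero_variance_fold_ratio_is_nine():
    rng = np.random.default_rng(0)
    fits = [fit_biphasic(np.arange(-45.0, 46.0),
                         simulate_constriction(ZERO_VAR, rng)[0])
            for _ in range(6)]
    s = summarize_constriction(fits)
    assert s["fold_ratio"] == pytest.approx(9.0, abs=1e-9)
    assert s["slow_rate_sd"] == pytest.approx(0.0, abs=1e-12)


def test_summarize_requires_five_fits(grid):
    d, _ = simulate_constriction(ZERO_VAR, seed=0)
    with pytest.raises(ValueError):
        summarize_constriction([fit_biphasic(grid, d)])


# -- condition comparison -------------------------------------------------------


def test_compare_curve_with_itself_is_identity(control_means):
    cc = compare_conditions(control_means["Mlc1"], control_means["Mlc1"])
    assert cc.peak_ratio_pct == pytest.approx(100.0)
    assert cc.peak_shift == 0.0
    assert cc.rate_ratio_pct == pytest.approx(100.0)
    assert cc.magnitude_ratio_pct == pytest.approx(100.0)


def test_compare_rejects_different_proteins(control_means):
    with pytest.raises(ValueError):
        compare_conditions(control_means["Mlc1"], control_means["Chs2"])


def _treated_mean(tpl, effect, seed, n=30):
    treated = apply_condition(tpl, effect)
    traces = [simulate_trace(treated, seed=seed * 1000 + i, cell_id=f"c{i}")[0]
              for i in range(n)]
    return aggregate(traces, protein_id=tpl.protein_id, condition="treated")


def test_mlc1_amplitude_and_shift_recovered(byid, control_means):
    mk_t = _treated_mean(byid["Mlc1"], ConditionEffect(amplitude_factor=0.66,
                                                       peak_shift=-3.0), seed=7)
    cc = compare_conditions(mk_t, control_means["Mlc1"])
    assert cc.peak_ratio_pct == pytest.approx(66.0, abs=5.0)
    assert cc.peak_shift == pytest.approx(-3.0, abs=1.0)


def test_chs2_rate_factor_recovered(byid, control_means):
    mk_t = _treated_mean(byid["Chs2"], ConditionEffect(rate_factor=0.37), seed=8)
    cc = compare_conditions(mk_t, control_means["Chs2"])
    assert cc.rate_ratio_pct == pytest.approx(37.0, abs=6.0)


# -- step drop ------------------------------------------------------------------


def test_step_drop_constant_curve_is_zero(grid):
    mk = _mk(grid, np.full(grid.shape, 50.0))
    assert measure_step_drop(mk, -6.0, -1.0) == 0.0


def test_step_drop_construction():
    grid = np.arange(-10.0, 11.0)
    mean = np.where(grid < -3.5, 100.0, 77.4)
    assert measure_step_drop(_mk(grid, mean), -6.0, -1.0) == pytest.approx(22.6)


def test_step_drop_zero_start_raises(grid):
    mk = _mk(grid, np.zeros(grid.shape))
    with pytest.raises(ValueError):
        measure_step_drop(mk, -6.0, -1.0)
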