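"""Constrained waveform optimization: oracles, residuals, properties."""
import numpy as np
import pytest

from gradwave import (EffectiveWaveform, OptimizationSpec, TimeGrid,
                      best_pgse, compute_btensor, compute_moment,
                      max_slew, maximize_b, minimize_duration, resample,
                      verify)
from gradwave.optimize import OptimizationResult

FAST = dict(gmax=80e-3, smax=60.0, gap=8e-3, n_points=60, restarts=2)


class TestMaximizeB:
    def test_zero_timing_infeasible(self):
        spec = OptimizationSpec(shape_target="linear", delta1=0.0,
                                delta2=0.0, gap=8e-3)
        with pytest.raises(ValueError):
            maximize_b(spec)

    def test_lte_m0_matches_pgse_oracle(self):
        """m0-only linear encoding reaches >= 95 % of the trapezoid PGSE b."""
        spec = OptimizationSpec(shape_target="linear", delta1=30e-3,
                                delta2=30e-3, gap=8e-3, null_orders=(0,),
                                n_points=100, restarts=3, seed=1,
                                gmax=80e-3, smax=60.0)
        res = maximize_b(spec)
        grid = TimeGrid.from_timings(30e-3, 8e-3, 30e-3, 1e-5)
        oracle = compute_btensor(best_pgse(80e-3, 60.0, grid)).b
        assert res.converged
        assert res.achieved_b >= 0.95 * oracle

    def test_deterministic_given_seed(self):
        spec = OptimizationSpec(shape_target="linear", delta1=20e-3,
                                delta2=16e-3, null_orders=(0, 1),
                                thresholds={1: 1e-4}, seed=7, **FAST)
        w1 = maximize_b(spec).waveform.g
        w2 = maximize_b(spec).waveform.g
        assert np.array_equal(w1, w2)

    def test_moderate_threshold_uses_inequality(self):
        """A sizeable L1 leaves residual motion encoding below the bound."""
        L1 = 2.0e3                      # rad s/m, far above nulling scale
        spec = OptimizationSpec(shape_target="linear", delta1=20e-3,
                                delta2=16e-3, null_orders=(0, 1),
                                thresholds={1: L1}, seed=4, **FAST)
        res = maximize_b(spec)
        w = resample(res.waveform, 1e-5)
        assert res.converged
        assert compute_moment(w, 1).magnitude <= L1 * (1 + 1e-3)
        # the slack must actually be used: more b than with full nulling
        spec0 = OptimizationSpec(shape_target="linear", delta1=20e-3,
                                 delta2=16e-3, null_orders=(0, 1),
                                 thresholds={1: 1e-4}, seed=4, **FAST)
        assert res.achieved_b >= maximize_b(spec0).achieved_b * 0.99

    def test_nulling_monotonically_costs_b(self):
        """Constraining higher moments never raises the achievable b.

        Checked on asymmetric linear encoding over three seeds (the
        odd-to-even exception reported for symmetric linear encoding does
        not apply to asymmetric timing).
        """
        for seed in (1, 2, 3):
            bs = []
            for orders in ((0,), (0, 1), (0, 1, 2)):
                spec = OptimizationSpec(
                    shape_target="linear", delta1=23e-3, delta2=17e-3,
                    null_orders=orders,
                    thresholds={n: 1e-4 for n in orders if n}, seed=seed,
                    **FAST)
                bs.append(maximize_b(spec).achieved_b)
            assert bs[0] >= bs[1] * 0.98
            assert bs[1] >= bs[2] * 0.98

    def test_symmetric_and_asymmetric_both_feasible(self):
        """m2-nulled solves succeed for 30/30 and 33/27 ms timings."""
        for d1, d2 in ((30e-3, 30e-3), (33e-3, 27e-3)):
            spec = OptimizationSpec(shape_target="linear", delta1=d1,
                                    delta2=d2, null_orders=(0, 1, 2),
                                    thresholds={1: 1e-4, 2: 1e-4}, seed=2,
                                    **FAST)
            res = maximize_b(spec)
            assert res.converged, res.residuals
            assert res.achieved_b > 0.5e9


class TestVerify:
    def test_constructed_slew_violation(self):
        """A triangle exceeding the slew bound reports the exact excess."""
        grid = TimeGrid.from_timings(10e-3, 8e-3, 10e-3, 1e-3)
        g = np.zeros((grid.n_samples, 3))
        g[1:grid.n_pre, 0] = 0.07        # 70 mT/m step in 1 ms = 70 T/m/s
        g[grid.n_pre] = 0.0
        w = EffectiveWaveform(grid=grid, g=g)
        spec = OptimizationSpec(shape_target="linear", gmax=80e-3, smax=60.0,
                                delta1=10e-3, delta2=10e-3, gap=8e-3)
        res = OptimizationResult(waveform=w, achieved_b=0, residuals={},
                                 converged=False, restarts_used=0,
                                 objective_history=[], spec=spec)
        resid = verify(res, spec)
        assert resid["slew"] == pytest.approx(70.0 - 60.0, rel=1e-9)

    def test_zero_waveform_b_residual_is_target(self):
        grid = TimeGrid.from_timings(10e-3, 8e-3, 10e-3, 5e-4)
        w = EffectiveWaveform(grid=grid, g=np.zeros((grid.n_samples, 3)))
        spec = OptimizationSpec(shape_target="linear", delta1=10e-3,
                                delta2=10e-3, gap=8e-3, b_target=1.0e9)
        res = OptimizationResult(waveform=w, achieved_b=0, residuals={},
                                 converged=False, restarts_used=0,
                                 objective_history=[], spec=spec)
        assert verify(res, spec)["b"] == pytest.approx(1.0e9)

    def test_returned_waveforms_pass_fine_verification(self):
        spec = OptimizationSpec(shape_target="planar", delta1=22e-3,
                                delta2=18e-3, null_orders=(0, 1),
                                thresholds={1: 1e-4}, maxwell_limit=100.0,
                                seed=5, **FAST)
        res = maximize_b(spec)
        assert res.converged
        assert res.residuals["amplitude"] <= 1e-3 * spec.gmax
        assert res.residuals["slew"] <= 1e-3 * spec.smax
        assert res.residuals["maxwell"] <= 1e-3 * spec.maxwell_limit
        assert res.residuals["shape"] <= 1e-3


class TestMinimizeDuration:
    def test_reaches_pgse_feasible_duration(self):
        """For m0-only linear specs the optimizer needs no more time than
        the analytic PGSE reaching the same b."""
        grid = TimeGrid.from_timings(20e-3, 8e-3, 20e-3, 1e-5)
        b_oracle = compute_btensor(best_pgse(80e-3, 60.0, grid)).b
        spec = OptimizationSpec(shape_target="linear", delta1=10e-3,
                                delta2=10e-3, gap=8e-3, null_orders=(0,),
                                b_target=b_oracle, n_points=60, restarts=2,
                                seed=1, gmax=80e-3, smax=60.0)
        res = minimize_duration(spec, duration_tol=1e-3)
        assert res.converged
        assert res.waveform.grid.tau <= grid.tau + 2e-3
        assert res.achieved_b == pytest.approx(b_oracle, rel=1e-6)

    def test_missing_target_rejected(self):
        spec = OptimizationSpec(shape_target="linear")
        with pytest.raises(ValueError):
            minimize_duration(spec)

    def test_unreachable_target_reports_cap(self):
        spec = OptimizationSpec(shape_target="linear", delta1=8e-3,
                                delta2=8e-3, gap=8e-3, null_orders=(0,),
                                b_target=50.0e9, n_points=40, restarts=1,
                                seed=1, gmax=80e-3, smax=60.0)
        with pytest.raises(RuntimeError, match="unreachable"):
            minimize_duration(spec, duration_cap=0.03)
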