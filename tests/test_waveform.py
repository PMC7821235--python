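"""Encoding metrics of effective waveforms against closed-form oracles."""
import numpy as np
import pytest

from gradwave import (EffectiveWaveform, PGSEParams, TimeGrid,
                      compute_btensor, compute_dephasing, compute_moment,
                      efficiency, make_monopolar, maxwell_index,
                      monopolar_m1, resample, rotate, stejskal_tanner_b)
from gradwave.units import GAMMA_H


def _single_lobe(g=0.05, delta=10e-3, dt=1e-5):
    """One rectangular-ish lobe in the first encoding period only."""
    grid = TimeGrid.from_timings(delta + 2e-3, 8e-3, 5e-3, dt)
    arr = np.zeros((grid.n_samples, 3))
    t0 = 1e-3
    k0, k1 = round(t0 / dt), round((t0 + delta) / dt)
    arr[k0:k1 + 1, 0] = g
    arr[k0, 0] = arr[k1, 0] = g / 2          # area-preserving edges
    return EffectiveWaveform(grid=grid, g=arr), t0, k0, k1


def _smooth(grid, amps=(0.04, 0.02, 0.03)):
    """Grid-independent smooth waveform: sinusoids under a C1 envelope
    that vanishes at the period edges and throughout the gap."""
    t = grid.times
    d1, gap, d2, tau = grid.delta1, grid.gap, grid.delta2, grid.tau
    env = np.zeros_like(t)
    pre = t <= d1
    post = t >= d1 + gap
    env[pre] = np.sin(np.pi * t[pre] / d1) ** 2
    env[post] = np.sin(np.pi * (t[post] - d1 - gap) / d2) ** 2
    g = np.zeros((grid.n_samples, 3))
    for a in range(3):
        g[:, a] = amps[a] * np.sin(2 * np.pi * (a + 1) * t / tau) * env
    g[grid.gap_slice] = 0.0
    g[0] = g[-1] = 0.0
    return EffectiveWaveform(grid=grid, g=g)


class TestDephasing:
    def test_zero_waveform(self):
        grid = TimeGrid.from_timings(10e-3, 8e-3, 10e-3, 1e-4)
        w = EffectiveWaveform(grid=grid, g=np.zeros((grid.n_samples, 3)))
        assert np.all(compute_dephasing(w).q == 0.0)

    def test_rectangular_lobe_closed_form(self):
        w, t0, k0, k1 = _single_lobe()
        q = compute_dephasing(w).q
        t = w.grid.times
        inside = slice(k0 + 1, k1)          # strictly inside the flat top
        expected = GAMMA_H * 0.05 * (t[inside] - t0)
        assert np.allclose(q[inside, 0], expected, rtol=1e-9)

    def test_final_dephasing_equals_m0(self, mono, bipolar):
        for w in (mono, bipolar):
            final = compute_dephasing(w).final
            m0 = compute_moment(w, 0).value
            assert np.allclose(final, m0, atol=1e-9)

    def test_constant_across_gap(self, mono):
        q = compute_dephasing(mono).q[mono.grid.gap_slice]
        assert np.ptp(q, axis=0).max() < 1e-9 * np.abs(q).max()


class TestBTensor:
    @pytest.mark.parametrize("g,delta", [(0.08, 15e-3), (0.03, 8e-3),
                                         (0.05, 22e-3)])
    def test_pgse_stejskal_tanner(self, g, delta):
        p = PGSEParams(g=g, delta=delta)
        w = make_monopolar(p)
        _, _, Delta, _ = p.resolve()
        assert compute_btensor(w).b == pytest.approx(
            stejskal_tanner_b(g, delta, Delta), rel=1e-4)

    def test_zero_waveform(self):
        grid = TimeGrid.from_timings(10e-3, 8e-3, 10e-3, 1e-4)
        w = EffectiveWaveform(grid=grid, g=np.zeros((grid.n_samples, 3)))
        assert compute_btensor(w).b == 0.0

    def test_brute_force_equivalence(self):
        """Trapezoid b-tensor equals an explicit loop over q samples."""
        grid = TimeGrid.from_timings(6e-3, 2e-3, 6e-3, 5e-4)
        w = _smooth(grid)
        # independent route: running integral + Riemann/trapezoid loop
        dt, gam = grid.dt, w.gamma
        q = np.zeros((grid.n_samples, 3))
        for i in range(1, grid.n_samples):
            q[i] = q[i - 1] + gam * 0.5 * dt * (w.g[i - 1] + w.g[i])
        B = np.zeros((3, 3))
        for i in range(grid.n_samples):
            wt = dt / 2 if i in (0, grid.n_samples - 1) else dt
            B += wt * np.outer(q[i], q[i])
        assert np.allclose(compute_btensor(w).matrix, B, rtol=1e-12)

    def test_amplitude_and_time_scaling(self):
        """b scales with amplitude^2 and (fixed shape) duration^3."""
        grid = TimeGrid.from_timings(10e-3, 4e-3, 10e-3, 1e-4)
        w = _smooth(grid)
        b0 = compute_btensor(w).b
        w2 = EffectiveWaveform(grid=grid, g=2.0 * w.g)
        assert compute_btensor(w2).b == pytest.approx(4.0 * b0, rel=1e-12)
        grid3 = TimeGrid.from_timings(30e-3, 12e-3, 30e-3, 3e-4)
        w3 = EffectiveWaveform(grid=grid3, g=w.g)
        assert compute_btensor(w3).b == pytest.approx(27.0 * b0, rel=1e-12)

    def test_shape_labels(self):
        from gradwave import BTensor
        assert BTensor(np.diag([1.0, 0, 0])).shape_label == "linear"
        assert BTensor(np.diag([1.0, 1.0, 0])).shape_label == "planar"
        assert BTensor(np.eye(3)).shape_label == "spherical"
        assert BTensor(np.diag([1.0, 0.5, 0.1])).shape_label == "general"


class TestMoments:
    def test_monopolar_m1_closed_form(self):
        p = PGSEParams(g=0.08, delta=15e-3)
        w = make_monopolar(p)
        _, _, Delta, _ = p.resolve()
        assert compute_moment(w, 1).magnitude == pytest.approx(
            monopolar_m1(0.08, 15e-3, Delta), rel=1e-6)

    def test_balanced_m0_zero(self, mono, bipolar):
        for w in (mono, bipolar):
            scale = GAMMA_H * 0.08 * w.grid.tau
            assert compute_moment(w, 0).magnitude < 1e-12 * scale

    def test_negative_order_rejected(self, mono):
        with pytest.raises(ValueError):
            compute_moment(mono, -1)

    def test_origin_shift_mixes_lower_orders(self, mono):
        """With m0 = 0 the first moment is origin-invariant, m2 is not."""
        m1a = compute_moment(mono, 1).value
        m1b = compute_moment(mono, 1, origin=5e-3).value
        assert np.allclose(m1a, m1b, rtol=1e-9)
        m2a = compute_moment(mono, 2).magnitude
        m2b = compute_moment(mono, 2, origin=5e-3).magnitude
        assert abs(m2a - m2b) > 1e-6 * m2a


class TestMaxwell:
    def test_mirrored_monopolar_is_nulled(self, mono):
        # physical monopolar gradients mirror around the refocusing
        scale = 0.08**2 * mono.grid.tau
        assert maxwell_index(mono) < 1e-9 * scale

    def test_single_lobe_closed_form(self):
        w, _, _, _ = _single_lobe(g=0.05, delta=10e-3)
        assert maxwell_index(w) == pytest.approx(0.05**2 * 10e-3, rel=1e-3)


class TestEfficiency:
    def test_back_to_back_pgse_kappa_one_third(self):
        grid = TimeGrid(n_pre=2000, n_post=2000, n_gap=0, dt=1e-5)
        T = grid.tau
        p = PGSEParams(g=0.05, delta=T / 2 - 1e-5, Delta=T / 2,
                       rise_time=1e-5, grid=grid)
        w = make_monopolar(p)
        assert efficiency(w, 0.05).kappa == pytest.approx(1 / 3, abs=1e-3)

    def test_time_rescale_invariance(self):
        grid = TimeGrid.from_timings(10e-3, 4e-3, 10e-3, 1e-4)
        w = _smooth(grid)
        k0 = efficiency(w, 0.05).kappa
        grid2 = TimeGrid.from_timings(20e-3, 8e-3, 20e-3, 2e-4)
        w2 = EffectiveWaveform(grid=grid2, g=w.g)
        assert efficiency(w2, 0.05).kappa == pytest.approx(k0, rel=1e-12)

    def test_zero_waveform(self):
        grid = TimeGrid.from_timings(10e-3, 8e-3, 10e-3, 1e-4)
        w = EffectiveWaveform(grid=grid, g=np.zeros((grid.n_samples, 3)))
        rep = efficiency(w, 0.05)
        assert rep.kappa == 0.0 and rep.self_balanced

    def test_crusher_moment_reported(self, mono):
        rep = efficiency(mono, 0.08)
        # monopolar holds full dephasing through the refocusing interval
        assert rep.crusher_moment == pytest.approx(
            GAMMA_H * 0.08 * 15e-3, rel=1e-3)
        assert not rep.self_balanced


class TestRotation:
    def test_identity(self, mono):
        assert np.array_equal(rotate(mono, np.eye(3)).g, mono.g)

    def test_invariants_under_rotation(self, bipolar):
        rng = np.random.default_rng(5)
        for _ in range(3):
            A = rng.standard_normal((3, 3))
            R, _ = np.linalg.qr(A)
            R *= np.linalg.det(R)
            wr = rotate(bipolar, R)
            assert compute_btensor(wr).b == pytest.approx(
                compute_btensor(bipolar).b, rel=1e-10)
            for n in (1, 2):
                assert compute_moment(wr, n).magnitude == pytest.approx(
                    compute_moment(bipolar, n).magnitude, rel=1e-10,
                    abs=1e-8)
            B0 = compute_btensor(bipolar).matrix
            assert np.allclose(compute_btensor(wr).matrix, R @ B0 @ R.T,
                               atol=1e-6 * np.abs(B0).max())

    def test_non_orthogonal_rejected(self, mono):
        with pytest.raises(ValueError):
            rotate(mono, np.diag([1.0, 1.0, 2.0]))

    def test_max_norm_rotation_flagged(self, mono):
        c, s = np.cos(np.pi / 4), np.sin(np.pi / 4)
        R = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]])
        # after a 45 degree tilt the per-axis peak is 80/sqrt(2) ~ 57 mT/m
        with pytest.warns(UserWarning):
            rotate(mono, R, gmax=0.05)
        rotate(mono, R, gmax=0.06)       # silent within the bound


class TestDiscretization:
    def test_grid_refinement_convergence(self):
        """Doubling resolution moves b, m1, m2, Maxwell by < 0.1 %."""
        vals = {}
        for dt in (2e-4, 1e-4):
            grid = TimeGrid.from_timings(10e-3, 4e-3, 10e-3, dt)
            w = _smooth(grid)
            vals[dt] = (compute_btensor(w).b,
                        compute_moment(w, 1).magnitude,
                        compute_moment(w, 2).magnitude,
                        maxwell_index(w))
        for a, b in zip(vals[2e-4], vals[1e-4]):
            assert a == pytest.approx(b, rel=1e-3)

    def test_resample_is_exact_on_interpolant(self, mono):
        fine = resample(mono, 2e-6)
        k = round(mono.grid.dt / fine.grid.dt)
        assert np.allclose(fine.g[::k], mono.g, atol=1e-15)
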