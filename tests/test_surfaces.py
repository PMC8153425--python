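"""Baseline zonation, signal propagation and the leaky aggregation."""

import numpy as np
import pytest

from circumroot.surfaces import (
    GrowthSurfaces,
    StimulusSource,
    aggregate_step,
    baseline_surface,
    circumferential_profile,
    phi_grid_2d,
    phi_grid_3d,
    propagate,
)

D_GRID = 6.0 - 0.1 * np.arange(60)


class TestBaseline:
    def test_peak_location(self):
        g = baseline_surface(3.0, 6.0, 1.0, D_GRID)
        assert D_GRID[np.argmax(g)] == pytest.approx(3.0)

    def test_zone_elongation_rate_normalized(self):
        # summed per-section rates are the whole-zone elongation rate
        for peak in (1.5, 3.0, 4.5):
            g = baseline_surface(peak, 6.0, 1.0, D_GRID)
            assert g.sum() == pytest.approx(1.0, abs=1e-9)

    def test_peak_shift_moves_bending_region(self):
        near = baseline_surface(1.5, 6.0, 1.0, D_GRID)
        far = baseline_surface(3.0, 6.0, 1.0, D_GRID)
        assert D_GRID[np.argmax(near)] < D_GRID[np.argmax(far)]

    def test_peak_outside_zone_rejected(self):
        with pytest.raises(ValueError):
            baseline_surface(7.0, 6.0, 1.0, D_GRID)


class TestPropagation:
    def source(self, v=5.0):
        return StimulusSource("gravity", v)

    def test_causality(self):
        src = self.source()
        src.emit(0.0, 1.0, 0.0)
        src.emit(1.0, 1.0, 0.0)
        assert propagate(src, 0.1, 3.0, 0.0) == 0.0  # front arrives at 0.6 h

    def test_constant_source_arrives_undamped(self):
        src = self.source(v=5.0)
        for i in range(11):
            src.emit(0.1 * i, 1.0, 0.0)
        assert propagate(src, 1.0, 3.0, 0.0) == pytest.approx(1.0)

    def test_antisymmetry_across_the_circumference(self):
        src = self.source()
        src.emit(0.0, 0.7, 0.3)
        src.emit(2.0, 0.7, 0.3)
        for d in (0.5, 2.0):
            s_peak = propagate(src, 2.0, d, 0.3)
            s_opp = propagate(src, 2.0, d, 0.3 + np.pi)
            assert s_opp == pytest.approx(-s_peak, abs=1e-12)

    def test_profile_zero_at_quarter_turn(self):
        assert circumferential_profile(np.pi / 2) == pytest.approx(0.0)
        assert circumferential_profile(-np.pi / 2) == pytest.approx(0.0)
        assert circumferential_profile(np.pi) == pytest.approx(-1.0)

    def test_advection_preserves_pulse_shape(self):
        """S(t, d) equals S(t - delta, d - v*delta) on aligned samples."""
        src = self.source(v=2.0)
        ts = 0.1 * np.arange(40)
        pulse = np.exp(-0.5 * ((ts - 1.0) / 0.3) ** 2)
        for t, s in zip(ts, pulse):
            src.emit(t, s, 0.0)
        d = np.array([1.0, 2.0, 3.0])
        phi = np.array([0.0])
        late = src.field_at(3.5, d, phi)
        # delta = 0.5 h shifts the pattern by v*delta = 1 D
        early = src.field_at(3.0, d - 1.0, phi)
        assert np.allclose(late, early, atol=1e-12)

    def test_zero_velocity_rejected(self):
        with pytest.raises(ValueError):
            StimulusSource("x", 0.0)


class TestAggregation:
    def test_resting_state_is_bias(self):
        out = aggregate_step(np.ones((4, 2)), [], [], 1.0, 0.1, 0.1)
        assert np.allclose(out, 1.0)

    def test_instantaneous_update_with_tau_equal_dt(self):
        s = np.full((3, 2), 0.2)
        out = aggregate_step(np.zeros((3, 2)), [s], [0.5], 1.0, 0.1, 0.1)
        assert np.allclose(out, 1.0 + 0.5 * 0.2)

    def test_geometric_relaxation_closed_form(self):
        """Constant drive relaxes as u + (S0-u)(1 - dt/tau)^k exactly."""
        dt, tau, u, s0 = 0.1, 2.0, 1.4, 0.0
        state = np.full((1, 1), s0)
        drive = np.full((1, 1), u - 1.0)  # plus bias 1 gives target u
        for k in range(1, 50):
            state = aggregate_step(state, [drive], [1.0], 1.0, tau, dt)
            expected = u + (s0 - u) * (1 - dt / tau) ** k
            assert state[0, 0] == pytest.approx(expected, abs=1e-12)

    def test_euler_first_order_convergence_to_exponential(self):
        """Halving dt roughly halves the error against exp(-t/tau)."""
        tau, t_end, u = 1.0, 2.0, 2.0

        def final_error(dt):
            state = np.zeros((1, 1))
            drive = np.full((1, 1), u - 1.0)
            for _ in range(int(round(t_end / dt))):
                state = aggregate_step(state, [drive], [1.0], 1.0, tau, dt)
            exact = u + (0.0 - u) * np.exp(-t_end / tau)
            return abs(state[0, 0] - exact)

        e1, e2 = final_error(0.05), final_error(0.025)
        assert 1.7 < e1 / e2 < 2.3

    def test_over_relaxation_rejected(self):
        with pytest.raises(ValueError):
            aggregate_step(np.zeros((1, 1)), [], [], 1.0, 0.05, 0.1)

    def test_inhibition_clamped_at_zero(self):
        s = np.full((2, 2), -1.0)
        out = aggregate_step(np.ones((2, 2)), [s], [5.0], 1.0, 0.1, 0.1)
        assert np.all(out == 0.0)


class TestGrowthSurfaces:
    def make(self, phi_grid):
        g_b = baseline_surface(3.0, 6.0, 1.0, D_GRID)
        return GrowthSurfaces(D_GRID, phi_grid, g_b, dt=0.1)

    def test_no_signal_reduces_to_baseline(self):
        surf = self.make(phi_grid_3d())
        surf.step([], 0.0)
        assert np.allclose(surf.G_s, surf.G_b[:, None])

    def test_extract_left_right_antipodal(self):
        surf = self.make(phi_grid_3d())
        src = StimulusSource("gravity", 5.0)
        for i in range(30):
            src.emit(0.1 * i, 1.0, 0.5)
        surf.step([(src, 0.5)], 3.0)
        g_l, g_r, phi = surf.extract()
        peak_row = np.argmax(surf.G_b)
        assert g_l[peak_row] > g_r[peak_row]
        # max-growth angle is the emission angle within grid resolution
        assert abs(phi[peak_row] - 0.5) < np.deg2rad(1.1)

    def test_two_flank_grid(self):
        surf = self.make(phi_grid_2d())
        src = StimulusSource("gravity", 5.0)
        for i in range(30):
            src.emit(0.1 * i, 1.0, 0.0)
        surf.step([(src, 0.5)], 3.0)
        g_l, g_r, phi = surf.extract()
        peak_row = np.argmax(surf.G_b)
        assert phi[peak_row] == 0.0
        assert g_l[peak_row] == pytest.approx(
            surf.G_b[peak_row] * 1.5, rel=1e-6)
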