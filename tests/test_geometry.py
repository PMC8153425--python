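"""Kinematics of the sectioned root: bending, growth, resampling."""

import numpy as np
import pytest

from circumroot.geometry import (
    BendStep,
    CrossSection,
    RootState,
    advance_section,
    bend_chain,
    bend_from_rates,
    cap_radius,
    grow_step_rates,
    resample,
)


def straight_root(orientation="vertical"):
    return RootState.initial(orientation=orientation)


class TestCapRadius:
    @pytest.mark.parametrize(
        "d, expected",
        [
            (2.0, 0.5),                      # beyond the cap: full radius
            (0.0, 0.0),                      # the very tip has zero radius
            (1.5, 0.5),                      # continuous at d_cap
            (0.75, 0.5 * 0.5 ** 0.4),        # inside the taper
        ],
    )
    def test_profile(self, d, expected):
        assert cap_radius(d, 1.5, 0.4, 1.0) == pytest.approx(expected,
                                                             abs=1e-12)

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            cap_radius(-0.1)

    def test_monotone_and_bounded(self):
        d = np.linspace(0, 3, 100)
        r = cap_radius(d)
        assert np.all(np.diff(r) >= -1e-15)
        assert np.all((r >= 0) & (r <= 0.5))


class TestBendFromRates:
    def test_equal_rates_straight(self):
        b = bend_from_rates(1.0, 1.0, 0.1, 1.0)
        assert b.theta == 0.0
        assert np.isinf(b.R_c)
        assert b.extension == pytest.approx(0.1)

    def test_differential_rates(self):
        b = bend_from_rates(1.2, 0.8, 0.1, 1.0)
        assert b.theta == pytest.approx(0.04)
        assert b.R_c == pytest.approx(2.5)
        # arc length of the increment equals the mean elongation
        assert b.R_c * b.theta == pytest.approx(b.extension)

    def test_rate_order_enforced(self):
        with pytest.raises(ValueError):
            bend_from_rates(0.8, 1.2, 0.1)


class TestAdvanceSection:
    def section(self):
        return CrossSection(np.zeros(3), np.eye(3), 0.5, 0.0)

    def test_zero_bend_translates_along_axis(self):
        bend = bend_from_rates(1.0, 1.0, 0.1)
        out = advance_section(self.section(), bend)
        assert np.allclose(out.center, [0, 0, 0.1])
        assert np.allclose(out.frame, np.eye(3))

    def test_opposite_growth_angles_mirror(self):
        b0 = bend_from_rates(1.2, 0.8, 0.1, phi=0.0)
        bpi = bend_from_rates(1.2, 0.8, 0.1, phi=np.pi)
        c0 = advance_section(self.section(), b0).center
        cpi = advance_section(self.section(), bpi).center
        assert np.allclose(c0 * [1, -1, 1], cpi, atol=1e-12)

    def test_constant_bend_traces_circle_of_radius_rc(self):
        """Repeated advancement keeps the center on the analytic circle."""
        bend = bend_from_rates(1.2, 0.8, 0.1, phi=0.3)
        sec = self.section()
        # circle center: offset by R_c opposite the max-growth direction
        e_phi = np.array([-np.sin(0.3), np.cos(0.3), 0.0])
        center = sec.center - bend.R_c * e_phi
        for _ in range(200):
            sec = advance_section(sec, bend)
            assert abs(np.linalg.norm(sec.center - center)
                       - bend.R_c) < 1e-6

    def test_rejects_degenerate_frame(self):
        sec = CrossSection(np.zeros(3), np.eye(3), 0.5, 0.0)
        sec.frame = sec.frame * 1.5
        bend = bend_from_rates(1.0, 1.0, 0.1)
        with pytest.raises(ValueError):
            advance_section(sec, bend)


class TestGrowStep:
    def test_uniform_rates_grow_axially(self):
        root = straight_root()
        n = root.n_sections
        g = np.full(n, 1.0 / n)
        grown = grow_step_rates(root, g, g, np.zeros(n), 0.1)
        assert np.allclose(grown.frames, root.frames)
        assert grown.total_length == pytest.approx(6.1, abs=1e-12)

    def test_total_extension_matches_rate_sum(self):
        root = straight_root()
        n = root.n_sections
        rng = np.random.default_rng(0)
        g_r = rng.uniform(0.0, 0.02, n)
        g_l = g_r + rng.uniform(0.0, 0.01, n)
        grown = grow_step_rates(root, g_l, g_r, rng.uniform(-np.pi, np.pi, n),
                                0.1)
        expected = 0.5 * (g_l + g_r).sum() * 0.1
        assert grown.total_length - root.total_length == pytest.approx(
            expected, abs=1e-9)

    def test_localized_bend_leaves_base_untouched(self):
        root = straight_root()
        n = root.n_sections
        g_l = np.zeros(n)
        g_r = np.zeros(n)
        g_l[40] = 0.2
        grown = grow_step_rates(root, g_l, g_r, np.zeros(n), 0.1)
        assert np.allclose(grown.frames[:40], root.frames[:40])
        assert np.allclose(grown.centers[:41], root.centers[:41])
        assert not np.allclose(grown.frames[40], root.frames[40])


class TestResample:
    def test_section_count_and_spacing(self):
        root = straight_root()
        n = root.n_sections
        assert n == 60  # 6.0 D zone / (0.1 h * 1.0 D/h)
        g = np.full(n, 1.0 / n)
        out = resample(grow_step_rates(root, g, g, np.zeros(n), 0.1))
        assert out.n_sections == 60
        spacing = np.linalg.norm(np.diff(out.centers, axis=0), axis=1)
        assert np.allclose(spacing, 0.1, atol=1e-9)
        assert out.total_length == pytest.approx(6.0, abs=1e-9)

    def test_straight_root_stays_collinear(self):
        root = straight_root()
        n = root.n_sections
        g = np.full(n, 1.0 / n)
        out = resample(grow_step_rates(root, g, g, np.zeros(n), 0.1))
        axis = out.centers[-1] - out.centers[0]
        axis /= np.linalg.norm(axis)
        rel = out.centers - out.centers[0]
        offplane = rel - np.outer(rel @ axis, axis)
        assert np.abs(offplane).max() < 1e-9

    def test_mature_trace_grows_and_freezes(self):
        root = straight_root()
        n = root.n_sections
        g = np.full(n, 1.0 / n)
        state = root
        snapshots = []
        for _ in range(5):
            state = resample(grow_step_rates(state, g, g, np.zeros(n), 0.1))
            snapshots.append([c.copy() for c in state.mature_centers])
        assert len(state.mature_centers) >= 4
        # previously frozen entries never change
        for a, b in zip(snapshots[-2], snapshots[-1]):
            assert np.allclose(a, b)

    def test_orientation_advects_with_material(self):
        """A bend laid down mid-zone migrates base-ward as the root grows."""
        root = straight_root()
        n = root.n_sections
        axis0 = root.frames[0][:, 2].copy()
        # one step with a strong bend at section 30 (d = 3.0)
        g_l = np.zeros(n)
        g_l[30] = 0.5
        state = resample(grow_step_rates(root, g_l, np.zeros(n),
                                         np.zeros(n), 0.1))

        def kink_index(s):
            tilt = np.degrees(
                np.arccos(np.clip(s.frames @ axis0, -1, 1)[:, 2]))
            half = 0.5 * tilt.max()
            return int(np.argmax(tilt > half))

        k0 = kink_index(state)
        g = np.full(n, 1.0 / n)
        for _ in range(20):  # 2 h of uniform growth
            state = resample(grow_step_rates(state, g, g, np.zeros(n), 0.1))
        # material at d=3 migrates base-ward at ~0.5 D/h -> >= 5 sections
        assert kink_index(state) <= k0 - 5


class TestFrameIntegrity:
    def test_orthonormality_over_thousand_steps(self):
        """Frames stay rotations (det = +1 within 1e-9) over 1000 steps."""
        from circumroot.environment import Environment
        from circumroot.simulate import SimulationConfig, Simulator

        cfg = SimulationConfig(orientation="horizontal", w_g=0.5, v_g=5.0,
                               peak_d=1.5, dim=2)
        sim = Simulator(cfg, Environment())
        for _ in range(1000):
            sim.step()
        F = sim.root.frames
        assert np.abs(np.linalg.det(F) - 1).max() < 1e-9
        gram = np.einsum("kij,kil->kjl", F, F)
        assert np.abs(gram - np.eye(3)).max() < 1e-9
        assert sim.root.total_length == pytest.approx(6.0, abs=1e-9)

    def test_zero_differential_growth_straight_trajectory(self):
        from circumroot.environment import Environment
        from circumroot.simulate import SimulationConfig, Simulator

        sim = Simulator(SimulationConfig(orientation="vertical"),
                        Environment())
        res = sim.run(5.0)
        # tip trajectory is a straight vertical line
        assert np.abs(res.tip[:, :2]).max() < 1e-9
        assert res.tip[-1, 2] == pytest.approx(-5.0, abs=1e-9)


class TestBendChain:
    def test_lengths_preserved(self):
        root = straight_root()
        bent = bend_chain(root, np.deg2rad(0.5), 0.0)
        assert np.allclose(
            np.linalg.norm(np.diff(bent.centers, axis=0), axis=1),
            np.linalg.norm(np.diff(root.centers, axis=0), axis=1),
            atol=1e-12,
        )

    def test_composition_is_additive(self):
        root = straight_root()
        twice = bend_chain(bend_chain(root, 0.01, 0.7), 0.02, 0.7)
        once = bend_chain(root, 0.03, 0.7)
        assert np.allclose(twice.centers, once.centers, atol=1e-9)
        assert np.allclose(twice.frames, once.frames, atol=1e-9)


try:
    from hypothesis import given, settings, strategies as st

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        theta=st.floats(1e-6, 0.3),
        phi=st.floats(-np.pi, np.pi),
        arc=st.floats(1e-4, 0.2),
    )
    def test_bend_rotation_is_special_orthogonal(theta, phi, arc):
        from circumroot.geometry import bend_offset, bend_rotation

        M = bend_rotation(theta, phi)
        assert abs(np.linalg.det(M) - 1) < 1e-12
        assert np.abs(M.T @ M - np.eye(3)).max() < 1e-12
        # the increment's chord length never exceeds its arc length
        assert np.linalg.norm(bend_offset(theta, phi, arc)) <= arc + 1e-12

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(d=st.floats(0, 10), d_cap=st.floats(0.5, 3.0),
           p_cap=st.floats(0.05, 0.95))
    def test_cap_radius_bounds(d, d_cap, p_cap):
        r = cap_radius(d, d_cap, p_cap, 1.0)
        assert 0.0 <= r <= 0.5
        if d >= d_cap:
            assert r == 0.5
except ImportError:  # pragma: no cover - hypothesis is an optional extra
    pass


def test_grow_step_wrapper_extends_and_resamples():
    """The surface-driven step keeps n sections and the zone length."""
    from circumroot.surfaces import (GrowthSurfaces, baseline_surface,
                                     phi_grid_2d)
    from circumroot.geometry import grow_step

    root = RootState.initial(orientation="vertical")
    d = root.section_d
    surf = GrowthSurfaces(d, phi_grid_2d(),
                          baseline_surface(3.0, 6.0, 1.0, d), dt=0.1)
    surf.step([], 0.0)
    out = grow_step(root, surf, 0.1)
    assert out.n_sections == root.n_sections
    assert out.total_length == pytest.approx(6.0, abs=1e-9)
    # straight growth: tip advanced by the baseline increment
    assert out.tip[2] == pytest.approx(root.tip[2] - 0.1, abs=1e-9)

    mismatched = GrowthSurfaces(d + 0.05, phi_grid_2d(),
                                baseline_surface(3.0, 6.0, 1.0, d), dt=0.1)
    with pytest.raises(ValueError):
        grow_step(root, mismatched, 0.1)
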