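"""Simulation engine: one growing root in an environment.

Each time step senses the stimuli at the apex (gravity, touch, internal
oscillator), emits them into the signal network, advances the aggregated
signal surface, applies the differential-growth kinematics, resamples the
elongation zone and resolves obstacle contacts with the passive bending
response.  Individual simulations are fully deterministic; randomness only
enters through parameter sampling in the experiment runners.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .environment import Environment
from .geometry import RootState, grow_step_rates, resample
from .gravitropism import GravitropicSource
from .metrics import (
    NutationMetrics,
    nutation_extrema,
    nutation_period_amplitude,
    tip_obstacle_angle,
)
from .oscillator import OscillatorState, oscillator_step, perceived_gradient
from .surfaces import (
    GrowthSurfaces,
    StimulusSource,
    baseline_surface,
    phi_grid_2d,
    phi_grid_3d,
)
from .thigmotropism import SensoryLayout, TouchMemory, detect_contact, \
    passive_correction

__all__ = ["SimulationConfig", "Simulator", "RunResult"]


@dataclass
class SimulationConfig:
    """All tunable model parameters (lengths in D, times in hours)."""

    dt: float = 0.1
    D: float = 1.0
    zone_length: float = 6.0
    G_base: float = 1.0
    peak_d: float = 3.0            # zonation peak distance from the tip
    sigma_frac: float = 0.1        # zonation Gaussian width / zone length
    d_cap: float = 1.5
    p_cap: float = 0.4
    dim: int = 3                   # 2 restricts phi to the two flanks
    tau: float | None = None       # surface decay; None -> dt (instantaneous)
    clamp: bool = True
    # gravitropism
    w_g: float = 0.0
    v_g: float = 5.0
    # thigmotropism
    w_t: float = 0.0
    v_t: float | None = None       # None -> v_g
    tau_touch: float | None = None  # decay of the touch signal; None -> dt
    sensory_angular: int = 16
    sensory_axial: int = 8
    correction_step_deg: float = 0.05
    correction_max_iter: int = 500
    contact_pad: float = 0.005     # grazing distance that still counts as touch
    penetration_tol: float = 0.01  # depth tolerated before the passive bend
    # internal oscillator
    w_s: float = 0.0
    v_s: float = 5.0
    oscillator_period: float = 2.0  # P, hours (T_s = 2 pi / P)
    phase_with_wall_clock: bool = False
    # initial state
    orientation: str = "vertical"
    tip_position: tuple = (0.0, 0.0, 0.0)
    self_collision_check: bool = False

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class RunResult:
    """Per-step trace of one simulation plus the final root state."""

    config: SimulationConfig
    t: np.ndarray
    tip: np.ndarray                # (n, 3)
    tip_dir: np.ndarray            # (n, 3)
    alpha_g_deg: np.ndarray
    one_side_rate: np.ndarray      # G_s at the zonation peak, phi = 0
    diff_rate: np.ndarray          # max over d of G_left - G_right
    C: np.ndarray
    contact: np.ndarray
    contact_d: np.ndarray          # tip distance of the touch mean point
    contact_phi: np.ndarray
    contact_alpha: np.ndarray
    obstacle_angle_deg: np.ndarray
    touch_strength: np.ndarray
    correction_iters: np.ndarray
    trapped_steps: int
    self_collisions: int
    root: RootState
    warnings: list = field(default_factory=list)

    def nutation_metrics(self, prominence_frac: float = 0.01) -> NutationMetrics:
        """Cycle quantification from the one-side growth-rate series."""
        idx, kinds = nutation_extrema(self.t, self.one_side_rate,
                                      prominence_frac)
        return nutation_period_amplitude(self.t[idx], kinds, self.tip[idx])

    def trace_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            dict(
                t=self.t,
                x=self.tip[:, 0], y=self.tip[:, 1], z=self.tip[:, 2],
                alpha_g_deg=self.alpha_g_deg,
                one_side_rate=self.one_side_rate,
                diff_rate=self.diff_rate,
                C=self.C,
                contact=self.contact.astype(int),
                d_t=self.contact_d,
                phi_t=self.contact_phi,
                alpha_t=self.contact_alpha,
                obstacle_angle_deg=self.obstacle_angle_deg,
                touch_strength=self.touch_strength,
            )
        )


class Simulator:
    """Steps one root through its environment."""

    def __init__(self, config: SimulationConfig,
                 environment: Environment | None = None):
        self.config = config
        self.env = environment or Environment()
        cfg = config
        self.root = RootState.initial(
            cfg.zone_length, cfg.dt, cfg.G_base, cfg.D,
            orientation=cfg.orientation, tip=cfg.tip_position,
        )
        n = self.root.n_sections
        phi_grid = phi_grid_2d() if cfg.dim == 2 else phi_grid_3d()
        d_grid = self.root.section_d
        G_b = baseline_surface(cfg.peak_d, cfg.zone_length, cfg.G_base,
                               d_grid, cfg.sigma_frac)
        self.surfaces = GrowthSurfaces(d_grid, phi_grid, G_b,
                                       tau=cfg.tau, dt=cfg.dt,
                                       clamp=cfg.clamp)
        self._peak_row = int(np.argmin(np.abs(d_grid - cfg.peak_d)))
        self._phi0_col = int(np.argmin(np.abs(phi_grid)))

        self.gravity = GravitropicSource(cfg.v_g, cfg.D, sense_d=cfg.d_cap)
        self.touch_source = StimulusSource(
            "touch", cfg.v_t if cfg.v_t is not None else cfg.v_g, D=cfg.D)
        self.touch_memory = TouchMemory(
            tau_decay=cfg.tau_touch if cfg.tau_touch is not None else cfg.dt)
        self.osc_source = StimulusSource("resource", cfg.v_s, D=cfg.D)
        self.oscillator = OscillatorState(
            P=cfg.oscillator_period,
            phase_with_wall_clock=cfg.phase_with_wall_clock)
        self.oscillator_emission = None  # optional override hook
        self.layout = SensoryLayout(cfg.sensory_angular, cfg.sensory_axial,
                                    cfg.d_cap, cfg.p_cap)

        self.t = 0.0
        self._C_prev = None
        self._G_avr_prev = cfg.G_base
        self._touch_event = None
        self._touch_phi = 0.0
        self.extra_obstacles = []   # e.g. other roots in multi-root scenes
        self._n = n

    # -- per-step pieces --------------------------------------------------
    def _obstacles(self):
        return list(self.env.obstacles) + list(self.extra_obstacles)

    def _snap_phi(self, phi: float) -> float:
        """In planar mode circumferential angles live on the two flanks."""
        if self.config.dim == 2:
            return 0.0 if abs(phi) <= np.pi / 2 else np.pi
        return phi

    def _sense_and_emit(self):
        cfg = self.config
        alpha_deg = np.nan
        if cfg.w_g != 0.0:
            g = self.env.g
            alpha, strength, phi_g = self.gravity.sense(self.root, g)
            alpha_deg = float(np.degrees(alpha))
            self.gravity.source.emit(self.t, strength, phi_g)
        s_t = 0.0
        if cfg.w_t != 0.0:
            event = self._touch_event
            if event is not None:
                self._touch_phi = event.phi_t
            s_t = self.touch_memory.step(event, cfg.dt)
            # the inhibition acts on the flank opposite the contact: the
            # touched flank is excited, so growth stimulation at the touch
            # area rotates the apex away from the obstacle
            phi_emit = (self._touch_phi + 2.0 * np.pi) % (2.0 * np.pi) - np.pi
            self.touch_source.emit(self.t, s_t, phi_emit)
        C = np.nan
        if self.env.resource is not None:
            C = float(self.env.concentration(self.root.tip))
        if cfg.w_s != 0.0:
            if self.oscillator_emission is not None:
                strength, phi = self.oscillator_emission(self.t, self)
            else:
                if self._C_prev is None or np.isnan(C):
                    dC = 0.0
                else:
                    dC = perceived_gradient(C, self._C_prev, cfg.dt,
                                            self._G_avr_prev)
                _, s_s, phi = oscillator_step(self.oscillator, dC, cfg.dt,
                                              t=self.t)
                if cfg.dim == 2:
                    # planar reduction of the rotating emission: the pi
                    # offset of the emission angle phi(t) = pi + t_s is
                    # kept, so the oscillation is emitted on the pi flank
                    strength, phi = s_s, np.pi
                else:
                    strength = 1.0
            self.osc_source.emit(self.t, strength, phi)
        self._C_prev = C if not np.isnan(C) else None
        return alpha_deg, C, s_t

    def _active_sources(self):
        cfg = self.config
        pairs = []
        if cfg.w_g != 0.0:
            pairs.append((self.gravity.source, cfg.w_g))
        if cfg.w_t != 0.0:
            pairs.append((self.touch_source, cfg.w_t))
        if cfg.w_s != 0.0:
            pairs.append((self.osc_source, cfg.w_s))
        return pairs

    def _count_self_collisions(self) -> int:
        centers = self.root.centers
        diff = centers[None, :, :] - centers[:, None, :]
        dist = np.linalg.norm(diff, axis=-1)
        n = len(centers)
        i, j = np.triu_indices(n, k=8)
        return int(np.sum(dist[i, j] < self.config.D))

    def step(self):
        cfg = self.config
        alpha_deg, C, s_t = self._sense_and_emit()
        self.surfaces.step(self._active_sources(), self.t)
        g_left, g_right, phi = self.surfaces.extract()
        grown = grow_step_rates(self.root, g_left, g_right, phi, cfg.dt)
        self._G_avr_prev = (grown.total_length - self.root.total_length) / cfg.dt
        self.root = resample(grown)

        iters = 0
        trapped = False
        event = None
        obstacles = self._obstacles()
        if obstacles:
            # any penetration anywhere along the root triggers the passive
            # bend; only grazing contact of the apical sensing region
            # (within contact_pad of the surface) initiates the touch signal
            pen = detect_contact(self.root, obstacles, self.layout,
                                 pad=-cfg.penetration_tol)
            if pen is not None:
                self.root, iters, trapped = passive_correction(
                    self.root, obstacles, self._snap_phi(pen.phi_t),
                    self.layout, cfg.correction_step_deg,
                    cfg.correction_max_iter, pad=-cfg.penetration_tol)
            event = detect_contact(self.root, obstacles, self.layout,
                                   pad=cfg.contact_pad,
                                   d_max=cfg.d_cap)
            if event is not None:
                event.phi_t = self._snap_phi(event.phi_t)
        self._touch_event = event
        self.t += cfg.dt
        self.root.t = self.t
        diff = float(np.max(g_left - g_right))
        one_side = float(self.surfaces.G_s[self._peak_row, self._phi0_col])
        return alpha_deg, C, s_t, diff, one_side, event, iters, trapped

    def run(self, duration: float) -> RunResult:
        cfg = self.config
        n_steps = int(round(duration / cfg.dt))
        m = n_steps + 1
        t = np.full(m, np.nan)
        tip = np.full((m, 3), np.nan)
        tip_dir = np.full((m, 3), np.nan)
        alpha = np.full(m, np.nan)
        one_side = np.full(m, np.nan)
        diff = np.full(m, np.nan)
        C = np.full(m, np.nan)
        contact = np.zeros(m, dtype=bool)
        contact_d = np.full(m, np.nan)
        contact_phi = np.full(m, np.nan)
        contact_alpha = np.full(m, np.nan)
        obs_angle = np.full(m, np.nan)
        touch_s = np.zeros(m)
        corr = np.zeros(m, dtype=int)
        warnings = []
        trapped_steps = 0
        collisions = 0

        plane = None
        for obs in self.env.obstacles:
            if hasattr(obs, "normal"):
                plane = obs
                break

        def log(i, alpha_i, C_i, s_t_i, diff_i, side_i, event, iters):
            t[i] = self.t
            tip[i] = self.root.tip
            tip_dir[i] = self.root.tip_direction
            alpha[i] = alpha_i
            one_side[i] = side_i
            diff[i] = diff_i
            C[i] = C_i
            contact[i] = event is not None
            if event is not None:
                contact_d[i] = event.d_t
                contact_phi[i] = event.phi_t
                contact_alpha[i] = event.alpha_t
            touch_s[i] = s_t_i
            corr[i] = iters
            if plane is not None:
                # root angle w.r.t. the obstacle: the apex direction (chord
                # over the cap, as sensed for gravitropism) vs the surface
                c_sense, _ = self.root.interpolate(cfg.d_cap)
                chord = self.root.tip - c_sense
                nrm = np.linalg.norm(chord)
                direction = chord / nrm if nrm > 1e-12 \
                    else self.root.tip_direction
                obs_angle[i] = tip_obstacle_angle(direction, plane)

        C0 = (float(self.env.concentration(self.root.tip))
              if self.env.resource is not None else np.nan)
        log(0, np.nan, C0, 0.0, 0.0,
            float(self.surfaces.G_s[self._peak_row, self._phi0_col]), None, 0)
        for i in range(1, m):
            alpha_i, C_i, s_t_i, diff_i, side_i, event, iters, trapped = \
                self.step()
            if trapped:
                trapped_steps += 1
                warnings.append(
                    f"t={self.t:.2f}: passive-correction iteration cap reached")
            if cfg.self_collision_check:
                collisions += self._count_self_collisions()
            log(i, alpha_i, C_i, s_t_i, diff_i, side_i, event, iters)

        return RunResult(
            config=cfg, t=t, tip=tip, tip_dir=tip_dir, alpha_g_deg=alpha,
            one_side_rate=one_side, diff_rate=diff, C=C, contact=contact,
            contact_d=contact_d, contact_phi=contact_phi,
            contact_alpha=contact_alpha,
            obstacle_angle_deg=obs_angle, touch_strength=touch_s,
            correction_iters=corr, trapped_steps=trapped_steps,
            self_collisions=collisions, root=self.root, warnings=warnings,
        )
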