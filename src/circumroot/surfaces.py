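"""Growth-response surfaces and stimulus-signal propagation.

The rate of axial elongation over the root surface is a field
G_s(t, d, phi) = G_b(d) * S_a(t, d, phi): a fixed baseline zonation profile
G_b multiplied by an aggregated signal surface S_a that integrates the
propagated stimulus signals with a leaky (continuous-time recurrent
network style) update

    S_a(t) = (1 - dt/tau) * S_a(t - dt) + (dt/tau) * f_a(sum_i w_i S_i + b)

with a linear activation f_a(x) = x and bias b = 1, so that without
stimuli G_s reduces to the baseline.  Stimulus signals are emitted at the
tip (d = 0) with strength in [-1, 1], advect along the root axis at a
finite speed with no attenuation, and fall off linearly around the
circumference from +s at the emission angle to -s at the opposite flank.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "circumferential_profile",
    "baseline_surface",
    "StimulusSource",
    "propagate",
    "aggregate_step",
    "GrowthSurfaces",
    "phi_grid_3d",
    "phi_grid_2d",
]


def phi_grid_3d(n: int = 361) -> np.ndarray:
    """Angular grid over [-pi, pi]; the two endpoints are the same flank."""
    return np.linspace(-np.pi, np.pi, n)


def phi_grid_2d() -> np.ndarray:
    """Planar mode: only the two flanks phi = 0 and phi = pi."""
    return np.array([0.0, np.pi])


def _wrap(angle):
    return (np.asarray(angle) + np.pi) % (2.0 * np.pi) - np.pi


def circumferential_profile(delta_phi) -> np.ndarray:
    """Antisymmetric-linear falloff around the emission angle.

    1 at delta_phi = 0, 0 at +-pi/2 and -1 at the opposite flank.
    """
    return 1.0 - 2.0 * np.abs(_wrap(delta_phi)) / np.pi


def baseline_surface(peak_d: float, zone_length: float, G_base: float,
                     d_grid: np.ndarray, sigma_frac: float = 0.1) -> np.ndarray:
    """Baseline zonation profile G_b over the distance grid.

    A Gaussian in d with standard deviation ``sigma_frac * zone_length``
    centered on ``peak_d``, scaled so the per-section rates sum to
    ``G_base``: with the aggregated signal at its resting value the whole
    zone then elongates at exactly the baseline rate.
    """
    if not 0 < peak_d < zone_length:
        raise ValueError("peak must lie inside the elongation zone")
    d_grid = np.asarray(d_grid, dtype=float)
    sigma = sigma_frac * zone_length
    w = np.exp(-0.5 * ((d_grid - peak_d) / sigma) ** 2)
    return G_base * w / w.sum()


@dataclass
class StimulusSource:
    """Time series of signal emissions propagating along the root axis.

    Emissions are stored as (time, strength, phi_peak) samples; the value
    felt at distance d and time t is the strength emitted at t - d*D/v
    (linear interpolation between samples, zero before the signal front
    arrives), modulated by the circumferential profile around the phi_peak
    of the emission time.
    """

    name: str
    velocity: float  # D / hour
    D: float = 1.0
    times: list = field(default_factory=list)
    strengths: list = field(default_factory=list)
    phis: list = field(default_factory=list)

    def __post_init__(self):
        if self.velocity <= 0:
            raise ValueError("propagation velocity must be positive")

    def emit(self, t: float, strength: float, phi_peak: float = 0.0):
        if not -1.0 - 1e-12 <= strength <= 1.0 + 1e-12:
            raise ValueError("signal strength must lie in [-1, 1]")
        if self.times and t < self.times[-1]:
            raise ValueError("emissions must be appended in time order")
        self.times.append(float(t))
        self.strengths.append(float(np.clip(strength, -1.0, 1.0)))
        self.phis.append(float(phi_peak))

    def field_at(self, t: float, d_grid: np.ndarray,
                 phi_grid: np.ndarray) -> np.ndarray:
        """Signal response surface S_i(t, d, phi) on the given grids."""
        d_grid = np.asarray(d_grid, dtype=float)
        phi_grid = np.asarray(phi_grid, dtype=float)
        if not self.times:
            return np.zeros((d_grid.size, phi_grid.size))
        te = t - d_grid * self.D / self.velocity
        times = np.asarray(self.times)
        s = np.interp(te, times, np.asarray(self.strengths), left=0.0)
        s = np.where(te < times[0] - 1e-12, 0.0, s)
        # emission angle: nearest emission sample (in-flight signals keep
        # the phi of their emission time)
        idx = np.clip(np.searchsorted(times, te), 0, len(times) - 1)
        lower = np.clip(idx - 1, 0, len(times) - 1)
        nearer = np.where(
            np.abs(times[idx] - te) <= np.abs(te - times[lower]), idx, lower
        )
        phi_e = np.asarray(self.phis)[nearer]
        prof = circumferential_profile(phi_grid[None, :] - phi_e[:, None])
        return s[:, None] * prof


def propagate(stimulus: StimulusSource, t: float, d: float,
              phi: float) -> float:
    """Point evaluation of a propagated stimulus signal."""
    if t < 0:
        raise ValueError("time must be non-negative")
    val = stimulus.field_at(t, np.array([d]), np.array([phi]))
    return float(val[0, 0])


def aggregate_step(S_a_prev: np.ndarray, stimuli, w, b, tau, dt: float,
                   clamp: bool = True) -> np.ndarray:
    """One leaky-integration update of the aggregated signal surface.

    ``stimuli`` is a sequence of stimulus fields and ``w`` the matching
    sensitivities (scalars or fields).  With tau = dt the update is
    instantaneous; dt > tau would over-relax the Euler step and is refused.
    """
    tau_arr = np.asarray(tau, dtype=float)
    if np.any(dt > tau_arr * (1 + 1e-12)):
        raise ValueError("dt must not exceed the decay constant tau")
    drive = np.asarray(b, dtype=float) * np.ones_like(S_a_prev)
    for w_i, s_i in zip(w, stimuli):
        drive = drive + w_i * s_i
    alpha = dt / tau_arr
    out = (1.0 - alpha) * S_a_prev + alpha * drive  # f_a is linear
    if clamp:
        out = np.maximum(out, 0.0)
    return out


class GrowthSurfaces:
    """Discretized growth fields over the (d, phi) grid of the active zone."""

    def __init__(self, d_grid: np.ndarray, phi_grid: np.ndarray,
                 G_b: np.ndarray, b: float = 1.0, tau: float | None = None,
                 dt: float = 0.1, clamp: bool = True):
        self.d_grid = np.asarray(d_grid, dtype=float)
        self.phi_grid = np.asarray(phi_grid, dtype=float)
        self.G_b = np.asarray(G_b, dtype=float)
        if np.any(self.G_b < 0):
            raise ValueError("baseline growth must be non-negative")
        if self.G_b.shape != self.d_grid.shape:
            raise ValueError("G_b must be defined per distance sample")
        self.b = float(b)
        self.tau = dt if tau is None else float(tau)
        if dt > self.tau * (1 + 1e-12):
            raise ValueError("dt must not exceed tau")
        self.dt = dt
        self.clamp = clamp
        # resting state: S_a relaxed onto the bias
        self.S_a = np.full((self.d_grid.size, self.phi_grid.size), self.b)
        self.G_s = self.G_b[:, None] * self.S_a
        # duplicate-endpoint handling for the wrapped 3-D grid
        wrapped = (
            self.phi_grid.size > 2
            and abs((self.phi_grid[-1] - self.phi_grid[0]) - 2 * np.pi) < 1e-9
        )
        self._m = self.phi_grid.size - 1 if wrapped else self.phi_grid.size
        if self._m % 2:
            raise ValueError("phi grid must pair every angle with its antipode")

    def step(self, sources_and_weights, t: float):
        """Advance S_a by one time step from the given (source, weight) pairs."""
        fields = [
            src.field_at(t, self.d_grid, self.phi_grid)
            for src, _ in sources_and_weights
        ]
        weights = [w for _, w in sources_and_weights]
        self.S_a = aggregate_step(self.S_a, fields, weights, self.b,
                                  self.tau, self.dt, clamp=self.clamp)
        self.G_s = self.G_b[:, None] * self.S_a
        return self.G_s

    def to_frame(self, t: float = np.nan):
        """Long-format dump (t, d, phi, G_b, S_a, G_s) for visualization."""
        import pandas as pd

        d, phi = np.meshgrid(self.d_grid, self.phi_grid, indexing="ij")
        return pd.DataFrame(
            dict(
                t=t,
                d=d.ravel(),
                phi=phi.ravel(),
                G_b=np.broadcast_to(self.G_b[:, None],
                                    self.S_a.shape).ravel(),
                S_a=self.S_a.ravel(),
                G_s=self.G_s.ravel(),
            )
        )

    def extract(self):
        """Per-distance (G_left, G_right, phi) for the kinematic update.

        G_left is the maximal rate over the circumference (smallest index
        wins ties), G_right the rate at the antipodal angle.
        """
        m = self._m
        core = self.G_s[:, :m]
        j_star = np.argmax(core, axis=1)
        rows = np.arange(core.shape[0])
        g_left = core[rows, j_star]
        j_opp = (j_star + m // 2) % m
        g_right = core[rows, j_opp]
        return g_left, g_right, self.phi_grid[j_star]
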