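"""Scenario runners: parameter sweeps and randomized studies.

Implements the four study designs: the gravitropic speed/sensitivity sweep
for two zonation peaks, the gravity-touch obstacle interplay, the
1000-root randomized gradient-climbing study, and the multi-root
specialization scene.  Individual simulations are deterministic; only the
gradient study draws random parameters (from a single seeded generator,
in a fixed order per run).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .environment import BoxWalls, Environment, LinearField, Plane, RadialField
from .metrics import performance_f
from .simulate import RunResult, SimulationConfig, Simulator

__all__ = [
    "SweepResult",
    "run_gravitropic_sweep",
    "run_obstacle_interplay",
    "steady_obstacle_angle",
    "run_gradient_study",
    "run_specialization",
    "RootChainObstacle",
]


@dataclass
class SweepResult:
    """Tabular summary of a sweep or randomized study."""

    table: pd.DataFrame
    summary: dict = field(default_factory=dict)
    runs: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# gravitropic sweep (signal speed x sensitivity x zonation peak)

def run_gravitropic_sweep(v_g_grid=(1.0, 5.0, 25.0),
                          w_g_grid=(0.1, 0.5, 1.0),
                          peaks=(1.5, 3.0),
                          duration: float = 16.0,
                          dim: int = 3,
                          keep_runs: bool = False) -> SweepResult:
    """Horizontal-start gravitropic runs over the full parameter grid.

    For each zonation peak the 3 x 3 grid of propagation speeds and
    sensitivities is simulated for ``duration`` hours.  The amplitude of
    differential growth is quantified per circumnutation cycle from the
    extrema of the one-side growth rate (the instants of maximal
    differential growth), as the distance between the middle extremum's
    tip position and the midpoint of its neighbours; amplitudes are pooled
    per peak group and the ratio of group medians (far peak over near
    peak) quantifies how a more distant growth zone amplifies the
    movements.  Per-step differential elongation rates are pooled as well
    for the group comparison rank test.
    """
    rows = []
    pooled_amp: dict[float, list] = {p: [] for p in peaks}
    pooled_diff: dict[float, list] = {p: [] for p in peaks}
    runs = []
    for peak in peaks:
        for v_g in v_g_grid:
            for w_g in w_g_grid:
                cfg = SimulationConfig(w_g=w_g, v_g=v_g, peak_d=peak,
                                       dim=dim, orientation="horizontal")
                res = Simulator(cfg, Environment()).run(duration)
                nut = res.nutation_metrics()
                diff = res.diff_rate[1:]
                pooled_amp[peak].extend(nut.amplitudes)
                pooled_diff[peak].append(diff)
                rows.append(dict(
                    peak_d=peak, v_g=v_g, w_g=w_g,
                    n_cycles=nut.n_cycles,
                    median_period=float(np.median(nut.periods))
                    if nut.periods.size else np.nan,
                    median_amplitude=float(np.median(nut.amplitudes))
                    if nut.amplitudes.size else np.nan,
                    median_diff_rate=float(np.median(diff)),
                    final_alpha_deg=float(res.alpha_g_deg[-1]),
                ))
                if keep_runs:
                    runs.append(res)
    table = pd.DataFrame(rows)
    amp_medians = {
        p: (float(np.median(pooled_amp[p])) if pooled_amp[p] else np.nan)
        for p in peaks
    }
    diff_medians = {p: float(np.median(np.concatenate(pooled_diff[p])))
                    for p in peaks}
    summary = {"amplitude_medians": amp_medians,
               "diff_rate_medians": diff_medians}
    if len(peaks) == 2:
        near, far = sorted(peaks)
        summary["amplitude_ratio"] = amp_medians[far] / amp_medians[near]
        from scipy.stats import ranksums

        if pooled_amp[near] and pooled_amp[far]:
            summary["ranksum_p"] = float(
                ranksums(pooled_amp[far], pooled_amp[near]).pvalue)
    return SweepResult(table, summary, runs)


# ---------------------------------------------------------------------------
# gravity-touch interplay on a horizontal plane

def run_obstacle_interplay(w_g: float = 0.5, w_t: float = 0.5,
                           tau_touch: float | None = None,
                           duration: float = 24.0,
                           plane_depth: float = 2.0,
                           peak_d: float = 1.5,
                           dim: int = 2) -> RunResult:
    """Vertical root meeting a horizontal plane obstacle.

    The root starts ``plane_depth`` diameters above the plane, aligns with
    gravity and then slides along the surface; the logged root-to-obstacle
    angle (apex direction vs the plane) characterizes the balance between
    the gravitropic (steepening) and thigmotropic (flattening) responses.
    The zonation peak sits in the apical half of the zone, where fast
    tropic responses are actuated.
    """
    plane = Plane(point=(0.0, 0.0, -plane_depth), normal=(0.0, 0.0, 1.0))
    env = Environment(obstacles=[plane])
    cfg = SimulationConfig(w_g=w_g, w_t=w_t, tau_touch=tau_touch, dim=dim,
                           peak_d=peak_d, orientation="vertical")
    return Simulator(cfg, env).run(duration)


def steady_obstacle_angle(result: RunResult,
                          settle: float = 5.0) -> float:
    """Mean tip-to-obstacle angle over the sliding phase.

    Contact steps later than ``settle`` hours after first contact are
    averaged (the approach transient is excluded).
    """
    contact_t = result.t[result.contact]
    if contact_t.size == 0:
        return np.nan
    t0 = contact_t[0] + settle
    mask = result.contact & (result.t >= t0)
    vals = result.obstacle_angle_deg[mask]
    vals = vals[np.isfinite(vals)]
    return float(np.mean(vals)) if vals.size else np.nan


# ---------------------------------------------------------------------------
# randomized gradient-climbing study

def run_gradient_study(n_runs: int = 1000, duration: float = 30.0,
                       seed: int = 0, slope: float = 0.05,
                       w_g: float = 0.5,
                       keep_runs: bool = False) -> SweepResult:
    """Randomized 2-D study of gradient climbing with the internal oscillator.

    Each root starts vertical in a linear horizontal concentration gradient
    (slope per 1 D, clipped to [0, 1]) and is parametrized with independent
    uniform draws  w_s ~ U[0,1],  v_s ~ U[0,10] D/h,  T_s ~ U[0, 2 pi],
    zonation peak d ~ U[0.5, 5.5] D.  The gravitropic pathway stays active
    at the package default sensitivity: only the oscillator parameters are
    randomized, and gravity's restoring pull is what keeps the ensemble's
    lateral excursions in the range where the performance statistic is
    informative rather than saturated.  After ``duration`` hours the
    performance f = (C(T) - C(0)) / (C*(T) - C(0)) is computed against the
    concentration C* reached by growing straight up-gradient at the
    baseline rate.  Runs are ranked by f into the usual groups (best 5%,
    best 25%, worst 25%, worst 5%, all).
    """
    rng = np.random.default_rng(seed)
    rows = []
    runs = []
    for i in range(n_runs):
        w_s = rng.uniform(0.0, 1.0)
        v_s = rng.uniform(0.0, 10.0)
        T_s = rng.uniform(0.0, 2.0 * np.pi)
        peak = rng.uniform(0.5, 5.5)
        res = simulate_gradient_run(w_s, v_s, T_s, peak, duration, slope,
                                    w_g=w_g)
        nut = res.nutation_metrics()
        f = gradient_performance(res, duration, slope)
        rows.append(dict(
            run=i, w_s=w_s, v_s=v_s, T_s=T_s, peak_d=peak, f=f,
            n_cycles=nut.n_cycles,
            median_period=float(np.median(nut.periods))
            if nut.periods.size else np.nan,
            median_amplitude=float(np.median(nut.amplitudes))
            if nut.amplitudes.size else np.nan,
        ))
        if keep_runs:
            runs.append(res)
    table = pd.DataFrame(rows)
    summary = gradient_group_summary(table)
    return SweepResult(table, summary, runs)


def simulate_gradient_run(w_s: float, v_s: float, T_s: float, peak: float,
                          duration: float = 30.0,
                          slope: float = 0.05,
                          w_g: float = 0.0) -> RunResult:
    """One deterministic 2-D gradient-climbing simulation."""
    env = Environment(resource=LinearField(slope=slope, c0=0.5))
    period = 2.0 * np.pi / T_s if T_s > 1e-9 else np.inf
    cfg = SimulationConfig(
        dim=2, orientation="vertical", w_s=w_s, w_g=w_g, v_g=5.0,
        v_s=max(v_s, 1e-6),  # a zero speed never delivers signal anyway
        oscillator_period=period if np.isfinite(period) else 1e9,
        peak_d=float(np.clip(peak, 0.11, 5.99)),
    )
    return Simulator(cfg, env).run(duration)


def gradient_performance(result: RunResult, duration: float,
                         slope: float = 0.05) -> float:
    """Performance f of a finished gradient run.

    The best achievable end concentration C* is the field value at the
    point reached by growing straight along the gradient at the baseline
    rate for the whole run (clipped by the field bounds).
    """
    C0 = float(result.C[0])
    C_end = float(result.C[-1])
    dist = result.config.G_base * duration
    C_best = float(np.clip(C0 + slope * dist, 0.0, 1.0))
    return performance_f(C0, C_end, C_best)


def gradient_group_summary(table: pd.DataFrame) -> dict:
    """Group medians of f after ranking (non-exclusive groups)."""
    f = np.sort(table["f"].to_numpy())[::-1]  # descending: best first
    n = len(f)
    k5 = max(1, int(round(0.05 * n)))
    k25 = max(1, int(round(0.25 * n)))
    return {
        "median_f_best5": float(np.median(f[:k5])),
        "median_f_best25": float(np.median(f[:k25])),
        "median_f_worst25": float(np.median(f[-k25:])),
        "median_f_worst5": float(np.median(f[-k5:])),
        "median_f_all": float(np.median(f)),
        "n_with_cycle": int((table["n_cycles"] >= 1).sum()),
        "n_runs": n,
    }


# ---------------------------------------------------------------------------
# multi-root specialization

class RootChainObstacle:
    """Another root's section chain seen as a capsule-chain obstacle."""

    def __init__(self, simulator: Simulator, radius: float = 0.5):
        self.simulator = simulator
        self.radius = radius

    def sdf(self, x) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        centers = self.simulator.root.centers
        a = centers[:-1]
        b = centers[1:]
        ab = b - a
        denom = np.einsum("ij,ij->i", ab, ab)
        denom[denom == 0] = 1.0
        ap = x[:, None, :] - a[None, :, :]
        tpar = np.clip(np.einsum("pij,ij->pi", ap, ab) / denom, 0.0, 1.0)
        closest = a[None, :, :] + tpar[:, :, None] * ab[None, :, :]
        dist = np.linalg.norm(x[:, None, :] - closest, axis=-1).min(axis=1)
        out = dist - self.radius
        return out[0] if out.size == 1 else out


ROOT_TYPES = {
    "crown": dict(w_g=-1.0, w_s=0.0, w_t=0.2),
    "primary": dict(w_g=0.95, w_s=0.05, w_t=0.2),
    "seminal": dict(w_g=0.05, w_s=0.95, w_t=0.2),
    "lateral": dict(w_g=0.7, w_s=0.3, w_t=0.2),
}


def run_specialization(duration: float = 30.0,
                       arena=((-10.0, -10.0, -16.0), (10.0, 10.0, 8.0)),
                       root_types: dict | None = None,
                       seed_positions: dict | None = None) -> dict:
    """Four differently parametrized roots growing in a walled arena.

    Crown, primary, seminal and lateral roots share the same model but
    differ in their sensitivities; the resource concentration peaks at the
    arena center.  Roots cannot penetrate the walls or each other.
    Returns a mapping root-type -> RunResult.
    """
    root_types = root_types or ROOT_TYPES
    lo, hi = (np.asarray(v, dtype=float) for v in arena)
    center = 0.5 * (lo + hi)
    env = Environment(
        obstacles=[BoxWalls(tuple(lo), tuple(hi))],
        resource=RadialField(center=tuple(center), slope=0.05),
    )
    if seed_positions is None:
        seed_positions = {
            "crown": (-6.0, -6.0, 0.0),
            "primary": (6.0, -6.0, 0.0),
            "seminal": (-6.0, 6.0, 0.0),
            "lateral": (6.0, 6.0, 0.0),
        }
    sims = {}
    for name, params in root_types.items():
        # negatively gravitropic roots emerge growing upward
        orientation = "vertical_up" if params.get("w_g", 0) < 0 \
            else "vertical"
        cfg = SimulationConfig(
            dim=3, orientation=orientation,
            tip_position=seed_positions[name],
            oscillator_period=2.0, v_s=5.0, v_g=5.0,
            **params,
        )
        sims[name] = Simulator(cfg, env)
    for name, sim in sims.items():
        sim.extra_obstacles = [
            RootChainObstacle(other) for oname, other in sims.items()
            if oname != name
        ]

    n_steps = int(round(duration / sims[next(iter(sims))].config.dt))
    logs = {name: [] for name in sims}
    for _ in range(n_steps):
        for name, sim in sims.items():
            sim.step()
            logs[name].append(
                (sim.t, *sim.root.tip,
                 float(env.concentration(sim.root.tip))))
    results = {}
    for name, sim in sims.items():
        arr = np.asarray(logs[name])
        results[name] = dict(
            t=arr[:, 0], tip=arr[:, 1:4], C=arr[:, 4],
            final_tip=sim.root.tip.copy(),
            final_C=float(arr[-1, 4]),
            config=sim.config,
        )
    return results
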