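"""Quantification of circumnutation and gradient-climbing performance.

Circumnutation cycles are read off the normalized growth rate on one side
of the root: its local minima and maxima mark the instants of maximal
differential growth.  Mapping those extrema back to the tip trajectory
gives per-cycle periods (time between consecutive same-type extrema) and
amplitudes ||(p1 + p3)/2 - p2|| for consecutive extrema triples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

__all__ = [
    "NutationMetrics",
    "nutation_extrema",
    "nutation_period_amplitude",
    "performance_f",
    "tip_obstacle_angle",
]


@dataclass
class NutationMetrics:
    """Extrema events and derived periods/amplitudes of one simulated root."""

    times: np.ndarray = field(default_factory=lambda: np.empty(0))
    kinds: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    points: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))
    periods: np.ndarray = field(default_factory=lambda: np.empty(0))
    amplitudes: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def n_cycles(self) -> int:
        """Complete cycles: two extremum-to-extremum intervals each."""
        return max(0, (len(self.times) - 1) // 2)


def nutation_extrema(t: np.ndarray, series: np.ndarray,
                     prominence_frac: float = 0.01):
    """Indices and kinds (+1 max, -1 min) of the growth-rate extrema.

    Local 3-point extrema with a minimum prominence of ``prominence_frac``
    times the series range, suppressing numerical ripple; a constant or
    monotone series yields no events.
    """
    series = np.asarray(series, dtype=float)
    if series.size < 3:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    rng = float(np.ptp(series))
    if rng <= 0:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    prom = prominence_frac * rng
    hi, _ = find_peaks(series, prominence=prom)
    lo, _ = find_peaks(-series, prominence=prom)
    idx = np.concatenate([hi, lo])
    kinds = np.concatenate([np.ones(len(hi), int), -np.ones(len(lo), int)])
    order = np.argsort(idx)
    return idx[order], kinds[order]


def nutation_period_amplitude(times: np.ndarray, kinds: np.ndarray,
                              points: np.ndarray) -> NutationMetrics:
    """Periods and amplitudes from extrema mapped onto the tip trajectory.

    The period is the time between consecutive extrema of the same type
    (one full cycle); the amplitude of each cycle is the distance between
    the middle extremum and the midpoint of its neighbours.
    """
    times = np.asarray(times, dtype=float)
    kinds = np.asarray(kinds, dtype=int)
    points = np.asarray(points, dtype=float)
    if len(times) < 3:
        return NutationMetrics(times, kinds, points)
    periods = []
    for kind in (1, -1):
        tk = times[kinds == kind]
        periods.extend(np.diff(tk))
    amps = [
        float(np.linalg.norm(0.5 * (points[i] + points[i + 2]) - points[i + 1]))
        for i in range(len(times) - 2)
    ]
    return NutationMetrics(times, kinds, points,
                           np.asarray(periods), np.asarray(amps))


def performance_f(C_start: float, C_end: float, C_best: float) -> float:
    """Normalized concentration gain f = (C_end - C_start)/(C_best - C_start).

    1 means the best achievable gain over the run duration; negative values
    mean the root grew down-gradient.  Clipped to [-1, 1].
    """
    if C_best <= C_start:
        raise ValueError("C_best must exceed the starting concentration")
    return float(np.clip((C_end - C_start) / (C_best - C_start), -1.0, 1.0))


def tip_obstacle_angle(tip_direction: np.ndarray, obstacle) -> float:
    """Angle (degrees) between the tip tangent and the obstacle surface plane."""
    r = np.asarray(tip_direction, dtype=float)
    r = r / np.linalg.norm(r)
    n = np.asarray(getattr(obstacle, "normal", obstacle), dtype=float)
    n = n / np.linalg.norm(n)
    cos_to_normal = np.clip(abs(r @ n), 0.0, 1.0)
    return float(np.degrees(np.arcsin(cos_to_normal)))
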