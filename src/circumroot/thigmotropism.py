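"""Touch sensing, passive obstacle avoidance and the thigmotropic signal.

The cap region (d < d_cap) is covered with rings of sensory points on the
root surface.  When points intersect an obstacle, their mean locates the
touch in root coordinates (d_t, phi_t); the cap taper then gives the
estimated root-to-obstacle angle

    alpha_t = arctan(p_cap * r_t**(p_cap - 1))

which maps to an inhibitory signal s_t = -2 alpha_t / pi emitted on the
contact flank.  A passive response repeatedly applies a minimal uniform
bend of every section at phi = phi_t until the root clears the obstacle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import (
    D_CAP_DEFAULT,
    P_CAP_DEFAULT,
    RootState,
    bend_chain,
    cap_radius,
)

__all__ = [
    "TouchEvent",
    "TouchMemory",
    "SensoryLayout",
    "sensory_points",
    "detect_contact",
    "touch_angle",
    "passive_correction",
    "touch_signal_step",
]


@dataclass
class SensoryLayout:
    """Placement of tactile points on the root surface.

    ``n_axial`` rings cover the tapered cap (d < d_cap); behind the cap,
    rings every ``body_spacing`` diameters extend the coverage over the
    whole elongation zone so that no part of the root can sink into an
    obstacle unnoticed.
    """

    n_angular: int = 16
    n_axial: int = 8
    d_cap: float = D_CAP_DEFAULT
    p_cap: float = P_CAP_DEFAULT
    body_spacing: float = 0.25


@dataclass
class TouchEvent:
    """Mean contact location and the derived obstacle-angle estimate."""

    mean_point: np.ndarray
    d_t: float
    phi_t: float
    r_t: float
    alpha_t: float

    @property
    def s_t(self) -> float:
        return -2.0 * self.alpha_t / np.pi


def touch_angle(r_t: float, p_cap: float = P_CAP_DEFAULT) -> float:
    """Root-to-obstacle angle estimated from the touched radius.

    Diverges to pi/2 as r_t -> 0 (contact at the very tip) and decreases
    monotonically with distance from the tip.
    """
    if r_t < 0:
        raise ValueError("radius must be non-negative")
    if not 0 < p_cap < 1:
        raise ValueError("p_cap must lie in (0, 1)")
    if r_t == 0:
        return np.pi / 2
    return float(np.arctan(p_cap * r_t ** (p_cap - 1.0)))


def sensory_points(root: RootState, layout: SensoryLayout | None = None):
    """World positions of the tactile points, with their (d, phi) labels.

    Rings of ``n_angular`` points at the surface radius r(d), at ``n_axial``
    stations from the very tip (a single point, r = 0) up the cap region.
    """
    layout = layout or SensoryLayout()
    d_cap_st = layout.d_cap * np.arange(layout.n_axial) / layout.n_axial
    zone = float(root.node_d[0])
    d_body = np.arange(layout.d_cap, zone + 1e-9, layout.body_spacing)
    d_s = np.concatenate([d_cap_st, d_body])
    ang = -np.pi + 2.0 * np.pi * np.arange(layout.n_angular) / layout.n_angular
    node_d = root.node_d  # decreasing base -> tip
    n = root.n_sections
    k = np.clip(np.searchsorted(-node_d, -d_s, side="right") - 1, 0, n - 1)
    span = node_d[k] - node_d[k + 1]
    w = np.where(span > 0, (node_d[k] - d_s) / np.where(span > 0, span, 1.0),
                 0.0)
    centers = (1 - w)[:, None] * root.centers[k] \
        + w[:, None] * root.centers[k + 1]
    frames = root.frames[k]  # (n_ax, 3, 3)
    r = cap_radius(d_s, layout.d_cap, layout.p_cap, root.D)
    # radial directions at each ring angle: -sin(phi) x + cos(phi) y
    e = (-np.sin(ang)[None, :, None] * frames[:, None, :, 0]
         + np.cos(ang)[None, :, None] * frames[:, None, :, 1])
    pts = centers[:, None, :] + r[:, None, None] * e  # (n_ax, n_ang, 3)
    ds = np.broadcast_to(d_s[:, None], pts.shape[:2])
    phis = np.broadcast_to(ang[None, :], pts.shape[:2])
    ring = r > 1e-12
    keep = np.ones(pts.shape[:2], dtype=bool)
    keep[~ring, 1:] = False  # a collapsed ring is a single tip point
    return pts[keep], ds[keep], phis[keep]


def detect_contact(root: RootState, obstacles,
                   layout: SensoryLayout | None = None,
                   pad: float = 0.0,
                   d_max: float | None = None) -> TouchEvent | None:
    """Mean of the sensory points inside any obstacle, in root coordinates.

    ``pad`` shifts the surface test: a small positive pad reports grazing
    contact (points within pad of the surface), a negative pad only actual
    penetration deeper than |pad|.  ``d_max`` restricts the responsive
    points to the apical region (the touch-sensing organ); points farther
    up the root still block penetration but do not initiate a signal.
    """
    layout = layout or SensoryLayout()
    if not obstacles:
        return None
    pts, ds, phis = sensory_points(root, layout)
    if d_max is not None:
        sel = ds <= d_max + 1e-12
        pts, ds, phis = pts[sel], ds[sel], phis[sel]
    inside = np.zeros(len(pts), dtype=bool)
    for obs in obstacles:
        inside |= np.asarray(obs.sdf(pts)) < pad
    if not inside.any():
        return None
    mean_point = pts[inside].mean(axis=0)
    d_t = float(ds[inside].mean())
    center, frame = root.interpolate(d_t)
    local = frame.T @ (mean_point - center)
    if np.hypot(local[0], local[1]) < 1e-12:
        phi_t = float(phis[inside][0])
    else:
        phi_t = float(np.arctan2(-local[0], local[1]))
    r_t = float(cap_radius(d_t, layout.d_cap, layout.p_cap, root.D))
    return TouchEvent(mean_point, d_t, phi_t, r_t,
                      touch_angle(r_t, layout.p_cap))


def passive_correction(root: RootState, obstacles, phi_t: float,
                       layout: SensoryLayout | None = None,
                       step_deg: float = 0.05,
                       max_iter: int = 500,
                       pad: float = -0.01) -> tuple[RootState, int, bool]:
    """Minimal uniform bending until the root stops intersecting obstacles.

    Every section is bent by ``step_deg`` at phi = phi_t per iteration,
    which moves the tip away from the contact flank.  The per-section step
    is kept small because it acts on every section at once (the tip turns
    by n times the step per iteration); larger steps overshoot the
    clearance and throw the apex off the obstacle.  Returns the corrected
    root, the number of iterations and a trapped flag (iteration cap hit;
    the simulation then continues with the contact held).
    """
    layout = layout or SensoryLayout()
    step = np.deg2rad(step_deg)

    def _penetration(state):
        pts, ds, _ = sensory_points(state, layout)
        inside = np.zeros(len(pts), dtype=bool)
        for obs in obstacles:
            inside |= np.asarray(obs.sdf(pts)) < pad
        return inside, ds

    inside, ds = _penetration(root)
    if not inside.any():
        return root, 0, False

    def clears(k):
        bent = bend_chain(root, k * step, phi_t)
        ins, _ = _penetration(bent)
        return not ins.any(), bent

    # exponential then binary search for the smallest clearing multiple of
    # the bend quantum (equivalent to, but much cheaper than, iterating)
    k = 1
    ok, bent = clears(k)
    while not ok and k < max_iter:
        k = min(2 * k, max_iter)
        ok, bent = clears(k)
    if not ok:
        return bent, max_iter, True
    lo, hi = k // 2, k  # lo fails (or 0), hi clears
    best = bent
    while hi - lo > 1:
        mid = (lo + hi) // 2
        ok, bent = clears(mid)
        if ok:
            hi, best = mid, bent
        else:
            lo = mid
    return best, hi, False


@dataclass
class TouchMemory:
    """Leaky filter of the touch signal with separate rise and decay rates.

    With tau_decay = dt the signal tracks -2 alpha_t / pi exactly and
    vanishes as soon as contact is lost; with a slow decay (10 h in the
    memory regime) the inhibition jumps on contact but fades geometrically
    by (1 - dt/tau) per step afterwards, remembering recent interactions.
    """

    tau_decay: float
    tau_rise: float | None = None  # default: immediate (the step size)
    state: float = 0.0

    def step(self, event: TouchEvent | None, dt: float) -> float:
        if self.tau_decay < dt * (1 - 1e-12):
            raise ValueError("decay constant must be at least dt")
        if event is not None:
            tau = self.tau_rise if self.tau_rise is not None else dt
            target = event.s_t
        else:
            tau = self.tau_decay
            target = 0.0
        alpha = dt / max(tau, dt)
        self.state = (1.0 - alpha) * self.state + alpha * target
        return self.state


def touch_signal_step(memory: TouchMemory, event: TouchEvent | None,
                      dt: float) -> float:
    """Functional wrapper around :meth:`TouchMemory.step`."""
    return memory.step(event, dt)
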