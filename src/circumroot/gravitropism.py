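"""Gravitropic stimulus generation at the root cap.

The cap senses the angle alpha_g between the tip direction and gravity and
emits an excitation of strength

    s_g = 2 * alpha_g / pi   (alpha_g <= pi/2), else 1

on the top side of the root (circumferential angle phi_g), with the usual
antisymmetric falloff so the bottom flank is inhibited by -s_g.  The signal
then propagates base-ward at speed v_g, producing downward bending; a
negative sensitivity w_g turns the same pathway into negative gravitropism.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .surfaces import StimulusSource

__all__ = ["gravity_strength", "top_side_angle", "GravitropicSource"]


def gravity_strength(alpha_g: float) -> float:
    """Signal strength from the tip-to-gravity angle (radians, [0, pi])."""
    if not -1e-12 <= alpha_g <= np.pi + 1e-12:
        raise ValueError("alpha_g must lie in [0, pi]")
    alpha_g = float(np.clip(alpha_g, 0.0, np.pi))
    return 2.0 * alpha_g / np.pi if alpha_g <= np.pi / 2 else 1.0


def top_side_angle(tip_frame: np.ndarray, g: np.ndarray,
                   prev_phi: float = 0.0, tol: float = 1e-9) -> float:
    """Circumferential angle of the top side of the root.

    Projects the up direction (-g) onto the tip cross-section plane and
    measures its angle from the frame's y axis.  When the tip is aligned
    with gravity the projection vanishes and the previous angle is kept
    (the strength is zero there, so the choice is inert).
    """
    g = np.asarray(g, dtype=float)
    norm = np.linalg.norm(g)
    if norm == 0:
        raise ValueError("gravity vector must be non-zero")
    up_local = tip_frame.T @ (-g / norm)
    px, py = up_local[0], up_local[1]
    if np.hypot(px, py) < tol:
        return prev_phi
    # circumferential direction at angle phi is -sin(phi) x + cos(phi) y
    return float(np.arctan2(-px, py))


@dataclass
class GravitropicSource:
    """Stateful gravity-signal emitter feeding the signal network.

    The sensed orientation r is the apex chord — the direction from the
    cross-section at ``sense_d`` (the cap length by default) to the very
    tip — rather than the axis of the last discrete section alone: the cap
    is the gravity-sensing organ and a chord over it is robust to the
    sub-section-scale curls that a single 0.1 D section would hide.  The
    emission angle phi_g is measured in the frame of that cross-section.
    """

    v_g: float = 5.0
    D: float = 1.0
    sense_d: float = 1.5

    def __post_init__(self):
        self.source = StimulusSource("gravity", self.v_g, D=self.D)
        self._phi_g = 0.0

    def sense(self, root, g: np.ndarray) -> tuple[float, float, float]:
        """(alpha_g, s_g, phi_g) from the current apex pose."""
        g = np.asarray(g, dtype=float)
        g_hat = g / np.linalg.norm(g)
        c_sense, f_sense = root.interpolate(min(self.sense_d,
                                                root.zone_length))
        chord = root.tip - c_sense
        norm = np.linalg.norm(chord)
        r = chord / norm if norm > 1e-12 else root.tip_direction
        alpha = float(np.arccos(np.clip(r @ g_hat, -1.0, 1.0)))
        strength = gravity_strength(alpha)
        self._phi_g = top_side_angle(f_sense, g, prev_phi=self._phi_g)
        return alpha, strength, self._phi_g

    def sense_and_emit(self, t: float, root, g: np.ndarray) -> tuple[float, float]:
        """Evaluate (s_g, phi_g) at the current apex pose and emit it."""
        _, strength, phi_g = self.sense(root, g)
        self.source.emit(t, strength, phi_g)
        return strength, phi_g
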