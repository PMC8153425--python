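"""Gravity, obstacles and scalar resource fields.

Obstacles expose an exact signed clearance (negative inside); resource
fields are pure point evaluations of a concentration C(x) clipped to
[0, 1].
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Plane",
    "Box",
    "UniformField",
    "LinearField",
    "RadialField",
    "Environment",
    "signed_clearance",
    "concentration",
]


# ---------------------------------------------------------------------------
# obstacles

@dataclass
class Plane:
    """Half-space obstacle: the region below the plane is solid."""

    point: tuple = (0.0, 0.0, 0.0)
    normal: tuple = (0.0, 0.0, 1.0)  # outward (free-space) direction

    def sdf(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        n = np.asarray(self.normal, dtype=float)
        n = n / np.linalg.norm(n)
        return (x - np.asarray(self.point)) @ n

    def to_dict(self):
        return {"type": "plane", "point": list(self.point),
                "normal": list(self.normal)}


@dataclass
class Box:
    """Axis-aligned solid box."""

    lo: tuple
    hi: tuple

    def sdf(self, x) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        lo = np.asarray(self.lo, dtype=float)
        hi = np.asarray(self.hi, dtype=float)
        center = 0.5 * (lo + hi)
        half = 0.5 * (hi - lo)
        q = np.abs(x - center) - half
        outside = np.linalg.norm(np.maximum(q, 0.0), axis=-1)
        inside = np.minimum(np.max(q, axis=-1), 0.0)
        out = outside + inside
        return out[0] if out.size == 1 else out

    def to_dict(self):
        return {"type": "box", "lo": list(self.lo), "hi": list(self.hi)}


@dataclass
class BoxWalls:
    """Inverted box: solid outside, free inside (an arena)."""

    lo: tuple
    hi: tuple

    def sdf(self, x) -> np.ndarray:
        return -Box(self.lo, self.hi).sdf(x)

    def to_dict(self):
        return {"type": "box_walls", "lo": list(self.lo), "hi": list(self.hi)}


def signed_clearance(obstacle, x):
    """Signed distance from point(s) ``x`` to the obstacle (negative inside)."""
    return obstacle.sdf(x)


# ---------------------------------------------------------------------------
# resource fields

@dataclass
class UniformField:
    value: float = 0.5

    def concentration(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        c = np.full(x.shape[:-1], float(np.clip(self.value, 0.0, 1.0)))
        return float(c) if c.ndim == 0 else c

    def to_dict(self):
        return {"type": "uniform", "value": self.value}


@dataclass
class LinearField:
    """C increases by ``slope`` per unit D along ``direction``, clipped to [0,1]."""

    origin: tuple = (0.0, 0.0, 0.0)
    direction: tuple = (1.0, 0.0, 0.0)
    slope: float = 0.05
    c0: float = 0.5

    def concentration(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        u = np.asarray(self.direction, dtype=float)
        u = u / np.linalg.norm(u)
        c = self.c0 + self.slope * (x - np.asarray(self.origin)) @ u
        return np.clip(c, 0.0, 1.0)

    def to_dict(self):
        return {"type": "linear", "origin": list(self.origin),
                "direction": list(self.direction), "slope": self.slope,
                "c0": self.c0}


@dataclass
class RadialField:
    """C peaks at ``center`` and decreases by ``slope`` per unit distance."""

    center: tuple = (0.0, 0.0, 0.0)
    slope: float = 0.05
    c_max: float = 1.0

    def concentration(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        r = np.linalg.norm(x - np.asarray(self.center), axis=-1)
        return np.clip(self.c_max - self.slope * r, 0.0, 1.0)

    def to_dict(self):
        return {"type": "radial", "center": list(self.center),
                "slope": self.slope, "c_max": self.c_max}


def concentration(fld, x):
    """Concentration C(x) in [0, 1]; pure and deterministic."""
    return fld.concentration(x)


_OBSTACLES = {"plane": Plane, "box": Box, "box_walls": BoxWalls}
_FIELDS = {"uniform": UniformField, "linear": LinearField,
           "radial": RadialField}


@dataclass
class Environment:
    """Gravity direction, obstacle set and optional resource field."""

    gravity: tuple = (0.0, 0.0, -1.0)
    obstacles: list = field(default_factory=list)
    resource: object | None = None

    @property
    def g(self) -> np.ndarray:
        g = np.asarray(self.gravity, dtype=float)
        if np.linalg.norm(g) == 0:
            raise ValueError("gravity vector must be non-zero")
        return g

    def concentration(self, x):
        if self.resource is None:
            raise ValueError("no resource field configured")
        return self.resource.concentration(x)

    # -- JSON round-trip --------------------------------------------------
    def to_json(self) -> str:
        return json.dumps(
            {
                "gravity": list(self.gravity),
                "obstacles": [o.to_dict() for o in self.obstacles],
                "resource": None if self.resource is None
                else self.resource.to_dict(),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "Environment":
        payload = json.loads(text)
        obstacles = []
        for o in payload.get("obstacles", []):
            kind = o.pop("type")
            obstacles.append(_OBSTACLES[kind](**o))
        resource = None
        r = payload.get("resource")
        if r is not None:
            kind = r.pop("type")
            resource = _FIELDS[kind](**r)
        return cls(tuple(payload.get("gravity", (0, 0, -1))), obstacles,
                   resource)
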