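"""Differential-growth kinematics of a root elongation zone.

The root apex is represented as an ordered chain of cylindrical
cross-sections.  Only the apical elongation zone (default 6 diameters, D)
moves: each simulation step every section elongates at the local growth
rate and, when the rate differs between opposite flanks, bends by

    theta = |G_left - G_right| * dt / D

with the new material laid down on a circular arc of radius

    R_c = (D / 2) * (G_left + G_right) / (G_left - G_right)

so that R_c * theta equals the elongation increment G_avr * dt.  After each
step the zone is re-split into ``n`` sections of equal length (0.1 D with
defaults), and material that leaves the zone is frozen onto an append-only
mature trace.

All lengths are expressed in multiples of the root diameter D, times in
hours, rates in D/hour.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "CrossSection",
    "BendStep",
    "RootState",
    "cap_radius",
    "bend_from_rates",
    "advance_section",
    "grow_step",
    "grow_step_rates",
    "resample",
    "bend_chain",
    "snapshot_frame",
    "mesh_obj",
]

_Z = np.array([0.0, 0.0, 1.0])

D_CAP_DEFAULT = 1.5
P_CAP_DEFAULT = 0.4


# ---------------------------------------------------------------------------
# small rotation helpers (column-vector convention, right-handed frames)

def rot_z(phi: float) -> np.ndarray:
    c, s = np.cos(phi), np.sin(phi)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def bend_rotation(theta, phi) -> np.ndarray:
    """Rotation of a section frame for a bend ``theta`` at growth angle ``phi``.

    The rotation axis lies in the cross-section plane, perpendicular to the
    direction of maximal growth (angle ``phi`` measured from the local y
    axis): axis = (cos phi, sin phi, 0).  For phi = 0 this is a rotation
    about x that tilts the local z axis toward -y, i.e. away from the
    faster-growing flank.  Broadcasts over leading dimensions.
    """
    theta = np.asarray(theta, dtype=float)
    phi = np.asarray(phi, dtype=float)
    ax = np.stack(
        [np.cos(phi), np.sin(phi), np.zeros_like(phi)], axis=-1
    )  # (..., 3)
    c = np.cos(theta)[..., None, None]
    s = np.sin(theta)[..., None, None]
    zero = np.zeros_like(ax[..., 0])
    K = np.stack(
        [
            np.stack([zero, -ax[..., 2], ax[..., 1]], axis=-1),
            np.stack([ax[..., 2], zero, -ax[..., 0]], axis=-1),
            np.stack([-ax[..., 1], ax[..., 0], zero], axis=-1),
        ],
        axis=-2,
    )
    eye = np.broadcast_to(np.eye(3), K.shape)
    return eye + s * K + (1.0 - c) * (K @ K)


def bend_offset(theta, phi, arc_len) -> np.ndarray:
    """Local displacement of the growth increment.

    An arc of length ``arc_len`` and turning angle ``theta`` starting along
    the local z axis and curving away from the max-growth direction at angle
    ``phi``.  Degenerates to a straight step ``(0, 0, arc_len)`` as theta->0.
    Broadcasts over leading dimensions; returns (..., 3).
    """
    theta = np.asarray(theta, dtype=float)
    phi = np.asarray(phi, dtype=float)
    arc_len = np.asarray(arc_len, dtype=float)
    straight = np.abs(theta) < 1e-12
    th = np.where(straight, 1.0, theta)
    rc = arc_len / th
    a = rc * (np.cos(th) - 1.0)  # <= 0: toward -y before the phi rotation
    b = rc * np.sin(th)
    a = np.where(straight, 0.0, a)
    b = np.where(straight, arc_len, b)
    return np.stack([-a * np.sin(phi), a * np.cos(phi), b], axis=-1)


def _renormalize_frames(frames: np.ndarray) -> np.ndarray:
    """Project near-rotation frames back onto SO(3) (Gram-Schmidt on z, y).

    The chain update composes O(n) rotations per step and feeds each frame
    into every tip-ward frame of the next step, which would compound the
    round-off in the determinant exponentially; re-orthonormalizing once
    per resample keeps the drift at machine precision indefinitely.
    """
    z = frames[..., :, 2]
    z = z / np.linalg.norm(z, axis=-1, keepdims=True)
    y = frames[..., :, 1]
    y = y - np.einsum("...i,...i->...", y, z)[..., None] * z
    y = y / np.linalg.norm(y, axis=-1, keepdims=True)
    x = np.cross(y, z)
    return np.stack([x, y, z], axis=-1)


def _orthonormal(frame: np.ndarray, tol: float = 1e-8) -> bool:
    return (
        np.allclose(frame.T @ frame, np.eye(3), atol=tol)
        and np.linalg.det(frame) > 0
    )


# ---------------------------------------------------------------------------
# domain types

def cap_radius(d, d_cap: float = D_CAP_DEFAULT, p_cap: float = P_CAP_DEFAULT,
               D: float = 1.0):
    """Cross-section radius r(d) of the tapered root cap.

    r(d) = 0.5*D*(d/d_cap)**p_cap for d < d_cap and 0.5*D beyond; the
    profile is continuous at d = d_cap and vanishes at the very tip.
    """
    d_arr = np.asarray(d, dtype=float)
    if np.any(d_arr < 0):
        raise ValueError("distance from tip must be non-negative")
    if not d_cap > 0:
        raise ValueError("d_cap must be positive")
    if not 0 < p_cap < 1:
        raise ValueError("p_cap must lie in (0, 1)")
    r = np.where(d_arr < d_cap, 0.5 * D * (d_arr / d_cap) ** p_cap, 0.5 * D)
    return float(r) if np.isscalar(d) or d_arr.ndim == 0 else r


@dataclass
class CrossSection:
    """One cylindrical cross-section of the root.

    ``frame`` columns are the local x, y, z axes; z points along the root
    axis toward the tip and y marks the reference (phi = 0) direction.
    """

    center: np.ndarray
    frame: np.ndarray
    radius: float
    d: float

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float)
        self.frame = np.asarray(self.frame, dtype=float)
        if not _orthonormal(self.frame):
            raise ValueError("cross-section frame must be a rotation matrix")


@dataclass
class BendStep:
    """Elongation + bending of one section over one time step."""

    G_left: float
    G_right: float
    theta: float
    R_c: float  # curvature radius of the new material; inf when straight
    phi: float
    extension: float  # centerline elongation G_avr * dt


def bend_from_rates(G_left: float, G_right: float, dt: float, D: float = 1.0,
                    phi: float = 0.0) -> BendStep:
    """Bend geometry from the flank elongation rates.

    theta = |G_left - G_right| dt / D and R_c = (D/2)(Gl+Gr)/(Gl-Gr); equal
    rates give a straight extension (theta = 0, R_c infinite).
    """
    if not (G_left >= G_right >= 0):
        raise ValueError("require G_left >= G_right >= 0")
    theta = abs(G_left - G_right) * dt / D
    g_avr = 0.5 * (G_left + G_right)
    if theta == 0.0:
        r_c = np.inf
    else:
        r_c = 0.5 * D * (G_left + G_right) / (G_left - G_right)
    return BendStep(G_left, G_right, theta, r_c, phi, g_avr * dt)


def advance_section(section: CrossSection, bend: BendStep) -> CrossSection:
    """Move one cross-section through a single growth increment.

    The center advances along an arc of radius R_c and angle theta in the
    plane of the max-growth direction; the frame rotates by the (twist-free)
    bend rotation.  With theta = 0 the center simply translates by the
    extension along the local z axis.
    """
    if not _orthonormal(section.frame):
        raise ValueError("cross-section frame must be orthonormal")
    A = section.frame
    delta = bend_offset(bend.theta, bend.phi, bend.extension)
    new_center = section.center + A @ delta
    if bend.theta == 0.0:
        new_frame = A.copy()
    else:
        new_frame = A @ bend_rotation(bend.theta, bend.phi)
    return CrossSection(new_center, new_frame, section.radius, section.d)


@dataclass
class _StepGeometry:
    """Exact geometry of one grow step, kept for arc-exact resampling."""

    straight_vec: np.ndarray  # (n, 3) world chord of the pre-existing material
    straight_len: np.ndarray  # (n,)
    inc: np.ndarray           # (n,) arc length of new material
    theta: np.ndarray         # (n,)
    phi: np.ndarray           # (n,)
    A_pre: np.ndarray         # (n, 3, 3) frame at the arc start


@dataclass
class RootState:
    """The growing elongation zone plus the frozen mature trace.

    ``centers`` holds the n+1 cross-section centers from the zone base
    (d = zone_length) to the tip (d = 0); ``frames[k]`` is the frame of the
    segment between centers k and k+1 and ``lengths[k]`` its arc length.
    """

    centers: np.ndarray                 # (n+1, 3)
    frames: np.ndarray                  # (n, 3, 3)
    lengths: np.ndarray                 # (n,)
    zone_length: float = 6.0
    D: float = 1.0
    t: float = 0.0
    mature_centers: list = field(default_factory=list)
    mature_frames: list = field(default_factory=list)
    _geom: _StepGeometry | None = None

    # -- constructors -----------------------------------------------------
    @classmethod
    def initial(cls, zone_length: float = 6.0, dt: float = 0.1,
                G_base: float = 1.0, D: float = 1.0,
                orientation: str | np.ndarray = "vertical",
                tip: Sequence[float] = (0.0, 0.0, 0.0)) -> "RootState":
        """Straight root of length ``zone_length``; n = zone/(dt*G_base)."""
        n = int(round(zone_length / (dt * G_base)))
        if orientation == "vertical":
            # tip pointing down, reference y toward +x
            frame = np.column_stack(
                [[0.0, 1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, -1.0]]
            )
        elif orientation == "vertical_up":
            frame = np.column_stack(
                [[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]]
            )
        elif orientation == "horizontal":
            # tip pointing +x, reference y up (+z)
            frame = np.column_stack(
                [[0.0, 1.0, 0.0], [0.0, 0.0, 1.0], [1.0, 0.0, 0.0]]
            )
        else:
            frame = np.asarray(orientation, dtype=float)
            if not _orthonormal(frame):
                raise ValueError("orientation frame must be a rotation matrix")
        tip = np.asarray(tip, dtype=float)
        z = frame[:, 2]
        ell = zone_length / n
        base = tip - zone_length * z
        centers = base[None, :] + np.arange(n + 1)[:, None] * ell * z[None, :]
        frames = np.broadcast_to(frame, (n, 3, 3)).copy()
        lengths = np.full(n, ell)
        return cls(centers, frames, lengths, zone_length=zone_length, D=D)

    # -- views ------------------------------------------------------------
    @property
    def n_sections(self) -> int:
        return len(self.lengths)

    @property
    def tip(self) -> np.ndarray:
        return self.centers[-1]

    @property
    def tip_frame(self) -> np.ndarray:
        return self.frames[-1]

    @property
    def tip_direction(self) -> np.ndarray:
        return self.frames[-1][:, 2]

    @property
    def node_d(self) -> np.ndarray:
        """Arc distance from the tip of every cross-section center."""
        rev = np.concatenate([[0.0], np.cumsum(self.lengths[::-1])])
        return rev[::-1]

    @property
    def section_d(self) -> np.ndarray:
        """Arc distance from the tip of each segment's base cross-section."""
        return self.node_d[:-1]

    @property
    def total_length(self) -> float:
        return float(self.lengths.sum())

    def radii(self, d_cap: float = D_CAP_DEFAULT,
              p_cap: float = P_CAP_DEFAULT) -> np.ndarray:
        return cap_radius(self.node_d, d_cap, p_cap, self.D)

    def sections(self) -> list[CrossSection]:
        """Cross-section view (base to tip); tip section reuses the last frame."""
        d = self.node_d
        r = self.radii()
        out = []
        for k in range(self.n_sections + 1):
            frame = self.frames[min(k, self.n_sections - 1)]
            out.append(CrossSection(self.centers[k].copy(), frame.copy(),
                                    float(r[k]), float(d[k])))
        return out

    def interpolate(self, d: float) -> tuple[np.ndarray, np.ndarray]:
        """Center and frame at arc distance ``d`` from the tip.

        Centers are interpolated linearly along the containing segment; the
        segment frame is used as-is.
        """
        node_d = self.node_d
        if d < -1e-12 or d > node_d[0] + 1e-12:
            raise ValueError("d outside the elongation zone")
        d = float(np.clip(d, 0.0, node_d[0]))
        # node_d decreases base->tip
        k = int(np.clip(np.searchsorted(-node_d, -d, side="right") - 1,
                        0, self.n_sections - 1))
        span = node_d[k] - node_d[k + 1]
        w = 0.0 if span <= 0 else (node_d[k] - d) / span
        center = (1 - w) * self.centers[k] + w * self.centers[k + 1]
        return center, self.frames[k]


# ---------------------------------------------------------------------------
# growth step

def grow_step_rates(root: RootState, G_left: np.ndarray, G_right: np.ndarray,
                    phi: np.ndarray, dt: float) -> RootState:
    """Extend and bend every section for one time step (no resampling).

    Sections are processed base to tip: each section's bend roto-translates
    all tip-ward material rigidly, exactly as in the incremental frame
    update A(t+dt, d) = A(t, d) . M.
    """
    n = root.n_sections
    G_left = np.asarray(G_left, dtype=float)
    G_right = np.asarray(G_right, dtype=float)
    phi = np.asarray(phi, dtype=float)
    if G_left.shape != (n,) or G_right.shape != (n,):
        raise ValueError("rate arrays must have one entry per section")
    if np.any(G_left < G_right):
        raise ValueError("G_left must dominate G_right")

    theta = (G_left - G_right) * dt / root.D
    inc = 0.5 * (G_left + G_right) * dt
    M = bend_rotation(theta, phi)            # (n,3,3)
    delta = bend_offset(theta, phi, inc)     # (n,3) local

    F = root.frames
    chords = np.diff(root.centers, axis=0)   # (n,3)
    new_centers = np.empty_like(root.centers)
    new_frames = np.empty_like(F)
    straight_vec = np.empty_like(chords)
    A_pre = np.empty_like(F)

    new_centers[0] = root.centers[0]
    R_acc = np.eye(3)
    for k in range(n):
        A = R_acc @ F[k]
        A_pre[k] = A
        sv = R_acc @ chords[k]
        straight_vec[k] = sv
        new_centers[k + 1] = new_centers[k] + sv + A @ delta[k]
        T = F[k] @ M[k]
        new_frames[k] = R_acc @ T
        R_acc = R_acc @ T @ F[k].T

    geom = _StepGeometry(
        straight_vec=straight_vec,
        straight_len=np.linalg.norm(chords, axis=1),
        inc=inc,
        theta=theta,
        phi=phi,
        A_pre=A_pre,
    )
    return replace(
        root,
        centers=new_centers,
        frames=new_frames,
        lengths=root.lengths + inc,
        _geom=geom,
    )


def _extract_rates(surfaces, d_vals: np.ndarray):
    """Per-section (G_left, G_right, phi) from a growth-response surface."""
    if not np.allclose(surfaces.d_grid, d_vals, atol=1e-9):
        raise ValueError("surface d-grid does not match the section layout")
    return surfaces.extract()


def grow_step(root: RootState, surfaces, dt: float) -> RootState:
    """One full growth iteration: extend + bend every section, then resample."""
    G_left, G_right, phi = _extract_rates(surfaces, root.section_d)
    grown = grow_step_rates(root, G_left, G_right, phi, dt)
    return resample(grown, dt)


# ---------------------------------------------------------------------------
# resampling

def _eval_on_grown(root: RootState, arcs: np.ndarray):
    """Points and frames at from-base arc positions on the grown curve.

    Each grown section is a straight chord followed by a circular arc (the
    new material); evaluation is exact on that piecewise curve.
    """
    geom = root._geom
    n = root.n_sections
    if geom is None:
        # straight-polyline fallback for states not produced by grow_step_rates
        seg_len = root.lengths
        geom = _StepGeometry(
            straight_vec=np.diff(root.centers, axis=0),
            straight_len=seg_len.copy(),
            inc=np.zeros(n),
            theta=np.zeros(n),
            phi=np.zeros(n),
            A_pre=root.frames.copy(),
        )
    s = geom.straight_len + geom.inc
    cum = np.concatenate([[0.0], np.cumsum(s)])
    pts = np.empty((len(arcs), 3))
    frames = np.empty((len(arcs), 3, 3))
    ks = np.clip(np.searchsorted(cum, arcs, side="right") - 1, 0, n - 1)
    for j, (a, k) in enumerate(zip(arcs, ks)):
        u = a - cum[k]
        L = geom.straight_len[k]
        base = root.centers[k]
        if u <= L or geom.inc[k] <= 0:
            frac = 0.0 if L == 0 else min(u, L) / L
            pts[j] = base + frac * geom.straight_vec[k]
            frames[j] = geom.A_pre[k]
        else:
            w = min(u - L, geom.inc[k])
            A = geom.A_pre[k]
            start = base + geom.straight_vec[k]
            th = geom.theta[k]
            if th < 1e-12:
                pts[j] = start + w * A[:, 2]
                frames[j] = A
            else:
                beta = th * w / geom.inc[k]
                pts[j] = start + A @ bend_offset(beta, geom.phi[k],
                                                 w)
                frames[j] = A @ bend_rotation(beta, geom.phi[k])
    return pts, frames


def resample(root: RootState, dt: float | None = None) -> RootState:
    """Re-split the apical ``zone_length`` into n equal-length sections.

    Material behind the zone (at the base) is appended to the mature trace
    and never moves again.  Section orientations are transported by
    spherical-linear interpolation between the grown sections' frames,
    knotted at the section centers in arc length: a section's frame samples
    the orientation of the material now occupying its span, so orientation
    advects through the zone exactly as the material does (growth tip-ward
    of a point pushes it base-ward in tip distance).  Centers are rebuilt
    as the polyline base + section-length steps along each section's axis,
    so consecutive centers are separated by exactly the section length.
    """
    from scipy.spatial.transform import Rotation, Slerp

    n = root.n_sections
    total = root.total_length
    cut = total - root.zone_length
    if cut < -1e-9:
        raise ValueError("root shorter than the elongation zone")
    cut = max(cut, 0.0)
    ell = root.zone_length / n
    cum = np.concatenate([[0.0], np.cumsum(root.lengths)])

    base_pt = _eval_on_grown(root, np.array([cut]))[0][0]

    knots = 0.5 * (cum[:-1] + cum[1:])      # grown-section centers
    samples = cut + ell * (np.arange(n) + 0.5)
    samples = np.clip(samples, knots[0], knots[-1])
    slerp = Slerp(knots, Rotation.from_matrix(root.frames))
    new_frames = slerp(samples).as_matrix()

    # freeze material that left the zone
    mature_centers = list(root.mature_centers)
    mature_frames = list(root.mature_frames)
    if cut > 1e-12:
        exited = cum[:-1] < cut - 1e-12
        for k in np.nonzero(exited)[0]:
            mature_centers.append(root.centers[k].copy())
            mature_frames.append(root.frames[k].copy())

    new_centers = np.empty((n + 1, 3))
    new_centers[0] = base_pt
    np.cumsum(ell * new_frames[:, :, 2], axis=0,
              out=new_centers[1:])
    new_centers[1:] += new_centers[0]
    return replace(
        root,
        centers=new_centers,
        frames=new_frames,
        lengths=np.full(n, ell),
        mature_centers=mature_centers,
        mature_frames=mature_frames,
        _geom=None,
    )


def bend_chain(root: RootState, theta: float, phi: float,
               mask: np.ndarray | None = None) -> RootState:
    """Rotate sections by ``theta`` at growth angle ``phi`` (no growth).

    Used by the passive touch response: a small uniform bend of each
    selected section moves the tip away from the flank at angle ``phi``.
    ``mask`` selects which sections bend (default: all); section lengths
    are preserved exactly.
    """
    n = root.n_sections
    M = bend_rotation(theta, phi)
    F = root.frames
    chords = np.diff(root.centers, axis=0)
    new_centers = np.empty_like(root.centers)
    new_frames = np.empty_like(F)
    new_centers[0] = root.centers[0]
    R_acc = np.eye(3)
    eye = np.eye(3)
    for k in range(n):
        T = F[k] @ M if (mask is None or mask[k]) else F[k] @ eye
        R_acc_next = R_acc @ T @ F[k].T
        new_centers[k + 1] = new_centers[k] + R_acc_next @ chords[k]
        new_frames[k] = R_acc @ T
        R_acc = R_acc_next
    return replace(root, centers=new_centers,
                   frames=_renormalize_frames(new_frames), _geom=None)


# ---------------------------------------------------------------------------
# export

def snapshot_frame(root: RootState):
    """Root snapshot as a pandas DataFrame (one row per cross-section)."""
    import pandas as pd

    rows = []
    d = root.node_d
    r = root.radii()
    for k in range(root.n_sections + 1):
        frame = root.frames[min(k, root.n_sections - 1)]
        rows.append(
            dict(
                t=root.t,
                section_index=k,
                d=d[k],
                cx=root.centers[k, 0],
                cy=root.centers[k, 1],
                cz=root.centers[k, 2],
                radius=r[k],
                **{
                    f"a{i}{j}": frame[i, j]
                    for i in range(3)
                    for j in range(3)
                },
            )
        )
    return pd.DataFrame(rows)


def mesh_obj(root: RootState, path, n_circ: int = 16):
    """Export the elongation-zone surface as a Wavefront OBJ mesh.

    Circumference points at |r(d)| are projected in each section's xy plane
    and consecutive circles are stitched with quads.
    """
    d = root.node_d
    r = root.radii()
    ang = np.linspace(-np.pi, np.pi, n_circ, endpoint=False)
    verts = []
    for k in range(root.n_sections + 1):
        frame = root.frames[min(k, root.n_sections - 1)]
        e = (-np.sin(ang)[:, None] * frame[:, 0]
             + np.cos(ang)[:, None] * frame[:, 1])
        ring = root.centers[k] + r[k] * e
        verts.append(ring)
    verts = np.concatenate(verts)
    lines = [f"v {x:.6f} {y:.6f} {z:.6f}" for x, y, z in verts]
    for k in range(root.n_sections):
        for a in range(n_circ):
            b = (a + 1) % n_circ
            i0 = k * n_circ + a + 1
            i1 = k * n_circ + b + 1
            j0 = (k + 1) * n_circ + a + 1
            j1 = (k + 1) * n_circ + b + 1
            lines.append(f"f {i0} {i1} {j1} {j0}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
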