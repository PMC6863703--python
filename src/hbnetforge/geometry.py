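"""Rigid-body transforms, hydrogen-bond geometry, and grid quantization.

All coordinates are in angstroms, all angles in degrees unless noted.
Counts produced downstream (placements, networks, matches) must be exactly
reproducible, so every operation here is deterministic: no randomness and a
documented tie rule for grid rounding (half away from zero).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import GeometryError, ValidationError

_ORTHO_TOL = 1e-8


def _as_xyz(p) -> np.ndarray:
    a = np.asarray(p, dtype=float)
    if a.shape[-1] != 3:
        raise ValueError(f"expected 3-vectors, got shape {a.shape}")
    if not np.all(np.isfinite(a)):
        raise GeometryError("non-finite coordinates")
    return a


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion x -> R @ x + t."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-7):
            raise ValidationError("rotation matrix is not orthonormal")
        if np.linalg.det(R) < 0:
            raise ValidationError("rotation matrix is a reflection (det < 0)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points) -> np.ndarray:
        pts = _as_xyz(points)
        return pts @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self o other: apply ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation)

    def to_dict(self) -> dict:
        return {
            "rotation": self.rotation.tolist(),
            "translation": self.translation.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        return cls(np.array(d["rotation"]), np.array(d["translation"]))


def apply_transform(t: RigidTransform, points) -> np.ndarray:
    """Apply a rigid transform to an (N, 3) array or a single 3-vector."""
    if not isinstance(t, RigidTransform):
        raise ValidationError("apply_transform requires a RigidTransform")
    return t.apply(points)


def angle_deg(p1, p2, p3) -> float:
    """Angle p1-p2-p3 at the vertex p2."""
    v1 = _as_xyz(p1) - _as_xyz(p2)
    v2 = _as_xyz(p3) - _as_xyz(p2)
    n1 = np.linalg.norm(v1)
    n2 = np.linalg.norm(v2)
    if n1 < 1e-12 or n2 < 1e-12:
        raise GeometryError("zero-length vector in angle computation")
    c = np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


def dihedral_deg(p0, p1, p2, p3) -> float:
    """Signed torsion p0-p1-p2-p3 in (-180, 180]."""
    b0 = _as_xyz(p0) - _as_xyz(p1)
    b1 = _as_xyz(p2) - _as_xyz(p1)
    b2 = _as_xyz(p3) - _as_xyz(p2)
    n1 = np.linalg.norm(b1)
    if n1 < 1e-12:
        raise GeometryError("degenerate central bond in dihedral")
    b1 = b1 / n1
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    return float(np.degrees(np.arctan2(y, x)))


def place_atom(a, b, c, dist: float, angle: float, dihedral: float) -> np.ndarray:
    """Place a new atom X bonded to ``c``.

    The result satisfies |X - c| = dist, angle(X, c, b) = angle and
    torsion(X, c, b, a) = dihedral (NeRF construction).
    """
    a, b, c = _as_xyz(a), _as_xyz(b), _as_xyz(c)
    ang = np.radians(angle)
    dih = np.radians(dihedral)
    bc = c - b
    nbc = np.linalg.norm(bc)
    if nbc < 1e-9:
        raise GeometryError("coincident reference atoms b and c")
    bc = bc / nbc
    ab = b - a
    n = np.cross(ab, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-9:
        raise GeometryError("collinear reference atoms in place_atom")
    n = n / nn
    m = np.cross(n, bc)
    d = np.array(
        [
            -dist * np.cos(ang),
            dist * np.sin(ang) * np.cos(dih),
            dist * np.sin(ang) * np.sin(dih),
        ]
    )
    return c + d[0] * bc + d[1] * m + d[2] * n


def kabsch(src: np.ndarray, dst: np.ndarray) -> RigidTransform:
    """Least-squares proper rigid superposition of src onto dst."""
    src = _as_xyz(src)
    dst = _as_xyz(dst)
    sc = src.mean(axis=0)
    dc = dst.mean(axis=0)
    H = (src - sc).T @ (dst - dc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    return RigidTransform(R, dc - R @ sc)


def superpose_frames(src, dst, tol: float = 0.05) -> RigidTransform:
    """Rigid transform mapping three ``src`` points onto three ``dst`` points.

    The triples must form congruent, non-degenerate triangles (pairwise
    distances agree within ``tol`` angstroms); pass a larger ``tol`` for
    distorted experimental geometry.
    """
    src = _as_xyz(src).reshape(3, 3)
    dst = _as_xyz(dst).reshape(3, 3)
    for pts, which in ((src, "src"), (dst, "dst")):
        v1 = pts[1] - pts[0]
        v2 = pts[2] - pts[0]
        if np.linalg.norm(np.cross(v1, v2)) < 1e-6:
            raise GeometryError(f"collinear {which} points in superpose_frames")
    if tol is not None:
        for i in range(3):
            for j in range(i + 1, 3):
                ds = np.linalg.norm(src[i] - src[j])
                dd = np.linalg.norm(dst[i] - dst[j])
                if abs(ds - dd) > tol:
                    raise GeometryError(
                        f"non-congruent triangles: |src {i}-{j}| = {ds:.4f}, "
                        f"|dst {i}-{j}| = {dd:.4f}"
                    )
    return kabsch(src, dst)


def rotation_about_axis(axis, angle: float) -> np.ndarray:
    """Rotation matrix about a (normalized) axis by ``angle`` degrees."""
    ax = _as_xyz(axis)
    n = np.linalg.norm(ax)
    if n < 1e-12:
        raise GeometryError("zero-length rotation axis")
    ax = ax / n
    th = np.radians(angle)
    K = np.array(
        [[0, -ax[2], ax[1]], [ax[2], 0, -ax[0]], [-ax[1], ax[0], 0]]
    )
    return np.eye(3) + np.sin(th) * K + (1 - np.cos(th)) * (K @ K)


# ---------------------------------------------------------------------------
# hydrogen-bond geometry


@dataclass(frozen=True)
class HBondParams:
    """Geometric window and scoring ramp for a hydrogen bond.

    ``d`` is the donor-heavy to acceptor-heavy distance, ``theta`` the donor
    angle D-H...A (at the hydrogen), ``psi`` the acceptor angle base-A...H
    (at the acceptor heavy atom).  The score is the negated product of linear
    ramps in d and theta, peaking at (ideal_d, ideal_theta) and reaching zero
    on the window boundary.
    """

    d_min: float = 2.6
    d_max: float = 3.2
    theta_min: float = 120.0
    psi_min: float = 90.0
    ideal_d: float = 2.8
    ideal_theta: float = 180.0
    weight: float = 1.0

    def __post_init__(self):
        if not (0 < self.d_min < self.ideal_d < self.d_max):
            raise ValidationError("require 0 < d_min < ideal_d < d_max")
        if not (0 < self.theta_min <= self.ideal_theta <= 180.0):
            raise ValidationError("require 0 < theta_min <= ideal_theta <= 180")
        if not (0 <= self.psi_min <= 180.0):
            raise ValidationError("psi_min out of range")

    def to_dict(self) -> dict:
        return {
            "d_min": self.d_min,
            "d_max": self.d_max,
            "theta_min": self.theta_min,
            "psi_min": self.psi_min,
            "ideal_d": self.ideal_d,
            "ideal_theta": self.ideal_theta,
            "weight": self.weight,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HBondParams":
        return cls(**d)


def _ramp(x: float, lo: float, peak: float, hi: float) -> float:
    if x <= lo or x >= hi:
        return 0.0
    if x <= peak:
        return (x - lo) / (peak - lo)
    return (hi - x) / (hi - peak)


def hbond_eval(
    donor_heavy,
    donor_h,
    acceptor_heavy,
    acceptor_bases,
    params: HBondParams | None = None,
):
    """Test and score one putative hydrogen bond.

    ``acceptor_bases`` may be a single base atom or an (N, 3) array of
    chemically equivalent base atoms; the most favourable (largest) acceptor
    angle over the bases is used, which makes the test symmetric under
    relabeling of equivalent lone-pair bases.

    Returns ``(ok, score)`` with score <= 0 when ok and exactly 0 otherwise.
    """
    params = params or HBondParams()
    D = _as_xyz(donor_heavy)
    H = _as_xyz(donor_h)
    A = _as_xyz(acceptor_heavy)
    bases = _as_xyz(acceptor_bases)
    if bases.ndim == 1:
        bases = bases[None, :]
    d = float(np.linalg.norm(D - A))
    if d < 0.5:
        raise GeometryError("overlapping donor and acceptor atoms")
    # tiny guard bands keep poses sampled exactly on the window boundary
    # stable under ~1e-8 A round-trips through a rigid transform
    eps_d, eps_a = 1e-6, 1e-4
    if not (params.d_min - eps_d <= d <= params.d_max + eps_d):
        return False, 0.0
    theta = angle_deg(D, H, A)
    if theta < params.theta_min - eps_a:
        return False, 0.0
    psi = max(angle_deg(b, A, H) for b in bases)
    if psi < params.psi_min - eps_a:
        return False, 0.0
    # theta ramp: window [theta_min, 180]; mirror above ideal_theta is empty
    # when ideal_theta == 180, so use a one-sided ramp there.
    if params.ideal_theta >= 180.0:
        ft = (theta - params.theta_min) / (180.0 - params.theta_min) if theta > params.theta_min else 0.0
        ft = min(ft, 1.0)
    else:
        ft = _ramp(theta, params.theta_min, params.ideal_theta, 2 * params.ideal_theta - params.theta_min)
    fd = _ramp(d, params.d_min, params.ideal_d, params.d_max)
    return True, -params.weight * fd * ft


# ---------------------------------------------------------------------------
# grid quantization


def snap_to_grid(point, spacing: float) -> tuple[int, int, int]:
    """Integer grid cell of a point: round(x / spacing), half away from zero."""
    if spacing <= 0:
        raise ValueError("grid spacing must be positive")
    p = _as_xyz(point)
    q = p / spacing
    idx = np.sign(q) * np.floor(np.abs(q) + 0.5)
    return tuple(int(v) for v in idx)


def grid_key(points: np.ndarray, spacing: float) -> tuple:
    """Tuple of grid cells for one or more reference atoms."""
    pts = _as_xyz(points)
    if pts.ndim == 1:
        pts = pts[None, :]
    return tuple(snap_to_grid(p, spacing) for p in pts)


def local_frame(coords: np.ndarray) -> RigidTransform:
    """Right-handed frame from the first three non-collinear points.

    Returns the transform mapping world coordinates into the local frame
    (origin at the first point, x toward the second, the third in the
    xy-half-plane with positive y).
    """
    pts = _as_xyz(coords)
    if pts.ndim != 2 or len(pts) < 3:
        raise GeometryError("need at least three points to define a frame")
    a0 = pts[0]
    ex = None
    for i in range(1, len(pts)):
        v = pts[i] - a0
        if np.linalg.norm(v) > 1e-6:
            ex = v / np.linalg.norm(v)
            i_ex = i
            break
    if ex is None:
        raise GeometryError("all points coincide; no frame")
    ez = None
    for j in range(1, len(pts)):
        if j == i_ex:
            continue
        w = pts[j] - a0
        n = np.cross(ex, w)
        if np.linalg.norm(n) > 1e-6:
            ez = n / np.linalg.norm(n)
            break
    if ez is None:
        raise GeometryError("points are collinear; no frame")
    ey = np.cross(ez, ex)
    R = np.stack([ex, ey, ez])  # rows: world -> local rotation
    return RigidTransform(R, -R @ a0)


def canonicalize_coords(coords: np.ndarray, ndigits: int = 6) -> np.ndarray:
    """Express coordinates in their own local frame, rounded to ``ndigits``.

    Two inputs that differ only by a global rigid motion map to identical
    arrays (up to the rounding precision), which is what makes every
    downstream count exactly invariant under rigid motions of the input.
    """
    frame = local_frame(coords)
    return np.round(frame.apply(coords), ndigits)
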