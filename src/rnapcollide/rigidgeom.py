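"""Rigid-body superposition and axis-angle / screw decomposition.

The superposition is the classic least-squares (Kabsch) solution via SVD
with a determinant correction so that reflections are never returned.
Rotations are summarised as an axis, an angle in degrees in [0, 180], and a
point on the screw axis, which together reproduce how domain motions are
conventionally reported for multi-subunit enzymes.
"""

from __future__ import annotations

import dataclasses

import numpy as np

__all__ = [
    "RigidTransform",
    "AxisAngle",
    "kabsch_superpose",
    "rotation_to_axis_angle",
    "axis_angle_to_rotation",
    "apply_transform",
]


class GeometryError(ValueError):
    """Degenerate geometry (too few or collinear points) or bad input."""


@dataclasses.dataclass(frozen=True)
class RigidTransform:
    rotation: np.ndarray  # 3x3, proper orthonormal
    translation: np.ndarray  # 3-vector, Å
    rmsd: float = 0.0  # fit residual, Å

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if R.shape != (3, 3) or t.shape != (3,):
            raise GeometryError("rotation must be 3x3 and translation a 3-vector")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-8):
            raise GeometryError("rotation is not orthonormal")
        if np.linalg.det(R) < 0:
            raise GeometryError("rotation has negative determinant (reflection)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    def compose(self, first: "RigidTransform") -> "RigidTransform":
        """Transform equivalent to applying ``first`` then ``self``."""
        return RigidTransform(
            self.rotation @ first.rotation,
            self.rotation @ first.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    @staticmethod
    def identity() -> "RigidTransform":
        return RigidTransform(np.eye(3), np.zeros(3))


@dataclasses.dataclass(frozen=True)
class AxisAngle:
    axis: np.ndarray  # unit 3-vector
    angle: float  # degrees, in [0, 180]
    point_on_axis: np.ndarray  # Å; screw-axis anchor

    def __post_init__(self) -> None:
        axis = np.asarray(self.axis, dtype=float)
        point = np.asarray(self.point_on_axis, dtype=float)
        if abs(np.linalg.norm(axis) - 1.0) > 1e-9:
            raise GeometryError("axis must be a unit vector")
        if self.angle < 0:
            raise GeometryError("angle must be non-negative")
        object.__setattr__(self, "axis", axis)
        object.__setattr__(self, "point_on_axis", point)


def kabsch_superpose(mobile: np.ndarray, target: np.ndarray) -> RigidTransform:
    """Least-squares rigid transform mapping ``mobile`` onto ``target``.

    Both arguments are (N, 3) arrays in matching order, N >= 3 and not
    collinear.  The returned transform minimises the RMSD of
    ``R @ mobile + t`` against ``target``; reflections are excluded.
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(target, dtype=float)
    if P.shape != Q.shape:
        raise GeometryError(f"length mismatch: {P.shape} vs {Q.shape}")
    if P.ndim != 2 or P.shape[1] != 3 or P.shape[0] < 3:
        raise GeometryError("need at least 3 points of dimension 3")

    pc = P.mean(axis=0)
    qc = Q.mean(axis=0)
    P0 = P - pc
    Q0 = Q - qc

    # collinearity check: second singular value of the centred cloud
    sv = np.linalg.svd(P0, compute_uv=False)
    if sv[1] <= 1e-9 * max(sv[0], 1.0):
        raise GeometryError("degenerate geometry: points are collinear")

    H = P0.T @ Q0
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    rmsd = float(np.sqrt(np.mean(np.sum((P0 @ R.T - Q0) ** 2, axis=1))))
    return RigidTransform(R, t, rmsd)


def rotation_to_axis_angle(transform: RigidTransform) -> AxisAngle:
    """Axis, angle (degrees, [0, 180]) and screw-axis point of a transform.

    The angle comes from the trace; the axis from the antisymmetric part,
    or from the +1 eigenvector for angles near 180°.  The axis point is the
    least-squares solution of ``(I - R) p = t_perp`` (the component of the
    translation perpendicular to the axis), i.e. the screw-axis anchor
    closest to the origin.
    """
    R = transform.rotation
    t = transform.translation
    cos_theta = np.clip((np.trace(R) - 1.0) / 2.0, -1.0, 1.0)
    angle = float(np.degrees(np.arccos(cos_theta)))

    if angle < 1e-12:
        return AxisAngle(np.array([0.0, 0.0, 1.0]), 0.0, np.zeros(3))

    v = np.array([R[2, 1] - R[1, 2], R[0, 2] - R[2, 0], R[1, 0] - R[0, 1]])
    if np.linalg.norm(v) > 1e-8:
        axis = v / np.linalg.norm(v)
    else:
        # angle ~ 180°: axis is the eigenvector of R with eigenvalue +1
        w, vec = np.linalg.eigh((R + R.T) / 2.0)
        axis = vec[:, np.argmax(w)]
        axis = axis / np.linalg.norm(axis)

    # screw decomposition: p solves (I - R) p = t - (axis . t) axis
    t_perp = t - np.dot(axis, t) * axis
    A = np.eye(3) - R
    point, *_ = np.linalg.lstsq(A, t_perp, rcond=None)
    # anchor chosen on the axis closest to the origin
    point = point - np.dot(point, axis) * axis
    return AxisAngle(axis, angle, point)


def axis_angle_to_rotation(
    axis: np.ndarray, angle_deg: float, point_on_axis: np.ndarray | None = None
) -> RigidTransform:
    """Rodrigues rotation about an axis through ``point_on_axis`` (default origin)."""
    axis = np.asarray(axis, dtype=float)
    n = np.linalg.norm(axis)
    if n == 0:
        raise GeometryError("zero axis")
    k = axis / n
    theta = np.radians(angle_deg)
    K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    R = np.eye(3) + np.sin(theta) * K + (1 - np.cos(theta)) * (K @ K)
    p = np.zeros(3) if point_on_axis is None else np.asarray(point_on_axis, float)
    t = p - R @ p
    return RigidTransform(R, t)


def apply_transform(positions: np.ndarray, transform: RigidTransform) -> np.ndarray:
    """Apply ``p -> R p + t`` to an (N, 3) array (or a single 3-vector)."""
    pos = np.asarray(positions, dtype=float)
    single = pos.ndim == 1
    pos = np.atleast_2d(pos)
    out = pos @ transform.rotation.T + transform.translation
    return out[0] if single else out
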