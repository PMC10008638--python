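"""Rigid-body math: transforms, Kabsch landmark fitting, Tait-Bryan angles.

All rotations are proper (det = +1); superimposition in this package is
strictly rigid.  Angles are degrees at the API surface (the clinical
relevance threshold is quoted in degrees) and radians internally.  The
Euler sequence is fixed throughout the package as intrinsic
Z(phi) -> Y(theta) -> X(psi), i.e. ``R = Rz(phi) @ Ry(theta) @ Rx(psi)``;
every serialized output records this convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DegenerateGeometryError",
    "EulerAngles",
    "GimbalLockWarning",
    "RigidTransform",
    "SixMeasures",
    "EULER_CONVENTION",
    "euler_from_rotation",
    "kabsch",
    "rotation_from_euler",
    "six_measures",
    "transform_from_six",
]

#: Tait-Bryan sequence used everywhere in this package.
EULER_CONVENTION = "intrinsic Z(phi)-Y(theta)-X(psi), R = Rz@Ry@Rx"

_ORTHO_TOL = 1e-9


class DegenerateGeometryError(ValueError):
    """Point configuration does not determine a unique rigid fit."""


class GimbalLockWarning(UserWarning):
    """theta is at +/-90 deg; phi/psi split is conventional (phi := 0)."""


def _check_rotation(r: np.ndarray, tol: float = 1e-7) -> np.ndarray:
    r = np.asarray(r, dtype=float)
    if r.shape != (3, 3):
        raise ValueError(f"rotation must be 3x3, got {r.shape}")
    if not np.all(np.isfinite(r)):
        raise ValueError("rotation contains non-finite entries")
    if not np.allclose(r.T @ r, np.eye(3), atol=tol):
        raise ValueError("rotation matrix is not orthonormal")
    if np.linalg.det(r) < 0:
        raise ValueError("rotation has det = -1 (reflection); rigid transforms only")
    return r


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid transform p -> R @ p + t, coordinates in millimetres."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "rotation", _check_rotation(self.rotation))
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if not np.all(np.isfinite(t)):
            raise ValueError("translation contains non-finite entries")
        object.__setattr__(self, "translation", t)

    @staticmethod
    def identity() -> "RigidTransform":
        return RigidTransform(np.eye(3), np.zeros(3))

    @staticmethod
    def from_matrix(m: np.ndarray) -> "RigidTransform":
        m = np.asarray(m, dtype=float)
        if m.shape != (4, 4):
            raise ValueError("expected a 4x4 homogeneous matrix")
        return RigidTransform(m[:3, :3], m[:3, 3])

    def matrix(self) -> np.ndarray:
        """4x4 homogeneous form."""
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equivalent to applying ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def invert(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rt, -rt @ self.translation)

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Apply to an (n, 3) array (or a single 3-vector)."""
        p = np.asarray(points, dtype=float)
        single = p.ndim == 1
        p = np.atleast_2d(p)
        if p.shape[0] == 0:
            raise ValueError("empty point list")
        if p.shape[1] != 3:
            raise ValueError("points must be (n, 3)")
        out = p @ self.rotation.T + self.translation
        return out[0] if single else out

    def to_json_dict(self) -> dict:
        return {
            "rotation": self.rotation.tolist(),
            "translation": self.translation.tolist(),
            "euler_convention": EULER_CONVENTION,
        }

    @staticmethod
    def from_json_dict(d: dict) -> "RigidTransform":
        return RigidTransform(np.asarray(d["rotation"]), np.asarray(d["translation"]))


@dataclass(frozen=True)
class EulerAngles:
    """Tait-Bryan angles in degrees.

    phi   : rotation about Z (occlusogingival axis) — mesiodistal rotation
    theta : rotation about Y (mesiodistal axis)     — buccolingual torque
    psi   : rotation about X (buccolingual axis)    — mesiodistal tip
    """

    phi: float
    theta: float
    psi: float
    gimbal_lock: bool = field(default=False, compare=False)


@dataclass(frozen=True)
class SixMeasures:
    """The six signed tooth-movement measures: three angles (deg), three
    translations (mm) along the local anatomical axes."""

    phi: float
    theta: float
    psi: float
    x: float
    y: float
    z: float
    gimbal_lock: bool = field(default=False, compare=False)

    def as_array(self) -> np.ndarray:
        return np.array([self.phi, self.theta, self.psi, self.x, self.y, self.z])


def _rx(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])


def _ry(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])


def _rz(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])


def rotation_from_euler(e: EulerAngles) -> np.ndarray:
    """Rotation matrix Rz(phi) @ Ry(theta) @ Rx(psi), angles in degrees."""
    phi, theta, psi = np.deg2rad([e.phi, e.theta, e.psi])
    if not np.all(np.isfinite([phi, theta, psi])):
        raise ValueError("angles must be finite")
    return _rz(phi) @ _ry(theta) @ _rx(psi)


def euler_from_rotation(r: np.ndarray) -> EulerAngles:
    """Decompose a proper rotation as Rz(phi) @ Ry(theta) @ Rx(psi).

    At gimbal lock (|theta| = 90 deg) only phi - psi (or phi + psi) is
    determined; the convention phi := 0 is applied, a
    :class:`GimbalLockWarning` is issued and the result is flagged.
    """
    r = _check_rotation(r)
    # r[2,0] = -sin(theta)
    s_theta = float(np.clip(-r[2, 0], -1.0, 1.0))
    theta = np.arcsin(s_theta)
    if 1.0 - abs(s_theta) < 1e-7:
        warnings.warn(
            "theta at +/-90 deg: phi set to 0, psi absorbs the free angle",
            GimbalLockWarning,
            stacklevel=2,
        )
        if s_theta > 0:  # theta = +90
            psi = float(np.arctan2(r[0, 1], r[0, 2]))
        else:  # theta = -90
            psi = float(np.arctan2(-r[0, 1], -r[0, 2]))
        phi = 0.0
        return EulerAngles(0.0, float(np.rad2deg(theta)), float(np.rad2deg(psi)),
                           gimbal_lock=True)
    phi = float(np.arctan2(r[1, 0], r[0, 0]))
    psi = float(np.arctan2(r[2, 1], r[2, 2]))
    return EulerAngles(
        float(np.rad2deg(phi)), float(np.rad2deg(theta)), float(np.rad2deg(psi))
    )


def six_measures(t: RigidTransform) -> SixMeasures:
    """Angles from the rotation, translations from the translation column."""
    e = euler_from_rotation(t.rotation)
    x, y, z = t.translation
    return SixMeasures(e.phi, e.theta, e.psi, float(x), float(y), float(z),
                       gimbal_lock=e.gimbal_lock)


def transform_from_six(m: SixMeasures) -> RigidTransform:
    """Inverse of :func:`six_measures`."""
    r = rotation_from_euler(EulerAngles(m.phi, m.theta, m.psi))
    return RigidTransform(r, np.array([m.x, m.y, m.z]))


def kabsch(source: np.ndarray, target: np.ndarray) -> tuple[RigidTransform, float]:
    """Least-squares rigid fit of corresponded point sets (Kabsch/Umeyama).

    Parameters
    ----------
    source, target : (n, 3) arrays of corresponded points, n >= 3.

    Returns
    -------
    (transform, rms) where ``transform.apply(source)`` best matches
    ``target`` in least squares (reflections excluded) and ``rms`` is the
    root-mean-square residual in mm.

    Raises
    ------
    DegenerateGeometryError
        If the source points are (near-)collinear: the rotation about the
        line is then unresolvable.  Tolerance: second/first singular value
        of the centred source < 1e-6.
    """
    src = np.asarray(source, dtype=float)
    tgt = np.asarray(target, dtype=float)
    if src.ndim != 2 or src.shape[1] != 3 or src.shape != tgt.shape:
        raise ValueError("source and target must be matching (n, 3) arrays")
    n = src.shape[0]
    if n < 3:
        raise ValueError(f"need at least 3 corresponded points, got {n}")
    c_src = src.mean(axis=0)
    c_tgt = tgt.mean(axis=0)
    p = src - c_src
    q = tgt - c_tgt
    sv = np.linalg.svd(p, compute_uv=False)
    if sv[1] / sv[0] < 1e-6:
        raise DegenerateGeometryError(
            "source points are collinear; rotation about the line is unresolvable"
        )
    h = p.T @ q
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    t = c_tgt - r @ c_src
    transform = RigidTransform(r, t)
    resid = transform.apply(src) - tgt
    rms = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return transform, rms
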