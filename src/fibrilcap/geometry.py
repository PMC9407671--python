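"""Rigid-body geometry primitives: transforms, Kabsch superposition, dihedrals.

All coordinates are in Angstrom, all angles in degrees unless noted.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DockError

__all__ = [
    "RigidTransform",
    "kabsch_superpose",
    "dihedral",
    "place_atom",
]


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion x -> R @ x + t."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if abs(np.linalg.det(R) - 1.0) > 1e-6:
            raise ValueError("rotation must be proper (det = +1)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self after other: (self ∘ other)(x) = self(other(x))."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        Rinv = self.rotation.T
        return RigidTransform(Rinv, -Rinv @ self.translation)


def kabsch_superpose(mobile: np.ndarray, target: np.ndarray) -> tuple[RigidTransform, float]:
    """Least-squares optimal superposition of ``mobile`` onto ``target``.

    Returns the proper rigid transform T minimizing ||T(mobile) - target||
    and the post-fit rmsd. Reflections are never returned.

    Raises
    ------
    DockError
        If the point sets differ in size, have fewer than 3 points, or are
        degenerate (collinear / coincident) so the rotation is ill-defined.
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(target, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise DockError("point sets must both be (n, 3) with equal n")
    n = P.shape[0]
    if n < 3:
        raise DockError("need at least 3 points for superposition")
    pc = P.mean(axis=0)
    qc = Q.mean(axis=0)
    P0 = P - pc
    Q0 = Q - qc
    H = P0.T @ Q0
    U, S, Vt = np.linalg.svd(H)
    # Degenerate if two smallest singular values vanish (collinear points).
    scale = max(S[0], 1e-12)
    if S[1] / scale < 1e-9:
        raise DockError("degenerate (collinear or coincident) point set")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    transform = RigidTransform(R, t)
    delta = transform.apply(P) - Q
    rmsd = float(np.sqrt((delta**2).sum() / n))
    return transform, rmsd


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees, in (-180, 180]."""
    b0 = np.asarray(p1) - np.asarray(p0)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = float(n1 @ n2)
    y = float(m1 @ n2)
    ang = np.degrees(np.arctan2(y, x))
    if ang <= -180.0:
        ang += 360.0
    return float(ang)


def place_atom(a, b, c, bond: float, angle: float, torsion: float) -> np.ndarray:
    """Place atom d so |cd| = bond, angle(b,c,d) = angle, dihedral(a,b,c,d) = torsion.

    The natural-extension (NeRF) construction used for building backbones
    from internal coordinates. Angles in degrees.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    c = np.asarray(c, dtype=float)
    ang = np.radians(angle)
    tor = np.radians(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = bond * np.array(
        [-np.cos(ang), np.sin(ang) * np.cos(tor), -np.sin(ang) * np.sin(tor)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n
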