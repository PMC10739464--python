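"""Low-level 3D geometry: rigid-body superposition and internal-coordinate
atom placement.

These primitives back the conformer engine and the L-RMSD evaluation:

* :func:`kabsch` — least-squares rigid fit (rotation + translation, proper
  rotation only, no scaling/reflection) of one point set onto another.
* :func:`place_atom` — NeRF (natural extension reference frame) placement of
  an atom from three reference atoms plus bond length, bond angle and
  torsion, used to grow peptide backbones residue by residue.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

# Ideal backbone internal coordinates (Å, degrees); standard Engh–Huber-style
# values used for de novo residue placement.
IDEAL_BOND = {
    ("N", "CA"): 1.458,
    ("CA", "C"): 1.525,
    ("C", "N"): 1.329,   # peptide bond to the next residue
    ("C", "O"): 1.231,
    ("CA", "CB"): 1.530,
}
IDEAL_ANGLE = {
    ("N", "CA", "C"): 111.2,
    ("CA", "C", "N"): 116.2,
    ("C", "N", "CA"): 121.7,
    ("CA", "C", "O"): 120.8,
    ("N", "CA", "CB"): 110.5,
}
OMEGA_TRANS = 180.0


@dataclass(frozen=True)
class Transform:
    """Rigid-body transform ``y = R @ x + t``."""

    rotation: np.ndarray   # (3, 3), proper rotation
    translation: np.ndarray  # (3,)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, dtype=float)
        return coords @ self.rotation.T + self.translation

    @staticmethod
    def identity() -> "Transform":
        return Transform(np.eye(3), np.zeros(3))


def kabsch(mobile: np.ndarray, target: np.ndarray) -> tuple[Transform, float]:
    """Least-squares fit of ``mobile`` onto ``target`` (paired points).

    Returns the rigid :class:`Transform` and the post-fit RMSD. The rotation
    is constrained to a proper rotation (det = +1); reflections are never
    produced.
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(target, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("kabsch requires two equally-shaped (n, 3) arrays")
    if len(P) < 3:
        raise ValueError("kabsch requires at least 3 paired points")
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    H = (P - cp).T @ (Q - cq)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cq - R @ cp
    tr = Transform(R, t)
    rmsd = float(np.sqrt(np.mean(np.sum((tr.apply(P) - Q) ** 2, axis=1))))
    return tr, rmsd


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ValueError("zero-length vector in geometry construction")
    return v / n


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               length: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom D bonded to C with |CD| = ``length``, angle B-C-D =
    ``angle_deg`` and torsion A-B-C-D = ``torsion_deg`` (NeRF construction).
    """
    theta = np.deg2rad(angle_deg)
    chi = np.deg2rad(torsion_deg - 180.0)
    w = _unit(np.asarray(c, float) - b)
    n = _unit(np.cross(np.asarray(b, float) - a, w))
    m = np.cross(n, w)
    d_local = length * np.array([-np.cos(theta),
                                 np.sin(theta) * np.cos(chi),
                                 np.sin(theta) * np.sin(chi)])
    return c + d_local[0] * w + d_local[1] * m + d_local[2] * n


def dihedral(p0, p1, p2, p3) -> float:
    """Signed torsion angle p0-p1-p2-p3 in degrees, in (-180, 180]."""
    b0 = np.asarray(p1, float) - p0
    b1 = np.asarray(p2, float) - p1
    b2 = np.asarray(p3, float) - p2
    b1u = _unit(b1)
    v = b0 - np.dot(b0, b1u) * b1u
    w = b2 - np.dot(b2, b1u) * b1u
    x = np.dot(v, w)
    y = np.dot(np.cross(b1u, v), w)
    return float(np.degrees(np.arctan2(y, x)))


def bond_angle(p0, p1, p2) -> float:
    """Bond angle p0-p1-p2 in degrees."""
    u = _unit(np.asarray(p0, float) - p1)
    v = _unit(np.asarray(p2, float) - p1)
    return float(np.degrees(np.arccos(np.clip(np.dot(u, v), -1.0, 1.0))))
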