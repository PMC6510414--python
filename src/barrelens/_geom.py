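"""Internal geometry helpers: dihedrals, atom placement, rigid-body fits."""

from __future__ import annotations

import math

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = ["dihedral", "place_atom", "kabsch", "apply_fit"]


def _cross3(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    # inline 3-vector cross product: np.cross has large call overhead
    return np.array(
        [
            a[1] * b[2] - a[2] * b[1],
            a[2] * b[0] - a[0] * b[2],
            a[0] * b[1] - a[1] * b[0],
        ]
    )


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in radians (IUPAC sign convention)."""
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = _cross3(b0, b1)
    n2 = _cross3(b1, b2)
    m1 = _cross3(n1, b1 / math.sqrt(float(b1 @ b1)))
    x = float(n1 @ n2)
    y = float(m1 @ n2)
    return math.atan2(y, x)


def place_atom(
    a: np.ndarray, b: np.ndarray, c: np.ndarray,
    bond: float, angle: float, torsion: float,
) -> np.ndarray:
    """NeRF placement of atom d bonded to c.

    ``bond`` = |c-d|, ``angle`` = angle(b, c, d) and ``torsion`` =
    dihedral(a, b, c, d), angles in radians.
    """
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = _cross3(b - a, bc)
    n /= np.linalg.norm(n)
    m = _cross3(n, bc)
    d_local = np.array(
        [
            -bond * np.cos(angle),
            bond * np.sin(angle) * np.cos(torsion),
            bond * np.sin(angle) * np.sin(torsion),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def kabsch(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid fit of ``mobile`` onto ``target`` (proper rotation).

    Returns (R, t, rmsd) with the fitted coordinates given by
    ``mobile @ R.T + t``.  Reflections are never produced.
    """
    mobile = np.asarray(mobile, float)
    target = np.asarray(target, float)
    cm = mobile.mean(axis=0)
    ct = target.mean(axis=0)
    rot, rssd = Rotation.align_vectors(target - ct, mobile - cm)
    R = rot.as_matrix()
    t = ct - cm @ R.T
    rmsd = rssd / np.sqrt(len(mobile))
    return R, t, float(rmsd)


def apply_fit(coords: np.ndarray, R: np.ndarray, t: np.ndarray) -> np.ndarray:
    return coords @ R.T + t


def pairwise_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Best-fit RMSD between two coordinate sets of identical atom order."""
    return kabsch(a, b)[2]
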