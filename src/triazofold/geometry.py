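"""Shared Cartesian geometry kernel.

Signed dihedrals follow the IUPAC convention: 0 for an eclipsed (cis)
arrangement, sign by the right-hand rule looking down the central bond,
reported in degrees on the half-open interval (-180, 180].
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "dihedral",
    "bond_angle",
    "place_atom",
    "kabsch",
    "wrap_angle",
]


def wrap_angle(deg: float | np.ndarray) -> float | np.ndarray:
    """Wrap an angle in degrees into (-180, 180]."""
    wrapped = -np.remainder(-np.asarray(deg, dtype=float) + 180.0, 360.0) + 180.0
    if np.ndim(wrapped) == 0:
        return float(wrapped)
    return wrapped


def dihedral(p1, p2, p3, p4) -> float:
    """Signed dihedral angle (degrees) of four points about the p2-p3 bond.

    Antisymmetric under reversal of the atom order.  Raises ``ValueError``
    for a zero-length central bond; returns ``nan`` when either terminal
    point is collinear with the central bond (torsion undefined).
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    nb2 = np.linalg.norm(b2)
    if nb2 < 1e-12:
        raise ValueError("zero-length central bond: dihedral undefined")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
        return float("nan")
    m = np.cross(n1, b2 / nb2)
    x = float(np.dot(n1, n2))
    y = -float(np.dot(m, n2))
    ang = np.degrees(np.arctan2(y, x))
    return wrap_angle(ang)


def bond_angle(p1, p2, p3) -> float:
    """Angle p1-p2-p3 in degrees, in [0, 180]."""
    p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p1, p2, p3))
    v1 = p1 - p2
    v2 = p3 - p2
    c = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def place_atom(a, b, c, bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place a fourth point D from three reference points (NeRF).

    The returned point satisfies |CD| = bond, angle(B, C, D) = angle_deg and
    dihedral(A, B, C, D) = torsion_deg.
    """
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    theta = np.radians(angle_deg)
    phi = np.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * np.cos(theta),
            bond * np.sin(theta) * np.cos(phi),
            bond * np.sin(theta) * np.sin(phi),
        ]
    )
    frame = np.column_stack([bc, m, n])
    return c + frame @ d_local


def kabsch(mobile: np.ndarray, reference: np.ndarray, weights=None):
    """Optimal rigid superposition of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` best fits ``reference`` in the
    least-squares sense.  Reflections are excluded via the determinant
    correction, so the rotation is always proper.

    Raises ``ValueError`` for fewer than 3 points or an all-collinear set.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise ValueError(
            f"point sets differ in shape: {mobile.shape} vs {reference.shape}"
        )
    if mobile.shape[0] < 3:
        raise ValueError("need at least 3 matched points for superposition")
    if weights is None:
        w = np.ones(mobile.shape[0])
    else:
        w = np.asarray(weights, dtype=float)
    wsum = w.sum()
    mu_m = (w[:, None] * mobile).sum(axis=0) / wsum
    mu_r = (w[:, None] * reference).sum(axis=0) / wsum
    x = mobile - mu_m
    y = reference - mu_r
    # a collinear point set leaves the rotation under-determined
    if (
        np.linalg.matrix_rank(x, tol=1e-9) < 2
        or np.linalg.matrix_rank(y, tol=1e-9) < 2
    ):
        raise ValueError("all points collinear: superposition ill-defined")
    h = (w[:, None] * x).T @ y
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    fitted = x @ rot.T
    resid = fitted - y
    rmsd = float(np.sqrt((w * (resid**2).sum(axis=1)).sum() / wsum))
    trans = mu_r - mu_m @ rot.T
    return rot, trans, rmsd
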