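"""Low-level vector geometry shared across modules.

Everything here works in plain numpy arrays: coordinates in Å, angles in
degrees unless a name says otherwise.  The signed-dihedral convention is
IUPAC (clockwise positive looking B→C), reported in [-180, 180) with the
trans geometry mapped to the -180 boundary.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "wrap_degrees",
    "dihedral",
    "place_atom",
    "internal_coords",
    "kabsch",
]


def wrap_degrees(angle):
    """Wrap angles (degrees) into [-180, 180); +180 maps to -180."""
    return (np.asarray(angle, dtype=float) + 180.0) % 360.0 - 180.0


def dihedral(p0, p1, p2, p3):
    """Signed dihedral angle(s) in degrees, range [-180, 180).

    Accepts single points (shape (3,)) or stacked frames (..., 3) and
    broadcasts over leading axes.
    """
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0 = p0 - p1  # points away from the bond so syn (cis) comes out 0
    b1 = p2 - p1
    b2 = p3 - p2
    b1n = np.linalg.norm(b1, axis=-1, keepdims=True)
    if np.any(b1n < 1e-12):
        raise ValueError("dihedral undefined: central atoms coincide")
    b1u = b1 / b1n
    # components perpendicular to the central bond
    v = b0 - np.sum(b0 * b1u, axis=-1, keepdims=True) * b1u
    w = b2 - np.sum(b2 * b1u, axis=-1, keepdims=True) * b1u
    x = np.sum(v * w, axis=-1)
    y = np.sum(np.cross(b1u, v) * w, axis=-1)
    return wrap_degrees(np.degrees(np.arctan2(y, x)))


def place_atom(a, b, c, bond, angle_deg, torsion_deg):
    """NeRF placement: position atom D bonded to ``c``.

    ``bond`` is the C-D distance (Å), ``angle_deg`` the B-C-D angle and
    ``torsion_deg`` the A-B-C-D dihedral.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    c = np.asarray(c, float)
    ang = np.radians(angle_deg)
    tor = np.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-10:
        # reference triple colinear: torsion ill-defined, pick any normal
        helper = np.array([1.0, 0.0, 0.0])
        if abs(np.dot(helper, bc)) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        n = np.cross(helper, bc)
        nn = np.linalg.norm(n)
    n /= nn
    m = np.cross(n, bc)
    # signs chosen so that dihedral(a, b, c, placed) == torsion_deg exactly
    d_local = np.array(
        [
            -bond * np.cos(ang),
            bond * np.sin(ang) * np.cos(tor),
            bond * np.sin(ang) * np.sin(tor),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def internal_coords(a, b, c, d):
    """Inverse of :func:`place_atom`: (bond, angle°, torsion°) of d w.r.t. (a,b,c)."""
    a, b, c, d = (np.asarray(p, float) for p in (a, b, c, d))
    bond = float(np.linalg.norm(d - c))
    v1 = b - c
    v2 = d - c
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    angle = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
    tors = float(dihedral(a, b, c, d))
    return bond, angle, tors


def kabsch(reference, mobile, weights=None):
    """Optimal weighted superposition of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` best fits ``reference`` in the
    weighted least-squares sense.  The rotation is proper (det = +1);
    reflections are corrected by flipping the smallest singular direction.
    """
    P = np.asarray(reference, float)
    Q = np.asarray(mobile, float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("coordinate sets must both be (n, 3)")
    n = P.shape[0]
    if n < 3:
        raise ValueError("need at least 3 atoms for superposition")
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weights, float)
        if w.shape != (n,) or np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be non-negative with positive sum")
        w = w / w.sum()
    pc = (w[:, None] * P).sum(axis=0)
    qc = (w[:, None] * Q).sum(axis=0)
    P0 = P - pc
    Q0 = Q - qc
    H = (w[:, None] * Q0).T @ P0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    fitted = Q0 @ R.T
    rmsd = float(np.sqrt(np.sum(w[:, None] * (fitted - P0) ** 2)))
    t = pc - qc @ R.T
    return R, t, rmsd
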