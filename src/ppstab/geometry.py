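"""Internal-coordinate atom placement and ideal peptide geometry.

Bond lengths/angles are the standard ideal values for a trans peptide:
N-CA 1.46 A, CA-C 1.52 A, C-N 1.33 A, C=O 1.23 A, CA-CB 1.53 A.
"""

from __future__ import annotations

import numpy as np

# ideal backbone internal coordinates
BOND_N_CA = 1.46
BOND_CA_C = 1.52
BOND_C_N = 1.33
BOND_C_O = 1.23
BOND_CA_CB = 1.53
ANGLE_N_CA_C = 111.0
ANGLE_CA_C_N = 116.6
ANGLE_C_N_CA = 121.9
ANGLE_CA_C_O = 120.5
TETRAHEDRAL = 109.47

# backbone dihedrals per conformation (phi, psi), degrees
CONFORMATIONS = {
    "extended": (-140.0, 135.0),
    "helical": (-57.0, -47.0),
}
OMEGA_TRANS = 180.0


def unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ValueError("zero-length vector")
    return v / n


def place_atom(
    a: np.ndarray, b: np.ndarray, c: np.ndarray,
    bond: float, angle_deg: float, dihedral_deg: float,
) -> np.ndarray:
    """Place atom D from reference atoms A, B, C.

    D is at distance ``bond`` from C, with angle B-C-D = ``angle_deg`` and
    dihedral A-B-C-D = ``dihedral_deg`` (NeRF construction).
    """
    angle = np.deg2rad(angle_deg)
    dihedral = np.deg2rad(dihedral_deg)
    bc = unit(c - b)
    n = unit(np.cross(b - a, bc))
    m = np.cross(n, bc)
    d_local = bond * np.array(
        [-np.cos(angle),
         np.sin(angle) * np.cos(dihedral),
         np.sin(angle) * np.sin(dihedral)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle in degrees."""
    b0 = p1 - p0
    b1 = unit(p2 - p1)
    b2 = p3 - p2
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    return float(np.rad2deg(np.arctan2(y, x)))


def angle(p0, p1, p2) -> float:
    """Bond angle at p1, degrees."""
    u, v = unit(p0 - p1), unit(p2 - p1)
    return float(np.rad2deg(np.arccos(np.clip(np.dot(u, v), -1.0, 1.0))))


def place_cbeta(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Idealized Cbeta: 1.53 A from CA, tetrahedral to N and C, L chirality.

    The direction is solved exactly from the actual N-CA-C geometry: equal
    angles of 109.47 deg to both backbone neighbours, with the
    out-of-plane component chosen so that the signed volume
    det[N-CA, C-CA, CB-CA] is positive (L-amino acids).
    """
    e1 = unit(n - ca)
    e2 = unit(c - ca)
    cos_t = np.cos(np.deg2rad(TETRAHEDRAL))
    bisect = e1 + e2
    # direction = alpha*(e1+e2) + beta*(e1 x e2); dot with e1 gives alpha
    dot12 = np.dot(e1, e2)
    alpha = cos_t / (1.0 + dot12)
    perp = np.cross(e1, e2)
    in_plane = alpha * bisect
    rem = 1.0 - np.dot(in_plane, in_plane)
    if rem < 0:
        raise ValueError("degenerate backbone geometry for Cbeta placement")
    beta = np.sqrt(rem / np.dot(perp, perp))
    direction = in_plane + beta * perp  # +beta gives L chirality
    return ca + BOND_CA_CB * direction


def kabsch(mobile: np.ndarray, reference: np.ndarray):
    """Least-squares proper rigid superposition of point sets.

    Returns ``(R, t, rmsd)`` with ``x' = R @ x + t`` mapping mobile onto
    reference; det(R) = +1 always (mirror solutions rejected).
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(reference, dtype=float)
    if P.shape != Q.shape:
        raise ValueError(f"point count mismatch: {P.shape} vs {Q.shape}")
    if P.shape[0] < 3:
        raise ValueError("need at least 3 points for superposition")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - pc, Q - qc
    if np.allclose(P0, 0) or np.allclose(Q0, 0):
        raise ValueError("degenerate (zero-spread) point set")
    H = P0.T @ Q0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    diff = (P0 @ R.T) - Q0
    rmsd = float(np.sqrt((diff ** 2).sum() / P.shape[0]))
    return R, t, rmsd
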