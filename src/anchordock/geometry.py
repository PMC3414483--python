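"""Low-level 3-D construction utilities.

Everything downstream (template threading, rotamer placement, the synthetic
groove) builds coordinates through the natural-extension reference frame
(NeRF) primitive in this module, so ideal bond lengths/angles enter in one
place only.  All angles are in degrees at the API surface and converted
internally.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "nerf_place",
    "bond_angle",
    "dihedral",
    "build_backbone",
    "ALPHA_HELIX",
    "BETA_STRAND",
]

# canonical backbone internal coordinates (Engh/Huber-style ideal values)
N_CA = 1.458
CA_C = 1.525
C_N = 1.329
C_O = 1.231
ANG_N_CA_C = 111.2
ANG_CA_C_N = 116.2
ANG_C_N_CA = 121.7
ANG_CA_C_O = 120.8

# (phi, psi) presets
ALPHA_HELIX = (-57.0, -47.0)
BETA_STRAND = (-130.0, 135.0)


def nerf_place(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle: float, torsion: float) -> np.ndarray:
    """Place atom D given three reference atoms.

    D is bonded to ``c`` with length ``bond``, makes angle(b, c, D) =
    ``angle`` and dihedral(a, b, c, D) = ``torsion`` (degrees).
    """
    ang = np.deg2rad(angle)
    tor = np.deg2rad(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-10:
        raise ValueError("collinear reference atoms in NeRF placement")
    n /= nn
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * np.cos(ang),
        bond * np.sin(ang) * np.cos(tor),
        -bond * np.sin(ang) * np.sin(tor),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def bond_angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a-b-c in degrees."""
    u = a - b
    v = c - b
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def dihedral(a: np.ndarray, b: np.ndarray, c: np.ndarray, d: np.ndarray) -> float:
    """Signed dihedral a-b-c-d in degrees, in (-180, 180]."""
    b1 = b - a
    b2 = c - b
    b3 = d - c
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m = np.cross(n1, b2 / np.linalg.norm(b2))
    x = np.dot(n1, n2)
    y = np.dot(m, n2)
    ang = float(np.degrees(np.arctan2(y, x)))
    return 180.0 if ang == -180.0 else ang


def build_backbone(phi_psi: list[tuple[float, float]],
                   omega: float = 180.0) -> list[dict[str, np.ndarray]]:
    """Build an ideal-geometry backbone (N, CA, C, O per residue).

    ``phi_psi`` gives one (phi, psi) pair per residue; phi of the first
    residue and psi of the last only orient terminal atoms.  The chain is
    built in an arbitrary local frame; callers rigidly transform it into
    place afterwards.
    """
    n_res = len(phi_psi)
    if n_res < 1:
        raise ValueError("need at least one residue")
    residues: list[dict[str, np.ndarray]] = []
    # seed frame for residue 0
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([N_CA, 0.0, 0.0])
    ang = np.deg2rad(ANG_N_CA_C)
    c0 = ca0 + CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
    residues.append({"N": n0, "CA": ca0, "C": c0})
    for i in range(1, n_res):
        prev = residues[-1]
        psi_prev = phi_psi[i - 1][1]
        n_i = nerf_place(prev["N"], prev["CA"], prev["C"],
                         C_N, ANG_CA_C_N, psi_prev)
        ca_i = nerf_place(prev["CA"], prev["C"], n_i,
                          N_CA, ANG_C_N_CA, omega)
        c_i = nerf_place(prev["C"], n_i, ca_i,
                         CA_C, ANG_N_CA_C, phi_psi[i][0])
        residues.append({"N": n_i, "CA": ca_i, "C": c_i})
    # carbonyl oxygens: trans to the next N (psi + 180)
    for i, res in enumerate(residues):
        psi = phi_psi[i][1]
        res["O"] = nerf_place(res["N"], res["CA"], res["C"],
                              C_O, ANG_CA_C_O, psi + 180.0)
    return residues


def principal_axis_frame(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rotation + centroid aligning the dominant axis of ``coords`` with x.

    Returns (R, centroid) with rows of R = new basis vectors; apply as
    ``(coords - centroid) @ R.T``.  Sign convention: the first point gets a
    negative x coordinate, making the orientation deterministic.
    """
    centroid = coords.mean(axis=0)
    centered = coords - centroid
    _, _, vt = np.linalg.svd(centered, full_matrices=True)
    r = vt
    if np.linalg.det(r) < 0:
        r[2] *= -1.0
    if (centered[0] @ r[0]) > 0:
        r[0] *= -1.0
        r[1] *= -1.0  # keep det = +1
    return r, centroid
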