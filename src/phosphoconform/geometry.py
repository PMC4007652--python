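"""Low-level geometric primitives shared across the package.

Provides the NeRF (natural extension reference frame) atom placement used to
build idealized peptide backbones, rigid-body transforms, and the
deterministic generalized-spiral (Fibonacci) point lattice used for surface
sampling.  Nothing here knows about files or residue chemistry beyond
standard backbone bond geometry.
"""

from __future__ import annotations

import numpy as np

# Ideal backbone internal coordinates (Engh-Huber averages, Å / degrees)
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
BOND_CA_CB = 1.521

ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8
ANGLE_N_CA_CB = 110.5
ANGLE_C_CA_CB = 110.1

HELIX_PHI, HELIX_PSI = -57.0, -47.0
EXTENDED_PHI, EXTENDED_PSI = -120.0, 120.0
STRAND_PHI, STRAND_PSI = -139.0, 135.0


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Place atom D given atoms A-B-C, the C-D bond length, the B-C-D angle
    and the A-B-C-D dihedral (NeRF construction)."""
    angle = np.deg2rad(angle_deg)
    dihedral = np.deg2rad(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = bond * np.array([
        -np.cos(angle),
        np.sin(angle) * np.cos(dihedral),
        np.sin(angle) * np.sin(dihedral),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def dihedral_angle(p0, p1, p2, p3) -> float:
    """Signed dihedral in degrees for four points."""
    b0 = np.asarray(p0) - np.asarray(p1)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    return float(np.rad2deg(np.arctan2(y, x)))


def build_backbone(n_res: int, phi_psi, include_cb: bool = True,
                   omega: float = 180.0) -> list[dict[str, np.ndarray]]:
    """Build an idealized peptide backbone from per-residue (phi, psi).

    ``phi_psi`` is either a single (phi, psi) pair applied to every residue
    or a sequence of ``n_res`` pairs.  Returns one dict per residue mapping
    atom name (N, CA, C, O and optionally CB) to its coordinate.  phi of the
    first residue and psi of the last are geometrically inert but must still
    be supplied when giving per-residue values.
    """
    pp = np.asarray(phi_psi, dtype=float)
    if pp.ndim == 1:
        pp = np.tile(pp, (n_res, 1))
    if pp.shape != (n_res, 2):
        raise ValueError(f"phi_psi must be a pair or shape ({n_res}, 2)")

    residues: list[dict[str, np.ndarray]] = []
    # seed residue: N at origin, CA on x, C in xy-plane
    n0 = np.zeros(3)
    ca0 = np.array([BOND_N_CA, 0.0, 0.0])
    ang = np.deg2rad(ANGLE_N_CA_C)
    c0 = ca0 + BOND_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
    residues.append({"N": n0, "CA": ca0, "C": c0})

    for i in range(1, n_res):
        prev = residues[-1]
        psi_prev = pp[i - 1, 1]
        n_i = place_atom(prev["N"], prev["CA"], prev["C"],
                         BOND_C_N, ANGLE_CA_C_N, psi_prev)
        ca_i = place_atom(prev["CA"], prev["C"], n_i,
                          BOND_N_CA, ANGLE_C_N_CA, omega)
        c_i = place_atom(prev["C"], n_i, ca_i,
                         BOND_CA_C, ANGLE_N_CA_C, pp[i, 0])
        residues.append({"N": n_i, "CA": ca_i, "C": c_i})

    # carbonyl O: anti-periplanar to the next residue's N (psi - 180)
    for i, res in enumerate(residues):
        psi = pp[i, 1]
        res["O"] = place_atom(res["N"], res["CA"], res["C"],
                              BOND_C_O, ANGLE_CA_C_O, psi - 180.0)

    if include_cb:
        for res in residues:
            res["CB"] = _place_cb(res["N"], res["CA"], res["C"])
    return residues


def _place_cb(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Place CB tetrahedrally off CA with L-amino-acid chirality."""
    u1 = n - ca
    u1 /= np.linalg.norm(u1)
    u2 = c - ca
    u2 /= np.linalg.norm(u2)
    g = float(np.dot(u1, u2))
    cos_a = np.cos(np.deg2rad(ANGLE_N_CA_CB))
    cos_b = np.cos(np.deg2rad(ANGLE_C_CA_CB))
    # solve CB_unit = a*u1 + b*u2 + c_out*perp with the two angle constraints
    det = 1.0 - g * g
    a = (cos_a - g * cos_b) / det
    b = (cos_b - g * cos_a) / det
    perp = np.cross(u1, u2)
    perp /= np.linalg.norm(perp)
    c2 = 1.0 - (a * a + b * b + 2 * a * b * g)
    c_out = np.sqrt(max(c2, 0.0))
    # L chirality: CB on the +cross(u1,u2) side (N->CA->C right-handed frame)
    direction = a * u1 + b * u2 + c_out * perp
    return ca + BOND_CA_CB * direction


def fibonacci_sphere(n_points: int) -> np.ndarray:
    """Deterministic near-uniform unit-sphere point set (golden spiral)."""
    i = np.arange(n_points, dtype=float)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n_points
    r = np.sqrt(np.maximum(1.0 - z * z, 0.0))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def rotation_matrix(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rodrigues rotation matrix about ``axis`` by ``angle_deg``."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    t = np.deg2rad(angle_deg)
    k = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(t) * k + (1 - np.cos(t)) * (k @ k)


def kabsch(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rigid superposition: returns (R, t) with
    ``mobile @ R.T + t ≈ target``."""
    mc = mobile.mean(axis=0)
    tc = target.mean(axis=0)
    h = (mobile - mc).T @ (target - tc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    r = vt.T @ corr @ u.T
    t = tc - r @ mc
    return r, t
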