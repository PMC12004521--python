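"""Backbone construction from internal coordinates.

Chains are rebuilt atom by atom with the standard natural-extension
reference-frame (NeRF) placement: each atom is positioned from the three
previously placed atoms given a bond length, a bond angle and a torsion.
Bond lengths and angles are the Engh-Huber ideal values; only the phi/psi
torsions vary, omega is held trans (180 deg).

Amide hydrogens are placed analytically in the peptide plane along the
external bisector of the C(i-1)-N and CA-N directions, 1.01 angstrom from N.
The first residue has no amide hydrogen (free N-terminus), matching the
convention that chain-terminal residues are never hydrogen-bond donors.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "place_atom",
    "build_backbone",
    "dihedral",
    "angle_between",
    "IDEAL_HELIX_PHI",
    "IDEAL_HELIX_PSI",
    "BOND_LENGTHS",
]

IDEAL_HELIX_PHI = -57.0
IDEAL_HELIX_PSI = -47.0

# Engh & Huber ideal backbone geometry (angstrom, degrees)
BOND_LENGTHS = {"N-CA": 1.458, "CA-C": 1.525, "C-N": 1.329, "C-O": 1.231, "N-H": 1.010}
BOND_ANGLES = {"N-CA-C": 111.2, "CA-C-N": 116.2, "C-N-CA": 121.7, "CA-C-O": 120.8}
OMEGA = 180.0


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, theta_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom D given chain A-B-C, |C-D| = bond, angle(B,C,D) = theta and
    torsion(A,B,C,D) = torsion (NeRF placement)."""
    theta = np.deg2rad(theta_deg)
    chi = np.deg2rad(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = bond * np.array(
        [-np.cos(theta), np.sin(theta) * np.cos(chi), np.sin(theta) * np.sin(chi)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def dihedral(p0, p1, p2, p3) -> float:
    """Signed torsion angle in degrees, IUPAC convention, in (-180, 180]."""
    b0 = np.asarray(p0) - np.asarray(p1)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    ang = np.degrees(np.arctan2(y, x))
    return 180.0 if np.isclose(ang, -180.0) else float(ang)


def angle_between(p0, p1, p2) -> float:
    """Planar angle at p1 in degrees, in [0, 180]."""
    v1 = np.asarray(p0, dtype=float) - np.asarray(p1, dtype=float)
    v2 = np.asarray(p2, dtype=float) - np.asarray(p1, dtype=float)
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def build_backbone(phi: np.ndarray, psi: np.ndarray,
                   with_cb: bool = False) -> dict[str, np.ndarray]:
    """Build backbone coordinates N, H, CA, C, O for a chain of len(phi) residues.

    phi[0] and psi[-1] are undefined for a real chain but must still be
    supplied (they orient the terminal O and are otherwise inert).

    Returns a dict of (n_residues, 3) arrays keyed by atom name; H[0] is NaN
    (no amide hydrogen at the N-terminus).  ``with_cb`` adds an idealised
    beta-carbon per residue (tetrahedral off the N-CA-C plane), giving each
    residue a minimal side-chain proxy for contact analyses.
    """
    phi = np.asarray(phi, dtype=float)
    psi = np.asarray(psi, dtype=float)
    n_res = len(phi)
    if len(psi) != n_res:
        raise ValueError("phi and psi must have the same length")
    if n_res < 2:
        raise ValueError("need at least 2 residues")

    N = np.empty((n_res, 3))
    CA = np.empty((n_res, 3))
    C = np.empty((n_res, 3))
    O = np.empty((n_res, 3))
    H = np.full((n_res, 3), np.nan)

    # seed residue 0 in the xy-plane
    N[0] = (0.0, 0.0, 0.0)
    CA[0] = (BOND_LENGTHS["N-CA"], 0.0, 0.0)
    th = np.deg2rad(BOND_ANGLES["N-CA-C"])
    C[0] = CA[0] + BOND_LENGTHS["CA-C"] * np.array([-np.cos(th), np.sin(th), 0.0])

    for i in range(1, n_res):
        N[i] = place_atom(N[i - 1], CA[i - 1], C[i - 1],
                          BOND_LENGTHS["C-N"], BOND_ANGLES["CA-C-N"], psi[i - 1])
        CA[i] = place_atom(CA[i - 1], C[i - 1], N[i],
                           BOND_LENGTHS["N-CA"], BOND_ANGLES["C-N-CA"], OMEGA)
        C[i] = place_atom(C[i - 1], N[i], CA[i],
                          BOND_LENGTHS["CA-C"], BOND_ANGLES["N-CA-C"], phi[i])

    for i in range(n_res):
        # carbonyl O: trans to the next amide N across the C(i) sp2 centre
        O[i] = place_atom(N[i], CA[i], C[i],
                          BOND_LENGTHS["C-O"], BOND_ANGLES["CA-C-O"], psi[i] + 180.0)
        if i > 0:
            u = N[i] - C[i - 1]
            v = N[i] - CA[i]
            direction = u / np.linalg.norm(u) + v / np.linalg.norm(v)
            direction /= np.linalg.norm(direction)
            H[i] = N[i] + BOND_LENGTHS["N-H"] * direction

    out = {"N": N, "H": H, "CA": CA, "C": C, "O": O}
    if with_cb:
        CB = np.empty((n_res, 3))
        for i in range(n_res):
            # tetrahedral branch off CA, out of the N-CA-C plane (L-configuration)
            CB[i] = place_atom(C[i], N[i], CA[i], 1.53, 110.4, 122.6)
        out["CB"] = CB
    return out
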