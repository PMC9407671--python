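"""Ideal peptide backbone construction from internal coordinates.

Builds N/CA/C/O traces residue-by-residue with standard bond lengths and
angles (Engh/Huber-style values), trans peptide bonds, and caller-supplied
(phi, psi) per residue. Shared by the scaffold builder and the synthetic
fibril generator.
"""
from __future__ import annotations

from math import cos, radians, sin, sqrt

import numpy as np

from .geometry import dihedral, place_atom

# Standard peptide geometry (Angstrom / degrees).
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8
OMEGA_TRANS = 180.0

# Ideal secondary-structure dihedrals.
HELIX_PHI_PSI = (-57.0, -47.0)
STRAND_PHI_PSI = (-139.0, 135.0)

BACKBONE_ATOMS = ("N", "CA", "C", "O")


def _place_scalar(a, b, c, bond, angle, torsion):
    """Scalar NeRF step (same construction as geometry.place_atom, tuple math).

    Kept free of numpy per-op overhead because backbone generation calls
    it hundreds of thousands of times during scaffold sampling.
    """
    ang = radians(angle)
    tor = radians(torsion)
    bcx, bcy, bcz = c[0] - b[0], c[1] - b[1], c[2] - b[2]
    ln = sqrt(bcx * bcx + bcy * bcy + bcz * bcz)
    bcx, bcy, bcz = bcx / ln, bcy / ln, bcz / ln
    abx, aby, abz = b[0] - a[0], b[1] - a[1], b[2] - a[2]
    nx = aby * bcz - abz * bcy
    ny = abz * bcx - abx * bcz
    nz = abx * bcy - aby * bcx
    ln = sqrt(nx * nx + ny * ny + nz * nz)
    nx, ny, nz = nx / ln, ny / ln, nz / ln
    mx = ny * bcz - nz * bcy
    my = nz * bcx - nx * bcz
    mz = nx * bcy - ny * bcx
    d0 = -bond * cos(ang)
    d1 = bond * sin(ang) * cos(tor)
    d2 = -bond * sin(ang) * sin(tor)
    return (
        c[0] + d0 * bcx + d1 * mx + d2 * nx,
        c[1] + d0 * bcy + d1 * my + d2 * ny,
        c[2] + d0 * bcz + d1 * mz + d2 * nz,
    )


def build_from_dihedrals(phi_psi: np.ndarray) -> np.ndarray:
    """Build an (n, 4, 3) backbone (N, CA, C, O per residue) from (phi, psi).

    phi of the first residue and psi of the last are used only where defined
    (psi of residue i orients its carbonyl oxygen and the next amide).
    """
    pp = np.asarray(phi_psi, dtype=float)
    n = pp.shape[0]
    if n < 1 or pp.shape[1] != 2:
        raise ValueError("phi_psi must be (n, 2) with n >= 1")
    phis = pp[:, 0].tolist()
    psis = pp[:, 1].tolist()

    out = np.empty((n, 4, 3))
    N = (0.0, 0.0, 0.0)
    CA = (BOND_N_CA, 0.0, 0.0)
    ang = radians(180.0 - ANGLE_N_CA_C)
    C = (CA[0] + BOND_CA_C * cos(ang), CA[1] + BOND_CA_C * sin(ang), 0.0)
    rows = []
    for i in range(n):
        if i > 0:
            Np, CAp, Cp = N, CA, C
            N = _place_scalar(Np, CAp, Cp, BOND_C_N, ANGLE_CA_C_N, psis[i - 1])
            CA = _place_scalar(CAp, Cp, N, BOND_N_CA, ANGLE_C_N_CA, OMEGA_TRANS)
            C = _place_scalar(Cp, N, CA, BOND_CA_C, ANGLE_N_CA_C, phis[i])
        # carbonyl oxygen: anti to the next amide nitrogen
        O = _place_scalar(N, CA, C, BOND_C_O, ANGLE_CA_C_O, psis[i] + 180.0)
        rows.append((N, CA, C, O))
    out[:] = rows
    return out


def backbone_dihedrals(coords: np.ndarray) -> np.ndarray:
    """Per-residue (phi, psi) in degrees from an (n, >=3, 3) backbone.

    Undefined angles (phi of the first residue, psi of the last) are NaN.
    """
    c = np.asarray(coords, dtype=float)
    n = c.shape[0]
    out = np.full((n, 2), np.nan)
    for i in range(n):
        if i > 0:
            out[i, 0] = dihedral(c[i - 1, 2], c[i, 0], c[i, 1], c[i, 2])
        if i < n - 1:
            out[i, 1] = dihedral(c[i, 0], c[i, 1], c[i, 2], c[i + 1, 0])
    return out


def virtual_cbeta(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Idealized C-beta position from backbone N, CA, C (tetrahedral geometry)."""
    b = ca - n
    cc = c - ca
    a = np.cross(b, cc)
    return -0.58273431 * a + 0.56802827 * b - 0.54067466 * cc + ca
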