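"""Backbone torsion geometry.

Signed dihedral angles follow the IUPAC convention used for Ramachandran
analysis: looking down the central bond (p2 -> p3), the angle is the rotation
carrying the p1 projection onto the p4 projection, positive clockwise, and is
reported on the half-open interval [-180, 180) so that every 2-degree
Ramachandran bin has an unambiguous owner (exactly +180 wraps to -180).
"""

from __future__ import annotations

import numpy as np

__all__ = ["DegenerateGeometryError", "wrap_angle", "compute_dihedral", "torsion_angles"]


class DegenerateGeometryError(ValueError):
    """Raised when a torsion is undefined (collinear atom triplet)."""


def wrap_angle(angle):
    """Wrap angle(s) in degrees onto [-180, 180); idempotent on that domain."""
    return (np.asarray(angle, dtype=float) + 180.0) % 360.0 - 180.0


def compute_dihedral(p1, p2, p3, p4) -> float:
    """Signed torsion angle (degrees) of four points, in [-180, 180).

    Uses the atan2 formulation, which is numerically stable near 0 and
    +-180.  The backbone phi angle of residue i is the torsion of
    C(i-1)-N(i)-CA(i)-C(i); psi is N(i)-CA(i)-C(i)-N(i+1).

    Raises
    ------
    DegenerateGeometryError
        If a bond vector vanishes or two consecutive bond vectors are
        parallel, in which case the torsion is undefined.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = np.linalg.norm(b2)
    if b2n == 0.0 or np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
        raise DegenerateGeometryError("torsion undefined: collinear or coincident atoms")
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2) / b2n)
    return float(wrap_angle(np.degrees(np.arctan2(y, x))))


def torsion_angles(p1: np.ndarray, p2: np.ndarray, p3: np.ndarray, p4: np.ndarray) -> np.ndarray:
    """Vectorized torsions for (n, 3) point stacks; degenerate rows give NaN."""
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = np.linalg.norm(b2, axis=-1)
    x = np.einsum("...i,...i->...", n1, n2)
    y = np.einsum("...i,...i->...", np.cross(n1, n2), b2) / np.where(b2n == 0, np.nan, b2n)
    bad = (np.linalg.norm(n1, axis=-1) < 1e-10) | (np.linalg.norm(n2, axis=-1) < 1e-10)
    out = wrap_angle(np.degrees(np.arctan2(y, x)))
    out = np.where(bad, np.nan, out)
    return out


# Idealized backbone internal coordinates (Engh-Huber-like averages, Angstrom
# and degrees) used by the synthetic peptide builder.
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
ANGLE_N_CA_C = 111.0
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
OMEGA_TRANS = 180.0


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom d so that |cd| = bond, angle(b,c,d) = angle and
    torsion(a,b,c,d) = torsion (the NeRF construction)."""
    ang = np.radians(angle_deg)
    tor = np.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = bond * np.array([
        -np.cos(ang),
        np.sin(ang) * np.cos(tor),
        np.sin(ang) * np.sin(tor),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n
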