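"""Internal-coordinate construction and torsion measurement for 4-point chains.

Used by the synthetic-data module to build coordinate fixtures with prescribed
dihedral angles, and as the numerical definition of the torsion convention:
cis = 0 deg, sign by the IUPAC rule (looking from atom B to atom C, the
rotation of A onto D counterclockwise is positive), stored on [0, 360).
"""

from __future__ import annotations

import numpy as np

__all__ = ["measure_dihedral", "place_fourth_atom", "build_chain"]


def measure_dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray,
                     degrees: bool = True) -> float | np.ndarray:
    """Signed torsion of the chain p0-p1-p2-p3, wrapped to [0, 360) deg.

    Accepts single points of shape (3,) or stacked frames of shape (n, 3).
    """
    b1 = np.asarray(p1, float) - np.asarray(p0, float)
    b2 = np.asarray(p2, float) - np.asarray(p1, float)
    b3 = np.asarray(p3, float) - np.asarray(p2, float)
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2_hat = b2 / np.linalg.norm(b2, axis=-1, keepdims=True)
    x = np.sum(n1 * n2, axis=-1)
    y = np.sum(np.cross(n1, n2) * b2_hat, axis=-1)
    ang = np.arctan2(y, x)
    if degrees:
        return np.degrees(ang) % 360.0
    return ang % (2.0 * np.pi)


def place_fourth_atom(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray,
                      bond_length: float, bond_angle_deg: float,
                      torsion_deg: float) -> np.ndarray:
    """Place the next atom at given internal coordinates (NeRF placement)."""
    p0, p1, p2 = (np.asarray(p, float) for p in (p0, p1, p2))
    theta = np.radians(bond_angle_deg)
    phi = np.radians(torsion_deg)
    # local displacement in the frame of the last bond
    d = bond_length * np.array(
        [-np.cos(theta), np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi)]
    )
    bc = p2 - p1
    bc /= np.linalg.norm(bc)
    ab = p1 - p0
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.stack([bc, np.cross(n, bc), n], axis=1)
    return p2 + m @ d


def build_chain(torsion_deg: float, bond_length: float = 1.5,
                bond_angle_deg: float = 109.5) -> np.ndarray:
    """Four points realising the requested torsion with fixed bonds/angles."""
    if not np.isfinite(torsion_deg):
        raise ValueError("target dihedral must be finite")
    theta = np.radians(bond_angle_deg)
    p0 = np.zeros(3)
    p1 = np.array([bond_length, 0.0, 0.0])
    p2 = p1 + bond_length * np.array([-np.cos(theta), np.sin(theta), 0.0])
    p3 = place_fourth_atom(p0, p1, p2, bond_length, bond_angle_deg, torsion_deg)
    return np.stack([p0, p1, p2, p3])
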