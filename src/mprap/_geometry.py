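"""Shared coarse-grained residue geometry.

Residues are modelled as four backbone atoms (N, CA, C, O) plus one
pseudo-side-chain sphere (atom name ``SC``) whose radius scales with the
amino acid's size.  The same constructor is used by the synthetic bundle
generator and by the extended Ala-X-Ala tripeptide that defines the 100%
reference areas for relative accessibility, so absolute and relative areas
are mutually consistent by construction.
"""
from __future__ import annotations

import numpy as np

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"

AA_THREE = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
    "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
    "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
    "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
    "X": "UNK",
}
THREE_TO_ONE = {v: k for k, v in AA_THREE.items()}

# van der Waals radii by element (Bondi-style values); unknown elements
# fall back to DEFAULT_VDW.
VDW_RADII = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "H": 1.20,
    "P": 1.80,
}
DEFAULT_VDW = 1.80

# Pseudo-side-chain sphere radius per amino acid (Angstrom), ordered roughly
# by side-chain volume.  Glycine carries no SC atom.
SC_RADIUS = {
    "G": 0.0,
    "A": 1.6, "S": 1.8, "C": 1.9, "P": 2.0, "T": 2.0, "D": 2.0,
    "V": 2.1, "N": 2.1, "E": 2.2, "I": 2.3, "L": 2.3, "Q": 2.3,
    "M": 2.4, "K": 2.4, "H": 2.4, "F": 2.6, "R": 2.6, "Y": 2.7,
    "W": 2.9,
    "X": 2.1,
}

CA_CA_EXTENDED = 3.8  # Angstrom, extended-chain CA spacing
HELIX_RISE = 1.5      # Angstrom per residue along the helix axis
HELIX_TWIST = 100.0   # degrees per residue
HELIX_RADIUS = 2.3    # CA distance from the helix axis


def _unit(v: np.ndarray) -> np.ndarray:
    n = float(np.linalg.norm(v))
    if n < 1e-12:
        raise ValueError("zero-length direction vector")
    return v / n


def atom_radius(name: str, aa: str, probe: float = 0.0) -> float:
    """Radius used in SASA for one atom: vdW (element from the atom name),
    or the per-amino-acid pseudo-side-chain radius for ``SC`` atoms."""
    if name.strip().upper() == "SC":
        base = SC_RADIUS.get(aa, SC_RADIUS["X"])
    else:
        element = name.strip()[0].upper()
        base = VDW_RADII.get(element, DEFAULT_VDW)
    return base + probe


def residue_atoms(aa: str, ca: np.ndarray, tangent: np.ndarray,
                  normal: np.ndarray) -> list[tuple[str, float, float, float]]:
    """Place the 4+1 coarse atoms of one residue.

    ``tangent`` points along the chain, ``normal`` is the side-chain
    direction; both are orthonormalized internally.
    """
    ca = np.asarray(ca, dtype=float)
    t = _unit(np.asarray(tangent, dtype=float))
    n = np.asarray(normal, dtype=float)
    n = n - np.dot(n, t) * t
    if np.linalg.norm(n) < 1e-9:  # degenerate: pick any perpendicular
        n = np.cross(t, [0.0, 0.0, 1.0])
        if np.linalg.norm(n) < 1e-9:
            n = np.cross(t, [0.0, 1.0, 0.0])
    n = _unit(n)
    m = np.cross(t, n)

    atoms = [
        ("N", *(ca - 1.25 * t)),
        ("CA", *ca),
        ("C", *(ca + 1.25 * t)),
        ("O", *(ca + 1.25 * t + 1.0 * m)),
    ]
    r_sc = SC_RADIUS.get(aa, SC_RADIUS["X"])
    if r_sc > 0.0:
        d = 1.5 + 0.6 * r_sc
        atoms.append(("SC", *(ca + d * n)))
    return [(name, float(x), float(y), float(z)) for name, x, y, z in atoms]


def extended_tripeptide(center_aa: str) -> list[list[tuple[str, float, float, float]]]:
    """Extended Ala-X-Ala tripeptide along the x axis.

    Side chains alternate above/below the chain as in an extended strand.
    Returns one atom list per residue (Ala, X, Ala).
    """
    seq = ["A", center_aa, "A"]
    out = []
    for i, aa in enumerate(seq):
        ca = np.array([i * CA_CA_EXTENDED, 0.0, 0.0])
        normal = np.array([0.0, 1.0, 0.0]) * (1.0 if i % 2 == 0 else -1.0)
        out.append(residue_atoms(aa, ca, np.array([1.0, 0.0, 0.0]), normal))
    return out


def helix_ca_positions(n_res: int, axis_xy: tuple[float, float], z_start: float,
                       direction: int, phase: float) -> np.ndarray:
    """CA coordinates of an ideal alpha helix with its axis parallel to z.

    ``direction`` is +1 (N-to-C running up in z) or -1 (running down);
    ``phase`` sets the helical-wheel rotation (radians).
    """
    i = np.arange(n_res)
    theta = phase + np.deg2rad(HELIX_TWIST) * i * direction
    x = axis_xy[0] + HELIX_RADIUS * np.cos(theta)
    y = axis_xy[1] + HELIX_RADIUS * np.sin(theta)
    z = z_start + HELIX_RISE * i * direction
    return np.stack([x, y, z], axis=1)


def bezier_arc(p0: np.ndarray, p1: np.ndarray, apex: np.ndarray,
               n_points: int) -> np.ndarray:
    """Quadratic Bezier arc from p0 to p1 through a control point above apex;
    used to route loops over or under the bundle."""
    t = np.linspace(0.0, 1.0, n_points + 2)[1:-1, None]
    p0 = np.asarray(p0, float)[None, :]
    p1 = np.asarray(p1, float)[None, :]
    c = np.asarray(apex, float)[None, :]
    return (1 - t) ** 2 * p0 + 2 * t * (1 - t) * c + t ** 2 * p1


def chain_frames(ca: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-residue tangents (central differences) for an ordered CA trace."""
    tang = np.zeros_like(ca)
    tang[1:-1] = ca[2:] - ca[:-2]
    tang[0] = ca[1] - ca[0]
    tang[-1] = ca[-1] - ca[-2]
    norms = np.linalg.norm(tang, axis=1, keepdims=True)
    norms[norms < 1e-12] = 1.0
    return ca, tang / norms
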