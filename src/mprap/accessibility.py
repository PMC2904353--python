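"""Solvent-accessible surface area and burial states.

Absolute per-residue SASA is computed with the Shrake-Rupley rolling-probe
algorithm: each atom's sphere is inflated by the probe radius, covered with
a deterministic Fibonacci lattice of surface points, and the fraction of
points not inside any neighbour's inflated sphere, times the sphere area,
is the atom's accessible area.  Residue areas are sums over atoms.

Relative accessibility (RSA, percent) normalises a residue's area by the
area the same residue type attains in an extended Ala-X-Ala tripeptide
built with the same coarse atom model, so a fully extended residue scores
100.  Reference tables for probe radii 1.4 A (water-sized) and 2.0 A
(CH2-sized) ship with the package and can be regenerated from code.

Burial is binary: RSA below the cutoff (default 25%) is buried, at or
above is exposed.  A residue exposed in its single chain but buried in the
full complex is an interface residue.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass
from enum import Enum
from importlib import resources

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from ._geometry import atom_radius, extended_tripeptide, AA_ORDER
from .errors import (
    ConfigurationError,
    DomainError,
    EmptyStructureError,
    MissingDataError,
)
from .structio import Structure, residue_z

DEFAULT_PROBE = 1.4
MEMBRANE_PROBE = 2.0
DEFAULT_CUTOFF = 25.0
DEFAULT_N_POINTS = 960
# half-thickness used when mixing probes (2.0 A inside the membrane slab)
DEFAULT_HALF_THICKNESS = 15.0


class BurialState(str, Enum):
    BURIED = "buried"
    EXPOSED = "exposed"


class InterfaceLabel(str, Enum):
    BURIED = "buried"
    INTERFACE = "interface"
    EXPOSED = "exposed"


@dataclass
class AccessibilityProfile:
    """Per-residue absolute (A^2) and relative (%) accessibility.

    ``table`` columns: chain, res_index, aa, abs_asa, rsa (NaN until
    :func:`relative_accessibility` fills it, and for 'X' residues).
    """

    probe_radius: float
    context: str  # "single_chain" | "complex"
    table: pd.DataFrame

    def rsa_map(self) -> dict:
        return {(r.chain, r.res_index): r.rsa for r in self.table.itertuples()}

    def abs_map(self) -> dict:
        return {(r.chain, r.res_index): r.abs_asa
                for r in self.table.itertuples()}


def fibonacci_sphere(n: int) -> np.ndarray:
    """n near-uniform points on the unit sphere (deterministic)."""
    i = np.arange(n, dtype=float) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    cos_theta = 1.0 - 2.0 * i / n
    sin_theta = np.sqrt(np.clip(1.0 - cos_theta ** 2, 0.0, 1.0))
    return np.stack([np.cos(phi) * sin_theta,
                     np.sin(phi) * sin_theta,
                     cos_theta], axis=1)


def atom_sasa(coords: np.ndarray, radii: np.ndarray, probe: float,
              n_points: int = DEFAULT_N_POINTS) -> np.ndarray:
    """Shrake-Rupley accessible area per atom (A^2).

    ``radii`` are bare vdW radii; spheres are inflated by ``probe``.
    """
    if probe <= 0:
        raise DomainError(f"probe radius must be positive, got {probe}")
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float) + probe
    n = len(coords)
    if n == 0:
        return np.zeros(0)
    sphere = fibonacci_sphere(n_points)
    tree = cKDTree(coords)
    rmax = radii.max()
    areas = np.empty(n)
    for i in range(n):
        ri = radii[i]
        nbr = [j for j in tree.query_ball_point(coords[i], ri + rmax)
               if j != i]
        nbr = [j for j in nbr
               if np.linalg.norm(coords[j] - coords[i]) < ri + radii[j]]
        pts = coords[i] + ri * sphere
        if nbr:
            d2 = ((pts[:, None, :] - coords[nbr][None, :, :]) ** 2).sum(-1)
            exposed = (d2 >= (radii[nbr] ** 2)[None, :]).all(axis=1)
            frac = exposed.mean()
        else:
            frac = 1.0
        areas[i] = 4.0 * math.pi * ri * ri * frac
    return areas


def _structure_arrays(structure: Structure, chain_ids=None):
    coords, radii, owner = [], [], []
    for site in structure.residues():
        if chain_ids is not None and site.chain_id not in chain_ids:
            continue
        for name, x, y, z in site.atoms:
            coords.append((x, y, z))
            radii.append(atom_radius(name, site.aa))
            owner.append((site.chain_id, site.res_index, site.aa))
    return np.array(coords), np.array(radii), owner


def compute_sasa(structure: Structure, probe: float = DEFAULT_PROBE,
                 context: str = "complex",
                 n_points: int = DEFAULT_N_POINTS) -> AccessibilityProfile:
    """Per-residue absolute SASA.

    ``context='complex'`` uses every chain and kept hetero group as
    occluders; ``context='single_chain'`` computes each chain in isolation
    (occluders restricted to that chain).
    """
    if probe <= 0:
        raise DomainError(f"probe radius must be positive, got {probe}")
    if context not in ("complex", "single_chain"):
        raise DomainError(f"unknown context {context!r}")
    if structure.n_residues == 0:
        raise EmptyStructureError("structure has no residues")

    per_residue: dict = {}
    aa_of: dict = {}
    if context == "complex":
        groups = [None]
    else:
        groups = [{cid} for cid in structure.chains]
    for group in groups:
        coords, radii, owner = _structure_arrays(structure, group)
        areas = atom_sasa(coords, radii, probe, n_points)
        for (cid, idx, aa), a in zip(owner, areas):
            key = (cid, idx)
            per_residue[key] = per_residue.get(key, 0.0) + float(a)
            aa_of[key] = aa

    rows = [(cid, idx, aa_of[(cid, idx)], per_residue[(cid, idx)], np.nan)
            for sites in structure.chains.values()
            for cid, idx in [(s.chain_id, s.res_index) for s in sites]]
    table = pd.DataFrame(rows,
                         columns=["chain", "res_index", "aa", "abs_asa", "rsa"])
    return AccessibilityProfile(probe_radius=probe, context=context,
                                table=table)


def compute_reference_areas(probe: float,
                            n_points: int = 4000) -> dict[str, float]:
    """Maximum residue areas from extended Ala-X-Ala tripeptides.

    Computed with a denser point lattice than routine SASA since these
    values sit in every RSA denominator.
    """
    ref = {}
    for aa in AA_ORDER:
        residues = extended_tripeptide(aa)
        coords, radii = [], []
        for res_atoms, res_aa in zip(residues, ["A", aa, "A"]):
            for name, x, y, z in res_atoms:
                coords.append((x, y, z))
                radii.append(atom_radius(name, res_aa))
        areas = atom_sasa(np.array(coords), np.array(radii), probe, n_points)
        n_center = len(residues[1])
        n_first = len(residues[0])
        ref[aa] = float(areas[n_first:n_first + n_center].sum())
    return ref


def load_reference_table(probe: float) -> dict[str, float]:
    """Shipped tripeptide reference areas for a supported probe radius."""
    key = f"{probe:.1f}"
    text = resources.files("mprap.data").joinpath(
        "rsa_reference.json").read_text()
    tables = json.loads(text)
    if key not in tables:
        raise ConfigurationError(
            f"no shipped RSA reference table for probe {key} A; "
            "use compute_reference_areas() to build one")
    return tables[key]


def relative_accessibility(profile: AccessibilityProfile,
                           reference_table: dict | None = None
                           ) -> AccessibilityProfile:
    """Fill ``rsa`` = 100 * abs_asa / reference(aa); 'X' residues stay NaN."""
    if reference_table is None:
        reference_table = load_reference_table(profile.probe_radius)
    table = profile.table.copy()
    rsa = np.full(len(table), np.nan)
    for i, row in enumerate(table.itertuples()):
        if row.aa == "X":
            continue
        if row.aa not in reference_table:
            raise ConfigurationError(
                f"reference table lacks an entry for {row.aa!r}")
        rsa[i] = 100.0 * row.abs_asa / reference_table[row.aa]
    table["rsa"] = rsa
    return AccessibilityProfile(profile.probe_radius, profile.context, table)


def binarize(rsa: float, cutoff: float = DEFAULT_CUTOFF) -> BurialState:
    """RSA below the cutoff is buried; at or above is exposed."""
    if not 0 < cutoff < 100:
        raise DomainError(f"cutoff must be in (0, 100), got {cutoff}")
    if rsa is None or (isinstance(rsa, float) and math.isnan(rsa)):
        raise MissingDataError("rsa value is missing")
    if rsa < 0:
        raise DomainError(f"rsa must be non-negative, got {rsa}")
    return BurialState.BURIED if rsa < cutoff else BurialState.EXPOSED


def label_interface(rsa_single: float, rsa_complex: float,
                    cutoff: float = DEFAULT_CUTOFF) -> InterfaceLabel:
    """Interface = exposed (>cutoff) alone but buried (<cutoff) in the
    complex; otherwise buried if complex-buried, else exposed."""
    for v in (rsa_single, rsa_complex):
        if v is None or (isinstance(v, float) and math.isnan(v)):
            raise MissingDataError("both single-chain and complex RSA required")
    if rsa_single > cutoff and rsa_complex < cutoff:
        return InterfaceLabel.INTERFACE
    if rsa_complex < cutoff:
        return InterfaceLabel.BURIED
    return InterfaceLabel.EXPOSED


def labeling_rsa(structure: Structure, probe_policy: str = "1.4",
                 context: str = "complex",
                 half_thickness: float = DEFAULT_HALF_THICKNESS,
                 n_points: int = DEFAULT_N_POINTS) -> pd.DataFrame:
    """RSA under a probe policy: '1.4', '2.0', or 'mixed' (2.0 A for
    residues inside the membrane slab |z| <= half_thickness, 1.4 outside).
    """
    if probe_policy not in ("1.4", "2.0", "mixed"):
        raise DomainError(f"unknown probe policy {probe_policy!r}")
    probes = [1.4, 2.0] if probe_policy == "mixed" else [float(probe_policy)]
    profs = {}
    for p in probes:
        prof = relative_accessibility(
            compute_sasa(structure, probe=p, context=context,
                         n_points=n_points))
        profs[p] = prof.table.set_index(["chain", "res_index"])
    rows = []
    for site in structure.residues():
        key = (site.chain_id, site.res_index)
        if probe_policy == "mixed":
            structure.require_oriented()
            p = 2.0 if abs(residue_z(site)) <= half_thickness else 1.4
        else:
            p = probes[0]
        rec = profs[p].loc[key]
        rows.append((site.chain_id, site.res_index, site.aa, p,
                     float(rec["abs_asa"]), float(rec["rsa"])))
    return pd.DataFrame(rows, columns=["chain", "res_index", "aa", "probe",
                                       "abs_asa", "rsa"])


def write_accessibility_tsv(profile: AccessibilityProfile, path,
                            cutoff: float = DEFAULT_CUTOFF) -> None:
    """TSV with a header line recording probe radius and context."""
    table = profile.table.copy()
    table["state"] = [
        binarize(r, cutoff).value if not math.isnan(r) else "NA"
        for r in table["rsa"].fillna(np.nan)
    ]
    with open(path, "w") as fh:
        fh.write(f"# probe_radius={profile.probe_radius:.2f}\t"
                 f"context={profile.context}\tcutoff={cutoff:.1f}\n")
        table.to_csv(fh, sep="\t", index=False, float_format="%.3f")
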