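"""Oriented membrane-protein structures: reading, writing, membrane regions.

Structures are expected to be pre-oriented the way membrane-structure
databases distribute them: membrane normal along z, membrane center at
z = 0.  Each residue carries a signed z coordinate (Angstrom) from which it
is classified into one of three membrane regions:

* ``core``        |z| < 10
* ``interface``   10 <= |z| <= 22  (lipid-water interface; boundaries
  fall here because the outer regions are defined by strict inequalities)
* ``nonmembrane`` |z| > 22

The 20 standard amino acids additionally partition into three
physico-chemical classes on the biological hydrophobicity scale:
hydrophobic (A F I L M V), weakly polar (G Y W C S T) and strongly polar
(D E K R H N P Q).
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
from Bio.PDB import PDBParser

from ._geometry import AA_THREE, THREE_TO_ONE
from .errors import (
    DomainError,
    EmptyStructureError,
    FormatError,
    InvalidResidueError,
    NotOrientedError,
    UnknownResidueError,
)


class Region(str, Enum):
    CORE = "core"
    INTERFACE = "interface"
    NONMEMBRANE = "nonmembrane"


class AAClass(str, Enum):
    HYDROPHOBIC = "hydrophobic"
    WEAKLY_POLAR = "weakly_polar"
    STRONGLY_POLAR = "strongly_polar"


HYDROPHOBIC = frozenset("AFILMV")
WEAKLY_POLAR = frozenset("GYWCST")
STRONGLY_POLAR = frozenset("DEKRHNPQ")
STANDARD_AA = frozenset(HYDROPHOBIC | WEAKLY_POLAR | STRONGLY_POLAR)

CORE_MAX_Z = 10.0
INTERFACE_MAX_Z = 22.0

# Solvent and membrane-lipid hetero groups are never part of the protein
# surface of interest and are always stripped on read.
WATER_RESNAMES = frozenset({"HOH", "WAT", "DOD", "H2O", "SOL", "TIP"})
LIPID_RESNAMES = frozenset({
    "POP", "POPC", "POPE", "POPG", "PC1", "PEE", "PLM", "PLC",
    "LDA", "LMT", "BOG", "DMU", "OLA", "OLC", "MYR", "PX4", "LHG",
})


@dataclass
class ResidueSite:
    """One residue: identity, coarse atoms, and membrane-frame z."""

    chain_id: str
    res_index: int
    aa: str
    atoms: list  # list of (atom_name, x, y, z)
    hetero: bool = False

    def __post_init__(self):
        if not self.atoms:
            raise InvalidResidueError(
                f"residue {self.chain_id}{self.res_index} has no atoms")
        self.aa = self.aa.upper()

    @property
    def z(self) -> float:
        return residue_z(self)


@dataclass
class Structure:
    """An ordered set of chains of :class:`ResidueSite`.

    ``oriented`` asserts the membrane frame (normal = z axis, center at
    z = 0); region logic refuses to run when it is false.
    """

    pdb_id: str
    chains: dict = field(default_factory=dict)  # chain_id -> list[ResidueSite]
    oriented: bool = True

    def __post_init__(self):
        for cid, sites in self.chains.items():
            idx = [s.res_index for s in sites]
            if any(b <= a for a, b in zip(idx, idx[1:])):
                raise FormatError(
                    f"residue numbering not strictly increasing in chain {cid}")

    @property
    def n_residues(self) -> int:
        return sum(len(c) for c in self.chains.values())

    def residues(self, standard_only: bool = False):
        """Iterate sites in chain/file order."""
        for sites in self.chains.values():
            for s in sites:
                if standard_only and s.aa not in STANDARD_AA:
                    continue
                yield s

    def require_oriented(self):
        if not self.oriented:
            raise NotOrientedError(
                f"structure {self.pdb_id} is not membrane-oriented; "
                "region operations are undefined")


def read_structure(path, drop_heteros: bool = True,
                   oriented: bool = True) -> Structure:
    """Read a pre-oriented PDB file.

    Waters and membrane lipids are always removed.  Other hetero groups
    (prosthetic groups such as retinal, hemes, ...) are kept when
    ``drop_heteros`` is false; they appear as ``aa='X'`` sites.
    Residues with insertion codes are rejected.
    """
    path = Path(path)
    parser = PDBParser(QUIET=True)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            bio = parser.get_structure(path.stem, str(path))
    except FileNotFoundError:
        raise
    except Exception as exc:  # Bio.PDB raises assorted types on bad input
        raise FormatError(f"cannot parse PDB file {path}: {exc}") from exc

    model = next(iter(bio), None)
    if model is None:
        raise EmptyStructureError(f"{path}: no model records")

    chains: dict[str, list[ResidueSite]] = {}
    for chain in model:
        sites = []
        for res in chain:
            hetflag, resseq, icode = res.id
            if icode.strip():
                raise FormatError(
                    f"{path}: insertion code {icode!r} at {chain.id}{resseq} "
                    "not supported")
            resname = res.get_resname().strip()
            if resname in WATER_RESNAMES or hetflag == "W":
                continue
            if resname in LIPID_RESNAMES:
                continue
            is_het = bool(hetflag.strip())
            if is_het and drop_heteros:
                continue
            aa = THREE_TO_ONE.get(resname, "X")
            atoms = [(a.get_name(), *map(float, a.get_coord())) for a in res]
            if not atoms:
                continue
            sites.append(ResidueSite(chain.id, int(resseq), aa, atoms,
                                     hetero=is_het))
        if sites:
            chains[chain.id] = sites

    if not chains:
        raise EmptyStructureError(f"{path}: no residues after filtering")
    return Structure(pdb_id=path.stem, chains=chains, oriented=oriented)


def write_structure(structure: Structure, path) -> None:
    """Write fixed-width ATOM/HETATM records (plus TER/END)."""
    lines = []
    serial = 1
    for cid, sites in structure.chains.items():
        for site in sites:
            resname = AA_THREE.get(site.aa, "UNK")
            record = "HETATM" if site.hetero else "ATOM  "
            for name, x, y, z in site.atoms:
                pad = name if len(name) >= 4 else f" {name:<3s}"
                element = "C" if name.upper() == "SC" else name.strip()[0]
                lines.append(
                    f"{record}{serial:5d} {pad:<4s}{resname:>4s} {cid}"
                    f"{site.res_index:4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
                    f"  1.00  0.00          {element:>2s}"
                )
                serial += 1
        lines.append(f"TER   {serial:5d}")
        serial += 1
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def residue_z(site: ResidueSite) -> float:
    """Signed membrane-frame z of a residue: CA if present, else the
    all-atom centroid."""
    if not site.atoms:
        raise InvalidResidueError("residue has no atoms")
    for name, _x, _y, z in site.atoms:
        if name.strip().upper() == "CA":
            return float(z)
    return float(np.mean([a[3] for a in site.atoms]))


def classify_region(z: float) -> Region:
    """Map |z| to membrane core / lipid-water interface / non-membrane."""
    if not math.isfinite(z):
        raise DomainError(f"non-finite z: {z!r}")
    az = abs(z)
    if az < CORE_MAX_Z:
        return Region.CORE
    if az <= INTERFACE_MAX_Z:
        return Region.INTERFACE
    return Region.NONMEMBRANE


def aa_class(aa: str) -> AAClass:
    """Physico-chemical class of a standard amino acid."""
    aa = aa.upper()
    if aa in HYDROPHOBIC:
        return AAClass.HYDROPHOBIC
    if aa in WEAKLY_POLAR:
        return AAClass.WEAKLY_POLAR
    if aa in STRONGLY_POLAR:
        return AAClass.STRONGLY_POLAR
    raise UnknownResidueError(f"not a standard amino acid: {aa!r}")
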