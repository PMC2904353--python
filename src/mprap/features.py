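"""Feature assembly: PSSM parsing and window encodings.

Each residue is described by a symmetric window (default 9) over its
chain; every window slot contributes 20 raw profile log-odds scores, one
normalised substitution rate, one membrane-frame z value (clamped to
+-40 A) and one padding flag, giving 9 x 23 = 207 features.  Slots that
fall off either terminus carry a zero payload and padding flag 1.  Raw
integer log-odds are used deliberately: they outperform frequencies or
rescaled profiles for this task.

The z input can come from the structure itself or from a per-residue
predicted-distance table (the externally predicted variant performs
slightly better in practice because crystallised membrane slabs are not
always centred on the hydrophobic stretch).
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import AlignmentError, DomainError, FormatError
from .structio import Structure, residue_z

# Column order of the classic iterative-profile ASCII output.
PSSM_ALPHABET = "ARNDCQEGHILKMFPSTWYV"
Z_CLAMP = 40.0
DEFAULT_WINDOW = 9
SLOT_WIDTH = 20 + 1 + 1 + 1  # pssm + rate + z + padding flag


@dataclass
class Pssm:
    """L x 20 integer log-odds, columns in :data:`PSSM_ALPHABET` order."""

    scores: np.ndarray
    letters: str

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2 or self.scores.shape[1] != 20:
            raise FormatError("PSSM must have exactly 20 score columns")
        if len(self.letters) != len(self.scores):
            raise FormatError("PSSM row letters do not match score rows")

    def __len__(self):
        return len(self.scores)


@dataclass
class ZSource:
    """Per-residue membrane-frame z values.

    ``mode`` records provenance: 'structure' (true coordinates) or
    'table' (externally predicted distances).
    """

    mode: str
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if not np.isfinite(self.values).all():
            raise DomainError("z table contains non-finite values")

    @classmethod
    def from_structure(cls, structure: Structure, chain_id: str) -> "ZSource":
        structure.require_oriented()
        zs = [residue_z(s) for s in structure.chains[chain_id]]
        return cls(mode="structure", values=np.array(zs))

    @classmethod
    def from_table(cls, path, query_length: int) -> "ZSource":
        values = read_z_table(path, query_length)
        return cls(mode="table", values=values)

    def __len__(self):
        return len(self.values)


@dataclass
class FeatureVector:
    """One window encoding; ``center_index`` is the 1-based residue."""

    values: np.ndarray
    center_index: int


def read_pssm(path, query: str | None = None) -> Pssm:
    """Parse the ASCII PSSM dialect: rows of index, residue letter, 20
    integer log-odds (the trailing percentage block and per-position
    statistics are ignored)."""
    path = Path(path)
    rows, letters = [], []
    expected = 1
    for line in path.read_text().splitlines():
        fields = line.split()
        if len(fields) < 22 or not fields[0].isdigit():
            continue
        idx = int(fields[0])
        if idx != expected:
            raise FormatError(
                f"{path}: row index {idx} out of order (expected {expected})")
        letter = fields[1].upper()
        if len(letter) != 1 or not letter.isalpha():
            raise FormatError(f"{path}: bad residue letter {fields[1]!r}")
        try:
            scores = [int(v) for v in fields[2:22]]
        except ValueError as exc:
            raise FormatError(
                f"{path}: malformed score row {idx}") from exc
        rows.append(scores)
        letters.append(letter)
        expected += 1
    if not rows:
        raise FormatError(f"{path}: no PSSM score rows found")
    pssm = Pssm(scores=np.array(rows), letters="".join(letters))
    if query is not None:
        if len(query) != len(pssm):
            raise FormatError(
                f"{path}: PSSM length {len(pssm)} vs query {len(query)}")
        for i, (a, b) in enumerate(zip(pssm.letters, query.upper()), start=1):
            if a != b and "X" not in (a, b):
                raise FormatError(
                    f"{path}: row {i} letter {a} != query letter {b}")
    return pssm


def read_z_table(path, query_length: int) -> np.ndarray:
    """Two-column TSV (res_index, z in Angstrom); header optional."""
    path = Path(path)
    values: dict[int, float] = {}
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t") if "\t" in line else line.split()
        try:
            idx, z = int(fields[0]), float(fields[1])
        except (ValueError, IndexError):
            if not values:  # tolerate a single header line
                continue
            raise FormatError(f"{path}: malformed z row {line!r}")
        values[idx] = z
    if set(values) != set(range(1, query_length + 1)):
        raise AlignmentError(
            f"{path}: z table does not cover residues 1..{query_length}")
    return np.array([values[i] for i in range(1, query_length + 1)])


def build_features(pssm: Pssm, rates, z: ZSource,
                   window: int = DEFAULT_WINDOW) -> list[FeatureVector]:
    """One 207-dimensional window encoding per residue."""
    if window % 2 == 0 or window < 1:
        raise DomainError(f"window must be a positive odd integer, got {window}")
    rate_values = np.asarray(getattr(rates, "rates", rates), dtype=float)
    length = len(pssm)
    if not (len(rate_values) == length == len(z)):
        raise AlignmentError(
            f"length mismatch: pssm={length} rates={len(rate_values)} "
            f"z={len(z)}")
    half = window // 2
    zc = np.clip(z.values, -Z_CLAMP, Z_CLAMP)
    out = []
    for center in range(length):
        vec = np.zeros(window * SLOT_WIDTH)
        for slot, pos in enumerate(range(center - half, center + half + 1)):
            base = slot * SLOT_WIDTH
            if 0 <= pos < length:
                vec[base:base + 20] = pssm.scores[pos]
                vec[base + 20] = rate_values[pos]
                vec[base + 21] = zc[pos]
            else:
                vec[base + 22] = 1.0
        out.append(FeatureVector(values=vec, center_index=center + 1))
    return out


def feature_matrix(vectors: list[FeatureVector]) -> np.ndarray:
    return np.vstack([v.values for v in vectors])


def write_feature_tsv(vectors: list[FeatureVector], path) -> None:
    mat = feature_matrix(vectors)
    header = "res_index\t" + "\t".join(
        f"f{i}" for i in range(mat.shape[1]))
    with open(path, "w") as fh:
        fh.write(header + "\n")
        for v in vectors:
            fh.write(str(v.center_index) + "\t" +
                     "\t".join(f"{x:g}" for x in v.values) + "\n")
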