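"""Per-residue evolutionary rates from multiple sequence alignments.

Two sources feed the same normalised profile: a self-contained column
statistic (Shannon entropy of the amino-acid distribution in each query
column, gaps excluded), or a parsed score file from an external
phylogenetic rate program in the common position/residue/score dialect.
Raw scores are z-normalised per protein — subtract the mean, divide by the
(population) standard deviation — so rates are comparable across proteins
regardless of alignment depth.  Sites that are evolving fast score high;
conserved sites score low.
"""
from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import (
    AlignmentError,
    FormatError,
    InsufficientHomologsError,
    MissingDataError,
)

MIN_HOMOLOGS = 4       # fewer identified homologs is flagged, not fatal
MAX_GAP_FRACTION = 0.5  # columns gappier than this get a missing raw rate


@dataclass
class Alignment:
    """Aligned sequences; row ``query_index`` is the structure's sequence."""

    sequences: list  # list of (identifier, aligned string)
    query_index: int = 0

    @property
    def length(self) -> int:
        return len(self.sequences[0][1])

    @property
    def depth(self) -> int:
        return len(self.sequences)

    def query_columns(self) -> list[int]:
        """Alignment columns where the query has a residue (not a gap)."""
        q = self.sequences[self.query_index][1]
        return [i for i, c in enumerate(q) if c != "-"]


@dataclass
class RateProfile:
    """Normalised per-residue rates (z-scores), one per query residue."""

    rates: np.ndarray
    source: str  # "rate4site_file" | "column_statistic"

    def __len__(self):
        return len(self.rates)


def read_alignment(path) -> Alignment:
    """Aligned FASTA; '.' is treated as '-', everything uppercased."""
    path = Path(path)
    seqs: list[tuple[str, str]] = []
    name, parts = None, []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            if name is not None:
                seqs.append((name, "".join(parts)))
            name, parts = line[1:].split()[0] if line[1:] else "", []
        else:
            parts.append(line.upper().replace(".", "-"))
    if name is not None:
        seqs.append((name, "".join(parts)))

    if len(seqs) < 2:
        raise InsufficientHomologsError(
            f"{path}: alignment needs at least 2 rows, found {len(seqs)}")
    lengths = {len(s) for _, s in seqs}
    if len(lengths) != 1:
        raise FormatError(f"{path}: ragged alignment, row lengths {lengths}")
    if len(seqs) - 1 < MIN_HOMOLOGS:
        warnings.warn(
            f"{path}: only {len(seqs) - 1} homolog rows (<{MIN_HOMOLOGS}); "
            "rate estimates will be unreliable", stacklevel=2)
    return Alignment(sequences=seqs)


def site_rate_statistic(alignment: Alignment) -> np.ndarray:
    """Raw rate per query residue: natural-log Shannon entropy of the
    column's amino-acid frequencies, gaps excluded.

    Columns with more than half gaps (or no residues at all) get NaN;
    :func:`normalize_rates` later imputes those at the protein mean.
    """
    cols = alignment.query_columns()
    raw = np.empty(len(cols))
    n_rows = alignment.depth
    for out_i, col in enumerate(cols):
        letters = [s[col] for _, s in alignment.sequences if s[col] != "-"]
        if not letters or 1.0 - len(letters) / n_rows > MAX_GAP_FRACTION:
            raw[out_i] = np.nan
            continue
        counts = np.array(list(Counter(letters).values()), dtype=float)
        p = counts / counts.sum()
        raw[out_i] = float(-(p * np.log(p)).sum())
    return raw


def read_rate4site(path, query_length: int) -> np.ndarray:
    """Parse the plain-text output of a per-site rate program.

    Expected data lines: position, residue letter, score (first three
    whitespace-separated fields); '#' comments and blank lines skipped.
    """
    path = Path(path)
    scores: dict[int, float] = {}
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) < 3:
            raise FormatError(f"{path}: malformed line {line!r}")
        try:
            pos = int(fields[0])
            score = float(fields[2])
        except ValueError as exc:
            raise FormatError(f"{path}: malformed line {line!r}") from exc
        scores[pos] = score
    if len(scores) != query_length or set(scores) != set(
            range(1, query_length + 1)):
        raise AlignmentError(
            f"{path}: {len(scores)} positions do not map onto query of "
            f"length {query_length}")
    return np.array([scores[i] for i in range(1, query_length + 1)])


def normalize_rates(raw, source: str = "column_statistic") -> RateProfile:
    """Z-score raw rates per protein (population SD).

    Degenerate proteins (zero spread) normalise to all zeros; missing
    (NaN) sites are imputed with 0 after normalisation, i.e. the protein
    mean.
    """
    raw = np.asarray(raw, dtype=float)
    finite = np.isfinite(raw)
    if not finite.any():
        raise MissingDataError("all rate values are missing")
    vals = raw[finite]
    mean = vals.mean()
    sd = vals.std()  # population SD: keeps normalisation idempotent
    out = np.zeros_like(raw)
    if sd > 0:
        out[finite] = (vals - mean) / sd
    return RateProfile(rates=out, source=source)


def write_rates_tsv(profile: RateProfile, sequence: str, path) -> None:
    with open(path, "w") as fh:
        fh.write("res_index\taa\trate\n")
        for i, (aa, r) in enumerate(zip(sequence, profile.rates), start=1):
            fh.write(f"{i}\t{aa}\t{r:.6f}\n")
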