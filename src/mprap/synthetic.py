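"""Self-contained synthetic fixtures: oriented helical bundles with known
accessibility, conservation and profile signals.

The generator emulates the statistical structure of real alpha-helical
membrane proteins without any external data:

* geometry — ideal alpha-helices (1.5 A rise, 100 deg twist) packed on a
  ring, spanning the membrane slab; loops and terminal tails arc over the
  bundle ends so the lipid-water interface and the aqueous region are both
  populated, and crossing loops/tails create buried sites outside the
  membrane;
* composition — residues are drawn per (region x burial) cell so that
  hydrophobic fractions match the observed targets: exposed sites are 73%
  hydrophobic in the membrane core but only 19% outside, while buried
  sites differ much less (60% vs 49%); the interface region interpolates;
* conservation — homolog rows substitute each site with probability
  linear in its true relative accessibility, planting the linear
  rate-vs-RSA relationship seen in nature; profile matrices (PSSM) are
  integer log-odds of the resulting column frequencies;
* complexes — C2-symmetric homodimers packed face to face plant a known
  set of interface residues (exposed alone, buried in the dimer).

Everything is a deterministic function of (spec, seed, protein index);
truth labels are computed from the emitted coordinates with the package's
own SASA, never assumed.
"""
from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import _geometry as geom
from .accessibility import (
    DEFAULT_CUTOFF,
    DEFAULT_PROBE,
    BurialState,
    binarize,
    compute_sasa,
    label_interface,
    load_reference_table,
    relative_accessibility,
)
from .conservation import Alignment, site_rate_statistic
from .errors import DomainError, MprapError
from .features import PSSM_ALPHABET, Pssm
from .structio import (
    HYDROPHOBIC,
    Region,
    ResidueSite,
    Structure,
    classify_region,
    write_structure,
)

HYDROPHOBIC_AAS = sorted(HYDROPHOBIC)
OTHER_AAS = sorted(set(geom.AA_ORDER) - HYDROPHOBIC)

# Hydrophobic fraction targets per (region, burial) cell; the interface
# region interpolates linearly between core and nonmembrane.
DEFAULT_COMPOSITION = {
    (Region.CORE, BurialState.EXPOSED): 0.73,
    (Region.CORE, BurialState.BURIED): 0.60,
    (Region.NONMEMBRANE, BurialState.EXPOSED): 0.19,
    (Region.NONMEMBRANE, BurialState.BURIED): 0.49,
    (Region.INTERFACE, BurialState.EXPOSED): 0.46,
    (Region.INTERFACE, BurialState.BURIED): 0.545,
}


@dataclass
class SyntheticSpec:
    """Study conditions for the fixture corpus (seed fully determines
    every file)."""

    n_proteins: int = 40
    n_families: int = 5
    helices_range: tuple = (3, 4)
    helix_length_range: tuple = (20, 22)
    loop_length: int = 8
    tail_length: int = 6
    composition: dict = field(default_factory=lambda: dict(DEFAULT_COMPOSITION))
    rate_base: float = 0.08
    rate_coupling: float = 0.55
    alignment_depth: int = 30
    noise_sd: float = 10.0
    probe: float = DEFAULT_PROBE
    cutoff: float = DEFAULT_CUTOFF
    seed: int = 1

    def __post_init__(self):
        for cell, frac in self.composition.items():
            if not 0.0 <= frac <= 1.0:
                raise DomainError(f"composition fraction out of [0,1]: {cell}")
        if self.rate_base + self.rate_coupling > 1.0 or self.rate_base < 0:
            raise DomainError(
                "substitution probability base+coupling must stay within [0,1]")


@dataclass
class FixtureBundle:
    """One synthetic protein with all mutually consistent views."""

    name: str
    family: str
    structure: Structure            # single chain (or dimer for complexes)
    sequence: str
    alignment: Alignment
    pssm: Pssm
    raw_rates: np.ndarray
    z: np.ndarray                   # true CA z per residue (chain A)
    truth: pd.DataFrame             # res_index, aa, z, region, rsa, state, ...
    is_complex: bool = False


# ---------------------------------------------------------------------------
# geometry

def _family_params(spec: SyntheticSpec, family_index: int) -> dict:
    rng = np.random.default_rng([spec.seed % (2 ** 31), 7919, family_index])
    n_h = int(rng.integers(spec.helices_range[0], spec.helices_range[1] + 1))
    helix_len = int(rng.integers(spec.helix_length_range[0],
                                 spec.helix_length_range[1] + 1))
    return {
        "n_helices": n_h,
        "helix_length": helix_len,
        "phases": rng.uniform(0, 2 * math.pi, size=n_h),
        "ring_radius": 4.7 / math.sin(math.pi / n_h),
    }


def _ca_trace(spec: SyntheticSpec, params: dict, rng) -> tuple[np.ndarray, list]:
    """Ordered CA coordinates plus a per-residue segment tag
    ('helix<k>', 'loop', 'tail')."""
    n_h = params["n_helices"]
    if n_h < 2:
        raise MprapError("need at least 2 helices to create buried residues")
    L = params["helix_length"]
    R = params["ring_radius"]
    span = (L - 1) * geom.HELIX_RISE
    z_lo, z_hi = -span / 2.0, span / 2.0

    helices = []
    for k in range(n_h):
        ang = 2 * math.pi * k / n_h
        axis = (R * math.cos(ang), R * math.sin(ang))
        direction = 1 if k % 2 == 0 else -1
        phase = params["phases"][k] + rng.normal(0, 0.15)
        z_start = z_lo if direction == 1 else z_hi
        helices.append(geom.helix_ca_positions(L, axis, z_start,
                                               direction, phase))

    ca, tags = [], []

    def arc_over(p0, p1, height, n_pts, pull=0.15):
        """Bezier whose control point sits near the bundle axis, ``height``
        above/below the helix ends, so consecutive arcs cross and occlude
        each other."""
        sign = 1.0 if (p0[2] + p1[2]) > 0 else -1.0
        mid = (np.asarray(p0) + np.asarray(p1)) / 2.0
        ctrl = np.array([mid[0] * pull, mid[1] * pull,
                         sign * (abs(mid[2]) + height)])
        return geom.bezier_arc(p0, p1, ctrl, n_pts)

    # N-terminal tail: drapes over the bundle end, descending outward
    first = helices[0][0]
    sign = 1.0 if first[2] > 0 else -1.0
    far = np.array([-1.4 * first[0], -1.4 * first[1],
                    sign * (abs(first[2]) + 8.0)])
    tail = arc_over(far, first, 10.0, spec.tail_length)
    for p in tail:
        ca.append(p)
        tags.append("tail")

    for k in range(n_h):
        for p in helices[k]:
            ca.append(p)
            tags.append(f"helix{k}")
        if k + 1 < n_h:
            p0, p1 = helices[k][-1], helices[k + 1][0]
            height = 12.0 + 4.0 * (k % 2) + rng.normal(0, 0.5)
            for p in arc_over(p0, p1, height, spec.loop_length):
                ca.append(p)
                tags.append("loop")

    last = helices[-1][-1]
    sign = 1.0 if last[2] > 0 else -1.0
    far = np.array([-1.4 * last[0], -1.4 * last[1],
                    sign * (abs(last[2]) + 8.0)])
    tail = arc_over(last, far, 10.0, spec.tail_length)
    for p in tail:
        ca.append(p)
        tags.append("tail")

    return np.array(ca), tags


def _facing(ca_xy: np.ndarray, normal_xy: np.ndarray) -> str:
    """Whether a helix side chain points toward or away from the bundle
    axis (the z axis)."""
    r = np.linalg.norm(ca_xy)
    if r < 1e-6:
        return "side"
    cos = -float(np.dot(normal_xy, ca_xy)) / (
        np.linalg.norm(normal_xy) * r + 1e-12)
    if cos > 0.3:
        return "inward"
    if cos < -0.3:
        return "outward"
    return "side"


def _normals(ca: np.ndarray, tags: list, params: dict) -> np.ndarray:
    """Side-chain directions: radially out of the local helix axis for
    helix residues, away from the bundle axis elsewhere."""
    n_h = params["n_helices"]
    R = params["ring_radius"]
    axes = {f"helix{k}": np.array([R * math.cos(2 * math.pi * k / n_h),
                                   R * math.sin(2 * math.pi * k / n_h)])
            for k in range(n_h)}
    out = np.zeros_like(ca)
    for i, (pos, tag) in enumerate(zip(ca, tags)):
        if tag in axes:
            v = pos[:2] - axes[tag]
            if np.linalg.norm(v) < 1e-6:
                v = np.array([1.0, 0.0])
            out[i] = [v[0], v[1], 0.0]
        else:
            # loop/tail residues alternate like an extended strand: side
            # chains point alternately into solvent (up, away from the
            # bundle) and down toward the bundle end, so arc residues are
            # bimodally buried/exposed rather than uniformly intermediate
            r = pos[:2]
            if np.linalg.norm(r) < 1e-6:
                r = np.array([1.0, 0.0])
            r = r / np.linalg.norm(r)
            up = 1.0 if pos[2] >= 0 else -1.0
            if i % 2 == 0:
                out[i] = [1.0 * r[0], 1.0 * r[1], 0.8 * up]
            else:
                out[i] = [-0.25 * r[0], -0.25 * r[1], -1.2 * up]
    return out


def _build_structure(ca: np.ndarray, tags: list, params: dict,
                     sequence: str, name: str, chain_id: str = "A",
                     transform=None) -> Structure:
    """Atoms for a CA trace + sequence; coordinates rounded to 3 decimals
    so emitted PDB files reproduce them exactly."""
    _, tangents = geom.chain_frames(ca)
    normals = _normals(ca, tags, params)
    sites = []
    for i, aa in enumerate(sequence):
        atoms = geom.residue_atoms(aa, ca[i], tangents[i], normals[i])
        if transform is not None:
            atoms = [(n, *transform(np.array([x, y, z])))
                     for n, x, y, z in atoms]
        atoms = [(n, round(x, 3), round(y, 3), round(z, 3))
                 for n, x, y, z in atoms]
        sites.append(ResidueSite(chain_id, i + 1, aa, atoms))
    return Structure(pdb_id=name, chains={chain_id: sites}, oriented=True)


def generate_structure(spec: SyntheticSpec, protein_index: int,
                       family_index: int | None = None):
    """Deterministic helical-bundle geometry for one protein.

    Returns (ca coordinates, segment tags, family params).  Proteins in
    the same family share fold parameters and differ by small jitter.
    """
    if family_index is None:
        family_index = protein_index % spec.n_families
    params = _family_params(spec, family_index)
    rng = np.random.default_rng([spec.seed % (2 ** 31), 104729, protein_index])
    ca, tags = _ca_trace(spec, params, rng)
    return ca, tags, params


# ---------------------------------------------------------------------------
# sequence and labels

def sample_aa(region: Region, burial: BurialState, spec: SyntheticSpec,
              rng) -> str:
    """Draw one residue from the (region x burial) composition cell."""
    frac = spec.composition[(region, burial)]
    if rng.random() < frac:
        return HYDROPHOBIC_AAS[rng.integers(len(HYDROPHOBIC_AAS))]
    return OTHER_AAS[rng.integers(len(OTHER_AAS))]


def _x_reference_area(probe: float) -> float:
    """Extended-tripeptide area of the generic 'X' residue used by the
    burial proxy before a sequence exists."""
    residues = geom.extended_tripeptide("X")
    coords, radii = [], []
    for res_atoms, aa in zip(residues, ["A", "X", "A"]):
        for n, x, y, z in res_atoms:
            coords.append((x, y, z))
            radii.append(geom.atom_radius(n, aa))
    from .accessibility import atom_sasa
    areas = atom_sasa(np.array(coords), np.array(radii), probe)
    n0, n1 = len(residues[0]), len(residues[1])
    return float(areas[n0:n0 + n1].sum())


def assign_sequence(structure: Structure, spec: SyntheticSpec, rng,
                    context: str = "single_chain") -> dict:
    """Amino acids drawn per (region x burial) cell.

    Burial comes from a proxy SASA pass over the sequence-free geometry
    (every residue a generic 'X'); region from the CA z.  Returns
    chain_id -> sequence string (identical across chains of a symmetric
    complex is NOT assumed here; the caller decides).
    """
    prof = compute_sasa(structure, probe=spec.probe, context=context)
    ref_x = _x_reference_area(spec.probe)
    rsa = {(r.chain, r.res_index): 100.0 * r.abs_asa / ref_x
           for r in prof.table.itertuples()}
    sequences = {}
    for cid, sites in structure.chains.items():
        seq = []
        for s in sites:
            region = classify_region(s.z)
            burial = binarize(rsa[(cid, s.res_index)], spec.cutoff)
            seq.append(sample_aa(region, burial, spec, rng))
        sequences[cid] = "".join(seq)
    return sequences


# ---------------------------------------------------------------------------
# alignment, rates, PSSM

def generate_alignment(sequence: str, true_rsa: np.ndarray,
                       spec: SyntheticSpec, rng, name: str = "query"):
    """Homolog rows mutated with per-site probability linear in true RSA.

    The per-site substitution probability is linear in the true RSA
    blurred by ``spec.noise_sd`` (evolution does not see accessibility
    noise-free).  Returns (Alignment, raw column-entropy rates, Pssm).
    """
    if spec.alignment_depth < 5:
        raise DomainError("alignment_depth must be at least 5")
    rsa_eff = np.asarray(true_rsa, dtype=float)
    if spec.noise_sd > 0:
        rsa_eff = np.clip(
            rsa_eff + rng.normal(0.0, spec.noise_sd, len(rsa_eff)), 0.0, 100.0)
    p = spec.rate_base + spec.rate_coupling * rsa_eff / 100.0
    if (p < 0).any() or (p > 1).any():
        raise DomainError("rate coupling drives substitution probability "
                          "outside [0, 1]")
    L = len(sequence)
    aas = list(geom.AA_ORDER)
    rows = [(name, sequence)]
    for h in range(spec.alignment_depth - 1):
        mutate = rng.random(L) < p
        row = [aas[rng.integers(20)] if m else c
               for c, m in zip(sequence, mutate)]
        rows.append((f"homolog{h + 1:03d}", "".join(row)))
    alignment = Alignment(sequences=rows, query_index=0)
    raw = site_rate_statistic(alignment)
    pssm = _pssm_from_alignment(alignment)
    return alignment, raw, pssm


def _pssm_from_alignment(alignment: Alignment) -> Pssm:
    """Integer log-odds of column frequencies vs a uniform background,
    emulating an iterative-profile search's ASCII matrix."""
    q = alignment.sequences[alignment.query_index][1]
    depth = alignment.depth
    bg = 1.0 / 20.0
    scores = np.zeros((len(q), 20))
    for i in range(len(q)):
        counts = {aa: 0 for aa in PSSM_ALPHABET}
        for _, s in alignment.sequences:
            if s[i] != "-":
                counts[s[i]] = counts.get(s[i], 0) + 1
        total = sum(counts.values())
        for j, aa in enumerate(PSSM_ALPHABET):
            freq = (counts[aa] + bg) / (total + 1.0)
            scores[i, j] = round(2.0 * math.log2(freq / bg))
    return Pssm(scores=scores, letters=q)


# ---------------------------------------------------------------------------
# bundle assembly

def _truth_table(structure: Structure, spec: SyntheticSpec,
                 tags_by_chain: dict, facing_by_chain: dict,
                 with_complex: bool) -> pd.DataFrame:
    ref = load_reference_table(spec.probe)
    single = relative_accessibility(
        compute_sasa(structure, probe=spec.probe, context="single_chain"), ref)
    rsa_single = single.rsa_map()
    if with_complex:
        cx = relative_accessibility(
            compute_sasa(structure, probe=spec.probe, context="complex"), ref)
        rsa_complex = cx.rsa_map()
    rows = []
    for cid, sites in structure.chains.items():
        for i, s in enumerate(sites):
            key = (cid, s.res_index)
            rs = rsa_single[key]
            rec = {
                "chain": cid, "res_index": s.res_index, "aa": s.aa,
                "z": s.z, "region": classify_region(s.z).value,
                "segment": tags_by_chain[cid][i],
                "facing": facing_by_chain[cid][i],
                "rsa_single": rs,
                "state_single": binarize(rs, spec.cutoff).value,
            }
            if with_complex:
                rc = rsa_complex[key]
                rec["rsa_complex"] = rc
                rec["state_complex"] = binarize(rc, spec.cutoff).value
                rec["interface"] = label_interface(rs, rc, spec.cutoff).value
            rows.append(rec)
    return pd.DataFrame(rows)


def _facings(ca: np.ndarray, tags: list, params: dict) -> list:
    normals = _normals(ca, tags, params)
    return [
        _facing(ca[i][:2], normals[i][:2]) if tags[i].startswith("helix")
        else "none"
        for i in range(len(ca))
    ]


def generate_protein(spec: SyntheticSpec, protein_index: int) -> FixtureBundle:
    """One single-chain fixture: structure, sequence, alignment, PSSM,
    rates, z and truth, all mutually consistent."""
    family_index = protein_index % spec.n_families
    ca, tags, params = generate_structure(spec, protein_index, family_index)
    name = f"syn{protein_index:03d}"
    rng = np.random.default_rng([spec.seed % (2 ** 31), 15485863,
                                 protein_index])

    proxy = _build_structure(ca, tags, params, "X" * len(ca), name)
    seq = assign_sequence(proxy, spec, rng)["A"]
    structure = _build_structure(ca, tags, params, seq, name)

    truth = _truth_table(structure, spec, {"A": tags},
                         {"A": _facings(ca, tags, params)},
                         with_complex=False)
    alignment, raw, pssm = generate_alignment(
        seq, truth["rsa_single"].to_numpy(), spec, rng, name=name)
    z = truth["z"].to_numpy()
    return FixtureBundle(name=name, family=f"fam{family_index}",
                         structure=structure, sequence=seq,
                         alignment=alignment, pssm=pssm, raw_rates=raw,
                         z=z, truth=truth)


def generate_complex(spec: SyntheticSpec, protein_index: int,
                     separation: float | None = None) -> FixtureBundle:
    """A C2-symmetric homodimer with planted interface residues.

    Chain B is chain A rotated 180 degrees about z and translated along x
    so the two bundles pack face to face: residues on the contact face
    are exposed in the single chain but buried in the dimer.
    """
    family_index = protein_index % spec.n_families
    ca, tags, params = generate_structure(spec, protein_index, family_index)
    name = f"cpx{protein_index:03d}"
    rng = np.random.default_rng([spec.seed % (2 ** 31), 32452843,
                                 protein_index])
    if separation is None:
        separation = 2.0 * params["ring_radius"] + 5.0

    def place_b(p):
        return (separation - p[0], -p[1], p[2])

    def dimer(sequence: str) -> Structure:
        a = _build_structure(ca, tags, params, sequence, name, "A")
        b = _build_structure(ca, tags, params, sequence, name, "B",
                             transform=place_b)
        return Structure(pdb_id=name,
                         chains={"A": a.chains["A"], "B": b.chains["B"]},
                         oriented=True)

    proxy = dimer("X" * len(ca))
    # Homodimer: one sequence, drawn from chain A's complex-context burial
    # so interface residues get buried-like composition, as in real
    # oligomer structures.
    prof = compute_sasa(proxy, probe=spec.probe, context="complex")
    ref_x = _x_reference_area(spec.probe)
    rsa = {(r.chain, r.res_index): 100.0 * r.abs_asa / ref_x
           for r in prof.table.itertuples()}
    seq = "".join(
        sample_aa(classify_region(s.z),
                  binarize(rsa[("A", s.res_index)], spec.cutoff), spec, rng)
        for s in proxy.chains["A"])
    structure = dimer(seq)

    facings = _facings(ca, tags, params)
    truth = _truth_table(structure, spec,
                         {"A": tags, "B": tags},
                         {"A": facings, "B": facings},
                         with_complex=True)
    # conservation couples to the complex-context accessibility: interface
    # residues behave like buried ones evolutionarily
    rsa_a = truth[truth["chain"] == "A"]["rsa_complex"].to_numpy()
    alignment, raw, pssm = generate_alignment(seq, rsa_a, spec, rng, name=name)
    z = truth[truth["chain"] == "A"]["z"].to_numpy()
    return FixtureBundle(name=name, family=f"fam{family_index}",
                         structure=structure, sequence=seq,
                         alignment=alignment, pssm=pssm, raw_rates=raw,
                         z=z, truth=truth, is_complex=True)


def generate_corpus(spec: SyntheticSpec) -> list:
    """The training corpus: ``spec.n_proteins`` single-chain bundles."""
    return [generate_protein(spec, i) for i in range(spec.n_proteins)]


# ---------------------------------------------------------------------------
# serialization

def write_pssm_file(pssm: Pssm, path) -> None:
    """ASCII matrix in the iterative-profile dialect the parser reads."""
    lines = [
        "",
        "Last position-specific scoring matrix computed, weighted observed "
        "percentages rounded down, information per position, and relative "
        "weight of gapless real matches to pseudocounts",
        "            " + "   ".join(PSSM_ALPHABET) + "   "
        + "   ".join(PSSM_ALPHABET),
    ]
    for i, (letter, row) in enumerate(zip(pssm.letters, pssm.scores), 1):
        ints = " ".join(f"{int(v):3d}" for v in row)
        pcts = " ".join(f"{max(0, int(v)) * 5:3d}" for v in row)
        lines.append(f"{i:5d} {letter}  {ints}  {pcts}  0.00 0.00")
    lines.append("")
    Path(path).write_text("\n".join(lines) + "\n")


def write_rate4site_file(raw_rates: np.ndarray, sequence: str, path) -> None:
    lines = ["# raw per-site substitution rates (column statistic)",
             "# POS SEQ SCORE"]
    for i, (aa, r) in enumerate(zip(sequence, raw_rates), 1):
        v = 0.0 if not np.isfinite(r) else r
        lines.append(f"{i:5d} {aa} {v:9.5f}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_alignment_file(alignment: Alignment, path) -> None:
    with open(path, "w") as fh:
        for name, seq in alignment.sequences:
            fh.write(f">{name}\n{seq}\n")


def write_bundle(bundle: FixtureBundle, outdir) -> dict:
    """Write all views of one bundle; returns {filename: sha256}."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    n = bundle.name
    write_structure(bundle.structure, outdir / f"{n}.pdb")
    write_alignment_file(bundle.alignment, outdir / f"{n}.afa")
    write_pssm_file(bundle.pssm, outdir / f"{n}.pssm")
    write_rate4site_file(bundle.raw_rates, bundle.sequence,
                         outdir / f"{n}.r4s")
    with open(outdir / f"{n}_z.tsv", "w") as fh:
        fh.write("res_index\tz\n")
        for i, z in enumerate(bundle.z, 1):
            fh.write(f"{i}\t{z:.3f}\n")
    bundle.truth.to_csv(outdir / f"{n}_truth.tsv", sep="\t", index=False,
                        float_format="%.3f")
    files = [f"{n}.pdb", f"{n}.afa", f"{n}.pssm", f"{n}.r4s",
             f"{n}_z.tsv", f"{n}_truth.tsv"]
    return {f: hashlib.sha256((outdir / f).read_bytes()).hexdigest()
            for f in files}


def write_corpus(bundles: list, outdir, spec: SyntheticSpec) -> Path:
    """Write every bundle plus a manifest with checksums and families."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": spec.seed, "n_proteins": len(bundles), "proteins": {}}
    for b in bundles:
        checksums = write_bundle(b, outdir)
        manifest["proteins"][b.name] = {
            "family": b.family, "length": len(b.sequence),
            "is_complex": b.is_complex, "files": checksums,
        }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path

# ---------------------------------------------------------------------------
# pipeline glue

def bundle_chain_data(bundle: FixtureBundle, window: int | None = None):
    """Assemble one :class:`mprap.model.ChainData` from a bundle.

    Features use the bundle's PSSM, normalised column rates and the true-z
    table; the regression target is single-chain RSA for monomers and
    full-complex RSA for complexes (interfaces count as buried, as in
    training on real oligomeric structures).
    """
    from .conservation import normalize_rates
    from .features import DEFAULT_WINDOW, ZSource, build_features, feature_matrix
    from .model import ChainData

    window = DEFAULT_WINDOW if window is None else window
    rates = normalize_rates(bundle.raw_rates)
    z = ZSource(mode="table", values=bundle.z)
    vectors = build_features(bundle.pssm, rates, z, window=window)
    truth_a = bundle.truth[bundle.truth["chain"] == "A"]
    y_col = "rsa_complex" if bundle.is_complex else "rsa_single"
    return ChainData(
        chain_key=bundle.name,
        family=bundle.family,
        X=feature_matrix(vectors),
        y_rsa=truth_a[y_col].to_numpy(dtype=float),
        z=truth_a["z"].to_numpy(dtype=float),
    )


def load_bundle(directory, name: str, family: str,
                is_complex: bool = False) -> FixtureBundle:
    """Read one bundle back through the package's own file readers."""
    from .conservation import read_alignment, read_rate4site
    from .features import read_pssm, read_z_table
    from .structio import read_structure

    directory = Path(directory)
    structure = read_structure(directory / f"{name}.pdb")
    truth = pd.read_csv(directory / f"{name}_truth.tsv", sep="\t")
    seq = "".join(truth[truth["chain"] == "A"]["aa"])
    alignment = read_alignment(directory / f"{name}.afa")
    pssm = read_pssm(directory / f"{name}.pssm", query=seq)
    raw = read_rate4site(directory / f"{name}.r4s", query_length=len(seq))
    z = read_z_table(directory / f"{name}_z.tsv", query_length=len(seq))
    return FixtureBundle(name=name, family=family, structure=structure,
                         sequence=seq, alignment=alignment, pssm=pssm,
                         raw_rates=raw, z=z, truth=truth,
                         is_complex=is_complex)


def load_corpus(directory) -> list:
    """Load every bundle listed in a fixture directory's manifest."""
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    return [
        load_bundle(directory, name, info["family"], info["is_complex"])
        for name, info in manifest["proteins"].items()
    ]
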