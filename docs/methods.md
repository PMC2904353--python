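# Methods

## Scope and model

The package predicts per-residue relative solvent accessibility (RSA,
percent of the residue's maximum area) for α-helical membrane proteins
from sequence-derived inputs, and evaluates that prediction in the
membrane frame. Structures are assumed pre-oriented: membrane normal
along z, membrane centre at z = 0. Three regions are defined from the
residue z coordinate (Cα when present, otherwise the all-atom
centroid): membrane core |z| < 10 Å, lipid–water interface
10 ≤ |z| ≤ 22 Å, non-membrane |z| > 22 Å. The outer regions are defined
by strict inequalities, so values exactly on a boundary fall in the
interface. The 20 amino acids partition into hydrophobic (A F I L M V),
weakly polar (G Y W C S T) and strongly polar (D E K R H N P Q) classes
on the biological hydrophobicity scale.

## Solvent-accessible surface area

SASA uses the Shrake–Rupley construction: each atom's van der Waals
sphere is inflated by the probe radius (default 1.4 Å, water-sized; 2.0 Å
approximates a CH₂ group), covered with a deterministic Fibonacci
lattice (960 points by default), and the fraction of points outside all
neighbouring inflated spheres, times the sphere area, is the atom's
accessible area. Residue areas are atom sums. Van der Waals radii are
element-keyed (C 1.70, N 1.55, O 1.52, S 1.80, H 1.20, P 1.80; 1.80 for
anything else). An isolated atom's area is exact by construction; on
random small molecules the lattice agrees with a 10⁶-point Monte-Carlo
rejection oracle to well under 2%.

RSA divides a residue's area by the area the same residue type attains
in an extended Ala-X-Ala tripeptide built from the same coarse atom
model. The reference tables for probes 1.4 and 2.0 Å ship with the
package (`mprap/data/rsa_reference.json`, denser 4000-point lattice) and
can be regenerated with `compute_reference_areas`. Burial is binary:
RSA < 25% is buried, ≥ 25% exposed (strict "less than" for buried; a
residue exactly at the cutoff is exposed). Training labels can
alternatively mix probes (2.0 Å inside a |z| ≤ 15 Å slab, 1.4 Å
outside) via a labelling-policy flag; pure 1.4 Å is the default. A
residue with single-chain RSA above the cutoff but full-complex RSA
below it is an interface residue.

## Conservation

The default per-site rate statistic is the natural-log Shannon entropy
of each query column's amino-acid distribution, gaps excluded; columns
with more than 50% gaps are treated as missing. Output files of an
external phylogenetic rate program (position / residue / score columns)
are accepted as a drop-in source. Raw rates are z-normalised per
protein (population standard deviation, which makes normalisation
idempotent; zero-spread proteins map to all zeros rather than erroring,
so degenerate toy inputs stay usable). Missing sites are imputed at the
protein mean (0 after normalisation). The entropy statistic applies no
sequence weighting; strongly redundant alignments will compress its
dynamic range. This is a deliberate simplification — phylogeny-aware
rate inference is treated as an external, pluggable step.

## Features

Each residue is encoded by a symmetric window of 9 positions; per
position: 20 raw integer profile log-odds (raw PSSM scores outperform
frequencies or rescaled scores for this task), the normalised rate, the
membrane-frame z clamped to ±40 Å (a bound on soluble-loop excursions
that keeps the feature scale finite), and a padding flag. Off-terminus
positions carry a zero payload with flag 1. The encoding is
207-dimensional regardless of protein length, shift-equivariant in the
interior, and local (one site's inputs touch at most 9 vectors). The z
input is per window slot, symmetric with the other inputs. z may come
from the structure or from a predicted-distance table; the table route
is the default in training since crystallised membrane slabs are not
always centred on the hydrophobic stretch.

## Training

The predictor is an ε-insensitive SVR (ε = 0.1 on the 0–100 RSA scale)
on real RSA targets; predictions are clamped to [0, 100]. A binary
screening mode (SVC on buried/exposed labels) exists for input
comparisons. Grid search covers C from 0.25 to 50 (the full 0.25-step
lattice is available; the default sub-samples 16 points, and a coarse
desk-scale grid uses C ∈ {5, 50} × γ ∈ {0.0005, 0.0015}), polynomial
exponents {2, 3, 4}, and rbf γ log-spaced in [0.0005, 0.05]. Model
selection maximises *out-of-fold* MCC after optimising the
real-to-binary cutoff over the half-integer lattice 0.5–99.5 (ties go
to the smallest cutoff); the winning grid point is refit on all data.
Cross-validation is 5-fold with whole families assigned to folds
(largest family first into the smallest fold after a seeded shuffle),
so no family ever spans a train/test boundary. All stochastic choices
derive from one integer seed recorded in the model metadata. Models
persist as JSON metadata plus a serialized-regressor blob; the metadata
alone validates schema compatibility.

For combining a membrane-specialised and a soluble-specialised
predictor, a z-gate trusts the membrane predictor strictly inside
|z| < 12.5 Å and the soluble one elsewhere.

## Evaluation

Buried is the positive class: TP = buried predicted buried, FN = buried
predicted exposed, TN = exposed predicted exposed, FP = exposed
predicted buried. Reports give accuracy, sensitivity, specificity and
MCC overall and per region, plus MAE (RSA points) and Pearson
correlation for the real-valued output. Zero-denominator rates are
reported as 0 with a warning inside `metrics`; empty strata report
missing values rather than zeros so degenerate fixtures fail loudly.
Structure QA scores the agreement between structure-derived and
sequence-predicted burial; MCC below 0.3 flags the structure as
suspicious (the threshold sits between published scores of retracted
structures, ≤ 0.26, and of their corrected successors, ≥ 0.64; it is
configurable). The interface sweep, restricted to residues exposed in
the single chain, plots the fraction of true interface residues
predicted below each RSA cutoff against the fraction of non-interface
residues above it, with precision reported per cutoff.

## Synthetic data

The generator emits, per protein: an oriented PDB file, an aligned
FASTA, a PSSM in the classic ASCII dialect, a rate file, a true-z table
and a truth TSV — all deterministic functions of (spec, seed, index)
and mutually consistent (truth RSA is recomputed from the emitted
coordinates, never assumed; coordinates are rounded to the PDB's three
decimals before labelling so files reproduce the labels exactly).

Geometry: ideal α-helices (rise 1.5 Å, twist 100°/residue, Cα radius
2.3 Å) packed antiparallel on a ring sized so neighbouring helices
touch, spanning z ≈ ±15 Å; residues are four backbone atoms plus one
pseudo-side-chain sphere whose radius scales with the amino acid.
Helix side chains point radially out of their local helix, so
ring-inward residues are buried against the bundle. Loops arc over the
bundle ends through |z| > 22 Å and terminal tails thread beneath them;
arc side chains alternate between solvent (up/outward) and the bundle
end (down/inward), giving buried and exposed sites in the interface and
aqueous regions rather than a uniform mid-range smear. Homodimer
complexes are C2-symmetric (chain B rotated 180° about z) and packed
face to face at a separation that plants ≥ 10 interface residues per
dimer.

Composition: amino acids are drawn per (region × burial) cell with
hydrophobic fractions 0.73/0.60 (core exposed/buried), 0.19/0.49
(non-membrane), linear interpolation for the interface region (no
region-specific data exist for it). Burial for this draw comes from a
sequence-free proxy SASA pass with a generic side-chain radius; truth
labels are then recomputed with the real side chains.

Conservation: homolog rows (alignment depth 30 — conservative for an
iterative profile search against a large sequence database) substitute
each site with probability 0.08 + 0.55 · RSA/100, where the RSA seen by
evolution is blurred with Gaussian noise of 10 RSA points — selection
does not track accessibility noise-free. This plants the linear
rate-vs-accessibility relationship (per-protein Pearson r ≈ 0.85) and,
through the column frequencies, a consistent PSSM (integer log-odds vs
a uniform background). For homodimers the coupling uses complex-context
RSA: interface residues evolve like buried ones, which is exactly what
makes them detectable from prediction. The default corpus is 40
proteins in 5 families of 8 (shared fold per family, jittered phases,
resampled sequences) to exercise family-grouped cross-validation.

What the generator does *not* emulate: real rotamer packing, β-barrels,
alignment gaps (the parser and rate statistic handle them; the
generator emits none by default), sequence redundancy within
alignments, and profile correlations beyond single columns. Passing
tests therefore demonstrate that the pipeline recovers a planted
accessibility signal under realistic geometry and noise — not
field-grade accuracy on crystal structures, which requires real
training data.

## Problem sizes and numerical choices

Desk-scale defaults keep every experiment on one CPU in minutes: 40
proteins (~4200 residues) for training and evaluation, 10 for the
data-size comparison, 4 homodimers for interface detection, the coarse
hyper-parameter grid, 960 surface points per atom (4000 for the shipped
reference tables). Degenerate inputs fail loudly by design: empty
structures, single-class truths, all-missing rates, zero-variance
regression targets and even feature windows all raise typed errors.
Nonstandard residues map to 'X', are carried through I/O and SASA, and
are excluded from composition statistics, RSA and training labels.
Insertion codes are rejected rather than silently renumbered.
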