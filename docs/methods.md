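# Methods

This note records the models, conventions and numerical choices behind
`npfrag`, in the order of the analysis chain.

## Standardization and curation

Raw structures pass through metal–organic bond disconnection (the metal is
discarded), largest-organic-fragment selection, and charge neutralization
before canonicalization. Neutralization touches protonatable and
deprotonatable groups only; permanent cations such as quaternary ammonium
are left charged, mirroring common standardizer behavior. Deduplication is
per dataset on the stereo-aware canonical SMILES, so enantiomers and
diastereomers remain distinct records.

Bioactivity curation keeps a record when its assay confidence equals the
required score (default 9, direct single-protein assays) **and** it reaches
either the pChEMBL floor (default 5.0) or the ligand-efficiency floor
(default 0.3); the "and/or" is an inclusive OR. Ligand efficiency uses the
standard Hopkins form LE = 1.37 · pActivity / heavy atoms (kcal/mol per
heavy atom); the 1.37 conversion is an exposed constant. Records lacking
activity annotations are dropped and counted in the log. Structures with
experimentally determined protonation/tautomer states are accepted as
pre-computed input; no protonation engine is part of this package.

## 2D descriptors

Fsp³ and FC_Stereo divide sp³-hybridized and stereogenic carbons by the
total carbon count. Stereocenter perception is symmetry-aware and, by
default, counts *potential* as well as assigned centers
(`include_unassigned=True`), so the measure does not depend on whether
configurations were drawn; the switch is exposed. Carbon-free molecules
score 0 by convention, with a warning.

The spatial score gives each heavy atom the product of four terms —
hybridization (sp 1, sp² 2, sp³ 3, other 4), stereo (×2 for stereogenic
atoms, where atoms of stereogenic double bonds count as stereogenic),
non-aromatic-ring membership (×2), and the squared heavy-neighbor count —
summed over the molecule; nSPS divides by the heavy-atom count. The
parameterization was validated term-for-term against an independently
published implementation on the 50-molecule oracle suite before freezing.
Both SPS and NP-likeness are computed on the hydrogen-suppressed graph, so
explicit hydrogens never change them.

HBA/HBD are acceptor/donor *atom-feature* counts (chemically aware: e.g.
pyrrole-type NH is a donor but not an acceptor); LogP is the Crippen
atom-contribution estimate; NAR counts aromatic rings in the smallest set
of smallest rings, so fused aromatics count per ring. Rule-of-Three bounds
are MW ≤ 300, HBD ≤ 3, HBA ≤ 3, cLogP ≤ 3 with the common NRB ≤ 3 and
TPSA ≤ 60 Å² extensions, all inclusive and all configurable. Threshold
compliance fractions (e.g. Fsp³ ≥ 0.42) are inclusive at the boundary.

NP-likeness is a fragment-contribution score: every heavy atom contributes
the log₁₀ ratio of its radius-2 circular environment's smoothed relative
frequency in a natural-product corpus versus a synthetic corpus; the sum is
divided by the atom count (size normalization) and clipped to the table's
score range. The packaged default table is trained on two small bundled
exemplar sets (~40 saturated, stereocenter-rich NP chemotypes vs ~40 flat
aromatic synthetic chemotypes). It reliably *orders* NP-like above
synthetic-like molecules, which is what the tests assert; absolute values
are not comparable with tables trained on large corpora, and a loader for
user-supplied tables is provided.

## 3D shape

In-silico conformers come from torsion-knowledge distance geometry
(ETKDGv3) started from random coordinates with a caller-supplied seed; the
same molecule and seed reproduce identical coordinates. One conformer per
molecule is generated (single-conformer protocol), with the seed recorded.

**PBF convention.** PBF is the mean absolute distance of a conformer's
atoms from their least-squares plane (SVD plane fit on centered
coordinates). The average runs over *all atoms present in the conformer*:
in-silico conformers carry explicit hydrogens, crystal conformers carry
the resolved heavy atoms only. nPBF always divides by the resolved
heavy-atom count. This pair of conventions is the one under which the two
canonical calibration molecules come out at their reference values
(amantadine ≈ 1.02 Å → nPBF ≈ 0.093 with 11 heavy atoms; salicylic acid
≈ 0.13 Å → 0.013 with 10): a heavy-atom-only average would give ~0.77 for
the cage and exactly 0 for the planar acid, and an atom-count-summed
"PBF" would be an order of magnitude larger. Degenerate inputs (< 3
usable atoms, collinear coordinates) raise a specific error rather than
returning 0.

Conformation comparison abstracts both conformers to an all-carbon,
all-single-bond graph, then minimizes the heavy-atom RMSD over optimal
rigid (Kabsch) superposition and over the abstracted graph's
automorphisms; only mutually resolved atoms are compared. Superposition is
required because in-silico and crystal frames share no coordinate system.
Automorphism enumeration is capped (default 10,000 matchings) with the
identity always included. ΔnPBF is signed: protein-bound minus in-silico.

Per-ligand aggregation over crystal copies keeps all fully resolved
copies, otherwise the single best-resolved one (ties break by structure id
then copy id), and averages descriptor values arithmetically.

## Pocket assignment

Structures are superposed onto the reference by least-squares Kabsch fit
over Cα atoms matched by chain id + residue number (same-protein
alignment; no sequence-alignment fallback), and the transform is applied
to every atom including ligands. Pocket pseudo-atoms are mass-weighted
centers of mass of the supplied reference-ligand atoms (geometric centroid
available as an option, since "center of mass" is sometimes used loosely).
A ligand copy is assigned to every pocket whose pseudo-atom lies within
the pocket radius (default 5.0 Å, boundary inclusive) of *any* resolved
heavy atom; a centroid-based alternative sits behind a flag. Fragment
classification over all copies: orthosteric-only (only the ATP-pocket
label A occurs), peripheral-only (labels occur, never A), both, or
unassigned.

## Crystal contacts

The unit cell and space-group operators (identity first) come from the
structure file; fractional/Cartesian conversion uses the standard
orthogonalization with **a** along x and **b** in the xy plane. Symmetry
mates are all operator + integer-translation images of the protein (and
its waters) with at least one atom within the cutoff (default 6 Å) of the
ligand copy; candidate translations are searched in a ±1 cell window
around the rounded fractional offset. The identity operator with zero
translation is never a mate. A copy is lattice-proximal when any of its
atoms is *strictly* closer to a mate than to the asymmetric unit — exact
ties resolve toward the asymmetric unit.

Surface partitioning samples each resolved heavy atom's solvent-accessible
sphere (van der Waals radius + 1.4 Å probe) with 960 deterministic
golden-spiral points, removes points buried by sibling atoms, and
attributes each accessible point's area to the entity owning the nearest
protein heavy atom, provided that atom is within the proximity cap
(default 6 Å, the same cap for all surface analyses); farther points stay
unassigned — which is why entity percentages need not sum to 100. The
sampler reproduces the closed-form exposed area of one- and two-sphere
systems to < 2%.

Polar contacts are distance-only on heavy atoms (inputs may lack
hydrogens): N/O/S pairs within 3.5 Å count as hydrogen bonds, contacts to
water oxygens are reported separately as water-mediated, and
charged–charged pairs within 4.0 Å are flagged as salt bridges. Protein
charged atoms come from a residue/atom-name lookup (Asp/Glu carboxylates,
Lys/Arg amines); ligand charged atoms must be supplied by index. No angle
criteria, no π-stacking, no interface energies.

## Scaffolds, similarity, growth vectors

Bemis–Murcko scaffolds keep ring systems plus linkers (exocyclic
double-bonded atoms retained); acyclic molecules yield an empty-scaffold
marker distinct from an error. The cyclic skeleton converts every scaffold
atom to carbon and every bond to single — this is the package's operational
"chemotype" proxy, documented as pluggable since chemotype is only loosely
defined in the field. Scaffold strings are stereo-stripped by default (flag
to retain).

Similarity uses Morgan fingerprints, radius 2, folded to 4096 bits, with
Tanimoto ranking and deterministic tie-breaks by reference id; folding
collisions are accepted as part of the method. Natural-product parent
search is stereospecific by default — a fragment in (S) configuration does
not match a parent embedding the (R) enantiomer — while growth-vector
substructure mapping ignores stereochemistry by default (derivatization
analysis); both are switchable. Growth vectors are fragment atoms whose
image in a parent bonds to atoms outside the match; symmetry-equivalent
fragment positions are merged by canonical atom ranking, and each parent
contributes at most one count per equivalence class. Sociability counts
library members sharing the fragment's cyclic skeleton, sharing its
scaffold, and containing it as a (stereospecific) substructure.

## Statistics

Kruskal–Wallis (tie-corrected, χ² p-value) is the omnibus test; an
all-identical degenerate input returns (H = 0, p = 1). Dunn's post-hoc z
statistics use pooled mean ranks with the Σ(t³−t)/(12(N−1)) tie
correction; two-sided normal p-values are Bonferroni-multiplied by the
number of group pairs within one descriptor (the adopted family) and
capped at 1. Cohen's d uses the pooled (not averaged) standard deviation,
mean-based, sign = first argument minus second; Hedges correction is off.
Significance threshold 0.05. Spearman's ρ handles ties and raises on
constant input. Monte-Carlo checks in the test suite verify family-wise
error control under a 5-group Gaussian null and near-certain detection of
a 2-SD shift at n = 50.

## Synthetic fixtures

The library generator assembles molecules from ~20 building-block cores
per profile with small substituent decoration: the *flat* profile draws
fused/linked aromatic cores (every output has ≥ 2 aromatic rings and
Fsp³ ≤ 0.2), the *three_d* profile saturated, stereocenter-bearing ring
cores (Fsp³ ≥ 0.42 — the literature three-dimensionality threshold — and
≤ 1 aromatic ring). Constraints are verified per molecule after
generation; violating draws are rejected and redrawn, and generation is
deterministic per seed. The libraries emulate the saturation/complexity
*contrast* between an NP-like fragment library and classical kinase
chemotypes; they do not emulate real activity distributions, molecular
size spread, or tautomer/protomer diversity, so passing comparisons show
that the statistics and descriptors recover a constructed effect, not that
any particular real library is three-dimensional.

The toy crystal is geometric, not physical: a cubic P1 cell (P2₁
optional, to exercise rotational symmetry), a cubic grid of Cα
pseudo-atoms for the protein, and rigid star-shaped ligand copies whose
central atom sits at an exact, constructed distance from each pocket
pseudo-atom (boundary cases at 4.9 Å inside and 5.1 Å outside the 5 Å
radius) or near the cell boundary so that exactly the intended copies are
lattice-proximal. A separate mirror layout places a wall of protein atoms
and centers a mirror-symmetric ligand between the wall and its +x lattice
image, giving a constructed 50/50 surface split. Ground truth (pocket
labels, binder classes, lattice flags) is emitted as a sidecar table and
is recoverable exactly by construction, with ≥ 0.5 Å margins on all
radii/cutoffs.

## Reference quantities and problem sizes

`scripts/acceptance.py` reports the PBF/nPBF of amantadine and salicylic
acid as the median over 25 replicate single-conformer embeddings seeded
from the command-line seed. The median is a variance-reduction device for
*reporting*: single-conformer PBF fluctuates by a few hundredths of an Å
with the embedding seed (the acid's carboxyl twist dominates its value),
while the replicate median is stable to ~0.01 Å. The library API default
remains the single-conformer protocol. Statistical acceptance checks use
n = 50 molecules per synthetic library and 1000 Monte-Carlo replicates for
the family-wise error check — sizes at which the constructed effects are
unambiguous while the full suite runs in well under a minute.

## Known limitations

- Pocket assignment assumes same-protein superposition; cross-family
  alignment is out of scope.
- Polar-contact typing is element- and lookup-based; no hydrogens, no
  geometry-aware hydrogen-bond criteria.
- The packaged NP-likeness table is exemplar-trained and supports ordering
  claims only.
- Kinase conformational-state classification (DFG/αC) and electron-density
  quality scoring are external concerns, deliberately not reimplemented.
- The reference-pair similarity check (a fragment vs a PDB chemical
  component, by accession) needs the two structures fetched from their
  databases; the repository ships no copy of either.
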