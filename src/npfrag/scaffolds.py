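"""Scaffold novelty, fingerprint similarity and growth-vector mining.

Novelty is assessed at two abstraction levels: the Bemis–Murcko scaffold
(ring systems plus linkers, substituents removed) and the cyclic skeleton
(the scaffold with every heavy atom turned into carbon and every bond into
a single bond), the latter serving as a loose chemotype proxy.  Similarity
ranking uses Morgan fingerprints (radius 2, 4096 bits) with the Tanimoto
coefficient.  Growth vectors are fragment atoms at which natural-product
parents carry substituents — candidate elaboration points — and
"sociability" counts how many library members share a fragment's chemotype
or scaffold or contain it outright.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

from rdkit import Chem
from rdkit.Chem import AllChem
from rdkit.Chem.Scaffolds import MurckoScaffold
from rdkit.DataStructs import TanimotoSimilarity

from .standardize import MoleculeRecord

MolLike = Union[Chem.Mol, MoleculeRecord, str]

#: Marker for the (empty) scaffold of acyclic molecules.
EMPTY_SCAFFOLD = ""

FP_RADIUS = 2
FP_NBITS = 4096


def _as_mol(mol: MolLike) -> Chem.Mol:
    if isinstance(mol, Chem.Mol):
        return mol
    if isinstance(mol, MoleculeRecord):
        return mol.mol()
    m = Chem.MolFromSmiles(mol)
    if m is None:
        raise ValueError(f"unparseable SMILES: {mol!r}")
    return m


@dataclass
class ScaffoldRecord:
    molecule_id: str
    bm_scaffold: str
    cyclic_skeleton: str


@dataclass
class SimilarityHit:
    query_id: str
    reference_id: str
    reference_dataset: str
    tanimoto: float


@dataclass
class GrowthVectorMap:
    """Per-fragment-atom counts of parents substituted at that atom.

    Counts are keyed by the representative atom index (the lowest index of
    each symmetry-equivalence class under canonical ranking); ``classes``
    maps every fragment atom to its representative.
    """

    fragment_id: str
    counts: dict[int, int] = field(default_factory=dict)
    classes: dict[int, int] = field(default_factory=dict)


def bemis_murcko(mol: MolLike, *, keep_stereo: bool = False) -> str:
    """Canonical SMILES of the Bemis–Murcko scaffold; '' for acyclic input."""
    m = _as_mol(mol)
    scaffold = MurckoScaffold.GetScaffoldForMol(m)
    if scaffold.GetNumAtoms() == 0:
        return EMPTY_SCAFFOLD
    if not keep_stereo:
        scaffold = Chem.Mol(scaffold)
        Chem.RemoveStereochemistry(scaffold)
    return Chem.MolToSmiles(scaffold)


def cyclic_skeleton(mol: MolLike) -> str:
    """Generic framework: scaffold with all atoms carbon, all bonds single."""
    m = _as_mol(mol)
    scaffold = MurckoScaffold.GetScaffoldForMol(m)
    if scaffold.GetNumAtoms() == 0:
        return EMPTY_SCAFFOLD
    generic = MurckoScaffold.MakeScaffoldGeneric(scaffold)
    return Chem.MolToSmiles(generic)


def scaffold_record(mol: MoleculeRecord) -> ScaffoldRecord:
    return ScaffoldRecord(mol.id, bemis_murcko(mol), cyclic_skeleton(mol))


# ---------------------------------------------------------------------------
# fingerprints


def morgan_fingerprint(mol: MolLike, radius: int = FP_RADIUS, nbits: int = FP_NBITS):
    return AllChem.GetMorganFingerprintAsBitVect(_as_mol(mol), radius, nBits=nbits)


def morgan_tanimoto(a: MolLike, b: MolLike, radius: int = FP_RADIUS,
                    nbits: int = FP_NBITS) -> float:
    """Tanimoto coefficient of folded Morgan fingerprints."""
    return TanimotoSimilarity(
        morgan_fingerprint(a, radius, nbits), morgan_fingerprint(b, radius, nbits)
    )


def top_k_similar(query: MoleculeRecord, references: Sequence[MoleculeRecord],
                  k: int = 3, *, radius: int = FP_RADIUS,
                  nbits: int = FP_NBITS) -> list[SimilarityHit]:
    """The k most similar references, descending Tanimoto, ties by id."""
    if not references:
        raise ValueError("empty reference set")
    if k > len(references):
        import warnings

        warnings.warn(f"k={k} exceeds reference count {len(references)}; returning all")
        k = len(references)
    qfp = morgan_fingerprint(query, radius, nbits)
    hits = [
        SimilarityHit(query.id, ref.id, ref.source_tag,
                      TanimotoSimilarity(qfp, morgan_fingerprint(ref, radius, nbits)))
        for ref in references
    ]
    hits.sort(key=lambda h: (-h.tanimoto, h.reference_id))
    return hits[:k]


# ---------------------------------------------------------------------------
# substructure mining


def find_np_parents(fragment: MolLike, np_set: Sequence[MoleculeRecord],
                    *, use_chirality: bool = True) -> list[str]:
    """Parents containing the fragment as a (stereo-respecting) substructure."""
    frag = _as_mol(fragment)
    return [
        parent.id
        for parent in np_set
        if parent.mol().HasSubstructMatch(frag, useChirality=use_chirality)
    ]


def growth_vectors(fragment: MoleculeRecord, parents: Sequence[MoleculeRecord],
                   *, use_chirality: bool = False) -> GrowthVectorMap:
    """Derivatization points of the fragment across its parent molecules.

    For every parent the fragment is substructure-mapped (all matches); a
    fragment atom whose image is bonded to any parent atom outside the match
    is a growth vector for that parent.  Symmetry-equivalent fragment atoms
    are merged by canonical ranking; each parent contributes at most one
    count per equivalence class.  Parents without a match are skipped.
    """
    frag = _as_mol(fragment)
    ranks = list(Chem.CanonicalRankAtoms(frag, breakTies=False))
    rep: dict[int, int] = {}
    classes: dict[int, int] = {}
    for idx, rank in enumerate(ranks):
        rep.setdefault(rank, idx)
        classes[idx] = rep[rank]
    counts: dict[int, int] = {}
    for parent in parents:
        pmol = parent.mol()
        matches = pmol.GetSubstructMatches(frag, useChirality=use_chirality, uniquify=True)
        if not matches:
            import warnings

            warnings.warn(f"parent {parent.id!r} does not contain fragment {fragment.id!r}")
            continue
        vector_classes: set[int] = set()
        for match in matches:
            matched = set(match)
            for frag_idx, parent_idx in enumerate(match):
                for nb in pmol.GetAtomWithIdx(parent_idx).GetNeighbors():
                    if nb.GetIdx() not in matched and nb.GetAtomicNum() > 1:
                        vector_classes.add(classes[frag_idx])
                        break
        for c in vector_classes:
            counts[c] = counts.get(c, 0) + 1
    return GrowthVectorMap(fragment.id, counts, classes)


def sociability_counts(fragment: MoleculeRecord, library: Sequence[MoleculeRecord],
                       *, use_chirality: bool = True) -> tuple[int, int, int]:
    """(same chemotype, same scaffold, contains fragment) counts in a library.

    Chemotype is operationalized as cyclic-skeleton equality; the
    substructure count is stereospecific by default.
    """
    frag = _as_mol(fragment)
    frag_scaffold = bemis_murcko(frag)
    frag_skeleton = cyclic_skeleton(frag)
    n_chemotype = n_scaffold = n_substructure = 0
    for member in library:
        m = member.mol()
        if cyclic_skeleton(m) == frag_skeleton:
            n_chemotype += 1
        if bemis_murcko(m) == frag_scaffold:
            n_scaffold += 1
        if m.HasSubstructMatch(frag, useChirality=use_chirality):
            n_substructure += 1
    return n_chemotype, n_scaffold, n_substructure


@dataclass
class NoveltyFlags:
    molecule_id: str
    scaffold_seen: dict[str, bool]
    skeleton_seen: dict[str, bool]

    @property
    def novel_scaffold(self) -> bool:
        return not any(self.scaffold_seen.values())

    @property
    def novel_skeleton(self) -> bool:
        return not any(self.skeleton_seen.values())


def novelty_report(queries: Sequence[ScaffoldRecord],
                   reference_sets: dict[str, Sequence[ScaffoldRecord]],
                   ) -> list[NoveltyFlags]:
    """Per-query flags: scaffold/skeleton previously seen in each reference set."""
    ref_scaffolds = {
        name: {r.bm_scaffold for r in recs} for name, recs in reference_sets.items()
    }
    ref_skeletons = {
        name: {r.cyclic_skeleton for r in recs} for name, recs in reference_sets.items()
    }
    out = []
    for q in queries:
        out.append(
            NoveltyFlags(
                q.molecule_id,
                {name: q.bm_scaffold in ref_scaffolds[name] for name in reference_sets},
                {name: q.cyclic_skeleton in ref_skeletons[name] for name in reference_sets},
            )
        )
    return out
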