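"""3D shape descriptors and conformation comparison.

The plane-of-best-fit (PBF) descriptor quantifies molecular
three-dimensionality as the mean absolute distance of a conformer's atoms
from their least-squares plane; planar molecules score 0, globular cages
around 1 Å.  The size-normalized form (nPBF) divides PBF by the heavy-atom
count so differently sized molecules become comparable.

Two conformer sources are supported: in-silico conformers from seeded
torsion-knowledge distance geometry (ETKDGv3, random-coordinate start) and
protein-bound crystal conformations, possibly with unresolved atoms.  PBF is
evaluated over all atoms present in the conformer — hydrogens are included
for in-silico conformers, while crystal conformers carry heavy atoms only —
and nPBF always normalizes by the resolved heavy-atom count.  This is the
convention under which the reference worked examples (amantadine PBF 1.02 Å,
nPBF 0.093; salicylic acid 0.13 Å, 0.013) are reproduced.

Conformation comparison uses an abstracted representation (all heavy atoms
as carbon, all bonds single) so tautomer/bond-order bookkeeping cannot
perturb the geometric comparison: the RMSD is minimized over rigid
superposition and over the automorphisms of the abstracted graph.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

from ._geom import fit_plane, kabsch, plane_distances
from .standardize import MoleculeRecord


class EmbeddingError(RuntimeError):
    pass


class DegenerateGeometryError(ValueError):
    pass


class IncompatibleConformersError(ValueError):
    pass


@dataclass
class Conformer:
    """One 3D instance of a molecule.

    ``coords``/``elements`` cover the atoms present: all atoms (with
    hydrogens) for in-silico conformers, heavy atoms for crystal ones.
    ``resolved_mask`` marks atoms with experimentally observed coordinates;
    in-silico conformers are fully resolved by construction.  ``bonds`` is
    the heavy-atom bond list (index pairs) used for graph-aware comparison.
    """

    molecule_id: str
    provenance: str  # "in_silico" | "crystal"
    elements: list[str]
    coords: np.ndarray
    resolved_mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    bonds: Optional[list[tuple[int, int]]] = None
    seed: Optional[int] = None
    structure_id: str = ""
    copy_id: str = ""

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.resolved_mask is None:
            self.resolved_mask = np.ones(len(self.elements), dtype=bool)
        self.resolved_mask = np.asarray(self.resolved_mask, dtype=bool)
        if self.coords.shape != (len(self.elements), 3):
            raise ValueError("coords must be (n_atoms, 3)")

    @property
    def heavy_mask(self) -> np.ndarray:
        return np.array([e.upper() != "H" for e in self.elements])

    @property
    def n_resolved_heavy(self) -> int:
        return int((self.heavy_mask & self.resolved_mask).sum())

    @property
    def fully_resolved(self) -> bool:
        return bool(self.resolved_mask.all())


@dataclass
class LigandCopySet:
    molecule_id: str
    copies: list[Conformer]


# ---------------------------------------------------------------------------
# conformer generation


def embed_conformer(mol: MoleculeRecord | Chem.Mol | str, seed: int = 42,
                    *, max_attempts: int = 5) -> Conformer:
    """One seeded ETKDGv3 conformer (random-coordinate start), hydrogens kept.

    The same molecule and seed always give identical coordinates.  On
    embedding failure the seed is perturbed deterministically up to
    ``max_attempts`` times before raising :class:`EmbeddingError`.
    """
    if isinstance(mol, MoleculeRecord):
        rdmol, mol_id = mol.mol(), mol.id
    elif isinstance(mol, Chem.Mol):
        rdmol, mol_id = mol, (mol.GetProp("_Name") if mol.HasProp("_Name") else "")
    else:
        rdmol = Chem.MolFromSmiles(mol)
        if rdmol is None:
            raise ValueError(f"unparseable SMILES: {mol!r}")
        mol_id = mol
    molh = Chem.AddHs(rdmol)
    conf_id = -1
    for attempt in range(max_attempts):
        params = AllChem.ETKDGv3()
        params.randomSeed = seed + 1000003 * attempt
        params.useRandomCoords = True
        conf_id = AllChem.EmbedMolecule(molh, params)
        if conf_id >= 0:
            break
    if conf_id < 0:
        raise EmbeddingError(f"embedding failed for molecule {mol_id!r}")
    coords = molh.GetConformer(conf_id).GetPositions()
    bonds = [
        (b.GetBeginAtomIdx(), b.GetEndAtomIdx())
        for b in molh.GetBonds()
        if b.GetBeginAtom().GetAtomicNum() > 1 and b.GetEndAtom().GetAtomicNum() > 1
    ]
    return Conformer(
        molecule_id=mol_id,
        provenance="in_silico",
        elements=[a.GetSymbol() for a in molh.GetAtoms()],
        coords=coords,
        bonds=bonds,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# plane-of-best-fit descriptors


def pbf(conf: Conformer) -> float:
    """Mean absolute distance (Å) of resolved atoms from their best-fit plane."""
    pts = conf.coords[conf.resolved_mask]
    if pts.shape[0] < 3:
        raise DegenerateGeometryError(
            f"PBF needs >= 3 resolved atoms (got {pts.shape[0]}) for {conf.molecule_id!r}"
        )
    try:
        centroid, normal = fit_plane(pts)
    except ValueError as err:
        raise DegenerateGeometryError(str(err)) from err
    return float(plane_distances(pts, centroid, normal).mean())


def npbf(conf: Conformer) -> float:
    """PBF normalized by the resolved heavy-atom count."""
    n_heavy = conf.n_resolved_heavy
    if n_heavy == 0:
        raise DegenerateGeometryError("no resolved heavy atoms")
    return pbf(conf) / n_heavy


def delta_npbf(crystal: Conformer, insilico: Conformer) -> float:
    """Signed nPBF difference, protein-bound minus in-silico."""
    return npbf(crystal) - npbf(insilico)


# ---------------------------------------------------------------------------
# conformation comparison


def _abstracted_mol(n_atoms: int, bonds: Sequence[tuple[int, int]]) -> Chem.Mol:
    """All-carbon, all-single-bond skeleton as an RDKit molecule."""
    em = Chem.RWMol()
    for _ in range(n_atoms):
        atom = Chem.Atom(6)
        atom.SetNoImplicit(True)
        em.AddAtom(atom)
    for i, j in bonds:
        em.AddBond(int(i), int(j), Chem.BondType.SINGLE)
    mol = em.GetMol()
    Chem.SanitizeMol(mol, Chem.SanitizeFlags.SANITIZE_SYMMRINGS)
    return mol


def graph_automorphisms(n_atoms: int, bonds: Sequence[tuple[int, int]],
                        max_matches: int = 10000) -> list[tuple[int, ...]]:
    """Automorphisms of the abstracted graph, capped at ``max_matches``.

    Beyond the cap the enumeration is truncated (deterministically); the
    identity permutation is always included.
    """
    mol = _abstracted_mol(n_atoms, bonds)
    matches = mol.GetSubstructMatches(mol, uniquify=False, maxMatches=max_matches)
    perms = [tuple(m) for m in matches]
    ident = tuple(range(n_atoms))
    if ident not in perms:
        perms.insert(0, ident)
    return perms


def abstracted_rmsd(a: Conformer, b: Conformer, *, max_matches: int = 10000) -> float:
    """Heavy-atom RMSD between two conformers of the same molecular graph.

    Both conformers are abstracted to an all-carbon, all-single-bond graph;
    the RMSD is minimized over optimal rigid superposition and over the graph
    automorphisms.  Only mutually resolved heavy atoms are compared.
    """
    heavy_a = np.flatnonzero(a.heavy_mask)
    heavy_b = np.flatnonzero(b.heavy_mask)
    if len(heavy_a) != len(heavy_b):
        raise IncompatibleConformersError("different heavy-atom counts")
    bonds = a.bonds if a.bonds is not None else b.bonds
    if bonds is None:
        raise IncompatibleConformersError("no bond graph available on either conformer")
    # reindex the heavy-atom graph to 0..n-1
    pos_a = {int(idx): k for k, idx in enumerate(heavy_a)}
    pos_b = {int(idx): k for k, idx in enumerate(heavy_b)}
    ref_pos = pos_a if a.bonds is not None else pos_b
    heavy_bonds = [(ref_pos[i], ref_pos[j]) for i, j in bonds if i in ref_pos and j in ref_pos]
    n = len(heavy_a)
    resolved_a = a.resolved_mask[heavy_a]
    resolved_b = b.resolved_mask[heavy_b]
    coords_a = a.coords[heavy_a]
    coords_b = b.coords[heavy_b]

    best = np.inf
    for perm in graph_automorphisms(n, heavy_bonds, max_matches=max_matches):
        perm = np.asarray(perm)
        mutual = resolved_a & resolved_b[perm]
        if mutual.sum() < 3:
            continue
        pa = coords_a[mutual]
        pb = coords_b[perm][mutual]
        _, _, rmsd = kabsch(pa, pb)
        best = min(best, rmsd)
    if not np.isfinite(best):
        raise IncompatibleConformersError("fewer than 3 mutually resolved atoms")
    return best


# ---------------------------------------------------------------------------
# per-ligand aggregation over crystal copies


def select_copies(copies: LigandCopySet | Sequence[Conformer]) -> list[Conformer]:
    """Retain all fully resolved copies; else the single best-resolved one.

    Ties in the resolved-atom count break deterministically by
    (structure_id, copy_id).
    """
    seq = copies.copies if isinstance(copies, LigandCopySet) else list(copies)
    if not seq:
        raise ValueError("empty copy set")
    full = [c for c in seq if c.fully_resolved]
    if full:
        return full
    return [
        sorted(seq, key=lambda c: (-int(c.resolved_mask.sum()), c.structure_id, c.copy_id))[0]
    ]


def aggregate_per_ligand(values: Sequence[float]) -> float:
    """Arithmetic mean of per-copy descriptor values."""
    if len(values) == 0:
        raise ValueError("no values to aggregate")
    return float(np.mean(values))


def write_conformers_sdf(conformers: Sequence[tuple[Chem.Mol, Conformer]], path) -> None:
    """Write embedded conformers to SDF, recording the seed as a property."""
    writer = Chem.SDWriter(str(path))
    for mol, conf in conformers:
        molh = Chem.AddHs(mol)
        rdconf = Chem.Conformer(molh.GetNumAtoms())
        for i, xyz in enumerate(conf.coords):
            rdconf.SetAtomPosition(i, xyz.tolist())
        molh.RemoveAllConformers()
        molh.AddConformer(rdconf, assignId=True)
        molh.SetProp("_Name", conf.molecule_id)
        if conf.seed is not None:
            molh.SetIntProp("embedding_seed", conf.seed)
        writer.write(molh)
    writer.close()
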