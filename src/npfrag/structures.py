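"""Protein–ligand structure I/O (PDB/mmCIF via gemmi) and shared containers."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import gemmi
import numpy as np

from .shape import Conformer

WATER_RESNAMES = {"HOH", "WAT", "DOD"}


@dataclass
class ProteinAtoms:
    """Column arrays for one set of protein (and water) atoms."""

    names: list[str]
    elements: list[str]
    chains: list[str]
    resnums: np.ndarray
    resnames: list[str]
    coords: np.ndarray

    def __len__(self) -> int:
        return len(self.names)

    @property
    def is_water(self) -> np.ndarray:
        return np.array([rn in WATER_RESNAMES for rn in self.resnames])

    def transformed(self, rot: np.ndarray, trans: np.ndarray) -> "ProteinAtoms":
        return replace(self, coords=self.coords @ np.asarray(rot).T + trans)


@dataclass
class CrystalLattice:
    """Unit cell plus fractional-coordinate symmetry operators.

    Operators are (3x3 rotation, translation) pairs in fractional
    coordinates with the identity first.
    """

    a: float
    b: float
    c: float
    alpha: float
    beta: float
    gamma: float
    operators: list[tuple[np.ndarray, np.ndarray]]

    def __post_init__(self):
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError("cell lengths must be positive")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0.0 < ang < 180.0:
                raise ValueError("cell angles must lie in (0, 180) degrees")
        if not self.operators:
            raise ValueError("no symmetry operators")
        r0, t0 = self.operators[0]
        if not (np.allclose(r0, np.eye(3)) and np.allclose(t0, 0.0)):
            raise ValueError("identity operator must come first")

    @property
    def orthogonalization(self) -> np.ndarray:
        """Standard orthogonalization matrix (a along x, b in the xy plane)."""
        al, be, ga = np.radians([self.alpha, self.beta, self.gamma])
        cos_al, cos_be, cos_ga = np.cos([al, be, ga])
        sin_ga = np.sin(ga)
        v = np.sqrt(1 - cos_al**2 - cos_be**2 - cos_ga**2 + 2 * cos_al * cos_be * cos_ga)
        return np.array(
            [
                [self.a, self.b * cos_ga, self.c * cos_be],
                [0.0, self.b * sin_ga, self.c * (cos_al - cos_be * cos_ga) / sin_ga],
                [0.0, 0.0, self.c * v / sin_ga],
            ]
        )

    @property
    def fractionalization(self) -> np.ndarray:
        return np.linalg.inv(self.orthogonalization)

    @classmethod
    def from_gemmi(cls, cell: gemmi.UnitCell, spacegroup: str) -> "CrystalLattice":
        sg = gemmi.find_spacegroup_by_name(spacegroup)
        if sg is None:
            raise ValueError(f"unknown space group {spacegroup!r}")
        ops = []
        for op in sg.operations():
            rot = np.array(op.rot, dtype=float) / op.DEN
            tran = np.array(op.tran, dtype=float) / op.DEN
            ops.append((rot, tran))
        # identity first, deterministic order for the rest
        ops.sort(key=lambda rt: (not (np.allclose(rt[0], np.eye(3)) and np.allclose(rt[1], 0)),
                                 rt[0].tolist(), rt[1].tolist()))
        return cls(cell.a, cell.b, cell.c, cell.alpha, cell.beta, cell.gamma, ops)


@dataclass
class StructureModel:
    """One crystal structure: protein atoms, waters, and ligand copies."""

    structure_id: str
    protein: ProteinAtoms
    ligands: list[Conformer] = field(default_factory=list)
    waters: Optional[ProteinAtoms] = None
    lattice: Optional[CrystalLattice] = None

    def transformed(self, rot: np.ndarray, trans: np.ndarray) -> "StructureModel":
        rot = np.asarray(rot)
        return StructureModel(
            structure_id=self.structure_id,
            protein=self.protein.transformed(rot, trans),
            ligands=[
                replace(lig, coords=lig.coords @ rot.T + trans) for lig in self.ligands
            ],
            waters=self.waters.transformed(rot, trans) if self.waters is not None else None,
            lattice=self.lattice,
        )


def load_structure(path, *, structure_id: Optional[str] = None) -> StructureModel:
    """Read a PDB or mmCIF file into a :class:`StructureModel`.

    Polymer ATOM records become protein atoms; non-water HETATM residues
    become crystal-provenance ligand :class:`~npfrag.shape.Conformer` copies
    (one per residue, copy id ``chain:resnum:resname``); waters are kept
    separately.  Unit cell and space group, when present, populate
    ``lattice``.
    """
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    model = st[0]
    p_names: list[str] = []
    p_elems: list[str] = []
    p_chains: list[str] = []
    p_resnums: list[int] = []
    p_resnames: list[str] = []
    p_coords: list[list[float]] = []
    w_names, w_elems, w_chains, w_resnums, w_resnames, w_coords = [], [], [], [], [], []
    ligands: list[Conformer] = []
    sid = structure_id or st.name or str(path)
    for chain in model:
        for res in chain:
            is_het = res.het_flag == "H"
            if res.name in WATER_RESNAMES:
                for atom in res:
                    w_names.append(atom.name)
                    w_elems.append(atom.element.name)
                    w_chains.append(chain.name)
                    w_resnums.append(res.seqid.num)
                    w_resnames.append(res.name)
                    w_coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
            elif is_het:
                elements = [a.element.name for a in res]
                coords = np.array([[a.pos.x, a.pos.y, a.pos.z] for a in res])
                ligands.append(
                    Conformer(
                        molecule_id=res.name,
                        provenance="crystal",
                        elements=elements,
                        coords=coords,
                        structure_id=sid,
                        copy_id=f"{chain.name}:{res.seqid.num}:{res.name}",
                    )
                )
            else:
                for atom in res:
                    p_names.append(atom.name)
                    p_elems.append(atom.element.name)
                    p_chains.append(chain.name)
                    p_resnums.append(res.seqid.num)
                    p_resnames.append(res.name)
                    p_coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
    protein = ProteinAtoms(
        p_names, p_elems, p_chains, np.array(p_resnums, dtype=int), p_resnames,
        np.array(p_coords, dtype=float).reshape(-1, 3),
    )
    if not np.isfinite(protein.coords).all():
        raise ValueError(f"non-finite coordinates in {path}")
    waters = None
    if w_names:
        waters = ProteinAtoms(
            w_names, w_elems, w_chains, np.array(w_resnums, dtype=int), w_resnames,
            np.array(w_coords, dtype=float).reshape(-1, 3),
        )
    lattice = None
    if st.cell and st.cell.a > 1.0 and st.spacegroup_hm:
        try:
            lattice = CrystalLattice.from_gemmi(st.cell, st.spacegroup_hm)
        except ValueError:
            lattice = None
    return StructureModel(sid, protein, ligands, waters, lattice)


def pad_to_record(conf: Conformer, n_heavy_expected: int,
                  bonds: Optional[Sequence[tuple[int, int]]] = None) -> Conformer:
    """Pad a crystal conformer with unresolved trailing atoms.

    Crystal files only contain the resolved atoms; when the parent molecule
    has ``n_heavy_expected`` heavy atoms and the file's atoms follow the
    molecule's atom ordering, the missing trailing atoms are appended as
    unresolved placeholders so resolution-aware selection and comparison can
    operate.
    """
    n_present = len(conf.elements)
    if n_present > n_heavy_expected:
        raise ValueError("conformer has more atoms than the parent molecule")
    if n_present == n_heavy_expected and bonds is None:
        return conf
    n_missing = n_heavy_expected - n_present
    coords = np.vstack([conf.coords, np.zeros((n_missing, 3))])
    elements = list(conf.elements) + ["C"] * n_missing
    mask = np.concatenate([conf.resolved_mask, np.zeros(n_missing, dtype=bool)])
    return replace(conf, coords=coords, elements=elements, resolved_mask=mask,
                   bonds=list(bonds) if bonds is not None else conf.bonds)
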