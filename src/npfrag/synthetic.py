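"""Synthetic fixtures: molecule libraries with controlled descriptor
structure, toy crystals with known ground truth, and reference molecules.

The library generator contrasts two chemotype worlds: a "flat" profile
assembled from fused/linked aromatic building blocks (Fsp3 near 0, at least
two aromatic rings) and a "three_d" profile assembled from saturated,
stereocenter-bearing ring blocks (Fsp3 at or above the literature
three-dimensionality threshold of 0.42, at most one aromatic ring).  Both
are deterministic per seed, so descriptor comparisons between them recover
a known saturation/complexity contrast.

The toy crystal is geometric, not physical: a P1 (optionally P21) cell with
a grid of C-alpha pseudo-atoms for the protein, small star-shaped rigid
ligand copies placed at controlled distances from pocket pseudo-atoms and
from the lattice interface, and a ground-truth sidecar recording expected
pocket labels, binder classes and lattice-contact flags.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import gemmi
import numpy as np
import pandas as pd
from rdkit import Chem
from scipy.spatial.distance import cdist

from .descriptors import fsp3, physchem_panel
from .pockets import PocketDefinition
from .shape import Conformer
from .standardize import MoleculeRecord, standardize_molecule
from .structures import CrystalLattice, ProteinAtoms

# ---------------------------------------------------------------------------
# molecule libraries

FLAT_CORES = [
    "c1ccc(-c2ccccc2)cc1", "c1ccc2ccccc2c1", "c1ccc(-c2ccncc2)cc1",
    "c1cnc2ccccc2c1", "c1ccc2[nH]ccc2c1", "c1ccc2occc2c1", "c1ccc2sccc2c1",
    "c1ccc(-c2ncccn2)cc1", "c1ccc(-c2cnccn2)cc1", "c1ccc(-n2cccn2)cc1",
    "c1ccc(-c2nc3ccccc3[nH]2)cc1", "c1ccc(-c2nc3ccccc3s2)cc1",
    "c1ccc(-c2ccc3ncccc3c2)cc1", "c1ccc2cc3ccccc3cc2c1",
    "c1ccc(Oc2ccccc2)cc1", "c1ccc(Nc2ccccc2)cc1",
    "c1ccc(-c2ccc3ccccc3c2)cc1", "c1ccc(-c2cccnc2)cc1",
    "c1ccc2ncncc2c1", "c1ccc(-c2ccoc2)cc1",
]
FLAT_SUBSTITUENTS = ["", "F", "Cl", "C#N", "O", "N"]

THREED_CORES = [
    "C[C@H]1CC[C@@H](O)CC1", "C[C@H]1CC[C@H](N)CC1", "C[C@@H]1CCC[C@H]1O",
    "O[C@H]1CC[C@@H](C(=O)O)CC1", "C[C@H]1CC[C@@H](C)CC1",
    "C[C@H]1CCCN[C@@H]1C", "C[C@H]1CCC[C@@H](O)C1", "N[C@H]1CC[C@@H](O)CC1",
    "C[C@H]1OCC[C@@H]1O", "C[C@H]1CN[C@@H](C)C1", "O[C@H]1CN[C@@H](CO)C1",
    "C[C@H]1C[C@H](O)C[C@@H](C)C1", "C[C@H]1CC[C@H]2CC[C@@H](C)C[C@H]2C1",
    "OC[C@H]1CC[C@@H](O)CC1", "C[C@@H](O)[C@H]1CCCO1",
    "C[C@H]1CC[C@@H](O)[C@H](C)C1", "N[C@@H]1CCC[C@H]1O",
    "C[C@H]1CC[C@H](C(N)=O)CC1", "O[C@@H]1CCC[C@H]1CO",
    "C[C@H]1CC[C@@H](c2ccccc2)CC1",
]
THREED_SUBSTITUENTS = ["", "C", "O", "CO", "N", "CC"]


@dataclass
class LibraryProfile:
    """Target descriptor structure for a generated library."""

    name: str  # "flat" | "three_d"
    n: int = 50
    seed: int = 7
    fsp3_max: Optional[float] = None
    fsp3_min: Optional[float] = None
    nar_min: Optional[int] = None
    nar_max: Optional[int] = None

    @classmethod
    def flat(cls, n: int = 50, seed: int = 7) -> "LibraryProfile":
        return cls("flat", n=n, seed=seed, fsp3_max=0.2, nar_min=2)

    @classmethod
    def three_d(cls, n: int = 50, seed: int = 7) -> "LibraryProfile":
        return cls("three_d", n=n, seed=seed, fsp3_min=0.42, nar_max=1)


class GenerationError(RuntimeError):
    pass


def _attach(mol: Chem.Mol, substituent: str, rng: np.random.Generator) -> Chem.Mol:
    """Bond a substituent fragment to a random host atom carrying hydrogens."""
    if not substituent:
        return mol
    frag = Chem.MolFromSmiles(substituent)
    hosts = [
        a.GetIdx() for a in mol.GetAtoms()
        if a.GetTotalNumHs() > 0 and a.GetAtomicNum() == 6
    ]
    if not hosts:
        return mol
    host = int(rng.choice(hosts))
    combined = Chem.RWMol(Chem.CombineMols(mol, frag))
    combined.AddBond(host, mol.GetNumAtoms(), Chem.BondType.SINGLE)
    out = combined.GetMol()
    try:
        Chem.SanitizeMol(out)
    except Exception:
        return mol
    return out


def _satisfies(profile: LibraryProfile, smiles: str) -> bool:
    val = fsp3(smiles)
    nar = physchem_panel(smiles)[6]
    if profile.fsp3_max is not None and val > profile.fsp3_max:
        return False
    if profile.fsp3_min is not None and val < profile.fsp3_min:
        return False
    if profile.nar_min is not None and nar < profile.nar_min:
        return False
    if profile.nar_max is not None and nar > profile.nar_max:
        return False
    return True


def generate_library(profile: LibraryProfile) -> list[MoleculeRecord]:
    """Deterministic-per-seed molecule set satisfying the profile constraints.

    Every output molecule is standardized and individually satisfies the
    profile's Fsp3 / aromatic-ring constraints (verified post hoc; violating
    draws are rejected and redrawn).
    """
    if profile.n < 1:
        raise GenerationError("profile.n must be >= 1")
    cores, subs = (
        (FLAT_CORES, FLAT_SUBSTITUENTS) if profile.name == "flat"
        else (THREED_CORES, THREED_SUBSTITUENTS)
    )
    rng = np.random.default_rng(profile.seed)
    records: list[MoleculeRecord] = []
    attempts = 0
    while len(records) < profile.n:
        attempts += 1
        if attempts > 200 * profile.n:
            raise GenerationError(f"profile {profile.name!r} appears unsatisfiable")
        core = Chem.MolFromSmiles(cores[int(rng.integers(len(cores)))])
        mol = _attach(core, subs[int(rng.integers(len(subs)))], rng)
        smiles = Chem.MolToSmiles(mol)
        if not _satisfies(profile, smiles):
            continue
        rec = standardize_molecule(
            smiles, id=f"{profile.name}_{len(records):03d}", source_tag="user"
        )
        records.append(rec)
    return records


# ---------------------------------------------------------------------------
# toy crystals


@dataclass
class CrystalPlacement:
    """One ligand copy: either anchored to a pocket or at the lattice interface.

    ``distance`` is the exact distance from the pocket pseudo-atom to the
    nearest ligand atom.  ``center``/``direction`` place interface or free
    copies explicitly.
    """

    ligand_id: str
    pocket_label: Optional[str] = None
    distance: float = 4.0
    center: Optional[np.ndarray] = None
    direction: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0, 0.0]))
    lattice_proximal: bool = False
    symmetric: bool = False


@dataclass
class CrystalLayout:
    cell_length: float = 40.0
    spacegroup: str = "P 1"
    protein_box: tuple[float, float] = (2.0, 26.0)
    protein_step: float = 4.0
    protein_coords: Optional[np.ndarray] = None  # explicit override of the grid
    pockets: dict[str, np.ndarray] = field(default_factory=dict)
    placements: list[CrystalPlacement] = field(default_factory=list)


@dataclass
class ToyCrystal:
    lattice: CrystalLattice
    protein: ProteinAtoms
    ligands: list[Conformer]
    pockets: list[PocketDefinition]
    ground_truth: pd.DataFrame
    spacegroup: str = "P 1"

    def write_pdb(self, path) -> None:
        st = gemmi.Structure()
        st.name = "toy"
        st.cell = gemmi.UnitCell(self.lattice.a, self.lattice.b, self.lattice.c,
                                 self.lattice.alpha, self.lattice.beta, self.lattice.gamma)
        st.spacegroup_hm = self.spacegroup
        model = gemmi.Model("1")
        chain = gemmi.Chain("A")
        for i in range(len(self.protein)):
            res = gemmi.Residue()
            res.name = "ALA"
            res.seqid = gemmi.SeqId(int(self.protein.resnums[i]), " ")
            res.het_flag = "A"
            atom = gemmi.Atom()
            atom.name = self.protein.names[i]
            atom.element = gemmi.Element(self.protein.elements[i])
            atom.pos = gemmi.Position(*self.protein.coords[i])
            res.add_atom(atom)
            chain.add_residue(res)
        model.add_chain(chain)
        lig_chain = gemmi.Chain("L")
        for n, lig in enumerate(self.ligands, start=1):
            res = gemmi.Residue()
            res.name = "LIG"
            res.seqid = gemmi.SeqId(n, " ")
            res.het_flag = "H"
            for k, (el, xyz) in enumerate(zip(lig.elements, lig.coords), start=1):
                atom = gemmi.Atom()
                atom.name = f"{el}{k}"
                atom.element = gemmi.Element(el)
                atom.pos = gemmi.Position(*xyz)
                res.add_atom(atom)
            lig_chain.add_residue(res)
        model.add_chain(lig_chain)
        st.add_model(model)
        st.setup_entities()
        st.write_pdb(str(path))

    def write_ground_truth(self, path) -> None:
        self.ground_truth.to_csv(path, index=False)


def _star_ligand(center: np.ndarray, direction: np.ndarray, ligand_id: str,
                 copy_id: str) -> Conformer:
    """Rigid 4-atom star: central atom at ``center``, arms pointing away from
    ``-direction`` so the central atom is the closest one to the anchor."""
    u = np.asarray(direction, dtype=float)
    u = u / np.linalg.norm(u)
    # orthonormal frame
    trial = np.array([0.0, 0.0, 1.0]) if abs(u[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    v = np.cross(u, trial)
    v /= np.linalg.norm(v)
    coords = np.array([center, center + 1.4 * u, center + 1.4 * v, center - 1.4 * v])
    return Conformer(
        molecule_id=ligand_id, provenance="crystal", elements=["C", "C", "C", "C"],
        coords=coords, bonds=[(0, 1), (0, 2), (0, 3)], copy_id=copy_id,
        structure_id="toy",
    )


def _symmetric_ligand(center: np.ndarray, axis: np.ndarray, ligand_id: str,
                      copy_id: str) -> Conformer:
    """5-atom rigid cross, mirror-symmetric about the plane through ``center``
    perpendicular to ``axis`` — used for the 50/50 surface-partition fixture."""
    u = np.asarray(axis, dtype=float)
    u = u / np.linalg.norm(u)
    trial = np.array([0.0, 0.0, 1.0]) if abs(u[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    v = np.cross(u, trial)
    v /= np.linalg.norm(v)
    coords = np.array([
        center, center + 1.4 * u, center - 1.4 * u, center + 1.4 * v, center - 1.4 * v,
    ])
    return Conformer(
        molecule_id=ligand_id, provenance="crystal", elements=["C"] * 5,
        coords=coords, bonds=[(0, 1), (0, 2), (0, 3), (0, 4)], copy_id=copy_id,
        structure_id="toy",
    )


def default_crystal_layout() -> CrystalLayout:
    """Pocket-recovery layout: boundary cases at 4.9 Å (in) and 5.1 Å (out),
    a dual binder, a peripheral binder and one lattice-interface copy."""
    pockets = {
        "A": np.array([10.0, 10.0, 10.0]),
        "B": np.array([24.0, 10.0, 10.0]),
        "G": np.array([10.0, 24.0, 10.0]),
    }
    placements = [
        CrystalPlacement("F1", pocket_label="A", distance=4.0),
        CrystalPlacement("F1", pocket_label="G", distance=4.0,
                         direction=np.array([0.0, 1.0, 0.0])),
        CrystalPlacement("F2", pocket_label="A", distance=4.9,
                         direction=np.array([0.0, 0.0, 1.0])),
        CrystalPlacement("F3", pocket_label="B", distance=5.1,
                         direction=np.array([0.0, 0.0, 1.0])),
        CrystalPlacement("F4", pocket_label="B", distance=3.0,
                         direction=np.array([0.0, 1.0, 0.0])),
        CrystalPlacement("F5", center=np.array([37.0, 14.0, 14.0]),
                         direction=np.array([-1.0, 0.0, 0.0]), lattice_proximal=True),
    ]
    return CrystalLayout(pockets=pockets, placements=placements)


def mirror_interface_layout() -> CrystalLayout:
    """A small cell with a protein wall at x = 2 whose +x lattice image
    mirrors it about the centered ligand: the two entities split the ligand
    surface 50/50.  The ligand's +x arm atom is strictly closer to the mate
    wall, so the copy is lattice-proximal."""
    ys, zs = np.meshgrid(np.arange(1.0, 9.5, 2.0), np.arange(1.0, 9.5, 2.0))
    wall = np.column_stack([np.full(ys.size, 2.0), ys.ravel(), zs.ravel()])
    layout = CrystalLayout(cell_length=10.0, protein_coords=wall, pockets={})
    layout.placements = [
        CrystalPlacement("M1", center=np.array([7.0, 5.0, 5.0]),
                         direction=np.array([1.0, 0.0, 0.0]),
                         lattice_proximal=True, symmetric=True)
    ]
    return layout


def generate_toy_crystal(layout: Optional[CrystalLayout] = None, seed: int = 7) -> ToyCrystal:
    """Build a :class:`ToyCrystal` with recoverable ground truth.

    Protein pseudo-atoms (one C-alpha per residue) sit on a cubic grid inside
    ``layout.protein_box``; protein atoms closer than 2.5 Å to any ligand
    atom are removed so placements never overlap; overlapping ligand
    placements raise :class:`GenerationError`.
    """
    layout = layout or default_crystal_layout()
    if not layout.placements:
        raise GenerationError("layout needs at least one placement")
    lo, hi = layout.protein_box
    if layout.cell_length <= 0:
        raise GenerationError("invalid cell")
    # ligands first
    ligands: list[Conformer] = []
    gt_rows = []
    per_ligand_labels: dict[str, set[str]] = {}
    for i, pl in enumerate(layout.placements):
        if pl.pocket_label is not None:
            anchor = layout.pockets[pl.pocket_label]
            center = anchor + pl.distance * (pl.direction / np.linalg.norm(pl.direction))
        else:
            center = np.asarray(pl.center, dtype=float)
        maker = _symmetric_ligand if pl.symmetric else _star_ligand
        conf = maker(center, pl.direction, pl.ligand_id, copy_id=f"copy{i + 1}")
        for prev in ligands:
            if cdist(conf.coords, prev.coords).min() < 2.0:
                raise GenerationError(f"overlapping placements: {conf.copy_id}, {prev.copy_id}")
        ligands.append(conf)
        expected = set()
        if pl.pocket_label is not None:
            radius = 5.0
            if pl.distance <= radius:
                expected.add(pl.pocket_label)
        per_ligand_labels.setdefault(pl.ligand_id, set()).update(expected)
        gt_rows.append(
            {
                "copy_id": conf.copy_id,
                "ligand_id": pl.ligand_id,
                "pocket_labels": "+".join(sorted(expected)),
                "lattice_proximal": pl.lattice_proximal,
            }
        )
    # protein grid (or explicit coordinates), avoiding ligand overlap
    if layout.protein_coords is not None:
        grid = np.asarray(layout.protein_coords, dtype=float).reshape(-1, 3)
    else:
        axis = np.arange(lo, hi + 1e-9, layout.protein_step)
        grid = np.array(np.meshgrid(axis, axis, axis)).reshape(3, -1).T
    if ligands:
        lig_all = np.vstack([l.coords for l in ligands])
        keep = cdist(grid, lig_all).min(axis=1) >= 2.5
        grid = grid[keep]
    n = grid.shape[0]
    protein = ProteinAtoms(
        names=["CA"] * n,
        elements=["C"] * n,
        chains=["A"] * n,
        resnums=np.arange(1, n + 1),
        resnames=["ALA"] * n,
        coords=grid,
    )
    lattice = CrystalLattice.from_gemmi(
        gemmi.UnitCell(layout.cell_length, layout.cell_length, layout.cell_length,
                       90.0, 90.0, 90.0),
        layout.spacegroup,
    )
    from .pockets import classify_binder

    gt = pd.DataFrame(gt_rows)
    gt["binder_class"] = [
        classify_binder([per_ligand_labels[ligand_id]]) for ligand_id in gt["ligand_id"]
    ]
    pockets = [PocketDefinition(k, v, 5.0) for k, v in sorted(layout.pockets.items())]
    return ToyCrystal(lattice, protein, ligands, pockets, gt, layout.spacegroup)


# ---------------------------------------------------------------------------
# reference molecules


REFERENCE_SMILES = {
    # globular cage amine: PBF ~1.0 A, 11 heavy atoms
    "amantadine": "NC12CC3CC(CC(C3)C1)C2",
    # near-planar aromatic acid: PBF ~0.13 A, 10 heavy atoms
    "salicylic_acid": "OC(=O)c1ccccc1O",
    "benzene": "c1ccccc1",
    "cyclohexane": "C1CCCCC1",
    "toluene": "Cc1ccccc1",
    "alanine_S": "C[C@H](N)C(=O)O",
}


def reference_fixtures() -> dict[str, MoleculeRecord]:
    """Named reference molecules with hand-checkable descriptor values."""
    return {
        name: standardize_molecule(smi, id=name, source_tag="user")
        for name, smi in REFERENCE_SMILES.items()
    }
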