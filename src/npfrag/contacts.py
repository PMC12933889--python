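"""Crystal-lattice contact analysis around ligand copies.

For each ligand copy the space-group symmetry is expanded to find
neighboring protein images ("symmetry mates") within a cutoff (default
6 Å).  A copy is flagged lattice-proximal when any of its atoms is strictly
closer to a mate than to the asymmetric unit, the ligand's solvent-exposed
surface is partitioned among the surrounding protein entities, and polar
interactions are counted per entity — together these separate genuine
binding sites from crystal-packing artifacts.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from itertools import product
from typing import Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .shape import Conformer
from .structures import CrystalLattice, ProteinAtoms, StructureModel

#: Bondi-style van der Waals radii (Å) for surface sampling.
VDW_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47, "P": 1.80,
    "S": 1.80, "CL": 1.75, "BR": 1.85, "I": 1.98,
}

POLAR_ELEMENTS = {"N", "O", "S"}

#: Protein atoms treated as charged for salt-bridge detection.
CHARGED_PROTEIN_ATOMS = {
    ("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"), ("GLU", "OE2"),
    ("LYS", "NZ"), ("ARG", "NH1"), ("ARG", "NH2"), ("ARG", "NE"),
}


@dataclass
class SymmetryMate:
    """A neighboring protein image: operator index, lattice shift, atoms."""

    op_index: int
    shift: tuple[int, int, int]
    atoms: ProteinAtoms

    @property
    def label(self) -> str:
        return f"mate_op{self.op_index}_{'_'.join(map(str, self.shift))}"


@dataclass
class SurfacePartition:
    """Percentage of ligand surface area attributed to each protein entity."""

    percentages: dict[str, float]
    unassigned: float
    total_area: float = 0.0

    def __post_init__(self):
        if any(p < -1e-9 for p in self.percentages.values()):
            raise ValueError("negative surface percentage")
        if sum(self.percentages.values()) > 100.0 + 1e-6:
            raise ValueError("surface percentages exceed 100")


@dataclass
class PolarContacts:
    hbonds: list[tuple[int, int, float]] = field(default_factory=list)
    salt_bridges: list[tuple[int, int, float]] = field(default_factory=list)
    water_mediated: list[tuple[int, int, float]] = field(default_factory=list)

    @property
    def n_hbonds(self) -> int:
        return len(self.hbonds)


def combine_atoms(*sets: Optional[ProteinAtoms]) -> ProteinAtoms:
    """Concatenate atom sets (e.g. protein plus its waters)."""
    parts = [s for s in sets if s is not None and len(s)]
    if not parts:
        raise ValueError("no atoms to combine")
    return ProteinAtoms(
        names=sum((p.names for p in parts), []),
        elements=sum((p.elements for p in parts), []),
        chains=sum((p.chains for p in parts), []),
        resnums=np.concatenate([p.resnums for p in parts]),
        resnames=sum((p.resnames for p in parts), []),
        coords=np.vstack([p.coords for p in parts]),
    )


def expand_symmetry(model: StructureModel, copy: Conformer, cutoff: float = 6.0,
                    *, lattice: Optional[CrystalLattice] = None,
                    include_waters: bool = True) -> list[SymmetryMate]:
    """Symmetry/lattice images of the protein near one ligand copy.

    Returns every image (space-group operator + integer lattice translation)
    with at least one atom within ``cutoff`` of at least one resolved ligand
    atom; the identity operator with zero translation (the asymmetric unit
    itself) is never returned.
    """
    lat = lattice or model.lattice
    if lat is None:
        raise ValueError("no crystal lattice available")
    if cutoff <= 0:
        return []
    atoms = model.protein
    if include_waters and model.waters is not None:
        atoms = combine_atoms(model.protein, model.waters)
    frac = atoms.coords @ lat.fractionalization.T
    lig = copy.coords[copy.resolved_mask]
    lig_frac_center = (lig @ lat.fractionalization.T).mean(axis=0)
    orth = lat.orthogonalization
    tree = cKDTree(lig)
    mates = []
    for k, (rot, tran) in enumerate(lat.operators):
        img = frac @ rot.T + tran
        base = np.round(lig_frac_center - img.mean(axis=0)).astype(int)
        for delta in product((-1, 0, 1), repeat=3):
            shift = base + np.array(delta)
            if k == 0 and not shift.any():
                continue
            cart = (img + shift) @ orth.T
            d, _ = tree.query(cart, k=1, distance_upper_bound=cutoff)
            if np.isfinite(d).any():
                mate_atoms = replace(atoms, coords=cart)
                mates.append(SymmetryMate(k, tuple(int(s) for s in shift), mate_atoms))
    return mates


def flag_lattice_proximal(copy: Conformer, asym_atoms: ProteinAtoms,
                          mates: Sequence[SymmetryMate]) -> bool:
    """True iff some ligand atom's nearest protein atom belongs to a mate.

    Exact ties break toward the asymmetric unit (strict "closer").
    """
    if not mates:
        return False
    lig = copy.coords[copy.resolved_mask]
    d_asym = cKDTree(asym_atoms.coords).query(lig, k=1)[0]
    for mate in mates:
        d_mate = cKDTree(mate.atoms.coords).query(lig, k=1)[0]
        if (d_mate < d_asym).any():
            return True
    return False


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5**0.5) * i
    return np.column_stack(
        [np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)]
    )


def surface_partition(copy: Conformer, entities: Sequence[tuple[str, ProteinAtoms]],
                      probe: float = 1.4, proximity_cap: float = 6.0,
                      n_points: int = 960) -> SurfacePartition:
    """Partition the ligand's solvent-accessible surface among protein entities.

    The surface is sampled with Shrake–Rupley-style sphere points on every
    resolved heavy atom (default 960 points/atom, probe 1.4 Å).  Each
    accessible point is attributed to the entity owning the nearest protein
    heavy atom, provided that atom lies within ``proximity_cap``; points
    without a sufficiently close protein atom stay unassigned.
    """
    if not entities:
        raise ValueError("at least one entity required")
    mask = copy.heavy_mask & copy.resolved_mask
    centers = copy.coords[mask]
    elems = [e for e, m in zip(copy.elements, mask) if m]
    if centers.shape[0] == 0:
        raise ValueError("ligand has no resolved heavy atoms")
    radii = np.array([VDW_RADII.get(e.upper(), 1.70) + probe for e in elems])
    unit = _sphere_points(n_points)
    trees = []
    for label, atoms in entities:
        heavy = np.array([e.upper() != "H" for e in atoms.elements])
        if not heavy.any():
            raise ValueError(f"entity {label!r} has no heavy atoms")
        trees.append((label, cKDTree(atoms.coords[heavy])))
    area_by_entity = {label: 0.0 for label, _ in entities}
    unassigned_area = 0.0
    total_area = 0.0
    for i, (center, r) in enumerate(zip(centers, radii)):
        pts = center + r * unit
        # accessibility: point outside every other atom's expanded sphere
        accessible = np.ones(n_points, dtype=bool)
        for j, (other, r_other) in enumerate(zip(centers, radii)):
            if j == i:
                continue
            if np.linalg.norm(other - center) < r + r_other:
                accessible &= np.linalg.norm(pts - other, axis=1) >= r_other
        if not accessible.any():
            continue
        w = 4.0 * np.pi * r * r / n_points
        pts_acc = pts[accessible]
        total_area += w * pts_acc.shape[0]
        dists = np.column_stack([tree.query(pts_acc, k=1)[0] for _, tree in trees])
        nearest = np.argmin(dists, axis=1)
        nearest_d = dists[np.arange(len(pts_acc)), nearest]
        within = nearest_d <= proximity_cap
        for k, (label, _) in enumerate(trees):
            area_by_entity[label] += w * int(((nearest == k) & within).sum())
        unassigned_area += w * int((~within).sum())
    if total_area <= 0:
        raise ValueError("zero accessible surface area")
    return SurfacePartition(
        percentages={k: 100.0 * v / total_area for k, v in area_by_entity.items()},
        unassigned=100.0 * unassigned_area / total_area,
        total_area=total_area,
    )


def polar_contacts(copy: Conformer, entity: ProteinAtoms,
                   hbond_cutoff: float = 3.5, saltbridge_cutoff: float = 4.0,
                   ligand_charged: Sequence[int] = ()) -> PolarContacts:
    """Distance-based polar interactions between a ligand copy and an entity.

    N/O/S heavy-atom pairs within ``hbond_cutoff`` count as hydrogen bonds
    (contacts to water oxygens are reported separately as water-mediated);
    pairs of charged atoms within ``saltbridge_cutoff`` are flagged as salt
    bridges.  Ligand charged atoms must be supplied by index since crystal
    conformers carry no formal charges.
    """
    out = PolarContacts()
    lig_polar = [
        i for i in range(len(copy.elements))
        if copy.resolved_mask[i] and copy.elements[i].upper() in POLAR_ELEMENTS
    ]
    if not lig_polar or len(entity) == 0:
        return out
    is_water = entity.is_water
    ent_polar = [
        j for j in range(len(entity)) if entity.elements[j].upper() in POLAR_ELEMENTS
    ]
    charged_lig = set(ligand_charged)
    for i in lig_polar:
        for j in ent_polar:
            d = float(np.linalg.norm(copy.coords[i] - entity.coords[j]))
            if d <= hbond_cutoff:
                if is_water[j]:
                    out.water_mediated.append((i, j, d))
                else:
                    out.hbonds.append((i, j, d))
            if (
                d <= saltbridge_cutoff
                and i in charged_lig
                and (entity.resnames[j], entity.names[j]) in CHARGED_PROTEIN_ATOMS
            ):
                out.salt_bridges.append((i, j, d))
    return out


def contact_report(rows: Sequence[dict], path) -> None:
    """CSV report, one row per (ligand copy, entity)."""
    fields = ["copy_id", "entity", "surface_pct", "n_hbonds", "n_saltbridges",
              "n_water_mediated", "lattice_proximal"]
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=fields)
        writer.writeheader()
        for row in rows:
            writer.writerow(row)
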