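"""Kinase binding-pocket assignment.

Pockets A–L are represented by pseudo-atoms: pocket A (the orthosteric ATP
site) at the center of mass of the adenine substructure of bound ATP, the
peripheral pockets at the center of mass of the reference ligands annotated
to occupy them.  After all structures are superposed onto a common reference
frame, a ligand copy is assigned to every pocket whose pseudo-atom lies
within a fixed radius (default 5 Å) of any of its resolved heavy atoms, and
each fragment is classified from the union of its copies' assignments as an
orthosteric-only, peripheral-only, dual or unassigned binder.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from ._geom import kabsch
from .shape import Conformer
from .structures import StructureModel

#: Standard atomic masses for center-of-mass pseudo-atom placement.
ATOMIC_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "F": 18.998,
    "P": 30.974, "S": 32.06, "CL": 35.45, "BR": 79.904, "I": 126.904,
}

POCKET_LABELS = tuple("ABCDEFGHIJKL")
ORTHOSTERIC_LABEL = "A"


class AlignmentError(ValueError):
    pass


@dataclass
class PocketDefinition:
    label: str
    pseudo_atom: np.ndarray
    radius: float = 5.0

    def __post_init__(self):
        self.pseudo_atom = np.asarray(self.pseudo_atom, dtype=float)
        if self.radius <= 0:
            raise ValueError("pocket radius must be positive")


@dataclass
class SuperpositionResult:
    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    n_matched: int


def superpose_to_reference(model: StructureModel, reference: StructureModel,
                           ) -> tuple[StructureModel, SuperpositionResult]:
    """Rigid Kabsch superposition of ``model`` onto ``reference`` over Cα.

    Cα pairs are matched by (chain id, residue number); the fitted transform
    is applied to all model atoms including ligand copies and waters.
    """
    def ca_map(m: StructureModel) -> dict[tuple[str, int], np.ndarray]:
        out = {}
        for i, name in enumerate(m.protein.names):
            if name.strip() == "CA":
                out[(m.protein.chains[i], int(m.protein.resnums[i]))] = m.protein.coords[i]
        return out

    ca_model = ca_map(model)
    ca_ref = ca_map(reference)
    keys = sorted(set(ca_model) & set(ca_ref))
    if len(keys) < 3:
        raise AlignmentError(f"only {len(keys)} matched C-alpha pairs (need >= 3)")
    moving = np.array([ca_model[k] for k in keys])
    target = np.array([ca_ref[k] for k in keys])
    rot, trans, rmsd = kabsch(moving, target)
    return model.transformed(rot, trans), SuperpositionResult(rot, trans, rmsd, len(keys))


def pocket_center(coords: np.ndarray, elements: Sequence[str] | None = None,
                  *, mode: str = "com") -> np.ndarray:
    """Pseudo-atom position for a pocket's reference-ligand atoms.

    ``mode='com'`` uses a mass-weighted center of mass with standard atomic
    masses; ``mode='centroid'`` the unweighted geometric centroid.
    """
    coords = np.asarray(coords, dtype=float).reshape(-1, 3)
    if coords.shape[0] == 0:
        raise ValueError("no atoms supplied")
    if mode == "centroid" or elements is None:
        return coords.mean(axis=0)
    if mode != "com":
        raise ValueError(f"unknown mode {mode!r}")
    masses = np.array([ATOMIC_MASSES.get(e.upper(), 12.011) for e in elements])
    return (coords * masses[:, None]).sum(axis=0) / masses.sum()


def assign_pockets(copy: Conformer, pockets: Sequence[PocketDefinition],
                   *, use_centroid: bool = False) -> set[str]:
    """Pocket labels whose pseudo-atom is within radius of the ligand copy.

    Default rule: any resolved heavy atom within the pocket radius
    (inclusive).  With ``use_centroid`` the copy's resolved-heavy-atom
    centroid is tested instead.
    """
    pts = copy.coords[copy.heavy_mask & copy.resolved_mask]
    if pts.shape[0] == 0:
        return set()
    if use_centroid:
        pts = pts.mean(axis=0, keepdims=True)
    labels = set()
    for pocket in pockets:
        d = np.linalg.norm(pts - pocket.pseudo_atom, axis=1)
        if d.min() <= pocket.radius:
            labels.add(pocket.label)
    return labels


def classify_binder(assignments: Iterable[set[str]]) -> str:
    """Fragment-level class from its copies' pocket assignments.

    orthosteric_only: every assigned copy sits only in the ATP pocket (A);
    peripheral_only: assignments exist and never include A; both: A and at
    least one peripheral label occur; unassigned: no copy was assigned.
    """
    all_labels: set[str] = set()
    for labels in assignments:
        all_labels |= labels
    if not all_labels:
        return "unassigned"
    has_ortho = ORTHOSTERIC_LABEL in all_labels
    has_peripheral = bool(all_labels - {ORTHOSTERIC_LABEL})
    if has_ortho and has_peripheral:
        return "both"
    return "orthosteric_only" if has_ortho else "peripheral_only"


# ---------------------------------------------------------------------------
# serialization


def write_pocket_definitions(pockets: Sequence[PocketDefinition], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["label", "x", "y", "z", "radius"])
        for p in pockets:
            writer.writerow([p.label, *(f"{v:.4f}" for v in p.pseudo_atom), p.radius])


def read_pocket_definitions(path) -> list[PocketDefinition]:
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(
                PocketDefinition(
                    row["label"],
                    np.array([float(row["x"]), float(row["y"]), float(row["z"])]),
                    float(row["radius"]),
                )
            )
    labels = [p.label for p in out]
    if len(labels) != len(set(labels)):
        raise ValueError("duplicate pocket labels")
    return out


def assignment_report(per_fragment: Mapping[str, Sequence[tuple[str, set[str]]]], path) -> None:
    """CSV report: fragment id, copy id, labels, fragment class."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["fragment_id", "copy_id", "labels", "binder_class"])
        for frag_id, copies in per_fragment.items():
            cls = classify_binder(labels for _, labels in copies)
            for copy_id, labels in copies:
                writer.writerow([frag_id, copy_id, "+".join(sorted(labels)), cls])
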