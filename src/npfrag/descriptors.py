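"""2D descriptor panel: physicochemical properties, saturation and
spatial-complexity scores, rule-of-three compliance.

The panel mirrors the comparison axes used to delineate fragment chemical
space: fundamental properties (MW, HBA, HBD, cLogP, NRB, TPSA, NAR),
carbon-based saturation measures (Fsp3, FC_Stereo), the spatial score
(SPS/nSPS) and natural-product likeness (see :mod:`npfrag.nplikeness`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, rdMolDescriptors

from .standardize import MoleculeRecord

MolLike = Union[Chem.Mol, MoleculeRecord, str]


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
class Ro3Bounds:
    """Rule-of-Three fragment-likeness bounds, all inclusive."""

    mw: float = 300.0
    hbd: int = 3
    hba: int = 3
    logp: float = 3.0
    nrb: int = 3
    tpsa: float = 60.0


@dataclass
class DescriptorVector:
    mw: float
    hba: int
    hbd: int
    logp: float
    nrb: int
    tpsa: float
    nar: int
    fsp3: float
    fc_stereo: float
    sps: float
    nsps: float
    np_likeness: Optional[float] = None
    ro3_compliant: Optional[bool] = None


def fsp3(mol: MolLike) -> float:
    """Fraction of carbons that are sp3-hybridized; 0 for carbon-free input."""
    m = _as_mol(mol)
    carbons = [a for a in m.GetAtoms() if a.GetAtomicNum() == 6]
    if not carbons:
        warnings.warn("fsp3 of a carbon-free molecule is 0 by convention")
        return 0.0
    n_sp3 = sum(1 for a in carbons if a.GetHybridization() == Chem.HybridizationType.SP3)
    return n_sp3 / len(carbons)


def fc_stereo(mol: MolLike, *, include_unassigned: bool = True) -> float:
    """Fraction of carbons that are stereogenic.

    Stereocenters are perceived symmetry-aware; with ``include_unassigned``
    (default) potential but unassigned centers count as stereogenic, so the
    measure does not depend on whether configurations were annotated.
    """
    m = _as_mol(mol)
    n_carbon = sum(1 for a in m.GetAtoms() if a.GetAtomicNum() == 6)
    if n_carbon == 0:
        warnings.warn("fc_stereo of a carbon-free molecule is 0 by convention")
        return 0.0
    centers = Chem.FindMolChiralCenters(
        m, includeUnassigned=include_unassigned, useLegacyImplementation=False
    )
    n_stereo_c = sum(1 for idx, _ in centers if m.GetAtomWithIdx(idx).GetAtomicNum() == 6)
    return n_stereo_c / n_carbon


# -- spatial score ----------------------------------------------------------

_HYBRIDIZATION_TERM = {
    Chem.HybridizationType.SP: 1,
    Chem.HybridizationType.SP2: 2,
    Chem.HybridizationType.SP3: 3,
}


def spatial_score(mol: MolLike) -> tuple[float, float]:
    """Spatial score (SPS) and its size-normalized form (nSPS).

    Each heavy atom contributes the product of four terms: a hybridization
    term (sp 1, sp2 2, sp3 3, anything else 4), a stereo term (2 for
    stereogenic atoms — tetrahedral centers and atoms of stereogenic double
    bonds, assigned or potential — else 1), a non-aromatic-ring term (2 for
    atoms in a non-aromatic ring, else 1) and the squared count of directly
    bonded heavy atoms.  nSPS divides the atom-term sum by the heavy-atom
    count.

    Computed on the hydrogen-suppressed graph, so explicit hydrogens do not
    change the value.
    """
    m = Chem.RemoveHs(_as_mol(mol))
    stereo_atoms: set[int] = set()
    for element in Chem.FindPotentialStereo(m):
        if str(element.type).startswith("Atom"):
            stereo_atoms.add(int(element.centeredOn))
        else:  # stereogenic double bond: both of its atoms count
            bond = m.GetBondWithIdx(int(element.centeredOn))
            stereo_atoms.update((bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()))
    ring_info = m.GetRingInfo()
    non_aromatic_ring_atoms: set[int] = set()
    for ring in ring_info.AtomRings():
        if not all(m.GetAtomWithIdx(i).GetIsAromatic() for i in ring):
            non_aromatic_ring_atoms.update(ring)
    total = 0.0
    n_heavy = m.GetNumHeavyAtoms()
    if n_heavy == 0:
        raise ValueError("spatial_score requires at least one heavy atom")
    for atom in m.GetAtoms():
        h = _HYBRIDIZATION_TERM.get(atom.GetHybridization(), 4)
        s = 2 if atom.GetIdx() in stereo_atoms else 1
        r = 2 if atom.GetIdx() in non_aromatic_ring_atoms else 1
        n = sum(1 for nb in atom.GetNeighbors() if nb.GetAtomicNum() > 1)
        total += h * s * r * n * n
    return total, total / n_heavy


def physchem_panel(mol: MolLike) -> tuple[float, int, int, float, int, float, int]:
    """(MW, HBA, HBD, cLogP, NRB, TPSA, NAR) for a standardized molecule.

    HBA/HBD are acceptor/donor atom counts; LogP is the Crippen
    atom-contribution estimate; NAR counts aromatic rings in the smallest
    set of smallest rings, so fused aromatics count per ring.
    """
    m = _as_mol(mol)
    return (
        Descriptors.MolWt(m),
        rdMolDescriptors.CalcNumHBA(m),
        rdMolDescriptors.CalcNumHBD(m),
        Crippen.MolLogP(m),
        rdMolDescriptors.CalcNumRotatableBonds(m),
        rdMolDescriptors.CalcTPSA(m),
        rdMolDescriptors.CalcNumAromaticRings(m),
    )


def ro3_compliance(v: DescriptorVector, bounds: Ro3Bounds = Ro3Bounds()) -> bool:
    """Rule-of-Three check with inclusive bounds on all six properties."""
    return (
        v.mw <= bounds.mw
        and v.hbd <= bounds.hbd
        and v.hba <= bounds.hba
        and v.logp <= bounds.logp
        and v.nrb <= bounds.nrb
        and v.tpsa <= bounds.tpsa
    )


def compliance_fraction(values: Sequence[float], cutoff: float) -> float:
    """Fraction of values reaching ``cutoff`` (inclusive, as in Fsp3 >= 0.42)."""
    if len(values) == 0:
        raise ValueError("compliance_fraction of an empty list is undefined")
    return sum(1 for v in values if v >= cutoff) / len(values)


def describe(mol: MolLike, *, np_scorer=None, ro3_bounds: Ro3Bounds = Ro3Bounds()) -> DescriptorVector:
    """Full 2D descriptor vector for one molecule."""
    m = _as_mol(mol)
    mw, hba, hbd, logp, nrb, tpsa, nar = physchem_panel(m)
    sps, nsps = spatial_score(m)
    v = DescriptorVector(
        mw=mw, hba=hba, hbd=hbd, logp=logp, nrb=nrb, tpsa=tpsa, nar=nar,
        fsp3=fsp3(m), fc_stereo=fc_stereo(m), sps=sps, nsps=nsps,
    )
    if np_scorer is not None:
        v.np_likeness = np_scorer.score(m)
    v.ro3_compliant = ro3_compliance(v, ro3_bounds)
    return v


def descriptor_table(records: Sequence[MoleculeRecord], *, np_scorer=None) -> pd.DataFrame:
    """One row per molecule: id, source_tag and the DescriptorVector fields."""
    rows = []
    for rec in records:
        v = describe(rec, np_scorer=np_scorer)
        rows.append({"id": rec.id, "source_tag": rec.source_tag, **v.__dict__})
    return pd.DataFrame(rows)
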