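"""Molecule standardization, curation and deduplication.

Every dataset entering the analysis — fragment hits, protein-bound ligands,
kinase bioactivity sets, approved drugs — is funnelled through the same
three-step standardization (metal disconnection, desalting to the largest
organic fragment, charge neutralization) followed by SMILES canonicalization
and per-dataset deduplication.  Bioactivity sets are additionally filtered on
pChEMBL and ligand efficiency in high-confidence assays before
standardization.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Optional, Sequence

from rdkit import Chem
from rdkit.Chem.MolStandardize import rdMolStandardize

logger = logging.getLogger(__name__)

#: Free-energy conversion used by the Hopkins ligand-efficiency definition,
#: LE = 1.37 * pActivity / heavy atoms (kcal/mol per heavy atom at 300 K).
LE_CONVERSION = 1.37

SOURCE_TAGS = (
    "fragments",
    "pdb_ligands",
    "chembl_kinase",
    "chembl_pka",
    "approved_pki",
    "oral_drugs",
    "np_parents",
    "user",
)


class StandardizationError(ValueError):
    """Raised when a structure cannot be parsed or standardized."""


class InorganicInputError(StandardizationError):
    """Raised when no organic (carbon-containing) component remains."""


@dataclass
class MoleculeRecord:
    """One standardized small molecule with identifiers and annotations.

    ``smiles_canonical`` is always a single connected, neutralized, canonical
    structure; ``heavy_atom_count`` is derived from it.
    """

    id: str
    smiles_raw: str
    smiles_canonical: str
    source_tag: str = "user"
    pchembl: Optional[float] = None
    assay_confidence: Optional[int] = None
    approval_year: Optional[int] = None
    heavy_atom_count: int = field(default=0)

    def mol(self) -> Chem.Mol:
        m = Chem.MolFromSmiles(self.smiles_canonical)
        if m is None:  # pragma: no cover - canonical strings always parse
            raise StandardizationError(f"stored SMILES no longer parses: {self.id}")
        return m


_metal_disconnector = rdMolStandardize.MetalDisconnector()
_largest_chooser = rdMolStandardize.LargestFragmentChooser(preferOrganic=True)
_uncharger = rdMolStandardize.Uncharger()


def standardize_smiles(raw: str) -> str:
    """Apply the standardization cascade to a raw SMILES and canonicalize.

    Steps, in order: metal–organic bond disconnection (the metal is dropped
    with the salt), largest-organic-fragment selection, charge neutralization
    of protonatable/deprotonatable groups (permanent cations such as
    quaternary nitrogen are untouched), canonical SMILES output.

    Raises
    ------
    StandardizationError
        If ``raw`` does not parse.
    InorganicInputError
        If no carbon-containing component survives desalting.
    """
    mol = Chem.MolFromSmiles(raw)
    if mol is None:
        raise StandardizationError(f"unparseable SMILES: {raw!r}")
    mol = _metal_disconnector.Disconnect(mol)
    mol = _largest_chooser.choose(mol)
    if not any(a.GetAtomicNum() == 6 for a in mol.GetAtoms()):
        raise InorganicInputError(f"no organic component in {raw!r}")
    mol = _uncharger.uncharge(mol)
    Chem.SanitizeMol(mol)
    return Chem.MolToSmiles(mol)


def standardize_molecule(
    raw: str,
    *,
    id: str = "",
    source_tag: str = "user",
    pchembl: Optional[float] = None,
    assay_confidence: Optional[int] = None,
    approval_year: Optional[int] = None,
) -> MoleculeRecord:
    """Standardize one raw structure string into a :class:`MoleculeRecord`."""
    canonical = standardize_smiles(raw)
    mol = Chem.MolFromSmiles(canonical)
    return MoleculeRecord(
        id=id or canonical,
        smiles_raw=raw,
        smiles_canonical=canonical,
        source_tag=source_tag,
        pchembl=pchembl,
        assay_confidence=assay_confidence,
        approval_year=approval_year,
        heavy_atom_count=mol.GetNumHeavyAtoms(),
    )


def standardize_records(records: Iterable[MoleculeRecord]) -> list[MoleculeRecord]:
    """Re-standardize existing records (idempotent); unparseable ones raise."""
    out = []
    for rec in records:
        canonical = standardize_smiles(rec.smiles_canonical or rec.smiles_raw)
        mol = Chem.MolFromSmiles(canonical)
        out.append(
            replace(rec, smiles_canonical=canonical, heavy_atom_count=mol.GetNumHeavyAtoms())
        )
    return out


def deduplicate(records: Sequence[MoleculeRecord]) -> list[MoleculeRecord]:
    """Keep the first record per (source_tag, canonical SMILES) pair.

    Stereochemistry-differing entries have different canonical strings and are
    kept distinct.
    """
    seen: set[tuple[str, str]] = set()
    out = []
    for rec in records:
        key = (rec.source_tag, rec.smiles_canonical)
        if key not in seen:
            seen.add(key)
            out.append(rec)
    return out


def ligand_efficiency(pchembl: float, heavy_atoms: int, *, conversion: float = LE_CONVERSION) -> float:
    """Ligand efficiency LE = conversion * pChEMBL / heavy-atom count.

    Units are kcal/mol per heavy atom with the default conversion of 1.37.
    """
    if heavy_atoms < 1:
        raise ValueError("heavy_atoms must be >= 1")
    if pchembl < 0:
        raise ValueError("pchembl must be >= 0")
    return conversion * pchembl / heavy_atoms


def curate_activity_dataset(
    records: Iterable[MoleculeRecord],
    pchembl_min: float = 5.0,
    le_min: float = 0.3,
    confidence_required: int = 9,
) -> list[MoleculeRecord]:
    """Activity-filter, standardize and deduplicate a bioactivity dataset.

    A record is retained when its assay confidence equals
    ``confidence_required`` and it reaches ``pchembl_min`` in pChEMBL or
    ``le_min`` in ligand efficiency (inclusive bounds, inclusive OR).  Records
    lacking pChEMBL or confidence annotations are dropped and counted in the
    log.
    """
    kept: list[MoleculeRecord] = []
    n_unannotated = 0
    for rec in records:
        if rec.pchembl is None or rec.assay_confidence is None:
            n_unannotated += 1
            continue
        if rec.assay_confidence != confidence_required:
            continue
        n_heavy = rec.heavy_atom_count or Chem.MolFromSmiles(
            rec.smiles_canonical or rec.smiles_raw
        ).GetNumHeavyAtoms()
        le = ligand_efficiency(rec.pchembl, n_heavy)
        if rec.pchembl >= pchembl_min or le >= le_min:
            kept.append(rec)
    if n_unannotated:
        logger.info("curation dropped %d records lacking annotations", n_unannotated)
    return deduplicate(standardize_records(kept))


# ---------------------------------------------------------------------------
# Readers / writers


def read_smiles_file(path, source_tag: str = "user") -> list[MoleculeRecord]:
    """Read a SMILES file: one molecule per line, optional tab-separated id."""
    out = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            smiles = parts[0]
            mol_id = parts[1] if len(parts) > 1 else f"mol{i}"
            out.append(standardize_molecule(smiles, id=mol_id, source_tag=source_tag))
    return out


def read_sdf(path, source_tag: str = "user") -> list[MoleculeRecord]:
    out = []
    for i, mol in enumerate(Chem.SDMolSupplier(str(path))):
        if mol is None:
            raise StandardizationError(f"unparseable SDF record #{i} in {path}")
        mol_id = mol.GetProp("_Name") if mol.HasProp("_Name") else f"mol{i}"
        out.append(standardize_molecule(Chem.MolToSmiles(mol), id=mol_id, source_tag=source_tag))
    return out


def read_activity_csv(path) -> list[MoleculeRecord]:
    """Read an activity table CSV: id, smiles, pchembl, confidence, source_tag."""
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(
                standardize_molecule(
                    row["smiles"],
                    id=row["id"],
                    source_tag=row.get("source_tag", "user") or "user",
                    pchembl=float(row["pchembl"]) if row.get("pchembl") else None,
                    assay_confidence=int(row["confidence"]) if row.get("confidence") else None,
                )
            )
    return out


def write_smiles_file(records: Sequence[MoleculeRecord], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f"{rec.smiles_canonical}\t{rec.id}\n")


def write_sdf(records: Sequence[MoleculeRecord], path) -> None:
    writer = Chem.SDWriter(str(path))
    for rec in records:
        mol = rec.mol()
        mol.SetProp("_Name", rec.id)
        mol.SetProp("source_tag", rec.source_tag)
        writer.write(mol)
    writer.close()
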