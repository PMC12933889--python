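"""Natural-product likeness scoring.

A fragment-contribution score: every heavy atom contributes the
log-frequency-ratio of its circular environment (radius 2) between a
natural-product corpus and a synthetic-compound corpus; the per-atom
contributions are summed and divided by the atom count, so the score is
size-normalized.  Positive values indicate NP-like atom environments,
negative values synthetic-like ones.

The packaged default table is trained on two small bundled exemplar sets
(sugar/terpenoid/alkaloid-like vs. flat synthetic chemotypes); it supports
ordering comparisons between NP-like and synthetic-like molecules, not
absolute comparability with scores from large-corpus tables.  A loader for
user-supplied tables is provided.
"""

from __future__ import annotations

import json
import math
from importlib import resources
from typing import Iterable, Union

from rdkit import Chem
from rdkit.Chem import AllChem

MolLike = Union[Chem.Mol, str]

_RADIUS = 2


def _as_mol(mol: MolLike) -> Chem.Mol:
    if isinstance(mol, Chem.Mol):
        return mol
    m = Chem.MolFromSmiles(mol)
    if m is None:
        raise ValueError(f"unparseable SMILES: {mol!r}")
    return m


def _atom_environments(mol: Chem.Mol) -> list[int]:
    """Largest-radius Morgan environment identifier per heavy atom.

    Computed on the hydrogen-suppressed graph so explicit hydrogens do not
    change the result.
    """
    m = Chem.RemoveHs(mol)
    info: dict[int, tuple] = {}
    AllChem.GetMorganFingerprint(m, _RADIUS, bitInfo=info)
    best: dict[int, tuple[int, int]] = {}  # atom -> (radius, bit)
    for bit, sites in info.items():
        for atom_idx, radius in sites:
            if atom_idx not in best or radius > best[atom_idx][0]:
                best[atom_idx] = (radius, bit)
    return [best[i][1] for i in sorted(best)]


class NPLikenessScorer:
    """Scores molecules against a fragment-contribution table."""

    def __init__(self, contributions: dict[int, float], score_min: float = -5.0,
                 score_max: float = 5.0):
        if not contributions:
            raise ValueError("empty contribution table")
        self.contributions = {int(k): float(v) for k, v in contributions.items()}
        self.score_min = score_min
        self.score_max = score_max

    def score(self, mol: MolLike) -> float:
        """Size-normalized NP-likeness; 0 if no environment is tabulated."""
        m = _as_mol(mol)
        envs = _atom_environments(m)
        if not envs:
            raise ValueError("molecule has no heavy atoms")
        total = sum(self.contributions.get(e, 0.0) for e in envs)
        return min(self.score_max, max(self.score_min, total / len(envs)))

    # -- persistence --------------------------------------------------------

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "radius": _RADIUS,
                    "score_min": self.score_min,
                    "score_max": self.score_max,
                    "contributions": {str(k): v for k, v in self.contributions.items()},
                },
                fh,
            )

    @classmethod
    def from_json(cls, path) -> "NPLikenessScorer":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(payload["contributions"], payload["score_min"], payload["score_max"])

    @classmethod
    def train(cls, np_molecules: Iterable[MolLike], synthetic_molecules: Iterable[MolLike],
              *, smoothing: float = 1.0, score_min: float = -5.0,
              score_max: float = 5.0) -> "NPLikenessScorer":
        """Train a contribution table from two corpora.

        Per environment ``e``: contribution = log10 of the ratio of its
        additively smoothed relative frequencies in the NP vs. synthetic
        corpus.
        """
        def env_counts(mols):
            counts: dict[int, int] = {}
            total = 0
            for mol in mols:
                for e in _atom_environments(_as_mol(mol)):
                    counts[e] = counts.get(e, 0) + 1
                    total += 1
            return counts, total

        np_counts, np_total = env_counts(np_molecules)
        sy_counts, sy_total = env_counts(synthetic_molecules)
        if np_total == 0 or sy_total == 0:
            raise ValueError("both training corpora must be non-empty")
        contributions = {}
        for e in set(np_counts) | set(sy_counts):
            f_np = (np_counts.get(e, 0) + smoothing) / (np_total + smoothing)
            f_sy = (sy_counts.get(e, 0) + smoothing) / (sy_total + smoothing)
            contributions[e] = math.log10(f_np / f_sy)
        return cls(contributions, score_min, score_max)

    @classmethod
    def default(cls) -> "NPLikenessScorer":
        """The packaged table trained on the bundled exemplar sets."""
        ref = resources.files("npfrag.data").joinpath("np_contributions.json")
        with resources.as_file(ref) as path:
            return cls.from_json(path)


def load_exemplars(name: str) -> list[str]:
    """Bundled exemplar SMILES: ``name`` is 'np' or 'synthetic'."""
    ref = resources.files("npfrag.data").joinpath(f"{name}_exemplars.smi")
    out = []
    for line in ref.read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line.split("\t")[0])
    return out
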