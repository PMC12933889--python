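"""3D shape descriptors: seeded embedding, PBF/nPBF, abstracted RMSD,
copy selection and aggregation."""

import networkx as nx
import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import npfrag as nf
from npfrag._geom import kabsch
from npfrag.shape import (
    Conformer,
    DegenerateGeometryError,
    IncompatibleConformersError,
    LigandCopySet,
    abstracted_rmsd,
    aggregate_per_ligand,
    delta_npbf,
    embed_conformer,
    npbf,
    pbf,
    select_copies,
)


def brute_force_rmsd(a: Conformer, b: Conformer) -> float:
    """Independent oracle: enumerate automorphisms with networkx, Kabsch each."""
    g = nx.Graph()
    g.add_nodes_from(range(len(a.elements)))
    g.add_edges_from(a.bonds)
    matcher = nx.algorithms.isomorphism.GraphMatcher(g, g)
    best = np.inf
    for mapping in matcher.isomorphisms_iter():
        perm = [mapping[i] for i in range(len(a.elements))]
        _, _, rmsd = kabsch(a.coords, b.coords[perm])
        best = min(best, rmsd)
    return best


def make_conf(coords, bonds, elements=None, **kw):
    coords = np.asarray(coords, dtype=float)
    return Conformer(
        molecule_id=kw.pop("molecule_id", "m"),
        provenance=kw.pop("provenance", "crystal"),
        elements=elements or ["C"] * len(coords),
        coords=coords,
        bonds=bonds,
        **kw,
    )


class TestEmbedding:
    def test_seeded_determinism(self):
        a = embed_conformer("CCOCC", seed=11)
        b = embed_conformer("CCOCC", seed=11)
        assert np.array_equal(a.coords, b.coords)

    def test_different_seeds_differ(self):
        a = embed_conformer("CCOCCN", seed=11)
        b = embed_conformer("CCOCCN", seed=12)
        assert not np.allclose(a.coords, b.coords)

    def test_single_heavy_atom_degenerate_downstream(self):
        conf = embed_conformer("C", seed=1)
        assert conf.n_resolved_heavy == 1
        # methane: 5 atoms incl H, PBF computable; a bare atom is not
        lone = make_conf([[0, 0, 0]], bonds=[])
        with pytest.raises(DegenerateGeometryError):
            pbf(lone)

    def test_hydrogens_present_and_flagged(self):
        conf = embed_conformer("CO", seed=1)
        assert sum(conf.heavy_mask) == 2
        assert len(conf.elements) == 6


class TestPBF:
    def test_planar_coordinates_give_zero(self):
        # idealized planar hexagon
        ang = np.linspace(0, 2 * np.pi, 6, endpoint=False)
        coords = np.column_stack([np.cos(ang), np.sin(ang), np.zeros(6)])
        conf = make_conf(coords, bonds=[(i, (i + 1) % 6) for i in range(6)])
        assert pbf(conf) == pytest.approx(0.0, abs=1e-12)

    def test_rigid_motion_invariance(self, rng):
        conf = embed_conformer("NC12CC3CC(CC(C3)C1)C2", seed=3)
        base = pbf(conf)
        for _ in range(5):
            rot = Rotation.random(random_state=rng.integers(2**31)).as_matrix()
            shifted = Conformer(
                molecule_id="m", provenance="in_silico", elements=conf.elements,
                coords=conf.coords @ rot.T + rng.normal(size=3) * 10,
                bonds=conf.bonds,
            )
            assert pbf(shifted) == pytest.approx(base, abs=1e-9)

    def test_collinear_raises(self):
        conf = make_conf([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]],
                         bonds=[(0, 1), (1, 2), (2, 3)])
        with pytest.raises(DegenerateGeometryError):
            pbf(conf)

    def test_npbf_normalization_exact(self):
        conf = embed_conformer("OC(=O)c1ccccc1O", seed=5)
        assert npbf(conf) * conf.n_resolved_heavy == pytest.approx(pbf(conf))

    def test_npbf_uses_resolved_heavy_atoms_only(self):
        ang = np.linspace(0, 2 * np.pi, 6, endpoint=False)
        coords = np.column_stack([np.cos(ang), np.sin(ang), [0.1, -0.1] * 3])
        mask = [True] * 5 + [False]
        conf = make_conf(coords, bonds=[(i, (i + 1) % 6) for i in range(6)],
                         resolved_mask=np.array(mask))
        assert npbf(conf) == pytest.approx(pbf(conf) / 5)


class TestDeltaNPBF:
    def test_identical_conformers_zero(self):
        conf = embed_conformer("c1ccccc1O", seed=2)
        assert delta_npbf(conf, conf) == 0.0

    def test_sign_convention(self):
        # crystal flatter than in-silico -> negative
        ang = np.linspace(0, 2 * np.pi, 6, endpoint=False)
        flat = make_conf(np.column_stack([np.cos(ang), np.sin(ang), np.zeros(6)]),
                         bonds=[(i, (i + 1) % 6) for i in range(6)])
        bent = make_conf(np.column_stack([np.cos(ang), np.sin(ang), [0.4, -0.4] * 3]),
                         bonds=[(i, (i + 1) % 6) for i in range(6)])
        assert delta_npbf(flat, bent) < 0


class TestAbstractedRMSD:
    def test_self_is_zero(self):
        conf = embed_conformer("CC(C)CO", seed=4)
        assert abstracted_rmsd(conf, conf) == pytest.approx(0.0, abs=1e-9)

    def test_rigid_copy_is_zero(self, rng):
        conf = embed_conformer("CCOC(=O)C", seed=4)
        rot = Rotation.random(random_state=1).as_matrix()
        moved = Conformer("m", "in_silico", conf.elements,
                          conf.coords @ rot.T + [3.0, -2.0, 7.0], bonds=conf.bonds)
        assert abstracted_rmsd(conf, moved) == pytest.approx(0.0, abs=1e-9)

    def test_symmetry(self):
        a = embed_conformer("c1ccncc1", seed=6)
        b = embed_conformer("c1ccncc1", seed=7)
        assert abstracted_rmsd(a, b) == pytest.approx(abstracted_rmsd(b, a), abs=1e-9)

    def test_graph_mismatch_raises(self):
        a = embed_conformer("CCO", seed=1)
        b = embed_conformer("CCCO", seed=1)
        with pytest.raises(IncompatibleConformersError):
            abstracted_rmsd(a, b)

    def test_automorphism_needed_for_symmetric_ring(self):
        """A rotated atom labeling of a symmetric ring must still give ~0."""
        ang = np.linspace(0, 2 * np.pi, 6, endpoint=False)
        coords = np.column_stack([np.cos(ang) * 1.4, np.sin(ang) * 1.4, np.zeros(6)])
        bonds = [(i, (i + 1) % 6) for i in range(6)]
        a = make_conf(coords, bonds)
        b = make_conf(np.roll(coords, 2, axis=0), bonds)  # relabeled ring
        assert abstracted_rmsd(a, b) == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_oracle(self, seed):
        """Equals exhaustive automorphism enumeration on small fixtures."""
        smiles = [
            "CCO", "CC(C)C", "c1ccccc1", "c1ccncc1", "C1CCCCC1", "CC(=O)O",
            "C1CC1", "CCOCC", "c1ccc(O)cc1", "CC(C)(C)C",
        ][seed % 10]
        a = embed_conformer(smiles, seed=100 + seed)
        b = embed_conformer(smiles, seed=200 + seed)
        # displace one atom of b to break exact coincidence
        coords = b.coords.copy()
        coords[0] += [1.0, 0.0, 0.0]
        b = Conformer("m", "in_silico", b.elements, coords, bonds=b.bonds)
        heavy = np.flatnonzero(a.heavy_mask)
        a_h = make_conf(a.coords[heavy], _reindex(a.bonds, heavy), ["C"] * len(heavy))
        b_h = make_conf(b.coords[heavy], _reindex(b.bonds, heavy), ["C"] * len(heavy))
        assert abstracted_rmsd(a_h, b_h) == pytest.approx(brute_force_rmsd(a_h, b_h),
                                                          abs=1e-6)


def _reindex(bonds, heavy):
    pos = {int(i): k for k, i in enumerate(heavy)}
    return [(pos[i], pos[j]) for i, j in bonds if i in pos and j in pos]


class TestCopySelection:
    def conf(self, n_resolved, n_total=10, structure_id="s1", copy_id="c1"):
        mask = np.array([True] * n_resolved + [False] * (n_total - n_resolved))
        return Conformer("m", "crystal", ["C"] * n_total,
                         np.random.default_rng(0).normal(size=(n_total, 3)),
                         resolved_mask=mask, structure_id=structure_id, copy_id=copy_id)

    def test_fully_resolved_copies_kept(self):
        copies = [self.conf(10, copy_id="a"), self.conf(10, copy_id="b"), self.conf(7)]
        kept = select_copies(copies)
        assert [c.copy_id for c in kept] == ["a", "b"]

    def test_best_resolved_fallback(self):
        copies = [self.conf(8, copy_id="a"), self.conf(10, n_total=11, copy_id="b"),
                  self.conf(9, copy_id="c")]
        kept = select_copies(LigandCopySet("m", copies))
        assert len(kept) == 1 and kept[0].copy_id == "b"

    def test_tie_breaks_deterministically(self):
        copies = [self.conf(8, structure_id="s2", copy_id="z"),
                  self.conf(8, structure_id="s1", copy_id="y")]
        assert select_copies(copies)[0].copy_id == "y"

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            select_copies([])


class TestAggregation:
    def test_mean(self):
        assert aggregate_per_ligand([0.03, 0.05]) == pytest.approx(0.04)

    def test_single_value(self):
        assert aggregate_per_ligand([0.7]) == 0.7

    def test_equal_values(self):
        assert aggregate_per_ligand([0.2] * 5) == pytest.approx(0.2)
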