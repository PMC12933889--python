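"""Symmetry expansion, lattice-contact flags, surface partition and polar
contacts."""

import numpy as np
import pytest

from npfrag.contacts import (
    SurfacePartition,
    expand_symmetry,
    flag_lattice_proximal,
    polar_contacts,
    surface_partition,
)
from npfrag.shape import Conformer
from npfrag.structures import CrystalLattice, ProteinAtoms, StructureModel

P1_OPS = [(np.eye(3), np.zeros(3))]


def atoms_at(coords, elements=None, names=None, resnames=None):
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    n = len(coords)
    return ProteinAtoms(
        names=list(names or ["CA"] * n),
        elements=list(elements or ["C"] * n),
        chains=["A"] * n,
        resnums=np.arange(1, n + 1),
        resnames=list(resnames or ["ALA"] * n),
        coords=coords,
    )


def lig_at(points, elements=None, **kw):
    points = np.atleast_2d(np.asarray(points, dtype=float))
    return Conformer("f", "crystal", elements or ["C"] * len(points), points, **kw)


def p1_model(protein_coords, cell=10.0):
    lattice = CrystalLattice(cell, cell, cell, 90, 90, 90, P1_OPS)
    return StructureModel("m", atoms_at(protein_coords), lattice=lattice)


class TestLatticeValidation:
    def test_bad_cell_raises(self):
        with pytest.raises(ValueError):
            CrystalLattice(-1, 10, 10, 90, 90, 90, P1_OPS)
        with pytest.raises(ValueError):
            CrystalLattice(10, 10, 10, 90, 181, 90, P1_OPS)

    def test_identity_must_come_first(self):
        rot = np.diag([-1.0, -1.0, 1.0])
        with pytest.raises(ValueError):
            CrystalLattice(10, 10, 10, 90, 90, 90, [(rot, np.zeros(3))])

    def test_orthogonal_cell_matrix(self):
        lat = CrystalLattice(10, 20, 30, 90, 90, 90, P1_OPS)
        assert np.allclose(lat.orthogonalization, np.diag([10.0, 20.0, 30.0]))


class TestExpandSymmetry:
    def test_far_protein_no_mates(self):
        model = p1_model([[5.0, 5.0, 5.0]], cell=50.0)
        lig = lig_at([25.0, 25.0, 25.0])
        assert expand_symmetry(model, lig, cutoff=6.0) == []

    def test_periodic_image_found_by_hand_geometry(self):
        # cell 10 A along x: protein at x=0.5, ligand at x=9.5 -> +x image at 10.5
        model = p1_model([[0.5, 5.0, 5.0]])
        lig = lig_at([9.5, 5.0, 5.0])
        mates = expand_symmetry(model, lig, cutoff=6.0)
        shifts = {m.shift for m in mates}
        assert (1, 0, 0) in shifts
        plus_x = next(m for m in mates if m.shift == (1, 0, 0))
        d = np.linalg.norm(plus_x.atoms.coords[0] - lig.coords[0])
        assert d == pytest.approx(1.0, abs=1e-9)

    def test_zero_cutoff_empty(self):
        model = p1_model([[0.5, 5.0, 5.0]])
        assert expand_symmetry(model, lig_at([9.5, 5.0, 5.0]), cutoff=0.0) == []

    def test_identity_zero_shift_never_a_mate(self):
        model = p1_model([[5.0, 5.0, 5.0]])
        lig = lig_at([5.0, 5.0, 6.0])  # right next to the asymmetric unit
        mates = expand_symmetry(model, lig, cutoff=6.0)
        assert all(not (m.op_index == 0 and m.shift == (0, 0, 0)) for m in mates)

    def test_identity_operator_reproduces_coordinates(self):
        lat = CrystalLattice(10, 10, 10, 90, 90, 90, P1_OPS)
        coords = np.array([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]])
        frac = coords @ lat.fractionalization.T
        back = frac @ lat.orthogonalization.T
        assert np.allclose(back, coords, atol=1e-9)

    def test_larger_cutoff_superset(self):
        model = p1_model([[0.5, 5.0, 5.0]])
        lig = lig_at([9.5, 5.0, 5.0])
        small = {(m.op_index, m.shift) for m in expand_symmetry(model, lig, cutoff=2.0)}
        large = {(m.op_index, m.shift) for m in expand_symmetry(model, lig, cutoff=6.0)}
        assert small <= large

    def test_p21_rotational_mate(self):
        """A 2-fold screw image is found for a non-translational space group."""
        import gemmi

        lat = CrystalLattice.from_gemmi(gemmi.UnitCell(10, 10, 10, 90, 90, 90), "P 21")
        model = StructureModel("m", atoms_at([[1.0, 2.0, 1.0]]), lattice=lat)
        # screw image of (1,2,1) under (-x, y+1/2, -z): (-1, 7, -1) + shifts
        lig = lig_at([-1.0, 7.0, -0.5])
        mates = expand_symmetry(model, lig, cutoff=6.0)
        assert any(m.op_index != 0 for m in mates)


class TestLatticeProximal:
    def test_no_mates_false(self):
        lig = lig_at([0.0, 0.0, 0.0])
        assert flag_lattice_proximal(lig, atoms_at([[3.0, 0, 0]]), []) is False

    def test_mate_closer_true(self):
        model = p1_model([[0.5, 5.0, 5.0]])
        lig = lig_at([9.5, 5.0, 5.0])
        mates = expand_symmetry(model, lig, cutoff=6.0)
        assert flag_lattice_proximal(lig, model.protein, mates) is True

    def test_exact_tie_goes_to_asymmetric_unit(self):
        model = p1_model([[2.0, 5.0, 5.0]])
        lig = lig_at([6.0, 5.0, 5.0])  # image at 12: 6 A away, asym 4 A -> asym closer
        mates = expand_symmetry(model, lig, cutoff=6.0)
        # construct the exact tie: ligand exactly midway between asym and image
        lig_mid = lig_at([7.0, 5.0, 5.0])
        mates_mid = expand_symmetry(model, lig_mid, cutoff=6.0)
        assert flag_lattice_proximal(lig_mid, model.protein, mates_mid) is False

    def test_monotone_in_mates(self):
        model = p1_model([[0.5, 5.0, 5.0]])
        lig = lig_at([9.5, 5.0, 5.0])
        mates = expand_symmetry(model, lig, cutoff=6.0)
        assert flag_lattice_proximal(lig, model.protein, []) is False
        assert flag_lattice_proximal(lig, model.protein, mates) is True

    def test_toy_crystal_fraction_matches_ground_truth(self, toy_crystal):
        crystal, model = toy_crystal
        gt = crystal.ground_truth
        flags = []
        for lig in model.ligands:
            mates = expand_symmetry(model, lig, cutoff=6.0)
            flags.append(flag_lattice_proximal(lig, model.protein, mates))
        assert flags == list(gt["lattice_proximal"])
        assert np.mean(flags) == gt["lattice_proximal"].mean()


class TestSurfacePartition:
    def test_enclosing_entity_gets_everything(self):
        # shell of protein atoms all around a single-atom ligand
        phi = np.linspace(0, np.pi, 8)[1:-1]
        theta = np.linspace(0, 2 * np.pi, 12, endpoint=False)
        pts = [
            4.0 * np.array([np.sin(p) * np.cos(t), np.sin(p) * np.sin(t), np.cos(p)])
            for p in phi for t in theta
        ] + [[0, 0, 4.0], [0, 0, -4.0]]
        part = surface_partition(lig_at([0.0, 0.0, 0.0]), [("cage", atoms_at(pts))])
        assert part.percentages["cage"] == pytest.approx(100.0, abs=1e-9)
        assert part.unassigned == pytest.approx(0.0, abs=1e-9)

    def test_isolated_ligand_fully_unassigned(self):
        part = surface_partition(lig_at([0.0, 0.0, 0.0]),
                                 [("far", atoms_at([[50.0, 0, 0]]))])
        assert part.percentages["far"] == 0.0
        assert part.unassigned == pytest.approx(100.0)

    def test_mirror_fixture_splits_evenly(self, mirror_crystal):
        crystal, model = mirror_crystal
        lig = model.ligands[0]
        mates = expand_symmetry(model, lig, cutoff=6.0)
        plus_x = next(m for m in mates if m.shift == (1, 0, 0))
        part = surface_partition(lig, [("asym", model.protein), ("mate", plus_x.atoms)])
        assert abs(part.percentages["asym"] - part.percentages["mate"]) <= 4.0
        assert abs(part.percentages["asym"] - 50.0) <= 2.0

    def test_rigid_invariance(self, rng):
        from scipy.spatial.transform import Rotation

        lig = lig_at([[0.0, 0, 0], [1.5, 0, 0]])
        wall = atoms_at([[4.0, y, z] for y in (-2.0, 0.0, 2.0) for z in (-2.0, 0.0, 2.0)])
        base = surface_partition(lig, [("w", wall)])
        rot = Rotation.random(random_state=3).as_matrix()
        t = rng.normal(size=3) * 5
        lig2 = lig_at(lig.coords @ rot.T + t)
        wall2 = atoms_at(wall.coords @ rot.T + t)
        moved = surface_partition(lig2, [("w", wall2)])
        assert moved.percentages["w"] == pytest.approx(base.percentages["w"], abs=0.5)

    def test_total_area_single_atom_analytic(self):
        # isolated carbon: SASA = 4 pi (r_vdw + probe)^2 exactly
        part = surface_partition(lig_at([0.0, 0.0, 0.0]),
                                 [("far", atoms_at([[99.0, 0, 0]]))])
        assert part.total_area == pytest.approx(4 * np.pi * (1.7 + 1.4) ** 2, rel=1e-12)

    def test_total_area_two_spheres_closed_form(self):
        # two equal carbons 2.0 A apart: exposed area of each sphere is
        # 4 pi R^2 minus the buried spherical cap 2 pi R h, h = R - d/2
        d, R = 2.0, 1.7 + 1.4
        lig = lig_at([[0.0, 0, 0], [d, 0, 0]])
        part = surface_partition(lig, [("far", atoms_at([[99.0, 0, 0]]))],
                                 n_points=4000)
        h = R - d / 2
        expected = 2 * (4 * np.pi * R**2 - 2 * np.pi * R * h)
        assert part.total_area == pytest.approx(expected, rel=0.02)

    def test_percentages_never_exceed_100(self):
        with pytest.raises(ValueError):
            SurfacePartition({"a": 70.0, "b": 40.0}, 0.0)


class TestPolarContacts:
    def test_nitrogen_oxygen_pair_counts(self):
        lig = lig_at([0.0, 0.0, 0.0], elements=["N"])
        ent = atoms_at([[2.9, 0, 0]], elements=["O"], names=["O"], resnames=["SER"])
        assert polar_contacts(lig, ent).n_hbonds == 1

    def test_beyond_cutoff_not_counted(self):
        lig = lig_at([0.0, 0.0, 0.0], elements=["N"])
        ent = atoms_at([[4.0, 0, 0]], elements=["O"], names=["O"], resnames=["SER"])
        assert polar_contacts(lig, ent).n_hbonds == 0

    def test_carbon_pairs_never_polar(self):
        lig = lig_at([0.0, 0.0, 0.0], elements=["C"])
        ent = atoms_at([[1.0, 0, 0]], elements=["C"])
        assert polar_contacts(lig, ent).n_hbonds == 0

    def test_water_contacts_reported_separately(self):
        lig = lig_at([0.0, 0.0, 0.0], elements=["N"])
        ent = atoms_at([[2.9, 0, 0]], elements=["O"], names=["O"], resnames=["HOH"])
        pc = polar_contacts(lig, ent)
        assert pc.n_hbonds == 0 and len(pc.water_mediated) == 1

    def test_salt_bridge_requires_charged_pair(self):
        lig = lig_at([0.0, 0.0, 0.0], elements=["N"])
        ent = atoms_at([[3.8, 0, 0]], elements=["O"], names=["OD1"], resnames=["ASP"])
        assert len(polar_contacts(lig, ent, ligand_charged=[0]).salt_bridges) == 1
        assert len(polar_contacts(lig, ent).salt_bridges) == 0
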