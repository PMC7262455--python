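import math

import numpy as np
import pytest

import flexscatter as fs
from flexscatter.exceptions import (
    AmbiguityError,
    DegenerateGeometryError,
    UnknownElementError,
    UnsupportedSpaceGroupError,
)
from flexscatter.structure_analysis import (
    AtomSet,
    ReferenceDistribution,
    sasa_percentile,
    shrake_rupley,
)


def _p1_structure(coords, cell=(200.0, 200.0, 200.0)):
    import gemmi

    st = gemmi.Structure()
    st.cell = gemmi.UnitCell(*cell, 90, 90, 90)
    st.spacegroup_hm = "P 1"
    model = gemmi.Model("1")
    chain = gemmi.Chain("A")
    res = gemmi.Residue()
    res.name = "GLY"
    res.seqid = gemmi.SeqId(1, " ")
    for i, (x, y, z) in enumerate(coords):
        a = gemmi.Atom()
        a.name = f"C{i+1}"
        a.element = gemmi.Element("C")
        a.pos = gemmi.Position(x, y, z)
        res.add_atom(a)
    chain.add_residue(res)
    model.add_chain(chain)
    st.add_model(model)
    return st


class TestExpandSymmetry:
    def test_p1_large_cell_keeps_only_identity(self):
        st = _p1_structure([[50.0, 50, 50], [53.0, 50, 50]])
        asm = fs.expand_symmetry(st, contact_radius=4.0)
        assert len(asm) == 1
        assert asm.molecules[0].op_triplet == "x,y,z"

    def test_identity_copy_superposes_on_input(self):
        st = _p1_structure([[50.0, 50, 50], [53.0, 50, 50]])
        asm = fs.expand_symmetry(st, contact_radius=4.0)
        ref = AtomSet.from_gemmi(st)
        assert np.allclose(asm.molecules[0].atoms.coords, ref.coords)

    def test_unknown_space_group(self):
        st = _p1_structure([[50.0, 50, 50], [53.0, 50, 50]])
        st.spacegroup_hm = "Q 9 9 9"
        with pytest.raises(UnsupportedSpaceGroupError):
            fs.expand_symmetry(st)

    def test_copies_superpose_after_inverting_operator(self):
        st, _ = fs.make_synthetic_filament_crystal()
        asm = fs.expand_symmetry(st, contact_radius=4.0, max_molecules=12)
        ref = {m.chain_id: m.atoms.coords for m in asm.molecules
               if m.op_triplet == "x,y,z" and m.shift == (0, 0, 0)}
        for mol in asm.molecules:
            back = (mol.atoms.coords - mol.trans) @ np.linalg.inv(mol.rot).T
            rmsd = np.sqrt(np.mean(
                np.sum((back - ref[mol.chain_id]) ** 2, axis=1)))
            assert rmsd < 1e-6


class TestTraceFilament:
    def test_crystal_filament_is_a_single_path(self):
        st, _ = fs.make_synthetic_filament_crystal()
        asm = fs.expand_symmetry(st, contact_radius=4.0, max_molecules=15)
        ordered = fs.trace_filament(asm, contact_cutoff=4.0)
        assert len(ordered) == len(asm)
        # consecutive molecules in path order are in contact; the path
        # rises monotonically along the filament axis
        z = [m.com[2] for m in ordered]
        dz = np.diff(z)
        assert np.all(dz > 0) or np.all(dz < 0)

    def test_single_molecule_singleton_path(self):
        st = _p1_structure([[50.0, 50, 50], [53.0, 50, 50]])
        asm = fs.expand_symmetry(st, contact_radius=4.0)
        assert len(fs.trace_filament(asm)) == 1

    def test_three_branch_star_is_ambiguous(self):
        from flexscatter.structure_analysis import Assembly, Molecule

        def mol(center, cid):
            atoms = AtomSet.from_arrays(
                np.array([center]), ["C"], chains=np.array([cid], object))
            return Molecule(atoms=atoms, chain_id=cid, op_index=0,
                            op_triplet="x,y,z", shift=(0, 0, 0),
                            rot=np.eye(3), trans=np.zeros(3))

        hub = mol([0.0, 0, 0], "H")
        arms = [mol([3.0, 0, 0], "A"), mol([-3.0, 0, 0], "B"),
                mol([0.0, 3.0, 0], "C")]
        asm = Assembly(molecules=[hub] + arms, cell=(1, 1, 1, 90, 90, 90),
                       spacegroup="P 1")
        with pytest.raises(AmbiguityError):
            fs.trace_filament(asm, contact_cutoff=4.0)


class TestFitHelix:
    @staticmethod
    def _helix_coms(n=20, radius=46.0, dphi=36.0, rise=3.62):
        t = np.arange(n)
        phi = np.radians(dphi * t)
        return np.column_stack([radius * np.cos(phi),
                                radius * np.sin(phi), rise * t])

    def test_constructed_inverse_is_exact(self):
        hp = fs.fit_helix(self._helix_coms())
        assert hp.molecules_per_turn == pytest.approx(10.0, abs=1e-6)
        assert hp.pitch == pytest.approx(36.2, abs=1e-6)
        assert hp.radius == pytest.approx(46.0, abs=1e-6)
        assert hp.pitch == pytest.approx(
            hp.rise_per_molecule * hp.molecules_per_turn, rel=1e-12)

    def test_rigid_rotation_invariance(self):
        from scipy.spatial.transform import Rotation

        coms = self._helix_coms()
        R = Rotation.from_euler("xyz", [0.3, 1.1, 0.5]).as_matrix()
        hp = fs.fit_helix(coms @ R.T + np.array([5.0, -3.0, 9.0]))
        assert hp.molecules_per_turn == pytest.approx(10.0, abs=1e-6)
        assert hp.pitch == pytest.approx(36.2, abs=1e-6)
        assert hp.radius == pytest.approx(46.0, abs=1e-6)

    def test_collinear_points_degenerate(self):
        pts = np.column_stack([np.zeros(6), np.zeros(6), np.arange(6.0)])
        with pytest.raises(DegenerateGeometryError):
            fs.fit_helix(pts)

    def test_crystal_filament_recovers_published_geometry(self):
        st, truth = fs.make_synthetic_filament_crystal()
        asm = fs.expand_symmetry(st, contact_radius=4.0, max_molecules=25)
        hp = fs.filament_helix(asm, contact_cutoff=4.0)
        assert hp.molecules_per_turn == pytest.approx(
            truth["molecules_per_turn"], rel=0.01)
        assert hp.pitch == pytest.approx(truth["pitch"], rel=0.01)
        assert hp.radius == pytest.approx(truth["radius_com"], rel=0.01)
        assert hp.outer_radius == pytest.approx(truth["outer_radius"],
                                                rel=0.01)
        assert hp.inner_radius < hp.radius < hp.outer_radius


class TestShrakeRupley:
    def test_isolated_atom_sphere_area(self):
        a = AtomSet.from_arrays(np.zeros((1, 3)), ["C"])
        res = shrake_rupley(a)
        assert res.atom_sasa[0] == pytest.approx(
            4.0 * math.pi * (1.70 + 1.40) ** 2, rel=0.01)

    def test_fully_enclosed_atom_is_buried(self):
        i = np.arange(30) + 0.5
        ph = np.arccos(1 - 2 * i / 30)
        th = math.pi * (1 + 5**0.5) * i
        shell = 2.0 * np.column_stack([np.cos(th) * np.sin(ph),
                                       np.sin(th) * np.sin(ph), np.cos(ph)])
        atoms = AtomSet.from_arrays(np.vstack([[0, 0, 0], shell]),
                                    ["C"] * 31)
        assert shrake_rupley(atoms).atom_sasa[0] == 0.0

    def test_distant_atoms_additive(self):
        pair = AtomSet.from_arrays(np.array([[0.0, 0, 0], [50.0, 0, 0]]),
                                   ["C", "C"])
        iso = 4.0 * math.pi * (1.70 + 1.40) ** 2
        assert np.allclose(shrake_rupley(pair).atom_sasa, iso, rtol=0.01)

    def test_point_count_convergence(self):
        rng = np.random.default_rng(3)
        pts = rng.uniform(0, 14, (50, 3))
        els = np.array(["C", "N", "O", "S", "C"] * 10, dtype=object)
        atoms = AtomSet.from_arrays(pts, els)
        s1 = shrake_rupley(atoms, n_points=960).atom_sasa
        s2 = shrake_rupley(atoms, n_points=1920).atom_sasa
        scale = 4.0 * math.pi * (1.80 + 1.40) ** 2
        # typical atoms converge well under 0.5% of the full sphere
        # area; the worst partially-buried atom can approach 1%
        assert np.mean(np.abs(s1 - s2)) / scale < 0.002
        assert np.max(np.abs(s1 - s2)) / scale < 0.01

    def test_agrees_with_independent_implementation(self):
        """Cross-check against biotite's Shrake-Rupley on a random cluster."""
        biotite_struc = pytest.importorskip("biotite.structure")
        rng = np.random.default_rng(0)
        pts = rng.uniform(0, 12, (40, 3))
        els = np.array(["C", "N", "O", "S"] * 10, dtype=object)
        mine = shrake_rupley(AtomSet.from_arrays(pts, els),
                             n_points=1920).atom_sasa
        arr = biotite_struc.AtomArray(40)
        arr.coord = pts
        arr.element = els.astype("U2")
        arr.atom_name = np.array(["X"] * 40)
        arr.res_id = np.arange(40) + 1
        arr.res_name = np.array(["ALA"] * 40)
        arr.chain_id = np.array(["A"] * 40)
        theirs = biotite_struc.sasa(arr, probe_radius=1.4,
                                    point_number=1920, vdw_radii="Single")
        assert np.max(np.abs(mine - theirs) / (theirs + 1.0)) < 0.05

    def test_unknown_element_rejected(self):
        a = AtomSet.from_arrays(np.zeros((1, 3)), ["Xx"])
        with pytest.raises(UnknownElementError):
            shrake_rupley(a)


class TestSasaPercentile:
    def test_value_above_all(self):
        # midpoint convention: all n entries strictly below -> 100 * n/n
        ref = ReferenceDistribution("TRP", np.arange(1.0, 101.0))
        assert sasa_percentile(1000.0, ref) == 100.0

    def test_median_of_odd_reference(self):
        ref = ReferenceDistribution("TRP", [1.0, 2.0, 3.0, 4.0, 5.0])
        assert sasa_percentile(3.0, ref) == 50.0

    def test_below_single_value_reference(self):
        assert sasa_percentile(0.0, ReferenceDistribution("TRP", [5.0])) == 0.0

    def test_load_reference_file(self, tmp_path):
        p = tmp_path / "trp_ref.txt"
        p.write_text("# synthetic reference\n12.5\n3.0\n88.0\n")
        ref = fs.structure_analysis.load_reference(p)
        assert np.array_equal(ref.values, [3.0, 12.5, 88.0])  # sorted
        assert sasa_percentile(12.5, ref) == pytest.approx(50.0)

    def test_monotone_non_decreasing(self):
        rng = np.random.default_rng(1)
        ref = ReferenceDistribution("TRP", rng.uniform(0, 200, 500))
        vals = np.linspace(-10, 250, 100)
        pct = [sasa_percentile(v, ref) for v in vals]
        assert np.all(np.diff(pct) >= 0)


class TestInterfaceContacts:
    def _pair(self, d):
        A = AtomSet.from_arrays(np.array([[0.0, 0, 0]]), ["N"],
                                names=np.array(["N"], object),
                                resnames=np.array(["ARG"], object),
                                resseq=np.array([52]))
        B = AtomSet.from_arrays(np.array([[d, 0.0, 0]]), ["O"],
                                names=np.array(["O1"], object),
                                resnames=np.array(["SO4"], object),
                                resseq=np.array([201]))
        return A, B

    def test_contact_inside_cutoff(self):
        table = fs.interface_contacts(*self._pair(3.4))
        assert len(table) == 1
        assert table.iloc[0].res_a == "ARG52"
        assert table.iloc[0].distance == pytest.approx(3.4)

    def test_no_contact_outside_cutoff(self):
        assert len(fs.interface_contacts(*self._pair(3.6))) == 0

    def test_carbon_atoms_ignored(self):
        A = AtomSet.from_arrays(np.array([[0.0, 0, 0]]), ["C"])
        B = AtomSet.from_arrays(np.array([[3.0, 0, 0]]), ["O"])
        assert len(fs.interface_contacts(A, B)) == 0
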