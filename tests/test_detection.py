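"""Geometric core: d/alpha computation and the chalcogen-bond criteria."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import chbkit as ck
from conftest import brute_force_chbs, chb_set, make_bare_disulphide


class TestVdwContactThreshold:
    @pytest.mark.parametrize("a,b,tol,expected", [
        ("O", "S", 0.1, 3.42),
        ("S", "S", 0.1, 3.70),
        ("O", "S", 0.0, 3.32),
    ])
    def test_values(self, a, b, tol, expected):
        assert ck.vdw_contact_threshold(a, b, tol) == pytest.approx(expected, abs=1e-12)

    def test_unknown_element(self):
        with pytest.raises(ck.UnknownElementError):
            ck.vdw_contact_threshold("Se", "S", 0.1)


class TestChbGeometry:
    @pytest.mark.parametrize("nu,expected_d,expected_alpha", [
        ((3.0, 0.0, 0.0), 3.0, 0.0),          # collinear prolongation
        ((0.0, 3.0, 0.0), 3.0, 90.0),         # perpendicular
        ((3.0, 0.5, 0.0), 3.0413812651, 9.4623222080),  # frozen vector-arithmetic oracle
    ])
    def test_single_partner(self, nu, expected_d, expected_alpha):
        d, alphas, alpha_min = ck.chb_geometry(nu, (0, 0, 0), [(-1.8, 0, 0)])
        assert d == pytest.approx(expected_d, abs=1e-9)
        assert alpha_min == pytest.approx(expected_alpha, abs=1e-6)
        assert alphas == [alpha_min]

    def test_degenerate_points(self):
        with pytest.raises(ck.DegenerateGeometryError):
            ck.chb_geometry((0, 0, 0), (0, 0, 0), [(-1.8, 0, 0)])
        with pytest.raises(ck.DegenerateGeometryError):
            ck.chb_geometry((3, 0, 0), (0, 0, 0), [(0, 0, 0)])

    def test_collinear_far_side_gives_alpha_180(self):
        _, _, alpha_min = ck.chb_geometry((-3.0, 0, 0), (0, 0, 0), [(-1.8, 0, 0)])
        assert alpha_min == pytest.approx(180.0, abs=1e-9)

    def test_rigid_body_invariance(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            s = rng.normal(size=3)
            nu = s + rng.normal(size=3) * 3
            partners = [s + rng.normal(size=3) * 2 for _ in range(2)]
            d0, a0, m0 = ck.chb_geometry(nu, s, partners)
            rot = Rotation.random(random_state=rng).as_matrix()
            t = rng.normal(size=3) * 10
            d1, a1, m1 = ck.chb_geometry(rot @ nu + t, rot @ s + t,
                                         [rot @ p + t for p in partners])
            assert abs(d1 - d0) < 1e-9
            assert np.allclose(a1, a0, atol=1e-9)

    def test_partner_order_symmetry(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            s = rng.normal(size=3)
            nu = s + rng.normal(size=3) * 3
            p1, p2 = (s + rng.normal(size=3) * 2 for _ in range(2))
            _, _, m_ab = ck.chb_geometry(nu, s, [p1, p2])
            _, _, m_ba = ck.chb_geometry(nu, s, [p2, p1])
            assert m_ab == pytest.approx(m_ba, abs=0)


class TestFindDisulphides:
    def test_canonical_pair(self):
        st = make_bare_disulphide()
        bonds = ck.find_disulphides(st)
        assert len(bonds) == 1
        assert bonds[0].ss_distance == pytest.approx(2.05, abs=0.01)

    def test_pair_beyond_cutoff_without_record(self):
        st = make_bare_disulphide()
        st.residues[1].get_atom("SG").coords = np.array([0.0, 0.0, -3.0])
        assert ck.find_disulphides(st) == []

    def test_closest_partner_wins(self):
        # SG1-SG2 = 2.05, SG2-SG3 = 2.4: greedy pairing keeps only the closer bond
        from chbkit.structure import Atom, Residue, Structure, StructureMetadata
        def cys(seq, x):
            return Residue("A", seq, "", "CYS",
                           [Atom(seq, "SG", "S", "", np.array([x, 0.0, 0.0]))])
        st = Structure(StructureMetadata(entry_id="T"),
                       [cys(1, 0.0), cys(2, 2.05), cys(3, 4.45)])
        bonds = ck.find_disulphides(st)
        assert len(bonds) == 1
        assert {bonds[0].res_a.seq_number, bonds[0].res_b.seq_number} == {1, 2}
        # exhaustive-pairing oracle agrees
        assert brute_force_chbs(st) == chb_set(ck.detect_chbs(st))


class TestDetectChbs:
    def test_passing_fixture(self):
        st = make_bare_disulphide([("O", "O", [2.954, 0.521, 0.0])])  # d=3, alpha=10
        chbs = ck.detect_chbs(st)
        assert len(chbs) == 1
        assert chbs[0].d == pytest.approx(3.0, abs=1e-3)
        assert chbs[0].alpha_min == pytest.approx(10.0, abs=0.05)
        assert chbs[0].passes

    def test_distance_slightly_too_long(self):
        # 3.50 A exceeds the 3.42 A O...S cutoff: contact exists, bond does not
        st = make_bare_disulphide([("O", "O", [3.4468, 0.6078, 0.0])])  # d=3.5, alpha=10
        assert ck.detect_chbs(st) == []

    def test_threshold_sharpness_in_distance(self):
        for d, expected in ((3.42 - 1e-6, 1), (3.42 + 1e-6, 0)):
            st = make_bare_disulphide([("O", "O", [d, 0.0, 0.0])])  # alpha = 0
            assert len(ck.detect_chbs(st)) == expected

    def test_threshold_sharpness_in_alpha(self):
        for alpha, expected in ((25.0 - 1e-6, 1), (25.0 + 1e-6, 0)):
            a = np.radians(alpha)
            st = make_bare_disulphide([("O", "O", [3.0 * np.cos(a), 3.0 * np.sin(a), 0.0])])
            assert len(ck.detect_chbs(st)) == expected

    def test_nucleophile_may_bond_both_sulfurs(self):
        # place an O on the prolongation of each CB-SG bond, equidistant targets
        st = make_bare_disulphide([("O", "O", [3.2, 0.0, 0.0])])
        sg_b = np.array([0.4959, 0.0, -1.9891])
        cb_b = np.array([0.60, -1.76, -2.41])
        axis = (sg_b - cb_b) / np.linalg.norm(sg_b - cb_b)
        st.residues.append(make_bare_disulphide(
            [("O", "O", sg_b + 3.2 * axis)]).residues[2])
        st.residues[-1].seq_number = 6
        chbs = ck.detect_chbs(st)
        donors = sorted(c.donor_residue[1] for c in chbs)
        assert donors == [1, 2]

    def test_same_residue_and_water_exclusions(self):
        st = make_bare_disulphide([("O", "O", [3.0, 0.0, 0.0])])
        # donor residue's own oxygen would pass geometrically but is excluded
        from chbkit.structure import Atom
        st.residues[0].atoms.append(Atom(90, "O", "O", "", np.array([3.05, 0.0, 0.0])))
        water = make_bare_disulphide([("O", "O", [3.10, 0.0, 0.0])]).residues[2]
        water.res_name = "HOH"
        water.seq_number = 7
        st.residues.append(water)
        chbs = ck.detect_chbs(st)
        assert len(chbs) == 1
        assert chbs[0].acceptor_residue == ("A", 5, "")

    def test_oracle_equivalence_on_random_structures(self):
        for seed in range(20):
            st = ck.random_structure(n_residues=60, n_disulphides=3, seed=seed)
            assert st.n_atoms <= 500
            assert chb_set(ck.detect_chbs(st)) == brute_force_chbs(st)

    def test_deterministic_order_and_tsv(self, tmp_path):
        st = ck.random_structure(n_residues=80, seed=5)
        chbs = ck.detect_chbs(st)
        keys = [(c.donor_residue, c.acceptor_residue, c.acceptor_atom) for c in chbs]
        assert keys == sorted(keys)
        out = tmp_path / "chbs.tsv"
        ck.write_chb_tsv(chbs, out, entry_id="RND")
        if chbs:
            header = out.read_text().splitlines()[0].split("\t")
            assert {"entry_id", "d", "alpha_min", "vdw_sum", "passes"} <= set(header)


def test_chbparams_validation():
    with pytest.raises(ValueError):
        ck.ChBParams(alpha_max=120.0)
    with pytest.raises(ValueError):
        ck.ChBParams(distance_tolerance=-0.1)
    assert ck.ChBParams().max_search_radius() == pytest.approx(3.70)
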