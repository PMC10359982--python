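"""Residue mapping, ChB matching, controls and pLDDT bands."""

import numpy as np
import pytest

import chbkit as ck
from chbkit.structure import DBRef


def _model_of(exp, sigma=0.0, seed=0):
    return ck.perturb_structure(exp, sigma, seed)


class TestBuildResidueMap:
    def test_identity_numbering(self, toy):
        model = _model_of(toy)
        rmap = ck.build_residue_map(toy, model)
        assert rmap.accession == "SYNTH001"
        assert rmap.pairs == {("A", 1): 1, ("A", 10): 10, ("A", 20): 20}
        assert rmap.unmapped == []

    def test_offset_arithmetic(self, toy):
        model = _model_of(toy)
        # renumber the experimental side: author numbering starts at 10
        exp = toy.copy()
        for res in exp.residues:
            res.seq_number += 9
        exp.metadata.dbrefs = [DBRef("A", "UNP", "SYNTH001", 10, 29, 1, 20)]
        rmap = ck.build_residue_map(exp, model)
        assert rmap.pairs == {("A", 10): 1, ("A", 19): 10, ("A", 29): 20}

    def test_residue_name_mismatch_goes_unmapped(self, toy):
        model = _model_of(toy)
        model.residues[2].res_name = "ALA"
        rmap = ck.build_residue_map(toy, model)
        assert ("A", 20) not in rmap.pairs
        assert ("A", 20, "") in rmap.unmapped

    def test_no_shared_accession_raises(self, toy):
        model = _model_of(toy)
        model.metadata.dbrefs = [DBRef("A", "UNP", "OTHER01", 1, 20, 1, 20)]
        with pytest.raises(ck.UnpairableError):
            ck.build_residue_map(toy, model)
        exp = toy.copy()
        exp.metadata.dbrefs = []
        with pytest.raises(ck.UnpairableError):
            ck.build_residue_map(exp, _model_of(toy))


class TestMatchChbs:
    def test_self_comparison_identity(self, toy):
        result = ck.compare_pair(toy, toy)
        assert result.summary.n_exp_chbs == 1
        assert ck.recovery_fraction(result.matched) == 1.0
        m = result.matched[0]
        assert m.delta_d == 0.0 and m.delta_alpha == 0.0
        assert all(v == 0.0 for v in result.control_deltas)

    def test_constructed_displacement_along_axis(self, toy):
        model = _model_of(toy)
        chb = ck.detect_chbs(toy)[0]
        acc = model.get_residue("A", 20).get_atom("O")
        donor_sg = model.get_residue("A", 1).get_atom("SG")
        direction = (acc.coords - donor_sg.coords) / np.linalg.norm(acc.coords - donor_sg.coords)
        acc.coords = acc.coords + 0.20 * direction
        rmap = ck.build_residue_map(toy, model)
        (m,) = ck.match_chbs([chb], toy, model, rmap)
        assert m.delta_d == pytest.approx(0.20, abs=1e-9)
        assert m.delta_alpha == pytest.approx(0.0, abs=1e-9)

    def test_broken_disulphide_is_flagged(self, toy):
        model = _model_of(toy)
        sg_b = model.get_residue("A", 10).get_atom("SG")
        sg_a = model.get_residue("A", 1).get_atom("SG")
        axis = (sg_b.coords - sg_a.coords) / np.linalg.norm(sg_b.coords - sg_a.coords)
        sg_b.coords = sg_a.coords + 3.0 * axis
        result = ck.compare_pair(toy, model)
        (m,) = result.matched
        assert m.absent_reason == "disulphide-broken"
        assert not m.recovered
        assert m.delta_d is None and m.delta_alpha is None

    def test_missing_acceptor_atom(self, toy):
        model = _model_of(toy)
        res = model.get_residue("A", 20)
        res.atoms = [a for a in res.atoms if a.name != "O"]
        result = ck.compare_pair(toy, model)
        assert result.matched[0].absent_reason == "atom-missing"

    def test_delta_antisymmetry(self, toy):
        model = _model_of(toy, sigma=0.02, seed=4)
        fwd = ck.compare_pair(toy, model)
        rev = ck.compare_pair(model, toy)
        assert fwd.summary.n_exp_chbs == rev.summary.n_exp_chbs == 1
        assert rev.matched[0].delta_d == pytest.approx(-fwd.matched[0].delta_d, abs=1e-12)
        assert rev.matched[0].delta_alpha == pytest.approx(-fwd.matched[0].delta_alpha,
                                                           abs=1e-12)

    def test_mean_plddt_reflects_model_bfactors(self, toy):
        model = _model_of(toy)
        result = ck.compare_pair(toy, model)
        assert result.matched[0].mean_plddt == pytest.approx(95.0)


class TestRecoveryFraction:
    def test_extremes_and_error(self, toy):
        result = ck.compare_pair(toy, toy)
        assert ck.recovery_fraction(result.matched) == 1.0
        broken = _model_of(toy)
        broken.get_residue("A", 10).get_atom("SG").coords += np.array([0.0, 0.0, -5.0])
        assert ck.recovery_fraction(ck.compare_pair(toy, broken).matched) == 0.0
        with pytest.raises(ValueError):
            ck.recovery_fraction([])

    def test_matches_generator_truth_table(self):
        spec = ck.PairedDatasetSpec(n_entries=60, noise_sigma=0.3, seed=5)
        exps, models, truth = ck.generate_paired_dataset(spec)
        report = ck.run_survey(list(zip(exps, models)))
        expected = truth.recovered_truth.sum() / truth.exp_pass.sum()
        assert report.recovery_fraction == pytest.approx(expected, abs=0)


class TestMainchainControl:
    def test_zero_on_identical_structures(self, toy):
        result = ck.compare_pair(toy, toy)
        assert result.control_deltas  # the toy contains at least one O...N contact
        assert all(v == 0.0 for v in result.control_deltas)

    def test_contact_beyond_cutoff_not_enumerated(self, toy):
        chbs = ck.detect_chbs(toy)
        chb_res = {c.donor_residue for c in chbs} | {c.acceptor_residue for c in chbs}
        model = _model_of(toy)
        rmap = ck.build_residue_map(toy, model)
        n_35 = len(ck.mainchain_contact_control(toy, model, rmap, chb_res, cutoff=3.5))
        # shrinking the cutoff below every contact distance empties the list
        n_tiny = len(ck.mainchain_contact_control(toy, model, rmap, chb_res, cutoff=0.5))
        assert n_tiny == 0 <= n_35

    def test_strict_cutoff_boundary(self, toy):
        # move a main-chain O to exactly 3.6 A from a main-chain N: not enumerated
        exp = toy.copy()
        o = exp.get_residue("A", 1).get_atom("O")
        n = exp.get_residue("A", 20).get_atom("N")
        axis = (o.coords - n.coords) / np.linalg.norm(o.coords - n.coords)
        o.coords = n.coords + 3.6 * axis
        chbs = ck.detect_chbs(exp)
        chb_res = {c.donor_residue for c in chbs} | {c.acceptor_residue for c in chbs}
        rmap = ck.build_residue_map(exp, _model_of(exp))
        deltas = ck.mainchain_contact_control(exp, _model_of(exp), rmap, chb_res)
        # with the O moved away, the O(1)...N(20) pair is out of range
        o.coords = n.coords + 3.4 * axis
        deltas_close = ck.mainchain_contact_control(exp, _model_of(exp), rmap, chb_res)
        assert len(deltas_close) == len(deltas) + 1

    def test_perturbed_deltas_match_direct_recomputation(self, toy):
        model = _model_of(toy, sigma=0.2, seed=8)
        result = ck.compare_pair(toy, model)
        chbs = ck.detect_chbs(toy)
        chb_res = {c.donor_residue for c in chbs} | {c.acceptor_residue for c in chbs}
        expected = []
        for res_o in toy.residues:
            for res_n in toy.residues:
                if res_o.key == res_n.key or abs(res_o.seq_number - res_n.seq_number) <= 1:
                    continue
                if res_o.key not in chb_res and res_n.key not in chb_res:
                    continue
                o, n = res_o.get_atom("O"), res_n.get_atom("N")
                if o is None or n is None:
                    continue
                d_exp = np.linalg.norm(o.coords - n.coords)
                if d_exp >= 3.5:
                    continue
                mo = model.get_residue(*res_o.key).get_atom("O")
                mn = model.get_residue(*res_n.key).get_atom("N")
                expected.append(abs(np.linalg.norm(mo.coords - mn.coords) - d_exp))
        assert sorted(result.control_deltas) == pytest.approx(sorted(expected), abs=1e-12)


class TestPlddtBand:
    @pytest.mark.parametrize("value,band", [
        (95.0, "high"), (45.0, "low"), (90.0, "medium"), (50.0, "medium"), (70.0, "medium"),
    ])
    def test_bands(self, value, band):
        assert ck.plddt_band(value) == band

    def test_domain_error(self):
        with pytest.raises(ValueError):
            ck.plddt_band(101.0)
        with pytest.raises(ValueError):
            ck.plddt_band(-1.0)
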