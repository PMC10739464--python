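"""L-RMSD metrics and the benchmark harness."""

import numpy as np
import pytest
from helpers_oracles import brute_force_superpose_rmsd, naive_backbone_lrmsd

from pmhckit.anchors import BindingCore
from pmhckit.errors import CorrespondenceError, EvaluationError
from pmhckit.evaluation import lrmsd, receptor_superpose, run_benchmark
from pmhckit.fixtures import FixtureSpec, make_toy_pmhc2, perturb_fixture


def _rotate(cpx, angle=0.5, axis=(0.3, 1.0, -0.2), shift=(1.0, 2.0, -3.0)):
    axis = np.asarray(axis) / np.linalg.norm(axis)
    K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    R = np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)
    out = cpx.copy()
    for residues in out.chains.values():
        for r in residues:
            for a in r.atoms:
                a.coord = R @ a.coord + np.asarray(shift)
    return out


class TestReceptorSuperpose:
    def test_identity(self, fix15):
        fitted = receptor_superpose(fix15.copy(), fix15)
        a = np.array([at.coord for r in fix15.peptide() for at in r.atoms])
        b = np.array([at.coord for r in fitted.peptide() for at in r.atoms])
        assert np.abs(a - b).max() < 1e-9

    def test_rigid_motion_removed_exactly(self, fix15, core15):
        fitted = receptor_superpose(_rotate(fix15), fix15)
        rep = lrmsd(fitted, fix15, core15)
        assert rep.whole < 1e-6 and rep.core < 1e-6

    def test_joint_rigid_transform_invariance(self, fix15, core15):
        moved = fix15.copy()
        v = np.array([0.0, 0.0, 1.5])
        for r in moved.peptide():
            for a in r.atoms:
                a.coord = a.coord + v
        base = lrmsd(receptor_superpose(moved, fix15), fix15, core15)
        rot = _rotate(moved, angle=1.1)
        again = lrmsd(receptor_superpose(rot, fix15), fix15, core15)
        assert again.whole == pytest.approx(base.whole, abs=1e-9)

    def test_fit_matches_rotation_search_oracle(self, rng):
        # 12-atom toy receptor: compare the fitted receptor RMSD with an
        # explicit rotation-search oracle
        from pmhckit.geometry import kabsch
        P = rng.normal(scale=4, size=(12, 3))
        Q = P + rng.normal(scale=0.7, size=(12, 3))
        _, fitted = kabsch(P, Q)
        assert fitted == pytest.approx(brute_force_superpose_rmsd(P, Q), abs=1e-4)

    def test_missing_receptor_residue_raises(self, fix15):
        broken = fix15.copy()
        del broken.chains["M"][10:]
        with pytest.raises(CorrespondenceError):
            receptor_superpose(broken, fix15)


class TestLRMSD:
    def test_zero_on_identity(self, fix15, core15):
        rep = lrmsd(fix15, fix15, core15)
        assert rep.core == rep.whole == 0.0
        assert rep.flanking == 0.0
        assert rep.n_core_atoms == 36 and rep.n_flank_atoms == 24

    def test_single_atom_displacement_closed_form(self, fix15, core15):
        # 6 Å on one core backbone atom over 36 core atoms: 6/sqrt(36) = 1.0
        model = fix15.copy()
        model.peptide()[core15.start].atom("CA").coord += np.array([6.0, 0, 0])
        rep = lrmsd(model, fix15, core15)
        assert rep.core == pytest.approx(1.0, abs=1e-12)
        assert rep.flanking == 0.0

    def test_quadratic_identity_on_perturbed_fixture(self, fix15, core15, rng):
        model = fix15.copy()
        for r in model.peptide():
            for a in r.atoms:
                a.coord = a.coord + rng.normal(scale=0.8, size=3)
        rep = lrmsd(model, fix15, core15)
        lhs = rep.whole ** 2 * rep.n_total_atoms
        rhs = rep.core ** 2 * rep.n_core_atoms + rep.flanking ** 2 * rep.n_flank_atoms
        assert lhs == pytest.approx(rhs, rel=1e-12)

    def test_flanking_absent_for_9mer(self):
        cpx = make_toy_pmhc2(FixtureSpec(peptide_seq="KFVAAWTLK", core_start=0))
        rep = lrmsd(cpx, cpx, BindingCore(0, 9))
        assert rep.flanking is None
        assert rep.n_flank_atoms == 0

    def test_matches_naive_double_loop_oracle(self, fix15, core15, rng):
        for _ in range(25):
            model = fix15.copy()
            for r in model.peptide():
                for a in r.atoms:
                    a.coord = a.coord + rng.normal(scale=1.5, size=3)
            rep = lrmsd(model, fix15, core15)
            oc, of, ow = naive_backbone_lrmsd(model, fix15, core15)
            assert rep.core == pytest.approx(oc, abs=1e-9)
            assert rep.flanking == pytest.approx(of, abs=1e-9)
            assert rep.whole == pytest.approx(ow, abs=1e-9)

    def test_length_mismatch_raises(self, fix15, core15):
        other = make_toy_pmhc2(FixtureSpec(peptide_seq="KFVAAWTLK", core_start=0))
        with pytest.raises(EvaluationError):
            lrmsd(other, fix15, BindingCore(0, 9))

    def test_peptide_shift_ground_truth(self, fix15, core15):
        shifted, gt = perturb_fixture(fix15, "peptide_shift", 2.0, seed=4)
        rep = lrmsd(shifted, fix15, core15)
        assert rep.whole == pytest.approx(gt["whole"], abs=1e-9)
        assert rep.whole == pytest.approx(2.0, abs=1e-9)


class TestBenchmark:
    def test_self_template_recovery(self, benchmark_set):
        summary = run_benchmark(benchmark_set[:2], leave_one_out=False,
                                n_models=2, seed=1, max_steps=30)
        assert not summary.failed_cases
        for case in summary.per_case:
            assert case.template_id == case.case_id
            assert case.best.whole < 0.2

    def test_near_duplicate_loo(self, benchmark_set):
        summary = run_benchmark(benchmark_set, leave_one_out=True,
                                n_models=3, seed=1, max_steps=30)
        assert not summary.failed_cases
        assert summary.success_rate(2.0, 3) == 1.0
        for case in summary.per_case:
            assert case.template_id != case.case_id

    def test_aggregates_recomputable_and_monotone(self, benchmark_set, tmp_path):
        summary = run_benchmark(benchmark_set, leave_one_out=True,
                                n_models=3, seed=1, max_steps=30)
        agg = summary.aggregates()
        best = sorted(c.best.whole for c in summary.per_case)
        assert agg["best_whole"]["median"] == pytest.approx(float(np.median(best)))
        assert agg["best_whole"]["mean"] == pytest.approx(float(np.mean(best)))
        # success rate monotone in threshold and k
        rates_thr = [summary.success_rate(t, 3) for t in (0.001, 0.5, 2.0, 10.0)]
        assert rates_thr == sorted(rates_thr)
        rates_k = [summary.success_rate(2.0, k) for k in (1, 2, 3)]
        assert rates_k == sorted(rates_k)
        summary.to_json(tmp_path / "s.json")
        summary.per_case_tsv(tmp_path / "c.tsv")
        summary.per_length_csv(tmp_path / "l.csv")
        assert (tmp_path / "s.json").stat().st_size > 0
        assert len((tmp_path / "c.tsv").read_text().splitlines()) == len(summary.per_case) + 1
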