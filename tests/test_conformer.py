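"""Conformer engine: core superposition, flank building, minimization,
ensemble generation."""

import numpy as np
import pytest
from helpers_oracles import brute_force_superpose_rmsd

from pmhckit import geometry as geo
from pmhckit.anchors import BindingCore, derive_restraints
from pmhckit.conformer import (
    Mode,
    ModellingJob,
    PairPotential,
    build_flanks,
    generate_ensemble,
    minimize_model,
    superpose_core,
    write_ensemble,
)
from pmhckit.errors import IncompleteBackboneError
from pmhckit.fixtures import FixtureSpec, make_toy_pmhc2
from pmhckit.structure_io import TemplateRecord

BACKBONE = ("N", "CA", "C", "O")


def core_residues(cpx, core):
    return [cpx.peptide()[i] for i in core.core_positions()]


def backbone_array(residues):
    return np.array([r.atom(n).coord for r in residues for n in BACKBONE])


class TestGeometry:
    def test_place_atom_reproduces_internal_coordinates(self, rng):
        for _ in range(20):
            a, b, c = rng.normal(scale=5, size=(3, 3))
            if np.linalg.norm(b - c) < 0.5:
                continue
            length = rng.uniform(1.0, 2.0)
            ang = rng.uniform(60, 170)
            tor = rng.uniform(-180, 180)
            d = geo.place_atom(a, b, c, length, ang, tor)
            assert np.linalg.norm(d - c) == pytest.approx(length, abs=1e-9)
            assert geo.bond_angle(b, c, d) == pytest.approx(ang, abs=1e-6)
            assert geo.dihedral(a, b, c, d) == pytest.approx(tor, abs=1e-6)

    def test_kabsch_recovers_rigid_motion(self, rng):
        P = rng.normal(size=(12, 3))
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta), 0],
                      [np.sin(theta), np.cos(theta), 0], [0, 0, 1]])
        Q = P @ R.T + np.array([1.0, -2.0, 3.0])
        tr, rmsd = geo.kabsch(P, Q)
        assert rmsd < 1e-9
        assert np.allclose(tr.apply(P), Q, atol=1e-9)


class TestSuperposeCore:
    def test_identity_on_self(self, fix15, core15, template15):
        tr, placed = superpose_core(core_residues(fix15, core15), template15)
        assert np.allclose(tr.rotation, np.eye(3), atol=1e-9)
        assert np.allclose(tr.translation, 0.0, atol=1e-9)
        assert np.allclose(backbone_array(placed),
                           backbone_array(core_residues(fix15, core15)))

    def test_translation_recovered(self, fix15, core15, template15):
        moved = [r.copy() for r in core_residues(fix15, core15)]
        for r in moved:
            for a in r.atoms:
                a.coord = a.coord + np.array([5.0, 0.0, 0.0])
        tr, _ = superpose_core(moved, template15)
        assert np.linalg.norm(tr.translation) == pytest.approx(5.0, abs=1e-9)

    def test_fit_matches_rotation_search_oracle(self, fix15, core15, template15, rng):
        moved = [r.copy() for r in core_residues(fix15, core15)]
        axis = rng.normal(size=3)
        rot = geo.Transform(
            _rotation_matrix(axis, 0.9), np.array([2.0, -1.0, 4.0]))
        for r in moved:
            for a in r.atoms:
                a.coord = rot.apply(a.coord) + rng.normal(scale=0.2, size=3)
        tr, _ = superpose_core(moved, template15)
        mob = backbone_array(moved)
        ref = backbone_array(core_residues(fix15, core15))
        fitted_rmsd = float(np.sqrt(np.mean(np.sum((tr.apply(mob) - ref) ** 2, axis=1))))
        assert fitted_rmsd == pytest.approx(brute_force_superpose_rmsd(mob, ref), abs=1e-4)

    def test_missing_backbone_atom_raises(self, fix15, core15, template15):
        broken = [r.copy() for r in core_residues(fix15, core15)]
        broken[0].atoms = [a for a in broken[0].atoms if a.name != "CA"]
        with pytest.raises(IncompleteBackboneError):
            superpose_core(broken, template15)


def _rotation_matrix(axis, angle):
    axis = axis / np.linalg.norm(axis)
    K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


class TestBuildFlanks:
    def test_zero_flanks_identity(self, fix15, core15):
        placed = [r.copy() for r in core_residues(fix15, core15)]
        out, flagged = build_flanks(placed, "", "", fix15, seed=3)
        assert not flagged
        assert np.allclose(backbone_array(out), backbone_array(placed))

    def test_built_bond_lengths_near_ideal(self, fix15, core15):
        placed = [r.copy() for r in core_residues(fix15, core15)]
        out, _ = build_flanks(placed, "AKV", "GLW", fix15, seed=3)
        assert len(out) == 15
        for i in (0, 1, 2, 12, 13, 14):   # the built residues after renumbering
            res = out[i]
            n, ca, c = (res.atom(x).coord for x in ("N", "CA", "C"))
            assert abs(np.linalg.norm(ca - n) - 1.458) < 0.05
            assert abs(np.linalg.norm(c - ca) - 1.525) < 0.05
        for i in (0, 1, 12, 13):          # peptide bonds between built residues
            d = np.linalg.norm(out[i + 1].atom("N").coord - out[i].atom("C").coord)
            assert abs(d - 1.329) < 0.05

    def test_seed_determinism(self, fix15, core15):
        placed = [r.copy() for r in core_residues(fix15, core15)]
        a, _ = build_flanks(placed, "AKV", "GLW", fix15, seed=42)
        b, _ = build_flanks(placed, "AKV", "GLW", fix15, seed=42)
        c, _ = build_flanks(placed, "AKV", "GLW", fix15, seed=43)
        assert np.array_equal(backbone_array(a), backbone_array(b))
        assert not np.array_equal(backbone_array(a), backbone_array(c))


class TestMinimize:
    def test_single_restraint_reaches_analytic_minimum(self):
        # two atoms, one free, restrained to 3.0 Å starting from 5.0 Å:
        # the only energy term has its minimum exactly at d = target
        coords = np.array([[0.0, 0, 0], [5.0, 0, 0]])
        free = np.array([False, True])
        pot = PairPotential(coords, free,
                            bonded_pairs=np.zeros((0, 2), dtype=int),
                            bonded_d0=np.zeros(0),
                            clash_pairs=np.zeros((0, 2), dtype=int),
                            restraint_pairs=np.array([[0, 1]]),
                            restraint_target=np.array([3.0]),
                            restraint_sd=np.array([0.0]))
        out, trace = pot.minimize(max_steps=200)
        assert np.linalg.norm(out[1] - out[0]) == pytest.approx(3.0, abs=1e-3)
        assert all(b <= a + 1e-12 for a, b in zip(trace, trace[1:]))

    def test_clean_self_model_is_fixed_point(self, fix15, core15, template15):
        restraints = derive_restraints(template15)
        relaxed, bd, trace = minimize_model(fix15.copy(), restraints,
                                            Mode.FIXED_CORE, core15)
        assert bd.restraint == pytest.approx(0.0, abs=1e-12)
        assert bd.bonded == pytest.approx(0.0, abs=1e-9)
        assert bd.total == bd.bonded + bd.clash + bd.restraint
        a = backbone_array(fix15.peptide())
        b = backbone_array(relaxed.peptide())
        assert np.abs(a - b).max() < 1e-6

    def test_fixed_core_backbone_bit_identical(self, fix15, core15, template15):
        # displace a flank atom so minimization actually moves things
        model = fix15.copy()
        model.peptide()[0].atom("CA").coord += np.array([0.3, 0.2, -0.1])
        restraints = derive_restraints(template15)
        relaxed, _, trace = minimize_model(model, restraints, Mode.FIXED_CORE, core15)
        before = backbone_array(core_residues(model, core15))
        after = backbone_array(core_residues(relaxed, core15))
        assert np.array_equal(before, after)
        assert all(b <= a + 1e-9 for a, b in zip(trace, trace[1:]))

    def test_flex_core_can_move_core_atoms(self, fix15, core15, template15):
        model = fix15.copy()
        model.peptide()[core15.start].atom("CB").coord += np.array([0.5, 0.0, 0.0])
        restraints = derive_restraints(template15, sd=0.0)
        relaxed, bd, _ = minimize_model(model, restraints, Mode.FLEX_CORE)
        moved = relaxed.peptide()[core15.start].atom("CB").coord
        orig = fix15.peptide()[core15.start].atom("CB").coord
        # the displaced anchor CB is pulled back toward its restrained contacts
        assert np.linalg.norm(moved - orig) < 0.5


class TestEnsemble:
    def test_default_job_emits_20_ranked_models(self, fix15, core15, template15):
        job = ModellingJob(fix15.chain_sequence("M"), fix15.chain_sequence("N"),
                           fix15.peptide_seq, core15, template15, seed=5)
        models = generate_ensemble(job, max_steps=30)
        assert len(models) == 20
        assert [m.rank for m in models] == list(range(1, 21))
        energies = [m.pseudo_energy for m in models]
        assert energies == sorted(energies)

    def test_reproducible_and_seed_sensitive(self, benchmark_set):
        # FIX1B is one residue longer than its twin -> de novo flank sampling
        target = benchmark_set[3]
        tmpl = benchmark_set[2]
        job = dict(alpha_seq=target.complex.chain_sequence("M"),
                   beta_seq=target.complex.chain_sequence("N"),
                   peptide_seq=target.complex.peptide_seq,
                   core=target.structural_core, template=tmpl, n_models=3)
        m1 = generate_ensemble(ModellingJob(**job, seed=9), max_steps=30)
        m2 = generate_ensemble(ModellingJob(**job, seed=9), max_steps=30)
        m3 = generate_ensemble(ModellingJob(**job, seed=10), max_steps=30)
        for a, b in zip(m1, m2):
            assert a.pseudo_energy == b.pseudo_energy
            assert np.array_equal(backbone_array(a.complex.peptide()),
                                  backbone_array(b.complex.peptide()))
        assert not np.array_equal(backbone_array(m1[0].complex.peptide()),
                                  backbone_array(m3[0].complex.peptide()))

    def test_write_ensemble_layout(self, fix15, core15, template15, tmp_path):
        job = ModellingJob(fix15.chain_sequence("M"), fix15.chain_sequence("N"),
                           fix15.peptide_seq, core15, template15, n_models=2, seed=1)
        models = generate_ensemble(job, max_steps=10)
        write_ensemble(models, tmp_path)
        assert (tmp_path / "model_1.pdb").exists()
        assert (tmp_path / "model_2.pdb").exists()
        lines = (tmp_path / "ranking.tsv").read_text().strip().splitlines()
        assert len(lines) == 3 and lines[0].startswith("rank\t")
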