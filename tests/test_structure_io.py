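"""Structure reading, chain standardization, template filters, writing."""

import numpy as np
import pytest

from pmhckit.anchors import BindingCore
from pmhckit.errors import (
    NonCanonicalResidueError,
    StandardizationError,
    StructureParseError,
)
from pmhckit.fixtures import FixtureSpec, make_toy_pmhc2
from pmhckit.structure_io import (
    MHCClass,
    PMHCComplex,
    RawStructure,
    TemplateRecord,
    filter_template_candidates,
    load_template_db,
    read_structure,
    save_template_db,
    standardize_chains,
    write_structure,
)


def _roundtrip(cpx, tmp_path, **kw):
    path = tmp_path / "x.pdb"
    write_structure(cpx, path, **kw)
    return read_structure(path, fmt="pdb")


class TestReadWrite:
    def test_round_trip_identity(self, fix15, tmp_path):
        raw = _roundtrip(fix15, tmp_path)
        std = standardize_chains(raw, MHCClass.II)
        assert std.peptide_seq == fix15.peptide_seq
        for cid in ("M", "N", "P"):
            for r0, r1 in zip(fix15.chains[cid], std.chains[cid]):
                assert [a.name for a in r0.atoms] == [a.name for a in r1.atoms]
                c0 = np.array([a.coord for a in r0.atoms])
                c1 = np.array([a.coord for a in r1.atoms])
                assert np.abs(c0 - c1).max() < 5e-4  # PDB has 3 decimals

    def test_fixture_residue_count(self, fix15):
        # 2 MHC chains x (167 helix + 13 floor) + 15-mer peptide
        assert sum(len(c) for c in fix15.chains.values()) == 2 * 180 + 15

    def test_altloc_collapse_keeps_highest_occupancy(self, tmp_path):
        pdb = (
            "ATOM      1  N  AALA A   1       0.000   0.000   0.000  0.40 10.00           N\n"
            "ATOM      2  N  BALA A   1       9.000   0.000   0.000  0.60 10.00           N\n"
            "ATOM      3  CA  ALA A   1       1.458   0.000   0.000  1.00 10.00           C\n"
            "END\n")
        p = tmp_path / "alt.pdb"
        p.write_text(pdb)
        raw = read_structure(p, fmt="pdb")
        res = raw.chains["A"][0]
        names = [a.name for a in res.atoms]
        assert names.count("N") == 1
        assert res.atom("N").coord[0] == pytest.approx(9.0)  # occ 0.60 wins

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(StructureParseError):
            read_structure(tmp_path / "nope.pdb")

    def test_keep_b2m_flag_drops_chain_b(self, tmp_path):
        cpx = make_toy_pmhc2(FixtureSpec(peptide_seq="AKFVAAWTL", core_start=0))
        classI = PMHCComplex("C1", MHCClass.I,
                             {"M": cpx.chains["M"], "B": cpx.chains["N"][:100],
                              "P": cpx.chains["P"]},
                             peptide_seq=cpx.peptide_seq)
        raw = _roundtrip(classI, tmp_path, keep_b2m=False)
        assert set(raw.chains) == {"M", "P"}
        raw = _roundtrip(classI, tmp_path, keep_b2m=True)
        assert set(raw.chains) == {"M", "B", "P"}


class TestStandardize:
    def test_class2_renaming_by_file_order(self, fix15):
        raw = RawStructure("X", {"A": fix15.chains["M"], "B": fix15.chains["N"],
                                 "C": fix15.chains["P"]})
        std = standardize_chains(raw, MHCClass.II)
        assert set(std.chains) == {"M", "N", "P"}
        assert std.chains["M"][0].resname == fix15.chains["M"][0].resname
        assert [r.seqnum for r in std.peptide()] == list(range(1, 16))

    def test_class1_beta2m_becomes_chain_b(self, fix15):
        raw = RawStructure("X", {"H": fix15.chains["M"],          # 180 residues
                                 "L": fix15.chains["N"][:100],    # ~beta2m length
                                 "C": fix15.chains["P"]})
        std = standardize_chains(raw, MHCClass.I)
        assert set(std.chains) == {"M", "B", "P"}
        assert len(std.chains["M"]) > len(std.chains["B"])

    def test_idempotent(self, fix15):
        once = standardize_chains(RawStructure("X", fix15.chains), MHCClass.II)
        twice = standardize_chains(once, MHCClass.II)
        assert set(twice.chains) == {"M", "N", "P"}
        assert twice.peptide_seq == once.peptide_seq
        a = np.array([at.coord for r in once.peptide() for at in r.atoms])
        b = np.array([at.coord for r in twice.peptide() for at in r.atoms])
        assert np.array_equal(a, b)

    def test_two_short_chains_ambiguous(self, fix15):
        raw = RawStructure("X", {"A": fix15.chains["M"], "B": fix15.chains["N"],
                                 "C": fix15.chains["P"], "D": fix15.chains["P"][:8]})
        with pytest.raises(StandardizationError):
            standardize_chains(raw, MHCClass.II)

    def test_non_canonical_peptide_residue_raises(self, fix15):
        bad = fix15.copy()
        bad.chains["P"][2].resname = "XYZ"
        with pytest.raises(NonCanonicalResidueError):
            standardize_chains(RawStructure("X", bad.chains), MHCClass.II)

    def test_modified_residue_mapped_to_parent(self, fix15):
        mod = fix15.copy()
        mod.chains["P"][0].resname = "MSE"   # selenomethionine -> MET
        std = standardize_chains(RawStructure("X", mod.chains), MHCClass.II)
        assert std.peptide_seq[0] == "M"


class TestFilters:
    @staticmethod
    def _cand(pep_len, pdb_id, **kw):
        pep = ("AKFVAAWTLKAAALGAKFVAAWTLKAAALG")[:pep_len]
        start = min(3, max(0, pep_len - 9))
        return make_toy_pmhc2(FixtureSpec(peptide_seq=pep, core_start=start,
                                          pdb_id=pdb_id, **kw))

    def test_length_bounds_and_signatures(self):
        cands = [self._cand(n, f"LEN{n}") for n in (5, 6, 7, 25, 26)]
        # a DM-chaperone complex: the alpha chain carries a packaged signature
        dm_sig = "WCWHWMWDWAWCWHWAW"
        dm_alpha = (dm_sig + "A" * 180)[:180]
        cands.append(self._cand(15, "DM1", alpha_seq=dm_alpha))
        # a CLIP-peptide complex
        cands.append(make_toy_pmhc2(FixtureSpec(
            peptide_seq="PVSKMRMATPLLMQA", core_start=4, pdb_id="CLIP1")))
        kept, rejected = filter_template_candidates(cands)
        assert sorted(t.pdb_id for t in kept) == ["LEN25", "LEN7"]
        reasons = dict(rejected)
        assert reasons["LEN5"] == reasons["LEN6"] == reasons["LEN26"] == "peptide_length"
        assert reasons["DM1"] == "dm_chaperone"
        assert reasons["CLIP1"] == "clip_peptide"

    def test_partition_property(self):
        cands = [self._cand(n, f"L{n}") for n in (6, 9, 12, 26)]
        kept, rejected = filter_template_candidates(cands)
        assert len(kept) + len(rejected) == len(cands)
        assert not ({t.pdb_id for t in kept} & {r[0] for r in rejected})


class TestTemplateDB:
    def test_save_load_round_trip(self, benchmark_set, tmp_path):
        save_template_db(benchmark_set, tmp_path / "db")
        loaded = load_template_db(tmp_path / "db")
        assert [t.pdb_id for t in loaded] == [t.pdb_id for t in benchmark_set]
        for orig, back in zip(benchmark_set, loaded):
            assert back.structural_core.start == orig.structural_core.start
            assert back.complex.peptide_seq == orig.complex.peptide_seq
            assert back.complex.alpha_allele == orig.complex.alpha_allele
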