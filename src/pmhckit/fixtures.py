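"""Idealized synthetic pMHC-II structures with known ground truth.

Real MHC grooves are two α-helices on a β-sheet floor holding an extended
peptide. The generator emulates that topology with a geometric
idealization: two long straight α-helices flank the peptide on either side
of the groove axis, an extended-strand "floor" runs underneath it, and the
peptide lies along the axis with the four anchor side chains (Cβ stubs)
pointing down at the floor so that every anchor residue has at least one
receptor heavy atom within 5 Å — and non-anchor side chains pointing up,
so the structural binding core is geometrically unambiguous. Nothing about
the fixture is energetically or evolutionarily realistic; its value is
exact, deterministic geometry (bitwise reproducible given the spec) with
closed-form perturbation ground truths, which makes every other module
testable without any external structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .anchors import BindingCore
from .errors import FixtureSpecError
from .residues import one_to_three
from .structure_io import (
    AtomRecord,
    MHCClass,
    PMHCComplex,
    ResidueRecord,
    TemplateRecord,
    save_template_db,
)

# groove geometry constants (Å)
CA_SPACING = 4.0          # peptide CA-CA spacing along the groove axis
FLOOR_Z = -5.5            # depth of the strand floor below the peptide plane
FLOOR_Y = 1.5             # lateral offset of the two floor strands
HELIX_RADIUS = 2.3
HELIX_RISE = 1.5
HELIX_TWIST_DEG = 100.0

AA20 = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class FixtureSpec:
    """Recipe for one synthetic pMHC-II complex.

    Peptide lengths 3–30 are accepted so that the template-set filters
    (which keep only 7–25) can be exercised with out-of-range candidates;
    default-range specs produce structures that pass all filters.
    """

    peptide_seq: str
    core_start: int = 0
    groove_width: float = 18.0
    helix_length: int = 167
    floor_length: int = 13
    seed: int = 0
    perturbation: tuple | None = None   # e.g. ("peptide_shift", 2.0)
    alpha_seq: str | None = None
    beta_seq: str | None = None
    alpha_allele: str = ""
    beta_allele: str = ""
    pdb_id: str = "FIX0"

    def __post_init__(self):
        if not 3 <= len(self.peptide_seq) <= 30:
            raise FixtureSpecError(
                f"fixture peptide length {len(self.peptide_seq)} outside 3..30")
        if len(self.peptide_seq) >= 9:
            BindingCore(self.core_start, len(self.peptide_seq))  # validates fit
        if self.groove_width < 10.0:
            raise FixtureSpecError("groove width below 10 Å would clash the helices")
        if self.helix_length < 1 or self.floor_length < 1:
            raise FixtureSpecError("helix and floor must have at least one residue")

    @property
    def chain_length(self) -> int:
        return self.helix_length + self.floor_length

    def resolved_chain_seq(self, which: str) -> str:
        seq = self.alpha_seq if which == "alpha" else self.beta_seq
        if seq is None:
            rng = np.random.default_rng(self.seed * 2 + (0 if which == "alpha" else 1))
            seq = "".join(rng.choice(list(AA20), size=self.chain_length))
        if len(seq) != self.chain_length:
            raise FixtureSpecError(
                f"{which} sequence length {len(seq)} != chain length {self.chain_length}")
        return seq


def _flat_residue(resname: str, seqnum: int, ca: np.ndarray, *,
                  cb_dz: float | None = None) -> ResidueRecord:
    """A residue in the idealized flat backbone layout used for the peptide
    and floor strands; ``cb_dz`` > 0 points the Cβ stub up, < 0 down."""
    ca = np.asarray(ca, float)
    atoms = [
        AtomRecord("N", "N", ca + np.array([-1.31, 0.64, 0.0])),
        AtomRecord("CA", "C", ca),
        AtomRecord("C", "C", ca + np.array([1.37, 0.67, 0.0])),
        AtomRecord("O", "O", ca + np.array([1.37, 1.90, 0.0])),
    ]
    if cb_dz is not None and resname != "GLY":
        atoms.append(AtomRecord("CB", "C", ca + np.array([0.0, -0.70, cb_dz])))
    return ResidueRecord(resname, seqnum, atoms)


def _helix_residue(resname: str, seqnum: int, i: int, x0: float, y0: float) -> ResidueRecord:
    t = np.deg2rad(HELIX_TWIST_DEG * i)
    dt = np.deg2rad(28.0)

    def on_helix(x_off, ang):
        return np.array([x0 + HELIX_RISE * i + x_off,
                         y0 + HELIX_RADIUS * np.cos(ang),
                         HELIX_RADIUS * np.sin(ang)])

    ca = on_helix(0.0, t)
    c = on_helix(0.8, t + dt)
    o = c + 1.231 * np.array([0.0, np.cos(t), np.sin(t)])
    return ResidueRecord(resname, seqnum, [
        AtomRecord("N", "N", on_helix(-0.8, t - dt)),
        AtomRecord("CA", "C", ca),
        AtomRecord("C", "C", c),
        AtomRecord("O", "O", o),
    ])


def _receptor_chain(seq: str, spec: FixtureSpec, side: int) -> list[ResidueRecord]:
    """One receptor chain: a straight helix at y = side * groove_width/2
    plus a floor strand segment under the peptide (side -1 covers even
    peptide positions, +1 odd positions)."""
    residues = []
    y_helix = side * spec.groove_width / 2.0
    for i in range(spec.helix_length):
        residues.append(_helix_residue(one_to_three(seq[i]), i + 1, i, -10.0, y_helix))
    for j in range(spec.floor_length):
        pos = 2 * j if side < 0 else 2 * j + 1
        ca = np.array([CA_SPACING * pos, side * FLOOR_Y, FLOOR_Z])
        residues.append(_flat_residue(one_to_three(seq[spec.helix_length + j]),
                                      spec.helix_length + j + 1, ca))
    return residues


def make_toy_pmhc2(spec: FixtureSpec) -> PMHCComplex:
    """Build the idealized complex for ``spec`` (deterministic: the same
    spec always yields bitwise-identical coordinates)."""
    anchors = set()
    if len(spec.peptide_seq) >= 9:
        anchors = set(BindingCore(spec.core_start, len(spec.peptide_seq)).anchors_0based())
    peptide = []
    for i, letter in enumerate(spec.peptide_seq):
        ca = np.array([CA_SPACING * i, 0.0, 0.0])
        cb_dz = -1.36 if i in anchors else 1.36
        peptide.append(_flat_residue(one_to_three(letter), i + 1, ca, cb_dz=cb_dz))

    chains = {
        "M": _receptor_chain(spec.resolved_chain_seq("alpha"), spec, -1),
        "N": _receptor_chain(spec.resolved_chain_seq("beta"), spec, +1),
        "P": peptide,
    }
    cpx = PMHCComplex(spec.pdb_id, MHCClass.II, chains,
                      alpha_allele=spec.alpha_allele, beta_allele=spec.beta_allele,
                      peptide_seq=spec.peptide_seq)
    cpx.validate()
    if anchors:
        rec = np.array([a.coord for cid in ("M", "N")
                        for r in chains[cid] for a in r.heavy_atoms()])
        for i in sorted(anchors):
            atoms = np.array([a.coord for a in peptide[i].heavy_atoms()])
            dmin = np.linalg.norm(atoms[:, None, :] - rec[None, :, :], axis=-1).min()
            if dmin > 5.0:
                raise FixtureSpecError(
                    f"anchor residue {i + 1} has no receptor atom within 5 Å "
                    f"(closest {dmin:.2f}); peptide probably too long for the floor")
    return cpx


def realize_fixture(spec: FixtureSpec) -> tuple[PMHCComplex, dict]:
    """Build the fixture and apply its perturbation (if any); returns the
    structure and the closed-form ground-truth RMSD contributions."""
    cpx = make_toy_pmhc2(spec)
    if spec.perturbation is None:
        return cpx, {}
    kind, magnitude = spec.perturbation
    core = BindingCore(spec.core_start, len(spec.peptide_seq)) \
        if len(spec.peptide_seq) >= 9 else None
    return perturb_fixture(cpx, kind, magnitude, spec.seed, core=core)


def perturb_fixture(complex: PMHCComplex, kind: str, magnitude: float, seed: int,
                    *, core: BindingCore | None = None) -> tuple[PMHCComplex, dict]:
    """Apply a controlled perturbation with exact expected L-RMSD values.

    ``peptide_shift``: rigid translation of the whole peptide by
    ``magnitude`` Å along a seeded random direction — every L-RMSD window
    equals ``magnitude`` exactly. ``flank_scramble``: every atom of every
    flank residue moves by ``magnitude`` Å in its own random direction —
    core L-RMSD stays 0, flanking L-RMSD equals ``magnitude``.
    ``core_register_shift``: coordinates untouched; the ground truth is the
    relabelled core start (anchor-misprediction analogue).
    """
    rng = np.random.default_rng(seed)
    out = complex.copy()
    pep = out.peptide()
    n_bb = lambda residues: sum(1 for r in residues for a in r.atoms
                                if a.name in ("N", "CA", "C", "O"))
    if kind == "peptide_shift":
        v = rng.normal(size=3)
        v = magnitude * v / np.linalg.norm(v)
        for res in pep:
            for at in res.atoms:
                at.coord = at.coord + v
        return out, {"whole": abs(magnitude), "core": abs(magnitude),
                     "flanking": abs(magnitude)}
    if kind == "flank_scramble":
        if core is None:
            raise FixtureSpecError("flank_scramble requires the binding core")
        flank_idx = set(core.n_flank_positions()) | set(core.c_flank_positions())
        if not flank_idx:
            raise FixtureSpecError("flank_scramble needs at least one flank residue")
        for i in sorted(flank_idx):
            for at in pep[i].atoms:
                v = rng.normal(size=3)
                at.coord = at.coord + magnitude * v / np.linalg.norm(v)
        nf = n_bb([pep[i] for i in flank_idx])
        nc = n_bb([pep[i] for i in core.core_positions()])
        whole = float(np.sqrt(nf * magnitude ** 2 / (nf + nc)))
        return out, {"whole": whole, "core": 0.0, "flanking": abs(magnitude)}
    if kind == "core_register_shift":
        if core is None:
            raise FixtureSpecError("core_register_shift requires the binding core")
        k = int(magnitude)
        shifted = BindingCore(core.start + k, core.peptide_length)
        return out, {"core_start": shifted.start}
    raise FixtureSpecError(f"unsupported perturbation kind {kind!r}")


# ---------------------------------------------------------------------------
# ready-made template sets

def _mutate(seq: str, n_mut: int, rng, alphabet: str = AA20) -> str:
    out = list(seq)
    for pos in rng.choice(len(seq), size=n_mut, replace=False):
        choices = [c for c in alphabet if c != out[pos]]
        out[pos] = choices[rng.integers(len(choices))]
    return "".join(out)


def _random_peptide(length: int, core_start: int, rng) -> str:
    """Random peptide avoiding glycine at anchors (a Gly anchor has no Cβ
    stub to contact the floor, making the structural core ambiguous)."""
    letters = list(rng.choice(list(AA20), size=length))
    anchors = BindingCore(core_start, length).anchors_0based()
    no_gly = AA20.replace("G", "")
    for i in anchors:
        if letters[i] == "G":
            letters[i] = no_gly[rng.integers(len(no_gly))]
    return "".join(letters)


def make_benchmark_set(n_pairs: int = 5, seed: int = 0, *,
                       extra_residue_pairs: int = 2) -> list[TemplateRecord]:
    """A leave-one-out benchmark set of near-duplicate fixture pairs.

    Each pair shares its MHC α/β sequences up to 2 substitutions (so
    identity ranking pairs the twins up) while pairs are mutually unrelated
    random sequences. Twins share peptide length and core register except
    in the last ``extra_residue_pairs`` pairs, where one twin carries one
    extra C-terminal flank residue — modelling that twin from its partner
    exercises de novo flank building.
    """
    records: list[TemplateRecord] = []
    rng = np.random.default_rng(seed)
    for p in range(n_pairs):
        length = int(rng.integers(13, 17))
        core_start = int(rng.integers(0, length - 9 + 1))
        spec_seed = int(rng.integers(0, 2 ** 31 - 1))
        alpha = "".join(rng.choice(list(AA20), size=167 + 13))
        beta = "".join(rng.choice(list(AA20), size=167 + 13))
        pep_a = _random_peptide(length, core_start, rng)
        extra = p >= n_pairs - extra_residue_pairs
        if extra:
            pep_b = pep_a + AA20[rng.integers(len(AA20))]
        else:
            flanks = [i for i in range(length)
                      if not core_start <= i < core_start + 9]
            pep_b = pep_a
            if flanks:
                pos = flanks[rng.integers(len(flanks))]
                repl = [c for c in AA20 if c != pep_a[pos]][rng.integers(19)]
                pep_b = pep_a[:pos] + repl + pep_a[pos + 1:]
        for member, pep, a_seq, b_seq in (
                ("A", pep_a, alpha, beta),
                ("B", pep_b, _mutate(alpha, 2, rng), _mutate(beta, 2, rng))):
            spec = FixtureSpec(
                peptide_seq=pep, core_start=core_start, seed=spec_seed,
                alpha_seq=a_seq, beta_seq=b_seq,
                alpha_allele=f"SYNA*{p:02d}:01", beta_allele=f"SYNB*{p:02d}:01",
                pdb_id=f"FIX{p}{member}")
            cpx = make_toy_pmhc2(spec)
            records.append(TemplateRecord(cpx, BindingCore(core_start, len(pep))))
    return records


def write_fixture_set(records: list[TemplateRecord], directory: str | Path) -> None:
    """Emit a fixture set in the standard template-database layout
    (standardized PDB files plus JSON index)."""
    save_template_db(records, directory)
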