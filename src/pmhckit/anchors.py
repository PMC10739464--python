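"""Binding cores, anchor positions and anchor distance restraints.

The MHC class II groove holds a 9-residue peptide core whose positions
P1, P4, P6 and P9 (offsets 0, 3, 5, 8 within the core) anchor into the four
main binding pockets. Modelling restrains these four anchors: every
template heavy-atom contact between an anchor residue and the receptor
within a cutoff becomes one harmonic distance restraint carried over to the
target peptide.

When the user supplies no anchors, the core can come from a pluggable
:class:`CorePredictor` (e.g. a wrapper around an external binding-core
predictor) or from the transparent built-in position-weight fallback
scorer, which makes no accuracy claim beyond being deterministic and
contract-compatible.
"""

from __future__ import annotations

import csv
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING, Protocol

import numpy as np

from .errors import AnchorError, CoreError, PeptideLengthError, RestraintError
from .residues import load_json_data

if TYPE_CHECKING:  # pragma: no cover - typing only
    from .structure_io import PMHCComplex, TemplateRecord
    from .template_select import CoreAlignment

logger = logging.getLogger(__name__)

#: anchor offsets within the 9-mer core (P1, P4, P6, P9)
ANCHOR_OFFSETS = (0, 3, 5, 8)
CORE_LENGTH = 9


@dataclass(frozen=True)
class BindingCore:
    """The 9-mer binding-core window of a peptide.

    ``start`` is the 0-based offset of core position P1 within the peptide;
    ``peptide_length`` is the full peptide length the core must fit in.
    """

    start: int
    peptide_length: int

    def __post_init__(self):
        if self.start < 0:
            raise CoreError(f"core start must be >= 0, got {self.start}")
        if self.peptide_length < CORE_LENGTH:
            raise CoreError(
                f"peptide of length {self.peptide_length} cannot hold a 9-mer core")
        if self.start + CORE_LENGTH > self.peptide_length:
            raise CoreError(
                f"core [{self.start}, {self.start + CORE_LENGTH}) exceeds peptide "
                f"length {self.peptide_length}")

    @property
    def end(self) -> int:
        """0-based exclusive end of the core window."""
        return self.start + CORE_LENGTH

    def anchors_0based(self) -> tuple[int, int, int, int]:
        return tuple(self.start + o for o in ANCHOR_OFFSETS)

    def anchors_1based(self) -> tuple[int, int, int, int]:
        return tuple(self.start + o + 1 for o in ANCHOR_OFFSETS)

    def core_positions(self) -> range:
        return range(self.start, self.end)

    def n_flank_positions(self) -> range:
        return range(0, self.start)

    def c_flank_positions(self) -> range:
        return range(self.end, self.peptide_length)

    def validate_for(self, peptide_length: int) -> None:
        if peptide_length != self.peptide_length:
            raise CoreError(
                f"core declared for a {self.peptide_length}-mer applied to a "
                f"{peptide_length}-mer peptide")


def core_from_user_anchors(peptide: str, anchor_positions) -> BindingCore:
    """Build a core from four user-supplied 1-based anchor positions.

    Positions must have the canonical spacing (P1, P1+3, P1+5, P1+8) and fit
    inside the peptide.
    """
    pos = tuple(int(p) for p in anchor_positions)
    if len(pos) != 4:
        raise AnchorError(f"exactly four anchor positions required, got {len(pos)}")
    spacing = tuple(p - pos[0] for p in pos)
    if spacing != ANCHOR_OFFSETS:
        raise AnchorError(
            f"anchors {pos} have spacing {spacing}; required spacing is "
            f"{ANCHOR_OFFSETS} (P1, P4, P6, P9)")
    if pos[0] < 1 or pos[3] > len(peptide):
        raise AnchorError(f"anchors {pos} do not fit a {len(peptide)}-mer peptide")
    return BindingCore(pos[0] - 1, len(peptide))


class CorePredictor(Protocol):
    """Callable contract for binding-core predictors."""

    def __call__(self, peptide: str, alpha_allele: str, beta_allele: str) -> BindingCore:
        ...  # pragma: no cover


class PocketProfile:
    """A 9-position × residue score table for the fallback core predictor."""

    def __init__(self, table: dict[int, dict[str, float]]):
        if sorted(table) != list(range(1, CORE_LENGTH + 1)):
            raise CoreError("pocket profile must cover core positions 1..9")
        self.table = table

    @classmethod
    def default(cls) -> "PocketProfile":
        raw = load_json_data("pocket_profile.json")["profile"]
        return cls({int(k): v for k, v in raw.items()})

    def score_window(self, window: str) -> float:
        return sum(self.table[i + 1].get(aa, 0.0) for i, aa in enumerate(window))


def predict_core_fallback(peptide: str, pocket_profile: PocketProfile | None = None
                          ) -> BindingCore:
    """Pick the 9-mer window maximizing the summed profile score.

    Ties resolve to the smallest start, which also makes the uniform-profile
    case deterministic.
    """
    if len(peptide) < CORE_LENGTH:
        raise PeptideLengthError(
            f"peptide of length {len(peptide)} is shorter than the 9-mer core")
    profile = pocket_profile or PocketProfile.default()
    best_start, best_score = 0, -np.inf
    for s in range(len(peptide) - CORE_LENGTH + 1):
        score = profile.score_window(peptide[s:s + CORE_LENGTH])
        if score > best_score:
            best_start, best_score = s, score
    return BindingCore(best_start, len(peptide))


class SubprocessCorePredictor:
    """Adapter wrapping an external binding-core predictor executable.

    Contract: the executable is invoked as
    ``<exe> [args...] <peptide> <alpha_allele> <beta_allele>`` and must
    print the 1-based core start position (first token of stdout).
    """

    def __init__(self, executable: str, *args: str):
        self.command = [executable, *args]

    def __call__(self, peptide: str, alpha_allele: str = "",
                 beta_allele: str = "") -> BindingCore:
        import subprocess

        proc = subprocess.run(self.command + [peptide, alpha_allele, beta_allele],
                              capture_output=True, text=True, check=False)
        if proc.returncode != 0:
            raise CoreError(
                f"core predictor {self.command[0]!r} failed "
                f"(exit {proc.returncode}): {proc.stderr.strip()}")
        try:
            start_1based = int(proc.stdout.split()[0])
        except (IndexError, ValueError):
            raise CoreError(
                f"core predictor {self.command[0]!r} printed no integer core "
                f"start: {proc.stdout!r}") from None
        return BindingCore(start_1based - 1, len(peptide))


def fallback_predictor(profile: PocketProfile | None = None) -> CorePredictor:
    """Adapt :func:`predict_core_fallback` to the :class:`CorePredictor`
    contract (allele names are accepted and ignored)."""
    def _predict(peptide: str, alpha_allele: str = "", beta_allele: str = "") -> BindingCore:
        return predict_core_fallback(peptide, profile)
    return _predict


def core_from_structure(complex: "PMHCComplex", cutoff: float = 5.0) -> BindingCore:
    """Derive the structural binding core of a template from its geometry.

    For every 9-mer window the receptor heavy-atom contacts (within
    ``cutoff`` Å) of the four putative anchor residues are counted; the
    window with the most contacts wins, ties going to the smallest start.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    pep = complex.peptide()
    if len(pep) < CORE_LENGTH:
        raise CoreError(f"{complex.pdb_id}: peptide shorter than the 9-mer core")
    receptor = np.array([a.coord
                         for cid in complex.receptor_chain_ids()
                         for r in complex.chains[cid]
                         for a in r.heavy_atoms()])
    per_res = []
    for res in pep:
        atoms = np.array([a.coord for a in res.heavy_atoms()])
        d = np.linalg.norm(atoms[:, None, :] - receptor[None, :, :], axis=-1)
        per_res.append(int((d <= cutoff).sum()))
    best_start, best = 0, -1
    for s in range(len(pep) - CORE_LENGTH + 1):
        n = sum(per_res[s + o] for o in ANCHOR_OFFSETS)
        if n > best:
            best_start, best = s, n
    if best == 0:
        raise CoreError(f"{complex.pdb_id}: no anchor-receptor contacts within "
                        f"{cutoff} Å in any core register")
    return BindingCore(best_start, len(pep))


@dataclass(frozen=True)
class DistanceRestraint:
    """Harmonic atom-pair restraint between a peptide anchor atom and a
    receptor atom: target distance and standard deviation, both in Å."""

    atom_a: tuple[str, int, str]  # (chain id "P", residue number, atom name)
    atom_b: tuple[str, int, str]  # (receptor chain id, residue number, atom name)
    target: float
    sd: float

    def __post_init__(self):
        if self.target <= 0:
            raise RestraintError(f"restraint target must be > 0, got {self.target}")
        if self.sd < 0:
            raise RestraintError(f"restraint sd must be >= 0, got {self.sd}")
        if self.atom_a[0] != "P":
            raise RestraintError("atom_a must sit on the peptide chain P")
        if self.atom_b[0] == "P":
            raise RestraintError("atom_b must sit on a receptor chain")


def derive_restraints(
    template: "TemplateRecord",
    correspondence: "CoreAlignment | None" = None,
    *,
    contact_cutoff: float = 5.0,
    sd: float = 0.0,
    side_chain_only: bool = False,
) -> list[DistanceRestraint]:
    """Turn the template's anchor contacts into distance restraints.

    For each of the four anchor residues of the template's structural core,
    every (anchor heavy atom, receptor heavy atom) pair within
    ``contact_cutoff`` Å becomes one restraint whose target is the observed
    template distance. Peptide residue numbers are re-indexed to the target
    peptide through ``correspondence`` (identity when omitted, i.e. when the
    template is modelled onto itself).

    An anchor without any contact is recorded as a warning; if all four are
    contact-free a :class:`RestraintError` is raised.
    """
    if contact_cutoff <= 0:
        raise ValueError("contact_cutoff must be positive")
    cpx = template.complex
    core = template.structural_core
    if core is None:
        raise RestraintError(
            f"{cpx.pdb_id}: template has no structural core to derive restraints from")
    pep = cpx.peptide()

    if correspondence is None:
        tmpl_to_target = {i: i for i in range(len(pep))}
    else:
        tmpl_to_target = {t: q for q, t in correspondence.offset_map.items()
                          if t is not None}

    receptor_atoms = [(cid, r.seqnum, a)
                      for cid in cpx.receptor_chain_ids()
                      for r in cpx.chains[cid]
                      for a in r.heavy_atoms()]
    rec_coords = np.array([a.coord for _, _, a in receptor_atoms])

    restraints: list[DistanceRestraint] = []
    empty_anchors = []
    for anchor_idx in core.anchors_0based():
        res = pep[anchor_idx]
        target_idx = tmpl_to_target.get(anchor_idx)
        if target_idx is None:
            raise RestraintError(
                f"{cpx.pdb_id}: anchor residue {anchor_idx + 1} has no "
                "counterpart in the core alignment")
        atoms = res.side_chain_atoms() if side_chain_only else res.heavy_atoms()
        found = 0
        for at in atoms:
            d = np.linalg.norm(rec_coords - at.coord, axis=1)
            for j in np.nonzero(d <= contact_cutoff)[0]:
                cid, seqnum, rat = receptor_atoms[j]
                restraints.append(DistanceRestraint(
                    atom_a=("P", target_idx + 1, at.name),
                    atom_b=(cid, seqnum, rat.name),
                    target=float(d[j]), sd=float(sd)))
                found += 1
        if found == 0:
            empty_anchors.append(anchor_idx + 1)
    if empty_anchors:
        msg = (f"{cpx.pdb_id}: anchor residue(s) {empty_anchors} have no receptor "
               f"contact within {contact_cutoff} Å")
        if len(empty_anchors) == len(ANCHOR_OFFSETS):
            raise RestraintError(msg)
        warnings.warn(msg, stacklevel=2)
        logger.warning(msg)
    return restraints


def write_restraints_tsv(restraints: list[DistanceRestraint], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["chainA", "resA", "atomA", "chainB", "resB", "atomB", "target", "sd"])
        for r in restraints:
            w.writerow([*r.atom_a, *r.atom_b, f"{r.target:.4f}", f"{r.sd:.4f}"])


def read_restraints_tsv(path: str | Path) -> list[DistanceRestraint]:
    out = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            out.append(DistanceRestraint(
                (row["chainA"], int(row["resA"]), row["atomA"]),
                (row["chainB"], int(row["resB"]), row["atomB"]),
                float(row["target"]), float(row["sd"])))
    return out
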