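"""Peptide conformer generation, refinement, scoring and ranking.

The engine follows the template-based recipe for class II grooves: the
receptor is taken rigidly from the template; the target peptide core is
placed on the template core conformation (the default "fixed core" mode
keeps it frozen); flank residues with a template counterpart in the
core-anchored alignment inherit the template backbone, and flank residues
beyond the template's ends are grown outward with ideal covalent geometry
and backbone torsions drawn from a packaged Ramachandran-favored set,
keeping the least-clashing of ``k`` draws per residue. Each model is then
relaxed by gradient-based minimization of a transparent three-term
pseudo-energy

``total = w_bonded * bonded + w_clash * clash + w_restraint * restraint``

with a harmonic bonded-geometry term (deviations of bonded and 1-3
distances from the starting conformation), a capped soft-sphere ``r^-12``
clash term, and flat-bottom harmonic anchor restraints. The total is the
model's pseudo-energy; an ensemble of ``n_models`` models (default 20) is
ranked ascending by it. No numerical equivalence with any external
objective function (e.g. MODELLER's molpdf) is claimed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
from scipy.optimize import minimize as _scipy_minimize

from . import geometry as geo
from .anchors import BindingCore, DistanceRestraint, derive_restraints
from .errors import (
    IncompleteBackboneError,
    NumericalError,
    PmhckitError,
)
from .residues import load_json_data, one_to_three
from .structure_io import (
    BACKBONE_ATOMS,
    AtomRecord,
    PMHCComplex,
    ResidueRecord,
    TemplateRecord,
)
from .template_select import CoreAlignment, align_peptide_to_template

logger = logging.getLogger(__name__)

# pseudo-energy parameters (documented defaults)
W_BONDED = 1.0
W_CLASH = 1.0
W_RESTRAINT = 10.0
K_BOND = 100.0        # Å^-2 stiffness inside the bonded term
CLASH_R0 = 3.0        # Å soft-sphere contact radius
CLASH_DMIN = 0.8      # Å distance floor capping the r^-12 repulsion
SD_FLOOR = 0.01       # Å, avoids division by zero for sd = 0 restraints
HARD_OVERLAP = 2.0    # Å; flank placement leaving a pair closer is flagged
NEIGHBOR_CUTOFF = 4.5  # Å initial-neighbor list for the clash term

#: CB placement: improper torsion C-N-CA-CB fixing the side-chain branch
CB_TORSION = 122.68


class Mode(Enum):
    FIXED_CORE = "fixed_core"
    FLEX_CORE = "flex_core"


@dataclass
class ModellingJob:
    """One modelling task: target sequences + core, chosen template, mode."""

    alpha_seq: str
    beta_seq: str
    peptide_seq: str
    core: BindingCore
    template: TemplateRecord
    mode: Mode = Mode.FIXED_CORE
    sd: float = 0.0
    n_models: int = 20
    seed: int = 0
    correspondence: CoreAlignment | None = None

    def __post_init__(self):
        if self.n_models < 1:
            raise ValueError("n_models must be >= 1")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        self.core.validate_for(len(self.peptide_seq))


@dataclass(frozen=True)
class EnergyBreakdown:
    bonded: float
    clash: float
    restraint: float

    @property
    def total(self) -> float:
        return self.bonded + self.clash + self.restraint


@dataclass
class ConformerModel:
    complex: PMHCComplex
    pseudo_energy: float
    rank: int
    seed_used: int
    breakdown: EnergyBreakdown
    flagged: bool = False
    energy_trace: list[float] = field(default_factory=list)


@dataclass
class ModelFailure:
    seed_used: int
    error: str


# ---------------------------------------------------------------------------
# residue placement helpers

def _require_backbone(res: ResidueRecord) -> dict[str, np.ndarray]:
    bb = res.backbone_coords()
    missing = [a for a in BACKBONE_ATOMS if a not in bb]
    if missing:
        raise IncompleteBackboneError(
            f"residue {res.resname}{res.seqnum} is missing backbone atom(s) {missing}")
    return bb


def _ideal_cb(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    return geo.place_atom(c, n, ca, geo.IDEAL_BOND[("CA", "CB")],
                          geo.IDEAL_ANGLE[("N", "CA", "CB")], CB_TORSION)


def residue_from_template(resname: str, seqnum: int, tmpl: ResidueRecord) -> ResidueRecord:
    """Place one target residue on a template residue: backbone copied; side
    chain copied when the residue type matches, otherwise rebuilt as an
    ideal-geometry CB stub (none for glycine)."""
    bb = _require_backbone(tmpl)
    atoms = [AtomRecord(name, "C" if name in ("CA", "C") else name[0], bb[name].copy())
             for name in BACKBONE_ATOMS]
    if resname == tmpl.resname:
        for at in tmpl.side_chain_atoms():
            atoms.append(at.copy())
    elif resname != "GLY":
        atoms.append(AtomRecord("CB", "C", _ideal_cb(bb["N"], bb["CA"], bb["C"])))
    return ResidueRecord(resname, seqnum, atoms)


def superpose_core(target_core_res: list[ResidueRecord],
                   template: TemplateRecord) -> tuple[geo.Transform, list[ResidueRecord]]:
    """Superpose a target core onto the template core and return the rigid
    transform plus the placed core residues.

    The fit is a proper least-squares rigid-body superposition over the
    9 x 4 core backbone atoms; placed backbone coordinates are exactly the
    template's, with side chains rebuilt per :func:`residue_from_template`.
    """
    if len(target_core_res) != 9:
        raise IncompleteBackboneError("target core must contain 9 residues")
    tmpl_core = [template.complex.peptide()[i]
                 for i in template.structural_core.core_positions()]
    tgt = np.array([_require_backbone(r)[a] for r in target_core_res for a in BACKBONE_ATOMS])
    tpl = np.array([_require_backbone(r)[a] for r in tmpl_core for a in BACKBONE_ATOMS])
    transform, _ = geo.kabsch(tgt, tpl)
    placed = [residue_from_template(res.resname, res.seqnum, t)
              for res, t in zip(target_core_res, tmpl_core)]
    return transform, placed


# ---------------------------------------------------------------------------
# flank building

def _load_torsions() -> list[tuple[float, float]]:
    return [tuple(p) for p in load_json_data("ramachandran_favored.json")["torsions"]]


def _psi_from_oxygen(res: ResidueRecord) -> float:
    bb = _require_backbone(res)
    return geo.dihedral(bb["N"], bb["CA"], bb["C"], bb["O"]) + 180.0


def _carbonyl_o(ca: np.ndarray, c: np.ndarray, n_next: np.ndarray) -> np.ndarray:
    u = (ca - c) / np.linalg.norm(ca - c)
    v = (n_next - c) / np.linalg.norm(n_next - c)
    w = u + v
    return c - geo.IDEAL_BOND[("C", "O")] * w / np.linalg.norm(w)


def _clash_score(new_atoms: np.ndarray, context: np.ndarray, r0: float) -> tuple[float, float]:
    """Soft-sphere score of candidate atoms against context atoms; returns
    (score, minimum distance)."""
    if len(context) == 0:
        return 0.0, np.inf
    d = np.linalg.norm(new_atoms[:, None, :] - context[None, :, :], axis=-1)
    dmin = float(d.min())
    d = np.clip(d, CLASH_DMIN, None)
    mask = d < r0
    score = float((((r0 / d[mask]) ** 12) - 1.0).sum()) if mask.any() else 0.0
    return score, dmin


def _residue_coords(res: ResidueRecord) -> np.ndarray:
    return np.array([a.coord for a in res.heavy_atoms()])


def build_flanks(placed: list[ResidueRecord], n_flank_seq: str, c_flank_seq: str,
                 receptor: PMHCComplex | np.ndarray, seed: int, *, k: int = 32,
                 clash_r0: float = CLASH_R0,
                 torsions: list[tuple[float, float]] | None = None,
                 ) -> tuple[list[ResidueRecord], bool]:
    """Grow flank residues outward from an already-placed peptide segment.

    Each new residue is appended (or prepended) with ideal bond lengths and
    angles; its backbone torsions come from ``k`` draws out of the packaged
    Ramachandran-favored set and the draw with the lowest soft-sphere clash
    score against the receptor and the peptide built so far wins (ties to
    the earliest draw; deterministic given ``seed``). If even the best draw
    leaves two atoms closer than the hard-overlap threshold the chain is
    kept but flagged.

    Returns the full residue list renumbered 1..L and the overlap flag.
    """
    if not placed:
        raise IncompleteBackboneError("cannot extend an empty placed segment")
    rng = np.random.default_rng(seed)
    tors = torsions or _load_torsions()
    if isinstance(receptor, PMHCComplex):
        rec_coords = np.array([a.coord
                               for cid in receptor.receptor_chain_ids()
                               for r in receptor.chains[cid]
                               for a in r.heavy_atoms()])
    else:
        rec_coords = np.asarray(receptor, dtype=float).reshape(-1, 3)

    chain = [r.copy() for r in placed]
    built: set[int] = set()   # ids of residues created here (may be re-touched)
    flagged = False

    def context_for(exclude_res: ResidueRecord) -> np.ndarray:
        pep = [a.coord for r in chain if r is not exclude_res for a in r.heavy_atoms()]
        return np.vstack([rec_coords] + ([np.array(pep)] if pep else []))

    # C-terminal growth
    for letter in c_flank_seq:
        prev = chain[-1]
        bb_prev = _require_backbone(prev)
        psi_link_default = _psi_from_oxygen(prev)
        cands = []
        for c_i in range(k):
            psi_link = psi_link_default if c_i == 0 else tors[rng.integers(len(tors))][1]
            phi, psi = tors[rng.integers(len(tors))]
            n = geo.place_atom(bb_prev["N"], bb_prev["CA"], bb_prev["C"],
                               geo.IDEAL_BOND[("C", "N")],
                               geo.IDEAL_ANGLE[("CA", "C", "N")], psi_link)
            ca = geo.place_atom(bb_prev["CA"], bb_prev["C"], n,
                                geo.IDEAL_BOND[("N", "CA")],
                                geo.IDEAL_ANGLE[("C", "N", "CA")], geo.OMEGA_TRANS)
            c = geo.place_atom(bb_prev["C"], n, ca,
                               geo.IDEAL_BOND[("CA", "C")],
                               geo.IDEAL_ANGLE[("N", "CA", "C")], phi)
            o = geo.place_atom(n, ca, c, geo.IDEAL_BOND[("C", "O")],
                               geo.IDEAL_ANGLE[("CA", "C", "O")], psi + 180.0)
            atoms = [AtomRecord("N", "N", n), AtomRecord("CA", "C", ca),
                     AtomRecord("C", "C", c), AtomRecord("O", "O", o)]
            resname = one_to_three(letter)
            if resname != "GLY":
                atoms.append(AtomRecord("CB", "C", _ideal_cb(n, ca, c)))
            cands.append((psi_link, ResidueRecord(resname, prev.seqnum + 1, atoms)))
        chosen_idx = min(range(len(cands)), key=lambda idx: _cand_key(cands, idx, context_for, clash_r0))
        psi_link, chosen = cands[chosen_idx]
        if id(prev) in built:
            # re-point the previous carbonyl O at the chosen next-N direction;
            # template-placed residues are never touched (frozen-core contract)
            prev.atom("O").coord = _carbonyl_o(bb_prev["CA"], bb_prev["C"],
                                               chosen.atom("N").coord)
        built.add(id(chosen))
        _, dmin = _clash_score(_residue_coords(chosen), context_for(chosen), clash_r0)
        if dmin < HARD_OVERLAP:
            flagged = True
        chain.append(chosen)

    # N-terminal growth (prepending, walking outward)
    for letter in reversed(n_flank_seq):
        nxt = chain[0]
        bb_next = _require_backbone(nxt)
        cands = []
        for _ in range(k):
            phi_link = tors[rng.integers(len(tors))][0]
            phi, psi = tors[rng.integers(len(tors))]
            c = geo.place_atom(bb_next["C"], bb_next["CA"], bb_next["N"],
                               geo.IDEAL_BOND[("C", "N")],
                               geo.IDEAL_ANGLE[("C", "N", "CA")], phi_link)
            ca = geo.place_atom(bb_next["CA"], bb_next["N"], c,
                                geo.IDEAL_BOND[("CA", "C")],
                                geo.IDEAL_ANGLE[("CA", "C", "N")], geo.OMEGA_TRANS)
            n = geo.place_atom(bb_next["N"], c, ca,
                               geo.IDEAL_BOND[("N", "CA")],
                               geo.IDEAL_ANGLE[("N", "CA", "C")], psi)
            o = _carbonyl_o(ca, c, bb_next["N"])
            atoms = [AtomRecord("N", "N", n), AtomRecord("CA", "C", ca),
                     AtomRecord("C", "C", c), AtomRecord("O", "O", o)]
            resname = one_to_three(letter)
            if resname != "GLY":
                atoms.append(AtomRecord("CB", "C", _ideal_cb(n, ca, c)))
            cands.append((None, ResidueRecord(resname, 1, atoms)))
        chosen_idx = min(range(len(cands)), key=lambda idx: _cand_key(cands, idx, context_for, clash_r0))
        chosen = cands[chosen_idx][1]
        built.add(id(chosen))
        _, dmin = _clash_score(_residue_coords(chosen), context_for(chosen), clash_r0)
        if dmin < HARD_OVERLAP:
            flagged = True
        chain.insert(0, chosen)

    out = [ResidueRecord(r.resname, i + 1, [a.copy() for a in r.atoms])
           for i, r in enumerate(chain)]
    return out, flagged


def _cand_key(cands, idx, context_for, r0):
    res = cands[idx][1]
    score, dmin = _clash_score(_residue_coords(res), context_for(res), r0)
    return (score, -dmin, idx)


# ---------------------------------------------------------------------------
# pseudo-energy and minimization

class PairPotential:
    """Pairwise pseudo-energy over an atom coordinate array.

    Terms (all non-negative):

    * ``bonded``: ``K_BOND * (d - d0)^2`` over bonded and 1-3 atom pairs,
      with d0 taken from the starting conformation.
    * ``clash``: ``(r0/d)^12 - 1`` for non-bonded pairs closer than ``r0``,
      with the distance floored at ``CLASH_DMIN`` (the r^-12 cap).
    * ``restraint``: flat-bottom harmonic,
      ``((d - target)/max(sd, SD_FLOOR))^2`` when ``|d - target| > sd``.
    """

    def __init__(self, coords: np.ndarray, free_mask: np.ndarray,
                 bonded_pairs: np.ndarray, bonded_d0: np.ndarray,
                 clash_pairs: np.ndarray,
                 restraint_pairs: np.ndarray, restraint_target: np.ndarray,
                 restraint_sd: np.ndarray, clash_r0: float = CLASH_R0):
        self.coords0 = coords.copy()
        self.free_mask = free_mask
        self.free_idx = np.nonzero(free_mask)[0]
        self.bonded_pairs = bonded_pairs
        self.bonded_d0 = bonded_d0
        self.clash_pairs = clash_pairs
        self.restraint_pairs = restraint_pairs
        self.restraint_target = restraint_target
        self.restraint_sd = restraint_sd
        self.clash_r0 = clash_r0

    def full_coords(self, x: np.ndarray) -> np.ndarray:
        coords = self.coords0.copy()
        coords[self.free_idx] = x.reshape(-1, 3)
        return coords

    def _pair_terms(self, coords, pairs):
        vec = coords[pairs[:, 0]] - coords[pairs[:, 1]]
        d = np.linalg.norm(vec, axis=1)
        return vec, d

    def breakdown(self, coords: np.ndarray) -> EnergyBreakdown:
        e_b = e_c = e_r = 0.0
        if len(self.bonded_pairs):
            _, d = self._pair_terms(coords, self.bonded_pairs)
            e_b = float(K_BOND * ((d - self.bonded_d0) ** 2).sum())
        if len(self.clash_pairs):
            _, d = self._pair_terms(coords, self.clash_pairs)
            dc = np.clip(d, CLASH_DMIN, None)
            mask = dc < self.clash_r0
            if mask.any():
                e_c = float((((self.clash_r0 / dc[mask]) ** 12) - 1.0).sum())
        if len(self.restraint_pairs):
            _, d = self._pair_terms(coords, self.restraint_pairs)
            dev = d - self.restraint_target
            sigma = np.maximum(self.restraint_sd, SD_FLOOR)
            active = np.abs(dev) > self.restraint_sd
            e_r = float(((dev[active] / sigma[active]) ** 2).sum())
        return EnergyBreakdown(W_BONDED * e_b, W_CLASH * e_c, W_RESTRAINT * e_r)

    def value_and_grad(self, x: np.ndarray) -> tuple[float, np.ndarray]:
        coords = self.full_coords(x)
        grad = np.zeros_like(coords)
        total = 0.0
        if len(self.bonded_pairs):
            vec, d = self._pair_terms(coords, self.bonded_pairs)
            dd = d - self.bonded_d0
            total += W_BONDED * K_BOND * float((dd ** 2).sum())
            g = (W_BONDED * K_BOND * 2.0 * dd / np.maximum(d, 1e-9))[:, None] * vec
            np.add.at(grad, self.bonded_pairs[:, 0], g)
            np.add.at(grad, self.bonded_pairs[:, 1], -g)
        if len(self.clash_pairs):
            vec, d = self._pair_terms(coords, self.clash_pairs)
            dc = np.clip(d, CLASH_DMIN, None)
            mask = (dc < self.clash_r0) & (d > CLASH_DMIN)
            e = np.where(dc < self.clash_r0, (self.clash_r0 / dc) ** 12 - 1.0, 0.0)
            total += W_CLASH * float(e.sum())
            coef = np.zeros_like(d)
            coef[mask] = W_CLASH * (-12.0) * (self.clash_r0 ** 12) / (dc[mask] ** 13)
            g = (coef / np.maximum(d, 1e-9))[:, None] * vec
            np.add.at(grad, self.clash_pairs[:, 0], g)
            np.add.at(grad, self.clash_pairs[:, 1], -g)
        if len(self.restraint_pairs):
            vec, d = self._pair_terms(coords, self.restraint_pairs)
            dev = d - self.restraint_target
            sigma = np.maximum(self.restraint_sd, SD_FLOOR)
            active = np.abs(dev) > self.restraint_sd
            total += W_RESTRAINT * float(((dev[active] / sigma[active]) ** 2).sum())
            coef = np.zeros_like(d)
            coef[active] = W_RESTRAINT * 2.0 * dev[active] / (sigma[active] ** 2)
            g = (coef / np.maximum(d, 1e-9))[:, None] * vec
            np.add.at(grad, self.restraint_pairs[:, 0], g)
            np.add.at(grad, self.restraint_pairs[:, 1], -g)
        if not np.isfinite(total):
            bd = self.breakdown(coords)
            for name in ("bonded", "clash", "restraint"):
                if not np.isfinite(getattr(bd, name)):
                    raise NumericalError(f"pseudo-energy term {name!r} is not finite")
            raise NumericalError("pseudo-energy total is not finite")
        return total, grad[self.free_idx].ravel()

    def minimize(self, max_steps: int = 200, gtol: float = 1e-4
                 ) -> tuple[np.ndarray, list[float]]:
        """L-BFGS-B descent over the free atoms; returns the relaxed full
        coordinate array and the per-iteration energy trace (non-increasing
        over accepted steps)."""
        x0 = self.coords0[self.free_idx].ravel()
        trace: list[float] = [self.value_and_grad(x0)[0]]
        if len(x0) == 0:
            return self.coords0.copy(), trace

        def cb(xk):
            trace.append(self.value_and_grad(xk)[0])

        res = _scipy_minimize(self.value_and_grad, x0, jac=True, method="L-BFGS-B",
                              callback=cb,
                              options={"maxiter": max_steps, "gtol": gtol})
        x_best = res.x if res.fun <= trace[0] else x0
        trace.append(min(float(res.fun), trace[-1]))
        return self.full_coords(x_best), trace


def _atom_table(model: PMHCComplex) -> tuple[list[tuple[str, int, str]], np.ndarray]:
    keys, coords = [], []
    for cid, residues in model.chains.items():
        for res in residues:
            for at in res.heavy_atoms():
                keys.append((cid, res.seqnum, at.name))
                coords.append(at.coord)
    return keys, np.array(coords)


def _peptide_bonded_pairs(model: PMHCComplex, index: dict) -> list[tuple[int, int]]:
    pairs = []
    pep = model.peptide()

    def idx(resnum, name):
        return index.get(("P", resnum, name))

    for res in pep:
        r = res.seqnum
        for a, b in [("N", "CA"), ("CA", "C"), ("C", "O"), ("CA", "CB"),
                     ("N", "C"), ("CA", "O"), ("N", "CB"), ("C", "CB")]:
            i, j = idx(r, a), idx(r, b)
            if i is not None and j is not None:
                pairs.append((i, j))
        for a, b in [("C", "N"), ("CA", "N"), ("O", "N"), ("C", "CA")]:
            i, j = idx(r, a), idx(r + 1, b)
            if i is not None and j is not None:
                pairs.append((i, j))
    return pairs


def minimize_model(model: PMHCComplex, restraints: list[DistanceRestraint],
                   mode: Mode = Mode.FIXED_CORE, core: BindingCore | None = None,
                   max_steps: int = 200) -> tuple[PMHCComplex, EnergyBreakdown, list[float]]:
    """Relax a model under the three-term pseudo-energy.

    Receptor atoms are always frozen; in ``FIXED_CORE`` mode every atom of
    the core residues is frozen as well (``core`` required), matching the
    default where the peptide core keeps the template conformation exactly.
    Returns the relaxed model, the weighted energy breakdown and the
    non-increasing per-iteration energy trace.
    """
    keys, coords = _atom_table(model)
    index = {k: i for i, k in enumerate(keys)}

    free = np.zeros(len(keys), dtype=bool)
    frozen_core = set()
    if mode is Mode.FIXED_CORE:
        if core is None:
            raise ValueError("FIXED_CORE minimization requires the binding core")
        frozen_core = {p + 1 for p in core.core_positions()}
    for i, (cid, resnum, name) in enumerate(keys):
        if cid != "P":
            continue
        if resnum in frozen_core:
            continue
        free[i] = True

    bonded = np.array(_peptide_bonded_pairs(model, index), dtype=int).reshape(-1, 2)
    d0 = np.linalg.norm(coords[bonded[:, 0]] - coords[bonded[:, 1]], axis=1) \
        if len(bonded) else np.zeros(0)

    bonded_set = {tuple(sorted(p)) for p in bonded.tolist()}
    pep_idx = [i for i, k in enumerate(keys) if k[0] == "P"]
    other_idx = [i for i, k in enumerate(keys) if k[0] != "P"]
    clash_pairs = []
    if pep_idx:
        pc = coords[pep_idx]
        if other_idx:
            oc = coords[other_idx]
            d = np.linalg.norm(pc[:, None, :] - oc[None, :, :], axis=-1)
            for a, b in zip(*np.nonzero(d < NEIGHBOR_CUTOFF)):
                clash_pairs.append((pep_idx[a], other_idx[b]))
        d = np.linalg.norm(pc[:, None, :] - pc[None, :, :], axis=-1)
        for a, b in zip(*np.nonzero(d < NEIGHBOR_CUTOFF)):
            if a >= b:
                continue
            ia, ib = pep_idx[a], pep_idx[b]
            if abs(keys[ia][1] - keys[ib][1]) < 2:   # same or adjacent residue
                continue
            if tuple(sorted((ia, ib))) in bonded_set:
                continue
            clash_pairs.append((ia, ib))
    clash_pairs = np.array(clash_pairs, dtype=int).reshape(-1, 2)

    r_pairs, r_target, r_sd = [], [], []
    for r in restraints:
        ia, ib = index.get(r.atom_a), index.get(r.atom_b)
        if ia is None or ib is None:
            raise PmhckitError(f"restraint references missing atom: {r.atom_a} / {r.atom_b}")
        r_pairs.append((ia, ib))
        r_target.append(r.target)
        r_sd.append(r.sd)
    r_pairs = np.array(r_pairs, dtype=int).reshape(-1, 2)

    pot = PairPotential(coords, free, bonded, d0, clash_pairs,
                        r_pairs, np.array(r_target), np.array(r_sd))
    new_coords, trace = pot.minimize(max_steps=max_steps)

    relaxed = model.copy()
    i = 0
    for cid, residues in relaxed.chains.items():
        for res in residues:
            for at in res.heavy_atoms():
                at.coord = new_coords[i]
                i += 1
    return relaxed, pot.breakdown(new_coords), trace


# ---------------------------------------------------------------------------
# ensemble generation

def _build_target_peptide(job: ModellingJob, correspondence: CoreAlignment,
                          seed: int) -> tuple[list[ResidueRecord], bool]:
    tmpl_pep = job.template.complex.peptide()
    mapped = {q: t for q, t in correspondence.offset_map.items() if t is not None}
    placed_positions = sorted(mapped)
    # mapped positions are contiguous around the core by construction
    placed = [residue_from_template(one_to_three(job.peptide_seq[q]), q + 1,
                                    tmpl_pep[mapped[q]])
              for q in placed_positions]
    n_extra = "".join(job.peptide_seq[q] for q in range(placed_positions[0]))
    c_extra = "".join(job.peptide_seq[q]
                      for q in range(placed_positions[-1] + 1, len(job.peptide_seq)))
    return build_flanks(placed, n_extra, c_extra, job.template.complex, seed)


def generate_ensemble(job: ModellingJob,
                      restraints: list[DistanceRestraint] | None = None,
                      failures: list[ModelFailure] | None = None,
                      max_steps: int = 200) -> list[ConformerModel]:
    """Build, minimize and rank an ensemble of ``job.n_models`` conformers.

    Model i uses seed ``job.seed + i``; all stochastic draws of a model flow
    from that one generator, so identical jobs reproduce identical
    ensembles. A failing model is recorded (in ``failures`` when supplied)
    without aborting the ensemble. Models are returned ranked ascending by
    pseudo-energy (rank 1 = lowest).
    """
    correspondence = job.correspondence or align_peptide_to_template(
        job.peptide_seq, job.core,
        job.template.complex.peptide_seq, job.template.structural_core)
    if restraints is None:
        restraints = derive_restraints(job.template, correspondence, sd=job.sd)

    receptor_chains = {cid: [r.copy() for r in residues]
                       for cid, residues in job.template.complex.chains.items()
                       if cid != "P"}
    models: list[ConformerModel] = []
    for i in range(job.n_models):
        seed_i = job.seed + i
        try:
            pep, flagged = _build_target_peptide(job, correspondence, seed_i)
            cpx = PMHCComplex(
                pdb_id=f"model_{seed_i}", mhc_class=job.template.complex.mhc_class,
                chains={**{cid: [r.copy() for r in res]
                           for cid, res in receptor_chains.items()},
                        "P": pep},
                peptide_seq=job.peptide_seq,
                resolution=None)
            relaxed, bd, trace = minimize_model(cpx, restraints, job.mode, job.core,
                                                max_steps=max_steps)
            models.append(ConformerModel(relaxed, bd.total, rank=0, seed_used=seed_i,
                                         breakdown=bd, flagged=flagged,
                                         energy_trace=trace))
        except PmhckitError as exc:
            logger.warning("model seed %d failed: %s", seed_i, exc)
            if failures is not None:
                failures.append(ModelFailure(seed_i, str(exc)))
    models.sort(key=lambda m: (m.pseudo_energy, m.seed_used))
    for rank, m in enumerate(models, start=1):
        m.rank = rank
    return models


def write_ensemble(models: list[ConformerModel], outdir: str | Path,
                   *, keep_b2m: bool = True) -> None:
    """Write ``model_1.pdb .. model_N.pdb`` (by rank) plus ``ranking.tsv``."""
    from .structure_io import write_structure
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for m in models:
        fname = f"model_{m.rank}.pdb"
        write_structure(m.complex, outdir / fname, keep_b2m=keep_b2m)
        rows.append((m.rank, fname, m.pseudo_energy, m.breakdown.bonded,
                     m.breakdown.clash, m.breakdown.restraint, int(m.flagged)))
    with open(outdir / "ranking.tsv", "w") as fh:
        fh.write("rank\tfile\tpseudo_energy\tbonded\tclash\trestraint\tflagged\n")
        for row in rows:
            fh.write("\t".join(f"{v:.4f}" if isinstance(v, float) else str(v)
                               for v in row) + "\n")
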