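"""Reading, standardizing, filtering and writing pMHC structures.

The template-set conventions implemented here: the MHC class II α chain is
renamed "M" and the β chain "N"; for class I the heavy chain is "M" and
β2-microglobulin "B"; the peptide is always chain "P" and renumbered 1..L.
Template candidates are kept only when the peptide is 7–25 residues long,
no DM-chaperone chain is present and the peptide is not CLIP (both detected
by configurable sequence signatures).

PDB/mmCIF parsing and PDB writing are delegated to :mod:`gemmi`; this module
owns the standardization and filtering semantics on top of it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path

import gemmi
import numpy as np

from .anchors import BindingCore, core_from_structure
from .errors import (
    EmptyStructureError,
    PmhckitError,
    StandardizationError,
    StructureParseError,
)
from .residues import load_json_data, three_to_one

PEPTIDE_MIN_LEN = 7
PEPTIDE_MAX_LEN = 25
BACKBONE_ATOMS = ("N", "CA", "C", "O")

#: chains at most this long are peptide candidates; at least MHC_MIN_LEN
#: residues marks an MHC domain chain
PEPTIDE_CHAIN_MAX = 30
MHC_MIN_LEN = 70


class MHCClass(Enum):
    I = "I"
    II = "II"


@dataclass
class AtomRecord:
    """One heavy atom: label, element symbol and Cartesian coordinate (Å)."""

    name: str
    element: str
    coord: np.ndarray

    def __post_init__(self):
        self.coord = np.asarray(self.coord, dtype=float)
        if not self.name:
            raise ValueError("atom name must be non-empty")
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise ValueError(f"atom {self.name}: coordinate must be a finite 3-vector")

    def copy(self) -> "AtomRecord":
        return AtomRecord(self.name, self.element, self.coord.copy())


@dataclass
class ResidueRecord:
    resname: str
    seqnum: int
    atoms: list[AtomRecord] = field(default_factory=list)

    def __post_init__(self):
        if self.seqnum < 1:
            raise ValueError("residue seqnum must be >= 1")
        names = [a.name for a in self.atoms]
        if len(names) != len(set(names)):
            raise ValueError(f"residue {self.resname}{self.seqnum}: duplicate atom names")

    def atom(self, name: str) -> AtomRecord | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def heavy_atoms(self) -> list[AtomRecord]:
        return [a for a in self.atoms if a.element.upper() not in ("H", "D")]

    def side_chain_atoms(self) -> list[AtomRecord]:
        return [a for a in self.heavy_atoms() if a.name not in BACKBONE_ATOMS]

    def backbone_coords(self) -> dict[str, np.ndarray]:
        return {a.name: a.coord for a in self.atoms if a.name in BACKBONE_ATOMS}

    def copy(self) -> "ResidueRecord":
        return ResidueRecord(self.resname, self.seqnum, [a.copy() for a in self.atoms])


@dataclass
class RawStructure:
    """Parsed but not yet standardized structure: chains of residues."""

    pdb_id: str
    chains: dict[str, list[ResidueRecord]]
    resolution: float | None = None

    def n_residues(self) -> int:
        return sum(len(r) for r in self.chains.values())


@dataclass
class PMHCComplex:
    """A standardized peptide-MHC complex (chains M/N/P or M[/B]/P)."""

    pdb_id: str
    mhc_class: MHCClass
    chains: dict[str, list[ResidueRecord]]
    alpha_allele: str = ""
    beta_allele: str = ""
    peptide_seq: str = ""
    resolution: float | None = None

    def peptide(self) -> list[ResidueRecord]:
        return self.chains["P"]

    def receptor_chain_ids(self) -> tuple[str, ...]:
        return ("M", "N") if self.mhc_class is MHCClass.II else ("M",)

    def chain_sequence(self, chain_id: str, *, strict: bool = False) -> str:
        return "".join(three_to_one(r.resname, strict=strict)
                       for r in self.chains[chain_id])

    def copy(self) -> "PMHCComplex":
        return PMHCComplex(
            self.pdb_id, self.mhc_class,
            {cid: [r.copy() for r in residues] for cid, residues in self.chains.items()},
            self.alpha_allele, self.beta_allele, self.peptide_seq, self.resolution,
        )

    def validate(self) -> None:
        required = {"M", "N", "P"} if self.mhc_class is MHCClass.II else {"M", "P"}
        if not required.issubset(self.chains):
            raise StandardizationError(
                f"{self.pdb_id}: chains {sorted(self.chains)} do not include {sorted(required)}")
        pep = self.peptide()
        if len(self.peptide_seq) != len(pep):
            raise StandardizationError(f"{self.pdb_id}: peptide_seq length mismatch")
        if [r.seqnum for r in pep] != list(range(1, len(pep) + 1)):
            raise StandardizationError(f"{self.pdb_id}: peptide numbering not contiguous 1..L")


@dataclass
class TemplateRecord:
    """One entry of the curated template set: a standardized complex plus the
    binding core observed in its structure.

    ``structural_core`` is ``None`` for peptides shorter than 9 residues
    (7- and 8-mers pass the template-set length filter but cannot hold a
    full 9-mer core); such templates are retained in the database but
    skipped by core-anchored template ranking.
    """

    complex: PMHCComplex
    structural_core: BindingCore | None
    source_path: str = ""

    @property
    def pdb_id(self) -> str:
        return self.complex.pdb_id

    @property
    def resolution(self) -> float | None:
        return self.complex.resolution

    def __post_init__(self):
        if self.structural_core is not None:
            self.structural_core.validate_for(len(self.complex.peptide()))


# ---------------------------------------------------------------------------
# reading

def _collapse_altlocs(res: gemmi.Residue) -> list[gemmi.Atom]:
    """Keep one atom per name: highest occupancy, ties by altloc label order."""
    by_name: dict[str, list[gemmi.Atom]] = {}
    for at in res:
        by_name.setdefault(at.name, []).append(at)
    kept = []
    for name, variants in by_name.items():
        variants.sort(key=lambda a: (-a.occ, a.altloc))
        kept.append(variants[0])
    return kept


def read_structure(path: str | Path, fmt: str = "auto") -> RawStructure:
    """Read a PDB or mmCIF file into a :class:`RawStructure`.

    Waters, hydrogens and non-polymer hetero groups (anything without a CA
    atom) are dropped; alternate locations are collapsed to the highest
    occupancy. Chain order follows the file.
    """
    path = Path(path)
    if not path.exists():
        raise StructureParseError(f"no such file: {path}")
    coor_fmt = {"auto": gemmi.CoorFormat.Detect,
                "pdb": gemmi.CoorFormat.Pdb,
                "mmcif": gemmi.CoorFormat.Mmcif}.get(fmt)
    if coor_fmt is None:
        raise ValueError(f"fmt must be pdb|mmcif|auto, got {fmt!r}")
    try:
        st = gemmi.read_structure(str(path), format=coor_fmt)
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"{path}: {exc}") from exc
    st.setup_entities()
    if len(st) == 0:
        raise EmptyStructureError(f"{path}: no models in file")
    model = st[0]
    chains: dict[str, list[ResidueRecord]] = {}
    for chain in model:
        residues: list[ResidueRecord] = []
        seq = 1
        for res in chain:
            if res.name in ("HOH", "DOD"):
                continue
            atoms = [a for a in _collapse_altlocs(res)
                     if a.element.name.upper() not in ("H", "D")]
            if not any(a.name == "CA" for a in atoms):
                continue  # ligand / sugar / ion: removed
            rec = ResidueRecord(res.name, seq, [
                AtomRecord(a.name, a.element.name, np.array([a.pos.x, a.pos.y, a.pos.z]))
                for a in atoms])
            residues.append(rec)
            seq += 1
        if residues:
            chains[chain.name] = residues
    if not chains:
        raise EmptyStructureError(f"{path}: no protein chains found")
    resolution = st.resolution if st.resolution and st.resolution > 0 else None
    return RawStructure(pdb_id=st.name or path.stem, chains=chains, resolution=resolution)


# ---------------------------------------------------------------------------
# standardization

def _renumber(residues: list[ResidueRecord]) -> list[ResidueRecord]:
    return [ResidueRecord(r.resname, i + 1, [a.copy() for a in r.atoms])
            for i, r in enumerate(residues)]


def standardize_chains(raw: RawStructure | PMHCComplex, mhc_class: MHCClass) -> PMHCComplex:
    """Assign chains to the M/N/P (class II) or M[/B]/P (class I) convention.

    Class II: exactly two chains of MHC-domain length (>= 70 residues) and one
    short chain (<= 30). The α chain is the first long chain in file order
    unless chains are already named M/N. Idempotent on standardized input.
    """
    if isinstance(raw, PMHCComplex):
        raw = RawStructure(raw.pdb_id, raw.chains, raw.resolution)
    long_ids = [cid for cid, res in raw.chains.items() if len(res) >= MHC_MIN_LEN]
    short_ids = [cid for cid, res in raw.chains.items() if len(res) <= PEPTIDE_CHAIN_MAX]
    if len(short_ids) != 1:
        raise StandardizationError(
            f"{raw.pdb_id}: expected exactly one peptide-length chain "
            f"(<= {PEPTIDE_CHAIN_MAX} residues), candidates: {short_ids or 'none'}")
    pep_id = short_ids[0]

    mapping: dict[str, str] = {}
    if mhc_class is MHCClass.II:
        if len(long_ids) != 2:
            raise StandardizationError(
                f"{raw.pdb_id}: class II needs exactly two MHC chains "
                f"(>= {MHC_MIN_LEN} residues), candidates: {long_ids}")
        if set(long_ids) == {"M", "N"}:
            mapping["M"], mapping["N"] = "M", "N"
        else:
            mapping[long_ids[0]], mapping[long_ids[1]] = "M", "N"
    else:
        if not 1 <= len(long_ids) <= 2:
            raise StandardizationError(
                f"{raw.pdb_id}: class I needs one heavy chain and optionally "
                f"β2m, candidates: {long_ids}")
        if set(long_ids) == {"M", "B"} or long_ids == ["M"]:
            for cid in long_ids:
                mapping[cid] = cid
        else:
            # heavy chain is the longer one; the other (~100 residues) is β2m
            ordered = sorted(long_ids, key=lambda c: -len(raw.chains[c]))
            mapping[ordered[0]] = "M"
            if len(ordered) == 2:
                mapping[ordered[1]] = "B"
    mapping[pep_id] = "P"

    leftovers = [cid for cid in raw.chains if cid not in mapping]
    if leftovers:
        raise StandardizationError(
            f"{raw.pdb_id}: unassignable chains {leftovers} "
            f"(lengths {[len(raw.chains[c]) for c in leftovers]})")

    chains = {}
    for old, new in mapping.items():
        residues = raw.chains[old]
        chains[new] = _renumber(residues) if new == "P" else [r.copy() for r in residues]
    pep_seq = "".join(three_to_one(r.resname, strict=True) for r in chains["P"])
    out = PMHCComplex(raw.pdb_id, mhc_class, chains, peptide_seq=pep_seq,
                      resolution=raw.resolution)
    out.validate()
    return out


# ---------------------------------------------------------------------------
# filtering

def _default_dm_signatures() -> dict:
    data = load_json_data("dm_signatures_synthetic.json")
    return {"alpha": data["alpha"], "beta": data["beta"]}


def _default_clip() -> list[str]:
    return list(load_json_data("clip_peptides.json")["cores"])


def filter_template_candidates(
    candidates: list[PMHCComplex],
    *,
    dm_signatures: dict | None = None,
    clip_sequences: list[str] | None = None,
    contact_cutoff: float = 5.0,
) -> tuple[list[TemplateRecord], list[tuple[str, str]]]:
    """Apply the template-set filters and derive each survivor's structural
    binding core.

    Kept: peptide length within [7, 25], no chain carrying a DM-chaperone
    sequence signature, peptide not matching a CLIP sequence. Never raises;
    every rejection carries a machine-readable reason code
    (``peptide_length`` / ``dm_chaperone`` / ``clip_peptide`` /
    ``core_detection_failed``).
    """
    if dm_signatures is None:
        dm_signatures = _default_dm_signatures()
    if clip_sequences is None:
        clip_sequences = _default_clip()
    dm_all = list(dm_signatures.get("alpha", [])) + list(dm_signatures.get("beta", []))

    kept: list[TemplateRecord] = []
    rejected: list[tuple[str, str]] = []
    for cand in candidates:
        pep_len = len(cand.peptide())
        if not PEPTIDE_MIN_LEN <= pep_len <= PEPTIDE_MAX_LEN:
            rejected.append((cand.pdb_id, "peptide_length"))
            continue
        chain_seqs = [cand.chain_sequence(cid) for cid in cand.chains if cid != "P"]
        if any(sig in seq for sig in dm_all for seq in chain_seqs):
            rejected.append((cand.pdb_id, "dm_chaperone"))
            continue
        if any(clip in cand.peptide_seq or cand.peptide_seq in clip
               for clip in clip_sequences):
            rejected.append((cand.pdb_id, "clip_peptide"))
            continue
        if pep_len < 9:
            kept.append(TemplateRecord(cand, None))  # no 9-mer core possible
            continue
        try:
            core = core_from_structure(cand, cutoff=contact_cutoff)
        except PmhckitError:
            rejected.append((cand.pdb_id, "core_detection_failed"))
            continue
        kept.append(TemplateRecord(cand, core))
    return kept, rejected


# ---------------------------------------------------------------------------
# writing

def to_gemmi(complex: PMHCComplex, *, keep_b2m: bool = True) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = complex.pdb_id
    model = gemmi.Model("1")
    for cid, residues in complex.chains.items():
        if cid == "B" and not keep_b2m:
            continue
        chain = gemmi.Chain(cid)
        for res in residues:
            g = gemmi.Residue()
            g.name = res.resname
            g.seqid = gemmi.SeqId(res.seqnum, " ")
            for at in res.atoms:
                ga = gemmi.Atom()
                ga.name = at.name
                ga.element = gemmi.Element(at.element)
                ga.pos = gemmi.Position(*at.coord)
                ga.occ = 1.0
                g.add_atom(ga)
            chain.add_residue(g)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    return st


def write_structure(complex: PMHCComplex, path: str | Path, *, keep_b2m: bool = True) -> None:
    """Write a standardized complex as a PDB file (chain B dropped when
    ``keep_b2m`` is false)."""
    path = Path(path)
    try:
        to_gemmi(complex, keep_b2m=keep_b2m).write_pdb(str(path))
    except OSError as exc:
        raise StructureParseError(f"cannot write {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# template database: directory of standardized PDBs + one JSON index

INDEX_NAME = "index.json"


def save_template_db(records: list[TemplateRecord], directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    index = []
    for rec in records:
        fname = f"{rec.pdb_id}.pdb"
        write_structure(rec.complex, directory / fname)
        index.append({
            "pdb_id": rec.pdb_id,
            "file": fname,
            "alpha_allele": rec.complex.alpha_allele,
            "beta_allele": rec.complex.beta_allele,
            "peptide_seq": rec.complex.peptide_seq,
            "core_start": None if rec.structural_core is None else rec.structural_core.start,
            "resolution": rec.complex.resolution,
            "mhc_class": rec.complex.mhc_class.value,
        })
    with open(directory / INDEX_NAME, "w") as fh:
        json.dump(index, fh, indent=1)


def load_template_db(directory: str | Path) -> list[TemplateRecord]:
    directory = Path(directory)
    with open(directory / INDEX_NAME) as fh:
        index = json.load(fh)
    records = []
    for entry in index:
        raw = read_structure(directory / entry["file"], fmt="pdb")
        cls = MHCClass(entry.get("mhc_class", "II"))
        cpx = standardize_chains(raw, cls)
        cpx = replace(cpx, pdb_id=entry["pdb_id"],
                      alpha_allele=entry.get("alpha_allele", ""),
                      beta_allele=entry.get("beta_allele", ""),
                      resolution=entry.get("resolution"))
        start = entry.get("core_start")
        core = None if start is None else BindingCore(start, len(cpx.peptide()))
        records.append(TemplateRecord(cpx, core, source_path=str(directory / entry["file"])))
    return records
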