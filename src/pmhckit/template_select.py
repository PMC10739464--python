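"""Template selection: MHC identity ranking refined by core-anchored
peptide alignment.

Candidates are first ranked by MHC sequence identity to the target α and β
chains (aggregated as their mean by default); candidates tied on identity
are reordered by a PAM30 peptide alignment score in which the two 9-mer
binding cores are forced into ungapped column-to-column register and the
flanks are paired outward from the core boundary, the shorter flank padded
with terminal gaps. Gap columns score 0, so flank-length differences are
neutral. The final tie-break is resolution (ascending, unknown last), then
template id, making the ranking total and deterministic.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path

from .anchors import CORE_LENGTH, BindingCore
from .errors import CoreError, SelectionError
from .sequence_db import SubstitutionMatrix, global_align, load_matrix
from .structure_io import TemplateRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CoreAlignment:
    """Column pairing between a target peptide and a template peptide.

    ``offset_map`` maps every target peptide position (0-based) to the
    template position it is paired with, or ``None`` for a gap column. Core
    position i of the target always maps to core position i of the template.
    """

    offset_map: dict[int, int | None]
    score: int


@dataclass(frozen=True)
class RankEntry:
    template_id: str
    alpha_identity_pct: float
    beta_identity_pct: float
    combined_identity: float
    peptide_score: int
    resolution: float | None = None


@dataclass
class TemplateRanking:
    entries: list[RankEntry] = field(default_factory=list)

    def best(self) -> RankEntry:
        return self.entries[0]

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t")
            w.writerow(["template_id", "alpha_id_pct", "beta_id_pct",
                        "combined_identity", "peptide_score", "selected"])
            for i, e in enumerate(self.entries):
                w.writerow([e.template_id, f"{e.alpha_identity_pct:.2f}",
                            f"{e.beta_identity_pct:.2f}", f"{e.combined_identity:.2f}",
                            e.peptide_score, int(i == 0)])


def align_peptide_to_template(target_pep: str, target_core: BindingCore,
                              template_pep: str, template_core: BindingCore,
                              matrix: SubstitutionMatrix | None = None) -> CoreAlignment:
    """Core-anchored peptide alignment.

    The 9 core columns are paired ungapped; flanking residues pair outward
    from the core boundaries position-by-position; whichever flank is
    shorter leaves terminal gap columns on its side. The score sums PAM30
    over residue-residue columns; gap columns contribute 0.
    """
    target_core.validate_for(len(target_pep))
    template_core.validate_for(len(template_pep))
    if CORE_LENGTH != 9:  # pragma: no cover - structural constant
        raise CoreError("binding cores must be 9-mers")
    if matrix is None:
        matrix = load_matrix("PAM30")

    offset_map: dict[int, int | None] = {}
    score = 0
    # core columns, ungapped
    for i in range(CORE_LENGTH):
        q, t = target_core.start + i, template_core.start + i
        offset_map[q] = t
        score += matrix.score(target_pep[q], template_pep[t])
    # N-terminal flank, walking outward (leftward) from the core boundary
    for j in range(1, target_core.start + 1):
        q = target_core.start - j
        t = template_core.start - j
        if t >= 0:
            offset_map[q] = t
            score += matrix.score(target_pep[q], template_pep[t])
        else:
            offset_map[q] = None  # terminal gap on the template side
    # C-terminal flank, walking outward (rightward)
    for j in range(len(target_pep) - target_core.end):
        q = target_core.end + j
        t = template_core.end + j
        if t < len(template_pep):
            offset_map[q] = t
            score += matrix.score(target_pep[q], template_pep[t])
        else:
            offset_map[q] = None
    return CoreAlignment(offset_map, score)


def _aggregate(alpha_id: float, beta_id: float, how: str) -> float:
    if how == "mean":
        return (alpha_id + beta_id) / 2.0
    if how == "min":
        return min(alpha_id, beta_id)
    raise SelectionError(f"unknown identity aggregation {how!r}")


def rank_templates(alpha_seq: str, beta_seq: str, target_pep: str,
                   target_core: BindingCore, templates: list[TemplateRecord],
                   *, aggregate: str = "mean", identity_tol: float = 0.0,
                   exclude_ids: tuple[str, ...] = (),
                   matrix: SubstitutionMatrix | None = None) -> TemplateRanking:
    """Rank the template set for one modelling target.

    Primary key: combined MHC identity (descending). Within groups tied on
    the primary key (to within ``identity_tol``), peptide alignment score
    decides (descending); remaining ties fall back to resolution (ascending,
    missing last) then template id. ``exclude_ids`` supports leave-one-out
    benchmarking.
    """
    pool = [t for t in templates if t.pdb_id not in exclude_ids]
    coreless = [t.pdb_id for t in pool if t.structural_core is None]
    if coreless:
        logger.info("skipping template(s) without a structural core: %s", coreless)
        pool = [t for t in pool if t.structural_core is not None]
    if not pool:
        raise SelectionError("template set is empty (after exclusions)")
    pep_matrix = matrix or load_matrix("PAM30")
    blosum = load_matrix("BLOSUM62")

    entries = []
    for tmpl in pool:
        cpx = tmpl.complex
        a_id = global_align(alpha_seq, cpx.chain_sequence("M"), blosum).identity_pct
        b_chain = "N" if "N" in cpx.chains else "M"
        b_id = global_align(beta_seq, cpx.chain_sequence(b_chain), blosum).identity_pct
        pep_score = align_peptide_to_template(
            target_pep, target_core, cpx.peptide_seq, tmpl.structural_core,
            pep_matrix).score
        entries.append(RankEntry(tmpl.pdb_id, a_id, b_id,
                                 _aggregate(a_id, b_id, aggregate), pep_score,
                                 tmpl.resolution))

    entries.sort(key=lambda e: (-e.combined_identity, e.template_id))
    # group by primary key within tolerance, then refine each group
    ordered: list[RankEntry] = []
    i = 0
    while i < len(entries):
        leader = entries[i].combined_identity
        j = i
        while j < len(entries) and leader - entries[j].combined_identity <= identity_tol:
            j += 1
        group = sorted(entries[i:j], key=lambda e: (
            -e.peptide_score,
            e.resolution if e.resolution is not None else float("inf"),
            e.template_id))
        ordered.extend(group)
        i = j
    return TemplateRanking(ordered)


def select_template(alpha_seq: str, beta_seq: str, target_pep: str,
                    target_core: BindingCore, templates: list[TemplateRecord],
                    **kwargs) -> TemplateRecord:
    """Return the highest-ranking template (pan-allele: the best-identity
    template is returned even when no template shares either allele)."""
    ranking = rank_templates(alpha_seq, beta_seq, target_pep, target_core,
                             templates, **kwargs)
    for e in ranking.entries:
        logger.info("template ranking: %s combined=%.2f pep=%d",
                    e.template_id, e.combined_identity, e.peptide_score)
    best_id = ranking.best().template_id
    return next(t for t in templates if t.pdb_id == best_id)
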