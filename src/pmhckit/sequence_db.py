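"""Reference sequence sets, substitution matrices and global alignment.

Template selection and allele-name assignment both reduce to ranking
pairwise sequence identities. MHC chains are globally homologous end to
end, so a Needleman–Wunsch global alignment with affine gaps (Gotoh's
algorithm) over BLOSUM62 with BLAST-like protein gap costs (open 11,
extend 1; a gap of length L costs open + L·extend) is used as the ranking
engine. Peptide scoring elsewhere uses PAM30, appropriate for short,
closely related sequences.

Matrices are packaged in NCBI format and parsed by :func:`load_matrix`;
`PAM30` and `BLOSUM62` are the canonical published tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

from .errors import AlphabetError, ConfigurationError
from .residues import CANONICAL_LETTERS, data_path

ALPHABET = "".join(sorted(CANONICAL_LETTERS)) + "X"

# BLAST protein defaults, used for MHC chain identity ranking
DEFAULT_GAP_OPEN = 11
DEFAULT_GAP_EXTEND = 1


@dataclass(frozen=True)
class SequenceRecord:
    """An identified protein sequence (an allele or a template chain)."""

    id: str
    seq: str

    def __post_init__(self):
        if not self.seq:
            raise ConfigurationError(f"sequence {self.id!r} is empty")
        bad = set(self.seq.upper()) - set(ALPHABET)
        if bad:
            raise AlphabetError(
                f"sequence {self.id!r} contains letters outside the 20 canonical "
                f"amino acids + X: {sorted(bad)}")


class SubstitutionMatrix:
    """Symmetric integer substitution scores over the protein alphabet."""

    def __init__(self, name: str, scores: dict[tuple[str, str], int]):
        self.name = name
        self.scores = scores
        letters = sorted({a for a, _ in scores})
        for a in letters:
            for b in letters:
                if scores.get((a, b)) != scores.get((b, a)):
                    raise ValueError(f"{name}: asymmetric entry for ({a}, {b})")
        self.letters = letters
        self._index = {a: i for i, a in enumerate(letters)}
        n = len(letters)
        self._array = np.zeros((n, n), dtype=np.int64)
        for (a, b), s in scores.items():
            self._array[self._index[a], self._index[b]] = s

    def score(self, a: str, b: str) -> int:
        try:
            return int(self._array[self._index[a.upper()], self._index[b.upper()]])
        except KeyError:
            bad = a if a.upper() not in self._index else b
            raise AlphabetError(
                f"letter {bad!r} is not in the {self.name} alphabet") from None

    def encode(self, seq: str) -> np.ndarray:
        try:
            return np.array([self._index[c] for c in seq.upper()], dtype=np.intp)
        except KeyError as exc:
            raise AlphabetError(
                f"letter {exc.args[0]!r} is not in the {self.name} alphabet") from None

    @property
    def array(self) -> np.ndarray:
        return self._array


def parse_ncbi_matrix(text: str, name: str = "custom") -> SubstitutionMatrix:
    """Parse a substitution matrix in NCBI format (column header line then
    one labelled row per letter; ``#`` comments ignored)."""
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.lstrip().startswith("#")]
    header = lines[0].split()
    scores: dict[tuple[str, str], int] = {}
    for ln in lines[1:]:
        parts = ln.split()
        row = parts[0]
        values = parts[1:]
        if len(values) != len(header):
            raise ValueError(f"{name}: row {row!r} has {len(values)} values, "
                             f"expected {len(header)}")
        for col, v in zip(header, values):
            scores[(row, col)] = int(v)
    return SubstitutionMatrix(name, scores)


@lru_cache(maxsize=8)
def load_matrix(name: str) -> SubstitutionMatrix:
    """Load a packaged matrix by name (``PAM30``, ``BLOSUM62``) or any
    NCBI-format matrix file by path."""
    packaged = data_path(f"{name}.txt")
    if packaged.is_file():
        return parse_ncbi_matrix(packaged.read_text(), name)
    p = Path(name)
    if p.exists():
        return parse_ncbi_matrix(p.read_text(), p.stem)
    raise ConfigurationError(f"unknown substitution matrix {name!r}")


def substitution_score(matrix: SubstitutionMatrix, a: str, b: str) -> int:
    """Symmetric matrix lookup for a single residue pair."""
    return matrix.score(a, b)


@dataclass(frozen=True)
class AlignmentResult:
    """A global pairwise alignment: score, gapped strings, percent identity
    over aligned columns."""

    score: int
    aligned_a: str
    aligned_b: str
    identity_pct: float

    def __post_init__(self):
        assert len(self.aligned_a) == len(self.aligned_b)


def _identity_pct(aligned_a: str, aligned_b: str) -> float:
    cols = [(a, b) for a, b in zip(aligned_a, aligned_b) if not (a == "-" and b == "-")]
    if not cols:
        return 0.0
    matches = sum(1 for a, b in cols if a == b and a != "-")
    return 100.0 * matches / len(cols)


def global_align(a: str, b: str, matrix: SubstitutionMatrix | None = None,
                 gap_open: int = DEFAULT_GAP_OPEN,
                 gap_extend: int = DEFAULT_GAP_EXTEND) -> AlignmentResult:
    """Optimal global alignment with affine gaps (Gotoh).

    Gap cost convention: a gap run of length L costs ``gap_open +
    L * gap_extend`` (BLAST-style). Traceback ties resolve deterministically
    preferring match/mismatch, then a gap in ``b``, then a gap in ``a``.
    Identity is computed over aligned columns (double-gap columns cannot
    occur in a pairwise optimal alignment).
    """
    if not a or not b:
        raise ConfigurationError("global_align requires two non-empty sequences")
    if matrix is None:
        matrix = load_matrix("BLOSUM62")
    ea, eb = matrix.encode(a), matrix.encode(b)
    m, n = len(ea), len(eb)
    NEG = np.int64(-(10 ** 12))
    go, ge = int(gap_open), int(gap_extend)

    M = np.full((m + 1, n + 1), NEG, dtype=np.int64)   # a[i-1] aligned to b[j-1]
    Ix = np.full((m + 1, n + 1), NEG, dtype=np.int64)  # gap in b (vertical)
    Iy = np.full((m + 1, n + 1), NEG, dtype=np.int64)  # gap in a (horizontal)
    M[0, 0] = 0
    for i in range(1, m + 1):
        Ix[i, 0] = -(go + i * ge)
    for j in range(1, n + 1):
        Iy[0, j] = -(go + j * ge)

    S = matrix.array
    for i in range(1, m + 1):
        sub = S[ea[i - 1], eb]  # scores vs all of b
        best_prev = np.maximum(np.maximum(M[i - 1, :-1], Ix[i - 1, :-1]), Iy[i - 1, :-1])
        M[i, 1:] = best_prev + sub
        # vertical gaps may open from M or Iy, or extend Ix (row i-1 only)
        Ix[i, :] = np.maximum(
            np.maximum(M[i - 1, :] - (go + ge), Iy[i - 1, :] - (go + ge)),
            Ix[i - 1, :] - ge)
        # horizontal pass is sequential within the row
        row_m, row_ix, row_iy = M[i], Ix[i], Iy[i]
        for j in range(1, n + 1):
            row_iy[j] = max(row_m[j - 1] - (go + ge), row_ix[j - 1] - (go + ge),
                            row_iy[j - 1] - ge)

    # deterministic traceback: ties prefer M, then Ix (gap in b), then Iy
    i, j = m, n
    state = int(np.argmax([M[i, j], Ix[i, j], Iy[i, j]]))
    score = int(max(M[i, j], Ix[i, j], Iy[i, j]))
    out_a: list[str] = []
    out_b: list[str] = []
    while i > 0 or j > 0:
        if state == 0:
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            target = M[i, j] - S[ea[i - 1], eb[j - 1]]
            i, j = i - 1, j - 1
            state = next(s for s, v in enumerate((M[i, j], Ix[i, j], Iy[i, j]))
                         if v == target)
        elif state == 1:
            out_a.append(a[i - 1])
            out_b.append("-")
            val = Ix[i, j]
            i -= 1
            state = next(s for s, v in enumerate(
                (M[i, j] - (go + ge), Ix[i, j] - ge, Iy[i, j] - (go + ge)))
                if v == val)
        else:
            out_a.append("-")
            out_b.append(b[j - 1])
            val = Iy[i, j]
            j -= 1
            state = next(s for s, v in enumerate(
                (M[i, j] - (go + ge), Ix[i, j] - (go + ge), Iy[i, j] - ge))
                if v == val)
    aligned_a = "".join(reversed(out_a))
    aligned_b = "".join(reversed(out_b))
    return AlignmentResult(score, aligned_a, aligned_b,
                           _identity_pct(aligned_a, aligned_b))


def identity_between(a: str, b: str, matrix: SubstitutionMatrix | None = None) -> float:
    return global_align(a, b, matrix).identity_pct


def assign_allele_name(mhc_seq: str, reference: list[SequenceRecord],
                       matrix: SubstitutionMatrix | None = None) -> tuple[str, float]:
    """Name an MHC chain by its closest reference allele.

    Returns the reference id with the highest global-alignment identity to
    ``mhc_seq``; exact ties resolve lexicographically by id.
    """
    if not reference:
        raise ConfigurationError("reference allele set is empty")
    if matrix is None:
        matrix = load_matrix("BLOSUM62")
    best: tuple[float, str] | None = None
    for rec in sorted(reference, key=lambda r: r.id):
        ident = global_align(mhc_seq, rec.seq, matrix).identity_pct
        if best is None or ident > best[0]:
            best = (ident, rec.id)
    return best[1], best[0]


# ---------------------------------------------------------------------------
# FASTA IO (Biopython-backed)

def read_fasta(path: str | Path) -> list[SequenceRecord]:
    return [SequenceRecord(rec.id, str(rec.seq).upper())
            for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(records: list[SequenceRecord], path: str | Path) -> None:
    SeqIO.write([_BioSeqRecord(Seq(r.seq), id=r.id, description="") for r in records],
                str(path), "fasta")


def packaged_reference_alleles() -> list[SequenceRecord]:
    """The small packaged synthetic reference allele set (a stand-in for a
    curated allele database, sufficient for exercising name assignment)."""
    return read_fasta(data_path("reference_alleles_synthetic.fasta"))
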