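"""Independent brute-force oracles used by the tests.

Each oracle deliberately takes a different computational route than the
library (explicit enumeration, double loops, parameterized rotation
search) so agreement is evidence of correctness, not tautology.
"""

import itertools

import numpy as np
from scipy.optimize import minimize as scipy_minimize
from scipy.spatial.transform import Rotation

BACKBONE = ("N", "CA", "C", "O")


def brute_force_align_score(a: str, b: str, score_fn, gap_open: int, gap_extend: int) -> int:
    """Max score over *all* monotone gapped alignments of a and b, scoring a
    gap run of length L as gap_open + L * gap_extend."""
    best = [-(10 ** 9)]

    def rec(i, j, cols):
        if i == len(a) and j == len(b):
            score, run = 0, None
            for x, y in cols:
                if x == "-" or y == "-":
                    side = 0 if x == "-" else 1
                    if run != side:
                        score -= gap_open
                    run = side
                    score -= gap_extend
                else:
                    score += score_fn(x, y)
                    run = None
            best[0] = max(best[0], score)
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, cols + [(a[i], b[j])])
        if i < len(a):
            rec(i + 1, j, cols + [(a[i], "-")])
        if j < len(b):
            rec(i, j + 1, cols + [("-", b[j])])

    rec(0, 0, [])
    return best[0]


def naive_backbone_lrmsd(model, reference, core):
    """Double-loop peptide backbone L-RMSD windows, computed from scratch
    with plain Python arithmetic (no vectorized paths)."""
    core_res = set(p + 1 for p in core.core_positions())
    sums = {"core": [0.0, 0], "flank": [0.0, 0]}
    for rm, rr in zip(model.peptide(), reference.peptide()):
        assert rm.seqnum == rr.seqnum
        for name in BACKBONE:
            am, ar = rm.atom(name), rr.atom(name)
            if am is None or ar is None:
                continue
            d2 = 0.0
            for k in range(3):
                d2 += (float(am.coord[k]) - float(ar.coord[k])) ** 2
            key = "core" if rm.seqnum in core_res else "flank"
            sums[key][0] += d2
            sums[key][1] += 1
    sc, nc = sums["core"]
    sf, nf = sums["flank"]
    core_rmsd = (sc / nc) ** 0.5
    flank_rmsd = (sf / nf) ** 0.5 if nf else None
    whole = ((sc + sf) / (nc + nf)) ** 0.5
    return core_rmsd, flank_rmsd, whole


def brute_force_superpose_rmsd(mobile: np.ndarray, target: np.ndarray) -> float:
    """Best-fit RMSD by explicit search over rotations: a coarse random
    quaternion grid followed by simplex refinement of the rotation vector.
    Centering removes the translation analytically."""
    P = mobile - mobile.mean(axis=0)
    Q = target - target.mean(axis=0)

    def rmsd_of(rotvec):
        R = Rotation.from_rotvec(rotvec).as_matrix()
        return float(np.sqrt(np.mean(np.sum((P @ R.T - Q) ** 2, axis=1))))

    rng = np.random.default_rng(0)
    best_vec, best = np.zeros(3), rmsd_of(np.zeros(3))
    for q in rng.normal(size=(600, 4)):
        vec = Rotation.from_quat(q / np.linalg.norm(q)).as_rotvec()
        r = rmsd_of(vec)
        if r < best:
            best, best_vec = r, vec
    res = scipy_minimize(rmsd_of, best_vec, method="Nelder-Mead",
                         options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000})
    return float(res.fun)


def count_contacts(anchor_residues, receptor_atoms, cutoff):
    """Exhaustive O(n^2) heavy-atom contact count per anchor residue."""
    counts = []
    for res in anchor_residues:
        n = 0
        for a in res.heavy_atoms():
            for coord in receptor_atoms:
                d = sum((float(a.coord[k]) - float(coord[k])) ** 2 for k in range(3)) ** 0.5
                if d <= cutoff:
                    n += 1
        counts.append(n)
    return counts


def all_sequences(alphabet, max_len):
    for L in range(1, max_len + 1):
        for tup in itertools.product(alphabet, repeat=L):
            yield "".join(tup)
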