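"""Segmental-duplication evidence and a gene-conversion permutation scan.

Duplicated chromosomal blocks leave conserved flanking genes around a
paralog pair: all-vs-all Needleman–Wunsch global alignments (BLOSUM62,
affine gaps 10/0.5 — needle-style defaults) of the two flank sets are
reduced to reciprocal-best pairs, and a segmental duplication is called
when enough pairs clear identity/similarity thresholds.

Gene conversion between paralogs is detected GENECONV-style: the
alignment is condensed to its polymorphic columns, each sequence pair is
scored by its longest run of agreement across those columns (a mismatch
terminates a run; no mismatches are tolerated within a fragment), and
the null distribution of the per-permutation *maximum* pairwise run is
obtained by jointly permuting the polymorphic columns.  Pair p-values
are Bonferroni-corrected over pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations, permutations

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .alignment import CodonAlignment
from .errors import InputError

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


@dataclass(frozen=True)
class PairwiseAlignmentResult:
    id_a: str
    id_b: str
    identity: float      # percent over all alignment columns
    similarity: float    # percent of columns with identical or positive-scoring pairs
    score: float
    aligned_length: int


@dataclass(frozen=True)
class ConversionCall:
    id_a: str
    id_b: str
    fragment_score: int          # length in polymorphic sites
    tract_start: int             # original column span, 1-based inclusive
    tract_end: int
    p_sim: float
    p_corrected: float


def _aligner(matrix=None, gap_open: float = 10.0, gap_extend: float = 0.5) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = matrix if matrix is not None else _BLOSUM62
    aligner.open_gap_score = -abs(gap_open)
    aligner.extend_gap_score = -abs(gap_extend)
    return aligner


def global_align(
    a: str,
    b: str,
    *,
    id_a: str = "a",
    id_b: str = "b",
    matrix=None,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> PairwiseAlignmentResult:
    """Needleman–Wunsch global protein alignment with affine gaps.

    Identity and similarity are percentages over *all* alignment columns;
    gap columns count as neither identical nor similar.
    """
    if not a or not b:
        raise InputError("empty sequence")
    aligner = _aligner(matrix, gap_open, gap_extend)
    aln = aligner.align(a.upper(), b.upper())[0]
    sa, sb = str(aln[0]), str(aln[1])
    sub = aligner.substitution_matrix
    ncols = len(sa)
    ident = simil = 0
    for x, y in zip(sa, sb):
        if x == "-" or y == "-":
            continue
        if x == y:
            ident += 1
            simil += 1
        elif sub[x, y] > 0:
            simil += 1
    return PairwiseAlignmentResult(
        id_a=id_a, id_b=id_b,
        identity=100.0 * ident / ncols,
        similarity=100.0 * simil / ncols,
        score=float(aln.score),
        aligned_length=ncols,
    )


def flank_duplication_scan(
    flanks_a: list[tuple[str, str]],
    flanks_b: list[tuple[str, str]],
    *,
    min_pairs: int = 3,
    identity_min: float = 70.0,
    similarity_min: float = 85.0,
) -> dict:
    """Reciprocal-best matching of two flanking-gene protein sets.

    Inputs are (id, protein) lists (up to ~10 genes per side).  Returns
    the matched-pair table, the conserved pairs, and the boolean
    segmental-duplication call (conserved pairs >= ``min_pairs``).
    """
    if not flanks_a or not flanks_b:
        raise InputError("each flank set needs at least one protein")
    results = {}
    for ia, sa in flanks_a:
        for ib, sb in flanks_b:
            results[(ia, ib)] = global_align(sa, sb, id_a=ia, id_b=ib)
    best_for_a = {
        ia: max((r for (xa, _), r in results.items() if xa == ia), key=lambda r: r.score)
        for ia, _ in flanks_a
    }
    best_for_b = {
        ib: max((r for (_, xb), r in results.items() if xb == ib), key=lambda r: r.score)
        for ib, _ in flanks_b
    }
    reciprocal = [
        r for ia, r in best_for_a.items()
        if best_for_b[r.id_b].id_a == ia
    ]
    conserved = [
        r for r in reciprocal
        if r.identity >= identity_min and r.similarity >= similarity_min
    ]
    table = pd.DataFrame([
        {
            "gene1": r.id_a, "gene2": r.id_b, "identity": r.identity,
            "similar": r.similarity, "score": r.score,
            "conserved": r in conserved,
        }
        for r in sorted(reciprocal, key=lambda r: -r.score)
    ])
    return {
        "pairs": table,
        "n_conserved": len(conserved),
        "duplication_called": len(conserved) >= min_pairs,
    }


# --------------------------------------------------------------------
# gene-conversion scan
# --------------------------------------------------------------------


def _as_char_matrix(aln) -> tuple[list[str], np.ndarray]:
    if isinstance(aln, CodonAlignment):
        ids = aln.ids
        seqs = [r.cds for r in aln.rows]
    else:
        ids = [i for i, _ in aln]
        seqs = [s for _, s in aln]
    if len({len(s) for s in seqs}) != 1:
        raise InputError("sequences are not aligned")
    return ids, np.array([list(s.upper()) for s in seqs])


def _longest_runs(agree: np.ndarray) -> np.ndarray:
    """Longest run of True per row of a 2-D (or batched) boolean array."""
    run = np.zeros(agree.shape[:-1], dtype=np.int32)
    best = np.zeros_like(run)
    for j in range(agree.shape[-1]):
        run = np.where(agree[..., j], run + 1, 0)
        np.maximum(best, run, out=best)
    return best


def _run_location(agree_row: np.ndarray) -> tuple[int, int]:
    """(start, end) polymorphic-column indices of the longest True run."""
    best_len = best_end = cur = 0
    for j, a in enumerate(agree_row):
        cur = cur + 1 if a else 0
        if cur > best_len:
            best_len, best_end = cur, j
    return best_end - best_len + 1, best_end


def geneconv_scan(
    aln,
    n_perm: int = 10000,
    seed: int | None = None,
    *,
    alpha: float = 0.05,
    max_memory_perms: int = 512,
) -> list[ConversionCall]:
    """Permutation scan for gene-conversion tracts among aligned sequences.

    ``aln`` is a :class:`CodonAlignment` or a list of (id, sequence)
    pairs.  All column permutations are enumerated exhaustively when the
    number of polymorphic columns is small enough (n! <= n_perm);
    otherwise ``n_perm`` Monte-Carlo permutations are drawn.  Returns the
    calls with Bonferroni-corrected p <= ``alpha``.
    """
    if n_perm < 1:
        raise InputError("n_perm must be >= 1")
    ids, mat = _as_char_matrix(aln)
    n_seq = len(ids)
    if n_seq < 3:
        raise InputError("gene-conversion scan needs at least 3 sequences")
    # polymorphic columns: >= 2 distinct non-gap characters
    poly_mask = np.zeros(mat.shape[1], dtype=bool)
    for j in range(mat.shape[1]):
        col = mat[:, j]
        vals = set(col[col != "-"])
        poly_mask[j] = len(vals) >= 2
    poly_cols = np.flatnonzero(poly_mask)
    if poly_cols.size == 0:
        return []
    sub = mat[:, poly_cols]
    pairs = list(combinations(range(n_seq), 2))
    agree = np.stack([
        (sub[i] == sub[j]) & (sub[i] != "-") & (sub[j] != "-")
        for i, j in pairs
    ])  # n_pairs x n_poly
    obs = _longest_runs(agree)
    n_poly = agree.shape[1]

    exhaustive = n_poly <= 20 and math.factorial(n_poly) <= n_perm
    if exhaustive:
        perms = np.array(list(permutations(range(n_poly))))
    else:
        rng = np.random.default_rng(seed)
        perms = np.array([rng.permutation(n_poly) for _ in range(n_perm)])
    null_max = np.empty(len(perms), dtype=np.int32)
    for lo in range(0, len(perms), max_memory_perms):
        chunk = perms[lo: lo + max_memory_perms]
        batch = agree[:, chunk]          # n_pairs x chunk x n_poly
        batch = np.swapaxes(batch, 0, 1)  # chunk x n_pairs x n_poly
        null_max[lo: lo + len(chunk)] = _longest_runs(batch).max(axis=1)

    n_pairs = len(pairs)
    calls = []
    for k, (i, j) in enumerate(pairs):
        exceed = int((null_max >= obs[k]).sum())
        if exhaustive:
            p = exceed / len(perms)
        else:
            p = (1 + exceed) / (len(perms) + 1)
        p_corr = min(1.0, p * n_pairs)
        if p_corr <= alpha and obs[k] >= 1:
            s, e = _run_location(agree[k])
            calls.append(ConversionCall(
                id_a=ids[i], id_b=ids[j],
                fragment_score=int(obs[k]),
                tract_start=int(poly_cols[s]) + 1,
                tract_end=int(poly_cols[e]) + 1,
                p_sim=p, p_corrected=p_corr,
            ))
    return sorted(calls, key=lambda c: c.p_corrected)
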