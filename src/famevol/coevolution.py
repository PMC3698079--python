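"""Mirror-tree co-evolution test between protein regions.

Two regions that evolve under shared constraints (the mirror-tree idea)
produce correlated pairwise-distance matrices.  The statistic is the
Pearson correlation over the n(n-1)/2 upper-triangle entries; inference
is by a one-tailed-upper Mantel permutation test that jointly permutes
the rows and columns of one matrix.  Both the "linear" and the "Mantel"
correlation are the same statistic on the same vectorization here; they
differ only in how a p-value is attached.

When the number of labels is small enough that all n! permutations fit
inside ``n_perm``, the null is enumerated exhaustively and the p-value is
exact; otherwise Monte-Carlo sampling with the (1 + k) / (n_perm + 1)
convention is used.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from .alignment import CodonAlignment, slice_domain, translate_alignment
from .errors import InputError, UndefinedCorrelationError
from .phylo import DistanceMatrix, protein_distance_matrix

DEFAULT_N_PERM = 5000


@dataclass(frozen=True)
class CoevolutionResult:
    domain_a: str
    domain_b: str
    r_linear: float
    r_mantel: float
    p_mantel: float
    n_perm: int
    seed: int | None = None
    exhaustive: bool = False


def _check_pair(D1: DistanceMatrix, D2: DistanceMatrix):
    if D1.labels != D2.labels:
        raise InputError("distance matrices have different labels or label order")
    if D1.n < 3:
        raise InputError("need at least 3 taxa")


def matrix_correlation(D1: DistanceMatrix, D2: DistanceMatrix) -> float:
    """Pearson r over the upper triangles of two distance matrices."""
    _check_pair(D1, D2)
    x, y = D1.upper_triangle(), D2.upper_triangle()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("zero variance in a distance-matrix triangle")
    return float(np.corrcoef(x, y)[0, 1])


def mantel_test(
    D1: DistanceMatrix,
    D2: DistanceMatrix,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | None = None,
    *,
    domain_a: str = "A",
    domain_b: str = "B",
) -> CoevolutionResult:
    """One-tailed-upper Mantel test; exact by enumeration when n! <= n_perm."""
    _check_pair(D1, D2)
    if n_perm < 1:
        raise InputError("n_perm must be >= 1")
    r_obs = matrix_correlation(D1, D2)
    n = D1.n
    x = D1.upper_triangle()
    x = (x - x.mean()) / x.std()
    v2 = D2.values
    iu = np.triu_indices(n, k=1)

    def r_for(perm) -> float:
        y = v2[np.ix_(perm, perm)][iu]
        sy = y.std()
        if sy == 0:
            return np.nan
        return float(np.dot(x, (y - y.mean()) / sy) / len(x))

    exhaustive = math.factorial(n) <= n_perm
    if exhaustive:
        count, total = 0, 0
        for perm in itertools.permutations(range(n)):
            total += 1
            if r_for(list(perm)) >= r_obs - 1e-12:
                count += 1
        p = count / total
        n_used = total
    else:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(n)
            if r_for(perm) >= r_obs - 1e-12:
                count += 1
        p = (1 + count) / (n_perm + 1)
        n_used = n_perm
    return CoevolutionResult(
        domain_a=domain_a,
        domain_b=domain_b,
        r_linear=r_obs,
        r_mantel=r_obs,
        p_mantel=p,
        n_perm=n_used,
        seed=seed,
        exhaustive=exhaustive,
    )


def coevolution_scan(
    aln: CodonAlignment,
    domains: list[str] | None = None,
    *,
    model: str = "poisson",
    n_perm: int = DEFAULT_N_PERM,
    seed: int | None = None,
) -> list[CoevolutionResult]:
    """Mantel co-evolution test for every unordered pair of annotated domains."""
    names = domains if domains is not None else [d.name for d in aln.domains]
    if len(names) < 2:
        raise InputError("need at least 2 annotated domains")
    mats = {}
    for name in names:
        prot = translate_alignment(slice_domain(aln, name))
        mats[name] = protein_distance_matrix(prot, model=model)
    out = []
    for a, b in itertools.combinations(names, 2):
        out.append(
            mantel_test(mats[a], mats[b], n_perm=n_perm, seed=seed, domain_a=a, domain_b=b)
        )
    return out
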