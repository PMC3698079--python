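"""Genetic-code constants shared across the package.

Everything is derived once, at import time, from Biopython's standard
nuclear codon table: the 61 sense codons in a fixed lexicographic order
(T, C, A, G base order, the order codon-model software conventionally
uses), index maps, synonymous-family groupings for codon-usage work, and
the sparse single-step structure of the codon graph that the GY94 rate
matrix is built on.
"""

from __future__ import annotations

import itertools

import numpy as np
from Bio.Data import CodonTable

GAP = "-"
BASES = "TCAG"
PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")

_standard = CodonTable.unambiguous_dna_by_id[1]

STOP_CODONS: frozenset[str] = frozenset(_standard.stop_codons)

#: the 61 sense codons, TCAG-major order
SENSE_CODONS: tuple[str, ...] = tuple(
    c for c in ("".join(t) for t in itertools.product(BASES, repeat=3))
    if c not in STOP_CODONS
)
CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(SENSE_CODONS)}
N_CODONS = len(SENSE_CODONS)  # 61

#: codon -> one-letter amino acid (sense codons only)
CODON_TO_AA: dict[str, str] = {c: _standard.forward_table[c] for c in SENSE_CODONS}

#: amino acid -> tuple of its codons
AA_TO_CODONS: dict[str, tuple[str, ...]] = {}
for _c, _a in CODON_TO_AA.items():
    AA_TO_CODONS.setdefault(_a, ())
    AA_TO_CODONS[_a] = AA_TO_CODONS[_a] + (_c,)

#: degeneracy of each amino-acid family under Wright's treatment
#: (Leu, Ser, Arg kept as single six-fold families)
FAMILY_DEGENERACY: dict[str, int] = {a: len(cs) for a, cs in AA_TO_CODONS.items()}

#: amino acids with a single codon: excluded from GC3s / ENC / CAI
NONDEGENERATE_AAS = frozenset(a for a, k in FAMILY_DEGENERACY.items() if k == 1)  # {M, W}


def is_transition(b1: str, b2: str) -> bool:
    """True if b1 -> b2 is a purine<->purine or pyrimidine<->pyrimidine change."""
    return (b1 in PURINES and b2 in PURINES) or (b1 in PYRIMIDINES and b2 in PYRIMIDINES)


def _single_step_structure():
    """Sparse structure of one-nucleotide codon changes among sense codons.

    Returns index arrays (i, j) and boolean arrays marking transitions and
    nonsynonymous changes, used to fill the GY94 rate matrix.
    """
    ii, jj, ts, nonsyn = [], [], [], []
    for i, ci in enumerate(SENSE_CODONS):
        for j, cj in enumerate(SENSE_CODONS):
            if i == j:
                continue
            diffs = [p for p in range(3) if ci[p] != cj[p]]
            if len(diffs) != 1:
                continue
            p = diffs[0]
            ii.append(i)
            jj.append(j)
            ts.append(is_transition(ci[p], cj[p]))
            nonsyn.append(CODON_TO_AA[ci] != CODON_TO_AA[cj])
    return (
        np.asarray(ii, dtype=np.intp),
        np.asarray(jj, dtype=np.intp),
        np.asarray(ts, dtype=bool),
        np.asarray(nonsyn, dtype=bool),
    )


SINGLE_STEP_I, SINGLE_STEP_J, SINGLE_STEP_TS, SINGLE_STEP_NONSYN = _single_step_structure()

#: third-position base of each sense codon, as an index into BASES
THIRD_POSITION_BASE = np.array([BASES.index(c[2]) for c in SENSE_CODONS], dtype=np.intp)


def codon_indices(cds: str) -> np.ndarray:
    """Encode an ungapped CDS as sense-codon indices; -1 for codons with N/gaps."""
    n = len(cds) // 3
    out = np.empty(n, dtype=np.int64)
    for k in range(n):
        out[k] = CODON_INDEX.get(cds[3 * k: 3 * k + 3], -1)
    return out
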