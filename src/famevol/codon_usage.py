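"""Codon-usage-bias statistics: GC by position, ENC, CAI, group tests.

ENC is Wright's effective number of codons: per amino-acid family the
codon homozygosity is estimated as F = (n * sum p_i^2 - 1) / (n - 1)
(undefined at n < 2), families are averaged within each degeneracy class
(2-, 3-, 4-, 6-fold; Leu/Ser/Arg kept as single six-fold families), and

    ENC = 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6,

with a missing three-fold (Ile) class imputed as (F2 + F4)/2 and the
result capped to [20, 61].  The mutation-only expectation at a given
GC3 fraction s is Wright's null curve ENC* = 2 + s + 29/(s^2 + (1-s)^2).

GC3 is reported by default over synonymously variable codons only
(Met and Trp excluded), with an all-positions variant alongside, since
published tools differ.  CAI is the Sharp–Li geometric mean of relative
adaptiveness weights, computable from a reference gene set with +0.5
pseudo-counts.  Between-group comparisons use the exact two-sided
Mann–Whitney U test, appropriate for family-sized samples.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .codata import (
    AA_TO_CODONS,
    CODON_TO_AA,
    FAMILY_DEGENERACY,
    GAP,
    NONDEGENERATE_AAS,
    STOP_CODONS,
)
from .errors import InputError

_GC = frozenset("GC")


def _codons_of(cds: str) -> list[str]:
    cds = cds.upper().replace("U", "T")
    if len(cds) % 3 != 0:
        raise InputError(f"CDS length {len(cds)} not a multiple of 3")
    out = []
    for i in range(0, len(cds), 3):
        c = cds[i: i + 3]
        if GAP in c or "N" in c or c in STOP_CODONS:
            continue
        out.append(c)
    return out


@dataclass(frozen=True)
class CodonUsageStats:
    gene: str
    gc: float
    gc1: float
    gc2: float
    gc3: float | None          # synonymously variable third positions
    gc3_all: float             # all third positions
    enc: float | None
    cai: float | None
    family_homozygosity: dict  # degeneracy class -> mean F-hat
    enc_missing_reason: str | None = None


def gc_by_position(cds: str) -> tuple[float, float, float | None, float]:
    """(GC, GC1, GC2, GC3-synonymous) fractions; GC3 is None if no
    synonymously variable codon exists.  The all-positions GC3 variant is
    available via :func:`codon_usage_stats`."""
    codons = _codons_of(cds)
    if not codons:
        raise InputError("empty or fully degenerate coding sequence")
    n = len(codons)
    gc1 = sum(c[0] in _GC for c in codons) / n
    gc2 = sum(c[1] in _GC for c in codons) / n
    gc3_all = sum(c[2] in _GC for c in codons) / n
    gc = sum(b in _GC for c in codons for b in c) / (3 * n)
    syn = [c for c in codons if CODON_TO_AA[c] not in NONDEGENERATE_AAS]
    gc3 = sum(c[2] in _GC for c in syn) / len(syn) if syn else None
    return gc, gc1, gc2, gc3, gc3_all


def enc(cds: str) -> tuple[float | None, dict, str | None]:
    """Wright's effective number of codons.

    Returns (ENC or None, per-degeneracy mean homozygosity, reason for a
    missing value).  Families observed with n < 2 codons are excluded
    from their degeneracy-class average.
    """
    codons = _codons_of(cds)
    counts_by_aa: dict[str, Counter] = {}
    for c in codons:
        counts_by_aa.setdefault(CODON_TO_AA[c], Counter())[c] += 1
    fbar: dict[int, float] = {}
    per_class: dict[int, list[float]] = {2: [], 3: [], 4: [], 6: []}
    for aa, cnt in counts_by_aa.items():
        k = FAMILY_DEGENERACY[aa]
        if k == 1:
            continue
        n = sum(cnt.values())
        if n < 2:
            continue
        p2 = sum((v / n) ** 2 for v in cnt.values())
        per_class[k].append((n * p2 - 1.0) / (n - 1.0))
    for k, vals in per_class.items():
        if vals:
            fbar[k] = float(np.mean(vals))
    for k in (2, 4, 6):
        if k not in fbar:
            return None, fbar, f"no usable {k}-fold family"
    if 3 not in fbar:
        fbar[3] = 0.5 * (fbar[2] + fbar[4])
    if min(fbar.values()) <= 0.0:
        return None, fbar, "zero homozygosity in a degeneracy class"
    value = 2.0 + 9.0 / fbar[2] + 1.0 / fbar[3] + 5.0 / fbar[4] + 3.0 / fbar[6]
    return float(min(max(value, 20.0), 61.0)), fbar, None


def expected_enc(s: float) -> float:
    """Wright's mutation-only ENC expectation at GC3 fraction ``s``."""
    if not 0.0 <= s <= 1.0:
        raise InputError("GC3 fraction must lie in [0, 1]")
    return 2.0 + s + 29.0 / (s * s + (1.0 - s) * (1.0 - s))


def reference_weights(reference_cds: list[str], pseudo: float = 0.5) -> dict[str, float]:
    """Relative-adaptiveness weights from a reference gene set.

    Per family, w_c = count_c / max family count, with zero counts
    replaced by ``pseudo`` (the Sharp–Li convention); single-codon
    families get weight 1.
    """
    counts: Counter = Counter()
    for cds in reference_cds:
        counts.update(_codons_of(cds))
    weights: dict[str, float] = {}
    for aa, fam in AA_TO_CODONS.items():
        adj = {c: (counts[c] if counts.get(c, 0) > 0 else pseudo) for c in fam}
        mx = max(adj.values())
        for c in fam:
            weights[c] = adj[c] / mx if mx > 0 else 1.0
    return weights


def cai(cds: str, weights: dict[str, float]) -> float:
    """Codon adaptation index: geometric mean of weights over the gene's
    codons, excluding Met, Trp and stops.  Codons missing from the weight
    table contribute a small pseudo-weight and trigger a warning."""
    codons = [c for c in _codons_of(cds) if CODON_TO_AA[c] not in NONDEGENERATE_AAS]
    if not codons:
        raise InputError("no codons usable for CAI")
    missing = [c for c in codons if c not in weights]
    if missing:
        warnings.warn(
            f"CAI weights missing for {sorted(set(missing))}; using pseudo-weight 0.01",
            stacklevel=2,
        )
    total = sum(math.log(max(weights.get(c, 0.01), 1e-6)) for c in codons)
    return math.exp(total / len(codons))


def codon_usage_stats(
    gene: str, cds: str, cai_weights: dict[str, float] | None = None
) -> CodonUsageStats:
    gc, gc1, gc2, gc3, gc3_all = gc_by_position(cds)
    enc_val, fbar, reason = enc(cds)
    cai_val = cai(cds, cai_weights) if cai_weights is not None else None
    return CodonUsageStats(
        gene=gene, gc=gc, gc1=gc1, gc2=gc2, gc3=gc3, gc3_all=gc3_all,
        enc=enc_val, cai=cai_val, family_homozygosity=fbar,
        enc_missing_reason=reason,
    )


def usage_table(stats_list: list[CodonUsageStats]) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "gene": s.gene, "GC": s.gc, "GC1": s.gc1, "GC2": s.gc2,
            "GC3": s.gc3, "GC3_all": s.gc3_all, "ENC": s.enc, "CAI": s.cai,
        }
        for s in stats_list
    ])


def compare_groups(
    stats_a: list, stats_b: list, metric: str = "GC3"
) -> float:
    """Exact two-sided Mann–Whitney U p-value for one codon-usage metric.

    Accepts lists of :class:`CodonUsageStats` or raw numbers.
    """
    def extract(group):
        attr = {"GC3": "gc3", "GC3_all": "gc3_all", "ENC": "enc", "CAI": "cai",
                "GC": "gc", "GC1": "gc1", "GC2": "gc2"}.get(metric, metric.lower())
        vals = []
        for s in group:
            v = getattr(s, attr) if isinstance(s, CodonUsageStats) else float(s)
            if v is not None and np.isfinite(v):
                vals.append(float(v))
        return vals

    a, b = extract(stats_a), extract(stats_b)
    if len(a) < 2 or len(b) < 2:
        raise InputError("need at least 2 values per group")
    pooled = a + b
    if max(pooled) == min(pooled):
        return 1.0
    has_ties = len(set(pooled)) < len(pooled)
    method = "exact" if (max(len(a), len(b)) <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(min(res.pvalue, 1.0))


def enc_gc3_table(stats_list: list[CodonUsageStats]) -> pd.DataFrame:
    """Per-gene (GC3, ENC, null-curve ENC*, deviation) rows for plotting.

    Genes with a missing ENC or GC3 are excluded.
    """
    rows = []
    for s in stats_list:
        if s.enc is None or s.gc3 is None:
            continue
        exp = expected_enc(s.gc3)
        rows.append({
            "gene": s.gene, "GC3": s.gc3, "ENC": s.enc,
            "ENC_expected": exp, "deviation": exp - s.enc,
        })
    return pd.DataFrame(rows, columns=["gene", "GC3", "ENC", "ENC_expected", "deviation"])
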