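"""Salt-tolerance phenotype statistics.

The tolerance index (TI) of a stressed seedling is its primary-root
length relative to the mean control root length:

    TI_i = (L_stress,i - mean(L_control)) / mean(L_control).

Genotype groups of TIs are compared by one-way ANOVA followed by
pairwise pooled-variance t-tests with Bonferroni correction (the classic
post-hoc), with significance letters at alpha (default 0.01, the level
used for root-growth assays of overexpression and T-DNA insertion
lines).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError


def tolerance_index(stress_lengths, control_lengths) -> np.ndarray:
    """Per-seedling tolerance index against the control-arm mean."""
    stress = np.asarray(list(stress_lengths), dtype=float)
    control = np.asarray(list(control_lengths), dtype=float)
    if stress.size == 0 or control.size == 0:
        raise InputError("each arm needs at least one seedling")
    if np.any(stress <= 0) or np.any(control <= 0):
        raise InputError("root lengths must be > 0")
    baseline = control.mean()
    return (stress - baseline) / baseline


@dataclass
class AnovaResult:
    F: float
    p: float
    df_between: int
    df_within: int
    ms_within: float
    pairwise: pd.DataFrame      # group_a, group_b, t, p_raw, p_bonferroni, significant
    letters: dict               # group -> significance letters at alpha
    alpha: float


def anova_bonferroni(groups: dict, alpha: float = 0.01) -> AnovaResult:
    """One-way ANOVA with Bonferroni-corrected pairwise t-tests.

    ``groups`` maps genotype name to a list of tolerance indices.
    Pairwise t statistics use the pooled within-group variance (the
    ANOVA mean square error) with N - k degrees of freedom.
    """
    names = list(groups)
    data = {g: np.asarray(list(v), dtype=float) for g, v in groups.items()}
    if len(names) < 2:
        raise InputError("need at least 2 groups")
    if any(v.size < 2 for v in data.values()):
        raise InputError("need at least 2 values per group")
    k = len(names)
    N = sum(v.size for v in data.values())
    grand = np.concatenate(list(data.values())).mean()
    ss_between = sum(v.size * (v.mean() - grand) ** 2 for v in data.values())
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in data.values())
    df_b, df_w = k - 1, N - k
    ms_w = ss_within / df_w
    if ms_w == 0.0 and ss_between == 0.0:
        F, p = 0.0, 1.0
    elif ms_w == 0.0:
        F, p = np.inf, 0.0
    else:
        F = (ss_between / df_b) / ms_w
        p = float(stats.f.sf(F, df_b, df_w))

    m = k * (k - 1) // 2
    rows = []
    for a, b in combinations(names, 2):
        va, vb = data[a], data[b]
        if ms_w == 0.0:
            t = 0.0 if va.mean() == vb.mean() else np.inf
            p_raw = 1.0 if t == 0.0 else 0.0
        else:
            se = np.sqrt(ms_w * (1.0 / va.size + 1.0 / vb.size))
            t = (va.mean() - vb.mean()) / se
            p_raw = float(2.0 * stats.t.sf(abs(t), df_w))
        p_adj = min(1.0, p_raw * m)
        rows.append({
            "group_a": a, "group_b": b, "t": float(t),
            "p_raw": p_raw, "p_bonferroni": p_adj,
            "significant": p_adj <= alpha,
        })
    pairwise = pd.DataFrame(rows)
    letters = _significance_letters(names, data, pairwise, alpha)
    return AnovaResult(
        F=float(F), p=float(p), df_between=df_b, df_within=df_w,
        ms_within=float(ms_w), pairwise=pairwise, letters=letters, alpha=alpha,
    )


def _significance_letters(names, data, pairwise, alpha) -> dict:
    """Compact letter display: groups sharing a letter do not differ at alpha."""
    differ = {
        frozenset((r.group_a, r.group_b))
        for r in pairwise.itertuples()
        if r.significant
    }
    order = sorted(names, key=lambda g: -data[g].mean())
    sets: list[set] = []
    for g in order:
        placed = False
        for s in sets:
            if all(frozenset((g, h)) not in differ for h in s):
                s.add(g)
                placed = True
        if not placed:
            sets.append({g})
    # absorb duplicate letter sets
    unique_sets = []
    for s in sets:
        if not any(s <= u for u in unique_sets):
            unique_sets.append(s)
    letters = {g: "" for g in names}
    for idx, s in enumerate(unique_sets):
        ch = chr(ord("a") + idx)
        for g in s:
            letters[g] += ch
    return letters


def read_phenotype_table(path) -> pd.DataFrame:
    """Read a TSV with columns genotype, treatment_mM, replicate, root_length_mm."""
    df = pd.read_csv(path, sep="\t")
    required = {"genotype", "treatment_mM", "root_length_mm"}
    missing = required - set(df.columns)
    if missing:
        raise InputError(f"phenotype table missing columns {sorted(missing)}")
    return df


def tolerance_table(df: pd.DataFrame, control_mM: float = 0.0) -> pd.DataFrame:
    """Per-seedling tolerance indices for every (genotype, stress) arm."""
    rows = []
    for (genotype, treatment), sub in df.groupby(["genotype", "treatment_mM"]):
        if treatment == control_mM:
            continue
        control = df[(df.genotype == genotype) & (df.treatment_mM == control_mM)]
        if control.empty:
            raise InputError(f"no control ({control_mM} mM) arm for genotype {genotype}")
        ti = tolerance_index(sub.root_length_mm, control.root_length_mm)
        for value in ti:
            rows.append({"genotype": genotype, "treatment_mM": treatment, "TI": value})
    return pd.DataFrame(rows)
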