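"""Protein distance matrices, neighbor-joining, bootstrap support.

These are the ingredients of the per-domain trees and of the distance
matrices the mirror-tree co-evolution test correlates.  Distances use
pairwise deletion for gaps (columns with a gap or unknown residue in
either member of a pair are dropped for that pair) and either the raw
proportion of differing sites (``p``) or its Poisson correction
``d = -ln(1 - p)``.

Neighbor joining follows Saitou & Nei with the Studier–Keppler Q
criterion; ties in Q are broken toward the lowest index pair so results
are deterministic, and negative estimated branch lengths are clamped to
zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import InputError, SaturationError, UndefinedDistanceError
from .trees import Node, PhyloTree

_MISSING = frozenset("-X*?")


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric non-negative distances with ordered labels."""

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        labels = tuple(self.labels)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "values", v)
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] != len(labels):
            raise InputError("distance matrix shape does not match labels")
        if len(set(labels)) != len(labels):
            raise InputError("duplicate labels in distance matrix")
        if not np.all(np.isfinite(v)):
            raise InputError("non-finite distances")
        if not np.allclose(v, v.T, atol=1e-12):
            raise InputError("distance matrix is not symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise InputError("distance matrix diagonal is not zero")

    @property
    def n(self) -> int:
        return len(self.labels)

    def upper_triangle(self) -> np.ndarray:
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def to_tsv(self, path) -> None:
        lines = ["\t".join(("",) + self.labels)]
        for lab, row in zip(self.labels, self.values):
            lines.append(lab + "\t" + "\t".join(f"{x:.6f}" for x in row))
        from pathlib import Path
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_tsv(cls, path) -> "DistanceMatrix":
        from pathlib import Path
        lines = [l for l in Path(path).read_text().splitlines() if l.strip()]
        labels = tuple(lines[0].split("\t")[1:])
        rows = [list(map(float, l.split("\t")[1:])) for l in lines[1:]]
        return cls(labels=labels, values=np.array(rows))


def protein_distance_matrix(rows, model: str = "poisson") -> DistanceMatrix:
    """Pairwise protein distances under the p or Poisson model.

    ``rows`` is a sequence of (label, aligned protein) pairs.  Columns with
    a gap/X in either member of a pair are excluded for that pair.
    """
    if model not in ("p", "poisson"):
        raise InputError(f"unknown distance model {model!r}")
    rows = list(rows)
    if len(rows) < 2:
        raise InputError("need at least two sequences")
    labels = tuple(lab for lab, _ in rows)
    seqs = [s for _, s in rows]
    if len({len(s) for s in seqs}) != 1:
        raise InputError("protein sequences are not aligned (unequal lengths)")
    arr = np.array([list(s) for s in seqs])
    ok = ~np.isin(arr, list(_MISSING))
    n = len(rows)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = ok[i] & ok[j]
            m = int(shared.sum())
            if m == 0:
                raise UndefinedDistanceError(
                    f"{labels[i]} and {labels[j]} share no comparable columns"
                )
            p = float((arr[i][shared] != arr[j][shared]).sum()) / m
            if model == "p":
                dij = p
            else:
                if p >= 1.0:
                    raise SaturationError(
                        f"Poisson distance saturated (p = 1) for {labels[i]} vs {labels[j]}"
                    )
                dij = -math.log(1.0 - p)
            d[i, j] = d[j, i] = dij
    return DistanceMatrix(labels=labels, values=d)


def nj_tree(D: DistanceMatrix) -> PhyloTree:
    """Neighbor-joining tree (Saitou–Nei, Studier–Keppler Q criterion).

    Returns an unrooted tree represented with a trifurcating root.
    Negative branch-length estimates are clamped to zero.  Ties in the Q
    criterion join the lowest-index pair.
    """
    n = D.n
    if n < 3:
        raise InputError("neighbor joining needs at least 3 taxa")
    d = D.values.copy()
    nodes = [Node(name=lab) for lab in D.labels]
    active = list(range(n))
    while len(active) > 3:
        r = len(active)
        sub = d[np.ix_(active, active)]
        R = sub.sum(axis=1)
        q = (r - 2) * sub - R[:, None] - R[None, :]
        np.fill_diagonal(q, np.inf)
        # lowest-index tie break: scan in (i, j) order
        best = None
        for a in range(r):
            for b in range(a + 1, r):
                if best is None or q[a, b] < best[0] - 1e-15:
                    best = (q[a, b], a, b)
        _, a, b = best
        i, j = active[a], active[b]
        li = 0.5 * d[i, j] + (R[a] - R[b]) / (2.0 * (r - 2))
        lj = d[i, j] - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        u = Node(children=[nodes[i], nodes[j]])
        nodes[i].length, nodes[j].length = li, lj
        # distances from the new node to the remaining taxa
        new_row = np.zeros(d.shape[0] + 1)
        for c in active:
            if c in (i, j):
                continue
            new_row[c] = 0.5 * (d[i, c] + d[j, c] - d[i, j])
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, :-1] = new_row[:-1]
        d[:-1, -1] = new_row[:-1]
        nodes.append(u)
        active = [c for c in active if c not in (i, j)] + [len(nodes) - 1]
    # final three-point formulas
    i, j, k = active
    li = 0.5 * (d[i, j] + d[i, k] - d[j, k])
    lj = 0.5 * (d[i, j] + d[j, k] - d[i, k])
    lk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
    nodes[i].length = max(li, 0.0)
    nodes[j].length = max(lj, 0.0)
    nodes[k].length = max(lk, 0.0)
    root = Node(children=[nodes[i], nodes[j], nodes[k]])
    return PhyloTree(root)


# ---- splits and topology comparison --------------------------------


def splits(tree: PhyloTree) -> set[frozenset[str]]:
    """Nontrivial bipartitions, each as the leaf set not containing an anchor."""
    all_leaves = frozenset(tree.leaf_names)
    anchor = min(all_leaves)
    out = set()
    for node in tree.postorder():
        if node is tree.root or node.is_leaf:
            continue
        side = frozenset(_names_under(node))
        if anchor in side:
            side = all_leaves - side
        if 1 < len(side) < len(all_leaves) - 1:
            out.add(side)
    return out


def _names_under(node: Node) -> list[str]:
    if node.is_leaf:
        return [node.name]
    out = []
    for c in node.children:
        out.extend(_names_under(c))
    return out


def compare_topologies(t1: PhyloTree, t2: PhyloTree) -> dict:
    """Robinson–Foulds-style split comparison of two trees on one leaf set."""
    if set(t1.leaf_names) != set(t2.leaf_names):
        raise InputError("trees have different leaf sets")
    s1, s2 = splits(t1), splits(t2)
    shared = s1 & s2
    return {
        "shared_splits": len(shared),
        "conflicting_splits_t1": len(s1 - s2),
        "conflicting_splits_t2": len(s2 - s1),
        "rf_distance": len(s1 ^ s2),
    }


def bootstrap_support(
    rows,
    B: int = 1000,
    *,
    model: str = "poisson",
    seed: int | None = None,
    builder=None,
) -> PhyloTree:
    """NJ tree with bootstrap support percentages on internal nodes.

    Alignment columns are resampled with replacement ``B`` times; support
    for each internal split of the reference tree is the percentage of
    replicate trees containing it.  ``builder`` maps a DistanceMatrix to a
    tree (default :func:`nj_tree`).
    """
    if B < 1:
        raise InputError("need at least one bootstrap replicate")
    rows = list(rows)
    builder = builder or nj_tree
    rng = np.random.default_rng(seed)
    ref = builder(protein_distance_matrix(rows, model=model))
    counts: dict[frozenset, int] = {s: 0 for s in splits(ref)}
    L = len(rows[0][1])
    labels = [lab for lab, _ in rows]
    arr = np.array([list(s) for _, s in rows])
    for _ in range(B):
        cols = rng.integers(0, L, size=L)
        rep_rows = [(lab, "".join(arr[i][cols])) for i, lab in enumerate(labels)]
        try:
            rep = builder(protein_distance_matrix(rep_rows, model=model))
        except (UndefinedDistanceError, SaturationError):
            continue
        rep_splits = splits(rep)
        for s in counts:
            if s in rep_splits:
                counts[s] += 1
    out = ref.copy()
    all_leaves = frozenset(out.leaf_names)
    anchor = min(all_leaves)
    for node in out.postorder():
        if node is out.root or node.is_leaf:
            continue
        side = frozenset(_names_under(node))
        if anchor in side:
            side = all_leaves - side
        if side in counts:
            node.label = f"{100.0 * counts[side] / B:.0f}"
    return out
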