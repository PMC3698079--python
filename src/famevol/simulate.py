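"""Forward simulator for multi-domain gene families.

Generates in-frame codon alignments for a gene family that arose by
duplications on the stem lineage of three species, with (i) a known gene
tree including one optional lineage-specific loss, (ii) two intra-gene
domains plus an inter-domain region whose branch rates share a tunable
fraction ``rho`` of their log-variance (the mirror-tree co-evolution
signal), (iii) an omega regime that is uniform (M0), a site mixture
(M2a), or clade-restricted positive selection (branch-site model A on a
labeled foreground clade), and (iv) species-specific third-position
nucleotide composition (a GC3 / codon-bias shift on terminal branches).

Defaults emulate an Alfin-like-style family: four ortholog groups over
three crucifer-like species with one loss (11 genes), a ~130-codon
DUF-like domain, ~70-codon linker and ~50-codon PHD-like domain,
predominantly purifying selection (omega0 ~ 0.07) with 10% of sites
under omega2 = 5 on one foreground clade, kappa = 2, rho = 0.8.
The ``al-family`` preset widens this to seven groups / 20 genes.

Ground truth (tree, per-site classes, per-branch region rate
multipliers, realized parameters) is returned alongside every alignment
so recovery can be tested at each pipeline stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alignment import CodingSequence, CodonAlignment, DomainAnnotation
from .codata import SENSE_CODONS
from .errors import InputError, LookupError_
from .gy94 import SpectralQ, f3x4_frequencies
from .trees import Node, PhyloTree

REGIONS = ("DUF3594", "inter-domain", "PHD")

#: three-species tree (A. thaliana-like, A. lyrata-like, halophyte outlier),
#: branch lengths in expected substitutions per codon site
DEFAULT_SPECIES_TREE = "((At:0.06,Al:0.06)AtAl:0.10,Th:0.16);"

_BASE_POS_FREQS = np.array([
    [0.25, 0.25, 0.25, 0.25],          # position 1 (T C A G)
    [0.25, 0.25, 0.25, 0.25],          # position 2
    [0.285, 0.215, 0.285, 0.215],      # position 3: GC3 = 0.43
])
_TH_POS_FREQS = np.array([
    [0.25, 0.25, 0.25, 0.25],
    [0.25, 0.25, 0.25, 0.25],
    [0.225, 0.275, 0.225, 0.275],      # GC3 = 0.55: the halophyte shift
])


@dataclass(frozen=True)
class OmegaSpec:
    """Selection regime: M0, site mixture M2a, or branch-site model A."""

    model: str = "branch-site-A"
    omega: float = 0.2        # M0 only
    p0: float = 0.81
    p1: float = 0.09
    omega0: float = 0.07
    omega2: float = 5.0

    def __post_init__(self):
        if self.model not in ("M0", "M2a", "branch-site-A"):
            raise InputError(f"unknown omega model {self.model!r}")
        for w in (self.omega, self.omega0, self.omega2):
            if w < 0:
                raise InputError("omega values must be >= 0")
        if self.model != "M0":
            if not (0 <= self.p0 <= 1 and 0 <= self.p1 <= 1 and self.p0 + self.p1 <= 1 + 1e-9):
                raise InputError("class proportions must lie in [0,1] and sum to <= 1")

    def class_table(self):
        """(proportions, background omegas, foreground omegas) per site class."""
        if self.model == "M0":
            return np.array([1.0]), (self.omega,), (self.omega,)
        p2 = max(0.0, 1.0 - self.p0 - self.p1)
        if self.model == "M2a":
            return (
                np.array([self.p0, self.p1, p2]),
                (self.omega0, 1.0, self.omega2),
                (self.omega0, 1.0, self.omega2),
            )
        tot = self.p0 + self.p1
        if tot <= 0:
            raise InputError("branch-site-A needs p0 + p1 > 0")
        p2a, p2b = p2 * self.p0 / tot, p2 * self.p1 / tot
        return (
            np.array([self.p0, self.p1, p2a, p2b]),
            (self.omega0, 1.0, self.omega0, 1.0),
            (self.omega0, 1.0, self.omega2, self.omega2),
        )


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    species_tree: str = DEFAULT_SPECIES_TREE
    n_groups: int = 4
    loss_spec: tuple[str, str] | None = ("AL3", "Th")  # (group label, species)
    region_lengths: tuple[int, int, int] = (130, 70, 50)
    kappa: float = 2.0
    omega_spec: OmegaSpec = field(default_factory=OmegaSpec)
    foreground: str = "AL1"
    pi_spec: dict = field(default_factory=lambda: {None: _BASE_POS_FREQS, "Th": _TH_POS_FREQS})
    rho: float = 0.8
    sigma_b: float = 0.5
    dup_spacing: float = 0.08   # branch length between successive duplications
    group_stem: float = 0.10    # stem above each group's species-tree root

    def __post_init__(self):
        if self.n_groups < 1:
            raise InputError("n_groups must be >= 1")
        if not (0.0 <= self.rho <= 1.0):
            raise InputError("rho must lie in [0, 1]")
        if self.sigma_b < 0:
            raise InputError("sigma_b must be >= 0")
        if self.kappa <= 0:
            raise InputError("kappa must be > 0")
        if any(l < 1 for l in self.region_lengths):
            raise InputError("region lengths must be >= 1 codon")


def al_family_preset(seed: int = 0, **overrides) -> SimulationConfig:
    """Seven ortholog groups, one halophyte loss: a 20-gene family."""
    kw = dict(n_groups=7, loss_spec=("AL3", "Th"), foreground="AL7")
    kw.update(overrides)
    return SimulationConfig(seed=seed, **kw)


@dataclass
class TruthRecord:
    gene_family_tree: PhyloTree
    site_class: dict          # region -> int array of per-site class indices
    branch_rates: dict        # region -> {branch name -> multiplier}
    kappa: float
    omega_spec: OmegaSpec
    rho: float
    sigma_b: float
    pi: dict                  # species key -> 61 codon frequencies
    seed: int


def sample_gene_family_tree(cfg: SimulationConfig) -> PhyloTree:
    """Gene-family tree: duplication caterpillar of species-tree copies.

    Groups are labeled AL1..ALn (each clade containing one leaf per
    species, named ``<species>_<group>``); the optional loss prunes one
    leaf.  Deterministic given the configuration.
    """
    species = PhyloTree.from_newick(cfg.species_tree)

    def group_subtree(k: int) -> Node:
        t = species.copy()
        for node in t.postorder():
            node.label = None
        for leaf in t.leaves:
            leaf.name = f"{leaf.name}_AL{k}"
        t.root.label = f"AL{k}"
        t.root.length = cfg.group_stem
        return t.root

    n = cfg.n_groups
    if n == 1:
        root = group_subtree(1)
        root.length = 0.0
        tree = PhyloTree(root)
    else:
        node = Node(name=f"dup{n - 1}",
                    children=[group_subtree(n - 1), group_subtree(n)])
        for k in range(n - 2, 0, -1):
            node.length = cfg.dup_spacing
            node = Node(name=f"dup{k}", children=[group_subtree(k), node])
        tree = PhyloTree(node)
    if cfg.loss_spec is not None:
        group, sp = cfg.loss_spec
        leaf = f"{sp}_{group}"
        if leaf not in tree.leaf_names:
            raise LookupError_(f"loss_spec names absent leaf {leaf!r}")
        tree.prune_leaf(leaf)
    return tree


def _name_internal_nodes(tree: PhyloTree) -> None:
    i = 0
    for node in tree.postorder():
        if node.name is None:
            node.name = f"n{i}"
            i += 1


def _branch_species(tree: PhyloTree) -> dict:
    """Species context of each branch: the species name for terminal
    branches, None (ancestral composition) for internal ones."""
    out = {}
    for node in tree.postorder():
        out[node.name] = node.name.split("_", 1)[0] if node.is_leaf else None
    return out


def simulate_alignment(cfg: SimulationConfig) -> tuple[CodonAlignment, TruthRecord]:
    """Evolve a codon alignment down the gene-family tree; returns truth."""
    rng = np.random.default_rng(cfg.seed)
    tree = sample_gene_family_tree(cfg)
    _name_internal_nodes(tree)
    if cfg.omega_spec.model == "branch-site-A":
        tree.set_foreground_clade(cfg.foreground)

    proportions, bg_omegas, fg_omegas = cfg.omega_spec.class_table()
    n_classes = len(proportions)
    region_lengths = dict(zip(REGIONS, cfg.region_lengths))
    n_sites = sum(region_lengths.values())

    # per-site classes per region
    site_class = {
        reg: rng.choice(n_classes, size=L, p=proportions)
        for reg, L in region_lengths.items()
    }

    # per-branch, per-region lognormal rate multipliers
    branch_names = [n.name for n in tree.postorder() if n is not tree.root]
    branch_rates = {reg: {} for reg in REGIONS}
    for b in branch_names:
        shared = rng.normal(0.0, cfg.sigma_b)
        for reg in REGIONS:
            eps = rng.normal(0.0, cfg.sigma_b)
            branch_rates[reg][b] = float(np.exp(cfg.rho * shared + (1.0 - cfg.rho) * eps))

    # codon frequencies and spectral decompositions per (species, omega)
    pi_by_species = {
        key: f3x4_frequencies(freqs) for key, freqs in cfg.pi_spec.items()
    }
    if None not in pi_by_species:
        raise InputError("pi_spec must contain a base (None) composition")
    decomp_cache: dict = {}

    def decomp(species_key, omega: float) -> SpectralQ:
        key = (species_key, omega)
        if key not in decomp_cache:
            pi = pi_by_species.get(species_key, pi_by_species[None])
            decomp_cache[key] = SpectralQ(cfg.kappa, omega, pi, scale=False)
        return decomp_cache[key]

    # branch lengths mean substitutions per codon averaged over site
    # classes (background omegas), per branch composition
    def mixture_scale(species_key) -> float:
        mu_bar = sum(
            p * decomp(species_key, bg).rate
            for p, bg in zip(proportions, bg_omegas)
        )
        return 1.0 / mu_bar

    scale_by_species = {}

    species_of = _branch_species(tree)

    # region/class site grouping (global site indices)
    offsets, off = {}, 0
    for reg in REGIONS:
        offsets[reg] = off
        off += region_lengths[reg]
    groups = []  # (region, class_index, global site indices)
    for reg in REGIONS:
        for c in range(n_classes):
            idx = np.flatnonzero(site_class[reg] == c) + offsets[reg]
            if idx.size:
                groups.append((reg, c, idx))

    # root sequence from the base composition
    pi0 = pi_by_species[None]
    states = {tree.root.name: rng.choice(len(SENSE_CODONS), size=n_sites, p=pi0)}

    def evolve(node):
        for child in node.children:
            parent_state = states[node.name]
            child_state = parent_state.copy()
            sp = species_of[child.name]
            fg = child.foreground
            if sp not in scale_by_species:
                scale_by_species[sp] = mixture_scale(sp)
            for reg, c, idx in groups:
                omega = fg_omegas[c] if fg else bg_omegas[c]
                t_eff = child.length * branch_rates[reg][child.name] * scale_by_species[sp]
                if t_eff <= 0:
                    continue
                P = decomp(sp, omega).transition_matrix(t_eff)
                cur = parent_state[idx]
                u = rng.random(idx.size)
                cum = np.cumsum(P[cur], axis=1)
                child_state[idx] = np.minimum(
                    (cum < u[:, None]).sum(axis=1), len(SENSE_CODONS) - 1
                )
            states[child.name] = child_state
            evolve(child)

    evolve(tree.root)

    rows = tuple(
        CodingSequence(
            id=leaf.name,
            cds="".join(SENSE_CODONS[s] for s in states[leaf.name]),
            species=leaf.name.split("_", 1)[0],
        )
        for leaf in tree.leaves
    )
    d1, d2, d3 = cfg.region_lengths
    domains = (
        DomainAnnotation(REGIONS[0], 1, d1),
        DomainAnnotation(REGIONS[1], d1 + 1, d1 + d2),
        DomainAnnotation(REGIONS[2], d1 + d2 + 1, d1 + d2 + d3),
    )
    aln = CodonAlignment(rows=rows, domains=domains)
    truth = TruthRecord(
        gene_family_tree=tree,
        site_class=site_class,
        branch_rates=branch_rates,
        kappa=cfg.kappa,
        omega_spec=cfg.omega_spec,
        rho=cfg.rho,
        sigma_b=cfg.sigma_b,
        pi=pi_by_species,
        seed=cfg.seed,
    )
    return aln, truth


def inject_conversion_tract(
    aln: CodonAlignment, donor: str, recipient: str, start_codon: int, end_codon: int
) -> CodonAlignment:
    """Overwrite the recipient's codon columns with the donor's in a tract."""
    if start_codon > end_codon:
        raise InputError(f"empty tract: start {start_codon} > end {end_codon}")
    if start_codon < 1 or end_codon > aln.n_codon_columns:
        raise InputError("tract outside alignment")
    donor_row = aln.row(donor)
    lo, hi = 3 * (start_codon - 1), 3 * end_codon
    new_rows = []
    for r in aln.rows:
        if r.id == recipient:
            cds = r.cds[:lo] + donor_row.cds[lo:hi] + r.cds[hi:]
            new_rows.append(CodingSequence(id=r.id, cds=cds, species=r.species))
        else:
            new_rows.append(r)
    return CodonAlignment(rows=tuple(new_rows), domains=aln.domains)
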