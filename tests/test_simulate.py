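"""Gene-family simulator: tree shape, determinism, model behavior."""

import numpy as np
import pytest

import famevol as fv
from famevol.codata import CODON_TO_AA, SENSE_CODONS, codon_indices
from famevol.errors import InputError, LookupError_
from famevol.simulate import OmegaSpec, SimulationConfig, al_family_preset


class TestGeneFamilyTree:
    def test_four_groups_one_loss_gives_11_leaves(self):
        tree = fv.sample_gene_family_tree(SimulationConfig(seed=0))
        assert len(tree.leaf_names) == 11
        assert "Th_AL3" not in tree.leaf_names

    def test_single_group_matches_species_tree(self):
        cfg = SimulationConfig(seed=0, n_groups=1, loss_spec=None)
        tree = fv.sample_gene_family_tree(cfg)
        assert sorted(tree.leaf_names) == ["Al_AL1", "At_AL1", "Th_AL1"]

    def test_al_family_preset_has_20_leaves(self):
        tree = fv.sample_gene_family_tree(al_family_preset())
        assert len(tree.leaf_names) == 20
        by_species = {"At": 0, "Al": 0, "Th": 0}
        for name in tree.leaf_names:
            by_species[name.split("_")[0]] += 1
        assert by_species == {"At": 7, "Al": 7, "Th": 6}

    def test_clade_labels_cover_groups(self):
        tree = fv.sample_gene_family_tree(SimulationConfig(seed=0))
        labels = tree.clade_labels
        assert set(labels) == {"AL1", "AL2", "AL3", "AL4"}
        assert sorted(labels["AL1"]) == ["Al_AL1", "At_AL1", "Th_AL1"]

    def test_loss_of_absent_leaf_rejected(self):
        cfg = SimulationConfig(seed=0, loss_spec=("AL9", "Th"))
        with pytest.raises(LookupError_):
            fv.sample_gene_family_tree(cfg)


class TestSimulateAlignment:
    def test_fixed_seed_reproducible(self):
        a1, _ = fv.simulate_alignment(SimulationConfig(seed=42))
        a2, _ = fv.simulate_alignment(SimulationConfig(seed=42))
        assert [r.cds for r in a1.rows] == [r.cds for r in a2.rows]
        a3, _ = fv.simulate_alignment(SimulationConfig(seed=43))
        assert [r.cds for r in a3.rows] != [r.cds for r in a1.rows]

    def test_omega_zero_forbids_amino_acid_change(self):
        cfg = SimulationConfig(
            seed=5, omega_spec=OmegaSpec(model="M0", omega=0.0),
            region_lengths=(60, 30, 30), rho=0.0, sigma_b=0.0,
        )
        aln, _ = fv.simulate_alignment(cfg)
        prots = {fv.translate(r.cds) for r in aln.rows}
        assert len(prots) == 1

    def test_zero_branch_lengths_copy_root(self):
        cfg = SimulationConfig(
            seed=5,
            species_tree="((At:0.0,Al:0.0):0.0,Th:0.0);",
            dup_spacing=0.0, group_stem=0.0,
            region_lengths=(30, 20, 20),
        )
        aln, _ = fv.simulate_alignment(cfg)
        assert len({r.cds for r in aln.rows}) == 1

    def test_domains_partition_columns(self):
        aln, _ = fv.simulate_alignment(SimulationConfig(seed=1))
        spans = sorted((d.start_codon, d.end_codon) for d in aln.domains)
        assert spans[0][0] == 1
        assert spans[-1][1] == aln.n_codon_columns
        for (a, b), (c, _) in zip(spans, spans[1:]):
            assert c == b + 1

    def test_truth_records_site_classes_and_rates(self):
        aln, truth = fv.simulate_alignment(SimulationConfig(seed=2))
        assert set(truth.site_class) == {"DUF3594", "inter-domain", "PHD"}
        assert len(truth.site_class["DUF3594"]) == 130
        for reg, rates in truth.branch_rates.items():
            assert all(r > 0 for r in rates.values())

    def test_stationary_composition_on_long_branch(self):
        """After a very long branch the codon distribution matches pi."""
        cfg = SimulationConfig(
            seed=9, n_groups=1, loss_spec=None,
            species_tree="((At:0.0,Al:0.0):0.0,Th:40.0);",
            region_lengths=(3000, 1500, 1500),
            omega_spec=OmegaSpec(model="M0", omega=0.5),
            pi_spec={None: np.full((3, 4), 0.25)},
            rho=0.0, sigma_b=0.0, dup_spacing=0.0, group_stem=0.0,
        )
        aln, truth = fv.simulate_alignment(cfg)
        th = next(r for r in aln.rows if r.id.startswith("Th"))
        codes = codon_indices(th.cds)
        freq = np.bincount(codes, minlength=61) / codes.size
        assert np.max(np.abs(freq - truth.pi[None])) < 0.02

    def test_purifying_selection_suppresses_nonsynonymous_divergence(self):
        """Under omega = 0.2 the nonsynonymous difference proportion stays
        below the synonymous proportion (NG86-style counting)."""
        cfg = SimulationConfig(
            seed=13, n_groups=1, loss_spec=None,
            region_lengths=(400, 200, 200),
            omega_spec=OmegaSpec(model="M0", omega=0.2),
            rho=0.0, sigma_b=0.0,
        )
        aln, _ = fv.simulate_alignment(cfg)

        def nsyn_fraction(codon):
            # fraction of the 9 single-nt neighbours that are nonsynonymous
            syn = non = 0
            for p in range(3):
                for b in "TCAG":
                    if b == codon[p]:
                        continue
                    alt = codon[:p] + b + codon[p + 1:]
                    if alt not in CODON_TO_AA:
                        continue
                    if CODON_TO_AA[alt] == CODON_TO_AA[codon]:
                        syn += 1
                    else:
                        non += 1
            total = syn + non
            return (non / total if total else 0.75, syn / total if total else 0.25)

        rows = aln.rows
        for a, b in [(rows[0], rows[1]), (rows[0], rows[2])]:
            N = S = nd = sd = 0.0
            for ca, cb in zip(a.codons(), b.codons()):
                fa_n, fa_s = nsyn_fraction(ca)
                N += 3 * fa_n
                S += 3 * fa_s
                if ca != cb:
                    diff = sum(x != y for x, y in zip(ca, cb))
                    if CODON_TO_AA.get(ca) == CODON_TO_AA.get(cb):
                        sd += diff
                    else:
                        nd += diff
            assert nd / N < sd / S

    def test_gc3_shift_applied_to_target_species(self):
        aln, _ = fv.simulate_alignment(
            SimulationConfig(seed=17, region_lengths=(300, 100, 100))
        )

        def gc3(rows):
            vals = []
            for r in rows:
                st = fv.gc_by_position(r.cds)
                vals.append(st[4])
            return np.mean(vals)

        th = [r for r in aln.rows if r.species == "Th"]
        at = [r for r in aln.rows if r.species == "At"]
        assert gc3(th) > gc3(at)


class TestConversionTract:
    def test_tract_copies_donor(self, m0_family):
        aln, _ = m0_family
        out = fv.inject_conversion_tract(aln, "At_AL1", "At_AL2", 10, 69)
        d = out.row("At_AL1").cds
        r = out.row("At_AL2").cds
        assert d[27:207] == r[27:207]

    def test_outside_tract_unchanged(self, m0_family):
        aln, _ = m0_family
        out = fv.inject_conversion_tract(aln, "At_AL1", "At_AL2", 10, 69)
        before = aln.row("At_AL2").cds
        after = out.row("At_AL2").cds
        assert before[:27] == after[:27]
        assert before[207:] == after[207:]
        for other in aln.ids:
            if other != "At_AL2":
                assert aln.row(other).cds == out.row(other).cds

    def test_empty_tract_rejected(self, m0_family):
        aln, _ = m0_family
        with pytest.raises(InputError):
            fv.inject_conversion_tract(aln, "At_AL1", "At_AL2", 10, 9)

    def test_unknown_sequence_rejected(self, m0_family):
        aln, _ = m0_family
        with pytest.raises(Exception):
            fv.inject_conversion_tract(aln, "nope", "At_AL2", 1, 5)


def test_shared_branch_rates_mirror_domain_distances():
    """With rho = 1 and strong rate dispersion the two domains' distance
    matrices agree; the correlation is far weaker at rho = 0."""
    def domain_corr(rho, seed):
        cfg = SimulationConfig(
            seed=seed, region_lengths=(300, 50, 300), rho=rho, sigma_b=1.0,
            omega_spec=OmegaSpec(model="M0", omega=0.2),
        )
        aln, _ = fv.simulate_alignment(cfg)
        mats = []
        for name in ("DUF3594", "PHD"):
            prot = fv.translate_alignment(fv.slice_domain(aln, name))
            mats.append(fv.protein_distance_matrix(prot))
        return fv.matrix_correlation(*mats)

    shared = np.median([domain_corr(1.0, s) for s in range(5)])
    indep = np.median([domain_corr(0.0, s) for s in range(5)])
    assert shared >= 0.9
    assert shared > indep


def test_invalid_configs_rejected():
    with pytest.raises(InputError):
        SimulationConfig(rho=1.5)
    with pytest.raises(InputError):
        SimulationConfig(sigma_b=-1)
    with pytest.raises(InputError):
        SimulationConfig(n_groups=0)
    with pytest.raises(InputError):
        OmegaSpec(model="M9")
    with pytest.raises(InputError):
        OmegaSpec(p0=0.9, p1=0.3)
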