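"""Codon-model likelihoods, fits, LRTs, empirical-Bayes site posteriors."""

import numpy as np
import pytest
from scipy.linalg import expm

import famevol as fv
from famevol.codata import CODON_INDEX
from famevol.codon_models import (
    LikelihoodEngine,
    beta_category_means,
    branch_site_scan,
    fit_model,
    site_posteriors,
)
from famevol.errors import InputError
from famevol.gy94 import build_rate_matrix
from famevol.trees import PhyloTree

PI61 = np.full(61, 1.0 / 61)


# ---- LRT arithmetic and omega classification -----------------------


class TestLRT:
    def test_site_model_worked_example(self):
        """The discrete-vs-one-ratio test from printed log-likelihoods."""
        res = fv.lrt(-5607.533, -5734.773, df=4)
        assert res.stat == pytest.approx(254.48, abs=1e-9)
        assert res.p < 0.01

    def test_equal_likelihoods_give_zero(self):
        res = fv.lrt(-5673.941, -5673.941, df=2)
        assert res.stat == 0.0
        assert res.p == 1.0

    def test_chi2_tail_df1(self):
        res = fv.lrt(-5444.364, -5444.364 - 5.909 / 2, df=1)
        # stat built to be 5.909
        assert res.stat == pytest.approx(5.909, abs=1e-9)
        assert res.p == pytest.approx(0.0151, abs=5e-4)

    def test_negative_difference_clamped(self):
        res = fv.lrt(-10.0, -9.0, df=1)
        assert res.stat == 0.0 and res.p == 1.0

    def test_df_validation(self):
        with pytest.raises(InputError):
            fv.lrt(-1.0, -2.0, df=0)


@pytest.mark.parametrize("omega,label", [
    (0.091, "purifying"), (1.0, "neutral"), (33.741, "positive"),
])
def test_classify_selection(omega, label):
    assert fv.classify_selection(omega) == label


def test_classify_selection_rejects_negative():
    with pytest.raises(InputError):
        fv.classify_selection(-0.1)


# ---- likelihood oracles --------------------------------------------


def _mixture_matrices(kappa, classes, pi):
    """Transition-matrix builder mirroring the documented scaling: class
    rate matrices are unscaled GY94, branch lengths divided by the
    proportion-weighted mean background rate."""
    mu = 0.0
    for p, bg, _ in classes:
        Q = build_rate_matrix(kappa, bg, pi, scale=False)
        mu += p * (-np.dot(pi, np.diag(Q)))

    def P(omega, t):
        Q = build_rate_matrix(kappa, omega, pi, scale=False)
        return expm(Q * t / mu)

    return P


def _aln(rows, domains=()):
    return fv.CodonAlignment(
        rows=tuple(fv.CodingSequence(i, s) for i, s in rows), domains=domains
    )


class TestLikelihoodOracles:
    def test_two_taxon_closed_form(self):
        rows = [("A", "ATGAAACCTGGG"), ("B", "ATGAGACCAGGT")]
        aln = _aln(rows)
        tree = PhyloTree.from_newick("(A:0.1,B:0.25);")
        classes = [(1.0, 0.3, 0.3)]
        lnl = fv.site_log_likelihood(aln, tree, kappa=2.0, classes=classes, pi=PI61)
        P = _mixture_matrices(2.0, classes, PI61)(0.3, 0.35)
        expected = sum(
            np.log(PI61[CODON_INDEX[a]] * P[CODON_INDEX[a], CODON_INDEX[b]])
            for a, b in zip(
                [rows[0][1][i:i + 3] for i in range(0, 12, 3)],
                [rows[1][1][i:i + 3] for i in range(0, 12, 3)],
            )
        )
        assert lnl == pytest.approx(expected, abs=1e-10)

    def test_three_taxon_mixture_brute_force(self):
        rows = [("A", "ATGAAACCTGGGTTA"), ("B", "ATGAGACCAGGTCTA"),
                ("C", "ATGAAACCAGGATTG")]
        aln = _aln(rows)
        tree = PhyloTree.from_newick("(A:0.1,B:0.2,C:0.15);")
        classes = [(0.7, 0.1, 0.1), (0.3, 1.5, 1.5)]
        lnl = fv.site_log_likelihood(aln, tree, kappa=1.8, classes=classes, pi=PI61)

        Pf = _mixture_matrices(1.8, classes, PI61)
        codes = [[CODON_INDEX[s[i:i + 3]] for i in range(0, 15, 3)] for _, s in rows]
        total = 0.0
        for site in range(5):
            site_l = 0.0
            for p, w, _ in classes:
                Pa, Pb, Pc = Pf(w, 0.1), Pf(w, 0.2), Pf(w, 0.15)
                # brute force over the single internal state
                l = sum(
                    PI61[i] * Pa[i, codes[0][site]] * Pb[i, codes[1][site]]
                    * Pc[i, codes[2][site]]
                    for i in range(61)
                )
                site_l += p * l
            total += np.log(site_l)
        assert lnl == pytest.approx(total, abs=1e-10)

    def test_four_taxon_branch_site_brute_force(self):
        rows = [("A", "ATGAAACCTGGGTTA"), ("B", "ATGAGACCAGGTCTA"),
                ("C", "ATGAAACCAGGATTG"), ("D", "ATGCGACCAGGATTA")]
        aln = _aln(rows)
        tree = PhyloTree.from_newick("((A:0.1,B:0.2):0.12,(C:0.05,D:0.3):0.08);")
        tree.label_clade(["A", "B"], "fg")
        tree.set_foreground_clade("fg")
        # branch-site-style classes: background omega on all branches,
        # foreground omega on the flagged (A, B) clade for class 2
        classes = [(0.6, 0.08, 0.08), (0.3, 1.0, 1.0), (0.1, 0.08, 4.0)]
        lnl = fv.site_log_likelihood(aln, tree, kappa=2.2, classes=classes, pi=PI61)

        Pf = _mixture_matrices(2.2, classes, PI61)
        codes = [[CODON_INDEX[s[i:i + 3]] for i in range(0, 15, 3)] for _, s in rows]
        total = 0.0
        for site in range(5):
            site_l = 0.0
            for p, bg, fg in classes:
                # foreground applies to the A-B clade stem and its leaves
                Pu = Pf(fg, 0.12)
                Pa, Pb = Pf(fg, 0.1), Pf(fg, 0.2)
                Pv = Pf(bg, 0.08)
                Pc, Pd = Pf(bg, 0.05), Pf(bg, 0.3)
                l = 0.0
                for r in range(61):
                    left = sum(
                        Pu[r, u] * Pa[u, codes[0][site]] * Pb[u, codes[1][site]]
                        for u in range(61)
                    )
                    right = sum(
                        Pv[r, v] * Pc[v, codes[2][site]] * Pd[v, codes[3][site]]
                        for v in range(61)
                    )
                    l += PI61[r] * left * right
                site_l += p * l
            total += np.log(site_l)
        assert lnl == pytest.approx(total, abs=1e-10)

    def test_zero_branch_lengths_identical_sequences(self):
        rows = [("A", "ATGAAA"), ("B", "ATGAAA"), ("C", "ATGAAA")]
        aln = _aln(rows)
        tree = PhyloTree.from_newick("(A:0,B:0,C:0);")
        lnl = fv.site_log_likelihood(
            aln, tree, kappa=2.0, classes=[(1.0, 0.2, 0.2)], pi=PI61
        )
        assert lnl == pytest.approx(2 * np.log(1.0 / 61), abs=1e-9)

    def test_lnl_invariant_to_row_order(self):
        rows = [("A", "ATGAAACCT"), ("B", "ATGAGACCA"), ("C", "ATGAAACCA")]
        tree = PhyloTree.from_newick("(A:0.1,B:0.2,C:0.15);")
        l1 = fv.site_log_likelihood(_aln(rows), tree, kappa=2.0,
                                    classes=[(1.0, 0.5, 0.5)], pi=PI61)
        l2 = fv.site_log_likelihood(_aln(rows[::-1]), tree, kappa=2.0,
                                    classes=[(1.0, 0.5, 0.5)], pi=PI61)
        assert l1 == pytest.approx(l2, abs=1e-12)


# ---- fitting -------------------------------------------------------


class TestM0Fit:
    def test_parameter_recovery(self, m0_family):
        aln, truth = m0_family
        fit = fv.fit_m0(aln, truth.gene_family_tree)
        assert fit.params["omega"] == pytest.approx(0.2, abs=0.05)
        assert fit.kappa == pytest.approx(2.0, abs=0.5)
        assert fit.model == "M0" and np.isfinite(fit.lnL)

    def test_leaf_mismatch_rejected(self, m0_family, tiny_alignment):
        _, truth = m0_family
        with pytest.raises(InputError):
            LikelihoodEngine(tiny_alignment, truth.gene_family_tree)


@pytest.fixture(scope="module")
def ladder(small_mixture_family):
    aln, truth = small_mixture_family
    tree = truth.gene_family_tree
    m0 = fv.fit_m0(aln, tree)
    fits = {"M0": m0}
    for m in ("M1a", "M2a", "M3", "M7", "M8"):
        fits[m] = fit_model(aln, tree, m, m0_fit=m0)
    return fits


class TestSiteModelLadder:
    def test_nesting(self, ladder):
        assert ladder["M2a"].lnL >= ladder["M1a"].lnL - 1e-6
        assert ladder["M3"].lnL >= ladder["M0"].lnL - 1e-6
        assert ladder["M8"].lnL >= ladder["M7"].lnL - 1e-2

    def test_m2a_on_neutral_data_is_degenerate(self, ladder):
        """Data without a positive class: the extra M2a class stays
        (near-)empty and the M1a-vs-M2a LRT is unremarkable."""
        p2 = ladder["M2a"].params["p2"]
        stat = fv.lrt(ladder["M2a"].lnL, ladder["M1a"].lnL, 2).stat
        assert p2 <= 0.10
        assert stat < 8.0

    def test_proportions_normalized(self, ladder):
        for fit in ladder.values():
            assert np.isclose(fit.proportions.sum(), 1.0, atol=1e-8)

    def test_posteriors_sum_to_one(self, ladder):
        post = ladder["M2a"].site_posteriors
        assert np.allclose(post.sum(axis=0), 1.0, atol=1e-9)

    def test_omega_bounds_respected(self, ladder):
        assert 1e-4 <= ladder["M2a"].params["omega0"] < 1.0
        assert 1.0 <= ladder["M2a"].params["omega2"] <= 999.0

    def test_unknown_model_rejected(self, small_mixture_family):
        aln, truth = small_mixture_family
        with pytest.raises(InputError):
            fit_model(aln, truth.gene_family_tree, "M99")


def test_beta_categories_average_to_mean():
    for p, q in [(0.4, 3.0), (2.0, 2.0), (0.2, 0.2)]:
        cats = beta_category_means(p, q)
        assert len(cats) == 10
        assert cats.mean() == pytest.approx(p / (p + q), abs=1e-6)
        assert np.all(np.diff(cats) > 0)


@pytest.fixture(scope="module")
def bs_scan(branch_site_family):
    aln, truth = branch_site_family
    return truth, branch_site_scan(aln, truth.gene_family_tree, ["AL1"])


class TestBranchSite:
    def test_detects_foreground_selection(self, bs_scan):
        truth, rows = bs_scan
        assert len(rows) == 1
        r = rows[0]
        assert r["p"] < 0.05
        assert r["alt"].params["omega2"] > 1.5

    def test_scan_emits_one_row_per_clade(self, branch_site_family):
        aln, truth = branch_site_family
        tree = truth.gene_family_tree
        labels = sorted(tree.clade_labels)
        assert labels == ["AL1", "AL2", "AL3", "AL4"]

    def test_selected_sites_enriched_in_true_positive_class(self, bs_scan):
        truth, rows = bs_scan
        alt = rows[0]["alt"]
        site_class = np.concatenate([
            truth.site_class["DUF3594"],
            truth.site_class["inter-domain"],
            truth.site_class["PHD"],
        ])
        post = alt.site_posteriors
        pos_mass = post[alt.positive_classes].sum(axis=0)
        called = np.flatnonzero(pos_mass > 0.95)
        assert called.size > 0
        frac_true = np.isin(site_class[called], (2, 3)).mean()
        assert frac_true >= 0.5

    def test_neb_and_beb_agree_on_strong_sites(self, bs_scan):
        _, rows = bs_scan
        alt = rows[0]["alt"]
        _, neb_sites = site_posteriors(alt, method="NEB", threshold=0.99)
        beb_post, _ = site_posteriors(alt, method="BEB", threshold=0.99)
        pos = np.array(alt.positive_classes)
        for site, _p in neb_sites[:5]:
            assert beb_post[pos, site - 1].sum() > 0.5

    def test_eb_requires_mixture(self, m0_family):
        aln, truth = m0_family
        fit = fv.fit_m0(aln, truth.gene_family_tree)
        with pytest.raises(InputError):
            site_posteriors(fit)
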