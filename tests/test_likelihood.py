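"""Pruning likelihoods, branch-length optimization, RELL topology tests."""

import itertools

import numpy as np
import pytest

from phylodiscord import trees
from phylodiscord.alignment import Alignment
from phylodiscord.likelihood import (
    SiteLikelihoodMatrix,
    constrained_search,
    optimize_branch_lengths,
    rell_tests,
    site_loglik,
    total_loglik,
    write_site_likelihoods,
)
from phylodiscord.models import SubstitutionModel


def brute_force_loglik(tree, aln, model):
    """Sum over all internal-state assignments (oracle for small trees)."""
    pi = model.frequencies
    nodes = list(tree.postorder())
    internals = [n for n in nodes if not n.is_leaf]
    out = np.zeros(aln.length)
    for s in range(aln.length):
        tot = 0.0
        for assign in itertools.product(range(4), repeat=len(internals)):
            amap = dict(zip((id(n) for n in internals), assign))
            p = pi[amap[id(tree)]]
            for n in nodes:
                if n.parent is None:
                    continue
                P = model.transition_matrix(n.length)
                ps = amap[id(n.parent)]
                if n.is_leaf:
                    mask = int(aln.row(n.label)[s]) or 15
                    p *= sum(P[ps, k] for k in range(4) if mask & (1 << k))
                else:
                    p *= P[ps, amap[id(n)]]
            tot += p
        out[s] = np.log(tot)
    return out


class TestSiteLoglik:
    def test_zero_branch_identical_pair(self):
        aln = Alignment([("a", "ACGT"), ("b", "ACGT")])
        t = trees.parse_newick("(a:0.0,b:0.0);")
        ll = site_loglik(t, aln, SubstitutionModel.jc69())
        assert np.allclose(ll, np.log(0.25))

    def test_two_taxon_jc_closed_form(self):
        d = 0.14
        aln = Alignment([("a", "AC"), ("b", "AG")])
        t = trees.parse_newick(f"(a:{d / 2},b:{d / 2});")
        ll = site_loglik(t, aln, SubstitutionModel.jc69())
        match = np.log(0.25 * (0.25 + 0.75 * np.exp(-4 * d / 3)))
        mismatch = np.log(0.25 * (0.25 - 0.25 * np.exp(-4 * d / 3)))
        assert ll[0] == pytest.approx(match, abs=1e-10)
        assert ll[1] == pytest.approx(mismatch, abs=1e-10)

    def test_rooting_invariance(self):
        t = trees.parse_newick("((a:0.1,b:0.2):0.05,(c:0.3,d:0.1):0.07);")
        aln = Alignment([("a", "ACGRT-"), ("b", "ACGTT?"),
                         ("c", "AAGCTN"), ("d", "ATGCTA")])
        model = SubstitutionModel.hky85(
            kappa=3.0, freqs=(0.3, 0.2, 0.3, 0.2), alpha=0.5, p_inv=0.2
        )
        base = site_loglik(t, aln, model)
        for lab in "abcd":
            rerooted = trees.reroot_at_leaf(t, lab)
            assert np.allclose(site_loglik(rerooted, aln, model), base, atol=1e-10)

    def test_matches_brute_force_enumeration(self, rng):
        t = trees.parse_newick(
            "((a:0.12,b:0.31):0.08,(c:0.2,(d:0.05,e:0.17):0.1):0.04);"
        )
        aln = Alignment(
            [(lab, "".join(rng.choice(list("ACGT-R"), size=8))) for lab in "abcde"]
        )
        model = SubstitutionModel.gtr(
            rates=(1, 2.5, 1.2, 0.8, 3.0, 1.0), freqs=(0.35, 0.15, 0.2, 0.3)
        )
        assert np.allclose(
            site_loglik(t, aln, model), brute_force_loglik(t, aln, model), atol=1e-10
        )

    def test_missing_branch_length_rejected(self):
        t = trees.parse_newick("(a,b);")
        aln = Alignment([("a", "A"), ("b", "A")])
        with pytest.raises(ValueError):
            site_loglik(t, aln, SubstitutionModel.jc69())


class TestOptimize:
    def test_identical_sequences_shrink_branches(self):
        aln = Alignment([("a", "ACGTACGT"), ("b", "ACGTACGT")])
        t = trees.parse_newick("(a:0.2,b:0.2);")
        opt, _ = optimize_branch_lengths(t, aln, SubstitutionModel.jc69())
        total = sum(n.length for n in opt.postorder() if n.parent is not None)
        assert total < 1e-6

    @pytest.mark.parametrize(
        "model,expected",
        [
            (SubstitutionModel.jc69(), -0.75 * np.log(1 - 4 * (1 / 6) / 3)),
        ],
    )
    def test_two_taxon_analytic_distance(self, model, expected):
        # 6 sites, 1 difference: ML distance has the closed JC form
        aln = Alignment([("a", "ACGTAC"), ("b", "ACGTAA")])
        t = trees.parse_newick("(a:0.05,b:0.05);")
        opt, _ = optimize_branch_lengths(t, aln, model, tol=1e-12)
        d = sum(n.length for n in opt.postorder() if n.parent is not None)
        assert d == pytest.approx(expected, abs=1e-6)

    def test_loglik_nondecreasing_over_sweeps(self, rng):
        aln = Alignment(
            [(lab, "".join(rng.choice(list("ACGT"), size=40))) for lab in "abcde"]
        )
        t = trees.parse_newick("((a:0.3,b:0.3):0.3,(c:0.3,d:0.3):0.3,e:0.3);")
        model = SubstitutionModel.jc69()
        before = total_loglik(t, aln, model)
        _, after = optimize_branch_lengths(t, aln, model, max_sweeps=3)
        assert after >= before - 1e-9


class TestConstrainedSearch:
    def test_satisfied_constraint_matches_best(self, rng):
        aln = Alignment(
            [("a", "AAAA"), ("b", "AAAC"), ("c", "CCCA"), ("d", "CCCC")]
        )
        from phylodiscord.parsimony import fitch_length, mp_search

        best, length = mp_search(aln, seed=0)
        constrained = constrained_search(aln, [frozenset(["a", "b"])])
        assert fitch_length(constrained, aln) == length

    def test_contradicted_clade_scores_worse(self):
        aln = Alignment(
            [("a", "AAAAAA"), ("b", "AAAAAA"), ("c", "CCCCCC"), ("d", "CCCCCC")]
        )
        from phylodiscord.parsimony import fitch_length, mp_search

        _, best_len = mp_search(aln, seed=0)
        forced = constrained_search(aln, [frozenset(["a", "c"])])
        assert fitch_length(forced, aln) > best_len


class TestRell:
    def test_self_comparison_p_is_one(self, rng):
        row = rng.normal(-2, 0.5, size=100)
        M = SiteLikelihoodMatrix(np.vstack([row, row.copy()]), ["t1", "t2"])
        with pytest.warns(UserWarning):
            res = rell_tests(M, n_boot=200, seed=0)
        assert res["p_wkh"][1] == 1.0
        assert res["p_wsh"][1] == 1.0

    def test_dominated_tree_rejected(self, rng):
        base = rng.normal(-2, 0.3, size=400)
        M = SiteLikelihoodMatrix(np.vstack([base, base - 0.05]), ["good", "bad"])
        res = rell_tests(M, n_boot=2000, seed=0)
        assert res["best"] == 0
        assert res["p_wkh"][1] < 0.01
        assert res["p_wsh"][1] < 0.01

    def test_wkh_agrees_with_z_test(self, rng):
        # on two trees RELL WKH reduces to a z-test of the mean site
        # difference at large bootstrap counts
        diff = rng.normal(0.004, 0.12, size=600)
        base = rng.normal(-2, 0.3, size=600)
        M = SiteLikelihoodMatrix(np.vstack([base + diff, base]), ["a", "b"])
        res = rell_tests(M, n_boot=20000, seed=1)
        from scipy import stats

        z = diff.sum() / (diff.std(ddof=0) * np.sqrt(len(diff)))
        p_z = 2 * stats.norm.sf(abs(z))
        loser = 1 if res["best"] == 0 else 0
        assert res["p_wkh"][loser] == pytest.approx(p_z, abs=0.03)

    def test_matrix_validation(self):
        with pytest.raises(ValueError):
            SiteLikelihoodMatrix(np.array([[1.0, np.inf]]), ["t"])
        with pytest.raises(ValueError):
            rell_tests(SiteLikelihoodMatrix(np.zeros((1, 5)), ["t"]))

    def test_site_likelihood_writer(self, tmp_path, rng):
        M = SiteLikelihoodMatrix(rng.normal(size=(2, 5)), ["t1", "t2"])
        path = tmp_path / "sitelik.tsv"
        write_site_likelihoods(M, str(path))
        lines = path.read_text().strip().splitlines()
        assert lines[0].split("\t") == ["site", "t1", "t2"]
        assert len(lines) == 6
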