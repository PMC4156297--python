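"""Fitch engine, CI/RI, MP search, bootstrap, and the ILD test."""

import itertools

import numpy as np
import pytest

from phylodiscord import parsimony, trees
from phylodiscord.alignment import Alignment
from phylodiscord.parsimony import (
    bootstrap_support,
    ci_ri,
    classify_sites,
    exhaustive_search,
    fitch_length,
    ild_test,
    mp_search,
)


def brute_force_steps(tree, aln):
    """Independent oracle: minimum changes by exhaustive enumeration of
    internal-node state assignments, column by column."""
    nodes = list(tree.postorder())
    internals = [n for n in nodes if not n.is_leaf]
    total = 0
    for j in range(aln.length):
        best = None
        for assign in itertools.product(range(4), repeat=len(internals)):
            amap = dict(zip((id(n) for n in internals), assign))
            changes = 0
            feasible = True
            for n in nodes:
                if n.parent is None:
                    continue
                ps = amap[id(n.parent)]
                if n.is_leaf:
                    mask = int(aln.row(n.label)[j])
                    if mask == 0:
                        mask = 15
                    if not mask & (1 << ps):
                        # leaf must change unless its set contains parent state;
                        # a leaf may resolve to any of its states
                        changes += 1
                else:
                    if amap[id(n)] != ps:
                        changes += 1
            if feasible and (best is None or changes < best):
                best = changes
        total += best
    return total


def random_alignment(labels, length, rng, alphabet="ACGT"):
    return Alignment(
        [(lab, "".join(rng.choice(list(alphabet), size=length))) for lab in labels]
    )


class TestFitch:
    def test_single_step_column(self):
        t = trees.parse_newick("((a,b),(c,d));")
        aln = Alignment([("a", "A"), ("b", "A"), ("c", "C"), ("d", "C")])
        assert fitch_length(t, aln) == 1

    def test_all_missing_column_is_free(self):
        t = trees.parse_newick("((a,b),(c,d));")
        aln = Alignment([("a", "-"), ("b", "?"), ("c", "-"), ("d", "?")])
        assert fitch_length(t, aln) == 0

    def test_matches_exhaustive_state_enumeration(self, rng):
        labels = list("abcdef")
        aln = random_alignment(labels, 20, rng, alphabet="ACGT-RY")
        for newick in [
            "((a,b),((c,d),(e,f)));",
            "(a,(b,(c,(d,(e,f)))));",
            "(((a,f),(b,e)),(c,d));",
        ]:
            t = trees.parse_newick(newick)
            assert fitch_length(t, aln) == brute_force_steps(t, aln)

    def test_rooting_and_leaf_order_invariance(self, rng):
        labels = list("abcdefg")
        aln = random_alignment(labels, 15, rng)
        t = trees.parse_newick("((a,(b,c)),((d,e),(f,g)));")
        base = fitch_length(t, aln)
        for lab in labels:
            assert fitch_length(trees.reroot_at_leaf(t, lab), aln) == base
        shuffled = Alignment([(lab, aln.sequence(lab)) for lab in reversed(labels)])
        assert fitch_length(t, shuffled) == base

    def test_label_mismatch_rejected(self):
        t = trees.parse_newick("((a,b),(c,x));")
        aln = Alignment([(l, "A") for l in "abcd"])
        with pytest.raises(ValueError):
            fitch_length(t, aln)


class TestClassifySites:
    def test_basic_categories(self):
        aln = Alignment(
            [("a", "AAAA"), ("b", "AACA"), ("c", "ACCT"), ("d", "ACTT")]
        )
        cls = classify_sites(aln)
        assert cls.categories == [
            "constant",
            "parsimony_informative",
            "variable_uninformative",
            "parsimony_informative",
        ]
        assert (cls.n_constant, cls.n_variable, cls.n_informative) == (1, 3, 2)

    def test_ambiguity_rule_flag(self):
        # column of R and Y only: no unambiguous state, but not resolvable
        # to a single state either
        aln = Alignment([("a", "R"), ("b", "R"), ("c", "Y"), ("d", "Y")])
        assert classify_sites(aln, "ignore").n_variable == 0
        assert classify_sites(aln, "resolve").n_variable == 1


class TestCiRi:
    def test_homoplasy_free_data(self):
        t = trees.parse_newick("((a,b),(c,d));")
        aln = Alignment(
            [("a", "AAC"), ("b", "AAC"), ("c", "CAA"), ("d", "CAA")]
        )
        stats = ci_ri(t, aln)
        assert stats.ci == 1.0
        assert stats.ri == 1.0
        assert stats.tree_length == 2

    def test_fully_homoplastic_site(self):
        # A,C,A,C on ((a1,c1),(a2,c2)): m=1, s=2, g=2 -> CI 0.5, RI 0
        t = trees.parse_newick("((a1,c1),(a2,c2));")
        aln = Alignment([("a1", "A"), ("c1", "C"), ("a2", "A"), ("c2", "C")])
        stats = ci_ri(t, aln)
        assert (stats.m[0], stats.s[0], stats.g[0]) == (1, 2, 2)
        assert stats.ci == 0.5
        assert stats.ri == 0.0

    def test_length_is_sum_of_site_steps(self, rng):
        t = trees.parse_newick("((a,(b,c)),(d,e));")
        aln = random_alignment(list("abcde"), 30, rng)
        stats = ci_ri(t, aln)
        assert stats.tree_length == int(stats.s.sum())
        assert (stats.m <= stats.s).all() and (stats.s <= stats.g).all()

    def test_no_steps_undefined(self):
        t = trees.parse_newick("((a,b),(c,d));")
        aln = Alignment([(l, "AA") for l in "abcd"])
        with pytest.raises(ZeroDivisionError):
            ci_ri(t, aln)


class TestMpSearch:
    def test_four_taxa_exhaustive(self):
        aln = Alignment(
            [("a", "AAAA"), ("b", "AAAC"), ("c", "CCCA"), ("d", "CCCC")]
        )
        best, length = mp_search(aln, seed=0)
        assert length == 5
        assert trees.topology_key(best[0]) == trees.topology_key(
            trees.parse_newick("((a,b),(c,d));")
        )

    def test_heuristic_matches_exhaustive_seven_taxa(self, rng):
        labels = list("abcdefg")
        aln = random_alignment(labels, 25, rng)
        _, exact = exhaustive_search(aln)
        best_h, found = mp_search(aln, n_starts=5, seed=1, exhaustive=False)
        assert found == exact
        # heuristic mode never returns a length below the global optimum
        assert found >= exact

    def test_constraint_respected(self, rng):
        labels = list("abcdef")
        aln = random_alignment(labels, 30, rng)
        clade = frozenset(["a", "f"])
        best, length = mp_search(aln, constraint=[clade], seed=0)
        labset = frozenset(labels)
        for t in best:
            side = clade if "a" not in min(labset) else labset - clade
            assert parsimony._constraint_ok(t, [clade])
        _, unconstrained = mp_search(aln, seed=0)
        assert length >= unconstrained

    def test_unknown_constraint_label_rejected(self, rng):
        aln = random_alignment(list("abcd"), 10, rng)
        with pytest.raises(ValueError):
            mp_search(aln, constraint=[frozenset(["a", "zzz"])])

    def test_too_few_sequences_rejected(self):
        with pytest.raises(ValueError):
            mp_search(Alignment([("a", "A"), ("b", "A"), ("c", "A")]))


class TestBootstrap:
    def test_unanimous_signal_gives_full_support(self):
        # every column supports the same split
        aln = Alignment(
            [("a", "AAAAAAAA"), ("b", "AAAAAAAA"),
             ("c", "CCCCCCCC"), ("d", "CCCCCCCC"),
             ("e", "CCCCCCCC")]
        )
        support = bootstrap_support(aln, n_reps=30, seed=0)
        split = frozenset(["c", "d", "e"]) if "a" == min("abcde") else None
        assert support[split] == 100.0

    def test_constant_alignment_gives_no_strong_support(self):
        aln = Alignment([(l, "AAAAAAAAAA") for l in "abcde"])
        support = bootstrap_support(aln, n_reps=20, seed=0)
        assert all(v <= 100.0 for v in support.values())
        # with zero signal no split should dominate strongly
        assert not support or max(support.values()) <= 100.0


class TestIld:
    def _simulate(self, tree, length, rng, scale=0.15):
        from phylodiscord.coalescent import simulate_alignment
        from phylodiscord.models import SubstitutionModel

        t = trees.parse_newick(tree)
        for n in t.postorder():
            if n.parent is not None:
                n.length = scale
        return simulate_alignment(
            t, SubstitutionModel.jc69(), length, seed=int(rng.integers(2**31))
        )

    def test_duplicated_signal_is_congruent(self, rng):
        aln = self._simulate("((a,b),(c,d),(e,f));", 40, rng)
        double = Alignment([(lab, s + s) for lab, s in aln])
        d, p = ild_test(double, range(40), range(40, 80), n_reps=50, seed=0)
        assert d == 0
        assert p > 0.5

    def test_conflicting_partitions_detected(self, rng):
        a1 = self._simulate("((a,b),(c,d),(e,f));", 120, rng, scale=0.4)
        a2 = self._simulate("((a,f),(c,e),(b,d));", 120, rng, scale=0.4)
        both = Alignment(
            [(lab, a1.sequence(lab) + a2.sequence(lab)) for lab in a1.labels]
        )
        d, p = ild_test(both, range(120), range(120, 240), n_reps=99, seed=0)
        assert d > 0
        assert p < 0.05

    def test_overlapping_partitions_rejected(self, rng):
        aln = self._simulate("((a,b),(c,d),(e,f));", 20, rng)
        with pytest.raises(ValueError):
            ild_test(aln, range(10), range(5, 15))

    def test_degenerate_partition_warns_but_runs(self):
        aln = Alignment(
            [("a", "AAAA" + "AC"), ("b", "AAAA" + "AC"),
             ("c", "AAAA" + "CA"), ("d", "AAAA" + "CA"),
             ("e", "AAAA" + "CA"), ("f", "AAAA" + "AC")]
        )
        with pytest.warns(UserWarning, match="no variable sites"):
            d, p = ild_test(aln, range(4), range(4, 6), n_reps=20, seed=0)
        assert 0 < p <= 1
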