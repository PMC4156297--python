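"""MSC gene-tree simulation, sequence evolution, and the
posterior-predictive hybridization test."""

import numpy as np
import pytest

from phylodiscord import trees
from phylodiscord.alignment import Alignment, p_distance
from phylodiscord.coalescent import (
    HybridizationEvent,
    LocusConfig,
    SpeciesTreeSample,
    check_msc_constraint,
    min_interspecies_distance,
    posterior_predictive_test,
    read_posterior,
    simulate_alignment,
    simulate_gene_tree,
    write_test_results,
)
from phylodiscord.models import SubstitutionModel

ONE_SPECIES = "A[&theta=0.01]:0.0;"
TWO_SPECIES = "(A[&theta=1e-6]:0.01,B[&theta=1e-6]:0.01)[&theta=1e-6];"


class TestSpeciesTree:
    def test_heights_from_lengths(self):
        s = SpeciesTreeSample.from_newick(
            "(A[&theta=0.01]:0.02,B[&theta=0.01]:0.02)[&theta=0.01];"
        )
        heights = {n.label: n.height for n in s.tree.postorder()}
        assert heights["A"] == 0.0
        assert s.tree.height == pytest.approx(0.02)

    def test_missing_theta_rejected(self):
        with pytest.raises(ValueError):
            SpeciesTreeSample.from_newick("(A:0.02,B:0.02);")

    def test_posterior_reader(self, tmp_path):
        path = tmp_path / "post.nwk"
        path.write_text(TWO_SPECIES + "\n" + TWO_SPECIES + "\n")
        post = read_posterior(str(path))
        assert len(post) == 2
        assert post[0].species == ["A", "B"]


class TestGeneTreeSimulation:
    def test_pairwise_tmrca_matches_theta_times_heredity(self, rng):
        s = SpeciesTreeSample.from_newick(ONE_SPECIES)
        t = np.mean(
            [simulate_gene_tree(s, {"A": 2}, heredity=2.0, rng=rng).height
             for _ in range(4000)]
        )
        assert t == pytest.approx(0.02, rel=0.08)

    def test_multi_sample_tmrca_expectation(self, rng):
        s = SpeciesTreeSample.from_newick(ONE_SPECIES)
        t = np.mean(
            [simulate_gene_tree(s, {"A": 6}, heredity=1.0, rng=rng).height
             for _ in range(4000)]
        )
        assert t == pytest.approx(2 * 0.01 * (1 - 1 / 6), rel=0.08)

    def test_tiny_theta_cross_coalescence_at_divergence(self, rng):
        s = SpeciesTreeSample.from_newick(TWO_SPECIES)
        for _ in range(20):
            g = simulate_gene_tree(s, {"A": 1, "B": 1}, rng=rng)
            assert g.height == pytest.approx(0.01, abs=5e-4)

    def test_msc_constraint_on_replicates(self, rng):
        s = SpeciesTreeSample.from_newick(
            "((A[&theta=0.004]:0.01,B[&theta=0.004]:0.01)[&theta=0.004]:0.01,"
            "C[&theta=0.004]:0.02)[&theta=0.004];"
        )
        species_of = {"A_1": "A", "A_2": "A", "B_1": "B", "C_1": "C"}
        for _ in range(50):
            g = simulate_gene_tree(s, {"A": 2, "B": 1, "C": 1}, rng=rng)
            assert check_msc_constraint(g, s, species_of)

    def test_explicit_tip_labels(self, rng):
        s = SpeciesTreeSample.from_newick(ONE_SPECIES)
        g = simulate_gene_tree(s, {"A": ["x", "y", "z"]}, rng=rng)
        assert sorted(trees.leaf_labels(g)) == ["x", "y", "z"]

    def test_empty_sampling_rejected(self, rng):
        s = SpeciesTreeSample.from_newick(ONE_SPECIES)
        with pytest.raises(ValueError):
            simulate_gene_tree(s, {}, rng=rng)


class TestSequenceSimulation:
    def test_zero_rate_gives_identical_sequences(self):
        t = trees.parse_newick("(x:0.5,y:0.5);")
        aln = simulate_alignment(t, SubstitutionModel.jc69(), 50, mu_rel=0.0, seed=1)
        assert aln.sequence("x") == aln.sequence("y")

    def test_jc_expected_difference(self):
        d = 0.2
        t = trees.parse_newick("(x:0.1,y:0.1);")
        aln = simulate_alignment(t, SubstitutionModel.jc69(), 60000, seed=3)
        expected = 0.75 * (1 - np.exp(-4 * d / 3))
        assert p_distance(aln.sequence("x"), aln.sequence("y")) == pytest.approx(
            expected, rel=0.05
        )

    def test_base_composition_converges_to_model(self):
        freqs = (0.4, 0.1, 0.2, 0.3)
        model = SubstitutionModel.hky85(kappa=2.0, freqs=freqs)
        t = trees.parse_newick("(x:0.3,y:0.3);")
        aln = simulate_alignment(t, model, 50000, seed=5)
        from phylodiscord.models import empirical_frequencies

        assert np.allclose(empirical_frequencies(aln), freqs, atol=0.01)


class TestMinDistance:
    def test_shared_haplotype_gives_zero(self):
        aln = Alignment([("A_1", "ACGT"), ("A_2", "ACGA"), ("B_1", "ACGT")])
        res = min_interspecies_distance(aln, {"A_1": "A", "A_2": "A", "B_1": "B"})
        d, pair = res[("A", "B")]
        assert d == 0.0
        assert pair == ("A_1", "B_1")

    def test_singletons_equal_plain_distance(self):
        aln = Alignment([("x", "ACGT"), ("y", "ACGA")])
        res = min_interspecies_distance(aln, {"x": "X", "y": "Y"})
        assert res[("X", "Y")][0] == p_distance("ACGT", "ACGA")

    def test_matches_exhaustive_pair_scan(self, rng):
        labels = [f"A_{i}" for i in range(3)] + [f"B_{i}" for i in range(4)]
        aln = Alignment(
            [(lab, "".join(rng.choice(list("ACGT"), size=30))) for lab in labels]
        )
        smap = {lab: lab.split("_")[0] for lab in labels}
        res = min_interspecies_distance(aln, smap)
        brute = min(
            p_distance(aln.sequence(a), aln.sequence(b))
            for a in labels[:3]
            for b in labels[3:]
        )
        assert res[("A", "B")][0] == pytest.approx(brute)

    def test_unknown_label_rejected(self):
        aln = Alignment([("x", "ACGT")])
        with pytest.raises(ValueError):
            min_interspecies_distance(aln, {"zzz": "A"})


class TestPosteriorPredictive:
    def test_large_observed_distance_gives_p_one(self):
        s = SpeciesTreeSample.from_newick(TWO_SPECIES)
        # observed sequences maximally distant: no simulation can exceed it
        obs = Alignment([("A_1", "A" * 40), ("B_1", "C" * 40)])
        res = posterior_predictive_test(
            [s.copy() for _ in range(40)],
            obs,
            {"A_1": "A", "B_1": "B"},
            LocusConfig(model=SubstitutionModel.jc69(), length=40),
            seed=0,
        )
        assert len(res) == 1
        assert res[0].p_value == 1.0
        assert not res[0].flagged

    def test_introgressed_zero_distance_flagged(self):
        # deep divergence, tiny theta: an observed shared haplotype is
        # essentially impossible under no migration
        s = SpeciesTreeSample.from_newick(
            "(A[&theta=0.001]:0.05,B[&theta=0.001]:0.05)[&theta=0.001];"
        )
        obs = Alignment([("A_1", "A" * 60), ("B_1", "A" * 60)])
        res = posterior_predictive_test(
            [s.copy() for _ in range(60)],
            obs,
            {"A_1": "A", "B_1": "B"},
            LocusConfig(model=SubstitutionModel.jc69(), length=60),
            seed=0,
        )
        assert res[0].p_value < 0.05
        assert res[0].flagged

    def test_burn_in_and_thinning(self):
        s = SpeciesTreeSample.from_newick(TWO_SPECIES)
        obs = Alignment([("A_1", "A" * 20), ("B_1", "C" * 20)])
        res = posterior_predictive_test(
            [s.copy() for _ in range(20)],
            obs,
            {"A_1": "A", "B_1": "B"},
            LocusConfig(model=SubstitutionModel.jc69(), length=20),
            burn_in=10,
            thinning=2,
            seed=0,
        )
        assert res[0].n_simulations == 5

    def test_no_retained_samples_rejected(self):
        s = SpeciesTreeSample.from_newick(TWO_SPECIES)
        obs = Alignment([("A_1", "AA"), ("B_1", "CC")])
        with pytest.raises(ValueError):
            posterior_predictive_test(
                [s], obs, {"A_1": "A", "B_1": "B"},
                LocusConfig(model=SubstitutionModel.jc69(), length=2),
                burn_in=5,
            )

    def test_result_writer(self, tmp_path):
        s = SpeciesTreeSample.from_newick(TWO_SPECIES)
        obs = Alignment([("A_1", "A" * 20), ("B_1", "C" * 20)])
        res = posterior_predictive_test(
            [s.copy() for _ in range(10)], obs, {"A_1": "A", "B_1": "B"},
            LocusConfig(model=SubstitutionModel.jc69(), length=20), seed=0,
        )
        path = tmp_path / "hyb.tsv"
        write_test_results(res, str(path), gene="cpDNA")
        lines = path.read_text().strip().splitlines()
        assert lines[0].startswith("Gene\t")
        assert lines[1].split("\t")[0] == "cpDNA"


class TestHybridizationPulse:
    def test_recent_pulse_moves_coalescence_below_divergence(self, rng):
        s = SpeciesTreeSample.from_newick(
            "(A[&theta=0.002]:0.03,B[&theta=0.002]:0.03)[&theta=0.002];"
        )
        ev = HybridizationEvent(donor="A", recipient="B", time=0.001, gamma=1.0)
        heights = [
            simulate_gene_tree(s, {"A": 1, "B": 1}, hybridization=[ev], rng=rng).height
            for _ in range(200)
        ]
        # with gamma=1 the two lineages share species A from t=0.001 on
        assert np.mean(heights) < 0.02

    def test_invalid_gamma_rejected(self):
        with pytest.raises(ValueError):
            HybridizationEvent("A", "B", 0.01, 1.5)
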