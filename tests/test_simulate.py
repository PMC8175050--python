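import numpy as np
import pytest

from hetphylo.alphabets import DNA
from hetphylo.errors import UsageError
from hetphylo.models import (
    GammaASRV,
    MixtureComposition,
    SingleComposition,
    SubstitutionModel,
    build_rate_matrix,
    jc69,
    transition_matrix,
    uniform_exchangeabilities,
)
from hetphylo.msa import composition_counts, constant_columns
from hetphylo.simulate import (
    fixture_info,
    fixture_trees,
    hogenom_like_bank,
    make_case_study,
    sample_profile_set,
    simulate_alignment,
    simulate_from_manifest,
)
from hetphylo.trees import parse_newick, robinson_foulds


class TestProfileSampler:
    def test_single_profile_on_simplex(self):
        ps = sample_profile_set(1, 20, seed=0)
        assert ps.profiles.shape == (1, 20)
        assert ps.profiles.sum() == pytest.approx(1.0)

    def test_huge_concentration_near_uniform(self):
        ps = sample_profile_set(5, 10, concentration=1e6, seed=1)
        assert np.allclose(ps.profiles, 0.1, atol=1e-3)

    def test_dirichlet_mean_is_uniform(self):
        ps = sample_profile_set(10_000, 4, concentration=0.2, seed=2)
        # per-coordinate SE ~ sqrt(0.104 / 10000) ~ 0.0032
        assert np.allclose(ps.profiles.mean(axis=0), 0.25, atol=0.01)

    def test_invalid_arguments(self):
        with pytest.raises(UsageError):
            sample_profile_set(0, 4)
        with pytest.raises(UsageError):
            sample_profile_set(2, 4, concentration=0.0)

    def test_bank_is_deterministic_and_clustered(self):
        b1 = hogenom_like_bank(64)
        b2 = hogenom_like_bank(64)
        assert np.array_equal(b1.profiles, b2.profiles)
        assert b1.K == 64 and b1.n_states == 20


class TestSimulator:
    def test_zero_branch_lengths_all_constant(self):
        tree = parse_newick("((a:0,b:0):0,(c:0,d:0):0);")
        aln, _ = simulate_alignment(tree, jc69(), 100, seed=3)
        cols, _ = constant_columns(aln)
        assert len(cols) == 100

    def test_two_taxon_difference_matches_closed_form(self):
        tree = parse_newick("(a:0.1,b:0.2);")
        pi = np.array([0.4, 0.3, 0.2, 0.1])
        model = SubstitutionModel(DNA, uniform_exchangeabilities(4),
                                  SingleComposition(pi))
        aln, _ = simulate_alignment(tree, model, 100_000, seed=4)
        Q = build_rate_matrix(model.exchangeabilities, pi)
        P = transition_matrix(Q, 0.3)
        expected = 1.0 - float((pi * np.diag(P)).sum())
        observed = np.mean(aln.matrix[0] != aln.matrix[1])
        se = np.sqrt(expected * (1 - expected) / 100_000)
        assert abs(observed - expected) < 3 * se

    def test_leaf_frequencies_match_composition(self):
        tree = parse_newick("((a:0.3,b:0.2):0.1,(c:0.25,d:0.15):0.1);")
        pi = np.array([0.35, 0.3, 0.2, 0.15])
        model = SubstitutionModel(DNA, uniform_exchangeabilities(4),
                                  SingleComposition(pi))
        aln, _ = simulate_alignment(tree, model, 100_000, seed=5)
        freqs = composition_counts(aln).frequencies()
        for label in aln.labels:
            for j, p in enumerate(pi):
                se = np.sqrt(p * (1 - p) / 100_000)
                assert abs(freqs.loc[label].iloc[j] - p) < 4 * se

    def test_deterministic_given_seed(self, four_taxon_tree, jc_gamma):
        a1, _ = simulate_alignment(four_taxon_tree, jc_gamma, 200, seed=9)
        a2, _ = simulate_alignment(four_taxon_tree, jc_gamma, 200, seed=9)
        a3, _ = simulate_alignment(four_taxon_tree, jc_gamma, 200, seed=10)
        assert a1 == a2
        assert a1 != a3

    def test_manifest_replay_exact(self, four_taxon_tree):
        bank = sample_profile_set(4, 4, seed=6)
        model = SubstitutionModel(DNA, uniform_exchangeabilities(4),
                                  MixtureComposition(bank, np.full(4, 0.25)),
                                  GammaASRV(0.8, 4))
        aln, meta = simulate_alignment(four_taxon_tree, model, 150, seed=7)
        again, _ = simulate_from_manifest(meta["manifest"])
        assert again == aln

    def test_continuous_gamma_rates(self, four_taxon_tree):
        model = jc69(GammaASRV(0.935, 4))
        aln, meta = simulate_alignment(four_taxon_tree, model, 5000, seed=8,
                                       continuous_gamma=True)
        assert meta["rate_categories"] is None
        assert meta["rates"].mean() == pytest.approx(1.0, abs=0.1)

    def test_mixture_metadata_records_profiles(self, four_taxon_tree):
        bank = sample_profile_set(3, 4, seed=1)
        model = SubstitutionModel(DNA, uniform_exchangeabilities(4),
                                  MixtureComposition(bank,
                                                     np.array([0.5, 0.25, 0.25])))
        aln, meta = simulate_alignment(four_taxon_tree, model, 1000, seed=2)
        idx = meta["profile_index"]
        assert idx.shape == (1000,)
        assert set(np.unique(idx)) <= {0, 1, 2}
        assert np.mean(idx == 0) == pytest.approx(0.5, abs=0.06)


class TestFixtures:
    def test_two_domain_regime(self):
        t = fixture_trees("two_domain_like", 12)
        assert len(t.leaf_names()) == 12
        lengths = {tuple(sorted(l.name for l in n.leaves())): n.length
                   for n in t.postorder() if n.parent is not None}
        assert lengths[("E1", "E2")] >= 1.5      # the long stem
        att = lengths[("A1", "A2", "A3", "A4", "E1", "E2")]
        assert att <= 0.05                        # short attachment edge
        assert lengths[("B1", "B2", "B3")] >= 1.5  # distant outgroup

    def test_fixture_determinism_and_distinctness(self):
        a = fixture_trees("two_domain_like", 12)
        b = fixture_trees("two_domain_like", 12)
        c = fixture_trees("three_domain_like", 12)
        assert a.to_newick() == b.to_newick()
        assert robinson_foulds(a, c) > 0

    def test_scaling_adds_backbone_taxa(self):
        t = fixture_trees("two_domain_like", 14)
        assert len(t.leaf_names()) == 14

    def test_thermus_like_lengths_in_range(self):
        t = fixture_trees("thermus_like")
        for n in t.postorder():
            if n.parent is not None:
                assert 0.05 <= n.length <= 0.5

    def test_info_clans_consistent_with_trees(self):
        from hetphylo.trees import is_clan

        t2 = fixture_trees("two_domain_like", 12)
        info = fixture_info("two_domain_like")
        assert all(is_clan(t2, c) for c in info["required_clans"])
        assert not any(is_clan(t2, c) for c in info["forbidden_clans"])
        t3 = fixture_trees("three_domain_like", 12)
        info3 = fixture_info("three_domain_like")
        assert all(is_clan(t3, c) for c in info3["required_clans"])


class TestCaseStudies:
    def test_composition_attraction_fails_chi2(self):
        from hetphylo.diagnostics import chi2_composition

        aln, tree, manifest = make_case_study("composition_attraction",
                                              seed=0, n_sites=5000)
        res = chi2_composition(composition_counts(aln))
        assert res.p_value < 0.05
        assert manifest["kind"] == "composition_attraction"

    def test_degenerate_map_equals_homogeneous(self):
        # identical vectors on every branch reduce to the single-pi process
        from hetphylo.models import BranchComposition, BranchCompositionMap, edge_key

        tree = parse_newick("((a:0.1,b:0.2):0.05,(c:0.15,d:0.1):0.05);")
        pi = np.array([0.4, 0.2, 0.2, 0.2])
        assignment = {edge_key(n): 0 for n in tree.postorder()
                      if n.parent is not None}
        het = SubstitutionModel(
            DNA, uniform_exchangeabilities(4),
            BranchComposition(BranchCompositionMap(pi[None, :], assignment, 0)))
        hom = SubstitutionModel(DNA, uniform_exchangeabilities(4),
                                SingleComposition(pi))
        a1, _ = simulate_alignment(tree, het, 300, seed=11)
        a2, _ = simulate_alignment(tree, hom, 300, seed=11)
        assert a1 == a2

    def test_branch_heterogeneous_manifest_replay(self):
        aln, tree, manifest = make_case_study("branch_heterogeneous", seed=3,
                                              n_sites=300)
        again, _ = simulate_from_manifest(manifest)
        assert again == aln

    def test_unknown_kind(self):
        with pytest.raises(UsageError):
            make_case_study("nope")
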