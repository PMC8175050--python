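import numpy as np
import pytest

from hetphylo.alphabets import AA, BIN, DNA, get_alphabet
from hetphylo.errors import UsageError
from hetphylo.likelihood import (
    PruningEngine,
    bootstrap_support,
    log_likelihood,
    optimize,
    search_topology,
)
from hetphylo.models import (
    BranchComposition,
    BranchCompositionMap,
    GammaASRV,
    MixtureComposition,
    ProfileSet,
    SingleComposition,
    SubstitutionModel,
    edge_key,
    jc69,
    transition_matrix,
    uniform_exchangeabilities,
)
from hetphylo.msa import Alignment, loads
from hetphylo.simulate import simulate_alignment
from hetphylo.trees import enumerate_topologies, parse_newick, robinson_foulds

from .conftest import random_model
from .oracles import brute_force_lnl


def _random_instance(rng):
    """Small random (tree, alignment, model) across composition modes."""
    alphabet = get_alphabet(rng.choice(["DNA", "BIN", "AA"]))
    c = alphabet.size
    n_leaves = int(rng.integers(2, 5))
    names = [f"t{i}" for i in range(n_leaves)]
    if n_leaves == 2:
        topo = parse_newick(f"({names[0]}:0.2,{names[1]}:0.3);")
    else:
        topos = list(enumerate_topologies(names))
        topo = topos[rng.integers(len(topos))]
    for n in topo.postorder():
        if n.parent is not None:
            n.length = float(rng.uniform(0.01, 0.9))
    asrv = None if rng.random() < 0.4 else GammaASRV(float(rng.uniform(0.3, 2.0)), 2)
    mode = rng.choice(["single", "mixture", "branch"])
    if mode in ("single", "mixture"):
        model = random_model(rng, alphabet, mode, asrv)
    else:
        R = np.triu(rng.uniform(0.3, 2.0, (c, c)), 1)
        R = R + R.T
        pool = rng.dirichlet(np.ones(c), 2)
        assignment = {edge_key(n): int(rng.integers(2))
                      for n in topo.postorder() if n.parent is not None}
        model = SubstitutionModel(
            alphabet, R,
            BranchComposition(BranchCompositionMap(pool, assignment, 0)), asrv)
    L = int(rng.integers(3, 8))
    chars = list(alphabet.states) + ["-", "?"]
    mat = rng.choice(chars, size=(n_leaves, L))
    return topo, Alignment(names, mat, alphabet), model


class TestPruningCorrectness:
    def test_matches_brute_force_across_modes(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            tree, aln, model = _random_instance(rng)
            got, _ = log_likelihood(tree, aln, model)
            want = brute_force_lnl(tree, aln, model)
            assert got == pytest.approx(want, rel=1e-8)

    def test_two_taxon_closed_form(self):
        # L(site) = pi_x P_xy(t1 + t2) for a reversible single-pi model
        rng = np.random.default_rng(1)
        model = random_model(rng, DNA, "single")
        tree = parse_newick("(a:0.15,b:0.25);")
        aln = loads(">a\nACGTAC\n>b\nACGAAC\n", "fasta", "DNA")
        from hetphylo.models import build_rate_matrix

        pi = model.composition.pi
        Q = build_rate_matrix(model.exchangeabilities, pi)
        P = transition_matrix(Q, 0.4)
        idx = [DNA.index(ch) for ch in "ACGT"]
        expected = 0.0
        for x, y in zip(aln.sequence("a"), aln.sequence("b")):
            expected += np.log(pi[DNA.index(x)] * P[DNA.index(x), DNA.index(y)])
        got, _ = log_likelihood(tree, aln, model)
        assert got == pytest.approx(expected, rel=1e-10)

    def test_all_missing_column_contributes_zero(self, four_taxon_tree, jc_gamma):
        base = loads(">t1\nACG\n>t2\nACG\n>t3\nACG\n>t4\nACG\n",
                     "fasta", "DNA")
        with_gap = loads(">t1\nACG-\n>t2\nACG?\n>t3\nACG-\n>t4\nACG-\n",
                         "fasta", "DNA")
        l1, _ = log_likelihood(four_taxon_tree, base, jc_gamma)
        l2, per_site = log_likelihood(four_taxon_tree, with_gap, jc_gamma)
        assert l2 == pytest.approx(l1, abs=1e-10)
        assert per_site[-1] == pytest.approx(0.0, abs=1e-12)

    def test_invariance_to_taxon_and_site_order(self, four_taxon_tree, jc_gamma):
        rng = np.random.default_rng(0)
        aln, _ = simulate_alignment(four_taxon_tree, jc_gamma, 50, seed=5)
        l0, _ = log_likelihood(four_taxon_tree, aln, jc_gamma)
        shuffled_taxa = aln.take_taxa(["t3", "t1", "t4", "t2"])
        l1, _ = log_likelihood(four_taxon_tree, shuffled_taxa, jc_gamma)
        cols = rng.permutation(aln.n_sites)
        l2, _ = log_likelihood(four_taxon_tree, aln.take_sites(cols), jc_gamma)
        assert l1 == pytest.approx(l0, rel=1e-12)
        assert l2 == pytest.approx(l0, rel=1e-12)

    def test_root_invariance_reversible_but_not_branch_map(self):
        rng = np.random.default_rng(3)
        aln = loads(">a\nACGTT\n>b\nACGAT\n>c\nGCGTA\n>d\nACTTA\n",
                    "fasta", "DNA")
        t1 = parse_newick("((a:0.1,b:0.2):0.05,(c:0.15,d:0.1):0.07);")
        t2 = parse_newick("(a:0.1,(b:0.2,((c:0.15,d:0.1):0.07):0.05):0.0);")
        t2b = parse_newick("(a:0.1,(b:0.2,(c:0.15,d:0.1):0.12):0.0);")
        single = random_model(rng, DNA, "single")
        la, _ = log_likelihood(t1, aln, single)
        lb, _ = log_likelihood(t2b, aln, single)
        assert la == pytest.approx(lb, rel=1e-10)
        # branch-heterogeneous compositions break the pulley principle
        pool = np.array([[0.7, 0.1, 0.1, 0.1], [0.1, 0.4, 0.4, 0.1]])
        def bmap_for(t):
            assignment = {edge_key(n): (0 if "a" in edge_key(n) else 1)
                          for n in t.postorder() if n.parent is not None}
            return SubstitutionModel(
                DNA, uniform_exchangeabilities(4),
                BranchComposition(BranchCompositionMap(pool, assignment, 0)),
                None)
        lh1, _ = log_likelihood(t1, aln, bmap_for(t1))
        lh2, _ = log_likelihood(t2b, aln, bmap_for(t2b))
        assert abs(lh1 - lh2) > 1e-6

    def test_identical_profiles_collapse_to_single(self, four_taxon_tree):
        pi = np.array([0.4, 0.3, 0.2, 0.1])
        single = SubstitutionModel(DNA, uniform_exchangeabilities(4),
                                   SingleComposition(pi))
        triple = SubstitutionModel(
            DNA, uniform_exchangeabilities(4),
            MixtureComposition(ProfileSet(np.tile(pi, (3, 1))),
                               np.array([0.2, 0.5, 0.3])))
        aln, _ = simulate_alignment(four_taxon_tree, single, 40, seed=9)
        l1, _ = log_likelihood(four_taxon_tree, aln, single)
        l2, _ = log_likelihood(four_taxon_tree, aln, triple)
        assert l2 == pytest.approx(l1, rel=1e-12)

    def test_float32_engine_close_to_float64(self, four_taxon_tree, jc_gamma):
        aln, _ = simulate_alignment(four_taxon_tree, jc_gamma, 200, seed=2)
        e64 = PruningEngine(four_taxon_tree, aln, jc_gamma, dtype=np.float64)
        e32 = PruningEngine(four_taxon_tree, aln, jc_gamma, dtype=np.float32)
        assert e32.lnl() == pytest.approx(e64.lnl(), abs=0.05)

    def test_leaf_mismatch_raises(self, jc_gamma):
        t = parse_newick("((a:1,b:1):1,(c:1,x:1):1);")
        aln = loads(">a\nAC\n>b\nAC\n>c\nAC\n>d\nAC\n", "fasta", "DNA")
        with pytest.raises(UsageError):
            log_likelihood(t, aln, jc_gamma)

    def test_multifurcation_rejected(self, jc_gamma):
        t = parse_newick("((a:1,b:1,c:1):1,(d:1,e:1):1);")
        aln = loads(">a\nAC\n>b\nAC\n>c\nAC\n>d\nAC\n>e\nAC\n", "fasta", "DNA")
        with pytest.raises(UsageError):
            log_likelihood(t, aln, jc_gamma)


class TestOptimize:
    def test_empty_free_returns_inputs(self, four_taxon_tree, jc_gamma):
        aln, _ = simulate_alignment(four_taxon_tree, jc_gamma, 100, seed=1)
        res = optimize(four_taxon_tree, aln, jc_gamma, free=())
        l0, _ = log_likelihood(four_taxon_tree, aln, jc_gamma)
        assert res.lnl == pytest.approx(l0)
        assert res.tree.to_newick() == four_taxon_tree.copy().to_newick()

    def test_lnl_never_decreases(self, four_taxon_tree, jc_gamma):
        aln, _ = simulate_alignment(four_taxon_tree, jc_gamma, 300, seed=4)
        start, _ = log_likelihood(four_taxon_tree, aln, jc_gamma)
        res = optimize(four_taxon_tree, aln, jc_gamma,
                       free=("branch_lengths", "alpha"), tol=1e-4,
                       max_sweeps=10)
        assert res.lnl >= start - 1e-9

    def test_branch_length_recovery(self):
        tree = parse_newick(
            "((a:0.12,b:0.3):0.08,(c:0.2,d:0.1):0.06,(e:0.25,f:0.15):0.1);")
        model = jc69()
        aln, _ = simulate_alignment(tree, model, 10_000, seed=11)
        res = optimize(tree, aln, model, free=("branch_lengths",),
                       tol=1e-6, max_sweeps=50)
        got = {tuple(sorted(l.name for l in n.leaves())): n.length
               for n in res.tree.postorder() if n.parent is not None}
        want = {tuple(sorted(l.name for l in n.leaves())): n.length
                for n in tree.postorder() if n.parent is not None}
        rel_errors = [abs(got[k] - want[k]) / want[k] for k in want]
        assert np.mean(rel_errors) < 0.10

    def test_gtr_and_composition_blocks_improve(self):
        tree = parse_newick("((a:0.2,b:0.3):0.1,(c:0.25,d:0.15):0.1);")
        gen = SubstitutionModel(
            DNA, np.array([[0, 1, 3, 1], [1, 0, 1, 5], [3, 1, 0, 1],
                           [1, 5, 1, 0]], float),
            SingleComposition(np.array([0.4, 0.25, 0.2, 0.15])))
        aln, _ = simulate_alignment(tree, gen, 2000, seed=8)
        start = jc69()
        res = optimize(tree, aln, start,
                       free=("branch_lengths", "gtr_rates", "compositions"),
                       tol=1e-3, max_sweeps=4)
        base = optimize(tree, aln, start, free=("branch_lengths",),
                        tol=1e-3, max_sweeps=4)
        assert res.lnl > base.lnl + 10


class TestSearch:
    def test_exhaustive_recovers_clean_four_taxon(self):
        tree = parse_newick("((a:0.1,b:0.1):0.15,(c:0.1,d:0.1):0.15);")
        model = jc69()
        aln, _ = simulate_alignment(tree, model, 2000, seed=3)
        best, lnl = search_topology(aln, model, strategy="exhaustive",
                                    free=("branch_lengths",), tol=1e-3)
        assert robinson_foulds(best, tree) == 0

    def test_exhaustive_taxon_cap(self, jc_gamma):
        labels = [f"t{i}" for i in range(9)]
        aln = Alignment(labels, np.full((9, 4), "A"), DNA)
        with pytest.raises(UsageError):
            search_topology(aln, jc_gamma, strategy="exhaustive")

    def test_nni_improves_on_start(self):
        tree = parse_newick(
            "((a:0.1,b:0.1):0.1,(c:0.1,d:0.1):0.1,(e:0.1,f:0.1):0.1);")
        model = jc69()
        aln, _ = simulate_alignment(tree, model, 1000, seed=6)
        wrong = parse_newick(
            "((a:0.1,c:0.1):0.1,(b:0.1,d:0.1):0.1,(e:0.1,f:0.1):0.1);")
        start_lnl, _ = log_likelihood(wrong, aln, model)
        best, lnl = search_topology(aln, model, strategy="nni", start=wrong,
                                    free=("branch_lengths",), tol=1e-3)
        assert lnl >= start_lnl
        assert robinson_foulds(best, tree) == 0

    def test_unknown_strategy(self, dna_alignment, jc_gamma):
        with pytest.raises(UsageError):
            search_topology(dna_alignment, jc_gamma, strategy="anneal")


class TestBootstrap:
    def test_supports_within_range_and_strong_signal(self):
        tree = parse_newick("((a:0.1,b:0.1):0.3,(c:0.1,d:0.1):0.3);")
        model = jc69()
        aln, _ = simulate_alignment(tree, model, 3000, seed=12)
        boot = bootstrap_support(aln, model, strategy="nni", B=10, seed=0)
        sups = [n.support for n in boot.postorder()
                if n.support is not None]
        assert sups and all(0 <= s <= 100 for s in sups)
        assert max(sups) >= 95  # clean strong-signal simulation

    def test_single_replicate_supports_are_binary(self):
        tree = parse_newick("((a:0.2,b:0.2):0.2,(c:0.2,d:0.2):0.2);")
        model = jc69()
        aln, _ = simulate_alignment(tree, model, 500, seed=13)
        boot = bootstrap_support(aln, model, strategy="nni", B=1, seed=5)
        sups = [n.support for n in boot.postorder() if n.support is not None]
        assert set(sups) <= {0.0, 100.0}
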