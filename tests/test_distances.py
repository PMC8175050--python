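import numpy as np
import pytest

from hetphylo.distances import (
    DistanceMatrix,
    distance_matrix,
    divergence_matrix,
    jc_distance,
    logdet_distance,
    neighbor_joining,
    read_phylip_distances,
    write_phylip_distances,
)
from hetphylo.errors import UsageError
from hetphylo.models import jc69
from hetphylo.msa import loads
from hetphylo.simulate import simulate_alignment
from hetphylo.trees import all_splits, parse_newick, robinson_foulds


class TestDivergenceMatrix:
    def test_identical_sequences_diagonal(self):
        a = loads(">x\nAACGT\n>y\nAACGT\n", "fasta", "DNA")
        F = divergence_matrix(a, "x", "y")
        assert np.allclose(F.F, np.diag(np.diag(F.F)))
        assert F.n == 5

    def test_pair_counts(self):
        a = loads(">x\nAC\n>y\nAG\n", "fasta", "DNA")
        F = divergence_matrix(a, "x", "y")
        assert F.F[0, 0] == 1  # A aligned to A
        assert F.F[1, 2] == 1  # C aligned to G

    def test_conservation_with_missing(self):
        a = loads(">x\nAC-GN\n>y\nA?CGT\n", "fasta", "DNA")
        F = divergence_matrix(a, "x", "y")
        assert F.n + F.n_skipped == a.n_sites

    def test_same_taxon_rejected(self):
        a = loads(">x\nAC\n>y\nAG\n", "fasta", "DNA")
        with pytest.raises(UsageError):
            divergence_matrix(a, "x", "x")


class TestLogDet:
    def test_identical_sequences_zero_paralinear(self):
        a = loads(">x\nAACCGGTTACGT\n>y\nAACCGGTTACGT\n", "fasta", "DNA")
        F = divergence_matrix(a, "x", "y")
        d, reason = logdet_distance(F, "paralinear")
        assert reason is None
        assert d == pytest.approx(0.0, abs=1e-12)

    def test_logdet_zero_for_identical_uniform(self):
        a = loads(">x\nACGT\n>y\nACGT\n", "fasta", "DNA")
        d, reason = logdet_distance(divergence_matrix(a, "x", "y"), "logdet")
        assert d == pytest.approx(0.0, abs=1e-12)

    def test_jc_branch_length_recovered(self):
        # paralinear distance is additive: a two-taxon JC tree of total
        # length 0.3 should give d ~ 0.3 (closed-form oracle)
        tree = parse_newick("(x:0.12,y:0.18);")
        aln, _ = simulate_alignment(tree, jc69(), 200_000, seed=21)
        F = divergence_matrix(aln, "x", "y")
        d, reason = logdet_distance(F, "paralinear")
        assert reason is None
        # MC standard error of d at this depth and size is ~1.5e-3
        assert d == pytest.approx(0.3, abs=0.005)
        dj, _ = jc_distance(F)
        assert dj == pytest.approx(0.3, abs=0.005)

    def test_zero_row_invalid(self):
        from hetphylo.distances import DivergenceMatrix

        F = DivergenceMatrix(np.diag([5.0, 5.0, 5.0, 0.0]), "x", "y")
        d, reason = logdet_distance(F)
        assert d is None and reason == "zero-marginal"

    def test_empty_pair_invalid(self):
        from hetphylo.distances import DivergenceMatrix

        F = DivergenceMatrix(np.zeros((4, 4)), "x", "y")
        assert logdet_distance(F)[1] == "empty"


class TestDistanceMatrix:
    def test_pair_count_and_symmetry(self, dna_alignment):
        dm = distance_matrix(dna_alignment, "p")
        T = dm.n_taxa
        assert np.allclose(dm.d, dm.d.T)
        assert np.allclose(np.diag(dm.d), 0.0)
        iu = np.triu_indices(T, 1)
        assert len(dm.d[iu]) == T * (T - 1) // 2

    def test_p_zero_matches_raw(self, dna_alignment):
        d0 = distance_matrix(dna_alignment, "p", constant_removal_p=0.0)
        draw = distance_matrix(dna_alignment, "p")
        assert np.allclose(d0.d, draw.d)

    def test_constant_removal_recorded_and_monotone_series(self):
        tree = parse_newick("((a:0.3,b:0.05):0.05,(c:0.3,d:0.05):0.05,e:0.05);")
        from hetphylo.models import GammaASRV

        aln, _ = simulate_alignment(tree, jc69(GammaASRV(0.5, 4)), 5000, seed=2)
        prev = None
        for p in (0.0, 0.5, 1.0):
            dm = distance_matrix(aln, "paralinear", constant_removal_p=p)
            assert dm.metadata["constant_removal_p"] == p
            mean_d = dm.d[np.triu_indices(5, 1)].mean()
            if prev is not None:
                assert mean_d >= prev  # removing slow sites stretches distances
            prev = mean_d


class TestNeighborJoining:
    def test_additive_four_taxon_exact(self):
        # distances from ((A:1,B:2):1,(C:3,D:4)); computed by hand
        labels = ["A", "B", "C", "D"]
        d = np.array([
            [0, 3, 5, 6],
            [3, 0, 6, 7],
            [5, 6, 0, 7],
            [6, 7, 7, 0],
        ], float)
        dm = DistanceMatrix(labels, d)
        tree = neighbor_joining(dm)
        want = parse_newick("((A:1,B:2):1,(C:3,D:4));")
        assert robinson_foulds(tree, want) == 0
        lengths = all_splits(tree, with_lengths=True)
        want_lengths = all_splits(want, with_lengths=True)
        for key, val in want_lengths.items():
            assert lengths[key] == pytest.approx(val, abs=1e-9)

    def test_three_taxon_closed_form(self):
        dm = DistanceMatrix(["a", "b", "c"],
                            np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0.0]]))
        tree = neighbor_joining(dm)
        got = {n.name: n.length for n in tree.postorder() if n.is_leaf}
        assert got["a"] == pytest.approx(1.0)
        assert got["b"] == pytest.approx(1.0)
        assert got["c"] == pytest.approx(3.0)

    def test_too_few_taxa(self):
        dm = DistanceMatrix(["a", "b"], np.array([[0, 1], [1, 0.0]]))
        with pytest.raises(UsageError):
            neighbor_joining(dm)

    def test_invalid_entries_block_nj(self):
        d = np.zeros((3, 3))
        valid = np.ones((3, 3), bool)
        valid[0, 1] = valid[1, 0] = False
        dm = DistanceMatrix(["a", "b", "c"], d, valid,
                            {("a", "b"): "saturation"})
        with pytest.raises(UsageError):
            neighbor_joining(dm)

    def test_additivity_recovery_six_taxa(self):
        # NJ on exact path-length distances recovers any 6-leaf tree
        rng = np.random.default_rng(17)
        from hetphylo.trees import enumerate_topologies

        topos = list(enumerate_topologies(list("ABCDEF")))
        for idx in rng.choice(len(topos), size=5, replace=False):
            t = topos[idx].copy()
            for n in t.postorder():
                if n.parent is not None:
                    n.length = float(rng.uniform(0.05, 0.8))
            splits = all_splits(t, with_lengths=True)
            labels = sorted(t.leaf_names())
            # path-length distances via split decomposition
            d = np.zeros((6, 6))
            leaves = frozenset(labels)
            for key, ln in splits.items():
                for i, x in enumerate(labels):
                    for j, y in enumerate(labels):
                        if (x in key) != (y in key):
                            d[i, j] += ln
            tree = neighbor_joining(DistanceMatrix(labels, d))
            assert robinson_foulds(tree, t) == 0

    def test_phylip_matrix_round_trip(self, tmp_path):
        dm = DistanceMatrix(["a", "b", "c"],
                            np.array([[0, 1.5, 2], [1.5, 0, 1], [2, 1, 0.0]]))
        p = tmp_path / "dist.phy"
        write_phylip_distances(dm, p)
        back = read_phylip_distances(p)
        assert back.labels == dm.labels
        assert np.allclose(back.d, dm.d)
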