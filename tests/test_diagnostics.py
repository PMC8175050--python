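import numpy as np
import pandas as pd
import pytest

from hetphylo.diagnostics import (
    TestResult as DiagnosticResult,
    chi2_composition,
    composition_fit_test,
    per_taxon_composition_test,
    site_rates,
    stuart_marginal_symmetry,
)
from hetphylo.distances import DivergenceMatrix
from hetphylo.errors import HetphyloError, UsageError
from hetphylo.models import GammaASRV, jc69
from hetphylo.msa import CompositionTable, composition_counts, loads
from hetphylo.simulate import make_case_study, simulate_alignment
from hetphylo.trees import parse_newick


def _table(rows, labels=None, states="AC"):
    labels = labels or [f"t{i}" for i in range(len(rows))]
    return CompositionTable(pd.DataFrame(rows, index=labels,
                                         columns=list(states)))


class TestChi2Composition:
    def test_identical_rows_zero(self):
        res = chi2_composition(_table([[30, 10], [30, 10]]))
        assert res.statistic == pytest.approx(0.0)
        assert res.approximate

    def test_two_by_two_contingency_value(self):
        # pooled expectation is 20 per cell; each cell contributes
        # (30-20)^2/20 = 5, so the statistic is 20 with 1 dof
        res = chi2_composition(_table([[30, 10], [10, 30]]))
        assert res.statistic == pytest.approx(20.0)
        assert res.dof == 1

    def test_zero_count_state_dropped(self):
        res = chi2_composition(_table([[30, 10, 0], [10, 30, 0]],
                                      states="ACG"))
        assert res.dof == 1  # G dropped, c' = 2

    def test_single_taxon_rejected(self):
        with pytest.raises(UsageError):
            chi2_composition(_table([[30, 10]]))

    def test_invariance_to_taxon_and_column_order(self, dna_alignment):
        ct = composition_counts(dna_alignment)
        base = chi2_composition(ct).statistic
        rng = np.random.default_rng(0)
        perm = dna_alignment.take_taxa(
            [dna_alignment.labels[i] for i in rng.permutation(4)])
        cols = dna_alignment.take_sites(rng.permutation(dna_alignment.n_sites))
        assert chi2_composition(composition_counts(perm)).statistic == \
            pytest.approx(base)
        assert chi2_composition(composition_counts(cols)).statistic == \
            pytest.approx(base)


class TestStuart:
    def test_symmetric_matrix_zero(self):
        F = np.array([[10, 3, 2, 1], [3, 9, 2, 2], [2, 2, 8, 4],
                      [1, 2, 4, 7]], float)
        res = stuart_marginal_symmetry(DivergenceMatrix(F, "x", "y"))
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == 1.0

    def test_quadratic_form_against_direct_solve(self):
        # full-rank hand case: every state pair shows some change
        F = np.array([[100, 20, 4, 3], [5, 100, 6, 2], [6, 3, 100, 7],
                      [4, 5, 2, 100]], float)
        rows, cols = F.sum(1), F.sum(0)
        u = (rows - cols)[:3]
        V = -(F + F.T)
        np.fill_diagonal(V, rows + cols - 2 * np.diag(F))
        expected = float(u @ np.linalg.solve(V[:3, :3], u))
        res = stuart_marginal_symmetry(DivergenceMatrix(F, "x", "y"))
        assert res.statistic == pytest.approx(expected, rel=1e-12)
        assert res.dof == 3

    def test_relabeling_invariance(self):
        F = np.array([[100, 20, 4, 3], [5, 100, 6, 2], [6, 3, 100, 7],
                      [4, 5, 2, 100]], float)
        base = stuart_marginal_symmetry(DivergenceMatrix(F, "x", "y")).statistic
        perm = np.array([2, 0, 3, 1])
        Fp = F[np.ix_(perm, perm)]
        got = stuart_marginal_symmetry(DivergenceMatrix(Fp, "x", "y")).statistic
        assert got == pytest.approx(base, rel=1e-9)

    def test_singular_covariance_raises_with_pooling_hint(self):
        # states G and T never change: the covariance is singular
        F = np.diag([100.0, 100.0, 100.0, 100.0])
        F[0, 1], F[1, 0] = 20.0, 5.0
        with pytest.raises(HetphyloError, match="pool"):
            stuart_marginal_symmetry(DivergenceMatrix(F, "x", "y"))


class TestSimulationBackedTests:
    def test_fit_test_detects_branch_heterogeneity(self):
        aln, tree, _ = make_case_study("branch_heterogeneous", seed=4,
                                       n_sites=800)
        model = jc69(GammaASRV(0.935, 4))
        res = composition_fit_test(aln, tree, model, n_sim=100, seed=0)
        assert res.p_value <= 0.01
        assert res.null_sample is not None and len(res.null_sample) == 100

    def test_fit_test_calibrated_on_null_data(self):
        tree = parse_newick("((a:0.2,b:0.1):0.05,(c:0.15,d:0.2):0.05);")
        model = jc69(GammaASRV(1.0, 4))
        aln, _ = simulate_alignment(tree, model, 500, seed=77)
        res = composition_fit_test(aln, tree, model, n_sim=100, seed=1)
        assert 0.01 < res.p_value

    def test_fit_test_nsim_validation(self, dna_alignment, four_taxon_tree,
                                      jc_gamma):
        with pytest.raises(UsageError):
            composition_fit_test(dna_alignment, four_taxon_tree, jc_gamma,
                                 n_sim=0)

    def test_per_taxon_results_order_and_pooled_taxon(self):
        tree = parse_newick("((a:0.2,b:0.1):0.05,(c:0.15,d:0.2):0.05);")
        model = jc69(GammaASRV(1.0, 4))
        aln, _ = simulate_alignment(tree, model, 400, seed=5)
        results = per_taxon_composition_test(aln, tree, model, n_sim=100,
                                             seed=2)
        assert [r.extras["taxon"] for r in results] == aln.labels
        for r in results:
            assert 0 <= r.p_value <= 1

    def test_result_json_round_trip(self, tmp_path):
        res = DiagnosticResult(1.5, 3, 0.2, method="demo",
                         null_sample=np.array([1.0, 2.0]))
        text = res.to_json(tmp_path / "r.json")
        import json

        back = json.loads(text)
        assert back["statistic"] == 1.5
        assert back["null_sample"] == [1.0, 2.0]


class TestSiteRates:
    def test_identical_sequences_share_minimal_rate(self):
        tree = parse_newick("((a:0.1,b:0.1):0.05,(c:0.1,d:0.1):0.05);")
        aln = loads(">a\nACGT\n>b\nACGT\n>c\nACGT\n>d\nACGT\n",
                    "fasta", "DNA")
        model = jc69(GammaASRV(0.5, 4))
        rates = site_rates(aln, tree, model)
        assert rates.shape == (4,)
        assert np.allclose(rates, rates[0])
        assert rates[0] < 1.0

    def test_two_category_hand_calculation(self):
        # one invariant and one variable column; the posterior-mean rate
        # is computed directly from the two category likelihoods
        tree = parse_newick("(a:0.3,b:0.3);")
        aln = loads(">a\nAA\n>b\nAC\n", "fasta", "DNA")
        model = jc69(GammaASRV(1.0, 2))
        from hetphylo.models import build_rate_matrix, transition_matrix

        r = model.asrv.rates()
        Q = build_rate_matrix(model.exchangeabilities,
                              model.composition.pi)
        expected = []
        for x, y in (("A", "A"), ("A", "C")):
            liks = np.array([
                0.25 * transition_matrix(Q, 0.6, rk)[0, "ACGT".index(y)]
                for rk in r])
            post = liks / liks.sum()
            expected.append(float(post @ r))
        got = site_rates(aln, tree, model)
        assert np.allclose(got, expected, atol=1e-10)

    def test_constant_sites_rank_below_variable(self):
        tree = parse_newick("((a:0.2,b:0.2):0.1,(c:0.2,d:0.2):0.1);")
        model = jc69(GammaASRV(0.7, 4))
        aln, _ = simulate_alignment(tree, model, 300, seed=8)
        rates = site_rates(aln, tree, model)
        assert rates.shape == (300,)
        from hetphylo.msa import constant_columns

        const, _ = constant_columns(aln)
        variable = np.setdiff1d(np.arange(300), const)
        assert rates[const].mean() < rates[variable].mean()

    def test_requires_asrv(self, dna_alignment, four_taxon_tree):
        with pytest.raises(UsageError):
            site_rates(dna_alignment, four_taxon_tree, jc69())
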