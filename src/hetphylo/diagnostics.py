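"""Compositional-heterogeneity test statistics and model-adequacy tests.

The workhorse statistic is the taxa-by-states composition chi-square:
observed per-taxon state counts against expectations from the pooled
composition.  Its asymptotic chi-square p-value is reported but flagged
approximate — alignment columns are correlated through the tree, so
wherever a fitted (tree, model) pair is available the statistic is
instead calibrated against a parametric-bootstrap null simulated under
that model (the tree-and-model composition fit test), and per-taxon
versions of the same idea.  Stuart's test of marginal symmetry
interrogates a single taxon pair's divergence matrix for a directional
composition shift.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.stats import chi2 as chi2_dist

from .distances import DivergenceMatrix
from .errors import HetphyloError, UsageError
from .likelihood import PruningEngine
from .models import SubstitutionModel
from .msa import Alignment, CompositionTable, composition_counts
from .simulate import simulate_alignment
from .trees import Tree

__all__ = [
    "TestResult",
    "chi2_composition",
    "per_taxon_composition_test",
    "stuart_marginal_symmetry",
    "composition_fit_test",
    "site_rates",
]

_MIN_SIM = 100


@dataclass
class TestResult:
    statistic: float
    dof: Optional[int]
    p_value: Optional[float]
    method: str
    approximate: bool = False
    null_sample: Optional[np.ndarray] = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.p_value is not None and not 0 <= self.p_value <= 1:
            raise ValueError("p-value outside [0, 1]")

    def to_dict(self) -> dict:
        d = dict(statistic=self.statistic, dof=self.dof, p_value=self.p_value,
                 method=self.method, approximate=self.approximate,
                 **self.extras)
        if self.null_sample is not None:
            d["null_sample"] = np.asarray(self.null_sample).tolist()
        return d

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _chi2_stat(counts: np.ndarray):
    """Contingency statistic and retained-state count; zero-count states
    are dropped (their expectation is identically zero)."""
    pooled = counts.sum(axis=0)
    keep = pooled > 0
    counts = counts[:, keep]
    pooled = pooled[keep]
    totals = counts.sum(axis=1, keepdims=True)
    expected = totals * (pooled / pooled.sum())[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        terms = (counts - expected) ** 2 / expected
    return float(np.nansum(terms)), int(keep.sum())


def chi2_composition(ct: CompositionTable) -> TestResult:
    """Taxa-by-states composition chi-square against the pooled composition.

    dof = (T-1)(c'-1) with c' the states of nonzero pooled count.  The
    chi-square-law p-value is approximate: sites are correlated on a
    tree, so prefer :func:`composition_fit_test` when a fitted model is
    available.
    """
    counts = ct.counts.to_numpy()
    if counts.shape[0] < 2:
        raise UsageError("composition test needs at least two taxa")
    stat, c_eff = _chi2_stat(counts)
    dof = (counts.shape[0] - 1) * (c_eff - 1)
    p = float(chi2_dist.sf(stat, dof)) if dof > 0 else None
    return TestResult(stat, dof, p, method="chi2-composition", approximate=True)


def _per_taxon_stats(counts: np.ndarray) -> np.ndarray:
    """Each taxon's composition chi-square against the pooled composition."""
    pooled = counts.sum(axis=0)
    freq = pooled / pooled.sum()
    totals = counts.sum(axis=1, keepdims=True)
    expected = totals * freq[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        terms = np.where(expected > 0, (counts - expected) ** 2 / expected, 0.0)
    return terms.sum(axis=1)


def _null_count_blocks(tree, model, labels, n_sites, n_sim, seed):
    """Per-simulation composition counts under (tree, model).

    Sites are independent under every supported model, so the n_sim
    null alignments are drawn as one long simulation and split into
    blocks — far cheaper than n_sim separate simulator calls and
    statistically identical.  Returns (n_sim, T, c) counts with taxa
    ordered as ``labels``.
    """
    big, _meta = simulate_alignment(tree, model, n_sites * n_sim, seed=seed)
    order = [big.labels.index(l) for l in labels]
    states = list(big.alphabet.states)
    out = np.zeros((n_sim, len(labels), len(states)), dtype=float)
    for s_idx, ch in enumerate(states):
        hits = big.matrix == ch
        for t_out, t_big in enumerate(order):
            out[:, t_out, s_idx] = hits[t_big].reshape(n_sim, n_sites).sum(axis=1)
    return out


def per_taxon_composition_test(a: Alignment, tree: Tree,
                               model: SubstitutionModel, n_sim: int = 100,
                               seed: int = 0):
    """Per-taxon composition chi-square with a simulated null.

    The null distribution of each taxon's statistic is built by
    simulating ``n_sim`` alignments under the fitted (tree, model) and
    recomputing; p is the upper-tail fraction.  Returns one
    :class:`TestResult` per taxon, in alignment order.
    """
    if n_sim < _MIN_SIM:
        raise UsageError(f"n_sim must be >= {_MIN_SIM}")
    obs = _per_taxon_stats(composition_counts(a).counts.to_numpy())
    blocks = _null_count_blocks(tree, model, a.labels, a.n_sites, n_sim, seed)
    null = np.vstack([_per_taxon_stats(b) for b in blocks])  # (n_sim, T)
    results = []
    for t_idx, label in enumerate(a.labels):
        p = float((null[:, t_idx] >= obs[t_idx]).mean())
        results.append(TestResult(
            float(obs[t_idx]), None, p,
            method="per-taxon composition chi2 (simulated null)",
            null_sample=null[:, t_idx].copy(),
            extras=dict(taxon=label, n_sim=n_sim),
        ))
    return results


def stuart_marginal_symmetry(F: DivergenceMatrix) -> TestResult:
    """Stuart's test of marginal symmetry for one taxon pair.

    With u the first c-1 components of (row sums - column sums) of the
    divergence matrix and V the marginal-homogeneity covariance
    (V_ij = -(F_ij + F_ji), V_ii = rowsum_i + colsum_i - 2 F_ii), the
    statistic is u' V^-1 u with c-1 degrees of freedom.  A singular V
    (sparse data: some states never change) raises rather than being
    silently pseudo-inverted; pool states and retry.
    """
    M = np.asarray(F.F, dtype=float)
    c = M.shape[0]
    if c < 2:
        raise UsageError("Stuart's test needs at least two states")
    rows = M.sum(axis=1)
    cols = M.sum(axis=0)
    u = (rows - cols)[: c - 1]
    V = -(M + M.T)
    np.fill_diagonal(V, rows + cols - 2 * np.diag(M))
    V = V[: c - 1, : c - 1]
    if np.allclose(u, 0):
        return TestResult(0.0, c - 1, 1.0, method="stuart-marginal-symmetry")
    try:
        sol = np.linalg.solve(V, u)
    except np.linalg.LinAlgError as exc:
        raise HetphyloError(
            "singular covariance in Stuart's test (some states show no "
            "change); pool sparse states and retry"
        ) from exc
    if np.linalg.cond(V) > 1e12:
        raise HetphyloError(
            "near-singular covariance in Stuart's test; pool sparse states"
        )
    stat = float(u @ sol)
    return TestResult(stat, c - 1, float(chi2_dist.sf(stat, c - 1)),
                      method="stuart-marginal-symmetry",
                      extras=dict(taxa=(F.taxon_i, F.taxon_j)))


def composition_fit_test(a: Alignment, tree: Tree, model: SubstitutionModel,
                         n_sim: int = 100, seed: int = 0) -> TestResult:
    """Tree-and-model composition fit test (parametric bootstrap).

    Simulates ``n_sim`` alignments under the fitted (tree, model) at
    its parameter values, recomputes the composition chi-square on
    each, and reports p as the upper-tail fraction of simulated
    statistics at or above the observed one.
    """
    if n_sim < 1:
        raise UsageError("n_sim must be positive")
    if n_sim < _MIN_SIM:
        raise UsageError(f"n_sim must be >= {_MIN_SIM}")
    obs, _ = _chi2_stat(composition_counts(a).counts.to_numpy())
    blocks = _null_count_blocks(tree, model, a.labels, a.n_sites, n_sim, seed)
    null = np.array([_chi2_stat(b)[0] for b in blocks])
    return TestResult(
        obs, None, float((null >= obs).mean()),
        method="tree-and-model composition fit test",
        null_sample=null,
        extras=dict(n_sim=n_sim,
                    null_range=[float(null.min()), float(null.max())]),
    )


def site_rates(a: Alignment, tree: Tree, model: SubstitutionModel) -> np.ndarray:
    """Posterior-mean rate per alignment column under the fitted model.

    rate(site) = sum_g r_g P(category g | site data), with categories
    marginalized over mixture components where present.  Used to rank
    sites for fast-site removal.
    """
    if model.asrv is None:
        raise UsageError("site rates require a model with gamma ASRV")
    eng = PruningEngine(tree, a, model)
    logliks, comps = eng.component_site_logliks()
    rates = np.array([c_["rate"] for c_ in comps])
    from scipy.special import logsumexp

    post = np.exp(logliks - logsumexp(logliks, axis=0, keepdims=True))
    return rates @ post
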