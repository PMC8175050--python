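"""Bayesian MCMC over trees and branch-heterogeneous composition models,
posterior-predictive adequacy, and stepping-stone marginal likelihoods.

Three model families are sampled:

* ``homogeneous`` — one composition vector (GTR+G-style, with the
  exchangeabilities held fixed at their supplied values);
* ``ndch`` — a pool of k composition vectors arranged on the branches,
  with the edge-to-vector assignment either sampled or fixed;
* ``ndch2`` — every branch and the root carry their own vector, tied
  together by a hierarchical Dirichlet prior: edge compositions are
  i.i.d. Dirichlet(gamma * pi_bar) around a sampled global mean pi_bar
  with sampled concentration gamma.

Priors: branch lengths Exp(10); free composition vectors flat
Dirichlet; gamma shape Exp(1); NDCH2 concentration log-uniform on
[1, 1e4]; topologies uniform.  All prior densities are normalized, so
stepping-stone estimates are proper marginal likelihoods (up to the
constant topology prior, which cancels between models on the same
taxa).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .errors import UsageError
from .likelihood import PruningEngine
from .models import (
    BranchComposition,
    BranchCompositionMap,
    GammaASRV,
    SingleComposition,
    SubstitutionModel,
    edge_key,
    smooth_composition,
)
from .msa import Alignment, composition_counts
from .simulate import simulate_alignment
from .trees import Tree

__all__ = [
    "BayesModelSpec",
    "PosteriorChain",
    "PowerSchedule",
    "mcmc_run",
    "posterior_predictive_chi2",
    "stepping_stone",
    "effective_sample_size",
]

_BL_RATE = 10.0          # exponential prior rate on branch lengths
_GAMMA_LO, _GAMMA_HI = 1.0, 1e4   # NDCH2 concentration bounds


@dataclass
class BayesModelSpec:
    """Structure of the sampled model (exchangeabilities stay fixed)."""

    kind: str  # homogeneous | ndch | ndch2
    alphabet: object
    exchangeabilities: np.ndarray
    asrv_ncats: Optional[int] = 4
    k: int = 2
    sample_assignment: bool = True
    free_composition: bool = True

    def __post_init__(self):
        if self.kind not in ("homogeneous", "ndch", "ndch2"):
            raise UsageError(f"unknown model kind {self.kind!r}")
        if self.kind == "ndch" and self.k < 1:
            raise UsageError("NDCH pool size must be >= 1")


@dataclass
class Sample:
    iteration: int
    lnl: float
    ln_prior: float
    tree: Tree
    model: SubstitutionModel
    alpha: Optional[float] = None
    extras: dict = field(default_factory=dict)


@dataclass
class PosteriorChain:
    samples: list
    interval: int
    seed: int
    acceptance: dict
    warnings: list = field(default_factory=list)

    def __len__(self):
        return len(self.samples)

    def trace_dataframe(self) -> pd.DataFrame:
        rows = []
        for s in self.samples:
            row = dict(iteration=s.iteration, lnl=s.lnl, ln_prior=s.ln_prior)
            if s.alpha is not None:
                row["alpha"] = s.alpha
            row.update(s.extras)
            rows.append(row)
        return pd.DataFrame(rows)

    def to_tsv(self, path) -> None:
        self.trace_dataframe().to_csv(path, sep="\t", index=False)

    def trees_newick(self) -> list:
        return [s.tree.to_newick() for s in self.samples]

    def manifest(self) -> dict:
        """JSON-serializable run summary: seed, interval, acceptance."""
        return dict(
            seed=self.seed,
            interval=self.interval,
            n_samples=len(self.samples),
            acceptance={k: {"accepted": a, "proposed": p}
                        for k, (a, p) in self.acceptance.items()},
            warnings=list(self.warnings),
        )

    def save_manifest(self, path) -> None:
        import json

        with open(path, "w") as fh:
            json.dump(self.manifest(), fh, indent=1)

    def split_frequencies(self) -> dict:
        from .trees import nontrivial_splits

        counts = {}
        for s in self.samples:
            for sp in nontrivial_splits(s.tree):
                counts[sp] = counts.get(sp, 0) + 1
        n = max(len(self.samples), 1)
        return {sp: c / n for sp, c in counts.items()}


# ---------------------------------------------------------------------------
# sampler state

class _State:
    def __init__(self, spec: BayesModelSpec, tree: Tree, rng):
        self.spec = spec
        self.tree = tree.copy()
        for n in self.tree.postorder():
            if n is not self.tree.root and (n.length is None or n.length <= 0):
                n.length = 0.05
        self.alpha = 1.0 if spec.asrv_ncats else None
        c = spec.alphabet.size if hasattr(spec.alphabet, "size") else None
        self.c = spec.exchangeabilities.shape[0]
        self.edges = [n for n in self.tree.postorder() if n is not self.tree.root]
        if spec.kind == "homogeneous":
            self.pi = np.full(self.c, 1.0 / self.c)
        elif spec.kind == "ndch":
            self.pool = np.tile(np.full(self.c, 1.0 / self.c), (spec.k, 1))
            self.assign = {id(n): int(rng.integers(spec.k)) for n in self.edges}
            self.root_assign = int(rng.integers(spec.k))
        else:  # ndch2
            self.pi_bar = np.full(self.c, 1.0 / self.c)
            self.gamma = 100.0
            self.vecs = {id(n): np.full(self.c, 1.0 / self.c)
                         for n in self.edges}
            self.root_vec = np.full(self.c, 1.0 / self.c)

    # -- model construction ----------------------------------------------
    def model(self) -> SubstitutionModel:
        spec = self.spec
        asrv = GammaASRV(self.alpha, spec.asrv_ncats) if spec.asrv_ncats else None
        if spec.kind == "homogeneous":
            comp = SingleComposition(self.pi)
        else:
            if spec.kind == "ndch":
                pool = self.pool
                assignment = {edge_key(n): self.assign[id(n)]
                              for n in self.edges}
                root_index = self.root_assign
            else:
                pool = np.vstack([self.vecs[id(n)] for n in self.edges]
                                 + [self.root_vec])
                assignment = {edge_key(n): i for i, n in enumerate(self.edges)}
                root_index = len(self.edges)
            comp = BranchComposition(BranchCompositionMap(
                pool, assignment, root_index,
                mode="NDCH" if spec.kind == "ndch" else "NDCH2"))
        return SubstitutionModel(spec.alphabet, spec.exchangeabilities, comp, asrv)

    # -- prior --------------------------------------------------------------
    def ln_prior(self) -> float:
        lp = 0.0
        for n in self.edges:
            lp += np.log(_BL_RATE) - _BL_RATE * n.length
        if self.alpha is not None:
            lp += -self.alpha  # Exp(1)
        flat = gammaln(self.c)  # log Gamma(c): flat-Dirichlet normalizer
        spec = self.spec
        if spec.kind == "homogeneous":
            if spec.free_composition:
                lp += flat
        elif spec.kind == "ndch":
            lp += spec.k * flat
            lp += -(len(self.edges) + 1) * np.log(spec.k)
        else:
            lp += flat  # pi_bar
            lp += -np.log(self.gamma) - np.log(np.log(_GAMMA_HI / _GAMMA_LO))
            a = self.gamma * smooth_composition(self.pi_bar)
            norm = gammaln(a.sum()) - gammaln(a).sum()
            for v in list(self.vecs.values()) + [self.root_vec]:
                lp += norm + ((a - 1) * np.log(v)).sum()
        return float(lp)

    def lnl(self, alignment) -> float:
        eng = PruningEngine(self.tree, alignment, self.model())
        return eng.lnl()

    # -- topology move ------------------------------------------------------
    def internal_edges(self):
        return [n for n in self.edges if not n.is_leaf and n.parent is not None]

    def nni_inplace(self, rng):
        """In-place NNI; returns an undo closure, or None if no move exists."""
        cands = [n for n in self.internal_edges()
                 if n.parent is not None and len(n.parent.children) >= 2]
        cands = [n for n in cands
                 if [c for c in n.parent.children if c is not n]]
        if not cands:
            return None
        v = cands[rng.integers(len(cands))]
        u = v.parent
        others = [c for c in u.children if c is not v]
        s = others[rng.integers(len(others))]
        a = v.children[rng.integers(len(v.children))]
        iv, isv = v.children.index(a), u.children.index(s)
        v.children[iv], u.children[isv] = s, a
        s.parent, a.parent = v, u

        def undo():
            v.children[iv], u.children[isv] = a, s
            a.parent, s.parent = v, u

        return undo


def _dirichlet_logpdf(x, a):
    return float(gammaln(a.sum()) - gammaln(a).sum() + ((a - 1) * np.log(x)).sum())


def _propose_dirichlet(x, rng, eps=300.0):
    """Dirichlet proposal centred on x; returns (x', log Hastings ratio)."""
    ax = eps * x
    xp = rng.dirichlet(ax)
    if np.any(xp < 1e-6):
        return None, 0.0
    axp = eps * xp
    lhr = _dirichlet_logpdf(x, axp) - _dirichlet_logpdf(xp, ax)
    return xp, lhr


def mcmc_run(alignment: Alignment, spec: BayesModelSpec, start_tree: Tree,
             iters: int, interval: int = 50, seed: int = 0,
             sample_topology: bool = True,
             likelihood_weight: float = 1.0,
             burn_in_fraction: float = 0.25) -> PosteriorChain:
    """Metropolis-Hastings sampler.

    The first ``burn_in_fraction`` of iterations is discarded, then one
    state is recorded every ``interval`` iterations.  With
    ``likelihood_weight`` beta in [0, 1] the chain targets the power
    posterior prior * L^beta (beta = 0 samples the prior; beta = 1 the
    posterior); the recorded lnL is always the full-data
    log-likelihood.  Deterministic given the seed.
    """
    if iters < 1:
        raise UsageError("iters must be >= 1")
    burn = int(iters * burn_in_fraction)
    if iters - burn < 1 or (iters - burn) // interval < 1:
        raise UsageError("no sampled iterations after burn-in; "
                         "increase iters or decrease interval")
    rng = np.random.default_rng(seed)
    state = _State(spec, start_tree, rng)
    beta = float(likelihood_weight)
    cur_lnl = state.lnl(alignment) if beta > 0 else None
    cur_prior = state.ln_prior()

    moves = [("branch", 0.35)]
    if sample_topology and state.internal_edges():
        moves.append(("nni", 0.15))
    if state.alpha is not None:
        moves.append(("alpha", 0.10))
    if spec.kind != "homogeneous" or spec.free_composition:
        moves.append(("composition", 0.30))
    if spec.kind == "ndch" and spec.sample_assignment:
        moves.append(("reassign", 0.05))
    if spec.kind == "ndch2":
        moves.append(("hyper", 0.10))
    names = [m[0] for m in moves]
    probs = np.array([m[1] for m in moves])
    probs /= probs.sum()
    accept = {n: [0, 0] for n in names}

    samples = []
    for it in range(1, iters + 1):
        move = names[rng.choice(len(names), p=probs)]
        accept[move][1] += 1
        lhr = 0.0
        undo = None

        if move == "branch":
            n = state.edges[rng.integers(len(state.edges))]
            old = n.length
            mult = np.exp(1.0 * (rng.random() - 0.5))
            n.length = old * mult
            lhr = np.log(mult)
            undo = lambda n=n, old=old: setattr(n, "length", old)
        elif move == "nni":
            undo = state.nni_inplace(rng)
            if undo is None:
                continue
        elif move == "alpha":
            old = state.alpha
            mult = np.exp(0.7 * (rng.random() - 0.5))
            state.alpha = old * mult
            lhr = np.log(mult)
            undo = lambda old=old: setattr(state, "alpha", old)
        elif move == "composition":
            if spec.kind == "homogeneous":
                tgt = ("pi", None)
            elif spec.kind == "ndch":
                tgt = ("pool", int(rng.integers(spec.k)))
            else:
                which = rng.integers(len(state.edges) + 2)
                if which < len(state.edges):
                    tgt = ("vec", id(state.edges[which]))
                elif which == len(state.edges):
                    tgt = ("root_vec", None)
                else:
                    tgt = ("pi_bar", None)
            kind, key = tgt
            if kind == "pi":
                old = state.pi
                new, lhr = _propose_dirichlet(old, rng)
                if new is None:
                    continue
                state.pi = new
                undo = lambda old=old: setattr(state, "pi", old)
            elif kind == "pool":
                old = state.pool[key].copy()
                new, lhr = _propose_dirichlet(old, rng)
                if new is None:
                    continue
                state.pool[key] = new
                undo = lambda key=key, old=old: state.pool.__setitem__(key, old)
            elif kind == "vec":
                old = state.vecs[key]
                new, lhr = _propose_dirichlet(old, rng)
                if new is None:
                    continue
                state.vecs[key] = new
                undo = lambda key=key, old=old: state.vecs.__setitem__(key, old)
            elif kind == "root_vec":
                old = state.root_vec
                new, lhr = _propose_dirichlet(old, rng)
                if new is None:
                    continue
                state.root_vec = new
                undo = lambda old=old: setattr(state, "root_vec", old)
            else:
                old = state.pi_bar
                new, lhr = _propose_dirichlet(old, rng)
                if new is None:
                    continue
                state.pi_bar = new
                undo = lambda old=old: setattr(state, "pi_bar", old)
        elif move == "reassign":
            which = rng.integers(len(state.edges) + 1)
            if which < len(state.edges):
                key = id(state.edges[which])
                old = state.assign[key]
                state.assign[key] = int(rng.integers(spec.k))
                undo = lambda key=key, old=old: state.assign.__setitem__(key, old)
            else:
                old = state.root_assign
                state.root_assign = int(rng.integers(spec.k))
                undo = lambda old=old: setattr(state, "root_assign", old)
        elif move == "hyper":
            old = state.gamma
            mult = np.exp(1.0 * (rng.random() - 0.5))
            new = old * mult
            if not _GAMMA_LO <= new <= _GAMMA_HI:
                continue
            state.gamma = new
            lhr = np.log(mult)
            undo = lambda old=old: setattr(state, "gamma", old)

        new_prior = state.ln_prior()
        if beta > 0:
            new_lnl = state.lnl(alignment)
            log_acc = beta * (new_lnl - cur_lnl) + new_prior - cur_prior + lhr
        else:
            new_lnl = None
            log_acc = new_prior - cur_prior + lhr
        if np.log(rng.random() + 1e-300) < log_acc:
            cur_lnl, cur_prior = new_lnl, new_prior
            accept[move][0] += 1
        else:
            undo()

        if it > burn and (it - burn) % interval == 0:
            lnl_rec = cur_lnl if cur_lnl is not None else state.lnl(alignment)
            extras = {}
            if spec.kind == "ndch2":
                extras["concentration"] = state.gamma
            samples.append(Sample(
                iteration=it, lnl=float(lnl_rec), ln_prior=float(cur_prior),
                tree=state.tree.copy(), model=state.model(),
                alpha=state.alpha, extras=extras,
            ))

    warnings = [f"no accepted {n} moves" for n, (a, p) in accept.items()
                if p > 0 and a == 0]
    return PosteriorChain(samples, interval, seed,
                          {n: tuple(v) for n, v in accept.items()}, warnings)


# ---------------------------------------------------------------------------
# posterior predictive adequacy

def posterior_predictive_chi2(chain: PosteriorChain, alignment: Alignment,
                              n_per_sample: int = 1, seed: int = 0):
    """Posterior-predictive composition test.

    For each posterior sample, simulate ``n_per_sample`` alignments of
    the observed dimensions under the sampled (tree, model) and compute
    the composition chi-square; p is the fraction of simulated
    statistics at or above the observed one.
    """
    from .diagnostics import TestResult, _chi2_stat

    if len(chain) == 0:
        raise UsageError("empty posterior chain")
    obs, _ = _chi2_stat(composition_counts(alignment).counts.to_numpy())
    rng = np.random.default_rng(seed)
    null = []
    for s in chain.samples:
        for _ in range(n_per_sample):
            sim, _meta = simulate_alignment(
                s.tree, s.model, alignment.n_sites,
                seed=int(rng.integers(0, 2**31 - 1)))
            null.append(_chi2_stat(
                composition_counts(sim).counts.to_numpy())[0])
    null = np.array(null)
    return TestResult(
        obs, None, float((null >= obs).mean()),
        method="posterior-predictive composition chi2",
        null_sample=null,
        extras=dict(null_range=[float(null.min()), float(null.max())],
                    n_draws=len(null)),
    )


# ---------------------------------------------------------------------------
# stepping-stone marginal likelihood

@dataclass
class PowerSchedule:
    betas: np.ndarray
    per_stone: list = field(default_factory=list)

    def __post_init__(self):
        b = np.asarray(self.betas, float)
        if b[0] != 0 or b[-1] != 1 or np.any(np.diff(b) <= 0):
            raise UsageError("betas must increase strictly from 0 to 1")
        self.betas = b


def effective_sample_size(x) -> float:
    """Initial-positive-sequence autocorrelation ESS estimate."""
    x = np.asarray(x, float)
    n = len(x)
    if n < 4 or np.var(x) == 0:
        return float(n)
    xc = x - x.mean()
    acf = np.correlate(xc, xc, mode="full")[n - 1:] / (np.arange(n, 0, -1))
    acf /= acf[0]
    s = 0.0
    for t in range(1, n):
        if acf[t] < 0:
            break
        s += acf[t]
    return float(n / (1 + 2 * s))


@dataclass
class SteppingStoneResult:
    ln_marginal: float
    schedule: PowerSchedule
    per_stone_ess: list
    warnings: list


def stepping_stone(alignment: Alignment, spec: BayesModelSpec, tree: Tree,
                   n_stones: int = 8, iters_per_stone: int = 2000,
                   seed: int = 0, sample_topology: bool = False,
                   interval: int = 5) -> SteppingStoneResult:
    """Stepping-stone estimator of the log marginal likelihood.

    Inverse temperatures follow Beta(0.3, 1) quantile spacing,
    beta_k = (k / n)^(1/0.3); each power posterior is sampled by
    :func:`mcmc_run` (warm-started chains, 25% per-stone burn-in) and
    the estimator sums ln mean exp[(beta_{k+1}-beta_k) lnL] across
    stones, computed with a max shift for stability.
    """
    if n_stones < 4:
        raise UsageError("need at least 4 stones")
    betas = (np.arange(n_stones + 1) / n_stones) ** (1 / 0.3)
    betas[0], betas[-1] = 0.0, 1.0
    total = 0.0
    ess_list = []
    warnings = []
    rng = np.random.default_rng(seed)
    cur_tree = tree
    for k in range(n_stones):
        chain = mcmc_run(alignment, spec, cur_tree, iters_per_stone,
                         interval=interval,
                         seed=int(rng.integers(0, 2**31 - 1)),
                         sample_topology=sample_topology,
                         likelihood_weight=float(betas[k]))
        lnls = np.array([s.lnl for s in chain.samples])
        d = betas[k + 1] - betas[k]
        shifted = d * lnls
        m = shifted.max()
        total += m + np.log(np.mean(np.exp(shifted - m)))
        ess = effective_sample_size(shifted)
        ess_list.append(ess)
        if ess < 10:
            warnings.append(f"stone {k} (beta={betas[k]:.4f}) ESS {ess:.1f} < 10")
        cur_tree = chain.samples[-1].tree  # warm start
    return SteppingStoneResult(float(total), PowerSchedule(betas),
                               ess_list, warnings)
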