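"""Phylogenetic likelihood under homogeneous, profile-mixture and
branch-heterogeneous (NDCH-style) substitution models.

The engine implements Felsenstein's pruning algorithm over compressed
site patterns, with per-component log-scaling against underflow.  A
"component" is one (composition, rate-category) pair: a single-pi model
with K gamma categories has K components; a mixture of M profiles has
M*K; a branch-composition model has K components whose transition
matrices differ per edge.

Site likelihood is the weighted sum over components,

    L(site) = sum_m w_m sum_g (1/G) L(site | pi_m, r_g),

computed in one batched pass per tree node.  Branch lengths are
expected substitutions per site under the edge's own generator (each
generator is normalized at its own composition).
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import logsumexp

from .errors import ModelError, UsageError
from .models import (
    BranchComposition,
    GammaASRV,
    MixtureComposition,
    SingleComposition,
    SpectralGenerator,
    SubstitutionModel,
    edge_key,
)
from .msa import Alignment
from .trees import (Node, Tree, enumerate_topologies, nni_neighbors,
                    spr_reattachments)

__all__ = [
    "PruningEngine",
    "log_likelihood",
    "optimize",
    "search_topology",
    "bootstrap_support",
    "OptimizeResult",
]

_MIN_BRANCH = 1e-9
_MAX_BRANCH = 20.0


def _encode_patterns(a: Alignment):
    """Compress alignment columns into unique patterns.

    Returns (codes (T, n_patterns), pattern weights, inverse site->pattern,
    charmap list giving the character for each code)."""
    chars = sorted(set(a.matrix.ravel().tolist()))
    lut = {ch: k for k, ch in enumerate(chars)}
    coded = np.vectorize(lut.get, otypes=[np.int16])(a.matrix)
    patterns, inverse, counts = np.unique(
        coded, axis=1, return_inverse=True, return_counts=True
    )
    return patterns, counts.astype(float), inverse.ravel(), chars


class PruningEngine:
    """Compiled likelihood evaluator for one (tree, alignment, model).

    The engine owns a copy of the tree; ``optimize_branches`` mutates
    that copy's branch lengths in place.
    """

    def __init__(self, tree: Tree, alignment: Alignment, model: SubstitutionModel,
                 dtype=np.float64):
        self.dtype = np.dtype(dtype)
        if model.alphabet.name != alignment.alphabet.name:
            raise UsageError(
                f"model alphabet {model.alphabet.name} != alignment "
                f"alphabet {alignment.alphabet.name}"
            )
        self.model = model
        self.alignment = alignment
        self.tree = tree.copy()
        tl = set(self.tree.leaf_names())
        al = set(alignment.labels)
        if tl != al:
            raise UsageError(
                f"leaf sets differ: tree-only {sorted(tl - al)}, "
                f"alignment-only {sorted(al - tl)}"
            )
        self._compile_tree()
        self._compile_patterns()
        self._compile_components()

    # -- compilation -------------------------------------------------------
    def _compile_tree(self):
        self.nodes = list(self.tree.postorder())
        self.index = {id(n): k for k, n in enumerate(self.nodes)}
        self.root_idx = self.index[id(self.tree.root)]
        root = self.tree.root
        for n in self.nodes:
            if n is root:
                continue
            if not n.is_leaf and len(n.children) != 2:
                raise UsageError("likelihood requires a binary tree "
                                 "(multifurcation found)")
        if len(root.children) not in (2, 3):
            raise UsageError("root must have two or three children")
        self.children = [
            [self.index[id(c)] for c in n.children] for n in self.nodes
        ]
        self.lengths = np.array(
            [n.length if n.length is not None else 0.0 for n in self.nodes]
        )
        if np.any(self.lengths < 0) or not np.all(np.isfinite(self.lengths)):
            raise UsageError("branch lengths must be finite and non-negative")
        self.edge_keys = [edge_key(n) for n in self.nodes]

    def _compile_patterns(self):
        patterns, w, inverse, chars = _encode_patterns(self.alignment)
        self.patterns = patterns
        self.pattern_weights = w
        self.site_to_pattern = inverse
        alpha = self.model.alphabet
        c = alpha.size
        basis = np.zeros((len(chars), c), dtype=self.dtype)
        for k, ch in enumerate(chars):
            for s in alpha.state_set(ch):
                basis[k, s] = 1.0
        # leaf partials indexed by node
        self.leaf_partials = {}
        for k, n in enumerate(self.nodes):
            if n.is_leaf:
                row = self.alignment.labels.index(n.name)
                self.leaf_partials[k] = basis[patterns[row]]

    def _compile_components(self):
        m = self.model
        rates = m.rate_categories()
        G = len(rates)
        comp = m.composition
        self._branch_mode = isinstance(comp, BranchComposition)
        if isinstance(comp, SingleComposition):
            gens = [SpectralGenerator(m.exchangeabilities, comp.pi)]
            self.comps = [
                dict(gen=0, rate=r, logw=-np.log(G), pi=gens[0].pi) for r in rates
            ]
        elif isinstance(comp, MixtureComposition):
            gens = [
                SpectralGenerator(m.exchangeabilities, p)
                for p in comp.profiles.profiles
            ]
            self.comps = []
            for k, g in enumerate(gens):
                for r in rates:
                    self.comps.append(
                        dict(gen=k, rate=r, mix=k,
                             logw=np.log(comp.weights[k] + 1e-300) - np.log(G),
                             pi=g.pi)
                    )
        else:
            bmap = comp.map
            gens = [SpectralGenerator(m.exchangeabilities, p) for p in bmap.pool]
            missing = [
                k for k, n in enumerate(self.nodes)
                if n is not self.tree.root and self.edge_keys[k] not in bmap.assignment
            ]
            if missing:
                raise ModelError(
                    f"branch map lacks assignments for {len(missing)} edges"
                )
            self.edge_gen = [
                bmap.assignment.get(self.edge_keys[k], bmap.root_index)
                for k in range(len(self.nodes))
            ]
            self.comps = [
                dict(gen=None, rate=r, logw=-np.log(G),
                     pi=gens[bmap.root_index].pi) for r in rates
            ]
        self.generators = gens
        self.ncomp = len(self.comps)
        self.logw = np.array([c_["logw"] for c_ in self.comps])
        self.root_pi = np.vstack([c_["pi"] for c_ in self.comps])
        self.comp_rates = np.array([c_["rate"] for c_ in self.comps])

    # -- parameter updates -------------------------------------------------
    def set_lengths(self, lengths):
        self.lengths = np.asarray(lengths, dtype=float).copy()
        for k, n in enumerate(self.nodes):
            if n is not self.tree.root:
                n.length = float(self.lengths[k])

    def set_alpha(self, alpha: float):
        self.model = self.model.with_(asrv=GammaASRV(alpha, self.model.asrv.ncats))
        self._compile_components()

    def set_weights(self, w):
        comp = self.model.composition
        if not isinstance(comp, MixtureComposition):
            raise UsageError("weights apply to mixture models only")
        self.model = self.model.with_(
            composition=MixtureComposition(comp.profiles, np.asarray(w, float))
        )
        new = self.model.composition
        for c_ in self.comps:
            if "mix" in c_:
                G = self.model.n_rate_categories()
                c_["logw"] = np.log(new.weights[c_["mix"]] + 1e-300) - np.log(G)
        self.logw = np.array([c_["logw"] for c_ in self.comps])

    # -- transition matrices ------------------------------------------------
    def _edge_P(self, node_idx: int) -> np.ndarray:
        """(ncomp, c, c) transition matrices for the edge above a node."""
        t = self.lengths[node_idx]
        out = np.empty((self.ncomp, self.model.n_states, self.model.n_states),
                       dtype=self.dtype)
        for m, c_ in enumerate(self.comps):
            gen = (
                self.generators[self.edge_gen[node_idx]]
                if self._branch_mode
                else self.generators[c_["gen"]]
            )
            out[m] = gen.transition(t, c_["rate"])
        return out

    # -- core recursion ------------------------------------------------------
    @property
    def _tiny(self):
        return 1e-300 if self.dtype == np.float64 else 1e-30

    def _postorder_partials(self):
        """Per-node conditional likelihoods (ncomp, P, c) and log-scale
        accumulators (ncomp, P)."""
        P_ = self.patterns.shape[1]
        partials = [None] * len(self.nodes)
        logscale = [None] * len(self.nodes)
        n_internal = 0
        for k, n in enumerate(self.nodes):
            if n.is_leaf:
                partials[k] = np.broadcast_to(
                    self.leaf_partials[k], (self.ncomp, P_, self.model.n_states)
                )
                logscale[k] = np.zeros((self.ncomp, P_), dtype=self.dtype)
                continue
            acc = None
            ls = np.zeros((self.ncomp, P_), dtype=self.dtype)
            for ci in self.children[k]:
                Pm = self._edge_P(ci)
                contrib = np.matmul(partials[ci], Pm.transpose(0, 2, 1))
                acc = contrib if acc is None else acc * contrib
                ls += logscale[ci]
            # rescaling every other level keeps the running maximum well
            # inside range while halving the cost of the max/divide pass
            n_internal += 1
            if n_internal % 2 == 0 or k == self.root_idx:
                scale = acc.max(axis=2)
                np.maximum(scale, self._tiny, out=scale)
                acc = acc / scale[:, :, None]
                ls += np.log(scale)
            partials[k] = acc
            logscale[k] = ls
        return partials, logscale

    def _pattern_loglik(self, partials, logscale):
        root = self.root_idx
        site = np.einsum("mpc,mc->mp", partials[root],
                         self.root_pi.astype(self.dtype))
        np.maximum(site, self._tiny, out=site)
        logcomp = np.log(site) + logscale[root] + self.logw[:, None]
        return logsumexp(logcomp, axis=0), logcomp

    def lnl(self) -> float:
        partials, logscale = self._postorder_partials()
        patt, _ = self._pattern_loglik(partials, logscale)
        return float(patt @ self.pattern_weights)

    def per_site_lnl(self) -> np.ndarray:
        partials, logscale = self._postorder_partials()
        patt, _ = self._pattern_loglik(partials, logscale)
        return patt[self.site_to_pattern]

    def component_site_logliks(self):
        """(ncomp, n_sites) per-component site log-likelihoods including
        component log-weights, plus the component (mixture, rate) labels."""
        partials, logscale = self._postorder_partials()
        _, logcomp = self._pattern_loglik(partials, logscale)
        return logcomp[:, self.site_to_pattern], self.comps

    # -- directional partials for branch optimization ------------------------
    def _preorder_partials(self, partials, logscale):
        """pre[v]: likelihood of all data outside subtree(v), viewed as a
        function of the state at v's parent, root prior included."""
        P_ = self.patterns.shape[1]
        pre = [None] * len(self.nodes)
        pre_ls = [None] * len(self.nodes)
        order = list(reversed(range(len(self.nodes))))  # root first
        root = self.root_idx
        pre[root] = np.broadcast_to(
            self.root_pi.astype(self.dtype)[:, None, :],
            (self.ncomp, P_, self.model.n_states)
        )
        pre_ls[root] = np.zeros((self.ncomp, P_), dtype=self.dtype)
        for k in order:
            if not self.children[k]:
                continue
            kids = self.children[k]
            contribs = {}
            for ci in kids:
                Pm = self._edge_P(ci)
                contribs[ci] = np.matmul(partials[ci], Pm.transpose(0, 2, 1))
            if k == root:
                pre_at_k = pre[k]
            else:
                # transport pre[k] (a function of the state at k's parent)
                # through k's own edge into k's frame
                pre_at_k = np.matmul(pre[k], self._edge_P(k))
            for ci in kids:
                acc = pre_at_k.copy()
                ls = pre_ls[k].copy()
                for cj in kids:
                    if cj is ci:
                        continue
                    np.multiply(acc, contribs[cj], out=acc)
                    ls = ls + logscale[cj]
                scale = acc.max(axis=2)
                np.maximum(scale, self._tiny, out=scale)
                acc /= scale[:, :, None]
                ls = ls + np.log(scale)
                pre[ci] = acc
                pre_ls[ci] = ls
        return pre, pre_ls

    def _edge_lnl(self, node_idx, t, pre, pre_ls, partials, logscale):
        """Total lnL as a function of one edge length, other edges fixed."""
        save = self.lengths[node_idx]
        self.lengths[node_idx] = t
        Pm = self._edge_P(node_idx)
        self.lengths[node_idx] = save
        contrib = np.matmul(partials[node_idx], Pm.transpose(0, 2, 1))
        site = (pre[node_idx] * contrib).sum(axis=2)
        np.maximum(site, self._tiny, out=site)
        logcomp = (
            np.log(site)
            + pre_ls[node_idx]
            + logscale[node_idx]
            + self.logw[:, None]
        )
        return float(logsumexp(logcomp, axis=0) @ self.pattern_weights)

    def _edge_spectral(self, node_idx: int):
        """Stacked eigensystems (left, right, rate-scaled eigenvalues)
        for the edge above a node, one layer per component."""
        c = self.model.n_states
        left = np.empty((self.ncomp, c, c), dtype=self.dtype)
        right = np.empty_like(left)
        lam = np.empty((self.ncomp, c), dtype=self.dtype)
        for m, c_ in enumerate(self.comps):
            gen = (self.generators[self.edge_gen[node_idx]]
                   if self._branch_mode else self.generators[c_["gen"]])
            left[m] = gen.left
            right[m] = gen.right
            lam[m] = gen.lam * c_["rate"]
        return left, right, lam

    def optimize_branches(self, tol: float = 1e-6, max_sweeps: int = 200):
        """Coordinate ascent: Brent on each branch length in turn.

        Within a sweep the directional partials are held fixed (refreshed
        between sweeps); a sweep that fails to improve the exact lnL is
        retried with damped (geometric half-step) updates and rolled
        back if still worse, which keeps the returned lnL monotone.
        Each edge's one-dimensional profile likelihood is evaluated
        through the edge's eigensystem, so a Brent trial costs one
        small contraction rather than a full pruning pass.
        """
        edge_ids = [k for k, n in enumerate(self.nodes) if n is not self.tree.root]

        def full(partials, logscale):
            patt, _ = self._pattern_loglik(partials, logscale)
            return float(patt @ self.pattern_weights)

        partials, logscale = self._postorder_partials()
        best = full(partials, logscale)
        # edges are updated in chunks with the directional partials
        # refreshed between chunks (block Gauss-Seidel): full Jacobi
        # sweeps overshoot badly when the start is far from the optimum
        chunk = max(8, len(edge_ids) // 2)
        for sweep in range(max_sweeps):
            saved = self.lengths.copy()
            for lo in range(0, len(edge_ids), chunk):
                if lo > 0:
                    partials, logscale = self._postorder_partials()
                pre, pre_ls = self._preorder_partials(partials, logscale)
                self._brent_edges(edge_ids[lo:lo + chunk], partials, logscale,
                                  pre, pre_ls)
            partials, logscale = self._postorder_partials()
            now = full(partials, logscale)
            if now < best:
                # collective overshoot within a chunk: retry with
                # geometric half-steps toward the proposal
                proposed = self.lengths.copy()
                recovered = False
                for _ in range(3):
                    self.lengths = np.sqrt(np.maximum(saved, _MIN_BRANCH)
                                           * np.maximum(proposed, _MIN_BRANCH))
                    proposed = self.lengths.copy()
                    partials, logscale = self._postorder_partials()
                    now = full(partials, logscale)
                    if now >= best:
                        recovered = True
                        break
                if not recovered:
                    self.lengths = saved
                    break
            gain, best = now - best, now
            if gain < tol:
                break
        self.set_lengths(self.lengths)
        return best

    def _brent_edges(self, edge_ids, partials, logscale, pre, pre_ls):
        for k in edge_ids:
            left, right, lam = self._edge_spectral(k)
            G = (np.matmul(pre[k], left)
                 * np.matmul(partials[k], right.transpose(0, 2, 1)))
            const = pre_ls[k] + logscale[k] + self.logw[:, None]

            def neg(x):
                site = np.matmul(G, np.exp(lam * np.exp(x))[:, :, None])[:, :, 0]
                np.maximum(site, self._tiny, out=site)
                return -float(
                    logsumexp(np.log(site) + const, axis=0)
                    @ self.pattern_weights)

            # search log-length in a x8 bracket around the current value
            # (re-centred every sweep, so large moves happen across sweeps)
            center = np.log(max(self.lengths[k], 1e-4))
            lo = max(np.log(_MIN_BRANCH), center - 2.08)
            hi = min(np.log(_MAX_BRANCH), center + 2.08)
            res = minimize_scalar(
                neg, bounds=(lo, hi), method="bounded",
                options={"xatol": 4e-3, "maxiter": 12},
            )
            self.lengths[k] = float(np.exp(res.x))


def log_likelihood(tree: Tree, alignment: Alignment, model: SubstitutionModel):
    """Total log-likelihood and the per-site log-likelihood vector."""
    eng = PruningEngine(tree, alignment, model)
    per_site = eng.per_site_lnl()
    return float(per_site.sum()), per_site


# ---------------------------------------------------------------------------
# optimization

class OptimizeResult:
    def __init__(self, tree, model, lnl, converged=True, n_sweeps=0):
        self.tree = tree
        self.model = model
        self.lnl = lnl
        self.converged = converged
        self.n_sweeps = n_sweeps

    def __iter__(self):  # (tree, model, lnl) unpacking
        return iter((self.tree, self.model, self.lnl))


def _optimize_alpha(eng: PruningEngine) -> float:
    if eng.model.asrv is None:
        raise UsageError("alpha optimization requires an ASRV model")
    def neg(loga):
        eng.set_alpha(float(np.exp(loga)))
        return -eng.lnl()
    res = minimize_scalar(neg, bounds=(np.log(0.02), np.log(50.0)),
                          method="bounded", options={"xatol": 3e-2, "maxiter": 8})
    eng.set_alpha(float(np.exp(res.x)))
    return -res.fun


def _optimize_weights_em(eng: PruningEngine, iters: int = 200, tol: float = 1e-8):
    """EM on mixture weights: with everything else fixed the component
    site likelihoods are constant, so each EM step is a cheap
    responsibility average and monotone in lnL."""
    comp = eng.model.composition
    if not isinstance(comp, MixtureComposition):
        raise UsageError("weight optimization requires a mixture model")
    logliks, comps = eng.component_site_logliks()
    mix_ids = np.array([c_["mix"] for c_ in comps])
    G = eng.model.n_rate_categories()
    base = logliks - np.log(comp.weights[mix_ids] + 1e-300)[:, None]
    K = comp.profiles.K
    w = comp.weights.copy()
    last = -np.inf
    for _ in range(iters):
        lw = np.log(w + 1e-300)[mix_ids][:, None]
        site = logsumexp(base + lw, axis=0)
        total = site.sum()
        resp = np.exp(base + lw - site[None, :])
        w_new = np.zeros(K)
        for k in range(K):
            w_new[k] = resp[mix_ids == k].sum()
        w = w_new / w_new.sum()
        if total - last < tol * max(1.0, abs(total)):
            break
        last = total
    eng.set_weights(w)
    return eng.lnl()


def _optimize_simplex_block(eng: PruningEngine, kind: str):
    """Softmax-reparameterized ascent for a single composition vector or
    the GTR exchangeabilities (small parameter blocks, full re-evals)."""
    from scipy.optimize import minimize

    m = eng.model
    if kind == "compositions":
        if not isinstance(m.composition, SingleComposition):
            raise UsageError("free compositions supported for single-pi models")
        x0 = np.log(m.composition.pi)
        def rebuild(x):
            pi = np.exp(x - x.max())
            return m.with_(composition=SingleComposition(pi / pi.sum()))
    elif kind == "gtr_rates":
        c = m.n_states
        iu = np.triu_indices(c, 1)
        x0 = np.log(m.exchangeabilities[iu])
        def rebuild(x):
            R = np.zeros((c, c))
            vals = np.exp(x - x.max())
            R[iu] = vals / vals.mean()
            return m.with_(exchangeabilities=R + R.T)
    else:
        raise UsageError(f"unknown block {kind!r}")

    tree, aln = eng.tree, eng.alignment

    def neg(x):
        e2 = PruningEngine(tree, aln, rebuild(x))
        e2.lengths = eng.lengths
        return -e2.lnl()

    res = minimize(neg, x0, method="Nelder-Mead",
                   options={"xatol": 1e-4, "fatol": 1e-6, "maxiter": 400})
    eng.model = rebuild(res.x)
    eng._compile_components()
    return eng.lnl()


def optimize(tree: Tree, alignment: Alignment, model: SubstitutionModel,
             free=("branch_lengths",), tol: float = 1e-6,
             max_sweeps: int = 200, bl_sweeps: int = 5,
             engine_dtype=np.float64) -> OptimizeResult:
    """Coordinate ascent over the requested parameter blocks.

    Blocks: ``branch_lengths``, ``alpha``, ``weights``, ``gtr_rates``,
    ``compositions``.  Sweeps repeat until the lnL gain drops below
    ``tol`` or ``max_sweeps`` is hit; the returned lnL never falls
    below the starting value.  Non-convergence sets
    ``result.converged = False`` rather than raising.
    """
    free = set(free)
    known = {"branch_lengths", "alpha", "weights", "gtr_rates", "compositions"}
    if free - known:
        raise UsageError(f"unknown parameter blocks {sorted(free - known)}")
    eng = PruningEngine(tree, alignment, model, dtype=engine_dtype)
    best = eng.lnl()
    if not free:
        return OptimizeResult(eng.tree, eng.model, best, True, 0)
    converged = False
    sweeps = 0
    for sweeps in range(1, max_sweeps + 1):
        if "branch_lengths" in free:
            best = eng.optimize_branches(tol=tol, max_sweeps=bl_sweeps)
        if "alpha" in free:
            best = _optimize_alpha(eng)
        if "weights" in free:
            best = _optimize_weights_em(eng)
        if "gtr_rates" in free:
            best = _optimize_simplex_block(eng, "gtr_rates")
        if "compositions" in free:
            best = _optimize_simplex_block(eng, "compositions")
        if sweeps > 1 and best - prev < tol:
            converged = True
            break
        prev = best
    return OptimizeResult(eng.tree, eng.model, best, converged, sweeps)


# ---------------------------------------------------------------------------
# topology search

def _default_start_lengths(t: Tree, default: float = 0.1) -> Tree:
    t = t.copy()
    for n in t.postorder():
        if n is not t.root and (n.length is None or n.length <= 0):
            n.length = default
    return t


def search_topology(alignment: Alignment, model: SubstitutionModel,
                    strategy: str = "nni", seed: int = 0,
                    start: Tree = None, free=("branch_lengths",),
                    tol: float = 1e-4, max_rounds: int = 25,
                    engine_dtype=np.float64, screen_top: int = 3,
                    spr_min_length: float = 0.5, _return_result: bool = False):
    """Maximum-likelihood topology search.

    ``exhaustive`` enumerates all unrooted topologies (allowed up to 8
    taxa; 10,395 at n=8) and optimizes each; ``nni`` hill-climbs from a
    neighbor-joining start tree (or ``start``): every
    nearest-neighbor-interchange of the current tree is scored cheaply
    at the current branch lengths, the ``screen_top`` best are refined
    by branch-length re-optimization, and the climb accepts the first
    refined neighbor that improves the current lnL.  The remaining free
    parameter blocks are re-tuned once the climb stalls.

    ``hillclimb`` augments ``nni`` with a restricted
    subtree-prune-regraft stage: whenever the NNI climb stalls, each
    long-branch subtree (pendant edge at least ``spr_min_length``) is
    scanned across every alternative attachment point, which lets the
    search jump between attachment basins that NNI alone cannot cross
    (the characteristic failure mode when a long stem is misplaced).

    Deterministic given the seed, which only breaks exact lnL ties.
    """
    rng = np.random.default_rng(seed)
    labels = list(alignment.labels)
    if strategy == "exhaustive":
        if len(labels) > 8:
            raise UsageError("exhaustive search is limited to 8 taxa")
        best = None
        for topo in enumerate_topologies(labels):
            cand = _default_start_lengths(topo)
            res = optimize(cand, alignment, model, free=free, tol=tol,
                           max_sweeps=10, engine_dtype=engine_dtype)
            if best is None or res.lnl > best.lnl + 1e-12:
                best = res
        return best.tree, best.lnl
    if strategy not in ("nni", "hillclimb"):
        raise UsageError(f"unknown search strategy {strategy!r}")

    if start is None:
        from .distances import distance_matrix, neighbor_joining
        dm = distance_matrix(alignment, variant="paralinear")
        if dm.n_invalid():
            dm = distance_matrix(alignment, variant="p")
        start = neighbor_joining(dm)

    init_sweeps = 2
    free_init = free
    if strategy == "hillclimb" and alignment.n_sites > 1200:
        # coarse-to-fine: run the full climb on a fixed random site
        # subsample, then polish the resulting tree (and carry its
        # tuned model parameters) against all sites
        sub_rng = np.random.default_rng(seed)
        cols = np.sort(sub_rng.choice(alignment.n_sites, 600, replace=False))
        rough = search_topology(
            alignment.take_sites(cols), model, strategy="hillclimb",
            seed=seed + 1, start=start, free=free, tol=tol,
            max_rounds=min(max_rounds, 4), engine_dtype=engine_dtype,
            screen_top=screen_top, spr_min_length=spr_min_length,
            _return_result=True)
        start, model = rough.tree, rough.model
        max_rounds = 0
        init_sweeps = 1
        free_init = ("branch_lengths",)
    else:
        free_init = free

    cur = optimize(_default_start_lengths(start), alignment, model,
                   free=free_init, tol=tol, max_sweeps=init_sweeps,
                   bl_sweeps=2, engine_dtype=engine_dtype)

    # screening uses a fixed random subset of columns when the
    # alignment is large; all accept/reject decisions and refinements
    # run on the full data
    if alignment.n_sites > 800:
        cols = rng.choice(alignment.n_sites, size=600, replace=False)
        screen_aln = alignment.take_sites(np.sort(cols))
        screen_scale = alignment.n_sites / 600.0
    else:
        screen_aln, screen_scale = alignment, 1.0

    def quick(tree):
        eng = PruningEngine(_default_start_lengths(tree), screen_aln,
                            cur.model, dtype=engine_dtype)
        return eng.lnl() * screen_scale

    def refine(tree):
        return optimize(_default_start_lengths(tree), alignment, cur.model,
                        free=("branch_lengths",), tol=tol, max_sweeps=1,
                        bl_sweeps=1, engine_dtype=engine_dtype)

    def try_candidates(cands, gate=None):
        scored = sorted(((quick(t), i) for i, t in enumerate(cands)),
                        reverse=True)
        top_q = scored[0][0]
        for q, idx in scored[:min(screen_top, 2)]:
            if q < top_q - 35.0:
                continue  # clearly behind the best-screened candidate
            if gate is not None and q < cur.lnl - gate:
                continue
            res = refine(cands[idx])
            if res.lnl > cur.lnl + 1e-6:
                return res
        return None

    def long_branch_scan():
        lengths = [(n.length or 0.0, tuple(sorted(l.name for l in n.leaves())))
                   for n in cur.tree.postorder()
                   if n.parent is not None
                   and 1 < len(n.leaves()) < len(labels) - 1]
        best = None
        for bl, key in sorted(lengths, reverse=True)[:2]:
            if bl < spr_min_length:
                continue
            cands = [t for _, t in spr_reattachments(cur.tree, set(key))]
            res = try_candidates(cands)
            if res is not None and (best is None or res.lnl > best.lnl):
                best = res
        return best

    def retune():
        if set(free) - {"branch_lengths"}:
            return optimize(cur.tree, alignment, cur.model, free=free,
                            tol=tol, max_sweeps=1, bl_sweeps=2,
                            engine_dtype=engine_dtype)
        return cur

    def nni_climb(budget):
        nonlocal cur
        for _ in range(budget):
            res = try_candidates(nni_neighbors(cur.tree), gate=25.0)
            if res is None:
                return
            cur = res

    # fixed pipeline: relocate long branches first (the moves a
    # misplaced stem needs), then NNI-polish, then a final relocation
    # check; non-topology parameters are re-tuned once at the end
    if strategy == "hillclimb":
        moved = long_branch_scan()
        if moved is not None:
            cur = moved
            cur = retune()
    nni_climb(max_rounds)
    if strategy == "hillclimb":
        moved = long_branch_scan()
        if moved is not None:
            cur = moved
            nni_climb(3)
    cur = retune()
    if _return_result:
        return cur
    return cur.tree, cur.lnl


def bootstrap_support(alignment: Alignment, model: SubstitutionModel,
                      strategy: str = "nni", B: int = 100, seed: int = 0,
                      free=("branch_lengths",)) -> Tree:
    """Nonparametric bootstrap: resample columns with replacement B
    times, re-search, and annotate each split of the best full-data
    tree with the percentage of replicates containing it."""
    from .trees import nontrivial_splits

    if B < 1:
        raise UsageError("B must be >= 1")
    rng = np.random.default_rng(seed)
    best, _ = search_topology(alignment, model, strategy=strategy, seed=seed,
                              free=free)
    target = nontrivial_splits(best)
    hits = {s: 0 for s in target}
    L = alignment.n_sites
    for b in range(B):
        cols = rng.integers(0, L, size=L)
        rep = alignment.take_sites(cols)
        t_b, _ = search_topology(rep, model, strategy=strategy,
                                 seed=seed + 1 + b, free=free)
        found = nontrivial_splits(t_b)
        for s in target:
            if s in found:
                hits[s] += 1
    leaves = frozenset(best.leaf_names())
    ref = min(leaves)
    for n in best.postorder():
        if n.is_leaf or n is best.root:
            continue
        below = frozenset(l.name for l in n.leaves())
        key = below if ref not in below else leaves - below
        if key in hits:
            n.support = 100.0 * hits[key] / B
    return best
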