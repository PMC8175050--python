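"""Independent reference implementations used to validate the package.

These deliberately avoid the pruning recursion and the spectral
decomposition: likelihoods are computed by brute-force enumeration of
internal-node states with expm-based transition matrices, and tree
distances by explicit split enumeration.  They are only usable at toy
sizes.
"""

import itertools

import numpy as np

from hetphylo.models import (
    BranchComposition,
    MixtureComposition,
    SingleComposition,
    build_rate_matrix,
    edge_key,
    smooth_composition,
    transition_matrix,
)


def brute_force_lnl(tree, alignment, model):
    """Sum over all internal-state assignments, one site at a time."""
    t = tree.copy()
    nodes = list(t.postorder())
    root = t.root
    internals = [n for n in nodes if not n.is_leaf]
    leaves = [n for n in nodes if n.is_leaf]
    c = model.n_states
    rates = model.rate_categories()
    G = len(rates)
    comp = model.composition
    per_edge = isinstance(comp, BranchComposition)
    if isinstance(comp, SingleComposition):
        items = [(comp.pi, build_rate_matrix(model.exchangeabilities, comp.pi), 1.0)]
    elif isinstance(comp, MixtureComposition):
        items = [
            (smooth_composition(p),
             build_rate_matrix(model.exchangeabilities, p), w)
            for p, w in zip(comp.profiles.profiles, comp.weights)
        ]
    else:
        bmap = comp.map
        Qs = {k: build_rate_matrix(model.exchangeabilities, bmap.pool[i])
              for k, i in bmap.assignment.items()}
        items = [(bmap.root_composition, None, 1.0)]

    total = 0.0
    for s in range(alignment.n_sites):
        obs = {
            l.name: alignment.alphabet.state_set(
                alignment.matrix[alignment.labels.index(l.name), s])
            for l in leaves
        }
        sitelik = 0.0
        for pi, Q, w in items:
            pi = smooth_composition(pi)
            for r in rates:
                P = {}
                for n in nodes:
                    if n is root:
                        continue
                    q = Qs[edge_key(n)] if per_edge else Q
                    P[id(n)] = transition_matrix(q, n.length or 0.0, r)
                tot = 0.0
                for assign in itertools.product(range(c), repeat=len(internals)):
                    st = {id(n): a for n, a in zip(internals, assign)}
                    pr = pi[st[id(root)]]
                    for n in nodes:
                        if n is root:
                            continue
                        ps = st[id(n.parent)]
                        if n.is_leaf:
                            pr *= sum(P[id(n)][ps, x] for x in obs[n.name])
                        else:
                            pr *= P[id(n)][ps, st[id(n)]]
                    tot += pr
                sitelik += w * (1.0 / G) * tot
        total += np.log(sitelik)
    return total


def splits_by_enumeration(tree):
    """Non-trivial splits via explicit leaf-set listing per edge."""
    t = tree.copy().deroot()
    leaves = frozenset(t.leaf_names())
    ref = min(leaves)
    out = set()
    for n in t.postorder():
        if n is t.root:
            continue
        below = frozenset(l.name for l in n.leaves())
        side = below if ref not in below else leaves - below
        if 1 < len(side) < len(leaves) - 1:
            out.add(side)
    return out


def rf_by_enumeration(t1, t2):
    return len(splits_by_enumeration(t1) ^ splits_by_enumeration(t2))
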