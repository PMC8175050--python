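"""Pairwise divergence matrices, LogDet/paralinear distances, and
neighbor joining.

The paralinear distance (the default) is additive under the general
Markov model, in which compositions may differ across the tree, so it
remains consistent where stationary-model distances are misled by
convergent composition.  With F_hat the joint state-pair frequency
matrix of a taxon pair, f and g its row and column sums, and c the
alphabet size:

    paralinear:  d = -(1/c) [ ln det F_hat
                              - (ln prod_x f_x + ln prod_y g_y) / 2 ]
    logdet:      d = -(1/c) ln det F_hat - ln c

The logdet variant's additive constant (-ln c) makes the distance zero
for identical sequences of uniform composition; paralinear is zero for
identical sequences of any composition.  Non-positive determinants
(saturation) and empty pairs yield flagged-invalid entries rather than
capped values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import UsageError
from .msa import Alignment, remove_constant_proportion
from .trees import Node, Tree

__all__ = [
    "DivergenceMatrix",
    "DistanceMatrix",
    "divergence_matrix",
    "logdet_distance",
    "jc_distance",
    "distance_matrix",
    "neighbor_joining",
    "write_phylip_distances",
    "read_phylip_distances",
]


@dataclass
class DivergenceMatrix:
    """Joint state-pair counts for one taxon pair: F[x, y] counts sites
    with plain state x in taxon_i and y in taxon_j."""

    F: np.ndarray
    taxon_i: str
    taxon_j: str
    n_skipped: int = 0

    @property
    def n(self) -> int:
        return int(self.F.sum())

    @property
    def n_states(self) -> int:
        return self.F.shape[0]


@dataclass
class DistanceMatrix:
    labels: list
    d: np.ndarray
    valid: np.ndarray = None
    reasons: dict = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        if self.valid is None:
            self.valid = np.ones(self.d.shape, dtype=bool)
        np.fill_diagonal(self.d, 0.0)

    @property
    def n_taxa(self) -> int:
        return len(self.labels)

    def n_invalid(self) -> int:
        iu = np.triu_indices(self.n_taxa, 1)
        return int((~self.valid[iu]).sum())


def divergence_matrix(a: Alignment, taxon_i: str, taxon_j: str) -> DivergenceMatrix:
    """Count aligned plain-state pairs; sites where either taxon carries
    a missing or ambiguous character are skipped."""
    if taxon_i == taxon_j:
        raise UsageError("divergence matrix needs two distinct taxa")
    alpha = a.alphabet
    c = alpha.size
    ri = a.matrix[a.labels.index(taxon_i)]
    rj = a.matrix[a.labels.index(taxon_j)]
    code = {s: k for k, s in enumerate(alpha.states)}
    xi = np.array([code.get(ch, -1) for ch in ri])
    xj = np.array([code.get(ch, -1) for ch in rj])
    keep = (xi >= 0) & (xj >= 0)
    F = np.zeros((c, c))
    np.add.at(F, (xi[keep], xj[keep]), 1.0)
    return DivergenceMatrix(F, taxon_i, taxon_j, n_skipped=int((~keep).sum()))


def logdet_distance(F: DivergenceMatrix, variant: str = "paralinear"):
    """Distance from a divergence matrix, or (None, reason) if invalid."""
    n = F.n
    if n == 0:
        return None, "empty"
    c = F.n_states
    Fh = F.F / n
    f = Fh.sum(axis=1)
    g = Fh.sum(axis=0)
    if np.any(f <= 0) or np.any(g <= 0):
        return None, "zero-marginal"
    sign, logdet = np.linalg.slogdet(Fh)
    if sign <= 0:
        return None, "saturation"
    if variant == "paralinear":
        d = -(logdet - 0.5 * (np.log(f).sum() + np.log(g).sum())) / c
    elif variant == "logdet":
        d = -logdet / c - np.log(c)
    else:
        raise UsageError(f"unknown variant {variant!r}")
    return float(d), None


def jc_distance(F: DivergenceMatrix):
    """Homogeneous-model (Jukes-Cantor type, c states) corrected distance."""
    n = F.n
    if n == 0:
        return None, "empty"
    c = F.n_states
    p = 1.0 - np.trace(F.F) / n
    arg = 1.0 - c / (c - 1.0) * p
    if arg <= 0:
        return None, "saturation"
    return float(-(c - 1.0) / c * np.log(arg)), None


def distance_matrix(a: Alignment, variant: str = "paralinear",
                    constant_removal_p: float = 0.0) -> DistanceMatrix:
    """All pairwise distances, optionally after removing a proportion of
    constant sites once, globally (the incremental rate-correction used
    with LogDet-style distances).

    Variants: ``paralinear``, ``logdet``, ``jc`` (stationary c-state
    correction), ``p`` (raw mismatch proportion).
    """
    if not 0 <= constant_removal_p <= 1:
        raise UsageError("constant_removal_p must be in [0, 1]")
    if constant_removal_p > 0:
        a = remove_constant_proportion(a, constant_removal_p)
    T = a.n_taxa
    d = np.zeros((T, T))
    valid = np.ones((T, T), dtype=bool)
    reasons = {}
    for i in range(T):
        for j in range(i + 1, T):
            F = divergence_matrix(a, a.labels[i], a.labels[j])
            if variant in ("paralinear", "logdet"):
                val, reason = logdet_distance(F, variant)
            elif variant == "jc":
                val, reason = jc_distance(F)
            elif variant == "p":
                val = 1.0 - np.trace(F.F) / F.n if F.n else None
                reason = None if F.n else "empty"
            else:
                raise UsageError(f"unknown variant {variant!r}")
            if val is None:
                valid[i, j] = valid[j, i] = False
                reasons[(a.labels[i], a.labels[j])] = reason
            else:
                d[i, j] = d[j, i] = max(val, 0.0)
    return DistanceMatrix(list(a.labels), d, valid, reasons,
                          metadata=dict(variant=variant,
                                        constant_removal_p=constant_removal_p,
                                        n_sites=a.n_sites))


def neighbor_joining(dm: DistanceMatrix) -> Tree:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    Ties in the Q criterion go to the lexicographically lowest index
    pair.  A negative branch length is clamped to zero and its deficit
    moved to the sibling edge, preserving the path length between the
    joined taxa.
    """
    if dm.n_invalid():
        bad = list(dm.reasons.items())[:3]
        raise UsageError(f"distance matrix has invalid entries, e.g. {bad}")
    T = dm.n_taxa
    if T < 3:
        raise UsageError("neighbor joining needs at least 3 taxa")
    D = dm.d.copy()
    nodes = [Node(name=l) for l in dm.labels]
    active = list(range(T))

    while len(active) > 3:
        r = len(active)
        sub = D[np.ix_(active, active)]
        R = sub.sum(axis=1)
        Q = (r - 2) * sub - R[:, None] - R[None, :]
        np.fill_diagonal(Q, np.inf)
        best = None
        for ai in range(r):
            for aj in range(ai + 1, r):
                q = Q[ai, aj]
                if best is None or q < best[0] - 1e-12:
                    best = (q, ai, aj)
        _, ai, aj = best
        i, j = active[ai], active[aj]
        dij = sub[ai, aj]
        li = 0.5 * dij + (R[ai] - R[aj]) / (2 * (r - 2))
        lj = dij - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        li, lj = max(li, 0.0), max(lj, 0.0)
        parent = Node()
        nodes[i].length = li
        nodes[j].length = lj
        parent.add(nodes[i])
        parent.add(nodes[j])
        new_row = np.zeros(D.shape[0] + 1)
        D = np.pad(D, ((0, 1), (0, 1)))
        u = D.shape[0] - 1
        for ak in range(r):
            k = active[ak]
            if k in (i, j):
                continue
            D[u, k] = D[k, u] = 0.5 * (sub[ai, ak] + sub[aj, ak] - dij)
        nodes.append(parent)
        active = [k for k in active if k not in (i, j)] + [u]

    a, b, c_ = active
    dab, dac, dbc = D[a, b], D[a, c_], D[b, c_]
    root = Node()
    la = 0.5 * (dab + dac - dbc)
    lb = 0.5 * (dab + dbc - dac)
    lc = 0.5 * (dac + dbc - dab)
    for k, l in zip((a, b, c_), (la, lb, lc)):
        nodes[k].length = max(l, 0.0)
        root.add(nodes[k])
    return Tree(root)


def write_phylip_distances(dm: DistanceMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"{dm.n_taxa}\n")
        for l, row in zip(dm.labels, dm.d):
            fh.write(l + "  " + " ".join(f"{x:.6f}" for x in row) + "\n")


def read_phylip_distances(path) -> DistanceMatrix:
    with open(path) as fh:
        n = int(fh.readline().split()[0])
        labels, rows = [], []
        for _ in range(n):
            parts = fh.readline().split()
            labels.append(parts[0])
            rows.append([float(x) for x in parts[1:]])
    return DistanceMatrix(labels, np.array(rows))
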