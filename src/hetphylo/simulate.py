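"""Simulation of alignments with site- and branch-compositional
heterogeneity, plus the packaged synthetic study fixtures.

The simulator draws, per site, a composition profile (for mixture
sources) and a rate (discrete- or continuous-gamma), then evolves a
root state down the tree with per-edge transition matrices.  Branch
lengths are expected substitutions per site under each edge's own
generator, matching the likelihood side.

The fixture trees are synthetic stand-ins for the empirical trees of
the published tree-of-life analyses this package's experiments emulate:
their *regime* (a long "eukaryote-stem-like" branch attached by a short
edge inside a short-branched clade, with a distant long-branched
outgroup clade) is reproduced with packaged constant branch lengths,
not the original empirical lengths, which are not public.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .alphabets import DNA, get_alphabet
from .errors import UsageError
from .models import (
    BranchComposition,
    BranchCompositionMap,
    GammaASRV,
    MixtureComposition,
    ProfileSet,
    SingleComposition,
    SpectralGenerator,
    SubstitutionModel,
    edge_key,
    uniform_exchangeabilities,
)
from .msa import Alignment
from .trees import Tree, parse_newick

__all__ = [
    "SimulationConfig",
    "sample_profile_set",
    "hogenom_like_bank",
    "simulate_alignment",
    "simulate_from_manifest",
    "fixture_trees",
    "fixture_info",
    "make_case_study",
]

# seed of the packaged synthetic profile bank (a stand-in for
# database-derived site-composition sets; fixed so the bank is a constant)
_BANK_SEED = 73

def sample_profile_set(K: int, c: int, concentration: float = 0.2,
                       seed: int = 0, names: bool = False) -> ProfileSet:
    """K independent symmetric-Dirichlet composition vectors.

    Low concentration (default 0.2) gives sparse, strongly skewed
    profiles of the kind seen in site-composition sets estimated from
    large databases; concentration >> 1 approaches uniform.
    """
    if K < 1 or concentration <= 0:
        raise UsageError("need K >= 1 and concentration > 0")
    rng = np.random.default_rng(seed)
    profiles = rng.dirichlet(np.full(c, concentration), size=K)
    return ProfileSet(profiles, names=[f"p{k}" for k in range(K)] if names else None)


def hogenom_like_bank(K: int = 64, c: int = 20, n_clusters: int = 16,
                      child_concentration: float = 60.0) -> ProfileSet:
    """The packaged synthetic site-composition bank (deterministic).

    A synthetic stand-in for database-derived amino-acid site
    compositions.  Real site-composition collections are strongly
    clustered (which is why moderate numbers of mixture components
    describe them well), so the bank is drawn hierarchically: sparse
    Dirichlet(0.2) cluster centers, each spawning K/n_clusters members
    from a concentrated Dirichlet around the center.  The seed is fixed
    so the bank is a packaged constant; simulations draw site
    compositions from the full bank, while inference mixtures use
    k-means centroids of it.
    """
    rng = np.random.default_rng(_BANK_SEED)
    if K % n_clusters:
        raise UsageError("bank size must be a multiple of n_clusters")
    centers = rng.dirichlet(np.full(c, 0.2), size=n_clusters)
    centers = np.maximum(centers, 1e-4)
    rows = []
    for center in centers:
        a = child_concentration * (center / center.sum())
        rows.extend(rng.dirichlet(a, size=K // n_clusters))
    return ProfileSet(np.array(rows))


@dataclass
class SimulationConfig:
    """Everything needed to reproduce one simulated alignment."""

    tree: Tree
    model: SubstitutionModel
    n_sites: int
    seed: int
    continuous_gamma: bool = False

    def __post_init__(self):
        if self.n_sites < 1:
            raise UsageError("n_sites must be >= 1")

    def run(self):
        return simulate_alignment(self.tree, self.model, self.n_sites,
                                  seed=self.seed,
                                  continuous_gamma=self.continuous_gamma)


def _site_rates(model, n_sites, continuous, rng):
    if model.asrv is None:
        return np.ones(n_sites), None
    if continuous:
        a = model.asrv.shape
        return rng.gamma(a, 1.0 / a, size=n_sites), None
    rates = model.asrv.rates()
    cats = rng.integers(0, len(rates), size=n_sites)
    return rates[cats], cats


def _sample_states(P_rows, rng):
    """Draw one categorical state per row of a (n, c) probability array."""
    cum = np.cumsum(P_rows, axis=1)
    u = rng.random(P_rows.shape[0])
    return np.minimum((u[:, None] > cum).sum(axis=1), P_rows.shape[1] - 1)


def simulate_alignment(tree: Tree, model: SubstitutionModel, n_sites: int,
                       seed: int = 0, continuous_gamma: bool = False):
    """Simulate an alignment under any composition mode of the model.

    Returns (Alignment, metadata) where metadata records the seed, the
    per-site profile index and rate, and a manifest sufficient for
    exact replay via :func:`simulate_from_manifest`.
    """
    rng = np.random.default_rng(seed)
    t = tree.copy()
    alpha = model.alphabet
    c = alpha.size
    comp = model.composition

    rates, rate_cats = _site_rates(model, n_sites, continuous_gamma, rng)

    if isinstance(comp, SingleComposition):
        gens = [SpectralGenerator(model.exchangeabilities, comp.pi)]
        profile_idx = np.zeros(n_sites, dtype=int)
        root_pi = np.tile(comp.pi, (n_sites, 1))
        edge_gen = None
    elif isinstance(comp, MixtureComposition):
        gens = [SpectralGenerator(model.exchangeabilities, p)
                for p in comp.profiles.profiles]
        profile_idx = rng.choice(comp.profiles.K, size=n_sites, p=comp.weights)
        root_pi = comp.profiles.profiles[profile_idx]
        edge_gen = None
    elif isinstance(comp, BranchComposition):
        bmap = comp.map
        gens = [SpectralGenerator(model.exchangeabilities, p) for p in bmap.pool]
        profile_idx = np.zeros(n_sites, dtype=int)
        root_pi = np.tile(bmap.root_composition, (n_sites, 1))
        edge_gen = {}
        for n in t.postorder():
            if n is not t.root:
                edge_gen[id(n)] = bmap.assignment[edge_key(n)]
    else:
        raise UsageError("unsupported composition mode for simulation")

    states = {id(t.root): _sample_states(root_pi, rng)}
    stack = [t.root]
    while stack:
        node = stack.pop()
        parent_states = states[id(node)]
        for child in node.children:
            bl = child.length if child.length is not None else 0.0
            if isinstance(comp, BranchComposition):
                gen = gens[edge_gen[id(child)]]
            else:
                gen = None  # per-site generator for mixtures
            child_states = np.empty(n_sites, dtype=int)
            if isinstance(comp, MixtureComposition):
                group_of = profile_idx
            else:
                group_of = np.zeros(n_sites, dtype=int)
            for g in np.unique(group_of):
                sel = group_of == g
                gsel = gens[g] if gen is None else gen
                if model.asrv is None:
                    P = gsel.transition(bl, 1.0)
                    child_states[sel] = _sample_states(
                        P[parent_states[sel]], rng)
                elif continuous_gamma:
                    rs = rates[sel]
                    E = np.exp(np.outer(rs * bl, gsel.lam))
                    rows = np.einsum(
                        "nc,nc,cd->nd",
                        gsel.left[parent_states[sel]], E, gsel.right)
                    np.maximum(rows, 0.0, out=rows)
                    rows /= rows.sum(axis=1, keepdims=True)
                    child_states[sel] = _sample_states(rows, rng)
                else:
                    for cat in np.unique(rate_cats[sel]):
                        sel2 = sel & (rate_cats == cat)
                        P = gsel.transition(bl, model.asrv.rates()[cat])
                        child_states[sel2] = _sample_states(
                            P[parent_states[sel2]], rng)
            states[id(child)] = child_states
            if child.children:
                stack.append(child)

    leaves = t.root.leaves()
    labels = [l.name for l in leaves]
    chars = np.array(list(alpha.states))
    matrix = np.vstack([chars[states[id(l)]] for l in leaves])
    aln = Alignment(labels, matrix, alpha)
    meta = dict(
        seed=seed,
        n_sites=n_sites,
        tree=t.to_newick(),
        profile_index=profile_idx,
        rates=rates,
        rate_categories=rate_cats,
        continuous_gamma=continuous_gamma,
        manifest=_manifest(tree, model, n_sites, seed, continuous_gamma),
    )
    return aln, meta


def _manifest(tree, model, n_sites, seed, continuous_gamma) -> dict:
    comp = model.composition
    m = dict(
        tree=tree.to_newick(),
        alphabet=model.alphabet.name,
        exchangeabilities=model.exchangeabilities.tolist(),
        n_sites=int(n_sites),
        seed=int(seed),
        continuous_gamma=bool(continuous_gamma),
        asrv=None if model.asrv is None else dict(
            shape=model.asrv.shape, ncats=model.asrv.ncats),
    )
    if isinstance(comp, SingleComposition):
        m["composition"] = dict(mode="single", pi=comp.pi.tolist())
    elif isinstance(comp, MixtureComposition):
        m["composition"] = dict(mode="mixture",
                                profiles=comp.profiles.profiles.tolist(),
                                weights=comp.weights.tolist())
    else:
        m["composition"] = dict(
            mode="branch",
            pool=comp.map.pool.tolist(),
            assignment={" ".join(k): int(v)
                        for k, v in comp.map.assignment.items()},
            root_index=int(comp.map.root_index),
            map_mode=comp.map.mode,
        )
    return m


def simulate_from_manifest(manifest: dict):
    """Replay a simulation exactly from its manifest."""
    tree = parse_newick(manifest["tree"])
    alpha = get_alphabet(manifest["alphabet"])
    comp_m = manifest["composition"]
    if comp_m["mode"] == "single":
        comp = SingleComposition(np.array(comp_m["pi"]))
    elif comp_m["mode"] == "mixture":
        comp = MixtureComposition(ProfileSet(np.array(comp_m["profiles"])),
                                  np.array(comp_m["weights"]))
    else:
        comp = BranchComposition(BranchCompositionMap(
            pool=np.array(comp_m["pool"]),
            assignment={tuple(k.split(" ")): v
                        for k, v in comp_m["assignment"].items()},
            root_index=comp_m["root_index"],
            mode=comp_m.get("map_mode", "NDCH"),
        ))
    asrv = manifest["asrv"]
    model = SubstitutionModel(
        alpha, np.array(manifest["exchangeabilities"]), comp,
        None if asrv is None else GammaASRV(asrv["shape"], asrv["ncats"]),
    )
    return simulate_alignment(tree, model, manifest["n_sites"],
                              seed=manifest["seed"],
                              continuous_gamma=manifest["continuous_gamma"])


# ---------------------------------------------------------------------------
# fixture trees

def _two_domain_newick(extra: int) -> str:
    # deep, short-branched ingroup (internal edges 0.12) so that basal
    # reattachment of the long stem meaningfully shortens its path to the
    # distant outgroup -- the geometry that makes the stem attractable
    core = ("((A1:0.216,A2:0.264):0.12,(A3:0.192,A4:0.288):0.12):0.12")
    euk = "(E1:0.15,E2:0.20):1.8"
    backbone = f"(({core},{euk}):0.05,(A5:0.24,A6:0.264):0.12):0.12"
    tail = "A7:0.24"
    for k in range(extra):
        tail = f"({tail},A{8 + k}:0.24):0.12"
    bac = "((B1:0.30,B2:0.28):0.15,B3:0.35):2.2"
    return f"({backbone},{tail},{bac});"


def _three_domain_newick(extra: int) -> str:
    core = "((A1:0.216,A2:0.264):0.12,(A3:0.192,A4:0.288):0.12):0.12"
    backbone = f"({core},(A5:0.24,A6:0.264):0.12):0.12"
    tail = "A7:0.24"
    for k in range(extra):
        tail = f"({tail},A{8 + k}:0.24):0.12"
    longpair = "(((B1:0.30,B2:0.28):0.15,B3:0.35):1.1,(E1:0.15,E2:0.20):1.8):1.1"
    return f"({backbone},{tail},{longpair});"


_THERMUS_NEWICK = ("((T:0.35,M:0.15):0.08,D:0.30,"
                   "(X1:0.12,(X2:0.10,X3:0.14):0.06):0.10);")


def fixture_trees(kind: str, scale: int = 12, seed: int = 0) -> Tree:
    """Packaged study trees (constant branch lengths, deterministic).

    ``two_domain_like``: a >= 1.5-substitutions "stem" branch carrying a
    two-leaf clade, attached by a 0.03 edge inside a short-branched
    clade, plus a distant long-branched three-leaf outgroup clade.
    ``three_domain_like``: the same leaves but with the two long
    branches joined.  ``thermus_like``: the six-taxon case-study
    topology with lengths in [0.05, 0.5].  ``scale`` adjusts the taxon
    count by adding backbone leaves (two_domain/three_domain only).
    """
    if kind == "thermus_like":
        return parse_newick(_THERMUS_NEWICK)
    if kind not in ("two_domain_like", "three_domain_like"):
        raise UsageError(f"unknown fixture kind {kind!r}")
    if scale < 12:
        raise UsageError("domain fixtures need scale >= 12")
    extra = scale - 12
    text = (_two_domain_newick(extra) if kind == "two_domain_like"
            else _three_domain_newick(extra))
    return parse_newick(text)


def fixture_info(kind: str, scale: int = 12) -> dict:
    """Metadata for a fixture: taxa and the topology-defining clan whose
    recovery is the experiment's readout."""
    if kind in ("two_domain_like", "three_domain_like"):
        archaea = {f"A{i}" for i in range(1, max(8, scale - 4))}
        bacteria = {"B1", "B2", "B3"}
        stem = {"E1", "E2"}
        if kind == "two_domain_like":
            # recovered iff the stem is placed within the ingroup: the
            # outgroup stays a clan, the stem neither joins it nor
            # leaves the ingroup intact as a clan of its own
            return dict(stem_taxa=sorted(stem), outgroup=sorted(bacteria),
                        required_clans=[bacteria],
                        forbidden_clans=[bacteria | stem, archaea])
        return dict(stem_taxa=sorted(stem), outgroup=sorted(bacteria),
                    required_clans=[bacteria | stem], forbidden_clans=[])
    if kind == "thermus_like":
        return dict(recovery_clan={"T", "D", "M"}, sister_pair={"T", "M"})
    raise UsageError(f"unknown fixture kind {kind!r}")


# ---------------------------------------------------------------------------
# case studies

def _gc_composition(gc: float) -> np.ndarray:
    """DNA composition with the given G+C content, G=C and A=T."""
    return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])


def _branch_map_for(tree: Tree, pool, special_edges: dict, root_index: int,
                    default_index: int, mode: str = "NDCH"):
    assignment = {}
    for n in tree.postorder():
        if n is tree.root:
            continue
        key = edge_key(n)
        assignment[key] = default_index
        for leafset, idx in special_edges.items():
            if set(key) == set(leafset):
                assignment[key] = idx
    return BranchCompositionMap(np.asarray(pool), assignment, root_index, mode)


def make_case_study(kind: str, seed: int = 0, n_sites: int = None,
                    asrv_shape: float = None):
    """Packaged synthetic case-study data sets.

    ``composition_attraction``: five DNA taxa on the tree
    ((A,B),(C,D),E) in which the two *non-sister* taxa A and C evolve
    along long branches toward a moderate-GC composition while every
    other branch keeps a high-GC composition; stationary-model analyses
    are pulled toward grouping A with C, while paralinear distances and
    branch-heterogeneous models recover the generating tree.

    ``branch_heterogeneous``: six DNA taxa on the thermus_like fixture
    with a second composition vector on the branches leading to the
    three "mesophile" tips — stationarity-violating data for the
    model-adequacy demonstrations.

    Returns (Alignment, generating Tree, manifest dict).
    """
    if kind == "composition_attraction":
        n_sites = n_sites or 10_000
        # moderate rate heterogeneity: strong enough that the constant-site
        # correction matters, weak enough that the attraction is driven by
        # the convergent composition rather than by rate compression
        asrv_shape = asrv_shape if asrv_shape is not None else 2.0
        tree = parse_newick(
            "((A:1.0,B:0.08):0.06,(C:1.0,D:0.08):0.06,E:0.08);")
        pool = np.vstack([_gc_composition(0.75), _gc_composition(0.55)])
        bmap = _branch_map_for(tree, pool,
                               special_edges={("A",): 1, ("C",): 1},
                               root_index=0, default_index=0)
        model = SubstitutionModel(DNA, uniform_exchangeabilities(4),
                                  BranchComposition(bmap),
                                  GammaASRV(asrv_shape, 4))
    elif kind == "branch_heterogeneous":
        n_sites = n_sites or 1_000
        asrv_shape = asrv_shape if asrv_shape is not None else 0.935
        tree = fixture_trees("thermus_like")
        pool = np.vstack([_gc_composition(0.70), _gc_composition(0.45)])
        bmap = _branch_map_for(
            tree, pool,
            special_edges={("X1",): 1, ("X2",): 1, ("X3",): 1,
                           ("X2", "X3"): 1, ("X1", "X2", "X3"): 1},
            root_index=0, default_index=0)
        model = SubstitutionModel(DNA, uniform_exchangeabilities(4),
                                  BranchComposition(bmap),
                                  GammaASRV(asrv_shape, 4))
    else:
        raise UsageError(f"unknown case study {kind!r}")

    aln, meta = simulate_alignment(tree, model, n_sites, seed=seed)
    manifest = dict(kind=kind, **meta["manifest"])
    return aln, tree, manifest
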