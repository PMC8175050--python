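"""Substitution models: exchangeabilities, compositions, rate matrices, ASRV.

A model couples a symmetric exchangeability matrix R with a composition
structure and optional discrete-gamma among-site rate variation.  Three
composition structures are supported:

* ``SingleComposition`` — one stationary vector pi (the classical
  homogeneous, stationary model);
* ``MixtureComposition`` — a fixed profile set with mixture weights
  (CXX/UDM-style across-site heterogeneity: sites are an unknown draw
  from K fixed compositions, only the weights are free);
* ``BranchComposition`` — a map assigning a composition vector to every
  branch and to the root (NDCH/NDCH2-style across-tree heterogeneity:
  compositions may change at speciation events, so the process is
  non-stationary and non-reversible as a whole).

The generator for composition pi is Q_ij = R_ij * pi_j (i != j), rows
summing to zero, scaled so that -sum_i pi_i Q_ii = 1: branch lengths
are expected substitutions per site at that composition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Optional, Union

import numpy as np
import scipy.linalg
from scipy.special import gammainc, gammaincinv

from .alphabets import AA, BIN, DNA, Alphabet, get_alphabet
from .errors import ModelError, UsageError

__all__ = [
    "ProfileSet",
    "BranchCompositionMap",
    "SingleComposition",
    "MixtureComposition",
    "BranchComposition",
    "GammaASRV",
    "SubstitutionModel",
    "build_rate_matrix",
    "transition_matrix",
    "discrete_gamma_rates",
    "SpectralGenerator",
    "jc69", "jc2", "poisson", "gtr", "tim2", "lg_exchangeabilities", "lg",
    "uniform_exchangeabilities",
]

COMPOSITION_FLOOR = 1e-6


def smooth_composition(pi) -> np.ndarray:
    """Project onto the simplex with every entry >= 1e-6."""
    pi = np.asarray(pi, dtype=float)
    if pi.ndim != 1 or np.any(pi < 0) or pi.sum() <= 0:
        raise ModelError("composition must be a non-negative vector with positive sum")
    pi = pi / pi.sum()
    low = pi < COMPOSITION_FLOOR
    if low.any():
        pi = pi.copy()
        pi[low] = COMPOSITION_FLOOR
        pi[~low] *= (1.0 - low.sum() * COMPOSITION_FLOOR) / pi[~low].sum()
    return pi


@dataclass
class ProfileSet:
    """K fixed composition vectors (rows on the simplex)."""

    profiles: np.ndarray
    names: Optional[list] = None

    def __post_init__(self):
        self.profiles = np.vstack([smooth_composition(p) for p in np.atleast_2d(self.profiles)])
        if self.names is not None and len(self.names) != self.K:
            raise ModelError("one name per profile required")

    @property
    def K(self) -> int:
        return self.profiles.shape[0]

    @property
    def n_states(self) -> int:
        return self.profiles.shape[1]

    @classmethod
    def from_file(cls, path) -> "ProfileSet":
        rows = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if line and not line.startswith("#"):
                    rows.append([float(x) for x in line.split()])
        return cls(np.array(rows))

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            for row in self.profiles:
                fh.write(" ".join(f"{x:.6f}" for x in row) + "\n")

    def subset(self, indices) -> "ProfileSet":
        names = [self.names[i] for i in indices] if self.names else None
        return ProfileSet(self.profiles[list(indices)], names)


@dataclass
class BranchCompositionMap:
    """Composition vectors arranged on the branches of a rooted tree.

    Edges are keyed by the sorted tuple of leaf names below the edge's
    child node, which is stable across tree copies.  ``mode`` records
    whether vectors are shared from a small pool (NDCH) or one-per-edge
    (NDCH2); the likelihood treats both identically.
    """

    pool: np.ndarray  # (m, c) composition vectors
    assignment: dict  # edge key -> pool row
    root_index: int
    mode: str = "NDCH"

    def __post_init__(self):
        self.pool = np.vstack([smooth_composition(p) for p in np.atleast_2d(self.pool)])
        m = self.pool.shape[0]
        if not 0 <= self.root_index < m:
            raise ModelError("root composition index out of range")
        for key, idx in self.assignment.items():
            if not 0 <= idx < m:
                raise ModelError(f"edge {key} assigned out-of-range vector {idx}")

    @property
    def root_composition(self) -> np.ndarray:
        return self.pool[self.root_index]

    def edge_composition(self, edge_key) -> np.ndarray:
        return self.pool[self.assignment[edge_key]]


def edge_key(node) -> tuple:
    """Stable identifier of the edge above a node."""
    return tuple(sorted(l.name for l in node.leaves()))


@dataclass
class SingleComposition:
    pi: np.ndarray

    def __post_init__(self):
        self.pi = smooth_composition(self.pi)


@dataclass
class MixtureComposition:
    profiles: ProfileSet
    weights: np.ndarray

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (self.profiles.K,) or np.any(w < 0):
            raise ModelError("weights must be non-negative, one per profile")
        if w.sum() <= 0:
            raise ModelError("weights must have positive sum")
        self.weights = w / w.sum()


@dataclass
class BranchComposition:
    map: BranchCompositionMap


CompositionMode = Union[SingleComposition, MixtureComposition, BranchComposition]


@dataclass
class GammaASRV:
    """Discrete-gamma rate variation: K equal-weight categories, each
    represented by its bin mean; mean rate exactly 1."""

    shape: float
    ncats: int = 4

    def __post_init__(self):
        if self.shape <= 0:
            raise ModelError("gamma shape must be positive")
        if self.ncats < 1:
            raise ModelError("need at least one rate category")

    def rates(self) -> np.ndarray:
        return discrete_gamma_rates(self.shape, self.ncats)


def discrete_gamma_rates(alpha: float, K: int) -> np.ndarray:
    """Mean-of-bin discretization of the mean-1 gamma distribution.

    The support is cut at the K-quantiles of Gamma(alpha, rate=alpha);
    each category's rate is the conditional mean within its bin, which
    has the closed form K * [I(alpha+1, g_{k+1}) - I(alpha+1, g_k)]
    with I the regularized incomplete gamma and g_k the standard-gamma
    quantiles.  Rates are renormalized to average exactly 1.
    """
    if alpha <= 0 or K < 1:
        raise UsageError("alpha must be > 0 and K >= 1")
    if K == 1:
        return np.ones(1)
    edges = np.concatenate([[0.0], gammaincinv(alpha, np.arange(1, K) / K), [np.inf]])
    upper = np.where(np.isinf(edges[1:]), 1.0, gammainc(alpha + 1, edges[1:]))
    lower = gammainc(alpha + 1, edges[:-1])
    rates = K * (upper - lower)
    return rates / rates.mean()


@dataclass
class SubstitutionModel:
    alphabet: Alphabet
    exchangeabilities: np.ndarray
    composition: CompositionMode
    asrv: Optional[GammaASRV] = None
    name: str = ""

    def __post_init__(self):
        self.alphabet = get_alphabet(self.alphabet)
        c = self.alphabet.size
        R = np.asarray(self.exchangeabilities, dtype=float)
        if R.shape != (c, c):
            raise ModelError(f"exchangeability matrix must be {c}x{c}")
        if not np.allclose(R, R.T):
            raise ModelError("exchangeability matrix must be symmetric")
        off = R[~np.eye(c, dtype=bool)]
        if np.any(off <= 0):
            raise ModelError("off-diagonal exchangeabilities must be positive")
        R = R.copy()
        np.fill_diagonal(R, 0.0)
        self.exchangeabilities = R
        self._check_composition(c)

    def _check_composition(self, c: int):
        comp = self.composition
        if isinstance(comp, SingleComposition):
            if comp.pi.shape != (c,):
                raise ModelError("composition dimension mismatch")
        elif isinstance(comp, MixtureComposition):
            if comp.profiles.n_states != c:
                raise ModelError("profile dimension mismatch")
        elif isinstance(comp, BranchComposition):
            if comp.map.pool.shape[1] != c:
                raise ModelError("branch composition dimension mismatch")
        else:
            raise ModelError(f"unknown composition mode {type(comp).__name__}")

    @property
    def n_states(self) -> int:
        return self.alphabet.size

    def n_rate_categories(self) -> int:
        return self.asrv.ncats if self.asrv else 1

    def rate_categories(self) -> np.ndarray:
        return self.asrv.rates() if self.asrv else np.ones(1)

    def with_(self, **kwargs) -> "SubstitutionModel":
        vals = dict(
            alphabet=self.alphabet,
            exchangeabilities=self.exchangeabilities,
            composition=self.composition,
            asrv=self.asrv,
            name=self.name,
        )
        vals.update(kwargs)
        return SubstitutionModel(**vals)


def build_rate_matrix(R, pi) -> np.ndarray:
    """Generator Q_ij = R_ij pi_j scaled to one expected substitution
    per unit branch length at composition pi."""
    R = np.asarray(R, dtype=float)
    pi = smooth_composition(pi)
    Q = R * pi[None, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mu = -(pi * np.diag(Q)).sum()
    if mu <= 0:
        raise ModelError("degenerate rate matrix (zero total rate)")
    return Q / mu


def transition_matrix(Q, t: float, rate: float = 1.0) -> np.ndarray:
    """P = exp(Q * rate * t); rows sum to 1."""
    if t < 0:
        raise UsageError("branch length must be non-negative")
    if rate <= 0:
        raise UsageError("rate must be positive")
    if t == 0:
        return np.eye(Q.shape[0])
    return scipy.linalg.expm(np.asarray(Q, dtype=float) * (rate * t))


class SpectralGenerator:
    """Eigendecomposition of a reversible generator for fast repeated
    transition-matrix evaluation.

    Reversibility (R symmetric) makes D^(1/2) Q D^(-1/2) symmetric, so
    the decomposition is real and numerically stable.
    """

    def __init__(self, R, pi):
        pi = smooth_composition(pi)
        Q = build_rate_matrix(R, pi)
        s = np.sqrt(pi)
        B = Q * s[:, None] / s[None, :]
        lam, V = np.linalg.eigh((B + B.T) / 2)
        self.pi = pi
        self.Q = Q
        self.lam = lam
        self.left = V / s[:, None]      # D^(-1/2) V
        self.right = V.T * s[None, :]   # V^T D^(1/2)

    def transition(self, t: float, rate: float = 1.0) -> np.ndarray:
        P = (self.left * np.exp(self.lam * rate * t)) @ self.right
        np.maximum(P, 0.0, out=P)
        return P / P.sum(axis=1, keepdims=True)

    def transition_derivative(self, t: float, rate: float = 1.0) -> np.ndarray:
        """dP/dt at branch length t (including the rate factor)."""
        return (self.left * (self.lam * rate * np.exp(self.lam * rate * t))) @ self.right


# ---------------------------------------------------------------------------
# presets

def uniform_exchangeabilities(c: int) -> np.ndarray:
    R = np.ones((c, c))
    np.fill_diagonal(R, 0.0)
    return R


def _dna_exchange(ac, ag, at, cg, ct, gt) -> np.ndarray:
    R = np.zeros((4, 4))
    pairs = {("A", "C"): ac, ("A", "G"): ag, ("A", "T"): at,
             ("C", "G"): cg, ("C", "T"): ct, ("G", "T"): gt}
    for (x, y), v in pairs.items():
        i, j = DNA.index(x), DNA.index(y)
        R[i, j] = R[j, i] = v
    return R


def jc69(asrv: Optional[GammaASRV] = None) -> SubstitutionModel:
    """Jukes-Cantor: uniform exchangeabilities and composition, DNA."""
    return SubstitutionModel(DNA, uniform_exchangeabilities(4),
                             SingleComposition(np.full(4, 0.25)), asrv, name="JC69")


def jc2(asrv: Optional[GammaASRV] = None) -> SubstitutionModel:
    """Two-state symmetric model for RY-recoded data."""
    return SubstitutionModel(BIN, uniform_exchangeabilities(2),
                             SingleComposition(np.full(2, 0.5)), asrv, name="JC2")


def poisson(composition=None, asrv: Optional[GammaASRV] = None) -> SubstitutionModel:
    """Uniform amino-acid exchangeabilities; composition defaults to uniform."""
    comp = composition if composition is not None else SingleComposition(np.full(20, 0.05))
    if isinstance(comp, np.ndarray):
        comp = SingleComposition(comp)
    return SubstitutionModel(AA, uniform_exchangeabilities(20), comp, asrv, name="Poisson")


def gtr(rates, pi, asrv: Optional[GammaASRV] = None) -> SubstitutionModel:
    """General time-reversible DNA model; rates = (AC, AG, AT, CG, CT, GT)."""
    return SubstitutionModel(DNA, _dna_exchange(*rates),
                             SingleComposition(np.asarray(pi, float)), asrv, name="GTR")


def tim2(a: float, b: float, e: float, pi, asrv: Optional[GammaASRV] = None) -> SubstitutionModel:
    """Transition-model variant: AC = AT and CG = GT constrained equal.

    Parameters: a = AC = AT, b = AG, e = CT (GT = CG = 1 reference rate).
    """
    return SubstitutionModel(DNA, _dna_exchange(a, b, a, 1.0, e, 1.0),
                             SingleComposition(np.asarray(pi, float)), asrv, name="TIM2")


def lg_exchangeabilities():
    """LG amino-acid exchangeabilities and frequencies from the packaged table."""
    text = resources.files("hetphylo.data").joinpath("lg.txt").read_text()
    rows = [[float(x) for x in line.split()]
            for line in text.splitlines() if line.strip() and not line.startswith("#")]
    R = np.zeros((20, 20))
    for i, row in enumerate(rows[:19], start=1):
        for j, v in enumerate(row):
            R[i, j] = R[j, i] = v
    freqs = np.array(rows[19])
    return R, freqs


def lg(composition=None, asrv: Optional[GammaASRV] = None) -> SubstitutionModel:
    """LG exchangeabilities; composition defaults to the LG frequencies.

    'LG' here means the fixed exchangeability table only — the
    composition slot stays a free model choice (pass a mixture for
    LG+CXX-style usage).
    """
    R, freqs = lg_exchangeabilities()
    comp = composition if composition is not None else SingleComposition(freqs)
    if isinstance(comp, np.ndarray):
        comp = SingleComposition(comp)
    return SubstitutionModel(AA, R, comp, asrv, name="LG")
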