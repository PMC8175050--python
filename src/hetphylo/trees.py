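"""Phylogenetic trees: newick I/O, clan queries, and tree-to-tree distances.

Trees are stored rooted (a ``Node`` hierarchy) but all topology
comparison is performed on the unrooted tree: a degree-2 root is
collapsed before splits are extracted.  Newick parsing is delegated to
dendropy; the in-memory structure is a minimal mutable node tree suited
to likelihood computation and topology moves.
"""

from __future__ import annotations

import itertools

import dendropy

from .errors import FormatError, UsageError

__all__ = [
    "Node",
    "Tree",
    "parse_newick",
    "write_newick",
    "is_clan",
    "robinson_foulds",
    "branch_score_distance",
    "all_splits",
    "nontrivial_splits",
    "nni_neighbors",
    "spr_reattachments",
    "enumerate_topologies",
]


class Node:
    __slots__ = ("name", "length", "support", "children", "parent")

    def __init__(self, name=None, length=None, support=None):
        self.name = name
        self.length = length
        self.support = support
        self.children = []
        self.parent = None

    def add(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def postorder(self):
        for c in self.children:
            yield from c.postorder()
        yield self

    def leaves(self):
        return [n for n in self.postorder() if n.is_leaf]

    def copy(self) -> "Node":
        n = Node(self.name, self.length, self.support)
        for c in self.children:
            n.add(c.copy())
        return n


class Tree:
    """A rooted view of a (possibly unrooted) phylogenetic tree."""

    def __init__(self, root: Node):
        self.root = root
        names = [l.name for l in root.leaves()]
        if len(set(names)) != len(names):
            raise FormatError("duplicate leaf labels in tree")

    # -- construction -----------------------------------------------------
    @classmethod
    def from_newick(cls, text: str) -> "Tree":
        return parse_newick(text)

    def copy(self) -> "Tree":
        return Tree(self.root.copy())

    # -- queries ----------------------------------------------------------
    def leaf_names(self):
        return [l.name for l in self.root.leaves()]

    def postorder(self):
        return self.root.postorder()

    def find(self, name: str) -> Node:
        for n in self.postorder():
            if n.name == name:
                return n
        raise KeyError(name)

    @property
    def n_leaves(self) -> int:
        return len(self.root.leaves())

    def is_binary_unrooted(self) -> bool:
        """Every internal vertex of the unrooted tree has degree 3."""
        t = self.copy()
        t.deroot()
        if len(t.root.children) != 3 and t.n_leaves > 3:
            return False
        for n in t.postorder():
            if n is t.root or n.is_leaf:
                continue
            if len(n.children) != 2:
                return False
        return True

    def total_length(self) -> float:
        return sum(n.length or 0.0 for n in self.postorder() if n is not self.root)

    def scale(self, k: float) -> "Tree":
        t = self.copy()
        for n in t.postorder():
            if n.length is not None:
                n.length *= k
        return t

    # -- unrooted view ----------------------------------------------------
    def deroot(self) -> "Tree":
        """Collapse a degree-2 root in place, yielding the unrooted view."""
        while len(self.root.children) == 2 and self.n_leaves > 2:
            a, b = self.root.children
            keep, move = (a, b) if not a.is_leaf else (b, a)
            if keep.is_leaf:
                break
            extra = (move.length or 0.0) + (keep.length or 0.0)
            self.root.children = list(keep.children)
            for c in self.root.children:
                c.parent = self.root
            self.root.name = keep.name
            move.length = extra
            self.root.add(move)
        return self

    def to_newick(self) -> str:
        return write_newick(self)

    def __repr__(self):
        return f"Tree({write_newick(self)!r})"


def parse_newick(text: str) -> Tree:
    try:
        dt = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises assorted parse errors
        raise FormatError(f"newick parse error: {exc}") from exc

    def convert(dn) -> Node:
        name = dn.taxon.label if dn.taxon is not None else dn.label
        support = None
        if dn.label is not None and not dn.is_leaf():
            try:
                support = float(dn.label)
            except ValueError:
                support = None
        node = Node(name=name, length=dn.edge.length, support=support)
        for dc in dn.child_nodes():
            node.add(convert(dc))
        return node

    return Tree(convert(dt.seed_node))


def _fmt_len(x) -> str:
    return "" if x is None else f":{x:.10g}"


def write_newick(t: Tree) -> str:
    def fmt(n: Node) -> str:
        if n.is_leaf:
            return f"{n.name}{_fmt_len(n.length)}"
        inner = ",".join(fmt(c) for c in n.children)
        label = ""
        if n.support is not None:
            label = f"{n.support:g}"
        elif n.name is not None:
            label = str(n.name)
        return f"({inner}){label}{_fmt_len(n.length)}"

    return fmt(t.root) + ";"


# ---------------------------------------------------------------------------
# splits

def _canon(side, all_leaves: frozenset) -> frozenset:
    """Canonical side of a bipartition: the side without the reference leaf."""
    ref = min(all_leaves)
    side = frozenset(side)
    return side if ref not in side else all_leaves - side


def all_splits(t: Tree, with_lengths: bool = False):
    """Bipartitions of the unrooted tree (including trivial leaf splits).

    With ``with_lengths`` returns a dict split -> branch length (merged
    across the collapsed root edge); otherwise a set of splits.
    """
    u = t.copy().deroot()
    leaves = frozenset(u.leaf_names())
    out = {}
    for n in u.postorder():
        if n is u.root:
            continue
        below = frozenset(l.name for l in n.leaves())
        key = _canon(below, leaves)
        out[key] = out.get(key, 0.0) + (n.length or 0.0)
    return out if with_lengths else set(out)


def nontrivial_splits(t: Tree):
    n = t.n_leaves
    return {s for s in all_splits(t) if 1 < len(s) < n - 1}


def is_clan(t: Tree, taxa) -> bool:
    """True iff one edge of the unrooted tree separates exactly ``taxa``.

    The full leaf set is a clan by convention (trivial split).
    """
    taxa = frozenset(taxa)
    leaves = frozenset(t.leaf_names())
    if not taxa <= leaves:
        raise UsageError(f"taxa not in tree: {sorted(taxa - leaves)}")
    if taxa == leaves:
        return True
    return _canon(taxa, leaves) in all_splits(t)


def _check_same_leaves(t1: Tree, t2: Tree):
    l1, l2 = set(t1.leaf_names()), set(t2.leaf_names())
    if l1 != l2:
        raise UsageError(
            f"leaf sets differ: only-in-first {sorted(l1 - l2)}, "
            f"only-in-second {sorted(l2 - l1)}"
        )


def robinson_foulds(t1: Tree, t2: Tree) -> int:
    """Number of non-trivial splits present in exactly one tree."""
    _check_same_leaves(t1, t2)
    return len(nontrivial_splits(t1) ^ nontrivial_splits(t2))


def branch_score_distance(t1: Tree, t2: Tree) -> float:
    """Kuhner-Felsenstein branch score: Euclidean distance between
    branch-length vectors indexed by the union of splits (all splits,
    including leaf splits); a split absent from a tree contributes 0."""
    _check_same_leaves(t1, t2)
    s1 = all_splits(t1, with_lengths=True)
    s2 = all_splits(t2, with_lengths=True)
    total = 0.0
    for key in set(s1) | set(s2):
        total += (s1.get(key, 0.0) - s2.get(key, 0.0)) ** 2
    return total ** 0.5


# ---------------------------------------------------------------------------
# topology moves and enumeration

def nni_neighbors(t: Tree):
    """All nearest-neighbor-interchange trees of the unrooted topology.

    Yields two neighbors per internal edge; branch lengths are carried
    over unchanged (the swapped subtrees keep their pendant lengths).
    """
    base = t.copy().deroot()
    nodes = list(base.postorder())
    index = {id(n): k for k, n in enumerate(nodes)}

    out = []
    for k, v in enumerate(nodes):
        if v.is_leaf or v.parent is None:
            continue
        u = v.parent
        others = [c for c in u.children if c is not v]
        if not others:
            continue
        s_idx = index[id(others[0])]
        for child_pos in (0, 1):
            nb = base.copy()
            nb_nodes = list(nb.postorder())
            v2, s2 = nb_nodes[k], nb_nodes[s_idx]
            a2 = v2.children[child_pos]
            u2 = v2.parent
            # swap a2 (child of v2) with s2 (child of u2)
            v2.children[child_pos] = s2
            s2.parent = v2
            u2.children[u2.children.index(s2)] = a2
            a2.parent = u2
            out.append(nb)
    return out


def spr_reattachments(t: Tree, subtree_leaves):
    """All subtree-prune-regraft placements of one subtree.

    The subtree identified by its leaf set is detached (the degree-2
    vertex left behind is smoothed away, lengths summed) and regrafted
    onto every other edge at its midpoint, keeping the subtree's
    pendant length.  Yields (target leaf set below the chosen edge,
    regrafted Tree).
    """
    subtree_leaves = frozenset(subtree_leaves)
    base = t.copy().deroot()

    # locate and detach the subtree
    sub = None
    for n in base.postorder():
        if n.parent is None:
            continue
        if frozenset(l.name for l in n.leaves()) == subtree_leaves:
            sub = n
            break
    if sub is None:
        raise UsageError(f"no edge subtends exactly {sorted(subtree_leaves)}")
    parent = sub.parent
    parent.children.remove(sub)
    # smooth the degree-2 vertex left behind
    if parent.parent is not None and len(parent.children) == 1:
        only = parent.children[0]
        gp = parent.parent
        only.length = (only.length or 0.0) + (parent.length or 0.0)
        gp.children[gp.children.index(parent)] = only
        only.parent = gp
    elif parent.parent is None and len(parent.children) == 2:
        Tree(parent).deroot()

    targets = [n for n in base.postorder() if n.parent is not None]
    keys = [frozenset(l.name for l in n.leaves()) for n in targets]
    base_text = write_newick(Tree(base.root))
    sub_text = write_newick(Tree(sub))
    for key in keys:
        nb = parse_newick(base_text)
        tgt = None
        for n in nb.postorder():
            if n.parent is not None and frozenset(
                    l.name for l in n.leaves()) == key:
                tgt = n
                break
        graft = parse_newick(sub_text).root
        graft.length = sub.length
        par = tgt.parent
        mid = Node()
        half = (tgt.length or 0.0) / 2
        mid.length, tgt.length = half, half
        par.children[par.children.index(tgt)] = mid
        mid.parent = par
        mid.children = [tgt, graft]
        tgt.parent = graft.parent = mid
        yield key, nb


def enumerate_topologies(leaf_names):
    """All unrooted binary topologies over the leaves, without lengths.

    The count is (2n-5)!! for n >= 3; only sensible for small n.
    """
    leaf_names = list(leaf_names)
    n = len(leaf_names)
    if n < 3:
        raise UsageError("need at least 3 leaves")

    def grow(tree_root: Node, remaining):
        if not remaining:
            yield Tree(tree_root.copy())
            return
        name, rest = remaining[0], remaining[1:]
        edges = [nd for nd in tree_root.postorder() if nd.parent is not None]
        for nd in edges:
            parent = nd.parent
            mid = Node()
            leaf = Node(name=name)
            pos = parent.children.index(nd)
            parent.children[pos] = mid
            mid.parent = parent
            mid.add(nd)
            mid.add(leaf)
            yield from grow(tree_root, rest)
            # undo
            parent.children[pos] = nd
            nd.parent = parent

    root = Node()
    for nm in leaf_names[:3]:
        root.add(Node(name=nm))
    yield from grow(root, leaf_names[3:])


def n_unrooted_topologies(n: int) -> int:
    """(2n-5)!! unrooted binary topologies on n labelled leaves."""
    out = 1
    for k in range(3, 2 * n - 4, 2):
        out *= k
    return out
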