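"""Phylogenetic tree data model and split algebra.

The package works with unrooted, possibly multifurcating trees on labelled
leaves.  Internally every tree is stored with an (arbitrary) root; unrooted
semantics are recovered through the bipartition (split) view, so two storage
orientations of the same unrooted tree compare equal.  Several algorithms
temporarily re-root trees at a designated leaf (the *outgroup* ``o``): in that
orientation every internal node corresponds to a *cluster*, a subset of
``L' = L \\ {o}``, which is the state space of the quartet dynamic program.

Newick reading is delegated to :mod:`dendropy`; numeric internal-node labels
are interpreted as branch support values in ``[0, 1]``.
"""

from __future__ import annotations

from typing import Iterable, Iterator, Optional, Sequence

import dendropy

__all__ = [
    "Node",
    "PhyloTree",
    "NewickParseError",
    "parse_newick",
    "read_newick_file",
    "write_newick",
    "write_newick_file",
    "restrict",
    "bipartitions",
    "clusters_of",
    "split_compatible",
    "is_compatible",
    "fn_fp",
    "rf_distance",
    "normalized_rf",
    "trees_isomorphic",
    "is_binary",
    "contract_by_support",
    "contract_edges",
    "tree_from_clusters",
    "mrca",
    "LcaIndex",
    "quartet_score",
]


class NewickParseError(ValueError):
    """Raised when a newick string cannot be parsed or validated."""


class Node:
    """A tree node; leaves carry a label, edges may carry a support value.

    ``support`` belongs to the edge between the node and its parent.
    """

    __slots__ = ("label", "children", "parent", "support")

    def __init__(self, label: Optional[str] = None, support: Optional[float] = None):
        self.label = label
        self.children: list["Node"] = []
        self.parent: Optional["Node"] = None
        self.support = support

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def remove_child(self, child: "Node") -> None:
        self.children.remove(child)
        child.parent = None

    def iter_preorder(self) -> Iterator["Node"]:
        stack = [self]
        while stack:
            nd = stack.pop()
            yield nd
            stack.extend(reversed(nd.children))

    def iter_postorder(self) -> Iterator["Node"]:
        # iterative to avoid recursion limits on caterpillar trees
        stack: list[tuple["Node", bool]] = [(self, False)]
        while stack:
            nd, expanded = stack.pop()
            if expanded:
                yield nd
            else:
                stack.append((nd, True))
                stack.extend((c, False) for c in reversed(nd.children))

    def iter_leaves(self) -> Iterator["Node"]:
        for nd in self.iter_preorder():
            if nd.is_leaf:
                yield nd

    def leaf_set(self) -> frozenset:
        return frozenset(nd.label for nd in self.iter_leaves())

    def copy(self) -> "Node":
        clone = Node(self.label, self.support)
        for c in self.children:
            clone.add_child(c.copy())
        return clone

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<Node {self.label or sorted(self.leaf_set())}>"


class PhyloTree:
    """A rooted storage of a (usually unrooted) phylogenetic tree."""

    def __init__(self, root: Node, rooted: bool = False):
        self.root = root
        self.rooted = rooted

    # -- construction -------------------------------------------------
    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        return parse_newick(text)

    def copy(self) -> "PhyloTree":
        return PhyloTree(self.root.copy(), self.rooted)

    # -- basic queries -------------------------------------------------
    def leaves(self) -> list[Node]:
        return list(self.root.iter_leaves())

    @property
    def leaf_labels(self) -> frozenset:
        return self.root.leaf_set()

    def __len__(self) -> int:
        return sum(1 for _ in self.root.iter_leaves())

    def iter_nodes(self, order: str = "pre") -> Iterator[Node]:
        if order == "pre":
            return self.root.iter_preorder()
        if order == "post":
            return self.root.iter_postorder()
        raise ValueError(f"unknown traversal order {order!r}")

    def find_leaf(self, label: str) -> Node:
        for nd in self.root.iter_leaves():
            if nd.label == label:
                return nd
        raise KeyError(f"leaf {label!r} not in tree")

    # -- manipulation --------------------------------------------------
    def suppress_unifurcations(self) -> None:
        """Remove all degree-2 internal nodes (and a unary chain at the root).

        A labelled root (the leaf-rooted presentation) is left alone.
        """
        _suppress_below(self.root)
        while len(self.root.children) == 1 and self.root.label is None:
            new_root = self.root.children[0]
            new_root.parent = None
            new_root.support = None
            self.root = new_root

    def validate(self) -> None:
        labels = [nd.label for nd in self.root.iter_leaves()]
        dupes = {x for x in labels if labels.count(x) > 1}
        if dupes:
            raise NewickParseError(f"duplicate leaf labels: {sorted(dupes)}")
        if any(lb in (None, "") for lb in labels):
            raise NewickParseError("empty leaf label")

    def root_at_leaf(self, label: str) -> "PhyloTree":
        """Return a copy re-rooted so the leaf ``label`` is the root.

        The returned tree's root is the leaf node itself with a single child;
        every other node's cluster is then a subset of ``L \\ {label}``.
        """
        # build an undirected adjacency and orient away from the leaf
        tree = self.copy()
        nodes = list(tree.root.iter_preorder())
        adj: dict[int, list[Node]] = {id(nd): [] for nd in nodes}
        for nd in nodes:
            for c in nd.children:
                adj[id(nd)].append(c)
                adj[id(c)].append(nd)
        start = None
        for nd in nodes:
            if nd.is_leaf and nd.label == label:
                start = nd
                break
        if start is None:
            raise KeyError(f"leaf {label!r} not in tree")
        for nd in nodes:
            nd.children = []
            nd.parent = None
        seen = {id(start)}
        queue = [start]
        while queue:
            nd = queue.pop()
            for nb in adj[id(nd)]:
                if id(nb) not in seen:
                    seen.add(id(nb))
                    nd.add_child(nb)
                    queue.append(nb)
        out = PhyloTree(start, rooted=True)
        # re-rooting can create degree-2 nodes (the old root)
        _suppress_below(start)
        return out

    def unroot_from_leaf(self) -> "PhyloTree":
        """Inverse presentation of :meth:`root_at_leaf` output: make the leaf
        an ordinary child so the tree prints as a conventional newick."""
        if not (self.root.label is not None and len(self.root.children) == 1):
            return self
        leaf = self.root
        body = leaf.children[0]
        leaf.children = []
        body.parent = None
        new_leaf = Node(leaf.label, leaf.support)
        if body.is_leaf:
            # two-leaf tree: keep both leaves under a fresh root
            top = Node()
            top.add_child(body)
            top.add_child(new_leaf)
            return PhyloTree(top, rooted=False)
        body.add_child(new_leaf)
        return PhyloTree(body, rooted=False)

    def canonicalize(self) -> None:
        """Sort children by smallest descendant label, for stable output."""
        keys: dict[int, str] = {}
        for nd in self.root.iter_postorder():
            if nd.is_leaf:
                keys[id(nd)] = nd.label
            else:
                nd.children.sort(key=lambda c: keys[id(c)])
                keys[id(nd)] = keys[id(nd.children[0])]

    # -- serialization -------------------------------------------------
    def to_newick(self, supports: bool = True) -> str:
        return write_newick(self, supports=supports)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<PhyloTree {self.to_newick()}>"


def _suppress_below(root: Node) -> None:
    """Suppress degree-2 nodes strictly below ``root`` (root may stay unary)."""
    for nd in list(root.iter_postorder()):
        if nd is root or nd.is_leaf:
            continue
        if len(nd.children) == 1:
            child = nd.children[0]
            parent = nd.parent
            idx = parent.children.index(nd)
            parent.children[idx] = child
            child.parent = parent
            if child.support is None:
                child.support = nd.support


# ---------------------------------------------------------------------------
# newick I/O
# ---------------------------------------------------------------------------

def parse_newick(text: str) -> PhyloTree:
    """Parse a newick string into a :class:`PhyloTree`.

    Accepted grammar: standard newick with optional branch lengths (ignored)
    and optional internal-node labels.  An internal label that parses as a
    float is stored as the support of the edge above that node; any other
    internal label is discarded.  Polytomies are preserved.
    """
    text = text.strip()
    if not text:
        raise NewickParseError("empty newick string")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise NewickParseError(f"malformed newick: {exc}") from None

    def convert(dnode) -> Node:
        if dnode.is_leaf():
            label = dnode.taxon.label if dnode.taxon is not None else dnode.label
            return Node(label)
        support = None
        if dnode.label is not None:
            try:
                support = float(dnode.label)
            except ValueError:
                support = None
        nd = Node(None, support)
        for c in dnode.child_nodes():
            nd.add_child(convert(c))
        return nd

    tree = PhyloTree(convert(dtree.seed_node), rooted=False)
    tree.suppress_unifurcations()
    tree.validate()
    return tree


def read_newick_file(path) -> list[PhyloTree]:
    """Read one tree per non-empty line."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                out.append(parse_newick(line))
    return out


def write_newick(tree: PhyloTree, supports: bool = True) -> str:
    def fmt(nd: Node) -> str:
        if nd.is_leaf:
            return nd.label
        inner = ",".join(fmt(c) for c in nd.children)
        sup = ""
        if supports and nd.support is not None and nd.parent is not None:
            sup = format(nd.support, "g")
        return f"({inner}){sup}"

    return fmt(tree.root) + ";"


def write_newick_file(path, trees: Iterable[PhyloTree]) -> None:
    with open(path, "w") as fh:
        for t in trees:
            fh.write(write_newick(t) + "\n")


# ---------------------------------------------------------------------------
# restriction and splits
# ---------------------------------------------------------------------------

def restrict(tree: PhyloTree, keep: Iterable[str]) -> PhyloTree:
    """Induced topology on ``keep`` (intersected with the tree's leaves)."""
    keep = frozenset(keep)
    kept = tree.leaf_labels & keep
    if not kept:
        raise ValueError("restriction would remove every leaf")

    def prune(nd: Node) -> Optional[Node]:
        if nd.is_leaf:
            return Node(nd.label, nd.support) if nd.label in kept else None
        new_children = [c2 for c in nd.children if (c2 := prune(c)) is not None]
        if not new_children:
            return None
        if len(new_children) == 1:
            # splice through; keep the surviving edge's support if any
            child = new_children[0]
            if child.support is None:
                child.support = nd.support
            return child
        new = Node(None, nd.support)
        for c in new_children:
            new.add_child(c)
        return new

    new_root = prune(tree.root)
    new_root.parent = None
    new_root.support = None
    out = PhyloTree(new_root, tree.rooted)
    out.suppress_unifurcations()
    return out


def bipartitions(tree: PhyloTree) -> frozenset:
    """All non-trivial splits, each a ``frozenset({sideA, sideB})``."""
    full = tree.leaf_labels
    n = len(full)
    out = set()
    if n < 4:
        return frozenset()
    leafsets: dict[int, frozenset] = {}
    for nd in tree.root.iter_postorder():
        if nd.is_leaf:
            leafsets[id(nd)] = frozenset([nd.label])
        else:
            leafsets[id(nd)] = frozenset().union(*(leafsets[id(c)] for c in nd.children))
    for nd in tree.root.iter_preorder():
        if nd is tree.root:
            continue
        side = leafsets[id(nd)]
        if 2 <= len(side) <= n - 2:
            out.add(frozenset({side, full - side}))
    return frozenset(out)


def clusters_of(tree: PhyloTree, outgroup: str) -> set:
    """Non-trivial clusters: for every split, the side not containing ``outgroup``."""
    out = set()
    for split in bipartitions(tree):
        a, b = tuple(split)
        out.add(b if outgroup in a else a)
    return out


def split_compatible(s1: frozenset, s2: frozenset) -> bool:
    """Two splits on the same leaf set are compatible iff some pair of sides
    is disjoint."""
    a1, b1 = tuple(s1)
    a2, b2 = tuple(s2)
    return (not (a1 & a2)) or (not (a1 & b2)) or (not (b1 & a2)) or (not (b1 & b2))


def is_compatible(cluster: frozenset, tree: PhyloTree) -> bool:
    """Is the bipartition ``cluster | L-minus-cluster`` compatible with ``tree``?

    The split is restricted to the tree's leaves; if either restricted side has
    fewer than two leaves the split is trivially compatible.  Otherwise it must
    be pairwise compatible with every split of the tree — sufficient because a
    tree's split system is pairwise compatible, so one further pairwise-
    compatible split always embeds jointly.
    """
    tl = tree.leaf_labels
    a = frozenset(cluster) & tl
    b = tl - a
    if len(a) < 2 or len(b) < 2:
        return True
    s = frozenset({a, b})
    return all(split_compatible(s, other) for other in bipartitions(tree))


def resolves(tree: PhyloTree, other: PhyloTree) -> bool:
    """True iff ``tree`` (restricted to ``other``'s leaves) displays every
    split of ``other`` — i.e. is a resolution of it."""
    r = restrict(tree, other.leaf_labels)
    return bipartitions(other) <= bipartitions(r)


# ---------------------------------------------------------------------------
# RF / FN / FP
# ---------------------------------------------------------------------------

def fn_fp(estimated: PhyloTree, reference: PhyloTree) -> tuple[int, int]:
    """False negatives and false positives of ``estimated`` w.r.t. ``reference``.

    Both trees are first restricted to their shared leaves.  FN counts
    reference splits absent from the estimate; FP counts estimate splits
    absent from the reference.
    """
    shared = estimated.leaf_labels & reference.leaf_labels
    if len(shared) < 4:
        raise ValueError("need at least 4 shared leaves to compare trees")
    be = bipartitions(restrict(estimated, shared))
    br = bipartitions(restrict(reference, shared))
    return len(br - be), len(be - br)


def rf_distance(a: PhyloTree, b: PhyloTree) -> int:
    fn, fp = fn_fp(a, b)
    return fn + fp


def normalized_rf(a: PhyloTree, b: PhyloTree) -> float:
    """RF divided by the total number of internal branches in both trees."""
    shared = a.leaf_labels & b.leaf_labels
    if len(shared) < 4:
        raise ValueError("need at least 4 shared leaves to compare trees")
    ba = bipartitions(restrict(a, shared))
    bb = bipartitions(restrict(b, shared))
    denom = len(ba) + len(bb)
    if denom == 0:
        return 0.0
    return len(ba ^ bb) / denom


def trees_isomorphic(a: PhyloTree, b: PhyloTree) -> bool:
    """Unrooted topological equality: same leaves and same split set."""
    if a.leaf_labels != b.leaf_labels:
        return False
    return bipartitions(a) == bipartitions(b)


def is_binary(tree: PhyloTree) -> bool:
    """Fully resolved in the unrooted sense: n - 3 internal splits."""
    n = len(tree.leaf_labels)
    if n < 4:
        return True
    return len(bipartitions(tree)) == n - 3


# ---------------------------------------------------------------------------
# contractions
# ---------------------------------------------------------------------------

def contract_edges(tree: PhyloTree, splits: Iterable[frozenset]) -> PhyloTree:
    """Return a copy with the internal edges realizing ``splits`` contracted."""
    target = set(splits)
    out = tree.copy()
    full = out.leaf_labels
    n = len(full)
    changed = True
    while changed:
        changed = False
        leafsets: dict[int, frozenset] = {}
        for nd in out.root.iter_postorder():
            if nd.is_leaf:
                leafsets[id(nd)] = frozenset([nd.label])
            else:
                leafsets[id(nd)] = frozenset().union(*(leafsets[id(c)] for c in nd.children))
        for nd in list(out.root.iter_preorder()):
            if nd is out.root or nd.is_leaf:
                continue
            side = leafsets[id(nd)]
            if 2 <= len(side) <= n - 2 and frozenset({side, full - side}) in target:
                parent = nd.parent
                idx = parent.children.index(nd)
                parent.children[idx:idx + 1] = nd.children
                for c in nd.children:
                    c.parent = parent
                changed = True
                break
    out.suppress_unifurcations()
    return out


def contract_by_support(tree: PhyloTree, threshold: float) -> PhyloTree:
    """Contract every internal edge whose support is <= ``threshold``.

    Every internal edge must carry a support value; otherwise the collapse
    semantics would be undefined and an error is raised.
    """
    out = tree.copy()
    internal = [nd for nd in out.root.iter_preorder()
                if nd is not out.root and not nd.is_leaf]
    if any(nd.support is None for nd in internal):
        raise ValueError("tree has internal edges without support values")
    for nd in internal:
        if nd.support <= threshold:
            parent = nd.parent
            idx = parent.children.index(nd)
            parent.children[idx:idx + 1] = nd.children
            for c in nd.children:
                c.parent = parent
    out.suppress_unifurcations()
    return out


# ---------------------------------------------------------------------------
# building trees from cluster families
# ---------------------------------------------------------------------------

def tree_from_clusters(clusters: Iterable[frozenset], leafset: Iterable[str],
                       outgroup: str) -> PhyloTree:
    """Assemble the unrooted tree displaying a laminar family of clusters.

    ``clusters`` are subsets of ``L \\ {outgroup}``; pairwise they must be
    nested or disjoint.  The result shows exactly these clusters as the sides
    of its splits not containing the outgroup.
    """
    leafset = frozenset(leafset)
    lprime = leafset - {outgroup}
    fam = {frozenset(c) for c in clusters if 1 < len(c) < len(lprime)}
    fam.add(lprime)
    ordered = sorted(fam, key=lambda c: (-len(c), sorted(c)))
    nodes: dict[frozenset, Node] = {}
    for c in ordered:
        nodes[c] = Node()
    # parent = smallest strictly-containing cluster
    children_map: dict[frozenset, list[frozenset]] = {c: [] for c in ordered}
    for i, c in enumerate(ordered):
        best = None
        for d in ordered[:i]:
            if c < d and (best is None or len(d) < len(best)):
                best = d
        if best is not None:
            if c & best != c:
                raise ValueError("cluster family is not laminar")
            children_map[best].append(c)
    for c in ordered:
        for d in sorted(children_map[c], key=sorted):
            nodes[c].add_child(nodes[d])
    # attach leaves to the smallest cluster containing them
    for leaf in sorted(lprime):
        best = None
        for c in ordered:
            if leaf in c and (best is None or len(c) < len(best)):
                best = c
        nodes[best].add_child(Node(leaf))
    root = nodes[lprime]
    root.add_child(Node(outgroup))
    tree = PhyloTree(root, rooted=False)
    tree.suppress_unifurcations()
    tree.canonicalize()
    return tree


# ---------------------------------------------------------------------------
# LCA
# ---------------------------------------------------------------------------

def mrca(tree_rooted: PhyloTree, labels: Iterable[str]) -> Node:
    """Most recent common ancestor of a set of leaf labels, by parent walks.

    Works on any rooted storage, including mid-surgery trees; linear time per
    query, which is all the desk-scale algorithms need.
    """
    labels = list(labels)
    if not labels:
        raise ValueError("mrca of empty set")
    leaf_map = {nd.label: nd for nd in tree_rooted.root.iter_leaves()}
    try:
        current = leaf_map[labels[0]]
    except KeyError:
        raise KeyError(f"leaf {labels[0]!r} not in tree") from None
    chain = []
    nd = current
    while nd is not None:
        chain.append(nd)
        nd = nd.parent
    chain_index = {id(nd): i for i, nd in enumerate(chain)}
    deepest = 0
    for lb in labels[1:]:
        try:
            nd = leaf_map[lb]
        except KeyError:
            raise KeyError(f"leaf {lb!r} not in tree") from None
        while id(nd) not in chain_index:
            nd = nd.parent
        deepest = max(deepest, chain_index[id(nd)])
    return chain[deepest]


class LcaIndex:
    """Constant-time LCA queries after linear-ish preprocessing.

    Euler tour + sparse table (range-minimum over tour depths).  Any correct
    index satisfying the contract would do; this one is simple and exact.
    The index is a snapshot: it must be rebuilt if the tree is modified.
    """

    def __init__(self, tree: PhyloTree):
        self.tree = tree
        tour: list[Node] = []
        depth: list[int] = []
        first: dict[int, int] = {}
        def walk(nd: Node, d: int) -> None:
            first.setdefault(id(nd), len(tour))
            tour.append(nd)
            depth.append(d)
            for c in nd.children:
                walk(c, d + 1)
                tour.append(nd)
                depth.append(d)
        import sys
        old = sys.getrecursionlimit()
        sys.setrecursionlimit(max(old, 4 * sum(1 for _ in tree.root.iter_preorder()) + 100))
        try:
            walk(tree.root, 0)
        finally:
            sys.setrecursionlimit(old)
        self._tour = tour
        self._depth = depth
        self._first = first
        self._nodes = {id(nd) for nd in tree.root.iter_preorder()}
        self._leaf_map = {nd.label: nd for nd in tree.root.iter_leaves()}
        # sparse table of argmin indices
        m = len(depth)
        table = [list(range(m))]
        j = 1
        while (1 << j) <= m:
            prev = table[-1]
            cur = []
            half = 1 << (j - 1)
            for i in range(m - (1 << j) + 1):
                a, b = prev[i], prev[i + half]
                cur.append(a if depth[a] <= depth[b] else b)
            table.append(cur)
            j += 1
        self._table = table

    def _rmq(self, lo: int, hi: int) -> int:
        # inclusive range argmin over depth
        span = hi - lo + 1
        k = span.bit_length() - 1
        a = self._table[k][lo]
        b = self._table[k][hi - (1 << k) + 1]
        return a if self._depth[a] <= self._depth[b] else b

    def _resolve(self, item) -> Node:
        if isinstance(item, Node):
            if id(item) not in self._nodes:
                raise KeyError("node not in indexed tree")
            return item
        try:
            return self._leaf_map[item]
        except KeyError:
            raise KeyError(f"leaf {item!r} not in indexed tree") from None

    def lca(self, *items) -> Node:
        if not items:
            raise ValueError("lca of empty set")
        nodes = [self._resolve(x) for x in items]
        result = nodes[0]
        for nd in nodes[1:]:
            i, j = self._first[id(result)], self._first[id(nd)]
            if i > j:
                i, j = j, i
            result = self._tour[self._rmq(i, j)]
        return result


def build_lca_index(tree: PhyloTree) -> LcaIndex:
    return LcaIndex(tree)


# ---------------------------------------------------------------------------
# quartet score (exact enumeration)
# ---------------------------------------------------------------------------

def quartet_score(tree: PhyloTree, genetrees: Sequence[PhyloTree]) -> int:
    """Number of induced 4-leaf topologies shared with the gene trees.

    Exact enumeration of every 4-subset shared between the candidate tree and
    each gene tree; quartets a gene tree leaves unresolved contribute nothing.
    Intended for desk-scale n (the dynamic program uses the same tables).
    """
    from .quartets import quartet_topologies

    qt = quartet_topologies(tree)
    score = 0
    for gt in genetrees:
        for key, topo in quartet_topologies(gt).items():
            if qt.get(key) == topo:
                score += 1
    return score
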