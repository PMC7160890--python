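"""RF-minimizing tree completion with multifurcating inputs and outputs.

Given a *backbone* tree ``T_b`` and a *reference* tree ``T_r`` sharing at
least one leaf, completion grafts the leaves of ``T_r`` missing from ``T_b``
onto ``T_b`` so that the result stays compatible with ``T_b`` (its
restriction to the backbone's leaves resolves the backbone) while the
Robinson-Foulds distance to ``T_r`` is minimized.

Three layers are provided:

* :func:`brf_plus` — the classic linear-time-style algorithm for binary
  backbone and binary complete reference, producing a binary completion that
  is RF-optimal among *binary* completions.  Each fully-missing subtree of the
  reference is grafted, in pre-order, as sister to the LCA (in the backbone)
  of the leaves of its sister nodes.
* :func:`brf_star` — the multifurcating-output variant.  At each grafting
  site it distinguishes two cases: if the sister leaves of the missing
  subtree exactly match the leaves below the anchor node, a new node above
  the anchor reproduces a reference branch (Case 1); otherwise a new node
  would create a spurious branch, so the subtree is attached as an extra
  child of the anchor, forming a polytomy (Case 2).  The output is a
  contraction of the :func:`brf_plus` output and attains the minimum RF
  distance among *all* trees (binary or not) compatible with the backbone.
* :func:`comp` — the general completion used to build constrained search
  spaces: it first resolves backbone polytomies with reference bipartitions
  that are compatible with the backbone (:func:`expand_backbone`), then runs
  the multifurcating-output grafting, inserting several fully-missing
  children of a reference polytomy as one group at the same position.
"""

from __future__ import annotations

from dataclasses import dataclass
from .tree import Node, PhyloTree, is_binary, mrca

__all__ = ["CompletionTask", "brf_plus", "brf_star", "expand_backbone", "comp"]


@dataclass
class CompletionTask:
    """A backbone/reference pair, rooted on demand at a shared leaf."""

    backbone: PhyloTree
    reference: PhyloTree

    @property
    def shared_leaves(self) -> frozenset:
        return self.backbone.leaf_labels & self.reference.leaf_labels

    @property
    def missing_leaves(self) -> frozenset:
        return self.reference.leaf_labels - self.backbone.leaf_labels

    def root_label(self) -> str:
        shared = self.shared_leaves
        if not shared:
            raise ValueError("backbone and reference share no leaf to root on")
        return min(shared)


# ---------------------------------------------------------------------------
# grafting core
# ---------------------------------------------------------------------------

def _graft(tb: PhyloTree, tr: PhyloTree, allow_polytomy: bool) -> None:
    """Insert every fully-missing subtree of ``tr`` into ``tb`` (in place).

    Both trees must be in the leaf-rooted presentation with the same root
    leaf.  ``tb`` is mutated; ``tr`` is only read.
    """
    present = set(tb.leaf_labels)
    tr_leafsets: dict[int, frozenset] = {}
    for nd in tr.root.iter_postorder():
        if nd.is_leaf:
            tr_leafsets[id(nd)] = frozenset([nd.label])
        else:
            tr_leafsets[id(nd)] = frozenset().union(
                *(tr_leafsets[id(c)] for c in nd.children))

    def insert_group(group: list[Node], sister_leaves: frozenset) -> None:
        subtrees = [g.copy() for g in group]
        if not sister_leaves:
            # degenerate: fewer than two shared leaves on this side; graft at
            # the root edge so the reference's own splits are preserved
            if not tb.root.children:
                for st in subtrees:
                    tb.root.add_child(st)
                return
            anchor = tb.root.children[0]
            new = Node()
            tb.root.children[tb.root.children.index(anchor)] = new
            new.parent = tb.root
            new.add_child(anchor)
            for st in subtrees:
                new.add_child(st)
            return
        anchor = mrca(tb, sister_leaves)
        anchor_leaves = anchor.leaf_set()
        case1 = anchor_leaves == sister_leaves
        if case1 or not allow_polytomy:
            parent = anchor.parent
            new = Node()
            parent.children[parent.children.index(anchor)] = new
            new.parent = parent
            new.add_child(anchor)
            for st in subtrees:
                new.add_child(st)
        else:
            for st in subtrees:
                anchor.add_child(st)

    def process(p: Node) -> None:
        group = [c for c in p.children if not (tr_leafsets[id(c)] & present)]
        if group:
            sisters: frozenset = frozenset()
            for c in p.children:
                if c not in group:
                    sisters |= tr_leafsets[id(c)]
            insert_group(group, sisters & frozenset(present))
            for c in group:
                present.update(tr_leafsets[id(c)])
        for c in p.children:
            if c not in group and not c.is_leaf:
                process(c)

    process(tr.root)


def _rooted_pair(task: CompletionTask) -> tuple[PhyloTree, PhyloTree]:
    o = task.root_label()
    tb = task.backbone.root_at_leaf(o)
    tr = task.reference.root_at_leaf(o)
    tb.canonicalize()
    tr.canonicalize()
    return tb, tr


def _finish(tb: PhyloTree) -> PhyloTree:
    out = tb.unroot_from_leaf()
    out.suppress_unifurcations()
    out.canonicalize()
    return out


def brf_plus(task: CompletionTask) -> PhyloTree:
    """Binary RF-optimal completion (binary backbone, binary complete reference)."""
    if not is_binary(task.backbone):
        raise ValueError("backbone must be binary for the binary completion")
    if not is_binary(task.reference):
        raise ValueError("reference must be binary for the binary completion")
    if not task.backbone.leaf_labels <= task.reference.leaf_labels:
        raise ValueError("reference must contain every backbone leaf")
    tb, tr = _rooted_pair(task)
    _graft(tb, tr, allow_polytomy=False)
    return _finish(tb)


def brf_star(task: CompletionTask) -> PhyloTree:
    """Multifurcating-output completion, RF-optimal among all trees
    compatible with the backbone (for binary backbone and reference)."""
    if not is_binary(task.reference):
        raise ValueError("reference must be binary here; use comp() otherwise")
    if not task.backbone.leaf_labels <= task.reference.leaf_labels:
        raise ValueError("reference must contain every backbone leaf")
    tb, tr = _rooted_pair(task)
    if not is_binary(task.backbone):
        _expand_rooted(tb, tr)
    _graft(tb, tr, allow_polytomy=True)
    return _finish(tb)


# ---------------------------------------------------------------------------
# backbone expansion
# ---------------------------------------------------------------------------

def _expand_rooted(tb: PhyloTree, tr: PhyloTree) -> None:
    """Resolve polytomies of ``tb`` with ``tr`` bipartitions compatible with
    ``tb`` (both trees leaf-rooted at the same leaf; ``tb`` mutated).

    Post-order over the reference: for every internal reference node whose
    shared leaves map to a polytomy of the backbone, the backbone children
    hit by those leaves are grouped under a new node — provided they carry no
    shared leaf outside the group (which would make the bipartition
    incompatible) and the grouping is a proper refinement.
    """
    shared = tb.leaf_labels & tr.leaf_labels
    for u in list(tr.root.iter_postorder()):
        if u.is_leaf or u is tr.root:
            continue
        s = u.leaf_set() & shared
        if len(s) < 2:
            continue
        v = mrca(tb, s)
        if v.is_leaf:
            continue
        hit = [c for c in v.children if c.leaf_set() & s]
        if len(hit) < 2 or len(hit) == len(v.children):
            continue
        if any((c.leaf_set() & shared) - s for c in hit):
            continue  # incompatible with this polytomy
        new = Node()
        for c in hit:
            v.children.remove(c)
            new.add_child(c)
        v.add_child(new)


def expand_backbone(backbone: PhyloTree, reference: PhyloTree) -> PhyloTree:
    """Add to the backbone every reference bipartition compatible with it.

    The output is a resolution of the backbone; a binary backbone is returned
    unchanged.
    """
    if is_binary(backbone):
        return backbone.copy()
    shared = backbone.leaf_labels & reference.leaf_labels
    if len(shared) < 3:
        return backbone.copy()
    o = min(shared)
    tb = backbone.root_at_leaf(o)
    tr = reference.root_at_leaf(o)
    tb.canonicalize()
    tr.canonicalize()
    _expand_rooted(tb, tr)
    return _finish(tb)


# ---------------------------------------------------------------------------
# the general completion
# ---------------------------------------------------------------------------

def comp(backbone: PhyloTree, reference: PhyloTree) -> PhyloTree:
    """Complete and resolve ``backbone`` using ``reference``.

    Both trees may be multifurcating and each may have leaves the other
    lacks.  The output contains every leaf of either input; restricted to the
    backbone's leaves it is a resolution of the backbone (hence compatible
    with it).  Fully-missing subtrees hanging off one reference polytomy are
    inserted as a group at a single position.
    """
    task = CompletionTask(backbone, reference)
    o = task.root_label()  # raises if no shared leaf
    tb = backbone.root_at_leaf(o)
    tr = reference.root_at_leaf(o)
    tb.canonicalize()
    tr.canonicalize()
    _expand_rooted(tb, tr)
    _graft(tb, tr, allow_polytomy=True)
    return _finish(tb)
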