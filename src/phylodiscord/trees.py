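"""Lightweight phylogenetic tree structure and Newick I/O.

A :class:`Node` tree is the in-memory form used by the parsimony,
likelihood and coalescent machinery; dendropy handles Newick parsing
(including BEAST-style bracketed per-branch metadata) and consensus
construction, and trees convert to/from dendropy at the boundary.

Unrooted semantics: algorithms that are rooting-invariant (Fitch length,
pruning likelihood under reversible models) simply operate on the rooted
representation; topologies are compared by their canonical split sets.
"""

from __future__ import annotations

from typing import Iterator

import dendropy

__all__ = [
    "Node",
    "parse_newick",
    "write_newick",
    "leaf_labels",
    "splits",
    "topology_key",
    "reroot_at_leaf",
    "strict_consensus",
    "enumerate_unrooted_topologies",
    "n_unrooted_topologies",
]


class Node:
    """Tree node: ``children`` (list), ``parent``, ``label``, ``length``.

    ``length`` is the branch length to the parent (None if absent).
    ``height`` and ``theta`` are used by species trees (node age in
    substitutions/site; per-branch population-size parameter).
    """

    __slots__ = ("children", "parent", "label", "length", "height", "theta")

    def __init__(self, label: str | None = None, length: float | None = None):
        self.children: list["Node"] = []
        self.parent: "Node" | None = None
        self.label = label
        self.length = length
        self.height: float | None = None
        self.theta: float | None = None

    # -- structure ---------------------------------------------------------

    def add(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["Node"]:
        return [n for n in self.postorder() if n.is_leaf]

    def postorder(self) -> Iterator["Node"]:
        stack, out = [self], []
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))

    def preorder(self) -> Iterator["Node"]:
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def copy(self) -> "Node":
        new = Node(self.label, self.length)
        new.height, new.theta = self.height, self.theta
        for ch in self.children:
            new.add(ch.copy())
        return new

    def find(self, label: str) -> "Node":
        for n in self.postorder():
            if n.label == label:
                return n
        raise KeyError(label)

    def __repr__(self) -> str:
        return f"<Node {write_newick(self)}>"


def leaf_labels(tree: Node) -> list[str]:
    return [n.label for n in tree.leaves()]


# -- Newick ----------------------------------------------------------------


def _from_dendropy(dnode) -> Node:
    label = None
    if dnode.taxon is not None:
        label = dnode.taxon.label
    elif dnode.label:
        label = dnode.label
    node = Node(label, dnode.edge.length)
    ann = {a.name: a.value for a in dnode.annotations}
    for a in dnode.edge.annotations:
        ann.setdefault(a.name, a.value)
    if "theta" in ann:
        node.theta = float(ann["theta"])
    elif "dmv" in ann:
        v = ann["dmv"]
        if isinstance(v, (list, tuple)):
            v = v[0]
        node.theta = float(v)
    if "height" in ann:
        node.height = float(ann["height"])
    for ch in dnode.child_nodes():
        node.add(_from_dendropy(ch))
    return node


def parse_newick(text: str) -> Node:
    """Parse a Newick string, keeping bracketed ``[&...]`` metadata.

    Recognized annotations: ``theta`` or ``dmv`` (population size, stored
    on :attr:`Node.theta`) and ``height``.
    """
    dt = dendropy.Tree.get(
        data=text,
        schema="newick",
        extract_comment_metadata=True,
        suppress_internal_node_taxa=True,
        preserve_underscores=True,
    )
    root = _from_dendropy(dt.seed_node)
    if root.is_leaf and root.theta is None:
        # single-node tree: dendropy hoists the comment to the tree level
        for a in dt.annotations:
            if a.name in ("theta", "dmv"):
                v = a.value
                if isinstance(v, (list, tuple)):
                    v = v[0]
                root.theta = float(v)
    return root


def parse_newick_list(path_or_text: str, from_file: bool = False) -> list[Node]:
    """Parse one tree per line (Newick list) or a NEXUS TREES block."""
    text = open(path_or_text).read() if from_file else path_or_text
    if text.lstrip().lower().startswith("#nexus"):
        tl = dendropy.TreeList.get(
            data=text, schema="nexus", extract_comment_metadata=True,
            preserve_underscores=True,
        )
        return [_from_dendropy(t.seed_node) for t in tl]
    return [
        parse_newick(line) for line in text.splitlines() if line.strip()
    ]


def write_newick(
    tree: Node, lengths: bool = True, metadata: bool = False, digits: int = 10
) -> str:
    """Serialize to Newick (no trailing semicolon added by callers' choice).

    With ``metadata=True``, per-node ``theta`` annotations are written as
    ``[&theta=...]`` comments after the label, the convention used for
    species trees with population sizes.
    """

    def fmt(node: Node) -> str:
        if node.is_leaf:
            s = node.label or ""
        else:
            s = "(" + ",".join(fmt(ch) for ch in node.children) + ")"
            if node.label:
                s += node.label
        if metadata and node.theta is not None:
            s += f"[&theta={node.theta:.{digits}g}]"
        if lengths and node.length is not None:
            s += f":{node.length:.{digits}g}"
        return s

    return fmt(tree) + ";"


# -- splits and topology identity -----------------------------------------


def splits(tree: Node, trivial: bool = False) -> frozenset[frozenset[str]]:
    """Unrooted bipartitions as canonical frozensets of leaf labels.

    Each split is represented by the side *not* containing the reference
    (lexicographically smallest) leaf label, so rooting does not matter.
    With ``trivial=False`` only internal (non-leaf, non-full) splits are
    returned.
    """
    all_labels = frozenset(leaf_labels(tree))
    ref = min(all_labels)
    out: set[frozenset[str]] = set()
    below: dict[int, frozenset[str]] = {}
    for node in tree.postorder():
        if node.is_leaf:
            below[id(node)] = frozenset([node.label])
        else:
            below[id(node)] = frozenset().union(
                *(below[id(ch)] for ch in node.children)
            )
        side = below[id(node)]
        if ref in side:
            side = all_labels - side
        lo, hi = (2, len(all_labels) - 2) if not trivial else (1, len(all_labels) - 1)
        if lo <= len(side) <= hi:
            out.add(side)
    return frozenset(out)


def topology_key(tree: Node) -> frozenset[frozenset[str]]:
    """Canonical identity of the unrooted topology (its internal splits)."""
    return splits(tree)


def reroot_at_leaf(tree: Node, label: str) -> Node:
    """Return a copy rerooted so that ``label`` hangs off the new root.

    Branch lengths are preserved along the inverted path; the old root, if
    left with a single child, is contracted (its two incident branch
    lengths summed).  Useful for checking rooting invariance.
    """
    tree = tree.copy()
    leaf = tree.find(label)
    if leaf.parent is None:
        return tree
    pivot = leaf.parent
    pivot.children.remove(leaf)
    leaf.parent = None
    # invert parent links from the pivot up to the old root
    prev, prev_len = pivot, pivot.length
    parent = pivot.parent
    pivot.parent = None
    while parent is not None:
        grand, parent_len = parent.parent, parent.length
        parent.children.remove(prev)
        prev.add(parent)
        parent.length = prev_len
        prev, prev_len = parent, parent_len
        parent = grand
    rest = _contract_unary(pivot)
    new_root = Node()
    new_root.add(leaf)
    new_root.add(rest)
    if rest is pivot:
        # root sits exactly at the old pivot: zero-length stub on that side
        rest.length = 0.0 if leaf.length is not None else None
    return new_root


def _contract_unary(root: Node) -> Node:
    """Remove unary internal nodes, summing branch lengths."""
    for node in list(root.postorder()):
        if not node.is_leaf and len(node.children) == 1 and node.parent is not None:
            child = node.children[0]
            if node.length is not None or child.length is not None:
                child.length = (node.length or 0.0) + (child.length or 0.0)
            parent = node.parent
            idx = parent.children.index(node)
            parent.children[idx] = child
            child.parent = parent
    while not root.is_leaf and len(root.children) == 1:
        root = root.children[0]
        root.parent = None
    return root


def strict_consensus(trees: list[Node]) -> Node:
    """Strict consensus of unrooted topologies (via dendropy)."""
    tns = dendropy.TaxonNamespace()
    tl = dendropy.TreeList(
        [
            dendropy.Tree.get(
                data=write_newick(t, lengths=False),
                schema="newick",
                taxon_namespace=tns,
                preserve_underscores=True,
            )
            for t in trees
        ],
        taxon_namespace=tns,
    )
    cons = tl.consensus(min_freq=1.0)
    return _from_dendropy(cons.seed_node)


# -- enumeration -----------------------------------------------------------


def n_unrooted_topologies(n: int) -> int:
    """(2n-5)!! unrooted binary topologies for n >= 3 leaves."""
    out = 1
    for k in range(3, n + 1):
        out *= 2 * k - 5
    return out


def enumerate_unrooted_topologies(labels: list[str]) -> Iterator[Node]:
    """Yield every unrooted binary topology over the labels.

    Trees are represented rooted at a trivaluate basal node (the standard
    unrooted representation).  Counts follow (2n-5)!!.
    """
    labels = list(labels)
    if len(labels) < 3:
        raise ValueError("need >= 3 labels")

    def edges_of(tree: Node) -> list[Node]:
        return [n for n in tree.postorder() if n.parent is not None]

    def attach_all(tree: Node, label: str) -> Iterator[Node]:
        for i, _ in enumerate(edges_of(tree)):
            t2 = tree.copy()
            edge_node = edges_of(t2)[i]
            parent = edge_node.parent
            idx = parent.children.index(edge_node)
            mid = Node()
            mid.add(edge_node)
            mid.add(Node(label))
            mid.parent = parent
            parent.children[idx] = mid
            yield t2

    base = Node()
    for lab in labels[:3]:
        base.add(Node(lab))
    trees = [base]
    for lab in labels[3:]:
        trees = [t2 for t in trees for t2 in attach_all(t, lab)]
    return iter(trees)
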