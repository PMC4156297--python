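"""Fitch parsimony: site classification, tree length, CI/RI, heuristic MP
search, bootstrap support, and the ILD partition-homogeneity test.

Leaf states are IUPAC base sets; gap and ``?`` are treated as full
uncertainty {A,C,G,T} ("gaps treated as missing data").  Trees are the
:mod:`phylodiscord.trees` structures; tree length is rooting-invariant
because the Fitch pass roots on an edge (or equivalently at a trivalent
node).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import iupac, trees
from .alignment import Alignment
from .trees import Node

__all__ = [
    "SiteClassification",
    "ParsimonyStats",
    "classify_sites",
    "fitch_length",
    "fitch_steps",
    "ci_ri",
    "mp_search",
    "exhaustive_search",
    "bootstrap_support",
    "ild_test",
]

_FULL = 15

# -- pattern compression ---------------------------------------------------


def _pattern_matrix(aln: Alignment, columns=None) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Unique column patterns of the (missing -> full set) mask matrix.

    Returns ``(P, weights, inverse)`` where ``P`` is (n_seq, n_patterns),
    ``weights`` counts occurrences and ``inverse`` maps each original
    column to its pattern index.
    """
    M = aln.matrix.copy()
    M[M == 0] = _FULL
    if columns is not None:
        M = M[:, np.asarray(columns, dtype=int)]
    pats, inverse, counts = np.unique(
        M, axis=1, return_inverse=True, return_counts=True
    )
    return pats, counts.astype(float), inverse


def _leaf_rows(aln: Alignment) -> dict[str, int]:
    return {lab: i for i, lab in enumerate(aln.labels)}


# -- Fitch -----------------------------------------------------------------


def fitch_steps(tree: Node, P: np.ndarray, rows: dict[str, int]) -> np.ndarray:
    """Per-pattern Fitch step counts (vectorized over pattern columns).

    ``P`` is an (n_seq, k) mask matrix with missing already widened to the
    full state set; ``rows`` maps leaf labels to rows of ``P``.
    """
    k = P.shape[1]
    steps = np.zeros(k, dtype=np.int64)
    state: dict[int, np.ndarray] = {}
    for node in tree.postorder():
        if node.is_leaf:
            state[id(node)] = P[rows[node.label]]
            continue
        acc = None
        for ch in node.children:
            s = state.pop(id(ch))
            if acc is None:
                acc = s
                continue
            inter = acc & s
            empty = inter == 0
            steps += empty
            acc = np.where(empty, acc | s, inter)
        state[id(node)] = acc
    return steps


def fitch_length(tree: Node, aln: Alignment, weights: np.ndarray | None = None) -> int:
    """Total Fitch tree length (sum over columns of small-parsimony steps)."""
    tree_labels = set(trees.leaf_labels(tree))
    if tree_labels != set(aln.labels):
        raise ValueError("tree leaf labels do not match alignment labels")
    P, w, inverse = _pattern_matrix(aln)
    if weights is not None:
        w = np.bincount(inverse, weights=np.asarray(weights, float), minlength=P.shape[1])
    steps = fitch_steps(tree, P, _leaf_rows(aln))
    return int(round(float(steps @ w)))


# -- site classification and CI/RI -----------------------------------------

_SUBSET_MASKS = [m for m in range(1, 16)]
_SUBSETS_BY_SIZE = sorted(_SUBSET_MASKS, key=lambda m: bin(m).count("1"))


def _min_states(col_masks: np.ndarray) -> int:
    """Minimum number of states resolving every non-missing base set.

    This is the minimum hitting set over the observed IUPAC sets (brute
    force over the 15 nonempty subsets of {A,C,G,T}), and equals the
    minimum possible parsimony steps of the column plus one.
    """
    sets = np.unique(col_masks[col_masks != 0])
    if sets.size == 0:
        return 0
    for cand in _SUBSETS_BY_SIZE:
        if all(int(s) & cand for s in sets):
            return bin(cand).count("1")
    return 4  # unreachable


@dataclass
class SiteClassification:
    """Per-column constant / variable-uninformative / parsimony-informative."""

    categories: list[str]
    n_constant: int
    n_variable: int
    n_informative: int


def classify_sites(aln: Alignment, ambiguity: str = "ignore") -> SiteClassification:
    """Classify columns for parsimony.

    ``ambiguity="ignore"`` (default): ambiguity codes contribute to no
    state count; a column is variable iff >= 2 distinct unambiguous states
    occur, informative iff >= 2 states are each borne by >= 2 sequences.
    ``ambiguity="resolve"``: a column is variable iff its base sets cannot
    all be resolved to one state (minimum hitting set >= 2); the
    informative rule is unchanged.
    """
    if ambiguity not in ("ignore", "resolve"):
        raise ValueError(f"unknown ambiguity rule {ambiguity!r}")
    M = aln.matrix
    npc = iupac.popcount(M)
    cats: list[str] = []
    for j in range(aln.length):
        col = M[:, j]
        unamb = col[npc[:, j] == 1]
        vals, counts = np.unique(unamb, return_counts=True)
        if ambiguity == "ignore":
            variable = vals.size >= 2
        else:
            variable = _min_states(col) >= 2
        informative = int((counts >= 2).sum()) >= 2
        if informative:
            cats.append("parsimony_informative")
        elif variable:
            cats.append("variable_uninformative")
        else:
            cats.append("constant")
    return SiteClassification(
        categories=cats,
        n_constant=cats.count("constant"),
        n_variable=len(cats) - cats.count("constant"),
        n_informative=cats.count("parsimony_informative"),
    )


@dataclass
class ParsimonyStats:
    """Tree length with consistency and retention indices.

    ``m`` is the per-site minimum steps (distinct resolvable states minus
    one), ``s`` the observed Fitch steps, ``g`` the maximum steps
    (attained on a star tree).  CI and RI are summed over variable sites;
    sites with ``g == m`` contribute only to the length.
    """

    tree_length: int
    ci: float
    ri: float
    n_variable: int
    n_informative: int
    m: np.ndarray = field(repr=False, default=None)
    s: np.ndarray = field(repr=False, default=None)
    g: np.ndarray = field(repr=False, default=None)


def ci_ri(tree: Node, aln: Alignment) -> ParsimonyStats:
    """Tree length, consistency index and retention index on ``aln``."""
    P, w, inverse = _pattern_matrix(aln)
    steps_pat = fitch_steps(tree, P, _leaf_rows(aln))
    s = steps_pat[inverse]  # per-column observed steps
    M = aln.matrix
    npc = iupac.popcount(M)
    L = aln.length
    m = np.zeros(L, dtype=np.int64)
    g = np.zeros(L, dtype=np.int64)
    for j in range(L):
        col = M[:, j]
        m[j] = max(0, _min_states(col) - 1)
        nonmissing = col != 0
        n_eff = int(nonmissing.sum())
        if n_eff:
            # a sequence "covers" a state if its base set contains it
            cover = max(
                int(((col & mask) != 0).sum()) for mask in (1, 2, 4, 8)
            )
            g[j] = n_eff - cover
    if not (m <= s).all() or not (s <= g).all():
        raise AssertionError("per-site step bounds violated (m <= s <= g)")
    cls = classify_sites(aln, ambiguity="resolve")
    var = np.array([c != "constant" for c in cls.categories]) & (g > m)
    sum_s = int(s[var].sum())
    if int(s.sum()) == 0:
        raise ZeroDivisionError("no observed steps: CI undefined")
    ci = float(m[var].sum() / sum_s) if sum_s else 1.0
    denom = float((g[var] - m[var]).sum())
    ri = float((g[var] - s[var]).sum() / denom) if denom else 1.0
    return ParsimonyStats(
        tree_length=int(s.sum()),
        ci=ci,
        ri=ri,
        n_variable=cls.n_variable,
        n_informative=cls.n_informative,
        m=m,
        s=s,
        g=g,
    )


# -- tree surgery ----------------------------------------------------------


def _edges(tree: Node) -> list[Node]:
    """Edges identified by their child node."""
    return [n for n in tree.postorder() if n.parent is not None]


def _insert_on_edge(edge_child: Node, subtree: Node) -> Node:
    """Bisect the edge above ``edge_child`` and hang ``subtree`` there."""
    parent = edge_child.parent
    idx = parent.children.index(edge_child)
    mid = Node()
    mid.add(edge_child)
    mid.add(subtree)
    mid.parent = parent
    parent.children[idx] = mid
    return mid


def _detach(node: Node, root: Node) -> Node:
    """Remove ``node``'s subtree; return the (possibly new) root."""
    parent = node.parent
    parent.children.remove(node)
    node.parent = None
    if parent is root:
        if len(root.children) == 1:
            new_root = root.children[0]
            new_root.parent = None
            return new_root
        return root
    if len(parent.children) == 1:
        only = parent.children[0]
        grand = parent.parent
        idx = grand.children.index(parent)
        grand.children[idx] = only
        only.parent = grand
    return root


def _has_clade(tree: Node, clade: frozenset, labels: frozenset) -> bool:
    present = clade & labels
    if len(present) < 2 or len(labels - present) < 1:
        return True
    ref = min(labels)
    side = present if ref not in present else labels - present
    return side in trees.splits(tree, trivial=True)


def _constraint_ok(tree: Node, constraint) -> bool:
    if not constraint:
        return True
    labels = frozenset(trees.leaf_labels(tree))
    return all(_has_clade(tree, frozenset(c), labels) for c in constraint)


# -- search ----------------------------------------------------------------


def exhaustive_search(
    aln: Alignment, weights: np.ndarray | None = None, constraint=None
) -> tuple[list[Node], int]:
    """Global optimum over every unrooted topology (feasible to ~8 taxa)."""
    P, w, inverse = _pattern_matrix(aln)
    if weights is not None:
        w = np.bincount(inverse, weights=np.asarray(weights, float), minlength=P.shape[1])
    rows = _leaf_rows(aln)
    best_len, best = None, []
    for tree in trees.enumerate_unrooted_topologies(aln.labels):
        if constraint and not _constraint_ok(tree, constraint):
            continue
        length = float(fitch_steps(tree, P, rows) @ w)
        if best_len is None or length < best_len - 1e-9:
            best_len, best = length, [tree]
        elif abs(length - best_len) <= 1e-9:
            best.append(tree)
    if best_len is None:
        raise ValueError("constraint incompatible with label set")
    return best, int(round(best_len))


def steps_matrix(aln: Alignment, max_taxa: int = 8) -> tuple[np.ndarray, np.ndarray, list]:
    """Fitch steps for every topology x every column pattern.

    Returns ``(T, inverse, topologies)`` where ``T[i, p]`` is the step
    count of topology ``i`` on pattern ``p`` and ``inverse`` maps columns
    to patterns.  The minimum tree length under any column weighting
    ``w`` is then ``min(T @ w_pattern)`` — the workhorse behind fast ILD
    permutation replicates on small taxon sets.
    """
    if aln.n > max_taxa:
        raise ValueError(f"steps_matrix limited to {max_taxa} taxa")
    P, _, inverse = _pattern_matrix(aln)
    rows = _leaf_rows(aln)
    topologies = list(trees.enumerate_unrooted_topologies(aln.labels))
    T = np.vstack([fitch_steps(t, P, rows) for t in topologies])
    return T, inverse, topologies


def _stepwise_addition(
    aln: Alignment, P, w, rows, order, constraint=None
) -> Node:
    labels = [aln.labels[i] for i in order]
    tree = Node()
    for lab in labels[:3]:
        tree.add(Node(lab))
    sub_rows = rows
    for lab in labels[3:]:
        best_len, best_tree = None, None
        for i in range(len(_edges(tree))):
            cand = tree.copy()
            _insert_on_edge(_edges(cand)[i], Node(lab))
            if constraint and not _constraint_ok(cand, constraint):
                continue
            length = float(fitch_steps(cand, P, sub_rows) @ w)
            if best_len is None or length < best_len:
                best_len, best_tree = length, cand
        if best_tree is None:
            raise ValueError("constraint incompatible during stepwise addition")
        tree = best_tree
    return tree


def _spr_neighbors(tree: Node, radius: int | None = None):
    """Yield SPR rearrangements of ``tree`` (copies).

    ``radius=1`` restricts regrafting to edges adjacent to the pruning
    site, which is the NNI neighborhood.
    """
    n_edges = len(_edges(tree))
    for prune_idx in range(n_edges):
        cand0 = tree.copy()
        edges0 = _edges(cand0)
        prune_node = edges0[prune_idx]
        pruned_labels = {n.label for n in prune_node.leaves()}
        all_labels = {n.label for n in cand0.leaves()}
        if len(all_labels - pruned_labels) < 2:
            continue
        origin_parent = prune_node.parent
        # neighborhood anchor: labels below the pruning site's siblings
        sibling_sets = [
            frozenset(n.label for n in sib.leaves())
            for sib in origin_parent.children
            if sib is not prune_node
        ]
        root0 = _detach(prune_node, cand0)
        rem_edges = _edges(root0)
        for idx in range(len(rem_edges)):
            if radius == 1:
                # limited neighborhood: regraft only within/above the regions
                # adjacent to the pruning site (NNI-like moves)
                below = frozenset(n.label for n in rem_edges[idx].leaves())
                if all(not (below <= s or s <= below) for s in sibling_sets):
                    continue
            cand = root0.copy()
            sub = prune_node.copy()
            _insert_on_edge(_edges(cand)[idx], sub)
            yield cand


def mp_search(
    aln: Alignment,
    n_starts: int = 10,
    swap: str = "spr",
    constraint=None,
    seed: int | None = None,
    weights: np.ndarray | None = None,
    exhaustive: bool | None = None,
) -> tuple[list[Node], int]:
    """Heuristic maximum-parsimony search.

    Random-addition stepwise insertion followed by SPR (or NNI-radius)
    hill climbing, repeated over ``n_starts`` random addition orders; all
    distinct topologies at the best length found are returned.  With
    ``exhaustive=True`` (default for <= 7 taxa when unconstrained) every
    topology is scored instead.
    """
    if aln.n < 4:
        raise ValueError("need >= 4 sequences")
    if constraint:
        labs = set(aln.labels)
        for clade in constraint:
            unknown = set(clade) - labs
            if unknown:
                raise ValueError(f"constraint labels not in alignment: {sorted(unknown)}")
    if exhaustive is None:
        exhaustive = aln.n <= 7
    if exhaustive:
        return exhaustive_search(aln, weights=weights, constraint=constraint)
    rng = np.random.default_rng(seed)
    P, w, inverse = _pattern_matrix(aln)
    if weights is not None:
        w = np.bincount(inverse, weights=np.asarray(weights, float), minlength=P.shape[1])
    rows = _leaf_rows(aln)

    def score(t: Node) -> float:
        return float(fitch_steps(t, P, rows) @ w)

    best_len: float | None = None
    best: dict[frozenset, Node] = {}
    for _ in range(n_starts):
        order = rng.permutation(aln.n)
        tree = _stepwise_addition(aln, P, w, rows, order, constraint=constraint)
        cur_len = score(tree)
        improved = True
        while improved:
            improved = False
            ties: list[Node] = []
            for cand in _spr_neighbors(tree, radius=1 if swap == "nni" else None):
                if constraint and not _constraint_ok(cand, constraint):
                    continue
                length = score(cand)
                if length < cur_len - 1e-9:
                    tree, cur_len, improved = cand, length, True
                    ties = []
                    break
                if abs(length - cur_len) <= 1e-9:
                    ties.append(cand)
        if best_len is None or cur_len < best_len - 1e-9:
            best_len = cur_len
            best = {trees.topology_key(tree): tree}
            for t in ties:
                best.setdefault(trees.topology_key(t), t)
        elif abs(cur_len - best_len) <= 1e-9:
            best.setdefault(trees.topology_key(tree), tree)
            for t in ties:
                best.setdefault(trees.topology_key(t), t)
    return list(best.values()), int(round(best_len))


# -- bootstrap -------------------------------------------------------------


def bootstrap_support(
    aln: Alignment,
    n_reps: int = 100,
    seed: int | None = None,
    n_starts: int = 1,
    swap: str = "spr",
) -> dict[frozenset, float]:
    """Nonparametric bootstrap clade support.

    Columns are resampled with replacement; one fast heuristic search per
    replicate; support is the percentage of replicates whose best tree
    contains the split (splits canonicalized as in
    :func:`phylodiscord.trees.splits`).
    """
    rng = np.random.default_rng(seed)
    counts: dict[frozenset, int] = {}
    for rep in range(n_reps):
        w = rng.multinomial(aln.length, np.full(aln.length, 1.0 / aln.length))
        tr, _ = mp_search(
            aln,
            n_starts=n_starts,
            swap=swap,
            seed=int(rng.integers(2**31 - 1)),
            weights=w,
        )
        for split in trees.splits(tr[0]):
            counts[split] = counts.get(split, 0) + 1
    return {s: 100.0 * c / n_reps for s, c in counts.items()}


# -- ILD / partition homogeneity -------------------------------------------


def ild_test(
    aln: Alignment,
    partA,
    partB,
    n_reps: int = 100,
    seed: int | None = None,
    search_kwargs: dict | None = None,
) -> tuple[int, float]:
    """Incongruence length difference (partition homogeneity) test.

    ``D = L(combined) - [L(A) + L(B)]`` with lengths from MP searches;
    per replicate, columns are randomly reassigned to pseudo-partitions
    of the original sizes.  The combined length is permutation-invariant,
    so a replicate is as extreme as the observation iff the sum of its
    partition lengths is <= the observed sum.  p uses the add-one
    convention ``(1 + #{D_rep >= D_obs}) / (n_reps + 1)``.
    """
    import warnings

    partA = np.asarray(sorted(partA), dtype=int)
    partB = np.asarray(sorted(partB), dtype=int)
    if np.intersect1d(partA, partB).size:
        raise ValueError("partitions overlap")
    cols = np.concatenate([partA, partB])
    sub = aln.columns(cols)
    nA = partA.size
    for name, part in (("A", partA), ("B", partB)):
        if classify_sites(aln.columns(part)).n_variable == 0:
            warnings.warn(f"partition {name} has no variable sites; ILD degenerate")
    kw = dict(search_kwargs or {})
    rng = np.random.default_rng(seed)

    if sub.n <= 8:
        # small taxon sets: precompute steps for every topology x pattern,
        # then each replicate is two matrix-vector products
        T, inverse, _ = steps_matrix(sub)
        k = T.shape[1]

        def lengths(colsA, colsB):
            wA = np.bincount(inverse[colsA], minlength=k).astype(float)
            wB = np.bincount(inverse[colsB], minlength=k).astype(float)
            return float((T @ wA).min()), float((T @ wB).min())

        idxA = np.arange(nA)
        idxB = np.arange(nA, cols.size)
        lA, lB = lengths(idxA, idxB)
        l_comb = float((T @ np.bincount(inverse, minlength=k).astype(float)).min())
        obs_sum = lA + lB
        hits = 0
        for _ in range(n_reps):
            perm = rng.permutation(cols.size)
            rA, rB = lengths(perm[:nA], perm[nA:])
            if rA + rB <= obs_sum + 1e-9:
                hits += 1
    else:
        def search_len(a: Alignment) -> int:
            kw.setdefault("n_starts", 2)
            return mp_search(a, seed=int(rng.integers(2**31 - 1)), **kw)[1]

        lA = search_len(sub.columns(np.arange(nA)))
        lB = search_len(sub.columns(np.arange(nA, cols.size)))
        l_comb = search_len(sub)
        obs_sum = lA + lB
        hits = 0
        for _ in range(n_reps):
            perm = rng.permutation(cols.size)
            rA = search_len(sub.columns(perm[:nA]))
            rB = search_len(sub.columns(perm[nA:]))
            if rA + rB <= obs_sum:
                hits += 1
    d_obs = int(round(l_comb - obs_sum))
    p = (1 + hits) / (n_reps + 1)
    return d_obs, p
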