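"""Per-site log-likelihoods by Felsenstein pruning, branch-length
optimization, constrained tree search, and RELL-based topology tests.

Leaf conditional vectors encode IUPAC ambiguity (1 for each compatible
base, all ones for gap/missing).  Discrete-gamma categories are averaged
and a proportion of invariant sites mixed in as a two-component site
mixture.  The weighted Kishino–Hasegawa (WKH) and weighted
Shimodaira–Hasegawa (WSH) tests resample estimated per-site
log-likelihoods (RELL) without re-optimization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from . import trees
from .alignment import Alignment
from .models import SubstitutionModel
from .trees import Node

__all__ = [
    "site_loglik",
    "total_loglik",
    "optimize_branch_lengths",
    "constrained_search",
    "SiteLikelihoodMatrix",
    "rell_tests",
    "write_site_likelihoods",
]

_MIN_BLEN = 1e-9
_MAX_BLEN = 10.0


def _leaf_partials(aln: Alignment) -> dict[str, np.ndarray]:
    """(L, 4) 0/1 conditional vectors per label; missing = all ones."""
    out = {}
    M = aln.matrix
    for i, lab in enumerate(aln.labels):
        col = M[i]
        full = np.where(col == 0, 15, col)
        part = np.stack([(full & m) != 0 for m in (1, 2, 4, 8)], axis=1)
        out[lab] = part.astype(float)
    return out


def site_loglik(
    tree: Node, aln: Alignment, model: SubstitutionModel
) -> np.ndarray:
    """Per-site log-likelihood vector under the pruning algorithm.

    Branch lengths must be present on every non-root node.  The root uses
    the model's stationary frequencies; under a reversible model the
    result is invariant to (re)rooting.
    """
    if set(trees.leaf_labels(tree)) != set(aln.labels):
        raise ValueError("tree leaf labels do not match alignment labels")
    rates, probs = model.category_rates()
    pi = model.frequencies
    leaf = _leaf_partials(aln)
    L = aln.length
    ncat = rates.size
    # per-branch transition matrices per category, computed on demand
    lik = np.zeros(L)
    cat_site_lik = np.zeros((ncat, L))
    for c, r in enumerate(rates):
        partial: dict[int, np.ndarray] = {}
        for node in tree.postorder():
            if node.is_leaf:
                partial[id(node)] = leaf[node.label]
            else:
                acc = np.ones((L, 4))
                for ch in node.children:
                    if ch.length is None:
                        raise ValueError("missing branch length")
                    P = model.transition_matrix(ch.length * r)
                    acc *= partial.pop(id(ch)) @ P.T
                partial[id(node)] = acc
        root_part = partial[id(tree)]
        cat_site_lik[c] = root_part @ pi
    lik = probs @ cat_site_lik
    if model.p_inv > 0:
        M = aln.matrix
        full = np.where(M == 0, 15, M)
        common = np.bitwise_and.reduce(full, axis=0)
        inv_lik = np.zeros(L)
        for k, m in enumerate((1, 2, 4, 8)):
            inv_lik += pi[k] * ((common & m) != 0)
        lik = model.p_inv * inv_lik + (1 - model.p_inv) * lik
    with np.errstate(divide="ignore"):
        return np.log(lik)


def total_loglik(tree: Node, aln: Alignment, model: SubstitutionModel) -> float:
    return float(site_loglik(tree, aln, model).sum())


def optimize_branch_lengths(
    tree: Node,
    aln: Alignment,
    model: SubstitutionModel,
    tol: float = 1e-8,
    max_sweeps: int = 20,
) -> tuple[Node, float]:
    """Coordinate-wise ML branch-length optimization.

    Sweeps over branches with bounded univariate optimization until the
    relative log-likelihood change drops below ``tol``; the total
    log-likelihood is nondecreasing across sweeps.  Returns the optimized
    tree (a copy) and its total log-likelihood.
    """
    tree = tree.copy()
    for node in tree.postorder():
        if node.parent is not None and node.length is None:
            node.length = 0.05
    cur = total_loglik(tree, aln, model)
    for _ in range(max_sweeps):
        for node in tree.postorder():
            if node.parent is None:
                continue

            def neg(t: float, node=node) -> float:
                node.length = t
                return -total_loglik(tree, aln, model)

            res = minimize_scalar(
                neg, bounds=(_MIN_BLEN, _MAX_BLEN), method="bounded",
                options={"xatol": 1e-10},
            )
            node.length = float(res.x)
        new = total_loglik(tree, aln, model)
        if new < cur - 1e-6:
            warnings.warn("branch-length sweep decreased log-likelihood")
        if abs(new - cur) <= tol * max(1.0, abs(cur)):
            cur = new
            break
        cur = new
    else:
        warnings.warn("branch-length optimization did not converge")
    return tree, cur


def constrained_search(aln: Alignment, constraint, criterion: str = "parsimony") -> Node:
    """Best constraint-compatible topology (parsimony criterion).

    Delegates to :func:`phylodiscord.parsimony.mp_search` with the clade
    constraints; the returned topology is intended for subsequent
    branch-length optimization under a likelihood model.
    """
    if criterion != "parsimony":
        raise ValueError("only the parsimony criterion is implemented")
    from .parsimony import mp_search

    best, _ = mp_search(aln, constraint=constraint, seed=0)
    return best[0]


@dataclass
class SiteLikelihoodMatrix:
    """Trees x sites grid of per-site log-likelihoods."""

    matrix: np.ndarray
    tree_labels: list[str]

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != len(self.tree_labels):
            raise ValueError("matrix must be (n_trees, n_sites) with one label per row")
        if not np.isfinite(self.matrix).all():
            raise ValueError("non-finite site log-likelihoods")

    @property
    def totals(self) -> np.ndarray:
        return self.matrix.sum(axis=1)


def write_site_likelihoods(M: SiteLikelihoodMatrix, path: str) -> None:
    """Sites x trees tab-separated table of per-site log-likelihoods."""
    with open(path, "w") as fh:
        fh.write("site\t" + "\t".join(M.tree_labels) + "\n")
        for s in range(M.matrix.shape[1]):
            fh.write(
                f"{s}\t" + "\t".join(f"{v:.10g}" for v in M.matrix[:, s]) + "\n"
            )


def rell_tests(
    M: SiteLikelihoodMatrix, n_boot: int = 10000, seed: int | None = None
) -> dict:
    """Weighted KH and weighted SH topology tests via RELL resampling.

    Site columns are resampled with replacement (no re-optimization).
    WKH: per tree, the log-likelihood difference to the best tree is
    standardized by its bootstrap standard deviation and referred to the
    centred bootstrap distribution, two-sided.  WSH: per tree, the null is
    the maximum standardized centred difference over all rival trees.

    Returns a dict with ``best`` (row index), ``delta`` (lnL differences
    to the best tree) and per-tree ``p_wkh`` / ``p_wsh`` arrays.
    """
    X = M.matrix
    T, S = X.shape
    if T < 2:
        raise ValueError("need >= 2 trees")
    rng = np.random.default_rng(seed)
    totals = X.sum(axis=1)
    best = int(np.argmax(totals))
    W = rng.multinomial(S, np.full(S, 1.0 / S), size=n_boot)  # (n_boot, S)
    B = W @ X.T  # (n_boot, T) bootstrap totals
    Bc = B - B.mean(axis=0, keepdims=True)

    p_wkh = np.ones(T)
    for t in range(T):
        if t == best:
            continue
        d_obs = totals[best] - totals[t]
        Dc = Bc[:, best] - Bc[:, t]
        sd = Dc.std()
        if sd == 0:
            warnings.warn("degenerate zero-variance difference; p set to 1")
            p_wkh[t] = 1.0
            continue
        p_wkh[t] = float(np.mean(np.abs(Dc) >= abs(d_obs)))

    # pairwise bootstrap standard deviations for the weighting
    sds = np.zeros((T, T))
    for i in range(T):
        for j in range(T):
            if i != j:
                sds[i, j] = (Bc[:, i] - Bc[:, j]).std()
    p_wsh = np.ones(T)
    for t in range(T):
        rivals = [j for j in range(T) if j != t and sds[j, t] > 0]
        if not rivals:
            if T > 1:
                warnings.warn("degenerate zero-variance differences; p set to 1")
            continue
        t_obs = max((totals[j] - totals[t]) / sds[j, t] for j in rivals)
        z = np.stack([(Bc[:, j] - Bc[:, t]) / sds[j, t] for j in rivals])
        t_null = z.max(axis=0)
        p_wsh[t] = float(np.mean(t_null >= t_obs))

    return {
        "best": best,
        "delta": totals[best] - totals,
        "p_wkh": p_wkh,
        "p_wsh": p_wsh,
        "totals": totals,
    }
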