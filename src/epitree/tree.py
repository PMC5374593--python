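"""Class-conditional maximum-weight dependence tree (Chow-Liu / TAN).

The model: given a binary phenotype C, approximate the joint distribution
of discrete variables X_1..X_n (SNP dosages and encoded demographics) by a
first-order dependence tree,

    P(X_1, ..., X_n | C) = prod_i P(X_i | X_{m_i}, C),

where m_i is the tree parent of node i (the root is conditioned on C
alone).  The tree maximizing the summed class-conditional mutual
information sum_i I(X_i, X_{m_i} | C) is also the maximum-likelihood tree,
so structure learning reduces to a maximum-weight spanning tree (Kruskal)
on the pairwise CMI matrix.  Every node additionally has the class node as
a parent, which makes the model a tree-augmented naive Bayes classifier:
assign "case" when the case-conditional factorization outweighs the
control-conditional one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .datatypes import CASE, CONTROL, MISSING, DiscreteData


# ---------------------------------------------------------------------------
# Conditional mutual information
# ---------------------------------------------------------------------------

def joint_counts(x, y, c, kx: int, ky: int) -> np.ndarray:
    """Class-stratified joint counts over pairwise-complete (x, y) samples.

    Returns an array of shape (2, kx, ky): counts[c, a, b].
    """
    x = np.asarray(x)
    y = np.asarray(y)
    c = np.asarray(c)
    ok = (x != MISSING) & (y != MISSING)
    code = (c[ok].astype(np.int64) * kx + x[ok]) * ky + y[ok]
    return np.bincount(code, minlength=2 * kx * ky).reshape(2, kx, ky)


def cmi_from_counts(counts: np.ndarray) -> float:
    """Plug-in (MLE) conditional mutual information from a (2, kx, ky) table.

    Natural log; 0*log 0 = 0; class weights P(c) estimated from the same
    complete pairs.  Nonnegative by construction (clipped at 0 against
    rounding).
    """
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total == 0:
        raise ValueError("no complete (x, y, c) triples")
    out = 0.0
    for c in range(counts.shape[0]):
        n_c = counts[c].sum()
        if n_c == 0:
            continue
        p = counts[c] / n_c
        px = p.sum(axis=1, keepdims=True)
        py = p.sum(axis=0, keepdims=True)
        nz = p > 0
        out += (n_c / total) * float(
            (p[nz] * np.log(p[nz] / (px * py)[nz])).sum()
        )
    return max(out, 0.0)


def estimate_cmi(x, y, c, kx: int, ky: int) -> float:
    """MLE estimate of I(X, Y | C) on pairwise-complete samples."""
    return cmi_from_counts(joint_counts(x, y, c, kx, ky))


def cmi_matrix(data: DiscreteData) -> np.ndarray:
    """Symmetric matrix of pairwise CMI estimates over all variables."""
    p = data.p
    W = np.zeros((p, p))
    cols = [np.ascontiguousarray(data.X[:, j]) for j in range(p)]
    for i in range(p):
        for j in range(i + 1, p):
            w = estimate_cmi(cols[i], cols[j], data.y, data.ks[i], data.ks[j])
            W[i, j] = W[j, i] = w
    return W


# ---------------------------------------------------------------------------
# Tree structure
# ---------------------------------------------------------------------------

@dataclass
class DependenceTree:
    """A (possibly reduced) dependence tree with per-node CPTs.

    ``parent[name] is None`` marks a root conditioned on the class alone;
    after node/edge removal the structure may be a forest with several such
    roots.  CPT shapes: root nodes (k, 2); others (k_child, k_parent, 2),
    the last axis being the class.
    """

    nodes: list[str]
    ks: dict[str, int]
    parent: dict[str, str | None]
    cpts: dict[str, np.ndarray] = field(default_factory=dict)
    class_prior: np.ndarray = field(default_factory=lambda: np.array([0.5, 0.5]))
    edge_weights: dict[tuple[str, str], float] = field(default_factory=dict)
    alpha: float = 1.0

    def edges(self) -> list[tuple[str, str]]:
        """Directed (child, parent) pairs, in node order."""
        return [(n, self.parent[n]) for n in self.nodes if self.parent[n] is not None]

    def undirected_edges(self) -> set[frozenset]:
        return {frozenset(e) for e in self.edges()}

    @property
    def roots(self) -> list[str]:
        return [n for n in self.nodes if self.parent[n] is None]

    def children(self, name: str) -> list[str]:
        return [n for n in self.nodes if self.parent[n] == name]

    @property
    def total_weight(self) -> float:
        return float(sum(self.edge_weights.get(e, 0.0) for e in self.edges()))

    def validate(self) -> None:
        seen = set(self.nodes)
        if len(seen) != len(self.nodes):
            raise ValueError("duplicate node names")
        for child, par in self.parent.items():
            if par is not None and par not in seen:
                raise ValueError(f"parent {par!r} of {child!r} is not a node")
        # acyclicity: walking up from every node must terminate
        for n in self.nodes:
            slow = n
            hops = 0
            while self.parent[slow] is not None:
                slow = self.parent[slow]
                hops += 1
                if hops > len(self.nodes):
                    raise ValueError("cyclic parent map")
        for name, cpt in self.cpts.items():
            sums = cpt.sum(axis=0)
            if not np.allclose(sums, 1.0, atol=1e-12):
                raise ValueError(f"CPT of {name!r} does not normalize")

    def copy(self) -> "DependenceTree":
        return DependenceTree(
            nodes=list(self.nodes),
            ks=dict(self.ks),
            parent=dict(self.parent),
            cpts={k: v.copy() for k, v in self.cpts.items()},
            class_prior=self.class_prior.copy(),
            edge_weights=dict(self.edge_weights),
            alpha=self.alpha,
        )


class _UnionFind:
    def __init__(self, n: int):
        self.up = list(range(n))

    def find(self, a: int) -> int:
        while self.up[a] != a:
            self.up[a] = self.up[self.up[a]]
            a = self.up[a]
        return a

    def union(self, a: int, b: int) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.up[rb] = ra
        return True


def maximum_spanning_tree(W: np.ndarray) -> list[tuple[int, int]]:
    """Kruskal maximum-weight spanning tree on a symmetric weight matrix.

    Ties are broken by lexicographic (i, j) order of the edge's endpoints,
    so the result is deterministic.
    """
    p = W.shape[0]
    edges = sorted(
        ((i, j) for i in range(p) for j in range(i + 1, p)),
        key=lambda e: (-W[e[0], e[1]], e[0], e[1]),
    )
    uf = _UnionFind(p)
    out = []
    for i, j in edges:
        if uf.union(i, j):
            out.append((i, j))
            if len(out) == p - 1:
                break
    return out


def build_mwdt(
    data: DiscreteData,
    W: np.ndarray | None = None,
    root: str | None = None,
) -> DependenceTree:
    """Learn the maximum-weight dependence-tree structure.

    Edge weights are the class-conditional MI estimates (computed from
    ``data`` unless a precomputed matrix ``W`` is passed).  The root
    defaults to the node with the largest total incident tree weight (ties
    broken by node order); any root yields the same joint distribution.
    Returns a structure-only tree (no CPTs).
    """
    if data.p < 2:
        raise ValueError("need at least 2 variables to build a tree")
    if W is None:
        W = cmi_matrix(data)
    mst = maximum_spanning_tree(W)

    adj: dict[int, list[int]] = {i: [] for i in range(data.p)}
    incident = np.zeros(data.p)
    for i, j in mst:
        adj[i].append(j)
        adj[j].append(i)
        incident[i] += W[i, j]
        incident[j] += W[i, j]

    if root is None:
        r = int(np.argmax(incident))
    else:
        r = data.names.index(root)

    parent_idx: dict[int, int | None] = {r: None}
    stack = [r]
    while stack:
        u = stack.pop()
        for v in sorted(adj[u]):
            if v not in parent_idx:
                parent_idx[v] = u
                stack.append(v)

    names = data.names
    parent = {
        names[i]: (names[parent_idx[i]] if parent_idx[i] is not None else None)
        for i in range(data.p)
    }
    weights = {
        (names[i], names[parent_idx[i]]): float(W[i, parent_idx[i]])
        for i in range(data.p)
        if parent_idx[i] is not None
    }
    return DependenceTree(
        nodes=list(names),
        ks={names[i]: int(data.ks[i]) for i in range(data.p)},
        parent=parent,
        edge_weights=weights,
    )


# ---------------------------------------------------------------------------
# CPT estimation
# ---------------------------------------------------------------------------

def _root_cpt(x, y, k: int, alpha: float) -> np.ndarray:
    """P(X | C) with Laplace smoothing, shape (k, 2)."""
    cpt = np.empty((k, 2))
    for cls in (CONTROL, CASE):
        sel = (y == cls) & (x != MISSING)
        counts = np.bincount(x[sel], minlength=k).astype(float)
        denom = counts.sum() + alpha * k
        if denom == 0:
            cpt[:, cls] = 1.0 / k
        else:
            col = (counts + alpha) / denom
            cpt[:, cls] = col / col.sum()  # guard rounding
    return cpt


def _child_cpt(x, xp, y, k: int, kp: int, alpha: float) -> np.ndarray:
    """P(X | X_parent, C) with Laplace smoothing, shape (k, kp, 2)."""
    counts = joint_counts(xp, x, y, kp, k)  # (2, kp, k)
    cpt = np.empty((k, kp, 2))
    for cls in (CONTROL, CASE):
        tab = counts[cls].T.astype(float)  # (k, kp)
        denom = tab.sum(axis=0) + alpha * k
        with np.errstate(invalid="ignore", divide="ignore"):
            col = (tab + alpha) / denom
        # empty parent cell at alpha=0 -> uniform (never hit by scoring)
        empty = denom == 0
        col[:, empty] = 1.0 / k
        cpt[:, :, cls] = col / col.sum(axis=0)
    return cpt


def fit_cpts(
    tree: DependenceTree, data: DiscreteData, alpha: float = 1.0
) -> DependenceTree:
    """Estimate all CPTs and the class prior from data.

    P(X_i = a | X_{m_i} = b, C = c) = (n_abc + alpha) / (n_bc + alpha k_i),
    using pairwise-complete samples for each factor.  With the default
    Laplace pseudocount alpha = 1 every probability is strictly positive,
    so classification scores are always finite.
    """
    out = tree.copy()
    out.alpha = alpha
    cols = {n: data.column(n) for n in tree.nodes}
    for name in tree.nodes:
        if name not in cols:
            raise KeyError(f"variable {name!r} absent from data")
        par = tree.parent[name]
        k = tree.ks[name]
        if par is None:
            out.cpts[name] = _root_cpt(cols[name], data.y, k, alpha)
        else:
            out.cpts[name] = _child_cpt(
                cols[name], cols[par], data.y, k, tree.ks[par], alpha
            )
    n_case = int((data.y == CASE).sum())
    n_ctrl = int((data.y == CONTROL).sum())
    out.class_prior = np.array([n_ctrl, n_case], dtype=float) / (n_case + n_ctrl)
    return out


def fit_mwdt(
    data: DiscreteData, alpha: float = 1.0, root: str | None = None
) -> DependenceTree:
    """Structure learning followed by CPT estimation (one call)."""
    return fit_cpts(build_mwdt(data, root=root), data, alpha=alpha)


# ---------------------------------------------------------------------------
# Scoring / classification
# ---------------------------------------------------------------------------

def score_samples(
    tree: DependenceTree, data: DiscreteData, use_prior: bool = False
) -> np.ndarray:
    """Log-likelihood-ratio scores, case vs control, for every sample.

    score = sum_i [log P(x_i | x_{m_i}, case) - log P(x_i | x_{m_i}, control)];
    a factor whose child or parent value is missing is skipped in both
    class products, keeping scores comparable.  The classification rule of
    the model compares the bare products, so the log prior ratio is added
    only when ``use_prior`` is set.
    """
    n = data.n
    scores = np.zeros(n)
    for name in tree.nodes:
        x = data.column(name)
        par = tree.parent[name]
        cpt = tree.cpts[name]
        if par is None:
            ok = x != MISSING
            xi = x[ok]
            scores[ok] += np.log(cpt[xi, CASE]) - np.log(cpt[xi, CONTROL])
        else:
            xp = data.column(par)
            ok = (x != MISSING) & (xp != MISSING)
            xi, bi = x[ok], xp[ok]
            scores[ok] += np.log(cpt[xi, bi, CASE]) - np.log(cpt[xi, bi, CONTROL])
    if use_prior:
        scores += math.log(tree.class_prior[CASE]) - math.log(
            tree.class_prior[CONTROL]
        )
    return scores


def predict(tree: DependenceTree, data: DiscreteData, use_prior: bool = False):
    """Predicted labels: case iff score > 0 (ties go to control)."""
    return (score_samples(tree, data, use_prior=use_prior) > 0).astype(np.int8)


def log_likelihood(tree: DependenceTree, data: DiscreteData) -> float:
    """Training log-likelihood of the full joint (class included)."""
    ll = 0.0
    prior = tree.class_prior
    for name in tree.nodes:
        x = data.column(name)
        par = tree.parent[name]
        cpt = tree.cpts[name]
        if par is None:
            ok = x != MISSING
            ll += float(np.log(cpt[x[ok], data.y[ok]]).sum())
        else:
            xp = data.column(par)
            ok = (x != MISSING) & (xp != MISSING)
            ll += float(np.log(cpt[x[ok], xp[ok], data.y[ok]]).sum())
    ll += float(np.log(prior[data.y]).sum())
    return ll


# ---------------------------------------------------------------------------
# AUC evaluation
# ---------------------------------------------------------------------------

def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve, Mann-Whitney form with mid-rank ties."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present to compute AUC")
    from sklearn.metrics import roc_auc_score

    return float(roc_auc_score(labels, scores))


def auc_resub(data: DiscreteData, tree: DependenceTree, use_prior: bool = False) -> float:
    """Resubstitution AUC: score the training samples with their own tree."""
    return auc(score_samples(tree, data, use_prior=use_prior), data.y)


def auc_cv(
    data: DiscreteData,
    k: int = 3,
    seed: int = 0,
    alpha: float = 1.0,
    use_prior: bool = False,
) -> float:
    """Stratified k-fold cross-validated AUC (default 3-fold).

    Tree structure and CPTs are refit on each training fold; out-of-fold
    scores are pooled into a single AUC.  Deterministic given ``seed``.
    """
    if k < 2:
        return auc_resub(data, fit_mwdt(data, alpha=alpha), use_prior=use_prior)
    from sklearn.model_selection import StratifiedKFold

    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    scores = np.zeros(data.n)
    for train_idx, test_idx in skf.split(data.X, data.y):
        tree = fit_mwdt(data.rows(train_idx), alpha=alpha)
        scores[test_idx] = score_samples(tree, data.rows(test_idx), use_prior=use_prior)
    return auc(scores, data.y)
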