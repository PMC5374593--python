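"""Independent brute-force oracles used to validate the implementation.

Everything here is deliberately written from first principles (exact
fractions, explicit enumeration, pair counting) and never calls the code
paths it checks.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction

import numpy as np


def hwe_exact_enumeration(n_hom_major: int, n_het: int, n_hom_minor: int) -> Fraction:
    """Exact two-sided HWE p-value as a rational number.

    Enumerates every heterozygote count compatible with the observed
    allele counts, computes each table's conditional probability with
    exact integer arithmetic, and sums those <= the observed table's.
    """
    n = n_hom_major + n_het + n_hom_minor
    na = 2 * n_hom_minor + n_het  # minor allele count
    na = min(na, 2 * n - na)

    def table_weight(h: int) -> int:
        # multinomial weight x 2^h; common normalizer cancels
        n_minor_hom = (na - h) // 2
        n_major_hom = n - h - n_minor_hom
        return (
            2**h
            * math.factorial(n)
            // (
                math.factorial(h)
                * math.factorial(n_minor_hom)
                * math.factorial(n_major_hom)
            )
        )

    hets = range(na % 2, na + 1, 2)
    weights = {h: table_weight(h) for h in hets}
    total = sum(weights.values())
    obs = weights[n_het]
    return Fraction(sum(w for w in weights.values() if w <= obs), total)


def cmi_direct(counts) -> float:
    """Direct evaluation of the plug-in conditional MI from a count cube."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    out = 0.0
    for c in range(counts.shape[0]):
        ncls = counts[c].sum()
        if ncls == 0:
            continue
        for a in range(counts.shape[1]):
            for b in range(counts.shape[2]):
                n_ab = counts[c, a, b]
                if n_ab == 0:
                    continue
                p_ab = n_ab / ncls
                p_a = counts[c, a, :].sum() / ncls
                p_b = counts[c, :, b].sum() / ncls
                out += (ncls / total) * p_ab * math.log(p_ab / (p_a * p_b))
    return out


def all_labeled_trees(n: int):
    """Every labeled spanning tree on n nodes, via Prufer sequences."""
    if n == 1:
        yield []
        return
    if n == 2:
        yield [(0, 1)]
        return
    for prufer in itertools.product(range(n), repeat=n - 2):
        degree = [1] * n
        for v in prufer:
            degree[v] += 1
        edges = []
        avail = sorted(i for i in range(n) if degree[i] == 1)
        deg = list(degree)
        for v in prufer:
            leaf = avail.pop(0)
            edges.append((leaf, v))
            deg[v] -= 1
            if deg[v] == 1:
                import bisect

                bisect.insort(avail, v)
        edges.append((avail[0], avail[1]))
        yield edges


def max_tree_weight_exhaustive(W: np.ndarray) -> float:
    """Maximum spanning-tree weight by exhaustive enumeration."""
    n = W.shape[0]
    return max(
        sum(W[a, b] for a, b in edges) for edges in all_labeled_trees(n)
    )


def auc_pair_counting(scores, labels) -> float:
    """AUC as the fraction of concordant case/control pairs (ties = 1/2)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for s_p in pos:
        for s_n in neg:
            if s_p > s_n:
                wins += 1.0
            elif s_p == s_n:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def trend_z_hypergeometric(table, scores=(0, 1, 2)) -> float:
    """Trend z-score via the explicit multivariate hypergeometric moments.

    Row 1 of the table is treated as a simple random sample (size r1,
    without replacement) of the column categories; the mean vector and
    covariance matrix of its category counts are written out explicitly
    and the score sum is standardized against them.
    """
    t = np.asarray(table, dtype=float)
    s = np.asarray(scores, dtype=float)
    col = t.sum(axis=0)
    n = col.sum()
    r1 = t[0].sum()
    mean = r1 * col / n
    k = len(col)
    cov = np.empty((k, k))
    f = r1 * (n - r1) / (n - 1)
    for i in range(k):
        for j in range(k):
            if i == j:
                cov[i, j] = f * (col[i] / n) * (1 - col[i] / n)
            else:
                cov[i, j] = -f * col[i] * col[j] / (n * n)
    u = s @ (t[0] - mean)
    var = s @ cov @ s
    return float(u / math.sqrt(var))


def tree_loglik_direct(edges, root, X, y, k=3) -> float:
    """Training log-likelihood of a directed tree at the MLE (alpha = 0).

    ``edges`` are (child, parent) column-index pairs covering all non-root
    columns.  Complete data assumed.  The class prior term is included.
    """
    n = len(y)
    ll = 0.0
    for cls in (0, 1):
        n_c = int((y == cls).sum())
        ll += n_c * math.log(n_c / n)
        rows = X[y == cls]
        rc = np.bincount(rows[:, root], minlength=k)
        for cnt in rc:
            if cnt:
                ll += cnt * math.log(cnt / n_c)
        for child, parent in edges:
            joint = np.zeros((k, k))
            for a, b in zip(rows[:, child], rows[:, parent]):
                joint[a, b] += 1
            pmarg = joint.sum(axis=0)
            for a in range(k):
                for b in range(k):
                    if joint[a, b]:
                        ll += joint[a, b] * math.log(joint[a, b] / pmarg[b])
    return ll
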