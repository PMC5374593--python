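"""Constructing the final SNP x SNP x environment network.

Two strategies are run and compared by cross-validated AUC: (1) backward
iterative elimination, which starts from all association candidates plus
every demographic variable and repeatedly drops the 50 SNPs with the
largest CMH p-values; (2) the same elimination applied to LD tag SNPs
obtained by greedy Carlson-style binning at r^2 >= 0.4.  The network with
the higher AUC wins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import MISSING, Dataset, DiscreteData
from .tree import DependenceTree, auc_cv, fit_mwdt


# ---------------------------------------------------------------------------
# Linkage disequilibrium
# ---------------------------------------------------------------------------

def ld_r2(geno_i: np.ndarray, geno_j: np.ndarray) -> float:
    """Composite LD: squared Pearson correlation of minor-allele dosages.

    Computed on pairwise-complete samples; a SNP monomorphic on the
    complete pairs gives r^2 = 0 with a warning.
    """
    gi = np.asarray(geno_i)
    gj = np.asarray(geno_j)
    ok = (gi != MISSING) & (gj != MISSING)
    if ok.sum() < 2:
        raise ValueError("need at least 2 complete pairs for r^2")
    a, b = gi[ok].astype(float), gj[ok].astype(float)
    if a.std() == 0 or b.std() == 0:
        warnings.warn("monomorphic SNP on complete pairs: r^2 set to 0", stacklevel=2)
        return 0.0
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def ld_r2_matrix(G: np.ndarray) -> np.ndarray:
    """Pairwise r^2 for the columns of a genotype matrix."""
    n, p = G.shape
    if not (G == MISSING).any():
        sd = G.std(axis=0)
        poly = sd > 0
        R = np.zeros((p, p))
        if poly.sum() >= 2:
            C = np.corrcoef(G[:, poly].astype(float), rowvar=False)
            R[np.ix_(poly, poly)] = C * C
        R[np.arange(p), np.arange(p)] = 1.0
        return R
    R = np.eye(p)
    for i in range(p):
        for j in range(i + 1, p):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                R[i, j] = R[j, i] = ld_r2(G[:, i], G[:, j])
    return R


@dataclass
class LDBinSet:
    """A partition of SNPs into LD bins, each represented by one tag."""

    bins: list[list[str]]
    tags: list[str]
    r2_threshold: float

    def __post_init__(self) -> None:
        flat = [s for b in self.bins for s in b]
        if len(flat) != len(set(flat)):
            raise ValueError("LD bins are not disjoint")
        for tag, members in zip(self.tags, self.bins):
            if tag not in members:
                raise ValueError(f"tag {tag} not in its bin")

    @property
    def snp_to_tag(self) -> dict[str, str]:
        return {s: t for t, b in zip(self.tags, self.bins) for s in b}


def bin_and_tag(
    ds: Dataset,
    snp_ids: list[str],
    r2_threshold: float = 0.4,
    p_values: dict[str, float] | None = None,
) -> LDBinSet:
    """Greedy Carlson-style LD binning with one tag SNP per bin.

    Within each chromosome (cross-chromosome r^2 is defined as 0), the SNP
    with the most unbinned partners at r^2 >= threshold is binned with
    those partners; the tag is the bin member with r^2 >= threshold to all
    other members, ties broken by smallest CMH p-value then by id order.
    Singleton SNPs become their own tags.
    """
    p_values = p_values or {}
    order = {s: i for i, s in enumerate(snp_ids)}

    def prio(s):
        return (p_values.get(s, 1.0), order[s])

    bins: list[list[str]] = []
    tags: list[str] = []
    by_chrom: dict[str, list[str]] = {}
    for s in snp_ids:
        by_chrom.setdefault(ds.snps[ds.snp_index(s)].chromosome, []).append(s)

    for chrom_snps in by_chrom.values():
        idx = [ds.snp_index(s) for s in chrom_snps]
        R = ld_r2_matrix(ds.genotypes[:, idx])
        linked = R >= r2_threshold
        np.fill_diagonal(linked, False)
        unbinned = set(range(len(chrom_snps)))
        while unbinned:
            counts = {
                i: sum(1 for j in unbinned if j != i and linked[i, j])
                for i in unbinned
            }
            best = min(
                unbinned, key=lambda i: (-counts[i], prio(chrom_snps[i]))
            )
            members = [best] + sorted(j for j in unbinned if linked[best, j])
            unbinned -= set(members)
            member_names = [chrom_snps[i] for i in sorted(members)]
            eligible = [
                i
                for i in members
                if all(linked[i, j] for j in members if j != i)
            ]
            tag_i = min(eligible, key=lambda i: prio(chrom_snps[i]))
            bins.append(member_names)
            tags.append(chrom_snps[tag_i])
    return LDBinSet(bins=bins, tags=tags, r2_threshold=r2_threshold)


# ---------------------------------------------------------------------------
# Backward search
# ---------------------------------------------------------------------------

@dataclass
class SearchTrace:
    """Per-iteration record of the backward elimination."""

    approach: str
    records: list[dict] = field(default_factory=list)

    def append(self, n_snps: int, cv_auc: float, removed: list[str]) -> None:
        self.records.append(
            {"n_snps": n_snps, "cv_auc": cv_auc, "removed": list(removed)}
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "iteration": range(len(self.records)),
                "n_snps": [r["n_snps"] for r in self.records],
                "cv_auc": [r["cv_auc"] for r in self.records],
                "removed": [",".join(r["removed"]) for r in self.records],
            }
        )


def backward_search(
    ds: Dataset,
    candidates: list[str],
    cmh_p: dict[str, float],
    demographics: list[str] | None = None,
    step: int = 50,
    k_folds: int = 3,
    seed: int = 0,
    alpha: float = 1.0,
    n_bins: int = 4,
    approach: str = "backward",
) -> tuple[DependenceTree, SearchTrace, float]:
    """Backward iterative elimination over CMH-ranked candidate SNPs.

    Iteration 0 evaluates all candidates plus every demographic variable;
    each later iteration removes the ``step`` SNPs with the largest CMH
    p-values and re-evaluates.  Elimination stops once at most ``step``
    SNPs remain (that final network is still evaluated).  The best network
    is the one with the highest cross-validated AUC, ties going to the
    smaller SNP set; its tree is refit on the full data.  Demographic
    variables are never removed.
    """
    if not candidates:
        raise ValueError("candidate list is empty")
    if demographics is None:
        demographics = ds.samples.schema.variables
    # worst-first removal order: largest p last in the kept list
    current = sorted(candidates, key=lambda s: (cmh_p.get(s, 1.0), s))
    trace = SearchTrace(approach=approach)
    evaluated: list[tuple[float, int, list[str]]] = []
    removed_prev: list[str] = []
    while True:
        data = DiscreteData.from_dataset(
            ds, snp_ids=current, demographics=demographics, n_bins=n_bins
        )
        cv = auc_cv(data, k=k_folds, seed=seed, alpha=alpha)
        trace.append(len(current), cv, removed_prev)
        evaluated.append((cv, len(current), list(current)))
        if len(current) <= step:
            break
        removed_prev = current[-step:]
        current = current[:-step]

    best = max(evaluated, key=lambda t: (t[0], -t[1]))
    best_snps = best[2]
    data = DiscreteData.from_dataset(
        ds, snp_ids=best_snps, demographics=demographics, n_bins=n_bins
    )
    tree = fit_mwdt(data, alpha=alpha)
    return tree, trace, best[0]


def build_final_network(
    ds: Dataset,
    assoc_table: pd.DataFrame,
    candidates: list[str],
    demographics: list[str] | None = None,
    step: int = 50,
    r2_threshold: float = 0.4,
    k_folds: int = 3,
    seed: int = 0,
    alpha: float = 1.0,
    n_bins: int = 4,
):
    """Run both search strategies and keep the higher-AUC network.

    Strategy A is backward elimination on the raw candidates; strategy B
    first collapses the candidates to LD tag SNPs (Carlson binning at the
    given r^2 threshold, tag choice prioritized by CMH p-value) and then
    runs the same elimination.  Ties are broken toward the network with
    fewer SNPs, then toward the plain backward strategy.  Returns
    ``(tree, traces, summary)``.
    """
    cmh_p = dict(zip(assoc_table["SNP"], assoc_table["P"]))
    tree_a, trace_a, auc_a = backward_search(
        ds, candidates, cmh_p, demographics, step, k_folds, seed, alpha, n_bins,
        approach="backward",
    )
    binset = bin_and_tag(ds, candidates, r2_threshold, cmh_p)
    tree_b, trace_b, auc_b = backward_search(
        ds, binset.tags, cmh_p, demographics, step, k_folds, seed, alpha, n_bins,
        approach="ld+backward",
    )

    def n_snps(tree):
        demo = set(demographics or ds.samples.schema.variables)
        return sum(1 for n in tree.nodes if n not in demo)

    key_a = (auc_a, -n_snps(tree_a), 1)  # final entry prefers backward on ties
    key_b = (auc_b, -n_snps(tree_b), 0)
    winner, tree = ("backward", tree_a) if key_a >= key_b else ("ld+backward", tree_b)
    summary = {
        "winner": winner,
        "auc_backward": auc_a,
        "auc_ld_backward": auc_b,
        "n_tags": len(binset.tags),
    }
    return tree, {"backward": trace_a, "ld+backward": trace_b}, summary
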