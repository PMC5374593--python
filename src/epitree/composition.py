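"""Ranking genes, pathways, demographic factors, and edges of the network.

Gene- and pathway-level importance is the cross-validated AUC of a fresh
sub-network built from the item's SNPs plus race and sex (the always-
included adjustment covariates).  Demographic-factor and edge importance
is the decline in resubstitution AUC when the factor (with all incident
edges) or the edge is removed from the full network.  Every observed AUC
or decline is compared against a permutation null of random same-size
sub-networks drawn from the background SNP set, giving a non-adjusted
p-value (r + 1) / (B + 1).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import Dataset, DiscreteData
from .io import INTERGENIC
from .tree import (
    DependenceTree,
    auc_cv,
    auc_resub,
    fit_cpts,
    fit_mwdt,
    _root_cpt,
)

log = logging.getLogger(__name__)


@dataclass
class AnnotationMaps:
    """SNP -> gene labels plus gene -> pathway sets (GMT)."""

    snp_to_gene: dict[str, str]
    pathways: dict[str, set[str]] = field(default_factory=dict)

    def gene_of(self, snp_id: str) -> str:
        gene = self.snp_to_gene.get(snp_id)
        if gene is None:
            warnings.warn(
                f"SNP {snp_id} has no annotation; assigned {INTERGENIC}",
                stacklevel=2,
            )
            return INTERGENIC
        return gene

    def genes_to_snps(self, snp_ids: list[str]) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for s in snp_ids:
            out.setdefault(self.gene_of(s), []).append(s)
        return out


@dataclass
class RankingReport:
    """Four ranked tables: genes, demographics, pathways, edges."""

    genes: pd.DataFrame
    demographics: pd.DataFrame
    pathways: pd.DataFrame
    edges: pd.DataFrame

    def write(self, prefix) -> None:
        for name in ("genes", "demographics", "pathways", "edges"):
            getattr(self, name).to_csv(f"{prefix}{name}.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# Sub-network AUCs
# ---------------------------------------------------------------------------

def subnetwork_auc(
    ds: Dataset,
    snp_subset: list[str],
    always_include: tuple[str, ...] = ("race", "sex"),
    k_folds: int = 3,
    seed: int = 0,
    alpha: float = 1.0,
    n_bins: int = 4,
) -> float:
    """CV AUC of a fresh dependence tree on a SNP subset plus race/sex."""
    if not snp_subset:
        raise ValueError("empty SNP subset")
    data = DiscreteData.from_dataset(
        ds, snp_ids=list(snp_subset), demographics=list(always_include), n_bins=n_bins
    )
    return auc_cv(data, k=k_folds, seed=seed, alpha=alpha)


# ---------------------------------------------------------------------------
# Node / edge removal
# ---------------------------------------------------------------------------

def _remove_node(tree: DependenceTree, data: DiscreteData, factor: str):
    """Drop a node and its incident edges; orphans hang off the class node."""
    if factor not in tree.nodes:
        raise KeyError(f"factor {factor!r} is not a node of the network")
    out = tree.copy()
    out.nodes.remove(factor)
    del out.parent[factor]
    del out.ks[factor]
    out.cpts.pop(factor, None)
    out.edge_weights = {
        e: w for e, w in out.edge_weights.items() if factor not in e
    }
    for child in list(out.parent):
        if out.parent[child] == factor:
            out.parent[child] = None
            out.cpts[child] = _root_cpt(
                data.column(child), data.y, out.ks[child], out.alpha
            )
    return out


def _remove_edge(tree: DependenceTree, data: DiscreteData, edge: tuple[str, str]):
    """Drop one edge; the former child becomes conditioned on C only."""
    child, parent = edge
    if tree.parent.get(child) != parent:
        if tree.parent.get(parent) == child:  # accept either orientation
            child, parent = parent, child
        else:
            raise KeyError(f"edge {edge!r} is not in the network")
    out = tree.copy()
    out.parent[child] = None
    out.edge_weights.pop((child, parent), None)
    out.cpts[child] = _root_cpt(data.column(child), data.y, out.ks[child], out.alpha)
    return out


def factor_decline(
    tree: DependenceTree, data: DiscreteData, factor: str
) -> float:
    """Decline in resubstitution AUC when a factor node is removed.

    The node and all edges touching it are deleted; orphaned children are
    re-attached to the class node alone (their CPTs refit as P(X | C)).
    The decline AUC_full - AUC_reduced can be negative.
    """
    full = auc_resub(data, tree)
    reduced_data = data.select([n for n in data.names if n != factor])
    reduced = _remove_node(tree, data, factor)
    return full - auc_resub(reduced_data, reduced)


def edge_decline(
    tree: DependenceTree, data: DiscreteData, edge: tuple[str, str]
) -> float:
    """Decline in resubstitution AUC when one interaction edge is removed."""
    full = auc_resub(data, tree)
    reduced = _remove_edge(tree, data, edge)
    return full - auc_resub(data, reduced)


# ---------------------------------------------------------------------------
# Permutation nulls
# ---------------------------------------------------------------------------

def _perm_pvalue(null: np.ndarray, observed: float) -> float:
    return float((np.sum(null >= observed) + 1) / (len(null) + 1))


def null_auc_distribution(
    ds: Dataset,
    n_snps: int,
    background_snps: list[str],
    B: int = 1000,
    seed: int = 0,
    always_include: tuple[str, ...] = ("race", "sex"),
    k_folds: int = 3,
    alpha: float = 1.0,
    n_bins: int = 4,
) -> np.ndarray:
    """AUCs of B random same-size sub-networks (plus race and sex)."""
    if len(background_snps) < n_snps:
        raise ValueError("background smaller than the requested sub-network")
    rng = np.random.default_rng(seed)
    out = np.empty(B)
    for b in range(B):
        subset = list(rng.choice(background_snps, size=n_snps, replace=False))
        out[b] = subnetwork_auc(
            ds, subset, always_include, k_folds, seed, alpha, n_bins
        )
    return out


def null_auc_pvalue(
    observed_auc: float,
    n_snps: int,
    background_snps: list[str],
    ds: Dataset,
    B: int = 1000,
    seed: int = 0,
    **kwargs,
) -> float:
    """p = (#{null AUC >= observed} + 1) / (B + 1); never zero."""
    null = null_auc_distribution(ds, n_snps, background_snps, B, seed, **kwargs)
    return _perm_pvalue(null, observed_auc)


def null_decline_distribution(
    ds: Dataset,
    n_snps: int,
    background_snps: list[str],
    mode: str = "random_snp",
    demographics: list[str] | None = None,
    B: int = 1000,
    seed: int = 0,
    alpha: float = 1.0,
    n_bins: int = 4,
) -> np.ndarray:
    """Declines in resubstitution AUC over B random full-size networks.

    Each replicate draws a random SNP set of the full network's size, keeps
    the full demographic set, fits a tree, and removes one random SNP node
    (``random_snp``) or one random edge (``random_edge``).
    """
    if mode not in ("random_snp", "random_edge"):
        raise ValueError(f"unknown mode {mode!r}")
    if len(background_snps) < n_snps:
        raise ValueError("background smaller than the network SNP count")
    if demographics is None:
        demographics = ds.samples.schema.variables
    rng = np.random.default_rng(seed)
    out = np.empty(B)
    for b in range(B):
        subset = list(rng.choice(background_snps, size=n_snps, replace=False))
        data = DiscreteData.from_dataset(
            ds, snp_ids=subset, demographics=demographics, n_bins=n_bins
        )
        tree = fit_mwdt(data, alpha=alpha)
        if mode == "random_snp":
            victim = subset[int(rng.integers(len(subset)))]
            out[b] = factor_decline(tree, data, victim)
        else:
            edges = tree.edges()
            victim_edge = edges[int(rng.integers(len(edges)))]
            out[b] = edge_decline(tree, data, victim_edge)
    return out


def null_decline_pvalue(
    observed_decline: float,
    mode: str,
    ds: Dataset,
    n_snps: int,
    background_snps: list[str],
    B: int = 1000,
    seed: int = 0,
    **kwargs,
) -> float:
    null = null_decline_distribution(
        ds, n_snps, background_snps, mode, B=B, seed=seed, **kwargs
    )
    return _perm_pvalue(null, observed_decline)


# ---------------------------------------------------------------------------
# Full composition report
# ---------------------------------------------------------------------------

def compose_report(
    tree: DependenceTree,
    ds: Dataset,
    maps: AnnotationMaps,
    background_snps: list[str],
    demographics: list[str] | None = None,
    B: int = 1000,
    seed: int = 0,
    k_folds: int = 3,
    alpha: float = 1.0,
    n_bins: int = 4,
    always_include: tuple[str, ...] = ("race", "sex"),
    sig_level: float = 0.05,
) -> RankingReport:
    """Rank every gene, demographic factor, pathway, and edge of a network.

    Gene/pathway items get a CV sub-network AUC and a p-value against
    random same-size sub-networks; demographic factors and edges get a
    resubstitution-AUC decline and a p-value against declines from random
    SNP (or edge) removals.  Null distributions depend on the item only
    through its size, so they are cached per distinct size.  Significance
    flags use the non-adjusted ``sig_level`` threshold.
    """
    if demographics is None:
        demographics = ds.samples.schema.variables
    demo_set = set(demographics)
    network_snps = [n for n in tree.nodes if n not in demo_set]
    data = DiscreteData.from_dataset(
        ds, snp_ids=network_snps, demographics=demographics, n_bins=n_bins
    )

    null_cache: dict[int, np.ndarray] = {}

    def auc_null(size: int) -> np.ndarray:
        if size not in null_cache:
            null_cache[size] = null_auc_distribution(
                ds, size, background_snps, B, seed,
                always_include=always_include, k_folds=k_folds,
                alpha=alpha, n_bins=n_bins,
            )
        return null_cache[size]

    # ---- genes (the Intergenic set is one item) ----
    gene_rows = []
    for gene, snps in sorted(maps.genes_to_snps(network_snps).items()):
        observed = subnetwork_auc(
            ds, snps, always_include, k_folds, seed, alpha, n_bins
        )
        p = _perm_pvalue(auc_null(len(snps)), observed)
        gene_rows.append(
            {"item": gene, "n_snps": len(snps), "auc": observed, "p_value": p}
        )
    genes = pd.DataFrame(
        gene_rows, columns=["item", "n_snps", "auc", "p_value"]
    ).sort_values(["p_value", "item"], kind="mergesort", ignore_index=True)

    # ---- pathways ----
    path_rows = []
    gene_map = maps.genes_to_snps(network_snps)
    for pw, genes_in_pw in sorted(maps.pathways.items()):
        snps = sorted(
            {s for g in genes_in_pw for s in gene_map.get(g, [])}
        )
        if not snps:
            log.warning("pathway %s has no SNPs in the network; skipped", pw)
            continue
        observed = subnetwork_auc(
            ds, snps, always_include, k_folds, seed, alpha, n_bins
        )
        p = _perm_pvalue(auc_null(len(snps)), observed)
        path_rows.append(
            {"item": pw, "n_snps": len(snps), "auc": observed, "p_value": p}
        )
    pathways = pd.DataFrame(
        path_rows, columns=["item", "n_snps", "auc", "p_value"]
    ).sort_values(["p_value", "item"], kind="mergesort", ignore_index=True)

    # ---- demographic factors (decline nulls shared: same network size) ----
    snp_null = null_decline_distribution(
        ds, len(network_snps), background_snps, "random_snp",
        demographics, B, seed, alpha, n_bins,
    ) if network_snps else np.array([])
    demo_rows = []
    for factor in demographics:
        if factor not in tree.nodes:
            continue
        d = factor_decline(tree, data, factor)
        p = _perm_pvalue(snp_null, d) if len(snp_null) else 1.0
        demo_rows.append({"item": factor, "auc_decline": d, "p_value": p})
    demo = pd.DataFrame(
        demo_rows, columns=["item", "auc_decline", "p_value"]
    ).sort_values(["p_value", "item"], kind="mergesort", ignore_index=True)

    # ---- edges ----
    edge_null = null_decline_distribution(
        ds, len(network_snps), background_snps, "random_edge",
        demographics, B, seed, alpha, n_bins,
    ) if network_snps else np.array([])
    edge_rows = []
    for child, parent in tree.edges():
        d = edge_decline(tree, data, (child, parent))
        p = _perm_pvalue(edge_null, d) if len(edge_null) else 1.0
        edge_rows.append(
            {"child": child, "parent": parent, "auc_decline": d, "p_value": p}
        )
    edges = pd.DataFrame(
        edge_rows, columns=["child", "parent", "auc_decline", "p_value"]
    ).sort_values(
        ["p_value", "child", "parent"], kind="mergesort", ignore_index=True
    )

    for frame in (genes, demo, pathways, edges):
        frame["significant"] = frame["p_value"] < sig_level
    return RankingReport(genes=genes, demographics=demo, pathways=pathways, edges=edges)
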