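"""Synthetic case-control genotype data with known ground truth.

The generator emulates the structure of a GWAS cohort like the one this
framework targets: a 30%/70% two-race mixture with race-offset allele
frequencies (population stratification), fifteen demographic variables
with the level structure of a typical interview battery (income,
education, childhood environment, trauma history, anthropometrics),
LD blocks, uniform missingness, and a planted class-conditional
dependence tree among a subset of SNPs.  Samples are drawn class-first,
then variables by ancestral sampling along the planted tree with
class-specific CPTs, which matches the factorization the estimator
assumes, so tree recovery is consistent as n grows.

Marker blocks, in column order:
  * ``n_tree`` SNPs wired into a planted dependence tree (epistasis);
  * ``n_causal`` contiguous strongly associated SNPs (the causal gene);
  * ``n_background`` weakly associated SNPs (polygenic background);
  * LD blocks: founder SNPs copied with flip noise;
  * the remainder: independent null SNPs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import (
    MISSING,
    Dataset,
    SampleTable,
    SNPRecord,
    VariableSchema,
)
from .composition import AnnotationMaps
from .io import INTERGENIC


@dataclass
class DemographicSpec:
    """One demographic variable: declared levels or a continuous range.

    ``class_effect`` is the total-variation shift of the case distribution
    relative to controls (categorical) or the mean shift in units of one
    SD (continuous); negative values tilt cases toward lower levels.
    """

    name: str
    levels: list[str] | None = None
    range: tuple[float, float] | None = None
    class_effect: float = 0.0

    @property
    def is_continuous(self) -> bool:
        return self.levels is None


def default_demographics() -> list[DemographicSpec]:
    """Fifteen interview-style variables (race handled separately)."""
    yn = ["no", "yes"]
    return [
        DemographicSpec("income", levels=[f"L{i}" for i in range(1, 10)],
                        class_effect=-0.15),
        DemographicSpec("childhood_home",
                        levels=["large_city", "suburbs", "small_city",
                                "village", "rural"]),
        DemographicSpec("education",
                        levels=["lt_hs", "hs_grad", "some_college",
                                "college_grad"], class_effect=-0.15),
        DemographicSpec("sex", levels=["F", "M"], class_effect=0.10),
        DemographicSpec("age", range=(18, 77)),
        DemographicSpec("race", levels=["AA", "EA"]),  # filled by generator
        DemographicSpec("sexually_abused", levels=yn, class_effect=0.05),
        DemographicSpec("physically_abused", levels=yn, class_effect=0.05),
        DemographicSpec("neglected", levels=yn),
        DemographicSpec("sexual_trauma", levels=yn),
        DemographicSpec("physical_trauma", levels=yn),
        DemographicSpec("nonphysical_trauma", levels=yn),
        DemographicSpec("weight", range=(85, 435)),
        DemographicSpec("religious_attendance", range=(0, 500)),
        DemographicSpec("height", range=(49, 80)),
    ]


@dataclass
class SimulationSpec:
    """Everything needed to draw one synthetic cohort.

    Effect sizes are total-variation distances in [0, 1]; the seed is
    mandatory.  Defaults are desk-scale but keep the cohort structure:
    equal-ish case/control arms, 0.3/0.7 race mixture, race-offset allele
    frequencies, 15 demographics, LD blocks, 1% missingness.
    """

    seed: int
    n_cases: int = 500
    n_controls: int = 500
    n_snps: int = 200
    # planted dependence tree
    n_tree: int = 20
    planted_edges: list[tuple[int, int]] | str = "random"
    dependence_noise: float = 0.25  # child copies parent w.p. 1 - noise
    edge_effect: float = 0.15  # TV distance between class CPTs per edge
    # direct class effects
    n_causal: int = 3
    causal_delta: float = 0.25  # case-control allele frequency difference
    n_background: int = 12
    background_delta: float = 0.12
    # stratification
    race_mix: float = 0.30  # P(AA)
    race_class_effect: float = 0.08
    race_offset_sd: float = 0.08
    # LD
    n_ld_blocks: int = 5
    ld_block_size: int = 3  # founder + (size-1) copies; 1 disables
    ld_flip_prob: float = 0.05
    # misc
    maf_range: tuple[float, float] = (0.1, 0.5)
    missing_rate: float = 0.01
    demographics: list[DemographicSpec] = field(default_factory=default_demographics)
    n_chromosomes: int = 10

    def validate(self) -> None:
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("need at least one sample per class")
        if not (0 <= self.edge_effect <= 1 and 0 <= self.dependence_noise <= 1):
            raise ValueError("effect sizes must be in [0, 1]")
        if not 0 < self.race_mix < 1:
            raise ValueError("race_mix must be in (0, 1)")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        lo, hi = self.maf_range
        if not 0 < lo <= hi < 1:
            raise ValueError("invalid maf_range")
        names = [d.name for d in self.demographics]
        if len(set(names)) != len(names):
            raise ValueError("duplicate demographic names")
        ld_cols = self.n_ld_blocks * self.ld_block_size if self.ld_block_size > 1 else 0
        used = self.n_tree + self.n_causal + self.n_background + ld_cols
        if used > self.n_snps:
            raise ValueError(
                f"marker blocks need {used} SNPs but n_snps = {self.n_snps}"
            )

    def planted_tree(self, rng: np.random.Generator) -> list[tuple[int, int]]:
        if self.planted_edges != "random":
            return [tuple(e) for e in self.planted_edges]
        # random labeled tree via a Prufer sequence
        m = self.n_tree
        if m < 2:
            return []
        if m == 2:
            return [(0, 1)]
        prufer = rng.integers(0, m, size=m - 2)
        degree = np.ones(m, dtype=int)
        for v in prufer:
            degree[v] += 1
        edges = []
        leaves = sorted(i for i in range(m) if degree[i] == 1)
        for v in prufer:
            leaf = leaves.pop(0)
            edges.append((leaf, int(v)))
            degree[v] -= 1
            if degree[v] == 1:
                import bisect

                bisect.insort(leaves, int(v))
        edges.append((leaves[0], leaves[1]))
        return edges


def _hwe_probs(p: np.ndarray) -> np.ndarray:
    """Genotype distribution under HWE for minor-allele frequency p."""
    return np.stack([(1 - p) ** 2, 2 * p * (1 - p), p * p], axis=-1)


def _sample_genotypes(rng, p: np.ndarray) -> np.ndarray:
    """Per-sample HWE genotypes for per-sample allele frequencies."""
    return rng.binomial(2, p).astype(np.int8)


def _tilted(base: np.ndarray, effect: float) -> np.ndarray:
    """Shift a categorical distribution by total-variation ``effect``.

    Positive effects move mass toward higher levels, negative toward
    lower; the result is clipped and renormalized.
    """
    k = len(base)
    if k < 2 or effect == 0:
        return base.copy()
    t = np.arange(k) - (k - 1) / 2
    t = t / (np.abs(t).sum() / 2)
    out = np.clip(base + effect * t, 1e-9, None)
    return out / out.sum()


def simulate_dataset(spec: SimulationSpec) -> tuple[Dataset, dict]:
    """Draw one cohort; returns (Dataset, ground_truth).

    Ground truth records the planted tree edges (as SNP ids), the causal
    and background SNP ids, LD block membership, and the demographic
    class effects.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_cases + spec.n_controls
    y = np.concatenate(
        [np.zeros(spec.n_controls, dtype=np.int8), np.ones(spec.n_cases, dtype=np.int8)]
    )

    # ---- race (stratification variable) ----
    p_aa = np.where(
        y == 1,
        np.clip(spec.race_mix + spec.race_class_effect / 2, 0.01, 0.99),
        np.clip(spec.race_mix - spec.race_class_effect / 2, 0.01, 0.99),
    )
    race = (rng.random(n) >= p_aa).astype(np.int16)  # 0 = AA, 1 = EA

    # ---- demographics ----
    demo_cols = {}
    for d in spec.demographics:
        if d.name == "race":
            demo_cols[d.name] = race.copy()
            continue
        if d.is_continuous:
            lo, hi = d.range
            mu, sd = (lo + hi) / 2, (hi - lo) / 6
            vals = rng.normal(mu + np.where(y == 1, d.class_effect * sd, 0.0), sd)
            demo_cols[d.name] = np.clip(vals, lo, hi)
        else:
            k = len(d.levels)
            base = np.full(k, 1.0 / k)
            dists = [base, _tilted(base, d.class_effect)]
            codes = np.empty(n, dtype=np.int16)
            for cls in (0, 1):
                mask = y == cls
                codes[mask] = rng.choice(k, size=int(mask.sum()), p=dists[cls])
            demo_cols[d.name] = codes

    # ---- SNP layout ----
    G = np.empty((n, spec.n_snps), dtype=np.int8)
    base_freq = rng.uniform(*spec.maf_range, size=spec.n_snps)
    race_offset = rng.normal(0, spec.race_offset_sd, size=spec.n_snps)

    def sample_freq(j, delta_case: float = 0.0) -> np.ndarray:
        """Per-sample allele frequency with race offset and class shift."""
        p = base_freq[j] + np.where(race == 0, race_offset[j], 0.0)
        p = p + np.where(y == 1, delta_case, 0.0)
        return np.clip(p, 0.02, 0.98)

    col = 0
    # planted tree block
    tree_idx = list(range(col, col + spec.n_tree))
    col += spec.n_tree
    edges = spec.planted_tree(rng)
    if spec.n_tree:
        children = {c for c, _ in edges} | {p for _, p in edges}
        parent_of: dict[int, int] = {}
        adj: dict[int, list[int]] = {i: [] for i in range(spec.n_tree)}
        for a, b in edges:
            adj[a].append(b)
            adj[b].append(a)
        order = []
        visited = set()
        for start in range(spec.n_tree):
            if start in visited:
                continue
            stack = [start]
            visited.add(start)
            while stack:
                u = stack.pop()
                order.append(u)
                for v in adj[u]:
                    if v not in visited:
                        visited.add(v)
                        parent_of[v] = u
                        stack.append(v)
        # a tree component shares its founder's allele frequency so that
        # copy-with-noise children stay in Hardy-Weinberg proportions
        for u in order:
            if u in parent_of:
                base_freq[tree_idx[u]] = base_freq[tree_idx[parent_of[u]]]
                race_offset[tree_idx[u]] = race_offset[tree_idx[parent_of[u]]]
        for u in order:
            j = tree_idx[u]
            if u not in parent_of:
                G[:, j] = _sample_genotypes(rng, sample_freq(j))
                continue
            parent_col = G[:, tree_idx[parent_of[u]]]
            hwe = _hwe_probs(np.clip(base_freq[j], 0.02, 0.98))
            eps = spec.dependence_noise
            # control CPT: copy parent w.p. 1 - eps, else HWE draw
            t0 = np.array(
                [(1 - eps) * np.eye(3)[b] + eps * hwe for b in range(3)]
            )  # (parent, child)
            t1 = (1 - spec.edge_effect) * t0 + spec.edge_effect * np.roll(
                t0, 1, axis=0
            )
            u_rand = rng.random(n)
            out = np.empty(n, dtype=np.int8)
            for cls, tab in ((0, t0), (1, t1)):
                for b in range(3):
                    mask = (y == cls) & (parent_col == b)
                    cum = np.cumsum(tab[b])
                    out[mask] = np.searchsorted(cum, u_rand[mask], side="right")
            G[:, j] = np.clip(out, 0, 2)

    # causal gene block (contiguous, strong direct effect)
    causal_idx = list(range(col, col + spec.n_causal))
    for j in causal_idx:
        G[:, j] = _sample_genotypes(rng, sample_freq(j, spec.causal_delta))
    col += spec.n_causal

    # polygenic background (weak direct effects)
    background_idx = list(range(col, col + spec.n_background))
    for j in background_idx:
        G[:, j] = _sample_genotypes(rng, sample_freq(j, spec.background_delta))
    col += spec.n_background

    # LD blocks: founder copied with flip noise
    ld_blocks: list[list[int]] = []
    if spec.ld_block_size > 1:
        for _ in range(spec.n_ld_blocks):
            block = list(range(col, col + spec.ld_block_size))
            founder = block[0]
            G[:, founder] = _sample_genotypes(rng, sample_freq(founder))
            for j in block[1:]:
                copy = G[:, founder].copy()
                flip = rng.random(n) < spec.ld_flip_prob
                copy[flip] = _sample_genotypes(rng, sample_freq(founder))[flip]
                G[:, j] = copy
            ld_blocks.append(block)
            col += spec.ld_block_size

    # independent null SNPs
    null_idx = list(range(col, spec.n_snps))
    for j in null_idx:
        G[:, j] = _sample_genotypes(rng, sample_freq(j))

    # ---- missingness ----
    if spec.missing_rate > 0:
        mask = rng.random(G.shape) < spec.missing_rate
        G[mask] = MISSING

    # ---- metadata ----
    per_chrom = int(np.ceil(spec.n_snps / spec.n_chromosomes))
    snps = []
    for j in range(spec.n_snps):
        chrom = str(j // per_chrom + 1)
        pos = (j % per_chrom + 1) * 1000
        snps.append(SNPRecord(f"rs{j + 1:06d}", chrom, pos, "A", "C"))

    schema = VariableSchema(
        levels={d.name: list(d.levels) for d in spec.demographics if d.levels},
        continuous=[d.name for d in spec.demographics if d.is_continuous],
        race="race" if any(d.name == "race" for d in spec.demographics) else None,
        sex="sex" if any(d.name == "sex" for d in spec.demographics) else None,
    )
    demo = pd.DataFrame(
        {name: demo_cols[name] for name in schema.variables},
        columns=schema.variables,
    )
    samples = SampleTable(
        [f"S{i + 1:05d}" for i in range(n)], y, demo, schema
    )
    ds = Dataset(snps, G, samples)

    ids = ds.snp_ids
    truth = {
        "tree_edges": [(ids[tree_idx[a]], ids[tree_idx[b]]) for a, b in edges],
        "tree_snps": [ids[j] for j in tree_idx],
        "causal_snps": [ids[j] for j in causal_idx],
        "background_snps": [ids[j] for j in background_idx],
        "null_snps": [ids[j] for j in null_idx],
        "ld_blocks": [[ids[j] for j in b] for b in ld_blocks],
        "demographic_effects": {
            d.name: d.class_effect for d in spec.demographics
        },
        "base_freq": base_freq.tolist(),
        "race_offset": race_offset.tolist(),
    }
    return ds, truth


def simulate_annotations(
    ds: Dataset,
    truth: dict,
    snps_per_gene: int = 5,
    intergenic_fraction: float = 0.2,
    n_pathways: int = 8,
    genes_per_pathway: int = 4,
    seed: int = 0,
) -> tuple[AnnotationMaps, dict]:
    """Assign SNPs to genes by position blocks and genes to pathways.

    Consecutive runs of ``snps_per_gene`` markers form a gene; a random
    fraction of gene blocks is relabeled Intergenic.  The planted causal
    SNPs are kept together in one (never intergenic) gene, and one planted
    pathway contains that gene.  Returns (AnnotationMaps, annotation truth).
    """
    rng = np.random.default_rng(seed)
    ids = ds.snp_ids
    snp_to_gene: dict[str, str] = {}
    gene_names: list[str] = []
    for g, start in enumerate(range(0, len(ids), snps_per_gene)):
        name = f"GENE{g + 1:04d}"
        if rng.random() < intergenic_fraction:
            name = INTERGENIC
        else:
            gene_names.append(name)
        for s in ids[start : start + snps_per_gene]:
            snp_to_gene[s] = name

    causal = truth.get("causal_snps", [])
    causal_gene = None
    if causal:
        causal_gene = snp_to_gene[causal[0]]
        if causal_gene == INTERGENIC:
            causal_gene = "GENE_CAUSAL"
            gene_names.append(causal_gene)
        for s in causal:
            snp_to_gene[s] = causal_gene

    pathways: dict[str, set[str]] = {}
    pool = [g for g in gene_names if g != causal_gene]
    for i in range(n_pathways):
        size = min(genes_per_pathway, len(pool))
        members = set(rng.choice(pool, size=size, replace=False)) if size else set()
        pathways[f"PATH{i + 1:03d}"] = members
    if causal_gene is not None:
        planted = set(
            rng.choice(pool, size=min(genes_per_pathway - 1, len(pool)), replace=False)
        )
        planted.add(causal_gene)
        pathways["PATH_CAUSAL"] = planted

    ann_truth = {"causal_gene": causal_gene, "causal_pathway": "PATH_CAUSAL"}
    return AnnotationMaps(snp_to_gene=snp_to_gene, pathways=pathways), ann_truth
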