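"""Readers and writers for the text formats the pipeline consumes.

Supported formats: PLINK text PED/MAP, a tab-separated covariate table
(``IID``, ``CLASS``, then demographic variables), the network edge-list /
CPT pair produced by :func:`write_network`, GMT gene sets, and a two-column
SNP-to-gene map.  Binary PLINK, VCF, imputation and phasing are out of
scope.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd

from .datatypes import (
    CASE,
    CONTROL,
    MISSING,
    Dataset,
    FormatError,
    SampleTable,
    SNPRecord,
    VariableSchema,
)

_VALID_ALLELES = {"A", "C", "G", "T"}


# ---------------------------------------------------------------------------
# PLINK text PED/MAP
# ---------------------------------------------------------------------------

def read_plink_text(
    ped_path,
    map_path,
    schema: VariableSchema | None = None,
) -> Dataset:
    """Read a PLINK text fileset into a :class:`Dataset`.

    The minor allele of each SNP is determined from the allele frequency in
    the full sample (cases + controls); ``0 0`` genotypes become MISSING;
    affection status 2 maps to case and 1 to control.  Hemizygous calls are
    already coded as two identical alleles in text PED, so X-chromosome
    males come out homozygous (0 or 2).

    Raises :class:`FormatError` on PED/MAP dimension mismatch or on a SNP
    with more than two observed alleles.
    """
    snp_meta = []
    with open(map_path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 4:
                raise FormatError(f"{map_path}:{ln}: expected 4 MAP columns")
            chrom, snp_id, _cm, pos = parts[:4]
            snp_meta.append((snp_id, chrom, int(pos)))
    p = len(snp_meta)

    ids, labels, rows = [], [], []
    with open(ped_path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * p:
                raise FormatError(
                    f"{ped_path}:{ln}: {len(parts)} fields, expected {6 + 2 * p} "
                    f"for {p} MAP SNPs"
                )
            ids.append(parts[1])
            pheno = parts[5]
            if pheno == "2":
                labels.append(CASE)
            elif pheno == "1":
                labels.append(CONTROL)
            else:
                raise FormatError(
                    f"{ped_path}:{ln}: affection status {pheno!r} not in {{1,2}}"
                )
            rows.append(parts[6:])

    n = len(ids)
    a1 = np.empty((n, p), dtype="U1")
    a2 = np.empty((n, p), dtype="U1")
    for i, row in enumerate(rows):
        a1[i] = row[0::2]
        a2[i] = row[1::2]

    genotypes = np.full((n, p), MISSING, dtype=np.int8)
    snps = []
    for j, (snp_id, chrom, pos) in enumerate(snp_meta):
        c1, c2 = a1[:, j], a2[:, j]
        half_missing = (c1 == "0") != (c2 == "0")
        if half_missing.any():
            raise FormatError(f"SNP {snp_id}: half-missing genotype call")
        called = c1 != "0"
        observed = set(c1[called]) | set(c2[called])
        bad = observed - _VALID_ALLELES
        if bad:
            raise FormatError(f"SNP {snp_id}: invalid allele code {sorted(bad)}")
        if len(observed) > 2:
            raise FormatError(
                f"SNP {snp_id}: more than two alleles observed {sorted(observed)}"
            )
        alleles = sorted(observed)
        if not alleles:  # fully missing column: keep placeholder alleles
            major, minor = "A", "C"
        elif len(alleles) == 1:
            major = alleles[0]
            minor = next(a for a in "ACGT" if a != major)
        else:
            x, y = alleles
            count_x = int((c1[called] == x).sum() + (c2[called] == x).sum())
            total = int(2 * called.sum())
            # tie -> lexicographically smaller allele is minor (deterministic)
            if count_x * 2 < total or (count_x * 2 == total):
                minor, major = x, y
            else:
                minor, major = y, x
        snps.append(SNPRecord(snp_id, chrom, pos, major, minor))
        dosage = (c1 == minor).astype(np.int8) + (c2 == minor).astype(np.int8)
        genotypes[called, j] = dosage[called]

    if schema is None:
        schema = VariableSchema()
    demo = pd.DataFrame(index=range(n), columns=schema.variables)
    samples = SampleTable(ids, np.array(labels, dtype=np.int8), demo, schema)
    return Dataset(snps, genotypes, samples)


def write_plink_text(ds: Dataset, ped_path, map_path) -> None:
    """Write a Dataset as PLINK text PED/MAP (inverse of read_plink_text)."""
    with open(map_path, "w") as fh:
        for s in ds.snps:
            fh.write(f"{s.chromosome}\t{s.snp_id}\t0\t{s.position}\n")
    G = ds.genotypes
    with open(ped_path, "w") as fh:
        for i, sid in enumerate(ds.samples.sample_ids):
            pheno = "2" if ds.samples.class_label[i] == CASE else "1"
            fields = [f"FAM{i}", sid, "0", "0", "0", pheno]
            for j, s in enumerate(ds.snps):
                g = G[i, j]
                if g == MISSING:
                    fields += ["0", "0"]
                elif g == 0:
                    fields += [s.allele_major, s.allele_major]
                elif g == 1:
                    fields += [s.allele_major, s.allele_minor]
                else:
                    fields += [s.allele_minor, s.allele_minor]
            fh.write(" ".join(fields) + "\n")


# ---------------------------------------------------------------------------
# Covariates
# ---------------------------------------------------------------------------

def read_covariates(tsv_path, schema: VariableSchema) -> SampleTable:
    """Read the covariate/phenotype table.

    Expected layout: tab-separated, header ``IID<TAB>CLASS<TAB><var>...``.
    ``CLASS`` accepts case/control (or 2/1).  Categorical values are
    validated against the schema's declared levels; continuous variables
    are kept raw (discretized later).  Missing values may be coded ``NA``.
    """
    df = pd.read_csv(tsv_path, sep="\t", dtype=str, keep_default_na=False)
    if "IID" not in df.columns or "CLASS" not in df.columns:
        raise FormatError(f"{tsv_path}: header must contain IID and CLASS")
    missing_vars = [v for v in schema.variables if v not in df.columns]
    if missing_vars:
        raise FormatError(f"{tsv_path}: missing variables {missing_vars}")

    labels = np.empty(len(df), dtype=np.int8)
    for i, raw in enumerate(df["CLASS"]):
        low = raw.strip().lower()
        if low in ("case", "2"):
            labels[i] = CASE
        elif low in ("control", "1"):
            labels[i] = CONTROL
        else:
            raise FormatError(
                f"{tsv_path}: sample {df['IID'][i]}: class {raw!r} is not "
                "case/control"
            )

    cols = {}
    for name in schema.variables:
        raw = df[name]
        if name in schema.levels:
            levels = schema.levels[name]
            codes = np.full(len(df), MISSING, dtype=np.int16)
            lookup = {lev: i for i, lev in enumerate(levels)}
            for i, val in enumerate(raw):
                v = val.strip()
                if v in ("", "NA"):
                    continue
                if v not in lookup:
                    raise FormatError(
                        f"{tsv_path}: sample {df['IID'][i]}: variable {name}: "
                        f"undeclared level {v!r}"
                    )
                codes[i] = lookup[v]
            cols[name] = codes
        else:
            vals = np.array(
                [math.nan if v.strip() in ("", "NA") else float(v) for v in raw]
            )
            cols[name] = vals
    demo = pd.DataFrame(cols, columns=schema.variables)
    return SampleTable(list(df["IID"]), labels, demo, schema)


def write_covariates(samples: SampleTable, tsv_path) -> None:
    """Write a SampleTable in the covariate TSV dialect read back above."""
    schema = samples.schema
    with open(tsv_path, "w") as fh:
        fh.write("IID\tCLASS\t" + "\t".join(schema.variables) + "\n")
        for i, sid in enumerate(samples.sample_ids):
            cls = "case" if samples.class_label[i] == CASE else "control"
            out = [sid, cls]
            for name in schema.variables:
                val = samples.demographics[name].iloc[i]
                if name in schema.levels:
                    code = int(val)
                    out.append("NA" if code == MISSING else schema.levels[name][code])
                else:
                    out.append("NA" if pd.isna(val) else repr(float(val)))
            fh.write("\t".join(out) + "\n")


# ---------------------------------------------------------------------------
# Discretization
# ---------------------------------------------------------------------------

def discretize(values, n_bins: int, method: str = "quantile"):
    """Bin a numeric vector into ``n_bins`` discrete states.

    Ties are assigned to the lower bin; NaN stays missing (code -1); empty
    quantile bins are merged so the number of resulting states may be below
    ``n_bins``.  Returns ``(codes, edges)`` where ``edges`` are the interior
    bin edges actually used (length = n_states - 1): value v goes to the
    first bin whose upper edge satisfies v <= edge.

    Deterministic given (values, n_bins, method).
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    values = np.asarray(values, dtype=float)
    ok = ~np.isnan(values)
    if not ok.any():
        raise ValueError("no non-missing values to discretize")
    v = values[ok]
    if method == "quantile":
        qs = np.quantile(v, np.linspace(0, 1, n_bins + 1)[1:-1])
    elif method == "equal_width":
        qs = np.linspace(v.min(), v.max(), n_bins + 1)[1:-1]
    else:
        raise ValueError(f"unknown method {method!r}")
    edges = np.unique(qs)  # merge empty/duplicate bins
    # drop edges that would create an empty top bin (all values <= edge)
    edges = edges[edges < v.max()]
    codes = np.full(values.shape, MISSING, dtype=np.int16)
    # ties to the lower bin: v <= edge stays below the cut
    codes[ok] = np.searchsorted(edges, v, side="left")
    return codes, edges


# ---------------------------------------------------------------------------
# Network serialization
# ---------------------------------------------------------------------------

_FLOAT_FMT = "%.17g"


def write_network(tree, edge_path, cpt_path) -> None:
    """Serialize a fitted dependence tree.

    ``edge_path`` gets a TSV of (child, parent, conditional-MI weight) rows;
    ``cpt_path`` a structured human-readable text file with the class prior
    and every conditional probability table.  ``read_network`` inverts both
    exactly (floats are printed with 17 significant digits).
    """
    tree.validate()
    with open(edge_path, "w") as fh:
        fh.write("child\tparent\tcmi\n")
        for child, parent in tree.edges():
            w = tree.edge_weights.get((child, parent), math.nan)
            fh.write(f"{child}\t{parent}\t{_FLOAT_FMT % w}\n")

    with open(cpt_path, "w") as fh:
        fh.write("# dependence-tree CPT file\n")
        fh.write(f"alpha\t{_FLOAT_FMT % tree.alpha}\n")
        fh.write(
            "class_prior\t"
            + "\t".join(_FLOAT_FMT % v for v in tree.class_prior)
            + "\n"
        )
        for name in tree.nodes:
            parent = tree.parent[name]
            k = tree.ks[name]
            cpt = tree.cpts[name]
            if parent is None:
                fh.write(f"node\t{name}\tROOT\t{k}\n")
                for cls in range(2):
                    fh.write(
                        f"p\t{cls}\t"
                        + "\t".join(_FLOAT_FMT % v for v in cpt[:, cls])
                        + "\n"
                    )
            else:
                kp = tree.ks[parent]
                fh.write(f"node\t{name}\t{parent}\t{k}\t{kp}\n")
                for cls in range(2):
                    for b in range(kp):
                        fh.write(
                            f"p\t{cls}\t{b}\t"
                            + "\t".join(_FLOAT_FMT % v for v in cpt[:, b, cls])
                            + "\n"
                        )


def read_network(edge_path, cpt_path):
    """Read a tree written by :func:`write_network`."""
    from .tree import DependenceTree

    edge_weights = {}
    with open(edge_path) as fh:
        header = fh.readline()
        if not header.startswith("child\tparent"):
            raise FormatError(f"{edge_path}: unexpected header")
        for line in fh:
            child, parent, w = line.rstrip("\n").split("\t")
            edge_weights[(child, parent)] = float(w)

    nodes: list[str] = []
    parent: dict[str, str | None] = {}
    ks: dict[str, int] = {}
    cpts: dict[str, np.ndarray] = {}
    alpha = 0.0
    class_prior = np.array([0.5, 0.5])
    current = None
    with open(cpt_path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            tag = parts[0]
            if tag == "alpha":
                alpha = float(parts[1])
            elif tag == "class_prior":
                class_prior = np.array([float(parts[1]), float(parts[2])])
            elif tag == "node":
                name, par = parts[1], parts[2]
                k = int(parts[3])
                nodes.append(name)
                ks[name] = k
                if par == "ROOT":
                    parent[name] = None
                    cpts[name] = np.empty((k, 2))
                else:
                    parent[name] = par
                    kp = int(parts[4])
                    cpts[name] = np.empty((k, kp, 2))
                current = name
            elif tag == "p":
                if current is None:
                    raise FormatError(f"{cpt_path}: probability row before node")
                if parent[current] is None:
                    cls = int(parts[1])
                    cpts[current][:, cls] = [float(x) for x in parts[2:]]
                else:
                    cls, b = int(parts[1]), int(parts[2])
                    cpts[current][:, b, cls] = [float(x) for x in parts[3:]]
            else:
                raise FormatError(f"{cpt_path}: unknown record {tag!r}")

    tree = DependenceTree(
        nodes=nodes,
        ks=ks,
        parent=parent,
        cpts=cpts,
        class_prior=class_prior,
        edge_weights=edge_weights,
        alpha=alpha,
    )
    tree.validate()
    return tree


# ---------------------------------------------------------------------------
# Annotation files
# ---------------------------------------------------------------------------

INTERGENIC = "Intergenic"


def read_snp_gene_map(tsv_path) -> dict[str, str]:
    """Read a two-column (snp_id, gene) TSV; blank gene -> Intergenic."""
    out = {}
    with open(tsv_path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            snp = parts[0]
            gene = parts[1] if len(parts) > 1 and parts[1] else INTERGENIC
            out[snp] = gene
    return out


def write_snp_gene_map(mapping: dict[str, str], tsv_path) -> None:
    with open(tsv_path, "w") as fh:
        for snp, gene in mapping.items():
            fh.write(f"{snp}\t{gene}\n")


def read_gmt(path) -> dict[str, set[str]]:
    """Read gene sets in GMT format (name, description, genes...)."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path}: GMT line needs name and description")
            sets[parts[0]] = set(g for g in parts[2:] if g)
    return sets


def write_gmt(sets: dict[str, set[str]], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write(name + "\t" + description + "\t" + "\t".join(sorted(genes)) + "\n")
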