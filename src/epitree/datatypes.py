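"""Core discrete data model: SNP records, genotype matrix, sample table.

Genotypes are stored as minor-allele dosage: 0 (homozygous wild-type, BB),
1 (heterozygote, Bb), 2 (homozygous mutant, bb), with ``MISSING`` (-1) as a
distinct fourth state that is never imputed at I/O time.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Sentinel for a missing genotype / demographic state.
MISSING: int = -1

#: Number of states of a SNP variable (dosage 0/1/2).
SNP_STATES: int = 3

CONTROL, CASE = 0, 1


class FormatError(ValueError):
    """Raised for malformed input files (PED/MAP/covariate/network)."""


@dataclass(frozen=True)
class SNPRecord:
    """A biallelic marker; ``position`` is 1-based as in MAP files."""

    snp_id: str
    chromosome: str
    position: int
    allele_major: str
    allele_minor: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"{self.snp_id}: position must be >= 1")
        if self.allele_major == self.allele_minor:
            raise ValueError(f"{self.snp_id}: major and minor allele identical")


@dataclass
class VariableSchema:
    """Declared demographic variables: categorical levels or continuous.

    ``levels`` maps a categorical variable to its ordered level list;
    ``continuous`` names variables kept raw until discretization.  ``race``
    and ``sex`` identify the special covariates used for stratification and
    for the always-included sub-network adjustment.
    """

    levels: dict[str, list[str]] = field(default_factory=dict)
    continuous: list[str] = field(default_factory=list)
    race: str | None = None
    sex: str | None = None

    @property
    def variables(self) -> list[str]:
        return list(self.levels) + list(self.continuous)


class SampleTable:
    """Per-sample class label plus demographic variables.

    The class label C is binary (0 = control, 1 = case) and never missing.
    Categorical demographics are stored as integer codes (``MISSING`` = -1)
    against the schema's level lists; continuous demographics are stored as
    floats (NaN = missing) and discretized downstream.
    """

    def __init__(
        self,
        sample_ids: list[str],
        class_label: np.ndarray,
        demographics: pd.DataFrame,
        schema: VariableSchema,
    ) -> None:
        if len(set(sample_ids)) != len(sample_ids):
            raise ValueError("duplicate sample ids")
        class_label = np.asarray(class_label, dtype=np.int8)
        if class_label.shape != (len(sample_ids),):
            raise ValueError("class label length mismatch")
        if not np.isin(class_label, [CONTROL, CASE]).all():
            raise ValueError("class label must be 0 (control) or 1 (case)")
        if list(demographics.columns) != schema.variables:
            raise ValueError("demographic columns do not match schema")
        self.sample_ids = list(sample_ids)
        self.class_label = class_label
        self.demographics = demographics.reset_index(drop=True)
        self.schema = schema

    def __len__(self) -> int:
        return len(self.sample_ids)

    @property
    def n_cases(self) -> int:
        return int((self.class_label == CASE).sum())

    @property
    def n_controls(self) -> int:
        return int((self.class_label == CONTROL).sum())

    def subset(self, mask: np.ndarray) -> "SampleTable":
        idx = np.flatnonzero(mask) if mask.dtype == bool else np.asarray(mask)
        return SampleTable(
            [self.sample_ids[i] for i in idx],
            self.class_label[idx],
            self.demographics.iloc[idx],
            self.schema,
        )

    def encode(self, n_bins: int = 4, method: str = "quantile"):
        """Encode all demographics as integer state codes.

        Categorical variables keep their declared level codes; continuous
        variables are quantile-discretized (default 4 bins).  Returns
        ``(codes, state_counts)`` where ``codes`` is an int16 array of shape
        (n_samples, n_variables) with ``MISSING`` = -1 and ``state_counts``
        maps variable name -> number of states.
        """
        from .io import discretize

        cols, ks = [], {}
        for name in self.schema.variables:
            col = self.demographics[name]
            if name in self.schema.levels:
                codes = col.to_numpy(dtype=np.int16)
                ks[name] = max(len(self.schema.levels[name]), 2)
            else:
                codes, _ = discretize(col.to_numpy(dtype=float), n_bins, method)
                codes = codes.astype(np.int16)
                ks[name] = max(int(codes.max(initial=0)) + 1, 2)
            cols.append(codes)
        return np.column_stack(cols).astype(np.int16), ks


@dataclass
class Dataset:
    """A case-control genotype dataset: markers x samples plus covariates."""

    snps: list[SNPRecord]
    genotypes: np.ndarray  # (n_samples, n_snps) int8: 0/1/2, MISSING=-1
    samples: SampleTable

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        n, p = self.genotypes.shape
        if n != len(self.samples):
            raise ValueError("genotype rows do not match sample table")
        if p != len(self.snps):
            raise ValueError("genotype columns do not match SNP list")
        ids = [s.snp_id for s in self.snps]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate SNP ids")
        legal = np.isin(self.genotypes, [0, 1, 2, MISSING])
        if not legal.all():
            raise ValueError("illegal genotype state present")

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    @property
    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self.snps]

    def snp_index(self, snp_id: str) -> int:
        try:
            return self.snp_ids.index(snp_id)
        except ValueError:
            raise KeyError(f"unknown SNP {snp_id!r}") from None

    def subset_snps(self, snp_ids: list[str]) -> "Dataset":
        idx = [self.snp_index(s) for s in snp_ids]
        return Dataset(
            [self.snps[i] for i in idx], self.genotypes[:, idx], self.samples
        )

    def subset_samples(self, mask: np.ndarray) -> "Dataset":
        idx = np.flatnonzero(mask) if mask.dtype == bool else np.asarray(mask)
        return Dataset(self.snps, self.genotypes[idx], self.samples.subset(mask))


@dataclass
class DiscreteData:
    """Flat discrete design: encoded variables plus the class vector.

    This is the container the dependence-tree machinery operates on; it
    pools SNP dosage columns (k = 3) and encoded demographic columns.
    """

    X: np.ndarray  # (n, p) int16, MISSING = -1
    y: np.ndarray  # (n,) int8, 0 control / 1 case, never missing
    names: list[str]
    ks: np.ndarray  # (p,) states per variable

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.int16)
        self.y = np.asarray(self.y, dtype=np.int8)
        self.ks = np.asarray(self.ks, dtype=np.int64)
        if self.X.shape != (len(self.y), len(self.names)):
            raise ValueError("design shape mismatch")
        if len(self.names) != len(self.ks):
            raise ValueError("state-count vector mismatch")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def column(self, name: str) -> np.ndarray:
        return self.X[:, self.names.index(name)]

    def select(self, names: list[str]) -> "DiscreteData":
        idx = [self.names.index(n) for n in names]
        return DiscreteData(self.X[:, idx], self.y, list(names), self.ks[idx])

    def rows(self, mask: np.ndarray) -> "DiscreteData":
        return DiscreteData(self.X[mask], self.y[mask], self.names, self.ks)

    @classmethod
    def from_dataset(
        cls,
        ds: Dataset,
        snp_ids: list[str] | None = None,
        demographics: list[str] | None = None,
        n_bins: int = 4,
        method: str = "quantile",
    ) -> "DiscreteData":
        """Assemble the discrete design from a Dataset.

        ``snp_ids`` defaults to every SNP, ``demographics`` to every schema
        variable; pass an empty list to exclude a block entirely.
        """
        if snp_ids is None:
            snp_ids = ds.snp_ids
        if demographics is None:
            demographics = ds.samples.schema.variables
        blocks, names, ks = [], [], []
        if snp_ids:
            idx = [ds.snp_index(s) for s in snp_ids]
            blocks.append(ds.genotypes[:, idx].astype(np.int16))
            names.extend(snp_ids)
            ks.extend([SNP_STATES] * len(snp_ids))
        if demographics:
            codes, kmap = ds.samples.encode(n_bins=n_bins, method=method)
            all_vars = ds.samples.schema.variables
            sel = [all_vars.index(d) for d in demographics]
            blocks.append(codes[:, sel])
            names.extend(demographics)
            ks.extend([kmap[d] for d in demographics])
        if not blocks:
            raise ValueError("no variables selected")
        return cls(np.hstack(blocks), ds.samples.class_label, names, np.array(ks))


def copy_dataset(ds: Dataset) -> Dataset:
    return Dataset(
        list(ds.snps),
        ds.genotypes.copy(),
        SampleTable(
            list(ds.samples.sample_ids),
            ds.samples.class_label.copy(),
            ds.samples.demographics.copy(),
            replace(ds.samples.schema),
        ),
    )
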