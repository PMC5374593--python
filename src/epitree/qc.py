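"""Marker and sample quality control.

The filter chain mirrors standard GWAS preprocessing: SNPs are dropped if
they violate Hardy-Weinberg equilibrium (exact test, per race stratum,
P < 1e-4 in any stratum), have minor allele frequency below 0.01, or a
call rate below 98%; samples with a genotyping rate not above 98% are
then removed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .datatypes import MISSING, Dataset

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def hwe_exact_test(n_hom_major: int, n_het: int, n_hom_minor: int) -> float:
    """Exact two-sided Hardy-Weinberg test p-value.

    Conditions on the observed allele counts and enumerates every possible
    heterozygote count; the p-value is the summed probability of all tables
    no more probable than the observed one (the convention PLINK uses).
    Always in (0, 1].
    """
    if min(n_hom_major, n_het, n_hom_minor) < 0:
        raise ValueError("genotype counts must be nonnegative")
    n = n_hom_major + n_het + n_hom_minor
    if n == 0:
        raise ValueError("all genotype counts are zero")
    n_minor = 2 * n_hom_minor + n_het
    n_major = 2 * n_hom_major + n_het
    if n_minor > n_major:
        n_minor, n_major = n_major, n_minor

    # possible het counts share the parity of the minor allele count
    hets = np.arange(n_minor % 2, n_minor + 1, 2)
    hom_minor = (n_minor - hets) // 2
    hom_major = n - hets - hom_minor
    # log P(het = h | n, n_minor) up to a common constant
    logp = (
        hets * np.log(2.0)
        - gammaln(hom_minor + 1)
        - gammaln(hets + 1)
        - gammaln(hom_major + 1)
    )
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    p_obs = probs[np.searchsorted(hets, n_het)]
    # include tables tied with the observed probability (tolerant compare)
    p = float(probs[probs <= p_obs * (1 + 1e-12)].sum())
    return min(p, 1.0)


# ---------------------------------------------------------------------------
# Filter reports
# ---------------------------------------------------------------------------

@dataclass
class QCReport:
    """Which markers/samples were removed, why, and under what thresholds."""

    thresholds: dict = field(default_factory=dict)
    removed: dict[str, list[str]] = field(default_factory=dict)  # id -> reasons
    counts: dict[str, int] = field(default_factory=dict)  # reason -> count
    n_before: int = 0
    n_after: int = 0
    removed_by_class: dict[str, int] = field(default_factory=dict)

    def add(self, item_id: str, reason: str) -> None:
        self.removed.setdefault(item_id, []).append(reason)
        self.counts[reason] = self.counts.get(reason, 0) + 1

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# thresholds: " + repr(self.thresholds) + "\n")
            fh.write(
                f"# kept {self.n_after} of {self.n_before}"
                + (
                    f"; removed by class {self.removed_by_class}"
                    if self.removed_by_class
                    else ""
                )
                + "\n"
            )
            fh.write("id\treasons\n")
            for item_id, reasons in self.removed.items():
                fh.write(f"{item_id}\t{','.join(reasons)}\n")


# ---------------------------------------------------------------------------
# SNP filters
# ---------------------------------------------------------------------------

def _genotype_counts(col: np.ndarray) -> tuple[int, int, int]:
    c = np.bincount(col[col != MISSING], minlength=3)
    return int(c[0]), int(c[1]), int(c[2])


def apply_snp_filters(
    ds: Dataset,
    hwe_p_min: float = 1e-4,
    maf_min: float = 0.01,
    call_rate_min: float = 0.98,
    hwe_strata: str | None = "race",
) -> tuple[Dataset, QCReport]:
    """Remove SNPs failing HWE (in any stratum), MAF, or call-rate filters.

    The three criteria are evaluated independently on the input, so the
    surviving set does not depend on the order of tests and the filter is
    idempotent.  MAF and call rate use all samples; HWE runs separately in
    each level of ``hwe_strata`` (pass None for a single pooled test).
    """
    report = QCReport(
        thresholds={
            "hwe_p_min": hwe_p_min,
            "maf_min": maf_min,
            "call_rate_min": call_rate_min,
            "hwe_strata": hwe_strata,
        },
        n_before=ds.n_snps,
    )
    G = ds.genotypes
    n = ds.n_samples

    strata_masks = [np.ones(n, dtype=bool)]
    if hwe_strata is not None:
        schema = ds.samples.schema
        if hwe_strata not in schema.variables:
            raise KeyError(f"stratum covariate {hwe_strata!r} not in schema")
        col = ds.samples.demographics[hwe_strata].to_numpy()
        levels = np.unique(col[col != MISSING])
        strata_masks = [col == lev for lev in levels]

    keep = np.ones(ds.n_snps, dtype=bool)
    for j, snp in enumerate(ds.snps):
        col = G[:, j]
        nonmiss = col != MISSING
        call_rate = nonmiss.mean() if n else 0.0
        if call_rate < call_rate_min:
            keep[j] = False
            report.add(snp.snp_id, "call_rate")
        if nonmiss.any():
            dosage_sum = int(col[nonmiss].sum())
            f = dosage_sum / (2 * int(nonmiss.sum()))
            maf = min(f, 1 - f)
        else:
            maf = 0.0
        if maf < maf_min:
            keep[j] = False
            report.add(snp.snp_id, "maf")
        for mask in strata_masks:
            counts = _genotype_counts(col[mask])
            if sum(counts) == 0:
                warnings.warn(
                    f"SNP {snp.snp_id}: empty stratum skipped in HWE test",
                    stacklevel=2,
                )
                continue
            if hwe_exact_test(*counts) < hwe_p_min:
                keep[j] = False
                report.add(snp.snp_id, "hwe")
                break

    kept_ids = [s.snp_id for s, k in zip(ds.snps, keep) if k]
    out = ds.subset_snps(kept_ids)
    report.n_after = len(kept_ids)
    log.info(
        "SNP QC: kept %d of %d (removed: %s)",
        report.n_after,
        report.n_before,
        report.counts,
    )
    return out, report


def apply_sample_filter(
    ds: Dataset, genotyping_rate_min: float = 0.98
) -> tuple[Dataset, QCReport]:
    """Keep samples whose genotyping rate is strictly above the threshold."""
    if ds.n_snps == 0:
        raise ValueError("sample filter needs at least one SNP")
    rates = (ds.genotypes != MISSING).mean(axis=1)
    keep = rates > genotyping_rate_min
    report = QCReport(
        thresholds={"genotyping_rate_min": genotyping_rate_min},
        n_before=ds.n_samples,
        n_after=int(keep.sum()),
    )
    for i, ok in enumerate(keep):
        if not ok:
            report.add(ds.samples.sample_ids[i], "genotyping_rate")
    removed = ~keep
    report.removed_by_class = {
        "case": int((ds.samples.class_label[removed] == 1).sum()),
        "control": int((ds.samples.class_label[removed] == 0).sum()),
    }
    if not keep.any():
        warnings.warn("sample filter removed every sample", stacklevel=2)
    out = ds.subset_samples(keep)
    log.info("sample QC: kept %d of %d", report.n_after, report.n_before)
    return out, report
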