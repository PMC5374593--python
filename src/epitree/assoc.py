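"""Single-marker association: stratified CMH ranking and the trend test.

The Cochran-Mantel-Haenszel test operates on 2x2 allele-count tables
(case/control x minor/major) stratified by a covariate (race by default),
which guards the ranking against population stratification.  The
Cochran-Armitage test compares genotype distributions between two groups
with linear scores (0, 1, 2) across the ordered dosage categories.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import MISSING, Dataset


def cmh_test(strata_tables) -> tuple[float, float]:
    """Cochran-Mantel-Haenszel 1-df chi-square over K 2x2 tables.

    No continuity correction.  A stratum with a zero row or column margin
    carries no information and is dropped with a warning; if every stratum
    is degenerate an error is raised.  With a single stratum the statistic
    reduces to (N-1)/N times the Pearson chi-square of that table.
    """
    tables = np.asarray(strata_tables, dtype=float)
    if tables.ndim == 2:
        tables = tables[None]
    if tables.ndim != 3 or tables.shape[1:] != (2, 2):
        raise ValueError("expected K stacked 2x2 tables")
    num = 0.0
    den = 0.0
    used = 0
    for k, t in enumerate(tables):
        if (t < 0).any():
            raise ValueError("counts must be nonnegative")
        r = t.sum(axis=1)
        c = t.sum(axis=0)
        n = t.sum()
        if n <= 1 or r.min() == 0 or c.min() == 0:
            warnings.warn(f"CMH: stratum {k} degenerate, dropped", stacklevel=2)
            continue
        num += t[0, 0] - r[0] * c[0] / n
        den += r[0] * r[1] * c[0] * c[1] / (n * n * (n - 1))
        used += 1
    if used == 0:
        raise ValueError("all strata degenerate")
    if den == 0:
        return 0.0, 1.0
    stat = num * num / den
    return float(stat), float(stats.chi2.sf(stat, df=1))


def cochran_armitage(table, scores=(0, 1, 2)) -> tuple[float, float]:
    """Two-sided Cochran-Armitage trend test on a 2 x k table.

    Rows are the two groups, columns the ordered categories with the given
    scores.  The statistic conditions on the column margins: the score sum
    of group 1 is compared with its hypergeometric expectation, using the
    exact finite-population variance.  Swapping the rows flips the sign of
    z and leaves the p-value unchanged; identical rows give z = 0, p = 1.
    """
    t = np.asarray(table, dtype=float)
    s = np.asarray(scores, dtype=float)
    if t.ndim != 2 or t.shape[0] != 2 or t.shape[1] != len(s):
        raise ValueError("expected a 2 x k table matching the score vector")
    if (t < 0).any():
        raise ValueError("counts must be nonnegative")
    r1, r2 = t.sum(axis=1)
    if r1 < 1 or r2 < 1:
        raise ValueError("both row totals must be >= 1")
    col = t.sum(axis=0)
    n = col.sum()
    u = float(s @ t[0] - r1 * (s @ col) / n)
    s_bar = (s @ col) / n
    pop_var = float(col @ (s - s_bar) ** 2) / n
    var = r1 * pop_var * (n - r1) / (n - 1) if n > 1 else 0.0
    if var <= 0:
        return 0.0, 1.0
    z = u / np.sqrt(var)
    return float(z), float(2 * stats.norm.sf(abs(z)))


def _allele_counts_by_group(G: np.ndarray, mask: np.ndarray):
    """Per-SNP (minor, major) allele counts within a sample mask."""
    sub = G[mask]
    nonmiss = sub != MISSING
    minor = np.where(nonmiss, sub, 0).sum(axis=0).astype(float)
    total = 2.0 * nonmiss.sum(axis=0)
    return minor, total - minor


def rank_snps_cmh(
    ds: Dataset,
    strata: str | None = "race",
    p_threshold: float = 5e-4,
) -> tuple[pd.DataFrame, list[str]]:
    """Rank every SNP by the stratified CMH allele test.

    Builds per-SNP 2x2xK allele-count tables (class x allele x stratum,
    missing genotypes excluded pairwise) and computes the 1-df CMH
    statistic for all SNPs at once.  Returns the full association table
    (columns SNP, CHR, BP, STAT, P, RANK, sorted ascending by p with ties
    broken by chromosome and position) and the candidate list of SNP ids
    with p < ``p_threshold``.  Monomorphic SNPs get p = 1.
    """
    G = ds.genotypes
    y = ds.samples.class_label
    if strata is not None:
        col = ds.samples.demographics[strata].to_numpy()
        levels = [lev for lev in np.unique(col) if lev != MISSING]
        strata_masks = [col == lev for lev in levels]
    else:
        strata_masks = [np.ones(ds.n_samples, dtype=bool)]

    num = np.zeros(ds.n_snps)
    den = np.zeros(ds.n_snps)
    for mask in strata_masks:
        case_minor, case_major = _allele_counts_by_group(G, mask & (y == 1))
        ctrl_minor, ctrl_major = _allele_counts_by_group(G, mask & (y == 0))
        r1 = case_minor + case_major
        r2 = ctrl_minor + ctrl_major
        c1 = case_minor + ctrl_minor
        c2 = case_major + ctrl_major
        n = r1 + r2
        ok = (n > 1) & (r1 > 0) & (r2 > 0) & (c1 > 0) & (c2 > 0)
        with np.errstate(invalid="ignore", divide="ignore"):
            e = r1 * c1 / n
            v = r1 * r2 * c1 * c2 / (n * n * (n - 1))
        num += np.where(ok, case_minor - e, 0.0)
        den += np.where(ok, v, 0.0)

    with np.errstate(invalid="ignore", divide="ignore"):
        stat = np.where(den > 0, num * num / den, 0.0)
    p = np.where(den > 0, stats.chi2.sf(stat, df=1), 1.0)

    df = pd.DataFrame(
        {
            "SNP": ds.snp_ids,
            "CHR": [s.chromosome for s in ds.snps],
            "BP": [s.position for s in ds.snps],
            "STAT": stat,
            "P": p,
        }
    )
    df = df.sort_values(["P", "CHR", "BP"], kind="mergesort").reset_index(drop=True)
    df["RANK"] = np.arange(1, len(df) + 1)
    candidates = df.loc[df["P"] < p_threshold, "SNP"].tolist()
    return df, candidates
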