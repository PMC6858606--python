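"""Count normalization and per-row differential abundance testing.

Normalization follows the median-of-ratios scheme: a pseudo-reference sample
is built from per-row geometric means over zero-free rows, and each sample's
size factor is the median ratio of its counts to that reference.  Testing is
a per-row negative-binomial Wald test with method-of-moments dispersion — a
desk-scale stand-in for the role a full shrinkage-based NB framework plays in
large cohorts — with a Welch t-test on log2(normalized + 1) as an alternative
mode.  Multiple testing is controlled by Benjamini-Hochberg.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class SampleDesign:
    """Two-condition design: sample -> condition in {A, B}.

    `library_total_reads` (optional) carries per-sample sequencing depth for
    stages where the tested matrix is a biased slice of the library — e.g. a
    masked, recurrence-filtered k-mer matrix dominated by condition-specific
    rows, on which median-of-ratios would absorb the very signal under test.
    """

    sample_ids: list[str]
    conditions: list[str]
    library_total_reads: list[int] | None = None

    def __post_init__(self) -> None:
        if len(self.sample_ids) != len(self.conditions):
            raise ValueError("sample_ids and conditions length mismatch")
        bad = set(self.conditions) - {"A", "B"}
        if bad:
            raise ValueError(f"conditions must be 'A'/'B', got {bad}")
        for c in ("A", "B"):
            if self.conditions.count(c) < 2:
                raise ValueError(f"need >= 2 samples in condition {c}")

    def mask(self, condition: str) -> np.ndarray:
        return np.array([c == condition for c in self.conditions])

    def depth_size_factors(self) -> np.ndarray:
        if self.library_total_reads is None:
            raise ValueError("library_total_reads not set")
        return size_factors_from_totals(self.library_total_reads)


def size_factors_from_totals(totals) -> np.ndarray:
    """Size factors proportional to library depth, geometric mean 1."""
    t = np.asarray(totals, dtype=float)
    if np.any(t <= 0):
        raise ValueError("library totals must be positive")
    return t / np.exp(np.mean(np.log(t)))


def median_of_ratios(matrix: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Per-sample size factors from the median-of-ratios procedure.

    Rows with any zero count are excluded from the reference; if no zero-free
    row exists a ValueError advises the pseudo-reference fallback
    (`median_of_ratios_nonzero`).
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 1:
        raise ValueError("matrix must be 2-D with >= 1 row")
    nonzero = np.all(X > 0, axis=1)
    if not nonzero.any():
        raise ValueError(
            "no zero-free rows: size factors undefined; use "
            "median_of_ratios_nonzero for the zero-excluding pseudo-reference"
        )
    ref = np.exp(np.mean(np.log(X[nonzero]), axis=1))
    factors = np.median(X[nonzero] / ref[:, None], axis=0)
    if np.any(factors <= 0):
        raise ValueError("non-positive size factor")
    return factors


def median_of_ratios_nonzero(matrix: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Fallback: geometric means over nonzero entries per row; rows with
    geomean 0 skipped; ratios computed only where counts are positive."""
    X = np.asarray(matrix, dtype=float)
    with np.errstate(divide="ignore"):
        logX = np.where(X > 0, np.log(X), np.nan)
    geo = np.exp(np.nanmean(logX, axis=1))
    use = np.isfinite(geo) & (geo > 0)
    if not use.any():
        raise ValueError("no usable rows for size factor estimation")
    ratios = np.where(X[use] > 0, X[use] / geo[use][:, None], np.nan)
    factors = np.nanmedian(ratios, axis=0)
    if np.any(~np.isfinite(factors)) or np.any(factors <= 0):
        raise ValueError("non-positive size factor in fallback")
    return factors


def nb_wald_test(
    matrix: pd.DataFrame,
    design: SampleDesign,
    size_factors: np.ndarray | None = None,
    pseudocount: float = 0.5,
    method: str = "nb_wald",
) -> pd.DataFrame:
    """Per-row two-sided differential test between conditions A and B.

    Returns a DataFrame indexed like `matrix` with columns baseMeanA,
    baseMeanB, log2FC (B over A, with `pseudocount` on the means), pvalue and
    padj (Benjamini-Hochberg).
    """
    X = matrix.to_numpy(dtype=float) if isinstance(matrix, pd.DataFrame) else np.asarray(matrix, float)
    index = matrix.index if isinstance(matrix, pd.DataFrame) else pd.RangeIndex(X.shape[0])
    if size_factors is None:
        try:
            size_factors = median_of_ratios(X)
        except ValueError:
            size_factors = median_of_ratios_nonzero(X)
    s = np.asarray(size_factors, dtype=float)
    if np.any(s <= 0):
        raise ValueError("size factors must be positive")
    Q = X / s[None, :]
    mA, mB = design.mask("A"), design.mask("B")
    nA, nB = int(mA.sum()), int(mB.sum())
    QA, QB = Q[:, mA], Q[:, mB]
    meanA, meanB = QA.mean(axis=1), QB.mean(axis=1)
    log2fc = np.log2((meanB + pseudocount) / (meanA + pseudocount))

    if method == "welch":
        LA, LB = np.log2(QA + 1.0), np.log2(QB + 1.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            _t, pval = stats.ttest_ind(LB, LA, axis=1, equal_var=False)
        pval = np.where(np.isnan(pval), 1.0, pval)
    elif method == "nb_wald":
        # method-of-moments dispersion pooled over within-condition residuals
        varA = QA.var(axis=1, ddof=1)
        varB = QB.var(axis=1, ddof=1)
        pooled_var = ((nA - 1) * varA + (nB - 1) * varB) / (nA + nB - 2)
        grand = (nA * meanA + nB * meanB) / (nA + nB)
        with np.errstate(divide="ignore", invalid="ignore"):
            alpha = (pooled_var - grand) / grand**2
        alpha = np.where(np.isfinite(alpha), alpha, 0.0)
        alpha = np.maximum(alpha, 1e-8)
        # Wald statistic on log2 FC with NB variance of the group means
        a = meanA + pseudocount
        b = meanB + pseudocount
        varMA = (a + alpha * a**2) / nA
        varMB = (b + alpha * b**2) / nB
        ln2sq = np.log(2.0) ** 2
        se = np.sqrt(varMA / (a**2 * ln2sq) + varMB / (b**2 * ln2sq))
        with np.errstate(divide="ignore", invalid="ignore"):
            z = log2fc / se
        z = np.where(np.isfinite(z), z, 0.0)
        pval = 2.0 * stats.norm.sf(np.abs(z))
    else:
        raise ValueError(f"unknown method {method!r}")

    degenerate = (meanA == 0) & (meanB == 0)
    pval = np.where(degenerate, 1.0, np.clip(pval, 0.0, 1.0))
    padj = benjamini_hochberg(pval)
    return pd.DataFrame(
        {
            "baseMeanA": meanA,
            "baseMeanB": meanB,
            "log2FC": log2fc,
            "pvalue": pval,
            "padj": padj,
        },
        index=index,
    )


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def select_de_kmers(
    results: pd.DataFrame, p_threshold: float = 0.05, direction: str = "both"
) -> pd.DataFrame:
    """Rows with adjusted p strictly below threshold, optionally sign-filtered."""
    keep = results["padj"] < p_threshold
    if direction == "up":
        keep &= results["log2FC"] > 0
    elif direction == "down":
        keep &= results["log2FC"] < 0
    elif direction != "both":
        raise ValueError(f"unknown direction {direction!r}")
    return results.loc[keep]
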