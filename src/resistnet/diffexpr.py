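"""Gene-level differential expression between two conditions.

The input is a transcript-level abundance table (either FPKM directly, or
raw fragment counts plus transcript length and library size from which FPKM
is computed).  The analysis keeps one representative transcript per
protein-coding gene — the isoform with the higher mean abundance across the
two conditions — computes a pseudocounted log2 fold change, drops
low-expression and abnormal-signal outliers, and flags the top fraction of
genes by |log2fc| as the differentially expressed set.

With a single profile per condition there is no replicate variance to model,
so the ranking statistic is the fold change itself; an auxiliary Welch test
on log abundance (`welch_log_test`) is available when replicate columns
exist.
"""

from __future__ import annotations

import logging
import math
from collections.abc import Iterable

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

PROTEIN_CODING = ("protein_coding",)


def compute_fpkm(count, length_bp, total_mapped):
    """Fragments per kilobase of transcript per million mapped reads.

    ``10^9 * count / (length_bp * total_mapped)``; accepts scalars or arrays.
    """
    count = np.asarray(count, dtype=float)
    length_bp = np.asarray(length_bp, dtype=float)
    total_mapped = np.asarray(total_mapped, dtype=float)
    if np.any(count < 0):
        raise ValueError("counts must be nonnegative")
    if np.any(length_bp < 1):
        raise ValueError("length_bp must be >= 1")
    if np.any(total_mapped < 1):
        raise ValueError("total_mapped must be >= 1")
    out = 1e9 * count / (length_bp * total_mapped)
    return float(out) if out.ndim == 0 else out


def fpkm_from_counts(table: pd.DataFrame) -> pd.DataFrame:
    """Add ``expr_a``/``expr_b`` FPKM columns from count columns.

    Expects ``count_a``, ``count_b``, ``length_bp`` and per-condition library
    sizes ``total_mapped_a``, ``total_mapped_b``.
    """
    out = table.copy()
    out["expr_a"] = compute_fpkm(out["count_a"], out["length_bp"], out["total_mapped_a"])
    out["expr_b"] = compute_fpkm(out["count_b"], out["length_bp"], out["total_mapped_b"])
    return out


def select_representative_transcripts(
    table: pd.DataFrame, coding_biotypes: Iterable[str] = PROTEIN_CODING
) -> pd.DataFrame:
    """One transcript per protein-coding gene: the highest mean abundance.

    Non-protein-coding genes are dropped.  Ties are broken by transcript_id
    so the choice is reproducible.  Idempotent.
    """
    if table.empty:
        raise ValueError("transcript table is empty")
    coding = table[table["biotype"].isin(set(coding_biotypes))].copy()
    coding["_mean"] = (coding["expr_a"] + coding["expr_b"]) / 2.0
    coding = coding.sort_values(
        ["gene_id", "_mean", "transcript_id"], ascending=[True, False, True]
    )
    out = coding.groupby("gene_id", sort=True).head(1).drop(columns="_mean")
    return out.reset_index(drop=True)


def compute_log_fold_change(expr_a, expr_b, pseudocount: float = 1.0):
    """log2((expr_b + pseudocount) / (expr_a + pseudocount)).

    Antisymmetric under swapping the two conditions; the pseudocount bounds
    fold changes for dropout transcripts.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    expr_a = np.asarray(expr_a, dtype=float)
    expr_b = np.asarray(expr_b, dtype=float)
    if np.any(expr_a < 0) or np.any(expr_b < 0):
        raise ValueError("abundances must be nonnegative")
    out = np.log2((expr_b + pseudocount) / (expr_a + pseudocount))
    return float(out) if out.ndim == 0 else out


def build_gene_table(transcripts: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """Representative-transcript selection + gene-level log2 fold change."""
    rep = select_representative_transcripts(transcripts)
    rep = rep[["gene_id", "transcript_id", "expr_a", "expr_b"]].copy()
    rep["log2fc"] = compute_log_fold_change(rep["expr_a"], rep["expr_b"], pseudocount)
    return rep


def filter_outliers(
    genes: pd.DataFrame, min_expr: float = 0.1, max_abs_log2fc: float = 10.0
) -> pd.DataFrame:
    """Drop genes expressed in neither condition and abnormal-signal genes.

    A gene is removed when both conditions fall below ``min_expr`` FPKM, or
    when |log2fc| exceeds ``max_abs_log2fc``.
    """
    if min_expr < 0 or max_abs_log2fc < 0:
        raise ValueError("thresholds must be >= 0")
    low = (genes["expr_a"] < min_expr) & (genes["expr_b"] < min_expr)
    extreme = genes["log2fc"].abs() > max_abs_log2fc
    keep = genes[~(low | extreme)].reset_index(drop=True)
    n_removed = len(genes) - len(keep)
    if n_removed:
        logger.info(
            "filter_outliers removed %d genes (%d low-expression, %d extreme fold change)",
            n_removed, int(low.sum()), int((extreme & ~low).sum()),
        )
    return keep


def top_fraction(genes: pd.DataFrame, q: float = 0.1) -> pd.DataFrame:
    """Flag the top ``max(1, floor(q*n))`` genes by |log2fc|.

    Boundary ties are broken by lexicographic gene_id; the returned table
    carries ``abs_log2fc``, dense ``rank`` and boolean ``top_flag`` columns.
    """
    if not (0.0 < q < 1.0):
        raise ValueError("q must be in (0, 1)")
    if genes.empty:
        raise ValueError("gene table is empty")
    out = genes.copy()
    out["abs_log2fc"] = out["log2fc"].abs()
    out = out.sort_values(["abs_log2fc", "gene_id"], ascending=[False, True], kind="mergesort")
    k = max(1, math.floor(q * len(out)))
    out["rank"] = np.arange(1, len(out) + 1)
    out["top_flag"] = out["rank"] <= k
    return out.reset_index(drop=True)


def top_gene_set(genes: pd.DataFrame) -> set[str]:
    """Gene ids flagged by :func:`top_fraction`."""
    return set(genes.loc[genes["top_flag"], "gene_id"])


def welch_log_test(a: np.ndarray, b: np.ndarray, pseudocount: float = 1.0) -> float:
    """Two-sided Welch t-test on log2 abundance, for replicated designs."""
    la = np.log2(np.asarray(a, dtype=float) + pseudocount)
    lb = np.log2(np.asarray(b, dtype=float) + pseudocount)
    return float(stats.ttest_ind(la, lb, equal_var=False).pvalue)
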