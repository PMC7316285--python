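"""FPKM quantification, expression-level binning and DEG calling.

Expression is quantified as FPKM (fragments per kilobase of transcript per
million mapped fragments). Differential expression between two groups uses
log2(FPKM + c) with a small pseudo-count c and a two-sided unequal-variance
t-test per gene; p-values are corrected with the Benjamini-Hochberg step-up
procedure and genes with corrected p strictly below alpha are called DEGs.

The t-test route is deliberately simple plumbing: it does not model counts
(no dispersion shrinkage, no size-factor normalization beyond FPKM). An
externally produced differential-expression table (gene_id, log2fc, pvalue
[, padj]) is accepted by :func:`call_degs` as an alternative entry point so
the downstream screening can run on published DEG tables.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .models import GeneModel  # noqa: F401  (part of this module's surface)

#: Default FPKM cut points separating the five expression levels.
DEFAULT_LEVEL_BOUNDARIES: tuple[float, ...] = (0.1, 1.0, 10.0, 100.0)

#: A gene is considered expressed in a group when mean FPKM exceeds this.
DEFAULT_EXPRESSED_THRESHOLD: float = 0.1

#: Pseudo-count (FPKM units) added before log2 transforms.
DEFAULT_PSEUDOCOUNT: float = 0.25


def fpkm(count: float, gene_length: int, total_fragments: float) -> float:
    """FPKM = count * 1e9 / (gene_length * total_fragments)."""
    if gene_length <= 0:
        raise ValueError("gene_length must be positive")
    if total_fragments <= 0:
        raise ValueError("total_fragments must be positive")
    return count * 1.0e9 / (gene_length * total_fragments)


def fpkm_matrix(
    counts: pd.DataFrame,
    gene_lengths: Mapping[str, int] | pd.Series,
    total_fragments: Mapping[str, float] | pd.Series | None = None,
) -> pd.DataFrame:
    """Convert a genes x samples fragment-count matrix to FPKM.

    ``total_fragments`` defaults to the per-sample column sums, i.e. the
    denominator counts the fragments assigned to genes in the matrix; a
    mapping of externally determined per-sample totals may be supplied
    instead.
    """
    lengths = pd.Series(gene_lengths).reindex(counts.index)
    if lengths.isna().any():
        missing = counts.index[lengths.isna()][:5].tolist()
        raise KeyError(f"missing gene lengths, e.g. {missing}")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    if total_fragments is None:
        totals = counts.sum(axis=0).astype(float)
    else:
        totals = pd.Series(total_fragments).reindex(counts.columns).astype(float)
    if totals.isna().any() or (totals <= 0).any():
        raise ValueError("per-sample totals must be positive for all samples")
    return counts.div(lengths, axis=0).div(totals, axis=1) * 1.0e9


def bin_expression_levels(
    fpkm_values: Sequence[float] | pd.Series,
    boundaries: Sequence[float] = DEFAULT_LEVEL_BOUNDARIES,
) -> tuple[np.ndarray, pd.Series]:
    """Assign each FPKM value one of five ordered expression levels.

    The four strictly increasing ``boundaries`` split the FPKM axis into
    levels 1 (lowest) through 5 (highest); a value equal to a boundary falls
    in the lower level. Returns (labels, per-level counts).
    """
    bounds = np.asarray(boundaries, dtype=float)
    if bounds.size != 4 or not np.all(np.diff(bounds) > 0):
        raise ValueError("boundaries must be 4 strictly increasing cut points")
    values = np.asarray(fpkm_values, dtype=float)
    labels = np.searchsorted(bounds, values, side="left") + 1
    counts = pd.Series(labels).value_counts().reindex(range(1, 6), fill_value=0)
    counts.index.name = "level"
    return labels, counts


def expressed_sets(
    fpkm_df: pd.DataFrame,
    groups: Mapping[str, str],
    threshold: float = DEFAULT_EXPRESSED_THRESHOLD,
) -> tuple[dict[str, set[str]], set[str]]:
    """Per-group expressed-gene sets and their intersection.

    A gene is expressed in a group iff its mean FPKM over that group's
    samples is strictly greater than ``threshold``.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    unknown = set(fpkm_df.columns) - set(groups)
    if unknown:
        raise KeyError(f"samples without a group label: {sorted(unknown)}")
    sets: dict[str, set[str]] = {}
    for group in sorted(set(groups.values())):
        cols = [s for s in fpkm_df.columns if groups[s] == group]
        mean = fpkm_df[cols].mean(axis=1)
        sets[group] = set(fpkm_df.index[mean > threshold])
    common: set[str] = set.intersection(*sets.values()) if sets else set()
    return sets, common


def de_test(
    counts: pd.DataFrame,
    groups: Mapping[str, str],
    gene_lengths: Mapping[str, int] | pd.Series,
    case_group: str,
    control_group: str,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    total_fragments: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Per-gene log2 fold change (case/control) and t-test p-value.

    log2fc = log2((mean FPKM case + c) / (mean FPKM control + c)); the
    p-value comes from a two-sided Welch t-test on log2(FPKM + c). Genes
    with identical values in both groups get p = 1.
    """
    for g in (case_group, control_group):
        n = sum(1 for s in counts.columns if groups.get(s) == g)
        if n < 2:
            raise ValueError(f"group {g!r} needs >= 2 samples, has {n}")
    fk = fpkm_matrix(counts, gene_lengths, total_fragments)
    case_cols = [s for s in fk.columns if groups[s] == case_group]
    ctrl_cols = [s for s in fk.columns if groups[s] == control_group]
    log_case = np.log2(fk[case_cols].to_numpy() + pseudocount)
    log_ctrl = np.log2(fk[ctrl_cols].to_numpy() + pseudocount)
    log2fc = np.log2(fk[case_cols].mean(axis=1) + pseudocount) - np.log2(
        fk[ctrl_cols].mean(axis=1) + pseudocount
    )
    t, p = stats.ttest_ind(log_case, log_ctrl, axis=1, equal_var=False)
    # Degenerate genes (zero variance in both groups): p is NaN; identical
    # means are a clean null (p=1), unequal constant groups are an extreme.
    p = np.asarray(p)
    nan = ~np.isfinite(p)
    if nan.any():
        diff = log_case.mean(axis=1) - log_ctrl.mean(axis=1)
        p[nan & (np.abs(diff) < 1e-12)] = 1.0
        p[nan & (np.abs(diff) >= 1e-12)] = np.finfo(float).tiny
    return pd.DataFrame(
        {"gene_id": counts.index, "log2fc": log2fc.to_numpy(), "pvalue": p}
    ).set_index("gene_id", drop=False)


def bh_adjust(pvalues: Sequence[float] | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_degs(
    de_table: pd.DataFrame,
    alpha: float = 0.05,
    annotation_status: Mapping[str, str] | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Call DEGs at BH-corrected p strictly below ``alpha``.

    ``de_table`` needs columns gene_id, log2fc, pvalue; a padj column is
    computed with :func:`bh_adjust` when absent, so externally corrected
    tables pass through unchanged. Returns the DEG table (with ``direction``
    up/down by the sign of log2fc and, when supplied, ``annotation_status``)
    and a breakdown of DEG counts by direction and annotation class. A DEG
    with log2fc exactly 0 is labelled direction ``tie``.
    """
    required = {"gene_id", "log2fc", "pvalue"}
    if not required.issubset(de_table.columns):
        raise KeyError(f"DE table must have columns {sorted(required)}")
    table = de_table.copy()
    if "padj" not in table.columns:
        table["padj"] = bh_adjust(table["pvalue"].to_numpy())
    degs = table[table["padj"] < alpha].copy()
    degs["direction"] = np.select(
        [degs["log2fc"] > 0, degs["log2fc"] < 0], ["up", "down"], default="tie"
    )
    if annotation_status is not None:
        degs["annotation_status"] = (
            degs["gene_id"].map(annotation_status).fillna("novel")
        )
    partition: dict[str, int] = {
        "n_degs": int(len(degs)),
        "n_up": int((degs["direction"] == "up").sum()),
        "n_down": int((degs["direction"] == "down").sum()),
    }
    if "annotation_status" in degs.columns:
        for status in ("annotated", "pseudogene", "novel"):
            partition[f"n_{status}"] = int(
                (degs["annotation_status"] == status).sum()
            )
    return degs, partition
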