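"""Relative qPCR quantification with the 2^-ddCt method.

Target-gene Ct values are normalized against the arithmetic mean Ct of the
reference genes measured on the same sample (for two references this equals
normalizing to the geometric mean of their linear quantities). Per-sample
dCt values are averaged within group; ddCt is the case-group mean minus the
calibrator-group mean, and the fold change is 2^-ddCt (amplification
efficiency fixed at 2). Samples are unpaired animals, so no per-sample
pairing is attempted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

PLATE_COLUMNS = ("gene", "sample", "group", "replicate", "ct")


def _validate_plate(plate: pd.DataFrame) -> None:
    missing = set(PLATE_COLUMNS) - set(plate.columns)
    if missing:
        raise KeyError(f"Ct plate is missing columns: {sorted(missing)}")
    if (plate["ct"] <= 0).any():
        raise ValueError("Ct values must be positive")


def mean_ct(plate: pd.DataFrame, gene: str, sample: str) -> float:
    """Arithmetic mean Ct over the replicates of one gene on one sample."""
    _validate_plate(plate)
    sel = plate[(plate["gene"] == gene) & (plate["sample"] == sample)]
    if sel.empty:
        raise KeyError(f"no Ct measurements for gene {gene!r} on sample {sample!r}")
    return float(sel["ct"].mean())


def sample_delta_ct(
    plate: pd.DataFrame, target_gene: str, reference_genes: Sequence[str], sample: str
) -> float:
    """dCt = mean Ct(target) - mean over references of mean Ct(ref)."""
    ref_cts = []
    for ref in reference_genes:
        try:
            ref_cts.append(mean_ct(plate, ref, sample))
        except KeyError as exc:
            raise KeyError(
                f"reference gene {ref!r} not measured on sample {sample!r}"
            ) from exc
    return mean_ct(plate, target_gene, sample) - float(np.mean(ref_cts))


def delta_delta_ct(
    plate: pd.DataFrame,
    target_gene: str,
    reference_genes: Sequence[str],
    case_group: str,
    calibrator_group: str,
) -> float:
    """Fold change 2^-ddCt of the target in case vs calibrator group."""
    _validate_plate(plate)
    if not reference_genes:
        raise ValueError("need at least one reference gene")
    delta: dict[str, list[float]] = {case_group: [], calibrator_group: []}
    for (sample, group), _ in plate.groupby(["sample", "group"], sort=True):
        if group in delta:
            delta[group].append(
                sample_delta_ct(plate, target_gene, reference_genes, sample)
            )
    for group, values in delta.items():
        if not values:
            raise ValueError(f"no samples found for group {group!r}")
    ddct = float(np.mean(delta[case_group]) - np.mean(delta[calibrator_group]))
    return 2.0 ** (-ddct)


@dataclass
class FoldChange:
    gene: str
    fold_change: float
    log2_ratio_qpcr: float
    log2_ratio_rnaseq: float | None = None


def fold_changes(
    plate: pd.DataFrame,
    target_genes: Sequence[str],
    reference_genes: Sequence[str],
    case_group: str,
    calibrator_group: str,
) -> pd.DataFrame:
    """2^-ddCt fold changes for several targets, as a tidy table."""
    rows = []
    for gene in target_genes:
        fc = delta_delta_ct(plate, gene, reference_genes, case_group, calibrator_group)
        rows.append(
            {"gene": gene, "fold_change": fc, "log2_ratio_qpcr": math.log2(fc)}
        )
    return pd.DataFrame(rows)


def correlate_with_rnaseq(
    qpcr_fold_changes: pd.DataFrame, rnaseq_log2fc: pd.Series | dict
) -> dict:
    """Pearson correlation of qPCR vs RNA-seq log2 ratios over shared genes.

    Returns r, its p-value, the fitted line (slope, intercept) and the
    scatter points; needs at least 3 shared genes.
    """
    rnaseq = pd.Series(rnaseq_log2fc)
    merged = qpcr_fold_changes.set_index("gene")[["log2_ratio_qpcr"]].join(
        rnaseq.rename("log2_ratio_rnaseq"), how="inner"
    )
    if len(merged) < 3:
        raise ValueError(
            f"need >= 3 genes shared between qPCR and RNA-seq, have {len(merged)}"
        )
    x = merged["log2_ratio_rnaseq"].to_numpy()
    y = merged["log2_ratio_qpcr"].to_numpy()
    r, p = stats.pearsonr(x, y)
    fit = stats.linregress(x, y)
    return {
        "pearson_r": float(r),
        "pvalue": float(p),
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
        "n_genes": int(len(merged)),
        "points": merged.reset_index(),
    }
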