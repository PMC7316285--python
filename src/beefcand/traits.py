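"""Two-group comparisons of growth and carcass traits.

Group summaries are reported as mean +/- SE; the difference between groups
is tested with an independent-sample Student t-test. The "SEM" printed next
to a two-group comparison in carcass-trait tables is the standard error of
the difference, SED = sqrt(SE1^2 + SE2^2). Significance tiers: p <= 0.01
highly significant, 0.01 < p <= 0.05 significant, 0.05 < p < 0.1 a trend.

The default test pools degrees of freedom (df = n1 + n2 - 2), the classical
SPSS-style independent-sample t-test; a Welch option is available.
Normality is checked with a Kolmogorov-Smirnov test against a normal with
parameters fitted from the sample (Lilliefors variant).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.diagnostic import lilliefors

TIER_HIGHLY_SIGNIFICANT = "highly_significant"
TIER_SIGNIFICANT = "significant"
TIER_TREND = "trend"
TIER_NS = "ns"


@dataclass(frozen=True)
class TraitSummary:
    trait: str
    group: str
    mean: float
    se: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"{self.trait}/{self.group}: need n >= 2")
        if self.se < 0:
            raise ValueError(f"{self.trait}/{self.group}: SE must be >= 0")


@dataclass(frozen=True)
class TraitComparison:
    trait: str
    mean_diff: float
    sed: float
    t_stat: float
    df: float
    pvalue: float
    tier: str


def sed_from_se(se_a: float, se_b: float) -> float:
    """Standard error of the difference of two independent means."""
    if se_a < 0 or se_b < 0:
        raise ValueError("standard errors must be >= 0")
    return math.hypot(se_a, se_b)


def significance_tier(p: float) -> str:
    if not (0 < p <= 1):
        raise ValueError("p must lie in (0, 1]")
    if p <= 0.01:
        return TIER_HIGHLY_SIGNIFICANT
    if p <= 0.05:
        return TIER_SIGNIFICANT
    if p < 0.1:
        return TIER_TREND
    return TIER_NS


def ttest_from_summary(
    a: TraitSummary, b: TraitSummary, welch: bool = False
) -> TraitComparison:
    """Independent-sample t-test computed from (mean, SE, n) summaries.

    With ``welch=True`` the Welch-Satterthwaite degrees of freedom are used
    instead of the pooled df = n_a + n_b - 2. A zero SED with equal means
    yields p = 1 by convention; a zero SED with unequal means is an error.
    """
    if a.trait != b.trait:
        raise ValueError(f"trait mismatch: {a.trait!r} vs {b.trait!r}")
    sed = sed_from_se(a.se, b.se)
    diff = a.mean - b.mean
    if sed == 0:
        if diff == 0:
            return TraitComparison(a.trait, 0.0, 0.0, 0.0, a.n + b.n - 2, 1.0, TIER_NS)
        raise ValueError(f"{a.trait}: zero SED with unequal means")
    t = diff / sed
    if welch:
        va, vb = a.se**2, b.se**2
        df = (va + vb) ** 2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
    else:
        df = a.n + b.n - 2
    p = 2 * stats.t.sf(abs(t), df)
    p = min(max(p, np.finfo(float).tiny), 1.0)
    return TraitComparison(a.trait, diff, sed, t, df, p, significance_tier(p))


def summarize_raw(trait: str, group: str, values: Sequence[float]) -> TraitSummary:
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError(f"{trait}/{group}: need >= 2 values")
    return TraitSummary(
        trait=trait,
        group=group,
        mean=float(v.mean()),
        se=float(v.std(ddof=1) / math.sqrt(v.size)),
        n=int(v.size),
    )


def ttest_from_raw(
    trait: str,
    values_a: Sequence[float],
    values_b: Sequence[float],
    welch: bool = False,
) -> TraitComparison:
    """t-test on raw per-animal values; equals the summary-based test."""
    return ttest_from_summary(
        summarize_raw(trait, "a", values_a),
        summarize_raw(trait, "b", values_b),
        welch=welch,
    )


def ks_normality(values: Sequence[float], alpha: float = 0.05) -> tuple[float, float, bool]:
    """Kolmogorov-Smirnov normality check with fitted mean and SD.

    Returns (statistic, p-value, pass flag); the sample passes when p >
    ``alpha``. Because the normal parameters are estimated from the sample,
    the Lilliefors correction of the p-value is used.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 4:
        raise ValueError("need at least 4 observations")
    if np.ptp(v) == 0:
        raise ValueError("constant sample has no defined normality test")
    stat, p = lilliefors(v, dist="norm")
    return float(stat), float(p), bool(p > alpha)


def compare_summary_table(summaries: "pd.DataFrame", welch: bool = False) -> "pd.DataFrame":
    """Run per-trait comparisons from a long summary table.

    Expects columns trait, group, mean, se, n with exactly two groups per
    trait; the difference is group1 - group2 in the table's group sort
    order. Output mirrors a carcass-trait table: per-group mean +/- SE, the
    SED, p-value and tier, with p and SED rounded to 3 decimals for report
    columns (unrounded values are retained).
    """
    import pandas as pd

    rows = []
    for trait, sub in summaries.groupby("trait", sort=False):
        sub = sub.sort_values("group")
        if len(sub) != 2:
            raise ValueError(f"trait {trait!r}: expected exactly 2 groups")
        recs = [
            TraitSummary(trait, r.group, float(r.mean), float(r.se), int(r.n))
            for r in sub.itertuples()
        ]
        cmp = ttest_from_summary(recs[0], recs[1], welch=welch)
        rows.append(
            {
                "trait": trait,
                "group_a": recs[0].group,
                "mean_a": recs[0].mean,
                "se_a": recs[0].se,
                "group_b": recs[1].group,
                "mean_b": recs[1].mean,
                "se_b": recs[1].se,
                "mean_diff": cmp.mean_diff,
                "sed": cmp.sed,
                "sed_3dp": round(cmp.sed, 3),
                "t_stat": cmp.t_stat,
                "df": cmp.df,
                "pvalue": cmp.pvalue,
                "pvalue_3dp": round(cmp.pvalue, 3),
                "tier": cmp.tier,
            }
        )
    return pd.DataFrame(rows)


def compare_raw_table(phenotypes: "pd.DataFrame", welch: bool = False) -> "pd.DataFrame":
    """Per-trait comparisons from a long raw table (trait, group, value)."""
    import pandas as pd

    summaries = []
    for (trait, group), sub in phenotypes.groupby(["trait", "group"], sort=False):
        s = summarize_raw(trait, group, sub["value"].to_numpy())
        summaries.append(
            {"trait": trait, "group": group, "mean": s.mean, "se": s.se, "n": s.n}
        )
    return compare_summary_table(pd.DataFrame(summaries), welch=welch)
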