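"""Zebrafish larval morphometrics: rank-sum group comparisons with
Bonferroni correction and significance stars, plus ddCt RT-qPCR
quantification.

Feature tables hold one larva per row with per-feature measurements
(total area, body length, eye distance, telencephalon width, head-trunk
angle, mid-/forebrain areas). Group comparisons use the two-sided
Wilcoxon rank-sum test — exact when both groups have at most 25
observations and the pooled values are tie-free, otherwise the normal
approximation with midranks and tie correction — and report a
median-ratio fold change (mean-ratio available by flag).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupComparison",
    "FISHINSPECTOR_ALIASES",
    "load_feature_tsv",
    "compare_feature",
    "adjust_and_star",
    "compare_features",
    "ddct_fold_change",
]

#: FishInspector 2.0 export column names mapped to canonical feature names
FISHINSPECTOR_ALIASES = {
    "contourDV_regionpropsArea": "total_area",
    "contourDV_regionpropsLengthOfCentralLine": "body_length",
    "YdistanceCenter_eye1DV_eye2DV": "eye_distance",
    "YdistanceEdge_eye1DV_eye2DV": "telencephalon_width",
}

STAR_THRESHOLDS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))

EXACT_MAX_N = 25
ENUMERATE_MAX_POOLED = 16  # full permutation null is cheap up to C(16,8)


@dataclass
class GroupComparison:
    feature: str
    group_test: str
    group_control: str
    n_test: int
    n_control: int
    fold_change: float
    statistic: float
    p: float
    p_adjusted: float | None = None
    stars: str = "ns"


def load_feature_tsv(path) -> pd.DataFrame:
    """Read a larva feature TSV, renaming FishInspector export columns."""
    df = pd.read_csv(path, sep="\t")
    return df.rename(columns=FISHINSPECTOR_ALIASES)


def compare_feature(
    table: pd.DataFrame,
    feature: str,
    test_group: str,
    control_group: str,
    group_col: str = "group",
    use_mean_fold_change: bool = False,
) -> GroupComparison:
    """Two-sided Wilcoxon rank-sum comparison of one feature between groups.

    Fold change is the ratio of group medians (test over control); pass
    ``use_mean_fold_change`` for a mean ratio instead. Requires at least 3
    non-missing larvae per group. When every value in both groups is
    identical the comparison degenerates to p = 1, fold change 1.
    """
    x = table.loc[table[group_col] == test_group, feature].dropna().to_numpy(float)
    y = table.loc[table[group_col] == control_group, feature].dropna().to_numpy(float)
    if len(x) < 3 or len(y) < 3:
        raise ValueError(f"need >= 3 larvae per group for {feature!r}")
    center = np.mean if use_mean_fold_change else np.median
    denom = center(y)
    fold = float(center(x) / denom) if denom != 0 else np.nan
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return GroupComparison(feature, test_group, control_group, len(x), len(y),
                               1.0, 0.0, 1.0)
    has_ties = len(np.unique(pooled)) < len(pooled)
    small = len(x) <= EXACT_MAX_N and len(y) <= EXACT_MAX_N
    if small and not has_ties:
        method = "exact"
    elif small and len(pooled) <= ENUMERATE_MAX_POOLED:
        # exhaustive midrank permutation null (exact even with ties)
        method = stats.PermutationMethod(n_resamples=np.inf)
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return GroupComparison(
        feature=feature,
        group_test=test_group,
        group_control=control_group,
        n_test=len(x),
        n_control=len(y),
        fold_change=fold,
        statistic=float(res.statistic),
        p=float(min(res.pvalue, 1.0)),
    )


def adjust_and_star(
    comparisons: list[GroupComparison], m: int | None = None
) -> list[GroupComparison]:
    """Bonferroni-adjust p-values in place and assign significance stars.

    ``m`` is the family size (defaults to the number of comparisons; it may
    not be smaller). Stars follow p_adj <= 0.05 '*', <= 0.01 '**',
    <= 0.001 '***', else 'ns' — thresholds inclusive.
    """
    if m is None:
        m = len(comparisons)
    if m < len(comparisons):
        raise ValueError("family size m must cover all comparisons")
    for c in comparisons:
        c.p_adjusted = min(1.0, m * c.p)
        c.stars = "ns"
        for cutoff, stars in STAR_THRESHOLDS:
            if c.p_adjusted <= cutoff:
                c.stars = stars
                break
    return comparisons


def compare_features(
    table: pd.DataFrame,
    features: list[str],
    test_group: str,
    control_group: str,
    m: int | None = None,
    **kwargs,
) -> pd.DataFrame:
    """Compare several features and Bonferroni-adjust as one family."""
    comps = [
        compare_feature(table, f, test_group, control_group, **kwargs)
        for f in features
    ]
    adjust_and_star(comps, m=m)
    return pd.DataFrame([vars(c) for c in comps])


def ddct_fold_change(ct: pd.DataFrame, test_group: str, control_group: str) -> dict:
    """Relative expression by the ddCt method: FC = 2^-(ddCt).

    ``ct`` holds columns ``sample``, ``group``, ``gene`` ('target' or
    'reference') and ``ct_value``, with at least 3 replicates of each gene
    in each group. dCt is the group-mean target Ct minus the group-mean
    reference Ct; ddCt = dCt_test - dCt_control. Per-replicate fold changes
    (each test replicate's dCt against the control-group mean dCt) are also
    returned for downstream testing.
    """
    out = {}
    for grp in (test_group, control_group):
        sub = ct[ct["group"] == grp]
        for gene in ("target", "reference"):
            n = (sub["gene"] == gene).sum()
            if n == 0:
                raise ValueError(f"missing {gene} gene measurements in group {grp!r}")
            if n < 3:
                raise ValueError(f"need >= 3 {gene} replicates in group {grp!r}")
        out[grp] = (
            sub[sub["gene"] == "target"]["ct_value"].mean()
            - sub[sub["gene"] == "reference"]["ct_value"].mean()
        )
    ddct = out[test_group] - out[control_group]
    test = ct[ct["group"] == test_group]
    ref_mean = test[test["gene"] == "reference"]["ct_value"].mean()
    replicate_fc = [
        float(2.0 ** -((row.ct_value - ref_mean) - out[control_group]))
        for row in test[test["gene"] == "target"].itertuples()
    ]
    return {
        "dct_test": float(out[test_group]),
        "dct_control": float(out[control_group]),
        "ddct": float(ddct),
        "fold_change": float(2.0 ** -ddct),
        "replicate_fold_changes": replicate_fc,
    }
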