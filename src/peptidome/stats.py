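"""Pre-classification statistics: age filter and gated group comparisons.

Two stages guard the classifier input.  First, any ion whose area rank-
correlates with subject age (Spearman) is removed, so the signature cannot
learn the age gap between patients and controls.  Second, each remaining
ion is compared between the two groups with a test chosen by the standard
assumption gate: Shapiro-Wilk normality per group and median-centred
Levene homogeneity decide between a pooled two-sample t-test and the
Mann-Whitney U test.  Calls are reported as Up / Down / n.s. with binned
p-values, matching the conventional reporting layout.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import FeatureMatrix

__all__ = ["age_correlation_filter", "group_compare", "p_bin"]


def p_bin(p: float) -> str:
    if p < 0.001:
        return "<0.001"
    if p < 0.05:
        return "<0.05"
    return ">0.05"


def age_correlation_filter(
    matrix: FeatureMatrix, alpha: float = 0.05, within: str | None = None
) -> tuple[list[str], pd.DataFrame]:
    """Exclude features whose areas rank-correlate with age.

    Returns the retained feature labels and a per-feature report with
    Spearman rho (midrank ties), its p-value and the exclusion flag.
    Constant features, for which rho is undefined, are retained with
    rho recorded as 0.

    When case and control age distributions differ, every genuine
    disease marker is marginally age-correlated through the group
    difference alone; ``within`` restricts the correlation to one group
    (typically the controls) so the filter removes ions tracking ageing
    rather than ions tracking disease.  ``None`` uses all subjects.
    """
    if "age" not in matrix.metadata.columns:
        raise ValueError("metadata must carry an 'age' column")
    if matrix.metadata["age"].isna().any():
        raise ValueError("ages missing for some subjects")
    if within is None:
        sub = matrix.metadata.index
    else:
        sub = matrix.metadata.index[matrix.metadata["group"] == within]
        if len(sub) < 4:
            raise ValueError(f"too few subjects in group {within!r} for the age filter")
    age = matrix.metadata.loc[sub, "age"].to_numpy(dtype=float)
    rows = []
    for label in matrix.features:
        x = matrix.areas.loc[sub, label].to_numpy(dtype=float)
        if np.all(x == x[0]):
            rows.append((label, 0.0, 1.0, False, True))
            continue
        rho, p = sps.spearmanr(x, age)
        rows.append((label, float(rho), float(p), bool(p < alpha), False))
    report = pd.DataFrame(
        rows, columns=["feature", "spearman_rho", "spearman_p", "age_excluded", "constant"]
    ).set_index("feature")
    retained = report.index[~report["age_excluded"]].tolist()
    return retained, report


def _compare_one(case: np.ndarray, ctrl: np.ndarray, normality_alpha: float):
    """Assumption gate -> test choice -> (test name, p, normality/levene p)."""
    if np.all(case == case[0]) and np.all(ctrl == ctrl[0]) and case[0] == ctrl[0]:
        return "none", 1.0, (np.nan, np.nan), np.nan
    # Shapiro-Wilk is undefined for constant samples; treat as non-normal
    try:
        p_norm_case = float(sps.shapiro(case).pvalue)
    except ValueError:
        p_norm_case = 0.0
    try:
        p_norm_ctrl = float(sps.shapiro(ctrl).pvalue)
    except ValueError:
        p_norm_ctrl = 0.0
    try:
        p_lev = float(sps.levene(case, ctrl, center="median").pvalue)
    except ValueError:
        p_lev = 0.0
    normal = p_norm_case >= normality_alpha and p_norm_ctrl >= normality_alpha
    homogeneous = p_lev >= normality_alpha
    if normal and homogeneous:
        stat = sps.ttest_ind(case, ctrl, equal_var=True)
        return "parametric", float(stat.pvalue), (p_norm_case, p_norm_ctrl), p_lev
    stat = sps.mannwhitneyu(case, ctrl, alternative="two-sided")
    return "nonparametric", float(stat.pvalue), (p_norm_case, p_norm_ctrl), p_lev


def group_compare(
    matrix: FeatureMatrix,
    case_group,
    control_group,
    alpha: float = 0.05,
    normality_alpha: float = 0.05,
    fdr: bool = False,
) -> pd.DataFrame:
    """Per-feature two-group comparison with Up/Down/n.s. direction calls.

    ``case_group`` / ``control_group`` may be a single group label or a
    collection of labels pooled together.  Direction is Up when the case
    median exceeds the control median at p < alpha, Down for the reverse,
    n.s. otherwise.  ``fdr=True`` additionally applies Benjamini-Hochberg
    and bases calls on the adjusted p-values (off by default: the
    conventional report is per-ion unadjusted p).
    """
    groups = matrix.metadata["group"]
    case_set = {case_group} if isinstance(case_group, str) else set(case_group)
    ctrl_set = {control_group} if isinstance(control_group, str) else set(control_group)
    case_ids = groups[groups.isin(case_set)].index
    ctrl_ids = groups[groups.isin(ctrl_set)].index
    if len(case_ids) < 3 or len(ctrl_ids) < 3:
        raise ValueError(
            f"need >= 3 subjects per group, got {len(case_ids)} vs {len(ctrl_ids)}"
        )
    rows = []
    for label in matrix.features:
        case = matrix.areas.loc[case_ids, label].to_numpy(dtype=float)
        ctrl = matrix.areas.loc[ctrl_ids, label].to_numpy(dtype=float)
        test, p, (pn_case, pn_ctrl), p_lev = _compare_one(case, ctrl, normality_alpha)
        rows.append({
            "feature": label,
            "test_used": test,
            "group_p": p,
            "normality_p_case": pn_case,
            "normality_p_control": pn_ctrl,
            "variance_homogeneity_p": p_lev,
            "median_case": float(np.median(case)),
            "median_control": float(np.median(ctrl)),
        })
    report = pd.DataFrame(rows).set_index("feature")
    p_eff = report["group_p"].to_numpy()
    if fdr:
        p_eff = sps.false_discovery_control(p_eff, method="bh")
        report["group_p_adj"] = p_eff
    direction = np.where(
        p_eff >= alpha, "n.s.",
        np.where(report["median_case"] > report["median_control"], "Up", "Down"),
    )
    # significant but identical medians: no call either way
    direction[(p_eff < alpha) & (report["median_case"] == report["median_control"])] = "n.s."
    report["direction"] = direction
    report["p_bin"] = [p_bin(p) for p in p_eff]
    report["alpha"] = alpha
    return report
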