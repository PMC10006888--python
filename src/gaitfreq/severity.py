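"""Severity grouping and univariate statistics.

Participants are split into three severity groups either by terciles of a
KOOS subscale (higher score = milder disease = G0) or by Kellgren-Lawrence
grade (controls G0, KL 1-2 G1, KL 3-4 G2).  Group comparisons use the
Wilcoxon rank-sum test (exact in small untied samples, normal
approximation with tie and continuity corrections otherwise) together with
Welch t confidence intervals for differences of means; a Holm-adjusted
p-value column is emitted alongside the raw values as a clearly labelled
extension.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

KOOS_CRITERIA = ("koos_pain", "koos_symptom", "koos_adl", "koos_sport", "koos_qol")
GROUPS = ("G0", "G1", "G2")


@dataclass
class SeverityGrouping:
    """criterion (KOOS subscale or 'kl') and participant id -> G0/G1/G2."""

    criterion: str
    assignment: dict


def assign_groups(participants, criterion: str) -> SeverityGrouping:
    """Three severity groups per participant.

    KOOS criteria: terciles (33rd/67th percentiles, linear interpolation) of
    the pooled scores; boundary values go to the milder (higher-score)
    group.  'kl': controls G0, KL grades 1-2 G1, KL grades 3-4 G2.
    """
    if criterion == "kl":
        assignment = {}
        missing = [
            p.id for p in participants if p.group == "patient" and p.kl_grade is None
        ]
        if missing:
            raise ValueError(f"missing KL grades for {missing}")
        for p in participants:
            if p.group == "control" or (p.kl_grade is not None and p.kl_grade == 0):
                assignment[p.id] = "G0"
            elif p.kl_grade in (1, 2):
                assignment[p.id] = "G1"
            else:
                assignment[p.id] = "G2"
        return SeverityGrouping("kl", assignment)

    if criterion not in KOOS_CRITERIA:
        raise ValueError(f"unknown severity criterion {criterion!r}")
    sub = criterion.removeprefix("koos_")
    missing = [p.id for p in participants if sub not in p.koos]
    if missing:
        raise ValueError(f"missing KOOS {sub} scores for {missing}")
    scores = np.array([p.koos[sub] for p in participants], dtype=float)
    p33, p67 = np.percentile(scores, [33, 67])
    if p33 == p67:
        raise ValueError("degenerate percentiles: scores do not separate terciles")
    assignment = {}
    for p, s in zip(participants, scores):
        if s >= p67:
            assignment[p.id] = "G0"
        elif s >= p33:
            assignment[p.id] = "G1"
        else:
            assignment[p.id] = "G2"
    return SeverityGrouping(criterion, assignment)


def wilcoxon_rank_sum(x, y):
    """Rank-sum statistic (midranks) and two-sided p-value.

    Exact enumeration when min(n_x, n_y) <= 8 with no ties; normal
    approximation with tie and continuity corrections otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    w = float(ranks[: x.size].sum())
    has_ties = np.unique(pooled).size < pooled.size
    if min(x.size, y.size) <= 8 and not has_ties:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
    else:
        res = stats.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True
        )
    return w, float(res.pvalue)


def _welch_ci(x, y, conf=0.95):
    """Welch t interval for mean(x) - mean(y); (0, 0) when all values tie."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.std(ddof=0) == 0 and y.std(ddof=0) == 0:
        d = x.mean() - y.mean()
        return (d, d)
    res = stats.ttest_ind(x, y, equal_var=False)
    ci = res.confidence_interval(confidence_level=conf)
    return (float(ci.low), float(ci.high))


def _holm(pvals):
    p = np.asarray(pvals, dtype=float)
    order = np.argsort(p)
    adj = np.empty_like(p)
    running = 0.0
    m = len(p)
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * p[i])
        adj[i] = min(1.0, running)
    return adj


def compare_table3(feature_df: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    """Patient-vs-control comparison of omega and the 18 harmonic powers.

    Returns one row per feature: group means with ranges, control-minus-
    patient Welch 95% CI, Wilcoxon p, and a Holm-adjusted p column
    (extension, not part of the original analysis convention).
    """
    groups = groups.loc[feature_df.index]
    ctrl = feature_df[groups == "control"]
    pat = feature_df[groups == "patient"]
    rows = []
    for col in feature_df.columns:
        x, y = ctrl[col].to_numpy(), pat[col].to_numpy()
        row = {
            "feature": col,
            "control_mean": x.mean() if x.size else np.nan,
            "control_min": x.min() if x.size else np.nan,
            "control_max": x.max() if x.size else np.nan,
            "patient_mean": y.mean() if y.size else np.nan,
            "patient_min": y.min() if y.size else np.nan,
            "patient_max": y.max() if y.size else np.nan,
        }
        if x.size < 2 or y.size < 2:
            row.update(diff_ci_low=np.nan, diff_ci_high=np.nan, flagged=True,
                       p_value=np.nan)
        else:
            lo, hi = _welch_ci(x, y)
            if np.unique(np.concatenate([x, y])).size == 1:
                p = 1.0
            else:
                _, p = wilcoxon_rank_sum(x, y)
            row.update(diff_ci_low=lo, diff_ci_high=hi, p_value=p, flagged=False)
        rows.append(row)
    out = pd.DataFrame(rows).set_index("feature")
    valid = out["p_value"].notna()
    out["p_holm"] = np.nan
    out.loc[valid, "p_holm"] = _holm(out.loc[valid, "p_value"].to_numpy())
    return out


def auxiliary_tests(participants, stride_periods=None) -> dict:
    """Chi-square sex test, Shapiro-Wilk normality screen, cadence comparison.

    ``stride_periods`` maps participant id -> stride period in seconds;
    cadence is 2 steps per stride: 120 / T steps per minute.
    """
    groups = np.array([p.group for p in participants])
    sexes = np.array([p.sex for p in participants])
    table = pd.crosstab(pd.Series(groups), pd.Series(sexes))
    expected = stats.contingency.expected_freq(table.to_numpy())
    if np.any(expected == 0):
        raise ValueError("expected cell count of zero in the sex-by-group table")
    chi2 = stats.chi2_contingency(table.to_numpy(), correction=True)
    out = {
        "sex_table": table,
        "sex_chi2": float(chi2.statistic),
        "sex_p": float(chi2.pvalue),
        "shapiro": {},
    }
    cont = {
        "age": np.array([p.age for p in participants]),
        "bmi": np.array([p.bmi for p in participants]),
    }
    for name, vals in cont.items():
        sw = stats.shapiro(vals)
        out["shapiro"][name] = {"W": float(sw.statistic), "p": float(sw.pvalue)}
    if stride_periods is not None:
        cad = pd.Series(
            {pid: 120.0 / t for pid, t in stride_periods.items()}, name="cadence"
        )
        by_group = {
            g: cad[[p.id for p in participants if p.group == g]].to_numpy()
            for g in ("control", "patient")
        }
        w, p = wilcoxon_rank_sum(by_group["control"], by_group["patient"])
        out["cadence"] = {
            "control_mean": float(by_group["control"].mean()),
            "patient_mean": float(by_group["patient"].mean()),
            "diff_ci": _welch_ci(by_group["control"], by_group["patient"]),
            "p": p,
        }
    return out


def selected_feature_boxdata(
    feature_df: pd.DataFrame, grouping: SeverityGrouping, selected
) -> pd.DataFrame:
    """Per-group distributions and pairwise Wilcoxon tests of selected features.

    One row per (feature, pair of groups); empty groups are skipped and
    flagged.  ``selected`` is the active set at the chosen penalty.
    """
    assign = pd.Series(grouping.assignment)
    assign = assign.loc[assign.index.intersection(feature_df.index)]
    rows = []
    for feat in selected:
        vals = {g: feature_df.loc[assign[assign == g].index, feat] for g in GROUPS}
        for g1, g2 in combinations(GROUPS, 2):
            row = {
                "criterion": grouping.criterion,
                "feature": feat,
                "pair": f"{g1}-{g2}",
                f"n_{g1}": len(vals[g1]),
                f"n_{g2}": len(vals[g2]),
            }
            if len(vals[g1]) == 0 or len(vals[g2]) == 0:
                row.update(p_value=np.nan, skipped=True)
            else:
                if (
                    np.unique(
                        np.concatenate([vals[g1].to_numpy(), vals[g2].to_numpy()])
                    ).size
                    == 1
                ):
                    row.update(p_value=1.0, skipped=False)
                else:
                    _, p = wilcoxon_rank_sum(vals[g1], vals[g2])
                    row.update(p_value=p, skipped=False)
            for g in (g1, g2):
                row[f"median_{g}"] = (
                    float(vals[g].median()) if len(vals[g]) else np.nan
                )
            rows.append(row)
    return pd.DataFrame(rows)
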