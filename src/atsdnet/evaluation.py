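"""Univariate screening and diagnostic evaluation of candidate ratios.

Candidates surviving the network analysis are screened univariately: a
Welch two-sample t-test contrasts model against control at every
disease-stage time point, and a paired t-test contrasts the typical
pre-onset point against every disease-stage point within model subjects.
A candidate passes only when *all* of those p-values fall below alpha.
Diagnostic performance is summarised by the ROC curve: the AUC via the
Mann-Whitney pair-counting estimator (ties count one half), its standard
error by the Hanley-McNeil formula, and the best cut-off as the Youden
index maximiser (ties broken toward higher specificity).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import CONTROL, MODEL, StageDesign, TimeSeriesDataset
from .errors import AtsdnetError
from .ratio_dynamics import ratio_series

Pair = tuple[str, str]
ALPHA = 0.05


# ---------------------------------------------------------------------------
# univariate tests


def group_tests(
    ds: TimeSeriesDataset, pair: Pair, stage_points: list[int], welch: bool = True
) -> dict[int, float]:
    """Model-vs-control two-sample t-test of a ratio at each listed time point.

    Welch's unequal-variance form by default.  Points where either group
    has fewer than two samples get NaN with a warning.
    """
    rs = ratio_series(ds, *pair)
    meta = ds.meta
    out: dict[int, float] = {}
    for t in stage_points:
        at_t = meta["time"].to_numpy() == t
        vals = rs.values[t] if t in rs.values else np.array([])
        groups = meta.loc[at_t, "group"].to_numpy()
        x = vals[groups == MODEL]
        y = vals[groups == CONTROL]
        if len(x) < 2 or len(y) < 2:
            warnings.warn(f"too few samples for a group test at T{t}", stacklevel=2)
            out[t] = float("nan")
            continue
        out[t] = float(stats.ttest_ind(x, y, equal_var=not welch).pvalue)
    return out


def paired_tests(
    ds: TimeSeriesDataset,
    pair: Pair,
    reference_point: int,
    stage_points: list[int],
) -> dict[int, float]:
    """Within-subject paired t-test, reference point vs each disease point.

    Model group only; subjects missing at either point of a comparison are
    excluded.  Fewer than two complete pairs, or identical paired values,
    yield NaN.
    """
    rs = ratio_series(ds, *pair, group=MODEL)
    ref_subjects = ds.subjects_at(reference_point, MODEL)
    ref = dict(zip(ref_subjects, rs.values[reference_point]))
    out: dict[int, float] = {}
    for t in stage_points:
        subjects = ds.subjects_at(t, MODEL)
        vals = dict(zip(subjects, rs.values[t]))
        common = [s for s in ref_subjects if s in vals]
        if len(common) < 2:
            warnings.warn(f"fewer than 2 complete pairs for T{reference_point} vs T{t}",
                          stacklevel=2)
            out[t] = float("nan")
            continue
        a = np.array([ref[s] for s in common])
        b = np.array([vals[s] for s in common])
        if np.all(a == b):
            warnings.warn(f"identical paired values for T{reference_point} vs T{t}; "
                          "t statistic undefined", stacklevel=2)
            out[t] = float("nan")
            continue
        out[t] = float(stats.ttest_rel(b, a).pvalue)
    return out


# ---------------------------------------------------------------------------
# ROC


@dataclass(frozen=True)
class RocResult:
    auc: float
    se: float
    ci_low: float
    ci_high: float
    cutoff: float
    sensitivity: float
    specificity: float
    curve: pd.DataFrame  # (cutoff, sensitivity, specificity) per threshold


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> RocResult:
    """ROC analysis with the pair-counting AUC and Youden best cut-off.

    ``labels`` are binary with 1 = disease (positive).  The AUC is the
    Mann-Whitney estimator: the fraction of (positive, negative) pairs
    ranked concordantly, ties counting one half.  The standard error uses
    Hanley & McNeil's formula and the 95% CI is a normal interval clipped
    to [0, 1].  Cut-offs classify ``score >= c`` as positive; the best
    cut-off maximises Youden's J with ties broken toward higher
    specificity, then toward the larger cut-off.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise AtsdnetError("ROC needs at least one sample in each class")

    diff = pos[:, None] - neg[None, :]
    auc = float((np.sum(diff > 0) + 0.5 * np.sum(diff == 0)) / diff.size)

    n_pos, n_neg = len(pos), len(neg)
    q1 = auc / (2 - auc)
    q2 = 2 * auc**2 / (1 + auc)
    var = (
        auc * (1 - auc)
        + (n_pos - 1) * (q1 - auc**2)
        + (n_neg - 1) * (q2 - auc**2)
    ) / (n_pos * n_neg)
    se = float(np.sqrt(max(var, 0.0)))
    ci_low = float(np.clip(auc - 1.959964 * se, 0, 1))
    ci_high = float(np.clip(auc + 1.959964 * se, 0, 1))

    rows = []
    for c in np.unique(scores):
        sens = float(np.mean(pos >= c))
        spec = float(np.mean(neg < c))
        rows.append((float(c), sens, spec))
    curve = pd.DataFrame(rows, columns=["cutoff", "sensitivity", "specificity"])
    j = curve["sensitivity"] + curve["specificity"] - 1
    best = curve.loc[
        curve.sort_values(
            by=["specificity", "cutoff"], ascending=[False, False]
        ).index
    ]
    best = best.loc[j[best.index] == j.max()].iloc[0]

    return RocResult(
        auc=auc,
        se=se,
        ci_low=ci_low,
        ci_high=ci_high,
        cutoff=float(best["cutoff"]),
        sensitivity=float(best["sensitivity"]),
        specificity=float(best["specificity"]),
        curve=curve,
    )


def disease_labels(
    ds: TimeSeriesDataset, design: StageDesign, pair: Pair
) -> tuple[np.ndarray, np.ndarray]:
    """Scores and labels for onset-stage vs pre-onset discrimination.

    Model-group samples only: positives are the samples at the onset-stage
    time points, negatives the samples at all earlier points.
    """
    rs = ratio_series(ds, *pair, group=MODEL)
    disease = set(design.disease_points(ds))
    scores, labels = [], []
    for t, vals in rs.values.items():
        lab = 1 if t in disease else 0
        scores.extend(vals.tolist())
        labels.extend([lab] * len(vals))
    return np.asarray(scores), np.asarray(labels)


# ---------------------------------------------------------------------------
# candidate report and screen


def candidate_report(
    ds: TimeSeriesDataset,
    design: StageDesign,
    pairs: list[Pair],
    alpha: float = ALPHA,
    welch: bool = True,
) -> pd.DataFrame:
    """Full per-candidate evaluation table.

    One row per ratio: group-test p-values at every disease-stage point,
    paired-test p-values (reference vs each disease point), ROC metrics,
    and the pass/fail screen flag.
    """
    disease = design.disease_points(ds)
    ref = design.reference_point(ds)
    rows = []
    for pair in pairs:
        gp = group_tests(ds, pair, disease, welch=welch)
        pp = paired_tests(ds, pair, ref, disease)
        scores, labels = disease_labels(ds, design, pair)
        roc = roc_auc(scores, labels)
        all_p = list(gp.values()) + list(pp.values())
        has_na = any(np.isnan(p) for p in all_p)
        passed = (not has_na) and all(p < alpha for p in all_p)
        row = {
            "ratio": f"{pair[0]}/{pair[1]}",
            "node_i": pair[0],
            "node_j": pair[1],
            **{f"p_group_T{t}": p for t, p in gp.items()},
            **{f"p_paired_T{ref}_T{t}": p for t, p in pp.items()},
            "auc": roc.auc,
            "auc_se": roc.se,
            "auc_ci_low": roc.ci_low,
            "auc_ci_high": roc.ci_high,
            "cutoff": roc.cutoff,
            "sensitivity": roc.sensitivity,
            "specificity": roc.specificity,
            "pass": passed,
            "fail_reason": "missing p-value" if has_na else
                           ("" if passed else "p >= alpha"),
        }
        rows.append(row)
    return pd.DataFrame(rows)


def screen_candidates(report: pd.DataFrame, alpha: float = ALPHA) -> list[str]:
    """Ratios passing the simultaneous screen: every p-value below alpha.

    Conservative on missing values: any NaN p-value fails the candidate.
    """
    p_cols = [c for c in report.columns if c.startswith("p_")]
    passing = []
    for _, row in report.iterrows():
        ps = row[p_cols].astype(float)
        if ps.isna().any():
            continue
        if (ps < alpha).all():
            passing.append(row["ratio"])
    return passing


# ---------------------------------------------------------------------------
# PCA and trajectories


def pca_summary(X: np.ndarray | pd.DataFrame) -> dict:
    """Autoscaled PCA: variance explained by the first two components.

    Constant columns are dropped with a warning.  Returns the per-component
    and cumulative variance fractions plus per-sample scores.
    """
    from sklearn.decomposition import PCA

    arr = np.asarray(X, dtype=float)
    if arr.shape[0] < 3 or arr.shape[1] < 2:
        raise AtsdnetError(f"PCA needs >= 3 samples and >= 2 columns, got {arr.shape}")
    sd = arr.std(axis=0)
    keep = sd > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} constant column(s) before PCA",
                      stacklevel=2)
        arr = arr[:, keep]
        sd = sd[keep]
    Z = (arr - arr.mean(axis=0)) / sd
    n_comp = min(2, Z.shape[1], Z.shape[0] - 1)
    pca = PCA(n_components=n_comp)
    scores = pca.fit_transform(Z)
    ratios = pca.explained_variance_ratio_
    return {
        "explained": [float(r) for r in ratios],
        "cumulative": float(ratios.sum()),
        "scores": pd.DataFrame(scores, columns=[f"PC{k+1}" for k in range(n_comp)]),
    }


def trajectory_summary(ds: TimeSeriesDataset, pair: Pair) -> pd.DataFrame:
    """Per-group, per-time-point mean and standard error of a ratio."""
    rs = ratio_series(ds, *pair)
    meta = ds.meta
    rows = []
    for t, vals in rs.values.items():
        groups = meta.loc[meta["time"] == t, "group"].to_numpy()
        for g in (CONTROL, MODEL):
            v = vals[groups == g]
            n = len(v)
            if n == 0:
                continue
            se = float(v.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
            rows.append({"group": g, "time": t, "mean": float(v.mean()),
                         "se": se, "n": n})
    return pd.DataFrame(rows)
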