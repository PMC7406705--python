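"""Model evaluation: repeated stratified cross-validation, ROC AUC with a
fold-averaged confidence interval, screening cutoff statistics, and the
rank-sum cohort characterization table.

The study design this mirrors is 100 repetitions of stratified 5-fold
cross-validation on a 48-subject cohort: per repetition each subject is
scored exactly once out-of-fold, AUCs are computed per test fold, and the
95% CI is the normal approximation over all repetition × fold AUCs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CohortTable
from .dsi import fit_dsi, score
from .hierarchy import FeatureHierarchy


class EvaluationError(ValueError):
    """Raised for unusable evaluation inputs (single-class labels etc.)."""


# ---------------------------------------------------------------------------
# ROC AUC


def roc_auc(scores, labels) -> float:
    """Rank-based ROC AUC with ties counted 1/2 (Mann–Whitney statistic).

    Equivalent to trapezoidal integration of the empirical ROC curve and to
    P(score+ > score−) + ½ P(tie). NaN scores are not allowed here; the CV
    machinery excludes flagged (all-missing) subjects before calling.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if np.isnan(s).any():
        raise EvaluationError("scores contain NaN")
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise EvaluationError("both classes are required to compute an AUC")
    ranks = stats.rankdata(s)  # average ranks handle ties as 1/2
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def confidence_interval(fold_aucs, method: str = "normal") -> tuple[float, float]:
    """95% CI of the mean AUC from the distribution of fold AUCs.

    ``normal``: mean ± 1.96 × SD of the fold AUCs, truncated to [0, 1];
    ``percentile``: the 2.5–97.5 percentile range. NaN fold AUCs (e.g.
    single-class test folds in leave-one-out) are ignored.
    """
    a = np.asarray(fold_aucs, dtype=float)
    a = a[~np.isnan(a)]
    if len(a) < 2:
        raise EvaluationError("need at least two fold AUCs")
    if method == "percentile":
        lo, hi = np.percentile(a, [2.5, 97.5])
    elif method == "normal":
        sd = a.std(ddof=1)
        lo, hi = a.mean() - 1.96 * sd, a.mean() + 1.96 * sd
    else:
        raise ValueError(f"unknown CI method {method!r}")
    return float(np.clip(lo, 0.0, 1.0)), float(np.clip(hi, 0.0, 1.0))


# ---------------------------------------------------------------------------
# Cross-validation


@dataclass
class CVResult:
    """Fold-level AUCs and pooled out-of-fold scores of one CV run."""

    fold_aucs: np.ndarray  # (repetitions, folds), NaN where undefined
    oof_scores: np.ndarray  # (repetitions, n_subjects)
    labels: np.ndarray  # (n_subjects,)
    mean_auc: float
    ci: tuple[float, float]

    @property
    def repetitions(self) -> int:
        return self.fold_aucs.shape[0]


def stratified_folds(labels, folds: int, rng: np.random.Generator) -> np.ndarray:
    """Random fold ids preserving class proportions.

    Members of each class are shuffled and dealt cyclically; the deal
    continues across classes from a random starting fold, so per-class fold
    sizes differ by at most one and total fold sizes stay balanced (with
    folds == n every fold holds exactly one subject).
    """
    y = np.asarray(labels)
    assignment = np.empty(len(y), dtype=int)
    offset = int(rng.integers(folds))
    for cls in (0, 1):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        assignment[idx] = (np.arange(len(idx)) + offset) % folds
        offset = (offset + len(idx)) % folds
    return assignment


def make_fold_plan(
    labels, repetitions: int, folds: int, seed: int
) -> np.ndarray:
    """(repetitions × n) fold-id matrix; a shared plan lets different feature
    sets be compared on identical partitions."""
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 77]))
    return np.stack(
        [stratified_folds(labels, folds, rng) for _ in range(repetitions)]
    )


def cross_validate(
    table: CohortTable,
    hierarchy: FeatureHierarchy,
    repetitions: int = 100,
    folds: int = 5,
    seed: int = 0,
    fold_plan: np.ndarray | None = None,
    ci_method: str = "normal",
) -> CVResult:
    """Repeated stratified k-fold cross-validation of the DSI model.

    The model is fully refit on every training split — orientations, error
    curves, leaf and group relevances — and test subjects are scored
    out-of-fold, so each subject receives exactly one score per repetition.
    Test folds that contain a single class get a NaN fold AUC (relevant only
    near leave-one-out); flagged all-missing subjects are excluded from AUC
    computation but keep a NaN pooled score.
    """
    labels = table.labels.to_numpy()
    n = len(labels)
    if folds < 2 or folds > n:
        raise EvaluationError(f"folds must be in [2, {n}]")
    if min((labels == 0).sum(), (labels == 1).sum()) < 2:
        raise EvaluationError("need at least two subjects per class")
    if fold_plan is None:
        fold_plan = make_fold_plan(labels, repetitions, folds, seed)
    if fold_plan.shape != (repetitions, n):
        raise EvaluationError("fold plan shape does not match (repetitions, n)")

    fold_aucs = np.full((repetitions, folds), np.nan)
    oof = np.full((repetitions, n), np.nan)
    for r in range(repetitions):
        for k in range(folds):
            test = fold_plan[r] == k
            train = ~test
            if len(np.unique(labels[train])) < 2:
                raise EvaluationError(
                    f"training fold {k} of repetition {r} lost a class; "
                    "use fewer folds or more subjects per class"
                )
            model = fit_dsi(table.subset(np.flatnonzero(train)), hierarchy)
            result = score(model, table.subset(np.flatnonzero(test)))
            s = result.scores.to_numpy()
            oof[r, test] = s
            ok = ~np.isnan(s)
            y_test = labels[test][ok]
            if len(np.unique(y_test)) == 2:
                fold_aucs[r, k] = roc_auc(s[ok], y_test)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN at LOO
        mean_auc = float(np.nanmean(fold_aucs))
    flat = fold_aucs[~np.isnan(fold_aucs)]
    ci = confidence_interval(flat, ci_method) if len(flat) >= 2 else (np.nan, np.nan)
    return CVResult(
        fold_aucs=fold_aucs, oof_scores=oof, labels=labels, mean_auc=mean_auc, ci=ci
    )


def resubstitution_auc(table: CohortTable, hierarchy: FeatureHierarchy) -> float:
    """AUC when training and testing on the full cohort (no cross-validation)."""
    model = fit_dsi(table, hierarchy)
    result = score(model, table)
    s = result.scores.to_numpy()
    ok = ~np.isnan(s)
    return roc_auc(s[ok], table.labels.to_numpy()[ok])


# ---------------------------------------------------------------------------
# Screening cutoff statistics


@dataclass
class CutoffStats:
    """Sensitivity/specificity/PPV/NPV/RPP per DSI cutoff, on the percent
    scale, as mean and 2.5–97.5 percentile range across CV repetitions.

    Undefined ratios (0/0, e.g. NPV when nobody is classified negative) are
    NaN and rendered as blank cells.
    """

    table: pd.DataFrame  # index: cutoff; columns: <stat>_{mean,lo,hi}

    STATS = ("sensitivity", "specificity", "ppv", "npv", "rpp")

    def mean(self, stat: str) -> pd.Series:
        return self.table[f"{stat}_mean"]


def _confusion_stats(scores: np.ndarray, labels: np.ndarray, cutoff: float):
    """Percent-scale screening statistics for the rule "DSI ≥ cutoff ⇒ positive"."""
    ok = ~np.isnan(scores)
    s, y = scores[ok], labels[ok]
    pred = s >= cutoff
    tp = int((pred & (y == 1)).sum())
    fp = int((pred & (y == 0)).sum())
    fn = int((~pred & (y == 1)).sum())
    tn = int((~pred & (y == 0)).sum())

    def ratio(num, den):
        return 100.0 * num / den if den > 0 else np.nan

    return {
        "sensitivity": ratio(tp, tp + fn),
        "specificity": ratio(tn, tn + fp),
        "ppv": ratio(tp, tp + fp),
        "npv": ratio(tn, tn + fn),
        "rpp": ratio(tp + fp, len(s)),
    }


def cutoff_table(cv: CVResult, cutoffs=None) -> CutoffStats:
    """Screening statistics over the cutoff grid from pooled out-of-fold scores.

    Per repetition, every subject's single out-of-fold DSI value is
    classified positive when ≥ the cutoff; the table reports the mean and
    the 2.5–97.5 percentile range of each statistic across repetitions.
    """
    if cutoffs is None:
        cutoffs = np.round(np.arange(0.0, 1.01, 0.1), 10)
    rows = {}
    for c in cutoffs:
        per_rep = pd.DataFrame(
            _confusion_stats(cv.oof_scores[r], cv.labels, c)
            for r in range(cv.repetitions)
        )
        row = {}
        for stat in CutoffStats.STATS:
            vals = per_rep[stat].to_numpy()
            vals = vals[~np.isnan(vals)]
            if len(vals) == 0:
                row[f"{stat}_mean"] = row[f"{stat}_lo"] = row[f"{stat}_hi"] = np.nan
            else:
                row[f"{stat}_mean"] = float(vals.mean())
                row[f"{stat}_lo"], row[f"{stat}_hi"] = (
                    float(v) for v in np.percentile(vals, [2.5, 97.5])
                )
        rows[float(c)] = row
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.index.name = "cutoff"
    return CutoffStats(table=frame)


# ---------------------------------------------------------------------------
# Cohort characterization


def characterize_cohort(table: CohortTable) -> pd.DataFrame:
    """Group summaries and rank-sum p-values, one row per feature.

    Continuous and ordinal features are summarized as mean (SD) per class,
    binary ones as count (%); group differences use the two-sided
    tie-corrected normal-approximation Wilcoxon rank-sum test for all
    feature kinds.
    """
    labels = table.labels.to_numpy()
    if not ((labels == 0).any() and (labels == 1).any()):
        raise EvaluationError("both classes are required")
    rows = []
    for feat in table.features:
        kind = table.feature_kinds[feat]
        neg = table.class_values(feat, 0)
        pos = table.class_values(feat, 1)
        row: dict = {"feature": feat, "kind": kind, "n_negative": len(neg), "n_positive": len(pos)}
        if len(neg) == 0 and len(pos) == 0:
            warnings.warn(f"feature {feat!r} is entirely missing", stacklevel=2)
            row.update(negative="", positive="", p_value=np.nan)
            rows.append(row)
            continue
        if kind == "binary":
            row["negative"] = f"{int(neg.sum())} ({100 * neg.mean():.0f}%)"
            row["positive"] = f"{int(pos.sum())} ({100 * pos.mean():.0f}%)"
        else:
            row["negative"] = f"{neg.mean():.3g} ({neg.std(ddof=1):.2g})"
            row["positive"] = f"{pos.mean():.3g} ({pos.std(ddof=1):.2g})"
        if len(np.unique(np.concatenate([neg, pos]))) == 1:
            row["p_value"] = 1.0
        else:
            # tie-corrected z without continuity correction: z^2 equals the
            # 1-df chi-square on a 2x2 contingency of a binary feature
            _, p = stats.mannwhitneyu(
                neg, pos, alternative="two-sided", method="asymptotic",
                use_continuity=False,
            )
            row["p_value"] = float(p)
        rows.append(row)
    return pd.DataFrame(rows).set_index("feature")
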