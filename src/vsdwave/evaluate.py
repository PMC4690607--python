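"""Classifier evaluation and treatment-effect statistics.

Covers the study-style readouts: confusion matrices with overall and
per-class accuracy, one-vs-rest ROC curves with trapezoidal AUC computed
from vote-fraction (OOB) scores, recording-level accuracy, mean class score
by true condition, and group statistics on the waveform metrics (pairwise
pooled-variance t-tests, one-way ANOVA with post-hoc Tukey HSD, alpha=0.05).
No multiple-testing correction is applied beyond Tukey.
"""

from __future__ import annotations

import itertools
import json

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .synthdata import FEATURES

ALPHA = 0.05


def confusion_report(
    predicted: pd.Series | np.ndarray, truth: pd.Series | np.ndarray
) -> dict:
    """Confusion matrix (true x predicted counts) plus accuracies in %."""
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    if predicted.shape != truth.shape:
        raise ValueError("predictions and truth must have equal length")
    if not set(np.unique(predicted)) & set(np.unique(truth)):
        raise ValueError("predicted and true class sets are disjoint")
    matrix = pd.crosstab(
        pd.Series(truth, name="true"), pd.Series(predicted, name="predicted")
    )
    classes = sorted(set(np.unique(truth)) | set(np.unique(predicted)))
    matrix = matrix.reindex(index=classes, columns=classes, fill_value=0)
    correct = np.diag(matrix.to_numpy()).sum()
    per_class = {
        c: 100.0 * matrix.loc[c, c] / matrix.loc[c].sum()
        for c in classes
        if matrix.loc[c].sum() > 0
    }
    return {
        "matrix": matrix,
        "overall_accuracy_pct": 100.0 * correct / len(truth),
        "per_class_accuracy_pct": per_class,
        "n": int(len(truth)),
    }


def roc_auc(
    scores: np.ndarray, truth: np.ndarray, positive_class
) -> tuple[np.ndarray, np.ndarray, float]:
    """One-vs-rest ROC from class scores; AUC by the trapezoid rule.

    Thresholds sweep the observed score values (ties collapse to one step).
    Returns ``(fpr, tpr, auc)``.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.min() < 0 or scores.max() > 1:
        raise ValueError("scores must lie in [0, 1]")
    y = (np.asarray(truth) == positive_class).astype(int)
    if y.sum() == 0 or y.sum() == y.size:
        raise ValueError("positive class must be present but not exhaustive")
    fpr, tpr, _ = roc_curve(y, scores)
    return fpr, tpr, float(np.trapezoid(tpr, fpr))


def group_stats(
    table: pd.DataFrame,
    group_col: str = "label",
    value_cols: list[str] | None = None,
    welch: bool = False,
) -> pd.DataFrame:
    """Treatment-effect statistics per metric.

    For every value column: all pairwise two-sample t-tests
    (pooled-variance Student's by default, Welch optionally), a one-way
    ANOVA across all groups, and post-hoc Tukey HSD pairs.  Returns a tidy
    frame with test, comparison, statistic, p-value and a significance flag
    at alpha = 0.05.
    """
    value_cols = value_cols or [c for c in FEATURES if c in table.columns]
    groups = sorted(table[group_col].unique())
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    rows = []
    for col in value_cols:
        samples = {g: table.loc[table[group_col] == g, col].to_numpy() for g in groups}
        for g1, g2 in itertools.combinations(groups, 2):
            t, p = stats.ttest_ind(samples[g1], samples[g2], equal_var=not welch)
            rows.append(
                {
                    "metric": col,
                    "test": "welch_t" if welch else "student_t",
                    "comparison": f"{g1} vs {g2}",
                    "statistic": float(t),
                    "p_value": float(p),
                    "significant": bool(p < ALPHA),
                }
            )
        if len(groups) > 2:
            f, p = stats.f_oneway(*samples.values())
            rows.append(
                {
                    "metric": col,
                    "test": "anova",
                    "comparison": " vs ".join(groups),
                    "statistic": float(f),
                    "p_value": float(p),
                    "significant": bool(p < ALPHA),
                }
            )
            tukey = pairwise_tukeyhsd(
                table[col].to_numpy(), table[group_col].to_numpy(), alpha=ALPHA
            )
            res = tukey.summary().data[1:]
            for g1, g2, meandiff, p_adj, *_, reject in res:
                rows.append(
                    {
                        "metric": col,
                        "test": "tukey_hsd",
                        "comparison": f"{g1} vs {g2}",
                        "statistic": float(meandiff),
                        "p_value": float(p_adj),
                        "significant": bool(reject),
                    }
                )
    return pd.DataFrame(rows)


def evaluation_report(
    predictions,
    truth: pd.Series | np.ndarray,
    recording_ids: pd.Series | np.ndarray | None = None,
) -> dict:
    """Assemble the full evaluation report for a prediction set.

    Includes the confusion report, per-class one-vs-rest ROC/AUC from the
    vote-fraction scores, the mean score assigned to each class by true
    condition, and (when recording IDs are available) recording-level
    accuracy by majority vote.
    """
    from .forest import aggregate_recording

    truth = np.asarray(truth)
    report = confusion_report(predictions.predicted.to_numpy(), truth)
    out = {
        "n_waveforms": report["n"],
        "overall_accuracy_pct": report["overall_accuracy_pct"],
        "per_class_accuracy_pct": report["per_class_accuracy_pct"],
        "confusion_matrix": {
            str(k): {str(c): int(v) for c, v in row.items()}
            for k, row in report["matrix"].to_dict("index").items()
        },
        "note": "no multiple-testing correction beyond Tukey HSD",
    }

    roc = {}
    for c in predictions.classes:
        try:
            fpr, tpr, auc = roc_auc(
                predictions.frame[f"score_{c}"].to_numpy(), truth, c
            )
            roc[str(c)] = {"auc": auc, "fpr": fpr.tolist(), "tpr": tpr.tolist()}
        except ValueError:
            continue
    out["roc"] = roc

    mean_scores = {}
    for true_c in np.unique(truth):
        mask = truth == true_c
        mean_scores[str(true_c)] = {
            str(c): float(predictions.frame.loc[mask, f"score_{c}"].mean())
            for c in predictions.classes
        }
    out["mean_score_by_true_class"] = mean_scores

    frame = predictions.frame
    if recording_ids is not None or "recording_id" in frame.columns:
        if recording_ids is not None:
            frame = frame.assign(recording_id=np.asarray(recording_ids))
            from .forest import PredictionSet

            predictions = PredictionSet(frame=frame, classes=predictions.classes)
        agg = aggregate_recording(predictions)
        true_by_rec = (
            pd.DataFrame({"recording_id": frame["recording_id"], "true": truth})
            .groupby("recording_id")["true"]
            .agg(lambda s: s.mode().iat[0])
        )
        agreed = (agg["predicted"] == true_by_rec.reindex(agg.index)).mean()
        out["recording_level_accuracy_pct"] = float(100.0 * agreed)
        out["n_recordings"] = int(len(agg))
    return out


def write_report(report: dict, json_path, text_path=None) -> None:
    """Write the evaluation report as JSON and an optional text summary."""
    with open(json_path, "w") as fh:
        json.dump(report, fh, indent=2)
    if text_path is None:
        return
    lines = [
        f"waveforms evaluated: {report['n_waveforms']}",
        f"overall accuracy: {report['overall_accuracy_pct']:.1f}%",
    ]
    for c, a in report["per_class_accuracy_pct"].items():
        lines.append(f"  {c}: {a:.1f}% correct")
    for c, r in report.get("roc", {}).items():
        lines.append(f"AUC[{c}] = {r['auc']:.3f}")
    if "recording_level_accuracy_pct" in report:
        lines.append(
            f"recording-level accuracy: {report['recording_level_accuracy_pct']:.1f}% "
            f"({report['n_recordings']} recordings)"
        )
    lines.append(report["note"])
    with open(text_path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
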