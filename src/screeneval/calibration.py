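"""AI-score dichotomisation and recall-threshold calibration.

The continuous exam-level malignancy score (0–10 scale) is turned into a
binary recall decision by a strict threshold: scores *above* the threshold
are recalls, the boundary is normal. Thresholds are calibrated against a
target reader operating point in one of two modes:

* ``match_sensitivity`` — the AI must detect at least as large a fraction of
  cancers as the reader; among qualifying thresholds, specificity is
  maximised.
* ``match_specificity`` — the AI must produce at most the reader's
  false-positive fraction; among qualifying thresholds, sensitivity is
  maximised.

The guarantee rule ("smallest achievable metric value >= target") is the
default; a "nearest" rule is available. Candidate thresholds are the
distinct observed scores plus a sentinel below the minimum (all-recall
operating point). Ties break toward the larger threshold, i.e. fewer
recalls.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
import json

import numpy as np
import pandas as pd

MATCH_SENSITIVITY = "match_sensitivity"
MATCH_SPECIFICITY = "match_specificity"


class CalibrationError(ValueError):
    """Calibration preconditions violated or target unattainable."""


@dataclass(frozen=True)
class CalibrationResult:
    """A recall threshold plus the operating point it achieves on the sample."""

    threshold: float
    mode: str
    target: float
    achieved_sensitivity: float
    achieved_specificity: float
    n_pos: int
    n_neg: int

    def to_json(self) -> str:
        return json.dumps(asdict(self))


def dichotomize(score, threshold: float):
    """Binary recall decision: 1 iff ``score > threshold`` (strict).

    Accepts a scalar or an array; the boundary score is *not* a recall.
    """
    arr = np.asarray(score)
    out = (arr > threshold).astype(np.int8)
    return int(out) if np.isscalar(score) or arr.ndim == 0 else out


def _check_inputs(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise CalibrationError("scores and labels must be equal-length 1-D arrays")
    if len(scores) == 0:
        raise CalibrationError("empty calibration sample")
    return scores, labels


def roc_points(scores, labels) -> pd.DataFrame:
    """Empirical ROC operating points of the strict-threshold rule.

    One row per candidate threshold — every distinct score plus a sentinel
    below the minimum (the all-recall point) — ordered by increasing
    threshold, with columns ``threshold``, ``sensitivity``, ``specificity``.
    Sensitivity is non-increasing and specificity non-decreasing in the
    threshold.
    """
    scores, labels = _check_inputs(scores, labels)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    distinct = np.unique(scores)
    thresholds = np.concatenate([[distinct[0] - 1.0], distinct])
    # recalls at threshold t: count of scores strictly greater than t
    order = np.argsort(scores, kind="stable")
    s_sorted = scores[order]
    l_sorted = labels[order]
    pos_cum = np.concatenate([[0], np.cumsum(l_sorted)])
    # index of first score > t
    idx = np.searchsorted(s_sorted, thresholds, side="right")
    tp = pos_cum[-1] - pos_cum[idx]
    recalls = len(scores) - idx
    fp = recalls - tp
    sens = tp / n_pos if n_pos else np.full(len(thresholds), np.nan)
    spec = (n_neg - fp) / n_neg if n_neg else np.full(len(thresholds), np.nan)
    return pd.DataFrame({"threshold": thresholds, "sensitivity": sens, "specificity": spec})


def calibrate(
    scores,
    labels,
    target: float,
    mode: str = MATCH_SENSITIVITY,
    *,
    rule: str = "guarantee",
) -> CalibrationResult:
    """Choose the recall threshold matched to a target sensitivity/specificity.

    Parameters
    ----------
    scores, labels
        Calibration sample: continuous scores and boolean cancer labels.
    target
        The reader's metric to match, in ``(0, 1]``.
    mode
        ``match_sensitivity`` or ``match_specificity``.
    rule
        ``"guarantee"`` (default): smallest achievable constrained-metric
        value >= target; among qualifying thresholds the complementary
        metric is maximised, ties toward the larger threshold.
        ``"nearest"``: threshold whose constrained metric is closest to the
        target (ties toward the larger threshold).

    Raises
    ------
    CalibrationError
        If the sample lacks positives/negatives for the requested mode, the
        target is out of range, or (guarantee rule) unattainable — the error
        names the maximum achievable value.
    """
    scores, labels = _check_inputs(scores, labels)
    if not (0.0 < target <= 1.0):
        raise CalibrationError(f"target {target} outside (0, 1]")
    if mode not in (MATCH_SENSITIVITY, MATCH_SPECIFICITY):
        raise CalibrationError(f"unknown mode {mode!r}")
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if mode == MATCH_SENSITIVITY and n_pos == 0:
        raise CalibrationError("match_sensitivity requires at least one positive label")
    if mode == MATCH_SPECIFICITY and n_neg == 0:
        raise CalibrationError("match_specificity requires at least one negative label")
    if n_pos == 0 or n_neg == 0:
        raise CalibrationError("calibration requires both classes")

    pts = roc_points(scores, labels)
    constrained = pts["sensitivity"] if mode == MATCH_SENSITIVITY else pts["specificity"]
    complementary = pts["specificity"] if mode == MATCH_SENSITIVITY else pts["sensitivity"]

    if rule == "guarantee":
        ok = constrained >= target
        if not ok.any():
            raise CalibrationError(
                f"target {target} unattainable; maximum achievable "
                f"{'sensitivity' if mode == MATCH_SENSITIVITY else 'specificity'} "
                f"is {constrained.max():.6g}"
            )
        cand = pts[ok]
        best = cand["specificity" if mode == MATCH_SENSITIVITY else "sensitivity"].max()
        cand = cand[np.isclose(cand["specificity" if mode == MATCH_SENSITIVITY else "sensitivity"], best)]
        row = cand.loc[cand["threshold"].idxmax()]
    elif rule == "nearest":
        dist = (constrained - target).abs()
        cand = pts[np.isclose(dist, dist.min())]
        row = cand.loc[cand["threshold"].idxmax()]
    else:
        raise CalibrationError(f"unknown rule {rule!r}")

    return CalibrationResult(
        threshold=float(row["threshold"]),
        mode=mode,
        target=float(target),
        achieved_sensitivity=float(row["sensitivity"]),
        achieved_specificity=float(row["specificity"]),
        n_pos=n_pos,
        n_neg=n_neg,
    )


def export_calibration(result: CalibrationResult, points: pd.DataFrame,
                       csv_path, json_path) -> None:
    """Write the ROC points as CSV and the calibration result as one-line JSON."""
    points.to_csv(csv_path, index=False)
    with open(json_path, "w") as fh:
        fh.write(result.to_json() + "\n")
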