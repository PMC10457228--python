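"""ROC construction, Youden operating point and the per-tissue-type
false-positive breakdown.

The classification rule at a threshold t is ``score >= t → tumor`` (closed
on the tumor side) everywhere in the package.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ramanmap.io_formats import NON_CANCEROUS_LABELS, TissueLabel


@dataclass
class ROCResult:
    """ROC curve over all unique-score thresholds.

    ``thresholds[k]`` produces the operating point ``(fpr[k], tpr[k])``
    under the rule score >= threshold; the leading point (0, 0) carries an
    infinite threshold.  Equal scores are grouped into one threshold step,
    so the trapezoidal ``auc`` equals the mid-rank Mann-Whitney
    formulation.
    """

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    youden_threshold: float = float("nan")
    sensitivity: float = float("nan")
    specificity: float = float("nan")


def roc(scores: np.ndarray, labels: np.ndarray) -> ROCResult:
    """Build the ROC curve of tumor scores against binary labels.

    ``labels`` is boolean (True = tumor).  Raises when only one class is
    present or any score is non-finite.
    """
    s = np.asarray(scores, dtype=float).ravel()
    y = np.asarray(labels, dtype=bool).ravel()
    if s.size != y.size:
        raise ValueError("scores and labels lengths differ")
    if not np.all(np.isfinite(s)):
        raise ValueError("scores must be finite")
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")

    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    y_sorted = y[order]
    # Group equal scores into single threshold steps.
    distinct = np.r_[np.diff(s_sorted) != 0, True]
    tp = np.cumsum(y_sorted)[distinct]
    fp = np.cumsum(~y_sorted)[distinct]
    thresholds = np.r_[np.inf, s_sorted[distinct]]
    tpr = np.r_[0.0, tp / n_pos]
    fpr = np.r_[0.0, fp / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    return ROCResult(thresholds=thresholds, tpr=tpr, fpr=fpr, auc=auc)


def youden_point(curve: ROCResult) -> dict[str, float]:
    """Operating point maximizing Youden's J = sensitivity + specificity − 1.

    Ties on J are broken toward higher specificity, then lower threshold.
    The result is also written back onto the curve.
    """
    j = curve.tpr - curve.fpr
    best = 0
    for k in range(1, j.size):
        if j[k] > j[best] + 1e-12:
            best = k
        elif abs(j[k] - j[best]) <= 1e-12:
            if curve.fpr[k] < curve.fpr[best] - 1e-12:
                best = k
            elif (
                abs(curve.fpr[k] - curve.fpr[best]) <= 1e-12
                and curve.thresholds[k] < curve.thresholds[best]
            ):
                best = k
    result = {
        "threshold": float(curve.thresholds[best]),
        "sensitivity": float(curve.tpr[best]),
        "specificity": float(1.0 - curve.fpr[best]),
    }
    curve.youden_threshold = result["threshold"]
    curve.sensitivity = result["sensitivity"]
    curve.specificity = result["specificity"]
    return result


def fp_breakdown(
    scores: np.ndarray, tissue_labels: np.ndarray, threshold: float
) -> dict[TissueLabel, float]:
    """Fraction of each non-cancerous tissue type scored as tumor.

    For every non-cancerous type with at least one spectrum, reports the
    fraction of its spectra with score >= ``threshold``; types without
    spectra are absent from the result rather than reported as zero.
    """
    s = np.asarray(scores, dtype=float).ravel()
    t = np.asarray(tissue_labels).ravel()
    if s.size != t.size:
        raise ValueError("scores and tissue labels lengths differ")
    out: dict[TissueLabel, float] = {}
    for label in NON_CANCEROUS_LABELS:
        sel = t == int(label)
        n = int(sel.sum())
        if n == 0:
            continue
        out[label] = float((s[sel] >= threshold).sum()) / n
    return out
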