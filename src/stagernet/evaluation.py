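"""Hypnogram agreement metrics.

Cohen's Kappa is the standard chance-corrected agreement score for sleep
staging (human inter-scorer agreement is around 0.75).  All metrics here
operate on the five scored classes in the fixed order (N3, N2, N1, REM,
WAKE); epochs whose *reference* stage is UNKNOWN are excluded before any
computation (the classifier never emits UNKNOWN, so no other masking can
arise).
"""

from __future__ import annotations

import numpy as np

from .core import CLASS_ORDER, EvaluationReport, Hypnogram, N_CLASSES, SleepStage


def _aligned_codes(pred: Hypnogram, truth: Hypnogram):
    if len(pred) != len(truth):
        raise ValueError(
            f"hypnogram lengths differ: {len(pred)} vs {len(truth)}"
        )
    p = pred.codes()
    t = truth.codes()
    keep = t != int(SleepStage.UNKNOWN)
    return p[keep], t[keep]


def _counts(pred_codes: np.ndarray, truth_codes: np.ndarray) -> np.ndarray:
    """5x5 count matrix, rows = true stage, columns = predicted stage."""
    counts = np.zeros((N_CLASSES, N_CLASSES), dtype=np.int64)
    np.add.at(counts, (truth_codes, pred_codes), 1)
    return counts


def _kappa_from_counts(counts: np.ndarray) -> float:
    n = counts.sum()
    if n == 0:
        raise ValueError("no scored epochs: Kappa is undefined")
    p_o = np.trace(counts) / n
    p_e = float(np.sum(counts.sum(axis=1) * counts.sum(axis=0)) / (n * n))
    if p_e >= 1.0 - 1e-15:
        # both raters use a single shared class: perfect agreement scores
        # 1, anything else scores 0 (the usual degenerate-marginal rule)
        return 1.0 if p_o >= 1.0 - 1e-15 else 0.0
    return float((p_o - p_e) / (1.0 - p_e))


def cohens_kappa(pred: Hypnogram, truth: Hypnogram) -> float:
    """Chance-corrected agreement between two stage sequences, in [-1, 1]."""
    p, t = _aligned_codes(pred, truth)
    return _kappa_from_counts(_counts(p, t))


def pooled_kappa(pairs: list[tuple[Hypnogram, Hypnogram]]) -> float:
    """Kappa over the union of epochs from several (pred, truth) pairs."""
    total = np.zeros((N_CLASSES, N_CLASSES), dtype=np.int64)
    for pred, truth in pairs:
        p, t = _aligned_codes(pred, truth)
        total += _counts(p, t)
    return _kappa_from_counts(total)


def mean_recording_kappa(pairs: list[tuple[Hypnogram, Hypnogram]]) -> float:
    """Equal-weight average of per-recording Kappa scores."""
    return float(np.mean([cohens_kappa(p, t) for p, t in pairs]))


def confusion_row_normalized(pred: Hypnogram, truth: Hypnogram):
    """Row-normalized 5x5 confusion matrix (rows = true stage).

    Rows with no support are all-zero; their indices are returned alongside.
    """
    p, t = _aligned_codes(pred, truth)
    counts = _counts(p, t)
    support = counts.sum(axis=1)
    out = np.zeros((N_CLASSES, N_CLASSES))
    nonzero = support > 0
    out[nonzero] = counts[nonzero] / support[nonzero, None]
    return out, list(np.flatnonzero(~nonzero))


def per_stage_metrics(pred: Hypnogram, truth: Hypnogram):
    """Precision, recall and F1 per class (0 where undefined)."""
    p, t = _aligned_codes(pred, truth)
    counts = _counts(p, t)
    tp = np.diag(counts).astype(np.float64)
    pred_totals = counts.sum(axis=0).astype(np.float64)
    true_totals = counts.sum(axis=1).astype(np.float64)
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(pred_totals > 0, tp / pred_totals, 0.0)
        recall = np.where(true_totals > 0, tp / true_totals, 0.0)
        denom = precision + recall
        f1 = np.where(denom > 0, 2 * precision * recall / denom, 0.0)
    return precision, recall, f1


def evaluate(pred: Hypnogram, truth: Hypnogram) -> EvaluationReport:
    """Full agreement report: Kappa, confusion matrix, per-stage scores."""
    p, t = _aligned_codes(pred, truth)
    confusion, zero_rows = confusion_row_normalized(pred, truth)
    precision, recall, f1 = per_stage_metrics(pred, truth)
    return EvaluationReport(
        kappa=_kappa_from_counts(_counts(p, t)),
        confusion=confusion,
        precision=precision,
        recall=recall,
        f1=f1,
        n_scored_epochs=int(len(t)),
        zero_support_rows=zero_rows,
    )
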