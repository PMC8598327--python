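"""Evaluation suite: confusion matrices, ACC/PRE/REC/F1 and sweep harness.

Per-class scores are one-vs-rest reductions of the P x P confusion matrix
(rows = true level, columns = predicted):

    PRE = TP / (TP + FP),  REC = TP / (TP + FN),
    F1  = 2 * PRE * REC / (PRE + REC),

with the 0/0 convention resolved to 0 and flagged.  Headline averages are
macro (unweighted over classes).  Levels also roll up into the three
regulatory areas (safe / warning / danger).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion

from .encoding import LEVELS, level_area

__all__ = ["confusion", "normalize_confusion", "metrics", "MetricReport", "sweep"]

AREA_ORDER = ["safe", "warning", "danger"]


def confusion(true_labels, predicted_labels, n_classes: int = 8) -> np.ndarray:
    """Integer count matrix, rows true / columns predicted."""
    t = np.asarray(true_labels, dtype=np.int64)
    p = np.asarray(predicted_labels, dtype=np.int64)
    if t.shape != p.shape:
        raise ValueError(f"length mismatch: {t.shape[0]} true vs {p.shape[0]} predicted")
    if t.size and (t.min() < 0 or t.max() >= n_classes or p.min() < 0 or p.max() >= n_classes):
        raise ValueError(f"labels out of range 0..{n_classes - 1}")
    return _sk_confusion(t, p, labels=np.arange(n_classes))


def normalize_confusion(cm: np.ndarray) -> np.ndarray:
    """Row-normalized matrix; all-zero rows (absent classes) stay zero."""
    cm = np.asarray(cm, dtype=float)
    totals = cm.sum(axis=1, keepdims=True)
    safe = np.where(totals > 0, totals, 1.0)
    return cm / safe


def _one_vs_rest(cm: np.ndarray):
    """Per-class TP, FP, FN, TN from a count matrix."""
    cm = np.asarray(cm, dtype=np.int64)
    tp = np.diag(cm).astype(float)
    fp = cm.sum(axis=0) - tp
    fn = cm.sum(axis=1) - tp
    tn = cm.sum() - tp - fp - fn
    return tp, fp, fn, tn


def _safe_div(num, den):
    num, den = np.asarray(num, float), np.asarray(den, float)
    out = np.zeros_like(num)
    np.divide(num, den, out=out, where=den > 0)
    return out


@dataclass
class MetricReport:
    """Overall accuracy, per-class and macro PRE/REC/F1, and area roll-ups."""

    accuracy: float
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    support: np.ndarray
    macro_precision: float
    macro_recall: float
    macro_f1: float
    area: dict = field(default_factory=dict)
    undefined_classes: list = field(default_factory=list)  # 0/0 conventions applied

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "per_class": {
                LEVELS[i] if i < len(LEVELS) else str(i): {
                    "precision": float(self.precision[i]),
                    "recall": float(self.recall[i]),
                    "f1": float(self.f1[i]),
                    "support": int(self.support[i]),
                }
                for i in range(len(self.precision))
            },
            "macro": {
                "precision": self.macro_precision,
                "recall": self.macro_recall,
                "f1": self.macro_f1,
            },
            "area": self.area,
            "undefined_classes": self.undefined_classes,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1)

    def to_text(self) -> str:
        lines = [f"accuracy: {self.accuracy:.4f}", ""]
        lines.append(f"{'level':>6} {'PRE':>7} {'REC':>7} {'F1':>7} {'support':>8}")
        for i in range(len(self.precision)):
            name = LEVELS[i] if i < len(LEVELS) else str(i)
            lines.append(
                f"{name:>6} {self.precision[i]:>7.3f} {self.recall[i]:>7.3f} "
                f"{self.f1[i]:>7.3f} {int(self.support[i]):>8}"
            )
        lines.append(
            f"{'macro':>6} {self.macro_precision:>7.3f} {self.macro_recall:>7.3f} "
            f"{self.macro_f1:>7.3f} {int(self.support.sum()):>8}"
        )
        return "\n".join(lines)


def metrics(cm: np.ndarray) -> MetricReport:
    """Metric report derived from a confusion-count matrix."""
    cm = np.asarray(cm, dtype=np.int64)
    if cm.size == 0 or cm.sum() == 0:
        raise ValueError("empty confusion matrix")
    tp, fp, fn, tn = _one_vs_rest(cm)
    pre = _safe_div(tp, tp + fp)
    rec = _safe_div(tp, tp + fn)
    f1 = _safe_div(2 * pre * rec, pre + rec)
    undefined = [
        LEVELS[i] if i < len(LEVELS) else str(i)
        for i in range(len(tp))
        if (tp[i] + fp[i] == 0) or (tp[i] + fn[i] == 0)
    ]

    area_report = {}
    if cm.shape[0] == len(LEVELS):
        idx = {a: [i for i, lv in enumerate(LEVELS) if level_area(lv) == a] for a in AREA_ORDER}
        acm = np.zeros((3, 3), dtype=np.int64)
        for i, a in enumerate(AREA_ORDER):
            for j, b in enumerate(AREA_ORDER):
                acm[i, j] = cm[np.ix_(idx[a], idx[b])].sum()
        atp, afp, afn, _ = _one_vs_rest(acm)
        apre, arec = _safe_div(atp, atp + afp), _safe_div(atp, atp + afn)
        af1 = _safe_div(2 * apre * arec, apre + arec)
        for i, a in enumerate(AREA_ORDER):
            area_report[a] = {
                "precision": float(apre[i]),
                "recall": float(arec[i]),
                "f1": float(af1[i]),
                "support": int(acm[i].sum()),
            }

    return MetricReport(
        accuracy=float(np.diag(cm).sum() / cm.sum()),
        precision=pre,
        recall=rec,
        f1=f1,
        support=cm.sum(axis=1),
        macro_precision=float(pre.mean()),
        macro_recall=float(rec.mean()),
        macro_f1=float(f1.mean()),
        area=area_report,
        undefined_classes=undefined,
    )


SWEEPABLE = ("batch_size", "K", "epochs", "layers", "windows")


def sweep(param: str, values, records, labels, base_config=None, seed: int = 0,
          train_frac: float = 0.9) -> pd.DataFrame:
    """Accuracy curve over one hyperparameter.

    Trains a fresh network per value under a fixed seed on a stratified
    train/test split of the given records and reports held-out accuracy.
    ``param`` is one of ``batch_size``, ``K``, ``epochs``, ``layers``,
    ``windows``.
    """
    from dataclasses import replace as _replace

    from .cascade import DSNConfig, DeepStackingNetwork
    from .simdata import split as _split

    if param not in SWEEPABLE:
        raise ValueError(f"unknown sweep parameter {param!r}; expected one of {SWEEPABLE}")
    base = base_config or DSNConfig()
    tr_rec, te_rec, tr_lab, te_lab = _split(records, labels, train_frac, seed)
    rows = []
    for value in values:
        if param == "K":
            cfg = _replace(base, k_folds=int(value), seed=seed)
        elif param == "layers":
            cfg = _replace(base, max_layers=int(value), seed=seed)
        elif param == "windows":
            cfg = _replace(base, scan=_replace(base.scan, windows=tuple(value)), seed=seed)
        else:
            cfg = _replace(base, **{param: int(value)}, seed=seed)
        model = DeepStackingNetwork(cfg).fit(tr_rec, tr_lab)
        pred, _ = model.predict(te_rec)
        from .encoding import encode_labels

        acc = float((pred == encode_labels(te_lab)).mean())
        rows.append({"param": param, "value": str(value), "accuracy": acc})
    return pd.DataFrame(rows)
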