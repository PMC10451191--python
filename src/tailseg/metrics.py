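"""Per-class segmentation metrics from dataset-level confusion tallies.

One confusion tally (TP/FP/FN per label) is accumulated over *all* pixels
of all evaluated images (micro accumulation), then turned into per-class
IoU, sensitivity and precision in percent.  The headline "Overall" number
is the unweighted (macro) mean over the foreground classes; a variant
including the background class is available for reports that use it.
Cells with a zero denominator (a label absent from both prediction and
truth) are flagged undefined and excluded from means rather than coerced
to 0 or 100.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import DataError

CONVENTIONS = ("foreground_macro", "all_class_macro")


@dataclass
class ConfusionTally:
    """Pixel-level TP/FP/FN per label 0..C, folded over a dataset."""

    C: int
    tp: np.ndarray
    fp: np.ndarray
    fn: np.ndarray

    @classmethod
    def empty(cls, C: int) -> "ConfusionTally":
        z = np.zeros(C + 1, dtype=np.int64)
        return cls(C, z.copy(), z.copy(), z.copy())

    @property
    def total_pixels(self) -> int:
        return int((self.tp + self.fn).sum())


def accumulate_confusion(pred_mask, true_mask, C: int,
                         tally: ConfusionTally | None = None) -> ConfusionTally:
    """Fold one prediction/truth mask pair into a (possibly new) tally."""
    pred = np.asarray(pred_mask)
    true = np.asarray(true_mask)
    if pred.shape != true.shape:
        raise DataError(
            f"prediction shape {pred.shape} != truth shape {true.shape}")
    for name, m in (("prediction", pred), ("truth", true)):
        if m.size and (m.min() < 0 or m.max() > C):
            bad = int(m.min()) if m.min() < 0 else int(m.max())
            raise DataError(f"{name} mask value {bad} outside 0..{C}")
    if tally is None:
        tally = ConfusionTally.empty(C)
    elif tally.C != C:
        raise DataError("tally class count does not match C")
    K = C + 1
    joint = np.bincount(true.ravel() * K + pred.ravel(), minlength=K * K)
    joint = joint.reshape(K, K)  # rows: truth, cols: prediction
    diag = np.diag(joint)
    tally.tp += diag
    tally.fn += joint.sum(axis=1) - diag
    tally.fp += joint.sum(axis=0) - diag
    return tally


@dataclass
class MetricsReport:
    """Per-class IoU / sensitivity / precision in percent, plus macro means.

    Undefined cells (zero denominator) hold ``nan`` and are listed in
    ``undefined``; macro means skip them.
    """

    C: int
    iou: np.ndarray
    sensitivity: np.ndarray
    precision: np.ndarray
    undefined: dict
    overall_foreground: dict
    overall_all: dict


def _safe_ratio(num, den):
    den = np.asarray(den, dtype=np.float64)
    out = np.full(den.shape, np.nan)
    ok = den > 0
    out[ok] = 100.0 * np.asarray(num, dtype=np.float64)[ok] / den[ok]
    return out


def per_class_metrics(tally: ConfusionTally) -> MetricsReport:
    """IoU/sensitivity/precision (percent) per label from a tally."""
    tp, fp, fn = tally.tp, tally.fp, tally.fn
    iou = _safe_ratio(tp, tp + fp + fn)
    sens = _safe_ratio(tp, tp + fn)
    prec = _safe_ratio(tp, tp + fp)
    undefined = {
        "iou": [i for i in range(tally.C + 1) if np.isnan(iou[i])],
        "sensitivity": [i for i in range(tally.C + 1) if np.isnan(sens[i])],
        "precision": [i for i in range(tally.C + 1) if np.isnan(prec[i])],
    }
    report = MetricsReport(
        C=tally.C, iou=iou, sensitivity=sens, precision=prec,
        undefined=undefined, overall_foreground={}, overall_all={})
    for key, vals in (("iou", iou), ("sensitivity", sens), ("precision", prec)):
        try:
            fg = overall_metrics(vals[1:], "foreground_macro")
        except DataError:
            fg = float("nan")
        try:
            allc = overall_metrics(vals[1:], "all_class_macro",
                                   background_value=vals[0])
        except DataError:
            allc = float("nan")
        report.overall_foreground[key] = fg
        report.overall_all[key] = allc
    return report


def overall_metrics(foreground_values, convention: str = "foreground_macro",
                    background_value: float | None = None) -> float:
    """Unweighted mean of per-class values.

    ``foreground_macro`` averages the C foreground classes only (the
    convention behind the headline mIoU); ``all_class_macro`` additionally
    includes the background value.  Undefined (nan) cells are excluded.
    """
    if convention not in CONVENTIONS:
        raise DataError(f"convention must be one of {CONVENTIONS}")
    vals = list(np.atleast_1d(np.asarray(foreground_values, dtype=np.float64)))
    if convention == "all_class_macro":
        if background_value is None:
            raise DataError("all_class_macro requires background_value")
        vals = [float(background_value)] + vals
    arr = np.array(vals, dtype=np.float64)
    defined = arr[~np.isnan(arr)]
    if defined.size == 0:
        raise DataError("all per-class cells are undefined")
    return float(defined.mean())


# ---------------------------------------------------------------------
# report output
# ---------------------------------------------------------------------

def format_report(report: MetricsReport, class_names=None) -> str:
    """Plain-text table: one row per metric, class columns plus Overall."""
    C = report.C
    names = class_names or [f"class {i}" for i in range(1, C + 1)]
    header = ["metric", "background", *names, "Overall(fg)", "Overall(all)"]
    rows = [header]
    for key, vals in (("IoU", report.iou),
                      ("Sensitivity", report.sensitivity),
                      ("Precision", report.precision)):
        cells = ["--" if np.isnan(v) else f"{v:.2f}" for v in vals]
        k = key.lower()
        rows.append([key, *cells,
                     f"{report.overall_foreground[k]:.2f}",
                     f"{report.overall_all[k]:.2f}"])
    widths = [max(len(r[i]) for r in rows) for i in range(len(header))]
    return "\n".join(
        "  ".join(c.ljust(w) for c, w in zip(r, widths)).rstrip()
        for r in rows) + "\n"


def write_report(report: MetricsReport, path) -> None:
    """Machine-readable key/value metrics file."""
    lines = []
    for key, vals in (("iou", report.iou),
                      ("sensitivity", report.sensitivity),
                      ("precision", report.precision)):
        for i, v in enumerate(vals):
            lines.append(f"{key}.class{i}={'nan' if np.isnan(v) else f'{v:.6f}'}")
        lines.append(f"{key}.overall_foreground="
                     f"{report.overall_foreground[key]:.6f}")
        lines.append(f"{key}.overall_all={report.overall_all[key]:.6f}")
    Path(path).write_text("\n".join(lines) + "\n")
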