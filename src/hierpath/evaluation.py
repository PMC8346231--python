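"""Confusion-matrix metrics, bootstrap uncertainty and Grad-CAM heatmaps.

Metrics follow the one-vs-rest convention: per class l the counts TP_l,
FP_l, FN_l, TN_l are tallied, micro-averaged precision / recall / F1 pool
the counts across classes before dividing, and overall accuracy is
correct / total.  For single-label multi-class prediction the micro
metrics all collapse to the accuracy — a useful internal consistency
check.  The +/- half-widths are central 95% bootstrap intervals over
resampled test items (the resampling scheme is this package's choice and
is labeled as such in reports).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.transform import resize

from . import nn
from .models import TrainedModel


@dataclass
class ConfusionCounts:
    """One-vs-rest counts per class; arrays of length ``n_classes``."""

    tp: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    tn: np.ndarray

    @property
    def n_classes(self) -> int:
        return len(self.tp)

    @property
    def total(self) -> int:
        return int(self.tp[0] + self.fp[0] + self.fn[0] + self.tn[0])


def confusion(y_true, y_pred, n_classes: int) -> ConfusionCounts:
    """Tally one-vs-rest confusion counts for integer labels in [0, L)."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if len(y_true) == 0:
        raise ValueError("empty label sequences")
    if len(y_true) != len(y_pred):
        raise ValueError("label sequences differ in length")
    for arr, name in ((y_true, "true"), (y_pred, "predicted")):
        if arr.min() < 0 or arr.max() >= n_classes:
            raise ValueError(f"{name} label outside [0, {n_classes})")
    tp = np.zeros(n_classes, dtype=int)
    fp = np.zeros(n_classes, dtype=int)
    fn = np.zeros(n_classes, dtype=int)
    for label in range(n_classes):
        tp[label] = int(np.sum((y_pred == label) & (y_true == label)))
        fp[label] = int(np.sum((y_pred == label) & (y_true != label)))
        fn[label] = int(np.sum((y_pred != label) & (y_true == label)))
    tn = len(y_true) - tp - fp - fn
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def _ratio(num: float, den: float) -> float | None:
    return num / den if den > 0 else None


@dataclass
class EvaluationReport:
    accuracy: float
    micro_precision: float | None
    micro_recall: float | None
    micro_f1: float | None
    per_class: dict[str, dict[str, float | None]] = field(default_factory=dict)
    half_widths: dict[str, float] = field(default_factory=dict)
    level: str = "patch"  # patch | slide
    hierarchy_level: str = "leaf"  # parent | child | leaf

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (
                "micro",
                self.micro_precision,
                self.micro_recall,
                self.micro_f1,
                self.half_widths.get("f1"),
            )
        ]
        for name, m in self.per_class.items():
            rows.append((name, m["precision"], m["recall"], m["f1"], None))
        return pd.DataFrame(
            rows, columns=["class", "precision", "recall", "f1", "pm95"]
        )


def compute_metrics(
    counts: ConfusionCounts,
    class_names: tuple[str, ...] | None = None,
    level: str = "patch",
    hierarchy_level: str = "leaf",
) -> EvaluationReport:
    """Accuracy, micro and per-class precision/recall/F1 from counts.

    Zero-denominator metrics are reported as ``None`` (undefined), never
    silently as 0.
    """
    names = class_names or tuple(str(i) for i in range(counts.n_classes))
    tp, fp, fn = counts.tp, counts.fp, counts.fn
    report = EvaluationReport(
        accuracy=float(tp.sum()) / counts.total,
        micro_precision=_ratio(tp.sum(), (tp + fp).sum()),
        micro_recall=_ratio(tp.sum(), (tp + fn).sum()),
        micro_f1=_ratio(2 * tp.sum(), (2 * tp + fp + fn).sum()),
        level=level,
        hierarchy_level=hierarchy_level,
    )
    for i, name in enumerate(names):
        report.per_class[name] = {
            "precision": _ratio(tp[i], tp[i] + fp[i]),
            "recall": _ratio(tp[i], tp[i] + fn[i]),
            "f1": _ratio(2 * tp[i], 2 * tp[i] + fp[i] + fn[i]),
        }
    return report


def evaluate(
    y_true,
    y_pred,
    class_names: tuple[str, ...],
    level: str = "patch",
    hierarchy_level: str = "leaf",
) -> EvaluationReport:
    counts = confusion(y_true, y_pred, len(class_names))
    return compute_metrics(counts, class_names, level, hierarchy_level)


_METRIC_FNS = {
    "accuracy": lambda t, p, L: float(np.mean(t == p)),
    "precision": lambda t, p, L: compute_metrics(confusion(t, p, L)).micro_precision,
    "recall": lambda t, p, L: compute_metrics(confusion(t, p, L)).micro_recall,
    "f1": lambda t, p, L: compute_metrics(confusion(t, p, L)).micro_f1,
}


def metric_uncertainty(
    y_true,
    y_pred,
    metric: str = "f1",
    n_boot: int = 1000,
    seed: int = 0,
    n_classes: int | None = None,
) -> float:
    """Half-width of the central 95% bootstrap interval, on the x100 scale.

    Test items are resampled with replacement ``n_boot`` times and the
    micro metric recomputed on each resample.
    """
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if len(y_true) < 2:
        raise ValueError("bootstrap needs at least two samples")
    if n_boot < 100:
        raise ValueError("use at least 100 bootstrap resamples")
    L = n_classes or int(max(y_true.max(), y_pred.max())) + 1
    fn = _METRIC_FNS[metric]
    rng = np.random.default_rng(seed)
    values = []
    for _ in range(n_boot):
        idx = rng.integers(0, len(y_true), size=len(y_true))
        v = fn(y_true[idx], y_pred[idx], L)
        if v is not None:
            values.append(v)
    lo, hi = np.percentile(values, [2.5, 97.5])
    return float((hi - lo) / 2.0 * 100.0)


# ---------------------------------------------------------------------------
# Grad-CAM


def gradcam(model: TrainedModel, patch: np.ndarray, target_class: int) -> np.ndarray:
    """Gradient-weighted class-activation heatmap for one patch.

    The gradient of the target-class logit is backpropagated to the last
    convolutional layer's feature maps; each map is weighted by its
    spatially averaged gradient, the weighted sum is rectified,
    max-normalized (unless all-zero) and upsampled to the patch size.
    """
    network = model.network
    conv_idx = [
        i for i, layer in enumerate(network.layers) if isinstance(layer, nn.Conv2D)
    ]
    if not conv_idx:
        raise ValueError("Grad-CAM needs at least one convolutional layer")
    last_conv = conv_idx[-1]
    patch = np.asarray(patch)
    from .models import resize_images

    x = resize_images(patch[None], network.input_shape[0])
    logits = network.forward(x, keep_outputs=True)
    n_classes = logits.shape[1]
    if not 0 <= target_class < n_classes:
        raise ValueError(f"class index {target_class} outside [0, {n_classes})")
    activations = network._outputs[last_conv + 1][0]  # (h, w, c)
    dout = np.zeros_like(logits)
    dout[0, target_class] = 1.0
    grads = network.backward(dout, upto=last_conv + 1)[0]  # d logit / d activations
    weights = grads.mean(axis=(0, 1))
    cam = np.maximum((activations * weights).sum(axis=2), 0.0)
    if cam.max() > 0:
        cam = cam / cam.max()
    return resize(
        cam, patch.shape[:2], order=1, anti_aliasing=False, preserve_range=True
    )


def gradcam_overlay(
    image: np.ndarray, heatmap: np.ndarray, alpha: float = 0.4
) -> np.ndarray:
    """Blend a heatmap (blue -> red ramp) over an RGB image, uint8 out."""
    base = image.astype(np.float64)
    if image.dtype != np.uint8:
        base = np.clip(base, 0, 1) * 255.0
    h = np.clip(np.asarray(heatmap, dtype=np.float64), 0, 1)
    color = np.stack([h * 255.0, np.zeros_like(h), (1 - h) * 255.0], axis=-1)
    out = (1 - alpha) * base + alpha * color
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def write_report(
    report: EvaluationReport, path_prefix: str | Path, pm_method: str = "bootstrap"
) -> None:
    """Write a report as CSV plus a plain-text summary."""
    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    report.to_frame().to_csv(f"{prefix}.csv", index=False)
    lines = [
        f"level: {report.level} / {report.hierarchy_level}",
        f"accuracy: {report.accuracy * 100:.2f}",
    ]
    for key in ("micro_precision", "micro_recall", "micro_f1"):
        value = getattr(report, key)
        shown = "undefined" if value is None else f"{value * 100:.2f}"
        hw = report.half_widths.get(key.replace("micro_", ""))
        if hw is not None:
            shown += f" +/- {hw:.2f} ({pm_method} 95%)"
        lines.append(f"{key}: {shown}")
    Path(f"{prefix}.txt").write_text("\n".join(lines) + "\n")
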