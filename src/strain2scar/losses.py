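"""Segmentation losses, the composite multi-fidelity objective, and
circular-ROI evaluation metrics.

All quantities are computed over the circular region of interest — the LV
disc — unless ``roi`` is omitted (then over the full grid, preserving the
literal all-pixels reading of the loss definitions).  Losses accept soft
probability maps; metrics require binary masks and are computed on the
infarct (pathological) class only, so background agreement never inflates
overlap scores.

Conventions for degenerate binary cases: if prediction and truth are both
empty, DSC = IoU = precision = recall = 1; if exactly one is empty they
are 0.  Soft Dice/IoU carry a small smoothing constant ``delta`` in
numerator and denominator to avoid 0/0.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

EPS = 1e-7      # probability clipping for the cross-entropy
DELTA = 1e-6    # Dice/IoU smoothing


def _prep(p, y, roi):
    p = np.asarray(p, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if p.shape != y.shape:
        raise ValueError("prediction and mask shapes differ")
    if roi is None:
        sel = np.ones(p.shape, dtype=bool)
    else:
        roi = np.asarray(roi).astype(bool)
        if roi.shape != p.shape[-roi.ndim:]:
            raise ValueError("roi shape incompatible with prediction")
        sel = np.broadcast_to(roi, p.shape)
    return p[sel], y[sel], sel


# ---------------------------------------------------------------------------
# losses

def bce_loss(p, y, roi=None, eps: float = EPS) -> float:
    """Binary cross-entropy, averaged over ROI pixels."""
    pv, yv, _ = _prep(p, y, roi)
    pv = np.clip(pv, eps, 1.0 - eps)
    return float(-np.mean(yv * np.log(pv) + (1.0 - yv) * np.log(1.0 - pv)))


def bce_grad(p, y, roi=None, eps: float = EPS) -> np.ndarray:
    """d(bce)/dp, zero outside the ROI."""
    p = np.asarray(p, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    _, _, sel = _prep(p, y, roi)
    pc = np.clip(p, eps, 1.0 - eps)
    g = (-y / pc + (1.0 - y) / (1.0 - pc)) / sel.sum()
    return np.where(sel, g, 0.0)


def dsc_loss(p, y, roi=None, delta: float = DELTA) -> float:
    """Soft Dice loss: 1 - (2 sum(py) + delta) / (sum p + sum y + delta)."""
    pv, yv, _ = _prep(p, y, roi)
    num = 2.0 * np.sum(pv * yv) + delta
    den = np.sum(pv) + np.sum(yv) + delta
    return float(1.0 - num / den)


def dsc_grad(p, y, roi=None, delta: float = DELTA) -> np.ndarray:
    p = np.asarray(p, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    pv, yv, sel = _prep(p, y, roi)
    num = 2.0 * np.sum(pv * yv) + delta
    den = np.sum(pv) + np.sum(yv) + delta
    g = -(2.0 * y * den - num) / den ** 2
    return np.where(sel, g, 0.0)


def iou_loss(p, y, roi=None, delta: float = DELTA) -> float:
    """Soft Jaccard loss: 1 - (sum(py) + delta) / (sum(p + y - py) + delta)."""
    pv, yv, _ = _prep(p, y, roi)
    inter = np.sum(pv * yv) + delta
    union = np.sum(pv + yv - pv * yv) + delta
    return float(1.0 - inter / union)


def iou_grad(p, y, roi=None, delta: float = DELTA) -> np.ndarray:
    p = np.asarray(p, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    pv, yv, sel = _prep(p, y, roi)
    inter = np.sum(pv * yv) + delta
    union = np.sum(pv + yv - pv * yv) + delta
    g = -(y * union - inter * (1.0 - y)) / union ** 2
    return np.where(sel, g, 0.0)


def mse_loss(p, y, roi=None) -> float:
    """Mean squared error over ROI pixels (the multi-fidelity data term)."""
    pv, yv, _ = _prep(p, y, roi)
    return float(np.mean((pv - yv) ** 2))


def mse_grad(p, y, roi=None) -> np.ndarray:
    p = np.asarray(p, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    _, _, sel = _prep(p, y, roi)
    g = 2.0 * (p - y) / sel.sum()
    return np.where(sel, g, 0.0)


LOSSES = {"bce": (bce_loss, bce_grad), "dsc": (dsc_loss, dsc_grad),
          "iou": (iou_loss, iou_grad), "mse": (mse_loss, mse_grad)}


@dataclass
class CompositeLossTerms:
    """The multi-fidelity objective MSE_L + MSE_H + lambda * sum(beta^2)."""

    mse_l: float
    mse_h: float
    l2_penalty: float
    total: float
    n_l: int
    n_h: int
    l2_rate: float


def composite_loss(pred_l, y_l, pred_h, y_h, weights=(), l2_rate: float = 0.0,
                   roi=None) -> CompositeLossTerms:
    """Evaluate the composite objective on low- and high-fidelity batches.

    ``pred_l``/``y_l`` and ``pred_h``/``y_h`` are sample-stacked arrays;
    either fidelity may be absent (None), but not both.  Each MSE term is
    the mean squared pixel error averaged over that fidelity's samples;
    ``weights`` is an iterable of weight tensors entering the L2 penalty.
    """
    if (pred_l is None or len(pred_l) == 0) and (pred_h is None or len(pred_h) == 0):
        raise ValueError("at least one fidelity batch must be nonempty")

    def _term(pred, y):
        if pred is None or len(pred) == 0:
            return 0.0, 0
        return mse_loss(pred, y, roi), len(pred)

    mse_l, n_l = _term(pred_l, y_l)
    mse_h, n_h = _term(pred_h, y_h)
    l2 = float(l2_rate * sum(np.sum(np.asarray(w, dtype=np.float64) ** 2)
                             for w in weights))
    return CompositeLossTerms(mse_l=mse_l, mse_h=mse_h, l2_penalty=l2,
                              total=mse_l + mse_h + l2, n_l=n_l, n_h=n_h,
                              l2_rate=l2_rate)


# ---------------------------------------------------------------------------
# metrics

def binarize(p, threshold: float = 0.5, roi=None) -> np.ndarray:
    """Threshold a probability map to a binary mask (strict >), zero outside ROI."""
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must lie strictly between 0 and 1")
    out = (np.asarray(p, dtype=np.float64) > threshold).astype(np.uint8)
    if roi is not None:
        out = out * np.asarray(roi).astype(np.uint8)
    return out


@dataclass
class EvalReport:
    """Pixel metrics over the ROI; IoU/DSC on the infarct class only."""

    accuracy: float
    precision: float
    recall: float
    iou: float
    dsc: float
    roi_pixel_count: int
    threshold: float = 0.5

    def as_dict(self):
        return asdict(self)


def evaluate(pred, truth, roi=None, threshold: float = 0.5) -> EvalReport:
    """Score a binary prediction against a binary ground-truth mask.

    Accuracy, precision and recall are computed over ROI pixels; IoU and
    DSC per their overlap definitions on the infarct class.  Pixels
    outside the ROI never influence the report.
    """
    pv, tv, sel = _prep(pred, truth, roi)
    n = pv.size
    if n == 0:
        raise ValueError("empty ROI")
    if not (np.isin(pv, (0, 1)).all() and np.isin(tv, (0, 1)).all()):
        raise ValueError("evaluate requires binary masks")
    tp = float(np.sum(pv * tv))
    fp = float(np.sum(pv * (1 - tv)))
    fn = float(np.sum((1 - pv) * tv))
    tn = n - tp - fp - fn
    accuracy = (tp + tn) / n
    p_total, g_total = tp + fp, tp + fn
    if p_total == 0 and g_total == 0:
        precision = recall = iou = dsc = 1.0
    elif p_total == 0 or g_total == 0:
        precision = recall = iou = dsc = 0.0
    else:
        precision = tp / p_total
        recall = tp / g_total
        union = tp + fp + fn
        iou = tp / union if union > 0 else 1.0
        dsc = 2.0 * tp / (p_total + g_total)
    return EvalReport(accuracy=accuracy, precision=precision, recall=recall,
                      iou=iou, dsc=dsc, roi_pixel_count=int(n),
                      threshold=threshold)
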