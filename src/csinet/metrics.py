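"""Reconstruction-quality and tumor-detectability metrics.

RMS reconstruction error is computed separately for the real and imaginary
permittivity parts over an evaluation mask (by default the breast
interior, since the exterior medium is known from the prior).  Tumor
detectability is the area under the pixel-wise ROC obtained by sweeping a
threshold over the reconstructed permittivity, with pixels pooled across
all phantoms of a test subset; the AUC equals the probability that a
random tumor pixel outranks a random non-tumor pixel (Mann-Whitney).
"""

from __future__ import annotations

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve


def rms_error(pred_image, truth_image, mask=None):
    """sqrt(mean over mask of squared differences)."""
    pred = np.asarray(pred_image, dtype=float)
    truth = np.asarray(truth_image, dtype=float)
    if pred.shape != truth.shape:
        raise ValueError("image shapes differ")
    if mask is None:
        mask = np.ones(pred.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty evaluation mask")
    d = pred[mask] - truth[mask]
    return float(np.sqrt(np.mean(d * d)))


def pixel_roc_auc(feature_images, tumor_masks, eval_masks=None):
    """Pooled pixel-wise ROC over one or more phantoms.

    Parameters
    ----------
    feature_images : array or sequence of arrays
        Per-pixel score; higher means more tumor-like.
    tumor_masks : array or sequence of arrays
        Boolean ground-truth tumor labels, same shapes.
    eval_masks : optional
        Restrict pooling (e.g. breast interior only).

    Returns
    -------
    (auc, (fpr, tpr, thresholds))
    """
    if isinstance(feature_images, np.ndarray) and feature_images.ndim == 2:
        feats = [feature_images]
        tumor_masks = [np.asarray(tumor_masks)]
        eval_masks = None if eval_masks is None else [np.asarray(eval_masks)]
    else:
        feats = [np.asarray(f) for f in feature_images]
        tumor_masks = [np.asarray(m) for m in tumor_masks]
        if eval_masks is not None:
            eval_masks = [np.asarray(m) for m in eval_masks]

    scores, labels = [], []
    for i, (f, t) in enumerate(zip(feats, tumor_masks)):
        sel = np.ones(f.shape, dtype=bool) if eval_masks is None else eval_masks[i]
        scores.append(f[sel].ravel())
        labels.append(t[sel].ravel())
    y = np.concatenate(labels).astype(int)
    s = np.concatenate(scores).astype(float)
    if y.min() == y.max():
        raise ValueError("pixel pool contains a single class only")
    auc = float(roc_auc_score(y, s))
    fpr, tpr, thr = roc_curve(y, s)
    return auc, (fpr, tpr, thr)
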