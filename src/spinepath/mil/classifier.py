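"""MIL training, slide prediction, Grad-CAM and classifier evaluation."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from sklearn.metrics import (
    average_precision_score,
    confusion_matrix,
    precision_recall_fscore_support,
    roc_auc_score,
)

from .net import AttentionMILModel, MILConfig


@dataclass
class SlidePrediction:
    slide_id: str
    class_probs: np.ndarray
    predicted_class: int
    attention: np.ndarray
    gradcam: list[np.ndarray] | None = None
    slide_heatmap: np.ndarray | None = None


def _softmax(logits):
    e = np.exp(logits - logits.max())
    return e / e.sum()


def _as_float(tiles: np.ndarray) -> np.ndarray:
    return np.asarray(tiles, dtype=np.float32) / 255.0


def _augment(tiles: np.ndarray, rng) -> np.ndarray:
    k = int(rng.integers(0, 4))
    out = np.rot90(tiles, k=k, axes=(1, 2))
    if rng.random() < 0.5:
        out = out[:, ::-1]
    if rng.random() < 0.5:
        out = out[:, :, ::-1]
    return np.ascontiguousarray(out)


def train_mil(train_bags, config: MILConfig | None = None) -> AttentionMILModel:
    """Train the attention-MIL classifier on slide-level labels.

    ``train_bags`` is a list of objects with ``tiles`` (n, T, T, 3) and
    integer ``label``.  Uses class-weighted cross-entropy (inverse class
    frequency by default), optional flip/rotation augmentation, and Adam.
    """
    config = config or MILConfig()
    labels = np.array([b.label for b in train_bags])
    present = np.unique(labels)
    if len(present) < 2:
        raise ValueError("training set must contain at least 2 classes")
    counts = np.bincount(labels, minlength=config.n_classes).astype(np.float64)
    if config.class_weights is None:
        weights = np.where(counts > 0, len(labels) / np.maximum(counts, 1) / config.n_classes, 0.0)
    else:
        weights = np.asarray(config.class_weights, dtype=np.float64)
        if (weights <= 0).any():
            raise ValueError("class weights must be positive")
    model = AttentionMILModel(config)
    rng = np.random.default_rng(config.seed + 1)
    model.training_log = []
    for epoch in range(config.epochs):
        order = rng.permutation(len(train_bags))
        total_loss = 0.0
        correct = 0
        for i in order:
            bag = train_bags[i]
            tiles = _as_float(bag.tiles)
            if config.augment:
                tiles = _augment(tiles, rng)
            logits, _ = model.forward_bag(tiles)
            probs = _softmax(logits)
            y = bag.label
            w = weights[y]
            total_loss += -w * np.log(max(probs[y], 1e-12))
            correct += int(np.argmax(probs) == y)
            dlogits = (probs - np.eye(config.n_classes)[y]) * w
            model.backward_bag(dlogits.astype(np.float32))
            model.adam_step(config.learning_rate)
        acc = correct / len(train_bags)
        model.training_log.append({"epoch": epoch, "loss": float(total_loss / len(train_bags)), "train_acc": acc})
        if acc == 1.0 and epoch >= 2:
            prev = model.training_log[-2]["train_acc"] if len(model.training_log) > 1 else 0
            if prev == 1.0:
                break
    model.trained = True
    return model


def encode_tiles(bag, model: AttentionMILModel) -> np.ndarray:
    """Deterministic per-tile embeddings for one bag."""
    if len(bag.tiles) == 0:
        raise ValueError("empty bag")
    return model.encode(_as_float(bag.tiles))


def attention_pool(model: AttentionMILModel, features: np.ndarray):
    """Gated-attention pooling: (slide embedding, softmax weights)."""
    if features.shape[0] < 1:
        raise ValueError("need at least one tile")
    return model.attention_pool(features.astype(np.float32))


def predict_slide(model: AttentionMILModel, bag, with_gradcam: bool = False) -> SlidePrediction:
    """Slide prediction; argmax ties break toward the lowest class index."""
    if not getattr(model, "trained", False):
        raise ValueError("model has not been trained")
    tiles = _as_float(bag.tiles)
    logits, attention = model.forward_bag(tiles)
    probs = _softmax(logits)
    pred = int(np.argmax(probs))  # np.argmax returns the first (lowest) maximum
    maps = None
    if with_gradcam:
        maps = [gradcam(model, t, pred) for t in bag.tiles]
    return SlidePrediction(
        slide_id=getattr(bag, "bag_id", ""),
        class_probs=probs,
        predicted_class=pred,
        attention=attention,
        gradcam=maps,
    )


def gradcam(model: AttentionMILModel, tile: np.ndarray, target_class: int) -> np.ndarray:
    """Grad-CAM on the last convolutional layer for a single tile.

    Channel weights are the spatial mean of the target-class gradient at
    the last conv activations; the rectified weighted activation sum is
    upsampled to tile size and min-max scaled to [0, 1].  A spatially
    constant map is degenerate and returned as all zeros.
    """
    tiles = _as_float(tile[None])
    h = model.encode(tiles)  # caches last conv activations
    a3 = model._a3[0]  # (H', W', C) post-ReLU
    hh, ww, _ = a3.shape
    # single-tile bag: attention weight is constant 1, so the class logit
    # gradient wrt the activations is Wc[:, c] spread over the GAP
    alpha = model.Wc[:, target_class] / (hh * ww)
    cam = np.maximum(a3 @ alpha, 0.0)
    # constant input: only padding artifacts at the border vary; the interior
    # is flat, which marks the map as degenerate
    interior = cam[2:-2, 2:-2]
    if interior.size and float(interior.max() - interior.min()) < 1e-9:
        return np.zeros(tile.shape[:2])
    zoom = tile.shape[0] / hh, tile.shape[1] / ww
    cam = ndi.zoom(cam, zoom, order=1)
    lo, hi = float(cam.min()), float(cam.max())
    if hi - lo < 1e-12:
        return np.zeros_like(cam)
    return (cam - lo) / (hi - lo)


def slide_heatmap(prediction: SlidePrediction, coords, tile_px: int, shape) -> np.ndarray:
    """Attention-weighted mosaic of per-tile Grad-CAM maps on slide coords."""
    out = np.zeros(shape, dtype=np.float64)
    norm = np.zeros(shape, dtype=np.float64)
    for (r, c), cam, a in zip(coords, prediction.gradcam, prediction.attention):
        out[r : r + tile_px, c : c + tile_px] += a * cam
        norm[r : r + tile_px, c : c + tile_px] += a
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(norm > 0, out / norm, 0.0)
    return out


def evaluate_classifier(
    model: AttentionMILModel, test_bags, n_boot: int = 1000, seed: int = 0
) -> dict:
    """Accuracy, per-class AUC/AP/P/R/F1 with bootstrap CIs, confusion matrix."""
    preds = [predict_slide(model, b) for b in test_bags]
    y_true = np.array([b.label for b in test_bags])
    y_pred = np.array([p.predicted_class for p in preds])
    probs = np.vstack([p.class_probs for p in preds])
    n_classes = probs.shape[1]
    report: dict = {"n": len(test_bags)}
    report["accuracy"] = float((y_true == y_pred).mean())
    report["confusion_matrix"] = confusion_matrix(y_true, y_pred, labels=range(n_classes)).tolist()
    prec, rec, f1, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=range(n_classes), zero_division=0
    )
    per_class = {}
    for k in range(n_classes):
        onevr = (y_true == k).astype(int)
        if len(np.unique(onevr)) < 2:
            auc = ap = float("nan")
        else:
            auc = float(roc_auc_score(onevr, probs[:, k]))
            ap = float(average_precision_score(onevr, probs[:, k]))
        per_class[k] = {
            "auc": auc,
            "average_precision": ap,
            "precision": float(prec[k]),
            "recall": float(rec[k]),
            "f1": float(f1[k]),
        }
    report["per_class"] = per_class
    # bootstrap CI on accuracy over slides
    rng = np.random.default_rng(seed)
    accs = []
    for _ in range(n_boot):
        idx = rng.integers(0, len(y_true), len(y_true))
        accs.append((y_true[idx] == y_pred[idx]).mean())
    lo, hi = np.percentile(accs, [2.5, 97.5])
    report["accuracy_ci95"] = (float(lo), float(hi))
    return report
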