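"""Insertion/deletion faithfulness of saliency explanations.

A saliency map ranks pixels; the deletion curve tracks the model's softmax
confidence in the target class as the top-t fraction of pixels is replaced by
a Gaussian-blurred copy of the image, and the insertion curve tracks
confidence as those pixels are restored into the blurred baseline.  Areas
under the curves (trapezoid rule over t in [0, 1]) summarize faithfulness:
low deletion AUC and high insertion AUC mean the ranked pixels really carry
the evidence.  Evaluation follows the correct-only protocol: only images the
model classifies correctly are scored, with target class = predicted class.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .errors import ConfigurationError, DegenerateInputError, ValidationError
from .saliency import SaliencyMap
from .stats import bootstrap_mean_ci


@dataclass
class BlurBaselineConfig:
    """Gaussian-blur baseline: kernel width, sigma, and curve step count."""

    kernel: int = 51
    sigma: float = 8.0
    steps: int = 50

    def __post_init__(self):
        if self.kernel < 1 or self.kernel % 2 == 0:
            raise ConfigurationError(f"blur kernel must be odd and positive, got {self.kernel}")
        if self.sigma <= 0:
            raise ConfigurationError("sigma must be positive")
        if self.steps < 1:
            raise ConfigurationError("steps must be positive")


@dataclass
class FaithfulnessCurve:
    fractions: np.ndarray
    confidences: np.ndarray
    mode: str

    def __post_init__(self):
        self.fractions = np.asarray(self.fractions, dtype=np.float64)
        self.confidences = np.asarray(self.confidences, dtype=np.float64)
        if self.mode not in ("insertion", "deletion"):
            raise ValidationError(f"unknown curve mode {self.mode!r}")
        t, f = self.fractions, self.confidences
        if t.shape != f.shape or t.ndim != 1 or t.size < 2:
            raise ValidationError("fractions/confidences must be matching 1-D arrays (>= 2 points)")
        if not (t[0] == 0.0 and t[-1] == 1.0 and (np.diff(t) > 0).all()):
            raise ValidationError("fractions must increase from 0 to 1")
        if ((f < -1e-9) | (f > 1 + 1e-9)).any():
            raise ValidationError("confidences must lie in [0, 1]")


@dataclass
class FaithfulnessResult:
    image_id: str
    target_class: int
    insertion_auc: float
    deletion_auc: float
    included: bool = True
    one_minus_deletion: float = field(init=False)

    def __post_init__(self):
        self.one_minus_deletion = 1.0 - self.deletion_auc


# ----------------------------------------------------------------------
def blur_baseline(image: np.ndarray, cfg: BlurBaselineConfig) -> np.ndarray:
    """Per-channel Gaussian blur with the configured kernel support."""
    image = np.asarray(image, dtype=np.float32)
    if image.ndim != 3 or image.shape[0] != 3:
        raise ValidationError(f"expected a (3, H, W) RGB image, got {image.shape}")
    radius = (cfg.kernel - 1) // 2
    if radius == 0:
        return image.copy()
    out = gaussian_filter1d(image, cfg.sigma, axis=1, mode="nearest", radius=radius)
    out = gaussian_filter1d(out, cfg.sigma, axis=2, mode="nearest", radius=radius)
    # a moving average cannot overshoot the input's range; clip guards rounding
    return np.clip(out, image.min(), image.max())


def _as_predictor(model):
    if callable(model) and not hasattr(model, "predict_proba"):
        return model
    return model.predict_proba


def _pixel_order(saliency: SaliencyMap) -> np.ndarray:
    v = saliency.values.ravel()
    if not np.isfinite(v).all():
        raise ValidationError("non-finite saliency values")
    # stable sort on -v: ties broken by row-major pixel index
    return np.argsort(-v, kind="stable")


def _step_counts(n_pixels: int, steps: int) -> np.ndarray:
    base, rem = divmod(n_pixels, steps)
    return np.array([base + 1] * rem + [base] * (steps - rem))


def _perturbation_curve(model, image, saliency: SaliencyMap, cfg: BlurBaselineConfig,
                        mode: str, target_class: int,
                        baseline: np.ndarray | None = None) -> FaithfulnessCurve:
    image = np.asarray(image, dtype=np.float32)
    if saliency.values.shape != image.shape[1:]:
        raise ValidationError(
            f"saliency shape {saliency.values.shape} != image spatial shape {image.shape[1:]}")
    predict = _as_predictor(model)
    base = blur_baseline(image, cfg) if baseline is None else np.asarray(baseline, np.float32)
    order = _pixel_order(saliency)
    counts = _step_counts(order.size, cfg.steps)

    start, fill = (image, base) if mode == "deletion" else (base, image)
    flat_start = start.reshape(3, -1)
    flat_fill = fill.reshape(3, -1)
    batch = np.empty((cfg.steps + 1,) + image.shape, dtype=np.float32)
    current = flat_start.copy()
    batch[0] = current.reshape(image.shape)
    pos = 0
    for k, cnt in enumerate(counts, start=1):
        idx = order[pos:pos + cnt]
        current[:, idx] = flat_fill[:, idx]
        pos += cnt
        batch[k] = current.reshape(image.shape)
    probs = np.asarray(predict(batch))
    fractions = np.concatenate([[0.0], np.cumsum(counts) / order.size])
    return FaithfulnessCurve(fractions, probs[:, target_class], mode=mode)


def deletion_curve(model, image, saliency: SaliencyMap, cfg: BlurBaselineConfig,
                   target_class: int, baseline: np.ndarray | None = None) -> FaithfulnessCurve:
    """Confidence as the most-salient pixels are replaced by the blurred image."""
    return _perturbation_curve(model, image, saliency, cfg, "deletion", target_class, baseline)


def insertion_curve(model, image, saliency: SaliencyMap, cfg: BlurBaselineConfig,
                    target_class: int, baseline: np.ndarray | None = None) -> FaithfulnessCurve:
    """Confidence as the most-salient pixels are restored into the blurred baseline."""
    return _perturbation_curve(model, image, saliency, cfg, "insertion", target_class, baseline)


def auc_trapezoid(curve: FaithfulnessCurve) -> float:
    """Trapezoidal approximation of the integral of confidence over t in [0, 1]."""
    if curve.fractions.size < 2:
        raise ValidationError("need at least 2 curve points")
    return float(np.trapezoid(curve.confidences, curve.fractions))


# ----------------------------------------------------------------------
def evaluate_faithfulness(model, dataset, explainer, cfg: BlurBaselineConfig,
                          correct_only: bool = True, n_boot: int = 2000,
                          seed: int = 0):
    """Per-image insertion/deletion AUCs plus a bootstrap summary.

    ``dataset`` yields (image_id, image, label); ``explainer(image, target)``
    returns a SaliencyMap.  Under the correct-only protocol, images the model
    misclassifies are dropped and the target class is the predicted class.
    """
    predict = _as_predictor(model)
    results: list[FaithfulnessResult] = []
    curves: dict[str, list[FaithfulnessCurve]] = {"insertion": [], "deletion": []}
    for image_id, image, label in dataset:
        probs = np.asarray(predict(np.asarray(image, np.float32)[None]))[0]
        pred = int(probs.argmax())
        if correct_only and pred != int(label):
            results.append(FaithfulnessResult(str(image_id), pred, np.nan, np.nan,
                                              included=False))
            continue
        sal = explainer(image, pred)
        ins = insertion_curve(model, image, sal, cfg, pred)
        dele = deletion_curve(model, image, sal, cfg, pred)
        curves["insertion"].append(ins)
        curves["deletion"].append(dele)
        results.append(FaithfulnessResult(str(image_id), pred,
                                          auc_trapezoid(ins), auc_trapezoid(dele)))
    included = [r for r in results if r.included]
    if not included:
        raise DegenerateInputError(
            "no images passed the correct-only filter; cannot summarize faithfulness")
    summary = {"n_images": len(included)}
    for key, vals in (("insertion_auc", [r.insertion_auc for r in included]),
                      ("deletion_auc", [r.deletion_auc for r in included]),
                      ("one_minus_deletion", [r.one_minus_deletion for r in included])):
        mean, lo, hi = bootstrap_mean_ci(vals, n_boot=n_boot, seed=seed)
        summary[key] = {"mean": mean, "ci_low": lo, "ci_high": hi}
    return results, summary, curves


# ----------------------------------------------------------------------
def write_results_csv(results: list[FaithfulnessResult], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["image_id", "target_class", "insertion_auc", "deletion_auc",
                    "one_minus_deletion", "included"])
        for r in results:
            w.writerow([r.image_id, r.target_class, r.insertion_auc,
                        r.deletion_auc, r.one_minus_deletion, int(r.included)])


def write_summary_json(summary: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2)


def plot_mean_curves(curve_sets: dict[str, dict[str, list[FaithfulnessCurve]]], path) -> None:
    """Mean +/- std insertion and deletion curves, one panel per mode."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5))
    for ax, mode in zip(axes, ("insertion", "deletion")):
        for label, curves in curve_sets.items():
            cs = curves[mode]
            if not cs:
                continue
            t = cs[0].fractions
            mat = np.stack([c.confidences for c in cs])
            mu, sd = mat.mean(axis=0), mat.std(axis=0)
            ax.plot(t, mu, label=label)
            ax.fill_between(t, mu - sd, mu + sd, alpha=0.2)
        ax.set_title(f"{mode} curve")
        ax.set_xlabel("fraction of pixels")
        ax.set_ylabel("confidence")
        ax.set_ylim(-0.02, 1.02)
        ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
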