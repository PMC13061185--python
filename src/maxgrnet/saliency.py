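"""Grad-CAM saliency for MaxGRNet-style networks, plus a random baseline.

Grad-CAM weights each channel of a chosen convolutional feature layer by the
spatial mean of the gradient of the target-class *logit* (pre-softmax class
score) with respect to that layer, sums the weighted channels, rectifies, and
bilinearly upsamples to the input resolution.  The logit choice makes the map
invariant to adding a constant to all logits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize as _sk_resize

from .architecture import MaxGRNet
from .errors import ConfigurationError, ValidationError

DEFAULT_LAYER = "last_mbconv_dw"


@dataclass
class SaliencyMap:
    """Per-pixel relevance on the input grid (non-negative, finite)."""

    values: np.ndarray
    target_class: int
    layer_id: str

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.ndim != 2:
            raise ValidationError(f"saliency must be 2-D, got shape {self.values.shape}")
        if not np.isfinite(self.values).all():
            raise ValidationError("saliency contains non-finite values")
        if (self.values < 0).any():
            raise ValidationError("saliency must be non-negative")

    def normalized(self) -> np.ndarray:
        """Min-max scaled copy in [0, 1] for visualization only."""
        v = self.values
        span = v.max() - v.min()
        return (v - v.min()) / span if span > 0 else np.zeros_like(v)


def resolve_layer(model: MaxGRNet, layer_id: str | None) -> str:
    layers = model.feature_layers()
    if layer_id is None or layer_id == DEFAULT_LAYER:
        # depthwise convolution of the final stage's last MBConv
        return [n for n in layers if n.endswith("mbconv.dw")][-1]
    if layer_id not in layers:
        raise ConfigurationError(
            f"unknown layer {layer_id!r}; valid layers: {layers}")
    return layer_id


def gradcam(model: MaxGRNet, image: np.ndarray, target_class: int,
            layer_id: str | None = None) -> SaliencyMap:
    """Class-discriminative saliency for one preprocessed image."""
    image = np.asarray(image, dtype=np.float32)
    if image.ndim != 3:
        raise ValidationError(f"expected a single (3, H, W) image, got {image.shape}")
    if not 0 <= target_class < model.cfg.num_classes:
        raise ValidationError(f"target_class {target_class} out of range")
    layer = resolve_layer(model, layer_id)

    model.zero_grad()
    logits = model.forward(image[None])
    feat = model._features[layer]
    seed = np.zeros_like(logits.data)
    seed[0, target_class] = 1.0
    logits.backward(seed)

    fmap = feat.data[0]                      # (C, h, w)
    grad = feat.grad[0]
    weights = grad.mean(axis=(1, 2))         # spatial mean of d score / d feature
    cam = np.maximum((weights[:, None, None] * fmap).sum(axis=0), 0.0)
    size = model.cfg.input_size
    up = _sk_resize(cam, (size, size), order=1, mode="edge",
                    anti_aliasing=False, preserve_range=True)
    return SaliencyMap(np.maximum(up, 0.0), target_class=int(target_class), layer_id=layer)


def random_saliency(shape: tuple[int, int], seed: int) -> SaliencyMap:
    """Uniform [0, 1) relevance map — the chance-level explainer baseline."""
    rng = np.random.default_rng(seed)
    return SaliencyMap(rng.random(shape, dtype=np.float32),
                       target_class=-1, layer_id="random")
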