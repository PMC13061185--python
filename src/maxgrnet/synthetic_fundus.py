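"""Seeded fundus-phantom generator with ground-truth lesion masks.

Produces retina-like images — a bright disc on a dark background — with one
class-discriminative, spatially localized feature per disease class:

* ``normal``       plain disc, empty lesion mask;
* ``cataract``     a broad bright haze over part of the disc;
* ``retinopathy``  scattered small bright dots;
* ``glaucoma``     an enlarged bright central cup.

The classes are deliberately easy: the generator's purpose is exercising the
classification, saliency and faithfulness pipeline end to end on a CPU, not
photorealism.  Each image's discriminative feature lies entirely inside its
returned binary mask, so the mask doubles as an oracle saliency map.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .saliency import SaliencyMap

CLASS_NAMES = ("normal", "cataract", "retinopathy", "glaucoma")


@dataclass
class PhantomSpec:
    image_size: int = 64
    classes: tuple[str, ...] = CLASS_NAMES
    n_per_class: int = 50
    noise_sigma: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.n_per_class < 1 or self.noise_sigma < 0 or self.image_size < 16:
            raise ValidationError("invalid phantom spec")
        unknown = set(self.classes) - set(CLASS_NAMES)
        if unknown:
            raise ValidationError(f"unknown phantom classes {sorted(unknown)}")


def _disc(size: int, cx: float, cy: float, r: float) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size]
    return ((xx - cx) ** 2 + (yy - cy) ** 2) <= r ** 2


def _class_pattern(cls: str, n: int) -> np.ndarray:
    """Fixed per-class lesion layout: (n, 3) rows of (dx, dy, parity).

    Offsets are in units of the lesion-region radius, drawn once from a
    class-keyed generator, so every image of a class shares the same texture
    phase (images of one class resemble each other) while the bright/dark
    parity keeps the texture zero-mean (heavy blur erases it).
    """
    prng = np.random.default_rng(zlib.crc32(f"phantom-pattern-{cls}".encode()))
    ang = prng.uniform(0, 2 * np.pi, n)
    rad = np.sqrt(prng.uniform(0, 1, n)) * 0.9
    parity = np.arange(n) % 2
    return np.column_stack([rad * np.cos(ang), rad * np.sin(ang), parity])


def _render(cls: str, size: int, rng: np.random.Generator,
            noise_sigma: float) -> tuple[np.ndarray, np.ndarray]:
    cx = size / 2 + rng.uniform(-1, 1)
    cy = size / 2 + rng.uniform(-1, 1)
    radius = size * rng.uniform(0.39, 0.41)
    disc = _disc(size, cx, cy, radius)

    # base retina: warm bright disc with a mild radial falloff
    yy, xx = np.mgrid[0:size, 0:size]
    dist = np.sqrt((xx - cx) ** 2 + (yy - cy) ** 2) / radius
    base = np.clip(1.0 - 0.35 * dist, 0.0, 1.0) * disc
    img = np.stack([0.85 * base, 0.45 * base, 0.25 * base])
    mask = np.zeros((size, size), dtype=bool)

    # every lesion is a high-frequency pattern inside a contiguous mask, so a
    # heavy Gaussian blur genuinely removes the class evidence
    def stamp(pattern, ccx, ccy, region_r, bright_rgb, dark_rgb, dot_r):
        stamped = np.zeros((size, size), dtype=bool)
        for dxu, dyu, parity in pattern:
            px = ccx + dxu * region_r + rng.uniform(-1.0, 1.0)
            py = ccy + dyu * region_r + rng.uniform(-1.0, 1.0)
            dot = _disc(size, px, py, dot_r * rng.uniform(0.9, 1.1)) & disc
            col = bright_rgb if parity == 0 else dark_rgb
            for ch in range(3):
                img[ch][dot] = col[ch]
            stamped |= dot
        return stamped

    if cls == "cataract":
        # broad speckled veil: white and dark flecks in equal measure over a
        # large central haze, zero-mean so heavy blur returns the plain disc
        hx = cx + rng.uniform(-0.1, 0.1) * radius
        hy = cy + rng.uniform(-0.1, 0.1) * radius
        hr = radius * rng.uniform(0.58, 0.65)
        # bright/dark fleck colours average to the local disc colour per
        # channel, so the blurred haze is indistinguishable from a plain disc
        stamp(_class_pattern("cataract", 22), hx, hy, hr,
              (1.0, 0.72, 0.40), (0.36, 0.0, 0.0), 2.2 * size / 64)
        mask = _disc(size, hx, hy, hr + 2.0) & disc
    elif cls == "retinopathy":
        # compact cluster of bright exudate-like and dark haemorrhage-like
        # dots in the upper temporal quadrant
        ang = np.pi / 4 + rng.uniform(-0.3, 0.3)
        rad = rng.uniform(0.38, 0.48) * radius
        ccx, ccy = cx + rad * np.cos(ang), cy + rad * np.sin(ang)
        cluster_r = radius * rng.uniform(0.36, 0.42)
        stamp(_class_pattern("retinopathy", 10), ccx, ccy, cluster_r,
              (1.0, 0.72, 0.10), (0.36, 0.0, 0.30), 2.8 * size / 64)
        mask = _disc(size, ccx, ccy, cluster_r + 3.0) & disc
    elif cls == "glaucoma":
        # enlarged cup: sharp bright rim with a dark inner ring (zero-mean
        # edge profile, wiped by heavy blur)
        cup_r = radius * rng.uniform(0.52, 0.58)
        rim_d = np.sqrt((xx - cx) ** 2 + (yy - cy) ** 2)
        rim = (np.abs(rim_d - cup_r) <= 1.6) & disc
        inner = (np.abs(rim_d - (cup_r - 3.2)) <= 1.6) & disc
        img[0][rim] = 1.0
        img[1][rim] = 0.72
        img[2][rim] = 0.40
        img[0][inner] = 0.36
        img[1][inner] = 0.0
        img[2][inner] = 0.0
        mask = (rim_d <= cup_r + 2.0) & disc

    # nuisance brightness jitter so global intensity statistics are not a shortcut
    img = img * rng.uniform(0.85, 1.05)
    img = np.clip(img + rng.normal(0, noise_sigma, img.shape), 0.0, 1.0)
    return img.astype(np.float32), mask


def generate(spec: PhantomSpec):
    """(images (N,3,S,S) in [0,1], integer labels, boolean masks (N,S,S)).

    N = n_per_class * len(classes); same seed gives bit-identical output.
    """
    images, labels, masks = [], [], []
    for label, cls in enumerate(spec.classes):
        for i in range(spec.n_per_class):
            # per-image child seed: images are independent of each other and
            # of the composition of the rest of the dataset
            rng = np.random.default_rng([spec.seed, label, i])
            img, mask = _render(cls, spec.image_size, rng, spec.noise_sigma)
            images.append(img)
            labels.append(label)
            masks.append(mask)
    return np.stack(images), np.array(labels), np.stack(masks)


def oracle_saliency(mask: np.ndarray) -> SaliencyMap:
    """Ground-truth saliency: 1 inside the lesion mask, 0 outside."""
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValidationError("mask must be 2-D")
    return SaliencyMap(mask.astype(np.float32), target_class=-1, layer_id="oracle")
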