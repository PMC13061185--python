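"""Image-directory ingestion, preprocessing, augmentation and leakage-safe splits.

The dataset index is a pandas DataFrame with one record per image:
``image_id, path, class_label, origin (real|augmented), parent_id, subset``.
Augmented records carry the id of their source image; the leakage rule —
an augmented variant must live in the same train/val/test subset as its
parent — is checked by :func:`verify_no_leakage` and enforced by
constructing plans only after subsets are assigned (split-then-augment).
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image, ImageFilter

from .errors import ConfigurationError, ValidationError

IMAGENET_MEAN = np.array([0.485, 0.456, 0.406], dtype=np.float32)
IMAGENET_STD = np.array([0.229, 0.224, 0.225], dtype=np.float32)

INDEX_COLUMNS = ["image_id", "path", "class_label", "origin", "parent_id", "subset"]


# ----------------------------------------------------------------------
def build_index(root) -> pd.DataFrame:
    """Index a class-per-subdirectory image tree (PNG/JPEG)."""
    root = Path(root)
    records = []
    for class_dir in sorted(p for p in root.iterdir() if p.is_dir()):
        for img in sorted(class_dir.iterdir()):
            if img.suffix.lower() not in (".png", ".jpg", ".jpeg"):
                continue
            rel = str(img.relative_to(root))
            image_id = hashlib.sha1(rel.encode()).hexdigest()[:16]
            records.append((image_id, str(img), class_dir.name, "real", "", "unassigned"))
    if not records:
        raise ValidationError(f"no images found under {root}")
    df = pd.DataFrame(records, columns=INDEX_COLUMNS)
    if df.image_id.duplicated().any():
        raise ValidationError("image_id collision in index")
    return df


def load_image(path) -> np.ndarray:
    """Decode to an RGB (H, W, 3) float array in [0, 1]."""
    try:
        img = Image.open(path)
        img.load()
    except OSError as exc:
        raise OSError(f"cannot read image file {path}: {exc}") from exc
    if img.mode in ("L", "LA", "I;16", "I"):
        warnings.warn(f"grayscale image {path}: replicating to 3 channels")
    img = img.convert("RGB")
    return np.asarray(img, dtype=np.float32) / 255.0


def preprocess(image, size: int = 224) -> np.ndarray:
    """Resize (bilinear), scale to [0,1], normalize per channel -> (3, size, size)."""
    if isinstance(image, (str, Path)):
        arr = load_image(image)
    elif isinstance(image, Image.Image):
        if image.mode != "RGB":
            if image.mode in ("L", "LA", "I"):
                warnings.warn("grayscale image: replicating to 3 channels")
            image = image.convert("RGB")
        arr = np.asarray(image, dtype=np.float32) / 255.0
    else:
        arr = np.asarray(image, dtype=np.float32)
        if arr.ndim == 2:
            warnings.warn("grayscale array: replicating to 3 channels")
            arr = np.repeat(arr[..., None], 3, axis=-1)
    if arr.shape[:2] != (size, size):
        pil = Image.fromarray((np.clip(arr, 0, 1) * 255).astype(np.uint8))
        arr = np.asarray(pil.resize((size, size), Image.BILINEAR), np.float32) / 255.0
    return ((arr - IMAGENET_MEAN) / IMAGENET_STD).transpose(2, 0, 1).copy()


# ----------------------------------------------------------------------
@dataclass
class AugmentParams:
    p_hflip: float = 0.5
    p_vflip: float = 0.5
    jitter: float = 0.2               # brightness/contrast/saturation factor range
    blur_kernel: int = 3
    blur_sigma: tuple[float, float] = (0.1, 2.0)


def augment(image: np.ndarray, seed: int, params: AugmentParams | None = None) -> np.ndarray:
    """Stochastic flip + color jitter + Gaussian blur; reproducible per seed.

    Operates on a (3, H, W) float array in [0, 1] and preserves shape/range.
    """
    params = params or AugmentParams()
    rng = np.random.default_rng(seed)
    img = np.asarray(image, dtype=np.float32).copy()
    if img.ndim != 3 or img.shape[0] != 3:
        raise ValidationError(f"expected a (3, H, W) image, got {img.shape}")
    if rng.random() < params.p_hflip:
        img = img[:, :, ::-1]
    if rng.random() < params.p_vflip:
        img = img[:, ::-1, :]
    j = params.jitter
    brightness, contrast, saturation = rng.uniform(1 - j, 1 + j, size=3)
    img = img * brightness
    img = (img - img.mean()) * contrast + img.mean()
    gray = img.mean(axis=0, keepdims=True)
    img = gray + (img - gray) * saturation
    sigma = rng.uniform(*params.blur_sigma)
    pil = Image.fromarray((np.clip(img, 0, 1).transpose(1, 2, 0) * 255).astype(np.uint8))
    pil = pil.filter(ImageFilter.GaussianBlur(radius=sigma))
    out = np.asarray(pil, np.float32).transpose(2, 0, 1) / 255.0
    return np.clip(out, 0.0, 1.0)


# ----------------------------------------------------------------------
def _largest_remainder(total: int, weights: np.ndarray) -> np.ndarray:
    """Integer allocation of `total` proportional to `weights`, sum-preserving."""
    raw = total * weights / weights.sum()
    counts = np.floor(raw).astype(int)
    rem = total - counts.sum()
    order = np.argsort(-(raw - counts), kind="stable")
    counts[order[:rem]] += 1
    return counts


def split_holdout(index: pd.DataFrame, ratios: dict[str, float], seed: int = 0) -> pd.DataFrame:
    """Stratified train/val/test assignment of real images."""
    if abs(sum(ratios.values()) - 1.0) > 1e-9:
        raise ConfigurationError(f"split ratios must sum to 1, got {ratios}")
    if (index.origin != "real").any():
        raise ValidationError("split_holdout expects an index of real images only")
    rng = np.random.default_rng(seed)
    out = index.copy()
    names = list(ratios)
    weights = np.array([ratios[n] for n in names], dtype=float)
    for cls, group in out.groupby("class_label"):
        ids = group.index.to_numpy()
        rng.shuffle(ids)
        counts = _largest_remainder(len(ids), weights)
        start = 0
        for name, cnt in zip(names, counts):
            out.loc[ids[start:start + cnt], "subset"] = name
            start += cnt
    return out


# ----------------------------------------------------------------------
@dataclass
class AugmentationPlan:
    """Per (class, subset) augmentation quotas plus per-parent copy assignment."""

    rows: pd.DataFrame                      # class_label, subset, real, target, augmented_needed
    assignments: pd.DataFrame               # parent_id, class_label, subset, n_copies

    def class_totals(self) -> pd.DataFrame:
        g = self.rows.groupby("class_label")[["real", "target", "augmented_needed"]].sum()
        return g.reset_index()


def plan_balancing(index: pd.DataFrame, target_per_class: int,
                   subset_shares: dict[str, float] | None = None,
                   seed: int = 0) -> AugmentationPlan:
    """Split-then-augment balancing plan to `target_per_class` images per class.

    The class target is divided over subsets proportionally to
    ``subset_shares`` (default 70/20/10); within each (class, subset) cell the
    needed copies are spread round-robin over a seeded shuffle of that cell's
    real parents.
    """
    if (index.subset == "unassigned").any():
        raise ValidationError("plan_balancing requires subsets to be assigned first "
                              "(split-then-augment)")
    shares = subset_shares or {"train": 0.7, "val": 0.2, "test": 0.1}
    names = list(shares)
    weights = np.array([shares[n] for n in names], dtype=float)
    subset_targets = dict(zip(names, _largest_remainder(target_per_class, weights)))
    rng = np.random.default_rng(seed)
    rows, assign = [], []
    for cls, group in index[index.origin == "real"].groupby("class_label"):
        if group.empty:
            raise ValidationError(f"class {cls!r} has no real images")
        for subset in names:
            cell = group[group.subset == subset]
            target = int(subset_targets[subset])
            real = len(cell)
            needed = max(0, target - real)
            rows.append((cls, subset, real, target, needed))
            if needed and real:
                parents = cell.image_id.to_numpy().copy()
                rng.shuffle(parents)
                copies = np.zeros(real, dtype=int)
                copies[: needed % real] = needed // real + 1
                copies[needed % real:] = needed // real
                for pid, c in zip(parents, copies):
                    if c:
                        assign.append((pid, cls, subset, int(c)))
            elif needed and not real:
                raise ValidationError(
                    f"class {cls!r} has no real images in subset {subset!r} to augment from")
    rows_df = pd.DataFrame(rows, columns=["class_label", "subset", "real", "target",
                                          "augmented_needed"])
    assign_df = pd.DataFrame(assign, columns=["parent_id", "class_label", "subset",
                                              "n_copies"])
    return AugmentationPlan(rows=rows_df, assignments=assign_df)


def apply_balancing(index: pd.DataFrame, plan: AugmentationPlan) -> pd.DataFrame:
    """Append augmented records (ids = parent id + copy ordinal) to the index."""
    records = []
    for row in plan.assignments.itertuples():
        for i in range(row.n_copies):
            records.append((f"{row.parent_id}-aug{i}", "", row.class_label,
                            "augmented", row.parent_id, row.subset))
    aug = pd.DataFrame(records, columns=INDEX_COLUMNS)
    return pd.concat([index, aug], ignore_index=True)


def verify_no_leakage(index: pd.DataFrame) -> list[str]:
    """Return violations (empty list = clean); callers decide whether to raise."""
    violations = []
    dup = index.image_id[index.image_id.duplicated()].unique()
    for d in dup:
        violations.append(f"duplicate image_id {d!r}")
    subset_of = dict(zip(index.image_id, index.subset))
    for row in index[index.origin == "augmented"].itertuples():
        parent_subset = subset_of.get(row.parent_id)
        if parent_subset is None:
            violations.append(f"augmented {row.image_id!r} has unknown parent {row.parent_id!r}")
        elif parent_subset != row.subset:
            violations.append(
                f"augmented {row.image_id!r} in subset {row.subset!r} but parent "
                f"{row.parent_id!r} in subset {parent_subset!r}")
    return violations


def save_index(index: pd.DataFrame, path) -> None:
    index.to_csv(path, index=False)


def load_index(path) -> pd.DataFrame:
    return pd.read_csv(path, keep_default_na=False, dtype=str)
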