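"""Dataset ingestion: image/mask pairs, RGB mask decoding, patient-level
splitting, and the augmentation set used during training.

The canonical interchange format is a manifest CSV with columns
``image_path, mask_path, patient_id, modality``; a directory of images
with a parallel ``masks`` directory works through the same records.

Masks may arrive either as grayscale PNGs (binarized at >127 on the
8-bit scale) or as RGB-coded annotations where lesion classes are drawn
in red (malignant) or green (benign) on black; both classes collapse to
a single foreground, since the network segments lesion vs background.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage
from skimage.transform import resize

__all__ = [
    "ImageRecord",
    "DatasetSplit",
    "AugmentationConfig",
    "decode_rgb_mask",
    "load_pair",
    "split_by_patient",
    "augment",
    "AugmentationDraw",
    "sample_augmentation",
    "apply_augmentation",
    "read_manifest",
    "write_manifest",
]


@dataclass(frozen=True)
class ImageRecord:
    image_path: str
    mask_path: str
    patient_id: str
    modality: str = "synthetic"

    def __post_init__(self):
        if not self.patient_id:
            raise ValueError("patient_id must be non-empty")


@dataclass
class DatasetSplit:
    train: list[ImageRecord]
    val: list[ImageRecord]
    test: list[ImageRecord]
    ratios: tuple[float, float, float]
    seed: int

    def __post_init__(self):
        pids = [
            {r.patient_id for r in part} for part in (self.train, self.val, self.test)
        ]
        for i in range(3):
            for j in range(i + 1, 3):
                overlap = pids[i] & pids[j]
                if overlap:
                    raise ValueError(f"patient leakage across splits: {sorted(overlap)}")


@dataclass
class AugmentationConfig:
    """Training-time augmentation switches.

    The default set uses flips, mild intensity jitter and continuous
    rotations within +/-15 degrees; ``right_angle_rotations`` swaps the
    continuous rotations for the 0/90/180/270-degree set and enables
    scale jitter, the alternative protocol.
    """

    enabled: bool = True
    hflip_prob: float = 0.5
    vflip_prob: float = 0.5
    max_rotation_deg: float = 15.0
    right_angle_rotations: bool = False
    intensity_jitter: float = 0.1
    scale_jitter: float = 0.0
    seed: int | None = None

    def __post_init__(self):
        for p in (self.hflip_prob, self.vflip_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("flip probabilities must lie in [0, 1]")
        if self.max_rotation_deg < 0:
            raise ValueError("max_rotation_deg must be >= 0")


def decode_rgb_mask(rgb_mask: np.ndarray) -> np.ndarray:
    """Collapse an RGB-coded annotation to a binary foreground mask.

    A pixel is foreground iff its dominant colour is red or green rather
    than black (near-black pixels stay background). 2-D grayscale input
    passes through the >127 threshold instead.
    """
    arr = np.asarray(rgb_mask)
    if arr.ndim == 2:
        return (arr > 127).astype(np.uint8)
    if arr.ndim != 3 or arr.shape[2] not in (3, 4):
        raise ValueError(f"expected 2-D grayscale or 3-channel mask, got {arr.shape}")
    rgb = arr[..., :3].astype(np.int64)
    # closer to red/green than to black: the dominant channel is bright
    dominant = rgb[..., :2].max(axis=-1)  # red or green intensity
    return (dominant > 127).astype(np.uint8)


def load_pair(
    record: ImageRecord, target_size: int = 256
) -> tuple[np.ndarray, np.ndarray]:
    """Load and standardise an (image, mask) pair.

    The image becomes float32 (3, S, S) in [0, 1] (grayscale replicated
    across channels, bilinear resize); the mask becomes uint8 (S, S) in
    {0, 1} (nearest-neighbour resize so it stays binary).
    """
    try:
        img = np.asarray(Image.open(record.image_path))
    except OSError as e:
        raise IOError(f"cannot read image {record.image_path}: {e}") from e
    try:
        msk = np.asarray(Image.open(record.mask_path))
    except OSError as e:
        raise IOError(f"cannot read mask {record.mask_path}: {e}") from e

    if img.ndim == 2:
        img = np.repeat(img[..., None], 3, axis=-1)
    img = img[..., :3].astype(np.float32) / 255.0
    if img.shape[:2] != (target_size, target_size):
        img = resize(img, (target_size, target_size), order=1, mode="reflect",
                     anti_aliasing=False, preserve_range=True).astype(np.float32)
    mask = decode_rgb_mask(msk)
    if mask.shape != (target_size, target_size):
        mask = resize(mask, (target_size, target_size), order=0, mode="constant",
                      anti_aliasing=False, preserve_range=True).astype(np.uint8)
    return np.ascontiguousarray(img.transpose(2, 0, 1)), mask


def split_by_patient(
    records: list[ImageRecord],
    ratios: tuple[float, float, float] = (0.70, 0.15, 0.15),
    seed: int = 0,
) -> DatasetSplit:
    """70/15/15 patient-level split: every image follows its patient.

    Patients are shuffled with the seed and assigned by flooring the
    cumulative ratio over patient counts, remainders going to train,
    so 20 patients split exactly 14/3/3.
    """
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError(f"ratios must sum to 1, got {ratios}")
    patients = sorted({r.patient_id for r in records})
    if len(patients) < 3:
        raise ValueError("need at least 3 patients to form three non-empty splits")
    rng = np.random.default_rng(seed)
    order = [patients[i] for i in rng.permutation(len(patients))]
    n = len(order)
    n_val = max(1, int(n * ratios[1]))
    n_test = max(1, int(n * ratios[2]))
    n_train = n - n_val - n_test
    assign: dict[str, str] = {}
    for pid in order[:n_train]:
        assign[pid] = "train"
    for pid in order[n_train : n_train + n_val]:
        assign[pid] = "val"
    for pid in order[n_train + n_val :]:
        assign[pid] = "test"
    parts = {"train": [], "val": [], "test": []}
    for r in records:
        parts[assign[r.patient_id]].append(r)
    return DatasetSplit(train=parts["train"], val=parts["val"], test=parts["test"],
                        ratios=ratios, seed=seed)


def _rebinarize(mask: np.ndarray) -> np.ndarray:
    return (mask > 0.5).astype(np.uint8)


@dataclass(frozen=True)
class AugmentationDraw:
    """One realisation of the augmentation randomness."""

    hflip: bool = False
    vflip: bool = False
    rotation_deg: float = 0.0
    right_angle_k: int = 0
    scale: float = 1.0
    intensity: float = 1.0


def sample_augmentation(cfg: AugmentationConfig, rng: np.random.Generator) -> AugmentationDraw:
    """Draw the transform parameters for one image."""
    if not cfg.enabled:
        return AugmentationDraw()
    hflip = bool(rng.random() < cfg.hflip_prob)
    vflip = bool(rng.random() < cfg.vflip_prob)
    rotation = 0.0
    right_k = 0
    if cfg.right_angle_rotations:
        right_k = int(rng.integers(0, 4))
    elif cfg.max_rotation_deg > 0:
        rotation = float(rng.uniform(-cfg.max_rotation_deg, cfg.max_rotation_deg))
    scale = 1.0
    if cfg.scale_jitter > 0:
        scale = float(rng.uniform(1.0 - cfg.scale_jitter, 1.0 + cfg.scale_jitter))
    intensity = 1.0
    if cfg.intensity_jitter > 0:
        intensity = float(rng.uniform(1.0 - cfg.intensity_jitter, 1.0 + cfg.intensity_jitter))
    return AugmentationDraw(hflip=hflip, vflip=vflip, rotation_deg=rotation,
                            right_angle_k=right_k, scale=scale, intensity=intensity)


def apply_augmentation(
    image: np.ndarray, mask: np.ndarray, draw: AugmentationDraw
) -> tuple[np.ndarray, np.ndarray]:
    """Apply one drawn transform identically to image and mask.

    Geometric transforms hit both (the mask with nearest-neighbour
    interpolation and re-binarisation); intensity jitter touches the
    image only.
    """
    if image.shape[-2:] != mask.shape[-2:]:
        raise ValueError("image and mask spatial sizes differ")
    img = image.copy()
    msk = mask.copy()

    if draw.hflip:
        img = img[..., ::-1].copy()
        msk = msk[..., ::-1].copy()
    if draw.vflip:
        img = img[..., ::-1, :].copy()
        msk = msk[..., ::-1, :].copy()
    if draw.right_angle_k:
        img = np.rot90(img, draw.right_angle_k, axes=(-2, -1)).copy()
        msk = np.rot90(msk, draw.right_angle_k, axes=(-2, -1)).copy()
    if draw.rotation_deg != 0.0:
        img = np.stack(
            [ndimage.rotate(c, draw.rotation_deg, reshape=False, order=1,
                            mode="reflect") for c in img]
        ).astype(np.float32)
        msk = _rebinarize(
            ndimage.rotate(msk.astype(np.float32), draw.rotation_deg,
                           reshape=False, order=0, mode="constant")
        )
    if draw.scale != 1.0:
        img = np.stack([_zoom_keep_size(c, draw.scale, order=1) for c in img]).astype(np.float32)
        msk = _rebinarize(_zoom_keep_size(msk.astype(np.float32), draw.scale, order=0))
    if draw.intensity != 1.0:
        img = np.clip(img * draw.intensity, 0.0, 1.0).astype(np.float32)
    return img, msk


def augment(
    image: np.ndarray,
    mask: np.ndarray,
    cfg: AugmentationConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample one augmentation draw and apply it; disabled cfg = identity."""
    if image.shape[-2:] != mask.shape[-2:]:
        raise ValueError("image and mask spatial sizes differ")
    if not cfg.enabled:
        return image, mask
    return apply_augmentation(image, mask, sample_augmentation(cfg, rng))


def _zoom_keep_size(plane: np.ndarray, factor: float, order: int) -> np.ndarray:
    """Uniform zoom that crops or reflect-pads back to the input size."""
    h, w = plane.shape
    zoomed = ndimage.zoom(plane, factor, order=order, mode="reflect")
    zh, zw = zoomed.shape
    if zh >= h:
        top, left = (zh - h) // 2, (zw - w) // 2
        return zoomed[top : top + h, left : left + w]
    pad_h, pad_w = h - zh, w - zw
    return np.pad(
        zoomed,
        ((pad_h // 2, pad_h - pad_h // 2), (pad_w // 2, pad_w - pad_w // 2)),
        mode="reflect",
    )


def read_manifest(path: str | os.PathLike) -> list[ImageRecord]:
    df = pd.read_csv(path)
    required = {"image_path", "mask_path", "patient_id"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    base = Path(path).parent
    records = []
    for row in df.itertuples(index=False):
        img, msk = Path(row.image_path), Path(row.mask_path)
        if not img.is_absolute():
            img = base / img
        if not msk.is_absolute():
            msk = base / msk
        records.append(
            ImageRecord(
                image_path=str(img),
                mask_path=str(msk),
                patient_id=str(row.patient_id),
                modality=str(getattr(row, "modality", "synthetic")),
            )
        )
    return records


def write_manifest(records: list[ImageRecord], path: str | os.PathLike) -> None:
    pd.DataFrame([vars(r) for r in records]).to_csv(path, index=False)
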