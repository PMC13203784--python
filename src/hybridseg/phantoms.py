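"""Synthetic multi-modality phantoms with exact ground-truth masks.

Four flavours emulate the statistical character of the breast-imaging
modalities the segmentation network targets:

* ``ultrasound`` — dark elliptical lesion(s) on a mid-gray background
  with multiplicative gamma-distributed speckle and mild depth shading;
* ``histology``  — many small dark elliptical "nuclei" on a pale
  textured background (mask = union of nuclei);
* ``mammogram``  — a bright soft-edged mass on a smooth intensity
  gradient;
* ``mri``        — a hyperintense region on a Gaussian-noise background.

The mask is rasterised from the generating geometry *before* any noise is
applied, so image/mask registration is exact by construction. Images of
one synthetic "patient" share a base lesion geometry with per-image
jitter, which makes patient-level splitting a meaningful leakage test.

These phantoms make no claim of photorealism or clinical validity; they
exist so the full pipeline is exercisable and statistically testable
without any external dataset.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

__all__ = ["PhantomConfig", "generate_phantom", "generate_dataset"]

MODALITIES = ("ultrasound", "histology", "mammogram", "mri")


@dataclass
class PhantomConfig:
    """Recipe for one synthetic dataset."""

    modality: str = "ultrasound"
    image_size: int = 256
    lesions_per_image: tuple[int, int] = (1, 2)
    radius_range: tuple[float, float] | None = None  # None: scale with image size
    foreground_contrast: float = 0.45
    noise_level: float = 0.15
    patients: int = 20
    images_per_patient: int = 4
    seed: int = 0

    def __post_init__(self):
        if self.modality not in MODALITIES:
            raise ValueError(f"modality must be one of {MODALITIES}")
        if self.image_size <= 0 or self.patients <= 0 or self.images_per_patient <= 0:
            raise ValueError("counts must be positive")
        if self.radius_range is None:
            # ~7-19% of the image side: 256px images get 18-48px lesions
            self.radius_range = (
                max(3.0, 0.07 * self.image_size),
                max(4.0, 0.1875 * self.image_size),
            )
        if self.radius_range[1] * 2 >= self.image_size:
            raise ValueError("lesion radius exceeds image bounds")
        if self.lesions_per_image[0] < 0 or self.lesions_per_image[0] > self.lesions_per_image[1]:
            raise ValueError("invalid lesions_per_image range")


def _ellipse_mask(size: int, cy: float, cx: float, ry: float, rx: float,
                  angle: float) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size]
    y = yy - cy
    x = xx - cx
    c, s = np.cos(angle), np.sin(angle)
    u = c * x + s * y
    v = -s * x + c * y
    return (u / rx) ** 2 + (v / ry) ** 2 <= 1.0


def _sample_lesions(cfg: PhantomConfig, rng: np.random.Generator,
                    base: list[dict] | None = None) -> list[dict]:
    """Sample lesion geometries, optionally jittering a patient base set."""
    if base is not None:
        out = []
        for les in base:
            jitter = cfg.image_size * 0.04
            out.append(
                {
                    "cy": les["cy"] + rng.normal(0, jitter),
                    "cx": les["cx"] + rng.normal(0, jitter),
                    "ry": max(3.0, les["ry"] * rng.uniform(0.9, 1.1)),
                    "rx": max(3.0, les["rx"] * rng.uniform(0.9, 1.1)),
                    "angle": les["angle"] + rng.normal(0, 0.2),
                }
            )
        return out
    lo, hi = cfg.lesions_per_image
    n = int(rng.integers(lo, hi + 1))
    size = cfg.image_size
    lesions = []
    for _ in range(n):
        r = rng.uniform(*cfg.radius_range)
        lesions.append(
            {
                "cy": rng.uniform(0.25 * size, 0.75 * size),
                "cx": rng.uniform(0.25 * size, 0.75 * size),
                "ry": r,
                "rx": r * rng.uniform(0.7, 1.3),
                "angle": rng.uniform(0, np.pi),
            }
        )
    return lesions


def _render_mask(cfg: PhantomConfig, lesions: list[dict]) -> np.ndarray:
    mask = np.zeros((cfg.image_size, cfg.image_size), dtype=bool)
    for les in lesions:
        mask |= _ellipse_mask(cfg.image_size, les["cy"], les["cx"],
                              les["ry"], les["rx"], les["angle"])
    return mask


def _soft_edge(mask: np.ndarray, sigma: float) -> np.ndarray:
    from scipy.ndimage import gaussian_filter

    return gaussian_filter(mask.astype(np.float64), sigma)


def _render_image(cfg: PhantomConfig, mask: np.ndarray,
                  rng: np.random.Generator) -> np.ndarray:
    size = cfg.image_size
    contrast = cfg.foreground_contrast
    noise = cfg.noise_level
    soft = _soft_edge(mask, sigma=2.0)
    if cfg.modality == "ultrasound":
        depth = np.linspace(1.0, 0.75, size)[:, None]  # attenuation with depth
        img = 0.55 * depth * (1.0 - contrast * soft)
        speckle = rng.gamma(shape=4.0, scale=0.25, size=(size, size))
        img = img * (1.0 - noise + noise * speckle)
    elif cfg.modality == "histology":
        img = _histology_background(size, rng)
        img = img * (1.0 - contrast * soft)
        img += rng.normal(0, 0.3 * noise, size=(size, size))
    elif cfg.modality == "mammogram":
        gy, gx = np.mgrid[0:size, 0:size] / size
        img = 0.35 + 0.25 * gy + 0.1 * gx
        img = img + contrast * soft
        img += rng.normal(0, 0.5 * noise, size=(size, size))
    else:  # mri
        img = 0.3 + rng.normal(0, noise, size=(size, size))
        img = img + contrast * soft
    return np.clip(img, 0.0, 1.0)


def _histology_background(size: int, rng: np.random.Generator) -> np.ndarray:
    from scipy.ndimage import gaussian_filter

    tex = gaussian_filter(rng.normal(0, 1, size=(size, size)), 4.0)
    tex = tex / (np.abs(tex).max() + 1e-9)
    return 0.85 + 0.08 * tex


def _histology_lesions(cfg: PhantomConfig, rng: np.random.Generator,
                       base: list[dict] | None = None) -> list[dict]:
    if base is not None:
        return _sample_lesions(cfg, rng, base)
    n = int(rng.integers(20, 81))
    size = cfg.image_size
    lesions = []
    for _ in range(n):
        r = rng.uniform(3, max(4, size // 32))
        lesions.append(
            {
                "cy": rng.uniform(0.05 * size, 0.95 * size),
                "cx": rng.uniform(0.05 * size, 0.95 * size),
                "ry": r,
                "rx": r * rng.uniform(0.8, 1.2),
                "angle": rng.uniform(0, np.pi),
            }
        )
    return lesions


def generate_phantom(
    cfg: PhantomConfig,
    rng: np.random.Generator,
    base_lesions: list[dict] | None = None,
) -> tuple[np.ndarray, np.ndarray, list[dict]]:
    """Draw one (image, mask) pair; returns the lesion geometry as well.

    A ``lesions_per_image`` range of (0, 0) yields an all-background
    image with an all-zero mask.
    """
    if cfg.modality == "histology":
        lesions = _histology_lesions(cfg, rng, base_lesions)
    else:
        lesions = _sample_lesions(cfg, rng, base_lesions)
    mask = _render_mask(cfg, lesions)
    image = _render_image(cfg, mask, rng)
    return image, mask.astype(np.uint8), lesions


def generate_dataset(cfg: PhantomConfig, out_dir: str | os.PathLike) -> pd.DataFrame:
    """Write PNG image/mask pairs plus a manifest CSV.

    The manifest (image_path, mask_path, patient_id, modality) is the
    canonical interchange format consumed by the loading and training
    code. Masks are stored as 8-bit PNGs with values {0, 255}.
    """
    out = Path(out_dir)
    try:
        (out / "images").mkdir(parents=True, exist_ok=True)
        (out / "masks").mkdir(parents=True, exist_ok=True)
    except OSError as e:
        raise IOError(f"cannot create output directory {out}: {e}") from e
    rng = np.random.default_rng(cfg.seed)
    rows = []
    for p in range(cfg.patients):
        patient_id = f"{cfg.modality[:2]}_patient_{p:03d}"
        patient_rng = np.random.default_rng(rng.integers(0, 2**31))
        if cfg.modality == "histology":
            base = _histology_lesions(cfg, patient_rng)
        else:
            base = _sample_lesions(cfg, patient_rng)
        for i in range(cfg.images_per_patient):
            image, mask, _ = generate_phantom(cfg, patient_rng, base_lesions=base)
            stem = f"{patient_id}_img_{i:02d}"
            img_path = out / "images" / f"{stem}.png"
            mask_path = out / "masks" / f"{stem}_mask.png"
            Image.fromarray((image * 255).round().astype(np.uint8)).save(img_path)
            Image.fromarray(mask * 255).save(mask_path)
            # paths relative to the manifest location, so the dataset moves freely
            rows.append(
                {
                    "image_path": str(img_path.relative_to(out)),
                    "mask_path": str(mask_path.relative_to(out)),
                    "patient_id": patient_id,
                    "modality": cfg.modality,
                }
            )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest
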