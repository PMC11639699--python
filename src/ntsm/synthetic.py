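"""Synthetic non-salient lesion image generator.

Emulates the defining regime of oral-mucosa photographs: lesions whose
intensity and texture closely match the surrounding tissue (camouflaged,
"non-salient" foreground), plus high-contrast distractor structures
(tooth-like bright shapes) that defeat purely contrast-driven segmentation.

Mechanisms (deliberately the simplest that produce the stated statistics):

* background — low-pass-filtered white noise (Gaussian blur with sigma
  ``texture_scale``) mapped onto a tissue-like reddish palette with a gentle
  illumination gradient;
* lesions — smooth closed blobs (an ellipse radially perturbed by a few
  random Fourier harmonics); the interior mean intensity is shifted by
  ``contrast_delta`` × 255 on all channels and the interior texture field is
  independently re-phased, so at ``contrast_delta = 0`` a lesion differs
  from the background only in texture phase;
* distractors — bright tooth-like ellipses drawn only where the lesion mask
  is zero, and never included in the mask.

Every sample is fully determined by ``(seed, index)``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage.draw import polygon as draw_polygon
from PIL import Image

BASE_COLOR = np.array([150.0, 92.0, 88.0])  # tissue-like reddish base
TEXTURE_AMPLITUDE = 18.0                     # std of the correlated texture field
GRADIENT_AMPLITUDE = 10.0                    # illumination gradient half-range
DISTRACTOR_COLOR = np.array([238.0, 234.0, 222.0])


@dataclass(frozen=True)
class SyntheticConfig:
    image_size: tuple[int, int] = (256, 256)
    n_lesions: int = 1
    contrast_delta: float = 0.2
    texture_scale: float = 12.0
    distractors: int = 2
    lesion_area_frac: tuple[float, float] = (0.01, 0.05)
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.contrast_delta <= 1.0:
            raise ValueError("contrast_delta must lie in [0, 1]")
        if self.texture_scale <= 0:
            raise ValueError("texture_scale must be positive")
        if self.n_lesions < 0 or self.distractors < 0:
            raise ValueError("counts must be >= 0")
        lo, hi = self.lesion_area_frac
        if not 0 < lo <= hi < 1:
            raise ValueError("lesion_area_frac must satisfy 0 < lo <= hi < 1")


@dataclass
class ImageSample:
    image: np.ndarray  # (h, w, 3) uint8
    mask: np.ndarray   # (h, w) uint8 in {0, 1}
    id: str


def _texture_field(shape, scale: float, rng: np.random.Generator) -> np.ndarray:
    field = ndimage.gaussian_filter(rng.normal(size=shape), sigma=scale, mode="reflect")
    sd = field.std()
    if sd > 0:
        field /= sd
    return field


def _blob_mask(
    shape: tuple[int, int], target_area: float, rng: np.random.Generator
) -> np.ndarray | None:
    """Rasterize one radially perturbed ellipse of (approximately) target_area."""
    h, w = shape
    n_theta = 256
    theta = np.linspace(0.0, 2.0 * np.pi, n_theta, endpoint=False)
    radius = np.ones(n_theta)
    for k in range(2, 6):
        amp = rng.normal(0.0, 0.08 / k)
        phase = rng.uniform(0.0, 2.0 * np.pi)
        radius += amp * np.cos(k * theta + phase)
    radius = np.clip(radius, 0.3, None)
    aspect = rng.uniform(0.6, 1.6)
    ry = radius * np.sqrt(aspect)
    rx = radius / np.sqrt(aspect)
    # normalize so the continuous (shoelace) area equals target_area
    y = ry * np.sin(theta)
    x = rx * np.cos(theta)
    area0 = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
    s = np.sqrt(target_area / area0)
    y, x = y * s, x * s
    r_max = max(np.abs(y).max(), np.abs(x).max())
    if 2 * r_max >= min(h, w) - 4:
        return None
    cy = rng.uniform(r_max + 2, h - r_max - 2)
    cx = rng.uniform(r_max + 2, w - r_max - 2)
    rr, cc = draw_polygon(y + cy, x + cx, shape=shape)
    mask = np.zeros(shape, dtype=bool)
    mask[rr, cc] = True
    return mask


def generate_sample(cfg: SyntheticConfig, index: int) -> ImageSample:
    """Deterministically generate one image/mask pair for (cfg.seed, index)."""
    h, w = cfg.image_size
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, index]))

    # background: palette + illumination gradient + correlated texture
    yy, xx = np.mgrid[0:h, 0:w]
    direction = rng.uniform(0.0, 2.0 * np.pi)
    ramp = (np.cos(direction) * (yy / max(h - 1, 1) - 0.5)
            + np.sin(direction) * (xx / max(w - 1, 1) - 0.5))
    bg_field = _texture_field((h, w), cfg.texture_scale, rng)
    img = (
        BASE_COLOR[None, None, :]
        + GRADIENT_AMPLITUDE * ramp[:, :, None]
        + TEXTURE_AMPLITUDE * bg_field[:, :, None]
    )

    # lesions: shifted mean + re-phased texture inside each blob
    lo, hi = cfg.lesion_area_frac
    span = hi - lo
    mask = np.zeros((h, w), dtype=bool)
    for _ in range(cfg.n_lesions):
        placed = False
        for _attempt in range(50):
            frac = rng.uniform(lo + 0.1 * span, hi - 0.1 * span)
            blob = _blob_mask((h, w), frac * h * w, rng)
            if blob is None or (blob & mask).any():
                continue
            area = int(blob.sum())
            if not (lo * h * w - 1 <= area <= hi * h * w + 1):
                continue
            lesion_field = _texture_field((h, w), cfg.texture_scale, rng)
            delta = cfg.contrast_delta * 255.0
            img[blob] = (
                BASE_COLOR[None, :]
                + delta
                + GRADIENT_AMPLITUDE * ramp[blob, None]
                + TEXTURE_AMPLITUDE * lesion_field[blob, None]
            )
            mask |= blob
            placed = True
            break
        if not placed:
            raise RuntimeError(
                "lesion placement failed after 50 attempts; "
                "try a smaller lesion_area_frac or fewer lesions"
            )

    # distractors: bright tooth-like ellipses, never overlapping the mask
    for _ in range(cfg.distractors):
        ry = rng.uniform(0.03, 0.08) * h
        rx = rng.uniform(0.03, 0.08) * w
        cy = rng.uniform(ry, h - ry)
        cx = rng.uniform(rx, w - rx)
        ang = rng.uniform(0.0, np.pi)
        dy, dx = yy - cy, xx - cx
        u = np.cos(ang) * dy + np.sin(ang) * dx
        v = -np.sin(ang) * dy + np.cos(ang) * dx
        ell = (u / ry) ** 2 + (v / rx) ** 2 <= 1.0
        ell &= ~mask
        shade = rng.uniform(-12.0, 8.0)
        img[ell] = DISTRACTOR_COLOR[None, :] + shade + 6.0 * bg_field[ell, None]

    image = np.clip(img, 0.0, 255.0).round().astype(np.uint8)
    return ImageSample(image=image, mask=mask.astype(np.uint8), id=f"synth_{index:04d}")


def generate_dataset(cfg: SyntheticConfig, n: int, out_dir) -> list[dict]:
    """Write n samples as PNGs under ``out_dir/images`` and ``out_dir/masks``.

    Returns the manifest (also written as ``manifest.csv``): one row per
    sample with its id and generation parameters.
    """
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "masks").mkdir(parents=True, exist_ok=True)
    manifest = []
    for i in range(n):
        s = generate_sample(cfg, i)
        Image.fromarray(s.image, mode="RGB").save(out_dir / "images" / f"{s.id}.png")
        Image.fromarray(s.mask, mode="L").save(out_dir / "masks" / f"{s.id}.png")
        row = {"id": s.id, "index": i, "mask_area": int(s.mask.sum())}
        row.update({k: str(v) for k, v in asdict(cfg).items()})
        manifest.append(row)
    with (out_dir / "manifest.csv").open("w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(manifest[0].keys()) if manifest else ["id"])
        writer.writeheader()
        writer.writerows(manifest)
    return manifest
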