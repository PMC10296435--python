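"""Synthetic study data: brain-slice phantoms, textured class sets, feature tables.

Real staged rs-fMRI collections are access-controlled, so the package ships
generators that emulate the relevant structure instead:

* **phantoms** — an elliptical "brain" containing k intensity-distinct blob
  regions, Gaussian noise and a smooth multiplicative bias field, with an
  exact ground-truth mask (background label 0, regions 1..k) for scoring
  segmentation;
* **class sets** — six-way labelled images whose classes differ in *texture*
  (grating wavelength and orientation inside the brain ellipse), not mean
  brightness, so the Gabor/GLCM feature stack — not a trivial intensity
  summary — has to carry the classification;
* **feature tables** — Gaussian tables with a known informative subset
  (class-conditional mean shifts) for scoring wrapper feature selection.

Every generator is deterministic under a fixed seed.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .imaging import RawImage, save_image
from .sas import SegmentationMask

DEFAULT_CLASSES = ("AD", "NC", "MCI", "EMCI", "LMCI", "SMC")
# mirrors the 138-subject staging pattern (one under-represented class)
DEFAULT_CLASS_COUNTS = (25, 25, 13, 25, 25, 25)


# ---------------------------------------------------------------------------
# phantoms


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry and contrast of a segmentation phantom.

    Region means must stay separated by at least 3 noise sigmas, otherwise
    the phantom would not constitute a well-posed segmentation target.
    """

    size: tuple[int, int] = (48, 48)
    k_regions: int = 3
    region_means: tuple[float, ...] | None = None  # defaults to even spacing
    background_mean: float = 0.15
    noise_sigma: float = 0.03
    bias_amplitude: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_regions < 1:
            raise ValueError("k_regions must be >= 1")
        means = self.resolved_means
        gaps = np.diff(np.sort(np.concatenate([[self.background_mean], means])))
        if self.noise_sigma > 0 and np.any(gaps < 3 * self.noise_sigma):
            raise ValueError("region means must be separated by >= 3 * noise_sigma")

    @property
    def resolved_means(self) -> np.ndarray:
        if self.region_means is not None:
            if len(self.region_means) != self.k_regions:
                raise ValueError("region_means length must equal k_regions")
            return np.asarray(self.region_means, dtype=float)
        return np.linspace(0.45, 0.95, self.k_regions)


def make_phantom(cfg: PhantomConfig) -> tuple[RawImage, SegmentationMask]:
    """Elliptical brain phantom with k blob regions and exact ground truth."""
    rng = np.random.default_rng(cfg.seed)
    H, W = cfg.size
    yy, xx = np.mgrid[0:H, 0:W]
    cy, cx = (H - 1) / 2.0, (W - 1) / 2.0
    brain = ((yy - cy) / (0.45 * H)) ** 2 + ((xx - cx) / (0.42 * W)) ** 2 <= 1.0

    gt = np.zeros((H, W), dtype=int)
    means = cfg.resolved_means
    # place k blob regions on a ring inside the ellipse, radii sized to fit
    angles = 2 * np.pi * (np.arange(cfg.k_regions) / cfg.k_regions) + rng.uniform(0, 2 * np.pi)
    ring_r = 0.22 * min(H, W)
    blob_r = min(0.16 * min(H, W), ring_r * np.sin(np.pi / max(cfg.k_regions, 2)) * 0.95)
    if blob_r < 2.0:
        raise ValueError(f"cannot fit {cfg.k_regions} regions into a {H}x{W} phantom")
    for r_idx, ang in enumerate(angles, start=1):
        by = cy + ring_r * np.sin(ang)
        bx = cx + ring_r * np.cos(ang)
        blob = (yy - by) ** 2 + (xx - bx) ** 2 <= blob_r**2
        gt[blob & brain] = r_idx

    img = np.full((H, W), 0.02)
    img[brain] = cfg.background_mean
    for r_idx, mu in enumerate(means, start=1):
        img[gt == r_idx] = mu
    # smooth multiplicative bias (low-frequency)
    phase_y, phase_x = rng.uniform(0, 2 * np.pi, size=2)
    bias = 1.0 + cfg.bias_amplitude * np.sin(2 * np.pi * yy / H + phase_y) * np.cos(
        2 * np.pi * xx / W + phase_x
    )
    img = img * bias + rng.normal(0.0, cfg.noise_sigma, size=(H, W))
    return RawImage(pixels=img), SegmentationMask(labels=gt, k=cfg.k_regions + 1)


# ---------------------------------------------------------------------------
# textured class images


@dataclass(frozen=True)
class ClassSetConfig:
    """Six-class textured image set; classes differ in grating texture."""

    classes: tuple[str, ...] = DEFAULT_CLASSES
    n_per_class: tuple[int, ...] | int = DEFAULT_CLASS_COUNTS
    size: tuple[int, int] = (48, 48)
    # (wavelength px, orientation rad) per class; defaults interleave
    texture_params: tuple[tuple[float, float], ...] | None = None
    noise_sigma: float = 0.04
    contrast: float = 0.35
    seed: int = 0

    def __post_init__(self) -> None:
        params = self.resolved_texture_params
        if len(set(params)) != len(self.classes):
            raise ValueError("per-class texture parameters must be pairwise distinct")

    @property
    def counts(self) -> tuple[int, ...]:
        if isinstance(self.n_per_class, int):
            return (self.n_per_class,) * len(self.classes)
        if len(self.n_per_class) != len(self.classes):
            raise ValueError("n_per_class length must match classes")
        return tuple(self.n_per_class)

    @property
    def resolved_texture_params(self) -> tuple[tuple[float, float], ...]:
        if self.texture_params is not None:
            return tuple(map(tuple, self.texture_params))
        n = len(self.classes)
        wavelengths = (4.0, 8.0)
        out = []
        for i in range(n):
            lam = wavelengths[i % 2]
            theta = np.pi * (i // 2) / max(1, (n + 1) // 2)
            out.append((lam, theta))
        return tuple(out)


def make_class_image(
    size: tuple[int, int],
    wavelength: float,
    orientation: float,
    noise_sigma: float,
    contrast: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One brain-ellipse image with an oriented grating texture inside."""
    H, W = size
    yy, xx = np.mgrid[0:H, 0:W]
    cy, cx = (H - 1) / 2.0, (W - 1) / 2.0
    brain = ((yy - cy) / (0.45 * H)) ** 2 + ((xx - cx) / (0.42 * W)) ** 2 <= 1.0
    phase = rng.uniform(0, 2 * np.pi)
    carrier = np.cos(
        2 * np.pi / wavelength * (xx * np.cos(orientation) + yy * np.sin(orientation)) + phase
    )
    img = np.full((H, W), 0.05)
    img[brain] = 0.55 + 0.5 * contrast * carrier[brain]
    img += rng.normal(0.0, noise_sigma, size=(H, W))
    return img


def make_class_dataset(
    cfg: ClassSetConfig, out_dir: str | Path | None = None
) -> tuple[list[np.ndarray], list[str], pd.DataFrame]:
    """Generate the labelled image set; optionally write PNGs + manifest CSV.

    Returns ``(images, labels, manifest)``; the manifest lists one row per
    image (path empty when not written) so downstream stages can consume
    either in-memory arrays or files.
    """
    rng = np.random.default_rng(cfg.seed)
    images: list[np.ndarray] = []
    labels: list[str] = []
    rows = []
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
    for cls, count, (lam, theta) in zip(cfg.classes, cfg.counts, cfg.resolved_texture_params):
        for i in range(count):
            img = make_class_image(cfg.size, lam, theta, cfg.noise_sigma, cfg.contrast, rng)
            images.append(img)
            labels.append(cls)
            path = ""
            if out_dir is not None:
                path = str(out_dir / f"{cls}_{i:03d}.png")
                save_image(RawImage(pixels=img), path, quantize=True)
            rows.append({"path": path, "label": cls})
    manifest = pd.DataFrame(rows)
    if out_dir is not None:
        manifest.to_csv(out_dir / "manifest.csv", index=False)
    return images, labels, manifest


# ---------------------------------------------------------------------------
# feature tables with known informative subset


def make_feature_table(
    n: int = 200,
    d: int = 30,
    n_informative: int = 5,
    effect_size: float = 3.0,
    seed: int = 0,
    n_classes: int = 2,
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Gaussian feature table with class-conditional mean shifts.

    Informative columns get means ``effect_size * class_index /
    (n_classes - 1)`` (unit noise sigma); the rest are pure noise.

    Each informative column is additionally made *individually necessary*:
    for column ``j`` one cross-class sample pair is planted that agrees on
    every other column and differs only in column ``j`` (by its
    class-conditional shift). Any feature subset that omits an informative
    column therefore leaves at least one pair of equal-attribute samples
    with different labels, so the informative set is the unique minimal
    subset that fully determines the label — without this, wrapper
    selectors can substitute arbitrary noise columns for an informative one
    and "ground truth" recall is not well defined. Returns
    ``(features, labels, informative_index_set)``.
    """
    if n_informative > d:
        raise ValueError("n_informative must be <= d")
    rng = np.random.default_rng(seed)
    labels = np.repeat(np.arange(n_classes), int(np.ceil(n / n_classes)))[:n]
    X = rng.normal(0.0, 1.0, size=(n, d))
    informative = rng.choice(d, size=n_informative, replace=False)
    informative.sort()
    if effect_size != 0 and n_classes > 1:
        shift = effect_size * labels / (n_classes - 1)
        for j in informative:
            X[:, j] += shift
        if n >= 2 * n_informative:
            class0 = np.flatnonzero(labels == 0)
            class1 = np.flatnonzero(labels == n_classes - 1)
            a_idx = rng.choice(class0, size=n_informative, replace=False)
            b_idx = rng.choice(class1, size=n_informative, replace=False)
            for p, j in enumerate(informative):
                a, b = a_idx[p], b_idx[p]
                keep = X[b, j]  # b's own class-shifted value in column j
                X[b, :] = X[a, :]
                X[b, j] = keep
    cols = [f"f{j:02d}" for j in range(d)]
    return pd.DataFrame(X, columns=cols), labels, informative
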