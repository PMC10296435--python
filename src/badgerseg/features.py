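"""Gabor-bank and GLCM (Haralick) texture features over segmented images.

Each segment of a mask (or the pooled foreground of a whole image) yields
one feature row: per Gabor filter the mean and standard deviation of the
response magnitude over the segment, plus twelve co-occurrence statistics
per GLCM offset. The co-occurrence accumulator is segment-aware — only
pixel pairs with both endpoints inside the segment are counted — which is
why it is written here rather than taken from an off-the-shelf full-frame
implementation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve
from skimage.filters import gabor_kernel


# ---------------------------------------------------------------------------
# Gabor bank


@dataclass(frozen=True)
class GaborBankConfig:
    """Geometry of the Gabor filter bank.

    Wavelengths grow geometrically from ``min_wavelength`` by
    ``scale_factor`` per scale; orientations are evenly spaced on [0, pi).
    """

    n_scales: int = 4
    n_orientations: int = 6
    min_wavelength: float = 4.0
    scale_factor: float = 2.0**0.5
    bandwidth: float = 1.0

    def __post_init__(self) -> None:
        if self.n_scales < 1 or self.n_orientations < 1:
            raise ValueError("need at least one scale and one orientation")
        if self.min_wavelength <= 0 or self.scale_factor <= 0:
            raise ValueError("wavelengths must be positive")

    @property
    def wavelengths(self) -> list[float]:
        return [self.min_wavelength * self.scale_factor**s for s in range(self.n_scales)]

    @property
    def orientations(self) -> list[float]:
        return [np.pi * o / self.n_orientations for o in range(self.n_orientations)]


@dataclass(frozen=True)
class GaborFilter:
    kernel: np.ndarray  # complex 2-D
    scale: int
    orientation: int
    wavelength: float
    theta: float


def gabor_bank(cfg: GaborBankConfig | None = None) -> list[GaborFilter]:
    """Build the filter bank; every kernel's real part is made DC-free.

    Removing the DC component of the even (cosine) part guarantees zero
    response magnitude on constant images, so features depend on texture,
    not brightness.
    """
    cfg = cfg or GaborBankConfig()
    filters = []
    for s, lam in enumerate(cfg.wavelengths):
        for o, theta in enumerate(cfg.orientations):
            k = gabor_kernel(frequency=1.0 / lam, theta=theta, bandwidth=cfg.bandwidth)
            k = k - k.real.mean()  # DC-free real part; imaginary part is already odd
            filters.append(
                GaborFilter(kernel=k, scale=s, orientation=o, wavelength=lam, theta=theta)
            )
    return filters


def gabor_responses(img: np.ndarray, bank: list[GaborFilter]) -> np.ndarray:
    """Response magnitude maps, shape (n_filters, H, W); 'same' convolution."""
    px = np.asarray(img, dtype=float)
    out = np.empty((len(bank), *px.shape))
    for i, f in enumerate(bank):
        resp = fftconvolve(px, f.kernel, mode="same")
        out[i] = np.abs(resp)
    return out


def gabor_features(
    img: np.ndarray,
    mask: np.ndarray,
    segment_id: int,
    bank: list[GaborFilter],
    responses: np.ndarray | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Mean and std of each filter's response magnitude over one segment.

    ``responses`` may carry precomputed magnitude maps to amortize the
    convolutions across segments of the same image.
    """
    sel = np.asarray(mask) == segment_id
    if not sel.any():
        raise ValueError(f"segment {segment_id} is empty")
    if responses is None:
        responses = gabor_responses(img, bank)
    vals = []
    names = []
    for i, f in enumerate(bank):
        seg = responses[i][sel]
        vals.extend([seg.mean(), seg.std()])
        names.extend(
            [f"gabor_s{f.scale}_o{f.orientation}_mean", f"gabor_s{f.scale}_o{f.orientation}_std"]
        )
    return np.array(vals), names


# ---------------------------------------------------------------------------
# GLCM


@dataclass(frozen=True)
class GLCMConfig:
    """Quantization and offset geometry for co-occurrence matrices."""

    levels: int = 32
    offsets: tuple[tuple[int, int], ...] = ((0, 1), (1, 0), (1, 1), (1, -1))
    symmetric: bool = True
    normalize: bool = True

    def __post_init__(self) -> None:
        if self.levels < 2:
            raise ValueError("levels must be >= 2")
        if len(self.offsets) == 0 or any(o == (0, 0) for o in self.offsets):
            raise ValueError("offsets must be non-empty and nonzero")


def quantize(img: np.ndarray, levels: int, lo: float | None = None, hi: float | None = None) -> np.ndarray:
    """Equal-width quantization of intensities into 0..levels-1."""
    px = np.asarray(img, dtype=float)
    lo = float(px.min()) if lo is None else lo
    hi = float(px.max()) if hi is None else hi
    if hi <= lo:
        return np.zeros(px.shape, dtype=int)
    q = np.floor((px - lo) / (hi - lo) * levels).astype(int)
    return np.clip(q, 0, levels - 1)


def glcm_matrix(
    img: np.ndarray,
    mask: np.ndarray,
    segment_id: int,
    cfg: GLCMConfig,
    offset: tuple[int, int] | None = None,
    quantized: np.ndarray | None = None,
) -> np.ndarray:
    """Co-occurrence matrix of quantized levels over in-segment pixel pairs.

    Counts ordered pairs (p, p+offset) whose endpoints both lie inside the
    segment; with ``symmetric`` the transpose is accumulated as well, and
    with ``normalize`` the counts become a probability matrix summing to 1.
    A single offset may be given; otherwise the first configured offset.
    """
    off = offset if offset is not None else cfg.offsets[0]
    q = quantized if quantized is not None else quantize(img, cfg.levels)
    sel = np.asarray(mask) == segment_id
    dy, dx = off
    H, W = q.shape
    # shifted-window overlap of in-segment endpoints
    y0, y1 = max(0, -dy), min(H, H - dy)
    x0, x1 = max(0, -dx), min(W, W - dx)
    src_sel = sel[y0:y1, x0:x1] & sel[y0 + dy : y1 + dy, x0 + dx : x1 + dx]
    a = q[y0:y1, x0:x1][src_sel]
    b = q[y0 + dy : y1 + dy, x0 + dx : x1 + dx][src_sel]
    if a.size == 0:
        raise ValueError(f"no valid pixel pairs in segment {segment_id} at offset {off}")
    L = cfg.levels
    P = np.zeros((L, L))
    np.add.at(P, (a, b), 1.0)
    if cfg.symmetric:
        P = P + P.T
    if cfg.normalize:
        P = P / P.sum()
    return P


_GLCM_FEATURE_NAMES = (
    "energy",
    "contrast",
    "correlation",
    "sum_of_squares",
    "homogeneity",
    "sum_average",
    "sum_variance",
    "sum_entropy",
    "entropy",
    "difference_variance",
    "difference_entropy",
    "information_correlation",
)


def _entropy2(p: np.ndarray) -> float:
    """Shannon entropy in bits with the 0*log0 := 0 convention."""
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def glcm_features(P: np.ndarray) -> dict[str, float]:
    """Twelve Haralick statistics of a normalized co-occurrence matrix.

    Energy, contrast, correlation, sum of squares (variance), homogeneity
    (inverse difference moment), sum average/variance/entropy, entropy,
    difference variance/entropy, and the first information measure of
    correlation. Logs are base 2; degenerate denominators yield 0.
    """
    P = np.asarray(P, dtype=float)
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise ValueError("P must be square")
    total = P.sum()
    if not np.isclose(total, 1.0, atol=1e-8):
        raise ValueError("P must be normalized to sum to 1")
    L = P.shape[0]
    i = np.arange(L)[:, None]
    j = np.arange(L)[None, :]
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    mu_x = float((px * np.arange(L)).sum())
    mu_y = float((py * np.arange(L)).sum())
    var_x = float((px * (np.arange(L) - mu_x) ** 2).sum())
    var_y = float((py * (np.arange(L) - mu_y) ** 2).sum())

    # diagonal-sum and diagonal-difference distributions
    k_sum = np.arange(2 * L - 1)
    p_sum = np.zeros(2 * L - 1)
    np.add.at(p_sum, (i + j).ravel(), P.ravel())
    k_diff = np.arange(L)
    p_diff = np.zeros(L)
    np.add.at(p_diff, np.abs(i - j).ravel(), P.ravel())

    energy = float((P**2).sum())
    contrast = float((P * (i - j) ** 2).sum())
    if var_x > 0 and var_y > 0:
        correlation = float((P * (i - mu_x) * (j - mu_y)).sum() / np.sqrt(var_x * var_y))
    else:
        correlation = 0.0
    sum_of_squares = var_x
    homogeneity = float((P / (1.0 + (i - j) ** 2)).sum())
    sum_average = float((p_sum * k_sum).sum())
    sum_variance = float((p_sum * (k_sum - sum_average) ** 2).sum())
    sum_entropy = _entropy2(p_sum)
    entropy = _entropy2(P.ravel())
    diff_mean = float((p_diff * k_diff).sum())
    difference_variance = float((p_diff * (k_diff - diff_mean) ** 2).sum())
    difference_entropy = _entropy2(p_diff)
    # first information measure of correlation
    hx, hy = _entropy2(px), _entropy2(py)
    outer = px[:, None] * py[None, :]
    valid = (P > 0) & (outer > 0)
    hxy1 = float(-(P[valid] * np.log2(outer[valid])).sum())
    denom = max(hx, hy)
    information_correlation = (entropy - hxy1) / denom if denom > 0 else 0.0

    return dict(
        zip(
            _GLCM_FEATURE_NAMES,
            (
                energy,
                contrast,
                correlation,
                sum_of_squares,
                homogeneity,
                sum_average,
                sum_variance,
                sum_entropy,
                entropy,
                difference_variance,
                difference_entropy,
                information_correlation,
            ),
        )
    )


# ---------------------------------------------------------------------------
# per-segment / per-image extraction


@dataclass(frozen=True)
class FeatureConfig:
    gabor: GaborBankConfig = field(default_factory=GaborBankConfig)
    glcm: GLCMConfig = field(default_factory=GLCMConfig)


def extract_features(
    img: np.ndarray,
    mask: np.ndarray,
    cfg: FeatureConfig | None = None,
    *,
    per_image: bool = False,
    background_label: int | None = None,
    image_id: str | None = None,
    bank: list[GaborFilter] | None = None,
) -> pd.DataFrame:
    """Feature rows for every segment, or one pooled row per image.

    With ``per_image`` all foreground pixels (every segment except
    ``background_label``) pool into a single row — the classification unit.
    Columns are ``[gabor_* | glcm_<dy>_<dx>_<stat>]``; a ``segment`` column
    records the segment id (-1 for pooled rows), plus an ``image`` column
    when ``image_id`` is given.
    """
    cfg = cfg or FeatureConfig()
    px = np.asarray(img, dtype=float)
    mask = np.asarray(mask)
    bank = bank if bank is not None else gabor_bank(cfg.gabor)
    responses = gabor_responses(px, bank)
    quantized = quantize(px, cfg.glcm.levels)

    if per_image:
        if background_label is not None:
            work_mask = (mask != background_label).astype(int)
        else:
            work_mask = np.ones_like(mask, dtype=int)
        if not work_mask.any():
            raise ValueError("no foreground pixels to pool")
        rows_spec = [(-1, work_mask, 1)]
    else:
        seg_ids = [s for s in np.unique(mask) if s != background_label]
        if len(seg_ids) == 0:
            raise ValueError("no non-background segments")
        rows_spec = [(int(s), mask, int(s)) for s in seg_ids]

    records = []
    for report_id, m, sid in rows_spec:
        gab_vals, gab_names = gabor_features(px, m, sid, bank, responses=responses)
        rec: dict[str, float] = dict(zip(gab_names, gab_vals))
        for dy, dx in cfg.glcm.offsets:
            P = glcm_matrix(px, m, sid, cfg.glcm, offset=(dy, dx), quantized=quantized)
            for name, val in glcm_features(P).items():
                rec[f"glcm_{dy}_{dx}_{name}"] = val
        rec["segment"] = report_id
        if image_id is not None:
            rec["image"] = image_id
        records.append(rec)
    return pd.DataFrame.from_records(records)
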