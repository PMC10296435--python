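"""Segmentation by aggregating superpixels.

The pipeline over-segments an image several times with mean-shift mode
seeking (at different spatial/range bandwidths), collects the superpixel
maps in a bag, joins pixels and superpixels in one bipartite graph, and
partitions that graph with a transfer cut: the normalized-cut eigenproblem
is solved on the small superpixel side and lifted back to pixels, where a
seeded k-means on the spectral embedding yields the final k-way mask.

Kernel density estimation and mean shift follow the classical form

    f_hat(x) = c_{k,d} / (n h^d) * sum_i k(||(x - x_i)/h||^2)

with a Gaussian or Epanechnikov profile k; modes are the stationary points
of f_hat reached by iterating the mean-shift vector, and pixels sharing a
mode (within h/2) form one cluster.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from skimage.measure import label as cc_label
from sklearn.cluster import KMeans

try:  # compiled mean-shift inner loop; numpy fallback keeps identical math
    from ._ms_fast import ms_iterate as _ms_iterate_fast
except ImportError:  # pragma: no cover
    _ms_iterate_fast = None

from .imaging import NormalizedImage

__all__ = [
    "KernelConfig",
    "SuperpixelMap",
    "SuperpixelBag",
    "BipartiteGraph",
    "SegmentationMask",
    "SASConfig",
    "kde_estimate",
    "mean_shift_modes",
    "mean_shift_superpixels",
    "build_bag",
    "build_bipartite_graph",
    "tcut_partition",
    "segment",
]


# ---------------------------------------------------------------------------
# kernels


@dataclass(frozen=True)
class KernelConfig:
    """Kernel profile and bandwidth for density estimation.

    ``profile`` selects the radially symmetric profile k(u) applied to the
    squared scaled distance u = ||(x - x_i)/h||^2:

    * ``gaussian``:      k(u) = exp(-u/2)
    * ``epanechnikov``:  k(u) = (1 - u) for u <= 1, else 0

    The normalization constant c_{k,d} (making the kernel integrate to one
    in d dimensions) is derived, not stored.
    """

    profile: str = "gaussian"
    bandwidth: float = 1.0

    def __post_init__(self) -> None:
        if self.profile not in ("gaussian", "epanechnikov"):
            raise ValueError(f"unknown kernel profile: {self.profile}")
        if not self.bandwidth > 0:
            raise ValueError("bandwidth must be positive")

    def c_kd(self, d: int) -> float:
        """Normalization constant for dimension ``d``."""
        if self.profile == "gaussian":
            return (2.0 * math.pi) ** (-d / 2.0)
        # Epanechnikov: c * integral_{||x||<=1} (1-||x||^2) dx = 1
        unit_ball = math.pi ** (d / 2.0) / math.gamma(d / 2.0 + 1.0)
        return (d + 2.0) / (2.0 * unit_ball)

    def k(self, u: np.ndarray) -> np.ndarray:
        """Profile value at squared scaled distance u."""
        u = np.asarray(u, dtype=float)
        if self.profile == "gaussian":
            return np.exp(-0.5 * u)
        return np.clip(1.0 - u, 0.0, None)

    def g(self, u: np.ndarray) -> np.ndarray:
        """-k'(u), the weight profile of the mean-shift vector."""
        u = np.asarray(u, dtype=float)
        if self.profile == "gaussian":
            return 0.5 * np.exp(-0.5 * u)
        return np.where(u <= 1.0, 1.0, 0.0)


def kde_estimate(points: np.ndarray, query: np.ndarray, cfg: KernelConfig) -> float:
    """Kernel density estimate at ``query`` from sample ``points`` (n x d)."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[0] == 0:
        raise ValueError("empty point set")
    q = np.asarray(query, dtype=float).reshape(-1)
    n, d = pts.shape
    h = cfg.bandwidth
    u = np.sum(((q[None, :] - pts) / h) ** 2, axis=1)
    return float(cfg.c_kd(d) / (n * h**d) * cfg.k(u).sum())


def _kde_batch(pts: np.ndarray, queries: np.ndarray, cfg: KernelConfig) -> np.ndarray:
    n, d = pts.shape
    u = _sq_dists(queries, pts) / cfg.bandwidth**2
    return cfg.c_kd(d) / (n * cfg.bandwidth**d) * cfg.k(u).sum(axis=1)


def _sq_dists(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise squared Euclidean distances (|a| x |b|), clipped at 0."""
    d2 = (
        np.sum(a * a, axis=1)[:, None]
        + np.sum(b * b, axis=1)[None, :]
        - 2.0 * a @ b.T
    )
    return np.clip(d2, 0.0, None)


def mean_shift_modes(
    points: np.ndarray,
    cfg: KernelConfig,
    tol: float = 1e-4,
    max_iter: int = 200,
    *,
    check_ascent: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean-shift mode seeking: iterate every point uphill on the KDE.

    Each trajectory moves to the g-weighted mean of the sample until the
    mean-shift vector norm falls to ``tol`` (or ``max_iter``); converged
    positions within h/2 of one another are merged into a single mode.

    Returns ``(modes, assignment)`` where ``modes`` is (m x d) and
    ``assignment`` maps each input point to a mode index. With
    ``check_ascent`` the KDE value is verified non-decreasing along every
    trajectory (Gaussian profile guarantee), raising on violation.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    n, d = pts.shape
    if n == 0:
        raise ValueError("empty point set")
    h = cfg.bandwidth
    use_fast = _ms_iterate_fast is not None and not check_ascent and n > 400
    if use_fast:
        y = _ms_iterate_fast(pts / h, tol / h, max_iter, cfg.profile == "gaussian") * h
    else:
        y = pts.copy()
        active = np.arange(n)
        prev_density = _kde_batch(pts, y, cfg) if check_ascent else None
        for _ in range(max_iter):
            u = _sq_dists(y[active], pts) / h**2
            w = cfg.g(u)
            wsum = w.sum(axis=1)
            # points with no in-support neighbours (epanechnikov) stay put
            ok = wsum > 0
            new = y[active].copy()
            new[ok] = (w[ok] @ pts) / wsum[ok, None]
            shift = np.linalg.norm(new - y[active], axis=1)
            y[active] = new
            if check_ascent:
                dens = _kde_batch(pts, y[active], cfg)
                if np.any(dens < prev_density[active] - 1e-10):
                    raise AssertionError("KDE decreased along a mean-shift trajectory")
                prev_density[active] = dens
            active = active[shift > tol]
            if active.size == 0:
                break
    modes, assignment = _merge_modes(y, merge_radius=h / 2.0)
    return modes, assignment


def _merge_modes(y: np.ndarray, merge_radius: float) -> tuple[np.ndarray, np.ndarray]:
    """Leader clustering of converged positions: points within
    ``merge_radius`` of an earlier-established mode share its id."""
    n = y.shape[0]
    assignment = np.full(n, -1, dtype=int)
    leaders: list[np.ndarray] = []
    r2 = merge_radius**2
    remaining = np.arange(n)
    while remaining.size:
        lead = y[remaining[0]]
        d2 = np.sum((y[remaining] - lead) ** 2, axis=1)
        close = d2 <= r2
        assignment[remaining[close]] = len(leaders)
        leaders.append(lead)
        remaining = remaining[~close]
    modes = np.empty((len(leaders), y.shape[1]))
    for m in range(len(leaders)):
        modes[m] = y[assignment == m].mean(axis=0)
    return modes, assignment


# ---------------------------------------------------------------------------
# superpixels


@dataclass(frozen=True)
class SuperpixelMap:
    """One over-segmentation: a dense 0..n-1 label grid over the image."""

    labels: np.ndarray
    bandwidth_used: tuple[float, float]

    @property
    def n_superpixels(self) -> int:
        return int(self.labels.max()) + 1


@dataclass(frozen=True)
class SuperpixelBag:
    """Ordered collection of superpixel maps over the same image."""

    maps: tuple[SuperpixelMap, ...]

    def __post_init__(self) -> None:
        if len(self.maps) == 0:
            raise ValueError("bag must contain at least one map")
        shapes = {m.labels.shape for m in self.maps}
        if len(shapes) != 1:
            raise ValueError("all maps in a bag must share the image shape")

    @property
    def total_superpixels(self) -> int:
        return sum(m.n_superpixels for m in self.maps)


def mean_shift_superpixels(
    img: NormalizedImage | np.ndarray,
    spatial_bandwidth: float,
    range_bandwidth: float,
    *,
    profile: str = "gaussian",
    tol: float = 1e-3,
    max_iter: int = 50,
) -> SuperpixelMap:
    """Mean-shift over-segmentation in joint (row, col, intensity) space.

    Features are pre-scaled to (row/h_s, col/h_s, intensity/h_r) so a unit
    isotropic bandwidth applies; 4-connected components of same-mode pixels
    become superpixels (each superpixel is therefore spatially contiguous).
    """
    if spatial_bandwidth <= 0 or range_bandwidth <= 0:
        raise ValueError("bandwidths must be positive")
    px = img.pixels if hasattr(img, "pixels") else np.asarray(img, dtype=float)
    h, w = px.shape
    rows, cols = np.mgrid[0:h, 0:w]
    feats = np.column_stack(
        [
            rows.ravel() / spatial_bandwidth,
            cols.ravel() / spatial_bandwidth,
            px.ravel() / range_bandwidth,
        ]
    )
    cfg = KernelConfig(profile=profile, bandwidth=1.0)
    _, assignment = mean_shift_modes(feats, cfg, tol=tol, max_iter=max_iter)
    mode_grid = assignment.reshape(h, w)
    labels = cc_label(mode_grid, connectivity=1)
    labels = labels - labels.min()
    # relabel densely 0..n-1
    _, dense = np.unique(labels, return_inverse=True)
    return SuperpixelMap(
        labels=dense.reshape(h, w),
        bandwidth_used=(spatial_bandwidth, range_bandwidth),
    )


# Three spatial scales with range bandwidths kept below typical inter-region
# intensity gaps, so no single map merges adjacent regions of distinct mean
# intensity while the coarse map still supplies region-level graph structure.
DEFAULT_BANDWIDTHS: tuple[tuple[float, float], ...] = ((4, 0.03), (8, 0.04), (12, 0.05))


def build_bag(
    img: NormalizedImage | np.ndarray,
    bandwidths: tuple[tuple[float, float], ...] = DEFAULT_BANDWIDTHS,
    **ms_kwargs,
) -> SuperpixelBag:
    """Collect one mean-shift superpixel map per (spatial, range) bandwidth."""
    if len(bandwidths) == 0:
        raise ValueError("need at least one bandwidth")
    maps = tuple(
        mean_shift_superpixels(img, hs, hr, **ms_kwargs) for hs, hr in bandwidths
    )
    return SuperpixelBag(maps=maps)


# ---------------------------------------------------------------------------
# bipartite graph


@dataclass(frozen=True)
class BipartiteGraph:
    """Pixels + superpixels (left side) against superpixels (right side).

    ``incidence`` is the (n_pixels + n_superpixels) x n_superpixels weight
    matrix B: pixel rows hold inclusion edges (weight ``w_in``, one per map
    containing the pixel), superpixel rows hold Gaussian intensity-similarity
    edges between spatially adjacent superpixels of the same map.
    """

    incidence: sparse.csr_matrix
    n_pixels: int
    image_shape: tuple[int, int]
    w_in: float
    sigma: float

    @property
    def n_superpixels(self) -> int:
        return self.incidence.shape[1]

    def edge_list(self) -> list[tuple[int, int, float]]:
        coo = self.incidence.tocoo()
        return [(int(i), int(j), float(v)) for i, j, v in zip(coo.row, coo.col, coo.data)]


def build_bipartite_graph(
    img: NormalizedImage | np.ndarray,
    bag: SuperpixelBag,
    w_in: float = 1.0,
    sigma_mode: str = "auto",
    sigma: float | None = None,
) -> BipartiteGraph:
    """Join all superpixel maps of the bag into one bipartite graph.

    Every pixel connects to its containing superpixel in every map with
    weight ``w_in``. Within each map, spatially adjacent superpixels i, j
    connect with weight exp(-(mu_i - mu_j)^2 / (2 sigma^2)) on their mean
    intensities; ``sigma`` defaults to the standard deviation of the
    adjacent-pair mean differences (floored at 1e-6).
    """
    px = img.pixels if hasattr(img, "pixels") else np.asarray(img, dtype=float)
    hgt, wid = px.shape
    n_pix = hgt * wid
    n_sp = bag.total_superpixels

    rows_out: list[np.ndarray] = []
    cols_out: list[np.ndarray] = []
    vals_out: list[np.ndarray] = []

    offset = 0
    pair_rows: list[np.ndarray] = []  # superpixel-side (left) rows
    pair_cols: list[np.ndarray] = []
    pair_diffs: list[np.ndarray] = []
    for m in bag.maps:
        lab = m.labels
        flat = lab.ravel()
        # pixel -> containing superpixel
        rows_out.append(np.arange(n_pix))
        cols_out.append(flat + offset)
        vals_out.append(np.full(n_pix, w_in, dtype=float))
        # mean intensity per superpixel
        means = np.bincount(flat, weights=px.ravel(), minlength=m.n_superpixels)
        means = means / np.bincount(flat, minlength=m.n_superpixels)
        # 4-adjacency between distinct labels
        adj = set()
        a, b = lab[:, :-1].ravel(), lab[:, 1:].ravel()
        mask = a != b
        adj.update(zip(np.minimum(a[mask], b[mask]), np.maximum(a[mask], b[mask])))
        a, b = lab[:-1, :].ravel(), lab[1:, :].ravel()
        mask = a != b
        adj.update(zip(np.minimum(a[mask], b[mask]), np.maximum(a[mask], b[mask])))
        if adj:
            ii = np.array([p[0] for p in adj])
            jj = np.array([p[1] for p in adj])
            pair_rows.append(ii + offset)
            pair_cols.append(jj + offset)
            pair_diffs.append(means[ii] - means[jj])
        offset += m.n_superpixels

    if pair_diffs:
        diffs = np.concatenate(pair_diffs)
        if sigma_mode == "auto":
            sig = max(float(np.std(diffs)), 1e-6)
        else:
            if sigma is None:
                raise ValueError("sigma_mode='fixed' requires sigma")
            sig = float(sigma)
        # floor keeps high-contrast adjacencies from underflowing to zero,
        # which would spuriously disconnect the graph
        wts = np.maximum(np.exp(-(diffs**2) / (2.0 * sig**2)), 1e-6)
        ii = np.concatenate(pair_rows)
        jj = np.concatenate(pair_cols)
        # symmetric: both orientations on the left side
        rows_out.append(n_pix + ii)
        cols_out.append(jj)
        vals_out.append(wts)
        rows_out.append(n_pix + jj)
        cols_out.append(ii)
        vals_out.append(wts)
    else:
        sig = float(sigma) if sigma is not None else 1e-6

    B = sparse.csr_matrix(
        (np.concatenate(vals_out), (np.concatenate(rows_out), np.concatenate(cols_out))),
        shape=(n_pix + n_sp, n_sp),
    )
    return BipartiteGraph(
        incidence=B, n_pixels=n_pix, image_shape=(hgt, wid), w_in=w_in, sigma=sig
    )


# ---------------------------------------------------------------------------
# transfer cut


@dataclass(frozen=True)
class SegmentationMask:
    """Final k-way pixel labelling (labels 0..k-1)."""

    labels: np.ndarray
    k: int

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if lab.min() < 0 or lab.max() >= self.k:
            raise ValueError("labels out of range 0..k-1")
        object.__setattr__(self, "labels", lab.astype(int))


def reduced_eigenproblem(graph: BipartiteGraph) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Transfer the bipartite normalized-cut problem to the superpixel side.

    For incidence B with left degrees D_X = diag(B 1) and right degrees
    D_Y = diag(B^T 1), the reduced problem is

        (D_Y - B^T D_X^{-1} B) v = gamma * D_Y v.

    Its eigenvalues gamma determine the full bipartite normalized-Laplacian
    spectrum through lambda = 1 +/- sqrt(1 - gamma) (plus |X| - |Y| extra
    eigenvalues at exactly 1). Returns (gamma, V, d_x) with eigenvalues
    ascending.
    """
    B = graph.incidence
    d_x = np.asarray(B.sum(axis=1)).ravel()
    d_y = np.asarray(B.sum(axis=0)).ravel()
    if np.any(d_x[: graph.n_pixels] <= 0) or np.any(d_y <= 0):
        raise ValueError("graph has isolated pixel or superpixel nodes")
    # superpixel left-rows with no (or numerically vanished) similarity
    # edges are isolated: they contribute nothing to the reduced problem
    keep = d_x > 1e-12
    B = B[keep]
    d_x = d_x[keep]
    Dx_inv = sparse.diags(1.0 / d_x)
    W_y = (B.T @ Dx_inv @ B).toarray()
    L_y = np.diag(d_y) - W_y
    from scipy.linalg import eigh

    gamma, V = eigh(L_y, np.diag(d_y))
    return gamma, V, d_x


def tcut_partition(graph: BipartiteGraph, k: int, seed: int = 0) -> SegmentationMask:
    """k-way transfer-cut partition of the bipartite graph.

    Solves the reduced generalized eigenproblem over superpixels, lifts the
    k smallest-eigenvalue eigenvectors to pixels through the inclusion edges
    (degree-weighted average), and clusters the pixel embedding with seeded
    k-means (k-means++, 10 restarts).
    """
    n_sp = graph.n_superpixels
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n_sp:
        raise ValueError(f"k={k} exceeds the number of superpixel nodes ({n_sp})")
    gamma, V, d_x = reduced_eigenproblem(graph)
    n_components = int(np.sum(gamma < 1e-10))
    if n_components > k:
        warnings.warn(
            f"graph has {n_components} connected components but k={k}; "
            "components will be merged by the embedding",
            stacklevel=2,
        )
    V_k = V[:, :k]
    B_pix = graph.incidence[: graph.n_pixels]
    emb = (B_pix @ V_k) / d_x[: graph.n_pixels, None]
    # row-normalize for angular clustering; constant first vector is harmless
    norms = np.linalg.norm(emb, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    emb = emb / norms
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    labels = km.fit_predict(emb)
    return SegmentationMask(labels=labels.reshape(graph.image_shape), k=k)


# ---------------------------------------------------------------------------
# end-to-end segmentation


@dataclass(frozen=True)
class SASConfig:
    """Configuration for the full superpixel-aggregation segmentation."""

    bandwidths: tuple[tuple[float, float], ...] = DEFAULT_BANDWIDTHS
    w_in: float = 1.0
    sigma_mode: str = "auto"
    sigma: float | None = None
    profile: str = "gaussian"
    tol: float = 1e-3
    max_iter: int = 50


def segment(
    img: NormalizedImage | np.ndarray,
    k: int,
    config: SASConfig | None = None,
    seed: int = 0,
) -> SegmentationMask:
    """Full SAS segmentation: bag -> bipartite graph -> transfer cut.

    Output labels are relabelled so segment ids ascend with segment mean
    intensity (deterministic given a seed).
    """
    cfg = config or SASConfig()
    px = img.pixels if hasattr(img, "pixels") else np.asarray(img, dtype=float)
    bag = build_bag(px, cfg.bandwidths, profile=cfg.profile, tol=cfg.tol, max_iter=cfg.max_iter)
    graph = build_bipartite_graph(px, bag, w_in=cfg.w_in, sigma_mode=cfg.sigma_mode, sigma=cfg.sigma)
    mask = tcut_partition(graph, k, seed=seed)
    return _sort_labels_by_intensity(mask, px)


def _sort_labels_by_intensity(mask: SegmentationMask, px: np.ndarray) -> SegmentationMask:
    labels = mask.labels
    present = np.unique(labels)
    means = [px[labels == lab].mean() for lab in present]
    order = present[np.argsort(means)]
    remap = np.full(int(labels.max()) + 1, -1)
    for new, old in enumerate(order):
        remap[old] = new
    return SegmentationMask(labels=remap[labels], k=mask.k)
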