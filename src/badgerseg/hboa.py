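"""Honey badger optimization with a rough-set wrapper fitness.

The honey badger algorithm is a population metaheuristic with two moves:
a *digging* phase (cardioid-shaped exploration around the best-so-far
solution, driven by a prey "smell intensity") and a *honey* phase
(contraction toward the best solution), balanced by a density factor
``alpha = l * exp(-iter / max_iter)`` that decays over iterations.

For feature selection, continuous agent positions in [0, 1]^d are
thresholded into boolean feature masks and scored by

    Fit(Z) = eta * |Z| / d + rho * (1 - gamma)

where gamma is the rough-set dependency degree of the class label on the
selected (discretized) features — the fraction of samples whose
feature-equivalence class is pure in the label. Lower fitness is better;
greedy acceptance keeps the best-so-far trace non-increasing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

EPS = 1e-12  # guards the 4*pi*d_i^2 denominator of the smell intensity


# ---------------------------------------------------------------------------
# population and moves


@dataclass
class BadgerPopulation:
    """Search state: agent positions, bounds and the incumbent solution."""

    positions: np.ndarray  # (n_agents, d)
    lb: np.ndarray
    ub: np.ndarray
    best_position: np.ndarray
    best_fitness: float
    fitnesses: np.ndarray
    iteration: int = 0
    max_iter: int = 100
    l: float = 2.0
    beta: float = 1.0


def init_population(
    n_agents: int,
    d: int,
    lb: float | np.ndarray,
    ub: float | np.ndarray,
    seed: int | np.random.Generator = 0,
    *,
    max_iter: int = 100,
    l: float = 2.0,
    beta: float = 1.0,
) -> BadgerPopulation:
    """Uniform initialization Z_i = LB + r1 * (UB - LB), r1 ~ U(0,1)."""
    if n_agents < 2:
        raise ValueError("need at least 2 agents")
    if d < 1:
        raise ValueError("d must be >= 1")
    lb = np.broadcast_to(np.asarray(lb, dtype=float), (d,)).copy()
    ub = np.broadcast_to(np.asarray(ub, dtype=float), (d,)).copy()
    if not np.all(lb < ub):
        raise ValueError("LB must be < UB elementwise")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    r1 = rng.random((n_agents, d))
    pos = lb + r1 * (ub - lb)
    return BadgerPopulation(
        positions=pos,
        lb=lb,
        ub=ub,
        best_position=pos[0].copy(),
        best_fitness=np.inf,
        fitnesses=np.full(n_agents, np.inf),
        max_iter=max_iter,
        l=l,
        beta=beta,
    )


def density_factor(iteration: int, max_iter: int, l: float = 2.0) -> float:
    """Decaying exploration/exploitation balance alpha = l * exp(-t/T)."""
    if not 0 <= iteration <= max_iter:
        raise ValueError("iteration must lie in [0, max_iter]")
    if l <= 1:
        raise ValueError("l must exceed 1")
    return float(l * np.exp(-iteration / max_iter))


def digging_update(pop: BadgerPopulation, agent_i: int, rng: np.random.Generator) -> np.ndarray:
    """Cardioid digging move around the incumbent, clipped to bounds.

    Z_new = Z_k + Q*beta*I_n*Z_k + Q*alpha*d_i*r3*|cos(2*pi*r4)*(1 - cos(2*pi*r5))|
    with smell intensity I_n = r2 * G / (4*pi*d_i^2 + eps), prey-distance
    d_i = Z_k - Z_i and G = (Z_i - Z_{i+1})^2 (wrap-around neighbour).
    """
    Z = pop.positions
    n, d = Z.shape
    zk = pop.best_position
    zi = Z[agent_i]
    z_next = Z[(agent_i + 1) % n]
    r2, r3, r4, r5 = (rng.random(d) for _ in range(4))
    r6 = rng.random()
    q = 1.0 if r6 <= 0.5 else -1.0
    alpha = density_factor(pop.iteration, pop.max_iter, pop.l)
    di = zk - zi
    g = (zi - z_next) ** 2
    intensity = r2 * g / (4.0 * np.pi * di**2 + EPS)
    z_new = (
        zk
        + q * pop.beta * intensity * zk
        + q * alpha * di * r3 * np.abs(np.cos(2 * np.pi * r4) * (1.0 - np.cos(2 * np.pi * r5)))
    )
    return np.clip(z_new, pop.lb, pop.ub)


def honey_update(pop: BadgerPopulation, agent_i: int, rng: np.random.Generator) -> np.ndarray:
    """Honey move: contraction toward the incumbent, Z_new = Z_k + Q*r7*alpha*d_i."""
    zk = pop.best_position
    zi = pop.positions[agent_i]
    r7 = rng.random(zi.shape[0])
    r6 = rng.random()
    q = 1.0 if r6 <= 0.5 else -1.0
    alpha = density_factor(pop.iteration, pop.max_iter, pop.l)
    z_new = zk + q * r7 * alpha * (zk - zi)
    return np.clip(z_new, pop.lb, pop.ub)


def optimize(
    objective,
    d: int,
    lb: float | np.ndarray = 0.0,
    ub: float | np.ndarray = 1.0,
    *,
    n_agents: int = 30,
    max_iter: int = 100,
    l: float = 2.0,
    beta: float = 1.0,
    seed: int = 0,
) -> tuple[np.ndarray, float, np.ndarray]:
    """Minimize a continuous objective with the honey badger algorithm.

    Each iteration every agent proposes either a digging or a honey move
    (fresh fair coin per agent) which replaces its position only if the
    objective improves (greedy acceptance). Returns
    ``(best_position, best_value, per-iteration best trace)``.
    """
    rng = np.random.default_rng(seed)
    pop = init_population(n_agents, d, lb, ub, rng, max_iter=max_iter, l=l, beta=beta)
    pop.fitnesses = np.array([objective(z) for z in pop.positions])
    best_idx = int(np.argmin(pop.fitnesses))
    pop.best_position = pop.positions[best_idx].copy()
    pop.best_fitness = float(pop.fitnesses[best_idx])
    trace = np.empty(max_iter)
    for it in range(max_iter):
        pop.iteration = it
        for i in range(n_agents):
            move = digging_update if rng.random() < 0.5 else honey_update
            candidate = move(pop, i, rng)
            f = float(objective(candidate))
            if f < pop.fitnesses[i]:
                pop.positions[i] = candidate
                pop.fitnesses[i] = f
                if f < pop.best_fitness:
                    pop.best_fitness = f
                    pop.best_position = candidate.copy()
        trace[it] = pop.best_fitness
    return pop.best_position, pop.best_fitness, trace


# ---------------------------------------------------------------------------
# rough-set fitness


@dataclass(frozen=True)
class FitnessConfig:
    """Weights and discretization of the rough-set wrapper fitness."""

    eta: float = 0.01  # subset-size weight
    rho: float = 0.99  # dependency weight; eta + rho = 1
    n_bins: int = 5
    threshold: float = 0.5

    def __post_init__(self) -> None:
        if not np.isclose(self.eta + self.rho, 1.0):
            raise ValueError("eta + rho must equal 1")
        if self.eta < 0 or self.rho < 0:
            raise ValueError("weights must be non-negative")
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must lie in (0, 1)")


@dataclass(frozen=True)
class DecisionTable:
    """Discretized condition attributes plus a decision (class) column."""

    attributes: np.ndarray  # (n, d) integer codes
    decision: np.ndarray  # (n,) integer class codes
    feature_names: tuple[str, ...]


def discretize(features: pd.DataFrame, labels: np.ndarray | pd.Series, n_bins: int = 5) -> DecisionTable:
    """Equal-frequency binning of each feature column into integer codes."""
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    codes = np.empty(features.shape, dtype=np.int64)
    for j, col in enumerate(features.columns):
        x = features[col].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            codes[:, j] = 0
            continue
        qs = np.quantile(x, np.linspace(0, 1, n_bins + 1)[1:-1])
        codes[:, j] = np.searchsorted(qs, x, side="right")
    _, dec = np.unique(np.asarray(labels), return_inverse=True)
    return DecisionTable(
        attributes=codes, decision=dec, feature_names=tuple(map(str, features.columns))
    )


def dependency_degree(dt: DecisionTable, selected: np.ndarray) -> float:
    """Rough-set dependency gamma = |POS_C(D)| / |U|.

    Samples are partitioned into equivalence classes by the selected
    attributes; the positive region is the union of classes whose members
    all share one decision label (the lower approximation of the decision
    partition).
    """
    selected = np.asarray(selected, dtype=bool)
    if not selected.any():
        raise ValueError("subset must select at least one attribute")
    sub = dt.attributes[:, selected]
    # group rows by their attribute tuple
    _, group = np.unique(sub, axis=0, return_inverse=True)
    # a group is in the positive region iff it holds exactly one label
    order = np.lexsort((dt.decision, group))
    g_sorted = group[order]
    d_sorted = dt.decision[order]
    boundaries = np.flatnonzero(np.diff(g_sorted) != 0)
    starts = np.concatenate([[0], boundaries + 1])
    ends = np.concatenate([boundaries + 1, [g_sorted.size]])
    pos = 0
    for s, e in zip(starts, ends):
        if np.all(d_sorted[s:e] == d_sorted[s]):
            pos += e - s
    return pos / dt.decision.size


def fitness(selected: np.ndarray, dt: DecisionTable, cfg: FitnessConfig) -> float:
    """Wrapper fitness eta*|Z|/d + rho*(1 - gamma); lower is better."""
    selected = np.asarray(selected, dtype=bool)
    gamma = dependency_degree(dt, selected)
    d = selected.size
    return cfg.eta * selected.sum() / d + cfg.rho * (1.0 - gamma)


def binarize(position: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Continuous position -> boolean mask; argmax rescue if empty."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    z = np.asarray(position, dtype=float)
    mask = z > threshold
    if not mask.any():
        mask = np.zeros_like(mask)
        mask[int(np.argmax(z))] = True
    return mask


# ---------------------------------------------------------------------------
# feature selection


@dataclass(frozen=True)
class SelectionResult:
    mask: np.ndarray
    feature_names: tuple[str, ...]
    best_fitness: float
    trace: np.ndarray
    gamma: float

    @property
    def selected_names(self) -> list[str]:
        return [n for n, m in zip(self.feature_names, self.mask) if m]


def select_features(
    features: pd.DataFrame,
    labels: np.ndarray | pd.Series,
    *,
    n_agents: int = 30,
    max_iter: int = 100,
    cfg: FitnessConfig | None = None,
    l: float = 2.0,
    beta: float = 1.0,
    seed: int = 0,
) -> SelectionResult:
    """Honey-badger wrapper feature selection on a feature table.

    Positions live in [0, 1]^d and are thresholded into masks before every
    fitness evaluation; fitness values are memoized per mask. The returned
    trace of best fitness per iteration is non-increasing by construction.
    """
    cfg = cfg or FitnessConfig()
    if features.shape[1] < 2:
        raise ValueError("need at least 2 features")
    if np.unique(np.asarray(labels)).size < 2:
        raise ValueError("need at least 2 classes")
    dt = discretize(features, labels, cfg.n_bins)
    cache: dict[bytes, float] = {}

    def objective(z: np.ndarray) -> float:
        mask = binarize(z, cfg.threshold)
        key = np.packbits(mask).tobytes()
        if key not in cache:
            cache[key] = fitness(mask, dt, cfg)
        return cache[key]

    best_z, best_f, trace = optimize(
        objective,
        d=features.shape[1],
        lb=0.0,
        ub=1.0,
        n_agents=n_agents,
        max_iter=max_iter,
        l=l,
        beta=beta,
        seed=seed,
    )
    mask = binarize(best_z, cfg.threshold)
    return SelectionResult(
        mask=mask,
        feature_names=tuple(map(str, features.columns)),
        best_fitness=best_f,
        trace=trace,
        gamma=dependency_degree(dt, mask),
    )


def pearson_screen(
    features: pd.DataFrame, labels: np.ndarray | pd.Series, mask: np.ndarray | None = None
) -> pd.DataFrame:
    """Pearson r (and two-sided p) of each selected feature vs the coded label.

    Report only — no filtering is applied. Zero-variance features are
    reported with r = 0 and flagged.
    """
    y = pd.Series(labels).astype("category").cat.codes.to_numpy(dtype=float)
    if y.size < 3:
        raise ValueError("need at least 3 samples")
    mask = np.ones(features.shape[1], dtype=bool) if mask is None else np.asarray(mask, dtype=bool)
    rows = []
    for col, keep in zip(features.columns, mask):
        if not keep:
            continue
        x = features[col].to_numpy(dtype=float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            rows.append({"feature": col, "r": 0.0, "p_value": 1.0, "zero_variance": True})
            continue
        r, p = stats.pearsonr(x, y)
        rows.append({"feature": col, "r": float(r), "p_value": float(p), "zero_variance": False})
    return pd.DataFrame(rows)
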