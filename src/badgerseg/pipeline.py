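"""End-to-end orchestration: normalize -> segment -> features -> select -> classify.

The evaluation protocol is a stratified 80:20 split of the image-level
labels; feature selection and scaler statistics are computed on training
rows only, so nothing about the held-out rows can leak into the model.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import features as feat
from . import hboa, metrics, mlp
from .imaging import normalize
from .sas import SASConfig, segment


@dataclass(frozen=True)
class PipelineConfig:
    """Stage configurations plus the split protocol.

    The default segmentation config for classification images uses a single
    mid-scale bandwidth and k=2 (background vs brain): the classification
    unit is one pooled feature row per image, so the segmenter only has to
    isolate the foreground.
    """

    sas: SASConfig = field(default_factory=lambda: SASConfig(bandwidths=((6, 0.15),)))
    k_segments: int = 2
    features: feat.FeatureConfig = field(default_factory=feat.FeatureConfig)
    fitness: hboa.FitnessConfig = field(default_factory=hboa.FitnessConfig)
    n_agents: int = 30
    max_iter: int = 100
    arch_hidden: tuple[int, ...] = (10, 10, 10)
    train: mlp.TrainConfig = field(default_factory=mlp.TrainConfig)
    split_fraction: float = 0.8
    split_seed: int = 0
    selection_seed: int = 0
    segment_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.split_fraction < 1:
            raise ValueError("split_fraction must lie in (0, 1)")


def stratified_split(
    labels, fraction: float = 0.8, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Per-class proportional split with largest-remainder rounding.

    Every class contributes round(fraction * n_c) training samples, where
    rounding distributes the leftover slots to the classes with the largest
    fractional remainders (ties by class order). Requires >= 2 samples per
    class so both sides are non-empty overall and deterministic per seed.
    """
    labels = np.asarray(labels)
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    classes, counts = np.unique(labels, return_counts=True)
    if np.any(counts < 2):
        raise ValueError("every class needs at least 2 samples")
    raw = counts * fraction
    base = np.floor(raw).astype(int)
    total_train = int(round(labels.size * fraction))
    remainder = raw - base
    leftover = total_train - base.sum()
    order = np.argsort(-remainder, kind="stable")
    for idx in order[: max(leftover, 0)]:
        base[idx] += 1
    # keep both sides non-empty per class
    base = np.clip(base, 1, counts - 1)
    train_idx, test_idx = [], []
    for cls, n_train in zip(classes, base):
        idx = np.flatnonzero(labels == cls)
        perm = rng.permutation(idx)
        train_idx.append(perm[:n_train])
        test_idx.append(perm[n_train:])
    return np.sort(np.concatenate(train_idx)), np.sort(np.concatenate(test_idx))


def extract_image_features(
    images: list[np.ndarray], cfg: PipelineConfig
) -> pd.DataFrame:
    """Normalize + segment each image, pool texture features over foreground."""
    bank = feat.gabor_bank(cfg.features.gabor)
    rows = []
    for i, img in enumerate(images):
        norm = normalize(img, 0.0, 1.0)
        mask = segment(norm, cfg.k_segments, cfg.sas, seed=cfg.segment_seed)
        # labels ascend with mean intensity; 0 is the dark background
        row = feat.extract_features(
            norm.pixels,
            mask.labels,
            cfg.features,
            per_image=True,
            background_label=0,
            bank=bank,
        )
        rows.append(row.drop(columns=["segment"]))
    return pd.concat(rows, ignore_index=True)


def run_pipeline(
    images: list[np.ndarray],
    labels,
    cfg: PipelineConfig | None = None,
    *,
    precomputed_features: pd.DataFrame | None = None,
) -> dict:
    """Run all six stages and evaluate on the held-out split.

    Returns a JSON-serializable report: selected features, per-stage
    timings, the held-out classification report and the seeds used.
    ``precomputed_features`` short-circuits the imaging stages (the table
    must align with ``labels``).
    """
    cfg = cfg or PipelineConfig()
    labels = np.asarray(labels)
    timings: dict[str, float] = {}

    t0 = time.perf_counter()
    if precomputed_features is None:
        table = extract_image_features(images, cfg)
    else:
        table = precomputed_features.reset_index(drop=True)
    timings["features_s"] = time.perf_counter() - t0
    if len(table) != labels.size:
        raise ValueError("feature rows and labels disagree")

    train_idx, test_idx = stratified_split(labels, cfg.split_fraction, cfg.split_seed)

    t0 = time.perf_counter()
    sel = hboa.select_features(
        table.iloc[train_idx],
        labels[train_idx],
        n_agents=cfg.n_agents,
        max_iter=cfg.max_iter,
        cfg=cfg.fitness,
        seed=cfg.selection_seed,
    )
    timings["selection_s"] = time.perf_counter() - t0
    screen = hboa.pearson_screen(table.iloc[train_idx], labels[train_idx], sel.mask)

    cols = sel.selected_names
    t0 = time.perf_counter()
    classes = sorted(np.unique(labels).tolist())
    model = mlp.train_lm(
        table.iloc[train_idx][cols].to_numpy(),
        labels[train_idx],
        mlp.MLPArchitecture(
            input_dim=len(cols), hidden_layers=cfg.arch_hidden, output_dim=len(classes)
        ),
        cfg.train,
        classes=classes,
    )
    timings["training_s"] = time.perf_counter() - t0

    y_pred, _ = mlp.predict(model, table.iloc[test_idx][cols].to_numpy())
    report = metrics.classification_report(labels[test_idx], y_pred, classes)
    y_pred_train, _ = mlp.predict(model, table.iloc[train_idx][cols].to_numpy())
    train_report = metrics.classification_report(labels[train_idx], y_pred_train, classes)

    return {
        "n_images": int(labels.size),
        "n_features_total": int(table.shape[1]),
        "n_features_selected": int(sel.mask.sum()),
        "selected_features": cols,
        "selection_fitness": float(sel.best_fitness),
        "selection_gamma": float(sel.gamma),
        "pearson_screen": screen.to_dict(orient="records"),
        "split": {
            "fraction": cfg.split_fraction,
            "train": int(train_idx.size),
            "test": int(test_idx.size),
        },
        "train_report": train_report,
        "test_report": report,
        "mlp_epochs": model.epochs_run,
        "mlp_final_error": float(model.final_error),
        "seeds": {
            "split": cfg.split_seed,
            "selection": cfg.selection_seed,
            "segment": cfg.segment_seed,
            "mlp": cfg.train.seed,
        },
        "timings": timings,
    }
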