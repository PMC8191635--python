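"""Gradient-boosted decision-tree classifier over fused feature blocks.

The boosting implementation is consumed behind a small backend interface:
``lightgbm`` (default) and ``sklearn`` (GradientBoostingClassifier) are
provided. Class imbalance is handled by per-class sample weights, by
default inversely proportional to class counts so both classes carry equal
total weight. Training is deterministic for a fixed seed with the
single-threaded backend settings used here.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .data_io import SampleSet, SplitSpec, split_dataset
from .sequence_features import FeatureBlock, fuse_features


@dataclass
class TrainConfig:
    """Booster hyperparameters and class weighting.

    ``class_weights`` is "auto" (weight of class y = N / (2 * N_y)) or an
    explicit (w_neg, w_pos) pair. ``backend`` selects the boosting
    implementation.
    """

    iterations: int = 500
    depth: int = 6
    learning_rate: float = 0.05
    class_weights: str | tuple[float, float] = "auto"
    seed: int = 0
    backend: str = "lightgbm"
    importance_type: str = "gain"

    def __post_init__(self) -> None:
        if self.backend not in ("lightgbm", "sklearn"):
            raise ValueError(f"unknown backend {self.backend!r}")


def resolve_class_weights(cfg: TrainConfig, y: np.ndarray
                          ) -> tuple[float, float]:
    """(w_neg, w_pos); "auto" balances the total weight of the classes."""
    if cfg.class_weights != "auto":
        w_neg, w_pos = cfg.class_weights
        return float(w_neg), float(w_pos)
    n = len(y)
    n_pos = int((y == 1).sum())
    n_neg = n - n_pos
    return n / (2.0 * n_neg), n / (2.0 * n_pos)


@dataclass
class TrainedModel:
    """A fitted booster plus the column contract it was trained under."""

    backend: str
    model: object
    columns: list[str]
    config: TrainConfig
    block_of_column: dict[str, str] = field(default_factory=dict)

    def _check_columns(self, X: FeatureBlock) -> np.ndarray:
        cols = X.prefixed_columns() if X.name != "fused" else X.columns
        if cols != self.columns:
            missing = [c for c in self.columns if c not in set(cols)]
            extra = [c for c in cols if c not in set(self.columns)]
            raise ValueError(
                f"feature columns do not match training columns; "
                f"missing={missing[:5]}, extra={extra[:5]}"
            )
        return X.matrix


def _block_map(columns: list[str],
               column_blocks: list[str] | None = None) -> dict[str, str]:
    if column_blocks is not None:
        return dict(zip(columns, column_blocks))
    return {c: c.split("_", 1)[0] for c in columns}


def train_model(train_X: FeatureBlock, train_y: np.ndarray,
                cfg: TrainConfig | None = None) -> TrainedModel:
    """Fit the gradient-boosted classifier on a fused feature block."""
    cfg = cfg or TrainConfig()
    y = np.asarray(train_y).astype(int)
    if y.min() == y.max():
        raise ValueError("training labels contain a single class")
    for cls in (0, 1):
        if (y == cls).sum() < 2:
            raise ValueError(f"need >= 2 samples of class {cls}")
    X = train_X.matrix
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite feature values")
    w_neg, w_pos = resolve_class_weights(cfg, y)
    sample_weight = np.where(y == 1, w_pos, w_neg)

    if cfg.backend == "lightgbm":
        import lightgbm as lgb

        model = lgb.LGBMClassifier(
            n_estimators=cfg.iterations,
            max_depth=cfg.depth,
            num_leaves=2 ** cfg.depth,
            learning_rate=cfg.learning_rate,
            objective="binary",
            random_state=cfg.seed,
            deterministic=True,
            force_row_wise=True,
            n_jobs=1,
            verbose=-1,
            importance_type=cfg.importance_type,
        )
        model.fit(X, y, sample_weight=sample_weight)
    else:
        from sklearn.ensemble import GradientBoostingClassifier

        model = GradientBoostingClassifier(
            n_estimators=cfg.iterations,
            max_depth=cfg.depth,
            learning_rate=cfg.learning_rate,
            random_state=cfg.seed,
        )
        model.fit(X, y, sample_weight=sample_weight)

    if train_X.name == "fused":
        columns = train_X.columns
        col_blocks = train_X.column_blocks
    else:
        columns = train_X.prefixed_columns()
        col_blocks = [train_X.name] * len(columns)
    return TrainedModel(cfg.backend, model, list(columns), cfg,
                        _block_map(columns, col_blocks))


def predict(model: TrainedModel, X: FeatureBlock,
            threshold: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
    """(probability of class 1, thresholded label) per sample."""
    mat = model._check_columns(X)
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*valid feature names.*")
        scores = model.model.predict_proba(mat)[:, 1]
    return scores, (scores >= threshold).astype(int)


@dataclass
class ImportanceReport:
    """Ranked feature importances plus per-block aggregates."""

    ranked: list[tuple[str, float]]
    block_scores: dict[str, float]
    embedding_fraction_top_n: float
    top_n: int

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({
                "ranked": self.ranked,
                "block_scores": self.block_scores,
                "embedding_fraction_top_n": self.embedding_fraction_top_n,
                "top_n": self.top_n,
            }, fh, indent=2)


EMBEDDING_BLOCK_NAMES = frozenset({"SocDim", "N2V", "GraRep"})


def feature_importance(model: TrainedModel, top_n: int = 20) -> ImportanceReport:
    """Rank columns by booster importance; aggregate per feature block.

    Also reports which fraction of the top-n columns comes from graph
    embedding blocks (the embeddings' share of the most informative
    features).
    """
    scores = np.asarray(model.model.feature_importances_, dtype=float)
    if top_n > len(model.columns):
        warnings.warn(
            f"top_n={top_n} exceeds {len(model.columns)} columns; clamping",
            stacklevel=2,
        )
        top_n = len(model.columns)
    order = np.argsort(-scores, kind="stable")
    ranked = [(model.columns[i], float(scores[i])) for i in order]
    block_scores: dict[str, float] = {}
    for col, s in ranked:
        block = model.block_of_column.get(col, col.split("_", 1)[0])
        block_scores[block] = block_scores.get(block, 0.0) + s
    top_blocks = [model.block_of_column.get(c, c.split("_", 1)[0])
                  for c, _ in ranked[:top_n]]
    emb = sum(b in EMBEDDING_BLOCK_NAMES for b in top_blocks)
    return ImportanceReport(ranked[:top_n], block_scores,
                            emb / top_n if top_n else 0.0, top_n)


def select_feature_blocks(train: SampleSet,
                          candidate_blocks: list[FeatureBlock],
                          cfg: TrainConfig | None = None,
                          n_keep: int = 3,
                          override: list[str] | None = None) -> list[str]:
    """Pick the feature blocks whose columns matter most to a probe model.

    A preliminary booster is trained on all fused candidates using an
    internal stratified 75/25 validation split of the training samples;
    blocks are ranked by their aggregate importance and the top ``n_keep``
    returned. An explicit ``override`` list bypasses the automatic choice.
    """
    if override is not None:
        known = {b.name for b in candidate_blocks}
        unknown = [t for t in override if t not in known]
        if unknown:
            raise ValueError(f"override names unknown blocks: {unknown}")
        return list(override)
    if len(candidate_blocks) < 2:
        raise ValueError("need >= 2 candidate blocks for selection")
    if n_keep > len(candidate_blocks):
        warnings.warn("n_keep exceeds candidate count; clamping", stacklevel=2)
        n_keep = len(candidate_blocks)
    cfg = cfg or TrainConfig()
    sub_train, _ = split_dataset(
        train, SplitSpec(train_fraction=0.75, seed=cfg.seed, stratified=True)
    )
    id_to_row = {sid: i for i, sid in enumerate(candidate_blocks[0].sample_ids)}
    rows = [id_to_row[s.id] for s in sub_train]
    fused = fuse_features([b.subset_rows(rows) for b in candidate_blocks])
    probe = train_model(fused, sub_train.labels, cfg)
    report = feature_importance(probe, top_n=len(fused.columns))
    ranked_blocks = sorted(report.block_scores.items(),
                           key=lambda kv: -kv[1])
    return [name for name, _ in ranked_blocks[:n_keep]]


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------

def save_model(model: TrainedModel, out_dir: str | Path) -> None:
    """Write a model bundle: booster file + JSON manifest of the contract."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "backend": model.backend,
        "columns": model.columns,
        "column_blocks": [model.block_of_column.get(c) for c in model.columns],
        "config": {
            "iterations": model.config.iterations,
            "depth": model.config.depth,
            "learning_rate": model.config.learning_rate,
            "class_weights": model.config.class_weights,
            "seed": model.config.seed,
            "backend": model.config.backend,
            "importance_type": model.config.importance_type,
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    if model.backend == "lightgbm":
        model.model.booster_.save_model(str(out / "booster.txt"))
    else:
        import joblib

        joblib.dump(model.model, out / "booster.joblib")


class _LgbBoosterWrapper:
    """predict_proba/feature_importances_ facade over a loaded booster."""

    def __init__(self, booster, importance_type: str):
        self._booster = booster
        self._importance_type = importance_type

    def predict_proba(self, X):
        p1 = self._booster.predict(X)
        return np.stack([1.0 - p1, p1], axis=1)

    @property
    def feature_importances_(self):
        return self._booster.feature_importance(
            importance_type=self._importance_type)


def load_model(in_dir: str | Path) -> TrainedModel:
    ind = Path(in_dir)
    manifest = json.loads((ind / "manifest.json").read_text())
    raw_cfg = dict(manifest["config"])
    if isinstance(raw_cfg.get("class_weights"), list):
        raw_cfg["class_weights"] = tuple(raw_cfg["class_weights"])
    cfg = TrainConfig(**raw_cfg)
    if manifest["backend"] == "lightgbm":
        import lightgbm as lgb

        booster = lgb.Booster(model_file=str(ind / "booster.txt"))
        inner = _LgbBoosterWrapper(booster, cfg.importance_type)
    else:
        import joblib

        inner = joblib.load(ind / "booster.joblib")
    columns = manifest["columns"]
    return TrainedModel(manifest["backend"], inner, columns, cfg,
                        _block_map(columns, manifest.get("column_blocks")))
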