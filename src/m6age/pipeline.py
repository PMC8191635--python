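"""End-to-end pipeline: encode -> graph -> embed -> fuse -> train -> evaluate.

The default protocol mirrors the transductive benchmark setting: the
class-conditional encoders (NPPS, BPB) are fitted on the training split
only, the sample-similarity graph is built over training and test samples
jointly (without labels), embeddings supplement the sequence features, and
a gradient-boosted model is trained on the training rows and evaluated on
the held-out rows. An inductive mode restricts the graph to training
samples and maps each test sample to the embedding of its nearest training
neighbor.

Every stage draws its seed from one global seed, and the run manifest
(config + seeds) suffices to replay a run bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .classifier import (TrainConfig, TrainedModel, feature_importance,
                         predict, save_model, select_feature_blocks,
                         train_model)
from .data_io import SampleSet, SplitSpec, read_fasta_samples, split_dataset
from .evaluation import MetricsReport, compute_metrics
from .graph_embeddings import EMBEDDING_TAGS, EmbeddingParams, embed_graph
from .sequence_features import (SEQUENCE_ENCODER_TAGS, FeatureBlock,
                                encode_block, fuse_features)
from .similarity_graph import FlnsaParams, build_graph, minmax_rescale
from .synthetic_data import SynthConfig, generate_dataset

logger = logging.getLogger("m6age")

#: per-dataset feature-block presets matching the published configurations
PRESETS: dict[str, dict] = {
    "A101": {"blocks": ["PseKNC", "CTD", "NPS"], "L": 101,
             "n_pos": 2518, "n_neg": 2518},
    "A25": {"blocks": ["EIIP", "NPPS", "NPS", "PseKNC", "NCP_ND"], "L": 25,
            "n_pos": 394, "n_neg": 394},
    "S21": {"blocks": ["NPPS", "NCP_ND"], "L": 21,
            "n_pos": 832, "n_neg": 3328},
    "H41": {"blocks": ["NCP_ND", "PseKNC", "NPPS"], "L": 41,
            "n_pos": 1130, "n_neg": 1130},
}


@dataclass
class PipelineConfig:
    """Everything one run needs; a single seed drives all stage seeds."""

    pos_fasta: str | None = None
    neg_fasta: str | None = None
    synth: SynthConfig | None = None
    blocks: list[str] | str = "auto"       # encoder tags, or "auto"
    n_keep_auto: int = 3
    encoder_params: dict = field(default_factory=dict)
    flnsa: FlnsaParams = field(default_factory=FlnsaParams)
    embedding: EmbeddingParams = field(default_factory=EmbeddingParams)
    embedding_methods: list[str] = field(default_factory=lambda: list(EMBEDDING_TAGS))
    train: TrainConfig = field(default_factory=TrainConfig)
    split: SplitSpec = field(default_factory=SplitSpec)
    use_graph: bool = True
    inductive: bool = False
    fit_on_all: bool = False
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if isinstance(self.blocks, list):
            unknown = [b for b in self.blocks
                       if b not in SEQUENCE_ENCODER_TAGS]
            if unknown:
                raise ValueError(f"unknown feature block tags: {unknown}")
        unknown = [m for m in self.embedding_methods if m not in EMBEDDING_TAGS]
        if unknown:
            raise ValueError(f"unknown embedding methods: {unknown}")

    def stage_seeds(self) -> dict[str, int]:
        """Deterministic per-stage seeds derived from the global seed."""
        ss = np.random.SeedSequence(self.seed)
        kids = ss.spawn(4)
        names = ("split", "flnsa", "embedding", "train")
        return {n: int(k.generate_state(1)[0] % (2 ** 31 - 1))
                for n, k in zip(names, kids)}

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if d.get("synth"):
            sy = dict(d["synth"])
            sy["background"] = tuple(sy["background"])
            d["synth"] = SynthConfig(**sy)
        d["flnsa"] = FlnsaParams(**d["flnsa"])
        d["embedding"] = EmbeddingParams(**d["embedding"])
        tc = dict(d["train"])
        if isinstance(tc.get("class_weights"), list):
            tc["class_weights"] = tuple(tc["class_weights"])
        d["train"] = TrainConfig(**tc)
        d["split"] = SplitSpec(**d["split"])
        return cls(**d)


def preset_config(name: str, seed: int = 0,
                  synth_overrides: dict | None = None) -> PipelineConfig:
    """A PipelineConfig mirroring one benchmark's block list and shape.

    Without real FASTA inputs, the preset pairs the published feature-block
    choice with a synthetic dataset of matching segment length and class
    ratio.
    """
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {list(PRESETS)}")
    p = PRESETS[name]
    synth_kwargs = dict(n_pos=p["n_pos"], n_neg=p["n_neg"], L=p["L"], seed=seed)
    synth_kwargs.update(synth_overrides or {})
    return PipelineConfig(
        synth=SynthConfig(**synth_kwargs),
        blocks=list(p["blocks"]),
        seed=seed,
    )


@dataclass
class PipelineResult:
    metrics: MetricsReport
    model: TrainedModel
    selected_blocks: list[str]
    importance: object
    manifest: dict
    test_ids: list[str]
    test_scores: np.ndarray


def _load_data(cfg: PipelineConfig) -> SampleSet:
    if cfg.synth is not None:
        return generate_dataset(cfg.synth)
    if cfg.pos_fasta and cfg.neg_fasta:
        return read_fasta_samples(cfg.pos_fasta, cfg.neg_fasta)
    raise ValueError("config must give either FASTA paths or a synth config")


def _encode_all(tags: list[str], data: SampleSet, fit_set: SampleSet,
                encoder_params: dict) -> list[FeatureBlock]:
    return [encode_block(t, data, fit_set, encoder_params.get(t))
            for t in tags]


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Execute the full pipeline and (optionally) write run artifacts."""
    t0 = time.time()
    seeds = cfg.stage_seeds()
    data = _load_data(cfg)
    logger.info("loaded %d samples (L=%d)", len(data), data.seq_length)

    split = dataclasses.replace(cfg.split, seed=seeds["split"])
    train_set, test_set = split_dataset(data, split)
    fit_set = data if cfg.fit_on_all else train_set
    logger.info("split: %d train / %d test", len(train_set), len(test_set))

    # ---- feature blocks --------------------------------------------------
    if cfg.blocks == "auto":
        candidates = _encode_all(list(SEQUENCE_ENCODER_TAGS), train_set,
                                 train_set, cfg.encoder_params)
        probe_cfg = dataclasses.replace(cfg.train, iterations=100,
                                        seed=seeds["train"])
        selected = select_feature_blocks(train_set, candidates, probe_cfg,
                                         n_keep=cfg.n_keep_auto)
        logger.info("auto-selected blocks: %s", selected)
    else:
        selected = list(cfg.blocks)
    seq_blocks = _encode_all(selected, data, fit_set, cfg.encoder_params)

    # ---- graph + embeddings ---------------------------------------------
    all_blocks = list(seq_blocks)
    if cfg.use_graph:
        flnsa = dataclasses.replace(cfg.flnsa, seed=seeds["flnsa"])
        emb_params = dataclasses.replace(cfg.embedding, seed=seeds["embedding"])
        fused_seq = fuse_features(seq_blocks)
        if cfg.inductive:
            train_ids = set(train_set.ids)
            rows = [i for i, sid in enumerate(fused_seq.sample_ids)
                    if sid in train_ids]
            graph_input = fused_seq.subset_rows(rows)
        else:
            graph_input = fused_seq
        graph = build_graph(graph_input, flnsa)
        logger.info("graph: %d nodes, %d edges (c=%d)",
                    graph.n_nodes, len(graph.edges()), graph.effective_c)
        for method in cfg.embedding_methods:
            emb = embed_graph(method, graph, emb_params)
            if cfg.inductive:
                emb = _extend_inductive(emb, fused_seq, graph_input)
            all_blocks.append(emb)

    fused = fuse_features(all_blocks)

    # ---- train / evaluate ------------------------------------------------
    id_to_row = {sid: i for i, sid in enumerate(fused.sample_ids)}
    train_rows = [id_to_row[s.id] for s in train_set]
    test_rows = [id_to_row[s.id] for s in test_set]
    train_cfg = dataclasses.replace(cfg.train, seed=seeds["train"])
    model = train_model(fused.subset_rows(train_rows), train_set.labels,
                        train_cfg)
    scores, labels = predict(model, fused.subset_rows(test_rows))
    metrics = compute_metrics(test_set.labels, labels, scores)
    importance = feature_importance(model, top_n=20)
    logger.info("test metrics: %s", metrics)

    manifest = {
        "config": cfg.to_dict(),
        "stage_seeds": seeds,
        "n_train": len(train_set),
        "n_test": len(test_set),
        "selected_blocks": selected,
        "n_features": fused.n_features,
        "runtime_s": round(time.time() - t0, 2),
    }
    if cfg.out_dir:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        metrics.to_json(out / "metrics.json")
        importance.to_json(out / "importance.json")
        save_model(model, out / "model")
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return PipelineResult(metrics, model, selected, importance, manifest,
                          test_set.ids, scores)


def _extend_inductive(emb: FeatureBlock, fused_all: FeatureBlock,
                      graph_input: FeatureBlock) -> FeatureBlock:
    """Give unseen samples the embedding of their nearest training neighbor."""
    train_pos = {sid: i for i, sid in enumerate(graph_input.sample_ids)}
    Xall = minmax_rescale(fused_all.matrix)
    Xtr = Xall[[fused_all.sample_ids.index(s) for s in graph_input.sample_ids]]
    rows = np.empty((fused_all.n_samples, emb.n_features))
    for i, sid in enumerate(fused_all.sample_ids):
        if sid in train_pos:
            rows[i] = emb.matrix[train_pos[sid]]
        else:
            d2 = ((Xtr - Xall[i]) ** 2).sum(axis=1)
            rows[i] = emb.matrix[int(np.argmin(d2))]
    return FeatureBlock(emb.name, rows, list(emb.columns),
                        list(fused_all.sample_ids))


def replay_manifest(manifest: dict | str | Path) -> PipelineResult:
    """Re-run a pipeline from its manifest; reproduces the report exactly."""
    if not isinstance(manifest, dict):
        manifest = json.loads(Path(manifest).read_text())
    cfg = PipelineConfig.from_dict(manifest["config"])
    cfg.out_dir = None
    return run_pipeline(cfg)
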