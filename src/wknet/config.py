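"""Run configuration, seed management, and the staged pipeline driver."""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict, fields
from pathlib import Path

import numpy as np
import yaml


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage substream of the global seed (stable across
    stage reordering)."""
    return int(
        np.random.SeedSequence(
            [int(global_seed), zlib.crc32(stage.encode())]
        ).generate_state(1)[0] % (2**31)
    )


_ALLOWED_STAGES = ("simulate", "preprocess", "split", "augment", "train",
                   "eval", "profile", "grade")


@dataclass
class RunConfig:
    """Configuration of a full simulate -> ... -> grade pipeline run."""

    seed: int = 0
    out_dir: str = "runs/run0"
    stages: list = field(default_factory=lambda: list(_ALLOWED_STAGES))
    verbosity: int = 1
    simulate: dict = field(default_factory=dict)   # generate_dataset kwargs
    preprocess: dict = field(default_factory=dict)  # PreprocessParams kwargs
    train: dict = field(default_factory=dict)      # TrainConfig kwargs
    model: dict = field(default_factory=dict)      # DetectorConfig kwargs
    grade: dict = field(default_factory=dict)      # simulate_sorting kwargs

    def __post_init__(self):
        unknown = [s for s in self.stages if s not in _ALLOWED_STAGES]
        if unknown:
            raise ValueError(f"unknown stages: {unknown}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    def seed_for(self, stage: str) -> int:
        return stage_seed(self.seed, stage)


def run_pipeline(config: RunConfig) -> Path:
    """Execute the configured stages in canonical order; every artifact is
    reproducible from (config, seed)."""
    from . import synthetic_xray as sx
    from .imaging_preprocess import PreprocessParams, preprocess
    from .data_pipeline import split_7_2_1, expand_8x
    from .model.detector import DetectorConfig, build_wknet, profile_model
    from .training import TrainConfig, train, prepare_items, evaluate_model
    from .grading import simulate_sorting

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    metrics: dict = {}
    stages = set(config.stages)
    ds_dir = out / "dataset"
    model = None
    items_by_id = {}

    if "simulate" in stages:
        kw = dict(n_images=24, walnuts_per_image=4, class_mix=(0.5, 0.5))
        kw.update(config.simulate)
        sx.generate_dataset(seed=config.seed_for("simulate"),
                            out_dir=str(ds_dir), **kw)
        metrics["simulate"] = {"n_images": kw["n_images"]}

    if stages & {"preprocess", "split", "augment", "train", "eval"}:
        for png in sorted((ds_dir / "images").glob("*.png")):
            items_by_id[png.stem] = sx.read_labeled_image(png)

    if "preprocess" in stages and items_by_id:
        params = PreprocessParams(**config.preprocess)
        for key in items_by_id:
            items_by_id[key] = preprocess(items_by_id[key], params)

    split = None
    if "split" in stages and items_by_id:
        split = split_7_2_1(sorted(items_by_id), config.seed_for("split"))
        (out / "split.json").write_text(json.dumps(asdict(split), indent=1))
        metrics["split"] = {k: len(getattr(split, k)) for k in
                            ("train", "val", "test")}

    train_items = [items_by_id[i] for i in (split.train if split else
                                            sorted(items_by_id))]
    if "augment" in stages and train_items:
        train_items = expand_8x(train_items, config.seed_for("augment"))
        metrics["augment"] = {"n_train_items": len(train_items)}

    tc = TrainConfig(seed=config.seed_for("train"), **config.train)
    mc = DetectorConfig(input_size=tc.input_size, **config.model)

    if "profile" in stages:
        model = model or build_wknet(mc, seed=config.seed_for("train"))
        prof = profile_model(model)
        base = build_wknet(DetectorConfig.baseline(input_size=tc.input_size),
                           seed=config.seed_for("train"))
        bprof = profile_model(base)
        metrics["profile"] = {
            "wknet_params_m": prof.params_m, "wknet_flops_g": prof.flops_g,
            "baseline_params_m": bprof.params_m,
            "baseline_flops_g": bprof.flops_g,
            "param_reduction_pct": 100 * (bprof.params - prof.params) / bprof.params,
        }

    if "train" in stages and train_items:
        model = model or build_wknet(mc, seed=config.seed_for("train"))
        prepared = prepare_items(train_items, tc.input_size)
        hist = train(model, prepared, tc, verbose=config.verbosity > 1)
        model.save(out / "weights.npz")
        (out / "history.json").write_text(json.dumps(hist.to_rows(), indent=1))
        census = model.weight_census()
        (out / "census.json").write_text(json.dumps(census, indent=1))
        metrics["train"] = {"final_loss": hist.epochs[-1]["loss_total"]}

    if "eval" in stages and model is not None and split is not None:
        val_items = prepare_items([items_by_id[i] for i in split.val],
                                  tc.input_size)
        rep = evaluate_model(model, val_items)
        metrics["eval"] = rep.to_dict()

    if "grade" in stages and model is not None:
        kw = dict(n_walnuts=50, defect_rate=0.5)
        kw.update(config.grade)
        res = simulate_sorting(model, seed=config.seed_for("grade"), **kw)
        metrics["grade"] = res.to_dict()

    (out / "metrics.json").write_text(json.dumps(metrics, indent=1, default=float))
    return out
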