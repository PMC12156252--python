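"""End-to-end orchestration: simulate -> features -> train -> evaluate.

A single YAML-serialisable configuration drives the whole run; every source
of randomness (cohort sampling, train/test split, fold assignment, search
sampling, booster seeds) is derived from one master seed, so a run is
reproducible bit-for-bit from its resolved config.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from popsono import io as cohort_io
from popsono.evaluation import evaluate_cohort
from popsono.features import build_dataset, write_feature_table
from popsono.modeling import (
    TARGETS,
    SearchConfig,
    predict_patients,
    save_model,
    split_patients,
    tune_and_train,
)
from popsono.simulate import (
    DESCENT_KEYS,
    TARGET_NAMES,
    SceneConfig,
    iter_cohort,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    n_patients: int = 40
    prevalence: dict | None = None
    scene: dict = field(default_factory=dict)  # SceneConfig overrides
    window: int = 60
    step: int = 30
    train_frac: float = 0.68
    train_count: int | None = None
    targets: list[str] = field(default_factory=lambda: list(TARGETS))
    n_iter: int = 10
    k_folds: int = 5
    seed: int = 0
    save_maps: bool = False

    def __post_init__(self) -> None:
        if self.window <= 0 or self.step <= 0:
            raise ValueError("window and step must be positive")
        if self.n_patients < 2:
            raise ValueError("n_patients must be at least 2")
        unknown = set(self.targets) - set(TARGETS)
        if unknown:
            raise ValueError(f"unknown targets: {sorted(unknown)}")
        self.scene_config()  # validate scene overrides eagerly

    def scene_config(self) -> SceneConfig:
        scene = dict(self.scene)
        if "n_frames" in scene and isinstance(scene["n_frames"], list):
            scene["n_frames"] = tuple(scene["n_frames"])
        if "organ_set" in scene:
            scene["organ_set"] = tuple(scene["organ_set"])
        return SceneConfig(**scene)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        canonical = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def _derive_seeds(master: int) -> dict[str, int]:
    rng = np.random.default_rng(master)
    names = ("cohort", "split", "search")
    return {name: int(s) for name, s in zip(names, rng.integers(0, 2**31, len(names)))}


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> Path:
    """Execute the full pipeline into ``out_dir`` and return that path.

    Outputs: resolved_config.yaml, cohort_labels.csv, features.csv (+ JSON
    schema), one model bundle per trainable target, predictions.csv,
    report.csv and a JSON-lines log.  Targets with no positive training
    patient are skipped with a logged warning and excluded from the report.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    events: list[dict] = []

    def log_event(stage: str, **info) -> None:
        events.append({"t": time.time(), "stage": stage, **info})
        logger.info("%s %s", stage, info)

    seeds = _derive_seeds(config.seed)
    scene = config.scene_config()
    resolved = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "master_seed": config.seed,
        "derived_seeds": seeds,
    }
    (out / "resolved_config.yaml").write_text(yaml.safe_dump(resolved, sort_keys=True))

    # --- simulate + features (streamed patient by patient) ----------------
    log_event("simulate", n_patients=config.n_patients)
    videos_for_h5 = []
    label_rows: list[dict] = []

    def stream():
        for video in iter_cohort(
            config.n_patients, config.prevalence, scene, seeds["cohort"]
        ):
            # keep only the light per-patient summary, not the maps
            label_rows.append(
                {
                    "patient_id": video.patient_id,
                    **video.ground_truth.labels,
                    **video.ground_truth.descents,
                }
            )
            if config.save_maps:
                videos_for_h5.append(video)
            yield video

    table = build_dataset(stream(), window=config.window, step=config.step)
    labels = pd.DataFrame(
        label_rows, columns=["patient_id", *TARGET_NAMES, *DESCENT_KEYS]
    )
    labels.to_csv(out / "cohort_labels.csv", index=False)
    if config.save_maps:
        cohort_io.save_cohort(out / "cohort.h5", videos_for_h5)
        videos_for_h5.clear()
    write_feature_table(table, out / "features.csv")
    log_event("features", rows=len(table), columns=table.shape[1])

    # --- split + train ----------------------------------------------------
    plan = split_patients(
        labels["patient_id"],
        train_frac=config.train_frac,
        seed=seeds["split"],
        train_count=config.train_count,
    )
    train_table = table[table["patient_id"].isin(plan.train_ids)].reset_index(drop=True)
    test_table = table[table["patient_id"].isin(plan.test_ids)].reset_index(drop=True)
    assert not set(train_table["patient_id"]) & set(test_table["patient_id"])
    log_event("split", n_train=len(plan.train_ids), n_test=len(plan.test_ids))

    search = SearchConfig(n_iter=config.n_iter, k=config.k_folds, seed=seeds["search"])
    models = {}
    models_dir = out / "models"
    for target in config.targets:
        y = train_table[target].to_numpy().astype(int)
        if y.sum() == 0 or y.sum() == len(y):
            log_event("train_skipped", target=target, reason="single-class training labels")
            continue
        model = tune_and_train(train_table, target, search)
        save_model(model, models_dir / target)
        models[target] = model
        log_event(
            "train", target=target, cv_ap=float(np.mean(model.cv_ap)),
            pos_weight=model.pos_weight, params=model.params,
        )

    # --- predict + evaluate -----------------------------------------------
    pred_frames = [predict_patients(m, test_table) for m in models.values()]
    predictions = (
        pd.concat(pred_frames, ignore_index=True)
        if pred_frames
        else pd.DataFrame(columns=["patient_id", "target", "prediction"])
    )
    predictions.to_csv(out / "predictions.csv", index=False)
    report = evaluate_cohort(models, test_table, labels, out_csv=out / "report.csv")
    log_event("evaluate", targets=list(models))

    (out / "run_log.jsonl").write_text(
        "\n".join(json.dumps(e) for e in events) + "\n"
    )
    return out
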