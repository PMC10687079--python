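"""End-to-end orchestration: simulate/ingest → cross-validate → attribute → evaluate.

A :class:`RunConfig` (YAML-serialisable) fully determines a run; every output
file is stamped with the config hash and global seed so reruns are traceable
and deterministic outputs reproduce exactly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import attribution as attr
from .data import ConnectivityDataset
from .evaluation import hellinger_distance
from .fc import matricize_lower_triangle, n_features as tri_features
from .harmonise import combat_fit, remove_site_effects
from .model import VARIANTS
from .synthetic import SyntheticSpec, generate_multisite_dataset
from .training import TrainConfig, cross_validate


@dataclass
class RunConfig:
    output_dir: str = "connharm_run"
    variant: str = "shred_iii"
    seed: int = 0
    manifest: str | None = None            # ingest real/exported data ...
    features: str | None = None
    synthetic: dict = field(default_factory=dict)   # ... or simulate
    train: dict = field(default_factory=dict)
    attribution_steps: int = 100
    top_fraction: float = 0.01
    hellinger_features: int = 50
    save_models: bool = False

    def validate(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; one of {VARIANTS}")
        if (self.manifest is None) != (self.features is None):
            raise ValueError("manifest and features must be given together")
        for p in (self.manifest, self.features):
            if p is not None and not Path(p).exists():
                raise ValueError(f"input path does not exist: {p}")
        TrainConfig(**{"seed": self.seed, **self.train})

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls(**payload)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def _load_dataset(config: RunConfig) -> ConnectivityDataset:
    if config.manifest is not None:
        return ConnectivityDataset.load(config.manifest, config.features)
    spec = SyntheticSpec(**{"seed": config.seed, **config.synthetic})
    return generate_multisite_dataset(spec).dataset


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline; returns a summary dict (also written to disk)."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = {"config_hash": config.config_hash(), "seed": config.seed}
    config.to_yaml(out / "config.yaml")

    def _stage(name, fn):
        try:
            return fn()
        except Exception as exc:
            (out / "FAILED").write_text(f"stage {name}: {exc}\n")
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    dataset = _stage("ingest", lambda: _load_dataset(config))
    dataset.save(out / "manifest.tsv", out / "features.tsv")

    train_cfg = TrainConfig(**{"seed": config.seed, **config.train})
    cv = _stage("crossval", lambda: cross_validate(dataset, train_cfg, config.variant))
    metrics = cv.metrics_frame()
    metrics.to_csv(out / "cv_metrics.tsv", sep="\t", index=False)
    if config.save_models:
        for r in cv.records:
            r.trained.model.save(out / f"model_seed{r.seed_index}_fold{r.fold}.json")

    def _attribute():
        groups = []
        for r in cv.records:
            train_split = dataset.subset(r.train_idx)
            test_split = dataset.subset(r.test_idx)
            baseline = attr.compute_baseline(train_split)
            scores = attr.attribute_subjects(r.trained, test_split, baseline,
                                             steps=config.attribution_steps)
            groups.append(attr.group_attribution(scores, test_split.diagnosis))
        return attr.aggregate_standardise(groups)

    aggregate = _stage("attribute", _attribute)
    pd.DataFrame({"feature": np.arange(aggregate.size), "score": aggregate}).to_csv(
        out / "saliency_scores.tsv", sep="\t", index=False)
    r_est = int(round((1 + np.sqrt(1 + 8 * aggregate.size)) / 2))
    if tri_features(r_est) == aggregate.size:
        full = matricize_lower_triangle(aggregate, r_est, symmetric=False)
        np.savetxt(out / "saliency_matrix.tsv", full, delimiter="\t")
        filtered = attr.top_fraction_filter(full, config.top_fraction)
        np.savetxt(out / "saliency_matrix_top.tsv", filtered, delimiter="\t")

    def _evaluate():
        sites = dataset.sites
        if len(sites) < 2:
            return {}
        sub = np.arange(min(config.hellinger_features, dataset.n_features))
        params = combat_fit(dataset)
        from .data import DesignInfo
        design = DesignInfo.fit(dataset)
        harmonised = remove_site_effects(dataset.features, design.covariate_matrix(dataset),
                                         design.site_index(dataset), params)
        a, b = (dataset.site == sites[0]), (dataset.site == sites[1])
        pre = [hellinger_distance(dataset.features[a, v], dataset.features[b, v]) for v in sub]
        post = [hellinger_distance(harmonised[a, v], harmonised[b, v]) for v in sub]
        return {"hellinger_pre_mean": float(np.mean(pre)),
                "hellinger_post_mean": float(np.mean(post))}

    site_diag = _stage("evaluate", _evaluate)

    summary = {
        **stamp,
        "variant": config.variant,
        "n_subjects": dataset.n_subjects,
        "n_features": dataset.n_features,
        "n_models": cv.n_models,
        "metrics": {k: {"mean": v[0], "sd": v[1]} for k, v in cv.summary().items()},
        **site_diag,
    }
    with open(out / "run.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    return summary
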