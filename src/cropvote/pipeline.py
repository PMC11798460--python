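"""End-to-end run configuration and orchestration.

A :class:`RunConfig` mirrors every stage's parameters in nested sections and
expands one global seed into per-stage sub-seeds, so a YAML file plus a seed
fully reproduces a run. ``run_all`` executes
preprocess → balance → feature engineering → train → evaluate
and persists one artifact per stage under the output directory, keyed by the
config hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .balance import AdasynConfig
from .evaluation import FitResult, PipelineConfig, run_experiment
from .features import FeatureConfig
from .nets import TrainConfig
from .panel import CropPanel
from .synthetic import (
    CategoricalFeatureSpec,
    NumericFeatureSpec,
    PanelSpec,
    default_spec,
    generate_panel,
    inject_missing,
    inject_outliers,
)

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Nested run configuration; any omitted field takes the stage default."""

    simulate: dict = field(default_factory=dict)  # PanelSpec overrides
    input_csv: str | None = None
    schema: dict | None = None
    preprocess: dict = field(default_factory=dict)
    balance: dict = field(default_factory=dict)
    features: dict = field(default_factory=dict)
    models: dict = field(default_factory=dict)
    evaluation: dict = field(default_factory=dict)
    seed: int = 0
    output_dir: str = "runs"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config sections: {sorted(unknown)}")
        return cls(**raw)

    def config_hash(self) -> str:
        payload = {k: getattr(self, k) for k in self.__dataclass_fields__}
        return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[:16]

    def panel_spec(self) -> PanelSpec:
        over = dict(self.simulate)
        if "numeric_features" in over:
            over["numeric_features"] = [NumericFeatureSpec(**f) for f in over["numeric_features"]]
        if "categorical_features" in over:
            over["categorical_features"] = [
                CategoricalFeatureSpec(**f) for f in over["categorical_features"]
            ]
        over.setdefault("seed", self.seed)
        return default_spec(**over)

    def pipeline_config(self) -> PipelineConfig:
        return PipelineConfig(
            window=self.models.get("window", 4),
            adasyn=AdasynConfig(**{k: v for k, v in self.balance.items() if k != "enabled"}),
            features=FeatureConfig(**self.features),
            train=TrainConfig(**{k: v for k, v in self.models.items()
                                 if k in TrainConfig.__dataclass_fields__}),
            gru_hidden=self.models.get("gru_hidden", 16),
            cnn_dense=self.models.get("cnn_dense", 16),
            regression=self.evaluation.get("regression", False),
        )


def load_or_simulate(config: RunConfig) -> CropPanel:
    if config.input_csv:
        from .io import SchemaMap, read_panel_csv

        if not config.schema:
            raise ConfigError("input_csv requires a schema section")
        return read_panel_csv(config.input_csv, SchemaMap(**config.schema))
    spec = config.panel_spec()
    panel = generate_panel(spec)
    if spec.missing_rate > 0:
        panel = inject_missing(panel, spec.missing_rate, spec.seed + 1)
    if spec.outlier_rate > 0:
        panel, _ = inject_outliers(panel, spec.outlier_rate, spec.outlier_magnitude_sd,
                                   spec.seed + 2)
    return panel


def run_all(config: RunConfig) -> FitResult:
    """Execute the full pipeline and persist per-stage artifacts."""
    out = Path(config.output_dir) / config.config_hash()
    out.mkdir(parents=True, exist_ok=True)
    stage = "simulate/ingest"
    try:
        panel = load_or_simulate(config)
        panel.to_csv(out / "panel.csv")

        stage = "pipeline"
        result = run_experiment(
            panel,
            config.pipeline_config(),
            test_fraction=config.evaluation.get("test_fraction", 0.2),
            seed=config.seed,
        )

        stage = "persist"
        (out / "preprocess_params.json").write_text(result.split.params.to_json())
        prov = pd.DataFrame(result.split.adasyn.provenance,
                            columns=["parent", "neighbor", "delta"])
        prov.to_csv(out / "adasyn_provenance.csv", index=False)
        (out / "feature_report.json").write_text(result.feature_report.to_json())
        for i, model in enumerate(result.models):
            model.save(out / f"model_{i}")
        (out / "evaluation_report.json").write_text(result.report.to_json())
        (out / "evaluation_report.txt").write_text(result.report.to_text())
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}; artifacts so far in {out}") from exc
    logger.info("run complete; artifacts in %s", out)
    return result


def plot_feature_ranking(feature_report, path) -> None:
    """Bar chart of Rising-Star scores, ranked."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    names = feature_report.ranked
    scores = [feature_report.scores[n] for n in names]
    fig, ax = plt.subplots(figsize=(max(4, 0.5 * len(names)), 3))
    ax.bar(range(len(names)), scores)
    ax.set_xticks(range(len(names)))
    ax.set_xticklabels(names, rotation=45, ha="right")
    ax.set_ylabel("Rising-Star score")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
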