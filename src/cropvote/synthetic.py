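"""Synthetic crop-panel generator.

Emulates the statistical structure of real regional yield panels — per-region
temporally autocorrelated weather/soil covariates, categorical management
effects, class imbalance between high- and low-yield region-years, missing
cells and outliers — so the whole pipeline can be exercised and tested
without external data.

The latent yield is linear in the features plus categorical level offsets and
Gaussian noise; the binary label marks region-years whose yield falls below a
quantile threshold (label 1 = minority, low-yield class). Missingness is
injected completely at random; outliers are additive shifts of several
feature standard deviations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import LABEL_COLUMN, YIELD_COLUMN, CropPanel

logger = logging.getLogger(__name__)

#: baseline yield level (tons/hectare) around which the latent signal varies
BASE_YIELD = 5.0


class SpecError(ValueError):
    """A PanelSpec field is out of its valid range."""


@dataclass
class NumericFeatureSpec:
    name: str
    mean: float = 0.0
    sd: float = 1.0
    ar1: float = 0.5  # AR(1) coefficient of the per-region series, in [0, 1)


@dataclass
class CategoricalFeatureSpec:
    name: str
    levels: list[str]
    offsets: list[float]  # per-level additive yield offset, tons/hectare

    def __post_init__(self) -> None:
        if len(self.levels) != len(self.offsets):
            raise SpecError(f"{self.name}: levels and offsets differ in length")


@dataclass
class PanelSpec:
    """Parameters of the synthetic data-generating process."""

    n_regions: int = 20
    n_steps: int = 10
    numeric_features: list[NumericFeatureSpec] = field(default_factory=list)
    categorical_features: list[CategoricalFeatureSpec] = field(default_factory=list)
    signal_weights: dict[str, float] = field(default_factory=dict)
    noise_sd: float = 1.0
    class_rule: float = 0.2  # yield quantile below which label = 1
    minority_fraction: float = 0.2
    missing_rate: float = 0.0
    outlier_rate: float = 0.0
    outlier_magnitude_sd: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_regions < 1:
            raise SpecError("n_regions must be a positive integer")
        if self.n_steps < 1:
            raise SpecError("n_steps must be a positive integer")
        if self.n_regions * self.n_steps < 10:
            raise SpecError("n_regions * n_steps must be at least 10")
        for f in self.numeric_features:
            if not (0.0 <= f.ar1 < 1.0):
                raise SpecError(f"numeric_features[{f.name}].ar1 must be in [0, 1)")
            if f.sd < 0:
                raise SpecError(f"numeric_features[{f.name}].sd must be nonnegative")
        if self.noise_sd < 0:
            raise SpecError("noise_sd must be nonnegative")
        if not (0.0 < self.class_rule < 1.0):
            raise SpecError("class_rule must be a quantile in (0, 1)")
        if not (0.0 < self.minority_fraction <= 0.5):
            raise SpecError("minority_fraction must be in (0, 0.5]")
        if not (0.0 <= self.missing_rate < 1.0):
            raise SpecError("missing_rate must be in [0, 1)")
        if not (0.0 <= self.outlier_rate < 1.0):
            raise SpecError("outlier_rate must be in [0, 1)")

    @property
    def n_rows(self) -> int:
        return self.n_regions * self.n_steps


def default_spec(**overrides) -> PanelSpec:
    """A realistic small panel: three weather/soil drivers plus noise."""
    base = dict(
        numeric_features=[
            NumericFeatureSpec("rainfall", mean=60.0, sd=15.0, ar1=0.6),
            NumericFeatureSpec("temperature", mean=22.0, sd=3.0, ar1=0.7),
            NumericFeatureSpec("soil_moisture", mean=0.3, sd=0.08, ar1=0.8),
        ],
        signal_weights={"rainfall": 0.04, "temperature": -0.15, "soil_moisture": 4.0},
        noise_sd=0.5,
    )
    base.update(overrides)
    return PanelSpec(**base)


def signal_spec(
    n_regions: int = 100,
    n_steps: int = 20,
    n_informative: int = 3,
    n_noise: int = 7,
    effect: float = 2.0,
    minority_fraction: float = 0.2,
    seed: int = 0,
    **overrides,
) -> PanelSpec:
    """A strong-signal benchmark panel: planted informative features.

    Each informative feature is a unit-sd AR(1) series contributing
    ``effect`` noise standard deviations to the latent yield (noise_sd = 1),
    so the per-feature standardized effect equals ``effect``; the noise
    features carry zero weight. Used as the signal-recovery fixture: a sound
    pipeline must rank the informative features first and classify well.
    """
    numeric = [
        NumericFeatureSpec(f"inf{i}", mean=0.0, sd=1.0, ar1=0.5) for i in range(n_informative)
    ] + [NumericFeatureSpec(f"noise{i}", mean=0.0, sd=1.0, ar1=0.5) for i in range(n_noise)]
    weights = {f"inf{i}": effect for i in range(n_informative)}
    return PanelSpec(
        n_regions=n_regions,
        n_steps=n_steps,
        numeric_features=numeric,
        signal_weights=weights,
        noise_sd=1.0,
        class_rule=minority_fraction,
        minority_fraction=minority_fraction,
        seed=seed,
        **overrides,
    )


def null_spec(n_regions: int = 30, n_steps: int = 10, seed: int = 0, **overrides) -> PanelSpec:
    """A no-signal null panel: all signal weights zero, balanced classes.

    With zero weights the labels are pure noise, so any legitimate pipeline
    must score at chance. The null uses minority_fraction = 0.5 so that the
    majority rate equals the chance level and a two-sided comparison against
    it is meaningful.
    """
    numeric = [NumericFeatureSpec(f"x{i}", mean=0.0, sd=1.0, ar1=0.5) for i in range(5)]
    return PanelSpec(
        n_regions=n_regions,
        n_steps=n_steps,
        numeric_features=numeric,
        signal_weights={},
        noise_sd=1.0,
        class_rule=0.5,
        minority_fraction=0.5,
        seed=seed,
        **overrides,
    )


def _ar1_series(rng: np.random.Generator, n: int, mean: float, sd: float, ar1: float) -> np.ndarray:
    """Stationary AR(1) around `mean` with marginal sd `sd`."""
    x = np.empty(n)
    x[0] = mean + sd * rng.standard_normal()
    innov_sd = sd * np.sqrt(1.0 - ar1 * ar1)
    for t in range(1, n):
        x[t] = mean + ar1 * (x[t - 1] - mean) + innov_sd * rng.standard_normal()
    return x


def generate_panel(spec: PanelSpec) -> CropPanel:
    """Draw a panel from the spec's data-generating process.

    Deterministic given ``spec.seed``. The label is 1 where latent yield
    falls below the ``class_rule`` quantile; labels nearest the threshold
    are then flipped so the minority share equals ``minority_fraction``
    within one row.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_rows
    regions = [f"R{r:03d}" for r in range(spec.n_regions)]

    data: dict[str, np.ndarray | list] = {
        "region_id": np.repeat(regions, spec.n_steps),
        "t": np.tile(np.arange(spec.n_steps), spec.n_regions),
    }
    for f in spec.numeric_features:
        cols = [
            _ar1_series(rng, spec.n_steps, f.mean, f.sd, f.ar1)
            for _ in range((spec.n_regions))
        ]
        data[f.name] = np.concatenate(cols)
    for c in spec.categorical_features:
        # categorical attributes (variety, soil type) are constant per region
        region_levels = rng.integers(0, len(c.levels), size=spec.n_regions)
        data[c.name] = [c.levels[i] for i in np.repeat(region_levels, spec.n_steps)]

    latent = np.full(n, BASE_YIELD)
    for name, w in spec.signal_weights.items():
        latent = latent + w * np.asarray(data[name], dtype=float)
    for c in spec.categorical_features:
        offs = dict(zip(c.levels, c.offsets))
        latent = latent + np.array([offs[v] for v in data[c.name]])
    latent = latent + spec.noise_sd * rng.standard_normal(n)
    data[YIELD_COLUMN] = latent

    threshold = np.quantile(latent, spec.class_rule)
    label = (latent < threshold).astype(int)
    label = _force_minority_count(label, latent, threshold, spec.minority_fraction)
    data[LABEL_COLUMN] = label

    df = pd.DataFrame(data)
    return CropPanel(
        df,
        numeric_features=[f.name for f in spec.numeric_features],
        categorical_features=[c.name for c in spec.categorical_features],
    )


def _force_minority_count(
    label: np.ndarray, latent: np.ndarray, threshold: float, minority_fraction: float
) -> np.ndarray:
    """Flip labels of rows nearest the threshold until the minority share
    equals round(minority_fraction * n)."""
    label = label.copy()
    n = len(label)
    target = int(round(minority_fraction * n))
    count = int(label.sum())
    if count == target:
        return label
    dist = np.abs(latent - threshold)
    if count < target:
        candidates = np.flatnonzero(label == 0)
        order = candidates[np.argsort(dist[candidates], kind="stable")]
        label[order[: target - count]] = 1
    else:
        candidates = np.flatnonzero(label == 1)
        order = candidates[np.argsort(dist[candidates], kind="stable")]
        label[order[: count - target]] = 0
    return label


def inject_missing(panel: CropPanel, rate: float, seed: int) -> CropPanel:
    """Blank out numeric feature cells completely at random.

    Each numeric cell is masked independently with probability ``rate``.
    Keys, categorical features, yield and labels are never masked.
    """
    if not (0.0 <= rate < 1.0):
        raise SpecError("missing rate must be in [0, 1)")
    out = panel.copy()
    if rate == 0.0 or not panel.numeric_features:
        return out
    rng = np.random.default_rng(seed)
    block = out.df[panel.numeric_features].to_numpy(dtype=float)
    mask = rng.random(block.shape) < rate
    block[mask] = np.nan
    out.df[panel.numeric_features] = block
    return out


def inject_outliers(
    panel: CropPanel, rate: float, magnitude_sd: float, seed: int
) -> tuple[CropPanel, list[tuple[int, str]]]:
    """Shift random numeric cells by ±magnitude_sd feature standard deviations.

    Returns the perturbed panel and the list of injected (row, column)
    positions so tests can assert against them.
    """
    if not (0.0 <= rate < 1.0):
        raise SpecError("outlier rate must be in [0, 1)")
    if magnitude_sd <= 0:
        raise SpecError("outlier magnitude_sd must be positive")
    out = panel.copy()
    positions: list[tuple[int, str]] = []
    if rate == 0.0 or not panel.numeric_features:
        return out, positions
    rng = np.random.default_rng(seed)
    for col in panel.numeric_features:
        values = out.df[col].to_numpy(dtype=float)
        sd = np.nanstd(values)
        if sd == 0 or not np.isfinite(sd):
            continue
        hit = np.flatnonzero(rng.random(len(values)) < rate)
        signs = rng.choice([-1.0, 1.0], size=len(hit))
        values[hit] = values[hit] + signs * magnitude_sd * sd
        out.df[col] = values
        positions.extend((int(i), col) for i in hit)
    logger.debug("injected %d outlier cells", len(positions))
    return out, positions
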