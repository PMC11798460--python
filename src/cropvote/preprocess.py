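"""Preprocessing: imputation, outlier winsorization, min-max scaling, one-hot.

All statistics are fitted on the training split only and stored in
:class:`PreprocessParams`, which then transforms any split identically —
the test split never contributes to a fence, a median, a vocabulary or a
scaling range.

Conventions:

* temporal numeric features are imputed by per-region linear interpolation
  over the time index (edges take the nearest observed value); static
  numerics use the training median and categoricals the training mode;
* outliers are winsorized to 1.5×IQR fences (clipping keeps the row — yield
  panels are small and rows are precious);
* min-max maps each feature to [0, 1] on the training data via
  (X − X_min)/(X_max − X_min); unseen data may land outside [0, 1] and is
  deliberately not clipped; a constant (degenerate-range) feature maps to 0;
* one-hot encodes each categorical against the training vocabulary; an
  unknown test-time level becomes the all-zero vector with a warning.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import CropPanel, PanelError

logger = logging.getLogger(__name__)

IQR_FACTOR = 1.5


class PreprocessError(ValueError):
    pass


@dataclass
class NumericParams:
    minimum: float
    maximum: float
    median: float
    fence_lower: float
    fence_upper: float
    degenerate: bool  # max == min on training data


@dataclass
class PreprocessParams:
    """Fitted state enabling identical transforms of unseen data."""

    numeric: dict[str, NumericParams] = field(default_factory=dict)
    vocabularies: dict[str, list[str]] = field(default_factory=dict)
    modes: dict[str, str] = field(default_factory=dict)
    temporal: list[str] = field(default_factory=list)  # interpolated features
    time_grid: tuple[int, int, int] = (0, 0, 1)

    def __post_init__(self) -> None:
        for name, p in self.numeric.items():
            if p.maximum < p.minimum:
                raise PreprocessError(f"{name}: max < min")
            if p.fence_upper < p.fence_lower:
                raise PreprocessError(f"{name}: fences inverted")
        for name, vocab in self.vocabularies.items():
            if not vocab:
                raise PreprocessError(f"{name}: empty vocabulary")

    # -- JSON round trip ----------------------------------------------------

    def to_json(self) -> str:
        payload = {
            "numeric": {k: vars(v) for k, v in self.numeric.items()},
            "vocabularies": self.vocabularies,
            "modes": self.modes,
            "temporal": self.temporal,
            "time_grid": list(self.time_grid),
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "PreprocessParams":
        raw = json.loads(text)
        return cls(
            numeric={k: NumericParams(**v) for k, v in raw["numeric"].items()},
            vocabularies=raw["vocabularies"],
            modes=raw["modes"],
            temporal=raw["temporal"],
            time_grid=tuple(raw["time_grid"]),
        )

    def one_hot_columns(self, feature: str) -> list[str]:
        return [f"{feature}={level}" for level in self.vocabularies[feature]]


def fit_preprocess(panel: CropPanel, temporal: list[str] | None = None) -> PreprocessParams:
    """Fit imputation statistics, IQR fences, min-max ranges and vocabularies.

    ``temporal`` names the numeric features to impute by within-region
    interpolation (default: all numeric features). The min-max range is
    computed after imputation and winsorization so that the training data
    itself maps exactly onto [0, 1].
    """
    if temporal is None:
        temporal = list(panel.numeric_features)
    unknown = set(temporal) - set(panel.numeric_features)
    if unknown:
        raise PreprocessError(f"temporal features not in panel: {sorted(unknown)}")

    params = PreprocessParams(temporal=list(temporal))
    t = panel.df["t"].to_numpy()
    params.time_grid = (int(t.min()), int(t.max()), 1)

    # first pass: medians and fences from observed values
    for name in panel.numeric_features:
        observed = panel.df[name].to_numpy(dtype=float)
        observed = observed[np.isfinite(observed)]
        if observed.size == 0:
            raise PreprocessError(f"feature {name!r} is entirely missing")
        if observed.size < 2:
            raise PreprocessError(f"feature {name!r} has fewer than 2 observed values")
        q1, q3 = np.quantile(observed, [0.25, 0.75])
        iqr = q3 - q1
        params.numeric[name] = NumericParams(
            minimum=np.nan,
            maximum=np.nan,
            median=float(np.median(observed)),
            fence_lower=float(q1 - IQR_FACTOR * iqr),
            fence_upper=float(q3 + IQR_FACTOR * iqr),
            degenerate=False,
        )

    for name in panel.categorical_features:
        values = panel.df[name].dropna()
        if values.empty:
            raise PreprocessError(f"categorical feature {name!r} is entirely missing")
        params.vocabularies[name] = sorted(values.astype(str).unique())
        params.modes[name] = str(values.mode(dropna=True).iloc[0])

    # second pass: min-max on the imputed + winsorized training data
    work = treat_outliers(impute(panel, params), params)
    for name in panel.numeric_features:
        col = work.df[name].to_numpy(dtype=float)
        lo, hi = float(col.min()), float(col.max())
        p = params.numeric[name]
        p.minimum, p.maximum = lo, hi
        p.degenerate = hi == lo
        if p.degenerate:
            logger.info("feature %s has degenerate (constant) range on training data", name)
    return params


def impute(panel: CropPanel, params: PreprocessParams) -> CropPanel:
    """Fill missing cells; no missing values remain afterwards."""
    out = panel.copy()
    for name in panel.numeric_features:
        median = params.numeric[name].median
        if name in params.temporal:
            filled = out.df.groupby("region_id", sort=False, group_keys=False)[
                ["t", name]
            ].apply(lambda g, n=name: _interp_region(g, n))
            col = filled[name].to_numpy(dtype=float)
        else:
            col = out.df[name].to_numpy(dtype=float)
        still = ~np.isfinite(col)
        if still.any():
            warnings.warn(
                f"feature {name!r}: {int(still.sum())} cells fell back to the "
                "global training median",
                stacklevel=2,
            )
            col[still] = median
        out.df[name] = col
    for name in panel.categorical_features:
        col = out.df[name]
        if col.isna().any():
            out.df[name] = col.fillna(params.modes[name])
    return out


def _interp_region(group: pd.DataFrame, name: str) -> pd.DataFrame:
    g = group.sort_values("t")
    y = g[name].to_numpy(dtype=float)
    ok = np.isfinite(y)
    if ok.any() and not ok.all():
        # np.interp handles edges by clamping to nearest observed value
        y[~ok] = np.interp(g["t"].to_numpy()[~ok], g["t"].to_numpy()[ok], y[ok])
    g[name] = y
    return g.loc[group.index]


def treat_outliers(panel: CropPanel, params: PreprocessParams) -> CropPanel:
    """Winsorize numeric features to their training 1.5×IQR fences."""
    out = panel.copy()
    clipped = 0
    for name in panel.numeric_features:
        p = params.numeric[name]
        col = out.df[name].to_numpy(dtype=float)
        finite = np.isfinite(col)
        outside = finite & ((col < p.fence_lower) | (col > p.fence_upper))
        clipped += int(outside.sum())
        col[finite] = np.clip(col[finite], p.fence_lower, p.fence_upper)
        out.df[name] = col
    logger.debug("winsorized %d cells", clipped)
    return out


def count_out_of_fence(panel: CropPanel, params: PreprocessParams) -> int:
    total = 0
    for name in panel.numeric_features:
        p = params.numeric[name]
        col = panel.df[name].to_numpy(dtype=float)
        finite = np.isfinite(col)
        total += int((finite & ((col < p.fence_lower) | (col > p.fence_upper))).sum())
    return total


def apply_minmax(panel: CropPanel, params: PreprocessParams) -> CropPanel:
    out = panel.copy()
    for name in panel.numeric_features:
        p = params.numeric[name]
        col = out.df[name].to_numpy(dtype=float)
        if p.degenerate:
            out.df[name] = np.zeros_like(col)
        else:
            out.df[name] = (col - p.minimum) / (p.maximum - p.minimum)
    return out


def invert_minmax(panel: CropPanel, params: PreprocessParams) -> CropPanel:
    out = panel.copy()
    for name in panel.numeric_features:
        p = params.numeric[name]
        col = out.df[name].to_numpy(dtype=float)
        if p.degenerate:
            out.df[name] = np.full_like(col, p.minimum)
        else:
            out.df[name] = col * (p.maximum - p.minimum) + p.minimum
    return out


def one_hot(panel: CropPanel, params: PreprocessParams) -> CropPanel:
    """Expand categoricals into binary indicator columns.

    Known levels activate exactly one indicator; an unknown test-time level
    yields the all-zero vector (and a warning) so column geometry is stable.
    """
    out = panel.copy()
    new_numeric = list(out.numeric_features)
    for name in panel.categorical_features:
        vocab = params.vocabularies[name]
        values = out.df[name].astype(str)
        unknown = ~values.isin(vocab)
        if unknown.any():
            warnings.warn(
                f"categorical {name!r}: {int(unknown.sum())} rows carry levels "
                "unseen in training; encoded as all-zero",
                stacklevel=2,
            )
        for level in vocab:
            out.df[f"{name}={level}"] = (values == level).astype(float)
        out.df = out.df.drop(columns=[name])
        new_numeric.extend(params.one_hot_columns(name))
    out.numeric_features = new_numeric
    out.categorical_features = []
    return out


def transform(panel: CropPanel, params: PreprocessParams) -> CropPanel:
    """Full fitted transform: impute → winsorize → min-max → one-hot."""
    return one_hot(apply_minmax(treat_outliers(impute(panel, params), params), params), params)


def align_temporal(panels: list[CropPanel], grid: tuple[int, int] | None = None) -> CropPanel:
    """Outer-join panels from different sources onto one (region, t) grid.

    The joined table covers every region and every time step of the grid
    (default: the union of observed ranges); gaps are forward-filled per
    region and otherwise left missing for :func:`impute`.
    """
    if not panels:
        raise PreprocessError("align_temporal needs at least one panel")
    region_sets = [set(p.df["region_id"]) for p in panels]
    common = set.intersection(*region_sets)
    if not common:
        raise PanelError("panels share no region_id keys")
    if grid is None:
        t_min = min(int(p.df["t"].min()) for p in panels)
        t_max = max(int(p.df["t"].max()) for p in panels)
    else:
        t_min, t_max = grid
    regions = sorted(set.union(*region_sets))
    index = pd.MultiIndex.from_product(
        [regions, range(t_min, t_max + 1)], names=["region_id", "t"]
    )
    joined = pd.DataFrame(index=index)
    numeric: list[str] = []
    categorical: list[str] = []
    for p in panels:
        part = p.df.set_index(["region_id", "t"])
        overlap = [c for c in part.columns if c in joined.columns]
        part = part.drop(columns=overlap)
        joined = joined.join(part, how="left")
        numeric.extend(f for f in p.numeric_features if f in part.columns)
        categorical.extend(f for f in p.categorical_features if f in part.columns)
    joined = joined.groupby(level="region_id", sort=False).ffill()
    joined = joined.reset_index()
    return CropPanel(joined, numeric, categorical)
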