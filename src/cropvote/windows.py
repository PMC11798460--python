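"""Sliding-window construction: panels → (window, label) training samples.

Each region's time series yields windows of L consecutive steps; the window
predicts the label (and yield) at its final step. Windows never cross region
boundaries, so region-grouped splits keep every window of a region on one
side of the split.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import LABEL_COLUMN, YIELD_COLUMN, CropPanel


@dataclass
class WindowSet:
    X: np.ndarray  # n × L × F
    y: np.ndarray  # label at window end (or -1 when absent)
    yields: np.ndarray  # yield at window end
    regions: np.ndarray  # region of each window
    t_end: np.ndarray  # time index of each window's final step
    feature_columns: list[str]

    def __len__(self) -> int:
        return len(self.X)

    @property
    def flat(self) -> np.ndarray:
        """Windows flattened to n × (L·F) for distance-based operations."""
        n, L, F = self.X.shape
        return self.X.reshape(n, L * F)

    def flat_names(self) -> list[str]:
        L = self.X.shape[1]
        return [f"{c}@lag{L - 1 - l}" for l in range(L) for c in self.feature_columns]


def build_windows(panel: CropPanel, window: int, feature_columns: list[str] | None = None) -> WindowSet:
    """Cut per-region sliding windows of `window` consecutive time steps."""
    cols = feature_columns if feature_columns is not None else panel.feature_columns
    has_yield = YIELD_COLUMN in panel.df.columns
    xs, ys, yds, regs, tend = [], [], [], [], []
    for region, g in panel.df.groupby("region_id", sort=True):
        g = g.sort_values("t")
        M = g[cols].to_numpy(dtype=float)
        labels = g[LABEL_COLUMN].to_numpy() if panel.has_labels else None
        yvals = g[YIELD_COLUMN].to_numpy(dtype=float) if has_yield else None
        tvals = g["t"].to_numpy()
        for start in range(0, len(g) - window + 1):
            end = start + window
            xs.append(M[start:end])
            ys.append(int(labels[end - 1]) if labels is not None else -1)
            yds.append(float(yvals[end - 1]) if yvals is not None else np.nan)
            regs.append(region)
            tend.append(int(tvals[end - 1]))
    if not xs:
        raise ValueError(f"no region has {window} consecutive steps")
    return WindowSet(
        X=np.stack(xs),
        y=np.asarray(ys, dtype=int),
        yields=np.asarray(yds, dtype=float),
        regions=np.asarray(regs, dtype=object),
        t_end=np.asarray(tend, dtype=int),
        feature_columns=list(cols),
    )


def unflatten(flat: np.ndarray, window: int, n_features: int) -> np.ndarray:
    return flat.reshape(len(flat), window, n_features)


def select_feature_columns(ws: WindowSet, kept: list[str]) -> WindowSet:
    """Restrict a window set to the kept feature columns (order preserved)."""
    idx = [ws.feature_columns.index(c) for c in kept]
    return WindowSet(
        X=ws.X[:, :, idx],
        y=ws.y,
        yields=ws.yields,
        regions=ws.regions,
        t_end=ws.t_end,
        feature_columns=list(kept),
    )
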