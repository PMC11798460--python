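"""Long-format crop panel: the package's universal exchange object.

A panel holds one row per (region, time-step) with numeric agro-environmental
features (weather, soil, management), optional categorical features (crop
variety, soil type, ...), a yield value in tons/hectare, and an optional
binary class label. By convention label 1 marks the minority class
(e.g. low-yield region-years).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

KEY_COLUMNS = ("region_id", "t")
YIELD_COLUMN = "yield"
LABEL_COLUMN = "label"


class PanelError(ValueError):
    """Raised when a panel violates its structural invariants."""


@dataclass
class CropPanel:
    """A long-format (region, time) table plus its feature typing.

    Parameters
    ----------
    df
        Columns ``region_id``, ``t``, the features, ``yield`` and optionally
        ``label``. ``(region_id, t)`` pairs must be unique.
    numeric_features, categorical_features
        Names of the feature columns by kind. One-hot expansion replaces
        categorical names with indicator column names.
    """

    df: pd.DataFrame
    numeric_features: list[str] = field(default_factory=list)
    categorical_features: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for col in KEY_COLUMNS:
            if col not in self.df.columns:
                raise PanelError(f"panel is missing key column {col!r}")
        if self.df.duplicated(subset=list(KEY_COLUMNS)).any():
            raise PanelError("duplicate (region_id, t) pairs in panel")
        if LABEL_COLUMN in self.df.columns:
            labels = self.df[LABEL_COLUMN].dropna()
            if not labels.isin([0, 1]).all():
                raise PanelError("labels must be 0/1")

    @property
    def feature_columns(self) -> list[str]:
        return list(self.numeric_features) + list(self.categorical_features)

    @property
    def has_labels(self) -> bool:
        return LABEL_COLUMN in self.df.columns

    @property
    def n_rows(self) -> int:
        return len(self.df)

    def copy(self) -> "CropPanel":
        return CropPanel(
            self.df.copy(),
            list(self.numeric_features),
            list(self.categorical_features),
        )

    # -- CSV round trip (RFC-4180; missing cells as empty string) ----------

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False, na_rep="")

    @classmethod
    def from_csv(cls, path, numeric_features, categorical_features) -> "CropPanel":
        df = pd.read_csv(path)
        df["region_id"] = df["region_id"].astype(str)
        df["t"] = df["t"].astype(int)
        if LABEL_COLUMN in df.columns:
            df[LABEL_COLUMN] = df[LABEL_COLUMN].astype(int)
        return cls(df, list(numeric_features), list(categorical_features))

    def equals(self, other: "CropPanel") -> bool:
        """Value equality of the underlying tables (NaN == NaN)."""
        try:
            pd.testing.assert_frame_equal(
                self.df.reset_index(drop=True), other.df.reset_index(drop=True)
            )
        except AssertionError:
            return False
        return True


def numeric_matrix(panel: CropPanel, columns=None) -> np.ndarray:
    """Feature columns of the panel as a float matrix (NaN for missing)."""
    cols = list(columns) if columns is not None else panel.feature_columns
    return panel.df[cols].to_numpy(dtype=float)
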