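"""CSV ingest with schema mapping.

Real yield panels differ only in column names, units and dialect, so one
long-format reader plus a :class:`SchemaMap` covers them all. Example maps
for the three common shapes (US county corn/soy panels, FAO/World-Bank
country panels, global four-crop panels) are bundled as plain dictionaries.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import pandas as pd

from .panel import LABEL_COLUMN, YIELD_COLUMN, CropPanel, PanelError

logger = logging.getLogger(__name__)


class SchemaError(ValueError):
    pass


@dataclass
class SchemaMap:
    """Maps source CSV columns onto the canonical panel columns."""

    region: str
    time: str
    yield_col: str
    numeric_features: dict[str, str] = field(default_factory=dict)  # canonical → source
    categorical_features: dict[str, str] = field(default_factory=dict)
    label: str | None = None
    units_note: str = "tons/hectare assumed; verify against the source"
    delimiter: str = ","
    decimal: str = "."

    def __post_init__(self) -> None:
        mapped = (
            [self.region, self.time, self.yield_col]
            + list(self.numeric_features.values())
            + list(self.categorical_features.values())
        )
        if self.label:
            mapped.append(self.label)
        if len(mapped) != len(set(mapped)):
            raise SchemaError("mapped source columns must be distinct")


#: canonical identity schema written by CropPanel.to_csv
def identity_schema(numeric: list[str], categorical: list[str] | None = None,
                    with_label: bool = True) -> SchemaMap:
    return SchemaMap(
        region="region_id",
        time="t",
        yield_col=YIELD_COLUMN,
        numeric_features={c: c for c in numeric},
        categorical_features={c: c for c in (categorical or [])},
        label=LABEL_COLUMN if with_label else None,
    )


#: example maps for the three common public panel shapes
EXAMPLE_SCHEMAS: dict[str, SchemaMap] = {
    "us_county_corn_soy": SchemaMap(
        region="FIPS", time="year", yield_col="yield_bu_acre",
        numeric_features={"precip": "precip_mm", "tmax": "tmax_c", "tmin": "tmin_c"},
        categorical_features={"crop": "crop"},
        units_note="bushels/acre in source",
    ),
    "fao_worldbank": SchemaMap(
        region="Area", time="Year", yield_col="hg/ha_yield",
        numeric_features={"rainfall": "average_rain_fall_mm_per_year",
                          "pesticides": "pesticides_tonnes", "temperature": "avg_temp"},
        categorical_features={"crop": "Item"},
        units_note="hg/ha in source; units not stated authoritatively",
    ),
    "global_four_crop": SchemaMap(
        region="Entity", time="Year", yield_col="yield_t_ha",
        numeric_features={"area": "area_harvested_ha", "production": "production_t"},
        categorical_features={"crop": "crop"},
        units_note="tons/hectare",
    ),
}


def read_panel_csv(path, schema: SchemaMap) -> CropPanel:
    """Read a long-format CSV through a schema map into a typed panel.

    Rows whose yield cannot be parsed are dropped with a warning count;
    duplicate (region, time) pairs are an error.
    """
    # region identifiers are codes, not numbers: keep leading zeros (FIPS)
    df = pd.read_csv(path, sep=schema.delimiter, decimal=schema.decimal,
                     dtype={schema.region: str})
    needed = (
        [schema.region, schema.time, schema.yield_col]
        + list(schema.numeric_features.values())
        + list(schema.categorical_features.values())
        + ([schema.label] if schema.label else [])
    )
    for col in needed:
        if col not in df.columns:
            raise SchemaError(f"mapped column {col!r} not present in {path}")

    rename = {schema.region: "region_id", schema.time: "t", schema.yield_col: YIELD_COLUMN}
    rename.update({src: dst for dst, src in schema.numeric_features.items()})
    rename.update({src: dst for dst, src in schema.categorical_features.items()})
    if schema.label:
        rename[schema.label] = LABEL_COLUMN
    out = df[needed].rename(columns=rename)

    out["region_id"] = out["region_id"].astype(str)
    out["t"] = pd.to_numeric(out["t"], errors="raise").astype(int)
    out[YIELD_COLUMN] = pd.to_numeric(out[YIELD_COLUMN], errors="coerce")
    bad = out[YIELD_COLUMN].isna() & df[schema.yield_col].notna()
    dropped = int(out[YIELD_COLUMN].isna().sum())
    if dropped:
        warnings.warn(f"dropped {dropped} rows with unparseable/missing yield "
                      f"({int(bad.sum())} unparseable)", stacklevel=2)
        out = out[out[YIELD_COLUMN].notna()].reset_index(drop=True)
    for c in schema.numeric_features:
        out[c] = pd.to_numeric(out[c], errors="coerce")
    if schema.label:
        out[LABEL_COLUMN] = out[LABEL_COLUMN].astype(int)
    if out.duplicated(subset=["region_id", "t"]).any():
        raise PanelError(f"duplicate (region, time) pairs in {path}")
    return CropPanel(out, list(schema.numeric_features), list(schema.categorical_features))
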