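"""Sample tables, feature layers, distances and descriptive statistics.

Input conventions
-----------------
* Sample tables are delimited text (CSV/TSV) with a header row naming
  ``site_id, x, y, altitude``, then element concentration columns (mg/kg),
  then optional ``AD_<element>`` atmospheric-deposition columns (ug/m2/day).
* Coordinates are planar meters.  Geographic (lon/lat) input must be
  projected upstream; all distances here are Euclidean.
* Feature layers are GeoJSON FeatureCollections whose Features carry a
  ``category`` property from the closed set
  {chemical_factory, metal_factory, nonmetal_factory, road, river} and a
  Point or LineString geometry in the same planar CRS as the samples.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry

__all__ = [
    "CATEGORIES",
    "FACTORY_CATEGORIES",
    "SchemaError",
    "ValidationError",
    "SampleTable",
    "FeatureLayer",
    "DistanceSet",
    "BackgroundTable",
    "read_samples",
    "read_feature_layers",
    "write_feature_layers",
    "min_distances",
    "describe",
    "load_hunan_background",
    "load_study_statistics",
]

FACTORY_CATEGORIES = ("chemical_factory", "metal_factory", "nonmetal_factory")
CATEGORIES = FACTORY_CATEGORIES + ("road", "river")

#: elements usable as a crustal reference
REFERENCE_CANDIDATES = ("Ca", "Mg", "Zn")

_MANDATORY = ("site_id", "x", "y", "altitude")


class SchemaError(ValueError):
    """A required column is missing or mis-typed."""


class ValidationError(ValueError):
    """A value violates a table invariant (e.g. non-positive concentration)."""


@dataclass
class SampleTable:
    """Per-site coordinates, altitude and element concentrations.

    Parameters
    ----------
    data : DataFrame indexed by ``site_id`` with columns ``x, y, altitude``,
        one column per element (mg/kg) and optional ``AD_<element>`` columns
        (ug/m2/day).
    elements : measured element names, in column order.
    """

    data: pd.DataFrame
    elements: list[str]
    rejected: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate site_id values: {dups}")
        for col in ("x", "y", "altitude"):
            if col not in df.columns:
                raise SchemaError(f"missing mandatory column {col!r}")
            if not np.isfinite(df[col].to_numpy(float)).all():
                raise ValidationError(f"non-finite values in column {col!r}")
        missing = [e for e in self.elements if e not in df.columns]
        if missing:
            raise SchemaError(f"missing element columns: {missing}")
        for e in self.elements:
            vals = df[e].to_numpy(float)
            bad = ~(vals > 0)
            if bad.any():
                site = df.index[bad][0]
                raise ValidationError(
                    f"non-positive concentration for element {e!r} at site {site!r}"
                )
        if not any(c in self.elements for c in REFERENCE_CANDIDATES):
            raise ValidationError(
                "element set contains no crustal-reference candidate "
                f"(one of {REFERENCE_CANDIDATES} required)"
            )

    def __len__(self) -> int:
        return len(self.data)

    @property
    def site_ids(self) -> list:
        return list(self.data.index)

    @property
    def coords(self) -> np.ndarray:
        return self.data[["x", "y"]].to_numpy(float)

    @property
    def deposition_elements(self) -> list[str]:
        return [c[3:] for c in self.data.columns if c.startswith("AD_")]

    def concentrations(self, elements: Sequence[str] | None = None) -> pd.DataFrame:
        return self.data[list(elements or self.elements)]

    def deposition(self, element: str) -> pd.Series:
        col = f"AD_{element}"
        if col not in self.data.columns:
            raise KeyError(f"no deposition column for element {element!r}")
        return self.data[col]

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index_label="site_id")


@dataclass
class FeatureLayer:
    """Typed point/polyline geometries (factories, roads, rivers)."""

    category: str
    geometries: list[BaseGeometry]
    feature_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValidationError(
                f"unknown category {self.category!r}; expected one of {CATEGORIES}"
            )
        for geom in self.geometries:
            if geom.is_empty:
                raise ValidationError(f"empty geometry in layer {self.category!r}")
            if geom.geom_type == "LineString" and len(geom.coords) < 2:
                raise ValidationError("polyline with fewer than 2 vertices")
        if not self.feature_ids:
            self.feature_ids = [
                f"{self.category}_{i}" for i in range(len(self.geometries))
            ]

    def __len__(self) -> int:
        return len(self.geometries)


@dataclass
class DistanceSet:
    """Shortest Euclidean distance from each site to each feature category.

    ``distances`` has one column per category that has at least one feature;
    categories with zero features are listed in ``absent`` rather than being
    reported as zero.
    """

    distances: pd.DataFrame
    absent: list[str] = field(default_factory=list)

    def __getitem__(self, category: str) -> pd.Series:
        if category in self.absent:
            raise KeyError(f"category {category!r} has no features; distance absent")
        return self.distances[category]

    @property
    def categories(self) -> list[str]:
        return list(self.distances.columns)


@dataclass
class BackgroundTable:
    """Per-element background (crustal/regional) and risk-screening values."""

    data: pd.DataFrame  # index element; columns background, screening, source_label

    def __post_init__(self) -> None:
        bg = self.data["background"].to_numpy(float)
        if not (bg > 0).all():
            raise ValidationError("background values must be > 0")
        scr = self.data["screening"].to_numpy(float)
        if not ((scr > 0) | np.isnan(scr)).all():
            raise ValidationError("screening values must be > 0 where present")

    @classmethod
    def from_csv(cls, path) -> "BackgroundTable":
        df = pd.read_csv(path)
        if "element" not in df.columns or "background" not in df.columns:
            raise SchemaError("background table needs 'element' and 'background' columns")
        df = df.set_index("element")
        if "screening" not in df.columns:
            df["screening"] = np.nan
        if "source_label" not in df.columns:
            df["source_label"] = "national"
        return cls(df[["background", "screening", "source_label"]])

    def background(self, element: str) -> float:
        try:
            return float(self.data.loc[element, "background"])
        except KeyError:
            raise KeyError(f"no background value for element {element!r}") from None

    def screening(self, element: str) -> float:
        return float(self.data.loc[element, "screening"])


def load_hunan_background() -> BackgroundTable:
    """Bundled Hunan provincial background + national risk-screening values."""
    with resources.files("soilsource.data").joinpath("hunan_background.csv").open() as fh:
        return BackgroundTable.from_csv(fh)


def load_study_statistics() -> pd.DataFrame:
    """Bundled published descriptive statistics of the motivating survey
    (109 paddy-field topsoils, Chang-Zhu-Tan region; raw data restricted)."""
    path = resources.files("soilsource.data").joinpath("study_descriptive_stats.csv")
    with path.open() as fh:
        return pd.read_csv(fh).set_index("element")


def read_samples(path, schema: Sequence[str]) -> SampleTable:
    """Read and validate a delimited sample table.

    Rows missing any mandatory field (coordinates, altitude, or a
    concentration for an element in ``schema``) are rejected; the rejected
    rows are kept on ``SampleTable.rejected`` and reported via a warning.
    A missing mandatory *column* raises :class:`SchemaError`.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    for col in _MANDATORY:
        if col not in df.columns:
            raise SchemaError(f"missing mandatory column {col!r}")
    missing_cols = [e for e in schema if e not in df.columns]
    if missing_cols:
        raise SchemaError(f"missing element columns: {missing_cols}")
    mandatory = list(_MANDATORY) + list(schema)
    bad = df[mandatory].isna().any(axis=1)
    rejected = df[bad]
    if bad.any():
        warnings.warn(
            f"rejected {int(bad.sum())} row(s) with missing mandatory fields: "
            f"{rejected['site_id'].tolist()}",
            stacklevel=2,
        )
    df = df[~bad].set_index("site_id")
    return SampleTable(df, list(schema), rejected=rejected if bad.any() else None)


def read_feature_layers(path) -> dict[str, FeatureLayer]:
    """Read a GeoJSON FeatureCollection into per-category layers."""
    if hasattr(path, "read"):
        gj = json.load(path)
    else:
        with open(path) as fh:
            gj = json.load(fh)
    if gj.get("type") != "FeatureCollection":
        raise SchemaError("expected a GeoJSON FeatureCollection")
    geoms: dict[str, list[BaseGeometry]] = {}
    ids: dict[str, list[str]] = {}
    for i, feat in enumerate(gj.get("features", [])):
        cat = feat.get("properties", {}).get("category")
        if cat not in CATEGORIES:
            raise ValidationError(f"feature {i} has unknown category {cat!r}")
        geoms.setdefault(cat, []).append(shape(feat["geometry"]))
        ids.setdefault(cat, []).append(
            str(feat.get("properties", {}).get("feature_id", f"{cat}_{i}"))
        )
    return {
        cat: FeatureLayer(cat, geoms[cat], ids[cat]) for cat in sorted(geoms)
    }


def write_feature_layers(layers: Iterable[FeatureLayer], path) -> None:
    feats = []
    for layer in layers:
        for fid, geom in zip(layer.feature_ids, layer.geometries):
            feats.append(
                {
                    "type": "Feature",
                    "properties": {"category": layer.category, "feature_id": fid},
                    "geometry": mapping(geom),
                }
            )
    gj = {"type": "FeatureCollection", "features": feats}
    if hasattr(path, "write"):
        json.dump(gj, path)
    else:
        with open(path, "w") as fh:
            json.dump(gj, fh)


def min_distances(
    samples: SampleTable, layers: Iterable[FeatureLayer] | Mapping[str, FeatureLayer]
) -> DistanceSet:
    """Shortest Euclidean distance from each site to each feature category.

    Point-to-polyline distance is the distance to the nearest point anywhere
    on the polyline (segment interiors included), as computed by shapely.
    Categories with zero features are flagged absent, never reported as 0.
    """
    if isinstance(layers, Mapping):
        layers = list(layers.values())
    else:
        layers = list(layers)
    from shapely.geometry import Point

    pts = [Point(xy) for xy in samples.coords]
    cols: dict[str, np.ndarray] = {}
    present = set()
    for layer in layers:
        if len(layer) == 0:
            continue
        present.add(layer.category)
        d = np.array(
            [min(p.distance(g) for g in layer.geometries) for p in pts], dtype=float
        )
        if layer.category in cols:
            cols[layer.category] = np.minimum(cols[layer.category], d)
        else:
            cols[layer.category] = d
    absent = [c for c in CATEGORIES if c not in present]
    df = pd.DataFrame(cols, index=samples.data.index)
    return DistanceSet(df, absent=absent)


def describe(samples: SampleTable, background: BackgroundTable) -> pd.DataFrame:
    """Descriptive statistics per element, mirroring a standard survey table.

    Returns one row per element with min, median, max, mean, sample SD
    (``ddof=1``), CV% (100*SD/mean), bias-adjusted skewness and excess
    kurtosis, the exceedance rate against the background value, and — where
    a risk-screening value exists — max/screening, mean/screening and
    median/screening ratios.
    """
    if len(samples) < 2:
        raise ValidationError("descriptive statistics need at least 2 samples (SD undefined)")
    rows = {}
    for e in samples.elements:
        v = samples.data[e].to_numpy(float)
        sd = float(np.std(v, ddof=1))
        mean = float(np.mean(v))
        row = {
            "minimum": float(np.min(v)),
            "median": float(np.median(v)),
            "maximum": float(np.max(v)),
            "mean": mean,
            "sd": sd,
            "cv_pct": 100.0 * sd / mean,
            "skewness": float(stats.skew(v, bias=False)),
            "kurtosis": float(stats.kurtosis(v, bias=False)),
        }
        try:
            bg = background.background(e)
            row["exceedance_rate"] = float(np.mean(v > bg))
        except KeyError:
            row["exceedance_rate"] = np.nan
        scr = np.nan
        if e in background.data.index:
            scr = background.screening(e)
        if np.isfinite(scr):
            row["max_over_screening"] = row["maximum"] / scr
            row["mean_over_screening"] = mean / scr
            row["median_over_screening"] = row["median"] / scr
            row["screening_exceedance_rate"] = float(np.mean(v > scr))
        else:
            row["max_over_screening"] = np.nan
            row["mean_over_screening"] = np.nan
            row["median_over_screening"] = np.nan
            row["screening_exceedance_rate"] = np.nan
        rows[e] = row
    out = pd.DataFrame(rows).T
    out.index.name = "element"
    return out
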