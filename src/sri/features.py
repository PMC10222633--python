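"""Feature-schema assembly and feature-table I/O.

Four schemas represent each one-minute recording:

========  =====================================================  ======
schema    contents                                               length
========  =====================================================  ======
ECO7      seven cumulative ecoacoustic indices                        7
ECO49     7 indices x 7 statistical descriptors of 1-s series        49
MFCC84    12 MFCC orders x 7 statistical descriptors                 84
MFCC1428  12 MFCCs x 119 one-second frames (50% overlap)           1428
========  =====================================================  ======

Descriptor conventions: sample standard deviation (n-1), adjusted
Fisher-Pearson skewness, population-moment excess kurtosis; a constant
series has skewness = kurtosis = 0 by definition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from sri.audio import AudioClip
from sri.errors import DegenerateInputError, UndefinedIndexError, ValidationError
from sri.indices import INDEX_NAMES, EcoParams, compute_index, index_time_series
from sri.mfcc import mfcc_matrix

__all__ = [
    "SCHEMAS",
    "DESCRIPTOR_NAMES",
    "FeatureVector",
    "FeatureTable",
    "stat_descriptors",
    "build_eco7",
    "build_eco49",
    "build_mfcc84",
    "build_mfcc1428",
    "build_feature_vector",
    "build_feature_table",
]

SCHEMAS = {"ECO7": 7, "ECO49": 49, "MFCC84": 84, "MFCC1428": 1428}

DESCRIPTOR_NAMES = ("min", "max", "mean", "median", "skewness", "kurtosis", "std")


def stat_descriptors(series) -> np.ndarray:
    """The seven statistical descriptors of a series, in fixed order:
    min, max, mean, median, skewness, kurtosis (excess), standard
    deviation (n-1). Missing (NaN) values are ignored.
    """
    x = np.asarray(series, dtype=np.float64)
    x = x[np.isfinite(x)]
    if x.size == 0:
        raise DegenerateInputError("empty or all-missing series")
    if x.size == 1 or np.ptp(x) == 0.0:
        v = float(x[0])
        return np.array([v, v, v, v, 0.0, 0.0, 0.0])
    skew = float(stats.skew(x, bias=False))
    kurt = float(stats.kurtosis(x, fisher=True, bias=True))
    sd = float(x.std(ddof=1))
    return np.array([
        float(x.min()), float(x.max()), float(x.mean()), float(np.median(x)),
        skew, kurt, sd,
    ])


@dataclass
class FeatureVector:
    """Named feature values of one recording under one schema."""

    schema: str
    names: list[str]
    values: np.ndarray
    recording_id: str = ""
    site_id: str | None = None
    missing: list[str] = field(default_factory=list)  # names whose value is NaN

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.schema not in SCHEMAS:
            raise ValidationError(f"unknown schema {self.schema!r}")
        expected = SCHEMAS[self.schema]
        if len(self.names) != expected or self.values.size != expected:
            raise ValidationError(
                f"{self.schema} expects {expected} features, got "
                f"{len(self.names)} names / {self.values.size} values"
            )
        if len(set(self.names)) != len(self.names):
            raise ValidationError("feature names must be unique")


def build_eco7(clip: AudioClip, params: EcoParams = EcoParams()) -> FeatureVector:
    """One cumulative value per index over the whole clip (7 features).

    An index that is undefined on the clip yields NaN, recorded in
    ``missing`` (table-level imputation fills it later).
    """
    if not np.any(clip.samples != 0):
        raise DegenerateInputError("silent clip: no index is defined")
    names, values, missing = [], [], []
    for name in INDEX_NAMES:
        names.append(name)
        try:
            values.append(compute_index(clip, name, params))
        except (DegenerateInputError, UndefinedIndexError):
            values.append(np.nan)
            missing.append(name)
    if len(missing) == len(names):
        raise DegenerateInputError("all indices undefined (silent clip?)")
    return FeatureVector("ECO7", names, np.array(values),
                         recording_id=clip.id, site_id=clip.site, missing=missing)


def build_eco49(clip: AudioClip, params: EcoParams = EcoParams(),
                step: float = 1.0) -> FeatureVector:
    """Descriptors of each index's one-second series (7 x 7 = 49)."""
    names, values, missing = [], [], []
    for idx_name in INDEX_NAMES:
        series = index_time_series(clip, idx_name, params, step=step)
        try:
            desc = stat_descriptors(series.values)
        except DegenerateInputError:
            desc = np.full(7, np.nan)
        for d_name, v in zip(DESCRIPTOR_NAMES, desc):
            names.append(f"{idx_name}_{d_name}")
            values.append(v)
            if not np.isfinite(v):
                missing.append(f"{idx_name}_{d_name}")
    if len(missing) == len(names):
        raise DegenerateInputError("all index series undefined")
    return FeatureVector("ECO49", names, np.array(values),
                         recording_id=clip.id, site_id=clip.site, missing=missing)


def build_mfcc84(clip: AudioClip) -> FeatureVector:
    """Descriptors of each MFCC order's frame series (12 x 7 = 84)."""
    mat = mfcc_matrix(clip)
    names, values = [], []
    for order in range(mat.coefficients.shape[1]):
        desc = stat_descriptors(mat.coefficients[:, order])
        for d_name, v in zip(DESCRIPTOR_NAMES, desc):
            names.append(f"mfcc{order + 1}_{d_name}")
            values.append(v)
    return FeatureVector("MFCC84", names, np.array(values),
                         recording_id=clip.id, site_id=clip.site)


def build_mfcc1428(clip: AudioClip, strict: bool = True) -> FeatureVector:
    """Row-major flattening of the 119 x 12 MFCC matrix (1428 features).

    In strict mode the clip must be exactly 60 s so every recording has
    the same frame count.
    """
    if strict and not np.isclose(clip.duration, 60.0, atol=0.5 / clip.rate):
        raise ValidationError(
            f"MFCC1428 requires a 60 s clip, got {clip.duration:.3f} s"
        )
    mat = mfcc_matrix(clip)
    names = [
        f"mfcc{order + 1}_w{frame}"
        for frame in range(mat.n_frames)
        for order in range(mat.coefficients.shape[1])
    ]
    return FeatureVector("MFCC1428", names, mat.flatten(),
                         recording_id=clip.id, site_id=clip.site)


_BUILDERS = {
    "ECO7": build_eco7,
    "ECO49": build_eco49,
    "MFCC84": build_mfcc84,
    "MFCC1428": build_mfcc1428,
}


def build_feature_vector(clip: AudioClip, schema: str, **kwargs) -> FeatureVector:
    """Dispatch to the builder for *schema* (case-insensitive)."""
    key = schema.upper()
    if key not in _BUILDERS:
        raise ValidationError(f"unknown schema {schema!r}")
    return _BUILDERS[key](clip, **kwargs)


@dataclass
class FeatureTable:
    """Recordings x features table for one schema.

    ``data`` is indexed by recording id with the schema columns plus a
    trailing ``imputed_features`` sidecar column naming any values that
    were filled with the column median.
    """

    schema: str
    data: pd.DataFrame
    site_map: dict[str, str | None]

    @property
    def feature_names(self) -> list[str]:
        return [c for c in self.data.columns if c != "imputed_features"]

    def matrix(self) -> np.ndarray:
        return self.data[self.feature_names].to_numpy(dtype=np.float64)

    def to_csv(self, path) -> None:
        out = self.data.copy()
        out.insert(0, "site_id", [self.site_map.get(r, "") or "" for r in out.index])
        out.index.name = "recording_id"
        out.to_csv(path)

    @classmethod
    def from_csv(cls, path, schema: str | None = None) -> "FeatureTable":
        df = pd.read_csv(path, index_col="recording_id", dtype={"site_id": str})
        df.index = df.index.astype(str)
        site_map = {r: (s if isinstance(s, str) and s else None)
                    for r, s in df["site_id"].items()}
        df = df.drop(columns=["site_id"])
        if "imputed_features" in df.columns:
            df["imputed_features"] = df["imputed_features"].fillna("")
        else:
            df["imputed_features"] = ""
        n_features = len([c for c in df.columns if c != "imputed_features"])
        if schema is None:
            by_len = {v: k for k, v in SCHEMAS.items()}
            # tables from other producers keep a width-tagged schema name
            schema = by_len.get(n_features, f"custom{n_features}")
        elif schema in SCHEMAS and SCHEMAS[schema] != n_features:
            raise ValidationError(
                f"schema {schema} expects {SCHEMAS[schema]} columns, found {n_features}"
            )
        return cls(schema=schema, data=df, site_map=site_map)

    @classmethod
    def from_vectors(cls, vectors: list[FeatureVector]) -> "FeatureTable":
        """Assemble a table, imputing missing values with column medians."""
        if not vectors:
            raise DegenerateInputError("no feature vectors")
        schema = vectors[0].schema
        ids = [v.recording_id for v in vectors]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate recording ids")
        for v in vectors:
            if v.schema != schema:
                raise ValidationError("all vectors must share one schema")
        df = pd.DataFrame(
            np.vstack([v.values for v in vectors]),
            index=pd.Index(ids, name="recording_id"),
            columns=vectors[0].names,
        )
        imputed = []
        medians = df.median()
        for rid in df.index:
            row_missing = df.loc[rid].index[df.loc[rid].isna()].tolist()
            imputed.append(";".join(row_missing))
        df = df.fillna(medians)
        df["imputed_features"] = imputed
        site_map = {v.recording_id: v.site_id for v in vectors}
        return cls(schema=schema, data=df, site_map=site_map)
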