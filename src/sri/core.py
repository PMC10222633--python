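"""The soundscape ranking index.

A recording's SRI is a weighted sum over its aurally surveyed sound
categories: bird abundance, species richness and singing activity earn
positive weights (c+ for moderate, c++ for strong biophony), road
traffic and other anthropogenic sources earn negative weights (c-,
c--), and absences are neutral (c0 = 0). The score is binned into three
environmental sound-quality classes:

    SRI < 0        -> poor
    0 <= SRI <= 2  -> medium
    SRI > 2        -> good

Site-level maps summarize the per-recording scores by their median.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from sri.errors import DegenerateInputError, ValidationError

__all__ = [
    "ABUNDANCE_LEVELS",
    "RICHNESS_LEVELS",
    "TRAFFIC_TYPES",
    "TRAFFIC_INTENSITIES",
    "OTHER_SOURCES",
    "QUALITY_CLASSES",
    "AuralLabel",
    "WeightSet",
    "activity_fraction",
    "sri_score",
    "quality_bin",
    "aggregate_sri",
    "score_table",
    "site_map",
    "read_labels_csv",
    "write_labels_csv",
]

ABUNDANCE_LEVELS = ("no", "few", "many")
RICHNESS_LEVELS = ("none", "le2", "gt2")
TRAFFIC_TYPES = ("none", "continuous", "intermittent")
TRAFFIC_INTENSITIES = ("zero", "low", "high")
OTHER_SOURCES = ("absent", "present")
QUALITY_CLASSES = ("poor", "medium", "good")

LABEL_COLUMNS = [
    "recording_id", "site_id", "birds_abundance", "species_richness",
    "singing_activity_pct", "traffic_type", "traffic_intensity", "other_sources",
]


@dataclass(frozen=True)
class AuralLabel:
    """The six aural-survey attributes of one recording."""

    birds_abundance: str
    species_richness: str
    singing_activity_pct: float
    traffic_type: str
    traffic_intensity: str
    other_sources: str
    recording_id: str = ""
    site_id: str = ""

    def __post_init__(self) -> None:
        checks = [
            ("birds_abundance", ABUNDANCE_LEVELS),
            ("species_richness", RICHNESS_LEVELS),
            ("traffic_type", TRAFFIC_TYPES),
            ("traffic_intensity", TRAFFIC_INTENSITIES),
            ("other_sources", OTHER_SOURCES),
        ]
        for attr, levels in checks:
            value = getattr(self, attr)
            if value not in levels:
                raise ValidationError(
                    f"{attr}={value!r} is not one of {levels}"
                )
        pct = self.singing_activity_pct
        if not np.isfinite(pct) or not 0 <= pct <= 100:
            raise ValidationError(
                f"singing_activity_pct must be in [0, 100], got {pct}"
            )


@dataclass(frozen=True)
class WeightSet:
    """The four free coefficients of the SRI weighted sum.

    c++ in [2, 5], c+ in [0, 2], c- in [-2, 0], c-- in [-5, -2];
    the neutral coefficient c0 is fixed at 0.
    """

    c_plusplus: float
    c_plus: float
    c_minus: float
    c_minusminus: float

    c_zero = 0.0

    def __post_init__(self) -> None:
        if not 2.0 <= self.c_plusplus <= 5.0:
            raise ValidationError(f"c++ must lie in [2, 5], got {self.c_plusplus}")
        if not 0.0 <= self.c_plus <= 2.0:
            raise ValidationError(f"c+ must lie in [0, 2], got {self.c_plus}")
        if not -2.0 <= self.c_minus <= 0.0:
            raise ValidationError(f"c- must lie in [-2, 0], got {self.c_minus}")
        if not -5.0 <= self.c_minusminus <= -2.0:
            raise ValidationError(f"c-- must lie in [-5, -2], got {self.c_minusminus}")

    def as_dict(self) -> dict[str, float]:
        return {
            "c_plusplus": self.c_plusplus,
            "c_plus": self.c_plus,
            "c_minus": self.c_minus,
            "c_minusminus": self.c_minusminus,
        }

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.as_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "WeightSet":
        """Load weights from JSON; extra keys (e.g. optimizer metadata
        written alongside a best set) are ignored."""
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        keys = ("c_plusplus", "c_plus", "c_minus", "c_minusminus")
        missing = [k for k in keys if k not in payload]
        if missing:
            raise ValidationError(f"weights JSON missing {missing}")
        return cls(**{k: float(payload[k]) for k in keys})


def activity_fraction(pct: float) -> float:
    """Quantized singing-activity fraction: 0, (0,25]->0.25, (25,50]->0.5,
    (50,75]->0.75, (75,100]->1.0 (right edges closed)."""
    if not np.isfinite(pct) or not 0 <= pct <= 100:
        raise ValidationError(f"activity percentage out of [0, 100]: {pct}")
    if pct == 0:
        return 0.0
    return float(np.ceil(pct / 25.0) * 0.25)


def sri_score(label: AuralLabel, w: WeightSet) -> float:
    """Weighted category sum for one recording.

    Terms: abundance (no->0, few->c+, many->c++), richness (none->0,
    le2->c+, gt2->c++), singing activity (fraction x c++), traffic type
    (none->c+, continuous->c-, intermittent->c--), traffic intensity
    (zero->c+, low->c-, high->c--), other sources (absent->0,
    present->c--).
    """
    abundance = {"no": 0.0, "few": w.c_plus, "many": w.c_plusplus}
    richness = {"none": 0.0, "le2": w.c_plus, "gt2": w.c_plusplus}
    traffic_type = {"none": w.c_plus, "continuous": w.c_minus,
                    "intermittent": w.c_minusminus}
    traffic_intensity = {"zero": w.c_plus, "low": w.c_minus,
                         "high": w.c_minusminus}
    other = {"absent": 0.0, "present": w.c_minusminus}
    return (
        abundance[label.birds_abundance]
        + richness[label.species_richness]
        + activity_fraction(label.singing_activity_pct) * w.c_plusplus
        + traffic_type[label.traffic_type]
        + traffic_intensity[label.traffic_intensity]
        + other[label.other_sources]
    )


def quality_bin(sri: float) -> str:
    """Map an SRI value to its quality class."""
    if not np.isfinite(sri):
        raise ValidationError(f"SRI must be finite, got {sri}")
    if sri < 0:
        return "poor"
    if sri <= 2:
        return "medium"
    return "good"


def aggregate_sri(scores, method: str = "mean") -> float:
    """Aggregate per-recording scores: 'mean' (the multi-recording SRI
    definition) or 'median' (the site-map summary)."""
    x = np.asarray(list(scores), dtype=np.float64)
    if x.size == 0:
        raise DegenerateInputError("no scores to aggregate")
    if method == "mean":
        return float(x.mean())
    if method == "median":
        return float(np.median(x))
    raise ValidationError(f"unknown aggregation method {method!r}")


def score_table(labels: list[AuralLabel], w: WeightSet) -> pd.DataFrame:
    """Per-recording SRI and quality class as a DataFrame."""
    rows = []
    for lab in labels:
        s = sri_score(lab, w)
        rows.append({
            "recording_id": lab.recording_id,
            "site_id": lab.site_id,
            "sri": s,
            "quality": quality_bin(s),
        })
    return pd.DataFrame(rows).set_index("recording_id")


def site_map(labels: list[AuralLabel], w: WeightSet,
             coordinates: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-site median SRI and quality class.

    ``coordinates``, if given, is a DataFrame indexed by site_id with
    ``x``/``y`` columns; unknown site ids are emitted without geometry.
    """
    for lab in labels:
        if not lab.site_id:
            raise ValidationError(
                f"recording {lab.recording_id!r} has no site_id"
            )
    per_rec = score_table(labels, w)
    grouped = per_rec.groupby("site_id")["sri"].median().rename("median_sri")
    out = grouped.to_frame()
    out["quality"] = [quality_bin(v) for v in out["median_sri"]]
    out["n_recordings"] = per_rec.groupby("site_id").size()
    if coordinates is not None:
        out = out.join(coordinates[["x", "y"]], how="left")
    return out


def site_map_geojson(site_table: pd.DataFrame) -> dict:
    """GeoJSON FeatureCollection of sites that carry coordinates."""
    features = []
    for site_id, row in site_table.iterrows():
        if "x" not in row or not np.isfinite(row.get("x", np.nan)):
            continue
        features.append({
            "type": "Feature",
            "geometry": {"type": "Point",
                         "coordinates": [float(row["x"]), float(row["y"])]},
            "properties": {
                "site_id": str(site_id),
                "median_sri": float(row["median_sri"]),
                "quality": str(row["quality"]),
            },
        })
    return {"type": "FeatureCollection", "features": features}


def read_labels_csv(path) -> list[AuralLabel]:
    """Read the aural-survey label dialect (strict validation)."""
    df = pd.read_csv(path, dtype={"recording_id": str, "site_id": str})
    missing = set(LABEL_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"labels CSV missing columns: {sorted(missing)}")
    labels = []
    for _, row in df.iterrows():
        labels.append(AuralLabel(
            birds_abundance=str(row["birds_abundance"]),
            species_richness=str(row["species_richness"]),
            singing_activity_pct=float(row["singing_activity_pct"]),
            traffic_type=str(row["traffic_type"]),
            traffic_intensity=str(row["traffic_intensity"]),
            other_sources=str(row["other_sources"]),
            recording_id=str(row["recording_id"]),
            site_id="" if pd.isna(row["site_id"]) else str(row["site_id"]),
        ))
    return labels


def write_labels_csv(labels: list[AuralLabel], path) -> None:
    pd.DataFrame([{
        "recording_id": lab.recording_id,
        "site_id": lab.site_id,
        "birds_abundance": lab.birds_abundance,
        "species_richness": lab.species_richness,
        "singing_activity_pct": lab.singing_activity_pct,
        "traffic_type": lab.traffic_type,
        "traffic_intensity": lab.traffic_intensity,
        "other_sources": lab.other_sources,
    } for lab in labels])[LABEL_COLUMNS].to_csv(path, index=False)
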