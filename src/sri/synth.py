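"""Synthetic labeled soundscapes and feature tables.

The field recordings behind the original study are not deposited, so
this module generates surrogates with the same structure: one-minute
48 kHz mono scenes mixing bird-song surrogates (frequency-modulated
chirp events concentrated in the 2-8 kHz biophony band, with event
density tracking the abundance/richness/activity attributes) and a
traffic surrogate (low-pass noise below 2 kHz, continuous or gated per
the traffic attributes), plus labeled feature tables with
class-conditional Gaussian features for optimizer tests.

All randomness flows from the seed of the spec; identical seeds give
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from sri.audio import AudioClip, write_wav
from sri.core import (
    ABUNDANCE_LEVELS,
    AuralLabel,
    WeightSet,
    quality_bin,
    sri_score,
    write_labels_csv,
)
from sri.errors import ConfigurationError, ValidationError
from sri.features import FeatureTable

__all__ = [
    "SceneSpec",
    "SynthTableSpec",
    "synth_soundscape",
    "synth_dataset",
    "synth_feature_table",
    "sample_label",
]

#: chirp events per minute at full singing activity, by abundance level
_EVENT_RATES = {"no": 0, "few": 18, "many": 60}
#: traffic RMS amplitude by intensity level (relative to unit-RMS birds)
_TRAFFIC_LEVELS = {"zero": 0.0, "low": 0.35, "high": 1.6}


@dataclass(frozen=True)
class SceneSpec:
    """Recipe for one synthetic scene."""

    label: AuralLabel
    duration: float = 60.0
    rate: int = 48000
    bird_band: tuple[float, float] = (2000.0, 8000.0)
    traffic_band: tuple[float, float] = (50.0, 2000.0)
    snr_db: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValidationError("duration must be positive")
        nyquist = self.rate / 2
        for name in ("bird_band", "traffic_band"):
            lo, hi = getattr(self, name)
            if not 0 <= lo < hi <= nyquist:
                raise ValidationError(f"{name} {lo, hi} outside (0, Nyquist)")


def _validate_consistency(label: AuralLabel) -> None:
    birdless = label.birds_abundance == "no"
    if birdless and label.singing_activity_pct > 0:
        raise ValidationError("abundance 'no' is inconsistent with activity > 0")
    if birdless != (label.species_richness == "none"):
        raise ValidationError("abundance and richness disagree about bird presence")
    if (label.traffic_type == "none") != (label.traffic_intensity == "zero"):
        raise ValidationError("traffic type and intensity disagree")


def _chirp(rate: int, dur: float, f0: float, f1: float, rng) -> np.ndarray:
    """One FM chirp event with a smooth amplitude envelope."""
    t = np.arange(int(dur * rate)) / rate
    tone = signal.chirp(t, f0=f0, f1=f1, t1=dur, method="quadratic")
    envelope = np.sin(np.pi * t / dur) ** 2
    return tone * envelope


def _bird_track(spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    """Chirp-train surrogate for avian vocalization.

    The event count follows the abundance level scaled by the singing
    activity; species richness selects how many distinct chirp motifs
    (frequency trajectories) are drawn.
    """
    label = spec.label
    n_samples = int(spec.duration * spec.rate)
    track = np.zeros(n_samples)
    activity = label.singing_activity_pct / 100.0
    rate_per_min = _EVENT_RATES[label.birds_abundance] * max(activity, 0.0)
    n_events = int(round(rate_per_min * spec.duration / 60.0))
    if n_events == 0:
        return track
    n_motifs = {"none": 0, "le2": 2, "gt2": 4}[label.species_richness]
    lo, hi = spec.bird_band
    motifs = []
    for _ in range(max(n_motifs, 1)):
        f0 = rng.uniform(lo, hi * 0.7)
        f1 = np.clip(f0 * rng.uniform(1.1, 1.6), lo, hi)
        motifs.append((f0, f1))
    for _ in range(n_events):
        f0, f1 = motifs[rng.integers(len(motifs))]
        dur = rng.uniform(0.08, 0.35)
        event = _chirp(spec.rate, dur, f0, f1, rng)
        start = rng.integers(0, n_samples - event.size)
        track[start:start + event.size] += event
    return track


def _traffic_track(spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    """Low-passed noise surrogate for road traffic."""
    label = spec.label
    n_samples = int(spec.duration * spec.rate)
    level = _TRAFFIC_LEVELS[label.traffic_intensity]
    if label.traffic_type == "none" or level == 0.0:
        return np.zeros(n_samples)
    noise = rng.standard_normal(n_samples)
    sos = signal.butter(4, spec.traffic_band[1], btype="lowpass",
                        fs=spec.rate, output="sos")
    noise = signal.sosfilt(sos, noise)
    if label.traffic_type == "intermittent":
        # gated bursts: ~3 s passes separated by quieter gaps
        t = np.arange(n_samples) / spec.rate
        gate = np.zeros(n_samples)
        pos = 0.0
        while pos < spec.duration:
            burst = rng.uniform(1.5, 4.0)
            gap = rng.uniform(2.0, 6.0)
            mask = (t >= pos) & (t < pos + burst)
            gate[mask] = 1.0
            pos += burst + gap
        gate = signal.sosfilt(signal.butter(2, 2.0, fs=spec.rate, output="sos"),
                              gate)
        noise = noise * np.clip(gate, 0.0, 1.0)
    rms = np.sqrt((noise**2).mean())
    if rms > 0:
        noise = noise / rms
    return noise * level


def _hum_track(spec: SceneSpec) -> np.ndarray:
    """Steady low-frequency tonal hum for 'other sound sources'."""
    t = np.arange(int(spec.duration * spec.rate)) / spec.rate
    return 0.4 * (np.sin(2 * np.pi * 120.0 * t) + 0.5 * np.sin(2 * np.pi * 240.0 * t))


def synth_soundscape(spec: SceneSpec) -> tuple[AudioClip, AuralLabel]:
    """Render one labeled synthetic scene.

    The mixture is peak-normalized to -3 dBFS; a faint wide-band noise
    floor (-60 dBFS) keeps spectra non-degenerate in silent scenes.
    """
    _validate_consistency(spec.label)
    rng = np.random.default_rng(spec.seed)
    n_samples = int(spec.duration * spec.rate)
    birds = _bird_track(spec, rng)
    bird_rms = np.sqrt((birds**2).mean())
    if bird_rms > 0:
        birds = birds / bird_rms * (10.0 ** (spec.snr_db / 20.0))
    traffic = _traffic_track(spec, rng)
    mix = birds + traffic
    if spec.label.other_sources == "present":
        mix = mix + _hum_track(spec)
    mix = mix + 1e-3 * rng.standard_normal(n_samples)  # -60 dBFS floor
    peak = np.abs(mix).max()
    mix = mix / peak * (10.0 ** (-3.0 / 20.0))
    clip = AudioClip(samples=mix, rate=spec.rate,
                     id=spec.label.recording_id or f"scene{spec.seed}",
                     site=spec.label.site_id or None)
    return clip, spec.label


def sample_label(rng: np.random.Generator, recording_id: str = "",
                 site_id: str = "") -> AuralLabel:
    """Draw one internally consistent aural label.

    Bird presence is drawn first; richness/activity are conditioned on
    it, and the traffic attributes are kept mutually consistent.
    """
    abundance = ABUNDANCE_LEVELS[rng.integers(3)]
    if abundance == "no":
        richness, activity = "none", 0.0
    else:
        richness = ("le2", "gt2")[rng.integers(2)]
        lo = 5.0 if abundance == "few" else 30.0
        hi = 60.0 if abundance == "few" else 100.0
        activity = float(np.round(rng.uniform(lo, hi), 1))
    traffic_type = ("none", "continuous", "intermittent")[rng.integers(3)]
    if traffic_type == "none":
        intensity = "zero"
    else:
        intensity = ("low", "high")[rng.integers(2)]
    other = ("absent", "present")[int(rng.random() < 0.15)]
    return AuralLabel(
        birds_abundance=abundance,
        species_richness=richness,
        singing_activity_pct=activity,
        traffic_type=traffic_type,
        traffic_intensity=intensity,
        other_sources=other,
        recording_id=recording_id,
        site_id=site_id,
    )


def synth_dataset(n: int, out_dir, site_grid: list[str] | None = None,
                  seed: int = 0, duration: float = 60.0,
                  rate: int = 48000) -> tuple[Path, Path, Path]:
    """Write *n* scenes as WAV files plus labels.csv and sites.csv.

    Sites are assigned cyclically over *site_grid* (default: a 4 x 4
    grid of 16 sites, mirroring a small recorder array). Returns the
    (wav directory, labels CSV, sites CSV) paths.
    """
    if n < 1:
        raise ConfigurationError("n must be >= 1")
    if site_grid is not None and len(site_grid) == 0:
        raise ConfigurationError("site grid is empty")
    if site_grid is None:
        site_grid = [f"S{i + 1:02d}" for i in range(16)]
    out_dir = Path(out_dir)
    wav_dir = out_dir / "wav"
    wav_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    labels = []
    for i in range(n):
        rid = f"rec{i + 1:04d}"
        site = site_grid[i % len(site_grid)]
        label = sample_label(rng, recording_id=rid, site_id=site)
        scene_seed = int(rng.integers(0, 2**31 - 1))
        clip, _ = synth_soundscape(SceneSpec(
            label=label, duration=duration, rate=rate, seed=scene_seed
        ))
        write_wav(wav_dir / f"{rid}.wav", clip)
        labels.append(label)
    labels_csv = out_dir / "labels.csv"
    write_labels_csv(labels, labels_csv)
    side = int(np.ceil(np.sqrt(len(site_grid))))
    sites_csv = out_dir / "sites.csv"
    pd.DataFrame({
        "site_id": site_grid,
        "x": [100.0 * (i % side) for i in range(len(site_grid))],
        "y": [100.0 * (i // side) for i in range(len(site_grid))],
    }).to_csv(sites_csv, index=False)
    return wav_dir, labels_csv, sites_csv


@dataclass(frozen=True)
class SynthTableSpec:
    """Recipe for a labeled synthetic feature table.

    Features are class-conditional Gaussians: recordings in quality
    class k (induced by ``true_weights``) have feature means offset by
    ``class_separation`` standard deviations per class step. With
    separation 0 the features carry no label information (null model).
    """

    n_recordings: int = 300
    true_weights: WeightSet = field(
        default_factory=lambda: WeightSet(2.5, 1.0, -1.0, -3.0)
    )
    n_features: int = 10
    class_separation: float = 6.0
    seed: int = 0
    balanced: bool = True

    def __post_init__(self) -> None:
        if self.n_recordings < 1:
            raise ConfigurationError("n_recordings must be >= 1")
        if self.class_separation < 0:
            raise ConfigurationError("class_separation must be >= 0")


def synth_feature_table(spec: SynthTableSpec) -> tuple[FeatureTable, list[AuralLabel]]:
    """Draw labels, bin them under the true weights, and emit Gaussian
    features whose class means are ``class_separation`` SDs apart.

    With ``balanced`` (default), labels are rejection-sampled so the
    three quality classes are as even as the sample size allows; a
    warning is raised if a class is still absent.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_recordings
    labels: list[AuralLabel] = []
    classes: list[str] = []
    if spec.balanced:
        quota = {c: (n + 2 - i) // 3 for i, c in enumerate(("poor", "medium", "good"))}
        filled = {c: 0 for c in quota}
        attempts = 0
        while len(labels) < n and attempts < 200 * n:
            attempts += 1
            rid = f"rec{len(labels) + 1:04d}"
            lab = sample_label(rng, recording_id=rid,
                               site_id=f"S{len(labels) % 16 + 1:02d}")
            cls = quality_bin(sri_score(lab, spec.true_weights))
            if filled[cls] < quota[cls]:
                labels.append(lab)
                classes.append(cls)
                filled[cls] += 1
        # top up with unconstrained draws if a class is unreachable
        while len(labels) < n:
            rid = f"rec{len(labels) + 1:04d}"
            lab = sample_label(rng, recording_id=rid,
                               site_id=f"S{len(labels) % 16 + 1:02d}")
            labels.append(lab)
            classes.append(quality_bin(sri_score(lab, spec.true_weights)))
    else:
        for i in range(n):
            lab = sample_label(rng, recording_id=f"rec{i + 1:04d}",
                               site_id=f"S{i % 16 + 1:02d}")
            labels.append(lab)
            classes.append(quality_bin(sri_score(lab, spec.true_weights)))
    if len(set(classes)) < 3:
        import warnings

        warnings.warn(
            f"only classes {sorted(set(classes))} realized in the sample",
            stacklevel=2,
        )
    class_idx = {"poor": 0, "medium": 1, "good": 2}
    means = np.array([class_idx[c] for c in classes], dtype=float)
    X = rng.standard_normal((n, spec.n_features)) + \
        spec.class_separation * means[:, None]
    df = pd.DataFrame(
        X,
        index=pd.Index([lab.recording_id for lab in labels], name="recording_id"),
        columns=[f"f{j + 1}" for j in range(spec.n_features)],
    )
    df["imputed_features"] = ""
    from sri.features import SCHEMAS

    by_len = {v: k for k, v in SCHEMAS.items()}
    table = FeatureTable(
        schema=by_len.get(spec.n_features, f"custom{spec.n_features}"),
        data=df,
        site_map={lab.recording_id: lab.site_id for lab in labels},
    )
    return table, labels
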