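"""The seven ecoacoustic indices.

H (acoustic entropy), ACI (acoustic complexity), NDSI (normalized
difference soundscape index), BI (bioacoustic index), DSC (spectral
centroid), ADI (acoustic diversity) and AEI (acoustic evenness), with
the canonical published definitions and configurable band parameters.

Each index is available cumulatively over a whole clip and as a
one-second-step time series; the latter feeds the statistical-descriptor
feature schema.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert

from sri.audio import AudioClip, Spectrogram, band_slice, compute_spectrogram
from sri.errors import DegenerateInputError, UndefinedIndexError, ValidationError

__all__ = [
    "EcoParams",
    "IndexSeries",
    "INDEX_NAMES",
    "acoustic_entropy_H",
    "acoustic_complexity_ACI",
    "ndsi",
    "bioacoustic_index_BI",
    "spectral_centroid_DSC",
    "acoustic_diversity_ADI",
    "acoustic_evenness_AEI",
    "compute_index",
    "index_time_series",
]

INDEX_NAMES = ("H", "ACI", "NDSI", "BI", "DSC", "ADI", "AEI")


@dataclass(frozen=True)
class EcoParams:
    """Band and threshold parameters shared by the indices.

    Attributes
    ----------
    anthrophony_band : (Hz, Hz)
        Technophony band for NDSI (road traffic and similar sources).
    biophony_band : (Hz, Hz)
        Biophony band for NDSI (avian vocalization range).
    bi_band : (Hz, Hz)
        Integration band of the bioacoustic index.
    adi_band_width : Hz
        Width of the contiguous sub-bands over which ADI/AEI measure
        occupancy.
    adi_threshold_db : dB
        Occupancy threshold relative to the spectrogram maximum
        (negative).
    analysis_band : (Hz, Hz)
        Overall band the indices are computed in.
    n_fft : int
        FFT length for index spectrograms.
    """

    anthrophony_band: tuple[float, float] = (1000.0, 2000.0)
    biophony_band: tuple[float, float] = (2000.0, 8000.0)
    bi_band: tuple[float, float] = (2000.0, 8000.0)
    adi_band_width: float = 1000.0
    adi_threshold_db: float = -50.0
    analysis_band: tuple[float, float] = (100.0, 12000.0)
    n_fft: int = 1024

    def __post_init__(self) -> None:
        for name in ("anthrophony_band", "biophony_band", "bi_band", "analysis_band"):
            lo, hi = getattr(self, name)
            if lo >= hi:
                raise ValidationError(f"{name}: lower edge {lo} must be < upper {hi}")
        if self.adi_band_width <= 0:
            raise ValidationError("adi_band_width must be positive")
        if self.adi_threshold_db >= 0:
            raise ValidationError("adi_threshold_db must be negative (relative dB)")


@dataclass
class IndexSeries:
    """Per-segment values of one index at a fixed time step."""

    index_name: str
    values: np.ndarray  # NaN marks segments where the index is undefined
    step: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.index_name not in INDEX_NAMES:
            raise ValidationError(f"unknown index {self.index_name!r}")

    def defined(self) -> np.ndarray:
        """Values with undefined (NaN) segments removed."""
        return self.values[np.isfinite(self.values)]


def _entropy_norm(weights: np.ndarray) -> float:
    """Normalized Shannon entropy of a non-negative weight vector.

    The vector is normalized to a probability profile; entropy is divided
    by log(n) where n is the full vector length (zeros included), so a
    uniform profile scores 1 and a point mass scores 0.
    """
    total = weights.sum()
    n = weights.size
    if total <= 0 or n < 2:
        raise UndefinedIndexError("degenerate probability profile")
    p = weights / total
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum() / np.log(n))


def _spec_for(clip: AudioClip, params: EcoParams) -> Spectrogram:
    spec = compute_spectrogram(clip, n_fft=params.n_fft)
    return band_slice(spec, *params.analysis_band)


def acoustic_entropy_H(clip: AudioClip, params: EcoParams = EcoParams()) -> float:
    """Acoustic entropy H = Ht x Hf in [0, 1].

    Ht is the normalized Shannon entropy of the Hilbert amplitude
    envelope; Hf that of the mean magnitude spectrum within the analysis
    band. White noise approaches 1; a steady pure tone approaches 0
    through the Hf factor.
    """
    if not np.any(clip.samples != 0):
        raise UndefinedIndexError("acoustic entropy undefined for an all-zero clip")
    envelope = np.abs(hilbert(clip.samples))
    ht = _entropy_norm(envelope)
    spec = _spec_for(clip, params)
    hf = _entropy_norm(spec.mean_spectrum())
    return ht * hf


def acoustic_complexity_ACI(spec: Spectrogram) -> float:
    """Acoustic complexity index: summed relative intensity modulation.

    For each frequency bin, the sum of absolute intensity differences
    between successive frames divided by the bin's total intensity;
    summed over bins. Bins with zero total intensity contribute 0.
    """
    if spec.n_frames < 2:
        raise DegenerateInputError("ACI requires at least two time frames")
    intens = spec.magnitudes
    num = np.abs(np.diff(intens, axis=0)).sum(axis=0)
    den = intens.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        per_bin = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    return float(per_bin.sum())


def _band_power(spec: Spectrogram, band: tuple[float, float]) -> float:
    lo, hi = band
    mask = (spec.freq_axis >= lo) & (spec.freq_axis <= hi)
    if not mask.any():
        raise DegenerateInputError(f"band {band} does not overlap the spectrogram")
    return float(spec.power()[:, mask].sum())


def ndsi(spec: Spectrogram, params: EcoParams = EcoParams()) -> float:
    """Normalized difference soundscape index (B - A)/(B + A) in [-1, 1].

    B is the summed power in the biophony band (default 2-8 kHz), A in
    the anthrophony band (default 1-2 kHz).
    """
    b = _band_power(spec, params.biophony_band)
    a = _band_power(spec, params.anthrophony_band)
    if a + b == 0:
        raise UndefinedIndexError("NDSI undefined: no energy in either band")
    return float((b - a) / (b + a))


def bioacoustic_index_BI(spec: Spectrogram, params: EcoParams = EcoParams()) -> float:
    """Bioacoustic index: dB-spectrum area above its in-band minimum.

    The mean magnitude spectrum within the BI band is converted to dB;
    the index is the trapezoidal area (dB x kHz) between the spectrum
    and its minimum value in the band. Invariant under amplitude
    scaling because the minimum is subtracted.
    """
    lo, hi = params.bi_band
    mask = (spec.freq_axis >= lo) & (spec.freq_axis <= hi)
    if not mask.any():
        raise DegenerateInputError(f"BI band {params.bi_band} has no bins")
    mean_spec = spec.mean_spectrum()[mask]
    freqs_khz = spec.freq_axis[mask] / 1000.0
    if np.all(mean_spec <= 0):
        raise UndefinedIndexError("BI undefined: silent band")
    floor = mean_spec[mean_spec > 0].min() * 1e-12
    db = 20.0 * np.log10(np.maximum(mean_spec, floor))
    rel = db - db.min()
    return float(np.trapezoid(rel, freqs_khz))


def spectral_centroid_DSC(spec: Spectrogram) -> float:
    """Mean over frames of the per-frame spectral center of mass (Hz).

    Frames with zero energy are excluded; an all-silent spectrogram is
    undefined.
    """
    series = spectral_centroid_series(spec)
    defined = series[np.isfinite(series)]
    if defined.size == 0:
        raise UndefinedIndexError("DSC undefined: all frames silent")
    return float(defined.mean())


def spectral_centroid_series(spec: Spectrogram) -> np.ndarray:
    """Per-frame spectral centroid in Hz; NaN for silent frames."""
    weights = spec.magnitudes
    totals = weights.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cent = (weights * spec.freq_axis).sum(axis=1) / totals
    cent[totals <= 0] = np.nan
    return cent


def _band_occupancy(spec: Spectrogram, params: EcoParams) -> np.ndarray:
    """Fraction of time-frequency cells above the relative-dB threshold,
    per contiguous ``adi_band_width`` band of the analysis band."""
    lo, hi = params.analysis_band
    width = params.adi_band_width
    n_bands = int(np.floor((hi - lo) / width))
    if n_bands < 2:
        raise DegenerateInputError(
            "analysis band admits fewer than two ADI bands"
        )
    db = spec.to_db()
    occupancies = np.empty(n_bands)
    for i in range(n_bands):
        f0, f1 = lo + i * width, lo + (i + 1) * width
        mask = (spec.freq_axis >= f0) & (spec.freq_axis < f1)
        if not mask.any():
            occupancies[i] = 0.0
            continue
        cells = db[:, mask]
        occupancies[i] = float((cells > params.adi_threshold_db).mean())
    return occupancies


def acoustic_diversity_ADI(spec: Spectrogram, params: EcoParams = EcoParams()) -> float:
    """Acoustic diversity: Shannon entropy of normalized band occupancies.

    Ranges from 0 (one occupied band) to ln(n_bands) (uniform occupancy).
    """
    occ = _band_occupancy(spec, params)
    total = occ.sum()
    if total <= 0:
        raise UndefinedIndexError("ADI undefined: zero occupancy everywhere")
    p = occ / total
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def acoustic_evenness_AEI(spec: Spectrogram, params: EcoParams = EcoParams()) -> float:
    """Acoustic evenness: Gini coefficient of the ADI occupancy vector.

    0 for perfectly even occupancy, approaching 1 - 1/n for a single
    occupied band out of n.
    """
    occ = _band_occupancy(spec, params)
    if occ.sum() <= 0:
        raise UndefinedIndexError("AEI undefined: zero occupancy everywhere")
    return _gini(occ)


def _gini(x: np.ndarray) -> float:
    """Gini coefficient of a non-negative vector (0 = perfect evenness)."""
    x = np.sort(np.asarray(x, dtype=np.float64))
    n = x.size
    total = x.sum()
    if total <= 0:
        return 0.0
    # mean absolute difference formulation via the sorted-rank identity
    ranks = np.arange(1, n + 1)
    return float((2.0 * (ranks * x).sum() / (n * total)) - (n + 1.0) / n)


def compute_index(clip: AudioClip, index_name: str,
                  params: EcoParams = EcoParams()) -> float:
    """Compute one cumulative index over the whole clip."""
    if index_name == "H":
        return acoustic_entropy_H(clip, params)
    spec = _spec_for(clip, params)
    if index_name == "ACI":
        return acoustic_complexity_ACI(spec)
    if index_name == "NDSI":
        return ndsi(spec, params)
    if index_name == "BI":
        return bioacoustic_index_BI(spec, params)
    if index_name == "DSC":
        return spectral_centroid_DSC(spec)
    if index_name == "ADI":
        return acoustic_diversity_ADI(spec, params)
    if index_name == "AEI":
        return acoustic_evenness_AEI(spec, params)
    raise ValidationError(f"unknown index {index_name!r}")


def index_time_series(clip: AudioClip, index_name: str,
                      params: EcoParams = EcoParams(),
                      step: float = 1.0) -> IndexSeries:
    """Compute an index on consecutive non-overlapping *step*-second
    segments; undefined segments are recorded as NaN.

    A 60 s clip at the default one-second step yields 60 values.
    """
    if step <= 0:
        raise ValidationError("step must be positive")
    if clip.duration < step:
        raise DegenerateInputError(
            f"step {step} s exceeds clip duration {clip.duration:.3f} s"
        )
    seg_len = int(round(step * clip.rate))
    n_segments = clip.samples.size // seg_len
    values = np.full(n_segments, np.nan)
    for i in range(n_segments):
        seg = AudioClip(
            samples=clip.samples[i * seg_len:(i + 1) * seg_len],
            rate=clip.rate,
            id=f"{clip.id}#{i}",
            site=clip.site,
        )
        try:
            values[i] = compute_index(seg, index_name, params)
        except (UndefinedIndexError, DegenerateInputError):
            values[i] = np.nan
    return IndexSeries(index_name=index_name, values=values, step=step)
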