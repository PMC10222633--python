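"""Audio ingestion and spectrogram computation.

A one-minute mono recording is the unit of analysis. Spectrograms use a
rectangular window with no overlap by default, so that with a 1024-point
FFT at 48 kHz the frequency resolution is FR = 46.875 Hz and the time
resolution TR = 1/FR ~= 0.0213 s — the configuration every ecoacoustic
index in :mod:`sri.indices` consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.io import wavfile

from sri.errors import DegenerateInputError, ValidationError

__all__ = ["AudioClip", "Spectrogram", "read_wav", "compute_spectrogram", "band_slice"]

#: dB floor applied when converting linear magnitudes to decibels.
DB_FLOOR = -120.0

_INT_FULL_SCALE = {
    np.dtype(np.int16): 2.0**15,
    np.dtype(np.int32): 2.0**31,
    np.dtype(np.uint8): 2.0**7,  # offset binary: subtract 128 first
}


@dataclass
class AudioClip:
    """Mono audio signal, full-scale normalized to [-1, 1].

    Parameters
    ----------
    samples : ndarray
        Mono amplitude sequence.
    rate : int
        Sampling rate in Hz.
    id : str
        Recording identifier.
    site : str or None
        Optional site identifier.
    """

    samples: np.ndarray
    rate: int
    id: str = ""
    site: str | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValidationError("AudioClip samples must be one-dimensional (mono)")
        if self.rate <= 0:
            raise ValidationError(f"sampling rate must be positive, got {self.rate}")
        if self.samples.size == 0:
            raise DegenerateInputError("zero-length audio")
        if not np.all(np.isfinite(self.samples)):
            raise ValidationError("audio contains non-finite samples")

    @property
    def duration(self) -> float:
        """Clip duration in seconds."""
        return self.samples.size / self.rate

    def scaled(self, factor: float) -> "AudioClip":
        """Return a copy with all samples multiplied by *factor*."""
        return replace(self, samples=self.samples * factor)


@dataclass
class Spectrogram:
    """Linear-magnitude spectrogram with axis metadata.

    ``magnitudes`` has one row per time frame and one column per
    frequency bin. ``freq_resolution`` (FR) is rate/n_fft;
    ``time_resolution`` (TR) equals 1/FR when frames do not overlap.
    """

    magnitudes: np.ndarray
    freq_axis: np.ndarray
    time_axis: np.ndarray
    freq_resolution: float
    time_resolution: float

    def __post_init__(self) -> None:
        self.magnitudes = np.asarray(self.magnitudes, dtype=np.float64)
        self.freq_axis = np.asarray(self.freq_axis, dtype=np.float64)
        self.time_axis = np.asarray(self.time_axis, dtype=np.float64)
        if self.magnitudes.ndim != 2:
            raise ValidationError("spectrogram must be a 2-D matrix")
        if self.magnitudes.shape[1] != self.freq_axis.size:
            raise ValidationError("freq_axis length must match number of columns")
        if self.magnitudes.shape[0] != self.time_axis.size:
            raise ValidationError("time_axis length must match number of rows")
        if np.any(self.magnitudes < 0):
            raise ValidationError("magnitudes must be non-negative")
        if self.freq_axis.size > 1 and np.any(np.diff(self.freq_axis) <= 0):
            raise ValidationError("freq_axis must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.magnitudes.shape[0]

    @property
    def n_bins(self) -> int:
        return self.magnitudes.shape[1]

    def power(self) -> np.ndarray:
        """Magnitude-squared (power) matrix."""
        return self.magnitudes**2

    def to_db(self, floor: float = DB_FLOOR) -> np.ndarray:
        """dB view relative to the spectrogram maximum, floored at *floor*."""
        peak = self.magnitudes.max()
        if peak <= 0:
            return np.full_like(self.magnitudes, floor)
        with np.errstate(divide="ignore"):
            db = 20.0 * np.log10(self.magnitudes / peak)
        return np.maximum(db, floor)

    def mean_spectrum(self) -> np.ndarray:
        """Mean linear magnitude per frequency bin, averaged over frames."""
        return self.magnitudes.mean(axis=0)


def read_wav(path, id: str | None = None, site: str | None = None,
             expected_rate: int | None = None) -> AudioClip:
    """Read a WAV file into a full-scale-normalized mono :class:`AudioClip`.

    Integer PCM (8/16/24/32-bit) is divided by its dtype full scale;
    float data is taken as already normalized. Multichannel input is
    averaged to mono.

    Parameters
    ----------
    expected_rate : int, optional
        When given, reject files whose sampling rate differs.
    """
    try:
        rate, data = wavfile.read(path)
    except (OSError, ValueError) as exc:
        raise OSError(f"cannot read WAV file {path!r}: {exc}") from exc
    if data.size == 0:
        raise DegenerateInputError(f"zero-length audio in {path!r}")
    if expected_rate is not None and rate != expected_rate:
        raise ValidationError(
            f"{path!r}: sampling rate {rate} Hz does not match required {expected_rate} Hz"
        )
    dtype = data.dtype
    if dtype == np.uint8:
        samples = (data.astype(np.float64) - 128.0) / _INT_FULL_SCALE[np.dtype(np.uint8)]
    elif dtype in (np.int16, np.int32):
        samples = data.astype(np.float64) / _INT_FULL_SCALE[np.dtype(dtype)]
    else:  # float32 / float64
        samples = data.astype(np.float64)
    if samples.ndim > 1:
        samples = samples.mean(axis=1)
    clip_id = id if id is not None else str(path)
    return AudioClip(samples=samples, rate=int(rate), id=clip_id, site=site)


def write_wav(path, clip: AudioClip) -> None:
    """Write a clip as 16-bit PCM WAV (clipping at full scale)."""
    scaled = np.clip(clip.samples, -1.0, 1.0)
    pcm = np.round(scaled * 32767.0).astype(np.int16)
    wavfile.write(path, clip.rate, pcm)


def compute_spectrogram(clip: AudioClip, n_fft: int = 1024,
                        overlap_fraction: float = 0.0) -> Spectrogram:
    """Magnitude spectrogram with a rectangular window.

    Frames of ``n_fft`` samples are taken at hop
    ``n_fft * (1 - overlap_fraction)``; each frame is transformed with a
    real FFT and the one-sided magnitude retained. No taper is applied,
    matching the reference ecoacoustic-index conventions.
    """
    if not 0 <= overlap_fraction < 1:
        raise ValidationError("overlap_fraction must lie in [0, 1)")
    if n_fft <= 0:
        raise ValidationError("n_fft must be positive")
    n = clip.samples.size
    if n < n_fft:
        raise DegenerateInputError(
            f"clip has {n} samples, shorter than n_fft={n_fft}"
        )
    hop = int(round(n_fft * (1.0 - overlap_fraction)))
    hop = max(hop, 1)
    n_frames = (n - n_fft) // hop + 1
    idx = np.arange(n_fft)[None, :] + hop * np.arange(n_frames)[:, None]
    frames = clip.samples[idx]
    mags = np.abs(np.fft.rfft(frames, axis=1))
    fr = clip.rate / n_fft
    freq_axis = np.fft.rfftfreq(n_fft, d=1.0 / clip.rate)
    tr = hop / clip.rate
    time_axis = hop * np.arange(n_frames) / clip.rate
    return Spectrogram(
        magnitudes=mags,
        freq_axis=freq_axis,
        time_axis=time_axis,
        freq_resolution=fr,
        time_resolution=tr,
    )


def band_slice(spec: Spectrogram, f_min: float = 100.0,
               f_max: float = 12000.0) -> Spectrogram:
    """Restrict a spectrogram to bins with ``f_min <= f <= f_max``."""
    if f_min >= f_max:
        raise DegenerateInputError(f"empty band: f_min={f_min} >= f_max={f_max}")
    mask = (spec.freq_axis >= f_min) & (spec.freq_axis <= f_max)
    if not mask.any():
        raise DegenerateInputError(
            f"band ({f_min}, {f_max}) Hz contains no spectrogram bins"
        )
    return Spectrogram(
        magnitudes=spec.magnitudes[:, mask],
        freq_axis=spec.freq_axis[mask],
        time_axis=spec.time_axis,
        freq_resolution=spec.freq_resolution,
        time_resolution=spec.time_resolution,
    )
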