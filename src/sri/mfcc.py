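"""Mel-frequency cepstral coefficients.

Twelve MFCCs per one-second Hamming window with 50% overlap: a 60 s
recording yields a 119 x 12 coefficient matrix. The mel filter bank has
40 triangular filters spanning 0 Hz to the Nyquist frequency; cepstral
orders 1-12 are retained (order 0 is a loudness proxy and is dropped so
the features are invariant under global amplitude scaling).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.fft import dct
from scipy.signal.windows import hamming

from sri.audio import AudioClip
from sri.errors import ConfigurationError, DegenerateInputError

__all__ = [
    "MelFilterBank",
    "MFCCMatrix",
    "mel_from_hz",
    "hz_from_mel",
    "frame_signal",
    "build_mel_filterbank",
    "mfcc_frame",
    "mfcc_matrix",
    "LOG_FLOOR_EPS",
]

#: additive floor applied to filter-bank energies before the logarithm
LOG_FLOOR_EPS = 1e-10

N_COEFFICIENTS = 12
N_FILTERS = 40


def mel_from_hz(f: np.ndarray | float) -> np.ndarray | float:
    """mel(f) = 2595 log10(1 + f/700)."""
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=np.float64) / 700.0)


def hz_from_mel(m: np.ndarray | float) -> np.ndarray | float:
    """Inverse of :func:`mel_from_hz`."""
    return 700.0 * (10.0 ** (np.asarray(m, dtype=np.float64) / 2595.0) - 1.0)


@dataclass
class MelFilterBank:
    """Triangular mel filter bank over one-sided FFT bins."""

    n_filters: int
    filters: np.ndarray       # (n_filters, n_bins)
    edge_freqs_hz: np.ndarray  # n_filters + 2 edge frequencies
    rate: int
    n_fft: int

    def apply(self, power_spectrum: np.ndarray) -> np.ndarray:
        """Filter-bank energies of a one-sided power spectrum."""
        return self.filters @ power_spectrum


@dataclass
class MFCCMatrix:
    """Frames x 12 MFCC matrix with frame timing metadata."""

    coefficients: np.ndarray
    frame_times: np.ndarray
    window: float = 1.0
    overlap: float = 0.5

    @property
    def n_frames(self) -> int:
        return self.coefficients.shape[0]

    def flatten(self) -> np.ndarray:
        """Row-major (frame-major) flattening."""
        return self.coefficients.reshape(-1)


def n_frames_for(duration: float, window: float = 1.0, overlap: float = 0.5) -> int:
    """floor((duration - window) / (window*(1-overlap))) + 1."""
    hop = window * (1.0 - overlap)
    return int(np.floor((duration - window) / hop + 1e-9)) + 1


def frame_signal(clip: AudioClip, window: float = 1.0,
                 overlap: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
    """Split a clip into Hamming-tapered frames.

    Returns ``(frames, frame_times)`` where ``frames`` has one row per
    window of ``window * rate`` samples taken at hop
    ``window * (1 - overlap)``.
    """
    win_len = int(round(window * clip.rate))
    if clip.samples.size < win_len:
        raise DegenerateInputError(
            f"clip of {clip.duration:.3f} s shorter than the {window} s window"
        )
    hop = int(round(win_len * (1.0 - overlap)))
    if hop <= 0:
        raise ConfigurationError("overlap must be < 1")
    n_frames = (clip.samples.size - win_len) // hop + 1
    idx = np.arange(win_len)[None, :] + hop * np.arange(n_frames)[:, None]
    taper = hamming(win_len, sym=False)
    frames = clip.samples[idx] * taper
    frame_times = hop * np.arange(n_frames) / clip.rate
    return frames, frame_times


def build_mel_filterbank(rate: int, n_fft: int,
                         n_filters: int = N_FILTERS) -> MelFilterBank:
    """Triangular filters with centers equally spaced on the mel scale
    over [0, rate/2], evaluated at the one-sided FFT bin frequencies."""
    if n_filters < 2:
        raise ConfigurationError("need at least 2 mel filters")
    n_bins = n_fft // 2 + 1
    if n_filters > n_bins:
        raise ConfigurationError(
            f"{n_filters} filters exceed the {n_bins} available FFT bins"
        )
    edges_mel = np.linspace(0.0, float(mel_from_hz(rate / 2.0)), n_filters + 2)
    edges_hz = np.asarray(hz_from_mel(edges_mel))
    bin_freqs = np.fft.rfftfreq(n_fft, d=1.0 / rate)
    filters = np.zeros((n_filters, n_bins))
    for i in range(n_filters):
        lo, mid, hi = edges_hz[i], edges_hz[i + 1], edges_hz[i + 2]
        rising = (bin_freqs - lo) / max(mid - lo, np.finfo(float).tiny)
        falling = (hi - bin_freqs) / max(hi - mid, np.finfo(float).tiny)
        filters[i] = np.maximum(0.0, np.minimum(rising, falling))
    return MelFilterBank(
        n_filters=n_filters,
        filters=filters,
        edge_freqs_hz=edges_hz,
        rate=rate,
        n_fft=n_fft,
    )


def log_mel_energies(frame: np.ndarray, bank: MelFilterBank) -> np.ndarray:
    """Log filter-bank energies of one (already tapered) frame.

    The frame is zero-padded to the bank's FFT length; energies are
    floored at ``LOG_FLOOR_EPS`` before the logarithm.
    """
    spectrum = np.abs(np.fft.rfft(frame, n=bank.n_fft)) ** 2
    energies = bank.apply(spectrum)
    return np.log(energies + LOG_FLOOR_EPS)


def mfcc_frame(frame: np.ndarray, bank: MelFilterBank,
               n_coefficients: int = N_COEFFICIENTS,
               include_order0: bool = False) -> np.ndarray:
    """MFCCs of one tapered frame.

    Power spectrum -> mel filter-bank energies -> log -> orthonormal
    type-II DCT; orders 1..n retained (order 0 optionally included).
    An all-zero frame hits the log floor everywhere and yields the
    all-zero coefficient vector.
    """
    log_e = log_mel_energies(frame, bank)
    cepstrum = dct(log_e, type=2, norm="ortho")
    if include_order0:
        return cepstrum[:n_coefficients]
    return cepstrum[1:n_coefficients + 1]


def next_pow2(n: int) -> int:
    return 1 << (int(n) - 1).bit_length()


def mfcc_matrix(clip: AudioClip, window: float = 1.0, overlap: float = 0.5,
                n_filters: int = N_FILTERS,
                n_coefficients: int = N_COEFFICIENTS,
                include_order0: bool = False) -> MFCCMatrix:
    """MFCC matrix of a clip: one row of coefficients per frame.

    For a 60 s clip at the defaults this is a 119 x 12 matrix.
    """
    frames, frame_times = frame_signal(clip, window=window, overlap=overlap)
    n_fft = next_pow2(frames.shape[1])
    bank = build_mel_filterbank(clip.rate, n_fft, n_filters=n_filters)
    spectra = np.abs(np.fft.rfft(frames, n=n_fft, axis=1)) ** 2
    energies = spectra @ bank.filters.T
    log_e = np.log(energies + LOG_FLOOR_EPS)
    cepstra = dct(log_e, type=2, norm="ortho", axis=1)
    if include_order0:
        coeffs = cepstra[:, :n_coefficients]
    else:
        coeffs = cepstra[:, 1:n_coefficients + 1]
    return MFCCMatrix(
        coefficients=coeffs,
        frame_times=frame_times,
        window=window,
        overlap=overlap,
    )
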