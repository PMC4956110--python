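"""Spectrogram front end: DPSS-tapered log spectrograms and amplitude envelopes.

The front end converts a single-channel waveform into a log-magnitude
time-frequency matrix with 1-ms frames. The short-time transform uses a
512-sample window tapered with the 0th-order discrete prolate spheroidal
sequence (time-half-bandwidth product NW = 4, i.e. half bandwidth
W = 4/512 cycles per sample), hopped by 32 samples at a 32 kHz sampling rate.
Only bins whose center frequency lies in the 1-8 kHz band are kept, which at
the default parameters yields 112 frequency rows.

Two amplitude envelopes are provided for boundary detection: the default sums
the log-magnitude spectrum over the band in each 1-ms frame; the alternative
full-wave rectifies the waveform, low-pass filters it and takes the logarithm.

Conventions (fixed here because the upstream description leaves them open):
frames are 0-based; frame ``t`` covers samples ``[t*hop, t*hop + fft_size)``;
a trailing partial frame is dropped; intervals are half-open ``[on, off)`` in
frames; magnitudes are floored at ``log_floor`` before the natural logarithm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as _sig

__all__ = [
    "SpectrogramParams",
    "Spectrogram",
    "NormalizationStats",
    "AmplitudeEnvelope",
    "compute_spectrogram",
    "fit_normalization",
    "apply_normalization",
    "envelope_from_spectrogram",
    "envelope_from_rectification",
    "align_to_frame_grid",
]


class InsufficientInputError(ValueError):
    """Waveform shorter than one analysis window."""


class InvalidInputError(ValueError):
    """Non-finite samples or otherwise malformed input."""


class IncompatibleStatsError(ValueError):
    """Normalization statistics do not match the spectrogram shape."""


class DegenerateTrainingDataWarning(UserWarning):
    """Zero-variance cells encountered while fitting normalization."""


@dataclass(frozen=True)
class SpectrogramParams:
    sample_rate: float = 32000.0
    fft_size: int = 512
    hop: int = 32
    taper_half_bandwidth: float = 4.0 / 512.0  # W, cycles/sample
    band_low: float = 1000.0
    band_high: float = 8000.0
    log_floor: float = 1e-10

    def __post_init__(self) -> None:
        if not (self.band_low < self.band_high <= self.sample_rate / 2):
            raise ValueError("need band_low < band_high <= Nyquist")
        if self.fft_size <= self.hop:
            raise ValueError("need fft_size > hop")
        ms_samples = self.sample_rate / 1000.0
        if abs(ms_samples / self.hop - round(ms_samples / self.hop)) > 1e-9:
            raise ValueError("hop must divide the samples per millisecond grid")

    @property
    def frame_ms(self) -> float:
        return self.hop / self.sample_rate * 1000.0

    @property
    def bin_hz(self) -> float:
        return self.sample_rate / self.fft_size

    @property
    def band_bins(self) -> tuple[int, int]:
        """rfft bin range [lo, hi) whose centers lie in [band_low, band_high)."""
        lo = int(np.ceil(self.band_low / self.bin_hz - 1e-9))
        hi = int(np.ceil(self.band_high / self.bin_hz - 1e-9))
        return lo, hi

    @property
    def n_rows(self) -> int:
        lo, hi = self.band_bins
        return hi - lo

    def row_frequencies(self) -> np.ndarray:
        lo, hi = self.band_bins
        return np.arange(lo, hi) * self.bin_hz

    def taper(self) -> np.ndarray:
        """0th-order DPSS taper, unit L2 energy."""
        w = _sig.windows.dpss(self.fft_size, self.taper_half_bandwidth * self.fft_size)
        return w / np.sqrt(np.sum(w**2))

    def n_frames(self, n_samples: int) -> int:
        if n_samples < self.fft_size:
            return 0
        return (n_samples - self.fft_size) // self.hop + 1

    @property
    def center_shift_frames(self) -> int:
        """Offset between a frame index and the frame's center time.

        Frame ``t`` covers samples ``[t*hop, t*hop + fft_size)``, so its
        center sample lies ``fft_size/2`` samples (8 frames at defaults)
        after the frame's nominal start.
        """
        return self.fft_size // (2 * self.hop)


@dataclass
class Spectrogram:
    values: np.ndarray  # (n_rows, n_frames)
    params: SpectrogramParams
    normalized: bool = False

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def frame_ms(self) -> float:
        return self.params.frame_ms


@dataclass
class NormalizationStats:
    """Mean/std of log magnitudes, either global scalars or per frequency row."""

    mean: np.ndarray  # () or (n_rows, 1)
    std: np.ndarray
    per_row: bool = False

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.std) <= 0):
            raise ValueError("std must be strictly positive")


@dataclass
class AmplitudeEnvelope:
    values: np.ndarray  # (n_frames,)
    frame_ms: float = 1.0

    def __len__(self) -> int:
        return len(self.values)


def _check_waveform(waveform, params: SpectrogramParams) -> np.ndarray:
    x = np.asarray(waveform, dtype=np.float64)
    if x.ndim != 1:
        raise InvalidInputError("waveform must be one-dimensional")
    if not np.all(np.isfinite(x)):
        raise InvalidInputError("waveform contains non-finite samples")
    if x.size < params.fft_size:
        raise InsufficientInputError(
            f"waveform has {x.size} samples; need at least {params.fft_size}"
        )
    return x


def compute_spectrogram(waveform, params: SpectrogramParams | None = None) -> Spectrogram:
    """DPSS-tapered log-magnitude spectrogram restricted to the analysis band.

    Frame ``t`` is the transform of samples ``[t*hop, t*hop + fft_size)``;
    values are ``log(max(|X|, log_floor))`` (natural log of magnitude).
    """
    params = params or SpectrogramParams()
    x = _check_waveform(waveform, params)
    n_frames = params.n_frames(x.size)
    frames = np.lib.stride_tricks.sliding_window_view(x, params.fft_size)[:: params.hop]
    frames = frames[:n_frames]
    spec = np.fft.rfft(frames * params.taper(), axis=1)
    lo, hi = params.band_bins
    mag = np.abs(spec[:, lo:hi]).T  # (n_rows, n_frames)
    values = np.log(np.maximum(mag, params.log_floor))
    return Spectrogram(values=values, params=params, normalized=False)


def fit_normalization(spectrograms, per_row: bool = False,
                      std_floor: float = 1e-6) -> NormalizationStats:
    """Mean/std over all frames of the supplied (training-fold) spectrograms.

    Uses the population standard deviation. By default a single global
    mean/std is computed over all cells; ``per_row=True`` switches to one
    statistic per frequency row.
    """
    specs = list(spectrograms)
    if not specs:
        raise ValueError("no spectrograms supplied")
    allv = np.concatenate([s.values for s in specs], axis=1)
    if per_row:
        mean = allv.mean(axis=1, keepdims=True)
        std = allv.std(axis=1, keepdims=True)
    else:
        mean = np.asarray(allv.mean())
        std = np.asarray(allv.std())
    if np.any(std < std_floor):
        warnings.warn(
            "zero/near-zero variance in training spectrograms; flooring std",
            DegenerateTrainingDataWarning,
        )
        std = np.maximum(std, std_floor)
    return NormalizationStats(mean=mean, std=std, per_row=per_row)


def apply_normalization(spec: Spectrogram, stats: NormalizationStats) -> Spectrogram:
    mean = np.asarray(stats.mean)
    if mean.ndim and mean.shape[0] not in (1, spec.n_rows):
        raise IncompatibleStatsError(
            f"stats rows {mean.shape[0]} vs spectrogram rows {spec.n_rows}"
        )
    values = (spec.values - stats.mean) / stats.std
    return Spectrogram(values=values, params=spec.params, normalized=True)


def envelope_from_spectrogram(spec: Spectrogram) -> AmplitudeEnvelope:
    """Sum of the log-magnitude spectrum over the band in each frame.

    Must be given a raw (un-normalized) spectrogram.
    """
    if spec.normalized:
        raise ValueError("envelope is defined on the raw log spectrogram")
    return AmplitudeEnvelope(values=spec.values.sum(axis=0), frame_ms=spec.frame_ms)


def envelope_from_rectification(waveform, params: SpectrogramParams | None = None,
                                cutoff: float = 200.0) -> AmplitudeEnvelope:
    """Full-wave rectification -> low-pass filter -> log, on the spectrogram grid.

    A 4th-order zero-phase Butterworth low-pass (default cutoff 200 Hz) smooths
    the rectified waveform; the result is floored, logged, and sampled at the
    centers of the spectrogram frames so both envelopes share a frame grid.
    """
    params = params or SpectrogramParams()
    if not (0 < cutoff < params.sample_rate / 2):
        raise ValueError(f"cutoff must lie in (0, Nyquist); got {cutoff}")
    x = _check_waveform(waveform, params)
    sos = _sig.butter(4, cutoff, fs=params.sample_rate, output="sos")
    smooth = _sig.sosfiltfilt(sos, np.abs(x))
    logenv = np.log(np.maximum(smooth, params.log_floor))
    n_frames = params.n_frames(x.size)
    centers = np.arange(n_frames) * params.hop + params.fft_size // 2
    centers = np.minimum(centers, x.size - 1)
    return AmplitudeEnvelope(values=logenv[centers], frame_ms=params.frame_ms)


def align_to_frame_grid(ann, params: SpectrogramParams, n_frames: int):
    """Map a waveform-time annotation onto the spectrogram frame grid.

    A frame is labeled by the note covering the frame's *center* sample, so a
    note spanning milliseconds ``[on, off)`` occupies frames
    ``[on - shift, off - shift)`` where ``shift`` is
    :attr:`SpectrogramParams.center_shift_frames`. Notes are clipped to the
    available frames; notes that vanish entirely are dropped.
    """
    from .annotations import Annotation, Note

    shift = params.center_shift_frames
    notes = []
    for n in ann.notes:
        onset = max(n.onset - shift, 0)
        offset = min(n.offset - shift, n_frames)
        if offset > onset:
            notes.append(Note(onset, offset, n.label))
    return Annotation(notes, n_frames, params.frame_ms)
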