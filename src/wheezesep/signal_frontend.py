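"""Audio I/O, STFT analysis/synthesis, and magnitude-spectrogram normalization.

The factorization operates on normalized magnitude spectrograms.  The analysis
convention is fixed here: an ``N``-sample Hamming window zero-padded to a
``2N``-point DFT, hop ``N/4`` (31.25 ms at the nominal 2048 Hz sampling rate),
left-aligned frames with no centering padding.  Synthesis is weighted
overlap-add compensated by the sum of squared windows, so the analysis/synthesis
round trip is exact (to float precision) wherever window overlap is complete.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import signal as sps
from scipy.fft import irfft, rfft
from scipy.io import wavfile

__all__ = [
    "AudioSignal",
    "StftConfig",
    "MagnitudeSpectrogram",
    "load_audio",
    "save_audio",
    "compute_stft",
    "normalize_magnitude",
    "denormalize",
    "synthesize",
]

DEFAULT_RATE = 2048.0


@dataclass
class AudioSignal:
    """Mono audio: dimensionless amplitude samples at a sampling rate in Hz."""

    samples: np.ndarray
    rate: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("AudioSignal is mono: samples must be 1-D")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        if self.rate <= 0:
            raise ValueError("rate must be positive")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.rate

    def power(self) -> float:
        """Mean squared amplitude over the whole signal."""
        return float(np.mean(self.samples**2))


@dataclass(frozen=True)
class StftConfig:
    """Analysis parameters: window length N, hop, DFT size (default 2N)."""

    window_length: int = 256
    hop: int = 64
    fft_size: int = 512
    window: str = "hamming"
    rate: float = DEFAULT_RATE

    def __post_init__(self) -> None:
        if not (0 < self.hop <= self.window_length):
            raise ValueError("require 0 < hop <= window_length")
        if self.fft_size < self.window_length:
            raise ValueError("fft_size must be >= window_length")

    @property
    def n_bins(self) -> int:
        return self.fft_size // 2 + 1

    @property
    def bin_spacing_hz(self) -> float:
        return self.rate / self.fft_size

    @property
    def hop_seconds(self) -> float:
        return self.hop / self.rate

    def taper(self) -> np.ndarray:
        # sym=False (periodic window) is the analysis convention for STFT
        return sps.get_window(self.window, self.window_length, fftbins=True)

    def to_dict(self) -> dict:
        return {
            "fs": self.rate,
            "window": self.window,
            "n": self.window_length,
            "hop": self.hop,
            "fft": self.fft_size,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StftConfig":
        return cls(
            window_length=int(d.get("n", 256)),
            hop=int(d.get("hop", 64)),
            fft_size=int(d.get("fft", 512)),
            window=str(d.get("window", "hamming")),
            rate=float(d.get("fs", DEFAULT_RATE)),
        )


@dataclass
class MagnitudeSpectrogram:
    """Non-negative F x T magnitude matrix with retained phase and scale.

    ``scale`` is the normalization divisor (mean magnitude at normalization
    time); it stays 1.0 until :func:`normalize_magnitude` is applied.
    """

    values: np.ndarray
    phase: np.ndarray
    config: StftConfig
    scale: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.phase = np.asarray(self.phase)
        if self.values.shape != self.phase.shape:
            raise ValueError("phase shape must equal values shape")
        if np.any(self.values < 0):
            raise ValueError("magnitude values must be non-negative")
        if self.scale <= 0:
            raise ValueError("scale must be positive")

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    def complex_values(self) -> np.ndarray:
        """De-normalized complex STFT: magnitude * scale * exp(i*phase)."""
        return self.values * self.scale * np.exp(1j * self.phase)


def load_audio(path: str | Path, target_rate: float = DEFAULT_RATE) -> AudioSignal:
    """Read a WAV file as a mono float signal at ``target_rate``.

    Multichannel input is mixed down by channel averaging; integer PCM is
    rescaled to [-1, 1]; resampling uses a polyphase filter.
    """
    rate, data = wavfile.read(str(path))
    if data.size == 0:
        raise ValueError(f"empty audio file: {path}")
    data = np.asarray(data)
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(np.float64) / float(np.iinfo(data.dtype).max)
    else:
        data = data.astype(np.float64)
    if data.ndim == 2:
        data = data.mean(axis=1)
    if rate != target_rate:
        frac = Fraction(target_rate / rate).limit_denominator(1000)
        data = sps.resample_poly(data, frac.numerator, frac.denominator)
    return AudioSignal(samples=data, rate=float(target_rate))


def save_audio(path: str | Path, signal: AudioSignal) -> None:
    """Write a mono float32 WAV file."""
    wavfile.write(str(path), int(signal.rate), signal.samples.astype(np.float32))


def compute_stft(signal: AudioSignal, config: StftConfig | None = None) -> MagnitudeSpectrogram:
    """Magnitude STFT with retained phase.

    Frames are left-aligned: frame t covers samples [t*hop, t*hop + N).  The
    window is zero-padded to ``fft_size`` before the DFT, so F = fft_size/2 + 1
    one-sided bins at spacing rate/fft_size Hz.
    """
    if config is None:
        config = StftConfig(rate=signal.rate)
    x = signal.samples
    n = config.window_length
    if len(x) < n:
        raise ValueError(f"signal ({len(x)} samples) shorter than one window ({n})")
    frames = sliding_window_view(x, n)[:: config.hop] * config.taper()
    spec = rfft(frames, n=config.fft_size, axis=1).T  # F x T
    return MagnitudeSpectrogram(
        values=np.abs(spec), phase=np.angle(spec), config=config, scale=1.0
    )


def normalize_magnitude(spec: MagnitudeSpectrogram) -> MagnitudeSpectrogram:
    """Divide the magnitude matrix by its global mean so mean(output) == 1.

    The divisor sum(X)/(F*T) is recorded in ``scale`` (composed with any
    existing scale) so the operation is invertible.
    """
    mean = float(spec.values.sum() / spec.values.size)
    if mean == 0.0:
        raise ValueError("cannot normalize an all-zero spectrogram")
    return replace(spec, values=spec.values / mean, scale=spec.scale * mean)


def denormalize(spec: MagnitudeSpectrogram) -> MagnitudeSpectrogram:
    """Undo :func:`normalize_magnitude` by multiplying back the recorded scale."""
    return replace(spec, values=spec.values * spec.scale, scale=1.0)


def synthesize(complex_spec: np.ndarray, config: StftConfig) -> AudioSignal:
    """Weighted overlap-add inverse STFT.

    ``complex_spec`` is a full complex F x T matrix (one-sided bins).  Each
    frame is inverse-DFT'd, truncated to the window length, weighted by the
    analysis window, and overlap-added; the result is divided by the summed
    squared window (floored where overlap is incomplete).  With this
    compensation the analysis-synthesis round trip is exact in the interior
    for any window/hop pair.
    """
    complex_spec = np.asarray(complex_spec)
    if complex_spec.shape[0] != config.n_bins:
        raise ValueError(
            f"expected {config.n_bins} frequency bins, got {complex_spec.shape[0]}"
        )
    n = config.window_length
    hop = config.hop
    win = config.taper()
    n_frames = complex_spec.shape[1]
    frames = irfft(complex_spec.T, n=config.fft_size, axis=1)[:, :n]
    out_len = (n_frames - 1) * hop + n
    out = np.zeros(out_len)
    wsum = np.zeros(out_len)
    wsq = win**2
    for t in range(n_frames):
        start = t * hop
        out[start : start + n] += frames[t] * win
        wsum[start : start + n] += wsq
    out /= np.maximum(wsum, 1e-12)
    return AudioSignal(samples=out, rate=config.rate)
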