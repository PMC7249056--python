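"""Synthetic wheeze/respiratory mixtures with SNR control and ground truth.

The generator emulates the acoustic structure of auscultation recordings:
wheezes are pitched, sustained (>100 ms) harmonic tones with fundamental in
100-1000 Hz (constant pitch or gentle linear chirp); normal respiratory
sounds are broadband noise concentrated in 60-1000 Hz with a smooth 1/f-like
spectral tilt, amplitude-modulated by per-stage breathing envelopes.
Mixtures are formed at a target wheeze-to-respiratory SNR by scaling the
lower-power signal, and ship with exact ground-truth sources, stage
boundaries and per-stage wheeze labels.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps

from .signal_frontend import DEFAULT_RATE, AudioSignal

__all__ = [
    "WheezeSpec",
    "RespiratorySpec",
    "MixtureCase",
    "generate_wheeze",
    "generate_respiratory",
    "draw_resonances",
    "mix_at_snr",
    "generate_training_y",
    "build_benchmark",
]

WHEEZE_BAND = (100.0, 1000.0)
RESP_BAND = (60.0, 1000.0)


@dataclass(frozen=True)
class WheezeSpec:
    """One wheeze event: pitch trajectory, duration, harmonics, placement."""

    f0_start: float = 400.0
    f0_end: float | None = None  # None = constant pitch
    duration: float = 0.6
    harmonics: tuple[float, ...] = (1.0, 0.4)
    onset: float = 0.0
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        end = self.f0_start if self.f0_end is None else self.f0_end
        lo, hi = min(self.f0_start, end), max(self.f0_start, end)
        if not (WHEEZE_BAND[0] <= lo and hi <= WHEEZE_BAND[1]):
            raise ValueError(
                f"fundamental trajectory [{lo}, {hi}] Hz outside {WHEEZE_BAND}"
            )
        if self.duration <= 0.1:
            raise ValueError("wheezes last longer than 100 ms")


@dataclass(frozen=True)
class RespiratorySpec:
    """Broadband breath-noise parameters.

    ``resonances`` are subject-specific spectral colorations, (center Hz,
    bandwidth Hz, linear gain) Gaussian bumps multiplying the in-band
    spectrum.  They emulate the airway/chest transfer function of one
    subject: shared by every stage of a recording, different between
    recordings, which is what limits how well respiratory material from other
    subjects can stand in as training data.
    """

    band: tuple[float, float] = RESP_BAND
    cycle_duration: float = 2.0  # seconds per inspiration/expiration stage
    n_stages: int = 4
    envelope_smoothness: float = 0.15  # attack/release fraction of a stage
    spectral_tilt: float = 0.5  # 1/f^tilt shaping inside the band
    amplitude: float = 1.0
    resonances: tuple[tuple[float, float, float], ...] = ()
    # inspiration/expiration alternation: odd stages (expirations) get a
    # steeper tilt, a reduced upper band edge and a lower level, so a single
    # clean stage never fully characterizes the recording's breath noise
    stage_contrast: float = 0.35

    def __post_init__(self) -> None:
        if self.band[0] < 0 or self.band[1] <= self.band[0]:
            raise ValueError("invalid band")
        if self.n_stages < 1:
            raise ValueError("n_stages >= 1")


@dataclass
class MixtureCase:
    """A generated mixture with exact ground truth."""

    mixture: AudioSignal
    wheeze: AudioSignal
    respiratory: AudioSignal
    stage_edges: list[int]  # sample indices, len n_stages + 1
    labels: list[int]  # per-stage wheeze presence
    snr_db: float
    seed: int


def generate_wheeze(spec: WheezeSpec, fs: float = DEFAULT_RATE, length: int | None = None) -> AudioSignal:
    """Harmonic tone following the pitch trajectory, raised-cosine faded.

    Harmonics whose frequency would exceed Nyquist are dropped.  If ``length``
    is given the event is placed at ``spec.onset`` inside a zero signal of
    that many samples.
    """
    n = int(round(spec.duration * fs))
    t = np.arange(n) / fs
    f0 = np.linspace(spec.f0_start, spec.f0_end or spec.f0_start, n)
    phase = 2 * np.pi * np.cumsum(f0) / fs
    out = np.zeros(n)
    for h, amp in enumerate(spec.harmonics, start=1):
        if np.max(f0) * h < fs / 2:
            out += amp * np.sin(h * phase)
    fade = max(2, int(0.05 * n))
    env = np.ones(n)
    ramp = 0.5 * (1 - np.cos(np.pi * np.arange(fade) / fade))
    env[:fade] = ramp
    env[-fade:] = ramp[::-1]
    out *= spec.amplitude * env
    if length is not None:
        sig = np.zeros(length)
        start = int(round(spec.onset * fs))
        stop = min(start + n, length)
        sig[start:stop] = out[: stop - start]
        out = sig
    return AudioSignal(samples=out, rate=fs)


def _shaped_noise(n: int, fs: float, spec: RespiratorySpec, rng: np.random.Generator) -> np.ndarray:
    """Band-limited Gaussian noise with a smooth 1/f^tilt spectral shape."""
    white = rng.standard_normal(n)
    freqs = np.fft.rfftfreq(n, 1 / fs)
    shape = np.zeros_like(freqs)
    lo, hi = spec.band
    in_band = (freqs >= lo) & (freqs <= hi)
    shape[in_band] = (np.maximum(freqs[in_band], lo)) ** (-spec.spectral_tilt)
    for fc, bw, gain in spec.resonances:
        shape *= 1.0 + gain * np.exp(-0.5 * ((freqs - fc) / bw) ** 2)
    spectrum = np.fft.rfft(white) * shape
    return np.fft.irfft(spectrum, n=n)


def draw_resonances(
    rng: np.random.Generator, n_min: int = 2, n_max: int = 4
) -> tuple[tuple[float, float, float], ...]:
    """Random subject-specific resonances within the wheeze-free band."""
    k = int(rng.integers(n_min, n_max + 1))
    return tuple(
        (float(rng.uniform(100.0, 900.0)), float(rng.uniform(30.0, 120.0)),
         float(rng.uniform(0.5, 2.0)))
        for _ in range(k)
    )


def generate_respiratory(
    spec: RespiratorySpec, fs: float = DEFAULT_RATE, seed: int = 0
) -> tuple[AudioSignal, list[int]]:
    """Breath noise over ``n_stages`` stages; returns (signal, stage edges).

    Each stage is independently drawn shaped noise under a smooth
    inhale/exhale amplitude envelope; edges are sample indices of stage
    boundaries (length n_stages + 1).
    """
    rng = np.random.default_rng(seed)
    stage_len = int(round(spec.cycle_duration * fs))
    parts = []
    for s in range(spec.n_stages):
        is_exp = s % 2 == 1
        c = spec.stage_contrast if is_exp else 0.0
        stage_spec = replace(
            spec,
            spectral_tilt=spec.spectral_tilt + c,
            band=(spec.band[0], spec.band[1] * (1.0 - 0.3 * c)),
        )
        noise = _shaped_noise(stage_len, fs, stage_spec, rng)
        att = max(2, int(spec.envelope_smoothness * stage_len))
        env = np.ones(stage_len)
        ramp = 0.5 * (1 - np.cos(np.pi * np.arange(att) / att))
        env[:att] = ramp
        env[-att:] = ramp[::-1]
        # expirations are quieter; mild per-stage loudness jitter on top
        level = (0.6 if is_exp else 1.0) * (0.85 + 0.3 * rng.uniform())
        parts.append(noise * env * level)
    samples = np.concatenate(parts)
    rms = np.sqrt(np.mean(samples**2))
    samples = spec.amplitude * samples / max(rms, 1e-300)
    edges = [i * stage_len for i in range(spec.n_stages + 1)]
    return AudioSignal(samples=samples, rate=fs), edges


def mix_at_snr(
    w: AudioSignal, r: AudioSignal, snr_db: float
) -> tuple[AudioSignal, AudioSignal, AudioSignal]:
    """Mix wheeze and respiratory signals at a target SNR (w relative to r).

    The higher-power signal is left fixed and the other is scaled so that
    10*log10(P_w / P_r) equals ``snr_db`` (powers over the whole signals).
    Ties are broken by fixing the wheeze.  Returns (mixture, scaled_w,
    scaled_r) with mixture = scaled_w + scaled_r exactly.
    """
    if len(w.samples) != len(r.samples) or w.rate != r.rate:
        raise ValueError("signals must share length and rate")
    p_w, p_r = w.power(), r.power()
    if p_w == 0 or p_r == 0:
        raise ValueError("zero-power input")
    target_ratio = 10.0 ** (snr_db / 10.0)
    if p_w >= p_r:
        w_s = w.samples
        r_s = r.samples * np.sqrt(p_w / (target_ratio * p_r))
    else:
        r_s = r.samples
        w_s = w.samples * np.sqrt(target_ratio * p_r / p_w)
    scaled_w = AudioSignal(w_s, w.rate)
    scaled_r = AudioSignal(r_s, r.rate)
    mixture = AudioSignal(w_s + r_s, w.rate)
    return mixture, scaled_w, scaled_r


def generate_training_y(
    fs: float = DEFAULT_RATE,
    total_duration: float = 128.0,
    n_stages: int = 54,
    seed: int = 777_000,
) -> AudioSignal:
    """Respiratory-only training signal: concatenated wheeze-free stages.

    Defaults produce 128 s over 54 stages.  Stages are drawn pairwise
    (inspiration + expiration) from different synthetic subjects, each with
    its own band edges, tilt and resonances, so the training material mixes
    many subjects and both stage types; the seed space is disjoint from the
    benchmark mixtures by the default offset.
    """
    if n_stages < 1:
        raise ValueError("n_stages >= 1")
    rng = np.random.default_rng(seed)
    stage_dur = total_duration / n_stages
    parts = []
    remaining = n_stages
    while remaining > 0:
        take = min(2, remaining)
        spec = RespiratorySpec(
            band=(60.0 + 20.0 * rng.uniform(), 900.0 + 200.0 * rng.uniform()),
            cycle_duration=stage_dur,
            n_stages=take,
            spectral_tilt=0.3 + 0.4 * rng.uniform(),
            resonances=draw_resonances(rng),
        )
        sig, _ = generate_respiratory(spec, fs, seed=int(rng.integers(2**31)))
        parts.append(sig.samples)
        remaining -= take
    return AudioSignal(np.concatenate(parts), fs)


def build_benchmark(
    n_cases: int = 16,
    snr_db: float = 0.0,
    seed: int = 0,
    fs: float = DEFAULT_RATE,
    stage_duration: float = 2.0,
    min_stages: int = 4,
    max_stages: int = 8,
) -> list[MixtureCase]:
    """A suite of labeled mixtures at one SNR.

    Every case has ``min_stages``..``max_stages`` respiratory stages, 1-5
    wheezes confined to a strict subset of stages (at least one stage stays
    wheeze-free), exact ground truth, and per-stage labels matching wheeze
    placement.  Case i uses the deterministic seed ``seed * 10000 + i``.
    """
    if n_cases < 1:
        raise ValueError("n_cases >= 1")
    cases = []
    for i in range(n_cases):
        case_seed = seed * 10_000 + i
        rng = np.random.default_rng(case_seed)
        n_stages = int(rng.integers(min_stages, max_stages + 1))
        resp_spec = RespiratorySpec(
            cycle_duration=stage_duration,
            n_stages=n_stages,
            spectral_tilt=0.3 + 0.4 * rng.uniform(),
            resonances=draw_resonances(rng),
        )
        resp, edges = generate_respiratory(resp_spec, fs, seed=int(rng.integers(2**31)))
        total_len = len(resp.samples)

        n_wheezes = int(rng.integers(1, 6))
        # wheezes occupy a strict subset of stages: >=1 stage stays clean
        n_wheezy = int(rng.integers(1, n_stages))  # 1 .. n_stages-1
        wheezy_stages = sorted(rng.choice(n_stages, size=n_wheezy, replace=False).tolist())
        wheeze_total = np.zeros(total_len)
        for _ in range(n_wheezes):
            stage = int(rng.choice(wheezy_stages))
            f0 = float(rng.uniform(120.0, 900.0))
            chirp = float(rng.uniform(-0.15, 0.15)) * f0
            f0_end = float(np.clip(f0 + chirp, 100.0, 1000.0))
            dur = float(rng.uniform(0.15, 0.8 * stage_duration))
            margin = stage_duration - dur
            onset = edges[stage] / fs + float(rng.uniform(0.0, max(margin, 0.01)))
            wspec = WheezeSpec(
                f0_start=f0,
                f0_end=f0_end,
                duration=dur,
                harmonics=(1.0, float(rng.uniform(0.2, 0.6))),
                onset=onset,
                amplitude=float(rng.uniform(0.5, 1.0)),
            )
            wheeze_total += generate_wheeze(wspec, fs, length=total_len).samples
        wheeze = AudioSignal(wheeze_total, fs)
        mixture, w_scaled, r_scaled = mix_at_snr(wheeze, resp, snr_db)
        labels = [1 if s in wheezy_stages else 0 for s in range(n_stages)]
        cases.append(
            MixtureCase(
                mixture=mixture,
                wheeze=w_scaled,
                respiratory=r_scaled,
                stage_edges=edges,
                labels=labels,
                snr_db=snr_db,
                seed=case_seed,
            )
        )
    return cases
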