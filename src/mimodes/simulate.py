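"""Seeded synthetic fixtures: decomposition test signals and two-class
motor-imagery EEG with event-related desynchronization (ERD).

Imagery trials attenuate the mu (8-12 Hz) and beta (18-26 Hz) rhythm
amplitudes on the contralateral channel (C3 for right-hand imagery) by a
configurable ERD depth over a 1/f background; relaxed trials keep full
rhythm amplitude everywhere. Every generator is a pure function of its
configuration and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.signal

from .errors import ConfigurationError
from .signals import Signal, TrialSet

__all__ = [
    "MiSimConfig",
    "make_test_signal",
    "simulate_mi_trials",
    "simulate_state_energy_pair",
]

#: channel attenuated during imagery (contralateral to right-hand imagery)
ERD_CHANNEL = "C3"


@dataclass(frozen=True)
class MiSimConfig:
    n_trials_per_class: int = 100
    channels: tuple = ("C3", "Cz", "C4")
    sampling_rate: float = 250.0
    samples_per_trial: int = 2000
    mu_band: tuple = (8.0, 12.0)
    beta_band: tuple = (18.0, 26.0)
    mu_amplitude: float = 1.0
    beta_amplitude: float = 0.5
    erd_depth: float = 0.5
    background: str = "pink"
    snr_db: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials_per_class < 1:
            raise ConfigurationError("n_trials_per_class must be >= 1")
        if not 0.0 <= self.erd_depth <= 1.0:
            raise ConfigurationError("erd_depth must be in [0, 1]")
        if self.background not in ("pink", "white"):
            raise ConfigurationError("background must be 'pink' or 'white'")
        if self.samples_per_trial < 16:
            raise ConfigurationError("samples_per_trial must be >= 16")
        if ERD_CHANNEL not in self.channels:
            raise ConfigurationError(f"channels must include {ERD_CHANNEL!r}")
        object.__setattr__(self, "channels", tuple(self.channels))
        object.__setattr__(self, "mu_band", tuple(float(f) for f in self.mu_band))
        object.__setattr__(self, "beta_band", tuple(float(f) for f in self.beta_band))


def _pink_noise(rng: np.random.Generator, n: int) -> np.ndarray:
    """Unit-variance 1/f noise via spectral shaping of white noise."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    scale = np.zeros_like(freqs)
    scale[1:] = 1.0 / np.sqrt(freqs[1:])
    x = np.fft.irfft(spec * scale, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _band_rhythm(
    rng: np.random.Generator, n: int, fs: float, band: tuple[float, float]
) -> np.ndarray:
    """Unit-RMS band-limited Gaussian oscillation (random phase by nature)."""
    sos = scipy.signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    x = scipy.signal.sosfiltfilt(sos, rng.standard_normal(n))
    rms = np.sqrt(np.mean(x * x))
    return x / rms if rms > 0 else x


def make_test_signal(kind: str, params: dict | None = None, seed: int = 0):
    """Analytic test signals with recorded ground-truth parts.

    Kinds: ``tone``, ``two_tone``, ``chirp``, ``tone_plus_trend``,
    ``intermittent``. Returns ``(Signal, parts)`` where ``parts`` maps
    component names to sample arrays summing exactly to the signal.
    """
    p = dict(params or {})
    fs = float(p.pop("sampling_rate", 250.0))
    duration = float(p.pop("duration", 8.0))
    n = int(round(fs * duration))
    t = np.arange(n) / fs
    rng = np.random.default_rng(seed)
    parts: dict[str, np.ndarray]
    if kind == "tone":
        f = float(p.pop("frequency", 10.0))
        a = float(p.pop("amplitude", 1.0))
        phase = float(p.pop("phase", -np.pi / 2))  # peak amplitude = a
        parts = {"tone": a * np.sin(2 * np.pi * f * t + phase)}
    elif kind == "two_tone":
        f1 = float(p.pop("f_slow", 1.0))
        f2 = float(p.pop("f_fast", 12.0))
        a1 = float(p.pop("a_slow", 1.0))
        a2 = float(p.pop("a_fast", 0.5))
        parts = {
            "slow": a1 * np.sin(2 * np.pi * f1 * t),
            "fast": a2 * np.sin(2 * np.pi * f2 * t),
        }
    elif kind == "chirp":
        f0 = float(p.pop("f0", 2.0))
        f1 = float(p.pop("f1", 20.0))
        parts = {"chirp": scipy.signal.chirp(t, f0, t[-1] if n else 1.0, f1)}
    elif kind == "tone_plus_trend":
        f = float(p.pop("frequency", 5.0))
        slope = float(p.pop("slope", 0.1))
        parts = {
            "tone": np.sin(2 * np.pi * f * t),
            "trend": slope * t,
        }
    elif kind == "intermittent":
        f_base = float(p.pop("f_base", 1.0))
        f_burst = float(p.pop("f_burst", 25.0))
        a_burst = float(p.pop("a_burst", 0.4))
        start = float(p.pop("burst_start", 0.25))
        stop = float(p.pop("burst_stop", 0.45))
        window = ((t >= start * duration) & (t < stop * duration)).astype(float)
        phase = rng.uniform(0, 2 * np.pi)
        parts = {
            "base": np.sin(2 * np.pi * f_base * t),
            "burst": a_burst * window * np.sin(2 * np.pi * f_burst * t + phase),
        }
    else:
        raise ConfigurationError(f"unknown test-signal kind {kind!r}")
    if p:
        raise ConfigurationError(f"unused parameters for kind {kind!r}: {sorted(p)}")
    total = np.sum(list(parts.values()), axis=0)
    return Signal(total, fs, channel_label=kind), parts


def simulate_mi_trials(config: MiSimConfig | None = None) -> TrialSet:
    """Two-class motor-imagery trial set with contralateral ERD.

    Relaxed trials carry full-amplitude mu+beta rhythms on every channel;
    imagery trials multiply both rhythm amplitudes on the ERD channel (C3)
    by ``1 - erd_depth``. Background noise (pink or white) is scaled from
    the relaxed-state rhythm power by ``snr_db`` and is identical in law
    across classes. Balanced labels; bitwise-reproducible per seed.
    """
    cfg = config or MiSimConfig()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.samples_per_trial
    fs = cfg.sampling_rate
    rhythm_power = cfg.mu_amplitude**2 + cfg.beta_amplitude**2
    noise_sd = np.sqrt(rhythm_power) / 10.0 ** (cfg.snr_db / 20.0)
    erd_gain = 1.0 - cfg.erd_depth

    trials = np.empty((2 * cfg.n_trials_per_class, len(cfg.channels), n))
    labels: list[str] = []
    for i in range(2 * cfg.n_trials_per_class):
        label = "relaxed" if i < cfg.n_trials_per_class else "imagery"
        labels.append(label)
        for c, ch in enumerate(cfg.channels):
            mu = cfg.mu_amplitude * _band_rhythm(rng, n, fs, cfg.mu_band)
            beta = cfg.beta_amplitude * _band_rhythm(rng, n, fs, cfg.beta_band)
            gain = erd_gain if (label == "imagery" and ch == ERD_CHANNEL) else 1.0
            if cfg.background == "pink":
                noise = _pink_noise(rng, n)
            else:
                noise = rng.standard_normal(n)
            trials[i, c] = gain * (mu + beta) + noise_sd * noise
    return TrialSet(
        trials=trials,
        labels=labels,
        channel_names=list(cfg.channels),
        sampling_rate=fs,
    )


def simulate_state_energy_pair(
    gain_high: float,
    gain_low: float,
    n_signals: int = 8,
    seed: int = 0,
    sampling_rate: float = 250.0,
    n_samples: int = 1000,
    snr_db: float = 30.0,
) -> tuple[list[Signal], list[Signal]]:
    """Matched oscillatory signal sets differing only in amplitude gain.

    Exercises IMF-energy separation between a high-arousal and a low-arousal
    state: at matched seeds the two sets share waveforms up to the gain.
    """
    if not gain_high > gain_low > 0:
        raise ConfigurationError("need gain_high > gain_low > 0")
    base_rng = np.random.default_rng(seed)
    high: list[Signal] = []
    low: list[Signal] = []
    t = np.arange(n_samples) / sampling_rate
    for _ in range(n_signals):
        f = base_rng.uniform(6.0, 14.0)
        phase = base_rng.uniform(0, 2 * np.pi)
        clean = np.sin(2 * np.pi * f * t + phase)
        noise = base_rng.standard_normal(n_samples) / 10.0 ** (snr_db / 20.0)
        wave = clean + noise
        high.append(Signal(gain_high * wave, sampling_rate))
        low.append(Signal(gain_low * wave, sampling_rate))
    return high, low
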