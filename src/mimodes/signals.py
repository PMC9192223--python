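"""Core data containers: single-channel signals and labeled multichannel trial sets."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, DegenerateInputError

#: class tokens accepted in label files
KNOWN_LABELS = frozenset({"relaxed", "imagery", "left", "right"})


@dataclass(frozen=True)
class Signal:
    """One channel of uniformly sampled data.

    Parameters
    ----------
    samples
        Real-valued sequence, arbitrary units (e.g. microvolts). At least 4
        samples, all finite.
    sampling_rate
        Sampling frequency in Hz, strictly positive.
    channel_label
        Optional channel name (e.g. ``"C3"``).
    """

    samples: np.ndarray
    sampling_rate: float
    channel_label: str | None = None

    def __post_init__(self) -> None:
        x = np.asarray(self.samples, dtype=np.float64)
        if x.ndim != 1:
            raise DegenerateInputError("samples must be one-dimensional")
        if x.size < 4:
            raise DegenerateInputError(
                f"signal needs at least 4 samples, got {x.size}"
            )
        if not np.all(np.isfinite(x)):
            raise DegenerateInputError("samples contain non-finite values")
        if not (self.sampling_rate > 0):
            raise ConfigurationError("sampling_rate must be > 0")
        object.__setattr__(self, "samples", x)
        object.__setattr__(self, "sampling_rate", float(self.sampling_rate))

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Length in seconds."""
        return self.n_samples / self.sampling_rate

    def times(self) -> np.ndarray:
        """Sample times in seconds; sample i occurs at i / sampling_rate."""
        return np.arange(self.n_samples) / self.sampling_rate

    def replace_samples(self, samples: np.ndarray) -> "Signal":
        """New Signal with the same metadata but different samples."""
        return Signal(samples, self.sampling_rate, self.channel_label)


def as_samples(signal) -> np.ndarray:
    """Return the float64 sample array of a Signal or array-like input."""
    if isinstance(signal, Signal):
        return signal.samples
    x = np.asarray(signal, dtype=np.float64)
    if x.ndim != 1:
        raise DegenerateInputError("expected a one-dimensional sequence")
    return x


@dataclass
class TrialSet:
    """Labeled multichannel trials sharing a common shape and sampling rate.

    ``trials`` has shape (n_trials, n_channels, n_samples). Labels are class
    tokens, one per trial (``relaxed``/``imagery`` or ``left``/``right``).
    """

    trials: np.ndarray
    labels: list[str]
    channel_names: list[str]
    sampling_rate: float
    trial_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.trials = np.asarray(self.trials, dtype=np.float64)
        if self.trials.ndim != 3:
            raise DegenerateInputError(
                "trials must have shape (n_trials, n_channels, n_samples)"
            )
        if len(self.labels) != self.trials.shape[0]:
            raise DegenerateInputError(
                f"{len(self.labels)} labels for {self.trials.shape[0]} trials"
            )
        for lab in self.labels:
            if lab not in KNOWN_LABELS:
                raise ConfigurationError(
                    f"unknown class label {lab!r}; expected one of "
                    f"{sorted(KNOWN_LABELS)}"
                )
        if len(self.channel_names) != self.trials.shape[1]:
            raise DegenerateInputError(
                f"{len(self.channel_names)} channel names for "
                f"{self.trials.shape[1]} channels"
            )
        if not (self.sampling_rate > 0):
            raise ConfigurationError("sampling_rate must be > 0")
        if not self.trial_ids:
            self.trial_ids = [f"trial_{i:04d}" for i in range(self.n_trials)]

    @property
    def n_trials(self) -> int:
        return self.trials.shape[0]

    @property
    def n_channels(self) -> int:
        return self.trials.shape[1]

    @property
    def n_samples(self) -> int:
        return self.trials.shape[2]

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise ConfigurationError(
                f"channel {name!r} not present; available: {self.channel_names}"
            ) from None

    def channel_signal(self, trial: int, name: str) -> Signal:
        """Extract one channel of one trial as a Signal."""
        return Signal(
            self.trials[trial, self.channel_index(name)],
            self.sampling_rate,
            channel_label=name,
        )

    def classes(self) -> list[str]:
        """Distinct labels in stable first-appearance order."""
        seen: list[str] = []
        for lab in self.labels:
            if lab not in seen:
                seen.append(lab)
        return seen

    def subset(self, indices) -> "TrialSet":
        idx = list(indices)
        return TrialSet(
            self.trials[idx],
            [self.labels[i] for i in idx],
            list(self.channel_names),
            self.sampling_rate,
            trial_ids=[self.trial_ids[i] for i in idx],
        )
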