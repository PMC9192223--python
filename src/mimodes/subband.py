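"""Wavelet-packet preprocessing and per-class data-matrix assembly.

The pipeline stage implemented here: (optional) wavelet denoising, level-4
wavelet-packet split of each chosen channel, EMD of the selected narrowband
nodes, retention of the most signal-correlated IMFs (in practice the first
two), and stacking of the retained IMFs into the per-class matrix fed to
CSP — 2 channels x 2 nodes x 2 IMFs = 8 rows of 2000 samples at the
defaults.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .emd import Decomposition, EmdConfig, emd
from .errors import ConfigurationError, DegenerateInputError
from .signals import Signal, TrialSet, as_samples
from .wavelets import (
    natural_node_index,
    pad_to_multiple,
    wavedec,
    waverec,
    wavelet_filters,
    wpt_node_coefficients,
    wpt_node_reconstruct,
)

__all__ = [
    "SubbandSelection",
    "ReconstructedMatrix",
    "wavelet_denoise",
    "wpt_decompose",
    "select_imfs_by_correlation",
    "build_trial_matrix",
    "build_class_matrix",
]


@dataclass(frozen=True)
class SubbandSelection:
    """Which wavelet-packet nodes to keep and how many IMFs of each."""

    wpt_level: int = 4
    nodes: tuple = ((4, 1), (4, 3))
    imfs_kept: int = 2
    wavelet_name: str = "db4"
    node_order: str = "frequency"

    def __post_init__(self) -> None:
        if self.wpt_level < 1:
            raise ConfigurationError("wpt_level must be >= 1")
        if self.imfs_kept < 1:
            raise ConfigurationError("imfs_kept must be >= 1")
        object.__setattr__(self, "nodes", tuple((int(l), int(i)) for l, i in self.nodes))
        for lev, idx in self.nodes:
            if lev < 1 or lev > self.wpt_level:
                raise ConfigurationError(
                    f"node level {lev} outside [1, wpt_level={self.wpt_level}]"
                )
            if not 0 <= idx < (1 << lev):
                raise ConfigurationError(
                    f"node index {idx} out of range for level {lev}"
                )
        wavelet_filters(self.wavelet_name)  # validates the name
        if self.node_order not in ("natural", "frequency"):
            raise ConfigurationError(
                f"node_order must be 'natural' or 'frequency', got {self.node_order!r}"
            )


@dataclass
class ReconstructedMatrix:
    """Stacked retained-IMF rows for one trial.

    ``row_annotations[i]`` is ``(channel, node, imf_index)``; ``imf_index``
    is None for zero rows padded when a node's EMD yielded too few IMFs.
    """

    data: np.ndarray
    row_annotations: list[tuple]
    class_label: str

    @property
    def n_rows(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


def wavelet_denoise(signal, wavelet_name: str = "db4", level: int = 4):
    """Soft-threshold wavelet denoising at the universal threshold.

    The noise scale is estimated from the finest detail coefficients as
    ``MAD / 0.6745`` and every detail level is soft-thresholded at
    ``sigma * sqrt(2 ln n)`` before inverse transform.
    """
    x = as_samples(signal)
    if x.size < (1 << level):
        raise DegenerateInputError(
            f"signal of {x.size} samples too short for level {level}"
        )
    padded = pad_to_multiple(x, 1 << level)
    coeffs = wavedec(padded, wavelet_name, level)
    finest = coeffs[-1]
    sigma = float(np.median(np.abs(finest))) / 0.6745
    thr = sigma * np.sqrt(2.0 * np.log(padded.size))
    out = [coeffs[0]]
    for d in coeffs[1:]:
        out.append(np.sign(d) * np.maximum(np.abs(d) - thr, 0.0))
    rec = waverec(out, wavelet_name)[: x.size]
    if isinstance(signal, Signal):
        return signal.replace_samples(rec)
    return rec


def wpt_decompose(signal, selection: SubbandSelection) -> dict:
    """Reconstruct each requested wavelet-packet node at full signal length.

    Returns a mapping ``(level, index) -> Signal`` (index in the selection's
    ``node_order`` convention). Each reconstruction is the node's isolated
    contribution; summing the reconstructions of all ``2**level`` nodes of a
    level recovers the input.
    """
    x = as_samples(signal)
    if x.size < (1 << selection.wpt_level):
        raise DegenerateInputError(
            f"signal of {x.size} samples too short for level {selection.wpt_level}"
        )
    fs = signal.sampling_rate if isinstance(signal, Signal) else 1.0
    out = {}
    for lev, idx in selection.nodes:
        nat = natural_node_index(lev, idx, selection.node_order)
        padded = pad_to_multiple(x, 1 << lev)
        coeffs = wpt_node_coefficients(padded, selection.wavelet_name, lev, nat)
        rec = wpt_node_reconstruct(coeffs, selection.wavelet_name, lev, nat)[: x.size]
        label = None
        if isinstance(signal, Signal) and signal.channel_label:
            label = f"{signal.channel_label}:({lev},{idx})"
        out[(lev, idx)] = Signal(rec, fs, channel_label=label)
    return out


def select_imfs_by_correlation(decomp: Decomposition, original, k: int) -> list[int]:
    """Indices (0-based, ascending) of the k IMFs most correlated with the source.

    Ranking is by absolute Pearson correlation with ties broken toward the
    lower IMF index; zero-variance IMFs score 0. If the decomposition has
    fewer than k IMFs, all indices are returned with a warning.
    """
    if decomp.n_imfs == 0:
        raise DegenerateInputError("decomposition has no IMFs")
    if k < 1:
        raise ConfigurationError("k must be >= 1")
    x = as_samples(original)
    if decomp.n_imfs <= k:
        if decomp.n_imfs < k:
            warnings.warn(
                f"requested {k} IMFs but decomposition has {decomp.n_imfs}",
                stacklevel=2,
            )
        return list(range(decomp.n_imfs))
    xc = x - x.mean()
    xnorm = float(np.linalg.norm(xc))
    scores = np.zeros(decomp.n_imfs)
    for j, c in enumerate(decomp.imfs):
        cc = c - c.mean()
        cnorm = float(np.linalg.norm(cc))
        if cnorm > 0 and xnorm > 0:
            scores[j] = abs(float(np.dot(xc, cc)) / (xnorm * cnorm))
    order = np.argsort(-scores, kind="stable")  # stable: ties -> lower index
    return sorted(int(j) for j in order[:k])


def build_trial_matrix(
    trial: np.ndarray,
    channel_names: list[str],
    sampling_rate: float,
    selection: SubbandSelection,
    channels=("C3", "C4"),
    class_label: str = "",
    emd_config: EmdConfig | None = None,
    denoise: bool = False,
) -> ReconstructedMatrix:
    """Sub-band/EMD rows for a single (channels x samples) trial."""
    name_to_row = {nm: i for i, nm in enumerate(channel_names)}
    for ch in channels:
        if ch not in name_to_row:
            raise ConfigurationError(
                f"channel {ch!r} not present; available: {list(channel_names)}"
            )
    rows: list[np.ndarray] = []
    ann: list[tuple] = []
    n_samples = trial.shape[1]
    for ch in channels:
        sig = Signal(trial[name_to_row[ch]], sampling_rate, channel_label=ch)
        if denoise:
            sig = wavelet_denoise(sig, selection.wavelet_name, selection.wpt_level)
        nodes = wpt_decompose(sig, selection)
        for node in selection.nodes:
            node_sig = nodes[node]
            dec = emd(node_sig, emd_config)
            if dec.n_imfs == 0:
                kept: list[int] = []
            else:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    kept = select_imfs_by_correlation(dec, node_sig, selection.imfs_kept)
            for j in kept[: selection.imfs_kept]:
                rows.append(dec.imfs[j])
                ann.append((ch, node, j))
            for _ in range(selection.imfs_kept - len(kept)):
                # zero-pad so the row-count contract holds regardless of EMD depth
                rows.append(np.zeros(n_samples))
                ann.append((ch, node, None))
    return ReconstructedMatrix(
        data=np.vstack(rows), row_annotations=ann, class_label=class_label
    )


def build_class_matrix(
    trials: TrialSet,
    selection: SubbandSelection | None = None,
    channels=("C3", "C4"),
    emd_config: EmdConfig | None = None,
    denoise: bool = False,
) -> dict[str, list[ReconstructedMatrix]]:
    """Per-class lists of reconstructed trial matrices.

    Each trial contributes one matrix with
    ``len(channels) * len(selection.nodes) * selection.imfs_kept`` rows and
    the trial's full sample count, rows ordered lexicographically by
    (channel, node, imf index).
    """
    sel = selection or SubbandSelection()
    out: dict[str, list[ReconstructedMatrix]] = {}
    for i in range(trials.n_trials):
        mat = build_trial_matrix(
            trials.trials[i],
            trials.channel_names,
            trials.sampling_rate,
            sel,
            channels=channels,
            class_label=trials.labels[i],
            emd_config=emd_config,
            denoise=denoise,
        )
        out.setdefault(trials.labels[i], []).append(mat)
    return out
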