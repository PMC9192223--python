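"""Orthogonal wavelet filter bank with periodized boundary handling.

Self-contained DWT / wavelet-packet primitives used by the sub-band stage.
Analysis uses circular (periodized) convolution with downsampling by 2, so
the transform is an orthogonal matrix and synthesis is its transpose:
perfect reconstruction is exact for even-length inputs.
"""

from __future__ import annotations

import numpy as np

from .errors import ConfigurationError

# Orthonormal scaling (lowpass) filters; sum = sqrt(2).
_SCALING_FILTERS = {
    "haar": np.array([0.7071067811865476, 0.7071067811865476]),
    "db1": np.array([0.7071067811865476, 0.7071067811865476]),
    "db2": np.array(
        [
            0.48296291314469025,
            0.8365163037378079,
            0.22414386804185735,
            -0.12940952255092145,
        ]
    ),
    "db4": np.array(
        [
            0.23037781330885523,
            0.7148465705525415,
            0.6308807679295904,
            -0.02798376941698385,
            -0.18703481171888114,
            0.030841381835986965,
            0.032883011666982945,
            -0.010597401784997278,
        ]
    ),
}


def wavelet_filters(name: str) -> tuple[np.ndarray, np.ndarray]:
    """(lowpass, highpass) analysis filters via the quadrature-mirror rule."""
    try:
        lo = _SCALING_FILTERS[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown wavelet {name!r}; available: {sorted(_SCALING_FILTERS)}"
        ) from None
    hi = (lo[::-1] * np.power(-1.0, np.arange(lo.size)))
    return lo, hi


def _analysis(x: np.ndarray, filt: np.ndarray) -> np.ndarray:
    # circular convolution + dyadic downsampling; len(x) must be even
    n = x.size
    idx = (np.arange(0, n, 2)[:, None] + np.arange(filt.size)[None, :]) % n
    return x[idx] @ filt


def _synthesis(approx, detail, lo, hi, n: int) -> np.ndarray:
    # transpose of the analysis operator (orthogonal => inverse)
    out = np.zeros(n)
    pos = np.arange(0, n, 2)
    for m in range(lo.size):
        tgt = (pos + m) % n
        if approx is not None:
            out[tgt] += lo[m] * approx
        if detail is not None:
            out[tgt] += hi[m] * detail
    return out


def dwt_step(x: np.ndarray, wavelet: str) -> tuple[np.ndarray, np.ndarray]:
    """One periodized analysis step -> (approximation, detail)."""
    if x.size % 2:
        raise ConfigurationError("dwt_step requires even length")
    lo, hi = wavelet_filters(wavelet)
    return _analysis(x, lo), _analysis(x, hi)


def idwt_step(approx: np.ndarray, detail: np.ndarray, wavelet: str) -> np.ndarray:
    lo, hi = wavelet_filters(wavelet)
    return _synthesis(approx, detail, lo, hi, 2 * approx.size)


def pad_to_multiple(x: np.ndarray, block: int) -> np.ndarray:
    """Edge-pad at the end so the length is a multiple of ``block``."""
    rem = x.size % block
    if rem == 0:
        return x
    return np.concatenate([x, np.full(block - rem, x[-1])])


def wavedec(x: np.ndarray, wavelet: str, level: int) -> list[np.ndarray]:
    """Multilevel DWT -> [a_L, d_L, d_{L-1}, ..., d_1]; len(x) % 2**level == 0."""
    if x.size % (1 << level):
        raise ConfigurationError("signal length must be divisible by 2**level")
    coeffs: list[np.ndarray] = []
    a = x
    for _ in range(level):
        a, d = dwt_step(a, wavelet)
        coeffs.append(d)
    coeffs.append(a)
    return coeffs[::-1]


def waverec(coeffs: list[np.ndarray], wavelet: str) -> np.ndarray:
    a = coeffs[0]
    for d in coeffs[1:]:
        a = idwt_step(a, d, wavelet)
    return a


def natural_node_index(level: int, index: int, order: str) -> int:
    """Map a node index in the given ordering to the tree's natural index.

    ``frequency`` (sequency) order sorts nodes by passband center; the
    natural index is the binary-to-Gray-code image of the frequency index.
    """
    if not 0 <= index < (1 << level):
        raise ConfigurationError(
            f"node index {index} out of range for level {level}"
        )
    if order == "natural":
        return index
    if order == "frequency":
        return index ^ (index >> 1)
    raise ConfigurationError(f"node_order must be 'natural' or 'frequency', got {order!r}")


def node_band(level: int, freq_index: int, sampling_rate: float) -> tuple[float, float]:
    """Nominal passband (Hz) of a frequency-ordered node at ``level``."""
    width = sampling_rate / 2 / (1 << level)
    return freq_index * width, (freq_index + 1) * width


def _node_path(level: int, natural_index: int) -> list[int]:
    # branch bits from the root: 0 = lowpass child, 1 = highpass child
    return [(natural_index >> (level - 1 - b)) & 1 for b in range(level)]


def wpt_node_coefficients(x: np.ndarray, wavelet: str, level: int, natural_index: int) -> np.ndarray:
    """Coefficients of one packet node; len(x) % 2**level == 0."""
    if x.size % (1 << level):
        raise ConfigurationError("signal length must be divisible by 2**level")
    data = x
    for bit in _node_path(level, natural_index):
        a, d = dwt_step(data, wavelet)
        data = d if bit else a
    return data


def wpt_node_reconstruct(
    coeffs: np.ndarray, wavelet: str, level: int, natural_index: int
) -> np.ndarray:
    """Time-domain contribution of one packet node (all other nodes zero)."""
    data = coeffs
    for bit in reversed(_node_path(level, natural_index)):
        if bit:
            data = idwt_step(np.zeros_like(data), data, wavelet)
        else:
            data = idwt_step(data, np.zeros_like(data), wavelet)
    return data
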