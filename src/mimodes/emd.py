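"""Empirical mode decomposition by envelope-mean sifting.

The sifting loop refines a proto-IMF ``h <- h - mean_envelope(h)`` until the
normalized squared change between successive proto-IMFs (the SD statistic)
drops below a threshold, conventionally chosen in [0.2, 0.3]. IMFs are peeled
off successive residuals until the residual is monotone or nearly so; the sum
of all IMFs plus the final residual reproduces the input exactly up to
floating-point rounding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import make_interp_spline

from .errors import ConfigurationError, DegenerateInputError, EnvelopeError
from .signals import Signal, as_samples

__all__ = [
    "EmdConfig",
    "SiftTrace",
    "Decomposition",
    "find_extrema",
    "mean_envelope",
    "sd_criterion",
    "extract_imf",
    "emd",
    "count_zero_crossings",
    "is_imf",
]


@dataclass(frozen=True)
class EmdConfig:
    """Sifting and decomposition parameters.

    ``sd_threshold`` stops sifting when the SD statistic falls below it
    (ideal range 0.2-0.3; default is the midpoint 0.25).
    ``boundary_mode`` controls envelope extension: ``"mirror"`` reflects the
    two outermost extrema about each endpoint, ``"clamp"`` holds the nearest
    extremum value at the endpoints.
    """

    sd_threshold: float = 0.25
    max_sift_iterations: int = 100
    max_imfs: int | None = None
    boundary_mode: str = "mirror"

    def __post_init__(self) -> None:
        if not (0.0 < self.sd_threshold <= 1.0):
            raise ConfigurationError("sd_threshold must be in (0, 1]")
        if self.max_sift_iterations < 1:
            raise ConfigurationError("max_sift_iterations must be >= 1")
        if self.max_imfs is not None and self.max_imfs < 1:
            raise ConfigurationError("max_imfs must be >= 1 or None")
        if self.boundary_mode not in ("mirror", "clamp"):
            raise ConfigurationError(
                f"boundary_mode must be 'mirror' or 'clamp', "
                f"got {self.boundary_mode!r}"
            )


@dataclass
class SiftTrace:
    """Per-iteration record of one IMF's sifting loop."""

    sd_values: list[float] = field(default_factory=list)
    converged: bool = False
    stop_reason: str = ""

    @property
    def n_iterations(self) -> int:
        return len(self.sd_values)

    @property
    def terminal_sd(self) -> float | None:
        """SD value at the accepting (last) iteration, if any sift ran."""
        return self.sd_values[-1] if self.sd_values else None


@dataclass
class Decomposition:
    """Ordered IMFs plus the final residual of one signal.

    Invariant: ``sum(imfs) + residual`` reproduces the source signal to
    floating-point accuracy, and every IMF's extrema and zero-crossing
    counts differ by at most one.
    """

    imfs: list[np.ndarray]
    residual: np.ndarray
    sd_threshold_used: float
    sift_traces: list[SiftTrace] = field(default_factory=list)

    @property
    def n_imfs(self) -> int:
        return len(self.imfs)

    @property
    def source_length(self) -> int:
        return self.residual.size

    def reconstruct(self) -> np.ndarray:
        """Sum of all IMFs plus the residual."""
        out = self.residual.copy()
        for c in self.imfs:
            out += c
        return out


def find_extrema(signal) -> tuple[np.ndarray, np.ndarray]:
    """Interior local maxima and minima of a sampled signal.

    A flat run of equal samples contributes exactly one extremum, at the
    first index of the run. Endpoints are never interior extrema.

    Returns
    -------
    (maxima_indices, minima_indices)
        Strictly increasing integer arrays.
    """
    x = as_samples(signal)
    if x.size < 4:
        raise DegenerateInputError(
            f"need at least 4 samples to locate extrema, got {x.size}"
        )
    d = np.diff(x)
    nz = np.flatnonzero(d != 0.0)
    if nz.size < 2:
        empty = np.empty(0, dtype=np.intp)
        return empty, empty
    s = np.sign(d[nz])
    change = np.flatnonzero(s[:-1] != s[1:])
    idx = nz[change] + 1  # first index of a plateau, or the peak itself
    rising = s[change] > 0
    return idx[rising], idx[~rising]


def count_zero_crossings(signal) -> int:
    """Number of sign changes, ignoring exact zeros."""
    x = as_samples(signal)
    s = np.sign(x)
    s = s[s != 0]
    if s.size < 2:
        return 0
    return int(np.count_nonzero(s[:-1] != s[1:]))


def is_imf(signal) -> bool:
    """True when extrema and zero-crossing counts differ by at most one."""
    mx, mn = find_extrema(signal)
    return abs((mx.size + mn.size) - count_zero_crossings(signal)) <= 1


def _fit_envelope(x: np.ndarray, idx: np.ndarray, mode: str) -> np.ndarray:
    """Spline through the extrema at ``idx``, extended per boundary mode."""
    n = x.size
    t = idx.astype(np.float64)
    v = x[idx]
    if mode == "mirror":
        # reflect the two extrema nearest each end about the endpoint sample
        left_src = idx[idx > 0][:2]
        right_src = idx[idx < n - 1][-2:]
        lt = (-left_src[::-1]).astype(np.float64)
        rt = (2 * (n - 1) - right_src[::-1]).astype(np.float64)
        t = np.concatenate([lt, t, rt])
        v = np.concatenate([x[left_src][::-1], v, x[right_src][::-1]])
    elif mode == "clamp":
        if idx[0] != 0:
            t = np.concatenate([[0.0], t])
            v = np.concatenate([[x[idx[0]]], v])
        if idx[-1] != n - 1:
            t = np.concatenate([t, [float(n - 1)]])
            v = np.concatenate([v, [x[idx[-1]]]])
    else:  # pragma: no cover - EmdConfig validates this
        raise ConfigurationError(f"unknown boundary_mode {mode!r}")
    # drop accidental duplicate knots from reflections touching the endpoint
    keep = np.concatenate([[True], np.diff(t) > 0])
    t, v = t[keep], v[keep]
    k = min(3, t.size - 1)
    spline = make_interp_spline(t, v, k=k)
    return np.asarray(spline(np.arange(n, dtype=np.float64)))


def mean_envelope(signal, boundary_mode: str = "mirror") -> np.ndarray:
    """Mean of the upper and lower cubic-spline extrema envelopes.

    Raises
    ------
    EnvelopeError
        If the signal has fewer than 2 maxima or 2 minima (the caller should
        then treat the signal as a residual).
    """
    x = as_samples(signal)
    maxima, minima = find_extrema(x)
    if maxima.size < 2 or minima.size < 2:
        raise EnvelopeError(
            f"envelope undefined: {maxima.size} maxima, {minima.size} minima"
        )
    upper = _fit_envelope(x, maxima, boundary_mode)
    lower = _fit_envelope(x, minima, boundary_mode)
    return 0.5 * (upper + lower)


def sd_criterion(curr, prev) -> float:
    """Normalized squared change between successive proto-IMFs.

    ``SD = sum((curr - prev)**2) / sum(prev**2)`` -- the ratio-of-sums form
    of the sifting-stop statistic.
    """
    c = as_samples(curr)
    p = as_samples(prev)
    if c.size != p.size:
        raise DegenerateInputError(
            f"length mismatch: {c.size} vs {p.size}"
        )
    denom = float(np.dot(p, p))
    if denom == 0.0:
        raise DegenerateInputError("SD undefined: reference proto-IMF is all zero")
    return float(np.dot(c - p, c - p) / denom)


def extract_imf(signal, config: EmdConfig | None = None) -> tuple[np.ndarray, SiftTrace]:
    """Sift one IMF out of a signal.

    Iterates ``h <- h - mean_envelope(h)`` until the SD statistic between
    successive proto-IMFs falls below ``config.sd_threshold`` and the IMF
    condition holds, or the iteration budget is exhausted (the current
    proto-IMF is then returned with ``converged=False`` in the trace).
    """
    cfg = config or EmdConfig()
    h = as_samples(signal).copy()
    trace = SiftTrace(stop_reason="max_iterations")
    for _ in range(cfg.max_sift_iterations):
        try:
            m = mean_envelope(h, cfg.boundary_mode)
        except EnvelopeError:
            trace.stop_reason = "envelope_exhausted"
            break
        h_new = h - m
        sd = sd_criterion(h_new, h)
        trace.sd_values.append(sd)
        h = h_new
        if sd < cfg.sd_threshold and is_imf(h):
            trace.converged = True
            trace.stop_reason = "sd_converged"
            break
    return h, trace


def emd(signal, config: EmdConfig | None = None) -> Decomposition:
    """Full empirical mode decomposition of a signal.

    IMFs are extracted from successive residuals
    ``r_j = r_{j-1} - c_j`` (with ``r_0`` the input) until the residual has
    fewer than 2 maxima or 2 minima, or ``config.max_imfs`` is reached.
    """
    cfg = config or EmdConfig()
    x = as_samples(signal)
    residual = x.copy()
    imfs: list[np.ndarray] = []
    traces: list[SiftTrace] = []
    while cfg.max_imfs is None or len(imfs) < cfg.max_imfs:
        maxima, minima = find_extrema(residual)
        if maxima.size < 2 or minima.size < 2:
            break
        imf, trace = extract_imf(residual, cfg)
        if trace.n_iterations == 0:
            break  # no sift possible; residual stands
        imfs.append(imf)
        traces.append(trace)
        residual = residual - imf
    return Decomposition(
        imfs=imfs,
        residual=residual,
        sd_threshold_used=cfg.sd_threshold,
        sift_traces=traces,
    )
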