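"""CSP spatial filtering, log-variance features, weighted pairwise scatter,
and per-IMF energy profiles."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .emd import Decomposition
from .errors import DegenerateInputError

__all__ = [
    "CspModel",
    "class_covariances",
    "csp_fit",
    "csp_features",
    "weighted_pairwise_scatter",
    "imf_energy_profile",
]


@dataclass
class CspModel:
    """Common-spatial-pattern filters.

    ``filters`` is (2*n_pairs, n_rows); the first ``n_pairs`` rows carry the
    largest generalized eigenvalues (most class-A-discriminative variance),
    the last ``n_pairs`` the smallest. Eigenvalues live in [0, 1] and come in
    complements: a filter with eigenvalue lambda for class A has 1 - lambda
    for class B.
    """

    filters: np.ndarray
    eigenvalues: np.ndarray
    n_pairs: int

    @property
    def n_filters(self) -> int:
        return self.filters.shape[0]


def _normalized_covariance(x: np.ndarray) -> np.ndarray | None:
    c = x @ x.T
    tr = float(np.trace(c))
    if tr <= 0:
        return None
    return c / tr


def class_covariances(matrices_a, matrices_b) -> tuple[np.ndarray, np.ndarray]:
    """Average trace-normalized spatial covariances per class.

    Each trial matrix (rows x samples) contributes ``X X^T / trace(X X^T)``;
    all-zero trials are excluded with a warning.
    """

    def mean_cov(mats, side):
        covs = []
        for i, x in enumerate(mats):
            x = np.asarray(x, dtype=np.float64)
            c = _normalized_covariance(x)
            if c is None:
                warnings.warn(f"excluding all-zero trial {i} ({side})", stacklevel=3)
                continue
            covs.append(c)
        if not covs:
            raise DegenerateInputError(f"no usable trials for class {side}")
        return np.mean(covs, axis=0)

    sa = mean_cov(matrices_a, "A")
    sb = mean_cov(matrices_b, "B")
    if sa.shape != sb.shape:
        raise DegenerateInputError("class covariance dimensions differ")
    return sa, sb


def csp_fit(sigma_a: np.ndarray, sigma_b: np.ndarray, n_pairs: int = 2) -> CspModel:
    """Solve ``sigma_a w = lambda (sigma_a + sigma_b) w`` and keep the
    ``n_pairs`` most extreme eigenvectors from each end.

    Retained filters satisfy ``W (sigma_a + sigma_b) W^T = I``. A small ridge
    (1e-6 of the mean diagonal) keeps the composite covariance invertible.
    """
    sigma_a = np.asarray(sigma_a, dtype=np.float64)
    sigma_b = np.asarray(sigma_b, dtype=np.float64)
    d = sigma_a.shape[0]
    if sigma_a.shape != (d, d) or sigma_b.shape != (d, d):
        raise DegenerateInputError("covariances must be square and same size")
    if not 1 <= n_pairs <= d // 2:
        raise DegenerateInputError(f"n_pairs must be in [1, {d // 2}]")
    composite = sigma_a + sigma_b
    composite = composite + (1e-6 * np.trace(composite) / d) * np.eye(d)
    try:
        evals, evecs = scipy.linalg.eigh(sigma_a, composite)
    except scipy.linalg.LinAlgError as exc:  # pragma: no cover
        raise DegenerateInputError(
            f"generalized eigenproblem failed: {exc}; composite condition "
            f"number {np.linalg.cond(composite):.3g}"
        ) from exc
    evals = np.clip(evals, 0.0, 1.0)
    top = list(range(d - 1, d - 1 - n_pairs, -1))  # largest first
    bottom = list(range(n_pairs))  # smallest, ascending
    keep = top + bottom
    return CspModel(
        filters=evecs[:, keep].T.copy(),
        eigenvalues=evals[keep].copy(),
        n_pairs=n_pairs,
    )


def csp_features(model: CspModel, trial: np.ndarray) -> np.ndarray:
    """Normalized log-variance of each CSP projection:
    ``f_i = log(var(w_i X) / sum_j var(w_j X))``."""
    x = np.asarray(trial, dtype=np.float64)
    if x.ndim == 1:
        x = x[None, :]
    if x.shape[0] != model.filters.shape[1]:
        raise DegenerateInputError(
            f"trial has {x.shape[0]} rows, filters expect {model.filters.shape[1]}"
        )
    proj = model.filters @ x
    var = proj.var(axis=1)
    eps = np.finfo(np.float64).eps
    if np.any(var <= 0):
        warnings.warn("zero-variance CSP projection floored at eps", stacklevel=2)
        var = np.maximum(var, eps)
    total = var.sum()
    return np.log(var / total)


def weighted_pairwise_scatter(points: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Weighted sum of pairwise outer products:
    ``S_w = 1/2 sum_ij W_ij (x_i - x_j)(x_i - x_j)^T``.

    Symmetric, and positive semidefinite for nonnegative weights. Under
    uniform weights ``W_ij = 1/n`` it reduces to the classical centered
    scatter ``sum_i (x_i - xbar)(x_i - xbar)^T``.
    """
    x = np.asarray(points, dtype=np.float64)
    w = np.asarray(weights, dtype=np.float64)
    if x.ndim != 2:
        raise DegenerateInputError("points must be (n, d)")
    n = x.shape[0]
    if w.shape != (n, n):
        raise DegenerateInputError(
            f"weights must be ({n}, {n}), got {w.shape}"
        )
    w = 0.5 * (w + w.T)  # the quadratic form only sees the symmetric part
    row = w.sum(axis=1)
    s = x.T @ (row[:, None] * x) - x.T @ w @ x
    return 0.5 * (s + s.T)


def imf_energy_profile(decomp: Decomposition, normalize: bool = False) -> np.ndarray:
    """Energy ``E_j = sum_t c_j(t)**2`` of each IMF, optionally as fractions."""
    if decomp.n_imfs == 0:
        raise DegenerateInputError("decomposition has no IMFs")
    e = np.array([float(np.dot(c, c)) for c in decomp.imfs])
    if normalize:
        total = e.sum()
        if total > 0:
            e = e / total
    return e
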