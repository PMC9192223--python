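"""Regularized discriminant with an FPR-capped decision threshold.

The decision value for class k is

    g_k(x) = -1/2 (x - xbar_k)^T T_r Gamma^-1 T_r^T (x - xbar_k)
             + ln K - 1/2 ln det Gamma

with ``T_r`` an optional rank-r projection (identity by default) and
``Gamma`` the projected within-class scatter pooled across classes. The
two-class decision score is ``g_positive - g_negative``; the operating
threshold is placed on the relaxed-state score distribution so that the
training false-positive rate does not exceed a bound (default 10%).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, DegenerateInputError

__all__ = [
    "DiscriminantModel",
    "DecisionThreshold",
    "DensityCurve",
    "fit_discriminant",
    "decision_values",
    "decision_score",
    "decision_density",
    "overlap_area",
    "select_threshold",
    "classify",
]


@dataclass
class DiscriminantModel:
    classes: list[str]
    class_means: dict[str, np.ndarray]
    projection: np.ndarray  # (d, r)
    gamma: np.ndarray  # (r, r), pooled; or per-class when gamma_by_class set
    class_counts: dict[str, int]
    gamma_by_class: dict[str, np.ndarray] | None = None

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    @property
    def dim(self) -> int:
        return self.projection.shape[0]


@dataclass
class DecisionThreshold:
    value: float
    fpr_max: float
    achieved_fpr: float
    side: str = "above_is_positive"


@dataclass
class DensityCurve:
    """Gaussian KDE of decision values evaluated on a regular grid."""

    grid: np.ndarray
    density: np.ndarray
    bandwidth: float

    def integral(self) -> float:
        return float(np.trapezoid(self.density, self.grid))


def _regularize(gamma: np.ndarray) -> np.ndarray:
    r = gamma.shape[0]
    # ridge only when near-singular; keeps ln det finite
    cond = np.linalg.cond(gamma)
    if not np.isfinite(cond) or cond > 1e12:
        warnings.warn("near-singular Gamma; adding ridge", stacklevel=3)
        gamma = gamma + (1e-8 * max(np.trace(gamma), 1.0) / r) * np.eye(r)
    return gamma


def fit_discriminant(
    features: np.ndarray,
    labels,
    projection_rank: int | None = None,
    per_class_gamma: bool = False,
) -> DiscriminantModel:
    """Fit class means and the (pooled) projected scatter ``Gamma``.

    ``Gamma`` is the per-class scatters ``sum_{x in C_k} (x - xbar_k)(...)^T``
    projected through ``T_r`` and pooled with weights ``(n_k - 1)``, i.e. the
    pooled within-class covariance in the projected space. ``T_r`` is the
    top-``projection_rank`` principal directions of the pooled scatter
    (identity when the rank equals the feature dimension).
    """
    x = np.asarray(features, dtype=np.float64)
    if x.ndim != 2:
        raise DegenerateInputError("features must be (n, d)")
    labels = list(labels)
    if len(labels) != x.shape[0]:
        raise DegenerateInputError("labels length must match feature rows")
    classes: list[str] = []
    for lab in labels:
        if lab not in classes:
            classes.append(lab)
    if len(classes) < 2:
        raise DegenerateInputError("need at least 2 classes")
    d = x.shape[1]

    means: dict[str, np.ndarray] = {}
    counts: dict[str, int] = {}
    scatters: dict[str, np.ndarray] = {}
    for lab in classes:
        xk = x[[i for i, l in enumerate(labels) if l == lab]]
        if xk.shape[0] < 2:
            raise DegenerateInputError(f"class {lab!r} has fewer than 2 samples")
        mk = xk.mean(axis=0)
        means[lab] = mk
        counts[lab] = xk.shape[0]
        centered = xk - mk
        scatters[lab] = centered.T @ centered

    pooled_scatter = sum(scatters.values())
    r = d if projection_rank is None else int(projection_rank)
    if not 1 <= r <= d:
        raise ConfigurationError(f"projection_rank must be in [1, {d}]")
    if r == d:
        proj = np.eye(d)
    else:
        evals, evecs = np.linalg.eigh(pooled_scatter)
        proj = evecs[:, ::-1][:, :r]

    dof = sum(counts[l] - 1 for l in classes)
    gamma = proj.T @ pooled_scatter @ proj / dof
    gamma = _regularize(gamma)
    gamma_by_class = None
    if per_class_gamma:
        gamma_by_class = {
            lab: _regularize(proj.T @ scatters[lab] @ proj / (counts[lab] - 1))
            for lab in classes
        }
    return DiscriminantModel(
        classes=classes,
        class_means=means,
        projection=proj,
        gamma=gamma,
        class_counts=counts,
        gamma_by_class=gamma_by_class,
    )


def decision_values(model: DiscriminantModel, x) -> dict[str, float]:
    """Per-class decision values ``g_k(x)``."""
    x = np.asarray(x, dtype=np.float64)
    if x.shape != (model.dim,):
        raise DegenerateInputError(f"x must have shape ({model.dim},)")
    k = model.n_classes
    out: dict[str, float] = {}
    for lab in model.classes:
        gamma = (
            model.gamma_by_class[lab] if model.gamma_by_class else model.gamma
        )
        sign, logdet = np.linalg.slogdet(gamma)
        if sign <= 0:
            raise DegenerateInputError("Gamma is not positive definite")
        diff = model.projection.T @ (x - model.class_means[lab])
        maha = float(diff @ np.linalg.solve(gamma, diff))
        out[lab] = -0.5 * maha + np.log(k) - 0.5 * logdet
    return out


def decision_score(
    model: DiscriminantModel,
    x,
    positive: str = "imagery",
    negative: str = "relaxed",
) -> float:
    """Two-class score ``g_positive(x) - g_negative(x)``."""
    g = decision_values(model, x)
    if positive not in g or negative not in g:
        raise ConfigurationError(
            f"model classes {model.classes} do not include "
            f"{positive!r}/{negative!r}"
        )
    return g[positive] - g[negative]


def silverman_bandwidth(values: np.ndarray) -> float:
    """0.9 * min(sd, IQR/1.34) * n**(-1/5)."""
    v = np.asarray(values, dtype=np.float64)
    sd = float(v.std(ddof=1))
    q75, q25 = np.percentile(v, [75, 25])
    iqr = float(q75 - q25)
    scale = min(sd, iqr / 1.34) if iqr > 0 else sd
    return 0.9 * scale * v.size ** (-0.2)


def decision_density(
    values, bandwidth: float | None = None, grid_size: int = 512
) -> DensityCurve:
    """Gaussian kernel density estimate of decision scores.

    The grid spans [min - 4h, max + 4h] (beyond the conventional 3h margin)
    so the curve integrates to 1 within 1e-3 by the trapezoid rule even for
    a single-point spike.
    """
    v = np.asarray(values, dtype=np.float64)
    if v.size < 5:
        raise DegenerateInputError("need at least 5 values for a density curve")
    h = bandwidth if bandwidth is not None else silverman_bandwidth(v)
    if not h > 0:
        warnings.warn("zero-variance scores; density is a narrow spike", stacklevel=2)
        h = max(abs(float(v[0])), 1.0) * 1e-6
    grid = np.linspace(v.min() - 4 * h, v.max() + 4 * h, grid_size)
    z = (grid[:, None] - v[None, :]) / h
    density = np.exp(-0.5 * z * z).sum(axis=1) / (v.size * h * np.sqrt(2 * np.pi))
    return DensityCurve(grid=grid, density=density, bandwidth=h)


def overlap_area(curve_a: DensityCurve, curve_b: DensityCurve) -> float:
    """Area under the pointwise minimum of two densities (0 disjoint, 1 identical)."""
    lo = min(curve_a.grid[0], curve_b.grid[0])
    hi = max(curve_a.grid[-1], curve_b.grid[-1])
    grid = np.linspace(lo, hi, max(curve_a.grid.size, curve_b.grid.size) * 2)
    fa = np.interp(grid, curve_a.grid, curve_a.density, left=0.0, right=0.0)
    fb = np.interp(grid, curve_b.grid, curve_b.density, left=0.0, right=0.0)
    return float(np.trapezoid(np.minimum(fa, fb), grid))


def select_threshold(relaxed_scores, fpr_max: float = 0.10) -> DecisionThreshold:
    """Threshold on decision scores capping the relaxed-state FPR.

    The fraction of relaxed (negative-class) scores at or above the returned
    threshold — ties count as positive — is at most ``fpr_max``; among
    admissible thresholds the lowest is chosen, placed midway between the
    adjacent order statistics when that preserves the cap.
    """
    if not 0.0 < fpr_max < 1.0:
        raise ConfigurationError("fpr_max must be in (0, 1)")
    s = np.sort(np.asarray(relaxed_scores, dtype=np.float64))
    if s.size < 10:
        raise DegenerateInputError("need at least 10 relaxed-state scores")

    def fpr_at(t: float) -> float:
        return float(np.count_nonzero(s >= t)) / s.size

    candidates = np.unique(s)
    thr = float(np.nextafter(candidates[-1], np.inf))  # fallback: FPR 0
    for c in candidates:
        if fpr_at(c) <= fpr_max:
            thr = float(c)
            break
    # center the threshold between adjacent distinct scores when possible
    below = candidates[candidates < thr]
    if below.size:
        mid = 0.5 * (float(below[-1]) + thr)
        if mid > float(below[-1]) and fpr_at(mid) <= fpr_max:
            thr = mid
    return DecisionThreshold(
        value=thr, fpr_max=fpr_max, achieved_fpr=fpr_at(thr)
    )


def classify(
    model: DiscriminantModel,
    threshold: DecisionThreshold,
    x,
    positive: str = "imagery",
    negative: str = "relaxed",
) -> str:
    """Positive (imagery) iff the decision score reaches the threshold."""
    score = decision_score(model, x, positive=positive, negative=negative)
    if threshold.side == "above_is_positive":
        return positive if score >= threshold.value else negative
    return positive if score <= threshold.value else negative
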