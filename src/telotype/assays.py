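"""Quantification of the non-sequencing assays.

Three independent measurements enter the TMM workflow from the wet lab:

* **Mean TRF** — telomere restriction fragment length from Southern
  blot densitometry, the optical-density weighted mean fragment length
  mean TRF = sum(OD_i * L_i) / sum(OD_i) in kb.
* **C-circle assay (CCA)** — dot-blot signal relative to the
  ALT-positive reference cell line CHLA-90, called positive under one
  of two published thresholds: th1 (signal >= 5% of reference) or th2
  (signal >= 20% of reference AND with-polymerase AUC at least 4x the
  polymerase-free AUC).
* **TERT expression threshold** — a two-component Gaussian mixture is
  fitted to log2 TERT expression of a cohort; the high/low threshold is
  the lowest expression value whose posterior probability of belonging
  to the right (high-expression) component reaches 95%. The cohort
  value 7.58 derived this way is shipped as the default constant.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import expit
from scipy.stats import norm
from sklearn.mixture import GaussianMixture

from .errors import ConfigError, DegenerateFitError, InputError

#: Cohort-derived log2 TERT expression cut-off between low and high.
TERT_EXPRESSION_THRESHOLD = 7.58


@dataclass(frozen=True)
class DensitometryProfile:
    """One Southern-blot lane: (fragment length kb, optical density)
    samples, lengths strictly monotone along the lane."""

    lanes: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        lengths = [length for length, _ in self.lanes]
        ods = [od for _, od in self.lanes]
        if not self.lanes:
            raise InputError("empty densitometry profile")
        if any(length <= 0 for length in lengths):
            raise InputError("fragment lengths must be positive")
        if any(od < 0 for od in ods):
            raise InputError("optical densities must be non-negative")
        diffs = np.diff(lengths)
        if len(lengths) > 1 and not (np.all(diffs > 0) or np.all(diffs < 0)):
            raise InputError("fragment lengths must be strictly monotone")


@dataclass(frozen=True)
class CCAMeasurement:
    sample_signal: float
    reference_signal: float  # CHLA-90 with polymerase
    no_polymerase_auc: float = 0.0
    with_polymerase_auc: float = 0.0

    def __post_init__(self) -> None:
        if self.reference_signal <= 0:
            raise InputError("reference signal must be positive")
        if min(
            self.sample_signal, self.no_polymerase_auc, self.with_polymerase_auc
        ) < 0:
            raise InputError("CCA signals must be non-negative")


@dataclass(frozen=True)
class TertThresholdFit:
    means: tuple[float, float]  # (low component, high component)
    sds: tuple[float, float]
    weights: tuple[float, float]
    threshold: float
    posterior_level: float = 0.95


def mean_trf(profile: DensitometryProfile) -> float:
    """OD-weighted mean fragment length in kb."""
    lengths = np.array([length for length, _ in profile.lanes], dtype=float)
    ods = np.array([od for _, od in profile.lanes], dtype=float)
    total = ods.sum()
    if total <= 0:
        raise InputError("all optical densities are zero")
    return float((ods * lengths).sum() / total)


def trf_heterogeneity(profile: DensitometryProfile) -> float:
    """OD-weighted standard deviation of fragment length (kb); a
    dispersion companion to :func:`mean_trf` — ALT telomeres are more
    heterogeneous — offered as an extension, not a calibrated assay."""
    lengths = np.array([length for length, _ in profile.lanes], dtype=float)
    ods = np.array([od for _, od in profile.lanes], dtype=float)
    total = ods.sum()
    if total <= 0:
        raise InputError("all optical densities are zero")
    mu = (ods * lengths).sum() / total
    return float(np.sqrt((ods * (lengths - mu) ** 2).sum() / total))


def cca_call(m: CCAMeasurement, rule: str = "th1") -> bool:
    """ALT-positivity call from a C-circle measurement under th1 or th2."""
    ratio = m.sample_signal / m.reference_signal
    if rule == "th1":
        return ratio >= 0.05
    if rule == "th2":
        return ratio >= 0.20 and m.with_polymerase_auc >= 4 * m.no_polymerase_auc
    raise ConfigError(f"unknown CCA rule {rule!r}; expected 'th1' or 'th2'")


def fit_tert_threshold(
    expr: Sequence[float],
    posterior_level: float = 0.95,
    seed: int = 0,
    n_restarts: int = 10,
    grid_step: float = 0.01,
) -> TertThresholdFit:
    """Fit a two-component Gaussian mixture to log2 expression values and
    locate the high-expression threshold.

    EM is initialized at the 25th/75th percentiles with the pooled SD
    and equal weights; ``n_restarts`` seeded jitters of that start are
    run and the best log-likelihood kept. The threshold is the smallest
    point of a ``grid_step`` grid over the observed range (restricted to
    values above the low-component mean, where posterior membership in
    the high component is meaningful) whose posterior reaches
    ``posterior_level``.
    """
    x = np.asarray(expr, dtype=float).reshape(-1, 1)
    if x.shape[0] < 20:
        raise InputError(
            f"need at least 20 expression values, got {x.shape[0]}"
        )
    if not (0 < posterior_level < 1):
        raise ConfigError("posterior_level must be in (0, 1)")
    rng = np.random.default_rng(seed)
    q25, q75 = np.percentile(x, [25, 75])
    pooled_sd = float(x.std())
    if pooled_sd == 0:
        raise DegenerateFitError("expression values are constant")

    best = None
    best_ll = -np.inf
    for restart in range(n_restarts):
        jitter = (
            rng.normal(0.0, 0.1 * pooled_sd, size=2) if restart else np.zeros(2)
        )
        means_init = np.array([[q25 + jitter[0]], [q75 + jitter[1]]])
        gm = GaussianMixture(
            n_components=2,
            covariance_type="full",
            means_init=means_init,
            weights_init=np.array([0.5, 0.5]),
            precisions_init=np.full((2, 1, 1), 1.0 / pooled_sd**2),
            max_iter=500,
            tol=1e-7,
            reg_covar=1e-8,
            random_state=restart,
        )
        gm.fit(x)
        ll = float(gm.score(x))
        if ll > best_ll:
            best_ll = ll
            best = gm

    means = best.means_.ravel()
    sds = np.sqrt(best.covariances_.ravel())
    weights = best.weights_.ravel()
    order = np.argsort(means)
    means, sds, weights = means[order], sds[order], weights[order]

    span = float(x.max() - x.min())
    if sds.min() < 1e-4 * span or weights.min() < 1e-3:
        raise DegenerateFitError(
            "mixture component collapsed "
            f"(sds={sds.tolist()}, weights={weights.tolist()})"
        )

    grid = np.arange(float(x.min()), float(x.max()) + grid_step / 2, grid_step)
    # log-space posterior: stable where both densities underflow
    log_low = np.log(weights[0]) + norm.logpdf(grid, means[0], sds[0])
    log_high = np.log(weights[1]) + norm.logpdf(grid, means[1], sds[1])
    posterior = expit(log_high - log_low)
    eligible = (posterior >= posterior_level) & (grid > means[0])
    if not eligible.any():
        raise DegenerateFitError(
            f"no grid point reaches posterior {posterior_level}; "
            "components overlap too strongly"
        )
    threshold = float(grid[np.argmax(eligible)])
    return TertThresholdFit(
        means=(float(means[0]), float(means[1])),
        sds=(float(sds[0]), float(sds[1])),
        weights=(float(weights[0]), float(weights[1])),
        threshold=threshold,
        posterior_level=posterior_level,
    )


def classify_tert_expression(
    x: float, threshold: float = TERT_EXPRESSION_THRESHOLD
) -> str:
    """'high' iff log2 expression strictly exceeds the threshold."""
    return "high" if x > threshold else "low"
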