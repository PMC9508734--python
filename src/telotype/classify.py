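"""TMM classification, ambiguity resolution, and ROC threshold tools.

Strict classification (the primary-marker rule set):

* TEL+ — any telomerase marker (MYCN amplification, TERT rearrangement,
  high TERT expression) positive, and neither APB nor CCA positive;
* ALT+ — APB and CCA concordantly positive, no telomerase marker;
* TMM- — all five markers negative;
* ambiguous — anything else: discordant APB/CCA, telomerase markers
  co-occurring with ALT assay positivity, or a missing APB/CCA assay.

Ambiguous samples are then resolved with the full evidence panel:
concordant APB+CCA dominates (ALT+); a genomic telomerase lesion (MNA
or TERT RA) dominates discordant assays (TEL+); otherwise at least
``min_aux_alt_markers`` auxiliary ALT markers (ATRX mutation, telomere
content ratio >= 1.22, mean TRF >= 9.01 kb, TERRA at or above the
ALT-group mean, TVR singleton ratio at or below the ALT-group mean,
any telomere insertion) call ALT+; failing that, TERT expression or
telomerase activity calls TEL+, and a sample with no usable evidence
stays ambiguous. Missing markers are excluded, never imputed.

ROC utilities derive such thresholds from cohorts with known labels:
an empirical ROC over all observed score thresholds (score >= t is
called positive), trapezoidal AUC, and Youden's J threshold proposal.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import warnings

import numpy as np
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

from .errors import InputError

TELOMERASE_MARKERS = ("mna", "tert_ra", "tert_expr_high")
LABELS = ("TEL_pos", "ALT_pos", "TMM_neg", "ambiguous")


@dataclass
class SampleFeatures:
    """One sample's marker vector. ``None`` means the assay or metric is
    unavailable."""

    sample_id: str
    mna: Optional[bool] = None
    tert_ra: Optional[bool] = None
    atrx_mut: Optional[bool] = None
    tert_expr_high: Optional[bool] = None
    telomerase_activity_high: Optional[bool] = None
    apb: Optional[bool] = None
    cca: Optional[bool] = None
    tc_ratio: Optional[float] = None
    trf_kb: Optional[float] = None
    terra_total: Optional[float] = None
    ttt_ggg_singleton_log2: Optional[float] = None
    n_insertions: Optional[int] = None


@dataclass(frozen=True)
class ClassifierConfig:
    tc_threshold: float = 1.22
    trf_threshold_kb: float = 9.01
    terra_alt_mean: float = 0.011
    singleton_alt_mean: Optional[float] = None  # cohort-derived, no default
    min_aux_alt_markers: int = 2


@dataclass
class TMMCall:
    sample_id: str
    label: str  # TEL_pos | ALT_pos | TMM_neg | ambiguous
    stage: str  # strict | resolved
    evidence: list[tuple[str, str]] = field(default_factory=list)


@dataclass(frozen=True)
class ROCCurve:
    """(threshold, sensitivity, specificity) at every observed score
    threshold (descending), plus the trapezoidal AUC. The first point
    is the +inf sentinel (nothing called positive)."""

    points: tuple[tuple[float, float, float], ...]
    auc: float


def _check_strict_preconditions(f: SampleFeatures) -> None:
    missing = []
    if all(getattr(f, m) is None for m in TELOMERASE_MARKERS):
        missing.append("all of mna/tert_ra/tert_expr_high")
    if f.apb is None and f.cca is None:
        missing.append("both of apb/cca")
    if missing:
        raise InputError(
            f"sample {f.sample_id}: cannot strictly classify, "
            f"missing {', '.join(missing)}"
        )


def strict_classify(f: SampleFeatures) -> TMMCall:
    """Strict TMM classification from the five primary markers."""
    _check_strict_preconditions(f)
    evidence = [
        (m, "positive" if getattr(f, m) else "negative")
        for m in (*TELOMERASE_MARKERS, "apb", "cca")
        if getattr(f, m) is not None
    ]
    telomerase = any(getattr(f, m) is True for m in TELOMERASE_MARKERS)
    if f.apb is None or f.cca is None:
        label = "ambiguous"
        evidence.append(("missing_assay", "apb" if f.apb is None else "cca"))
    elif telomerase and not f.apb and not f.cca:
        label = "TEL_pos"
    elif f.apb and f.cca and not telomerase:
        label = "ALT_pos"
    elif not telomerase and not f.apb and not f.cca:
        label = "TMM_neg"
    else:
        label = "ambiguous"
    return TMMCall(sample_id=f.sample_id, label=label, stage="strict", evidence=evidence)


def resolve_ambiguous(
    f: SampleFeatures, cfg: ClassifierConfig = ClassifierConfig()
) -> TMMCall:
    """Resolve a strictly-ambiguous sample by weighted multi-marker
    evidence (see module docstring for the rule order)."""
    strict = strict_classify(f)
    if strict.label != "ambiguous":
        raise InputError(
            f"sample {f.sample_id} is not ambiguous (strict: {strict.label})"
        )
    evidence: list[tuple[str, str]] = []

    if f.apb is True and f.cca is True:
        evidence.append(("apb+cca_concordant", "ALT"))
        return TMMCall(f.sample_id, "ALT_pos", "resolved", evidence)

    if f.mna is True or f.tert_ra is True:
        marker = "mna" if f.mna else "tert_ra"
        evidence.append((marker, "TEL"))
        return TMMCall(f.sample_id, "TEL_pos", "resolved", evidence)

    checks: list[tuple[str, Optional[bool]]] = [
        ("atrx_mut", f.atrx_mut if f.atrx_mut is not None else None),
        (
            "tc_ratio",
            None if f.tc_ratio is None else f.tc_ratio >= cfg.tc_threshold,
        ),
        (
            "trf_kb",
            None if f.trf_kb is None else f.trf_kb >= cfg.trf_threshold_kb,
        ),
        (
            "terra_total",
            None if f.terra_total is None else f.terra_total >= cfg.terra_alt_mean,
        ),
        (
            "tvr_singleton_depleted",
            None
            if (f.ttt_ggg_singleton_log2 is None or cfg.singleton_alt_mean is None)
            else f.ttt_ggg_singleton_log2 <= cfg.singleton_alt_mean,
        ),
        (
            "telomere_insertions",
            None if f.n_insertions is None else f.n_insertions >= 1,
        ),
    ]
    available = [(name, hit) for name, hit in checks if hit is not None]
    score = sum(hit for _, hit in available)
    evidence.extend(
        (name, "ALT" if hit else "not_ALT") for name, hit in available
    )
    if available and score >= cfg.min_aux_alt_markers:
        return TMMCall(f.sample_id, "ALT_pos", "resolved", evidence)
    if f.tert_expr_high is True or f.telomerase_activity_high is True:
        marker = (
            "tert_expr_high" if f.tert_expr_high else "telomerase_activity_high"
        )
        evidence.append((marker, "TEL"))
        return TMMCall(f.sample_id, "TEL_pos", "resolved", evidence)
    if not available:
        evidence.append(("no_auxiliary_markers", "unresolved"))
    return TMMCall(f.sample_id, "ambiguous", "resolved", evidence)


def classify_sample(
    f: SampleFeatures, cfg: ClassifierConfig = ClassifierConfig()
) -> TMMCall:
    """strict_classify, escalating to resolve_ambiguous only when needed."""
    call = strict_classify(f)
    if call.label == "ambiguous":
        return resolve_ambiguous(f, cfg)
    return call


# --------------------------------------------------------------------------
# ROC / threshold derivation


def empirical_roc(
    scores: Sequence[float], labels: Sequence[bool]
) -> ROCCurve:
    """Empirical ROC with every observed threshold enumerated (rule:
    score >= threshold is called positive) and trapezoidal AUC, which
    equals the pairwise concordance statistic."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if s.shape != y.shape or s.ndim != 1:
        raise InputError("scores and labels must be equal-length 1-D")
    if not np.isfinite(s).all():
        raise InputError("scores must be finite")
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise InputError("both classes must be present")

    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    y_sorted = y[order]
    tps = np.cumsum(y_sorted)
    fps = np.cumsum(~y_sorted)
    # last index of each tied block = counts with score >= that value
    last = np.nonzero(np.r_[s_sorted[1:] != s_sorted[:-1], True])[0]
    thresholds = s_sorted[last]
    sens = tps[last] / n_pos
    spec = 1.0 - fps[last] / n_neg
    points = [(float("inf"), 0.0, 1.0)] + [
        (float(t), float(se), float(sp))
        for t, se, sp in zip(thresholds, sens, spec)
    ]
    fpr = np.r_[0.0, fps[last] / n_neg]
    tpr = np.r_[0.0, sens]
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(points=tuple(points), auc=auc)


def propose_threshold(curve: ROCCurve) -> tuple[float, float, float]:
    """The observed threshold maximizing Youden's J = sens + spec - 1;
    ties broken toward higher specificity, then the lower threshold."""
    finite = [p for p in curve.points if np.isfinite(p[0])]
    if not finite:
        raise InputError("degenerate ROC curve")
    return min(finite, key=lambda p: (-(p[1] + p[2] - 1.0), -p[2], p[0]))


@dataclass
class CombinedModel:
    """Binary logistic combination of two predictors."""

    params: np.ndarray  # (intercept, b1, b2)
    bse: np.ndarray
    probabilities: np.ndarray
    separated: bool = False


def combine_predictors(
    x1: Sequence[float], x2: Sequence[float], labels: Sequence[bool]
) -> CombinedModel:
    """Maximum-likelihood logistic regression of the labels on two
    covariates; the fitted probabilities feed a combined ROC curve.

    Perfect separation is flagged and probabilities from the diverging
    fit are capped away from 0/1; exact collinearity is an error.
    """
    a = np.asarray(x1, dtype=float)
    b = np.asarray(x2, dtype=float)
    y = np.asarray(labels, dtype=float)
    if not (a.shape == b.shape == y.shape):
        raise InputError("x1, x2, labels must be equal-length")
    if y.min() == y.max():
        raise InputError("both classes must be present")
    # a constant covariate carries no information: drop it so the model
    # degrades gracefully to the single-covariate fit
    cols = [a, b]
    keep = [i for i, c in enumerate(cols) if np.ptp(c) > 0]
    if not keep:
        raise InputError("both predictors are constant")
    X = sm.add_constant(
        np.column_stack([cols[i] for i in keep]), has_constant="add"
    )
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise InputError("collinear predictors: design matrix is rank-deficient")
    model = sm.Logit(y, X)
    separated = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            res = model.fit(disp=0)
        except Exception:  # PerfectSeparationError on older statsmodels
            separated = True
            res = model.fit(method="bfgs", maxiter=200, disp=0, skip_hessian=True)
    if any(
        issubclass(w.category, PerfectSeparationWarning) for w in caught
    ):
        separated = True
    prob = np.asarray(res.predict(X))
    if not separated and (prob.min() < 1e-10 or prob.max() > 1 - 1e-10):
        fitted_hard = np.all((prob > 0.5) == (y > 0.5))
        if fitted_hard:
            separated = True
    prob = np.clip(prob, 1e-8, 1 - 1e-8)
    if res.normalized_cov_params is not None:
        fit_bse = np.asarray(res.bse)
    else:
        fit_bse = np.full(len(res.params), np.nan)
    # re-expand dropped (constant) covariates with zero coefficient
    params = np.zeros(3)
    bse = np.full(3, np.nan)
    params[0], bse[0] = res.params[0], fit_bse[0]
    for out_idx, col_idx in enumerate(keep, start=1):
        params[col_idx + 1] = res.params[out_idx]
        bse[col_idx + 1] = fit_bse[out_idx]
    return CombinedModel(
        params=params,
        bse=bse,
        probabilities=prob,
        separated=separated,
    )


# --------------------------------------------------------------------------
# Subgroup statistics


@dataclass
class GroupComparison:
    kruskal_stat: float
    kruskal_p: float
    dunn: list[dict]  # group_1, group_2, z, p, p_adj


def dunn_test(
    groups: Mapping[str, Sequence[float]], adjust: str = "bonferroni"
) -> list[dict]:
    """Dunn's rank-based pairwise post-hoc test with tie correction and
    Bonferroni family adjustment."""
    names = list(groups)
    values = [np.asarray(groups[n], dtype=float) for n in names]
    pooled = np.concatenate(values)
    n_total = pooled.size
    ranks = sps.rankdata(pooled)
    mean_ranks = {}
    start = 0
    for name, vals in zip(names, values):
        mean_ranks[name] = ranks[start : start + vals.size].mean()
        start += vals.size
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    base_var = n_total * (n_total + 1) / 12.0 - tie_term / (12.0 * (n_total - 1))
    out = []
    pairs = [
        (names[i], names[j])
        for i in range(len(names))
        for j in range(i + 1, len(names))
    ]
    for g1, g2 in pairs:
        n1, n2 = len(groups[g1]), len(groups[g2])
        se = np.sqrt(base_var * (1.0 / n1 + 1.0 / n2))
        z = (mean_ranks[g1] - mean_ranks[g2]) / se if se > 0 else 0.0
        p = 2.0 * sps.norm.sf(abs(z))
        p_adj = min(1.0, p * len(pairs)) if adjust == "bonferroni" else p
        out.append(
            {"group_1": g1, "group_2": g2, "z": float(z), "p": float(p), "p_adj": float(p_adj)}
        )
    return out


def group_compare(groups: Mapping[str, Sequence[float]]) -> GroupComparison:
    """Kruskal-Wallis omnibus test followed by Dunn's pairwise
    comparisons (Bonferroni-adjusted)."""
    if len(groups) < 2:
        raise InputError("need at least two groups")
    for name, vals in groups.items():
        if len(vals) < 2:
            raise InputError(f"group {name!r} has fewer than 2 values")
    pooled = np.concatenate([np.asarray(v, dtype=float) for v in groups.values()])
    if np.ptp(pooled) == 0:  # all values identical: H = 0 by definition
        return GroupComparison(
            kruskal_stat=0.0,
            kruskal_p=1.0,
            dunn=dunn_test(groups),
        )
    stat, p = sps.kruskal(*groups.values())
    return GroupComparison(
        kruskal_stat=float(stat), kruskal_p=float(p), dunn=dunn_test(groups)
    )


def correlate(
    x: Sequence[float], y: Sequence[float], method: str = "pearson"
) -> tuple[float, float]:
    """Pearson or Spearman correlation with two-sided p-value."""
    if method == "pearson":
        r, p = sps.pearsonr(x, y)
    elif method == "spearman":
        r, p = sps.spearmanr(x, y)
    else:
        raise InputError(f"unknown correlation method {method!r}")
    return float(r), float(p)
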