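"""Strict classification, ambiguity resolution, ROC tools and subgroup
statistics."""
import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import kruskal, rankdata, norm as norm_dist

from telotype.classify import (
    ClassifierConfig,
    SampleFeatures,
    combine_predictors,
    correlate,
    dunn_test,
    empirical_roc,
    group_compare,
    propose_threshold,
    resolve_ambiguous,
    strict_classify,
)
from telotype.errors import InputError


def features(**kw):
    defaults = dict(
        sample_id="s", mna=False, tert_ra=False, tert_expr_high=False,
        apb=False, cca=False,
    )
    defaults.update(kw)
    return SampleFeatures(**defaults)


class TestStrictClassification:
    def test_primary_labels(self):
        assert strict_classify(features(mna=True)).label == "TEL_pos"
        assert strict_classify(features(tert_ra=True)).label == "TEL_pos"
        assert strict_classify(features(tert_expr_high=True)).label == "TEL_pos"
        assert strict_classify(features(apb=True, cca=True)).label == "ALT_pos"
        assert strict_classify(features()).label == "TMM_neg"

    def test_ambiguous_variants(self):
        # telomerase marker despite concordant ALT assays
        amb = features(tert_expr_high=True, apb=True, cca=True)
        assert strict_classify(amb).label == "ambiguous"
        # discordant assays
        assert strict_classify(features(apb=True)).label == "ambiguous"
        assert strict_classify(features(cca=True)).label == "ambiguous"
        # missing assay
        assert strict_classify(features(cca=None)).label == "ambiguous"

    def test_precondition_errors(self):
        with pytest.raises(InputError, match="mna"):
            strict_classify(
                SampleFeatures(sample_id="x", apb=True, cca=True)
            )
        with pytest.raises(InputError, match="apb"):
            strict_classify(SampleFeatures(sample_id="x", mna=True))

    @settings(derandomize=True, max_examples=64)
    @given(st.tuples(*[st.booleans()] * 5))
    def test_total_and_deterministic_on_full_features(self, flags):
        mna, tert_ra, tert_hi, apb, cca = flags
        f = features(
            mna=mna, tert_ra=tert_ra, tert_expr_high=tert_hi, apb=apb, cca=cca
        )
        first = strict_classify(f).label
        assert first in {"TEL_pos", "ALT_pos", "TMM_neg", "ambiguous"}
        assert strict_classify(f).label == first


class TestResolution:
    CFG = ClassifierConfig(singleton_alt_mean=-1.0)

    def test_concordant_assays_dominate(self):
        f = features(tert_expr_high=True, apb=True, cca=True, tc_ratio=0.5)
        assert resolve_ambiguous(f, self.CFG).label == "ALT_pos"

    def test_genomic_lesion_dominates_discordant_assays(self):
        f = features(mna=True, cca=True, tc_ratio=9.9, n_insertions=5)
        assert resolve_ambiguous(f, self.CFG).label == "TEL_pos"

    def test_aux_score_calls_alt(self):
        f = features(apb=True, tc_ratio=4.0, n_insertions=2)
        call = resolve_ambiguous(f, self.CFG)
        assert call.label == "ALT_pos"
        assert ("tc_ratio", "ALT") in call.evidence

    def test_aux_below_minimum_falls_back_to_tert(self):
        f = features(apb=True, tert_expr_high=True, tc_ratio=0.5,
                     n_insertions=0)
        assert resolve_ambiguous(f, self.CFG).label == "TEL_pos"

    def test_no_evidence_stays_ambiguous(self):
        f = features(apb=True)
        call = resolve_ambiguous(f, self.CFG)
        assert call.label == "ambiguous"
        assert ("no_auxiliary_markers", "unresolved") in call.evidence

    def test_non_ambiguous_input_rejected(self):
        with pytest.raises(InputError):
            resolve_ambiguous(features(mna=True), self.CFG)

    def test_missing_markers_excluded_not_imputed(self):
        # only insertions available among aux markers: score 1 < 2
        f = features(apb=True, n_insertions=3)
        assert resolve_ambiguous(f, self.CFG).label == "ambiguous"


def concordance_oracle(scores, labels):
    """O(n^2) pairwise concordance with 0.5 credit for ties."""
    pos = [s for s, y in zip(scores, labels) if y]
    neg = [s for s, y in zip(scores, labels) if not y]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestROC:
    def test_perfect_separation(self):
        curve = empirical_roc([1, 2, 3, 10, 11, 12],
                              [False] * 3 + [True] * 3)
        assert curve.auc == pytest.approx(1.0)

    def test_null_scores_near_half(self):
        rng = np.random.default_rng(17)
        scores = rng.normal(size=10_000)
        labels = rng.random(10_000) < 0.5
        assert empirical_roc(scores, labels).auc == pytest.approx(0.5, abs=0.02)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_auc_equals_concordance_oracle(self, seed):
        rng = np.random.default_rng(seed)
        # discrete scores force ties
        scores = rng.integers(0, 8, size=60).astype(float)
        labels = rng.random(60) < 0.4
        if labels.all() or not labels.any():
            labels[0] = not labels[0]
        curve = empirical_roc(scores, labels)
        assert curve.auc == pytest.approx(
            concordance_oracle(scores, labels), abs=1e-12
        )

    def test_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(5)
        scores = rng.normal(size=300)
        labels = rng.random(300) < 0.3
        curve = empirical_roc(scores, labels)
        assert curve.auc == pytest.approx(roc_auc_score(labels, scores))

    def test_monotone_points(self):
        rng = np.random.default_rng(2)
        curve = empirical_roc(rng.normal(size=50), rng.random(50) < 0.5)
        sens = [p[1] for p in curve.points]
        fpr = [1 - p[2] for p in curve.points]
        assert sens == sorted(sens) and fpr == sorted(fpr)

    def test_one_class_errors(self):
        with pytest.raises(InputError):
            empirical_roc([1.0, 2.0], [True, True])


def youden_oracle(scores, labels):
    """Exhaustive Youden search over observed thresholds with the
    spec'd tie-breaks (higher specificity, then lower threshold)."""
    best = None
    pos = np.asarray(labels, dtype=bool)
    s = np.asarray(scores, dtype=float)
    for t in sorted(set(scores)):
        sens = float(np.mean(s[pos] >= t))
        spec = float(np.mean(s[~pos] < t))
        key = (-(sens + spec - 1), -spec, t)
        if best is None or key < best[0]:
            best = (key, (t, sens, spec))
    return best[1]


class TestThresholdProposal:
    def test_separated_groups(self):
        curve = empirical_roc([1, 2, 3, 4], [False, False, True, True])
        thr, sens, spec = propose_threshold(curve)
        assert (thr, sens, spec) == (3.0, 1.0, 1.0)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        scores = np.round(rng.normal(size=80), 1)
        labels = rng.normal(size=80) + (scores > 0) > 0.3
        if labels.all() or not labels.any():
            labels[0] = not labels[0]
        curve = empirical_roc(scores, labels)
        assert propose_threshold(curve) == youden_oracle(scores, labels)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(7)
        scores = rng.uniform(0.5, 5.0, size=60)
        labels = rng.random(60) < 0.4
        if not labels.any():
            labels[0] = True
        t1, s1, p1 = propose_threshold(empirical_roc(scores, labels))
        t2, s2, p2 = propose_threshold(empirical_roc(np.log(scores), labels))
        assert (s1, p1) == (s2, p2)
        assert t2 == pytest.approx(np.log(t1))


class TestCombinedPredictors:
    def test_constant_covariate_reduces_to_single(self):
        rng = np.random.default_rng(1)
        x1 = rng.normal(size=400)
        labels = rng.random(400) < 1 / (1 + np.exp(-2 * x1))
        model = combine_predictors(x1, np.ones(400), labels)
        assert model.params[2] == 0.0  # dropped covariate
        single = empirical_roc(x1, labels).auc
        combined = empirical_roc(model.probabilities, labels).auc
        assert combined == pytest.approx(single, abs=1e-9)
        # genuine collinearity (x2 a shifted copy of x1) is an error
        with pytest.raises(InputError, match="collinear"):
            combine_predictors(x1, 2 * x1 + 1, labels)

    def test_coefficient_recovery_within_three_se(self):
        rng = np.random.default_rng(3)
        n = 5000
        x1 = rng.normal(size=n)
        x2 = rng.normal(size=n)
        true = np.array([0.5, 1.0, -0.7])  # intercept, b1, b2
        eta = true[0] + true[1] * x1 + true[2] * x2
        labels = rng.random(n) < 1 / (1 + np.exp(-eta))
        model = combine_predictors(x1, x2, labels)
        assert not model.separated
        for est, se, truth in zip(model.params, model.bse, true):
            assert abs(est - truth) <= 3 * se

    def test_probabilities_monotone_in_x1_at_fixed_x2(self):
        rng = np.random.default_rng(9)
        x1 = np.linspace(-2, 2, 200)
        x2 = rng.normal(size=200)
        labels = x1 + rng.normal(0, 0.5, 200) > 0
        model = combine_predictors(x1, x2, labels)
        assert model.params[1] > 0
        b0, b1, b2 = model.params
        grid = np.linspace(-3, 3, 50)
        probs = 1 / (1 + np.exp(-(b0 + b1 * grid + b2 * 0.7)))
        assert np.all(np.diff(probs) > 0)

    def test_perfect_separation_flagged_and_capped(self):
        x1 = np.r_[np.zeros(20), np.ones(20)]
        x2 = np.r_[np.linspace(0, 1, 20), np.linspace(2, 3, 20)]
        labels = np.r_[np.zeros(20, bool), np.ones(20, bool)]
        model = combine_predictors(x1, x2, labels)
        assert model.separated
        assert model.probabilities.min() >= 1e-8
        assert model.probabilities.max() <= 1 - 1e-8


def dunn_hand_oracle(groups):
    """Independent Dunn computation: explicit pooled ranking, tie
    correction, and normal two-sided p, Bonferroni-adjusted."""
    names = list(groups)
    pooled = np.concatenate([np.asarray(groups[n], float) for n in names])
    ranks = rankdata(pooled)
    n_total = len(pooled)
    sizes, mean_ranks, start = {}, {}, 0
    for name in names:
        k = len(groups[name])
        sizes[name] = k
        mean_ranks[name] = ranks[start : start + k].mean()
        start += k
    ties = {}
    for v in pooled:
        ties[v] = ties.get(v, 0) + 1
    tie_sum = sum(t**3 - t for t in ties.values())
    var = n_total * (n_total + 1) / 12 - tie_sum / (12 * (n_total - 1))
    out = {}
    pairs = list(itertools.combinations(names, 2))
    for g1, g2 in pairs:
        se = np.sqrt(var * (1 / sizes[g1] + 1 / sizes[g2]))
        z = (mean_ranks[g1] - mean_ranks[g2]) / se
        p = 2 * (1 - norm_dist.cdf(abs(z)))
        out[(g1, g2)] = (z, min(1.0, p * len(pairs)))
    return out


class TestGroupStatistics:
    TOY = {
        "TMM_neg": [1.0, 2.0, 2.0, 3.0, 4.0],
        "ALT_pos": [6.0, 7.0, 8.0, 8.0, 12.0],
        "TEL_pos": [2.0, 3.0, 3.5, 4.0, 5.0],
    }

    def test_identical_groups_statistic_zero(self):
        same = {"a": [1.0, 1.0], "b": [1.0, 1.0], "c": [1.0, 1.0]}
        result = group_compare(same)
        assert result.kruskal_stat == 0.0
        assert result.kruskal_p == pytest.approx(1.0)

    def test_kruskal_matches_scipy(self):
        result = group_compare(self.TOY)
        stat, p = kruskal(*self.TOY.values())
        assert result.kruskal_stat == pytest.approx(stat)
        assert result.kruskal_p == pytest.approx(p)

    def test_dunn_matches_hand_oracle(self):
        oracle = dunn_hand_oracle(self.TOY)
        for row in dunn_test(self.TOY):
            z, p_adj = oracle[(row["group_1"], row["group_2"])]
            assert row["z"] == pytest.approx(z)
            assert row["p_adj"] == pytest.approx(p_adj)

    def test_degenerate_group_errors(self):
        with pytest.raises(InputError):
            group_compare({"a": [1.0], "b": [1.0, 2.0]})
        with pytest.raises(InputError):
            group_compare({"a": [1.0, 2.0]})

    def test_correlations(self):
        x = np.arange(10.0)
        assert correlate(x, 2 * x + 1)[0] == pytest.approx(1.0)
        assert correlate(x, np.exp(x), method="spearman")[0] == pytest.approx(1.0)
        with pytest.raises(InputError):
            correlate(x, x, method="kendall")
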