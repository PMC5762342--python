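import numpy as np
import pandas as pd
import pytest

from lncdys.biomarker_panel import (
    PanelMarker,
    auc_confidence_interval,
    auc_score,
    build_panel,
    classify_sample,
    marker_roc,
    optimal_cutoff,
    roc_curve,
)


def u_statistic_auc(scores, labels):
    """Pairwise Mann-Whitney oracle, ties counted one half."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return (wins + 0.5 * ties) / (pos.size * neg.size)


def exhaustive_youden(scores, labels, direction="higher_in_positive"):
    best = -2.0
    uniq = np.unique(scores)
    mids = np.r_[uniq[0] - 1, (uniq[:-1] + uniq[1:]) / 2, uniq[-1] + 1]
    for c in mids:
        pred = scores > c if direction == "higher_in_positive" else scores < c
        sens = (pred & (labels == 1)).sum() / (labels == 1).sum()
        spec = (~pred & (labels == 0)).sum() / (labels == 0).sum()
        best = max(best, sens + spec - 1)
    return best


class TestRoc:
    def test_perfect_separation(self):
        scores = np.r_[np.zeros(5), np.ones(5)]
        labels = np.r_[np.zeros(5), np.ones(5)]
        assert auc_score(scores, labels) == 1.0

    def test_null_scores_near_half(self, rng):
        scores = rng.normal(size=4000)
        labels = rng.integers(0, 2, 4000)
        assert auc_score(scores, labels) == pytest.approx(0.5, abs=0.05)

    def test_trapezoid_equals_u_statistic(self, rng):
        for _ in range(50):
            n = rng.integers(6, 40)
            scores = rng.choice([0.0, 0.5, 1.0, 2.0, 3.5], size=n)
            labels = np.r_[0, 1, rng.integers(0, 2, n - 2)]
            assert auc_score(scores, labels) == pytest.approx(
                u_statistic_auc(scores, labels), abs=1e-12
            )

    def test_score_negation_symmetry(self, rng):
        scores = rng.choice([1.0, 2.0, 2.0, 5.0], size=30)
        labels = np.r_[0, 1, rng.integers(0, 2, 28)]
        assert auc_score(scores, labels) + auc_score(-scores, labels) == (
            pytest.approx(1.0)
        )

    def test_monotone_transform_invariance(self, rng):
        scores = rng.normal(size=50)
        labels = np.r_[np.zeros(25), np.ones(25)]
        assert auc_score(np.exp(scores), labels) == pytest.approx(
            auc_score(scores, labels)
        )

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            roc_curve([1, 2, 3], [1, 1, 1])


class TestOptimalCutoff:
    def test_separated_classes(self):
        scores = np.r_[np.full(5, 1.0), np.full(5, 3.0)]
        labels = np.r_[np.zeros(5), np.ones(5)]
        cut, sens, spec = optimal_cutoff(scores, labels)
        assert 1.0 < cut < 3.0
        assert sens == spec == 1.0

    def test_matches_exhaustive_oracle(self, rng):
        for _ in range(30):
            scores = rng.choice(np.linspace(0, 1, 7), size=25)
            labels = np.r_[0, 1, rng.integers(0, 2, 23)]
            _, sens, spec = optimal_cutoff(scores, labels)
            assert sens + spec - 1 == pytest.approx(
                exhaustive_youden(scores, labels), abs=1e-12
            )

    def test_direction_flip_preserves_operating_point(self):
        scores = np.r_[np.full(4, 5.0), np.full(4, 1.0)]
        labels = np.r_[np.zeros(4), np.ones(4)]  # positives score LOWER
        cut, sens, spec = optimal_cutoff(scores, labels, "lower_in_positive")
        assert 1.0 < cut < 5.0
        assert sens == spec == 1.0


class TestDelongInterval:
    def test_degenerate_perfect_auc(self):
        scores = np.r_[np.zeros(5), np.ones(5)]
        labels = np.r_[np.zeros(5), np.ones(5)]
        with pytest.warns(UserWarning):
            lo, hi = auc_confidence_interval(scores, labels)
        assert (lo, hi) == (1.0, 1.0)

    def test_interval_widens_as_n_shrinks(self, rng):
        def width(n):
            scores = np.r_[rng.normal(0, 1, n), rng.normal(1, 1, n)]
            labels = np.r_[np.zeros(n), np.ones(n)]
            lo, hi = auc_confidence_interval(scores, labels)
            return hi - lo

        big = np.mean([width(400) for _ in range(3)])
        small = np.mean([width(25) for _ in range(3)])
        assert small > big

    def test_coverage_near_nominal(self, rng):
        """~95% of DeLong intervals cover the true AUC at n = 50 + 50."""
        # true AUC for N(0,1) vs N(1,1): Phi(1/sqrt(2))
        from scipy.stats import norm

        true_auc = norm.cdf(1 / np.sqrt(2))
        hits = 0
        reps = 300
        for _ in range(reps):
            scores = np.r_[rng.normal(0, 1, 50), rng.normal(1, 1, 50)]
            labels = np.r_[np.zeros(50), np.ones(50)]
            lo, hi = auc_confidence_interval(scores, labels)
            hits += lo <= true_auc <= hi
        assert hits / reps == pytest.approx(0.95, abs=0.04)


def three_tier_marker(rng, up=True, sigma=1e-3):
    """Normal / low-risk / high-risk tiers patterned on the panel semantics."""
    tiers = (0.08, 0.25, 0.60) if up else (0.60, 0.25, 0.08)
    normal = tiers[0] + sigma * rng.normal(size=10)
    low = tiers[1] + sigma * rng.normal(size=10)
    high = tiers[2] + sigma * rng.normal(size=10)
    cols = (
        [f"N{i}" for i in range(10)]
        + [f"L{i}" for i in range(10)]
        + [f"H{i}" for i in range(10)]
    )
    expr = pd.DataFrame([np.r_[normal, low, high]], index=["M"], columns=cols)
    return expr, cols[:10], cols[10:20], cols[20:]


class TestPanel:
    def test_up_marker_cutoffs_between_tiers(self, rng):
        expr, normal, low, high = three_tier_marker(rng, up=True)
        panel = build_panel(expr, normal, low, high)
        assert len(panel) == 1
        m = panel[0]
        assert m.direction == "higher_in_positive"
        assert 0.08 < m.low_cutoff < 0.25 < m.high_cutoff < 0.60

    def test_down_marker_zones_reversed(self, rng):
        expr, normal, low, high = three_tier_marker(rng, up=False)
        m = build_panel(expr, normal, low, high)[0]
        assert m.direction == "lower_in_positive"
        assert m.low_cutoff > m.high_cutoff

    def test_overlapping_tiers_flagged_ambiguous(self, rng, caplog):
        expr, normal, low, high = three_tier_marker(rng, sigma=5.0)
        with caplog.at_level("WARNING"):
            panel = build_panel(expr, normal, low, high)
        assert panel == [] and "ambiguous" in caplog.text

    def test_risk_contrast_auc_is_one(self, rng):
        expr, _, low, high = three_tier_marker(rng, up=True)
        scores = expr.loc["M", low + high].to_numpy()
        labels = np.r_[np.zeros(10), np.ones(10)]
        assert auc_score(scores, labels) == 1.0

    def test_tiny_group_errors(self, rng):
        expr, normal, low, high = three_tier_marker(rng)
        with pytest.raises(ValueError):
            build_panel(expr, normal[:1], low, high)


class TestClassifySample:
    panel = [PanelMarker("up", "higher_in_positive", 0.151, 0.346)]

    @pytest.mark.parametrize(
        "value,zone",
        [
            (0.05, "normal"),
            (0.2, "low_risk"),
            (0.9, "high_risk"),
            (0.151, "normal"),    # boundary goes to the lower zone
            (0.346, "low_risk"),
        ],
    )
    def test_up_marker_zones(self, value, zone):
        res = classify_sample(self.panel, {"up": value})
        assert res["zones"]["up"] == zone and res["call"] == zone

    def test_down_marker_zones(self):
        panel = [PanelMarker("dn", "lower_in_positive", 0.5, 0.2)]
        assert classify_sample(panel, {"dn": 0.8})["call"] == "normal"
        assert classify_sample(panel, {"dn": 0.3})["call"] == "low_risk"
        assert classify_sample(panel, {"dn": 0.1})["call"] == "high_risk"
        assert classify_sample(panel, {"dn": 0.5})["call"] == "normal"

    def test_majority_and_ties(self):
        panel = [
            PanelMarker("a", "higher_in_positive", 1, 2),
            PanelMarker("b", "higher_in_positive", 1, 2),
            PanelMarker("c", "higher_in_positive", 1, 2),
        ]
        res = classify_sample(panel, {"a": 0.5, "b": 0.5, "c": 3.0})
        assert res["call"] == "normal"
        two = classify_sample(panel[:2], {"a": 0.5, "b": 3.0})
        assert two["call"] == "indeterminate"

    def test_missing_gene_named(self):
        with pytest.raises(KeyError, match="up"):
            classify_sample(self.panel, {"other": 1.0})


def test_marker_roc_reports_consistent_operating_point(rng):
    scores = np.r_[rng.normal(0, 1, 60), rng.normal(2, 1, 60)]
    labels = np.r_[np.zeros(60), np.ones(60)]
    res = marker_roc(scores, labels)
    assert res.ci_low <= res.auc <= res.ci_high
    # reported sens/spec are achieved at the reported cutoff
    pred = scores > res.cutoff
    assert (pred & (labels == 1)).sum() / 60 == pytest.approx(res.sensitivity)
    assert (~pred & (labels == 0)).sum() / 60 == pytest.approx(res.specificity)
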