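"""Diff%, two-way mixed ICC, KDE thresholds, classification, Jaccard."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from adcstab.stability import (
    ThresholdPair,
    classify_feature,
    classify_features,
    derive_thresholds,
    diff_percent,
    fit_kde_quantile,
    icc_two_way_mixed,
    jaccard,
    kde_cdf,
    kde_chi2_diagnostic,
    summarize,
)

from oracles import icc_anova_oracle


class TestDiffPercent:
    @pytest.mark.parametrize(
        "orig,transf,expected",
        [(2.0, 1.0, 50.0), (5.0, 5.0, 0.0), (-2.0, -1.0, 50.0), (-3.0, 3.0, 200.0)],
    )
    def test_arithmetic(self, orig, transf, expected):
        assert diff_percent(orig, transf) == pytest.approx(expected)

    def test_zero_reference_is_undefined_marker(self):
        assert np.isnan(diff_percent(0.0, 1.0))
        assert np.isnan(diff_percent(float("nan"), 1.0))


class TestIcc:
    def test_identical_columns_give_one(self):
        assert icc_two_way_mixed([1, 2, 3], [1, 2, 3]) == 1.0

    def test_degenerate_constant_columns_convention(self):
        assert icc_two_way_mixed([5, 5, 5], [5, 5, 5]) == 1.0

    def test_worked_example_matches_anova_oracle(self):
        got = icc_two_way_mixed([1, 2, 3], [1.1, 1.9, 3.2])
        assert got == pytest.approx(icc_anova_oracle([1, 2, 3], [1.1, 1.9, 3.2]), abs=1e-12)

    def test_oracle_suite_100_random_samples(self):
        rng = np.random.default_rng(77)
        for _ in range(100):
            n = int(rng.integers(3, 21))
            a = rng.normal(0, 1, n)
            b = a + rng.normal(0, 0.5, n)
            got = icc_two_way_mixed(a, b)
            want = icc_anova_oracle(list(a), list(b))
            assert got == pytest.approx(want, rel=1e-10, abs=1e-10)
            assert got <= 1.0

    def test_cross_check_against_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(5)
        a = rng.normal(0, 1, 12)
        b = a + rng.normal(0, 0.4, 12)
        df = pd.DataFrame(
            {
                "subject": list(range(12)) * 2,
                "rater": ["o"] * 12 + ["t"] * 12,
                "score": np.concatenate([a, b]),
            }
        )
        table = pg.intraclass_corr(df, "subject", "rater", "score").set_index("Type")
        assert icc_two_way_mixed(a, b) == pytest.approx(table.loc["ICC(C,1)", "ICC"], abs=1e-10)
        assert icc_two_way_mixed(a, b, form="agreement") == pytest.approx(
            table.loc["ICC(A,1)", "ICC"], abs=1e-10
        )

    def test_nan_pairs_excluded_and_small_n_undefined(self):
        a = [1.0, np.nan, 3.0, 4.0]
        b = [1.1, 2.0, 2.9, 4.2]
        assert np.isfinite(icc_two_way_mixed(a, b))
        assert np.isnan(icc_two_way_mixed([1.0, np.nan], [1.0, 2.0]))

    def test_parameter_recovery_from_known_variance_components(self):
        """Two-way model with subject variance s2 and error variance e2 has
        analytic consistency ICC s2/(s2+e2); the estimate over many subjects
        lands inside its Monte-Carlo interval."""
        rng = np.random.default_rng(99)
        s2, e2 = 1.0, 0.25
        n = 500
        subj = rng.normal(0, np.sqrt(s2), n)
        a = subj + rng.normal(0, np.sqrt(e2), n)
        b = 0.3 + subj + rng.normal(0, np.sqrt(e2), n)  # fixed column offset
        icc = icc_two_way_mixed(a, b)
        expected = s2 / (s2 + e2)
        se = (1 - expected**2) * np.sqrt(2.0 / n)
        assert abs(icc - expected) < 4 * se


class TestKdeQuantile:
    def test_single_value_median_is_the_value(self):
        assert fit_kde_quantile([0.42], 0.5) == pytest.approx(0.42, abs=1e-9)

    def test_single_value_q09_closed_form(self):
        got = fit_kde_quantile([0.0], 0.9, bandwidth=0.05)
        assert got == pytest.approx(0.05 * norm.ppf(0.9), abs=1e-6)

    def test_two_separated_values_median_is_midpoint(self):
        assert fit_kde_quantile([0.0, 1.0], 0.5) == pytest.approx(0.5, abs=1e-6)

    def test_monotone_in_q_and_cdf_roundtrip(self, rng):
        values = rng.uniform(-0.2, 1.0, size=40)
        qs = np.linspace(0.05, 0.95, 10)
        ts = [fit_kde_quantile(values, q) for q in qs]
        assert all(t1 < t2 for t1, t2 in zip(ts, ts[1:]))
        for q, t in zip(qs, ts):
            assert kde_cdf(np.array(t), values, 0.05) == pytest.approx(q, abs=1e-6)

    def test_identical_pool_thresholds_within_bandwidth_scale(self):
        pair = derive_thresholds([0.6] * 10, [0.6] * 10, bandwidth=0.05)
        # single-kernel quantiles: c + h*Phi^-1(q)
        assert pair.icc_min == pytest.approx(0.6 + 0.05 * norm.ppf(0.1), abs=1e-6)
        assert pair.icc_max == pytest.approx(0.6 + 0.05 * norm.ppf(0.9), abs=1e-6)

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError):
            fit_kde_quantile([], 0.5)

    def test_chi2_diagnostic_reports_fields(self, rng):
        rep = kde_chi2_diagnostic(rng.normal(0.5, 0.2, 200))
        assert set(rep) == {"chi2", "dof", "p_value"}
        assert 0 <= rep["p_value"] <= 1


class TestClassification:
    THRESHOLDS = ThresholdPair(icc_min=0.78, icc_max=0.46)

    @pytest.mark.parametrize(
        "icc10,icc100,label",
        [
            (0.9, 0.3, "selected"),
            (0.5, 0.1, "unstable"),  # rule order: stability checked first
            (0.95, 0.9, "non_discriminative"),
            (0.78, 0.46, "selected"),  # boundary uses >= and <=
            (float("nan"), 0.3, "undefined"),
        ],
    )
    def test_selection_rule(self, icc10, icc100, label):
        assert classify_feature(icc10, icc100, self.THRESHOLDS) == label


class TestJaccard:
    def test_examples(self):
        assert jaccard({"a", "b"}, {"b", "c"}) == pytest.approx(1 / 3)
        assert jaccard({"a"}, {"a"}) == 1.0
        assert jaccard({"a"}, {"b"}) == 0.0
        assert jaccard(set(), set()) == 1.0


def _tidy_table(n_subjects, values_by_transform, feature="f", binning=16):
    rows = []
    for tid, vals in values_by_transform.items():
        for i, v in enumerate(vals):
            rows.append((f"s{i:02d}", binning, feature, v, tid))
    return pd.DataFrame(rows, columns=["subject_id", "binning", "feature_name", "value", "transform_id"])


class TestSummarize:
    def test_protocol_counts(self, rng):
        orig = rng.normal(1, 0.2, 18)
        table = _tidy_table(
            18,
            {
                "original": orig,
                "t010+x": orig + rng.normal(0, 0.01, 18),
                "t010-x": orig + rng.normal(0, 0.01, 18),
                "t010+y": orig + rng.normal(0, 0.01, 18),
                "t010-y": orig + rng.normal(0, 0.01, 18),
            },
        )
        (rec,) = summarize(table, 0.1, 16)
        assert rec.n_diffpct == 72  # 18 subjects x 4 translations
        assert len(rec.icc_by_translation) == 4
        assert rec.diffpct_mean >= 0
        assert rec.icc_mean <= 1

    def test_identical_transforms_give_zero_diff_and_unit_icc(self, rng):
        orig = rng.normal(1, 0.2, 10)
        table = _tidy_table(
            10, {tid: orig for tid in ["original", "t010+x", "t010-x", "t010+y", "t010-y"]}
        )
        (rec,) = summarize(table, 0.1, 16)
        assert rec.diffpct_mean == 0.0
        assert rec.icc_mean == 1.0

    def test_missing_variant_rejected_by_name(self, rng):
        orig = rng.normal(1, 0.2, 5)
        table = _tidy_table(5, {"original": orig, "t010+x": orig, "t010-x": orig, "t010+y": orig})
        with pytest.raises(ValueError, match="t010-y"):
            summarize(table, 0.1, 16)


def test_classify_features_joins_both_entities(rng):
    orig = rng.normal(1, 0.3, 12)
    same = {tid: orig for tid in ["original", "t010+x", "t010-x", "t010+y", "t010-y"]}
    far = {
        "original": orig,
        "t100+x": rng.normal(1, 0.3, 12),
        "t100-x": rng.normal(1, 0.3, 12),
        "t100+y": rng.normal(1, 0.3, 12),
        "t100-y": rng.normal(1, 0.3, 12),
    }
    rec10 = summarize(_tidy_table(12, same), 0.1, 16)
    rec100 = summarize(_tidy_table(12, far), 1.0, 16)
    out = classify_features(rec10, rec100, ThresholdPair(icc_min=0.78, icc_max=0.46))
    assert list(out.columns) == ["feature_name", "binning", "icc_10", "icc_100", "label"]
    assert out.loc[0, "icc_10"] == 1.0
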