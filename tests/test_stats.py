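"""Confusion/accuracy/precision, the two-proportion chi-square with phi,
correlation machinery, and inter-rater agreement."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from qcla.records import ValidationError
from qcla.stats import (
    class_accuracy_precision,
    coefficient_correlations,
    compare_correlations,
    confusion,
    fisher_ci,
    interrater_agreement,
    matched_correlations,
    phi_ci,
    phi_from_chi2,
    two_proportion_chi2,
)


class TestConfusion:
    def test_perfect_prediction_is_diagonal(self):
        labels = ["harmony", "satisfaction", "depression", "anxiety"] * 3
        cm = confusion(labels, labels)
        assert np.array_equal(cm.counts, np.diag([3, 3, 3, 3]))
        assert cm.percent_correct == 100.0

    def test_single_predicted_class_single_column(self):
        true = ["harmony", "satisfaction", "depression", "anxiety"]
        cm = confusion(true, ["depression"] * 4)
        assert cm.counts[:, 2].sum() == 4 and cm.counts.sum() == 4

    def test_hand_tally(self):
        true = ["harmony"] * 3 + ["satisfaction"] * 3 + ["depression"] * 3 + ["anxiety"] * 3
        pred = [
            "harmony", "harmony", "satisfaction",
            "satisfaction", "harmony", "satisfaction",
            "depression", "anxiety", "depression",
            "anxiety", "anxiety", "depression",
        ]
        cm = confusion(true, pred)
        expected = np.array(
            [[2, 1, 0, 0], [1, 2, 0, 0], [0, 0, 2, 1], [0, 0, 1, 2]]
        )
        assert np.array_equal(cm.counts, expected)
        assert cm.counts.sum(axis=1).tolist() == [3, 3, 3, 3]

    def test_unknown_label_rejected(self):
        with pytest.raises(ValidationError):
            confusion(["joy"], ["harmony"])


class TestAccuracyPrecision:
    def test_diagonal_gives_perfect_scores(self):
        labels = ["harmony", "satisfaction", "depression", "anxiety"] * 2
        cm = confusion(labels, labels)
        for e in cm.labels:
            acc, prec = class_accuracy_precision(cm, e)
            assert acc == 100.0 and prec == 100.0

    def test_hand_computed_toy(self):
        true = ["depression"] * 4 + ["anxiety"] * 4
        pred = ["depression", "depression", "anxiety", "anxiety",
                "depression", "anxiety", "anxiety", "anxiety"]
        cm = confusion(true, pred)
        acc, prec = class_accuracy_precision(cm, "depression")
        # TP=2 FP=1 FN=2 TN=3 -> accuracy 62.5, precision 2/3
        assert acc == pytest.approx(62.5)
        assert prec == pytest.approx(200 / 3)

    def test_precision_undefined_without_positive_predictions(self):
        true = ["harmony", "harmony", "depression", "satisfaction", "anxiety"]
        pred = ["harmony", "harmony", "harmony", "satisfaction", "anxiety"]
        _, prec = class_accuracy_precision(confusion(true, pred), "depression")
        assert prec is None


class TestTwoProportionChi2:
    def test_equal_proportions_null(self):
        s = two_proportion_chi2(0.4, 0.4, 200)
        assert s.chi2 == 0.0 and s.phi == 0.0 and s.p_value == 1.0

    @pytest.mark.parametrize(
        "p1,p2,N,chi2_expected",
        [
            (0.64, 0.44, 400, 16.10),
            (0.44, 0.30, 400, 8.41),
            (0.55, 0.31, 100, 5.88),
            (0.90, 0.82, 263, 3.50),
            (0.56, 0.50, 34, 0.12),
            (0.64, 0.63, 400, 0.04),
        ],
    )
    def test_printed_statistics_reproduced(self, p1, p2, N, chi2_expected):
        assert two_proportion_chi2(p1, p2, N).chi2 == pytest.approx(
            chi2_expected, abs=0.005
        )

    def test_degenerate_pooled_proportion_rejected(self):
        with pytest.raises(ValidationError):
            two_proportion_chi2(0.0, 0.0, 100)
        with pytest.raises(ValidationError):
            two_proportion_chi2(1.0, 1.0, 100)

    def test_equals_pearson_on_integral_tables(self):
        """Closed form == cell-wise 2x2 Pearson chi-square whenever the
        implied counts are integers (exhaustive, group sizes up to 30)."""
        for n in range(1, 31):
            a = np.repeat(np.arange(n + 1), n + 1)
            b = np.tile(np.arange(n + 1), n + 1)
            keep = ~(((a + b) == 0) | ((a + b) == 2 * n))
            a, b = a[keep], b[keep]
            # independent cell-wise oracle: sum (O-E)^2 / E over the 2x2 table
            table = np.stack([a, n - a, b, n - b], axis=1).astype(float)
            col1, col2 = a + b, 2 * n - (a + b)
            e = np.stack(
                [col1 * n, col2 * n, col1 * n, col2 * n], axis=1
            ) / (2.0 * n)
            pearson = np.sum((table - e) ** 2 / e, axis=1)
            closed = np.array(
                [two_proportion_chi2(ai / n, bi / n, 2 * n).chi2 for ai, bi in zip(a, b)]
            )
            assert np.allclose(closed, pearson, atol=1e-9)

    def test_spot_check_against_scipy(self):
        obs = np.array([[22, 8], [13, 17]])
        expected = sps.chi2_contingency(obs, correction=False).statistic
        got = two_proportion_chi2(22 / 30, 13 / 30, 60).chi2
        assert got == pytest.approx(expected, abs=1e-9)


class TestPhi:
    @pytest.mark.parametrize(
        "chi2,N,phi_expected", [(16.10, 400, 0.20), (8.41, 400, 0.14), (45.63, 100, 0.68)]
    )
    def test_phi_relation_reproduces_printed_values(self, chi2, N, phi_expected):
        assert phi_from_chi2(chi2, N) == pytest.approx(phi_expected, abs=0.0051)

    def test_ci_straddles_zero_under_null(self):
        lo, hi = phi_ci(0.5, 0.5, 200, rng=0)
        assert lo <= 0.0 <= hi

    def test_ci_ordered_and_contains_point(self):
        lo, hi = phi_ci(0.64, 0.44, 400, rng=1)
        point = phi_from_chi2(two_proportion_chi2(0.64, 0.44, 400).chi2, 400)
        assert lo <= point <= hi

    def test_ci_width_shrinks_with_n(self):
        widths = []
        for N in (100, 400, 1600, 6400):
            lo, hi = phi_ci(0.6, 0.4, N, rng=2)
            widths.append(hi - lo)
        assert all(w1 > w2 for w1, w2 in zip(widths, widths[1:]))


class TestCorrelations:
    def test_fisher_ci_contains_r(self):
        st = fisher_ci(0.3, 100)
        assert st.ci95[0] < 0.3 < st.ci95[1]

    def test_fisher_ci_coverage(self):
        """~95% of Fisher intervals should cover the true correlation
        (bivariate normal, rho=0.5, n=200, 2000 replicates)."""
        rho, n, reps = 0.5, 200, 2000
        rng = np.random.default_rng(6)
        x = rng.standard_normal((reps, n))
        y = rho * x + math.sqrt(1 - rho**2) * rng.standard_normal((reps, n))
        xc = x - x.mean(axis=1, keepdims=True)
        yc = y - y.mean(axis=1, keepdims=True)
        rs = np.sum(xc * yc, axis=1) / np.sqrt(
            np.sum(xc**2, axis=1) * np.sum(yc**2, axis=1)
        )
        covered = [
            fisher_ci(r, n).ci95[0] <= rho <= fisher_ci(r, n).ci95[1] for r in rs
        ]
        assert np.mean(covered) == pytest.approx(0.95, abs=0.02)

    def test_equal_correlations_not_different(self):
        z, p = compare_correlations(0.4, 0.4, 100)
        assert z == 0.0 and p == 1.0

    def test_matched_row_strongly_significant(self):
        z, p = compare_correlations(0.19, 0.76, 434)
        assert p < 0.001

    def test_small_n_rejected(self):
        with pytest.raises(ValidationError):
            compare_correlations(0.1, 0.2, 3)


class TestCoefficientCorrelations:
    def test_identical_and_negated_vectors(self):
        v = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        out = coefficient_correlations(
            {"harmony": v, "satisfaction": v, "depression": -v, "anxiety": 2 * v}
        )
        r = out["r"]
        assert r[0, 1] == pytest.approx(1.0)
        assert r[0, 2] == pytest.approx(-1.0)
        assert r[0, 3] == pytest.approx(1.0)
        assert np.allclose(r, r.T)

    def test_matches_pearson_oracle(self, rng):
        a, b = rng.standard_normal(5), rng.standard_normal(5)
        out = coefficient_correlations({"harmony": a, "satisfaction": b})
        expected = sps.pearsonr(a, b).statistic
        assert abs(out["r"][0, 1] - expected) < 1e-12

    def test_constant_vector_rejected(self):
        with pytest.raises(ValidationError):
            coefficient_correlations(
                {"harmony": np.ones(5), "satisfaction": np.arange(5.0)}
            )


class TestInterrater:
    def test_identical_correct_everywhere(self):
        nids = ["n1", "n1", "n2", "n2"]
        pred = ["harmony", "harmony", "anxiety", "anxiety"]
        true = ["harmony", "harmony", "anxiety", "anxiety"]
        out = interrater_agreement(nids, pred, true)
        assert out["agreement"] == 100.0 and out["correct"] == 100.0

    def test_identical_but_always_wrong(self):
        nids = ["n1", "n1"]
        pred = ["harmony", "harmony"]
        true = ["anxiety", "anxiety"]
        out = interrater_agreement(nids, pred, true)
        assert out["agreement"] == 100.0 and out["correct"] == 0.0

    def test_hand_enumerated_pairs(self):
        # n1: agree+correct; n2: disagree; n3: three raters, one agreeing
        # correct pair out of three pairs
        nids = ["n1", "n1", "n2", "n2", "n3", "n3", "n3"]
        pred = ["harmony", "harmony", "anxiety", "depression",
                "satisfaction", "satisfaction", "anxiety"]
        true = ["harmony"] * 2 + ["anxiety"] * 2 + ["satisfaction"] * 3
        out = interrater_agreement(nids, pred, true)
        assert out["n_pairs"] == 5
        assert out["agreement"] == pytest.approx(2 / 5 * 100)
        assert out["correct"] == pytest.approx(2 / 5 * 100)
        assert out["correct"] <= out["agreement"]

    def test_no_repeated_narrative_rejected(self):
        with pytest.raises(ValidationError):
            interrater_agreement(["n1", "n2"], ["harmony"] * 2, ["harmony"] * 2)


class TestMatchedCorrelations:
    def test_pearson_oracle_on_hand_data(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        y1 = [1.1, 1.9, 3.2, 3.8, 5.1, 6.0]
        y2 = [6.0, 5.0, 4.0, 3.0, 2.0, 1.0]
        out = matched_correlations(x, y1, y2)
        assert out["scales"].r == pytest.approx(sps.pearsonr(x, y1).statistic)
        assert out["words"].r == pytest.approx(-1.0)
        assert 0.0 <= out["p_compare"] <= 1.0

    def test_too_few_matches_rejected(self):
        with pytest.raises(ValidationError):
            matched_correlations([1, 2, 3], [1, 2, 3], [3, 2, 1])
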