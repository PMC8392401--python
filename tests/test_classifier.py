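"""ROC construction, cut-off selection, the sequential two-criteria
protocol, quadrants and diagnostic evaluation."""

import numpy as np
import pytest
from sklearn.base import clone
from sklearn.metrics import roc_auc_score

import ffcmargin as fm
from ffcmargin.classify import NEGATIVE, POSITIVE


def pair_count_auc(scores, y, high_is_positive=True):
    """Brute-force concordance oracle with ties counted 1/2."""
    s = np.asarray(scores, float)
    if not high_is_positive:
        s = -s
    pos, neg = s[np.asarray(y) == 1], s[np.asarray(y) == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def qset(ratio, two_r1=None, sid="q"):
    return fm.QuantifierSet(sample_id=sid, ratio=ratio, two_r1=two_r1)


class TestROCCurve:
    def test_perfect_separation_auc_one(self):
        roc = fm.roc_curve([1, 2, 3, 10, 11, 12], ["negative"] * 3 + ["positive"] * 3)
        assert roc.auc == pytest.approx(1.0)

    def test_uninformative_scores_auc_half(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(size=4000)
        labels = ["positive" if v else "negative" for v in rng.integers(0, 2, 4000)]
        assert fm.roc_curve(scores, labels).auc == pytest.approx(0.5, abs=0.03)

    def test_trapezoid_auc_equals_pair_count_oracle(self):
        rng = np.random.default_rng(13)
        for _ in range(100):
            n = rng.integers(4, 30)
            y = np.r_[1, 0, rng.integers(0, 2, n - 2)]  # both classes present
            scores = np.round(rng.normal(size=n), 1)  # coarse grid forces ties
            labels = ["positive" if v else "negative" for v in y]
            for orient, hip in [("high_is_positive", True), ("low_is_positive", False)]:
                roc = fm.roc_curve(scores, labels, orient)
                assert roc.auc == pytest.approx(pair_count_auc(scores, y, hip), abs=1e-12)

    def test_matches_sklearn_auc(self):
        rng = np.random.default_rng(5)
        scores = rng.normal(size=200)
        y = rng.integers(0, 2, 200)
        y[:2] = [0, 1]
        labels = ["positive" if v else "negative" for v in y]
        assert fm.roc_curve(scores, labels).auc == pytest.approx(
            roc_auc_score(y, scores), abs=1e-12
        )

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(size=60)
        labels = ["positive" if v else "negative" for v in np.r_[1, 0, rng.integers(0, 2, 58)]]
        base = fm.roc_curve(scores, labels).auc
        assert fm.roc_curve(np.exp(scores), labels).auc == pytest.approx(base, abs=1e-12)
        assert fm.roc_curve(3 * scores - 7, labels).auc == pytest.approx(base, abs=1e-12)

    def test_endpoints_and_monotone_sweep(self):
        roc = fm.roc_curve([3.0, 1.0, 2.0, 2.0], ["positive", "negative"] * 2)
        assert roc.sensitivity[0] == 0 and roc.one_minus_specificity[0] == 0
        assert roc.sensitivity[-1] == 1 and roc.one_minus_specificity[-1] == 1
        assert np.all(np.diff(roc.sensitivity) >= 0)
        assert np.all(np.diff(roc.one_minus_specificity) >= 0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fm.roc_curve([1.0, 2.0], ["positive", "positive"])


class TestBestCutoff:
    def test_separated_groups_gap_midpoint(self):
        roc = fm.roc_curve([1, 2, 3, 10, 11, 12], ["negative"] * 3 + ["positive"] * 3)
        assert fm.best_cutoff(roc, "youden") == pytest.approx(6.5)

    def test_youden_matches_exhaustive_scan(self):
        # Gaussian two-group simulation scored by an independent exhaustive
        # threshold scan over all candidate cut-offs
        rng = np.random.default_rng(21)
        h = rng.normal(1.83, 0.36, 400)
        mt = np.r_[rng.normal(2.66, 0.48, 430), rng.normal(3.42, 0.53, 210)]
        scores = np.r_[h, mt]
        y = np.r_[np.zeros(400), np.ones(640)]
        labels = ["positive" if v else "negative" for v in y]
        roc = fm.roc_curve(scores, labels)
        cut = fm.best_cutoff(roc, "youden")

        best_j, best_t = -np.inf, None
        for t in roc.thresholds[np.isfinite(roc.thresholds)]:
            sens = np.mean(scores[y == 1] > t)
            spec = np.mean(scores[y == 0] <= t)
            if sens + spec - 1 > best_j + 1e-12:
                best_j, best_t = sens + spec - 1, t
        assert cut == pytest.approx(best_t)
        # the crossing of the two class densities lies near the cut-off
        assert 2.0 < cut < 2.4

    def test_equal_error_rate_on_symmetric_problem(self):
        rng = np.random.default_rng(8)
        neg = rng.normal(0.0, 1.0, 3000)
        pos = rng.normal(4.0, 1.0, 3000)
        labels = ["negative"] * 3000 + ["positive"] * 3000
        roc = fm.roc_curve(np.r_[neg, pos], labels)
        assert fm.best_cutoff(roc, "equal_error_rate") == pytest.approx(2.0, abs=0.15)

    def test_low_is_positive_orientation_returns_original_units(self):
        roc = fm.roc_curve(
            [30.0, 31.0, 35.0, 10.0, 12.0, 14.0],
            ["negative"] * 3 + ["positive"] * 3,
            "low_is_positive",
        )
        cut = fm.best_cutoff(roc, "youden")
        assert 14.0 < cut < 30.0


class TestClassifySingle:
    protocol = fm.CutoffProtocol()

    @pytest.mark.parametrize(
        "ratio, expected",
        [(3.42, POSITIVE), (2.19, NEGATIVE), (2.1900001, POSITIVE), (1.83, NEGATIVE)],
    )
    def test_ratio_rule_boundary(self, ratio, expected):
        assert fm.classify_single(qset(ratio), self.protocol, "ratio").predicted == expected

    @pytest.mark.parametrize(
        "two_r1, expected",
        [(24.0, POSITIVE), (24.0000001, NEGATIVE), (12.2, POSITIVE), (34.7, NEGATIVE)],
    )
    def test_two_r1_rule_boundary(self, two_r1, expected):
        d = fm.classify_single(qset(2.0, two_r1), self.protocol, "two_r1")
        assert d.predicted == expected

    def test_two_r1_rule_requires_measurement(self):
        with pytest.raises(fm.MissingMeasurementError):
            fm.classify_single(qset(2.0), self.protocol, "two_r1")


class TestClassifySequential:
    protocol = fm.CutoffProtocol()

    @pytest.mark.parametrize(
        "ratio, two_r1, predicted, path",
        [
            (2.50, None, POSITIVE, "first_criterion"),
            (1.80, None, NEGATIVE, "first_criterion"),
            (2.00, 30.0, NEGATIVE, "second_criterion"),  # healthy confirmed
            (2.00, 20.0, POSITIVE, "second_criterion"),  # band FN recovered
            (1.95, 20.0, POSITIVE, "second_criterion"),  # band is inclusive
            (2.19, 30.0, NEGATIVE, "second_criterion"),
        ],
    )
    def test_ratio_first_paths(self, ratio, two_r1, predicted, path):
        d = fm.classify_sequential(qset(ratio, two_r1), self.protocol)
        assert (d.predicted, d.path) == (predicted, path)

    def test_band_sample_without_two_r1_signals_extra_acquisition(self):
        with pytest.raises(fm.MissingMeasurementError, match="0.39"):
            fm.classify_sequential(qset(2.0), self.protocol)

    @pytest.mark.parametrize(
        "ratio, two_r1, predicted, path",
        [
            (1.5, 20.0, POSITIVE, "first_criterion"),
            (3.0, 30.0, NEGATIVE, "first_criterion"),
            (3.0, 25.0, POSITIVE, "second_criterion"),
            (1.5, 25.0, NEGATIVE, "second_criterion"),
            (1.5, 26.5, NEGATIVE, "second_criterion"),  # band upper edge inclusive
        ],
    )
    def test_two_r1_first_paths(self, ratio, two_r1, predicted, path):
        proto = fm.CutoffProtocol(order="two_r1_first")
        d = fm.classify_sequential(qset(ratio, two_r1), proto)
        assert (d.predicted, d.path) == (predicted, path)

    def test_collapse_band_low_equals_cutoff(self):
        # with a zero-width band the sequential rule is the Ratio-only rule
        collapsed = fm.CutoffProtocol(ratio_band_low=2.19)
        for ratio in np.arange(1.5, 3.01, 0.01):
            for two_r1 in (12.0, 24.0, 26.0, 35.0):
                q = qset(round(float(ratio), 3), two_r1)
                seq = fm.classify_sequential(q, collapsed)
                single = fm.classify_single(q, collapsed, "ratio")
                assert seq.predicted == single.predicted

    def test_sequential_dominance_over_random_cohorts(self):
        # band deferral can only flip negatives to positives: sensitivity
        # never drops and specificity never rises vs the Ratio-only rule
        rng = np.random.default_rng(17)
        proto = fm.CutoffProtocol()
        for _ in range(200):
            n = int(rng.integers(20, 60))
            classes = rng.choice(["H", "M", "T"], size=n)
            classes[:2] = ["H", "M"]
            qs, truth = [], []
            for i, c in enumerate(classes):
                mu_r, sd_r = {"H": (1.83, 0.36), "M": (2.66, 0.48), "T": (3.42, 0.53)}[c]
                mu_s, sd_s = {"H": (34.7, 8.7), "M": (19.5, 5.7), "T": (12.2, 2.9)}[c]
                qs.append(
                    qset(max(rng.normal(mu_r, sd_r), 0.1),
                         max(rng.normal(mu_s, sd_s), 0.1), sid=str(i))
                )
                truth.append(c)
            seq = fm.evaluate([fm.classify_sequential(q, proto) for q in qs], truth)
            single = fm.evaluate([fm.classify_single(q, proto, "ratio") for q in qs], truth)
            assert seq.sensitivity >= single.sensitivity
            assert seq.specificity <= single.specificity


class TestAssignQuadrant:
    @pytest.mark.parametrize(
        "ratio, two_r1, quadrant",
        [
            (3.42, 12.2, "I"),  # tumour-like: both rules positive
            (2.50, 30.0, "II"),
            (1.83, 34.7, "III"),  # healthy-like: both rules negative
            (2.00, 20.0, "IV"),
            (2.19, 24.0, "IV"),  # boundary conventions: ratio neg, 2R1 pos
        ],
    )
    def test_quadrants(self, ratio, two_r1, quadrant):
        assert fm.assign_quadrant(qset(ratio, two_r1)) == quadrant

    def test_quadrant_decision_consistency(self):
        # I u II <=> ratio-positive; I u IV <=> 2R1-positive
        proto = fm.CutoffProtocol()
        rng = np.random.default_rng(4)
        for _ in range(300):
            q = qset(float(rng.uniform(1.0, 4.5)), float(rng.uniform(5.0, 50.0)))
            quad = fm.assign_quadrant(q, proto)
            ratio_pos = fm.classify_single(q, proto, "ratio").predicted == POSITIVE
            two_r1_pos = fm.classify_single(q, proto, "two_r1").predicted == POSITIVE
            assert (quad in ("I", "II")) == ratio_pos
            assert (quad in ("I", "IV")) == two_r1_pos


class TestEvaluate:
    def _decisions(self, preds):
        return [fm.Decision(str(i), p, "first_criterion") for i, p in enumerate(preds)]

    def test_study_cohort_counts(self):
        preds = [POSITIVE] * 56 + [NEGATIVE] * 8 + [NEGATIVE] * 34 + [POSITIVE] * 6
        truth = ["M"] * 30 + ["T"] * 21 + ["M"] * 13 + ["H"] * 40
        s = fm.evaluate(self._decisions(preds), truth)
        assert (s.tp, s.fn, s.tn, s.fp) == (56, 8, 34, 6)
        assert s.sensitivity == pytest.approx(0.875)
        assert s.specificity == pytest.approx(0.85)

    def test_degenerate_predictions(self):
        preds = [NEGATIVE] * 4
        truth = ["M", "T", "H", "H"]
        s = fm.evaluate(self._decisions(preds), truth)
        assert s.sensitivity == 0.0 and s.specificity == 1.0
        all_right = [POSITIVE, POSITIVE, NEGATIVE, NEGATIVE]
        s2 = fm.evaluate(self._decisions(all_right), truth)
        assert s2.sensitivity == s2.specificity == s2.accuracy == 1.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            fm.evaluate(self._decisions([POSITIVE]), ["M", "H"])


class TestSequentialCutoffClassifier:
    def _data(self, n=60, seed=0):
        rng = np.random.default_rng(seed)
        X, y = [], []
        for c, n_c in [("H", n // 2), ("M", n // 4), ("T", n - n // 2 - n // 4)]:
            mu_r, sd_r = {"H": (1.83, 0.36), "M": (2.66, 0.48), "T": (3.42, 0.53)}[c]
            mu_s, sd_s = {"H": (34.7, 8.7), "M": (19.5, 5.7), "T": (12.2, 2.9)}[c]
            for _ in range(n_c):
                X.append([max(rng.normal(mu_r, sd_r), 0.1), max(rng.normal(mu_s, sd_s), 0.1)])
                y.append(0 if c == "H" else 1)
        return np.asarray(X), np.asarray(y)

    def test_predict_matches_functional_api(self):
        X, y = self._data()
        clf = fm.SequentialCutoffClassifier(pos_label=1).fit(X, y)
        preds = clf.predict(X)
        proto = fm.CutoffProtocol()
        expected = [
            1 if fm.classify_sequential(qset(r, t), proto).predicted == POSITIVE else 0
            for r, t in X
        ]
        assert preds.tolist() == expected

    def test_sklearn_contract(self):
        X, y = self._data()
        clf = fm.SequentialCutoffClassifier(pos_label=1)
        cloned = clone(clf)
        assert cloned.get_params() == clf.get_params()
        clf.set_params(order="two_r1_first").fit(X, y)
        assert clf.protocol_.order == "two_r1_first"
        assert 0.0 <= clf.fit(X, y).score(X, y) <= 1.0

    def test_select_cutoffs_recovers_separation(self):
        # well separated training data: re-selected cut-offs must fall in the gaps
        X = np.array([[1.5, 35.0]] * 10 + [[3.5, 12.0]] * 10)
        y = np.array([0] * 10 + [1] * 10)
        clf = fm.SequentialCutoffClassifier(select_cutoffs=True, pos_label=1).fit(X, y)
        assert 1.5 < clf.protocol_.ratio_cutoff < 3.5
        assert 12.0 < clf.protocol_.two_r1_cutoff < 35.0
        assert clf.predict(X).tolist() == y.tolist()

    def test_nan_two_r1_allowed_outside_band_only(self):
        clf = fm.SequentialCutoffClassifier(pos_label=1).fit(
            np.array([[3.0, 12.0], [1.5, 30.0]]), [1, 0]
        )
        assert clf.predict(np.array([[3.0, np.nan]])).tolist() == [1]
        with pytest.raises(fm.MissingMeasurementError):
            clf.predict(np.array([[2.0, np.nan]]))
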