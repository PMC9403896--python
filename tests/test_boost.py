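"""ICABoost: screening, stump search, weight dynamics and prediction."""

import numpy as np
import pytest

from emolearn import boost as mb


def oracle_best_stump(A, targets, D, components):
    """Independent brute-force stump search: every midpoint threshold of
    every admissible component, both polarities, scanned in the same
    deterministic tie-break order (component, threshold, +1 before -1)."""
    best = None
    for j in components:
        a = A[:, j]
        vals = np.unique(a)
        thresholds = (
            [-np.inf]
            + [(vals[i] + vals[i + 1]) / 2 for i in range(len(vals) - 1)]
            + [np.inf]
        )
        for thr in thresholds:
            for pol in (1, -1):
                pred = np.where(pol * (a - thr) > 0, 1.0, -1.0)
                err = float(D[pred != targets].sum())
                if best is None or err < best[0] - 1e-12:
                    best = (err, int(j), float(thr), pol)
    return best


def screening_all(A):
    """ScreeningResult that admits every component (for stump-level tests)."""
    m = A.shape[1]
    return mb.ScreeningResult(
        class_k="x",
        components=np.arange(m),
        u=np.zeros(m),
        polarity=np.ones(m, dtype=int),
    )


class TestScreening:
    def test_perfectly_separating_component_is_admitted(self):
        A = np.array([[5.0], [6.0], [7.0], [0.0], [1.0], [2.0]])
        y = ["k", "k", "k", "o", "o", "o"]
        res = mb.screen_components(A, y, "k")
        assert list(res.components) == [0]
        assert res.polarity[0] == 1
        # threshold is the midpoint of the class and rest means
        assert res.u[0] == pytest.approx((6.0 + 1.0) / 2)

    def test_constant_component_is_rejected(self):
        A = np.ones((6, 1))
        y = ["k", "k", "k", "o", "o", "o"]
        res = mb.screen_components(A, y, "k")
        assert res.components.size == 0

    def test_admission_matches_exhaustive_count_oracle(self, rng):
        A = rng.normal(size=(10, 6))
        y = list(rng.choice(["k", "o"], size=10))
        y[0] = "k"  # ensure both present
        y[1] = "o"
        res = mb.screen_components(A, y, "k")
        yk = np.asarray(y) == "k"
        Q_k = yk.sum()
        expected = []
        for j in range(6):
            mk, mo = A[yk, j].mean(), A[~yk, j].mean()
            u = (mk + mo) / 2
            pol = 1 if mk > mo else -1
            count = int(np.sum(pol * (A[yk, j] - u) > 0))
            if count > Q_k / 2:
                expected.append(j)
        assert list(res.components) == expected

    def test_absent_class_raises(self, rng):
        with pytest.raises(ValueError, match="not present"):
            mb.screen_components(rng.normal(size=(4, 2)), ["a"] * 4, "z")


class TestEncodeLabels:
    def test_pm_one_encoding(self):
        y = ["a", "b", "a", "c", "b"]
        np.testing.assert_array_equal(
            mb.encode_labels(y, "a"), [1.0, -1.0, 1.0, -1.0, -1.0]
        )
        assert (mb.encode_labels(["a"] * 3, "a") == 1).all()
        assert (mb.encode_labels(["b"] * 3, "a") == -1).all()


class TestBestWeak:
    def test_perfect_separation_gives_zero_error_and_capped_alpha(self):
        A = np.array([[0.0], [1.0], [10.0], [11.0]])
        t = np.array([-1.0, -1.0, 1.0, 1.0])
        w = mb.SampleWeights.uniform(4)
        weak = mb.best_weak(A, t, w, screening_all(A))
        assert weak.weighted_error == 0.0
        eps_min = 1.0 / 8.0
        assert weak.alpha == pytest.approx(0.5 * np.log((1 - eps_min) / eps_min))

    def test_six_sample_toy_matches_enumeration_oracle(self):
        A = np.array([[1.0, 3.0], [2.0, 1.0], [3.0, 2.0], [4.0, 6.0], [5.0, 4.0], [6.0, 5.0]])
        t = np.array([-1.0, -1.0, 1.0, -1.0, 1.0, 1.0])
        w = mb.SampleWeights.uniform(6)
        weak = mb.best_weak(A, t, w, screening_all(A))
        err, j, thr, pol = oracle_best_stump(A, t, w.D, range(2))
        assert (weak.weighted_error, weak.component_j, weak.threshold, weak.polarity) == (
            pytest.approx(err), j, pytest.approx(thr), pol
        )

    @pytest.mark.parametrize("seed", range(8))
    def test_random_small_instances_match_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n, m = 8, 4
        A = rng.normal(size=(n, m)).round(2)  # ties likely after rounding
        t = rng.choice([-1.0, 1.0], size=n)
        D = rng.uniform(0.1, 1.0, size=n)
        D /= D.sum()
        w = mb.SampleWeights(D=D)
        try:
            weak = mb.best_weak(A, t, w, screening_all(A))
        except mb.NoWeakLearnerError:
            err = oracle_best_stump(A, t, D, range(m))[0]
            assert err >= 0.5
            return
        err, j, thr, pol = oracle_best_stump(A, t, D, range(m))
        assert weak.weighted_error == pytest.approx(err, abs=1e-12)
        assert (weak.component_j, weak.polarity) == (j, pol)
        assert weak.threshold == pytest.approx(thr)

    def test_hopeless_instance_raises_no_weak_learner(self):
        A = np.ones((4, 2))  # constant activations: every stump is constant
        t = np.array([1.0, 1.0, -1.0, -1.0])
        with pytest.raises(mb.NoWeakLearnerError):
            mb.best_weak(A, t, mb.SampleWeights.uniform(4), screening_all(A))


class TestUpdateWeights:
    def _weak(self, alpha):
        return mb.WeakClassifier(0, "k", 0.0, 1, alpha, 0.25)

    def test_weights_renormalise_to_one(self, rng):
        D = rng.uniform(size=20)
        w = mb.SampleWeights(D=D / D.sum())
        correctness = rng.choice([-1.0, 1.0], size=20)
        w2 = mb.update_weights(w, self._weak(0.7), correctness)
        assert abs(w2.D.sum() - 1.0) < 1e-12
        assert w2.round_t == w.round_t + 1

    def test_misclassified_samples_gain_relative_weight(self, rng):
        w = mb.SampleWeights.uniform(10)
        correctness = np.array([1.0] * 5 + [-1.0] * 5)
        w2 = mb.update_weights(w, self._weak(0.5), correctness)
        assert w2.D[5:].min() > w2.D[:5].max()

    def test_three_sample_hand_computation(self):
        # eps = 1/4 with one misclassified sample of weight 1/4
        D = np.array([0.25, 0.25, 0.5])
        w = mb.SampleWeights(D=D)
        alpha = 0.5 * np.log(3.0)  # = 1/2 ln((1-eps)/eps), eps = 0.25
        correctness = np.array([-1.0, 1.0, 1.0])
        w2 = mb.update_weights(w, self._weak(alpha), correctness)
        raw = D * np.exp(-alpha * correctness)
        expect = raw / raw.sum()
        np.testing.assert_allclose(w2.D, expect, atol=1e-12)
        # the single error now carries half the distribution
        assert w2.D[0] == pytest.approx(0.5, abs=1e-12)


def _separable_activations(scale=0.5):
    """One dedicated component per class (detector-style activations): a
    single threshold on component k isolates class k."""
    rng = np.random.default_rng(5)
    classes = list("abcde")
    y = list(np.repeat(classes, 6))
    A = rng.normal(scale=scale, size=(30, 5))
    for i, lab in enumerate(y):
        A[i, classes.index(lab)] += 8.0
    return A, y


class TestTraining:
    def test_separable_problem_reaches_zero_training_error_in_one_round(self):
        A, y = _separable_activations()
        strong = mb.train_icaboost(A, y, T=1)
        pred, _ = mb.predict(strong, A)
        assert pred == y

    def test_training_error_non_increasing_in_rounds(self):
        A, y = _separable_activations(scale=3.0)  # moderate class overlap
        errors = []
        for T in range(1, 11):
            strong = mb.train_icaboost(A, y, T=T)
            pred, _ = mb.predict(strong, A)
            errors.append(np.mean(np.asarray(pred) != np.asarray(y)))
        assert all(e2 <= e1 + 1e-12 for e1, e2 in zip(errors, errors[1:]))

    def test_every_stored_stump_beats_chance(self, rng):
        A = rng.normal(size=(60, 5))
        A[:, 2] += np.repeat([0, 1.0, 2.0], 20)
        y = list(np.repeat(["a", "b", "c"], 20))
        strong = mb.train_icaboost(A, y, T=8)
        for stumps in strong.stumps.values():
            assert stumps  # non-empty per class
            for wk in stumps:
                assert wk.weighted_error < 0.5
                assert wk.alpha > 0

    def test_training_error_bound_product_holds(self, rng):
        """AdaBoost bound: one-vs-rest training error of each ensemble is
        at most prod_t 2 sqrt(eps_t (1 - eps_t))."""
        A = rng.normal(size=(50, 4))
        A[:, 0] += np.repeat([0.0, 1.5], 25)
        A[:, 1] -= np.repeat([0.0, 1.0], 25)
        y = list(np.repeat(["a", "b"], 25))
        strong = mb.train_icaboost(A, y, T=10)
        _, conf = mb.predict(strong, A)
        for ci, c in enumerate(strong.classes):
            targets = mb.encode_labels(y, c)
            err = np.mean(np.where(conf[:, ci] > 0, 1.0, -1.0) != targets)
            bound = np.prod(
                [2 * np.sqrt(w.weighted_error * (1 - w.weighted_error)) for w in strong.stumps[c]]
            )
            assert err <= bound + 1e-12

    def test_boosting_rounds_match_oracle_on_small_instance(self):
        """Full-round equivalence: at every round the trained stump equals
        the brute-force minimiser under the updated weights."""
        rng = np.random.default_rng(3)
        A = rng.normal(size=(8, 3)).round(1)
        A[:, 1] += np.array([2.0] * 4 + [0.0] * 4)
        y = ["k"] * 4 + ["o"] * 4
        T = 4
        strong = mb.train_icaboost(A, y, T=T)
        screening = mb.screen_components(A, y, "k")
        targets = mb.encode_labels(y, "k")
        weights = mb.SampleWeights.uniform(8)
        for wk in strong.stumps["k"]:
            err, j, thr, pol = oracle_best_stump(A, targets, weights.D, screening.components)
            assert (wk.component_j, wk.polarity) == (j, pol)
            assert wk.weighted_error == pytest.approx(err, abs=1e-12)
            assert wk.threshold == pytest.approx(thr)
            weights = mb.update_weights(weights, wk, targets * wk.decide(A))
            assert abs(weights.D.sum() - 1.0) < 1e-12  # conservation each round

    def test_class_without_admissible_components_is_named(self):
        A = np.ones((6, 2))
        y = ["a", "a", "a", "b", "b", "b"]
        with pytest.raises(mb.ScreeningError, match="'a'"):
            mb.train_icaboost(A, y, T=2)


class TestPredict:
    def test_single_stump_per_class_reproduces_the_vote_pattern(self):
        A, y = _separable_activations()
        strong = mb.train_icaboost(A, y, T=1)
        pred, conf = mb.predict(strong, A)
        for ci, c in enumerate(strong.classes):
            wk = strong.stumps[c][0]
            np.testing.assert_allclose(conf[:, ci], wk.alpha * wk.decide(A))

    def test_batch_equals_per_sample_prediction(self):
        A, y = _separable_activations()
        strong = mb.train_icaboost(A, y, T=3)
        batch, _ = mb.predict(strong, A)
        singles = [mb.predict(strong, A[i])[0][0] for i in range(len(A))]
        assert batch == singles

    def test_dimension_mismatch_raises(self):
        A, y = _separable_activations()
        strong = mb.train_icaboost(A, y, T=1)
        max_j = max(w.component_j for v in strong.stumps.values() for w in v)
        with pytest.raises(ValueError):
            mb.predict(strong, np.zeros((3, max_j)))

    def test_serialization_round_trip(self):
        A, y = _separable_activations()
        strong = mb.train_icaboost(A, y, T=2)
        clone = mb.StrongClassifier.from_dict(strong.to_dict())
        p1, c1 = mb.predict(strong, A)
        p2, c2 = mb.predict(clone, A)
        assert p1 == p2
        np.testing.assert_allclose(c1, c2)


class TestNearestMeanBaseline:
    def _fit(self):
        A = np.array(
            [[0.0, 0], [0.2, 0], [5.0, 0], [5.2, 0], [0, 5.0], [0.2, 5.0]], dtype=float
        )
        y = ["calm", "calm", "angry", "angry", "happy", "happy"]
        return mb.ica_nearest_baseline(A, y), A, y

    def test_query_at_class_mean_returns_that_class(self):
        clf, A, y = self._fit()
        assert clf.predict(np.array([5.1, 0.0]))[0] == "angry"

    def test_equidistant_query_breaks_ties_lexicographically(self):
        A = np.array([[1.0, 0], [-1.0, 0], [0, 1.0], [0, -1.0]], dtype=float)
        y = ["b", "b", "a", "a"]  # both class means at the origin
        # add a calm sample pair to provide the neutral reference
        A = np.vstack([A, [[10.0, 10.0], [10.0, 10.0]]])
        y += ["calm", "calm"]
        clf = mb.ica_nearest_baseline(A, y)
        assert clf.predict(np.array([0.0, 0.0]))[0] == "a"

    def test_matches_brute_force_distance_loop(self, rng):
        A = rng.normal(size=(10, 3))
        y = ["calm"] * 3 + ["angry"] * 3 + ["happy"] * 4
        clf = mb.ica_nearest_baseline(A, y)
        queries = rng.normal(size=(6, 3))
        classes = sorted(set(y))
        means = {c: A[np.asarray(y) == c].mean(axis=0) for c in classes}
        for q, pred in zip(queries, clf.predict(queries)):
            dists = {c: np.linalg.norm(q - means[c]) for c in classes}
            assert pred == min(sorted(dists), key=lambda c: dists[c])

    def test_missing_neutral_class_raises(self, rng):
        with pytest.raises(ValueError, match="neutral"):
            mb.ica_nearest_baseline(rng.normal(size=(4, 2)), ["a", "a", "b", "b"])


def test_boosted_classifier_beats_euclidean_baseline_on_surrogate(benchmark_reports):
    """The feature-selective boosted classifier outperforms holistic
    nearest-mean matching in the same ICA feature space."""
    assert benchmark_reports["icaboost"].macro > benchmark_reports["ica_nearest"].macro
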