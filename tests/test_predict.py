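import math
import warnings

import numpy as np
import pytest

from fusctl.predict import (
    FEATURE_NAMES_12,
    FEATURE_NAMES_20,
    Dataset,
    MLPModel,
    ShapResult,
    TrainConfig,
    build_dataset,
    confusion_metrics,
    mean_abs_shap,
    oversample,
    shap_attributions,
    top_k_features,
    train_mlp,
    train_test_split,
    undersample,
)
from tests.conftest import make_frame, make_record


def record_with_events(event_pulses, n=20):
    frames = [
        make_frame(
            pulse_index=i + 1,
            time_s=float(i),
            broadband=8.0 if (i + 1) in event_pulses else 0.0,
        )
        for i in range(n)
    ]
    return make_record(frames)


class TestBuildDataset:
    def test_row_count_drops_last_pulse(self):
        ds = build_dataset([record_with_events(set(), n=130)])
        assert ds.n == 129

    def test_single_event_labels_previous_row(self):
        k = 7  # event at pulse 7 (1-based)
        ds = build_dataset([record_with_events({k})])
        expected = np.zeros(19, dtype=int)
        expected[k - 2] = 1  # row index k-2 == pulse k-1
        assert ds.y.tolist() == expected.tolist()

    def test_event_free_run_all_zero(self):
        ds = build_dataset([record_with_events(set())])
        assert ds.y.sum() == 0

    def test_shifting_event_shifts_one_label(self):
        a = build_dataset([record_with_events({10})]).y
        b = build_dataset([record_with_events({11})]).y
        assert a.sum() == b.sum() == 1
        assert np.flatnonzero(b)[0] - np.flatnonzero(a)[0] == 1

    def test_feature_sets(self):
        recs = [record_with_events({5})]
        assert build_dataset(recs, 12).feature_names == FEATURE_NAMES_12
        assert build_dataset(recs, 20).feature_names == FEATURE_NAMES_20
        assert build_dataset(recs, 20).X.shape[1] == 20

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            build_dataset([])

    def test_event_at_last_pulse_labels_final_row(self):
        # the last pulse contributes no feature row, but its event flag is
        # the label of the second-to-last pulse's row
        ds = build_dataset([record_with_events({20})])
        assert ds.y.tolist() == [0] * 18 + [1]


class TestUndersample:
    def make_imbalanced(self, n_pos=100, n_neg=10000, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n_pos + n_neg, 12))
        y = np.r_[np.ones(n_pos, int), np.zeros(n_neg, int)]
        return Dataset(X, y, FEATURE_NAMES_12)

    def test_balances_one_to_one(self):
        ds = self.make_imbalanced()
        out = undersample(ds, np.random.default_rng(1))
        assert out.n == 200
        assert out.n_positive == 100

    def test_already_balanced_unchanged_up_to_order(self):
        ds = self.make_imbalanced(50, 50)
        out = undersample(ds, np.random.default_rng(1))
        assert sorted(map(tuple, out.X)) == sorted(map(tuple, ds.X))

    def test_seeded_determinism(self):
        ds = self.make_imbalanced()
        a = undersample(ds, np.random.default_rng(9))
        b = undersample(ds, np.random.default_rng(9))
        assert np.array_equal(a.X, b.X)

    def test_no_positives_rejected(self):
        ds = self.make_imbalanced(n_pos=0, n_neg=100)
        with pytest.raises(ValueError):
            undersample(ds, np.random.default_rng(0))

    def test_oversample_parity(self):
        ds = self.make_imbalanced(100, 1000)
        out = oversample(ds, np.random.default_rng(0))
        assert out.n == 2000
        assert out.n_positive == 1000


class TestTrainTestSplit:
    def test_stratified_ratio(self):
        ds = TestUndersample().make_imbalanced(200, 1800)
        train, test = train_test_split(ds, 0.2, seed=0)
        assert test.n == 400
        assert test.n_positive == 40
        assert train.n_positive == 160


def separable_toy(n=400, seed=0, margin=3.0):
    """Two informative features (of 12) with a wide margin."""
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, size=n)
    X = rng.normal(size=(n, 12))
    X[:, 0] += margin * (2 * y - 1)
    X[:, 1] -= margin * (2 * y - 1)
    return Dataset(X, y, FEATURE_NAMES_12)


class TestTrainMLP:
    def test_matches_logistic_oracle_on_separable_data(self):
        ds = separable_toy()
        model, _ = train_mlp(ds, TrainConfig(epochs=150, seed=0))
        m = confusion_metrics(model.classify(ds.X), ds.y)
        assert m.sensitivity >= 0.99

        from sklearn.linear_model import LogisticRegression

        oracle = LogisticRegression(max_iter=1000).fit(ds.X, ds.y)
        mo = confusion_metrics(oracle.predict(ds.X), ds.y)
        assert mo.sensitivity >= 0.99  # oracle agrees the task is separable

    def test_all_zero_labels_give_low_output(self):
        rng = np.random.default_rng(0)
        ds = Dataset(rng.normal(size=(200, 12)), np.zeros(200, int), FEATURE_NAMES_12)
        model, _ = train_mlp(ds, TrainConfig(epochs=50, seed=0))
        assert np.all(model.forward(ds.X) < 0.5)

    def test_deterministic_given_seed(self):
        ds = separable_toy()
        cfg = TrainConfig(epochs=60, seed=3)
        m1, _ = train_mlp(ds, cfg)
        m2, _ = train_mlp(ds, cfg)
        assert np.array_equal(m1.W1, m2.W1)
        assert np.array_equal(m1.w2, m2.w2)

    def test_parameter_count(self):
        ds = separable_toy(n=100)
        model, _ = train_mlp(ds, TrainConfig(epochs=5, seed=0))
        assert model.n_params == 141


class TestPredict:
    def zero_model(self):
        return MLPModel(
            W1=np.zeros((10, 12)),
            b1=np.zeros(10),
            w2=np.zeros(10),
            b2=0.0,
            x_mean=np.zeros(12),
            x_sd=np.ones(12),
            feature_names=FEATURE_NAMES_12,
        )

    def test_zero_weights_give_half_and_positive(self):
        # closed form: output = sigmoid(0) = 0.5 exactly
        p, flag = self.zero_model().predict(np.zeros(12))
        assert p == pytest.approx(0.5)
        assert flag is True  # 0.5 or greater is positive

    def test_just_below_half_is_negative(self):
        model = self.zero_model()
        model.b2 = -0.05
        p, flag = model.predict(np.zeros(12))
        assert p < 0.5 and flag is False

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            self.zero_model().predict(np.zeros(11))

    def test_output_in_open_interval(self):
        rng = np.random.default_rng(0)
        model = MLPModel(
            W1=rng.normal(size=(10, 12)),
            b1=rng.normal(size=10),
            w2=rng.normal(size=10),
            b2=0.0,
            x_mean=np.zeros(12),
            x_sd=np.ones(12),
            feature_names=FEATURE_NAMES_12,
        )
        probs = model.forward(rng.normal(size=(100, 12)))
        assert np.all((probs > 0) & (probs < 1))


class TestConfusionMetrics:
    def test_paper_training_counts(self):
        # counts reconstructed from the printed ratios
        m = confusion_metrics(
            np.r_[np.ones(3244), np.zeros(142), np.ones(246), np.zeros(3140)],
            np.r_[np.ones(3244), np.ones(142), np.zeros(246), np.zeros(3140)],
        )
        assert (m.tp, m.fn, m.fp, m.tn) == (3244, 142, 246, 3140)
        assert m.accuracy == pytest.approx(6384 / 6772)
        assert m.sensitivity == pytest.approx(3244 / 3386)
        assert m.precision == pytest.approx(3244 / 3490)
        assert m.specificity == pytest.approx(3140 / 3386)
        assert round(100 * m.accuracy) == 94
        assert round(100 * m.sensitivity) == 96
        assert round(100 * m.precision) == 93
        assert round(100 * m.specificity) == 93

    def test_perfect_predictor(self):
        m = confusion_metrics([1, 0, 1, 0], [1, 0, 1, 0])
        assert m.accuracy == m.sensitivity == m.precision == m.specificity == 1.0

    def test_all_negative_predictor(self):
        m = confusion_metrics([0, 0, 0, 0], [1, 0, 1, 0])
        assert m.sensitivity == 0.0
        assert m.specificity == 1.0

    def test_zero_denominator_warns_nan(self):
        with warnings.catch_warnings(record=True) as w:
            warnings.simplefilter("always")
            m = confusion_metrics([0, 0], [0, 0])
            assert math.isnan(m.sensitivity)
            assert any("sensitivity" in str(x.message) for x in w)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            confusion_metrics([], [])

    def test_counts_rederivable_from_metrics(self):
        m = confusion_metrics(
            np.r_[np.ones(30), np.zeros(5), np.ones(7), np.zeros(58)],
            np.r_[np.ones(30), np.ones(5), np.zeros(7), np.zeros(58)],
        )
        n_pos = m.tp + m.fn
        assert round(m.sensitivity * n_pos) == m.tp
        assert round(m.specificity * (m.tn + m.fp)) == m.tn
        assert round(m.accuracy * m.n) == m.tp + m.tn


class TestShap:
    def test_linear_model_closed_form(self):
        rng = np.random.default_rng(0)
        w = rng.normal(size=8)
        f = lambda X: np.atleast_2d(X) @ w
        background = rng.normal(size=(200, 8))
        x = rng.normal(size=8)
        res = shap_attributions(f, x, background, n_samples=4000, seed=1)
        expected = w * (x - background.mean(axis=0))
        assert np.allclose(res.phi, expected, atol=0.15)

    def test_ignored_feature_near_zero(self):
        rng = np.random.default_rng(2)
        w = rng.normal(size=6)
        w[3] = 0.0
        f = lambda X: np.atleast_2d(X) @ w
        res = shap_attributions(
            f, rng.normal(size=6), rng.normal(size=(100, 6)), n_samples=3000, seed=0
        )
        assert abs(res.phi[3]) < 0.05

    def test_local_accuracy_exact_for_sampled_base(self):
        rng = np.random.default_rng(3)
        model = MLPModel(
            W1=rng.normal(size=(10, 12)),
            b1=rng.normal(size=10),
            w2=rng.normal(size=10),
            b2=0.1,
            x_mean=np.zeros(12),
            x_sd=np.ones(12),
            feature_names=FEATURE_NAMES_12,
        )
        background = rng.normal(size=(60, 12))
        for k in range(10):
            x = rng.normal(size=12)
            res = shap_attributions(model, x, background, n_samples=500, seed=k)
            fx = float(model.forward(x[None])[0])
            assert res.local_accuracy_residual(fx) < 1e-10

    def test_insufficient_samples_rejected(self):
        with pytest.raises(ValueError):
            shap_attributions(
                lambda X: np.zeros(len(np.atleast_2d(X))),
                np.zeros(12),
                np.zeros((5, 12)),
                n_samples=10,
            )


class TestTopK:
    def linear_results(self, w, n=30, seed=0):
        rng = np.random.default_rng(seed)
        f = lambda X: np.atleast_2d(X) @ w
        background = rng.normal(size=(100, len(w)))
        return [
            shap_attributions(f, rng.normal(size=len(w)), background,
                              n_samples=len(w) * 40, seed=i)
            for i in range(n)
        ]

    def test_recovers_informative_features(self):
        w = np.zeros(10)
        w[[2, 5, 8]] = (5.0, 4.0, 3.0)
        results = self.linear_results(w)
        top = top_k_features(results, k=3)
        assert {t[0] for t in top} == {2, 5, 8}

    def test_constant_model_deterministic_order(self):
        f = lambda X: np.full(len(np.atleast_2d(X)), 0.3)
        rng = np.random.default_rng(0)
        results = [
            shap_attributions(f, rng.normal(size=6), rng.normal(size=(50, 6)),
                              n_samples=60, seed=i)
            for i in range(5)
        ]
        top = top_k_features(results, k=6)
        assert [t[0] for t in top] == [0, 1, 2, 3, 4, 5]  # tie-break by index
        assert all(t[2] < 1e-12 for t in top)

    def test_k_equals_d_is_permutation(self):
        w = np.arange(1.0, 6.0)
        results = self.linear_results(w, n=5)
        top = top_k_features(results, k=5)
        assert sorted(t[0] for t in top) == [0, 1, 2, 3, 4]

    def test_k_too_large_rejected(self):
        results = [ShapResult(phi=np.zeros(4), base_value=0.0)]
        with pytest.raises(ValueError):
            top_k_features(results, k=5)

    def test_mean_abs_shap_requires_results(self):
        with pytest.raises(ValueError):
            mean_abs_shap([])
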