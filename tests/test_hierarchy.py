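"""Hierarchical model: assembly, aggregation, pretraining, end-to-end fit."""

import numpy as np
import pytest

from floorgait.hierarchy import (
    FeatureDataset,
    ModelConfig,
    Standardizer,
    aggregate_mean,
    assemble_step_features,
    build_trace_input,
    encode_biometrics,
    pretrain_level,
    train_hierarchical,
)
from floorgait.nn import MLP
from floorgait.records import Biometrics


class TestAssembly:
    def test_step_vector_dimension_and_order(self):
        vec = assemble_step_features(
            step_time=0.5, toe_probability=0.2, sensor_id=3,
            basic=(0.0, 1.0, 0.1, 3.0), dominant_freq_strike=15.0,
            dominant_freq_off=60.0, psd_bands=np.array([0.5, 0.3, 0.2]),
        )
        assert vec.shape == (12,)
        assert vec[0] == 0.5 and vec[2] == 3.0 and vec[7] == 15.0

    def test_non_finite_feature_signaled(self):
        with pytest.raises(ValueError):
            assemble_step_features(
                np.nan, 0.2, 0, (0, 1, 0, 3), 15.0, 60.0, np.ones(3) / 3
            )

    def test_trace_input_dimension(self):
        probs = np.tile(np.full(6, 1 / 6), (4, 1))
        out = build_trace_input(probs, np.zeros(14))
        assert out.shape == (20,)
        assert out[14:].sum() == pytest.approx(1.0)  # mean of simplex points

    def test_biometric_encoding(self):
        bio = Biometrics(age=10, weight=30, height=1.5, gender="female")
        vec = encode_biometrics(bio)
        np.testing.assert_allclose(vec, [10.0, 0.0, 30 / 1.5**2])


class TestAggregation:
    def test_single_member_identity(self):
        np.testing.assert_array_equal(aggregate_mean([[1.0, 2.0]]), [1.0, 2.0])

    def test_elementwise_mean(self):
        np.testing.assert_array_equal(
            aggregate_mean([[0.0, 2.0], [2.0, 0.0]]), [1.0, 1.0]
        )

    def test_permutation_invariance(self):
        rng = np.random.default_rng(0)
        X = rng.random((7, 6))
        perm = rng.permutation(7)
        np.testing.assert_allclose(aggregate_mean(X), aggregate_mean(X[perm]))

    def test_empty_group_signaled(self):
        with pytest.raises(ValueError):
            aggregate_mean(np.empty((0, 6)))


class TestMLP:
    def test_forward_shapes_and_softmax_simplex(self):
        net = MLP((12, 32, 16), n_classes=6, seed=0)
        proba = net.predict_proba(np.random.default_rng(1).random((5, 12)))
        assert proba.shape == (5, 6)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0)

    def test_gradient_matches_finite_differences(self):
        """Backprop agrees with a numerical gradient on a tiny network."""
        from floorgait.nn import cross_entropy_grad

        rng = np.random.default_rng(2)
        net = MLP((4, 8), n_classes=3, dropout=0.0, seed=3)
        X = rng.random((6, 4))
        y = np.array([0, 1, 2, 0, 1, 2])

        logits, cache = net.forward(X)
        loss0, dlogits = cross_entropy_grad(logits, y)
        dW, db, _ = net.backward(cache, dlogits)

        eps = 1e-6
        for l in (0, 1):
            for idx in [(0, 0), (1, 2)]:
                net.W[l][idx] += eps
                lp, _ = cross_entropy_grad(net.forward(X)[0], y)
                net.W[l][idx] -= 2 * eps
                lm, _ = cross_entropy_grad(net.forward(X)[0], y)
                net.W[l][idx] += eps
                numeric = (lp - lm) / (2 * eps)
                assert dW[l][idx] == pytest.approx(numeric, abs=1e-5)

    def test_dropout_only_in_training(self):
        net = MLP((4, 16), n_classes=2, dropout=0.5, seed=0)
        X = np.ones((3, 4))
        a = net.predict_proba(X)
        b = net.predict_proba(X)
        np.testing.assert_array_equal(a, b)


class TestPretraining:
    def _separable(self, n=120, seed=0):
        rng = np.random.default_rng(seed)
        y = rng.integers(0, 3, n)
        X = np.zeros((n, 4))
        X[np.arange(n), y] = 4.0
        X += rng.normal(0, 0.1, X.shape)
        return X, y

    def test_separable_data_learned(self):
        X, y = self._separable()
        cfg = ModelConfig(pretrain_epochs=300)
        net = pretrain_level(X, y, (4, 32), cfg, seed=1)
        acc = np.mean(np.argmax(net.predict_proba(X), axis=1) == y)
        assert acc >= 0.95

    def test_single_class_signaled(self):
        X = np.random.default_rng(0).random((20, 4))
        with pytest.raises(ValueError):
            pretrain_level(X, np.zeros(20, dtype=int), (4, 8), ModelConfig(), 0)

    def test_seeded_determinism(self):
        X, y = self._separable()
        cfg = ModelConfig(pretrain_epochs=50)
        a = pretrain_level(X, y, (4, 16), cfg, seed=5)
        b = pretrain_level(X, y, (4, 16), cfg, seed=5)
        for wa, wb in zip(a.parameters(), b.parameters()):
            np.testing.assert_array_equal(wa, wb)


def _toy_dataset(n_persons=8, traces_pp=4, steps_pt=6, seed=0):
    """Small synthetic feature tables with stage-dependent structure."""
    rng = np.random.default_rng(seed)
    labels = np.array([p % 4 for p in range(n_persons)])
    step_X, step_trace, trace_X, trace_person = [], [], [], []
    for p in range(n_persons):
        for t in range(traces_pp):
            trace_person.append(p)
            trace_X.append(
                np.concatenate([[labels[p] * 1.0], rng.normal(0, 0.2, 13)])
            )
            for _ in range(steps_pt):
                row = rng.normal(0, 0.3, 12)
                row[0] += labels[p]
                step_trace.append(len(trace_person) - 1)
                step_X.append(row)
    bio = rng.normal(0, 1, (n_persons, 3)) + labels[:, None]
    return FeatureDataset(
        step_X=np.asarray(step_X),
        step_trace=np.asarray(step_trace),
        trace_X=np.asarray(trace_X),
        trace_person=np.asarray(trace_person),
        person_bio=bio,
        person_label=labels,
    )


@pytest.fixture(scope="module")
def trained():
    data = _toy_dataset()
    cfg = ModelConfig(
        step_widths=(12, 32, 16), trace_widths=(20, 32, 16),
        person_widths=(9, 16), pretrain_epochs=150, joint_epochs=40,
    )
    return train_hierarchical(data, cfg, seed=0), data


class TestTrainHierarchical:
    def test_probabilities_are_simplex(self, trained):
        model, data = trained
        preds = model.predict_stage(data)
        for p in preds:
            assert p.probabilities.shape == (6,)
            assert p.probabilities.sum() == pytest.approx(1.0)
            assert p.stage == int(np.argmax(p.probabilities))

    def test_learns_separable_cohort(self, trained):
        model, data = trained
        assert model.metrics["person_accuracy"] >= 0.9

    def test_duplicating_traces_leaves_prediction_unchanged(self, trained):
        model, data = trained
        doubled = FeatureDataset(
            step_X=np.vstack([data.step_X, data.step_X]),
            step_trace=np.concatenate(
                [data.step_trace, data.step_trace + data.trace_X.shape[0]]
            ),
            trace_X=np.vstack([data.trace_X, data.trace_X]),
            trace_person=np.concatenate([data.trace_person, data.trace_person]),
            person_bio=data.person_bio,
            person_label=data.person_label,
        )
        a = model.predict_stage(data)
        b = model.predict_stage(doubled)
        for pa, pb in zip(a, b):
            np.testing.assert_allclose(pa.probabilities, pb.probabilities, atol=1e-12)

    def test_standardization_uses_training_rows_only(self):
        """A distribution shift confined to test rows must not leak into
        the fitted scaler statistics."""
        data = _toy_dataset(seed=3)
        cfg = ModelConfig(
            step_widths=(12, 16), trace_widths=(20, 16), person_widths=(9, 8),
            pretrain_epochs=10, joint_epochs=5,
        )
        seed = 11
        # reproduce the internal footstep split
        rng = np.random.default_rng(seed)
        n = data.step_X.shape[0]
        perm = rng.permutation(n)
        train_idx = np.zeros(n, dtype=bool)
        train_idx[perm[: int(round(0.8 * n))]] = True
        shifted = data.step_X.copy()
        shifted[~train_idx] += 1000.0  # poison only the held-out rows
        poisoned = FeatureDataset(
            step_X=shifted, step_trace=data.step_trace, trace_X=data.trace_X,
            trace_person=data.trace_person, person_bio=data.person_bio,
            person_label=data.person_label,
        )
        model = train_hierarchical(poisoned, cfg, seed=seed)
        np.testing.assert_allclose(
            model.step_scaler.mean_, data.step_X[train_idx].mean(axis=0)
        )

    def test_model_round_trips_through_file(self, trained, tmp_path):
        model, data = trained
        path = tmp_path / "model.joblib"
        model.save(path)
        from floorgait.hierarchy import HierarchicalModel

        loaded = HierarchicalModel.load(path)
        a = model.predict_stage(data)
        b = loaded.predict_stage(data)
        for pa, pb in zip(a, b):
            np.testing.assert_array_equal(pa.probabilities, pb.probabilities)

    def test_single_stage_cohort_signaled(self):
        data = _toy_dataset()
        data.person_label[:] = 2
        with pytest.raises(ValueError):
            train_hierarchical(data, ModelConfig(pretrain_epochs=5), seed=0)


def test_standardizer_constant_feature_safe():
    s = Standardizer().fit(np.array([[1.0, 5.0], [1.0, 7.0]]))
    out = s.transform(np.array([[1.0, 6.0]]))
    assert np.all(np.isfinite(out))
    assert out[0, 0] == 0.0
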