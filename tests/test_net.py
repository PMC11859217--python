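"""Dose-effect classifier: training, DET feedback, saliency, adjustment."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from comboratio import net
from comboratio.records import ConcentrationRecord


def make_records(x, y, labels=("A", "B")):
    return [
        ConcentrationRecord(
            time=0.0,
            concentrations=dict(zip(labels, map(float, row))),
            effective=int(t),
        )
        for row, t in zip(np.atleast_2d(x), y)
    ]


@pytest.fixture(scope="module")
def separable_records():
    # 200 nonnegative 2-feature records, classes separated by margin 1.0
    rng = np.random.default_rng(7)
    x = rng.uniform(0, 4, size=(400, 2))
    score = x[:, 0] - x[:, 1]
    x = x[np.abs(score) > 0.5][:200]
    y = (x[:, 0] - x[:, 1] > 0).astype(int)
    return make_records(x, y)


class TestBuildNet:
    def test_same_seed_gives_identical_initial_parameters(self):
        cfg = net.NetConfig(input_components=("A", "B", "C"), seed=13)
        n1, n2 = net.build_net(cfg), net.build_net(cfg)
        for key in n1.params:
            np.testing.assert_array_equal(n1.params[key], n2.params[key])

    def test_kernel_wider_than_input_rejected(self):
        cfg = net.NetConfig(input_components=("A", "B", "C"), conv_layers=((16, 5),))
        with pytest.raises(net.ConfigurationError, match="kernel"):
            net.build_net(cfg)

    def test_untrained_forward_pass_is_a_probability(self):
        cfg = net.NetConfig(input_components=("A", "B", "C"))
        model = net.build_net(cfg)
        p = model.predict_proba(np.zeros((1, 3)))
        assert 0.0 < p[0] < 1.0


class TestTrain:
    def test_learns_linearly_separable_data(self, separable_records):
        cfg = net.NetConfig(input_components=("A", "B"), epochs=200, seed=7)
        model, history = net.train(net.build_net(cfg), separable_records, cfg)
        metrics = net.evaluate(model, separable_records, net.DETState())
        assert metrics.accuracy >= 0.99
        assert history[-1] <= history[0]

    def test_zero_epochs_returns_initial_net(self, separable_records):
        cfg = net.NetConfig(input_components=("A", "B"), epochs=0, seed=3)
        before = net.build_net(cfg)
        initial = {k: v.copy() for k, v in before.params.items()}
        model, history = net.train(before, separable_records, cfg)
        assert history == []
        for key, val in initial.items():
            np.testing.assert_array_equal(model.params[key], val)

    def test_training_is_deterministic(self, separable_records):
        cfg = net.NetConfig(input_components=("A", "B"), epochs=30, seed=5)
        _, h1 = net.train(net.build_net(cfg), separable_records, cfg)
        _, h2 = net.train(net.build_net(cfg), separable_records, cfg)
        assert h1 == h2

    def test_single_class_data_warns_but_trains(self):
        recs = make_records(np.ones((10, 2)), np.ones(10))
        cfg = net.NetConfig(input_components=("A", "B"), epochs=2)
        with pytest.warns(RuntimeWarning, match="single class"):
            net.train(net.build_net(cfg), recs, cfg)

    def test_too_few_records_rejected(self):
        cfg = net.NetConfig(input_components=("A", "B"))
        with pytest.raises(ValueError, match="2 records"):
            net.train(net.build_net(cfg), make_records([[1, 1]], [1]), cfg)


class TestDET:
    def test_probability_above_threshold_is_effective(self):
        det = net.DETState(value=0.6)
        assert net.apply_det(0.8, det) == 1

    def test_probability_below_threshold_is_ineffective(self):
        det = net.DETState(value=0.6)
        assert net.apply_det(0.3, det) == 0

    def test_tie_counts_as_effective(self):
        det = net.DETState(value=0.6)
        assert net.apply_det(0.6, det) == 1

    def test_improving_accuracy_raises_det(self):
        det = net.update_det(net.DETState(value=0.5, step=0.01), 0.9, 0.8)
        assert det.value == pytest.approx(0.51)
        assert det.history[-1][1] == pytest.approx(0.51)

    def test_degrading_accuracy_lowers_det(self):
        det = net.update_det(net.DETState(value=0.5, step=0.01), 0.7, 0.8)
        assert det.value == pytest.approx(0.49)

    def test_det_clamped_at_upper_bound(self):
        det = net.update_det(net.DETState(value=0.95, step=0.01), 0.9, 0.8)
        assert det.value == 0.95

    def test_equal_accuracy_leaves_det_unchanged(self):
        det = net.update_det(net.DETState(value=0.5, step=0.01), 0.8, 0.8)
        assert det.value == 0.5

    @given(
        p=st.floats(min_value=0, max_value=1),
        q=st.floats(min_value=0, max_value=1),
    )
    @settings(max_examples=50, derandomize=True)
    def test_monotone_in_probability(self, p, q):
        det = net.DETState(value=0.5)
        lo, hi = sorted((p, q))
        assert net.apply_det(lo, det) <= net.apply_det(hi, det)


class TestContributionWeights:
    def test_unused_input_gets_zero_weight(self):
        cfg = net.NetConfig(input_components=("A", "B"), seed=2)
        model = net.build_net(cfg)
        # zero every parameter touching input channel position 1 ("B")
        model.params["convW0"][:, :, 1] = 0.0
        recs = make_records(np.random.default_rng(0).uniform(0, 2, (20, 2)), np.zeros(20))
        w = net.contribution_weights(model, recs)
        assert w.weights["B"] == pytest.approx(0.0, abs=1e-12)
        assert w.weights["A"] == pytest.approx(1.0)

    def test_weights_sum_to_one(self, separable_records):
        cfg = net.NetConfig(input_components=("A", "B"), epochs=50, seed=1)
        model, _ = net.train(net.build_net(cfg), separable_records, cfg)
        w = net.contribution_weights(model, separable_records)
        assert sum(w.weights.values()) == pytest.approx(1.0, abs=1e-9)
        assert all(v >= 0 for v in w.weights.values())

    def test_duplicated_symmetric_inputs_share_weight(self):
        # make the network exactly symmetric in its two inputs by averaging
        # the kernel across the input positions of the first conv layer
        cfg = net.NetConfig(input_components=("A", "B"), seed=4, conv_layers=((8, 2),))
        model = net.build_net(cfg)
        w0 = model.params["convW0"]
        sym = w0.mean(axis=2, keepdims=True)
        model.params["convW0"] = np.repeat(sym, w0.shape[2], axis=2)
        rng = np.random.default_rng(1)
        base = rng.uniform(0, 2, size=(30, 1))
        recs = make_records(np.hstack([base, base]), np.zeros(30))
        w = net.contribution_weights(model, recs)
        assert w.weights["A"] == pytest.approx(w.weights["B"], abs=1e-6)


@pytest.fixture(scope="module")
def monotone_net():
    rng = np.random.default_rng(1)
    x = rng.uniform(0, 4, size=(300, 1))
    y = (x[:, 0] > 2).astype(int)
    recs = make_records(x, y, labels=("A",))
    cfg = net.NetConfig(input_components=("A",), conv_layers=((8, 1),),
                        pool_width=1, epochs=300, seed=1)
    model, _ = net.train(net.build_net(cfg), recs, cfg)
    return model, recs


class TestAdjustConcentrations:

    def test_zero_delta_returns_unit_factors(self, monotone_net):
        model, recs = monotone_net
        res = net.adjust_concentrations(model, recs, 0.0, net.DETState())
        assert res.factors == {"A": 1.0}
        assert res.records == list(recs)

    def test_monotone_net_scales_up_to_hit_target(self, monotone_net):
        model, recs = monotone_net
        res = net.adjust_concentrations(model, recs, 0.05, net.DETState())
        assert res.factors["A"] > 1.0
        assert abs(res.achieved_fraction - res.target_fraction) <= 0.01

    def test_labels_never_modified(self, monotone_net):
        model, recs = monotone_net
        res = net.adjust_concentrations(model, recs, 0.05, net.DETState())
        assert [r.effective for r in res.records] == [r.effective for r in recs]

    def test_unreachable_target_raises_infeasibility(self, monotone_net):
        model, recs = monotone_net
        with pytest.raises((net.InfeasibleAdjustmentError, ValueError)):
            net.adjust_concentrations(model, recs, 0.6, net.DETState())


class TestEvaluate:
    def test_confusion_matrix_arithmetic(self):
        # 9 TP, 1 FP, 1 FN, 9 TN via a hand-built constant-output model
        y = np.array([1] * 10 + [0] * 10)
        pred = np.array([1] * 9 + [0] + [1] + [0] * 9)

        class Stub:
            config = net.NetConfig(input_components=("A",))

            def predict_proba(self, x):
                return pred.astype(float)

        recs = make_records(np.ones((20, 1)), y, labels=("A",))
        m = net.evaluate(Stub(), recs, net.DETState(value=0.5))
        assert m.precision == pytest.approx(0.9)
        assert m.recall == pytest.approx(0.9)
        assert m.f1 == pytest.approx(0.9)
        assert m.accuracy == pytest.approx(0.9)

    def test_perfect_predictions(self, separable_records):
        cfg = net.NetConfig(input_components=("A", "B"), epochs=200, seed=7)
        model, _ = net.train(net.build_net(cfg), separable_records, cfg)
        m = net.evaluate(model, separable_records, net.DETState())
        if m.accuracy == 1.0:
            assert m.precision == m.recall == m.f1 == 1.0

    def test_all_negative_predictions_give_zero_recall(self):
        y = np.array([1, 1, 0, 0])

        class Stub:
            config = net.NetConfig(input_components=("A",))

            def predict_proba(self, x):
                return np.zeros(4)

        recs = make_records(np.ones((4, 1)), y, labels=("A",))
        with pytest.warns(RuntimeWarning, match="precision"):
            m = net.evaluate(Stub(), recs, net.DETState(value=0.5))
        assert m.recall == 0.0
        assert m.precision == 0.0
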