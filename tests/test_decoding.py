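"""Population decoding: CV accuracy, nulls, CDFs, projection, agreement."""

import numpy as np
import pytest

import calpop
from calpop.decoding import TrialTensor
from calpop.errors import AlignmentError, LabelError, SplitError


def _separable_tensor(n=6, m_per_class=10, gap=2.0, noise=0.1, seed=0, t=60):
    """Trials of class 1 sit ``gap`` z above class 0 on every neuron."""
    rng = np.random.default_rng(seed)
    act = rng.normal(0.0, noise, (n, 2 * m_per_class, t))
    act[:, :m_per_class, :] += gap
    labels = np.r_[np.ones(m_per_class, int), np.zeros(m_per_class, int)]
    return TrialTensor(act, labels, frame_rate=30.0, align_index=0,
                       neuron_ids=[f"n{i}" for i in range(n)])


class TestBuildTrialTensor:
    def test_trial_counting_and_labels(self, two_event_session):
        _, _, _, _, ep_a, ep_b = two_event_session
        subset = list(ep_a.neuron_ids[:10])
        tensor = calpop.build_trial_tensor(ep_a, ep_b, subset)
        assert tensor.n_trials == ep_a.n_trials + ep_b.n_trials
        assert tensor.labels.sum() == ep_a.n_trials
        assert tensor.n_neurons == 10

    def test_empty_subset_rejected(self, two_event_session):
        _, _, _, _, ep_a, ep_b = two_event_session
        with pytest.raises(ValueError):
            calpop.build_trial_tensor(ep_a, ep_b, [])

    def test_unknown_neurons_rejected(self, two_event_session):
        _, _, _, _, ep_a, ep_b = two_event_session
        with pytest.raises(AlignmentError):
            calpop.build_trial_tensor(ep_a, ep_b, ["nope"])

    def test_single_class_rejected(self):
        with pytest.raises(LabelError):
            TrialTensor(np.zeros((2, 4, 5)), np.ones(4, int), 30.0, 0, ["a", "b"])


class TestDecodeCv:
    def test_separable_tensor_is_perfect(self):
        tensor = _separable_tensor()
        # feasibility: a single fit on all trials separates them
        out = calpop.decode_cv(tensor, folds=10, seed=1, window=None)
        assert out.mean_accuracy == 1.0
        assert np.all(out.fold_accuracies == 1.0)

    def test_folds_reduced_with_warning(self):
        tensor = _separable_tensor(m_per_class=3)
        with pytest.warns(UserWarning, match="reducing folds"):
            out = calpop.decode_cv(tensor, folds=10, seed=2, window=None)
        assert out.folds_used == 3

    def test_affine_feature_invariance(self):
        """Rescaling all features by a common affine map leaves accuracy fixed."""
        tensor = _separable_tensor(gap=0.4, noise=0.5, seed=3)
        base = calpop.decode_cv(tensor, folds=5, seed=4, window=None)
        scaled = TrialTensor(
            tensor.activity * 7.0 + 2.0, tensor.labels, 30.0, 0, tensor.neuron_ids
        )
        again = calpop.decode_cv(scaled, folds=5, seed=4, window=None)
        np.testing.assert_allclose(
            again.fold_accuracies, base.fold_accuracies
        )

    def test_flatten_features_shape(self):
        tensor = _separable_tensor(n=3, t=20)
        X = tensor.features(flatten=True)
        assert X.shape == (tensor.n_trials, 3 * 20)


class TestShuffledNull:
    def test_separable_beats_every_shuffle(self):
        tensor = _separable_tensor()
        res = calpop.shuffled_null(tensor, n_shuffles=30, folds=5, seed=5,
                                   window=None)
        assert res.real_accuracy == 1.0
        assert res.p_value == pytest.approx(1 / 31)

    def test_zero_shuffles_rejected(self):
        with pytest.raises(ValueError):
            calpop.shuffled_null(_separable_tensor(), n_shuffles=0)


class TestPerformanceCdf:
    def test_single_step(self):
        cdf = calpop.performance_cdf([1.0, 1.0, 1.0])
        np.testing.assert_allclose(cdf, [[1.0, 1.0]])

    def test_two_point(self):
        cdf = calpop.performance_cdf([1.0, 0.5])
        np.testing.assert_allclose(cdf, [[0.5, 0.5], [1.0, 1.0]])

    def test_monotone_and_terminal_one(self):
        rng = np.random.default_rng(6)
        cdf = calpop.performance_cdf(rng.random(25))
        assert np.all(np.diff(cdf[:, 1]) >= 0)
        assert cdf[-1, 1] == 1.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            calpop.performance_cdf([])


class TestTimecourse:
    def test_latency_structure_recovered(self):
        """Ensembles diverging only after onset: chance before, high after."""
        rng = np.random.default_rng(7)
        n, m, f = 6, 12, 600
        a = rng.normal(0.0, 0.3, (n, m, f))
        b = rng.normal(0.0, 0.3, (n, m, f))
        a[:, :, 300:450] += 2.0  # class difference only in [0, 5) s
        ids = [f"n{i}" for i in range(n)]
        ep_a = calpop.EpochTensor(a, 10.0, 10.0, 30.0, ids, np.arange(m), label="A")
        ep_b = calpop.EpochTensor(b, 10.0, 10.0, 30.0, ids, np.arange(m), label="B")
        res = calpop.decode_timecourse(
            ep_a, ep_b, ids, folds=5, time_grid=np.array([-6.0, -3.0, 1.0, 3.0]),
            seed=8, n_null=2,
        )
        assert res.accuracy[0] < 0.8  # pre-onset ~ chance
        assert res.accuracy[2] > 0.9  # post-onset separable
        assert np.all((res.null_accuracy > 0.15) & (res.null_accuracy < 0.85))

    def test_grid_outside_epochs_rejected(self, two_event_session):
        _, _, _, _, ep_a, ep_b = two_event_session
        with pytest.raises(calpop.errors.WindowError):
            calpop.decode_timecourse(
                ep_a, ep_b, list(ep_a.neuron_ids[:4]),
                time_grid=np.array([9.8]), seed=9, n_null=0,
            )


class TestProjectionDecoder:
    def test_margin_property_and_threshold_inf(self, two_event_session):
        _, events, truth, z, _, _ = two_event_session
        subset = sorted(truth.responsive_to("A"))
        res = calpop.projection_decoder(z, events, "A", subset, seed=10)
        # positive side = event class, asserted on training data
        assert res.train_event_mean > res.train_baseline_mean
        assert res.train_event_mean > 0
        none = calpop.projection_decoder(
            z, events, "A", subset, threshold=np.inf, seed=10
        )
        assert none.predicted_intervals == []

    def test_intervals_sorted_inside_test_span(self, two_event_session):
        _, events, truth, z, _, _ = two_event_session
        subset = sorted(truth.responsive_to("A"))
        res = calpop.projection_decoder(z, events, "A", subset, seed=11)
        lo, hi = res.test_span
        for (s0, e0), (s1, e1) in zip(
            res.predicted_intervals, res.predicted_intervals[1:]
        ):
            assert e0 <= s1
        for s, e in res.predicted_intervals:
            assert lo <= s < e <= hi + 1e-9

    def test_half_without_events_raises(self, two_event_session):
        _, events, truth, z, _, _ = two_event_session
        subset = sorted(truth.responsive_to("A"))
        with pytest.raises(SplitError):
            calpop.projection_decoder(z, events, "A", subset, split_frac=0.01)


class TestEventAgreement:
    def test_identical_intervals(self):
        iv = [(0.0, 5.0), (10.0, 12.0)]
        res = calpop.event_agreement(iv, iv, 30.0, span=(0.0, 20.0))
        assert res.frame_accuracy == 1.0
        assert res.iou == 1.0
        assert res.hit_rate == 1.0

    def test_disjoint_intervals(self):
        res = calpop.event_agreement(
            [(0.0, 2.0)], [(5.0, 7.0)], 30.0, span=(0.0, 10.0)
        )
        assert res.iou == 0.0
        assert res.hit_rate == 0.0

    def test_half_overlap_is_one_third(self):
        res = calpop.event_agreement(
            [(0.0, 2.0)], [(1.0, 3.0)], 30.0, span=(0.0, 4.0)
        )
        assert res.iou == pytest.approx(1 / 3)

    def test_empty_actual_flagged(self):
        with pytest.warns(UserWarning, match="hit rate"):
            res = calpop.event_agreement([(0.0, 1.0)], [], 30.0, span=(0.0, 5.0))
        assert np.isnan(res.hit_rate)


class TestChanceCalibration:
    def test_iid_shuffled_labels_center_on_half(self):
        """Label-shuffled decoding is unbiased for 0.5 accuracy."""
        rng = np.random.default_rng(12)
        tensor = _separable_tensor(gap=2.0, m_per_class=20, seed=13, t=30)
        accs = []
        for _ in range(20):
            while True:
                y = rng.integers(0, 2, tensor.n_trials)
                if 2 <= y.sum() <= tensor.n_trials - 2:
                    break
            shuffled = TrialTensor(
                tensor.activity, y, 30.0, 0, tensor.neuron_ids
            )
            out = calpop.decode_cv(shuffled, folds=10, seed=14, window=None)
            accs.append(out.mean_accuracy)
        # mean over repeats sits inside the 95% binomial band for M labels
        band = 1.96 * np.sqrt(0.25 / tensor.n_trials)
        assert abs(np.mean(accs) - 0.5) < band
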