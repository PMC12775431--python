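"""Permutation-test activation, SRI selectivity, phase cells, registration."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import calpop
from calpop.ensembles import detect_activated
from calpop.errors import InsufficientDataError, RegistrationError, WindowError


def _epochs(values):
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    return calpop.EpochTensor(
        values, 10.0, 10.0, 30.0, [f"n{i}" for i in range(n)],
        np.arange(values.shape[1]),
    )


class TestDetectActivated:
    def test_strong_responder_activated(self):
        rng = np.random.default_rng(0)
        values = rng.normal(0.0, 0.2, (1, 20, 600))
        values[0, :, 300:450] += 1.5
        res = detect_activated(_epochs(values), seed=1)
        assert res.activated[0]
        assert res.p_value[0] == pytest.approx(1 / 1001)
        assert res.response[0] > 1.0

    def test_magnitude_rule_is_conjunctive(self):
        """A significant but sub-0.2 z response must not count as activated."""
        rng = np.random.default_rng(1)
        values = rng.normal(0.0, 0.01, (1, 20, 600))
        values[0, :, 300:450] += 0.1
        res = detect_activated(_epochs(values), seed=2)
        assert res.p_value[0] < 0.05
        assert 0.05 < res.response[0] < 0.2
        assert not res.activated[0]

    def test_p_value_floor_and_ceiling(self):
        rng = np.random.default_rng(2)
        res = detect_activated(
            _epochs(rng.normal(size=(5, 8, 600))), n_perm=200, seed=3
        )
        assert np.all(res.p_value >= 1 / 201)
        assert np.all(res.p_value <= 1.0)

    def test_exact_matches_bruteforce_enumeration(self):
        """Exact-mode p-values equal an independent all-permutations oracle."""
        rng = np.random.default_rng(3)
        m = 6
        values = rng.normal(0.0, 0.5, (3, m, 600))
        values[0, :, 300:450] += 0.8
        ep = _epochs(values)
        res = detect_activated(ep, exact=True)
        # oracle: recompute window means and enumerate all 2^m label swaps
        base = values[:, :, 150:300].mean(axis=2)
        evt = values[:, :, 300:450].mean(axis=2)
        for n in range(3):
            diff = evt[n] - base[n]
            obs = np.mean(diff)
            count = 0
            for signs in itertools.product((1.0, -1.0), repeat=m):
                if np.mean(np.asarray(signs) * diff) >= obs:
                    count += 1
            assert res.p_value[n] == count / 2**m
        assert res.params["n_perm"] == 2**m

    def test_single_trial_raises(self):
        with pytest.raises(InsufficientDataError):
            detect_activated(_epochs(np.zeros((1, 1, 600))))

    def test_overlapping_windows_raise(self):
        with pytest.raises(WindowError):
            detect_activated(
                _epochs(np.zeros((1, 4, 600))),
                baseline=calpop.WindowSpec(-5, 1),
                event=calpop.WindowSpec(0, 5),
            )

    def test_seed_determinism(self):
        rng = np.random.default_rng(4)
        ep = _epochs(rng.normal(size=(4, 10, 600)))
        a = detect_activated(ep, seed=7)
        b = detect_activated(ep, seed=7)
        np.testing.assert_array_equal(a.p_value, b.p_value)


class TestSri:
    @pytest.mark.parametrize(
        "a, b, expected",
        [(0.3, 0.1, 0.5), (0.4, 0.4, 0.0), (0.5, 0.0, 1.0)],
    )
    def test_formula(self, a, b, expected):
        res = calpop.compute_sri(np.array([a]), np.array([b]))
        assert res.sri[0] == pytest.approx(expected)

    def test_degenerate_denominator_undefined(self):
        res = calpop.compute_sri(np.array([0.2, -0.1]), np.array([-0.2, -0.1]))
        assert np.isnan(res.sri).all()
        assert list(res.category) == ["undefined", "undefined"]

    @given(
        a=st.floats(min_value=1e-3, max_value=10.0),
        b=st.floats(min_value=1e-3, max_value=10.0),
    )
    def test_antisymmetry(self, a, b):
        ab = calpop.compute_sri(np.array([a]), np.array([b])).sri[0]
        ba = calpop.compute_sri(np.array([b]), np.array([a])).sri[0]
        assert ab == pytest.approx(-ba)
        assert -1.0 <= ab <= 1.0

    def test_mismatched_shapes_raise(self):
        with pytest.raises(RegistrationError):
            calpop.compute_sri(np.zeros(3), np.zeros(4))

    @pytest.mark.parametrize(
        "sri, expected",
        [
            (0.25, "A_selective"),
            (-0.30, "B_selective"),
            (0.0, "shared"),
            (0.2, "shared"),
            (-0.2, "shared"),
            (np.nan, "undefined"),
        ],
    )
    def test_classification_cutoffs(self, sri, expected):
        assert calpop.classify_selectivity(np.array([sri]))[0] == expected


class TestPhaseCells:
    def test_constructed_phenotypes(self, toy_epochs):
        """Ramp in [-5,0) only -> pre; response in [0,5) -> post; flat -> neither."""
        res = calpop.identify_phase_cells(toy_epochs, n_perm=500, seed=5)
        by_id = dict(zip(res.neuron_ids, res.phase))
        assert by_id["pre_cell"] == "pre"
        assert by_id["post_cell"] == "post"
        assert by_id["flat"] == "neither"

    def test_short_epochs_rejected(self):
        values = np.zeros((1, 4, 300))
        ep = calpop.EpochTensor(values, 5.0, 5.0, 30.0, ["n0"], np.arange(4))
        with pytest.raises(WindowError):
            calpop.identify_phase_cells(ep)

    def test_uses_max_statistic(self, toy_epochs):
        res = calpop.identify_phase_cells(toy_epochs, n_perm=500, seed=6)
        # winning response is a window max, so it exceeds the bump mean
        assert res.max_response[res.neuron_ids.index("pre_cell")] > 0.9


class TestJoinRegistered:
    def _frames(self, n_a=4, n_b=4):
        a = pd.DataFrame({"neuron_id": [f"a{i}" for i in range(n_a)],
                          "response": np.arange(n_a, dtype=float)})
        b = pd.DataFrame({"neuron_id": [f"b{i}" for i in range(n_b)],
                          "response": np.arange(n_b, dtype=float) * 2})
        return a, b

    def test_identity_mapping_preserves_all(self):
        a, b = self._frames()
        mapping = pd.DataFrame(
            {"id_a": a["neuron_id"], "id_b": b["neuron_id"]}
        )
        merged, un_a, un_b = calpop.join_registered(a, b, mapping)
        assert len(merged) == 4
        assert un_a == [] and un_b == []

    def test_empty_mapping_reports_all_unmatched(self):
        a, b = self._frames()
        mapping = pd.DataFrame({"id_a": [], "id_b": []})
        merged, un_a, un_b = calpop.join_registered(a, b, mapping)
        assert merged.empty
        assert len(un_a) == 4 and len(un_b) == 4

    def test_partial_mapping_set_arithmetic(self):
        a, b = self._frames(10, 10)
        mapping = pd.DataFrame(
            {"id_a": [f"a{i}" for i in range(3)],
             "id_b": [f"b{i}" for i in range(3)]}
        )
        merged, un_a, un_b = calpop.join_registered(a, b, mapping)
        assert len(merged) == 3
        assert len(un_a) == 7 and len(un_b) == 7

    def test_duplicate_mapping_rejected(self):
        a, b = self._frames()
        mapping = pd.DataFrame({"id_a": ["a0", "a0"], "id_b": ["b0", "b1"]})
        with pytest.raises(RegistrationError, match="duplicate"):
            calpop.join_registered(a, b, mapping)


class TestRecoveryOnSynthetic:
    def test_detection_recovers_ground_truth(self, two_event_session):
        _, _, truth, _, ep_a, _ = two_event_session
        res = detect_activated(ep_a, seed=21)
        flags = dict(zip(res.neuron_ids, res.activated))
        resp = truth.responsive_to("A")
        nulls = set(res.neuron_ids) - truth.responsive_to("A") - truth.responsive_to("B")
        assert np.mean([flags[n] for n in resp]) >= 0.9
        assert np.mean([flags[n] for n in nulls]) <= 0.1

    def test_power_monotone_in_amplitude(self):
        """Detection sensitivity is non-decreasing across 3 amplitude levels."""
        rates = []
        for amp in (0.2, 0.8, 2.0):
            cfg = calpop.SessionConfig(
                n_neurons=40, duration=500.0, seed=31,
                ensembles=[calpop.EnsembleSpec("A", 0.5, amp)],
                event_schedule=[calpop.ScheduleSpec("A", 8, 25.0, 5.0)],
            )
            traces, events, truth = calpop.generate_session(cfg)
            z = calpop.zscore(calpop.compute_dff(traces))
            ep = calpop.extract_epochs(z, events, "A")
            res = detect_activated(ep, n_perm=500, seed=32)
            flags = dict(zip(res.neuron_ids, res.activated))
            resp = truth.responsive_to("A")
            rates.append(np.mean([flags[n] for n in resp]))
        assert rates[0] <= rates[1] <= rates[2]
        assert rates[2] >= 0.9
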