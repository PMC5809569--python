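"""Share simulation: limits, symmetry, sweeps, holdout validation, MAE."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from partworth import (
    AttributeSpec,
    ChoiceTask,
    Profile,
    RFCConfig,
    Scenario,
    ScenarioError,
    holdout_mae,
    mean_absolute_error,
    predict_holdout_shares,
    read_scenario,
    rfc_shares,
    rfc_shares_by_class,
    sensitivity_sweep,
)
from partworth.postestimation import IndividualPartWorths


def _attrs():
    return [
        AttributeSpec(1, "a", ("a1", "a2", "a3")),
        AttributeSpec(2, "b", ("b1", "b2", "b3")),
    ]


def _partworths(values):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    return IndividualPartWorths(
        values=values,
        respondent_ids=[f"r{i}" for i in range(values.shape[0])],
        attributes=_attrs(),
    )


def _scenario():
    return Scenario(
        (
            Profile("left", {"a": 1, "b": 1}),
            Profile("right", {"a": 2, "b": 2}),
        )
    )


class TestNoiseFreeLimit:
    def test_equals_deterministic_first_choice(self):
        # respondent 1 prefers left, respondent 2 prefers right
        pw = _partworths(
            [
                [1.0, -0.5, -0.5, 0.8, -0.4, -0.4],
                [-1.0, 0.5, 0.5, -0.8, 0.4, 0.4],
            ]
        )
        config = RFCConfig(iterations=10, attribute_error_scale=0, product_error_scale=0)
        result = rfc_shares(_scenario(), pw, config)
        assert result.shares.tolist() == [50.0, 50.0]
        assert result.se.tolist() == [0.0, 0.0]

    def test_ties_split_equally(self):
        pw = _partworths([[0.0] * 6])
        config = RFCConfig(iterations=5, attribute_error_scale=0, product_error_scale=0)
        result = rfc_shares(_scenario(), pw, config)
        assert result.shares.tolist() == [50.0, 50.0]

    def test_share_conservation(self):
        rng = np.random.default_rng(1)
        pw = _partworths(rng.normal(size=(9, 6)))
        config = RFCConfig(iterations=2000, attribute_error_scale=1.0,
                           product_error_scale=0.5, seed=4)
        result = rfc_shares(_scenario(), pw, config)
        assert result.shares.sum() == pytest.approx(100.0, abs=1e-6)


class TestProductNoiseLogitLimit:
    def test_converges_to_softmax_shares(self):
        """Product-only Gumbel(0,1) noise is exactly the logit model, so the
        Monte Carlo shares must approach the mean per-respondent softmax."""
        rng = np.random.default_rng(8)
        values = rng.normal(scale=0.8, size=(12, 6))
        pw = _partworths(values)
        scenario = _scenario()
        config = RFCConfig(
            iterations=200_000, attribute_error_scale=0.0,
            product_error_scale=1.0, seed=3,
        )
        result = rfc_shares(scenario, pw, config)
        # closed form: mean over respondents of softmax of profile utilities
        b = np.zeros((6, 2))
        b[[0, 3], 0] = 1.0
        b[[1, 4], 1] = 1.0
        u = values @ b
        probs = np.exp(u) / np.exp(u).sum(axis=1, keepdims=True)
        expected = 100.0 * probs.mean(axis=0)
        tol = 3.0 * np.maximum(result.se, 0.05)
        assert (np.abs(result.shares - expected) <= tol).all()

    def test_identical_profiles_half_half(self):
        scenario = Scenario(
            (Profile("p1", {"a": 1, "b": 2}), Profile("p2", {"a": 1, "b": 2}))
        )
        pw = _partworths(np.random.default_rng(0).normal(size=(5, 6)))
        config = RFCConfig(iterations=40_000, attribute_error_scale=1.0,
                           product_error_scale=0.7, seed=1)
        result = rfc_shares(scenario, pw, config)
        assert np.abs(result.shares - 50.0).max() <= 4 * max(result.se.max(), 0.2)


class TestDeterminismAndClasses:
    def test_seed_determinism(self):
        rng = np.random.default_rng(5)
        pw = _partworths(rng.normal(size=(7, 6)))
        config = RFCConfig(iterations=5000, seed=11)
        r1 = rfc_shares(_scenario(), pw, config)
        r2 = rfc_shares(_scenario(), pw, config)
        assert r1.shares.tolist() == r2.shares.tolist()
        assert r1.se.tolist() == r2.se.tolist()

    def test_class_breakdown(self):
        pw = _partworths(
            [
                [1.0, -0.5, -0.5, 0.8, -0.4, -0.4],
                [-1.0, 0.5, 0.5, -0.8, 0.4, 0.4],
            ]
        )
        labels = np.array([1, 2])
        config = RFCConfig(iterations=10, attribute_error_scale=0, product_error_scale=0)
        result = rfc_shares(_scenario(), pw, config, class_labels=labels)
        assert result.class_shares[1].tolist() == [100.0, 0.0]
        assert result.class_shares[2].tolist() == [0.0, 100.0]

    def test_by_class_mode_weights_by_share(self):
        cu = np.array(
            [
                [1.0, -0.5, -0.5, 0.8, -0.4, -0.4],
                [-1.0, 0.5, 0.5, -0.8, 0.4, 0.4],
            ]
        )
        config = RFCConfig(iterations=10, attribute_error_scale=0, product_error_scale=0)
        result = rfc_shares_by_class(
            _scenario(), cu, np.array([0.25, 0.75]), _attrs(), config
        )
        assert result.shares == pytest.approx([25.0, 75.0])


class TestSweep:
    def test_noop_sweep_unchanged(self):
        rng = np.random.default_rng(2)
        pw = _partworths(rng.normal(size=(6, 6)))
        config = RFCConfig(iterations=4000, seed=9)
        base = rfc_shares(_scenario(), pw, config)
        swept = sensitivity_sweep(_scenario(), "right", "a", [2], pw, config)
        assert swept[2].shares == pytest.approx(base.shares)

    def test_monotone_utilities_monotone_shares(self):
        """If the swept attribute's utilities increase with level, the target
        profile's share is non-decreasing across the sweep."""
        values = np.array([[-1.0, 0.0, 1.0, 0.3, -0.1, -0.2]] * 8)
        pw = _partworths(values)
        config = RFCConfig(iterations=40_000, attribute_error_scale=1.0, seed=6)
        swept = sensitivity_sweep(_scenario(), "right", "a", [1, 2, 3], pw, config)
        shares = [swept[lv].shares[1] for lv in (1, 2, 3)]
        assert shares[0] <= shares[1] <= shares[2]

    def test_unknown_profile_rejected(self):
        pw = _partworths(np.zeros((1, 6)))
        with pytest.raises(ScenarioError):
            sensitivity_sweep(_scenario(), "nope", "a", [1], pw, RFCConfig(iterations=10))


class TestScenarioValidation:
    def test_unknown_attribute(self):
        s = Scenario((Profile("p", {"zzz": 1}), Profile("q", {})))
        with pytest.raises(ScenarioError, match="unknown attribute"):
            s.resolve(_attrs())

    def test_out_of_range_level(self):
        s = Scenario((Profile("p", {"a": 9}), Profile("q", {})))
        with pytest.raises(ScenarioError, match="out of range"):
            s.resolve(_attrs())

    def test_level_labels_resolve(self):
        s = Scenario((Profile("p", {"a": "a3"}), Profile("q", {"b": "b1"})))
        assert s.resolve(_attrs()) == [{1: 3}, {2: 1}]

    def test_single_profile_rejected(self):
        with pytest.raises(ScenarioError):
            Scenario((Profile("only", {}),))

    def test_read_scenario_file(self, tmp_path):
        path = tmp_path / "scenario.yaml"
        path.write_text(
            "profiles:\n"
            "  - name: basic\n"
            "    levels: {a: 1, b: b2}\n"
            "  - name: enhanced\n"
            "    levels: {a: 3}\n"
        )
        s = read_scenario(path)
        assert [p.name for p in s.profiles] == ["basic", "enhanced"]
        assert s.resolve(_attrs()) == [{1: 1, 2: 2}, {1: 3}]


class TestHoldoutPrediction:
    def _task(self, position=6):
        return ChoiceTask(
            0, position, True, (1, 2), np.array([[1, 2], [2, 3], [3, 1]])
        )

    def test_single_respondent_zero_noise(self):
        values = np.array([[1.0, -0.3, -0.7, 0.5, 0.2, -0.7]])
        pw = _partworths(values)
        config = RFCConfig(iterations=1, attribute_error_scale=0, product_error_scale=0)
        result = predict_holdout_shares(pw, [self._task()], config)[6]
        utilities = [
            values[0, 0] + values[0, 4],  # a1 + b2
            values[0, 1] + values[0, 5],  # a2 + b3
            values[0, 2] + values[0, 3],  # a3 + b1
        ]
        expected = np.zeros(3)
        expected[int(np.argmax(utilities))] = 100.0
        assert result.shares == pytest.approx(expected)

    def test_shares_sum_to_100(self):
        rng = np.random.default_rng(3)
        pw = _partworths(rng.normal(size=(11, 6)))
        config = RFCConfig(iterations=3000, seed=2)
        shares = predict_holdout_shares(pw, [self._task(6), self._task(14)], config)
        for result in shares.values():
            assert result.shares.sum() == pytest.approx(100.0, abs=1e-6)

    def test_conflicting_holdout_content_rejected(self):
        other = ChoiceTask(0, 6, True, (1, 2), np.array([[2, 1], [3, 2], [1, 3]]))
        pw = _partworths(np.zeros((1, 6)))
        with pytest.raises(ScenarioError, match="differ across versions"):
            predict_holdout_shares(pw, [self._task(6), other], RFCConfig(iterations=1))


class TestMae:
    def test_identity(self):
        assert mean_absolute_error([40, 40, 20], [40, 40, 20]) == 0.0

    def test_hand_computed(self):
        assert mean_absolute_error([50, 30, 20], [40, 40, 20]) == pytest.approx(20 / 3)

    @given(
        st.lists(st.floats(0, 100, allow_nan=False), min_size=2, max_size=6),
    )
    @settings(max_examples=30, deadline=None)
    def test_matches_elementwise_oracle(self, pred):
        rng = np.random.default_rng(len(pred))
        obs = rng.uniform(0, 100, size=len(pred))
        expected = sum(abs(p - o) for p, o in zip(pred, obs)) / len(pred)
        assert mean_absolute_error(pred, obs) == pytest.approx(expected)

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            mean_absolute_error([1, 2], [1, 2, 3])

    def test_holdout_mae_aggregates(self):
        per_task, overall = holdout_mae(
            {6: np.array([50, 30, 20]), 14: np.array([10, 20, 70])},
            {6: np.array([40, 40, 20]), 14: np.array([10, 20, 70])},
        )
        assert per_task[6] == pytest.approx(20 / 3)
        assert per_task[14] == 0.0
        assert overall == pytest.approx(10 / 3)

    def test_holdout_mae_key_mismatch(self):
        with pytest.raises(ValueError):
            holdout_mae({6: np.zeros(3)}, {14: np.zeros(3)})
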