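"""Mixture estimation: probabilities, EM behavior, indices, tests."""

import numpy as np
import pytest

from partworth import (
    AttributeSpec,
    DesignConfig,
    SyntheticConfig,
    bootstrap_lrt,
    choice_probabilities,
    compute_fit_indices,
    entropy_r2,
    fit_latent_class,
    log_likelihood,
    posterior_assign,
    simulate_respondents,
    split_holdout,
    wald_tests,
)
from partworth.latent_class import LatentClassSolution
from partworth.data import effects_columns


from helpers import oracle_conditional_logit


def _random_small_dataset(seed):
    attrs = [
        AttributeSpec(1, "a", ("a1", "a2", "a3")),
        AttributeSpec(2, "b", ("b1", "b2", "b3", "b4")),
        AttributeSpec(3, "c", ("c1", "c2", "c3")),
    ]
    rng = np.random.default_rng(seed)
    total = sum(a.n_levels for a in attrs)
    utils = rng.normal(0, 1, size=(1, total))
    pos = 0
    for a in attrs:
        k = a.n_levels
        utils[:, pos : pos + k] -= utils[:, pos : pos + k].mean()
        pos += k
    cfg = SyntheticConfig(
        attributes=attrs,
        segment_shares=np.array([1.0]),
        segment_utilities=utils,
        design=DesignConfig(
            n_versions=4, tasks_per_version=8, alternatives_per_task=3,
            attributes_per_task=2, seed=seed,
        ),
        n_respondents=50,
        seed=seed,
    )
    dataset, _ = simulate_respondents(cfg)
    return dataset


class TestChoiceProbabilities:
    def test_symmetry(self):
        rows = np.zeros((3, 4))
        assert choice_probabilities(np.zeros(4), rows) == pytest.approx([1 / 3] * 3)

    def test_closed_form(self):
        # utilities (ln 2, 0, 0) -> shares (1/2, 1/4, 1/4)
        rows = np.array([[np.log(2.0)], [0.0], [0.0]])
        assert choice_probabilities(np.ones(1), rows) == pytest.approx([0.5, 0.25, 0.25])

    def test_matches_direct_softmax(self):
        rng = np.random.default_rng(0)
        rows = rng.normal(size=(5, 7))
        beta = rng.normal(size=7)
        u = rows @ beta
        expected = np.exp(u) / np.exp(u).sum()
        assert choice_probabilities(beta, rows) == pytest.approx(expected, abs=1e-12)


class TestLogLikelihood:
    def test_uniform_closed_form(self, small_attributes):
        from partworth import ChoiceDataset, ChoiceObservation, ChoiceTask

        tasks, obs = {}, []
        for pos in range(1, 19):
            t = ChoiceTask(1, pos, False, (1,), np.array([[1], [2], [3]]))
            tasks[t.key] = t
            obs.append(ChoiceObservation("r1", 1, pos, 1))
        ds = ChoiceDataset(small_attributes, tasks, obs)
        p = ds.n_parameters
        ll = log_likelihood(ds, np.ones(1), np.zeros((1, p)))
        assert ll == pytest.approx(18 * np.log(1 / 3), abs=1e-10)

    def test_degenerate_mixture_weights(self):
        ds = _random_small_dataset(3)
        X, chosen, resp, _ = ds.to_arrays()
        rng = np.random.default_rng(1)
        betas = rng.normal(scale=0.5, size=(2, ds.n_parameters))
        ll_mix = log_likelihood(ds, np.array([1.0, 0.0]), betas)
        ll_single = log_likelihood(ds, np.ones(1), betas[:1])
        assert ll_mix == pytest.approx(ll_single, abs=1e-10)

    def test_single_class_equals_pooled_logit(self):
        """C = 1 mixture likelihood is the plain conditional-logit likelihood."""
        ds = _random_small_dataset(4)
        X, chosen, _, _ = ds.to_arrays()
        rng = np.random.default_rng(2)
        beta = rng.normal(scale=0.5, size=ds.n_parameters)
        u = np.einsum("tap,p->ta", X, beta)
        direct = float(
            (u[np.arange(len(u)), chosen] - np.log(np.exp(u).sum(axis=1))).sum()
        )
        assert log_likelihood(ds, np.ones(1), beta[None]) == pytest.approx(direct, abs=1e-10)


class TestFitLatentClass:
    @pytest.mark.parametrize("seed", [0, 1])
    def test_single_class_matches_newton_oracle(self, seed):
        ds = _random_small_dataset(seed)
        X, chosen, _, _ = ds.to_arrays()
        beta_oracle, ll_oracle = oracle_conditional_logit(X, chosen)
        sol = fit_latent_class(ds, 1, seed=seed)
        assert np.abs(sol.coefficients[0] - beta_oracle).max() < 1e-6
        assert sol.loglik == pytest.approx(ll_oracle, abs=1e-8)

    def test_em_trace_monotone(self, small_synthetic):
        _, dataset, _ = small_synthetic
        est, _ = split_holdout(dataset)
        sol = fit_latent_class(est, 2, n_starts=2, seed=0, compute_se=False)
        trace = np.array(sol.ll_trace)
        assert (np.diff(trace) >= -1e-8).all()

    def test_small_recovery_and_canonical_order(self, small_synthetic):
        cfg, dataset, truth = small_synthetic
        est, _ = split_holdout(dataset)
        sol = fit_latent_class(est, 2, n_starts=4, seed=1, compute_se=False)
        assert sol.shares[0] >= sol.shares[1]  # decreasing-share order
        assert sol.shares.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.abs(sol.posterior.sum(axis=1) - 1).max() < 1e-9

    def test_standard_errors_and_z(self):
        ds = _random_small_dataset(5)
        sol = fit_latent_class(ds, 1, seed=0)
        assert sol.se is not None and (sol.se > 0).all()
        assert sol.z == pytest.approx(sol.coefficients / sol.se)

    def test_more_classes_than_respondents_rejected(self):
        ds = _random_small_dataset(6)
        with pytest.raises(ValueError):
            fit_latent_class(ds, ds.n_respondents + 1)

    def test_solution_round_trip(self, tmp_path):
        ds = _random_small_dataset(7)
        sol = fit_latent_class(ds, 1, seed=0)
        path = tmp_path / "solution.json"
        sol.save(path)
        back = LatentClassSolution.load(path)
        assert back.loglik == pytest.approx(sol.loglik)
        assert back.coefficients == pytest.approx(sol.coefficients)
        assert back.column_map == sol.column_map


class TestPosteriorAssign:
    def _solution(self, posterior):
        attrs = [AttributeSpec(1, "a", ("x", "y"))]
        c = posterior.shape[1]
        return LatentClassSolution(
            n_classes=c,
            shares=np.full(c, 1 / c),
            coefficients=np.zeros((c, 1)),
            loglik=0.0,
            posterior=posterior,
            respondent_ids=[f"r{i}" for i in range(posterior.shape[0])],
            attributes=attrs,
            column_map=effects_columns(attrs),
        )

    def test_argmax(self):
        sol = self._solution(np.array([[0.9, 0.1], [0.2, 0.8]]))
        assert posterior_assign(sol).tolist() == [1, 2]

    def test_tie_breaks_low(self):
        sol = self._solution(np.array([[0.5, 0.5]]))
        assert posterior_assign(sol).tolist() == [1]


class TestFitIndices:
    def test_zero_case(self):
        row = compute_fit_indices(0.0, 1, 0, 10)
        assert (row.aic, row.aic3, row.bic, row.caic) == (0.0, 0.0, 0.0, 0.0)

    def test_entropy_extremes(self):
        assert entropy_r2(np.full((8, 2), 0.5)) == pytest.approx(0.0)
        assert entropy_r2(np.eye(4)[[0, 1, 2, 3, 0]]) == pytest.approx(1.0)
        assert entropy_r2(np.ones((5, 1))) == 1.0

    def test_entropy_hand_computed(self):
        h = np.array([[0.9, 0.1], [0.2, 0.8]])
        ent = -(0.9 * np.log(0.9) + 0.1 * np.log(0.1)) - (
            0.2 * np.log(0.2) + 0.8 * np.log(0.8)
        )
        assert entropy_r2(h) == pytest.approx(1 - ent / (2 * np.log(2)), abs=1e-12)


class TestBootstrapLrt:
    def test_identical_fits_statistic_zero(self):
        ds = _random_small_dataset(8)
        sol = fit_latent_class(ds, 1, seed=0, compute_se=False)
        result = bootstrap_lrt(
            ds, 1, 2, n_bootstrap=3, seed=0, n_starts=1, sol0=sol, sol1=sol, max_iter=60
        )
        assert result.statistic == 0.0
        assert result.p_value == 1.0

    def test_machinery_on_small_data(self):
        ds = _random_small_dataset(9)
        result = bootstrap_lrt(ds, 1, 2, n_bootstrap=3, seed=1, n_starts=1, max_iter=60)
        assert result.statistic >= -1e-6
        assert 0.0 <= result.p_value <= 1.0
        assert len(result.bootstrap_statistics) == 3

    def test_invalid_args(self):
        ds = _random_small_dataset(8)
        with pytest.raises(ValueError):
            bootstrap_lrt(ds, 2, 2)
        with pytest.raises(ValueError):
            bootstrap_lrt(ds, 1, 2, n_bootstrap=0)


class TestWald:
    def test_equal_betas_equality_wald_zero(self):
        attrs = [AttributeSpec(1, "a", ("x", "y", "z"))]
        beta = np.array([[0.4, -0.1], [0.4, -0.1]])
        sol = LatentClassSolution(
            n_classes=2,
            shares=np.array([0.5, 0.5]),
            coefficients=beta,
            loglik=0.0,
            posterior=np.full((4, 2), 0.5),
            respondent_ids=[f"r{i}" for i in range(4)],
            attributes=attrs,
            column_map=effects_columns(attrs),
            covariance=np.eye(5),  # 2*2 betas + 1 share parameter
        )
        table = wald_tests(sol)
        assert table.loc["a", "wald_equal"] == pytest.approx(0.0, abs=1e-12)
        assert table.loc["a", "wald_zero_class1"] == pytest.approx(
            0.4**2 + 0.1**2
        )

    def test_fitted_solution_produces_finite_tests(self):
        ds = _random_small_dataset(10)
        sol = fit_latent_class(ds, 1, seed=0)
        table = wald_tests(sol)
        assert np.isfinite(table["wald_zero_class1"]).all()
        assert ((table["p_zero_class1"] >= 0) & (table["p_zero_class1"] <= 1)).all()
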