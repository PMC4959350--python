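"""Unit and property tests for the RBM energy model, exact oracles and
CD-k training."""

import numpy as np
import pytest
from scipy.special import expit

from painrbm.rbm import (
    RBMParameters,
    TrainingConfig,
    all_binary_vectors,
    cd_k_gradient,
    energy,
    exact_log_likelihood_gradient,
    exact_log_partition,
    exact_mean_log_likelihood,
    free_energy,
    gibbs_step,
    hidden_conditional,
    initial_parameters,
    train_rbm,
    visible_conditional,
)

from oracles import (
    bit_vectors,
    enum_free_energy,
    enum_log_partition,
    random_params,
)


class TestEnergy:
    def test_all_zero_configuration_has_zero_energy(self, rng):
        params = random_params(rng, 4, 3)
        assert energy(np.zeros(4), np.zeros(3), params) == 0.0

    def test_hand_computed_single_unit_case(self):
        params = RBMParameters(W=[[2.0]], b=[0.5], c=[-0.25])
        # -b*v - c*h - v*W*h = -0.5 + 0.25 - 2
        assert energy([1], [1], params) == pytest.approx(-2.25)

    def test_rejects_non_binary_and_mismatched_inputs(self, rng):
        params = random_params(rng, 3, 2)
        with pytest.raises(ValueError):
            energy([0.5, 0, 1], [0, 1], params)
        with pytest.raises(ValueError):
            energy([0, 1], [0, 1], params)

    def test_energy_consistent_with_joint_enumeration(self, rng):
        """The Boltzmann weight recovered from the enumerated joint must
        equal e^{-E} for every configuration."""
        params = random_params(rng, 3, 2)
        log_z = enum_log_partition(params)
        total = 0.0
        for v in bit_vectors(3):
            for h in bit_vectors(2):
                total += np.exp(-energy(v, h, params) - log_z)
        assert total == pytest.approx(1.0, abs=1e-12)


class TestFreeEnergy:
    def test_collapses_to_bias_term_when_weights_vanish(self, rng):
        b = rng.normal(size=5)
        params = RBMParameters(W=np.zeros((5, 3)), b=b, c=np.zeros(3))
        v = np.array([1, 0, 1, 1, 0.0])
        assert free_energy(v, params) == pytest.approx(-b @ v - 3 * np.log(2))

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_hidden_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        m, n = int(rng.integers(2, 9)), int(rng.integers(1, 9))
        params = random_params(rng, m, n, scale=1.5)
        for v in bit_vectors(m)[:: max(1, 2 ** (m - 4))]:
            expected = enum_free_energy(v, params)
            assert free_energy(v, params) == pytest.approx(expected, rel=1e-10)

    def test_large_hidden_bias_does_not_overflow(self):
        params = RBMParameters(W=np.zeros((2, 2)), b=np.zeros(2), c=[1000.0, 0.0])
        f = free_energy(np.array([1.0, 0.0]), params)
        assert np.isfinite(f)
        assert f == pytest.approx(-1000.0 - np.log(2), rel=1e-12)

    def test_bias_shift_on_active_unit_shifts_free_energy_exactly(self, rng):
        """Adding delta to b_i changes f(v) by exactly -delta when v_i=1."""
        params = random_params(rng, 4, 3)
        v = np.array([1.0, 0, 1, 0])
        delta = 0.731
        shifted = RBMParameters(
            W=params.W, b=params.b + delta * v, c=params.c
        )
        assert free_energy(v, shifted) == pytest.approx(
            free_energy(v, params) - delta * 2, rel=1e-12
        )


class TestPartitionFunction:
    def test_zero_parameters_give_uniform_distribution(self):
        params = RBMParameters(W=np.zeros((4, 3)), b=np.zeros(4), c=np.zeros(3))
        assert exact_log_partition(params) == pytest.approx(7 * np.log(2))

    @pytest.mark.parametrize("seed", range(5))
    def test_probabilities_normalize(self, seed):
        rng = np.random.default_rng(100 + seed)
        params = random_params(rng, 5, 4)
        log_z = exact_log_partition(params)
        V = all_binary_vectors(5)
        total = np.exp(-free_energy(V, params) - log_z).sum()
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_matches_double_enumeration(self, rng):
        params = random_params(rng, 2, 2)
        assert exact_log_partition(params) == pytest.approx(
            enum_log_partition(params), rel=1e-12
        )

    def test_refuses_models_beyond_the_oracle_cap(self):
        params = RBMParameters(W=np.zeros((25, 2)), b=np.zeros(25), c=np.zeros(2))
        with pytest.raises(ValueError, match="oracle"):
            exact_log_partition(params)


class TestConditionals:
    def test_zero_parameters_give_half(self, rng):
        params = RBMParameters(W=np.zeros((3, 4)), b=np.zeros(3), c=np.zeros(4))
        assert np.allclose(hidden_conditional(np.ones(3), params), 0.5)
        assert np.allclose(visible_conditional(np.ones(4), params), 0.5)

    def test_saturation_at_large_bias(self):
        params = RBMParameters(W=np.zeros((2, 2)), b=[-50.0, 0], c=[50.0, 0])
        assert hidden_conditional(np.zeros(2), params)[0] == pytest.approx(1.0, abs=1e-15)
        assert visible_conditional(np.zeros(2), params)[0] == pytest.approx(0.0, abs=1e-15)

    def test_hidden_conditional_matches_enumerated_joint(self, rng):
        params = random_params(rng, 3, 3)
        v = np.array([1.0, 0, 1])
        weights = np.array([np.exp(-energy(v, h, params)) for h in bit_vectors(3)])
        for j in range(3):
            mask = np.array([h[j] == 1 for h in bit_vectors(3)])
            expected = weights[mask].sum() / weights.sum()
            assert hidden_conditional(v, params)[j] == pytest.approx(expected, rel=1e-10)

    def test_visible_conditional_matches_enumerated_joint(self, rng):
        params = random_params(rng, 3, 2)
        h = np.array([1.0, 0])
        weights = np.array([np.exp(-energy(v, h, params)) for v in bit_vectors(3)])
        for i in range(3):
            mask = np.array([v[i] == 1 for v in bit_vectors(3)])
            expected = weights[mask].sum() / weights.sum()
            assert visible_conditional(h, params)[i] == pytest.approx(expected, rel=1e-10)


class TestGibbsSampling:
    def test_deterministic_given_generator_state(self, rng):
        params = random_params(rng, 5, 4)
        v = np.array([1.0, 0, 1, 0, 1])
        h1, v1 = gibbs_step(v, params, np.random.default_rng(7))
        h2, v2 = gibbs_step(v, params, np.random.default_rng(7))
        assert np.array_equal(h1, h2) and np.array_equal(v1, v2)

    def test_saturated_conditionals_are_deterministic(self):
        params = RBMParameters(W=np.zeros((2, 2)), b=[50.0, -50.0], c=[50.0, -50.0])
        h, v = gibbs_step(np.array([1.0, 0]), params, np.random.default_rng(0))
        assert np.array_equal(h, [1, 0]) and np.array_equal(v, [1, 0])

    def test_factorized_chain_reaches_logistic_stationary_means(self):
        """With W = 0 the visible chain is iid Bernoulli(logistic(b))."""
        b = np.array([-1.0, 0.3, 1.5])
        params = RBMParameters(W=np.zeros((3, 2)), b=b, c=np.zeros(2))
        rng = np.random.default_rng(11)
        v = np.zeros(3)
        draws = np.empty((10_000, 3))
        for i in range(10_000):
            _, v = gibbs_step(v, params, rng)
            draws[i] = v
        p = expit(b)
        se = np.sqrt(p * (1 - p) / 10_000)
        assert np.all(np.abs(draws.mean(axis=0) - p) < 3 * se + 1e-9)


class TestCDGradient:
    def test_visible_bias_gradient_centers_on_batch_mean(self):
        """When logistic(b) already equals the data mean and W = 0, the
        CD-1 visible-bias gradient averages to zero."""
        rng = np.random.default_rng(3)
        batch_mean = np.array([0.25, 0.5, 0.75])
        b = np.log(batch_mean / (1 - batch_mean))
        params = RBMParameters(W=np.zeros((3, 2)), b=b, c=np.zeros(2))
        batch = (rng.random((400, 3)) < batch_mean).astype(float)
        # data mean itself fluctuates; recenter b on the realized mean
        realized = batch.mean(axis=0)
        params.b = np.log(realized / (1 - realized))
        dbs = []
        for seed in range(200):
            _, db, _ = cd_k_gradient(batch, params, 1, np.random.default_rng(seed))
            dbs.append(db)
        mean_db = np.mean(dbs, axis=0)
        se = np.std(dbs, axis=0, ddof=1) / np.sqrt(len(dbs))
        assert np.all(np.abs(mean_db) < 3 * se + 1e-12)

    def test_positive_statistics_exact_for_repeated_vector(self, rng):
        params = random_params(rng, 4, 3)
        v = np.array([1.0, 0, 1, 1])
        batch = np.tile(v, (5, 1))
        dW, db, dc = cd_k_gradient(batch, params, 1, np.random.default_rng(0))
        ph = hidden_conditional(v, params)
        # negative phase recomputed with the same sampler to isolate the
        # positive statistics
        rng2 = np.random.default_rng(0)
        H = (rng2.random((5, 3)) < np.tile(ph, (5, 1))).astype(float)
        PV = expit(params.b + H @ params.W.T)
        PH2 = expit(params.c + PV @ params.W)
        assert np.allclose(dW, np.outer(v, ph) - PV.T @ PH2 / 5)

    def test_empty_batch_rejected(self, rng):
        params = random_params(rng, 3, 2)
        with pytest.raises(ValueError):
            cd_k_gradient(np.empty((0, 3)), params, 1, np.random.default_rng(0))

    def test_seed_averaged_cd1_aligns_with_exact_gradient(self):
        """On a tiny model the CD-1 estimator, averaged over many seeds,
        points in the same half-space as the exact likelihood gradient."""
        rng = np.random.default_rng(42)
        params = random_params(rng, 4, 3, scale=0.8)
        batch = (rng.random((40, 4)) < 0.4).astype(float)
        gW, gb, gc = exact_log_likelihood_gradient(batch, params)
        exact = np.concatenate([gW.ravel(), gb, gc])
        acc = np.zeros_like(exact)
        for seed in range(1000):
            dW, db, dc = cd_k_gradient(batch, params, 1, np.random.default_rng(seed))
            acc += np.concatenate([dW.ravel(), db, dc])
        acc /= 1000
        cosine = acc @ exact / (np.linalg.norm(acc) * np.linalg.norm(exact))
        assert cosine > 0


class TestTraining:
    def test_training_is_bit_reproducible(self, rng):
        data = (rng.random((60, 5)) < 0.5).astype(float)
        config = TrainingConfig(n_hidden=4, epochs=5, seed=9)
        p1 = train_rbm(data, config)
        p2 = train_rbm(data, config)
        assert np.array_equal(p1.W, p2.W)
        assert np.array_equal(p1.b, p2.b)
        assert np.array_equal(p1.c, p2.c)

    def test_zero_learning_rate_returns_initialization(self, rng):
        data = (rng.random((40, 4)) < 0.5).astype(float)
        config = TrainingConfig(n_hidden=3, epochs=3, learning_rate=0.0, seed=5)
        trained = train_rbm(data, config)
        init = initial_parameters(4, config)
        assert np.array_equal(trained.W, init.W)
        assert np.array_equal(trained.b, init.b)
        assert np.array_equal(trained.c, init.c)

    def test_training_increases_exact_log_likelihood(self):
        """Data from a known enumerable RBM: CD-1 training must beat the
        initialization in exact mean log-likelihood."""
        rng = np.random.default_rng(8)
        true = random_params(rng, 6, 3, scale=1.2)
        V = all_binary_vectors(6)
        logp = -free_energy(V, true) - exact_log_partition(true)
        data = V[rng.choice(64, size=500, p=np.exp(logp))]
        config = TrainingConfig(n_hidden=3, epochs=120, seed=2)
        trained = train_rbm(data, config)
        ll_init = exact_mean_log_likelihood(data, initial_parameters(6, config))
        ll_final = exact_mean_log_likelihood(data, trained)
        assert ll_final > ll_init

    def test_inconsistent_rows_rejected(self):
        with pytest.raises(ValueError):
            train_rbm([[0, 1], [1, 0, 1]], TrainingConfig(epochs=1))

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            TrainingConfig(n_hidden=0)
        with pytest.raises(ValueError):
            TrainingConfig(k=0)
        with pytest.raises(ValueError):
            TrainingConfig(epochs=0)


class TestSerialization:
    def test_round_trip_preserves_parameters(self, rng, tmp_path):
        params = random_params(rng, 5, 3)
        path = tmp_path / "model.json"
        params.save(path, extra={"seed": 7})
        loaded = RBMParameters.load(path)
        assert np.array_equal(params.W, loaded.W)
        assert np.array_equal(params.b, loaded.b)
        assert np.array_equal(params.c, loaded.c)

    def test_non_finite_parameters_rejected(self):
        with pytest.raises(ValueError):
            RBMParameters(W=[[np.nan]], b=[0.0], c=[0.0])
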