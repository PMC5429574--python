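import numpy as np
import pytest

from combistate import (CombinatorialHMM, SymbolSequence, backward,
                        baum_welch_step, bic, forward, forward_backward,
                        init_random_model, posteriors, train, viterbi)
from combistate.hmm import floor_normalize

from helpers_brute import (apply_floor, enum_em_step, enum_likelihood,
                           enum_posteriors, enum_viterbi, random_toy_model)


def toy(pi, A, B, floor=1e-12):
    return CombinatorialHMM.from_params(np.asarray(pi, float),
                                        np.asarray(A, float),
                                        np.asarray(B, float), floor=floor)


def seq(symbols, m):
    return SymbolSequence("ct", "chr1", np.asarray(symbols), "full", m)


class TestFloorNormalize:
    def test_rows_sum_to_one_with_floor_respected(self, rng):
        rows = rng.dirichlet(np.ones(6), size=10)
        rows[:, 0] = 0.0
        out = floor_normalize(rows, 1e-6)
        assert np.allclose(out.sum(axis=1), 1.0, atol=1e-12)
        assert (out >= 1e-6 - 1e-15).all()

    def test_matches_independent_implementation(self, rng):
        rows = rng.dirichlet(np.full(4, 0.2), size=20)
        assert np.allclose(floor_normalize(rows, 1e-3),
                           apply_floor(rows, 1e-3), atol=1e-12)


class TestForward:
    def test_single_state_product_form(self):
        model = toy([1.0], [[1.0]], [[0.5, 0.5]])
        fb = forward(model, seq([0, 1, 0], 2))
        assert np.isclose(np.exp(fb.log_likelihood), 0.125)

    def test_first_position_unscaled_values(self):
        model = toy([0.6, 0.4], [[0.5, 0.5], [0.5, 0.5]],
                    [[0.5, 0.5], [0.25, 0.75]])
        fb = forward(model, seq([0, 0], 2))
        unscaled = fb.alpha[0] * fb.scales[0]
        assert np.allclose(unscaled, [0.30, 0.10])

    def test_matches_exhaustive_path_sum(self, rng):
        for _ in range(20):
            n, m, T = rng.integers(1, 4), rng.integers(2, 5), rng.integers(2, 9)
            pi, A, B = random_toy_model(rng, n, m)
            obs = rng.integers(0, m, size=T)
            ll = forward(toy(pi, A, B), seq(obs, m)).log_likelihood
            assert np.isclose(ll, np.log(enum_likelihood(pi, A, B, obs)),
                              rtol=1e-12)

    def test_scaled_rows_sum_to_one(self, rng):
        pi, A, B = random_toy_model(rng, 3, 4)
        fb = forward(toy(pi, A, B), seq(rng.integers(0, 4, 50), 4))
        assert np.allclose(fb.alpha.sum(axis=1), 1.0, atol=1e-12)

    def test_symbol_outside_alphabet_rejected(self):
        model = toy([1.0], [[1.0]], [[0.5, 0.5]])
        with pytest.raises(ValueError):
            forward(model, seq([2], 3))


class TestBackward:
    def test_last_position_is_one(self, rng):
        pi, A, B = random_toy_model(rng, 3, 3)
        fb = backward(toy(pi, A, B), seq(rng.integers(0, 3, 10), 3))
        assert np.allclose(fb.beta[-1], 1.0)

    def test_single_state_product_form(self):
        model = toy([1.0], [[1.0]], [[0.3, 0.7]])
        obs = [0, 1, 1]
        fb = backward(model, seq(obs, 2))
        # unscaled beta_t = prod_{u>t} b(o_u); scaled by prod_{u>t} c_u = b(o_u)
        assert np.allclose(fb.beta, 1.0)

    def test_forward_backward_identity_at_every_position(self, rng):
        for _ in range(5):
            pi, A, B = random_toy_model(rng, 3, 4)
            fb = backward(toy(pi, A, B), seq(rng.integers(0, 4, 12), 4))
            # scaled identity: sum_i alpha_t(i) beta_t(i) = 1 for all t
            assert np.allclose((fb.alpha * fb.beta).sum(axis=1), 1.0, atol=1e-10)


class TestPosteriors:
    def test_single_state_everywhere(self):
        model = toy([1.0], [[1.0]], [[0.4, 0.6]])
        post = posteriors(model, seq([0, 1, 0], 2))
        assert np.allclose(post.gamma, 1.0)

    def test_matches_enumeration(self, rng):
        for _ in range(10):
            pi, A, B = random_toy_model(rng, 2, 3)
            obs = rng.integers(0, 3, size=6)
            post = posteriors(toy(pi, A, B), seq(obs, 3))
            gamma, xi = enum_posteriors(pi, A, B, obs)
            assert np.allclose(post.gamma, gamma, rtol=1e-10, atol=1e-12)
            assert np.allclose(post.xi, xi, rtol=1e-10, atol=1e-12)

    def test_transition_posterior_marginalizes_to_occupancy(self, rng):
        pi, A, B = random_toy_model(rng, 3, 4)
        post = posteriors(toy(pi, A, B), seq(rng.integers(0, 4, 6), 4))
        assert np.allclose(post.xi.sum(axis=2), post.gamma[:-1], atol=1e-10)
        assert np.allclose(post.xi.sum(axis=(1, 2)), 1.0, atol=1e-10)

    def test_private_symbols_give_one_hot_posteriors(self):
        model = toy([0.5, 0.5], [[0.5, 0.5], [0.5, 0.5]],
                    [[1.0, 0.0], [0.0, 1.0]], floor=0.0)
        post = posteriors(model, seq([0, 1, 1, 0], 2))
        assert np.allclose(post.gamma, [[1, 0], [0, 1], [0, 1], [1, 0]])


class TestBaumWelch:
    def test_single_state_recovers_symbol_frequencies(self):
        model = toy([1.0], [[1.0]], [[0.5, 0.25, 0.25]])
        new = baum_welch_step(model, [seq([0, 0, 1, 2], 3)])
        assert np.allclose(new.emissionprob_[0], [0.5, 0.25, 0.25])

    def test_matches_enumerated_em_step(self, rng):
        for _ in range(5):
            pi, A, B = random_toy_model(rng, 2, 3)
            obs_list = [rng.integers(0, 3, size=rng.integers(3, 7))
                        for _ in range(2)]
            new = baum_welch_step(toy(pi, A, B),
                                  [seq(o, 3) for o in obs_list])
            pi_e, A_e, B_e = enum_em_step(pi, A, B, obs_list)
            assert np.allclose(new.startprob_, apply_floor(pi_e, 1e-12)[0],
                               rtol=1e-10, atol=1e-10)
            assert np.allclose(new.transmat_, apply_floor(A_e, 1e-12),
                               rtol=1e-10, atol=1e-10)
            assert np.allclose(new.emissionprob_, apply_floor(B_e, 1e-12),
                               rtol=1e-10, atol=1e-10)

    def test_updated_model_is_row_stochastic_with_floor(self, rng):
        pi, A, B = random_toy_model(rng, 4, 5)
        model = toy(pi, A, B, floor=1e-6)
        new = baum_welch_step(model, [seq(rng.integers(0, 5, 100), 5)])
        for arr, axis in ((new.startprob_, 0), (new.transmat_, 1),
                          (new.emissionprob_, 1)):
            assert np.allclose(arr.sum(axis=axis), 1.0, atol=1e-9)
            assert (arr >= 1e-6 - 1e-15).all()

    def test_empty_sequence_set_rejected(self, rng):
        pi, A, B = random_toy_model(rng, 2, 2)
        with pytest.raises(ValueError):
            baum_welch_step(toy(pi, A, B), [])


class TestTraining:
    def test_trace_length_equals_iterations(self, rng):
        pi, A, B = random_toy_model(rng, 2, 3)
        _, trace = train(toy(pi, A, B), [seq(rng.integers(0, 3, 40), 3)], 7)
        assert trace.n_iterations == 7

    def test_log_likelihood_never_decreases(self, rng):
        for _ in range(3):
            pi, A, B = random_toy_model(rng, 3, 4)
            obs = [seq(rng.integers(0, 4, 120), 4) for _ in range(2)]
            _, trace = train(toy(pi, A, B, floor=1e-6), obs, 50)
            diffs = np.diff(trace.log_likelihood)
            assert (diffs >= -1e-8).all()

    def test_truth_model_is_near_stationary_on_own_data(self):
        import combistate as cs
        panel = cs.MarkPanel(("m1", "m2"), tf="m1")
        spec = cs.GeneratorSpec(panel=panel,
                                state_mark_probs=np.array([[0.9, 0.1],
                                                           [0.1, 0.8]]),
                                self_transition=0.9,
                                seq_lengths=(1_000_000,))
        data = cs.sample_generative_model(spec, seed=5)
        new = baum_welch_step(data.model, data.sequences)
        tv_a = 0.5 * np.abs(new.transmat_ - data.model.transmat_).sum(axis=1)
        tv_b = 0.5 * np.abs(new.emissionprob_ - data.model.emissionprob_).sum(axis=1)
        assert (tv_a < 1e-3).all()
        assert (tv_b < 1e-3).all()


class TestViterbi:
    def test_single_state_constant_path(self):
        model = toy([1.0], [[1.0]], [[0.5, 0.5]])
        assert viterbi(model, seq([0, 1, 0], 2)).tolist() == [0, 0, 0]

    def test_private_symbols_read_off_path(self):
        model = toy([0.5, 0.5], [[0.5, 0.5], [0.5, 0.5]],
                    [[1.0, 0.0], [0.0, 1.0]], floor=0.0)
        obs = [0, 1, 1, 0, 1]
        assert viterbi(model, seq(obs, 2)).tolist() == obs

    def test_matches_exhaustive_maximum(self, rng):
        for _ in range(10):
            pi, A, B = random_toy_model(rng, 3, 3)
            obs = rng.integers(0, 3, size=7)
            path = viterbi(toy(pi, A, B), seq(obs, 3))
            from helpers_brute import path_probability
            _, best_p = enum_viterbi(pi, A, B, obs)
            got_p = path_probability(pi, A, B, obs, tuple(path))
            assert np.isclose(got_p, best_p, rtol=1e-12)

    def test_ties_break_to_lowest_state(self):
        model = toy([0.5, 0.5], [[0.5, 0.5], [0.5, 0.5]],
                    [[0.5, 0.5], [0.5, 0.5]])
        assert viterbi(model, seq([0, 1, 0, 1], 2)).tolist() == [0, 0, 0, 0]

    def test_path_probability_bounded_by_total(self, rng):
        pi, A, B = random_toy_model(rng, 3, 4)
        obs = rng.integers(0, 4, size=8)
        model = toy(pi, A, B)
        from helpers_brute import path_probability
        p_path = path_probability(pi, A, B, obs, tuple(viterbi(model, seq(obs, 4))))
        assert p_path <= np.exp(forward(model, seq(obs, 4)).log_likelihood) + 1e-15


class TestBic:
    def test_closed_form_for_uniform_two_state_model(self):
        model = toy([0.5, 0.5], [[0.5, 0.5], [0.5, 0.5]],
                    [[0.5, 0.5], [0.5, 0.5]])
        obs = seq([0, 1] * 5, 2)          # T = 10
        # lnL = 10 ln(1/2); k = n(n-1) + n(m-1) + (n-1) = 2 + 2 + 1 = 5
        expected = -2 * 10 * np.log(0.5) + 5 * np.log(10)
        assert np.isclose(bic(model, [obs]), expected)

    def test_single_state_penalty(self):
        model = toy([1.0], [[1.0]], [[0.25] * 4])
        obs = seq([0, 1, 2, 3] * 5, 4)    # T = 20, k = m - 1 = 3
        expected = -2 * 20 * np.log(0.25) + 3 * np.log(20)
        assert np.isclose(bic(model, [obs]), expected)

    def test_penalty_increases_with_states_at_equal_likelihood(self):
        obs = seq([0, 1] * 10, 2)
        uniform2 = toy([0.5, 0.5], [[0.5, 0.5], [0.5, 0.5]],
                       [[0.5, 0.5], [0.5, 0.5]])
        uniform3 = toy([1 / 3] * 3, np.full((3, 3), 1 / 3), np.full((3, 2), 0.5))
        assert np.isclose(uniform2.score([obs]), uniform3.score([obs]))
        assert bic(uniform3, [obs]) > bic(uniform2, [obs])


class TestEstimatorApi:
    def test_init_is_reproducible_and_valid(self):
        a = init_random_model(4, 6, seed=11)
        b = init_random_model(4, 6, seed=11)
        assert np.array_equal(a.transmat_, b.transmat_)
        assert np.array_equal(a.emissionprob_, b.emissionprob_)
        a._check_params()
        assert (a.emissionprob_ >= a.floor - 1e-15).all()

    def test_single_state_init_is_degenerate_simplex(self):
        model = init_random_model(1, 3, seed=0)
        assert model.startprob_.tolist() == [1.0]
        assert model.transmat_.tolist() == [[1.0]]

    def test_fit_with_lengths_matches_sequence_list(self, rng):
        obs = [rng.integers(0, 4, 60) for _ in range(3)]
        seqs = [seq(o, 4) for o in obs]
        m1 = CombinatorialHMM(n_states=3, n_iter=10, random_state=2).fit(seqs)
        m2 = CombinatorialHMM(n_states=3, n_iter=10, random_state=2).fit(
            np.concatenate(obs), lengths=[60, 60, 60])
        assert np.allclose(m1.transmat_, m2.transmat_)
        assert np.allclose(m1.emissionprob_, m2.emissionprob_)

    def test_sklearn_params_round_trip(self):
        model = CombinatorialHMM(n_states=7, n_iter=42)
        clone = CombinatorialHMM(**model.get_params())
        assert clone.get_params() == model.get_params()

    def test_matches_hmmlearn_likelihood_and_decoding(self, rng):
        hmmlearn_hmm = pytest.importorskip("hmmlearn.hmm")
        pi, A, B = random_toy_model(rng, 3, 4, floor=1e-6)
        model = toy(pi, A, B, floor=1e-6)
        obs = rng.integers(0, 4, size=200)
        ref = hmmlearn_hmm.CategoricalHMM(n_components=3)
        ref.startprob_, ref.transmat_, ref.emissionprob_ = pi, A, B
        ref.n_features = 4
        X = obs.reshape(-1, 1)
        assert np.isclose(model.score(obs), ref.score(X), rtol=1e-10)
        assert np.array_equal(model.predict(obs), ref.predict(X))
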