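"""HMM inference against brute-force enumeration oracles, EM behaviour,
state labelling and budget computation."""

import numpy as np
import pytest
from scipy.special import logsumexp
from scipy.stats import bernoulli, gamma

import colonyflux as cf
from colonyflux.hmm import (
    canonicalize,
    compute_budget,
    emission_loglik,
    fit_em,
    forward_backward,
    label_states,
    path_logprob,
    viterbi,
)
from conftest import make_features, sample_from_model


def enumerate_paths(model, fs):
    """Brute-force total likelihood and best path over all 3^T paths."""
    T = len(fs)
    logps = {}
    for code in range(3 ** T):
        path = np.array([(code // 3 ** t) % 3 for t in range(T)])
        logps[tuple(path)] = path_logprob(model, fs, path)
    total = logsumexp(np.array(list(logps.values())))
    best = max(logps, key=logps.get)
    return total, np.array(best), logps


class TestEmissions:
    def test_both_streams_missing_gives_zeros(self, toy_model):
        logB = emission_loglik(toy_model, [np.nan], [np.nan])
        assert np.array_equal(logB, np.zeros((1, 3)))

    def test_zero_wingbeat_contributes_log_zero_mass(self):
        m = cf.HmmModel(
            init=np.full(3, 1 / 3),
            trans=np.full((3, 3), 1 / 3),
            zero_mass=np.array([0.01, 0.95, 0.9]),
            shape=np.ones(3),
            rate=np.ones(3),
            p_near=np.array([0.5, 0.5, 0.5]),
        )
        logB = emission_loglik(m, [0.0], [np.nan])
        assert logB[0, 0] == pytest.approx(np.log(0.01))

    def test_matches_independent_density_arithmetic(self, toy_model):
        w, nr = 3.4, 1.0
        logB = emission_loglik(toy_model, [w], [nr])
        for s in range(3):
            expected = (
                np.log1p(-toy_model.zero_mass[s])
                + gamma.logpdf(w, toy_model.shape[s], scale=1 / toy_model.rate[s])
                + bernoulli.logpmf(nr, toy_model.p_near[s])
            )
            assert logB[0, s] == pytest.approx(expected, abs=1e-12)

    def test_negative_wingbeat_rejected(self, toy_model):
        with pytest.raises(ValueError):
            emission_loglik(toy_model, [-1.0], [0.0])


class TestForwardBackward:
    def test_length_one_posterior_is_normalised_init_times_emission(self, toy_model):
        fs = make_features([3.5], [0.0])
        ll, post = forward_backward(toy_model, fs)
        b = np.exp(emission_loglik(toy_model, fs.wingbeat, fs.near))[0]
        expected = toy_model.init * b
        expected /= expected.sum()
        assert np.allclose(post[0], expected, atol=1e-12)
        assert ll == pytest.approx(np.log((toy_model.init * b).sum()))

    @pytest.mark.parametrize("T", [2, 3, 6])
    def test_likelihood_equals_path_enumeration(self, toy_model, T):
        rng = np.random.default_rng(T)
        fs, _ = sample_from_model(toy_model, T, rng)
        ll, post = forward_backward(toy_model, fs)
        total, _, _ = enumerate_paths(toy_model, fs)
        assert abs(ll - total) < 1e-10
        assert np.allclose(post.sum(axis=1), 1.0, atol=1e-9)

    def test_uninformative_model_gives_uniform_posteriors(self):
        m = cf.HmmModel(
            init=np.full(3, 1 / 3),
            trans=np.eye(3),
            zero_mass=np.full(3, 0.5),
            shape=np.ones(3),
            rate=np.ones(3),
            p_near=np.full(3, 0.5),
        )
        fs = make_features([0.0, 0.0, 0.0], [1.0, 0.0, 1.0])
        _, post = forward_backward(m, fs)
        assert np.allclose(post, 1 / 3, atol=1e-12)


class TestViterbi:
    def test_recovers_generating_path_with_sharp_emissions(self, toy_model):
        rng = np.random.default_rng(123)
        fs, states = sample_from_model(toy_model, 400, rng)
        path = viterbi(toy_model, fs)
        assert np.mean(path.states == states) > 0.97

    @pytest.mark.parametrize("T", [2, 4])
    def test_matches_enumerated_best_path(self, toy_model, T):
        rng = np.random.default_rng(40 + T)
        fs, _ = sample_from_model(toy_model, T, rng)
        path = viterbi(toy_model, fs)
        _, best, logps = enumerate_paths(toy_model, fs)
        assert path_logprob(toy_model, fs, path.states) == pytest.approx(
            logps[tuple(best)], abs=1e-10
        )

    def test_beats_random_alternative_paths(self, toy_model):
        rng = np.random.default_rng(7)
        fs, _ = sample_from_model(toy_model, 50, rng)
        lp_best = path_logprob(toy_model, fs, viterbi(toy_model, fs).states)
        for _ in range(1000):
            alt = rng.integers(0, 3, 50)
            assert lp_best >= path_logprob(toy_model, fs, alt) - 1e-12

    def test_fully_symmetric_model_returns_lowest_index_path(self):
        m = cf.HmmModel(
            init=np.full(3, 1 / 3),
            trans=np.full((3, 3), 1 / 3),
            zero_mass=np.full(3, 0.5),
            shape=np.ones(3),
            rate=np.ones(3),
            p_near=np.full(3, 0.5),
        )
        fs = make_features([0.0] * 4, [1.0] * 4)
        path = viterbi(m, fs)
        assert (path.states == 0).all()  # flight is the lowest index


class TestEm:
    def test_parameter_recovery_from_simulated_data(self, toy_model):
        rng = np.random.default_rng(99)
        series = [sample_from_model(toy_model, 1000, rng)[0] for _ in range(50)]
        fitted, trace = fit_em(series, max_iter=200)
        fitted = canonicalize(fitted)
        assert np.abs(fitted.trans - toy_model.trans).max() < 0.05
        assert np.abs(fitted.p_near - toy_model.p_near).max() < 0.05

    def test_init_at_truth_is_near_fixed_point(self, toy_model):
        # the first step absorbs the finite-sample gap between the true
        # parameters and the MLE; afterwards improvements are negligible
        rng = np.random.default_rng(17)
        series = [sample_from_model(toy_model, 800, rng)[0] for _ in range(5)]
        _, trace = fit_em(series, init=toy_model, max_iter=50, tol=1e-6)
        rel = np.diff(trace) / abs(trace[0])
        assert (rel >= -1e-12).all()
        assert (rel[1:] < 2e-4).all()
        assert (rel[1:] <= rel[0]).all()

    def test_loglik_trace_monotone_nondecreasing(self, toy_model):
        rng = np.random.default_rng(23)
        series = [sample_from_model(toy_model, 300, rng)[0] for _ in range(3)]
        _, trace = fit_em(series, max_iter=100, tol=0.0)
        diffs = np.diff(trace)
        assert (diffs >= -1e-8).all()


class TestLabelling:
    def test_generator_true_parameters_map_canonically(self, toy_model):
        assert label_states(toy_model) == {0: "flight", 1: "colony", 2: "water"}

    def test_labelling_invariant_under_state_permutation(self, toy_model):
        perm = np.array([2, 0, 1])
        from dataclasses import replace

        shuffled = replace(
            toy_model,
            init=toy_model.init[perm],
            trans=toy_model.trans[np.ix_(perm, perm)],
            zero_mass=toy_model.zero_mass[perm],
            shape=toy_model.shape[perm],
            rate=toy_model.rate[perm],
            p_near=toy_model.p_near[perm],
        )
        canon = canonicalize(shuffled)
        assert np.allclose(canon.trans, toy_model.trans)
        assert np.allclose(canon.p_near, toy_model.p_near)

    def test_tied_states_raise(self, toy_model):
        from dataclasses import replace

        tied = replace(toy_model, zero_mass=np.zeros(3), shape=np.ones(3) * 2,
                       rate=np.ones(3))
        with pytest.raises(ValueError):
            label_states(tied)


class TestBudget:
    def _path(self, states, missing=None):
        states = np.asarray(states)
        T = len(states)
        return cf.StatePath(
            t0=None,
            midpoints=(np.arange(T) + 0.5) * 15.0,
            states=states,
            posterior=np.full((T, 3), 1 / 3),
            missing=np.zeros(T, bool) if missing is None else np.asarray(missing),
        )

    def test_all_flight(self):
        b = compute_budget(self._path([0, 0, 0]))
        assert b.proportions.tolist() == [1.0, 0.0, 0.0]

    def test_counts_arithmetic(self):
        states = np.array([0] * 60 + [1] * 90 + [2] * 90)
        b = compute_budget(self._path(states))
        assert np.allclose(b.proportions, [0.25, 0.375, 0.375])

    def test_missing_windows_excluded(self):
        states = np.array([0, 1, 2, 2])
        missing = np.array([False, False, True, True])
        b = compute_budget(self._path(states, missing))
        assert np.allclose(b.proportions, [0.5, 0.5, 0.0])

    def test_proportions_sum_to_one_for_random_paths(self, rng):
        for _ in range(20):
            b = compute_budget(self._path(rng.integers(0, 3, 100)))
            assert b.proportions.sum() == pytest.approx(1.0, abs=1e-12)

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError):
            compute_budget(self._path([0, 1], missing=[True, True]))
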