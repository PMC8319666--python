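"""HMM core: forward/Viterbi against enumeration, EM behavior, labeling."""

import numpy as np
import pytest
from scipy.stats import norm

import wormstates as ws
from wormstates.hmm import posterior_probs, _log_emissions, _viterbi_batch

from conftest import brute_force_forward, brute_force_viterbi, random_valid_params


class TestForward:
    def test_single_state_model_sums_emission_logpdfs(self):
        params = ws.HMMParams(pi=[1.0], A=[[1.0]], means=[0.5], sds=[1.2])
        rng = np.random.default_rng(0)
        obs = rng.normal(0.5, 1.2, 50)
        expected = norm.logpdf(obs, 0.5, 1.2).sum()
        assert ws.forward_log_likelihood(params, obs) == pytest.approx(expected, abs=1e-9)

    def test_length_one_sequence_is_log_mixture_density(self):
        rng = np.random.default_rng(1)
        params = random_valid_params(rng)
        y = 0.3
        expected = np.log(
            sum(
                params.pi[i] * norm.pdf(y, params.means[i], params.sds[i])
                for i in range(3)
            )
        )
        assert ws.forward_log_likelihood(params, np.array([y])) == pytest.approx(
            expected, abs=1e-9
        )

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_path_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        params = random_valid_params(rng)
        T = int(rng.integers(2, 7))
        obs = rng.normal(0, 2, T)
        assert ws.forward_log_likelihood(params, obs) == pytest.approx(
            brute_force_forward(params, obs), abs=1e-9
        )

    def test_rejects_invalid_params(self):
        bad = ws.HMMParams(pi=[0.5, 0.5, 0.5], A=np.eye(3), means=[0, 1, 2], sds=[1, 1, 1])
        with pytest.raises(ValueError):
            ws.forward_log_likelihood(bad, np.zeros(5))


class TestViterbi:
    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_argmax_path(self, seed):
        rng = np.random.default_rng(100 + seed)
        params = random_valid_params(rng)
        T = int(rng.integers(2, 7))
        obs = rng.normal(0, 2, T)
        expected_path, expected_lp = brute_force_viterbi(params, obs)
        logB = _log_emissions(params, obs[None, :])
        got = tuple(_viterbi_batch(params, logB)[0])
        assert got == expected_path

    def test_dominant_emissions_pin_every_frame(self):
        params = ws.HMMParams(
            pi=np.full(3, 1 / 3),
            A=np.full((3, 3), 1 / 3),
            means=np.array([-3.0, 0.0, 3.0]),
            sds=np.array([0.3, 0.3, 0.3]),
        )
        obs = np.full(40, 0.0)  # exactly at state D's mean
        seq = ws.viterbi_decode(params, obs)
        assert np.all(seq.labels == "D")

    def test_posteriors_sum_to_one_and_viterbi_bounded_by_forward(self):
        rng = np.random.default_rng(7)
        params = random_valid_params(rng)
        obs = rng.normal(0, 2, 200)
        seq = ws.viterbi_decode(params, obs)
        np.testing.assert_allclose(seq.posteriors.sum(axis=1), 1.0, atol=1e-9)
        # path log-probability cannot exceed the total forward likelihood
        path_lp = brute_force_path_logprob(params, seq, obs)
        assert path_lp <= seq.log_likelihood + 1e-9

    def test_decoding_invariant_to_common_emission_rescaling(self):
        rng = np.random.default_rng(8)
        params = random_valid_params(rng)
        obs = rng.normal(0, 2, 100)
        logB = _log_emissions(params, obs[None, :])
        base = _viterbi_batch(params, logB)
        shifted = _viterbi_batch(params, logB + 3.7)  # common factor on all densities
        np.testing.assert_array_equal(base, shifted)

    def test_high_accuracy_on_well_separated_synthetic_session(self, control_config):
        states = ws.simulate_state_sequence(control_config, seed=21)
        y = ws.simulate_log_speeds(states, control_config, seed=22)
        params = generating_params(control_config)
        seq = ws.viterbi_decode(params, y)
        assert (seq.state_idx == states).mean() >= 0.99


class TestBaumWelch:
    def test_loglik_trace_monotone_nondecreasing(self):
        rng = np.random.default_rng(3)
        seqs = [rng.normal(0, 2, 300) for _ in range(4)]
        _, trace = ws.fit_baum_welch(seqs, max_iter=60)
        assert np.all(np.diff(trace) >= -1e-8)

    def test_single_state_data_collapses_occupancy(self):
        """Data drawn from one state of a separated model: refitting from
        that model leaves >=99% of the posterior mass on that state. (With
        an uninformative init, EM on single-state data splits the mixture
        into overlapping components -- the usual degenerate-mixture
        behavior -- which is why the screen protocol fits on control
        groups where all three states occur.)"""
        rng = np.random.default_rng(4)
        seqs = [rng.normal(0.7, 0.2, 800) for _ in range(3)]  # dwelling only
        A = np.full((3, 3), 0.025)
        np.fill_diagonal(A, 0.95)
        init = ws.HMMParams(
            pi=np.full(3, 1 / 3), A=A,
            means=np.array([-1.9, 0.7, 2.3]), sds=np.array([0.5, 0.35, 0.3]),
        )
        params, _ = ws.fit_baum_welch(seqs, init=init, max_iter=100)
        posts = [posterior_probs(params, s)[0] for s in seqs]
        occupancy = np.concatenate(posts).mean(axis=0)
        assert occupancy[1] >= 0.99

    def test_recovers_generating_model(self, control_config):
        """20 sessions from a known chain: A within 0.01, means within 0.05."""
        seqs, truths = [], []
        for k in range(20):
            st = ws.simulate_state_sequence(control_config, seed=1000 + k)
            truths.append(st)
            seqs.append(ws.simulate_log_speeds(st, control_config, seed=2000 + k))
        params, trace = ws.fit_baum_welch(seqs)
        assert np.all(np.diff(trace) >= -1e-8)
        true = generating_params(control_config)
        np.testing.assert_allclose(params.A, true.A, atol=0.01)
        np.testing.assert_allclose(params.means, true.means, atol=0.05)
        # decoded accuracy with the fitted model
        hits = total = 0
        for st, y in zip(truths, seqs):
            seq = ws.viterbi_decode(params, y)
            hits += int((seq.state_idx == st).sum())
            total += st.size
        assert hits / total >= 0.99

    def test_short_sequences_excluded_with_warning(self):
        rng = np.random.default_rng(5)
        good = rng.normal(0, 1, 500)
        with pytest.warns(UserWarning):
            params, _ = ws.fit_baum_welch([good, np.array([1.0])], max_iter=20)
        with pytest.raises(ValueError):
            ws.fit_baum_welch([np.array([1.0])])


class TestLabeling:
    def test_ascending_means_map_to_q_d_r(self):
        p = ws.HMMParams(pi=np.full(3, 1 / 3), A=np.eye(3), means=[-3.0, 0.0, 2.0], sds=[1, 1, 1])
        assert ws.label_states(p) == {0: "Q", 1: "D", 2: "R"}

    def test_permuted_means_follow_the_permutation(self):
        p = ws.HMMParams(pi=np.full(3, 1 / 3), A=np.eye(3), means=[2.0, -3.0, 0.0], sds=[1, 1, 1])
        assert ws.label_states(p) == {0: "R", 1: "Q", 2: "D"}

    def test_tied_means_rejected(self):
        p = ws.HMMParams(pi=np.full(3, 1 / 3), A=np.eye(3), means=[0.0, 0.0, 1.0], sds=[1, 1, 1])
        with pytest.raises(ValueError):
            ws.label_states(p)

    def test_fitted_labels_match_generator_identities(self, control_config):
        st = ws.simulate_state_sequence(control_config, seed=31)
        y = ws.simulate_log_speeds(st, control_config, seed=32)
        params, _ = ws.fit_baum_welch([y])
        assert ws.label_states(params) == {0: "Q", 1: "D", 2: "R"}


class TestAgainstHmmlearn:
    """Independent cross-check: hmmlearn's GaussianHMM scores the same
    parameters identically (it is never used as the implementation)."""

    def test_forward_loglik_agrees(self):
        hmmlearn = pytest.importorskip("hmmlearn.hmm")
        rng = np.random.default_rng(9)
        params = random_valid_params(rng)
        obs = rng.normal(0, 2, 500)
        ref = hmmlearn.GaussianHMM(n_components=3, covariance_type="diag", init_params="")
        ref.startprob_ = params.pi
        ref.transmat_ = params.A
        ref.means_ = params.means[:, None]
        ref.covars_ = (params.sds**2)[:, None]
        assert ws.forward_log_likelihood(params, obs) == pytest.approx(
            ref.score(obs[:, None]), abs=1e-7
        )


def generating_params(config: ws.SimulationConfig) -> ws.HMMParams:
    """The HMM that exactly matches the synthetic generator's law."""
    P = ws.transition_matrix(config)
    pi0 = ws.stationary_distribution(P)
    return ws.HMMParams(
        pi=pi0,
        A=P,
        means=np.array([e.mu for e in config.emissions]),
        sds=np.array([e.sigma for e in config.emissions]),
    )


def brute_force_path_logprob(params, seq, obs):
    idx = seq.state_idx  # params is already in ascending-mean order here
    lp = np.log(params.pi[idx[0]]) + norm.logpdf(obs[0], params.means[idx[0]], params.sds[idx[0]])
    for t in range(1, len(obs)):
        lp += np.log(params.A[idx[t - 1], idx[t]])
        lp += norm.logpdf(obs[t], params.means[idx[t]], params.sds[idx[t]])
    return lp
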