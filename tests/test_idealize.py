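import itertools

import numpy as np
import pytest
from scipy.stats import norm

import ribofret as rf
from ribofret.errors import ValidationError
from ribofret.idealize import compute_fret, dwell_segments, fit_transitions, viterbi_idealize
from ribofret.schemes import PhotophysicsParams


class TestComputeFret:
    def test_definition(self):
        donor = np.array([130.0])  # donor - bg = 30
        acceptor = np.array([170.0])  # acceptor - bg = 70
        assert compute_fret(donor, acceptor, 100.0, None)[0] == pytest.approx(0.7)

    def test_zero_acceptor_limit(self):
        E = compute_fret(np.array([400.0]), np.array([100.0]), 100.0, None)
        assert E[0] == pytest.approx(0.0)

    def test_noiseless_trace_reproduces_drawn_fret(self, two_state_scheme):
        quiet = PhotophysicsParams(channel_noise_sd=0.0, donor_bleach_rate=0.0, blink_rate=0.0)
        path = rf.sample_state_path(two_state_scheme, 3.0, 0.015, seed=1)
        tr = rf.render_trace(path, two_state_scheme, quiet, seed=1)
        E = compute_fret(tr.donor, tr.acceptor, quiet.background_level, None)
        np.testing.assert_allclose(E, tr.true_fret, atol=1e-6)

    def test_frames_at_and_after_bleach_excluded(self):
        donor = np.full(50, 400.0)
        acceptor = np.full(50, 400.0)
        assert len(compute_fret(donor, acceptor, 100.0, bleach_frame=20)) == 20

    def test_mostly_dark_trace_rejected(self):
        donor = np.full(50, 90.0)
        acceptor = np.full(50, 90.0)
        with pytest.raises(ValidationError):
            compute_fret(donor, acceptor, 100.0, None)


def brute_force_viterbi(obs, model):
    """Exhaustive max-probability path; the oracle for small instances."""
    n = model.n_states
    best_logp, best_path = -np.inf, None
    for path in itertools.product(range(n), repeat=len(obs)):
        logp = np.log(model.startprob[path[0]])
        logp += norm.logpdf(obs[0], model.means[path[0]], model.sds[path[0]])
        for prev, cur, x in zip(path, path[1:], obs[1:]):
            logp += np.log(model.transmat[prev, cur])
            logp += norm.logpdf(x, model.means[cur], model.sds[cur])
        if logp > best_logp:
            best_logp, best_path = logp, path
    return np.array(best_path), best_logp


class TestViterbi:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_exhaustive_enumeration(self, seed):
        """Viterbi equals brute-force search over all 4^8 paths."""
        model = rf.builtin_model("selection4").with_transmat(
            np.array(
                [
                    [0.90, 0.06, 0.03, 0.01],
                    [0.20, 0.60, 0.15, 0.05],
                    [0.05, 0.15, 0.60, 0.20],
                    [0.01, 0.01, 0.08, 0.90],
                ]
            )
        )
        # uniform start so every state is reachable at t=0
        import dataclasses

        model = dataclasses.replace(model, startprob=np.full(4, 0.25))
        rng = np.random.default_rng(seed)
        obs = rng.uniform(-0.1, 0.9, size=8)
        path = viterbi_idealize(obs, model)
        oracle_path, oracle_logp = brute_force_viterbi(obs, model)
        np.testing.assert_array_equal(path.states, oracle_path)
        assert path.log_likelihood == pytest.approx(oracle_logp)

    def test_noiseless_observations_recover_true_path(self):
        model = rf.builtin_model("pretrans3").with_transmat(
            np.array([[0.9, 0.05, 0.05], [0.05, 0.9, 0.05], [0.05, 0.05, 0.9]])
        )
        true = np.array([0, 0, 1, 1, 2, 2, 2, 1, 0])
        obs = model.means[true]
        path = viterbi_idealize(obs, model)
        np.testing.assert_array_equal(path.states, true)

    def test_dwell_segments_partition_frames(self):
        states = np.array([0, 0, 1, 1, 1, 2, 0, 0])
        segs = dwell_segments(states)
        assert segs == [(0, 0, 2), (1, 2, 3), (2, 5, 1), (0, 6, 2)]
        assert sum(n for _, _, n in segs) == len(states)
        assert all(a != b for (a, _, _), (b, _, _) in zip(segs, segs[1:]))

    def test_accommodated_window_assignment(self):
        """Observations nearer 0.72 than 0.46 idealize to the accommodated
        state once the path is there (state-window sanity property)."""
        model = rf.builtin_model("selection4").with_transmat(
            rf.idealize._sticky_transmat(4)
        )
        obs = np.concatenate([np.full(5, 0.2), np.full(10, 0.65), np.full(10, 0.75)])
        path = viterbi_idealize(obs, model)
        assert np.all(path.states[-10:] == 3)


class TestTransitionEM:
    @pytest.fixture(scope="class")
    def em_recovery(self):
        """Simulate from a known 3-state transition matrix, refit by EM."""
        target = np.array([0.36, 0.44, 0.20])
        scheme = rf.exchange_scheme(
            ("h2", "h1", "c"), [0.22, 0.42, 0.72], [0.075] * 3, target, exchange_rate=2.0
        )
        model = rf.builtin_model("pretrans3")
        rng = np.random.default_rng(11)
        # discrete-time truth: P = expm(Q dt) of the exchange generator
        from scipy.linalg import expm

        true_P = expm(scheme.rate_matrix * 0.015)
        seqs = []
        for _ in range(150):
            path = rf.sample_state_path(scheme, 6.0, 0.015, rng=rng)
            E = np.clip(rng.normal(scheme.fret_mean[path], scheme.fret_sd[path]), 0, 1)
            seqs.append(E)
        return seqs, model, true_P

    def test_recovers_transition_probabilities(self, em_recovery):
        seqs, model, true_P = em_recovery
        fit = fit_transitions(seqs, model)
        # off-diagonal transition probabilities within 20% relative or small
        # absolute error (rare transitions carry few counts)
        est = fit.model.transmat
        for i in range(3):
            for j in range(3):
                if i != j:
                    assert est[i, j] == pytest.approx(true_P[i, j], rel=0.2, abs=0.005)

    def test_loglik_nondecreasing(self, em_recovery):
        seqs, model, _ = em_recovery
        fit = fit_transitions(seqs, model)
        hist = np.array(fit.loglik_history)
        assert np.all(np.diff(hist) >= -1e-6)

    def test_order_invariance(self, em_recovery):
        seqs, model, _ = em_recovery
        a = fit_transitions(seqs, model).model.transmat
        b = fit_transitions(seqs[::-1], model).model.transmat
        np.testing.assert_allclose(a, b, atol=1e-8)

    def test_single_state_data_gives_identity_row(self):
        model = rf.builtin_model("pretrans3")
        rng = np.random.default_rng(4)
        seqs = [rng.normal(0.72, 0.05, 300) for _ in range(12)]
        fit = fit_transitions(seqs, model)
        c = model.state_index("classical")
        assert fit.model.transmat[c, c] > 0.98
        assert fit.occupancy[c] > 0.95
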