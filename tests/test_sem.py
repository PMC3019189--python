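"""Forward algorithm, posterior sampling and stochastic EM training."""

from collections import Counter

import numpy as np
import pytest
from scipy.stats import chisquare

from hmmtrain.baum_welch import expected_counts_fb
from hmmtrain.core import CountVector, aggregate_counts, update_parameters
from hmmtrain.exact import (
    exact_best_path,
    exact_log_likelihood,
    exact_posterior_paths,
)
from hmmtrain.sem import (
    forward_full,
    sample_path_backtrace,
    sem_counts_linear,
    stochastic_em_train,
)
from hmmtrain.testing import random_model, random_symbols
from hmmtrain.viterbi import UnreachableSequenceError, viterbi_train


class TestForward:
    def test_toy1_single_path_likelihood(self, toy1):
        model, _ = toy1
        assert np.exp(forward_full(model, "AAB").log_prob) == pytest.approx(0.018)

    @pytest.mark.parametrize("case", range(20))
    def test_matches_bruteforce_path_sum(self, case):
        rng = np.random.default_rng(3000 + case)
        model = random_model(rng, int(rng.integers(1, 4)), int(rng.integers(2, 4)))
        x = random_symbols(rng, model, int(rng.integers(1, 9)))
        lp = forward_full(model, x).log_prob
        assert lp == pytest.approx(exact_log_likelihood(model, x), rel=1e-10)

    def test_probability_bounds(self, toy2, rng):
        model, _ = toy2
        for L in (1, 3, 10):
            x = random_symbols(rng, model, L)
            lp = forward_full(model, x).log_prob
            assert lp <= 0.0
            assert lp >= exact_best_path(model, x)[1] - 1e-12

    def test_agrees_with_hmmlearn_on_equal_end_probability(self, toy2):
        """Independent cross-check: with equal End probability tau from
        every emitting state, P(X) = tau (1-tau)^(L-1) P'(X) where P' is
        the End-free chain with renormalised transitions."""
        hmmlearn = pytest.importorskip("hmmlearn.hmm")
        model, _ = toy2
        tau = 0.2
        hm = hmmlearn.CategoricalHMM(n_components=2, n_features=2, init_params="")
        hm.startprob_ = np.array([0.6, 0.4])
        hm.transmat_ = model.trans[1:3, 1:3] / (1 - tau)
        hm.emissionprob_ = model.emit[1:3]
        for x in ("H", "HTH", "TTHHT"):
            obs = model.encode(x).reshape(-1, 1)
            expected = (np.log(tau) + (len(x) - 1) * np.log(1 - tau)
                        + hm.score(obs))
            assert forward_full(model, x).log_prob == pytest.approx(expected,
                                                                    rel=1e-10)

    def test_unreachable_raises(self, toy1):
        model, _ = toy1
        bad = model.copy()
        bad.emit[1] = [1.0, 0.0]
        with pytest.raises(UnreachableSequenceError):
            forward_full(bad, "AB")


class TestBacktraceSampler:
    def test_point_mass_posterior(self, toy1, rng):
        model, _ = toy1
        fwd = forward_full(model, "AAB")
        for _ in range(5):
            p = sample_path_backtrace(model, "AAB", fwd, rng)
            assert p.states.tolist() == [0, 1, 1, 1, 2]
            assert np.exp(p.log_prob) == pytest.approx(0.018)

    def test_matches_enumerated_posterior(self, toy2, rng):
        model, _ = toy2
        x = "HT"
        post = exact_posterior_paths(model, x)
        fwd = forward_full(model, x)
        n = 20_000
        counts = Counter(tuple(sample_path_backtrace(model, x, fwd, rng)
                               .emitting_states.tolist()) for _ in range(n))
        paths = sorted(post)
        obs = np.array([counts.get(p, 0) for p in paths], dtype=float)
        exp = np.array([post[p] for p in paths]) * n
        assert chisquare(obs, f_exp=exp).pvalue > 0.001

    def test_zero_forward_states_never_selected(self, rng):
        # state 2 cannot emit 'a': never on a sampled path for 'aaa'
        model = random_model(rng, 2, 2)
        model.emit[2] = [0.0, 1.0]
        fwd = forward_full(model, "aaa")
        for _ in range(50):
            p = sample_path_backtrace(model, "aaa", fwd, rng)
            assert 2 not in p.emitting_states


class TestLinearSampler:
    def test_point_mass_chains_identical(self, toy1):
        model, _ = toy1
        cvs, log_p = sem_counts_linear(model, "AAB", K=3, seed=99)
        assert np.exp(log_p) == pytest.approx(0.018)
        for cv in cvs:
            assert cv.trans[1, 1] == 2 and cv.trans[1, 2] == 1
            assert cv.emit[1, 0] == 2 and cv.emit[1, 1] == 1

    def test_reported_likelihood_matches_forward(self, rng):
        for _ in range(10):
            model = random_model(rng, int(rng.integers(1, 5)),
                                 int(rng.integers(2, 4)))
            x = random_symbols(rng, model, int(rng.integers(1, 30)))
            _, log_p = sem_counts_linear(model, x, K=2,
                                         seed=int(rng.integers(2 ** 31)))
            assert log_p == pytest.approx(forward_full(model, x).log_prob,
                                          rel=1e-10)

    def test_count_vector_distribution_matches_posterior(self, toy2):
        """Theorem-2 check at unit scale: the sampled count vectors follow
        the exact enumerated posterior over paths."""
        model, _ = toy2
        x = "HT"
        post = exact_posterior_paths(model, x)
        obs_idx = model.encode(x)
        sig_prob: dict[tuple, float] = {}
        for states, p in post.items():
            cv = CountVector.from_path(model, (0,) + states + (3,), obs_idx)
            sig = (tuple(cv.trans.ravel()), tuple(cv.emit.ravel()))
            sig_prob[sig] = sig_prob.get(sig, 0.0) + p
        n = 20_000
        counts: Counter = Counter()
        for chunk in range(4):
            cvs, _ = sem_counts_linear(model, x, K=n // 4, seed=500 + chunk)
            for cv in cvs:
                counts[(tuple(cv.trans.ravel()), tuple(cv.emit.ravel()))] += 1
        assert set(counts) <= set(sig_prob)
        sigs = sorted(sig_prob)
        obs = np.array([counts.get(s, 0) for s in sigs], dtype=float)
        exp = np.array([sig_prob[s] for s in sigs]) * n
        assert chisquare(obs, f_exp=exp).pvalue > 0.001

    def test_chain_mean_matches_forward_backward_expectation(self, toy2):
        model, _ = toy2
        x = "HTH"
        ref, _ = expected_counts_fb(model, x)
        K = 4000
        cvs, _ = sem_counts_linear(model, x, K=K, seed=7)
        mean_t = np.mean([cv.trans for cv in cvs], axis=0)
        mean_e = np.mean([cv.emit for cv in cvs], axis=0)
        # per-entry Monte-Carlo error << 0.05 at K=4000
        assert np.abs(mean_t - ref.trans).max() < 0.05
        assert np.abs(mean_e - ref.emit).max() < 0.05

    def test_seed_reproducibility(self, toy2):
        model, _ = toy2
        a, lp_a = sem_counts_linear(model, "HTHT", K=3, seed=11)
        b, lp_b = sem_counts_linear(model, "HTHT", K=3, seed=11)
        assert lp_a == lp_b
        for ca, cb in zip(a, b):
            assert np.array_equal(ca.trans, cb.trans)
            assert np.array_equal(ca.emit, cb.emit)


class TestStochasticEMTraining:
    def test_point_mass_equals_viterbi_fixed_point(self, toy1):
        model, par = toy1
        data = ["AAB", "ABBA", "BA"]
        sem_run = stochastic_em_train(model, par, data, n_paths=1, max_iter=5,
                                      tol=0.0, seed=1)
        vit_run = viterbi_train(model, par, data, max_iter=5)
        assert sem_run.final_values == pytest.approx(vit_run.final_values)

    def test_same_seed_same_run(self, toy2, rng):
        model, par = toy2
        data = [random_symbols(rng, model, 20) for _ in range(5)]
        runs = [stochastic_em_train(model, par, data, n_paths=3, max_iter=6,
                                    tol=0.0, seed=42) for _ in range(2)]
        assert runs[0].final_values == runs[1].final_values
        assert runs[0].log_scores == runs[1].log_scores

    def test_one_iteration_matches_two_step_reference_in_expectation(self, toy2):
        """One linear-pass SEM update agrees in expectation with a two-step
        (full forward matrix + stochastic back-tracing) update over
        replicate runs."""
        model, par = toy2
        data = ["HTHHT", "TTHTH", "HHHTT"]
        reps = 400
        key = "trans_A/to_B"
        lin, two = [], []
        rng = np.random.default_rng(8)
        for r in range(reps):
            total = CountVector.zeros(model)
            for i, x in enumerate(data):
                cvs, _ = sem_counts_linear(model, x, K=1, seed=10_000 + r * 31 + i)
                total += cvs[0]
            lin.append(update_parameters(aggregate_counts(total, par), par, 1.0)[key])
            total = CountVector.zeros(model)
            for x in data:
                fwd = forward_full(model, x)
                p = sample_path_backtrace(model, x, fwd, rng)
                total += CountVector.from_path(model, p.states, model.encode(x))
            two.append(update_parameters(aggregate_counts(total, par), par, 1.0)[key])
        se = np.sqrt(np.var(lin) / reps + np.var(two) / reps)
        assert abs(np.mean(lin) - np.mean(two)) < 5 * se + 1e-9

    def test_loglik_tolerance_stops(self, toy1):
        model, par = toy1
        run = stochastic_em_train(model, par, ["AAB", "ABA"], n_paths=1,
                                  max_iter=50, tol=1e-6, seed=2)
        assert run.stop_reason == "loglik_converged"
        assert run.n_iter < 50

    def test_invalid_k_rejected(self, toy1):
        model, par = toy1
        with pytest.raises(ValueError):
            sem_counts_linear(model, "AAB", K=0, seed=1)
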