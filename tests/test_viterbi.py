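"""Viterbi decoding and training: oracle equivalence and brute force."""

import numpy as np
import pytest

from hmmtrain.core import CountVector, HmmModel, aggregate_counts, update_parameters
from hmmtrain.exact import exact_best_path
from hmmtrain.testing import random_model, random_symbols
from hmmtrain.viterbi import (
    UnreachableSequenceError,
    viterbi_counts_linear,
    viterbi_full,
    viterbi_train,
)


class TestViterbiDecoding:
    def test_toy1_unique_path(self, toy1):
        model, _ = toy1
        vp = viterbi_full(model, "AAB")
        assert vp.states.tolist() == [0, 1, 1, 1, 2]
        assert np.exp(vp.log_prob) == pytest.approx(0.018)

    def test_toy2_matches_enumeration(self, toy2):
        model, _ = toy2
        for x in ("HH", "HT", "TTH", "HTHT"):
            _, best_lp = exact_best_path(model, x)
            assert viterbi_full(model, x).log_prob == pytest.approx(best_lp, abs=1e-10)

    def test_all_ties_choose_lowest_state_index(self):
        # two interchangeable states: every path has equal probability
        trans = np.array([[0, .5, .5, 0], [0, .4, .4, .2],
                          [0, .4, .4, .2], [0, 0, 0, 0.]])
        emit = np.array([[0, 0], [.5, .5], [.5, .5], [0, 0.]])
        model = HmmModel(["Start", "P", "Q", "End"], ["x", "y"], trans, emit)
        vp = viterbi_full(model, "xyx")
        assert vp.emitting_states.tolist() == [1, 1, 1]
        cv, _ = viterbi_counts_linear(model, "xyx")
        assert cv.trans[1, 1] == 2 and cv.trans[0, 1] == 1 and cv.trans[1, 3] == 1

    def test_unreachable_sequence_raises(self):
        trans = np.array([[0, 1, 0], [0, .5, .5], [0, 0, 0.]])
        emit = np.array([[0, 0], [1.0, 0.0], [0, 0.]])
        model = HmmModel(["Start", "S", "End"], ["a", "b"], trans, emit)
        with pytest.raises(UnreachableSequenceError):
            viterbi_full(model, "ab")
        with pytest.raises(UnreachableSequenceError):
            viterbi_counts_linear(model, "ab")


class TestLinearCountsOracle:
    def test_toy1_counts(self, toy1):
        model, _ = toy1
        cv, log_v = viterbi_counts_linear(model, "AAB")
        assert cv.trans[0, 1] == 1 and cv.trans[1, 1] == 2 and cv.trans[1, 2] == 1
        assert cv.emit[1, 0] == 2 and cv.emit[1, 1] == 1
        assert np.exp(log_v) == pytest.approx(0.018)

    @pytest.mark.parametrize("case", range(60))
    def test_counts_equal_traceback_counting(self, case):
        """Theorem-1 check: one-pass counts == counting along the traceback
        path, exactly, on random HMMs."""
        rng = np.random.default_rng(1000 + case)
        model = random_model(rng, int(rng.integers(1, 6)), int(rng.integers(2, 5)))
        x = random_symbols(rng, model, int(rng.integers(1, 51)))
        vp = viterbi_full(model, x)
        ref = CountVector.from_path(model, vp.states, model.encode(x))
        cv, log_v = viterbi_counts_linear(model, x)
        assert np.array_equal(cv.trans, ref.trans)
        assert np.array_equal(cv.emit, ref.emit)
        assert log_v == pytest.approx(vp.log_prob, abs=1e-10)

    @pytest.mark.parametrize("case", range(20))
    def test_value_is_bruteforce_maximum(self, case):
        rng = np.random.default_rng(2000 + case)
        model = random_model(rng, int(rng.integers(1, 4)), int(rng.integers(2, 4)))
        x = random_symbols(rng, model, int(rng.integers(1, 9)))
        _, best_lp = exact_best_path(model, x)
        _, log_v = viterbi_counts_linear(model, x)
        assert log_v == pytest.approx(best_lp, abs=1e-10)

    def test_count_totals(self, toy2, rng):
        model, _ = toy2
        for L in (1, 7, 40):
            x = random_symbols(rng, model, L)
            cv, _ = viterbi_counts_linear(model, x)
            assert cv.total_transitions() == L + 1
            assert cv.total_emissions() == L


class TestViterbiTraining:
    def test_toy1_one_step_fixed_point(self, toy1, rng):
        """A single-path model: emission estimates are the empirical symbol
        frequencies plus pseudocounts after one iteration, then fixed."""
        model, par = toy1
        data = ["AAB", "ABAB", "BBBAA"]
        n_a = sum(s.count("A") for s in data)
        n_b = sum(s.count("B") for s in data)
        run = viterbi_train(model, par, data, max_iter=10, pseudocount=1.0)
        want_a = (n_a + 1) / (n_a + n_b + 2)
        assert run.records[0].values["emit_S/A"] == pytest.approx(want_a)
        assert run.stop_reason == "counts_unchanged"
        assert run.records[-1].values == run.records[-2].values

    def test_zero_max_iter_rejected(self, toy1):
        model, par = toy1
        with pytest.raises(ValueError):
            viterbi_train(model, par, ["AAB"], max_iter=0)

    def test_empty_dataset_rejected(self, toy1):
        model, par = toy1
        with pytest.raises(ValueError):
            viterbi_train(model, par, [])

    def test_matches_two_step_reference_loop(self, toy2, rng):
        """The linear training loop reproduces a reference loop built on
        full-matrix Viterbi + explicit path counting, iteration by
        iteration."""
        model, par = toy2
        data = [random_symbols(rng, model, 30) for _ in range(10)]
        run = viterbi_train(model, par, data, max_iter=8, pseudocount=1.0)

        ref_model = model
        for rec in run.records:
            total = CountVector.zeros(ref_model)
            for x in data:
                vp = viterbi_full(ref_model, x)
                total += CountVector.from_path(ref_model, vp.states,
                                               ref_model.encode(x))
            vals = update_parameters(aggregate_counts(total, par), par, 1.0)
            assert vals == pytest.approx(rec.values)
            ref_model = par.build_model(vals, ref_model)

    def test_strict_path_identity_stop(self, toy2, rng):
        model, par = toy2
        data = [random_symbols(rng, model, 25) for _ in range(6)]
        run = viterbi_train(model, par, data, max_iter=30,
                            strict_path_identity=True)
        assert run.stop_reason in ("paths_unchanged", "max_iterations")
        if run.stop_reason == "paths_unchanged":
            # parameters at the stop are a fixed point of the update
            again = viterbi_train(run.final_model, par, data, max_iter=1)
            assert again.final_values == pytest.approx(run.final_values)

    def test_updated_models_always_valid(self, toy2, rng):
        from hmmtrain.core import validate_model
        model, par = toy2
        data = [random_symbols(rng, model, 20) for _ in range(5)]
        run = viterbi_train(model, par, data, max_iter=5)
        assert validate_model(run.final_model) == []
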