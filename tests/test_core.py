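"""Model validation, parameter updates, initialization and simulation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hmmtrain.core import (
    Coord,
    CountVector,
    FactorGroup,
    HmmModel,
    Member,
    Parameterization,
    aggregate_counts,
    random_initialize,
    simulate_sequence,
    update_parameters,
    validate_model,
)


# --------------------------------------------------------------------------
# validate_model
# --------------------------------------------------------------------------

class TestValidateModel:
    def test_builders_produce_valid_models(self, toy1, toy2, casino,
                                           extended_casino, cpg):
        for model, _ in (toy1, toy2, casino, extended_casino, cpg):
            assert validate_model(model) == []

    def test_bad_row_sum_reported(self, toy1):
        model = toy1[0].copy()
        model.trans[1, 1] = 0.7  # row now sums to 1.1
        issues = validate_model(model)
        assert len(issues) == 1 and "sums to" in issues[0]

    def test_transition_into_start_reported(self, toy1):
        model = toy1[0].copy()
        model.trans[1, 0] = 0.0001
        assert any("into Start" in v for v in validate_model(model))

    def test_transition_out_of_end_reported(self, toy1):
        model = toy1[0].copy()
        model.trans[2, 1] = 0.5
        assert any("out of End" in v for v in validate_model(model))


# --------------------------------------------------------------------------
# update_parameters
# --------------------------------------------------------------------------

def _two_member_par(const=1.0):
    g = FactorGroup("g", [Member("a"), Member("b")], kind="transition")
    par = Parameterization(
        groups={"g": g},
        trans_coords={(1, 1): Coord(const, [("g", "a")]),
                      (1, 2): Coord(const, [("g", "b")])},
        emit_coords={(1, 0): Coord(1.0)},
    )
    return par


class TestUpdateParameters:
    def test_counts_plus_pseudocount_normalised(self):
        par = _two_member_par()
        vals = update_parameters({"g/a": 2, "g/b": 6}, par, pseudocount=1)
        assert vals == {"g/a": pytest.approx(0.3), "g/b": pytest.approx(0.7)}

    def test_zero_counts_give_uniform_with_pseudocounts(self):
        par = _two_member_par()
        vals = update_parameters({"g/a": 0, "g/b": 0}, par, pseudocount=1)
        assert vals == {"g/a": pytest.approx(0.5), "g/b": pytest.approx(0.5)}

    def test_fixed_remainder_split_by_counts(self):
        # fixed probability 0.1 stays; the remaining 0.9 splits 4:4
        par = _two_member_par(const=0.9)
        par.trans_coords[(1, 3)] = Coord(0.1)
        vals = update_parameters({"g/a": 4, "g/b": 4}, par, pseudocount=0)
        model = HmmModel(["Start", "S", "T", "End"], ["x", "y"],
                         np.zeros((4, 4)), np.zeros((4, 2)))
        built = par.build_model(vals, model)
        assert built.trans[1, 1] == pytest.approx(0.45)
        assert built.trans[1, 2] == pytest.approx(0.45)
        assert built.trans[1, 3] == pytest.approx(0.1)

    def test_all_zero_without_pseudocount_raises(self):
        par = _two_member_par()
        with pytest.raises(ZeroDivisionError):
            update_parameters({"g/a": 0, "g/b": 0}, par, pseudocount=0)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.lists(st.floats(min_value=0, max_value=1e6), min_size=2,
                    max_size=6), st.floats(min_value=0.01, max_value=10))
    def test_updated_groups_always_normalised(self, counts, pc):
        members = [Member(f"m{i}") for i in range(len(counts))]
        par = Parameterization(
            groups={"g": FactorGroup("g", members, kind="emission")},
            trans_coords={}, emit_coords={
                (1, i): Coord(1.0, [("g", f"m{i}")]) for i in range(len(counts))})
        vals = update_parameters(
            {f"g/m{i}": c for i, c in enumerate(counts)}, par, pc)
        assert sum(vals.values()) == pytest.approx(1.0)
        assert all(v > 0 for v in vals.values())


# --------------------------------------------------------------------------
# random_initialize
# --------------------------------------------------------------------------

class TestRandomInitialize:
    def test_reproducible(self, casino):
        _, par = casino
        a = random_initialize(par, np.random.default_rng(5))
        b = random_initialize(par, np.random.default_rng(5))
        assert a == b

    def test_groups_sum_to_one_and_model_valid(self, cpg, rng):
        model, par = cpg
        vals = random_initialize(par, rng)
        par.check_values(vals)
        built = par.build_model(vals, model)
        assert validate_model(built) == []

    def test_flat_marginal_mean(self, rng):
        # flat on the 2-simplex: first coordinate ~ Beta(1,1), mean 1/2
        par = _two_member_par()
        n = 10_000
        draws = [random_initialize(par, rng)["g/a"] for _ in range(n)]
        se = np.sqrt(1 / 12 / n)
        assert abs(np.mean(draws) - 0.5) < 3 * se


# --------------------------------------------------------------------------
# aggregate_counts
# --------------------------------------------------------------------------

class TestAggregateCounts:
    def test_tied_coordinates_pool(self, extended_casino):
        model, par = extended_casino
        cv = CountVector.zeros(model)
        cv.emit[1, 2] = 2  # F1 reads '3'
        cv.emit[2, 2] = 5  # F2 reads '3'
        agg = aggregate_counts(cv, par)
        assert agg["emit_F/3"] == 7

    def test_empty_counts_all_zero(self, casino):
        model, par = casino
        agg = aggregate_counts(CountVector.zeros(model), par)
        assert set(agg.values()) == {0.0}

    def test_per_group_mass_conservation(self, cpg, rng):
        model, par = cpg
        cv = CountVector.zeros(model)
        cv.trans = rng.random(cv.trans.shape) * (model.trans > 0)
        cv.emit = rng.random(cv.emit.shape) * (model.emit > 0)
        agg = aggregate_counts(cv, par)
        for g in par.groups.values():
            member_total = sum(agg[par.key(g.name, m.name)] for m in g.members)
            coord_total = 0.0
            for coords, table in ((par.trans_coords, cv.trans),
                                  (par.emit_coords, cv.emit)):
                for c, coord in coords.items():
                    if any(gn == g.name for gn, _ in coord.factors):
                        coord_total += table[c]
            assert member_total == pytest.approx(coord_total)

    def test_counts_on_fixed_coordinates_are_dropped(self, casino):
        model, par = casino
        cv = CountVector.zeros(model)
        cv.trans[1, 3] = 11  # F -> End is fixed
        agg = aggregate_counts(cv, par)
        assert set(agg.values()) == {0.0}


# --------------------------------------------------------------------------
# simulation
# --------------------------------------------------------------------------

class TestSimulate:
    def test_toy1_labels_single_state(self, toy1, rng):
        model, _ = toy1
        seq = simulate_sequence(model, rng)
        assert set(seq.labels.tolist()) == {1}
        assert set(seq.symbols) <= {"A", "B"}

    def test_forced_length_one(self):
        model = HmmModel(["Start", "S", "End"], ["A", "B"],
                         np.array([[0, 1, 0], [0, 0, 1], [0, 0, 0.]]),
                         np.array([[0, 0], [0.5, 0.5], [0, 0.]]))
        rng = np.random.default_rng(0)
        for _ in range(10):
            assert len(simulate_sequence(model, rng)) == 1

    def test_start_state_frequency_matches_binomial(self, toy2, rng):
        model, _ = toy2
        n = 100_000
        first = sum(simulate_sequence(model, rng).labels[0] == 1
                    for _ in range(n))
        se = np.sqrt(0.6 * 0.4 / n)
        assert abs(first / n - 0.6) < 3 * se

    def test_emission_conditionals_match_model(self, toy2, rng):
        from scipy.stats import chisquare
        model, _ = toy2
        counts = np.zeros((2, 2))  # state (A, B) x symbol (H, T)
        total = 0
        while total < 100_000:
            seq = simulate_sequence(model, rng)
            obs = model.encode(seq.symbols)
            for s, y in zip(seq.labels, obs):
                counts[s - 1, y] += 1
            total += len(seq)
        for row, probs in zip(counts, ([0.8, 0.2], [0.3, 0.7])):
            p = chisquare(row, f_exp=row.sum() * np.array(probs)).pvalue
            assert p > 0.001

    def test_exact_length_conditioning(self, toy1, rng):
        model, _ = toy1
        for _ in range(5):
            assert len(simulate_sequence(model, rng, exact_length=7)) == 7

    def test_retry_budget_exhaustion_raises(self, toy1, rng):
        model, _ = toy1
        with pytest.raises(RuntimeError, match="retry budget"):
            # probability of an exact 400-length path is ~0.6^400
            simulate_sequence(model, rng, exact_length=400, max_tries=50)

    def test_path_count_totals(self, toy2, rng):
        model, _ = toy2
        seq = simulate_sequence(model, rng)
        obs = model.encode(seq.symbols)
        path = [model.start] + seq.labels.tolist() + [model.end]
        cv = CountVector.from_path(model, path, obs)
        assert cv.total_transitions() == len(seq) + 1
        assert cv.total_emissions() == len(seq)
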