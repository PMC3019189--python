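"""Builders for the example HMMs, toy fixtures and the dataset generator.

Three study models:

* **dishonest casino** — fair (F) and loaded (L) die states over symbols
  1..6; 8 structural transitions, 12 emissions, 12 free parameters.
* **extended dishonest casino** — the loaded die is used in multiples of
  two and the fair die in multiples of three (wait chains F1-F2-F3 and
  L1-L2 with tied emissions); 7 states, 11 transitions, 30 emissions,
  12 free parameters.
* **CpG island model** — two fully connected 4-state blocks (+ inside,
  - outside CpG islands) with delta-function emissions; 10 states, 80
  transitions; transitions are parameterized as a shared fixed End
  probability, per-block switch probabilities and per-source-base
  next-base distributions of the destination block.

The generating ("true") parameter values are package defaults (the models'
published descriptions are structural only) and every value can be
overridden.
"""

from __future__ import annotations

import numpy as np

from .core import (
    DERIVED,
    FREE,
    Coord,
    FactorGroup,
    HmmModel,
    LabeledDataset,
    Member,
    Parameterization,
    child_seed,
    simulate_sequence,
)

__all__ = [
    "build_dishonest_casino",
    "build_extended_casino",
    "build_cpg_model",
    "build_toy1",
    "build_toy2",
    "get_model",
    "generate_dataset",
    "MODEL_BUILDERS",
]

DICE = ["1", "2", "3", "4", "5", "6"]

# Mean sequence length under the default End probabilities is a few
# thousand symbols, commensurate with the 5000-symbol study datasets.
CASINO_END_PROB = 0.0004
EXTENDED_END_PROB = 0.001
CPG_END_PROB = 0.0004

# Default within-block next-base conditionals: the classic CpG-island
# transition frequencies (CpG-enriched '+' block, CG-depleted '-' block),
# normalised to exact row sums.
CPG_PLUS_ROWS = {
    "A": [0.180, 0.274, 0.426, 0.120],
    "C": [0.171, 0.368, 0.274, 0.188],
    "G": [0.161, 0.339, 0.375, 0.125],
    "T": [0.079, 0.355, 0.384, 0.182],
}
CPG_MINUS_ROWS = {
    "A": [0.300, 0.205, 0.285, 0.210],
    "C": [0.322, 0.298, 0.078, 0.302],
    "G": [0.248, 0.246, 0.298, 0.208],
    "T": [0.177, 0.239, 0.292, 0.292],
}
CPG_SWITCH = {"plus": 0.005, "minus": 0.0025}


def _finalize(states, alphabet, codes, groups, trans_coords, emit_coords,
              default_values, relabelings, true_params):
    par = Parameterization(groups={g.name: g for g in groups},
                           trans_coords=trans_coords, emit_coords=emit_coords,
                           default_values=default_values,
                           relabelings=relabelings)
    problems = par.validate()
    if problems:
        raise AssertionError(f"builder produced invalid parameterization: {problems}")
    if true_params:
        par.default_values = _apply_overrides(par, true_params)
    S, A = len(states), len(alphabet)
    template = HmmModel(states, alphabet, np.zeros((S, S)), np.zeros((S, A)), codes)
    model = par.build_model(par.default_values, template)
    return model, par


def _apply_overrides(par: Parameterization, overrides: dict[str, float]):
    """Override member values ("group/member": value); members of an
    affected group that are not overridden are rescaled to fill the
    remainder, so every group still sums to 1."""
    values = dict(par.default_values)
    all_keys = {par.key(g.name, m.name) for g in par.groups.values() for m in g.members}
    bad = set(overrides) - all_keys
    if bad:
        raise KeyError(f"unknown parameter name(s): {sorted(bad)}")
    touched = {k.split("/", 1)[0] for k in overrides}
    for k, v in overrides.items():
        if not (0.0 <= float(v) <= 1.0):
            raise ValueError(f"override {k}={v} outside [0, 1]")
        values[k] = float(v)
    for gname in touched:
        g = par.groups[gname]
        keys = [par.key(gname, m.name) for m in g.members]
        fixed = [k for k in keys if k in overrides]
        rest = [k for k in keys if k not in overrides]
        fixed_sum = sum(values[k] for k in fixed)
        if fixed_sum > 1.0 + 1e-12:
            raise ValueError(f"overrides for group {gname} sum to {fixed_sum} > 1")
        rest_sum = sum(values[k] for k in rest)
        remainder = 1.0 - fixed_sum
        if rest:
            if rest_sum <= 0:
                for k in rest:
                    values[k] = remainder / len(rest)
            else:
                for k in rest:
                    values[k] *= remainder / rest_sum
        elif abs(fixed_sum - 1.0) > 1e-9:
            raise ValueError(f"full override of group {gname} must sum to 1")
    return values


# --------------------------------------------------------------------------
# dishonest casino
# --------------------------------------------------------------------------

def build_dishonest_casino(true_params: dict[str, float] | None = None,
                           end_prob: float = CASINO_END_PROB):
    """Fair/loaded die HMM: Start, F, L, End over symbols 1..6.

    Start->F/L and ->End probabilities are fixed; the two die-switch
    probabilities and 2 x 5 emission values are free (12 free parameters).
    """
    states = ["Start", "F", "L", "End"]
    codes = ["", "F", "L", ""]
    tau = end_prob
    groups = []
    trans_coords = {}
    emit_coords = {}
    defaults = {}
    for idx, s in ((1, "F"), (2, "L")):
        groups.append(FactorGroup(f"trans_{s}",
                                  [Member("switch", FREE), Member("stay", DERIVED)],
                                  kind="transition"))
        other = 2 if s == "F" else 1
        trans_coords[(idx, other)] = Coord(1.0 - tau, [(f"trans_{s}", "switch")])
        trans_coords[(idx, idx)] = Coord(1.0 - tau, [(f"trans_{s}", "stay")])
        trans_coords[(idx, 3)] = Coord(tau)
        members = [Member(y, FREE) for y in DICE[:-1]] + [Member("6", DERIVED)]
        groups.append(FactorGroup(f"emit_{s}", members, kind="emission"))
        for y_i, y in enumerate(DICE):
            emit_coords[(idx, y_i)] = Coord(1.0, [(f"emit_{s}", y)])
    trans_coords[(0, 1)] = Coord(0.5)
    trans_coords[(0, 2)] = Coord(0.5)
    defaults.update({"trans_F/switch": 0.05, "trans_F/stay": 0.95,
                     "trans_L/switch": 0.10, "trans_L/stay": 0.90})
    for y in DICE:
        defaults[f"emit_F/{y}"] = 1.0 / 6.0
        defaults[f"emit_L/{y}"] = 0.5 if y == "6" else 0.1
    swap = {}
    for a, b in (("F", "L"), ("L", "F")):
        swap[f"trans_{a}/switch"] = f"trans_{b}/switch"
        swap[f"trans_{a}/stay"] = f"trans_{b}/stay"
        for y in DICE:
            swap[f"emit_{a}/{y}"] = f"emit_{b}/{y}"
    return _finalize(states, DICE, codes, groups, trans_coords, emit_coords,
                     defaults, [swap], true_params)


# --------------------------------------------------------------------------
# extended dishonest casino
# --------------------------------------------------------------------------

def build_extended_casino(true_params: dict[str, float] | None = None,
                          end_prob: float = EXTENDED_END_PROB):
    """Wait-chain casino: fair die in multiples of three, loaded die in
    multiples of two.  Emissions are tied along each chain, so the free
    parameters are the same 12 as for the plain casino.
    """
    states = ["Start", "F1", "F2", "F3", "L1", "L2", "End"]
    codes = ["", "F", "G", "H", "L", "M", ""]
    F1, F2, F3, L1, L2, END = 1, 2, 3, 4, 5, 6
    tau = end_prob
    groups = [
        FactorGroup("trans_F", [Member("switch", FREE), Member("stay", DERIVED)],
                    kind="transition"),
        FactorGroup("trans_L", [Member("switch", FREE), Member("stay", DERIVED)],
                    kind="transition"),
        FactorGroup("emit_F", [Member(y, FREE) for y in DICE[:-1]]
                    + [Member("6", DERIVED)], kind="emission"),
        FactorGroup("emit_L", [Member(y, FREE) for y in DICE[:-1]]
                    + [Member("6", DERIVED)], kind="emission"),
    ]
    trans_coords = {
        (0, F1): Coord(0.5),
        (0, L1): Coord(0.5),
        (F1, F2): Coord(1.0),
        (F2, F3): Coord(1.0),
        (L1, L2): Coord(1.0),
        (F3, L1): Coord(1.0 - tau, [("trans_F", "switch")]),
        (F3, F1): Coord(1.0 - tau, [("trans_F", "stay")]),
        (F3, END): Coord(tau),
        (L2, F1): Coord(1.0 - tau, [("trans_L", "switch")]),
        (L2, L1): Coord(1.0 - tau, [("trans_L", "stay")]),
        (L2, END): Coord(tau),
    }
    emit_coords = {}
    for idx in (F1, F2, F3):
        for y_i, y in enumerate(DICE):
            emit_coords[(idx, y_i)] = Coord(1.0, [("emit_F", y)])
    for idx in (L1, L2):
        for y_i, y in enumerate(DICE):
            emit_coords[(idx, y_i)] = Coord(1.0, [("emit_L", y)])
    defaults = {"trans_F/switch": 0.05, "trans_F/stay": 0.95,
                "trans_L/switch": 0.10, "trans_L/stay": 0.90}
    for y in DICE:
        defaults[f"emit_F/{y}"] = 1.0 / 6.0
        defaults[f"emit_L/{y}"] = 0.5 if y == "6" else 0.1
    # the two chains have different lengths: no relabelling symmetry
    return _finalize(states, DICE, codes, groups, trans_coords, emit_coords,
                     defaults, [], true_params)


# --------------------------------------------------------------------------
# CpG island model
# --------------------------------------------------------------------------

def build_cpg_model(true_params: dict[str, float] | None = None,
                    end_prob: float = CPG_END_PROB):
    """Two-block CpG-island HMM over A, C, G, T with delta emissions.

    Every emitting state is connected to every emitting state (80
    structural transitions including Start and End edges).  A transition
    from state ``u`` to ``v`` factorises as
    ``(1 - tau) * switch-or-stay(block u -> block v) * row_{block v}(base u -> base v)``
    with ``tau`` the shared fixed End probability; cross-block moves use
    the destination block's next-base row for the source base.  Emissions
    are fixed delta functions and are never trained.
    """
    bases = ["A", "C", "G", "T"]
    plus = [f"{b}+" for b in bases]
    minus = [f"{b}-" for b in bases]
    states = ["Start"] + plus + minus + ["End"]
    codes = [""] + bases + [b.lower() for b in bases] + [""]
    tau = end_prob
    END = len(states) - 1

    def block(i):  # state index -> block name
        return "plus" if 1 <= i <= 4 else "minus"

    def base(i):
        return bases[(i - 1) % 4]

    groups = []
    defaults = {}
    for blk in ("plus", "minus"):
        groups.append(FactorGroup(f"switch_{blk}",
                                  [Member("switch", FREE), Member("stay", DERIVED)],
                                  kind="transition"))
        s = CPG_SWITCH[blk]
        defaults[f"switch_{blk}/switch"] = s
        defaults[f"switch_{blk}/stay"] = 1.0 - s
        rows = CPG_PLUS_ROWS if blk == "plus" else CPG_MINUS_ROWS
        for b in bases:
            members = [Member(t, FREE) for t in bases[:-1]] + [Member("T", DERIVED)]
            groups.append(FactorGroup(f"row_{blk}_{b}", members, kind="transition"))
            row = np.asarray(rows[b], dtype=float)
            row = row / row.sum()
            for t, v in zip(bases, row):
                defaults[f"row_{blk}_{b}/{t}"] = float(v)
    start_states = plus + minus
    groups.append(FactorGroup(
        "start",
        [Member(s, FREE) for s in start_states[:-1]] + [Member(start_states[-1], DERIVED)],
        kind="transition"))
    for s in start_states:
        defaults[f"start/{s}"] = 1.0 / 8.0

    trans_coords = {}
    for i, s in enumerate(start_states, start=1):
        trans_coords[(0, i)] = Coord(1.0, [("start", s)])
    for u in range(1, 9):
        trans_coords[(u, END)] = Coord(tau)
        for v in range(1, 9):
            move = "stay" if block(u) == block(v) else "switch"
            trans_coords[(u, v)] = Coord(
                1.0 - tau,
                [(f"switch_{block(u)}", move),
                 (f"row_{block(v)}_{base(u)}", base(v))])
    emit_coords = {}
    for u in range(1, 9):
        emit_coords[(u, (u - 1) % 4)] = Coord(1.0)  # delta emission, fixed

    swap = {}
    for a, b in (("plus", "minus"), ("minus", "plus")):
        swap[f"switch_{a}/switch"] = f"switch_{b}/switch"
        swap[f"switch_{a}/stay"] = f"switch_{b}/stay"
        for src in bases:
            for t in bases:
                swap[f"row_{a}_{src}/{t}"] = f"row_{b}_{src}/{t}"
    for b in bases:
        swap[f"start/{b}+"] = f"start/{b}-"
        swap[f"start/{b}-"] = f"start/{b}+"
    return _finalize(states, bases, codes, groups, trans_coords, emit_coords,
                     defaults, [swap], true_params)


# --------------------------------------------------------------------------
# toy fixtures
# --------------------------------------------------------------------------

def build_toy1(true_params: dict[str, float] | None = None):
    """Single emitting state over {A, B}: exactly one path per length."""
    states = ["Start", "S", "End"]
    groups = [
        FactorGroup("trans_S", [Member("stay", FREE), Member("end", DERIVED)],
                    kind="transition"),
        FactorGroup("emit_S", [Member("A", FREE), Member("B", DERIVED)],
                    kind="emission"),
    ]
    trans_coords = {(0, 1): Coord(1.0),
                    (1, 1): Coord(1.0, [("trans_S", "stay")]),
                    (1, 2): Coord(1.0, [("trans_S", "end")])}
    emit_coords = {(1, 0): Coord(1.0, [("emit_S", "A")]),
                   (1, 1): Coord(1.0, [("emit_S", "B")])}
    defaults = {"trans_S/stay": 0.6, "trans_S/end": 0.4,
                "emit_S/A": 0.5, "emit_S/B": 0.5}
    return _finalize(states, ["A", "B"], ["", "S", ""], groups,
                     trans_coords, emit_coords, defaults, [], true_params)


def build_toy2(true_params: dict[str, float] | None = None):
    """Two emitting states over {H, T}; all paths enumerable at small L."""
    states = ["Start", "A", "B", "End"]
    groups = [
        FactorGroup("start", [Member("A", FREE), Member("B", DERIVED)],
                    kind="transition"),
        FactorGroup("trans_A", [Member("to_A", FREE), Member("to_B", FREE),
                                Member("end", DERIVED)], kind="transition"),
        FactorGroup("trans_B", [Member("to_A", FREE), Member("to_B", FREE),
                                Member("end", DERIVED)], kind="transition"),
        FactorGroup("emit_A", [Member("H", FREE), Member("T", DERIVED)],
                    kind="emission"),
        FactorGroup("emit_B", [Member("H", FREE), Member("T", DERIVED)],
                    kind="emission"),
    ]
    trans_coords = {
        (0, 1): Coord(1.0, [("start", "A")]),
        (0, 2): Coord(1.0, [("start", "B")]),
        (1, 1): Coord(1.0, [("trans_A", "to_A")]),
        (1, 2): Coord(1.0, [("trans_A", "to_B")]),
        (1, 3): Coord(1.0, [("trans_A", "end")]),
        (2, 1): Coord(1.0, [("trans_B", "to_A")]),
        (2, 2): Coord(1.0, [("trans_B", "to_B")]),
        (2, 3): Coord(1.0, [("trans_B", "end")]),
    }
    emit_coords = {
        (1, 0): Coord(1.0, [("emit_A", "H")]),
        (1, 1): Coord(1.0, [("emit_A", "T")]),
        (2, 0): Coord(1.0, [("emit_B", "H")]),
        (2, 1): Coord(1.0, [("emit_B", "T")]),
    }
    defaults = {
        "start/A": 0.6, "start/B": 0.4,
        "trans_A/to_A": 0.5, "trans_A/to_B": 0.3, "trans_A/end": 0.2,
        "trans_B/to_A": 0.3, "trans_B/to_B": 0.5, "trans_B/end": 0.2,
        "emit_A/H": 0.8, "emit_A/T": 0.2,
        "emit_B/H": 0.3, "emit_B/T": 0.7,
    }
    return _finalize(states, ["H", "T"], ["", "A", "B", ""], groups,
                     trans_coords, emit_coords, defaults, [], true_params)


MODEL_BUILDERS = {
    "dishonest_casino": build_dishonest_casino,
    "extended_casino": build_extended_casino,
    "cpg_island": build_cpg_model,
    "toy1": build_toy1,
    "toy2": build_toy2,
}

_ALIASES = {
    "casino": "dishonest_casino",
    "dishonest-casino": "dishonest_casino",
    "extended-casino": "extended_casino",
    "cpg": "cpg_island",
    "cpg-island": "cpg_island",
}


def get_model(name: str, true_params: dict[str, float] | None = None):
    """Build a registered example model by name; returns (model, parameterization)."""
    key = _ALIASES.get(name, name)
    if key not in MODEL_BUILDERS:
        raise KeyError(f"unknown model {name!r}; known: "
                       f"{sorted(MODEL_BUILDERS) + sorted(_ALIASES)}")
    return MODEL_BUILDERS[key](true_params=true_params)


# --------------------------------------------------------------------------
# dataset generation
# --------------------------------------------------------------------------

def generate_dataset(model: HmmModel, n_sequences: int, length: int,
                     seed: int, name: str = "sim",
                     max_tries: int = 2_000_000) -> LabeledDataset:
    """Simulate ``n_sequences`` labelled sequences of exactly ``length``
    symbols (rejection of paths with any other length).

    Per-sequence seeds derive from ``seed`` and the record index, so the
    dataset is reproducible independently of generation order.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    sequences = []
    for i in range(n_sequences):
        rng = np.random.default_rng(child_seed(seed, 7, i))
        seq = simulate_sequence(model, rng, exact_length=length,
                                max_tries=max_tries)
        seq.id = f"{name}_{i:04d}"
        sequences.append(seq)
    return LabeledDataset(sequences=sequences,
                          metadata={"name": name, "seed": int(seed),
                                    "n_sequences": int(n_sequences),
                                    "length": int(length)})
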