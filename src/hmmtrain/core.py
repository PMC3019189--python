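"""Core HMM data model: states, probabilities, parameter tying and updates.

The package works with first-order hidden Markov models in which state 0 is
a silent ``Start`` state, the last state is a silent ``End`` state and every
other state emits one symbol per step.  A sequence ``x_1..x_L`` is generated
by a state path ``pi_0 = Start, pi_1, ..., pi_L, pi_{L+1} = End``; every
path therefore uses exactly ``L + 1`` transitions and ``L`` emissions.

Trainable structure is described by a :class:`Parameterization`: every
transition/emission probability is either a fixed constant or a product of
a constant and one or more *factor-group members*, where each factor group
is a small probability distribution (its member values sum to 1).  This
covers plain per-row tying (one factor per probability) as well as
structured decompositions such as "block switch probability x next-base
distribution" used by the CpG-island model.  Count-based training updates
each group by normalising pooled counts plus pseudocounts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "HmmModel",
    "Member",
    "FactorGroup",
    "Coord",
    "Parameterization",
    "CountVector",
    "LabeledSequence",
    "LabeledDataset",
    "IterationRecord",
    "TrainingRun",
    "validate_model",
    "simulate_sequence",
    "random_initialize",
    "aggregate_counts",
    "update_parameters",
    "child_seed",
]

ROW_SUM_TOL = 1e-9

FREE = "free"
DERIVED = "derived"
FIXED = "fixed"


# --------------------------------------------------------------------------
# model
# --------------------------------------------------------------------------

@dataclass
class HmmModel:
    """A first-order HMM with silent Start (index 0) and End (last index).

    Parameters
    ----------
    states
        Ordered state names; ``states[0]`` is Start, ``states[-1]`` is End,
        everything in between emits.
    alphabet
        Ordered single-character symbols.
    trans
        ``(S, S)`` transition probability matrix ``t[i, j]``.
    emit
        ``(S, A)`` emission probability matrix ``e[i, y]``; the Start and
        End rows are all zero.
    state_codes
        Optional per-state single characters used in label files; silent
        states may use ``""``.
    """

    states: list[str]
    alphabet: list[str]
    trans: np.ndarray
    emit: np.ndarray
    state_codes: list[str] | None = None

    def __post_init__(self) -> None:
        self.trans = np.asarray(self.trans, dtype=np.float64)
        self.emit = np.asarray(self.emit, dtype=np.float64)
        if self.trans.shape != (self.n_states, self.n_states):
            raise ValueError("trans must be (S, S)")
        if self.emit.shape != (self.n_states, self.n_symbols):
            raise ValueError("emit must be (S, A)")
        if self.state_codes is None:
            self.state_codes = ["" if i in (0, self.end) else self.states[i][0]
                                for i in range(self.n_states)]
        self._sym_index = {s: i for i, s in enumerate(self.alphabet)}
        self._code_index = {c: i for i, c in enumerate(self.state_codes) if c}

    # -- basic structure ---------------------------------------------------
    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def n_symbols(self) -> int:
        return len(self.alphabet)

    @property
    def start(self) -> int:
        return 0

    @property
    def end(self) -> int:
        return self.n_states - 1

    @property
    def emitting(self) -> range:
        return range(1, self.n_states - 1)

    @property
    def t_max(self) -> int:
        """Connectivity: maximum out-degree over states."""
        return int(np.max(np.count_nonzero(self.trans, axis=1)))

    # -- encode / decode ---------------------------------------------------
    def encode(self, symbols: str) -> np.ndarray:
        """Map a symbol string to int indices; raises on unknown symbols."""
        try:
            return np.array([self._sym_index[c] for c in symbols], dtype=np.int64)
        except KeyError as exc:
            bad = exc.args[0]
            pos = next(i for i, c in enumerate(symbols) if c == bad)
            raise ValueError(
                f"symbol {bad!r} at position {pos + 1} is not in the model "
                f"alphabet {self.alphabet}") from None

    def decode_symbols(self, indices: np.ndarray) -> str:
        return "".join(self.alphabet[int(i)] for i in indices)

    def encode_labels(self, codes: str) -> np.ndarray:
        try:
            return np.array([self._code_index[c] for c in codes], dtype=np.int64)
        except KeyError as exc:
            raise ValueError(f"unknown state label character {exc.args[0]!r}") from None

    def decode_labels(self, indices: np.ndarray) -> str:
        return "".join(self.state_codes[int(i)] for i in indices)

    def copy(self) -> "HmmModel":
        return HmmModel(list(self.states), list(self.alphabet),
                        self.trans.copy(), self.emit.copy(),
                        list(self.state_codes))

    def log_trans(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return np.log(self.trans)

    def log_emit(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return np.log(self.emit)


def validate_model(model: HmmModel) -> list[str]:
    """Check structural invariants; returns human-readable violations.

    Reports (never raises): row sums of transitions out of any state with
    at least one outgoing edge, emission row sums of emitting states,
    transitions into Start / out of End, emissions by silent states, and
    negative entries.
    """
    v: list[str] = []
    S = model.n_states
    for i in range(S):
        row = model.trans[i]
        if np.any(row < 0):
            v.append(f"transition row {model.states[i]}: negative entry")
        if np.any(row > 0) and abs(row.sum() - 1.0) > ROW_SUM_TOL:
            v.append(f"transition row {model.states[i]}: sums to {row.sum():.12g}, not 1")
    for i in model.emitting:
        row = model.emit[i]
        if np.any(row < 0):
            v.append(f"emission row {model.states[i]}: negative entry")
        if abs(row.sum() - 1.0) > ROW_SUM_TOL:
            v.append(f"emission row {model.states[i]}: sums to {row.sum():.12g}, not 1")
    if np.any(model.trans[:, model.start] > 0):
        srcs = [model.states[i] for i in np.nonzero(model.trans[:, model.start] > 0)[0]]
        v.append(f"transitions into Start from {srcs}")
    if np.any(model.trans[model.end] > 0):
        v.append("transitions out of End")
    for i in (model.start, model.end):
        if np.any(model.emit[i] != 0):
            v.append(f"silent state {model.states[i]} has emission probability")
    return v


# --------------------------------------------------------------------------
# parameterization
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Member:
    """One outcome of a factor group; ``role`` is ``free`` or ``derived``.

    A ``derived`` member is the remainder of its group (not counted as an
    independent parameter) but is updated from counts like any other.
    """

    name: str
    role: str = FREE


@dataclass
class FactorGroup:
    """A normalised set of members; member values sum to 1.

    ``kind`` is ``"transition"`` or ``"emission"`` and determines which of
    the two convergence metrics the group's free members contribute to.
    """

    name: str
    members: list[Member]
    kind: str = "transition"

    def member_names(self) -> list[str]:
        return [m.name for m in self.members]


@dataclass
class Coord:
    """Parameter structure of one probability coordinate.

    ``value = const * prod(group[member] for group, member in factors)``.
    A coordinate with no factors is FIXED at ``const``.
    """

    const: float = 1.0
    factors: list[tuple[str, str]] = field(default_factory=list)


@dataclass
class Parameterization:
    """Maps every structural probability coordinate to its parameters.

    ``trans_coords[(i, j)]`` / ``emit_coords[(i, y)]`` list the structural
    support of the model; coordinates absent from both maps are
    structurally zero.  ``default_values`` are the generating ("true")
    member values used by the simulator.  ``relabelings`` is the model's
    state-relabelling symmetry group (beyond identity): each element is a
    dict renaming free-member keys, used to align trained with true values
    for convergence metrics.
    """

    groups: dict[str, FactorGroup]
    trans_coords: dict[tuple[int, int], Coord]
    emit_coords: dict[tuple[int, int], Coord]
    default_values: dict[str, float] = field(default_factory=dict)
    relabelings: list[dict[str, str]] = field(default_factory=list)

    # values are flat dicts keyed "group/member"
    @staticmethod
    def key(group: str, member: str) -> str:
        return f"{group}/{member}"

    def free_parameter_names(self) -> list[str]:
        return [self.key(g.name, m.name)
                for g in self.groups.values() for m in g.members if m.role == FREE]

    @property
    def n_free_parameters(self) -> int:
        return len(self.free_parameter_names())

    def coord_role(self, coord: Coord) -> str:
        if not coord.factors:
            return FIXED
        roles = {self._member(g, m).role for g, m in coord.factors}
        return DERIVED if roles == {DERIVED} else FREE

    def _member(self, gname: str, mname: str) -> Member:
        for m in self.groups[gname].members:
            if m.name == mname:
                return m
        raise KeyError(f"no member {mname!r} in group {gname!r}")

    def validate(self) -> list[str]:
        """Internal consistency: factor references exist, coords unique."""
        v = []
        for coords in (self.trans_coords, self.emit_coords):
            for c, coord in coords.items():
                seen_groups = set()
                for g, m in coord.factors:
                    if g not in self.groups:
                        v.append(f"coordinate {c}: unknown group {g!r}")
                        continue
                    if m not in self.groups[g].member_names():
                        v.append(f"coordinate {c}: unknown member {g}/{m}")
                    if g in seen_groups:
                        v.append(f"coordinate {c}: group {g!r} referenced twice")
                    seen_groups.add(g)
                if coord.const < 0:
                    v.append(f"coordinate {c}: negative constant")
        for g in self.groups.values():
            names = g.member_names()
            if len(set(names)) != len(names):
                v.append(f"group {g.name}: duplicate member names")
            if g.kind not in ("transition", "emission"):
                v.append(f"group {g.name}: bad kind {g.kind!r}")
        return v

    # -- values <-> model --------------------------------------------------
    def check_values(self, values: Mapping[str, float]) -> None:
        for g in self.groups.values():
            total = 0.0
            for m in g.members:
                k = self.key(g.name, m.name)
                if k not in values:
                    raise KeyError(f"missing value for {k}")
                if values[k] < 0:
                    raise ValueError(f"negative value for {k}")
                total += values[k]
            if abs(total - 1.0) > ROW_SUM_TOL:
                raise ValueError(
                    f"group {g.name}: member values sum to {total:.12g}, not 1")

    def build_model(self, values: Mapping[str, float] | None,
                    template: HmmModel) -> HmmModel:
        """Fill ``template``'s probability tables from member values."""
        if values is None:
            values = self.default_values
        self.check_values(values)
        model = template.copy()
        model.trans[:] = 0.0
        model.emit[:] = 0.0
        for (i, j), coord in self.trans_coords.items():
            model.trans[i, j] = self._coord_value(coord, values)
        for (i, y), coord in self.emit_coords.items():
            model.emit[i, y] = self._coord_value(coord, values)
        return model

    def _coord_value(self, coord: Coord, values: Mapping[str, float]) -> float:
        p = coord.const
        for g, m in coord.factors:
            p *= values[self.key(g, m)]
        return p


def random_initialize(parameterization: Parameterization,
                      rng: np.random.Generator) -> dict[str, float]:
    """Draw member values flat (Dirichlet with concentration 1) per group.

    Tied coordinates share members, so they automatically receive identical
    values; fixed coordinates (constants) are untouched.  Reproducible:
    the same generator state yields the same values.
    """
    values: dict[str, float] = {}
    for g in parameterization.groups.values():
        draw = rng.dirichlet(np.ones(len(g.members)))
        for m, x in zip(g.members, draw):
            values[parameterization.key(g.name, m.name)] = float(x)
    return values


# --------------------------------------------------------------------------
# counts and updates
# --------------------------------------------------------------------------

@dataclass
class CountVector:
    """Transition and emission usage counts over model coordinates.

    Integer-valued for a single decoded/sampled path (sum of transition
    counts = L + 1, emissions = L); real-valued for posterior expectations.
    """

    trans: np.ndarray  # (S, S)
    emit: np.ndarray   # (S, A)

    @classmethod
    def zeros(cls, model: HmmModel) -> "CountVector":
        return cls(np.zeros((model.n_states, model.n_states)),
                   np.zeros((model.n_states, model.n_symbols)))

    @classmethod
    def from_path(cls, model: HmmModel, path: Sequence[int],
                  obs: np.ndarray) -> "CountVector":
        """Count transitions/emissions along a full Start..End path."""
        cv = cls.zeros(model)
        for a, b in zip(path[:-1], path[1:]):
            cv.trans[a, b] += 1
        emitting = [s for s in path if s not in (model.start, model.end)]
        if len(emitting) != len(obs):
            raise ValueError("path emits a different number of symbols than observed")
        for s, y in zip(emitting, obs):
            cv.emit[s, y] += 1
        return cv

    def __iadd__(self, other: "CountVector") -> "CountVector":
        self.trans += other.trans
        self.emit += other.emit
        return self

    def total_transitions(self) -> float:
        return float(self.trans.sum())

    def total_emissions(self) -> float:
        return float(self.emit.sum())

    def allclose(self, other: "CountVector", atol: float = 0.0) -> bool:
        return (np.allclose(self.trans, other.trans, rtol=0.0, atol=atol)
                and np.allclose(self.emit, other.emit, rtol=0.0, atol=atol))


def aggregate_counts(counts: CountVector,
                     parameterization: Parameterization) -> dict[str, float]:
    """Pool raw coordinate counts onto factor-group members.

    Every coordinate adds its count to each member it references, so tied
    coordinates pool and product coordinates feed every factor.  Counts on
    fixed coordinates attach to no member and do not enter any
    normalisation.  Mass conservation holds per group: the member counts of
    a group sum to the raw counts of the coordinates referencing it.
    """
    agg = {parameterization.key(g.name, m.name): 0.0
           for g in parameterization.groups.values() for m in g.members}
    for (i, j), coord in parameterization.trans_coords.items():
        c = counts.trans[i, j]
        for g, m in coord.factors:
            agg[parameterization.key(g, m)] += c
    for (i, y), coord in parameterization.emit_coords.items():
        c = counts.emit[i, y]
        for g, m in coord.factors:
            agg[parameterization.key(g, m)] += c
    return agg


def update_parameters(agg_counts: Mapping[str, float],
                      parameterization: Parameterization,
                      pseudocount: float = 1.0) -> dict[str, float]:
    """Count-normalisation update: one pseudocount per group member.

    ``value = (count + pseudocount) / sum_group(count + pseudocount)``,
    applied per factor group; fixed constants are untouched (they live in
    the coordinates, not in any group).  Raises if a group's counts plus
    pseudocounts are all zero (nothing to normalise on).
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    values: dict[str, float] = {}
    for g in parameterization.groups.values():
        keys = [parameterization.key(g.name, m.name) for m in g.members]
        w = np.array([float(agg_counts.get(k, 0.0)) + pseudocount for k in keys])
        if np.any(w < 0):
            raise ValueError(f"group {g.name}: negative count")
        total = w.sum()
        if total <= 0:
            raise ZeroDivisionError(
                f"group {g.name}: all counts and pseudocounts are zero; "
                "cannot normalise (use a positive pseudocount)")
        for k, x in zip(keys, w / total):
            values[k] = float(x)
    return values


# --------------------------------------------------------------------------
# sequences and datasets
# --------------------------------------------------------------------------

@dataclass
class LabeledSequence:
    """A symbol string with an optional true emitting-state path."""

    symbols: str
    labels: np.ndarray | None = None  # int state indices, length == len(symbols)
    id: str = ""

    def __post_init__(self) -> None:
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=np.int64)
            if len(self.labels) != len(self.symbols):
                raise ValueError(
                    f"labels length {len(self.labels)} != sequence length "
                    f"{len(self.symbols)}")

    def __len__(self) -> int:
        return len(self.symbols)


@dataclass
class LabeledDataset:
    sequences: list[LabeledSequence]
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sequences)

    def __iter__(self):
        return iter(self.sequences)


# --------------------------------------------------------------------------
# training run bookkeeping
# --------------------------------------------------------------------------

@dataclass
class IterationRecord:
    iteration: int
    log_score: float              # sum over sequences of the iteration's score
    values: dict[str, float]      # member values *after* this iteration's update


@dataclass
class TrainingRun:
    """Per-iteration parameter trajectory and stopping information."""

    records: list[IterationRecord]
    stop_reason: str
    final_model: HmmModel
    init_values: dict[str, float] | None = None
    config: dict = field(default_factory=dict)

    @property
    def n_iter(self) -> int:
        return len(self.records)

    @property
    def final_values(self) -> dict[str, float]:
        return self.records[-1].values

    @property
    def log_scores(self) -> list[float]:
        return [r.log_score for r in self.records]


# --------------------------------------------------------------------------
# simulation
# --------------------------------------------------------------------------

def child_seed(root_seed: int, *key: int) -> int:
    """Deterministic per-purpose child seed (< 2**31) from a root seed.

    Keys identify (purpose, sequence index, iteration, chain ...), so
    replays are independent of evaluation order.
    """
    ss = np.random.SeedSequence([int(root_seed)] + [int(k) for k in key])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2 ** 31))


def simulate_sequence(model: HmmModel, rng: np.random.Generator,
                      max_length: int = 100_000,
                      exact_length: int | None = None,
                      max_tries: int = 1_000_000) -> LabeledSequence:
    """Sample one sequence by ancestral simulation from Start to End.

    Without ``exact_length``, paths longer than ``max_length`` are rejected
    and redrawn.  With ``exact_length``, whole paths are redrawn until one
    emits exactly that many symbols (the model's conditional distribution
    given length), aborting a trial as soon as it overshoots.
    """
    from . import _kernels

    if exact_length is not None and exact_length < 1:
        raise ValueError("exact_length must be >= 1")
    seed = int(rng.integers(2 ** 31))
    cap = exact_length if exact_length is not None else max_length
    states, syms, status = _kernels.simulate(
        model.trans, model.emit, np.int64(-1 if exact_length is None else exact_length),
        np.int64(cap), np.int64(max_tries), np.int64(seed))
    if status == 1:
        raise RuntimeError(
            f"simulation retry budget of {max_tries} trials exhausted "
            f"(End state unreachable at the requested length?)")
    if status == 2:
        raise RuntimeError("model has a state with no outgoing transitions "
                           "on a sampled path")
    return LabeledSequence(symbols=model.decode_symbols(syms), labels=states)
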