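"""Brute-force path enumeration: exact small-scale references.

Enumerates every Start -> emitting^L -> End state path for a sequence,
giving exact joint probabilities, the exact likelihood, the exact maximum
path, the exact posterior over paths and exact posterior-expected counts.
Exponential in L; intended for validating the dynamic-programming passes
on tiny inputs, independently of their implementation.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

from .core import CountVector, HmmModel

__all__ = [
    "enumerate_paths",
    "exact_log_likelihood",
    "exact_best_path",
    "exact_posterior_paths",
    "exact_expected_counts",
]


def _path_log_prob(model: HmmModel, states: tuple[int, ...],
                   obs: np.ndarray) -> float:
    lt = model.log_trans()
    le = model.log_emit()
    full = (model.start,) + states + (model.end,)
    lp = 0.0
    for a, b in zip(full[:-1], full[1:]):
        lp += lt[a, b]
    for s, y in zip(states, obs):
        lp += le[s, y]
    return lp


def enumerate_paths(model: HmmModel, symbols: str):
    """Yield ``(states, log_prob)`` for every emitting-state assignment."""
    obs = model.encode(symbols)
    for states in itertools.product(model.emitting, repeat=len(obs)):
        lp = _path_log_prob(model, states, obs)
        if lp > -math.inf:
            yield states, lp


def exact_log_likelihood(model: HmmModel, symbols: str) -> float:
    """log P(X) by exhaustive path summation."""
    lps = [lp for _, lp in enumerate_paths(model, symbols)]
    if not lps:
        return -math.inf
    m = max(lps)
    return m + math.log(sum(math.exp(lp - m) for lp in lps))


def exact_best_path(model: HmmModel, symbols: str) -> tuple[tuple[int, ...], float]:
    """Max-probability path value and one argmax path (first in
    lexicographic order; under exact ties the identity of the returned
    path may differ from the DP's tie-break, its probability never does).
    """
    best = None
    best_lp = -math.inf
    for states, lp in enumerate_paths(model, symbols):
        if lp > best_lp + 1e-12:
            best, best_lp = states, lp
    if best is None:
        raise ValueError("sequence unreachable under the model")
    return best, best_lp


def exact_posterior_paths(model: HmmModel, symbols: str) -> dict[tuple[int, ...], float]:
    """Exact posterior P(path | X) over all nonzero-probability paths."""
    entries = list(enumerate_paths(model, symbols))
    if not entries:
        raise ValueError("sequence unreachable under the model")
    m = max(lp for _, lp in entries)
    ws = {states: math.exp(lp - m) for states, lp in entries}
    z = sum(ws.values())
    return {states: w / z for states, w in ws.items()}


def exact_expected_counts(model: HmmModel, symbols: str) -> CountVector:
    """Posterior-expected transition/emission counts by enumeration."""
    obs = model.encode(symbols)
    post = exact_posterior_paths(model, symbols)
    out = CountVector.zeros(model)
    for states, p in post.items():
        cv = CountVector.from_path(
            model, (model.start,) + states + (model.end,), obs)
        out.trans += p * cv.trans
        out.emit += p * cv.emit
    return out
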