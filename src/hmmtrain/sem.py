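"""Forward algorithm, posterior path sampling and stochastic EM training.

Stochastic EM re-estimates parameters from the counts of K state paths
sampled per sequence from the posterior P(path | X).  The classical route
computes the full scaled forward matrix and stochastically backtracks
through it; the linear-memory route samples a previous state at every
(position, state) cell while the forward column advances, propagating
per-current-state cumulative count tables — one table set per chain — so
retained memory is independent of the sequence length.  The two routes
are equivalent in distribution (not draw-for-draw: they consume
randomness differently).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .core import (
    CountVector,
    HmmModel,
    IterationRecord,
    LabeledSequence,
    Parameterization,
    TrainingRun,
    aggregate_counts,
    child_seed,
    update_parameters,
)
from .viterbi import UnreachableSequenceError, ViterbiPath

__all__ = [
    "ForwardMatrix",
    "forward_full",
    "sample_path_backtrace",
    "sem_counts_linear",
    "stochastic_em_train",
]


@dataclass
class ForwardMatrix:
    """Scaled forward values: ``fhat[k, m] = f_m(k) / prod(c[1..k])``."""

    fhat: np.ndarray   # (L + 1, S)
    scales: np.ndarray  # (L + 1,), c[0] = 1
    log_prob: float
    obs: np.ndarray


def forward_full(model: HmmModel, seq: LabeledSequence | str) -> ForwardMatrix:
    """Full scaled forward matrix and log P(X) (Start -> ... -> End)."""
    symbols = seq.symbols if isinstance(seq, LabeledSequence) else seq
    obs = model.encode(symbols)
    if obs.size < 1:
        raise ValueError("sequence must have length >= 1")
    fhat, c, log_p, ok = _kernels.forward_full(model.trans, model.emit, obs)
    if not ok:
        raise UnreachableSequenceError(
            f"sequence {getattr(seq, 'id', '') or symbols[:20]!r} has zero "
            "probability under the model")
    return ForwardMatrix(fhat=fhat, scales=c, log_prob=float(log_p), obs=obs)


def sample_path_backtrace(model: HmmModel, seq: LabeledSequence | str,
                          fwd: ForwardMatrix,
                          rng: np.random.Generator) -> ViterbiPath:
    """Two-step stochastic back-tracing: draw one path from P(path | X).

    Starts in the silent End state at position L and repeatedly samples the
    previous state with probability proportional to ``f_n(k') t[n, i]``
    (the emission and current forward value cancel in the normalisation;
    within-column scaling cancels as well).  The forward matrix can be
    reused across calls to sample additional paths.
    """
    obs = fwd.obs
    L = obs.size
    S = model.n_states
    states = np.empty(L + 2, dtype=np.int64)
    states[0] = model.start
    states[L + 1] = model.end
    # silent End at position L: previous state emitted x_L
    w = fwd.fhat[L, :] * model.trans[:, model.end]
    cur = _draw(w, rng)
    states[L] = cur
    log_prob = 0.0
    for k in range(L, 1, -1):
        w = fwd.fhat[k - 1, :] * model.trans[:, cur]
        cur = _draw(w, rng)
        states[k - 1] = cur
    if L >= 1 and states[1] == model.start:
        raise RuntimeError("internal sampling inconsistency")
    lt, le = model.log_trans(), model.log_emit()
    for a, b in zip(states[:-1], states[1:]):
        log_prob += lt[a, b]
    for s, y in zip(states[1:-1], obs):
        log_prob += le[s, y]
    return ViterbiPath(states=states, log_prob=float(log_prob))


def _draw(weights: np.ndarray, rng: np.random.Generator) -> int:
    total = weights.sum()
    if total <= 0:
        raise RuntimeError("degenerate back-tracing distribution "
                           "(all candidate previous states have zero mass)")
    return int(rng.choice(len(weights), p=weights / total))


def sem_counts_linear(model: HmmModel, seq: LabeledSequence | str, K: int,
                      seed: int | np.random.Generator,
                      ) -> tuple[list[CountVector], float]:
    """One-pass sampling counts for K independent chains.

    Each returned :class:`CountVector` is distributed as the counts of one
    path drawn from the posterior P(path | X); all chains share a single
    forward pass.  Returns the chain counts and log P(X).
    """
    cvs, log_p, _ = _sem_linear_raw(model, seq, K, seed)
    return cvs, log_p


def _sem_linear_raw(model: HmmModel, seq, K: int,
                    seed) -> tuple[list[CountVector], float, int]:
    if K < 1:
        raise ValueError("K must be >= 1")
    symbols = seq.symbols if isinstance(seq, LabeledSequence) else seq
    obs = model.encode(symbols)
    if obs.size < 1:
        raise ValueError("sequence must have length >= 1")
    if isinstance(seed, np.random.Generator):
        seed = int(seed.integers(2 ** 31))
    T, E, log_p, nbytes, ok = _kernels.sem_linear(
        model.trans, model.emit, obs, K, int(seed))
    if not ok:
        raise UnreachableSequenceError(
            f"sequence {getattr(seq, 'id', '') or symbols[:20]!r} has zero "
            "probability under the model")
    return ([CountVector(T[c], E[c]) for c in range(K)], float(log_p), int(nbytes))


def sem_retained_nbytes(model: HmmModel, seq, K: int = 1) -> int:
    """Bytes of DP/count state retained by the linear sampling pass."""
    return _sem_linear_raw(model, seq, K, 0)[2]


def stochastic_em_train(model0: HmmModel, parameterization: Parameterization,
                        dataset, *, n_paths: int = 1, max_iter: int = 50,
                        pseudocount: float = 1.0, tol: float = 1e-4,
                        seed: int = 0, callback=None) -> TrainingRun:
    """Stochastic EM: pool sampled-path counts over chains and sequences.

    Per iteration, ``n_paths`` chains are sampled per sequence with the
    linear one-pass algorithm, counts are summed over chains and sequences,
    pooled by parameter ties, and re-normalised with pseudocounts (applied
    once to the pooled counts).  Stops when |delta log-likelihood| < tol or
    at ``max_iter``.  Chain seeds derive deterministically from ``seed``
    per (iteration, sequence), so runs replay exactly.
    """
    sequences = list(dataset)
    if not sequences:
        raise ValueError("dataset is empty")
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    model = model0
    records: list[IterationRecord] = []
    stop_reason = "max_iterations"
    prev_ll: float | None = None
    for q in range(1, max_iter + 1):
        total = CountVector.zeros(model)
        ll = 0.0
        for idx, seq in enumerate(sequences):
            s = child_seed(seed, 1, q, idx)
            cvs, log_p = sem_counts_linear(model, seq, n_paths, s)
            for cv in cvs:
                total += cv
            ll += log_p
        values = update_parameters(aggregate_counts(total, parameterization),
                                   parameterization, pseudocount)
        model = parameterization.build_model(values, model)
        records.append(IterationRecord(iteration=q, log_score=ll, values=values))
        if callback is not None:
            callback(q, model, values)
        if prev_ll is not None and abs(ll - prev_ll) < tol:
            stop_reason = "loglik_converged"
            break
        prev_ll = ll
    return TrainingRun(records=records, stop_reason=stop_reason,
                       final_model=model,
                       config={"algorithm": "stochastic_em", "n_paths": n_paths,
                               "max_iter": max_iter, "pseudocount": pseudocount,
                               "tol": tol, "seed": seed})
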