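"""Baum-Welch (EM) training: forward-backward and linear-memory passes.

The forward-backward route is the textbook two-step baseline; the
linear-memory route propagates posterior-expected per-current-state count
tables forward in one pass (predecessor mixing under the stochastic
back-tracing distribution) and is implemented to an equivalence contract
against the forward-backward counts.
"""

from __future__ import annotations

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
    update_parameters,
)
from .viterbi import UnreachableSequenceError

__all__ = ["expected_counts_fb", "expected_counts_linear", "baum_welch_train"]


def expected_counts_fb(model: HmmModel, seq: LabeledSequence | str,
                       ) -> tuple[CountVector, float]:
    """Posterior-expected counts via scaled forward-backward.

    ``E[T_ij] = sum_k f_i(k) t_ij e_j(x_{k+1}) b_j(k+1) / P(X)`` with the
    silent End handled at termination, and ``E[E_i(y)]`` the summed
    posterior state occupancy over positions reading ``y``.
    """
    symbols = seq.symbols if isinstance(seq, LabeledSequence) else seq
    obs = model.encode(symbols)
    if obs.size < 1:
        raise ValueError("sequence must have length >= 1")
    fhat, c, log_p, ok = _kernels.forward_full(model.trans, model.emit, obs)
    if not ok:
        raise UnreachableSequenceError(
            f"sequence {getattr(seq, 'id', '') or symbols[:20]!r} has zero "
            "probability under the model")
    S, A, L = model.n_states, model.n_symbols, obs.size
    t, e = model.trans, model.emit
    end = model.end
    # scaled backward: bhat[k, m] = b_m(k) / prod(c[k+1..L])
    bhat = np.zeros((L + 1, S))
    bhat[L, :] = t[:, end]
    for k in range(L - 1, 0, -1):
        y = obs[k]  # x_{k+1}
        bhat[k, :] = (t[:, :] @ (e[:, y] * bhat[k + 1, :])) / c[k + 1]
    px = float(fhat[L, :] @ t[:, end])  # scaled P(X)
    T = np.zeros((S, S))
    E = np.zeros((S, A))
    gamma = fhat * bhat / px  # posterior state occupancy, rows 1..L
    for k in range(1, L + 1):
        E[:, obs[k - 1]] += gamma[k]
    for k in range(1, L):
        y = obs[k]
        T += np.outer(fhat[k, :], e[:, y] * bhat[k + 1, :]) * t / (c[k + 1] * px)
    T[:, end] += fhat[L, :] * t[:, end] / px
    T[0, :] = gamma[1]  # the k-loop contributes nothing to row 0 (fhat[k,0]=0, k>=1)
    E[0, :] = 0.0
    E[end, :] = 0.0
    return CountVector(T, E), float(log_p)


def expected_counts_linear(model: HmmModel, seq: LabeledSequence | str,
                           ) -> tuple[CountVector, float]:
    """One-pass posterior-expected counts; memory independent of length."""
    cv, log_p, _ = _bw_linear_raw(model, seq)
    return cv, log_p


def _bw_linear_raw(model: HmmModel, seq) -> tuple[CountVector, float, int]:
    symbols = seq.symbols if isinstance(seq, LabeledSequence) else seq
    obs = model.encode(symbols)
    if obs.size < 1:
        raise ValueError("sequence must have length >= 1")
    T, E, log_p, nbytes, ok = _kernels.bw_linear(model.trans, model.emit, obs)
    if not ok:
        raise UnreachableSequenceError(
            f"sequence {getattr(seq, 'id', '') or symbols[:20]!r} has zero "
            "probability under the model")
    return CountVector(T, E), float(log_p), int(nbytes)


def bw_retained_nbytes(model: HmmModel, seq) -> int:
    """Bytes of DP/count state retained by the linear expected-count pass."""
    return _bw_linear_raw(model, seq)[2]


def baum_welch_train(model0: HmmModel, parameterization: Parameterization,
                     dataset, *, max_iter: int = 50, pseudocount: float = 1.0,
                     tol: float = 1e-4, engine: str = "linear",
                     callback=None) -> TrainingRun:
    """EM loop over posterior-expected counts.

    ``engine`` selects the linear-memory pass (default) or the
    forward-backward reference.  With pseudocount 0 the summed
    log-likelihood is non-decreasing (EM monotonicity); pseudocounts
    regularise the update and break strict monotonicity of the
    unpenalised likelihood.  Stops on |delta log-likelihood| < tol or at
    ``max_iter``.
    """
    if engine not in ("linear", "forward-backward"):
        raise ValueError(f"unknown engine {engine!r}")
    counts_fn = expected_counts_linear if engine == "linear" else expected_counts_fb
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
        for seq in sequences:
            cv, log_p = counts_fn(model, seq)
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
                       config={"algorithm": "baum_welch", "engine": engine,
                               "max_iter": max_iter, "pseudocount": pseudocount,
                               "tol": tol})
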