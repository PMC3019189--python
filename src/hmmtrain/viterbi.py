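"""Viterbi decoding and Viterbi training (classical and linear-memory).

Viterbi training re-estimates parameters from the transition/emission
counts of each training sequence's current Viterbi path.  The classical
route materialises the full ``(L+1, S)`` matrix and tracebacks; the
linear-memory route propagates per-current-state cumulative count tables
alongside a single column of Viterbi values, so the retained state does
not grow with the sequence length, and yields the exact same counts.
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
    update_parameters,
)

__all__ = ["ViterbiPath", "viterbi_full", "viterbi_counts_linear", "viterbi_train"]


@dataclass
class ViterbiPath:
    """A complete Start..End state path with its joint log probability."""

    states: np.ndarray  # length L + 2, states[0] = Start, states[-1] = End
    log_prob: float

    @property
    def emitting_states(self) -> np.ndarray:
        return self.states[1:-1]


class UnreachableSequenceError(ValueError):
    """The sequence has probability zero under the model."""


def _check_nonempty(obs: np.ndarray) -> None:
    if obs.size < 1:
        raise ValueError("sequence must have length >= 1")


def viterbi_full(model: HmmModel, seq: LabeledSequence | str) -> ViterbiPath:
    """Classical two-step Viterbi: full matrix, then traceback.

    Ties in the argmax are broken toward the lowest previous-state index,
    identically to :func:`viterbi_counts_linear`.
    """
    symbols = seq.symbols if isinstance(seq, LabeledSequence) else seq
    obs = model.encode(symbols)
    _check_nonempty(obs)
    path, log_v, ok = _kernels.viterbi_full(model.log_trans(), model.log_emit(), obs)
    if not ok:
        raise UnreachableSequenceError(
            f"sequence {getattr(seq, 'id', '') or symbols[:20]!r} has zero "
            "probability under the model")
    full = np.concatenate(([model.start], path, [model.end]))
    return ViterbiPath(states=full, log_prob=float(log_v))


def viterbi_counts_linear(model: HmmModel, seq: LabeledSequence | str,
                          ) -> tuple[CountVector, float]:
    """One-pass Viterbi-path counts; memory independent of sequence length.

    Returns the integer transition/emission counts of the Viterbi path and
    its log probability ``log v_End(L)``.
    """
    cv, log_v, _h, _b = _viterbi_linear_raw(model, seq)
    return cv, log_v


def _viterbi_linear_raw(model: HmmModel, seq: LabeledSequence | str,
                        ) -> tuple[CountVector, float, int, int]:
    symbols = seq.symbols if isinstance(seq, LabeledSequence) else seq
    obs = model.encode(symbols)
    _check_nonempty(obs)
    T, E, log_v, path_hash, nbytes, ok = _kernels.viterbi_linear(
        model.log_trans(), model.log_emit(), obs)
    if not ok:
        raise UnreachableSequenceError(
            f"sequence {getattr(seq, 'id', '') or symbols[:20]!r} has zero "
            "probability under the model")
    return CountVector(T, E), float(log_v), int(path_hash), int(nbytes)


def viterbi_retained_nbytes(model: HmmModel, seq: LabeledSequence | str) -> int:
    """Bytes of DP/count state retained by the linear pass (measured by the
    kernel itself from the buffers it allocates)."""
    return _viterbi_linear_raw(model, seq)[3]


def viterbi_train(model0: HmmModel, parameterization: Parameterization,
                  dataset, *, max_iter: int = 100, pseudocount: float = 1.0,
                  strict_path_identity: bool = False,
                  callback=None) -> TrainingRun:
    """Iterative Viterbi training with the linear-memory count pass.

    Each iteration counts every sequence's Viterbi path, pools counts over
    sequences and parameter ties, and re-normalises with pseudocounts.
    Stops when the pooled member counts repeat exactly (the Viterbi paths
    no longer move the parameters) — or, with ``strict_path_identity``,
    when the per-sequence path hashes repeat — or at ``max_iter``.
    """
    sequences = list(dataset)
    if not sequences:
        raise ValueError("dataset is empty")
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    model = model0
    records: list[IterationRecord] = []
    prev_agg: dict | None = None
    prev_hashes: tuple | None = None
    stop_reason = "max_iterations"
    for q in range(1, max_iter + 1):
        total = CountVector.zeros(model)
        score = 0.0
        hashes = []
        for seq in sequences:
            cv, log_v, h, _ = _viterbi_linear_raw(model, seq)
            total += cv
            score += log_v
            hashes.append(h)
        agg = aggregate_counts(total, parameterization)
        values = update_parameters(agg, parameterization, pseudocount)
        model = parameterization.build_model(values, model)
        records.append(IterationRecord(iteration=q, log_score=score, values=values))
        if callback is not None:
            callback(q, model, values)
        if strict_path_identity:
            if prev_hashes is not None and tuple(hashes) == prev_hashes:
                stop_reason = "paths_unchanged"
                break
            prev_hashes = tuple(hashes)
        else:
            if prev_agg is not None and agg == prev_agg:
                stop_reason = "counts_unchanged"
                break
            prev_agg = agg
    return TrainingRun(records=records, stop_reason=stop_reason,
                       final_model=model,
                       config={"algorithm": "viterbi", "max_iter": max_iter,
                               "pseudocount": pseudocount,
                               "strict_path_identity": strict_path_identity})
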