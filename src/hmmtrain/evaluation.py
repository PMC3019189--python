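"""Prediction accuracy, parameter convergence and cross-validation.

Performance follows the study convention: per-position binary
classification of the Viterbi-decoded state against the true label
(positive = a designated state set, e.g. the loaded-die or '+' states),
with ``performance = sensitivity x specificity``.  Parameter convergence
is the mean absolute difference between trained and generating values of
the free parameters, split into emission and transition parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .baum_welch import baum_welch_train
from .core import (
    FREE,
    HmmModel,
    LabeledDataset,
    Parameterization,
    TrainingRun,
    child_seed,
    random_initialize,
)
from .sem import stochastic_em_train
from .viterbi import viterbi_full, viterbi_train

__all__ = [
    "PerformanceScore",
    "ConvergenceScore",
    "decode_and_score",
    "parameter_distance",
    "cross_validate",
    "default_configs",
]


@dataclass
class PerformanceScore:
    tp: int
    fp: int
    tn: int
    fn: int
    positive_states: tuple[int, ...]
    specificity_mode: str = "tnr"

    # empty-denominator convention: nothing to misclassify counts as perfect
    @property
    def sensitivity(self) -> float:
        d = self.tp + self.fn
        return self.tp / d if d else 1.0

    @property
    def specificity(self) -> float:
        if self.specificity_mode == "precision":
            d = self.tp + self.fp
            return self.tp / d if d else 1.0
        d = self.tn + self.fp
        return self.tn / d if d else 1.0

    @property
    def performance(self) -> float:
        return self.sensitivity * self.specificity


@dataclass
class ConvergenceScore:
    """Mean |trained - true| over free parameters, by parameter kind.

    ``nan`` where a model has no trainable parameters of that kind (the
    CpG model trains no emissions).
    """

    emission_distance: float
    transition_distance: float
    relabeling_used: bool = False


def _resolve_states(model: HmmModel, positive_states) -> tuple[int, ...]:
    out = []
    for s in positive_states:
        if isinstance(s, (int, np.integer)):
            out.append(int(s))
        elif s in model.states:
            out.append(model.states.index(s))
        else:
            raise KeyError(f"unknown state {s!r}")
    return tuple(sorted(out))


def decode_and_score(model: HmmModel, dataset, positive_states,
                     specificity_mode: str = "tnr") -> PerformanceScore:
    """Viterbi-decode every labelled sequence and score per position."""
    pos = _resolve_states(model, positive_states)
    pos_set = np.zeros(model.n_states, dtype=bool)
    pos_set[list(pos)] = True
    tp = fp = tn = fn = 0
    for seq in dataset:
        if seq.labels is None:
            raise ValueError(f"sequence {seq.id!r} has no true labels")
        pred = pos_set[viterbi_full(model, seq).emitting_states]
        true = pos_set[seq.labels]
        tp += int(np.sum(pred & true))
        fp += int(np.sum(pred & ~true))
        tn += int(np.sum(~pred & ~true))
        fn += int(np.sum(~pred & true))
    return PerformanceScore(tp, fp, tn, fn, pos, specificity_mode)


def parameter_distance(trained_values: dict[str, float],
                       true_values: dict[str, float],
                       parameterization: Parameterization,
                       align: str = "relabel") -> ConvergenceScore:
    """Mean absolute error of free parameters against generating values.

    With ``align="relabel"`` (default) the trained values are first
    aligned to the truth by the best member renaming from the model's
    state-relabelling symmetry group (exchangeable states such as the
    casino's F/L or the CpG blocks are only identified up to relabelling);
    ``align="strict"`` compares names directly.
    """
    if align not in ("relabel", "strict"):
        raise ValueError(f"unknown align mode {align!r}")
    perms: list[dict[str, str] | None] = [None]
    if align == "relabel":
        perms += parameterization.relabelings
    best: ConvergenceScore | None = None
    for perm in perms:
        em, tr = [], []
        for g in parameterization.groups.values():
            bucket = em if g.kind == "emission" else tr
            for m in g.members:
                if m.role != FREE:
                    continue
                k = parameterization.key(g.name, m.name)
                kt = perm.get(k, k) if perm else k
                if kt not in trained_values or k not in true_values:
                    raise KeyError(f"parameter {k!r} missing from values")
                bucket.append(abs(trained_values[kt] - true_values[k]))
        score = ConvergenceScore(
            emission_distance=float(np.mean(em)) if em else float("nan"),
            transition_distance=float(np.mean(tr)) if tr else float("nan"),
            relabeling_used=perm is not None)
        if best is None or _total(score) < _total(best):
            best = score
    return best


def _total(s: ConvergenceScore) -> float:
    vals = [v for v in (s.emission_distance, s.transition_distance)
            if not np.isnan(v)]
    return float(np.sum(vals))


def default_configs(ks=(1, 3, 5)) -> list[dict]:
    """The study's algorithm roster: Viterbi, Baum-Welch, SEM K in {1,3,5}."""
    cfgs = [{"name": "viterbi", "algorithm": "viterbi"},
            {"name": "baum_welch", "algorithm": "baum_welch"}]
    for k in ks:
        cfgs.append({"name": f"stochastic_em_{k}", "algorithm": "stochastic_em",
                     "n_paths": k})
    return cfgs


def _fold_indices(n: int, n_folds: int) -> list[np.ndarray]:
    if n < n_folds:
        raise ValueError(f"{n} sequences cannot be split into {n_folds} folds")
    return [np.asarray(a) for a in np.array_split(np.arange(n), n_folds)]


def cross_validate(model_true: HmmModel, parameterization: Parameterization,
                   dataset: LabeledDataset, configs: list[dict] | None = None,
                   *, n_folds: int = 3, seed: int = 0,
                   positive_states=None, specificity_mode: str = "tnr",
                   max_iter: int = 20, pseudocount: float = 1.0,
                   tol: float = 0.0, share_init: bool = True,
                   align: str = "relabel",
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """N-fold cross-evaluation of the training algorithms.

    Each fold holds out one part for evaluation and trains every
    configuration on the rest, starting (by default) from one shared
    random initialization per fold.  After every training iteration the
    held-out performance and the parameter distances to the generating
    values are recorded.  Returns the tidy per-iteration table and a
    mean/sd summary across folds.
    """
    if configs is None:
        configs = default_configs()
    if positive_states is None:
        raise ValueError("positive_states is required")
    sequences = list(dataset)
    folds = _fold_indices(len(sequences), n_folds)
    rows: list[dict] = []
    for f, test_idx in enumerate(folds):
        test_set = [sequences[i] for i in test_idx]
        train_set = [s for i, s in enumerate(sequences)
                     if i not in set(test_idx.tolist())]
        fold_rng = np.random.default_rng(child_seed(seed, 3, f))
        shared_init = random_initialize(parameterization, fold_rng)
        for c_i, cfg in enumerate(configs):
            if share_init:
                init_values = shared_init
            else:
                rng = np.random.default_rng(child_seed(seed, 4, f, c_i))
                init_values = random_initialize(parameterization, rng)
            model0 = parameterization.build_model(init_values, model_true)

            def record(q, model, values, cfg=cfg, f=f):
                perf = decode_and_score(model, test_set, positive_states,
                                        specificity_mode)
                conv = parameter_distance(values, parameterization.default_values,
                                          parameterization, align=align)
                rows.append({
                    "fold": f, "algorithm": cfg["name"],
                    "n_paths": cfg.get("n_paths", 0), "iteration": q,
                    "sensitivity": perf.sensitivity,
                    "specificity": perf.specificity,
                    "performance": perf.performance,
                    "emission_distance": conv.emission_distance,
                    "transition_distance": conv.transition_distance,
                })
            _dispatch(cfg, model0, parameterization, train_set,
                      max_iter=max_iter, pseudocount=pseudocount,
                      tol=tol, seed=child_seed(seed, 5, f, c_i),
                      callback=record)
    df = pd.DataFrame(rows)
    metrics = ["sensitivity", "specificity", "performance",
               "emission_distance", "transition_distance"]
    summary = (df.groupby(["algorithm", "n_paths", "iteration"])[metrics]
               .agg(["mean", "std"]))
    summary.columns = [f"{m}_{s}" for m, s in summary.columns]
    summary = summary.reset_index()
    return df, summary


def _dispatch(cfg: dict, model0, parameterization, train_set, *,
              max_iter, pseudocount, tol, seed, callback) -> TrainingRun:
    alg = cfg["algorithm"]
    if alg == "viterbi":
        return viterbi_train(model0, parameterization, train_set,
                             max_iter=max_iter, pseudocount=pseudocount,
                             callback=callback)
    if alg == "baum_welch":
        return baum_welch_train(model0, parameterization, train_set,
                                max_iter=max_iter, pseudocount=pseudocount,
                                tol=tol, engine=cfg.get("engine", "linear"),
                                callback=callback)
    if alg == "stochastic_em":
        return stochastic_em_train(model0, parameterization, train_set,
                                   n_paths=cfg.get("n_paths", 1),
                                   max_iter=max_iter, pseudocount=pseudocount,
                                   tol=tol, seed=seed, callback=callback)
    raise ValueError(f"unknown algorithm {alg!r}")
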