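"""Scikit-learn style estimators wrapping the three training algorithms.

Each estimator holds an HMM structure (a registered example-model name or
an explicit ``(HmmModel, Parameterization)``), fits its free parameters to
a collection of symbol sequences, and predicts per-position hidden states
by Viterbi decoding.  They compose with sklearn tooling (``clone``,
``get_params`` / ``set_params``); ``X`` is a list of sequences (strings or
:class:`~hmmtrain.core.LabeledSequence`), ``y`` is unused.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .baum_welch import baum_welch_train
from .core import (
    HmmModel,
    LabeledSequence,
    Parameterization,
    random_initialize,
)
from .models import get_model
from .sem import forward_full, stochastic_em_train
from .viterbi import viterbi_full, viterbi_train

__all__ = ["ViterbiTrainingHMM", "StochasticEMHMM", "BaumWelchHMM"]


class _BaseHMMTrainer(BaseEstimator):
    """Shared fit/predict plumbing; subclasses implement ``_train``."""

    def __init__(self, model="dishonest_casino", parameterization=None,
                 max_iter=50, pseudocount=1.0, init="random",
                 random_state=None):
        self.model = model
        self.parameterization = parameterization
        self.max_iter = max_iter
        self.pseudocount = pseudocount
        self.init = init
        self.random_state = random_state

    # -- helpers -----------------------------------------------------------
    def _resolve(self) -> tuple[HmmModel, Parameterization]:
        if isinstance(self.model, str):
            return get_model(self.model)
        if not isinstance(self.model, HmmModel):
            raise TypeError("model must be a registered name or an HmmModel")
        if not isinstance(self.parameterization, Parameterization):
            raise TypeError("an explicit HmmModel requires a Parameterization")
        return self.model, self.parameterization

    @staticmethod
    def _as_sequences(X) -> list[LabeledSequence]:
        seqs = [s if isinstance(s, LabeledSequence) else LabeledSequence(str(s))
                for s in X]
        if not seqs:
            raise ValueError("X must contain at least one sequence")
        return seqs

    def _train(self, model0, par, seqs):  # pragma: no cover - abstract
        raise NotImplementedError

    # -- sklearn API -------------------------------------------------------
    def fit(self, X, y=None):
        """Fit free parameters to sequences; returns self."""
        model, par = self._resolve()
        seqs = self._as_sequences(X)
        if self.init == "random":
            rng = np.random.default_rng(self.random_state)
            self.init_values_ = random_initialize(par, rng)
            model0 = par.build_model(self.init_values_, model)
        elif self.init == "model":
            self.init_values_ = None
            model0 = model
        else:
            raise ValueError(f"unknown init {self.init!r}")
        run = self._train(model0, par, seqs)
        self.parameterization_ = par
        self.history_ = run
        self.model_ = run.final_model
        self.values_ = run.final_values
        self.n_iter_ = run.n_iter
        self.stop_reason_ = run.stop_reason
        self.log_score_ = run.records[-1].log_score
        return self

    def predict(self, X):
        """Viterbi state path (int indices, positions 1..L) per sequence."""
        self._check_fitted()
        return [viterbi_full(self.model_, s).emitting_states
                for s in self._as_sequences(X)]

    def predict_labels(self, X):
        """Viterbi paths as state-code strings."""
        self._check_fitted()
        return [self.model_.decode_labels(p) for p in self.predict(X)]

    def score(self, X, y=None):
        """Total forward log-likelihood of the sequences."""
        self._check_fitted()
        return float(sum(forward_full(self.model_, s).log_prob
                         for s in self._as_sequences(X)))

    def _check_fitted(self):
        if not hasattr(self, "model_"):
            raise AttributeError("estimator is not fitted; call fit first")


class ViterbiTrainingHMM(_BaseHMMTrainer):
    """Viterbi training with the one-pass linear-memory count algorithm.

    Stops when the pooled path counts repeat exactly (the Viterbi paths no
    longer change the parameters) or after ``max_iter`` iterations.
    """

    def __init__(self, model="dishonest_casino", parameterization=None,
                 max_iter=50, pseudocount=1.0, init="random",
                 random_state=None, strict_path_identity=False):
        super().__init__(model, parameterization, max_iter, pseudocount,
                         init, random_state)
        self.strict_path_identity = strict_path_identity

    def _train(self, model0, par, seqs):
        return viterbi_train(model0, par, seqs, max_iter=self.max_iter,
                             pseudocount=self.pseudocount,
                             strict_path_identity=self.strict_path_identity)


class StochasticEMHMM(_BaseHMMTrainer):
    """Stochastic EM: counts from ``n_paths`` posterior path samples per
    sequence per iteration, drawn by the one-pass linear-memory sampler."""

    def __init__(self, model="dishonest_casino", parameterization=None,
                 max_iter=50, pseudocount=1.0, init="random",
                 random_state=None, n_paths=1, tol=1e-4):
        super().__init__(model, parameterization, max_iter, pseudocount,
                         init, random_state)
        self.n_paths = n_paths
        self.tol = tol

    def _train(self, model0, par, seqs):
        seed = 0 if self.random_state is None else int(self.random_state)
        return stochastic_em_train(model0, par, seqs, n_paths=self.n_paths,
                                   max_iter=self.max_iter,
                                   pseudocount=self.pseudocount,
                                   tol=self.tol, seed=seed)


class BaumWelchHMM(_BaseHMMTrainer):
    """Baum-Welch EM over posterior-expected counts (linear-memory pass by
    default; ``engine="forward-backward"`` for the two-step reference)."""

    def __init__(self, model="dishonest_casino", parameterization=None,
                 max_iter=50, pseudocount=1.0, init="random",
                 random_state=None, tol=1e-4, engine="linear"):
        super().__init__(model, parameterization, max_iter, pseudocount,
                         init, random_state)
        self.tol = tol
        self.engine = engine

    def _train(self, model0, par, seqs):
        return baum_welch_train(model0, par, seqs, max_iter=self.max_iter,
                                pseudocount=self.pseudocount, tol=self.tol,
                                engine=self.engine)
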