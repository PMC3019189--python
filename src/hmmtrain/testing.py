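"""Utilities for validation studies: random models and sequences.

Random fully connected HMMs with Dirichlet-distributed rows provide a
tie-free test bed on which the one-pass algorithms can be compared
exactly against their two-step counterparts and against brute-force
path enumeration.
"""

from __future__ import annotations

import numpy as np

from .core import HmmModel

__all__ = ["random_model", "random_symbols"]


def random_model(rng: np.random.Generator, n_emitting: int,
                 n_symbols: int, alpha: float = 1.0) -> HmmModel:
    """A random valid HMM: full connectivity among emitting states, every
    emitting state reaches End, Dirichlet(alpha) rows."""
    if n_emitting < 1 or n_symbols < 2:
        raise ValueError("need >= 1 emitting state and >= 2 symbols")
    S = n_emitting + 2
    trans = np.zeros((S, S))
    trans[0, 1:-1] = rng.dirichlet(np.full(n_emitting, alpha))
    for i in range(1, S - 1):
        trans[i, 1:] = rng.dirichlet(np.full(n_emitting + 1, alpha))
    emit = np.zeros((S, n_symbols))
    for i in range(1, S - 1):
        emit[i] = rng.dirichlet(np.full(n_symbols, alpha))
    states = ["Start"] + [f"S{i}" for i in range(1, S - 1)] + ["End"]
    alphabet = [chr(ord("a") + i) for i in range(n_symbols)]
    codes = [""] + [chr(ord("A") + i) for i in range(n_emitting)] + [""]
    return HmmModel(states, alphabet, trans, emit, codes)


def random_symbols(rng: np.random.Generator, model: HmmModel, length: int) -> str:
    """Uniform random symbol string over the model alphabet (every string
    has nonzero probability under a fully supported random model)."""
    idx = rng.integers(0, model.n_symbols, size=length)
    return "".join(model.alphabet[i] for i in idx)
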