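"""Synthetic data generation and generic maximum-likelihood training.

Two kinds of inputs are generated: sequences sampled from an HMM (for
parameter-recovery studies) and i.i.d. binary sequences with a controlled
frequency of 1s. The binary generator emulates the low-complexity genomic
inputs that make pair-substitution compression effective — a whole-genome
pairwise alignment summarised as identical/different site indicators is
essentially a rare-event binary string. What it does not emulate is the
autocorrelation of real alignments (variant sites cluster), so compression
ratios on real data differ from the i.i.d. prediction even at equal symbol
frequency.

Training maximises the compressed-sequence log-likelihood with the
Nelder-Mead simplex method through a user-supplied parameterisation (a map
from a real vector to a model). Real applications map a handful of
domain parameters to full matrices; the bundled softmax parameterisation
(rows of A and B softmaxed, uniform pi) is a generic default for tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.optimize import minimize

from .compress import PreprocessedSequence
from .forward import forward_zip
from .model import HMMParams, ObservedSequence, validate_hmm

__all__ = [
    "SimulationSpec",
    "TrainResult",
    "sample_sequence",
    "random_binary_sequence",
    "train_nelder_mead",
    "softmax_parameterization",
]


@dataclass(frozen=True)
class SimulationSpec:
    """Length, frequency of 1s and seed for an i.i.d. binary sequence."""

    length: int
    one_frequency: float
    seed: int

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("length must be at least 1")
        if not 0.0 <= self.one_frequency <= 1.0:
            raise ValueError("one_frequency must lie in [0, 1]")


def sample_sequence(
    hmm: HMMParams, length: int, seed: int
) -> tuple[np.ndarray, ObservedSequence]:
    """Sample a hidden path and observations from the model's joint law."""
    if length < 1:
        raise ValueError("length must be at least 1")
    rng = np.random.default_rng(seed)
    n, m = hmm.n_states, hmm.n_observables
    hidden = np.empty(length, dtype=np.int64)
    tokens = np.empty(length, dtype=np.int64)
    state = rng.choice(n, p=hmm.pi)
    for t in range(length):
        if t > 0:
            state = rng.choice(n, p=hmm.trans[state])
        hidden[t] = state
        tokens[t] = rng.choice(m, p=hmm.emit[state])
    return hidden, ObservedSequence(tokens=tokens, alphabet_size=m)


def random_binary_sequence(spec: SimulationSpec) -> ObservedSequence:
    """I.i.d. tokens over {0, 1} with ``Pr(1) = one_frequency``."""
    rng = np.random.default_rng(spec.seed)
    tokens = (rng.random(spec.length) < spec.one_frequency).astype(np.int64)
    return ObservedSequence(tokens=tokens, alphabet_size=2)


@dataclass(frozen=True)
class TrainResult:
    params: np.ndarray
    loglik: float
    n_evaluations: int


def train_nelder_mead(
    pre: PreprocessedSequence,
    parameterization: Callable[[np.ndarray], HMMParams],
    start: np.ndarray,
    options: dict | None = None,
) -> TrainResult:
    """Maximise the compressed-sequence log-likelihood over a parameterisation.

    The objective is ``-forward_zip(pre, parameterization(theta)).loglik``;
    parameter vectors yielding invalid models score ``-inf`` (the optimiser
    may probe them freely). Deterministic for a fixed start and options.
    Raises when the starting point itself has non-finite log-likelihood.
    """
    start = np.asarray(start, dtype=np.float64)

    def objective(theta: np.ndarray) -> float:
        try:
            hmm = parameterization(theta)
        except (ValueError, FloatingPointError):
            return np.inf
        if validate_hmm(hmm):
            return np.inf
        return -forward_zip(pre, hmm).loglik

    f0 = objective(start)
    if not np.isfinite(f0):
        raise ValueError(f"objective is not finite at the starting point (got {-f0})")

    opts = {"xatol": 1e-6, "fatol": 1e-8, "maxiter": 2000}
    if options:
        opts.update(options)
    res = minimize(objective, start, method="Nelder-Mead", options=opts)
    return TrainResult(params=np.asarray(res.x), loglik=float(-res.fun), n_evaluations=int(res.nfev))


def softmax_parameterization(
    n_states: int, n_observables: int
) -> tuple[Callable[[np.ndarray], HMMParams], int]:
    """Generic unconstrained parameterisation: softmax rows of A and B, uniform pi.

    Returns the map and the parameter count ``N*N + N*M``. The softmax is
    shift-invariant per row, so the map is many-to-one; it covers all strictly
    positive row-stochastic matrices, which suffices for generic training.
    """
    n_params = n_states * n_states + n_states * n_observables

    def softmax_rows(block: np.ndarray) -> np.ndarray:
        z = block - block.max(axis=1, keepdims=True)
        ez = np.exp(z)
        return ez / ez.sum(axis=1, keepdims=True)

    def build(theta: np.ndarray) -> HMMParams:
        theta = np.asarray(theta, dtype=np.float64)
        if theta.shape != (n_params,):
            raise ValueError(f"expected {n_params} parameters, got {theta.shape}")
        a_block = theta[: n_states * n_states].reshape(n_states, n_states)
        b_block = theta[n_states * n_states :].reshape(n_states, n_observables)
        return HMMParams(
            pi=np.full(n_states, 1.0 / n_states),
            trans=softmax_rows(a_block),
            emit=softmax_rows(b_block),
        )

    return build, n_params
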