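"""Classical HMM algorithms on the uncompressed sequence.

These serve two roles: independent oracles for the compressed-sequence
likelihood (scaled forward, and exact path enumeration at tiny sizes) and the
standard decoders (Viterbi, posterior) that a complete HMM toolkit provides.
Decoding runs on the raw sequence — the pair-substitution preprocessing
cannot be reused there, because max-product recursions do not factor through
the composite matrices.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .model import HMMParams, ObservedSequence

__all__ = [
    "DecodingResult",
    "forward_scaled",
    "likelihood_bruteforce",
    "viterbi",
    "posterior_decode",
]

_BRUTEFORCE_LIMIT = 10**6


@dataclass(frozen=True)
class DecodingResult:
    """Hidden-state path with its score.

    For Viterbi, ``score`` is the joint log probability of the best path; for
    posterior decoding, ``posteriors[:, t]`` is ``Pr(x_t = i | Y)`` and
    ``score`` the sequence log-likelihood.
    """

    path: np.ndarray
    score: float
    posteriors: np.ndarray | None = None


def _check(seq: ObservedSequence, hmm: HMMParams) -> None:
    if seq.alphabet_size != hmm.n_observables:
        raise ValueError(
            f"sequence alphabet size {seq.alphabet_size} does not match "
            f"model emission alphabet {hmm.n_observables}"
        )


def _forward_columns(seq: ObservedSequence, hmm: HMMParams) -> tuple[np.ndarray, np.ndarray]:
    """Scaled forward table: per-column-normalised alpha and column sums."""
    y = seq.tokens
    n, t_len = hmm.n_states, seq.length
    alpha = np.zeros((n, t_len))
    scale = np.zeros(t_len)
    col = hmm.pi * hmm.emit[:, y[0]]
    for t in range(t_len):
        if t > 0:
            col = hmm.emit[:, y[t]] * (hmm.trans.T @ col)
        s = col.sum()
        scale[t] = s
        if s == 0.0:
            return alpha, scale  # impossible prefix; remaining scales stay 0
        col = col / s
        alpha[:, t] = col
    return alpha, scale


def forward_scaled(seq: ObservedSequence, hmm: HMMParams) -> float:
    """Classical forward algorithm with per-column rescaling.

    Returns ``log Pr(Y | lambda)`` as the sum of log column sums, or ``-inf``
    for a sequence the model cannot produce.
    """
    _check(seq, hmm)
    _, scale = _forward_columns(seq, hmm)
    if np.any(scale == 0.0):
        return -np.inf
    return float(np.log(scale).sum())


def likelihood_bruteforce(seq: ObservedSequence, hmm: HMMParams) -> float:
    """Exact likelihood by summing the joint probability over all hidden paths.

    Only feasible for tiny instances; guarded at ``N**T <= 1e6``.
    """
    _check(seq, hmm)
    n, t_len = hmm.n_states, seq.length
    if n**t_len > _BRUTEFORCE_LIMIT:
        raise ValueError(f"instance too large for enumeration: {n}^{t_len} paths")
    y = seq.tokens
    total = 0.0
    for path in itertools.product(range(n), repeat=t_len):
        p = hmm.pi[path[0]] * hmm.emit[path[0], y[0]]
        for t in range(1, t_len):
            p *= hmm.trans[path[t - 1], path[t]] * hmm.emit[path[t], y[t]]
        total += p
    return float(np.log(total)) if total > 0 else -np.inf


def viterbi(seq: ObservedSequence, hmm: HMMParams) -> DecodingResult:
    """Most probable hidden path in log space; ties break to the lower state index."""
    _check(seq, hmm)
    y = seq.tokens
    n, t_len = hmm.n_states, seq.length
    with np.errstate(divide="ignore"):
        log_pi = np.log(hmm.pi)
        log_a = np.log(hmm.trans)
        log_b = np.log(hmm.emit)

    delta = log_pi + log_b[:, y[0]]
    back = np.zeros((t_len, n), dtype=np.int64)
    for t in range(1, t_len):
        cand = delta[:, None] + log_a  # (from, to)
        back[t] = np.argmax(cand, axis=0)  # argmax returns the lowest index on ties
        delta = cand[back[t], np.arange(n)] + log_b[:, y[t]]

    path = np.zeros(t_len, dtype=np.int64)
    path[-1] = int(np.argmax(delta))
    for t in range(t_len - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return DecodingResult(path=path, score=float(delta[path[-1]]))


def posterior_decode(seq: ObservedSequence, hmm: HMMParams) -> DecodingResult:
    """Forward-backward posterior state probabilities and their argmax path.

    The backward pass reuses the forward column scales (the standard stable
    formulation), so the per-column products ``alpha * beta`` are already the
    posteriors up to one final normalisation.
    """
    _check(seq, hmm)
    y = seq.tokens
    n, t_len = hmm.n_states, seq.length
    alpha, scale = _forward_columns(seq, hmm)
    if np.any(scale == 0.0):
        raise ValueError("sequence has zero likelihood under the model")

    beta = np.zeros((n, t_len))
    beta[:, -1] = 1.0
    for t in range(t_len - 2, -1, -1):
        beta[:, t] = hmm.trans @ (hmm.emit[:, y[t + 1]] * beta[:, t + 1]) / scale[t + 1]

    post = alpha * beta
    post = post / post.sum(axis=0, keepdims=True)
    path = np.argmax(post, axis=0).astype(np.int64)  # ties -> lower index
    return DecodingResult(path=path, score=float(np.log(scale).sum()), posteriors=post)
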