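"""Two-stage numerically stable likelihood over a compressed sequence.

The forward recursion is a right-to-left matrix chain: with per-symbol
matrices ``C_o = B_o A*`` (``B_o`` the diagonal of emission probabilities of
``o``, ``A*`` the transpose of the transition matrix) and the initial vector
``C_1 = B_{y_1} pi``, the likelihood is the entry sum of
``C_{y_T} ... C_{y_2} C_1``. A composite symbol standing for the adjacent
observation pair (first ``l``, then ``r``) therefore uses the product
``C_r @ C_l`` — the later observation applies on the left.

Stage 1 builds one matrix per alphabet symbol (originals by formula,
composites by one matrix product each, in rule order) in ``O(M' N^3)`` time.
Every matrix is normalised by its entry sum ``c`` and the log scale is
tracked per symbol: ``s~ = log c`` for originals and
``s~ = log c + s~_left + s~_right`` for composites, so the scale of a deep
composite is recovered without ever forming the underflowing raw product.

Stage 2 sweeps the compressed remainder with matrix-vector multiplications in
``O(T' N^2)`` time, renormalising the state vector at every step by its entry
sum ``d`` and accumulating ``d~ = log d``. The log-likelihood is the sum of
the per-token symbol scales plus the per-step vector scales.

A zero entry sum (``c = 0`` or ``d = 0``) means the observation sequence is
impossible under the model; the result is ``-inf``, never an exception, so
that optimisers may probe degenerate parameter regions freely.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .compress import PreprocessedSequence, ThresholdEntry, select_threshold
from .model import HMMParams

__all__ = [
    "ScaledMatrixSet",
    "LikelihoodResult",
    "build_C",
    "build_init_vector",
    "compute_symbol_tables",
    "forward_zip",
    "forward_zip_blocked",
]


@dataclass(frozen=True)
class ScaledMatrixSet:
    """Per-symbol normalised matrices with log scaling factors.

    ``matrices[o]`` sums to 1 unless symbol ``o`` is degenerate (raw entry
    sum 0), in which case ``degenerate[o]`` is set and ``log_scales[o]`` is
    ``-inf``. ``init_vector`` is the raw (unnormalised) ``C_1``.
    """

    matrices: np.ndarray  # (M', N, N)
    log_scales: np.ndarray  # (M',)
    init_vector: np.ndarray  # (N,)
    degenerate: np.ndarray  # (M',) bool


@dataclass(frozen=True)
class LikelihoodResult:
    loglik: float
    stage2_steps: int
    stage1_products: int
    log_scale_sum: float  # sum of per-step d~ values


def build_C(hmm: HMMParams, symbol: int) -> np.ndarray:
    """Per-symbol forward matrix ``C_o = B_o A*``: entry (j, k) = b[j,o] * a[k,j]."""
    if not (0 <= symbol < hmm.n_observables):
        raise ValueError(f"symbol {symbol} outside alphabet [0, {hmm.n_observables})")
    return hmm.emit[:, symbol][:, None] * hmm.trans.T


def build_init_vector(hmm: HMMParams, first_symbol: int) -> np.ndarray:
    """Initial forward column ``C_1 = B_{y_1} pi``: entry i = b[i, y_1] * pi[i]."""
    if not (0 <= first_symbol < hmm.n_observables):
        raise ValueError(f"symbol {first_symbol} outside alphabet [0, {hmm.n_observables})")
    return hmm.emit[:, first_symbol] * hmm.pi


def compute_symbol_tables(
    hmm: HMMParams,
    pre: PreprocessedSequence,
    n_min: int | None = None,
) -> ScaledMatrixSet:
    """Stage 1: normalised matrices and log scales for the first M' symbols.

    Original symbols come straight from the model; composites are one matrix
    product of their constituents' normalised matrices each, taken in rule
    order so constituents always exist first.
    """
    if hmm.n_observables != pre.original_alphabet_size:
        raise ValueError(
            f"model emits {hmm.n_observables} symbols but preprocessing was built "
            f"for alphabet size {pre.original_alphabet_size}"
        )
    entry = select_threshold(pre, n_min if n_min is not None else hmm.n_states)
    m_used = entry.alphabet_size_used
    m_orig = pre.original_alphabet_size
    n = hmm.n_states

    matrices = np.zeros((m_used, n, n))
    log_scales = np.full(m_used, -np.inf)
    degenerate = np.zeros(m_used, dtype=bool)

    for o in range(m_orig):
        raw = build_C(hmm, o)
        c = raw.sum()
        if c == 0.0:
            degenerate[o] = True
            continue
        matrices[o] = raw / c
        log_scales[o] = np.log(c)

    for rule in pre.table.rules[: m_used - m_orig]:
        o, left, right = rule.new_symbol, rule.left, rule.right
        if degenerate[left] or degenerate[right]:
            degenerate[o] = True
            continue
        # later observation (right constituent) applies on the left of the chain
        prod = matrices[right] @ matrices[left]
        c = prod.sum()
        if c == 0.0:
            degenerate[o] = True
            continue
        matrices[o] = prod / c
        log_scales[o] = np.log(c) + log_scales[left] + log_scales[right]

    return ScaledMatrixSet(
        matrices=matrices,
        log_scales=log_scales,
        init_vector=build_init_vector(hmm, pre.first_symbol),
        degenerate=degenerate,
    )


def _chosen_entry(pre: PreprocessedSequence, hmm: HMMParams, n_min: int | None) -> ThresholdEntry:
    return select_threshold(pre, n_min if n_min is not None else hmm.n_states)


def forward_zip(
    pre: PreprocessedSequence,
    hmm: HMMParams,
    n_min: int | None = None,
) -> LikelihoodResult:
    """Log-likelihood of the model given the compressed sequence (stage 2).

    Starting from the raw initial vector, each compressed token contributes
    one matrix-vector multiplication followed by renormalisation. Returns the
    sum of per-token symbol scales and per-step vector scales; ``-inf`` when
    the sequence is impossible under the model.
    """
    entry = _chosen_entry(pre, hmm, n_min)
    tables = compute_symbol_tables(hmm, pre, n_min=entry.n_min)
    tokens = entry.tokens
    stage1_products = entry.alphabet_size_used - pre.original_alphabet_size

    v = tables.init_vector
    if tokens.size == 0:  # T = 1: the initial column is the whole likelihood
        total = v.sum()
        loglik = float(np.log(total)) if total > 0 else -np.inf
        return LikelihoodResult(loglik, 0, stage1_products, 0.0)

    if tables.degenerate[tokens].any():
        return LikelihoodResult(-np.inf, int(tokens.size), stage1_products, -np.inf)

    d_log_sum = 0.0
    for t in tokens:
        v = tables.matrices[t] @ v
        d = v.sum()
        if d == 0.0:
            return LikelihoodResult(-np.inf, int(tokens.size), stage1_products, -np.inf)
        v = v / d
        d_log_sum += np.log(d)

    loglik = float(tables.log_scales[tokens].sum() + d_log_sum)
    return LikelihoodResult(loglik, int(tokens.size), stage1_products, float(d_log_sum))


def forward_zip_blocked(
    pre: PreprocessedSequence,
    hmm: HMMParams,
    n_blocks: int,
    n_min: int | None = None,
) -> LikelihoodResult:
    """Blocked stage 2: per-block matrix products combined right-to-left.

    The compressed remainder is split into contiguous blocks; each block's
    matrix product is accumulated with per-multiplication renormalisation, and
    the block products are then applied to the initial vector in time order.
    The contract is value equality with :func:`forward_zip` — blocks are
    independent and may be evaluated concurrently, but no execution strategy
    is implied. Stage 1 is never parallelised: its workload is too small to
    repay the coordination.
    """
    if n_blocks < 1:
        raise ValueError("n_blocks must be at least 1")
    entry = _chosen_entry(pre, hmm, n_min)
    tables = compute_symbol_tables(hmm, pre, n_min=entry.n_min)
    tokens = entry.tokens
    stage1_products = entry.alphabet_size_used - pre.original_alphabet_size

    if tokens.size == 0:
        total = tables.init_vector.sum()
        loglik = float(np.log(total)) if total > 0 else -np.inf
        return LikelihoodResult(loglik, 0, stage1_products, 0.0)
    if n_blocks > tokens.size:
        warnings.warn(
            f"n_blocks={n_blocks} exceeds compressed length {tokens.size}; clamping",
            stacklevel=2,
        )
        n_blocks = int(tokens.size)

    if tables.degenerate[tokens].any():
        return LikelihoodResult(-np.inf, int(tokens.size), stage1_products, -np.inf)

    n = hmm.n_states
    bounds = np.linspace(0, tokens.size, n_blocks + 1).astype(int)
    d_log_sum = 0.0
    block_products = []
    for b in range(n_blocks):
        block = tokens[bounds[b] : bounds[b + 1]]
        prod = tables.matrices[block[0]]
        for t in block[1:]:
            prod = tables.matrices[t] @ prod  # later token on the left
            d = prod.sum()
            if d == 0.0:
                return LikelihoodResult(-np.inf, int(tokens.size), stage1_products, -np.inf)
            prod = prod / d
            d_log_sum += np.log(d)
        block_products.append(prod)

    v = tables.init_vector
    for prod in block_products:  # blocks in time order; each applies on the left
        v = prod @ v
        d = v.sum()
        if d == 0.0:
            return LikelihoodResult(-np.inf, int(tokens.size), stage1_products, -np.inf)
        v = v / d
        d_log_sum += np.log(d)

    loglik = float(tables.log_scales[tokens].sum() + d_log_sum)
    return LikelihoodResult(loglik, int(tokens.size), stage1_products, float(d_log_sum))
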