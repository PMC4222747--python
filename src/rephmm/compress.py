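"""Model-independent sequence compression by most-frequent-pair substitution.

The likelihood of an HMM can be written as a right-to-left chain of
per-symbol matrix multiplications applied to an initial vector. A repeated
adjacent pair of observed symbols corresponds to a repeated matrix product,
so replacing the most frequent non-overlapping pair by a fresh composite
symbol lets the evaluation compute that product once and reuse it. Repeating
the substitution yields a short sequence over an extended alphabet plus a
table mapping each composite symbol to its two constituents.

The compression depends only on the observed sequence — never on the model —
so it is computed once, optionally saved to disk, and reused across many
likelihood evaluations (e.g. every iteration of a training run).

Stopping is governed by a cost model: replacing a pair that occurs ``p``
times saves ``p`` matrix-vector multiplications per future likelihood
evaluation at the price of one extra matrix-matrix multiplication, so with
``e`` expected reuses and measured times ``t_mv`` / ``t_mm`` for the two
multiply shapes at the smallest state count of interest ``N_min``, a round is
worth running only while ``e * (t_mv * p - t_mm)`` exceeds the round's own
cost. Several ``N_min`` thresholds may be requested; larger state counts make
the composite product more expensive and therefore stop earlier, so a
snapshot of the partially compressed sequence is kept per threshold. With no
thresholds the compression simply stops the first time the best pair count
repeats (``p_i == p_{i-1}``).

Greedy left-to-right semantics everywhere: after a counted occurrence at
positions ``(t, t+1)`` the next candidate for that pair starts at ``t+2``, so
a run of ``r`` identical symbols contributes ``r // 2`` occurrences. Ties
between equally frequent pairs break to the lexicographically smallest
``(left, right)``.
"""

from __future__ import annotations

import json
import time
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .model import ObservedSequence

__all__ = [
    "PairRule",
    "SubstitutionTable",
    "ThresholdEntry",
    "PreprocessedSequence",
    "CompressionCalibration",
    "RoundStats",
    "count_pairs",
    "select_pair",
    "replace_pair",
    "calibrate",
    "should_stop",
    "preprocess",
    "expand_symbol",
    "expand_sequence",
    "save_preprocessing",
    "load_preprocessing",
    "select_threshold",
]

FORMAT_VERSION = 1


@dataclass(frozen=True)
class PairRule:
    """Composite symbol ``new_symbol`` standing for the adjacent pair (left, right)."""

    new_symbol: int
    left: int
    right: int

    def __post_init__(self) -> None:
        if not (self.left < self.new_symbol and self.right < self.new_symbol):
            raise ValueError(
                f"rule {self.new_symbol} -> ({self.left}, {self.right}): "
                "constituents must predate the composite"
            )


@dataclass(frozen=True)
class SubstitutionTable:
    """Ordered pair rules; rule ``i`` defines symbol ``original_alphabet_size + i``."""

    original_alphabet_size: int
    rules: tuple[PairRule, ...] = ()

    def __post_init__(self) -> None:
        for i, rule in enumerate(self.rules):
            expected = self.original_alphabet_size + i
            if rule.new_symbol != expected:
                raise ValueError(
                    f"rule {i} defines symbol {rule.new_symbol}, expected {expected}"
                )

    @property
    def extent(self) -> int:
        """Total number of symbols: originals plus composites."""
        return self.original_alphabet_size + len(self.rules)


@dataclass(frozen=True)
class ThresholdEntry:
    """Snapshot of the compressed remainder saved for one ``N_min`` threshold."""

    n_min: int
    alphabet_size_used: int
    tokens: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "tokens", np.asarray(self.tokens, dtype=np.int64))


@dataclass(frozen=True)
class PreprocessedSequence:
    """First original symbol plus per-threshold compressed remainders.

    The first symbol ``y_1`` is kept apart because the evaluation treats it as
    the initial vector, not a matrix; the compressed tokens cover original
    positions ``2..T``.
    """

    first_symbol: int
    original_length: int
    original_alphabet_size: int
    table: SubstitutionTable
    per_threshold: tuple[ThresholdEntry, ...]
    e_used: float = 1.0


@dataclass(frozen=True)
class CompressionCalibration:
    """Cost-model inputs for the stopping criterion.

    ``t_mv`` / ``t_mm`` are seconds for an ``(N_min x N_min) @ vector`` and an
    ``(N_min x N_min) @ (N_min x N_min)`` multiply. When ``None`` they are
    measured per threshold at preprocess time; explicit values override the
    measurement (used for reproducible tests). ``e`` is the expected number of
    reuses of the preprocessing.
    """

    t_mv: float | None = None
    t_mm: float | None = None
    e: float = 1.0
    thresholds: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.t_mv is not None and self.t_mv <= 0:
            raise ValueError("t_mv must be positive")
        if self.t_mm is not None and self.t_mm <= 0:
            raise ValueError("t_mm must be positive")
        if self.e < 1:
            raise ValueError("e must be at least 1")
        object.__setattr__(self, "thresholds", tuple(sorted(set(int(t) for t in self.thresholds))))
        if self.thresholds and self.thresholds[0] < 1:
            raise ValueError("thresholds must be positive state counts")


@dataclass(frozen=True)
class RoundStats:
    """Per-round accounting: ``pair_count`` is the best count found by the
    round's trailing scan; ``round_seconds`` its wall-clock duration."""

    round_index: int
    pair_count: int
    round_seconds: float


def _run_length_encode(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Return (run start indices, run lengths) of maximal equal runs."""
    if x.size == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    boundaries = np.flatnonzero(x[1:] != x[:-1])
    starts = np.concatenate(([0], boundaries + 1))
    ends = np.concatenate((boundaries, [x.size - 1]))
    return starts, ends - starts + 1


def count_pairs(tokens: Sequence[int] | np.ndarray) -> dict[tuple[int, int], int]:
    """Count non-overlapping occurrences of every adjacent symbol pair.

    Greedy left-to-right per pair: identical-symbol pairs contribute
    ``run // 2`` per maximal run; distinct-symbol pairs cannot self-overlap,
    so their count is the plain number of adjacent matches.
    """
    x = np.asarray(tokens, dtype=np.int64)
    if x.size < 2:
        return {}
    extent = int(x.max()) + 1
    codes = x[:-1] * extent + x[1:]
    uniq, cnt = np.unique(codes, return_counts=True)
    counts = {(int(c) // extent, int(c) % extent): int(n) for c, n in zip(uniq, cnt)}

    # Correct identical-symbol pairs for overlap: a run of r contributes r//2.
    starts, lengths = _run_length_encode(x)
    long = lengths >= 2
    if np.any(long):
        vals = x[starts[long]]
        halves = lengths[long] // 2
        diag = np.zeros(extent, dtype=np.int64)
        np.add.at(diag, vals, halves)
        for s in np.unique(vals):
            counts[(int(s), int(s))] = int(diag[s])
    return counts


def select_pair(
    counts: dict[tuple[int, int], int],
) -> tuple[tuple[int, int], int] | None:
    """Most frequent pair; ties break to the lexicographically smallest pair."""
    if not counts:
        return None
    best = min(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return best[0], best[1]


def replace_pair(
    tokens: Sequence[int] | np.ndarray,
    pair: tuple[int, int],
    new_symbol: int,
) -> np.ndarray:
    """Greedily replace non-overlapping occurrences of ``pair`` by ``new_symbol``.

    Consistent with :func:`count_pairs`: output length shrinks by exactly the
    pair's non-overlapping count.
    """
    x = np.asarray(tokens, dtype=np.int64)
    if x.size and (x == new_symbol).any():
        raise ValueError(f"new symbol {new_symbol} already present in sequence")
    left, right = pair
    if x.size < 2:
        return x.copy()
    if left != right:
        pos = np.flatnonzero((x[:-1] == left) & (x[1:] == right))
    else:
        starts, lengths = _run_length_encode(x)
        sel = (x[starts] == left) & (lengths >= 2)
        starts, halves = starts[sel], lengths[sel] // 2
        # start, start+2, ... within each run — flattened without a Python loop
        total = int(halves.sum())
        offsets = np.arange(total) - np.repeat(np.cumsum(halves) - halves, halves)
        pos = np.repeat(starts, halves) + 2 * offsets
    if pos.size == 0:
        return x.copy()
    out = x.copy()
    out[pos] = new_symbol
    return np.delete(out, pos + 1)


def calibrate(n_min: int, repetitions: int = 10, seed: int = 0) -> tuple[float, float]:
    """Measure (t_mv, t_mm): median seconds for the two multiply shapes."""
    if n_min < 1:
        raise ValueError("n_min must be positive")
    if repetitions < 1:
        raise ValueError("repetitions must be positive")
    rng = np.random.default_rng(seed)
    mat_a = rng.random((n_min, n_min))
    mat_b = rng.random((n_min, n_min))
    vec = rng.random(n_min)
    t_mv = []
    t_mm = []
    for _ in range(repetitions):
        t0 = time.perf_counter()
        mat_a @ vec
        t_mv.append(time.perf_counter() - t0)
        t0 = time.perf_counter()
        mat_a @ mat_b
        t_mm.append(time.perf_counter() - t0)
    tiny = 1e-12  # timer resolution floor; keeps both strictly positive
    return max(float(np.median(t_mv)), tiny), max(float(np.median(t_mm)), tiny)


def should_stop(calib: CompressionCalibration, p_prev: int, pre_prev: float) -> bool:
    """Stopping rule: true when ``e*(t_mv*p_prev - t_mm) - pre_prev <= 0``.

    ``p_prev`` is the best pair count found by the previous round's scan and
    ``pre_prev`` that round's duration, used as the estimate for the next
    round's cost. Requires concrete ``t_mv``/``t_mm`` on ``calib``.
    """
    if calib.t_mv is None or calib.t_mm is None:
        raise ValueError("should_stop needs concrete t_mv and t_mm")
    if p_prev < 0 or pre_prev < 0:
        raise ValueError("p_prev and pre_prev must be non-negative")
    return calib.e * (calib.t_mv * p_prev - calib.t_mm) - pre_prev <= 0


def preprocess(
    seq: ObservedSequence,
    calib: CompressionCalibration | None = None,
    stats_out: list[RoundStats] | None = None,
) -> PreprocessedSequence:
    """Compress ``seq`` by repeated most-frequent-pair substitution.

    The first symbol is split off; substitution runs on positions ``2..T``.
    With thresholds, each ``N_min`` (processed from largest to smallest, since
    larger state counts stop earlier) snapshots the sequence when its own
    criterion fires; without thresholds a single snapshot is stored under
    ``N_min = 1`` when the best pair count first repeats.

    ``stats_out``, when given, receives one :class:`RoundStats` per scan
    (round 0 is the initial scan).
    """
    if calib is None:
        calib = CompressionCalibration()

    current = seq.tokens[1:].copy()
    table_rules: list[PairRule] = []
    entries: list[ThresholdEntry] = []
    m_orig = seq.alphabet_size

    # Per-threshold cost-model times, measured unless explicitly overridden.
    per_threshold_calib: dict[int, CompressionCalibration] = {}
    for n_min in calib.thresholds:
        if calib.t_mv is not None and calib.t_mm is not None:
            per_threshold_calib[n_min] = calib
        else:
            t_mv, t_mm = calibrate(n_min)
            per_threshold_calib[n_min] = replace(calib, t_mv=t_mv, t_mm=t_mm)

    active = sorted(calib.thresholds, reverse=True)  # largest N_min stops first

    t0 = time.perf_counter()
    counts = count_pairs(current)
    best = select_pair(counts)
    pre_prev = time.perf_counter() - t0
    p_prev = best[1] if best is not None else 0
    if stats_out is not None:
        stats_out.append(RoundStats(0, p_prev, pre_prev))

    def snapshot(n_min: int) -> None:
        entries.append(
            ThresholdEntry(
                n_min=n_min,
                alphabet_size_used=m_orig + len(table_rules),
                tokens=current.copy(),
            )
        )

    round_index = 0
    while True:
        round_index += 1
        if calib.thresholds:
            while active and should_stop(per_threshold_calib[active[0]], p_prev, pre_prev):
                snapshot(active.pop(0))
            if not active:
                break
        if best is None:  # no pair left at all (remainder shorter than 2)
            break
        t0 = time.perf_counter()
        pair, count = best
        new_symbol = m_orig + len(table_rules)
        current = replace_pair(current, pair, new_symbol)
        table_rules.append(PairRule(new_symbol=new_symbol, left=pair[0], right=pair[1]))
        counts = count_pairs(current)
        best = select_pair(counts)
        p_i = best[1] if best is not None else 0
        pre_prev = time.perf_counter() - t0
        if stats_out is not None:
            stats_out.append(RoundStats(round_index, p_i, pre_prev))
        stop_default = not calib.thresholds and (p_i == p_prev or best is None)
        p_prev = p_i
        if stop_default:
            break

    # Any thresholds whose criterion never fired before pairs ran out.
    for n_min in active:
        snapshot(n_min)
    if not calib.thresholds:
        snapshot(1)

    return PreprocessedSequence(
        first_symbol=int(seq.tokens[0]),
        original_length=seq.length,
        original_alphabet_size=m_orig,
        table=SubstitutionTable(original_alphabet_size=m_orig, rules=tuple(table_rules)),
        per_threshold=tuple(sorted(entries, key=lambda e: e.n_min)),
        e_used=calib.e,
    )


def expand_symbol(symbol: int, table: SubstitutionTable) -> np.ndarray:
    """Recursively expand a symbol to its original-alphabet token sequence."""
    if not (0 <= symbol < table.extent):
        raise ValueError(f"symbol {symbol} outside table extent {table.extent}")
    m = table.original_alphabet_size
    stack = [int(symbol)]
    out: list[int] = []
    while stack:
        s = stack.pop()
        if s < m:
            out.append(s)
        else:
            rule = table.rules[s - m]
            stack.append(rule.right)  # right expands after left: push right first
            stack.append(rule.left)
    return np.asarray(out, dtype=np.int64)


def expand_sequence(pre: PreprocessedSequence, n_min: int | None = None) -> ObservedSequence:
    """Reconstruct the original sequence from a stored threshold's snapshot."""
    entry = select_threshold(pre, n_min) if n_min is not None else pre.per_threshold[0]
    m = pre.original_alphabet_size
    # Expand every distinct symbol once, then concatenate per token.
    expansions = {int(s): expand_symbol(int(s), pre.table) for s in np.unique(entry.tokens)}
    pieces = [np.asarray([pre.first_symbol], dtype=np.int64)]
    pieces.extend(expansions[int(s)] for s in entry.tokens)
    tokens = np.concatenate(pieces)
    return ObservedSequence(tokens=tokens, alphabet_size=m)


def select_threshold(pre: PreprocessedSequence, n_states: int) -> ThresholdEntry:
    """Stored entry with the largest ``N_min <= n_states``; fall back to the
    smallest stored threshold (with a warning) when none qualifies."""
    if n_states < 1:
        raise ValueError("n_states must be positive")
    if not pre.per_threshold:
        raise ValueError("preprocessing contains no stored thresholds")
    eligible = [e for e in pre.per_threshold if e.n_min <= n_states]
    if eligible:
        return max(eligible, key=lambda e: e.n_min)
    fallback = min(pre.per_threshold, key=lambda e: e.n_min)
    warnings.warn(
        f"no stored threshold <= {n_states} states; falling back to N_min={fallback.n_min}",
        stacklevel=2,
    )
    return fallback


def save_preprocessing(pre: PreprocessedSequence, directory: str | Path) -> None:
    """Persist the preprocessing as plain-text files in ``directory``.

    Layout: ``meta.json`` (format version, T, M, first symbol, e, thresholds
    with their alphabet sizes), ``rules.txt`` (one ``new left right`` triple
    per line in creation order), and ``tokens_<N_min>.txt`` per threshold.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = {
        "format_version": FORMAT_VERSION,
        "original_length": pre.original_length,
        "original_alphabet_size": pre.original_alphabet_size,
        "first_symbol": pre.first_symbol,
        "e_used": pre.e_used,
        "thresholds": [
            {"n_min": e.n_min, "alphabet_size_used": e.alphabet_size_used}
            for e in pre.per_threshold
        ],
    }
    (directory / "meta.json").write_text(json.dumps(meta, indent=2) + "\n")
    (directory / "rules.txt").write_text(
        "".join(f"{r.new_symbol} {r.left} {r.right}\n" for r in pre.table.rules)
    )
    for entry in pre.per_threshold:
        (directory / f"tokens_{entry.n_min}.txt").write_text(
            " ".join(str(int(t)) for t in entry.tokens) + "\n"
        )


def load_preprocessing(directory: str | Path, n_states: int) -> PreprocessedSequence:
    """Load a saved preprocessing restricted to the best threshold for ``n_states``."""
    directory = Path(directory)
    meta_path = directory / "meta.json"
    if not meta_path.is_file():
        raise FileNotFoundError(f"missing metadata file: {meta_path}")
    try:
        meta = json.loads(meta_path.read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"corrupt metadata file {meta_path}: {exc}") from exc
    if meta.get("format_version") != FORMAT_VERSION:
        raise ValueError(f"{meta_path}: unsupported format version {meta.get('format_version')}")
    if not meta.get("thresholds"):
        raise ValueError(f"{meta_path}: no stored thresholds")

    rules_path = directory / "rules.txt"
    if not rules_path.is_file():
        raise FileNotFoundError(f"missing rules file: {rules_path}")
    rules = []
    for lineno, line in enumerate(rules_path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 3:
            raise ValueError(f"{rules_path}: line {lineno}: expected 'new left right'")
        rules.append(PairRule(new_symbol=int(parts[0]), left=int(parts[1]), right=int(parts[2])))
    table = SubstitutionTable(
        original_alphabet_size=int(meta["original_alphabet_size"]), rules=tuple(rules)
    )

    entries = []
    for item in meta["thresholds"]:
        tok_path = directory / f"tokens_{int(item['n_min'])}.txt"
        if not tok_path.is_file():
            raise FileNotFoundError(f"missing tokens file: {tok_path}")
        parts = tok_path.read_text().split()
        tokens = np.asarray([int(p) for p in parts], dtype=np.int64)
        entries.append(
            ThresholdEntry(
                n_min=int(item["n_min"]),
                alphabet_size_used=int(item["alphabet_size_used"]),
                tokens=tokens,
            )
        )
    pre = PreprocessedSequence(
        first_symbol=int(meta["first_symbol"]),
        original_length=int(meta["original_length"]),
        original_alphabet_size=int(meta["original_alphabet_size"]),
        table=table,
        per_threshold=tuple(sorted(entries, key=lambda e: e.n_min)),
        e_used=float(meta["e_used"]),
    )
    chosen = select_threshold(pre, n_states)
    return replace(pre, per_threshold=(chosen,))
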