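"""Hidden Markov model parameters, validation, text serialization, sequences.

An HMM over ``N`` hidden states and ``M`` observable symbols is parameterised
by ``lambda = (pi, A, B)``:

* ``pi`` — length-``N`` initial state distribution, ``pi[i] = Pr(x_1 = i)``;
* ``A`` — ``N x N`` row-stochastic transition matrix,
  ``A[i, j] = Pr(x_t = j | x_{t-1} = i)``;
* ``B`` — ``N x M`` row-stochastic emission matrix,
  ``B[i, o] = Pr(y_t = o | x_t = i)``.

Zero entries are legal everywhere (sparse transition structures and
deterministic toy models need them); downstream code treats ``log 0`` as
``-inf`` rather than raising.

Observed sequences are plain integer token arrays over a declared alphabet
size; the alphabet size is explicit because the symbols actually present in a
file need not exhaust the symbols the model can emit.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "HMMParams",
    "ObservedSequence",
    "validate_hmm",
    "read_hmm",
    "write_hmm",
    "random_hmm",
    "read_seq",
    "write_seq",
]

#: Absolute tolerance on probability-vector sums.
ROW_SUM_TOL = 1e-9

_MAGIC = "rephmm_hmm 1"


@dataclass(frozen=True)
class HMMParams:
    """Container for ``(pi, A, B)``; arrays are copied and stored as float64."""

    pi: np.ndarray
    trans: np.ndarray
    emit: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "pi", np.asarray(self.pi, dtype=np.float64).reshape(-1))
        object.__setattr__(self, "trans", np.atleast_2d(np.asarray(self.trans, dtype=np.float64)))
        object.__setattr__(self, "emit", np.atleast_2d(np.asarray(self.emit, dtype=np.float64)))

    @property
    def n_states(self) -> int:
        return self.pi.shape[0]

    @property
    def n_observables(self) -> int:
        return self.emit.shape[1]


@dataclass(frozen=True)
class ObservedSequence:
    """Integer token sequence over the alphabet ``{0, ..., alphabet_size - 1}``."""

    tokens: np.ndarray
    alphabet_size: int

    def __post_init__(self) -> None:
        tokens = np.asarray(self.tokens, dtype=np.int64).reshape(-1)
        object.__setattr__(self, "tokens", tokens)
        if self.alphabet_size < 1:
            raise ValueError("alphabet_size must be positive")
        if tokens.size < 1:
            raise ValueError("observed sequence must contain at least one token")
        if tokens.min() < 0 or tokens.max() >= self.alphabet_size:
            bad = int(np.flatnonzero((tokens < 0) | (tokens >= self.alphabet_size))[0])
            raise ValueError(
                f"token {int(tokens[bad])} at position {bad} outside alphabet "
                f"[0, {self.alphabet_size})"
            )

    @property
    def length(self) -> int:
        return self.tokens.shape[0]


def validate_hmm(hmm: HMMParams) -> list[str]:
    """Return a list of invariant violations; an empty list means valid.

    Checks shapes, non-negativity and row-stochasticity of ``pi``, ``A`` and
    ``B`` to within ``ROW_SUM_TOL``. This is a reporting operation: it never
    raises.
    """
    issues: list[str] = []
    n = hmm.pi.shape[0]
    if hmm.trans.shape != (n, n):
        issues.append(f"trans has shape {hmm.trans.shape}, expected ({n}, {n})")
    if hmm.emit.shape[0] != n:
        issues.append(f"emit has {hmm.emit.shape[0]} rows, expected {n}")

    for name, arr in (("pi", hmm.pi), ("trans", hmm.trans), ("emit", hmm.emit)):
        if not np.all(np.isfinite(arr)):
            issues.append(f"{name} contains non-finite entries")
        neg = np.argwhere(arr < 0)
        for idx in neg:
            issues.append(f"{name} entry {tuple(int(i) for i in idx)} is negative")

    if abs(hmm.pi.sum() - 1.0) > ROW_SUM_TOL:
        issues.append(f"pi sums to {hmm.pi.sum()!r}, expected 1")
    if hmm.trans.shape == (n, n):
        for i, s in enumerate(hmm.trans.sum(axis=1)):
            if abs(s - 1.0) > ROW_SUM_TOL:
                issues.append(f"trans row {i} sums to {s!r}, expected 1")
    if hmm.emit.shape[0] == n:
        for i, s in enumerate(hmm.emit.sum(axis=1)):
            if abs(s - 1.0) > ROW_SUM_TOL:
                issues.append(f"emit row {i} sums to {s!r}, expected 1")
    return issues


def _require_valid(hmm: HMMParams) -> None:
    issues = validate_hmm(hmm)
    if issues:
        raise ValueError("invalid HMM: " + "; ".join(issues))


class HMMFormatError(ValueError):
    """Raised when an HMM file does not follow the documented text format."""


def _format_matrix(arr: np.ndarray) -> str:
    # 17 significant digits round-trips any float64 exactly.
    return "\n".join(" ".join(f"{v:.17g}" for v in row) for row in np.atleast_2d(arr))


def write_hmm(hmm: HMMParams, path: str | Path) -> None:
    """Write ``hmm`` to ``path`` in the line-oriented text format.

    The format is: a magic header, ``N``/``M`` size lines, then ``pi``, ``A``
    and ``B`` blocks of whitespace-separated decimals. Numbers are printed with
    17 significant digits so that :func:`read_hmm` reproduces every entry to
    full float64 precision.
    """
    _require_valid(hmm)
    out = io.StringIO()
    out.write(f"{_MAGIC}\n")
    out.write(f"N {hmm.n_states}\n")
    out.write(f"M {hmm.n_observables}\n")
    out.write("pi\n" + _format_matrix(hmm.pi) + "\n")
    out.write("A\n" + _format_matrix(hmm.trans) + "\n")
    out.write("B\n" + _format_matrix(hmm.emit) + "\n")
    Path(path).write_text(out.getvalue())


def _content_lines(text: str) -> list[tuple[int, str]]:
    lines: list[tuple[int, str]] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        stripped = raw.split("#", 1)[0].strip()
        if stripped:
            lines.append((lineno, stripped))
    return lines


def read_hmm(path: str | Path) -> HMMParams:
    """Parse an HMM file written by :func:`write_hmm` and validate it."""
    path = Path(path)
    lines = _content_lines(path.read_text())
    if not lines or lines[0][1] != _MAGIC:
        raise HMMFormatError(f"{path}: line 1: missing '{_MAGIC}' header")

    def expect(idx: int, prefix: str) -> tuple[int, str]:
        if idx >= len(lines):
            raise HMMFormatError(f"{path}: unexpected end of file, expected '{prefix}'")
        lineno, text = lines[idx]
        if not text.startswith(prefix):
            raise HMMFormatError(f"{path}: line {lineno}: expected '{prefix}', got '{text}'")
        return lineno, text

    lineno, text = expect(1, "N ")
    try:
        n = int(text.split()[1])
    except (IndexError, ValueError) as exc:
        raise HMMFormatError(f"{path}: line {lineno}: bad N line") from exc
    lineno, text = expect(2, "M ")
    try:
        m = int(text.split()[1])
    except (IndexError, ValueError) as exc:
        raise HMMFormatError(f"{path}: line {lineno}: bad M line") from exc
    if n < 1 or m < 1:
        raise HMMFormatError(f"{path}: N and M must be positive (got N={n}, M={m})")

    idx = 3

    def read_block(name: str, rows: int, cols: int) -> np.ndarray:
        nonlocal idx
        lineno, text = expect(idx, name)
        if text != name:
            raise HMMFormatError(f"{path}: line {lineno}: expected block '{name}'")
        idx += 1
        block = np.empty((rows, cols))
        for r in range(rows):
            if idx >= len(lines):
                raise HMMFormatError(f"{path}: unexpected end of file in block '{name}'")
            lineno, text = lines[idx]
            parts = text.split()
            if len(parts) != cols:
                raise HMMFormatError(
                    f"{path}: line {lineno}: block '{name}' row {r} has "
                    f"{len(parts)} entries, expected {cols}"
                )
            try:
                block[r] = [float(p) for p in parts]
            except ValueError as exc:
                raise HMMFormatError(f"{path}: line {lineno}: non-numeric entry") from exc
            idx += 1
        return block

    pi = read_block("pi", 1, n)[0]
    trans = read_block("A", n, n)
    emit = read_block("B", n, m)
    if idx != len(lines):
        lineno, _ = lines[idx]
        raise HMMFormatError(f"{path}: line {lineno}: trailing content after B block")

    hmm = HMMParams(pi=pi, trans=trans, emit=emit)
    _require_valid(hmm)
    return hmm


def random_hmm(n_states: int, n_observables: int, seed: int) -> HMMParams:
    """Draw a valid model with rows sampled from flat Dirichlet distributions."""
    if n_states < 1 or n_observables < 1:
        raise ValueError("n_states and n_observables must be positive")
    rng = np.random.default_rng(seed)
    pi = rng.dirichlet(np.ones(n_states))
    trans = rng.dirichlet(np.ones(n_states), size=n_states)
    emit = rng.dirichlet(np.ones(n_observables), size=n_states)
    return HMMParams(pi=pi, trans=trans, emit=emit)


def read_seq(path: str | Path, alphabet_size: int) -> ObservedSequence:
    """Read whitespace-separated integer tokens from a text file."""
    path = Path(path)
    parts = path.read_text().split()
    if not parts:
        raise ValueError(f"{path}: empty sequence file")
    tokens = np.empty(len(parts), dtype=np.int64)
    for i, p in enumerate(parts):
        try:
            tokens[i] = int(p)
        except ValueError as exc:
            raise ValueError(f"{path}: token {i}: '{p}' is not an integer") from exc
    try:
        return ObservedSequence(tokens=tokens, alphabet_size=alphabet_size)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def write_seq(seq: ObservedSequence | Sequence[int], path: str | Path) -> None:
    tokens = seq.tokens if isinstance(seq, ObservedSequence) else np.asarray(seq)
    Path(path).write_text(" ".join(str(int(t)) for t in tokens) + "\n")
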