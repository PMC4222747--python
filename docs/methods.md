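# Methods

## Model and likelihood

An HMM `λ = (π, A, B)` over `N` hidden states and `M` observable symbols
assigns an observed sequence `Y₁:T` the likelihood
`Pr(Y | λ) = Σ_paths Pr(Y, X | λ)`. The forward recursion computes this as a
right-to-left matrix chain: `α_T = C_{y_T} ··· C_{y₂} C₁` with
`C_o = B_o Aᵀ` (entry `(j, k) = b_{j,o} · a_{k,j}`) and `C₁ = B_{y₁} π`, and
`Pr(Y | λ)` is the entry sum of `α_T`. The chain convention puts later
observations on the **left**; consequently the composite matrix for an
adjacent observation pair (first `l`, then `r`) is `C_r · C_l`. This
orientation is not checkable by notation alone, so the test suite enforces it
by equivalence with the classical scaled forward and with exact path
enumeration, including models with structural zeros.

## Pair-substitution compression

Each round finds the most frequent adjacent pair of symbols, counted
greedily left-to-right without overlap (a run of `r` identical symbols
contributes `⌊r/2⌋`), and replaces every counted occurrence with a fresh
symbol. Ties between equally frequent pairs break to the lexicographically
smallest `(left, right)`; any fixed rule would do, but this one is
deterministic and independent of hash iteration order. Counts are recomputed
on the post-replacement sequence, so each round is two vectorised passes;
fusing them into one pass is a permissible optimisation only if it produces
identical output.

The first symbol `y₁` never participates in substitution and is stored
separately: the evaluation consumes it as the initial *vector* `C₁`, not as a
matrix, so keeping it apart makes the two-stage product well-formed without
any expansion at evaluation time. The compressed remainder therefore covers
positions `2..T`, and the expansion invariant (first symbol + recursively
expanded remainder equals the input exactly) is asserted property-style over
random sequences and at every stored threshold.

## Stopping criterion

Replacing a pair with count `p` saves `p` matrix-vector products per future
likelihood evaluation and costs one matrix-matrix product plus the round
itself. With `e` expected reuses of the preprocessing (default 1) and
measured times `t_mv`, `t_mm` at state count `N_min`, iteration `i` runs only
while `e·(t_mv·p_{i−1} − t_mm) − pre_{i−1} > 0`, where `pre_{i−1}` — the
previous round's duration — estimates the upcoming round's cost. For the
first decision the only cost paid so far is the initial pair scan, so its
duration serves as `pre₀`. `t_mv` and `t_mm` are medians over repeated
measurements, floored at 1 ps to survive timer-resolution zeros; explicit
values on the calibration object override measurement so that tests and
reruns are exactly reproducible.

Multiple `N_min` thresholds are processed from largest to smallest: a larger
state count makes the matrix-matrix product relatively costlier, so its
criterion fires no later, and compression continues for the smaller
thresholds after each snapshot. With no thresholds, compression stops the
first time the best pair count repeats (`p_i = p_{i−1}`) — a model-free
proxy for diminishing returns. Whatever the rule, a snapshot taken at any
stopping point evaluates to the same likelihood (the same chain regrouped);
this invariance is tested to below 1e−9 relative drift.

## Numerical stability

Probability matrices shrink exponentially under multiplication, so both
stages renormalise. Stage 1 divides every matrix by its entry sum `c` and
propagates log scales: `s̃ = log c` for original symbols,
`s̃ = log c + s̃_left + s̃_right` for composites, so the scale of a deeply
nested composite is exact without forming the underflowing raw product.
Stage 2 renormalises the state vector after every multiplication by its
entry sum `d`, accumulating `d̃ = log d`. The log-likelihood (natural log
throughout) is `Σ s̃_{tokens} + Σ d̃`. The initial vector `C₁` is used raw;
its mass enters through the first `d`, which is algebraically equivalent to
normalising it up front.

Degenerate mass (`c = 0` or `d = 0`) means the observations are impossible
under the model; the result is `−∞`, never an exception, because optimisers
routinely probe such parameter regions. Length-1 sequences are legal: the
likelihood is the entry sum of `C₁` alone.

The blocked stage-2 variant partitions the compressed remainder into
contiguous blocks, forms each block's normalised matrix product, and applies
the block products to `C₁` in time order. Its contract is value equality
with the sequential sweep (≤1e−9 relative), which is what makes concurrent
block evaluation safe; no threading is built in. Stage 1 is kept sequential
by design — its workload (`M′` small products) does not repay coordination.

## Reference algorithms

The classical scaled forward (per-column normalisation, log of the column
sums) is the primary oracle; exact path enumeration (guarded at
`N^T ≤ 10⁶`) is the second, independent one, and the two are checked against
each other as well — plus against an external library implementation in one
cross-check test. Viterbi runs in log space with ties broken toward the
lower state index; posterior decoding reuses the forward column scales in
the backward pass (the standard stable formulation) and returns both the
posterior table and its per-position argmax path, since either may be wanted.
Decoding operates on the uncompressed sequence: max-product recursions do not
factor through composite matrices, so the preprocessing cannot be reused
there.

## Synthetic data and training

Binary sequences with i.i.d. tokens and `Pr(1) = f` emulate low-complexity
genomic inputs — a pairwise alignment summarised as identical/different site
indicators is a rare-event binary string, and `f` sweeps the compressibility
axis (defaults used in tests: `T = 10⁵`, `f ∈ {0.0001, 0.001, 0.01, 0.05}`,
5 seeds per point). What they do not emulate is autocorrelation: variant
sites cluster in real alignments, so real compression ratios differ from the
i.i.d. prediction at equal frequency. Passing the monotonicity check
therefore demonstrates the work-saving *mechanism* (fewer stage-2 steps on
less complex input), not a wall-clock prediction for any particular genome.

Training maximises the compressed-sequence log-likelihood with Nelder-Mead
through a user-supplied parameterisation (vector → model), mirroring how
domain models map a few scientific parameters to full matrices; a generic
softmax parameterisation (rows of `A` and `B`, uniform `π`) is bundled.
Defaults: `xatol = 1e−6`, `fatol = 1e−8`, `maxiter = 2000`; invalid parameter
vectors score `−∞` rather than raising. The optimiser settings are this
package's own choices, documented rather than claimed optimal. The recovery
study (2-state symmetric switch rate 0.1, emission fidelity 0.9, `T = 5000`)
recovers the rate within 0.05 absolute; at these sizes every test and the
acceptance script finish in a few minutes on one core.

## File formats

All persistence is plain text. HMM files: magic `rephmm_hmm 1`, `N`/`M`
lines, `pi`/`A`/`B` blocks, `#` comments, numbers printed with 17
significant digits so round-trips are exact to the float64 bit. Sequences:
whitespace-separated base-10 integers with the alphabet size supplied by the
caller (symbols present in a file need not exhaust the model's alphabet).
Preprocessing directories: `meta.json` (format version, length, alphabet,
first symbol, `e`, thresholds with their alphabet sizes), `rules.txt`
(`new left right` per line, creation order), one `tokens_<N_min>.txt` per
threshold. Loading selects the largest stored `N_min ≤ n_states`, falling
back to the smallest with a warning.

## Limitations

- One table per sequence: no shared compression across multiple sequences.
- No Baum-Welch; training is generic likelihood maximisation only.
- The cost model assumes matrix multiplications dominate evaluation time;
  for very small `N` the Python-level loop overhead blurs the measured
  `t_mv`/`t_mm` ratio, which is why reproducible pipelines inject explicit
  times.
- Validation tolerance on row sums is 1e−9 absolute — tolerant of parsed
  decimals, strict enough to catch construction bugs.
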