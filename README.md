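# rephmm

A hidden Markov model (HMM) likelihood toolkit that exploits repetitions in
the observed sequence to speed up the forward algorithm.

Genome-scale HMM analyses — comparative-genomics models over alignment
columns, gene finders, segmentation models — evaluate the forward algorithm
on sequences of 10⁷–10⁹ symbols, often hundreds of times inside a likelihood
optimisation. The forward recursion can be written as a matrix chain: with
per-symbol matrices `C_o = B_o Aᵀ` (`B_o` the diagonal matrix of emission
probabilities of symbol `o`, `A` the transition matrix) and initial vector
`C₁ = B_{y₁} π`,

    Pr(Y₁:T | λ) = Σᵢ (C_{y_T} C_{y_{T-1}} ··· C_{y₂} C₁)ᵢ .

Because matrix multiplication is associative, a repeated substring of the
observations is a repeated sub-product that only needs to be computed once.
`rephmm` compresses the sequence by repeatedly replacing the most frequent
non-overlapping adjacent pair of symbols with a fresh composite symbol
(digram/re-pair style). The compression depends only on the sequence — never
on the model — so one preprocessing is saved to disk and reused for every
model evaluated against that sequence.

The likelihood is then computed in two stages:

1. **Stage 1** (`O(M′N³)`): build one matrix per alphabet symbol — originals
   by formula, each composite as one product of its constituents' matrices.
   Every matrix is normalised by its entry sum `c`, with log scales tracked
   per symbol (`s̃ = log c` for originals, `s̃ = log c + s̃_left + s̃_right`
   for composites).
2. **Stage 2** (`O(T′N²)`): sweep the compressed remainder with matrix-vector
   products, renormalising the state vector each step by its entry sum `d`
   and accumulating `d̃ = log d`. The result is

       log Pr(Y₁:T | λ) = Σₜ s̃_{y′ₜ} + Σⱼ d̃ⱼ ,

   finite wherever the probability is positive, no matter how long the
   sequence — the naive product underflows to zero within a few thousand
   symbols.

Compression stops when it stops paying: replacing a pair occurring `p` times
saves `p` matrix-vector products per future evaluation at the price of one
matrix-matrix product, so with `e` expected reuses and measured times
`t_mv`, `t_mm` for the two shapes at the smallest state count of interest,
rounds run only while `e·(t_mv·p − t_mm)` exceeds the round's own cost.
Snapshots can be kept for several state-count thresholds at once.

The package also provides the classical scaled forward algorithm, an exact
path-enumeration likelihood (both used as oracles in the test suite), Viterbi
and posterior decoding, HMM sampling, synthetic binary sequences of
controlled complexity, and Nelder-Mead likelihood training through arbitrary
parameterisations.

## Worked example

The 14-symbol binary sequence `10100010011001` contains the pair `01` four
times without overlap, so its composite matrix is computed once and reused
three times. Preprocess it and evaluate a 2-state model:

```sh
$ printf '1 0 1 0 0 0 1 0 0 1 1 0 0 1\n' > fig.txt
$ rephmm preprocess fig.txt pp -m 2
round 0: best pair count 4, 0.000325s
round 1: best pair count 3, 0.000128s
round 2: best pair count 1, 0.000082s
round 3: best pair count 1, 0.000085s
stopped for N_min=1: alphabet 5, compressed length 5
pp
$ rephmm likelihood model.txt --preprocessed pp
loglik -10.5385428838
stage2_steps 5 stage1_products 3
```

Round 0 finds the most frequent pair (4 occurrences); with no state-count
thresholds, compression stops the first time the best count repeats (rounds
2–3, both 1). The 13 trailing symbols compress to 5 tokens over an alphabet
of 5 (2 original symbols + 3 composites), so stage 2 performs 5 matrix-vector
products and stage 1 adds 3 matrix products — 8 multiplications in place of
the classical 13. The log-likelihood is identical to the classical
algorithm's, which is always available for auditing:

```sh
$ rephmm likelihood model.txt --seq-file fig.txt -m 2 --reference
loglik -10.5385428838
```

Here `model.txt` holds `π = (0.5, 0.5)`, `A = [[0.9, 0.1], [0.2, 0.8]]`,
`B = [[0.7, 0.3], [0.1, 0.9]]` in the package's text format (see
`rephmm.model.write_hmm`). On compressible inputs the saving is drastic: the
all-zeros sequence of length 1024 needs 19 multiplications instead of 1023.

Decoding and training run from the same files:

```sh
$ rephmm decode fig.txt model.txt -m 2 --mode posterior --out path.txt --posterior-out post.txt
score -10.5385428838
$ rephmm train fig.txt -m 2 -n 2 --seed 0
```

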