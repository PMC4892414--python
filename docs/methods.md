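# Methods

## Security model

Both parties are **semi-honest**: they follow the protocol but may try to
infer extra information from the messages they legitimately receive. One
targeted strengthening beyond that model is included: the guard term
folded into every server reply destroys the response to any query vector
that is not a well-formed unit vector, so a user who deviates by encoding
several non-zero slots (to extract multiple table entries from one reply)
learns nothing. Full malicious security would additionally require
zero-knowledge proofs that each ciphertext encrypts a bit; those are out
of scope, but the abstract cryptosystem interface leaves room for schemes
that support them.

What each party learns:

- **User:** the match length only. Interval endpoints stay rotation-masked
  throughout; termination is signalled by `ε` shuffled flags of which at
  most one decrypts to zero, hiding the exact match count.
- **Server:** nothing about the query symbols (they arrive encrypted under
  the user's key and every branch of the reply is computed), nothing about
  the true start position beyond membership in the `D` declared positions,
  and nothing about the match length (rounds continue with decoys until
  the fixed round budget is exhausted; all rounds are shape-identical).
- **Transcript observer:** only public parameters. Per-round sizes are
  constant: upload `2D(M+1) + 1` and download `2|Σ| + ε` ciphertexts in
  linear mode.

The server must never hold the user's secret key; the test suite includes
a structural check that no server-side object reaches one.

## Cryptosystem

The additively homomorphic layer is an abstract interface (`encrypt`,
`add`, `smul`, `rerandomize`, zero test) with a Paillier implementation:

- `n = pq` with `g = n + 1`, so `Enc(m) = (1 + mn)·r^n mod n²`. Decryption
  uses CRT with precomputed per-prime constants.
- Negation uses the modular inverse `c^(−1) mod n²` rather than an
  `(n−1)`-fold exponentiation.
- `encrypt_trivial` (deterministic, randomizer 1) exists only as a
  starting accumulator inside homomorphic sums whose result is
  re-randomized before leaving the party that computed it.
- Multiplicative randomizers are drawn uniformly from `1 .. n−1`; rotation
  masks uniformly from `0 .. L−1` where `L` is the table length — the
  rotation modulus is the vector length, never the cryptosystem modulus.

Key size defaults to 512 bits in examples and tests to keep runtimes
short; production use should choose ≥ 2048 bits (`keygen(2048)`). A
lifted-ElGamal-style scheme (faster, but decryption limited to small
plaintexts plus a zero test) would satisfy the same interface; only
Paillier is implemented here.

## Protocol parameters and defaults

- `D` (declared positions, default 1): the true start position is hidden
  among `D − 1` decoys sampled uniformly from the other valid start
  positions. Upload scales linearly in `D`.
- `ε` (anonymity level, default 1): the match must be carried by at least
  `ε` haplotypes; the user only learns whether the interval size dropped
  below `ε`. Download grows by one flag per unit of `ε`.
- `transport` (default `linear`): `linear` sends length-`L` reply vectors;
  `scot` uses the sublinear two-dimensional `(block, offset)` encoding
  with `B = ⌈√L⌉`. Under rotation masking the additive de-masking of an
  encrypted block index cannot undo the modulo-`K` wraparound of the block
  coordinate, so the sublinear transport sends **two** indicator vectors
  (block and offset) and the server de-rotates both before evaluation.
- Round budget: a query of length `ℓ` runs `ℓ + 1` rounds. The flag of
  round `i` tests prefix length `i − 2`, so distinguishing a full-length
  match from length `ℓ − 1` requires one round beyond `ℓ`. The final
  round is flag-only; if its column index would fall past the last panel
  position it is clamped (the looked-up values are never used), while an
  overflow in any earlier round is an error.

## Synthetic data

`generate_panel` draws `M` haplotypes by copying blocks from a small set
of founder haplotypes (block lengths geometric with mean
`block_length_mean`, default 20 positions) and then applying independent
point mutations (rate 0.01). This emulates the linkage-disequilibrium
block structure that makes PBWT intervals informative: rows share long
stretches, so set-longest matches of 5–30 positions are typical at the
default `M=100, N=200`. It does **not** emulate realistic allele
frequency spectra, recombination hotspots, population structure, or
phasing error; panels are binary by default but any alphabet size ≥ 2 is
supported. Real data can be loaded from phased biallelic SNP records of a
VCF (indels and multi-allelic records are skipped; unphased genotypes are
an error, never silently phased).

## Baseline

The exhaustive baseline builds, for each `k = 1, 2, …`, a presence table
over all `|Σ|^k` k-mers starting at `t` (thresholded at `ε`) and fetches
the user's bit by single-shot sublinear OT, stopping at the first absent
k-mer. Table size is capped at `2^20` entries; beyond that the approach is
declared intractable, which is the point of the comparison: its per-step
communication grows like `√(|Σ|^k)` while the recursive protocol's is
constant per round, so the baseline loses above moderate match lengths.

## Numerical and implementation choices

- All arithmetic on ciphertexts is exact big-integer arithmetic; there is
  no floating point anywhere in the protocol path.
- PBWT construction is the incremental counting sort (`O(MN)`), validated
  against an explicit reverse-prefix sorting oracle in the tests.
- Plaintext spaces: table entries are indices `< L ≤ D(M+1)`, far below
  the Paillier modulus, so additive masks modulo `L` never wrap the
  plaintext space.
- Communication accounting counts ciphertexts per logical message and
  converts to bytes as `2 × key_bits / 8` per Paillier ciphertext
  (elements of `Z_{n²}`). Byte counts exclude framing overhead.

## Limitations

- Semi-honest model with the single guard strengthening described above;
  no bit-ness proofs.
- Both roles run in one process; there is no network layer. The
  transcript object records exactly what would cross the wire.
- Queries are contiguous haplotype segments: no wildcards, no set-maximal
  (all-positions) variant, no indels.
- No benchmarking at biobank scale; the accounting comparisons are in
  ciphertext counts, not wall-clock time.
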