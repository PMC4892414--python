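# pbwtsec

Privacy-preserving set-longest-match search over haplotype panels,
combining the positional Burrows–Wheeler transform (PBWT) with additively
homomorphic encryption and recursive oblivious transfer.

## The problem

A server holds a panel of `M` haplotype sequences over `N` genomic
positions. A user holds a short query haplotype and a start position `t`,
and wants the **set-longest match**: the largest `k` such that at least
`ε` panel haplotypes agree with the query on positions `t .. t+k-1`. This
is the core primitive behind genotype imputation, relative detection, and
rare-variant lookups — but both sides' data are sensitive. The user must
not reveal the query (or even `t`, or how long the match was), and the
server must not reveal anything about the panel beyond the single match
length.

## The algorithm

**Plaintext PBWT.** Column `k` of the PBWT stores the `(k+1)`-th symbols
of all haplotypes stably sorted by their reversed prefixes `x[k..1]`. A
set of haplotypes matching the query's first `i` symbols is then a
contiguous interval `(f, g]` with `g − f` matches, updated per symbol `c`
in O(1) via a lookup vector

```
v_c[i] = CF_c + Rank_c(col, i),        f' = v_c[f],   g' = v_c[g],
```

where `Rank_c(col, i)` counts occurrences of `c` in the first `i` entries
of the sorted column and `CF_c` counts symbols smaller than `c`. Search
starts from `(0, M]` and extends one position per step; the first step at
which `g − f < ε` determines the match length.

**Private evaluation.** The interval endpoints are never revealed to
either side:

- The user sends `Enc(c)` plus two encrypted indicator vectors marking the
  (rotation-masked) positions of `f` and `g` inside a concatenated table of
  `D` declared start positions (`D − 1` decoys hide the true `t`).
- The server answers with one ciphertext per alphabet symbol and endpoint,
  computed as an inner product of the indicator vector with its lookup
  tables — an oblivious transfer, so the server never learns which entry
  was read. Replies are masked by fresh random rotations modulo the table
  length, so the user never learns plaintext endpoints either; successive
  rounds chain these masked lookups (recursive OT).
- Each round also carries `ε` shuffled encrypted flags, of which one
  decrypts to zero exactly when the interval has dropped below `ε`
  matches. The user keeps sending shape-identical decoy rounds afterwards,
  so the transcript length never leaks the match length.
- Replies for the symbol the query did *not* send are multiplied by a
  conditional randomizer keyed to `Enc(S_i) − Enc(c)`, so only the reply
  consistent with the committed query symbol is meaningful.
- A guard term `w = r·(Σ_i Enc(q_i) − Enc(1))` is folded into every reply;
  it vanishes only for well-formed unit-vector queries and otherwise
  destroys the response, blocking multi-slot extraction attacks.

Two OT transports are provided: a **linear** one (reply vectors of length
`L`) and a **sublinear** one encoding indices in a two-dimensional
`(block, offset)` code of size about `√L` each. The per-round upload in
linear mode is exactly `2D(M+1) + 1` ciphertexts and the download exactly
`2|Σ| + ε`, constant across rounds and independent of the query content.

An **exhaustive baseline** answers the same question by enumerating all
`|Σ|^k` possible k-mers into a presence table queried via single-shot
sublinear OT for growing `k`; its cost grows like `√(|Σ|^k)` per step and
overtakes the recursive protocol at moderate match lengths.

## Worked example

Generate a synthetic panel with haplotype-block structure, check the
plaintext answer, then run both protocol roles locally:

```console
$ pbwtsec synth --m 30 --n 60 --seed 7 -o demo_panel.txt
wrote 30x60 panel to demo_panel.txt

$ pbwtsec query demo_panel.txt --query 010110 --start 12
set-longest match at position 12: length 3, 5 matching haplotype(s)

$ pbwtsec demo demo_panel.txt --query 010110 --start 12 \
      --decoys 3 --eps 2 --seed 42 --save-transcript demo_tr.json
protocol match length: 3 (plaintext oracle: 3, 5 matching)
rounds: 7
upload per round (ciphertexts): 187
download per round (ciphertexts): 6
total: 1351 ciphertexts ~ 168.9 KiB
```

The encrypted protocol returns the same length 3 that the plaintext PBWT
search found. With `D = 3` declared positions and `M = 30` the upload is
`2·3·31 + 1 = 187` ciphertexts per round; with a binary alphabet and
`ε = 2` the download is `2·2 + 2 = 6`. All 7 rounds are identical in
shape (the query has 6 symbols; round `i` tests prefix length `i − 2`, so
`ℓ + 1` rounds cover every outcome). Verify a saved transcript with:

```console
$ pbwtsec account demo_tr.json
{
  "rounds": 7,
  "uploads_per_round": [187, 187, 187, 187, 187, 187, 187],
  "downloads_per_round": [6, 6, 6, 6, 6, 6, 6],
  "total_ciphertexts": 1351,
  "total_bytes": 172928
}
```

The exhaustive baseline gives the same answer with different
communication scaling:

```console
$ pbwtsec baseline demo_panel.txt --query 010110 --start 12 --seed 42
baseline match length: 3
total communication: 25 ciphertexts over 4 k-mer probes
```

Cheap here, but its per-probe cost grows like `√(2^k)` while the
recursive protocol's stays flat.

Python API equivalent:

```python
from pbwtsec import SynthConfig, generate_panel, run_protocol

panel = generate_panel(SynthConfig(M=30, N=60, seed=7))
result = run_protocol(panel, [0, 1, 0, 1, 1, 0], t=12, D=3, eps=2, seed=42)
print(result.match_length)
```

## Reproduction

`scripts/acceptance.py` runs the package's main computations — end-to-end
protocol instances checked against a plaintext oracle, recursive-OT
chains, homomorphic identities, match-flag soundness, the two-slot decode
attack with and without the guard, and the communication accounting
comparison against the exhaustive baseline — and writes the resulting
quantities to a JSON file:

```console
$ python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

All randomness derives from `--seed`. The run takes about a minute on one
CPU.

## Layout

- `src/pbwtsec/pbwt.py` — plaintext PBWT construction and interval search
- `src/pbwtsec/crypto.py` — additively homomorphic interface + Paillier
- `src/pbwtsec/ot.py` — OT, rotation masking, recursive and sublinear OT
- `src/pbwtsec/protocol.py` — the two-party search protocol
- `src/pbwtsec/baseline.py` — exhaustive k-mer baseline over sublinear OT
- `src/pbwtsec/synth.py`, `panel.py` — synthetic panels, plain/VCF input
- `src/pbwtsec/transcript.py` — communication accounting
- `docs/methods.md` — model, assumptions, and design notes
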