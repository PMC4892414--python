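"""Exhaustive k-mer baseline achieving the same utility as the PBWT search.

Instead of extending an interval one symbol per round, the server
enumerates every possible k-mer starting at position t and stores a
presence bit (thresholded at the anonymity level eps); the user fetches the
bit for its own k-mer by single-shot sublinear-communication OT, for
k = 1, 2, ... until a lookup returns 0.  The table has |sigma|^k entries,
so per-step communication grows like sqrt(|sigma|^k) reply blocks - the
exponential-versus-linear separation the recursive protocol exists to
avoid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .crypto import KeyPair, keygen, make_rng
from .ot import scot_prepare, scot_reply
from .panel import HaplotypePanel
from .transcript import ProtocolTranscript

__all__ = ["KmerTable", "build_kmer_table", "exhaustive_longest_match",
           "encode_kmer", "TABLE_CAP"]

TABLE_CAP = 1 << 20  # hard cap on |sigma|^k table entries


def encode_kmer(symbols, alphabet_size: int) -> int:
    """Big-endian base-|sigma| integer code of a k-mer."""
    code = 0
    for s in symbols:
        s = int(s)
        if not 0 <= s < alphabet_size:
            raise ValueError("symbol out of alphabet range")
        code = code * alphabet_size + s
    return code


@dataclass(frozen=True)
class KmerTable:
    """Presence bits for all k-mers starting at position t, thresholded at
    eps: presence[code(w)] = 1 iff at least eps haplotypes carry w."""

    k: int
    t: int
    eps: int
    presence: np.ndarray


def build_kmer_table(panel: HaplotypePanel, t: int, k: int, eps: int = 1,
                     cap: int = TABLE_CAP) -> KmerTable:
    if t + k - 1 > panel.N or t < 1 or k < 1:
        raise ValueError("k-mer window out of panel range")
    size = panel.alphabet_size**k
    if size > cap:
        raise ValueError(
            f"table of {size} entries exceeds the cap of {cap}; the "
            "exhaustive approach is intractable at this match length"
        )
    counts = np.zeros(size, dtype=np.int64)
    window = panel.sequences[:, t - 1 : t - 1 + k]
    weights = panel.alphabet_size ** np.arange(k - 1, -1, -1)
    codes = window @ weights
    np.add.at(counts, codes, 1)
    return KmerTable(k=k, t=t, eps=eps, presence=(counts >= eps).astype(np.int64))


def exhaustive_longest_match(panel: HaplotypePanel, query, t: int,
                             eps: int = 1, *, max_k: int | None = None,
                             keypair: KeyPair | None = None,
                             key_bits: int = 512, seed: int | None = None,
                             cap: int = TABLE_CAP,
                             transcript: ProtocolTranscript | None = None,
                             ) -> int:
    """Find the set-longest match by querying presence tables of growing k
    over single-shot SC-OT; stops at the first absent k-mer."""
    query = [int(s) for s in np.asarray(query)]
    ell = len(query)
    if ell < 1:
        raise ValueError("query must be non-empty")
    if t + ell - 1 > panel.N:
        raise ValueError("query runs past the last panel position")
    max_k = ell if max_k is None else min(max_k, ell)
    rng = make_rng(seed)
    if keypair is None:
        keypair = keygen(key_bits, rng)
    pk, sk = keypair.public_key, keypair.secret_key
    if transcript is not None:
        transcript.meta.update({
            "M": panel.M, "alphabet_size": panel.alphabet_size,
            "eps": eps, "transport": "scot-baseline", "key_bits": key_bits,
        })
    for k in range(1, max_k + 1):
        table = build_kmer_table(panel, t, k, eps, cap=cap)
        code = encode_kmer(query[:k], panel.alphabet_size)
        idx, enc_t0, encq = scot_prepare(code, len(table.presence), pk, rng)
        if transcript:
            transcript.log(k, "user", "kmer-query", 1 + encq.length)
        replies = scot_reply(enc_t0, encq, table.presence, pk, rng)
        if transcript:
            transcript.log(k, "server", "kmer-reply", len(replies))
        if sk.decrypt(replies[idx.t0]) != 1:
            return k - 1
    return max_k
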