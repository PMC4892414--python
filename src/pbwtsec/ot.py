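"""Oblivious transfer over additively homomorphic encryption.

Three layers:

* plain 1-out-of-L OT with linear communication: the user uploads an
  encrypted unit indicator vector, the server replies with the encrypted
  inner product against its plaintext vector;
* recursive OT with rotation masking (ROT): each fetched value indexes the
  next lookup; the server adds a random rotation r modulo the *vector
  length* to its reply, and de-rotates the user's next indicator vector by
  the stored offset, so the user only ever sees uniformly masked
  intermediate values while the server recovers true coordinates in
  encrypted form only;
* sublinear-communication OT (SC-OT): the index is split into a
  two-dimensional (block, within-block) representation of size about
  sqrt(L) each, cutting the upload from L to ~2 sqrt(L) ciphertexts at the
  price of ~L/sqrt(L) reply ciphertexts, the non-target blocks being masked
  by r_k * (t0 - k) terms.

The recursive SC-OT variant sends both coordinates as indicator vectors
(never as Enc(t0)): de-masking an additively masked block coordinate would
wrap modulo the block count, which homomorphic arithmetic modulo the
cryptosystem modulus cannot undo, whereas rotating an indicator vector is
an exact group action.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass

from .crypto import AHEPublicKey, AHESecretKey, Ciphertext, keygen, make_rng
from .transcript import ProtocolTranscript

__all__ = [
    "EncQueryVector",
    "SCOTIndex",
    "prep_query",
    "ot_reply",
    "perm",
    "rot_reply",
    "recursive_ot",
    "scot_encode",
    "scot_decode",
    "scot_prepare",
    "scot_reply",
    "scot_recursive_reply",
]


@dataclass(frozen=True)
class EncQueryVector:
    """Encrypted indicator vector; honest plaintext is a unit vector.

    Bit-ness cannot be verified without the secret key - the protocol layer
    adds a homomorphic sum check (guard) to every reply instead.
    """

    entries: tuple[Ciphertext, ...]

    @property
    def length(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class SCOTIndex:
    """Two-dimensional index t = t0 * block + t1 with block = ceil(sqrt(L))."""

    t0: int
    t1: int
    block: int


def prep_query(t: int, length: int, pk: AHEPublicKey,
               rng: random.Random | None = None) -> EncQueryVector:
    """Encrypt the unit indicator vector with its 1 at position t."""
    if not 0 <= t < length:
        raise ValueError(f"index {t} out of range 0..{length - 1}")
    rng = rng or make_rng()
    return EncQueryVector(
        tuple(pk.encrypt(1 if i == t else 0, rng) for i in range(length))
    )


def _weighted_sum(pk: AHEPublicKey, entries, weights) -> Ciphertext:
    """Homomorphic inner product of encrypted entries with plaintext weights."""
    acc = pk.encrypt_trivial(0)
    for entry, w in zip(entries, weights):
        w = int(w)
        if w:
            acc = pk.add(acc, pk.smul(w, entry))
    return acc


def ot_reply(encq: EncQueryVector, v, pk: AHEPublicKey,
             rng: random.Random | None = None) -> Ciphertext:
    """Server reply of plain OT: decrypts to v[t] for an honest query at t."""
    if encq.length != len(v):
        raise ValueError("query vector and database lengths differ")
    rng = rng or make_rng()
    return pk.rerandomize(_weighted_sum(pk, encq.entries, v), rng)


def _rotate(encq: EncQueryVector, r: int) -> EncQueryVector:
    """Move entry i to position (i - r) mod L without re-randomizing; only
    for server-internal de-rotation of aggregates that get re-randomized."""
    length = encq.length
    out: list[Ciphertext | None] = [None] * length
    for i, entry in enumerate(encq.entries):
        out[(i - r) % length] = entry
    return EncQueryVector(tuple(out))  # type: ignore[arg-type]


def perm(encq: EncQueryVector, r: int, pk: AHEPublicKey,
         rng: random.Random | None = None) -> EncQueryVector:
    """Rotation by r with re-randomization so positions are unlinkable."""
    if not 0 <= r < encq.length:
        raise ValueError(f"rotation offset {r} out of range")
    rng = rng or make_rng()
    rotated = _rotate(encq, r)
    return EncQueryVector(tuple(pk.rerandomize(c, rng) for c in rotated.entries))


def rot_reply(encq_masked: EncQueryVector, v, r: int, r_prev: int,
              pk: AHEPublicKey, rng: random.Random | None = None) -> Ciphertext:
    """ROT: de-rotate the user's masked query by r_prev, reply with the
    looked-up value masked by +r modulo the vector length."""
    length = len(v)
    if encq_masked.length != length:
        raise ValueError("query vector and database lengths differ")
    rng = rng or make_rng()
    true_q = _rotate(encq_masked, r_prev)
    masked_v = [(int(x) + r) % length for x in v]
    return pk.rerandomize(_weighted_sum(pk, true_q.entries, masked_v), rng)


# ---------------------------------------------------------------------------
# Sublinear-communication OT
# ---------------------------------------------------------------------------

def scot_encode(t: int, length: int) -> SCOTIndex:
    """Split index t into (block, within-block) with block = ceil(sqrt(L))."""
    if not 0 <= t < length:
        raise ValueError(f"index {t} out of range 0..{length - 1}")
    b = math.isqrt(length)
    if b * b < length:
        b += 1
    return SCOTIndex(t0=t // b, t1=t % b, block=b)


def scot_decode(idx: SCOTIndex) -> int:
    return idx.t0 * idx.block + idx.t1


def _n_blocks(length: int, block: int) -> int:
    return -(-length // block)


def scot_prepare(t: int, length: int, pk: AHEPublicKey,
                 rng: random.Random | None = None
                 ) -> tuple[SCOTIndex, Ciphertext, EncQueryVector]:
    """User side of single-shot SC-OT: Enc(t0) plus the within-block
    indicator vector of length ceil(sqrt(L))."""
    rng = rng or make_rng()
    idx = scot_encode(t, length)
    enc_t0 = pk.encrypt(idx.t0, rng)
    encq = prep_query(idx.t1, idx.block, pk, rng)
    return idx, enc_t0, encq


def scot_reply(enc_t0: Ciphertext, encq: EncQueryVector, v,
               pk: AHEPublicKey, rng: random.Random | None = None
               ) -> list[Ciphertext]:
    """Server side of single-shot SC-OT: one ciphertext per block; only the
    user's block decrypts to v[t], the others are masked by r_k * (t0 - k)
    with nonzero random r_k."""
    rng = rng or make_rng()
    b = encq.length
    k_blocks = _n_blocks(len(v), b)
    padded = [int(x) for x in v] + [0] * (k_blocks * b - len(v))
    out = []
    for k in range(k_blocks):
        acc = _weighted_sum(pk, encq.entries, padded[k * b : (k + 1) * b])
        r_k = rng.randrange(1, pk.n)
        mask = pk.smul(r_k, pk.add(enc_t0, pk.encrypt_trivial(-k)))
        out.append(pk.rerandomize(pk.add(acc, mask), rng))
    return out


def scot_recursive_reply(q0: EncQueryVector, q1: EncQueryVector, v,
                         a_prev: int, b_prev: int, a_new: int, b_new: int,
                         pk: AHEPublicKey, rng: random.Random | None = None
                         ) -> tuple[list[Ciphertext], list[Ciphertext]]:
    """One server round of recursive OT over the SC-OT transport.

    The user's block indicator q0 (length K = ceil(L/B)) and within-block
    indicator q1 (length B) are built against coordinates masked by the
    previous offsets (a_prev mod K, b_prev mod B).  The server de-rotates
    both, looks up the derived vectors v0 = v div B and v1 = v mod B masked
    by the next offsets (a_new, b_new), and returns the two reply vectors
    rotated by a_prev so the user indexes them with its *masked* block
    coordinate.  Non-target blocks carry a nonzero r_k * (1 - q0'[k]) mask.
    """
    rng = rng or make_rng()
    b = q1.length
    k_blocks = q0.length
    if _n_blocks(len(v), b) > k_blocks:
        raise ValueError("block indicator too short for the database")
    q0_true = _rotate(q0, a_prev)
    q1_true = _rotate(q1, b_prev)
    pad = k_blocks * b - len(v)
    u0 = [((int(x) // b) + a_new) % k_blocks for x in v] + [0] * pad
    u1 = [((int(x) % b) + b_new) % b for x in v] + [0] * pad
    enc_one = pk.encrypt_trivial(1)
    c0: list[Ciphertext | None] = [None] * k_blocks
    c1: list[Ciphertext | None] = [None] * k_blocks
    for k in range(k_blocks):
        # 0 iff k is the user's true block, else masked by a nonzero factor
        not_mine = pk.add(enc_one, pk.neg(q0_true.entries[k]))
        out_slot = (k + a_prev) % k_blocks
        for u, dest in ((u0, c0), (u1, c1)):
            acc = _weighted_sum(pk, q1_true.entries, u[k * b : (k + 1) * b])
            mask = pk.smul(rng.randrange(1, pk.n), not_mine)
            dest[out_slot] = pk.rerandomize(pk.add(acc, mask), rng)
    return c0, c1  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# Recursive OT driver (both transports)
# ---------------------------------------------------------------------------

def recursive_ot(x1: int, v, rounds: int, *,
                 keypair=None, key_bits: int = 512, seed: int | None = None,
                 transport: str = "linear",
                 transcript: ProtocolTranscript | None = None) -> int:
    """Run user and server of recursive OT in-process and return x_rounds
    under the chain x_{k+1} = v[x_k].

    The user issues ``rounds - 1`` lookups; every intermediate reply is
    rotation-masked, and only the final round (r = 0) reveals the result.
    """
    length = len(v)
    if not 0 <= x1 < length:
        raise ValueError("start index out of range")
    if rounds < 1:
        raise ValueError("round count must be at least 1")
    if any(not 0 <= int(x) < length for x in v):
        raise ValueError("vector entries must be indices into the vector")
    if transport not in ("linear", "scot"):
        raise ValueError(f"unknown transport {transport!r}")
    master = make_rng(seed)
    user_rng = make_rng(master.getrandbits(48) if seed is not None else None)
    server_rng = make_rng(master.getrandbits(48) if seed is not None else None)
    if keypair is None:
        keypair = keygen(key_bits, user_rng)
    pk, sk = keypair.public_key, keypair.secret_key

    if transport == "linear":
        t = x1
        r_prev = 0
        for i in range(1, rounds):
            encq = prep_query(t, length, pk, user_rng)
            if transcript:
                transcript.log(i, "user", "ot-query", length)
            r = 0 if i == rounds - 1 else server_rng.randrange(length)
            c = rot_reply(encq, v, r, r_prev, pk, server_rng)
            r_prev = r
            if transcript:
                transcript.log(i, "server", "ot-reply", 1)
            t = sk.decrypt(c)
        return t

    # SC-OT transport
    idx = scot_encode(x1, length)
    b = idx.block
    k_blocks = _n_blocks(length, b)
    t0, t1 = idx.t0, idx.t1  # user's (masked) coordinates; true at round 1
    a_prev = b_prev = 0
    for i in range(1, rounds):
        q0 = prep_query(t0, k_blocks, pk, user_rng)
        q1 = prep_query(t1, b, pk, user_rng)
        if transcript:
            transcript.log(i, "user", "scot-query", k_blocks + b)
        last = i == rounds - 1
        a_new = 0 if last else server_rng.randrange(k_blocks)
        b_new = 0 if last else server_rng.randrange(b)
        c0, c1 = scot_recursive_reply(q0, q1, v, a_prev, b_prev, a_new, b_new,
                                      pk, server_rng)
        if transcript:
            transcript.log(i, "server", "scot-reply", 2 * k_blocks)
        t0_next = sk.decrypt(c0[t0])
        t1_next = sk.decrypt(c1[t0])
        t0, t1 = t0_next, t1_next
        a_prev, b_prev = a_new, b_new
    if rounds == 1:
        return x1
    return t0 * b + t1
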