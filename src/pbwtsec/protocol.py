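"""The two-party privacy-preserving set-longest-match protocol.

The server holds the PBWT of a haplotype panel; the user holds a query
haplotype of length ell and a start position t (optionally hidden among D
declared positions).  Each round the user uploads an encrypted query letter
and two encrypted indicator vectors marking its (rotation-masked) interval
endpoints; the server answers with, for every alphabet symbol c, the
endpoint lookups in the symbol's interval-update table - rotation-masked,
conditionally randomized by r * (S[i] - c) so only the true letter's reply
is meaningful - plus eps shuffled encrypted flags that reveal only whether
fewer than eps haplotypes still match.  The user learns the match length
from the round at which a flag decrypts to zero and nothing else; the
server never sees a plaintext endpoint, letter, or flag verdict.

A query of length ell takes ell + 1 shape-identical rounds: the flag of
round i reports on the interval the user sent at round i, which reflects
i - 1 consumed letters, so one trailing flag-only round is needed to tell a
full-length match from one letter shorter.  After the user learns its
result it keeps sending decoy rounds of identical shape, so the transcript
length and per-round ciphertext counts are a function of the public
parameters alone.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .crypto import (AHEPublicKey, AHESecretKey, Ciphertext, KeyPair, keygen,
                     make_rng)
from .ot import EncQueryVector, _rotate, _weighted_sum, prep_query, scot_encode, \
    scot_recursive_reply
from .panel import HaplotypePanel
from .pbwt import PBWTIndex, build_pbwt, cf
from .transcript import ProtocolTranscript

__all__ = [
    "ClientMessage",
    "RoundReply",
    "ClientSession",
    "ServerSession",
    "ProtocolResult",
    "run_protocol",
    "build_concealed_tables",
    "is_longest",
    "is_longest_gt_eps",
    "guard_w",
    "decode_malicious",
    "MaliciousDecode",
]


# ---------------------------------------------------------------------------
# Messages
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClientMessage:
    """Per-round upload: Enc(S[i]) plus the endpoint indicator vectors.

    Linear transport: ``vectors`` holds "f" and "g" (each of length
    D * (M+1)).  SC-OT transport: "f0"/"f1" and "g0"/"g1" (block and
    within-block indicators).
    """

    enc_letter: Ciphertext
    vectors: dict

    @property
    def n_ciphertexts(self) -> int:
        return 1 + sum(v.length for v in self.vectors.values())


@dataclass(frozen=True)
class RoundReply:
    """Per-round download: for every symbol c the masked endpoint lookups
    (one ciphertext each in linear mode, two reply vectors each in SC-OT
    mode), plus eps shuffled flags."""

    e_f: dict
    e_g: dict
    flags: list

    @property
    def n_ciphertexts(self) -> int:
        def count(e) -> int:
            total = 0
            for val in e.values():
                if isinstance(val, Ciphertext):
                    total += 1
                else:
                    c0, c1 = val
                    total += len(c0) + len(c1)
            return total

        return count(self.e_f) + count(self.e_g) + len(self.flags)


# ---------------------------------------------------------------------------
# Encrypted flags and the malicious-model guard
# ---------------------------------------------------------------------------

def _enc_index(entries, pk: AHEPublicKey) -> Ciphertext:
    """Enc(position of the 1) from an encrypted unit indicator vector."""
    return _weighted_sum(pk, entries, range(len(entries)))


def is_longest(encq_f: EncQueryVector, encq_g: EncQueryVector,
               r_f_prev: int, r_g_prev: int, pk: AHEPublicKey,
               rng: random.Random | None = None) -> Ciphertext:
    """Encrypted termination flag: decrypts to 0 iff f = g.

    The endpoint vectors are de-rotated with the stored offsets; each
    position contributes r_i * (q'_f[i] - q'_g[i]) with fresh randomness, so
    identical indicators cancel exactly and distinct ones leave a random
    nonzero residue (failure probability ~ 1/n).
    """
    if encq_f.length != encq_g.length:
        raise ValueError("endpoint vectors have different lengths")
    rng = rng or make_rng()
    qf = _rotate(encq_f, r_f_prev).entries
    qg = _rotate(encq_g, r_g_prev).entries
    acc = pk.encrypt_trivial(0)
    for cf_i, cg_i in zip(qf, qg):
        diff = pk.add(cf_i, pk.neg(cg_i))
        acc = pk.add(acc, pk.smul(rng.randrange(1, pk.n), diff))
    return pk.rerandomize(acc, rng)


def _flags_from_enc_interval(enc_f: Ciphertext, enc_g: Ciphertext, eps: int,
                             pk: AHEPublicKey, rng: random.Random) -> list:
    diff = pk.add(enc_g, pk.neg(enc_f))  # Enc(g - f)
    flags = []
    for j in range(eps):
        shifted = pk.add(diff, pk.encrypt_trivial(-j))
        flags.append(pk.rerandomize(pk.smul(rng.randrange(1, pk.n), shifted), rng))
    rng.shuffle(flags)
    return flags


def is_longest_gt_eps(encq_f: EncQueryVector, encq_g: EncQueryVector,
                      r_f_prev: int, r_g_prev: int, eps: int,
                      pk: AHEPublicKey,
                      rng: random.Random | None = None) -> list:
    """eps shuffled flags; exactly one decrypts to 0 iff g - f < eps.

    Enc(f) and Enc(g) are reconstructed homomorphically from the de-rotated
    indicator vectors (sum of i * q'[i]); flag j is a fresh random multiple
    of Enc(g - f - j).  The shuffle hides which deficit fired, so the user
    learns only that the match count dropped below eps.
    """
    if eps < 1:
        raise ValueError("eps must be at least 1")
    rng = rng or make_rng()
    enc_f = _enc_index(_rotate(encq_f, r_f_prev).entries, pk)
    enc_g = _enc_index(_rotate(encq_g, r_g_prev).entries, pk)
    return _flags_from_enc_interval(enc_f, enc_g, eps, pk, rng)


def guard_w(encq: EncQueryVector, pk: AHEPublicKey,
            rng: random.Random | None = None) -> Ciphertext:
    """Homomorphic sum check against the two-slot attack: decrypts to 0 iff
    the indicator entries sum to 1; added to every reply so a malformed-sum
    query turns its own answers into garbage."""
    rng = rng or make_rng()
    acc = pk.encrypt_trivial(-1)
    for entry in encq.entries:
        acc = pk.add(acc, entry)
    return pk.rerandomize(pk.smul(rng.randrange(1, pk.n), acc), rng)


class MaliciousDecode(NamedTuple):
    div_part: int  # the element multiplied by x (v[j])
    mod_part: int  # the unit-weighted element (v[i])


def decode_malicious(dec_value: int, x: int) -> MaliciousDecode:
    """Decode the two-slot attack aggregate v[i] + x * v[j]: with x larger
    than any database element, the div part recovers v[j] and the mod part
    v[i].  This is the leak the guard exists to block."""
    if x <= 0:
        raise ValueError("multiplier must be positive")
    return MaliciousDecode(div_part=dec_value // x, mod_part=dec_value % x)


# ---------------------------------------------------------------------------
# Concealed-position lookup tables
# ---------------------------------------------------------------------------

def build_concealed_tables(index: PBWTIndex, positions, round_i: int,
                           *, n_rounds: int | None = None) -> dict:
    """Per-symbol lookup vectors V_c over D position slots for one round.

    Slot j (1-based) covers columns of start position positions[j-1]; its
    M+1 lookup entries are offset by o_j = (j-1)(M+1) so every slot's
    lookups stay inside the slot.  D = 1 reduces exactly to the single
    lookup vector of the current column.  A column index past the panel is
    a position-overflow error, except in the final (flag-only) round where
    the unused tables are clamped to the last column.
    """
    m = index.M
    cols = []
    for j, t_j in enumerate(positions, start=1):
        col_idx = t_j - 1 + (round_i - 1)
        if col_idx >= index.N:
            if n_rounds is not None and round_i == n_rounds:
                col_idx = index.N - 1  # flag-only round; values never consumed
            else:
                raise ValueError(
                    f"position {t_j} overflows the panel at round {round_i}"
                )
        cols.append(index.column(col_idx))
    tables: dict[int, list[int]] = {}
    for c in range(index.alphabet_size):
        v = []
        for j, col in enumerate(cols, start=1):
            o_j = (j - 1) * (m + 1)
            base = cf(col, c) + o_j
            v.append(base)
            running = 0
            for i in range(1, m + 1):
                running += int(col[i - 1] == c)
                v.append(base + running)
        tables[c] = v
    return tables


# ---------------------------------------------------------------------------
# Server
# ---------------------------------------------------------------------------

class ServerSession:
    """Server role: holds the PBWT and only the user's *public* key."""

    def __init__(self, index: PBWTIndex, pk: AHEPublicKey, positions,
                 eps: int, n_rounds: int, *, transport: str = "linear",
                 guard: bool = True, zero_masks: bool = False,
                 rng: random.Random | None = None,
                 transcript: ProtocolTranscript | None = None):
        if transport not in ("linear", "scot"):
            raise ValueError(f"unknown transport {transport!r}")
        if not 1 <= eps <= index.M:
            raise ValueError("eps must lie in 1..M")
        self.index = index
        self.pk = pk
        self.positions = list(positions)
        self.eps = eps
        self.n_rounds = n_rounds
        self.transport = transport
        self.guard = guard
        self.zero_masks = zero_masks
        self.rng = rng or make_rng()
        self.transcript = transcript
        self.round_no = 0
        self.L = len(self.positions) * (index.M + 1)
        if transport == "scot":
            idx = scot_encode(0, self.L)
            self.B = idx.block
            self.K = -(-self.L // self.B)
            self._rot = {"f": (0, 0), "g": (0, 0)}  # (block, within-block)
        else:
            self._rot = {"f": 0, "g": 0}

    # -- helpers -----------------------------------------------------------
    def _rand(self, modulus: int) -> int:
        return 0 if self.zero_masks else self.rng.randrange(modulus)

    def _conditional_randomizer(self, enc_letter: Ciphertext, c: int) -> Ciphertext:
        """Enc(r * (S[i] - c)): zero exactly for the user's letter."""
        if self.zero_masks:
            return self.pk.encrypt_trivial(0)
        diff = self.pk.add(enc_letter, self.pk.encrypt_trivial(-c))
        return self.pk.smul(self.rng.randrange(1, self.pk.n), diff)

    # -- one protocol round ------------------------------------------------
    def round(self, msg: ClientMessage) -> RoundReply:
        self.round_no += 1
        if self.round_no > self.n_rounds:
            raise RuntimeError("protocol already finished")
        if self.transcript:
            self.transcript.log(self.round_no, "user", "query", msg.n_ciphertexts)
        tables = build_concealed_tables(self.index, self.positions,
                                        self.round_no, n_rounds=self.n_rounds)
        if self.transport == "linear":
            reply = self._round_linear(msg, tables)
        else:
            reply = self._round_scot(msg, tables)
        if self.transcript:
            self.transcript.log(self.round_no, "server", "reply", reply.n_ciphertexts)
        return reply

    def _round_linear(self, msg: ClientMessage, tables: dict) -> RoundReply:
        pk, rng, L = self.pk, self.rng, self.L
        q = {ep: msg.vectors[ep] for ep in ("f", "g")}
        for ep in ("f", "g"):
            if q[ep].length != L:
                raise ValueError("malformed query vector length")
        flags = is_longest_gt_eps(q["f"], q["g"], self._rot["f"], self._rot["g"],
                                  self.eps, pk, rng)
        r_new = {ep: self._rand(L) for ep in ("f", "g")}
        e: dict[str, dict] = {"f": {}, "g": {}}
        for ep in ("f", "g"):
            true_q = _rotate(q[ep], self._rot[ep])
            w = guard_w(q[ep], pk, rng) if self.guard else None
            for c, table in tables.items():
                masked = [(x + r_new[ep]) % L for x in table]
                out = _weighted_sum(pk, true_q.entries, masked)
                out = pk.add(out, self._conditional_randomizer(msg.enc_letter, c))
                if w is not None:
                    out = pk.add(out, w)
                e[ep][c] = pk.rerandomize(out, rng)
        self._rot = {ep: r_new[ep] for ep in ("f", "g")}
        return RoundReply(e_f=e["f"], e_g=e["g"], flags=flags)

    def _round_scot(self, msg: ClientMessage, tables: dict) -> RoundReply:
        pk, rng = self.pk, self.rng
        q0 = {ep: msg.vectors[f"{ep}0"] for ep in ("f", "g")}
        q1 = {ep: msg.vectors[f"{ep}1"] for ep in ("f", "g")}
        for ep in ("f", "g"):
            if q0[ep].length != self.K or q1[ep].length != self.B:
                raise ValueError("malformed query vector length")
        # flags from the 2-D representation: Enc(f) = B*Enc(t0) + Enc(t1)
        enc_end = {}
        for ep in ("f", "g"):
            a_prev, b_prev = self._rot[ep]
            e0 = _enc_index(_rotate(q0[ep], a_prev).entries, pk)
            e1 = _enc_index(_rotate(q1[ep], b_prev).entries, pk)
            enc_end[ep] = pk.add(pk.smul(self.B, e0), e1)
        flags = _flags_from_enc_interval(enc_end["f"], enc_end["g"], self.eps,
                                         pk, rng)
        new_rot = {ep: (self._rand(self.K), self._rand(self.B)) for ep in ("f", "g")}
        e: dict[str, dict] = {"f": {}, "g": {}}
        for ep in ("f", "g"):
            a_prev, b_prev = self._rot[ep]
            a_new, b_new = new_rot[ep]
            w = None
            if self.guard:
                w = pk.add(guard_w(q0[ep], pk, rng), guard_w(q1[ep], pk, rng))
            for c, table in tables.items():
                c0, c1 = scot_recursive_reply(q0[ep], q1[ep], table,
                                              a_prev, b_prev, a_new, b_new,
                                              pk, rng)
                cond = self._conditional_randomizer(msg.enc_letter, c)
                post = []
                for vec in (c0, c1):
                    cur = [pk.add(ct, cond) for ct in vec]
                    if w is not None:
                        cur = [pk.add(ct, w) for ct in cur]
                    post.append(cur)
                e[ep][c] = (post[0], post[1])
        self._rot = new_rot
        return RoundReply(e_f=e["f"], e_g=e["g"], flags=flags)


# ---------------------------------------------------------------------------
# Client
# ---------------------------------------------------------------------------

class ClientSession:
    """User role: holds the query, the key pair, and the masked interval."""

    def __init__(self, query, t: int, positions, M: int, keypair: KeyPair,
                 eps: int, *, alphabet_size: int = 2, transport: str = "linear",
                 rng: random.Random | None = None):
        self.query = [int(s) for s in query]
        if any(not 0 <= s < alphabet_size for s in self.query):
            raise ValueError("query symbol out of alphabet range")
        positions = list(positions)
        if t not in positions:
            raise ValueError("true position t must be among the declared positions")
        self.slot = positions.index(t) + 1  # 1-based slot x with t = t_x
        self.M = M
        self.D = len(positions)
        self.L = self.D * (M + 1)
        self.alphabet_size = alphabet_size
        self.eps = eps
        self.transport = transport
        self.pk: AHEPublicKey = keypair.public_key
        self._sk: AHESecretKey = keypair.secret_key
        self.rng = rng or make_rng()
        self.n_rounds = len(self.query) + 1
        self.round_no = 0
        self.finished = False
        self.result_length: int | None = None
        o_x = (self.slot - 1) * (M + 1)
        if transport == "scot":
            idx = scot_encode(0, self.L)
            self.B = idx.block
            self.K = -(-self.L // self.B)
            f_idx, g_idx = scot_encode(o_x, self.L), scot_encode(o_x + M, self.L)
            self._coords = {"f": (f_idx.t0, f_idx.t1), "g": (g_idx.t0, g_idx.t1)}
        else:
            self._coords = {"f": o_x, "g": o_x + M}

    # -- message construction ---------------------------------------------
    def _letter(self) -> int:
        i = self.round_no  # building the message for round round_no + 1
        if self.finished or i >= len(self.query):
            return self.rng.randrange(self.alphabet_size)  # decoy letter
        return self.query[i]

    def _build_message(self) -> ClientMessage:
        enc_letter = self.pk.encrypt(self._letter(), self.rng)
        vectors: dict[str, EncQueryVector] = {}
        if self.transport == "linear":
            for ep in ("f", "g"):
                pos = (self.rng.randrange(self.L) if self.finished
                       else self._coords[ep])
                vectors[ep] = prep_query(pos, self.L, self.pk, self.rng)
        else:
            for ep in ("f", "g"):
                if self.finished:
                    t0, t1 = self.rng.randrange(self.K), self.rng.randrange(self.B)
                else:
                    t0, t1 = self._coords[ep]
                vectors[f"{ep}0"] = prep_query(t0, self.K, self.pk, self.rng)
                vectors[f"{ep}1"] = prep_query(t1, self.B, self.pk, self.rng)
        self.round_no += 1
        return ClientMessage(enc_letter=enc_letter, vectors=vectors)

    def open(self) -> ClientMessage:
        if self.round_no != 0:
            raise RuntimeError("session already opened")
        return self._build_message()

    def consume(self, reply: RoundReply) -> ClientMessage | None:
        """Digest the reply of round ``round_no``; return the next message,
        or None once all rounds are done."""
        i = self.round_no
        if not self.finished:
            if any(self._sk.is_zero(flag) for flag in reply.flags):
                # the interval sent this round (i-1 letters) fell below eps
                self.finished = True
                self.result_length = i - 2
            elif i < self.n_rounds:
                c = self.query[i - 1]
                if self.transport == "linear":
                    self._coords = {
                        "f": self._sk.decrypt(reply.e_f[c]),
                        "g": self._sk.decrypt(reply.e_g[c]),
                    }
                else:
                    for ep, e in (("f", reply.e_f[c]), ("g", reply.e_g[c])):
                        c0, c1 = e
                        t0_cur = self._coords[ep][0]
                        self._coords[ep] = (
                            self._sk.decrypt(c0[t0_cur]),
                            self._sk.decrypt(c1[t0_cur]),
                        )
            else:
                self.result_length = len(self.query)  # survived every flag
        if i >= self.n_rounds:
            if self.result_length is None:
                self.result_length = len(self.query)
            return None
        return self._build_message()


# ---------------------------------------------------------------------------
# Driver
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProtocolResult:
    match_length: int
    transcript: ProtocolTranscript


def run_protocol(panel: HaplotypePanel, query, t: int, D: int = 1,
                 eps: int = 1, *, key_bits: int = 512,
                 seed: int | None = None, transport: str = "linear",
                 guard: bool = True, decoy_positions=None,
                 zero_masks: bool = False, keypair: KeyPair | None = None,
                 ) -> ProtocolResult:
    """Run both protocol roles in-process and return the match length the
    user learns, together with the full communication transcript.

    ``D - 1`` decoy start positions conceal t among D declared positions;
    eps is the anonymity level; seed drives every source of randomness
    (keys, masks, decoys, shuffles).
    """
    query = [int(s) for s in np.asarray(query)]
    ell = len(query)
    if ell < 1:
        raise ValueError("query must be non-empty")
    if not 1 <= t <= panel.N or t + ell - 1 > panel.N:
        raise ValueError("query window out of panel range")
    if D < 1:
        raise ValueError("need at least one declared position")
    master = make_rng(seed)
    sub = (lambda: make_rng(master.getrandbits(48))) if seed is not None \
        else (lambda: make_rng())
    key_rng, client_rng, server_rng, decoy_rng = sub(), sub(), sub(), sub()
    if keypair is None:
        keypair = keygen(key_bits, key_rng)

    if decoy_positions is None:
        valid = [p for p in range(1, panel.N - ell + 2) if p != t]
        if len(valid) < D - 1:
            raise ValueError("panel too short for the requested decoy count")
        decoy_positions = decoy_rng.sample(valid, D - 1)
    elif len(decoy_positions) != D - 1:
        raise ValueError("need exactly D - 1 decoy positions")
    positions = list(decoy_positions) + [t]
    decoy_rng.shuffle(positions)

    index = build_pbwt(panel)
    n_rounds = ell + 1
    transcript = ProtocolTranscript(meta={
        "M": panel.M, "N": panel.N, "D": D,
        "alphabet_size": panel.alphabet_size, "eps": eps,
        "transport": transport, "key_bits": key_bits,
        "query_length": ell, "rounds": n_rounds,
    })
    client = ClientSession(query, t, positions, panel.M, keypair, eps,
                           alphabet_size=panel.alphabet_size,
                           transport=transport, rng=client_rng)
    server = ServerSession(index, keypair.public_key, positions, eps, n_rounds,
                           transport=transport, guard=guard,
                           zero_masks=zero_masks, rng=server_rng,
                           transcript=transcript)
    msg = client.open()
    while msg is not None:
        msg = client.consume(server.round(msg))
    assert client.result_length is not None
    return ProtocolResult(match_length=client.result_length, transcript=transcript)
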