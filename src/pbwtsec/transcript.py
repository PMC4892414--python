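"""Protocol transcripts and communication accounting.

Every message either party sends is logged with its ciphertext count; the
accounting layer turns a transcript into per-round upload/download tallies
and checks them against the closed-form predictions.  For the linear-OT
transport each round costs exactly ``2 D (M+1) + 1`` ciphertexts upstream
(one encrypted query letter plus two indicator vectors over D position
slots) and ``2 |sigma| + eps`` downstream (interval replies for every
symbol plus the shuffled anonymity flags), independent of round index and
query content - the shape-indistinguishability the decoy machinery relies
on is precisely this constancy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

__all__ = ["Message", "ProtocolTranscript", "TranscriptSummary", "account_transcript"]


@dataclass(frozen=True)
class Message:
    round: int
    sender: str  # "user" or "server"
    kind: str
    n_ciphertexts: int


@dataclass
class ProtocolTranscript:
    """Ordered record of every protocol message, plus instance metadata
    (M, D, alphabet size, eps, transport, key bits) used for accounting."""

    meta: dict = field(default_factory=dict)
    messages: list[Message] = field(default_factory=list)

    def log(self, round: int, sender: str, kind: str, n_ciphertexts: int) -> None:
        if sender not in ("user", "server"):
            raise ValueError(f"unknown sender {sender!r}")
        self.messages.append(Message(round, sender, kind, n_ciphertexts))

    @property
    def rounds(self) -> int:
        return max((m.round for m in self.messages), default=0)

    def _per_round(self, sender: str) -> list[int]:
        counts = [0] * self.rounds
        for m in self.messages:
            if m.sender == sender:
                counts[m.round - 1] += m.n_ciphertexts
        return counts

    def uploads_per_round(self) -> list[int]:
        return self._per_round("user")

    def downloads_per_round(self) -> list[int]:
        return self._per_round("server")

    @property
    def total_ciphertexts(self) -> int:
        return sum(m.n_ciphertexts for m in self.messages)

    def to_json(self) -> str:
        return json.dumps(
            {
                "format": "pbwtsec-transcript",
                "version": 1,
                "meta": self.meta,
                "messages": [
                    [m.round, m.sender, m.kind, m.n_ciphertexts] for m in self.messages
                ],
            }
        )

    @classmethod
    def from_json(cls, payload: str) -> "ProtocolTranscript":
        obj = json.loads(payload)
        if obj.get("format") != "pbwtsec-transcript":
            raise ValueError("unrecognized transcript envelope")
        tr = cls(meta=obj.get("meta", {}))
        for rnd, sender, kind, n in obj["messages"]:
            tr.log(rnd, sender, kind, n)
        return tr


@dataclass(frozen=True)
class TranscriptSummary:
    rounds: int
    uploads_per_round: list[int]
    downloads_per_round: list[int]
    total_ciphertexts: int
    total_bytes: int


def expected_round_counts(meta: dict) -> tuple[int, int] | None:
    """Closed-form (upload, download) ciphertexts per round, linear mode."""
    if meta.get("transport") != "linear":
        return None
    try:
        m, d = meta["M"], meta["D"]
        sigma, eps = meta["alphabet_size"], meta["eps"]
    except KeyError:
        return None
    return 2 * d * (m + 1) + 1, 2 * sigma + eps


def account_transcript(transcript: ProtocolTranscript) -> TranscriptSummary:
    """Summarize a transcript; verify the closed-form per-round counts for
    the linear transport and that every round has both directions."""
    if transcript.rounds == 0:
        raise ValueError("empty transcript")
    ups = transcript.uploads_per_round()
    downs = transcript.downloads_per_round()
    if any(u == 0 for u in ups) or any(d == 0 for d in downs):
        raise ValueError("truncated transcript: a round is missing a direction")
    expected = expected_round_counts(transcript.meta)
    if expected is not None:
        exp_up, exp_down = expected
        for i, (u, d) in enumerate(zip(ups, downs), start=1):
            if u != exp_up:
                raise ValueError(
                    f"round {i}: upload {u} != expected {exp_up} ciphertexts"
                )
            if d != exp_down:
                raise ValueError(
                    f"round {i}: download {d} != expected {exp_down} ciphertexts"
                )
    key_bits = transcript.meta.get("key_bits", 0)
    ct_bytes = 2 * key_bits // 8  # Paillier ciphertexts live mod n^2
    return TranscriptSummary(
        rounds=transcript.rounds,
        uploads_per_round=ups,
        downloads_per_round=downs,
        total_ciphertexts=transcript.total_ciphertexts,
        total_bytes=transcript.total_ciphertexts * ct_bytes,
    )
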