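"""Additively homomorphic public-key encryption (Paillier by default).

The whole protocol stack only relies on the abstract contract:

* ``Dec(Enc(m1) + Enc(m2)) = m1 + m2  (mod n)`` - ciphertext addition,
* ``Dec(e * Enc(m)) = e * m           (mod n)`` - plaintext-scalar multiply,
* probabilistic encryption (two encryptions of one message differ),

exposed through :class:`AHEPublicKey` / :class:`AHESecretKey`.  The default
backend is Paillier over plain Python big integers: decryption needs no
discrete logarithm, so arbitrary plaintexts in 0..n-1 round-trip exactly.
A lifted-ElGamal backend (exact zero test, small-range decryption) could be
slotted in behind the same interface.

Key sizes of 512-1024 bits keep the test suite fast; they are NOT secure
for production use, where >= 2048-bit moduli are the accepted floor.
"""

from __future__ import annotations

import hashlib
import json
import math
import random
from abc import ABC, abstractmethod
from dataclasses import dataclass

import sympy

__all__ = [
    "Ciphertext",
    "KeyPair",
    "AHEPublicKey",
    "AHESecretKey",
    "PaillierPublicKey",
    "PaillierSecretKey",
    "keygen",
    "make_rng",
]

MIN_KEY_BITS = 256


def make_rng(seed: int | None = None) -> random.Random:
    """A seedable random source; unseeded falls back to the OS CSPRNG."""
    if seed is None:
        return random.SystemRandom()
    return random.Random(seed)


@dataclass(frozen=True)
class Ciphertext:
    """Opaque additively homomorphic ciphertext bound to one public key."""

    value: int
    key_id: str

    def to_json(self) -> str:
        return json.dumps(
            {"format": "pbwtsec-ciphertext", "version": 1,
             "key_id": self.key_id, "value": hex(self.value)}
        )

    @classmethod
    def from_json(cls, payload: str) -> "Ciphertext":
        obj = json.loads(payload)
        if obj.get("format") != "pbwtsec-ciphertext" or obj.get("version") != 1:
            raise ValueError("unrecognized ciphertext envelope")
        return cls(value=int(obj["value"], 16), key_id=obj["key_id"])


class AHEPublicKey(ABC):
    """Encryption side of an additively homomorphic scheme."""

    key_id: str
    n: int  # plaintext modulus

    @abstractmethod
    def encrypt(self, m: int, rng: random.Random | None = None) -> Ciphertext: ...

    @abstractmethod
    def encrypt_trivial(self, m: int) -> Ciphertext:
        """Deterministic encryption with unit randomness.  Only for terms
        that are folded into an aggregate which is re-randomized before it
        leaves the computing party."""

    @abstractmethod
    def add(self, c1: Ciphertext, c2: Ciphertext) -> Ciphertext: ...

    @abstractmethod
    def smul(self, e: int, c: Ciphertext) -> Ciphertext: ...

    @abstractmethod
    def rerandomize(self, c: Ciphertext, rng: random.Random | None = None) -> Ciphertext: ...

    def neg(self, c: Ciphertext) -> Ciphertext:
        """Enc(-m) from Enc(m)."""
        return self.smul(-1, c)

    def sub(self, c1: Ciphertext, c2: Ciphertext) -> Ciphertext:
        return self.add(c1, self.neg(c2))


class AHESecretKey(ABC):
    @abstractmethod
    def decrypt(self, c: Ciphertext) -> int: ...

    def decrypt_signed(self, c: Ciphertext) -> int:
        """Decrypt mapping the upper half of the plaintext ring to negatives."""
        m = self.decrypt(c)
        n = self.public_key.n  # type: ignore[attr-defined]
        return m - n if m > n // 2 else m

    def is_zero(self, c: Ciphertext) -> bool:
        return self.decrypt(c) == 0


@dataclass(frozen=True)
class KeyPair:
    public_key: "PaillierPublicKey"
    secret_key: "PaillierSecretKey"
    key_bits: int


class PaillierPublicKey(AHEPublicKey):
    def __init__(self, n: int):
        self.n = n
        self.n_squared = n * n
        self.key_id = hashlib.sha256(hex(n).encode()).hexdigest()[:16]

    # -- helpers ---------------------------------------------------------
    def _check(self, *cts: Ciphertext) -> None:
        for c in cts:
            if c.key_id != self.key_id:
                raise ValueError("ciphertext was produced under a different key")

    def _random_unit(self, rng: random.Random) -> int:
        while True:
            r = rng.randrange(1, self.n)
            if math.gcd(r, self.n) == 1:  # fails only if r hits a prime factor
                return r

    # -- interface -------------------------------------------------------
    def encrypt(self, m: int, rng: random.Random | None = None) -> Ciphertext:
        rng = rng or make_rng()
        m %= self.n
        nude = (1 + m * self.n) % self.n_squared  # (n+1)^m mod n^2
        r = self._random_unit(rng)
        return Ciphertext((nude * pow(r, self.n, self.n_squared)) % self.n_squared,
                          self.key_id)

    def encrypt_trivial(self, m: int) -> Ciphertext:
        m %= self.n
        return Ciphertext((1 + m * self.n) % self.n_squared, self.key_id)

    def add(self, c1: Ciphertext, c2: Ciphertext) -> Ciphertext:
        self._check(c1, c2)
        return Ciphertext((c1.value * c2.value) % self.n_squared, self.key_id)

    def smul(self, e: int, c: Ciphertext) -> Ciphertext:
        self._check(c)
        e %= self.n  # negative scalars land on n - |e|
        if e == 0:
            return self.encrypt_trivial(0)
        return Ciphertext(pow(c.value, e, self.n_squared), self.key_id)

    def neg(self, c: Ciphertext) -> Ciphertext:
        # modular inverse is much cheaper than a (n-1)-exponent power
        self._check(c)
        return Ciphertext(pow(c.value, -1, self.n_squared), self.key_id)

    def rerandomize(self, c: Ciphertext, rng: random.Random | None = None) -> Ciphertext:
        self._check(c)
        rng = rng or make_rng()
        r = self._random_unit(rng)
        return Ciphertext((c.value * pow(r, self.n, self.n_squared)) % self.n_squared,
                          self.key_id)

    # -- serialization ---------------------------------------------------
    def to_json(self) -> str:
        return json.dumps(
            {"format": "pbwtsec-public-key", "version": 1,
             "scheme": "paillier", "n": hex(self.n)}
        )

    @classmethod
    def from_json(cls, payload: str) -> "PaillierPublicKey":
        obj = json.loads(payload)
        if obj.get("format") != "pbwtsec-public-key" or obj.get("scheme") != "paillier":
            raise ValueError("unrecognized public-key envelope")
        return cls(int(obj["n"], 16))


class PaillierSecretKey(AHESecretKey):
    def __init__(self, p: int, q: int):
        if p == q:
            raise ValueError("prime factors must differ")
        self.p, self.q = p, q
        self.public_key = PaillierPublicKey(p * q)
        # CRT precomputation: decrypt mod p and mod q separately
        self._p2, self._q2 = p * p, q * q
        self._hp = pow(self._l_func(pow(1 + self.public_key.n, p - 1, self._p2), p), -1, p)
        self._hq = pow(self._l_func(pow(1 + self.public_key.n, q - 1, self._q2), q), -1, q)
        self._q_inv = pow(q, -1, p)

    @staticmethod
    def _l_func(x: int, p: int) -> int:
        return (x - 1) // p

    def decrypt(self, c: Ciphertext) -> int:
        if c.key_id != self.public_key.key_id:
            raise ValueError("ciphertext was produced under a different key")
        mp = (self._l_func(pow(c.value, self.p - 1, self._p2), self.p) * self._hp) % self.p
        mq = (self._l_func(pow(c.value, self.q - 1, self._q2), self.q) * self._hq) % self.q
        return mq + ((mp - mq) * self._q_inv % self.p) * self.q

    def to_json(self) -> str:
        return json.dumps(
            {"format": "pbwtsec-secret-key", "version": 1,
             "scheme": "paillier", "p": hex(self.p), "q": hex(self.q)}
        )

    @classmethod
    def from_json(cls, payload: str) -> "PaillierSecretKey":
        obj = json.loads(payload)
        if obj.get("format") != "pbwtsec-secret-key" or obj.get("scheme") != "paillier":
            raise ValueError("unrecognized secret-key envelope")
        return cls(int(obj["p"], 16), int(obj["q"], 16))


def _random_prime(bits: int, rng: random.Random) -> int:
    while True:
        cand = rng.getrandbits(bits) | (1 << (bits - 1)) | 1
        p = int(sympy.nextprime(cand))
        if p.bit_length() == bits:
            return p


def keygen(key_bits: int = 2048, rng: random.Random | None = None) -> KeyPair:
    """Generate a Paillier key pair with an n of ``key_bits`` bits."""
    if key_bits < MIN_KEY_BITS:
        raise ValueError(f"key size below {MIN_KEY_BITS} bits is not supported")
    rng = rng or make_rng()
    half = key_bits // 2
    p = _random_prime(half, rng)
    q = _random_prime(key_bits - half, rng)
    while q == p:
        q = _random_prime(key_bits - half, rng)
    sk = PaillierSecretKey(p, q)
    return KeyPair(public_key=sk.public_key, secret_key=sk, key_bits=key_bits)
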