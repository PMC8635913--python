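"""Pluggable signature scheme for the simulated ledger.

The default scheme is a deterministic HMAC-SHA256 construction: every party
holds a secret key registered with the simulation's key registry, a signature
is HMAC(secret, message), and verification recomputes it. This gives the
simulation the contract it needs — per-party unforgeable-in-simulation,
deterministic signatures over canonical bytes — without modeling real
public-key cryptography (key distribution and forgery are out of scope).
"""

from __future__ import annotations

import hashlib
import hmac

import numpy as np


class SignatureScheme:
    """Interface: sign/verify per party over raw message bytes."""

    def keygen(self, party_id: str, seed: int) -> bytes:
        raise NotImplementedError

    def sign(self, secret: bytes, message: bytes) -> bytes:
        raise NotImplementedError

    def verify(self, secret: bytes, message: bytes, signature: bytes) -> bool:
        raise NotImplementedError


class HMACScheme(SignatureScheme):
    """Deterministic HMAC-SHA256 simulation of digital signatures."""

    def keygen(self, party_id: str, seed: int) -> bytes:
        rng = np.random.default_rng(
            np.random.SeedSequence([seed, 13, abs(hash(party_id)) % (2**31)])
        )
        material = rng.bytes(16) + party_id.encode()
        return hashlib.sha256(material).digest()

    def sign(self, secret: bytes, message: bytes) -> bytes:
        return hmac.new(secret, message, hashlib.sha256).digest()

    def verify(self, secret: bytes, message: bytes, signature: bytes) -> bool:
        return hmac.compare_digest(self.sign(secret, message), signature)


class KeyRegistry:
    """Holds every party's key; the simulation's stand-in for a PKI."""

    def __init__(self, scheme: SignatureScheme | None = None, seed: int = 0):
        self.scheme = scheme or HMACScheme()
        self.seed = seed
        self._keys: dict[str, bytes] = {}

    def register(self, party_id: str) -> None:
        if party_id not in self._keys:
            self._keys[party_id] = self.scheme.keygen(party_id, self.seed)

    def parties(self) -> list[str]:
        return sorted(self._keys)

    def fingerprint(self, party_id: str) -> str:
        return hashlib.sha256(self._keys[party_id]).hexdigest()[:16]

    def sign(self, party_id: str, message: bytes) -> bytes:
        return self.scheme.sign(self._keys[party_id], message)

    def verify(self, party_id: str, message: bytes, signature: bytes) -> bool:
        if party_id not in self._keys:
            return False
        return self.scheme.verify(self._keys[party_id], message, signature)

    def to_dict(self) -> dict[str, str]:
        return {p: k.hex() for p, k in self._keys.items()}

    @classmethod
    def from_dict(cls, d: dict[str, str], scheme: SignatureScheme | None = None) -> "KeyRegistry":
        reg = cls(scheme)
        reg._keys = {p: bytes.fromhex(k) for p, k in d.items()}
        return reg
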