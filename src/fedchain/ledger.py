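"""The simulated blockchain that coordinates training.

One block per training round, SHA-256 hash-chained to its predecessor,
holding the round's qualified gradient transactions with their device and
verifier signatures. Committee selection is reputation-weighted consistent
hashing: miners own contiguous arcs of an integer ring proportional to their
reputation, and repeated rehashing of the previous block's hash walks the
ring until the committee is filled. All serialization is canonical
(documented field order, 8-byte big-endian integers, length-prefixed byte
strings) so block hashes are reproducible byte-for-byte.
"""

from __future__ import annotations

import bisect
import hashlib
import json
import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .crypto import KeyRegistry

HASH_LEN = 32
ZERO_HASH = b"\x00" * HASH_LEN


class LedgerError(RuntimeError):
    pass


class AuditError(LedgerError):
    """A stored chain failed re-verification."""


class ConsensusError(LedgerError):
    """Committee selection is infeasible (too few eligible miners)."""


# ---------------------------------------------------------------------------
# canonical serialization primitives


def _u64(x: int) -> bytes:
    return struct.pack(">Q", x)


def _i64(x: int) -> bytes:
    return struct.pack(">q", x)


def _lp(b: bytes) -> bytes:
    return _u64(len(b)) + b


class _Reader:
    def __init__(self, data: bytes):
        self.data = data
        self.off = 0

    def take(self, n: int) -> bytes:
        if self.off + n > len(self.data):
            raise LedgerError("truncated block data")
        out = self.data[self.off : self.off + n]
        self.off += n
        return out

    def u64(self) -> int:
        return struct.unpack(">Q", self.take(8))[0]

    def i64(self) -> int:
        return struct.unpack(">q", self.take(8))[0]

    def lp(self) -> bytes:
        return self.take(self.u64())


def gradient_to_bytes(values: np.ndarray) -> bytes:
    """Canonical gradient encoding: little-endian float64, flat order."""
    return np.asarray(values, dtype="<f8").tobytes()


def gradient_from_bytes(b: bytes) -> np.ndarray:
    return np.frombuffer(b, dtype="<f8").copy()


# ---------------------------------------------------------------------------
# blocks


@dataclass(frozen=True)
class Transaction:
    """One qualified gradient: device signature plus verifier endorsements."""

    device_id: str
    gradient_bytes: bytes
    device_signature: bytes
    endorsements: tuple[tuple[str, bytes], ...]  # (verifier_id, signature)

    def to_bytes(self) -> bytes:
        parts = [
            _lp(self.device_id.encode()),
            _lp(self.gradient_bytes),
            _lp(self.device_signature),
            _u64(len(self.endorsements)),
        ]
        for vid, sig in self.endorsements:
            parts.append(_lp(vid.encode()))
            parts.append(_lp(sig))
        return b"".join(parts)

    @classmethod
    def from_reader(cls, r: _Reader) -> "Transaction":
        device_id = r.lp().decode()
        grad = r.lp()
        dsig = r.lp()
        n_end = r.u64()
        ends = tuple((r.lp().decode(), r.lp()) for _ in range(n_end))
        return cls(device_id, grad, dsig, ends)


_BLOCK_MAGIC = b"BLK1"
_GENESIS_MAGIC = b"GEN1"


@dataclass(frozen=True)
class Block:
    """One training round's record."""

    round: int
    prev_hash: bytes
    committee: tuple[str, ...]
    transactions: tuple[Transaction, ...]
    leader_id: str
    leader_signature: bytes
    is_empty: bool = False

    def header_bytes(self) -> bytes:
        """Everything the leader signs (all fields except its signature)."""
        parts = [
            _BLOCK_MAGIC,
            _u64(self.round),
            self.prev_hash,
            bytes([1 if self.is_empty else 0]),
            _u64(len(self.committee)),
        ]
        for cid in self.committee:
            parts.append(_lp(cid.encode()))
        parts.append(_u64(len(self.transactions)))
        for tx in self.transactions:
            parts.append(tx.to_bytes())
        parts.append(_lp(self.leader_id.encode()))
        return b"".join(parts)

    def to_bytes(self) -> bytes:
        return self.header_bytes() + _lp(self.leader_signature)

    def hash(self) -> bytes:
        return hashlib.sha256(self.to_bytes()).digest()

    @classmethod
    def from_bytes(cls, data: bytes) -> "Block":
        r = _Reader(data)
        if r.take(4) != _BLOCK_MAGIC:
            raise LedgerError("not a block")
        rnd = r.u64()
        prev = r.take(HASH_LEN)
        is_empty = bool(r.take(1)[0])
        committee = tuple(r.lp().decode() for _ in range(r.u64()))
        txs = tuple(Transaction.from_reader(r) for _ in range(r.u64()))
        leader = r.lp().decode()
        sig = r.lp()
        return cls(rnd, prev, committee, txs, leader, sig, is_empty)


@dataclass(frozen=True)
class GenesisBlock:
    """Round-0 record: initial model, horizon, keys, reputations, rules."""

    arch_id: str
    initial_params_bytes: bytes
    total_rounds: int
    public_keys: tuple[tuple[str, str], ...]  # (party_id, key fingerprint)
    initial_reputations: tuple[tuple[str, int], ...]
    reputation_rule_id: str = "plus-minus-one-blacklist-at-zero"

    def to_bytes(self) -> bytes:
        parts = [
            _GENESIS_MAGIC,
            _u64(0),
            ZERO_HASH,
            _lp(self.arch_id.encode()),
            _lp(self.initial_params_bytes),
            _u64(self.total_rounds),
            _u64(len(self.public_keys)),
        ]
        for pid, fp in self.public_keys:
            parts.append(_lp(pid.encode()))
            parts.append(_lp(fp.encode()))
        parts.append(_u64(len(self.initial_reputations)))
        for pid, rep in self.initial_reputations:
            parts.append(_lp(pid.encode()))
            parts.append(_i64(rep))
        parts.append(_lp(self.reputation_rule_id.encode()))
        return b"".join(parts)

    def hash(self) -> bytes:
        return hashlib.sha256(self.to_bytes()).digest()

    @classmethod
    def from_bytes(cls, data: bytes) -> "GenesisBlock":
        r = _Reader(data)
        if r.take(4) != _GENESIS_MAGIC:
            raise LedgerError("not a genesis block")
        r.u64()
        r.take(HASH_LEN)
        arch = r.lp().decode()
        w0 = r.lp()
        total = r.u64()
        keys = tuple((r.lp().decode(), r.lp().decode()) for _ in range(r.u64()))
        reps = tuple((r.lp().decode(), r.i64()) for _ in range(r.u64()))
        rule = r.lp().decode()
        return cls(arch, w0, total, keys, reps, rule)


# ---------------------------------------------------------------------------
# reputation


@dataclass
class ReputationTable:
    """Integer reputation per participant; zero means permanent blacklist."""

    reputation: dict[str, int] = field(default_factory=dict)
    miners: set[str] = field(default_factory=set)
    blacklist: set[str] = field(default_factory=set)

    def copy(self) -> "ReputationTable":
        return ReputationTable(
            dict(self.reputation), set(self.miners), set(self.blacklist)
        )

    def eligible_miners(self) -> list[str]:
        return sorted(
            m
            for m in self.miners
            if m not in self.blacklist and self.reputation.get(m, 0) > 0
        )

    def is_blacklisted(self, pid: str) -> bool:
        return pid in self.blacklist


def update_reputation(
    table: ReputationTable, round_events: dict[str, int]
) -> ReputationTable:
    """Apply +/-1 reputation deltas, floor at 0, blacklist at 0.

    ``round_events`` maps participant id to a signed delta: +1 for a device
    whose gradient was qualified or a verifier whose verdict matched the
    final accepted set, -1 for a rejected gradient, an incorrect verdict, or
    a leader whose block was rejected.
    """
    out = table.copy()
    for pid, delta in round_events.items():
        if pid not in out.reputation:
            raise LedgerError(f"unknown participant {pid!r}")
        if pid in out.blacklist:
            continue
        out.reputation[pid] = max(0, out.reputation[pid] + delta)
        if out.reputation[pid] == 0:
            out.blacklist.add(pid)
    return out


# ---------------------------------------------------------------------------
# consistent-hashing committee selection


@dataclass(frozen=True)
class HashRing:
    """Contiguous integer arcs, one per eligible miner, length = reputation."""

    owners: tuple[str, ...]
    boundaries: tuple[int, ...]  # cumulative arc ends, ascending
    total_space: int

    @classmethod
    def build(cls, table: ReputationTable) -> "HashRing":
        miners = table.eligible_miners()  # ascending id order
        if not miners:
            raise ConsensusError("no eligible miners to build a hash ring")
        ends, acc = [], 0
        for m in miners:
            acc += table.reputation[m]
            ends.append(acc)
        return cls(tuple(miners), tuple(ends), acc)

    def owner_of(self, point: int) -> str:
        idx = bisect.bisect_right(self.boundaries, point % self.total_space)
        return self.owners[idx]


def select_committee(
    last_block_hash: bytes, table: ReputationTable, M: int
) -> list[str]:
    """Deterministic committee: rehash the last block hash onto the ring.

    h_0 is the previous block's hash; h_{k+1} = SHA-256(h_k). Each digest,
    read as a big-endian integer mod the ring size, selects the arc owner;
    duplicates are skipped and rehashing continues until M distinct miners
    are chosen.
    """
    ring = HashRing.build(table)
    if len(ring.owners) < M:
        raise ConsensusError(
            f"need {M} eligible miners, have {len(ring.owners)}"
        )
    chosen: list[str] = []
    h = last_block_hash
    while len(chosen) < M:
        h = hashlib.sha256(h).digest()
        owner = ring.owner_of(int.from_bytes(h, "big"))
        if owner not in chosen:
            chosen.append(owner)
    return chosen


def select_leader(committee: list[str], last_block_hash: bytes) -> str:
    """Hash-derived deterministic leader pick from the committee."""
    if not committee:
        raise ConsensusError("empty committee")
    digest = hashlib.sha256(last_block_hash + b"leader").digest()
    return committee[int.from_bytes(digest, "big") % len(committee)]


# ---------------------------------------------------------------------------
# block construction / approval


def build_block(
    round_index: int,
    prev_hash: bytes,
    committee: list[str],
    transactions: list[Transaction],
    leader_id: str,
    registry: KeyRegistry,
    is_empty: bool = False,
) -> Block:
    """Leader assembles and signs the round's block (possibly empty)."""
    unsigned = Block(
        round_index,
        prev_hash,
        tuple(committee),
        tuple(transactions),
        leader_id,
        b"",
        is_empty,
    )
    digest = hashlib.sha256(unsigned.header_bytes()).digest()
    sig = registry.sign(leader_id, digest)
    return Block(
        round_index,
        prev_hash,
        tuple(committee),
        tuple(transactions),
        leader_id,
        sig,
        is_empty,
    )


def verify_block(block: Block, registry: KeyRegistry) -> bool:
    """One verifier's check: leader signature, device signatures,
    endorsement majorities from committee members."""
    digest = hashlib.sha256(block.header_bytes()).digest()
    if not registry.verify(block.leader_id, digest, block.leader_signature):
        return False
    if block.leader_id not in block.committee:
        return False
    M = len(block.committee)
    for tx in block.transactions:
        if not registry.verify(tx.device_id, tx.gradient_bytes, tx.device_signature):
            return False
        valid = {
            vid
            for vid, sig in tx.endorsements
            if vid in block.committee and registry.verify(vid, tx.gradient_bytes, sig)
        }
        if not len(valid) > M / 2:
            return False
    return True


def approve_block(
    block: Block,
    committee: list[str],
    registry: KeyRegistry,
    dissenting: set[str] | None = None,
) -> tuple[bool, dict[str, bool]]:
    """Committee vote: valid iff approvals are a strict > 2/3 majority.

    Honest members vote according to ``verify_block``; members listed in
    ``dissenting`` invert their vote (used by the adversary harness). If the
    vote fails, the caller appends an empty block so the chain never stalls.
    """
    dissenting = dissenting or set()
    votes: dict[str, bool] = {}
    for member in committee:
        v = verify_block(block, registry)
        votes[member] = (not v) if member in dissenting else v
    approvals = sum(votes.values())
    return approvals > 2 * len(committee) / 3, votes


# ---------------------------------------------------------------------------
# the chain


@dataclass
class Chain:
    genesis: GenesisBlock
    blocks: list[Block] = field(default_factory=list)

    def last_hash(self) -> bytes:
        return self.blocks[-1].hash() if self.blocks else self.genesis.hash()

    def append(self, block: Block) -> None:
        if block.prev_hash != self.last_hash():
            raise LedgerError("block does not extend the chain head")
        self.blocks.append(block)

    def audit(self, registry: KeyRegistry) -> bool:
        """Re-walk the chain verifying every link, signature, and majority."""
        prev = self.genesis.hash()
        for i, block in enumerate(self.blocks):
            if block.prev_hash != prev:
                raise AuditError(f"block {i}: broken hash link")
            if not verify_block(block, registry):
                raise AuditError(f"block {i}: signature or endorsement failure")
            if block.is_empty and block.transactions:
                raise AuditError(f"block {i}: empty block carries transactions")
            prev = block.hash()
        return True

    def save(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        (d / "genesis.bin").write_bytes(self.genesis.to_bytes())
        for i, b in enumerate(self.blocks):
            (d / f"block_{i + 1:05d}.bin").write_bytes(b.to_bytes())
        index = {
            "n_blocks": len(self.blocks),
            "genesis_hash": self.genesis.hash().hex(),
            "block_hashes": [b.hash().hex() for b in self.blocks],
        }
        (d / "chain.json").write_text(json.dumps(index, indent=1))

    @classmethod
    def load(cls, directory) -> "Chain":
        d = Path(directory)
        genesis = GenesisBlock.from_bytes((d / "genesis.bin").read_bytes())
        index = json.loads((d / "chain.json").read_text())
        blocks = [
            Block.from_bytes((d / f"block_{i + 1:05d}.bin").read_bytes())
            for i in range(index["n_blocks"])
        ]
        return cls(genesis, blocks)
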