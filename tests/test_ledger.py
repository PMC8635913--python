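"""Hash chaining, committee selection, approval, and reputation rules."""

import hashlib

import numpy as np
import pytest
from scipy.stats import chisquare

from fedchain.crypto import HMACScheme, KeyRegistry
from fedchain.ledger import (
    AuditError,
    Block,
    Chain,
    ConsensusError,
    GenesisBlock,
    LedgerError,
    ReputationTable,
    Transaction,
    approve_block,
    build_block,
    gradient_to_bytes,
    select_committee,
    select_leader,
    update_reputation,
    verify_block,
)


def make_table(reps: dict[str, int], miners=None) -> ReputationTable:
    return ReputationTable(dict(reps), set(miners or reps))


@pytest.fixture
def registry():
    reg = KeyRegistry(seed=0)
    for p in ["device-000", "device-001", "m0", "m1", "m2", "m3", "m4"]:
        reg.register(p)
    return reg


def make_tx(registry, device="device-000", values=(1.0, 2.0), endorsers=("m0", "m1", "m2")):
    gb = gradient_to_bytes(np.asarray(values))
    return Transaction(
        device,
        gb,
        registry.sign(device, gb),
        tuple((m, registry.sign(m, gb)) for m in endorsers),
    )


class TestCommitteeSelection:
    def test_single_eligible_miner(self):
        table = make_table({"m0": 5})
        assert select_committee(b"\x01" * 32, table, 1) == ["m0"]

    def test_deterministic(self):
        table = make_table({"m0": 1, "m1": 2, "m2": 3})
        h = hashlib.sha256(b"block").digest()
        assert select_committee(h, table, 2) == select_committee(h, table, 2)

    def test_excludes_blacklisted(self):
        table = make_table({"m0": 1, "m1": 2, "m2": 3})
        table.blacklist.add("m2")
        for trial in range(50):
            h = hashlib.sha256(bytes([trial])).digest()
            assert "m2" not in select_committee(h, table, 2)

    def test_too_few_eligible(self):
        table = make_table({"m0": 1})
        with pytest.raises(ConsensusError):
            select_committee(b"\x00" * 32, table, 2)

    def test_selection_proportional_to_reputation(self):
        """Chi-square goodness of fit against 1:3 reputation arcs."""
        table = make_table({"m0": 1, "m1": 3})
        counts = {"m0": 0, "m1": 0}
        n = 10_000
        for i in range(n):
            h = hashlib.sha256(i.to_bytes(8, "big")).digest()
            counts[select_committee(h, table, 1)[0]] += 1
        stat, p = chisquare(
            [counts["m0"], counts["m1"]], [n * 0.25, n * 0.75]
        )
        assert p > 0.01


class TestLeaderSelection:
    def test_committee_of_one(self):
        assert select_leader(["m0"], b"\x00" * 32) == "m0"

    def test_deterministic(self):
        c = ["m0", "m1", "m2"]
        h = hashlib.sha256(b"x").digest()
        assert select_leader(c, h) == select_leader(c, h)

    def test_binomial_concentration(self):
        """Each of 5 members leads 2000 +/- 5*sqrt(2000*0.8) of 1e4 rounds."""
        committee = [f"m{i}" for i in range(5)]
        counts = dict.fromkeys(committee, 0)
        for i in range(10_000):
            h = hashlib.sha256(i.to_bytes(8, "big")).digest()
            counts[select_leader(committee, h)] += 1
        bound = 5 * np.sqrt(2000 * 0.8)
        assert all(abs(c - 2000) <= bound for c in counts.values())


class TestBlocks:
    def test_empty_block_is_valid(self, registry):
        b = build_block(1, b"\x00" * 32, ["m0", "m1", "m2"], [], "m0", registry, is_empty=True)
        assert verify_block(b, registry)
        assert len(b.transactions) == 0

    def test_serialization_round_trip(self, registry):
        tx = make_tx(registry)
        b = build_block(3, b"\x07" * 32, ["m0", "m1", "m2"], [tx], "m1", registry)
        assert Block.from_bytes(b.to_bytes()) == b

    def test_single_bit_mutation_changes_hash(self, registry):
        b = build_block(1, b"\x00" * 32, ["m0"], [make_tx(registry, endorsers=("m0",))], "m0", registry)
        raw = bytearray(b.to_bytes())
        rng = np.random.default_rng(5)
        for _ in range(20):
            i = int(rng.integers(len(raw)))
            bit = 1 << int(rng.integers(8))
            mutated = bytearray(raw)
            mutated[i] ^= bit
            assert hashlib.sha256(bytes(mutated)).digest() != b.hash()

    def test_genesis_round_trip(self, registry):
        g = GenesisBlock(
            "logistic",
            gradient_to_bytes(np.zeros(9)),
            50,
            (("device-000", registry.fingerprint("device-000")),),
            (("device-000", 10),),
        )
        assert GenesisBlock.from_bytes(g.to_bytes()) == g


class TestApproval:
    def _block(self, registry, committee):
        tx = make_tx(registry, endorsers=tuple(committee))
        return build_block(1, b"\x00" * 32, committee, [tx], committee[0], registry)

    def test_unanimous_three_approves(self, registry):
        c = ["m0", "m1", "m2"]
        valid, votes = approve_block(self._block(registry, c), c, registry)
        assert valid and sum(votes.values()) == 3

    def test_two_of_three_is_not_enough(self, registry):
        c = ["m0", "m1", "m2"]
        valid, _ = approve_block(self._block(registry, c), c, registry, dissenting={"m2"})
        assert not valid  # 2 > 2 is false

    def test_five_of_six_approves(self, registry):
        reg = registry
        reg.register("m5")
        c = ["m0", "m1", "m2", "m3", "m4", "m5"]
        valid, _ = approve_block(self._block(reg, c), c, reg, dissenting={"m5"})
        assert valid  # 5 > 4

    def test_bad_leader_signature_rejected_by_all(self, registry):
        c = ["m0", "m1", "m2"]
        b = self._block(registry, c)
        forged = Block(
            b.round, b.prev_hash, b.committee, b.transactions, b.leader_id, b"junk"
        )
        valid, votes = approve_block(forged, c, registry)
        assert not valid and not any(votes.values())


class TestReputation:
    def test_qualified_device_gains(self):
        t = make_table({"d0": 10}, miners=[])
        t2 = update_reputation(t, {"d0": 1})
        assert t2.reputation["d0"] == 11

    def test_zero_reputation_blacklists(self):
        t = make_table({"d0": 1}, miners=[])
        t2 = update_reputation(t, {"d0": -1})
        assert t2.reputation["d0"] == 0
        assert t2.is_blacklisted("d0")

    def test_blacklisted_never_recovers(self):
        t = make_table({"d0": 1}, miners=[])
        t2 = update_reputation(t, {"d0": -1})
        t3 = update_reputation(t2, {"d0": 1})
        assert t3.is_blacklisted("d0")
        assert t3.reputation["d0"] == 0

    def test_unknown_participant(self):
        with pytest.raises(LedgerError):
            update_reputation(make_table({"d0": 1}), {"ghost": 1})

    def test_blacklisted_miner_owns_no_arc(self):
        table = make_table({"m0": 3, "m1": 3})
        table = update_reputation(table, {"m0": -3})
        assert table.eligible_miners() == ["m1"]


class TestChain:
    def _chain(self, registry, n_blocks=3):
        g = GenesisBlock("logistic", gradient_to_bytes(np.zeros(9)), 50, (), ())
        chain = Chain(g)
        committee = ["m0", "m1", "m2"]
        for t in range(1, n_blocks + 1):
            tx = make_tx(registry, values=(float(t), 0.0))
            chain.append(
                build_block(t, chain.last_hash(), committee, [tx], "m0", registry)
            )
        return chain

    def test_audit_passes(self, registry):
        assert self._chain(registry).audit(registry)

    def test_append_rejects_wrong_prev_hash(self, registry):
        chain = self._chain(registry)
        orphan = build_block(9, b"\x01" * 32, ["m0"], [], "m0", registry)
        with pytest.raises(LedgerError):
            chain.append(orphan)

    def test_save_load_audit(self, tmp_path, registry):
        chain = self._chain(registry)
        chain.save(tmp_path / "chain")
        loaded = Chain.load(tmp_path / "chain")
        assert loaded.audit(registry)
        assert [b.hash() for b in loaded.blocks] == [b.hash() for b in chain.blocks]

    def test_tampered_block_detected(self, tmp_path, registry):
        chain = self._chain(registry)
        d = tmp_path / "chain"
        chain.save(d)
        target = d / "block_00002.bin"
        raw = bytearray(target.read_bytes())
        raw[len(raw) // 2] ^= 0x01  # flip one bit mid-block
        target.write_bytes(bytes(raw))
        with pytest.raises((AuditError, LedgerError)):
            Chain.load(d).audit(registry)


def test_hmac_scheme_contract():
    scheme = HMACScheme()
    k1 = scheme.keygen("alice", 0)
    k2 = scheme.keygen("bob", 0)
    sig = scheme.sign(k1, b"message")
    assert scheme.verify(k1, b"message", sig)
    assert not scheme.verify(k2, b"message", sig)
    assert not scheme.verify(k1, b"other", sig)
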