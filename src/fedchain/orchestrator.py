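"""End-to-end driver for the blockchain-coordinated training protocol.

One round executes, in order: local training on every non-blacklisted
device; adaptive clipping and Gaussian noising of each update; signed
transaction submission; reputation-weighted committee selection; multi-KRUM
verification with majority endorsement; leader block building and 2/3
committee approval; the global model step (mean of the block's qualified
gradients, unit server step); the clipper-prior EMA update; moments-account
accumulation; and reputation bookkeeping. Training stops at the round
horizon, on privacy-budget exhaustion, or on convergence of the training
loss.

All randomness flows from named sub-seeds of the experiment seed (data,
split, partition, init, per-device-per-round batching, per-device-per-round
noise, attack), so any module can be replayed in isolation.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import accountant as acct
from . import attacks as atk
from . import ledger as led
from . import models
from . import privacy as priv
from . import synthetic_data as synth
from .crypto import KeyRegistry
from .verification import GradientPool, default_byzantine_count, endorse_and_accept


@dataclass(frozen=True)
class ExperimentConfig:
    """All knobs of one simulated training run (defaults: the reference
    desk-scale experiment — 20 devices, batch 64, 20 local iterations,
    G=1e-6, beta=1.2, sigma=4, delta=1e-4, gamma=0.1, C=3, epsilon=3)."""

    # data
    n_samples: int = 768
    positive_rate: float = 0.35
    noise_scale: float = 1.0
    test_fraction: float = 0.3
    data_csv: str | None = None  # optional external nine-column CSV
    standardize: bool = True
    # federation
    K: int = 20
    T: int = 50
    M: int = 5
    n_miners: int = 10
    initial_reputation: int = 10
    # local training
    arch_id: str = "logistic"
    batch_size: int = 64
    local_iterations: int = 20
    lr: float = 0.1
    # adaptive DP
    G: float = 1e-6
    beta: float = 1.2
    sigma: float = 4.0
    gamma: float = 0.1
    C: float = 3.0
    # privacy budget / accountant
    epsilon: float = 3.0
    delta: float = 1e-4
    enforce_budget: bool = True
    accountant_enabled: bool = True
    composition_mode: str = "sum_over_devices_and_rounds"
    mechanism_mode: str = "absolute"
    # verification
    verification_enabled: bool = True
    f: int | None = None  # None -> ceil(0.3 * pool size) per round
    krum_squared: bool = False
    # attack
    poisoned_fraction: float = 0.0
    malicious_verifier_ids: tuple[str, ...] = ()
    # stopping
    convergence_rel_tol: float = 1e-4
    convergence_patience: int = 5
    # bookkeeping
    seed: int = 0
    metrics_csv: str | None = None
    chain_dir: str | None = None
    summary_json: str | None = None

    def __post_init__(self) -> None:
        if self.K < 1 or self.T < 1 or self.M < 1:
            raise ValueError("K, T, M must be >= 1")
        if self.M > self.n_miners:
            raise ValueError("committee size M cannot exceed the miner count")
        if not 0.0 <= self.poisoned_fraction <= 1.0:
            raise ValueError("poisoned_fraction must be in [0, 1]")

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        if "malicious_verifier_ids" in d:
            d["malicious_verifier_ids"] = tuple(d["malicious_verifier_ids"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["malicious_verifier_ids"] = list(d["malicious_verifier_ids"])
        return d


@dataclass
class RoundRecord:
    """Everything one appended block contributes to the metrics stream."""

    round: int
    C_t: float
    qualified: int
    rejected_devices: list[str]
    committee: list[str]
    leader: str
    block_empty: bool
    spent_epsilon: float
    train_loss: float
    accuracy: float
    attack_success_rate: float
    blacklist_size: int
    detection_precision: float
    detection_recall: float

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["rejected_devices"] = ";".join(self.rejected_devices)
        d["committee"] = ";".join(self.committee)
        return d


def device_id(i: int) -> str:
    return f"device-{i:03d}"


def miner_id(i: int) -> str:
    return f"miner-{i:03d}"


def device_train_seed(seed: int, device_index: int, round_index: int) -> np.random.SeedSequence:
    """The named batching/training stream of one device in one round."""
    return np.random.SeedSequence([seed, 5, device_index, round_index])


@dataclass
class FLState:
    """Mutable state threaded through rounds."""

    cfg: ExperimentConfig
    params: models.ModelParams
    chain: led.Chain
    registry: KeyRegistry
    table: led.ReputationTable
    clipper: priv.ClipperState
    moments: acct.MomentLedger
    budget: acct.PrivacyBudget
    partition: synth.DevicePartition
    poisoned: list[int]
    train: synth.ClinicalDataset
    test: synth.ClinicalDataset
    round_index: int = 0
    loss_history: list[float] = field(default_factory=list)
    exhausted: bool = False


def setup_experiment(cfg: ExperimentConfig) -> FLState:
    """Generate (or load) data, build the genesis block, and initialize state."""
    if cfg.data_csv is not None:
        ds = synth.load_csv(cfg.data_csv)
    else:
        ds = synth.generate_pima_like(
            cfg.n_samples,
            seed=int(np.random.SeedSequence([cfg.seed, 1]).generate_state(1)[0] % 2**31),
            positive_rate=cfg.positive_rate,
            noise_scale=cfg.noise_scale,
        )
    split_seed = int(np.random.SeedSequence([cfg.seed, 2]).generate_state(1)[0] % 2**31)
    train, test = synth.train_test_split(ds, cfg.test_fraction, split_seed)
    if cfg.standardize:
        train, test = train.standardized(), test.standardized()
    part_seed = int(np.random.SeedSequence([cfg.seed, 3]).generate_state(1)[0] % 2**31)
    partition = synth.partition_devices(train, cfg.K, part_seed)
    attack_cfg = atk.AttackConfig(
        poisoned_fraction=cfg.poisoned_fraction,
        seed=cfg.seed,
        malicious_verifier_ids=frozenset(cfg.malicious_verifier_ids),
    )
    partition, poisoned = atk.apply_attack(partition, attack_cfg)

    init_seed = int(np.random.SeedSequence([cfg.seed, 4]).generate_state(1)[0] % 2**31)
    params = models.init_params(cfg.arch_id, init_seed)

    registry = KeyRegistry(seed=cfg.seed)
    parties = [device_id(i) for i in range(cfg.K)] + [
        miner_id(j) for j in range(cfg.n_miners)
    ]
    for p in parties:
        registry.register(p)

    table = led.ReputationTable(
        reputation={p: cfg.initial_reputation for p in parties},
        miners={miner_id(j) for j in range(cfg.n_miners)},
    )
    genesis = led.GenesisBlock(
        arch_id=cfg.arch_id,
        initial_params_bytes=led.gradient_to_bytes(params.values),
        total_rounds=cfg.T,
        public_keys=tuple((p, registry.fingerprint(p)) for p in sorted(parties)),
        initial_reputations=tuple((p, cfg.initial_reputation) for p in sorted(parties)),
    )
    chain = led.Chain(genesis)
    clipper = priv.ClipperState(
        gamma=cfg.gamma,
        beta=cfg.beta,
        fixed_C=cfg.C,
        prior_threshold=cfg.G,
        sigma=cfg.sigma,
    )
    moments = acct.MomentLedger(composition_mode=cfg.composition_mode)
    budget = acct.PrivacyBudget(epsilon=cfg.epsilon, delta=cfg.delta)
    return FLState(
        cfg=cfg,
        params=params,
        chain=chain,
        registry=registry,
        table=table,
        clipper=clipper,
        moments=moments,
        budget=budget,
        partition=partition,
        poisoned=poisoned,
        train=train,
        test=test,
    )


def run_round(state: FLState) -> RoundRecord:
    """Execute one full training round and append its block."""
    cfg = state.cfg
    state.round_index += 1
    t = state.round_index
    # sigma == 0 switches the whole DP mechanism off (no clipping, no noise,
    # no prior tracking): the pipeline then reduces to plain federated
    # averaging plus verification, the no-privacy baseline.
    dp_active = cfg.sigma > 0
    C_t = priv.clipping_threshold(state.clipper)
    prev_hash = state.chain.last_hash()

    # 1-3: local training, clip + noise, signed transaction submission.
    transactions: list[led.Transaction] = []
    active_indices: list[int] = []
    for i in range(cfg.K):
        did = device_id(i)
        if state.table.is_blacklisted(did):
            continue
        shard = state.partition.shards[i]
        seed = device_train_seed(cfg.seed, i, t)
        update = models.local_train(
            state.params,
            shard,
            cfg.batch_size,
            cfg.local_iterations,
            cfg.lr,
            seed,
            round_index=t,
            device_id=did,
        )
        g = priv.GradientVector(update.gradient, t, did)
        if dp_active:
            g = priv.clip_gradient(g, C_t)
            g = priv.add_noise(g, C_t, cfg.sigma, priv.device_noise_rng(cfg.seed, i, t))
        grad_bytes = led.gradient_to_bytes(g.values)
        transactions.append(
            led.Transaction(
                did, grad_bytes, state.registry.sign(did, grad_bytes), ()
            )
        )
        active_indices.append(i)

    R = len(transactions)
    committee = led.select_committee(prev_hash, state.table, cfg.M)

    # 4-5: gradient verification and majority endorsement.
    if cfg.verification_enabled:
        f = cfg.f if cfg.f is not None else default_byzantine_count(R)
        pool = GradientPool(tuple(transactions), f)
        malicious = set(cfg.malicious_verifier_ids) & set(committee)
        accepted, verdicts = endorse_and_accept(
            pool,
            committee,
            state.registry,
            squared=cfg.krum_squared,
            malicious_verifiers=malicious,
        )
    else:
        accepted = [
            led.Transaction(
                tx.device_id,
                tx.gradient_bytes,
                tx.device_signature,
                tuple(
                    (m, state.registry.sign(m, tx.gradient_bytes)) for m in committee
                ),
            )
            for tx in transactions
        ]
        verdicts = {m: {tx.device_id for tx in transactions} for m in committee}

    # 5-6: leader builds the block; the committee votes (> 2/3 to accept).
    leader = led.select_leader(committee, prev_hash)
    block = led.build_block(t, prev_hash, committee, accepted, leader, state.registry)
    dissenting = set(cfg.malicious_verifier_ids) & set(committee)
    valid, _votes = led.approve_block(block, committee, state.registry, dissenting)
    if not valid:
        block = led.build_block(
            t, prev_hash, committee, [], leader, state.registry, is_empty=True
        )
    state.chain.append(block)

    # 6: global model step = subtract the mean of the block's gradients.
    accepted_ids = {tx.device_id for tx in block.transactions}
    if block.transactions:
        G = np.stack(
            [led.gradient_from_bytes(tx.gradient_bytes) for tx in block.transactions]
        )
        global_grad = G.mean(axis=0)
        state.params = models.ModelParams(
            state.params.values - global_grad, cfg.arch_id
        )
    else:
        global_grad = np.zeros_like(state.params.values)

    # EMA prior update with this round's global gradient.
    if dp_active:
        state.clipper = priv.update_prior(
            state.clipper, priv.GradientVector(global_grad, t, "global")
        )

    # Moments accounting: one noised release per active device this round.
    if cfg.accountant_enabled and dp_active:
        noise_std = C_t * cfg.sigma if cfg.mechanism_mode == "absolute" else cfg.sigma
        by_q: dict[float, int] = {}
        for i in active_indices:
            q = acct.sampling_probability(cfg.batch_size, state.partition.shards[i].n)
            by_q[q] = by_q.get(q, 0) + 1
        for q, count in by_q.items():
            spec = acct.MechanismSpec(
                q=q, noise_std=noise_std, mode=cfg.mechanism_mode
            )
            state.moments = acct.accumulate(state.moments, spec, devices=count)
    state.exhausted = (
        acct.is_exhausted(state.budget, state.moments)
        if cfg.accountant_enabled and dp_active
        else False
    )

    # Reputation bookkeeping.
    events: dict[str, int] = {}
    submitted_ids = {tx.device_id for tx in transactions}
    if not block.is_empty:
        for did in submitted_ids:
            events[did] = 1 if did in accepted_ids else -1
    final_ids = accepted_ids if not block.is_empty else {
        tx.device_id for tx in accepted
    }
    for m in committee:
        events[m] = 1 if verdicts.get(m, set()) == final_ids else -1
    if block.is_empty:
        events[leader] = -1
    state.table = led.update_reputation(state.table, events)

    rejected = sorted(submitted_ids - accepted_ids)
    # Detection counts every device whose update is excluded from the block,
    # whether rejected by multi-KRUM this round or already blacklisted.
    excluded_idx = {
        i for i in range(cfg.K) if device_id(i) not in accepted_ids
    }
    precision, recall = atk.detection_precision_recall(
        excluded_idx, set(state.poisoned)
    )
    loss, _ = models.loss_and_grad(state.params, state.train.features, state.train.labels)
    acc, asr = models.evaluate(state.params, state.test)
    state.loss_history.append(loss)
    return RoundRecord(
        round=t,
        C_t=C_t,
        qualified=len(block.transactions),
        rejected_devices=rejected,
        committee=list(committee),
        leader=leader,
        block_empty=block.is_empty,
        spent_epsilon=state.budget.spent_epsilon,
        train_loss=loss,
        accuracy=acc,
        attack_success_rate=asr,
        blacklist_size=len(state.table.blacklist),
        detection_precision=precision,
        detection_recall=recall,
    )


def _converged(losses: list[float], rel_tol: float, patience: int) -> bool:
    if len(losses) < patience + 1:
        return False
    recent = losses[-(patience + 1):]
    for prev, cur in zip(recent, recent[1:]):
        if abs(cur - prev) / max(abs(prev), 1e-12) >= rel_tol:
            return False
    return True


def run_experiment(cfg: ExperimentConfig) -> tuple[list[RoundRecord], FLState]:
    """Run rounds until the horizon, budget exhaustion, or convergence."""
    state = setup_experiment(cfg)
    records: list[RoundRecord] = []
    for _ in range(cfg.T):
        records.append(run_round(state))
        if cfg.enforce_budget and state.exhausted:
            break
        if _converged(
            state.loss_history, cfg.convergence_rel_tol, cfg.convergence_patience
        ):
            break
    if cfg.metrics_csv:
        records_to_frame(records).to_csv(cfg.metrics_csv, index=False)
    if cfg.chain_dir:
        state.chain.save(cfg.chain_dir)
        Path(cfg.chain_dir, "keys.json").write_text(
            json.dumps(state.registry.to_dict(), indent=1)
        )
    if cfg.summary_json:
        Path(cfg.summary_json).write_text(json.dumps(summarize(records, state), indent=1))
    return records, state


def records_to_frame(records: list[RoundRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.to_dict() for r in records])


def summarize(records: list[RoundRecord], state: FLState) -> dict:
    last = records[-1]
    return {
        "rounds": len(records),
        "final_accuracy": last.accuracy,
        "final_attack_success_rate": last.attack_success_rate,
        "spent_epsilon": last.spent_epsilon,
        "budget_exhausted": state.exhausted,
        "blacklist": sorted(state.table.blacklist),
        "poisoned_devices": state.poisoned,
    }
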