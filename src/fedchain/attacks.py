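"""Adversary harness: label-flipping data poisoning and malicious verifiers.

The poisoning adversary is static: before training starts, a seeded draw
designates a fraction of devices, and every label in their shards is
inverted while the features stay byte-identical. Malicious verifiers and
block dissenters are optional toggles that exercise the majority-signature
and reputation defences; they are capped below one third of the miners, the
honest-majority assumption the consensus protocol rests on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .synthetic_data import ClinicalDataset, DevicePartition


@dataclass(frozen=True)
class AttackConfig:
    """Which devices are poisoned and which verifiers misbehave."""

    poisoned_fraction: float = 0.0
    seed: int = 0
    malicious_verifier_ids: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not 0.0 <= self.poisoned_fraction <= 1.0:
            raise ValueError("poisoned_fraction must be in [0, 1]")


def flip_labels(shard: ClinicalDataset) -> ClinicalDataset:
    """Invert every binary label; features are untouched (same buffer)."""
    return ClinicalDataset(
        shard.features, 1 - shard.labels, {**shard.provenance, "label_flipped": True}
    )


def resolve_poisoned_devices(cfg: AttackConfig, K: int) -> list[int]:
    """Seeded draw of round(fraction * K) device indices, without replacement."""
    n_poison = int(round(cfg.poisoned_fraction * K))
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 23]))
    return sorted(rng.choice(K, size=n_poison, replace=False).tolist())


def apply_attack(
    partition: DevicePartition, cfg: AttackConfig
) -> tuple[DevicePartition, list[int]]:
    """Replace the designated devices' shards with label-flipped copies.

    Returns the attacked partition and the poisoned device indices.
    """
    poisoned = set(resolve_poisoned_devices(cfg, partition.K))
    shards = tuple(
        flip_labels(s) if i in poisoned else s for i, s in enumerate(partition.shards)
    )
    return DevicePartition(shards), sorted(poisoned)


def detection_precision_recall(
    rejected: set[int], poisoned: set[int]
) -> tuple[float, float]:
    """How well the round's rejection set matches the true poisoned set."""
    # vacuous conventions: an empty rejection set raises no false alarms
    precision = 1.0 if not rejected else len(rejected & poisoned) / len(rejected)
    recall = 1.0 if not poisoned else len(rejected & poisoned) / len(poisoned)
    return precision, recall
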