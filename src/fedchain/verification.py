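"""Multi-KRUM gradient verification and committee endorsement.

Each gradient in the round's transaction pool gets a quality score: the sum
of its plain Euclidean distances to its R - f - 2 nearest neighbours, where
R is the pool size and f the assumed number of Byzantine gradients. The
R - f lowest-scoring gradients are qualified. A qualified gradient still
needs endorsement signatures from a strict majority of the verification
committee before it enters the block — each honest verifier recomputes the
scores independently, so a single colluding verifier cannot push a rejected
gradient through.

The distances are plain (unsquared) norms by default; the squared variant of
the original multi-KRUM formulation is available via ``squared=True``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .crypto import KeyRegistry
from .ledger import Transaction, gradient_from_bytes


class VerificationError(RuntimeError):
    pass


@dataclass(frozen=True)
class GradientPool:
    """The round's transaction pool plus the assumed Byzantine count f."""

    transactions: tuple[Transaction, ...]
    f: int

    def __post_init__(self) -> None:
        if self.R < self.f + 3:
            raise VerificationError(
                f"pool of R={self.R} too small for f={self.f} (need R >= f + 3)"
            )

    @property
    def R(self) -> int:
        return len(self.transactions)

    @property
    def device_ids(self) -> list[str]:
        return [tx.device_id for tx in self.transactions]

    def gradient_matrix(self) -> np.ndarray:
        return np.stack(
            [gradient_from_bytes(tx.gradient_bytes) for tx in self.transactions]
        )


@dataclass(frozen=True)
class QualityScores:
    """Per-gradient multi-KRUM scores, aligned with the pool; lower is better."""

    device_ids: tuple[str, ...]
    scores: np.ndarray


def default_byzantine_count(R: int, fraction: float = 0.3) -> int:
    """Default f = ceil(fraction * R), the assumed poisoned share."""
    return int(np.ceil(fraction * R))


def krum_scores(pool: GradientPool, squared: bool = False) -> QualityScores:
    """Sum of distances from each gradient to its R - f - 2 nearest others."""
    G = pool.gradient_matrix()
    D = cdist(G, G)  # plain Euclidean
    if squared:
        D = D**2
    n_neighbors = pool.R - pool.f - 2
    scores = np.empty(pool.R)
    for i in range(pool.R):
        others = np.delete(D[i], i)
        others.sort()
        scores[i] = others[:n_neighbors].sum()
    return QualityScores(tuple(pool.device_ids), scores)


def select_qualified(pool: GradientPool, scores: QualityScores) -> list[str]:
    """The R - f lowest-scoring device ids; ties broken by ascending id."""
    if tuple(pool.device_ids) != scores.device_ids:
        raise VerificationError("scores were not computed on this pool")
    order = sorted(range(pool.R), key=lambda i: (scores.scores[i], scores.device_ids[i]))
    keep = order[: pool.R - pool.f]
    return [scores.device_ids[i] for i in keep]


@dataclass(frozen=True)
class Endorsement:
    """Verifier signatures accumulated by one qualified gradient."""

    device_id: str
    signatures: tuple[tuple[str, bytes], ...]


def endorse_and_accept(
    pool: GradientPool,
    committee: list[str],
    registry: KeyRegistry,
    squared: bool = False,
    malicious_verifiers: set[str] | None = None,
) -> tuple[list[Transaction], dict[str, set[str]]]:
    """Run independent verification per committee member and tally signatures.

    Every honest verifier recomputes the multi-KRUM scores on the pool and
    signs the gradients it finds qualified. A malicious verifier signs the
    complement (rejected gradients) instead, modelling collusion. A gradient
    is accepted iff it carries strictly more than M/2 valid signatures; the
    accepted transactions are returned with their endorsements attached.

    Returns (accepted transactions, per-verifier qualified-id sets).
    """
    if not committee:
        raise VerificationError("committee must have at least one member")
    malicious_verifiers = malicious_verifiers or set()
    honest_qualified = set(select_qualified(pool, krum_scores(pool, squared)))
    verdicts: dict[str, set[str]] = {}
    signatures: dict[str, list[tuple[str, bytes]]] = {
        tx.device_id: [] for tx in pool.transactions
    }
    for member in committee:
        if member in malicious_verifiers:
            endorsed = set(pool.device_ids) - honest_qualified
        else:
            endorsed = honest_qualified
        verdicts[member] = endorsed
        for tx in pool.transactions:
            if tx.device_id in endorsed:
                sig = registry.sign(member, tx.gradient_bytes)
                signatures[tx.device_id].append((member, sig))
    M = len(committee)
    accepted: list[Transaction] = []
    for tx in pool.transactions:
        valid = [
            (vid, sig)
            for vid, sig in signatures[tx.device_id]
            if registry.verify(vid, tx.gradient_bytes, sig)
        ]
        if len(valid) > M / 2:
            accepted.append(
                Transaction(
                    tx.device_id,
                    tx.gradient_bytes,
                    tx.device_signature,
                    tuple(valid),
                )
            )
    return accepted, verdicts
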