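"""Moments-accountant privacy tracking for the subsampled Gaussian mechanism.

Each noised upload is modeled by a pair of Gaussians mu0 = N(0, s^2) and
mu1 = N(shift, s^2) and their mixture mu = (1-q) mu0 + q mu1, where q is the
sampling probability of local training and s the noise standard deviation.
The lambda-th log-moment of the privacy-loss variable is

    alpha(lambda) = log max(E1, E2),
    E1 = E_{x ~ mu0} (mu0(x) / mu(x))^lambda,
    E2 = E_{x ~ mu}  (mu(x) / mu0(x))^lambda,

computed by adaptive quadrature on the real line, carried out in log-space so
that moments far beyond float range compose without overflow. Log-moments add
across devices and rounds, and convert to an (epsilon, delta) guarantee by the
tail bound delta = min_lambda exp(alpha(lambda) - lambda * epsilon), i.e.

    epsilon(delta) = min_lambda (alpha(lambda) + log(1/delta)) / lambda.

Two mechanism conventions are supported. ``absolute`` uses a unit shift
with s = C_t * sigma, exactly as the adaptive-DP construction writes it: a
shrinking clipping threshold then *shrinks the noise relative to the fixed
shift* and increases per-round cost. ``normalized`` uses s = sigma (noise
measured in units of the sensitivity), the convention of the DP-SGD
literature, under which alpha is independent of C_t. Both are first-class so
the divergence between the two readings is explicit and testable.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.integrate import quad_vec

DEFAULT_LAMBDAS = tuple(range(1, 101))

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


class AccountantError(RuntimeError):
    """Raised when a log-moment integral fails to converge."""


@dataclass(frozen=True)
class MechanismSpec:
    """One round's noised release, as seen by the accountant.

    q         sampling probability of local training, in [0, 1].
    shift     mean separation of mu0 and mu1 (1 in both conventions here).
    noise_std Gaussian standard deviation: C_t * sigma in ``absolute``
              mode, sigma in ``normalized`` mode.
    """

    q: float
    noise_std: float
    shift: float = 1.0
    mode: str = "absolute"

    def __post_init__(self) -> None:
        if not 0.0 <= self.q <= 1.0:
            raise ValueError("q must be in [0, 1]")
        if self.noise_std <= 0:
            raise ValueError("noise_std must be positive")
        if self.mode not in ("absolute", "normalized"):
            raise ValueError(f"unknown mode {self.mode!r}")


def _log_mix(x: np.ndarray, q: float, s: float, shift: float) -> np.ndarray:
    """log of (1-q) N(0,s^2) + q N(shift,s^2) at x, stable for q in {0,1}."""
    l0 = -0.5 * (x / s) ** 2 - np.log(s) - _LOG_SQRT_2PI
    l1 = -0.5 * ((x - shift) / s) ** 2 - np.log(s) - _LOG_SQRT_2PI
    if q == 0.0:
        return l0
    if q == 1.0:
        return l1
    return np.logaddexp(np.log1p(-q) + l0, np.log(q) + l1)


@lru_cache(maxsize=4096)
def _log_moments_cached(
    q: float, noise_std: float, shift: float, lambdas: tuple[int, ...]
) -> tuple[float, ...]:
    lams = np.asarray(lambdas, dtype=float)
    if q == 0.0:
        return tuple(0.0 for _ in lambdas)
    s = noise_std

    def log_f(x: float, which: str) -> np.ndarray:
        l0 = -0.5 * (x / s) ** 2 - np.log(s) - _LOG_SQRT_2PI
        lm = _log_mix(np.asarray(x), q, s, shift)
        if which == "E1":
            return l0 + lams * (l0 - lm)
        return lm + lams * (lm - l0)

    lam_max = float(lams.max())
    lo = min(0.0, shift) - lam_max * abs(shift) - 14.0 * s
    hi = max(0.0, shift) + (lam_max + 1.0) * abs(shift) + 14.0 * s
    # Per-lambda shift so every component of the vector integrand is O(1).
    grid = np.linspace(lo, hi, 4001)
    out: dict[str, np.ndarray] = {}
    for which in ("E1", "E2"):
        vals = np.stack([log_f(x, which) for x in grid])
        m = vals.max(axis=0)

        def integrand(x: float, which=which, m=m) -> np.ndarray:
            return np.exp(log_f(x, which) - m)

        res, err = quad_vec(
            integrand, lo, hi, epsabs=1e-11, epsrel=1e-11, norm="max"
        )
        if not np.all(np.isfinite(res)) or err > 1e-8 * max(1.0, float(np.max(res))):
            raise AccountantError(
                f"log-moment integration failed (err={err!r}) for q={q}, s={s}"
            )
        out[which] = m + np.log(res)
    alpha = np.maximum(out["E1"], out["E2"])
    # alpha >= 0 analytically (Jensen); clamp quadrature jitter at zero.
    alpha = np.maximum(alpha, 0.0)
    return tuple(float(a) for a in alpha)


def log_moments(spec: MechanismSpec, lambdas=DEFAULT_LAMBDAS) -> np.ndarray:
    """alpha(lambda) over a grid of integer moment orders."""
    lams = tuple(int(l) for l in lambdas)
    if any(l < 1 for l in lams):
        raise ValueError("moment orders must be >= 1")
    return np.array(_log_moments_cached(spec.q, spec.noise_std, spec.shift, lams))


def log_moment(spec: MechanismSpec, lam: int) -> float:
    """The single log-moment alpha(lambda) = log max(E1, E2); always >= 0."""
    return float(log_moments(spec, (lam,))[0])


@dataclass
class MomentLedger:
    """Accumulated log-moments over a grid of moment orders.

    ``composition_mode`` controls the device dimension of the sum:
    ``sum_over_devices_and_rounds`` adds K copies of each round's moments
    (the strict sequential-composition bound over all device releases);
    ``rounds_only`` adds one copy per round (parallel composition across
    devices holding disjoint shards).
    """

    lambdas: tuple[int, ...] = DEFAULT_LAMBDAS
    totals: np.ndarray = field(default=None)  # type: ignore[assignment]
    entries: list[dict] = field(default_factory=list)
    composition_mode: str = "sum_over_devices_and_rounds"

    def __post_init__(self) -> None:
        if self.totals is None:
            self.totals = np.zeros(len(self.lambdas))
        self.totals = np.asarray(self.totals, dtype=float)
        if self.totals.shape != (len(self.lambdas),):
            raise ValueError("totals must align with the lambda grid")
        if self.composition_mode not in ("sum_over_devices_and_rounds", "rounds_only"):
            raise ValueError(f"unknown composition_mode {self.composition_mode!r}")

    def copy(self) -> "MomentLedger":
        return MomentLedger(
            self.lambdas, self.totals.copy(), list(self.entries), self.composition_mode
        )


@dataclass
class PrivacyBudget:
    """Target (epsilon, delta) and the epsilon spent so far at that delta."""

    epsilon: float
    delta: float
    spent_epsilon: float = 0.0


def accumulate(
    ledger: MomentLedger, spec: MechanismSpec, devices: int = 1, rounds: int = 1
) -> MomentLedger:
    """Add ``rounds`` rounds of ``devices`` identical releases to the ledger."""
    alpha = log_moments(spec, ledger.lambdas)
    mult = devices if ledger.composition_mode == "sum_over_devices_and_rounds" else 1
    out = ledger.copy()
    out.totals = out.totals + mult * rounds * alpha
    out.entries.append(
        {"spec": dataclasses.asdict(spec), "devices": devices, "rounds": rounds}
    )
    return out


def epsilon_for_delta(ledger: MomentLedger, delta: float) -> float:
    """Invert the tail bound: the best epsilon over the lambda grid."""
    if not 0.0 < delta < 1.0:
        raise ValueError("delta must be in (0, 1)")
    if not ledger.entries:
        return 0.0
    lams = np.asarray(ledger.lambdas, dtype=float)
    eps = (ledger.totals + np.log(1.0 / delta)) / lams
    return float(max(eps.min(), 0.0))


def is_exhausted(budget: PrivacyBudget, ledger: MomentLedger) -> bool:
    """True once the spent epsilon at the target delta exceeds the budget."""
    spent = epsilon_for_delta(ledger, budget.delta)
    budget.spent_epsilon = max(budget.spent_epsilon, spent)
    return spent > budget.epsilon


def sampling_probability(batch_size: int, shard_size: int) -> float:
    """q = min(1, batch / shard): the local-training sampling probability."""
    if shard_size < 1:
        raise ValueError("shard_size must be >= 1")
    return min(1.0, batch_size / shard_size)
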