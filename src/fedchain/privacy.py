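"""Adaptive differential privacy for device uploads.

The clipping threshold adapts to an exponential moving average (EMA) of the
squared L2 norm of the global gradient — "prior knowledge" accumulated the
way RMSProp accumulates squared gradients. While that prior is still below a
floor G the threshold stays at a fixed C; afterwards it tracks
beta * sqrt(prior). Each device clips its update to the round's threshold
C_t and adds i.i.d. Gaussian noise of standard deviation C_t * sigma per
coordinate.

The prior is a scalar EMA of the squared *norm* (not per-coordinate): its
square root is used directly as a scalar L2 clipping threshold, which is the
only dimensionally consistent reading.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class GradientVector:
    """A flat per-round update from one device (raw, clipped, or noised)."""

    values: np.ndarray
    round: int = 0
    device_id: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "values", np.asarray(self.values, dtype=np.float64).ravel()
        )

    @property
    def norm(self) -> float:
        return float(np.linalg.norm(self.values))


@dataclass(frozen=True)
class ClipperState:
    """Adaptive-clipping state and DP hyperparameters.

    prior           EMA of the squared L2 norm of the global gradient; 0
                    before the first round.
    gamma           EMA exponent (0 < gamma <= 1); default 0.1.
    beta            clipping factor applied to sqrt(prior); default 1.2.
    fixed_C         initial threshold used while prior <= G; default 3.
    prior_threshold the floor G below which the fixed threshold applies;
                    default 1e-6.
    sigma           noise multiplier; per-coordinate noise std is C_t*sigma.
    """

    prior: float = 0.0
    gamma: float = 0.1
    beta: float = 1.2
    fixed_C: float = 3.0
    prior_threshold: float = 1e-6
    sigma: float = 4.0

    def __post_init__(self) -> None:
        if self.prior < 0:
            raise ValueError("prior must be non-negative")
        if not 0.0 < self.gamma <= 1.0:
            raise ValueError("gamma must be in (0, 1]")
        if self.beta <= 0 or self.fixed_C <= 0:
            raise ValueError("beta and fixed_C must be positive")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, s: str) -> "ClipperState":
        return cls(**json.loads(s))


def update_prior(state: ClipperState, global_grad: GradientVector) -> ClipperState:
    """EMA step: prior <- (1 - gamma) * prior + gamma * ||g_global||^2.

    A non-finite global gradient signals a diverged round: the state is
    returned unchanged with a warning rather than poisoning the EMA.
    """
    sq = float(np.dot(global_grad.values, global_grad.values))
    if not np.isfinite(sq):
        warnings.warn(
            "non-finite global gradient; clipper prior left unchanged",
            RuntimeWarning,
            stacklevel=2,
        )
        return state
    new_prior = (1.0 - state.gamma) * state.prior + state.gamma * sq
    return dataclasses.replace(state, prior=new_prior)


def clipping_threshold(state: ClipperState) -> float:
    """The round's threshold C_t: fixed_C while prior <= G, else beta*sqrt(prior).

    Equality with G falls to the fixed branch (conservative early-stage
    behavior; the adaptive rule leaves the boundary case open).
    """
    if state.prior <= state.prior_threshold:
        return state.fixed_C
    return state.beta * float(np.sqrt(state.prior))


def clip_gradient(g: GradientVector, C_t: float) -> GradientVector:
    """Scale g to L2 norm at most C_t: g / max(1, ||g|| / C_t)."""
    if C_t <= 0:
        raise ValueError("C_t must be positive")
    scale = max(1.0, g.norm / C_t)
    return GradientVector(g.values / scale, g.round, g.device_id)


def add_noise(
    g_clipped: GradientVector,
    C_t: float,
    sigma: float,
    rng: np.random.Generator,
) -> GradientVector:
    """Add i.i.d. N(0, (C_t * sigma)^2) noise to every coordinate."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if sigma == 0.0:
        return g_clipped
    noise = rng.normal(0.0, C_t * sigma, size=g_clipped.values.shape)
    return GradientVector(g_clipped.values + noise, g_clipped.round, g_clipped.device_id)


def device_noise_rng(global_seed: int, device_index: int, round_index: int) -> np.random.Generator:
    """Per-(device, round) noise stream, independent of training streams."""
    return np.random.default_rng(
        np.random.SeedSequence([global_seed, 7, device_index, round_index])
    )


def calibrate_prior_threshold(priors: list[float], round_index: int) -> float:
    """Optional helper: set G to the prior observed in a given round."""
    if not 0 <= round_index < len(priors):
        raise ValueError("round_index outside the recorded prior history")
    return priors[round_index]
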