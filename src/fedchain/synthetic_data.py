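"""Synthetic Pima-like clinical tabular data.

Generates datasets with the nine-column diabetes schema (eight integer
clinical predictors plus a binary ``Outcome``) from a documented generative
model with a known ground-truth logistic coefficient vector, so that every
downstream component — local training, privacy, verification, attacks — is
testable without downloading anything.

The feature constants below are fixture constants chosen to be plausible for
a diabetes cohort (means/spreads in the right ballpark, non-negative,
integer-valued); they are not estimates of the real Pima data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

FEATURE_NAMES = (
    "Pregnanci",
    "Glucose",
    "BloodPressure",
    "SkinThickness",
    "Insulin",
    "BMI",
    "DiabetesPedigreeFunction",
    "Age",
)
LABEL_NAME = "Outcome"
N_FEATURES = len(FEATURE_NAMES)

# Per-column (mean, std, lower bound, upper bound) of the latent Gaussian
# before rounding; loading on the shared "metabolic risk" factor in [0, 1).
_FEATURE_MEAN = np.array([3.5, 120.0, 70.0, 22.0, 90.0, 32.0, 0.5, 33.0])
_FEATURE_STD = np.array([3.2, 30.0, 12.0, 10.0, 70.0, 7.0, 0.35, 11.0])
_FEATURE_LO = np.zeros(8)
_FEATURE_HI = np.array([17.0, 200.0, 122.0, 99.0, 850.0, 67.0, 2.5, 81.0])
_FACTOR_LOADING = np.array([0.2, 0.6, 0.3, 0.35, 0.5, 0.45, 0.15, 0.3])

# Ground-truth standardized logistic coefficients: risk increases with every
# predictor, dominated by glucose / BMI / age as in the diabetes literature.
_TRUE_BETA = np.array([0.25, 1.1, 0.15, 0.2, 0.35, 0.7, 0.3, 0.55])

# DiabetesPedigreeFunction is stored ×100 so that an integer column (per the
# schema) keeps two significant digits.
_PEDIGREE_SCALE = 100.0


@dataclass(frozen=True)
class ClinicalDataset:
    """A tabular clinical dataset: (n, 8) feature matrix + binary labels."""

    features: np.ndarray
    labels: np.ndarray
    provenance: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        f = np.asarray(self.features, dtype=float)
        y = np.asarray(self.labels)
        if f.ndim != 2 or f.shape[1] != N_FEATURES:
            raise ValueError(f"features must be (n, {N_FEATURES}), got {f.shape}")
        if y.shape != (f.shape[0],):
            raise ValueError("labels must be a vector with one entry per row")
        if not np.isin(y, (0, 1)).all():
            raise ValueError("labels must be binary 0/1")
        object.__setattr__(self, "features", f)
        object.__setattr__(self, "labels", y.astype(np.int64))

    @property
    def n(self) -> int:
        return self.features.shape[0]

    @property
    def positive_rate(self) -> float:
        return float(self.labels.mean())

    def subset(self, idx: np.ndarray) -> "ClinicalDataset":
        return ClinicalDataset(self.features[idx], self.labels[idx], dict(self.provenance))

    def standardized(self) -> "ClinicalDataset":
        """Features rescaled by the generator's fixed column statistics.

        Uses the generator constants (not the empirical moments), so the same
        deterministic transform applies to every shard and the test set.
        """
        scale = _FEATURE_STD.copy()
        mean = _FEATURE_MEAN.copy()
        scale_adj = scale.copy()
        scale_adj[6] *= _PEDIGREE_SCALE
        mean_adj = mean.copy()
        mean_adj[6] *= _PEDIGREE_SCALE
        z = (self.features - mean_adj) / scale_adj
        return ClinicalDataset(z, self.labels, dict(self.provenance))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.features, columns=list(FEATURE_NAMES))
        df[LABEL_NAME] = self.labels
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def load_csv(path) -> ClinicalDataset:
    """Load a dataset from a CSV with the nine-column schema (Outcome last)."""
    df = pd.read_csv(path)
    expected = list(FEATURE_NAMES) + [LABEL_NAME]
    if list(df.columns) != expected:
        raise ValueError(f"CSV columns {list(df.columns)} != expected {expected}")
    return ClinicalDataset(
        df[list(FEATURE_NAMES)].to_numpy(dtype=float),
        df[LABEL_NAME].to_numpy(),
        provenance={"source": str(path)},
    )


@dataclass(frozen=True)
class DevicePartition:
    """A disjoint, exhaustive split of a training set across K devices."""

    shards: tuple[ClinicalDataset, ...]

    @property
    def K(self) -> int:
        return len(self.shards)

    @property
    def sizes(self) -> list[int]:
        return [s.n for s in self.shards]


def generate_pima_like(
    n: int,
    seed: int,
    positive_rate: float = 0.35,
    noise_scale: float = 1.0,
) -> ClinicalDataset:
    """Generate n Pima-schema samples with a known logistic ground truth.

    Features are correlated through a shared latent risk factor, truncated to
    plausible non-negative ranges, and rounded to integers. Labels follow
    Bernoulli(sigmoid(z @ beta + b)) on the standardized features, with the
    intercept b chosen by bisection so the expected positive rate over the
    drawn sample equals ``positive_rate``.

    Parameters
    ----------
    n : number of samples (>= 1).
    seed : RNG seed; generation is bit-reproducible given (parameters, seed).
    positive_rate : target marginal frequency of Outcome == 1, in (0, 1).
    noise_scale : multiplier on the idiosyncratic per-feature noise.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if not 0.0 < positive_rate < 1.0:
        raise ValueError(f"positive_rate must be in (0, 1), got {positive_rate}")
    if noise_scale < 0:
        raise ValueError("noise_scale must be non-negative")

    rng = np.random.default_rng(seed)
    factor = rng.normal(size=(n, 1))
    eps = rng.normal(size=(n, N_FEATURES)) * noise_scale
    load = _FACTOR_LOADING[None, :]
    idio = np.sqrt(1.0 - _FACTOR_LOADING**2)[None, :]
    z_latent = factor * load + eps * idio
    x = np.clip(
        _FEATURE_MEAN[None, :] + _FEATURE_STD[None, :] * z_latent,
        _FEATURE_LO[None, :],
        _FEATURE_HI[None, :],
    )
    x[:, 6] *= _PEDIGREE_SCALE
    x = np.rint(x)

    # Standardize with the fixed generator constants for the label model.
    mean_adj = _FEATURE_MEAN.copy()
    mean_adj[6] *= _PEDIGREE_SCALE
    scale_adj = _FEATURE_STD.copy()
    scale_adj[6] *= _PEDIGREE_SCALE
    z = (x - mean_adj) / scale_adj
    logits = z @ _TRUE_BETA

    def mean_prob(b: float) -> float:
        return float(np.mean(1.0 / (1.0 + np.exp(-(logits + b)))))

    lo_b, hi_b = -30.0, 30.0
    for _ in range(200):
        mid = 0.5 * (lo_b + hi_b)
        if mean_prob(mid) < positive_rate:
            lo_b = mid
        else:
            hi_b = mid
    b = 0.5 * (lo_b + hi_b)

    p = 1.0 / (1.0 + np.exp(-(logits + b)))
    y = (rng.random(n) < p).astype(np.int64)

    return ClinicalDataset(
        x,
        y,
        provenance={
            "generator": "generate_pima_like",
            "n": n,
            "seed": seed,
            "positive_rate": positive_rate,
            "noise_scale": noise_scale,
            "true_beta": _TRUE_BETA.tolist(),
            "intercept": b,
        },
    )


def train_test_split(
    ds: ClinicalDataset, test_fraction: float, seed: int
) -> tuple[ClinicalDataset, ClinicalDataset]:
    """Disjoint, exhaustive random split; test size = round(n * test_fraction)."""
    if not 0.0 < test_fraction < 1.0:
        raise ValueError(f"test_fraction must be in (0, 1), got {test_fraction}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(ds.n)
    n_test = int(round(ds.n * test_fraction))
    test_idx = perm[:n_test]
    train_idx = perm[n_test:]
    return ds.subset(train_idx), ds.subset(test_idx)


def partition_devices(ds: ClinicalDataset, K: int, seed: int) -> DevicePartition:
    """Random shuffle then contiguous chunking into K shards (sizes differ <= 1)."""
    if K < 1:
        raise ValueError(f"K must be >= 1, got {K}")
    if K > ds.n:
        raise ValueError(f"K={K} exceeds dataset size n={ds.n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(ds.n)
    chunks = np.array_split(perm, K)
    return DevicePartition(tuple(ds.subset(c) for c in chunks))
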