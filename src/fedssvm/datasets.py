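"""Synthetic EHR-like cohorts for binary hospitalization-risk classification.

Cohorts mix continuous (age/BMI/vitals-like, standard normal) and binary
(diagnosis/medication indicator) feature blocks. Labels come from a sparse
ground-truth linear rule with optional label noise and a tunable class
balance, so support-recovery and accuracy claims can be checked against a
known truth. All randomness flows through explicitly passed integer seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split as _sk_split

__all__ = [
    "CohortSpec",
    "GroundTruth",
    "Dataset",
    "AgentPartition",
    "generate_dataset",
    "partition",
    "train_test_split",
    "read_csv",
    "write_csv",
]


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic cohort generator.

    Attributes
    ----------
    n_samples : number of patients.
    n_continuous : count of continuous (standard-normal) features.
    n_binary : count of 0/1 indicator features; per-feature prevalence is
        drawn uniform(0.05, 0.5).
    sparsity : number of nonzero entries of the ground-truth weight vector.
    signal_scale : magnitude of the nonzero true weights (sign is random).
    label_noise : probability in [0, 0.5) of flipping a generated label.
    positive_fraction_target : desired pre-noise class balance in (0, 1).
    seed : integer RNG seed; the generated dataset is a pure function of
        the spec including this seed.
    """

    n_samples: int
    n_continuous: int
    n_binary: int
    sparsity: int
    signal_scale: float = 1.0
    label_noise: float = 0.0
    positive_fraction_target: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1 or self.n_continuous < 1 or self.n_binary < 1:
            raise ValueError("all counts must be >= 1")
        d = self.n_continuous + self.n_binary
        if not (1 <= self.sparsity <= d):
            raise ValueError(f"sparsity must be in [1, {d}], got {self.sparsity}")
        if not (0.0 <= self.label_noise < 0.5):
            raise ValueError("label_noise must lie in [0, 0.5)")
        if not (0.0 < self.positive_fraction_target < 1.0):
            raise ValueError("positive_fraction_target must lie in (0, 1)")
        if self.signal_scale <= 0:
            raise ValueError("signal_scale must be positive")

    @property
    def n_features(self) -> int:
        return self.n_continuous + self.n_binary


@dataclass(frozen=True)
class GroundTruth:
    """The sparse linear rule that generated the labels."""

    theta: np.ndarray
    theta0: float
    support: np.ndarray  # sorted indices of nonzero weights


@dataclass
class Dataset:
    """Feature matrix plus +/-1 labels, optionally with the generating rule."""

    features: np.ndarray
    labels: np.ndarray
    feature_names: list[str]
    ground_truth: Optional[GroundTruth] = None

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.features.ndim != 2:
            raise ValueError("features must be a 2-D array")
        if self.features.shape[0] != self.labels.shape[0]:
            raise ValueError("features and labels disagree on sample count")
        if not np.isfinite(self.features).all():
            raise ValueError("features contain non-finite values")
        if not np.isin(self.labels, (-1, 1)).all():
            raise ValueError("labels must be +/-1")
        if len(self.feature_names) != self.features.shape[1]:
            raise ValueError("feature_names length must equal feature count")
        self.labels = self.labels.astype(int)

    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    def subset(self, idx: np.ndarray) -> "Dataset":
        return Dataset(
            self.features[idx],
            self.labels[idx],
            list(self.feature_names),
            self.ground_truth,
        )


@dataclass
class AgentPartition:
    """A dataset split across m agents."""

    parts: list[Dataset]
    mode: str
    skew_alpha: Optional[float] = None

    @property
    def m(self) -> int:
        return len(self.parts)

    @property
    def n_total(self) -> int:
        return sum(p.n_samples for p in self.parts)


class BalanceTargetError(RuntimeError):
    """Bias bisection could not hit the requested class balance."""


def _bisect_bias(scores: np.ndarray, target: float, tol: float = 0.02,
                 max_steps: int = 100) -> float:
    """Find theta0 so that mean(scores + theta0 > 0) is within tol of target.

    The positive fraction is a nondecreasing step function of theta0, so
    bisection on an enclosing bracket suffices.
    """
    lo = -float(scores.max()) - 1.0  # fraction 0
    hi = -float(scores.min()) + 1.0  # fraction 1

    def frac(b: float) -> float:
        return float(np.mean(scores + b > 0))

    b = 0.0
    for _ in range(max_steps):
        b = 0.5 * (lo + hi)
        f = frac(b)
        if abs(f - target) <= tol:
            return b
        if f < target:
            lo = b
        else:
            hi = b
    raise BalanceTargetError(
        f"could not reach positive fraction {target:.3f} within +/-{tol}: "
        f"achieved {frac(b):.3f} after {max_steps} bisection steps"
    )


def generate_dataset(spec: CohortSpec) -> Dataset:
    """Generate a seeded synthetic cohort with a sparse linear ground truth.

    Pre-noise labels are sign(phi' theta* + theta0*) with sign(0) -> +1;
    theta* has exactly ``spec.sparsity`` nonzeros at positions drawn without
    replacement across both feature blocks, each of magnitude
    ``spec.signal_scale`` with random sign. theta0* is tuned by bisection so
    the pre-noise positive fraction lands within 0.02 of the target. Labels
    are then flipped independently at rate ``spec.label_noise``.
    """
    rng = np.random.default_rng(spec.seed)
    n, dc, db = spec.n_samples, spec.n_continuous, spec.n_binary
    d = dc + db

    x_cont = rng.standard_normal((n, dc))
    prevalence = rng.uniform(0.05, 0.5, size=db)
    x_bin = (rng.random((n, db)) < prevalence).astype(float)
    x = np.hstack([x_cont, x_bin])

    # keep >= 1 continuous feature in the support: a purely indicator-based
    # score has large atoms and the bias bisection cannot hit arbitrary
    # class fractions; the rest of the support spans both blocks
    first = rng.integers(dc)
    rest = np.setdiff1d(np.arange(d), [first])
    extra = rng.choice(rest, size=spec.sparsity - 1, replace=False)
    support = np.sort(np.concatenate([[first], extra])).astype(int)
    theta = np.zeros(d)
    theta[support] = spec.signal_scale * rng.choice([-1.0, 1.0], size=spec.sparsity)

    scores = x @ theta
    theta0 = _bisect_bias(scores, spec.positive_fraction_target)

    margins = scores + theta0
    labels = np.where(margins > 0, 1, np.where(margins < 0, -1, 1))
    if spec.label_noise > 0:
        flips = rng.random(n) < spec.label_noise
        labels = np.where(flips, -labels, labels)

    names = [f"cont_{k}" for k in range(dc)] + [f"bin_{k}" for k in range(db)]
    return Dataset(x, labels, names, GroundTruth(theta, theta0, support))


def partition(data: Dataset, m: int, mode: str = "iid",
              skew_alpha: float = 1.0, seed: int = 0) -> AgentPartition:
    """Split a dataset across ``m`` agents.

    mode="iid": random shuffle then a near-equal split (sizes differ by <= 1).
    mode="label_skew": per-class Dirichlet(skew_alpha) proportions across
    agents, the standard non-IID federated protocol. Rows are never dropped,
    duplicated or mutated.
    """
    n = data.n_samples
    if m < 1:
        raise ValueError("m must be >= 1")
    if m > n:
        raise ValueError(f"cannot split {n} samples across {m} agents")
    rng = np.random.default_rng(seed)

    if mode == "iid":
        perm = rng.permutation(n)
        chunks = np.array_split(perm, m)
    elif mode == "label_skew":
        if skew_alpha <= 0:
            raise ValueError("skew_alpha must be positive")
        assignment = np.empty(n, dtype=int)
        for cls in (-1, 1):
            idx = np.flatnonzero(data.labels == cls)
            if idx.size == 0:
                continue
            idx = rng.permutation(idx)
            props = rng.dirichlet(np.full(m, skew_alpha))
            cuts = np.floor(np.cumsum(props)[:-1] * idx.size + 0.5).astype(int)
            for agent, part in enumerate(np.split(idx, cuts)):
                assignment[part] = agent
        chunks = [np.flatnonzero(assignment == j) for j in range(m)]
        # every agent must own at least one row: steal from the largest
        for j in range(m):
            if chunks[j].size == 0:
                big = int(np.argmax([c.size for c in chunks]))
                chunks[j] = chunks[big][-1:]
                chunks[big] = chunks[big][:-1]
    else:
        raise ValueError(f"unknown partition mode {mode!r}")

    parts = [data.subset(c) for c in chunks]
    return AgentPartition(parts, mode, skew_alpha if mode == "label_skew" else None)


def train_test_split(data: Dataset, test_fraction: float, seed: int = 0
                     ) -> tuple[Dataset, Dataset]:
    """Disjoint, exhaustive, label-stratified split (seeded)."""
    if not (0.0 < test_fraction < 1.0):
        raise ValueError("test_fraction must lie strictly in (0, 1)")
    n = data.n_samples
    n_test = int(round(n * test_fraction))
    if n_test < 1 or n - n_test < 1:
        raise ValueError("split would leave an empty train or test set")
    idx = np.arange(n)
    stratify = data.labels if len(np.unique(data.labels)) > 1 else None
    tr, te = _sk_split(idx, test_size=n_test, random_state=seed,
                       stratify=stratify, shuffle=True)
    return data.subset(np.sort(tr)), data.subset(np.sort(te))


def write_csv(data: Dataset, path) -> None:
    """Write header + feature columns + final integer `label` column."""
    df = pd.DataFrame(data.features, columns=data.feature_names)
    df["label"] = data.labels
    df.to_csv(path, index=False)


def read_csv(path) -> Dataset:
    df = pd.read_csv(path)
    if "label" not in df.columns:
        raise ValueError("dataset CSV must contain a 'label' column")
    labels = df.pop("label").to_numpy()
    return Dataset(df.to_numpy(dtype=float), labels, list(df.columns))
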