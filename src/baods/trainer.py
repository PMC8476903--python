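"""Training loop, per-epoch target augmentation and patient-wise K-fold CV.

Training uses Adam (lr 0.001, weight decay 0.0002, betas 0.9/0.999) and
one of the three losses; the reference ranking vector of each sample is
re-drawn with a random circular shift in {-2..+2} degrees every epoch.
The accuracy metric is the MSE against the *unaugmented* reference. All
randomness flows from the config seed, so identical (seed, config,
data) give identical traces and parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .net import LossConfig, NetSpec, build_net, loss_and_grad, mse
from .nn import Adam, Network
from .targets import SBeam


@dataclass
class TrainConfig:
    learning_rate: float = 0.001
    weight_decay: float = 0.0002
    beta1: float = 0.9
    beta2: float = 0.999
    epochs: int = 5000
    loss: LossConfig = field(default_factory=LossConfig)
    seed: int = 0
    batch_size: int | None = 1
    folds: int = 5
    augment: bool = True
    # mirror the target's random shift onto the input's angle axis
    # (rounded to whole angle blocks); off by default — the standard
    # augmentation perturbs the reference scores only
    paired_shift: bool = False

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("K must be >= 2")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate <= 0 or self.weight_decay < 0:
            raise ValueError("rates must be positive")


@dataclass
class FoldAssignment:
    """Mapping case_id -> fold index in [0, K)."""

    assignment: dict[str, int]
    k: int

    def fold_ids(self, fold: int) -> list[str]:
        return [c for c, f in self.assignment.items() if f == fold]


def kfold_split(case_ids: list[str], k: int, seed: int = 0) -> FoldAssignment:
    """Patient-wise folds: seeded shuffle then round-robin assignment.

    Folds are disjoint, cover every case exactly once, and their sizes
    differ by at most one. The assignment depends only on the sorted
    set of ids and the seed, not on the input order.
    """
    ids = sorted(set(case_ids))
    if len(ids) != len(case_ids):
        raise ValueError("case ids must be unique")
    if len(ids) < k:
        raise ValueError(f"need at least {k} cases for {k} folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    return FoldAssignment(
        {ids[p]: i % k for i, p in enumerate(perm)}, k
    )


#: One training sample: (case_id, feature rows x bins, reference S_beam).
Sample = tuple[str, np.ndarray, SBeam]


@dataclass
class TrainResult:
    network: Network
    trace: list[dict[str, float]]

    @property
    def final_mse(self) -> float:
        return self.trace[-1]["mse"]


def train(
    network: Network,
    dataset: list[Sample],
    config: TrainConfig,
) -> TrainResult:
    """Fixed-epoch training of the ranking network.

    Each epoch the (possibly shifted) targets are regenerated, the
    samples are visited in a seeded shuffled order in batches of
    ``batch_size`` (None = full batch), and one Adam step is taken per
    batch. The per-epoch record holds the mean training loss and the
    MSE of the same forward outputs against the unaugmented targets.
    """
    if not dataset:
        raise ValueError("dataset is empty")
    rng = np.random.default_rng(config.seed)
    opt = Adam(
        network,
        lr=config.learning_rate,
        betas=(config.beta1, config.beta2),
        weight_decay=config.weight_decay,
    )
    refs = [s[2].scores for s in dataset]
    xs = [np.asarray(s[1], dtype=np.float32) for s in dataset]
    n = len(dataset)
    bs = config.batch_size or n
    trace: list[dict[str, float]] = []
    rows_per_angle = 25 * 9
    for epoch in range(config.epochs):
        exs = xs
        if config.augment:
            shifts = [int(rng.integers(-2, 3)) for _ in range(n)]
            targets = [np.roll(refs[i], shifts[i]) for i in range(n)]
            if config.paired_shift:
                exs = []
                for i in range(n):
                    n_angles = xs[i].shape[0] // rows_per_angle
                    blocks = int(round(shifts[i] * n_angles / 360.0))
                    exs.append(
                        np.roll(xs[i], blocks * rows_per_angle, axis=0)
                    )
        else:
            targets = refs
        order = rng.permutation(n)
        ep_loss = 0.0
        ep_sq = 0.0
        for start in range(0, n, bs):
            idx = order[start : start + bs]
            x = np.stack([exs[i] for i in idx])[:, None, :, :]
            t = np.stack([targets[i] for i in idx])
            network.zero_grad()
            y = network.forward(x, training=True)
            value, grad = loss_and_grad(config.loss, t, y)
            if not np.isfinite(value):
                raise RuntimeError(f"non-finite loss at epoch {epoch}")
            network.backward(grad.astype(y.dtype))
            opt.step()
            ep_loss += value * len(idx)
            r = np.stack([refs[i] for i in idx])
            ep_sq += ((y - r) ** 2).sum()
        trace.append(
            {
                "epoch": float(epoch),
                "loss": ep_loss / n,
                "mse": ep_sq / (n * 360),
            }
        )
    return TrainResult(network, trace)


def evaluate_mse(network: Network, dataset: list[Sample]) -> float:
    """Mean MSE of eval-mode predictions against reference targets."""
    errs = []
    for _, x, ref in dataset:
        y = network.forward(
            np.asarray(x, dtype=np.float32)[None, None], training=False
        )[0]
        errs.append(mse(ref.scores, y))
    return float(np.mean(errs))


@dataclass
class CVSummary:
    fold_mse: list[float]

    @property
    def mean(self) -> float:
        return float(np.mean(self.fold_mse))

    @property
    def sd(self) -> float:
        return float(np.std(self.fold_mse))


def crossvalidate(
    dataset: list[Sample],
    spec: NetSpec,
    config: TrainConfig,
) -> CVSummary:
    """Patient-wise K-fold cross-validation.

    For each fold a fresh network is trained on the other folds and the
    MSE is measured on the held-out cases; the summary carries the
    per-fold MSEs with their mean and standard deviation.
    """
    folds = kfold_split([s[0] for s in dataset], config.folds, config.seed)
    fold_mse = []
    for k in range(config.folds):
        held = set(folds.fold_ids(k))
        train_set = [s for s in dataset if s[0] not in held]
        test_set = [s for s in dataset if s[0] in held]
        network = build_net(spec, seed=config.seed + k)
        train(network, train_set, config)
        fold_mse.append(evaluate_mse(network, test_set))
    return CVSummary(fold_mse)
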