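"""Pre-training and layer-freezing fine-tune protocols.

Three protocols adapt the network to a new subject after pre-training on a
source corpus:

* ``EEGNet_0`` — no transfer: the whole network is randomly re-initialized
  and trained from scratch on the target data.
* ``EEGNet_1`` — load pre-trained weights, freeze Block 1 (the temporal and
  spatial filters, which capture subject-general structure), retrain
  Block 2 and a freshly initialized classifier head.
* ``EEGNet_2`` — as above but freeze Blocks 1 and 2; only the classifier
  head is trained.

In every protocol the classifier head is re-initialized.  Frozen blocks
keep their batch-norm running statistics fixed as well, so their function
is bitwise constant throughout fine-tuning.  Training minimizes categorical
cross-entropy with Adam and re-projects the dense max-norm constraint after
every update.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import nn
from .io import TrialTensor
from .model import EEGNet, EEGNetConfig, apply_max_norm


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings: Adam, categorical cross-entropy."""

    learning_rate: float = 1e-4
    epochs: int = 100
    batch_size: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


#: Reduced-epoch fine-tuning profile (fewer epochs at the same low rate).
FINETUNE_EPOCHS = 30

_PLAN_FROZEN = {
    "EEGNet_0": frozenset(),
    "EEGNet_1": frozenset({"block1"}),
    "EEGNet_2": frozenset({"block1", "block2"}),
}


@dataclass(frozen=True)
class TransferPlan:
    """Which blocks are frozen and whether source weights are loaded.

    The classifier head is always re-initialized for the target task.
    """

    name: str
    frozen_blocks: frozenset[str] = field(default_factory=frozenset)
    reinit_classifier: bool = True

    def __post_init__(self) -> None:
        if self.name not in _PLAN_FROZEN:
            raise ValueError(
                f"unknown plan {self.name!r}; expected one of {sorted(_PLAN_FROZEN)}"
            )
        if frozenset(self.frozen_blocks) != _PLAN_FROZEN[self.name]:
            raise ValueError(
                f"plan {self.name} must freeze {sorted(_PLAN_FROZEN[self.name])}"
            )

    @property
    def uses_source_weights(self) -> bool:
        return self.name != "EEGNet_0"

    @classmethod
    def from_name(cls, name: str) -> "TransferPlan":
        key = name.strip()
        canonical = {p.lower(): p for p in _PLAN_FROZEN}
        if key.lower() not in canonical:
            raise ValueError(
                f"unknown plan {name!r}; expected one of {sorted(_PLAN_FROZEN)}"
            )
        key = canonical[key.lower()]
        return cls(name=key, frozen_blocks=_PLAN_FROZEN[key])


@dataclass
class History:
    """Per-epoch training loss and accuracy."""

    loss: list[float] = field(default_factory=list)
    accuracy: list[float] = field(default_factory=list)


def _check_trainable_data(trials: TrialTensor) -> None:
    if np.unique(trials.labels).size < 2:
        raise ValueError("training data must contain at least two classes")


def train(model: EEGNet, trials: TrialTensor, tc: TrainConfig,
          log=None) -> History:
    """Run the optimization loop on the trainable subset of the model.

    Shuffles each epoch, applies Adam, and re-projects the dense max-norm
    bound after every step.  Returns the per-epoch history (loss and
    accuracy are averaged over the epoch's minibatches, so they reflect the
    training-mode forward passes actually taken).
    """
    _check_trainable_data(trials)
    params = model.parameters()
    if not any(p.trainable for p in params):
        raise RuntimeError("model has no trainable parameters")
    opt = nn.Adam(params, lr=tc.learning_rate)
    rng = np.random.default_rng(tc.seed)
    x = trials.data
    y = trials.labels
    m = x.shape[0]
    history = History()
    for epoch in range(tc.epochs):
        order = rng.permutation(m)
        losses, hits = [], 0
        for start in range(0, m, tc.batch_size):
            idx = order[start:start + tc.batch_size]
            logits = model.forward(x[idx], training=True, rng=rng)
            probs = nn.softmax(logits.astype(np.float64))
            loss, grad = nn.cross_entropy(probs, y[idx])
            for p in params:
                p.grad = None
            model.backward(grad)
            opt.step()
            apply_max_norm(model)
            losses.append(loss)
            hits += int((probs.argmax(axis=1) == y[idx]).sum())
        history.loss.append(float(np.mean(losses)))
        history.accuracy.append(hits / m)
        if log is not None:
            log(epoch=epoch, loss=history.loss[-1], accuracy=history.accuracy[-1])
    return history


def pretrain(trials: TrialTensor, cfg: EEGNetConfig, tc: TrainConfig,
             log=None) -> tuple[dict[str, np.ndarray], History]:
    """Train from random initialization and return the weight container.

    The resulting dictionary holds every parameter plus batch-norm running
    statistics under block-prefixed names, ready for :func:`apply_plan`.
    """
    _check_trainable_data(trials)
    model = EEGNet(cfg, seed=tc.seed)
    history = train(model, trials, tc, log=log)
    return model.get_weights(), history


def apply_plan(weights: dict[str, np.ndarray] | None, plan: TransferPlan,
               cfg: EEGNetConfig, seed: int = 0) -> EEGNet:
    """Build a model for fine-tuning under a transfer plan.

    Loads source weights into block1/block2 (unless the plan trains from
    scratch), flags frozen parameters non-trainable, and leaves the
    classifier head freshly initialized for the target task.
    """
    if plan.uses_source_weights and weights is None:
        raise ValueError(f"plan {plan.name} requires pre-trained source weights")
    model = EEGNet(cfg, seed=seed)
    if plan.uses_source_weights:
        model.set_weights(weights, blocks={"block1", "block2"})
    for block in plan.frozen_blocks:
        model.set_block_trainable(block, False)
    return model


def finetune(model: EEGNet, trials: TrialTensor, tc: TrainConfig,
             log=None) -> History:
    """Fine-tune the trainable parameters only; frozen ones are untouched."""
    return train(model, trials, tc, log=log)


def evaluate_accuracy(model: EEGNet, trials: TrialTensor) -> float:
    """Classification accuracy of the model on a trial set."""
    return float((model.predict(trials.data) == trials.labels).mean())


__all__ = [
    "TrainConfig", "TransferPlan", "History", "FINETUNE_EPOCHS",
    "train", "pretrain", "apply_plan", "finetune", "evaluate_accuracy",
]
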