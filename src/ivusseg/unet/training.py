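"""Training loop, patient-level splitting and label-preserving augmentation.

The split is always by patient for the test set (no frame of a test patient
ever reaches training), while the validation fraction is drawn frame-wise
from the training patients — the design that prevents the optimistic bias
of frame-level test splits on pullback data, where neighboring frames of
one patient are nearly identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ivusseg.phantom import PullbackSequence
from ivusseg.unet.layers import Adam, softmax_cross_entropy
from ivusseg.unet.model import UNet


@dataclass
class TrainConfig:
    """Optimization recipe: batch 2, categorical cross-entropy, Adam at 1e-3.

    Augmentation applies horizontal/vertical flips and 90-degree-multiple
    rotations jointly to frame and mask; 20% of the training frames are
    held out for validation.  ``class_weights`` (optional, length 5)
    reweights the loss per true class, a lever for the stent-class pixel
    imbalance; default is unweighted.
    """

    batch_size: int = 2
    learning_rate: float = 0.001
    validation_fraction: float = 0.2
    max_epochs: int = 8
    early_stop_patience: int = 10
    augment: bool = True
    class_weights: Sequence[float] | None = None
    rng_seed: int = 0

    def validate(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if not 0.0 < self.validation_fraction < 1.0:
            raise ValueError("validation_fraction must be in (0, 1)")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")


@dataclass
class SplitPlan:
    """Patient-disjoint train/test split plus frame-level validation picks."""

    train_patients: list[str]
    test_patients: list[str]
    validation_frames: list[tuple[str, int]]  # (patient_id, frame_index)

    def __post_init__(self) -> None:
        if set(self.train_patients) & set(self.test_patients):
            raise ValueError("train and test patient sets must be disjoint")
        vp = {p for p, _ in self.validation_frames}
        if not vp <= set(self.train_patients):
            raise ValueError("validation frames must come from training patients")


def make_split(
    sequences: Sequence[PullbackSequence],
    test_n_patients: int,
    rng: np.random.Generator,
    validation_fraction: float = 0.2,
) -> SplitPlan:
    """Patient-level split: whole patients go to test, never single frames.

    ``round(validation_fraction * n_training_frames)`` frames from the
    training patients are reserved for validation.
    """
    ids = [s.patient_id for s in sequences]
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate patient ids")
    if test_n_patients < 1 or test_n_patients >= len(ids):
        raise ValueError(
            f"need 1 <= test_n_patients < n_patients, got {test_n_patients} of {len(ids)}"
        )
    order = rng.permutation(len(ids))
    test = sorted(ids[i] for i in order[:test_n_patients])
    train = sorted(ids[i] for i in order[test_n_patients:])
    by_id = {s.patient_id: s for s in sequences}
    pool = [(p, k) for p in train for k in range(len(by_id[p]))]
    n_val = int(round(validation_fraction * len(pool)))
    pick = rng.choice(len(pool), size=n_val, replace=False)
    val = sorted(pool[i] for i in pick)
    return SplitPlan(train_patients=train, test_patients=test, validation_frames=val)


def augment(
    frame: np.ndarray,
    mask: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Random flip/rotation applied identically to frame and label mask.

    Horizontal flip, vertical flip (each with probability 1/2) and a
    rotation by a uniformly drawn multiple of 90 degrees.  All three are
    pixel permutations, so per-class pixel counts are exactly preserved and
    labels stay crisp (no interpolation).
    """
    frame = np.asarray(frame)
    mask = np.asarray(mask)
    if frame.shape != mask.shape:
        raise ValueError(f"frame {frame.shape} and mask {mask.shape} must have equal shape")
    if rng.random() < 0.5:
        frame, mask = frame[:, ::-1], mask[:, ::-1]
    if rng.random() < 0.5:
        frame, mask = frame[::-1, :], mask[::-1, :]
    k = int(rng.integers(0, 4))
    if k:
        frame, mask = np.rot90(frame, k), np.rot90(mask, k)
    return np.ascontiguousarray(frame), np.ascontiguousarray(mask)


def frames_from_sequences(
    sequences: Sequence[PullbackSequence],
    patients: Sequence[str] | None = None,
    exclude_frames: Sequence[tuple[str, int]] | None = None,
    only_frames: Sequence[tuple[str, int]] | None = None,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Flatten sequences into (image, label) training pairs.

    ``patients`` restricts to a patient subset; ``exclude_frames`` /
    ``only_frames`` filter by (patient_id, frame_index), matching the
    bookkeeping of :class:`SplitPlan`.
    """
    keep = None if patients is None else set(patients)
    excl = set(exclude_frames) if exclude_frames else set()
    only = set(only_frames) if only_frames is not None else None
    out = []
    for seq in sequences:
        if keep is not None and seq.patient_id not in keep:
            continue
        for k, (frame, mask, _gt) in enumerate(seq.frames):
            key = (seq.patient_id, k)
            if key in excl:
                continue
            if only is not None and key not in only:
                continue
            out.append((frame.image, mask.labels))
    return out


@dataclass
class TrainingHistory:
    """Per-epoch loss curves plus the index of the checkpointed epoch."""

    epochs: list[int] = field(default_factory=list)
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    best_epoch: int = -1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"epoch": self.epochs, "train_loss": self.train_loss, "val_loss": self.val_loss}
        )

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(Path(path), index=False)


def _batch(pairs: list[tuple[np.ndarray, np.ndarray]]) -> tuple[np.ndarray, np.ndarray]:
    x = np.stack([p[0] for p in pairs])[:, None].astype(np.float32)
    y = np.stack([p[1] for p in pairs]).astype(np.int64)
    return x, y


def evaluate_loss(
    model: UNet,
    pairs: Sequence[tuple[np.ndarray, np.ndarray]],
    batch_size: int = 8,
    class_weights: Sequence[float] | None = None,
) -> float:
    """Mean cross-entropy over a frame set (no dropout, no augmentation)."""
    if len(pairs) == 0:
        raise ValueError("cannot evaluate on an empty frame set")
    losses, weights = [], []
    for i in range(0, len(pairs), batch_size):
        x, y = _batch(list(pairs[i : i + batch_size]))
        logits = model.forward(x, train=False)
        loss, _, _ = softmax_cross_entropy(logits, y, class_weights)
        losses.append(loss)
        weights.append(len(y))
    return float(np.average(losses, weights=weights))


def train(
    model: UNet,
    train_pairs: Sequence[tuple[np.ndarray, np.ndarray]],
    config: TrainConfig,
    val_pairs: Sequence[tuple[np.ndarray, np.ndarray]] | None = None,
    max_steps_per_epoch: int | None = None,
) -> TrainingHistory:
    """Train with Adam on categorical cross-entropy; checkpoint best val loss.

    Deterministic under a fixed ``config.rng_seed``.  When ``val_pairs`` is
    empty/None the training loss doubles as the checkpoint criterion.  The
    weights achieving the minimum recorded validation loss are restored
    into ``model`` before returning.
    """
    config.validate()
    train_pairs = list(train_pairs)
    if len(train_pairs) == 0:
        raise ValueError("training set is empty")
    rng = np.random.default_rng(config.rng_seed)
    opt = Adam(model.conv_layers, lr=config.learning_rate)
    cw = None if config.class_weights is None else np.asarray(config.class_weights, float)

    history = TrainingHistory()
    best_val = np.inf
    best_weights = model.get_weights()
    since_best = 0
    for epoch in range(config.max_epochs):
        order = rng.permutation(len(train_pairs))
        if max_steps_per_epoch is not None:
            order = order[: max_steps_per_epoch * config.batch_size]
        epoch_losses = []
        for i in range(0, len(order), config.batch_size):
            chunk = [train_pairs[j] for j in order[i : i + config.batch_size]]
            if config.augment:
                chunk = [augment(f, m, rng) for f, m in chunk]
            x, y = _batch(chunk)
            logits = model.forward(x, train=True, rng=rng)
            loss, dlogits, _ = softmax_cross_entropy(logits, y, cw)
            model.backward(dlogits)
            opt.step()
            epoch_losses.append(loss)
        tr_loss = float(np.mean(epoch_losses))
        if val_pairs:
            vl = evaluate_loss(model, val_pairs, class_weights=cw)
        else:
            vl = tr_loss
        history.epochs.append(epoch)
        history.train_loss.append(tr_loss)
        history.val_loss.append(vl)
        if vl < best_val:
            best_val = vl
            best_weights = model.get_weights()
            history.best_epoch = epoch
            since_best = 0
        else:
            since_best += 1
            if since_best >= config.early_stop_patience:
                break
    model.set_weights(best_weights)
    return history
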