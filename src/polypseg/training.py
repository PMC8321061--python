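"""Training: Adam with a step learning-rate schedule, video-grouped k-fold
cross-validation, and the per-pixel cross-entropy objective.

The learning-rate law is ``lr(e) = initial_lr * decay_factor ** (e //
decay_every)`` — an initial rate of 1e-4 decayed by 0.1 after every 10
epochs over a 30-epoch run by default.  Fold assignment is grouped by video
sequence: frames from one sequence never straddle the training and
validation sides of a fold, since consecutive colonoscopy frames are highly
correlated and splitting them inflates validation scores.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from . import nn
from .phantoms import SegmentationSample
from .augment import AugmentationSpec, augment_subset


class TrainingDiverged(RuntimeError):
    """Raised when the loss becomes non-finite; names the epoch and batch."""

    def __init__(self, epoch: int, batch: int):
        super().__init__(f"non-finite loss at epoch {epoch}, batch {batch}")
        self.epoch, self.batch = epoch, batch


@dataclass
class TrainingSpec:
    epochs: int = 30
    initial_learning_rate: float = 1e-4
    decay_factor: float = 0.1
    decay_every: int = 10
    batch_size: int = 8
    optimizer: str = "adam"
    loss: str = "cross_entropy"
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 1 or self.decay_every < 1:
            raise ValueError("epochs, batch_size and decay_every must be >= 1")
        if self.initial_learning_rate <= 0 or self.decay_factor <= 0:
            raise ValueError("learning rate and decay factor must be positive")
        if self.optimizer != "adam":
            raise ValueError("only the Adam optimizer family is supported")
        if self.loss != "cross_entropy":
            raise ValueError("only per-pixel cross-entropy loss is supported")

    def learning_rate(self, epoch: int) -> float:
        return self.initial_learning_rate * self.decay_factor ** (epoch // self.decay_every)

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# Grouped fold plan


@dataclass
class FoldPlan:
    """Mapping sequence_id -> fold index in 1..k, grouped by sequence."""

    assignment: dict[str, int]
    k: int
    frame_counts: dict[int, int]

    def fold_of(self, sample: SegmentationSample) -> int:
        return self.assignment[sample.sequence_id]

    def split(self, samples, fold: int):
        """(train side, validation side) for one fold."""
        train = [s for s in samples if self.assignment[s.sequence_id] != fold]
        val = [s for s in samples if self.assignment[s.sequence_id] == fold]
        return train, val


def make_fold_plan(samples, k: int, seed: int = 0) -> FoldPlan:
    """Assign whole sequences to k folds, balancing frame counts greedily."""
    if k < 1:
        raise ValueError("k must be >= 1")
    counts: dict[str, int] = {}
    for s in samples:
        counts[s.sequence_id] = counts.get(s.sequence_id, 0) + 1
    if len(counts) < k:
        raise ValueError(f"need at least {k} distinct sequences, got {len(counts)}")
    rng = np.random.default_rng(seed)
    seqs = sorted(counts)
    rng.shuffle(seqs)
    # largest-first greedy into the currently lightest fold
    seqs.sort(key=lambda sid: -counts[sid])
    fold_load = {f: 0 for f in range(1, k + 1)}
    assignment: dict[str, int] = {}
    for sid in seqs:
        fold = min(fold_load, key=lambda f: (fold_load[f], f))
        assignment[sid] = fold
        fold_load[fold] += counts[sid]
    return FoldPlan(assignment=assignment, k=k, frame_counts=fold_load)


# ---------------------------------------------------------------------------
# Input preparation


def compute_input_stats(samples) -> tuple[np.ndarray, np.ndarray]:
    """Per-channel mean/std of the training corpus on the [0, 1] scale."""
    acc = np.zeros(3)
    acc2 = np.zeros(3)
    n = 0
    for s in samples:
        x = s.image.astype(np.float64) / 255.0
        acc += x.reshape(-1, 3).sum(axis=0)
        acc2 += (x.reshape(-1, 3) ** 2).sum(axis=0)
        n += x.shape[0] * x.shape[1]
    mean = acc / n
    std = np.sqrt(np.maximum(acc2 / n - mean ** 2, 1e-8))
    return mean.astype(np.float32), std.astype(np.float32)


def to_network_input(image: np.ndarray, stats) -> np.ndarray:
    """HWC uint8 -> normalized 1CHW float32."""
    x = image.astype(np.float32) / 255.0
    if stats is not None:
        mean, std = stats
        x = (x - mean[None, None, :]) / std[None, None, :]
    return np.ascontiguousarray(x.transpose(2, 0, 1)[None])


# ---------------------------------------------------------------------------
# Training loop


def train(network, train_samples, spec: TrainingSpec,
          log_callback=None) -> dict:
    """Train in place; returns {"epoch_loss": [...], "lr": [...], "iter_loss": [...]}.

    The network's input normalization statistics are fitted on the training
    corpus and stored on the network so that inference uses the same scaling.
    """
    samples = list(train_samples)
    if not samples:
        raise ValueError("training set is empty")
    hw = network.spec.input_size
    for s in samples:
        if s.mask.shape != hw:
            raise ValueError(
                f"sample {s.frame_id} has shape {s.mask.shape}, expected {hw}")
    stats = compute_input_stats(samples)
    network.input_stats = stats
    rng = np.random.default_rng(spec.seed)
    for path in network.paths:
        path.dropout.rng = np.random.default_rng(rng.integers(0, 2 ** 31))
    opt = nn.Adam(network.params(), lr=spec.initial_learning_rate)

    xs = np.concatenate([to_network_input(s.image, stats) for s in samples])
    ys = np.stack([s.mask.astype(np.int64) for s in samples])

    trace = {"epoch_loss": [], "lr": [], "iter_loss": []}
    n = len(samples)
    for epoch in range(spec.epochs):
        opt.lr = spec.learning_rate(epoch)
        order = rng.permutation(n)
        losses = []
        for b, start in enumerate(range(0, n, spec.batch_size)):
            idx = order[start:start + spec.batch_size]
            scores = network.forward(xs[idx], training=True)
            loss, grad = nn.softmax_cross_entropy(scores, ys[idx])
            if not np.isfinite(loss):
                raise TrainingDiverged(epoch, b)
            opt.zero_grad()
            network.backward(grad)
            opt.step()
            losses.append(loss)
            trace["iter_loss"].append(loss)
        trace["epoch_loss"].append(float(np.mean(losses)))
        trace["lr"].append(opt.lr)
        if log_callback is not None:
            log_callback(epoch, opt.lr, trace["epoch_loss"][-1])
    return trace


# ---------------------------------------------------------------------------
# Cross-validation


def cross_validate(samples, arch_spec, train_spec: TrainingSpec,
                   aug_spec: AugmentationSpec, k: int, seed: int | None = None,
                   postprocess_spec=None, log_callback=None):
    """Video-grouped k-fold cross-validation on a corpus.

    For each fold the training side is augmented (the validation side never
    is), a fresh network is trained, and per-frame metrics are computed on
    the untouched validation frames with size/circularity strata referenced
    to the fold's training distribution.  Returns {fold: [MetricsRecord]}.
    """
    from .architecture import build_network
    from .inference import predict, postprocess, PostprocessSpec
    from .evaluation import evaluate_frame, stratify

    import dataclasses

    samples = list(samples)
    seed = train_spec.seed if seed is None else seed
    if tuple(aug_spec.target_size) != tuple(arch_spec.input_size):
        aug_spec = dataclasses.replace(aug_spec, target_size=tuple(arch_spec.input_size))
    plan = make_fold_plan(samples, k, seed=seed)
    pp = postprocess_spec or PostprocessSpec()
    results: dict[int, list] = {}
    for fold in range(1, k + 1):
        train_side, val_side = plan.split(samples, fold)
        if not train_side or not val_side:
            raise ValueError(f"fold {fold} has an empty side")
        aug = augment_subset(train_side, aug_spec)
        net = build_network(arch_spec, seed=seed + fold)
        cb = (lambda e, lr, l, _f=fold: log_callback(_f, e, lr, l)) if log_callback else None
        train(net, aug, train_spec, log_callback=cb)
        records = []
        for s in val_side:
            prob = predict(net, s.image)
            pred = postprocess(prob, pp)
            records.append(evaluate_frame(s.frame_id, pred, s.mask))
        train_areas = [float(s.mask.sum()) for s in train_side]
        from .evaluation import mask_circularity
        train_circ = [mask_circularity(s.mask) for s in train_side if s.mask.any()]
        stratify(records, train_areas, train_circ)
        results[fold] = records
    return results
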