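"""Training strategies: supervised (SL), pretrain-then-finetune (SSL), and the
noisy-student variant (SSL-NS).

SSL pretrains on cross-species pseudo-labeled positives (plus an equal number
of labeled-genome negatives) and then fine-tunes every layer on the original
labeled data; the pretraining provides a better parameter initialization.

SSL-NS iterates a teacher-student loop: the current teacher scores each
pseudo-positive with a confidence weight (its predicted probability, in
[0, 1]); Gaussian noise (mean 0, SD 0.1 by default) is added to the weights
once per iteration and the result clipped back to [0, 1]; a freshly
initialized student is pretrained on the weighted pseudo-positives plus
weight-1 negatives, then fine-tuned on the labeled data, and becomes the next
teacher. Five iterations by default; the final student is returned.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .labeling import LabeledDataset, SequenceExample
from .models import ClassifierModel, ModelSpec, build_model, encode_batch
from .nn import Adam, weighted_bce_with_logits


@dataclass(frozen=True)
class TrainConfig:
    """Optimization and strategy hyperparameters.

    ``ns_iterations`` (k) and ``ns_noise_sd``/``ns_noise_mean`` parameterize
    the noisy-student loop. None of the optimizer settings are prescribed by
    the method itself; the defaults are conventional for small CNNs.
    """

    learning_rate: float = 1e-3
    batch_size: int = 64
    max_epochs: int = 50
    early_stop_patience: int = 5
    validation_fraction: float = 0.1
    seed: int = 0
    ns_iterations: int = 5
    ns_noise_sd: float = 0.1
    ns_noise_mean: float = 0.0

    def __post_init__(self) -> None:
        if self.ns_iterations < 1:
            raise ValueError("ns_iterations must be >= 1")
        if self.ns_noise_sd < 0:
            raise ValueError("ns_noise_sd must be >= 0")
        if not 0 < self.validation_fraction < 1:
            raise ValueError("validation_fraction must be in (0, 1)")
        if self.batch_size < 1 or self.max_epochs < 1:
            raise ValueError("batch_size and max_epochs must be >= 1")


@dataclass
class TrainedModel:
    model: ClassifierModel
    strategy: str  # "SL" | "SSL" | "SSL-NS"
    history: list[dict]
    config: TrainConfig


def _dataset_arrays(dataset: LabeledDataset) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    x = encode_batch([e.sequence for e in dataset.examples])
    y = np.array([e.label for e in dataset.examples], dtype=np.float64)
    w = np.array([e.weight for e in dataset.examples], dtype=np.float64)
    return x, y, w


def _fit(model: ClassifierModel, dataset: LabeledDataset, config: TrainConfig,
         phase: str, seed: int) -> list[dict]:
    """Minimize weighted BCE with Adam; early-stop on validation loss and
    restore the best-validation parameters. Returns the per-epoch history."""
    if len(dataset) == 0:
        raise ValueError("cannot train on an empty dataset")
    labels = {e.label for e in dataset.examples}
    if len(labels) < 2:
        raise ValueError("dataset contains a single class; cannot train/validate")
    x, y, w = _dataset_arrays(dataset)
    rng = np.random.default_rng(seed)
    n = len(x)
    perm = rng.permutation(n)
    n_val = max(1, int(round(config.validation_fraction * n)))
    if n_val >= n:
        raise ValueError("validation split leaves no training data")
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    if len({int(v) for v in y[tr_idx]}) < 2:
        # degenerate split on tiny data: move one example of the missing class
        missing = ({0, 1} - {int(v) for v in y[tr_idx]}).pop()
        swap = next(i for i, j in enumerate(val_idx) if int(y[j]) == missing)
        tr_idx = np.append(tr_idx, val_idx[swap])
        val_idx = np.delete(val_idx, swap)
        if len(val_idx) == 0:
            raise ValueError("dataset too small to hold out a validation split")
    xt, yt, wt = x[tr_idx], y[tr_idx], w[tr_idx]
    xv, yv, wv = x[val_idx], y[val_idx], w[val_idx]

    opt = Adam(model.net.params, lr=config.learning_rate)
    history: list[dict] = []
    best_loss = np.inf
    best_state = model.net.get_state()
    patience_left = config.early_stop_patience
    for epoch in range(config.max_epochs):
        order = rng.permutation(len(xt))
        tot, seen = 0.0, 0
        for i in range(0, len(xt), config.batch_size):
            idx = order[i : i + config.batch_size]
            logits = model.net.forward_logits(xt[idx], train=True, rng=rng)
            loss, dz = weighted_bce_with_logits(logits, yt[idx], wt[idx])
            model.net.backward(dz)
            opt.step(model.net.grads)
            tot += loss * len(idx)
            seen += len(idx)
        val_logits = model.net.forward_logits(xv, train=False)
        val_loss, _ = weighted_bce_with_logits(val_logits, yv, wv)
        history.append({"phase": phase, "epoch": epoch,
                        "train_loss": tot / seen, "val_loss": val_loss})
        if val_loss < best_loss - 1e-7:
            best_loss = val_loss
            best_state = model.net.get_state()
            patience_left = config.early_stop_patience
        else:
            patience_left -= 1
            if patience_left <= 0:
                break
    model.net.set_state(best_state)
    return history


def train_supervised(spec: ModelSpec, labeled: LabeledDataset,
                     config: TrainConfig) -> TrainedModel:
    """Standard supervised learning on the labeled (balanced) dataset."""
    model = build_model(spec)
    history = _fit(model, labeled, config, phase="sl", seed=config.seed)
    return TrainedModel(model, "SL", history, config)


def train_ssl(spec: ModelSpec, pretrain_set: LabeledDataset,
              finetune_set: LabeledDataset, config: TrainConfig) -> TrainedModel:
    """Pretrain on pseudo-labeled data, then fine-tune all layers on the
    labeled data. An empty pretraining set degenerates to plain SL."""
    if len(pretrain_set) == 0:
        warnings.warn("empty pretraining set: SSL degenerates to supervised learning")
        trained = train_supervised(spec, finetune_set, config)
        return TrainedModel(trained.model, "SSL", trained.history, config)
    if pretrain_set.input_length != finetune_set.input_length:
        raise ValueError(
            f"dialect mismatch: pretrain length {pretrain_set.input_length} vs "
            f"finetune length {finetune_set.input_length}"
        )
    model = build_model(spec)
    hist1 = _fit(model, pretrain_set, config, phase="pretrain", seed=config.seed)
    hist2 = _fit(model, finetune_set, config, phase="finetune",
                 seed=config.seed + 1)
    return TrainedModel(model, "SSL", hist1 + hist2, config)


def compute_confidence_weights(teacher: TrainedModel,
                               pseudo_positives: Sequence[SequenceExample]) -> np.ndarray:
    """Teacher-predicted probability of each pseudo-positive, in [0, 1]."""
    if not pseudo_positives:
        return np.empty(0)
    return teacher.model.predict([e.sequence for e in pseudo_positives])


def add_weight_noise(weights: np.ndarray, mean: float = 0.0, sd: float = 0.1,
                     seed: int = 0) -> np.ndarray:
    """Add i.i.d. Gaussian noise to confidence weights and clip to [0, 1]."""
    weights = np.asarray(weights, dtype=np.float64)
    if sd == 0 and mean == 0:
        return weights.copy()
    rng = np.random.default_rng(seed)
    return np.clip(weights + rng.normal(mean, sd, size=weights.shape), 0.0, 1.0)


def _seed_for(base: int, *tags: int) -> int:
    """Deterministic derived seed, kept below 2**31."""
    return int(np.random.SeedSequence([base, *tags]).generate_state(1)[0] % (2**31))


def train_ssl_ns(spec: ModelSpec, labeled: LabeledDataset,
                 pseudo_positives: Sequence[SequenceExample],
                 negative_pool: Sequence[SequenceExample],
                 config: TrainConfig) -> TrainedModel:
    """Iterated noisy teacher-student training (SSL-NS).

    teacher_0 is trained on the labeled data; each iteration scores the
    pseudo-positives with the previous teacher, perturbs the confidence
    weights with Gaussian noise, pretrains a freshly initialized student on
    the weighted pseudo-positives plus weight-1 negatives, fine-tunes it on
    the labeled data, and promotes it to teacher. Returns the final student.
    """
    if not pseudo_positives:
        raise ValueError(
            "no pseudo-positive examples: use supervised training (SL) instead"
        )
    if len(negative_pool) < len(pseudo_positives):
        raise ValueError("negative pool smaller than the pseudo-positive set")
    teacher = train_supervised(spec, labeled, config)
    history = list(teacher.history)
    student = teacher
    neg_rng = np.random.default_rng(_seed_for(config.seed, 999))
    for t in range(1, config.ns_iterations + 1):
        conf = compute_confidence_weights(teacher, pseudo_positives)
        noisy = add_weight_noise(conf, mean=config.ns_noise_mean,
                                 sd=config.ns_noise_sd,
                                 seed=_seed_for(config.seed, t))
        weighted_pos = [
            replace_weight(e, float(wi)) for e, wi in zip(pseudo_positives, noisy)
        ]
        neg_idx = neg_rng.choice(len(negative_pool), size=len(pseudo_positives),
                                 replace=False)
        negatives = [negative_pool[int(i)] for i in neg_idx]
        pretrain = LabeledDataset(examples=weighted_pos + negatives,
                                  dialect=labeled.dialect, balanced=True)
        student_spec = replace_seed(spec, _seed_for(spec.seed, t, 7))
        student_cfg = replace(config, seed=_seed_for(config.seed, t, 11))
        student = train_ssl(student_spec, pretrain, labeled, student_cfg)
        for h in student.history:
            history.append({**h, "ns_iteration": t})
        teacher = student
    return TrainedModel(student.model, "SSL-NS", history, config)


def replace_weight(example: SequenceExample, weight: float) -> SequenceExample:
    return SequenceExample(
        sequence=example.sequence, label=example.label, weight=weight,
        species=example.species, origin=example.origin,
        source_chrom=example.source_chrom, source_id=example.source_id,
    )


def replace_seed(spec: ModelSpec, seed: int) -> ModelSpec:
    return ModelSpec(family=spec.family, n_filters=spec.n_filters,
                     input_length=spec.input_length,
                     dilation_rates=spec.dilation_rates, seed=seed)
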