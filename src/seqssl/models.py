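"""One-hot sequence encoding and the four CNN classifier architectures.

Four families are provided:

* ``shallow_cnn`` — conv(64 or 256 filters, kernel 24, ReLU) -> global max pool
  -> dropout 0.2 -> dense 10 -> dropout 0.2 -> sigmoid unit. With 64 filters
  this totals 6,869 trainable scalars (~7K); with 256 filters, 27,413 (~27K).
* ``deep_cnn`` — the shallow stack with five successive dilated convolutions
  (kernel 3, ReLU, additive residual skip, 'same' padding) inserted after the
  first convolution. Dilation rates default to (2, 4, 8, 16, 32).
* ``deepbind`` — conv(16 filters, kernel 24, ReLU) -> global max pool ->
  dense 32 -> dropout 0.5 -> sigmoid unit.
* ``deepsea`` — conv(320, kernel 8) -> max pool 4/4 -> dropout 0.2 ->
  conv(480, kernel 8) -> max pool 4/4 -> dropout 0.2 -> conv(960, kernel 8) ->
  dropout 0.5 -> flatten -> dense 925 -> sigmoid unit; fixed 1 kb input.

Hidden dense layers use ReLU. The globally max-pooled families accept any
input length >= the kernel span without rebuilding, so their parameter counts
are input-length independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import nn
from .nn import (Conv1D, Dense, Dropout, Flatten, GlobalMaxPool, MaxPool1D,
                 ReLU, Residual, Sequential)

MODEL_FAMILIES = ("shallow_cnn", "deep_cnn", "deepbind", "deepsea")

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": -1}
_ENCODE_LUT = np.zeros((256, 4), dtype=nn.DTYPE)
for _b, _i in _BASE_INDEX.items():
    if _i >= 0:
        _ENCODE_LUT[ord(_b), _i] = 1.0
_VALID_BYTES = frozenset(ord(b) for b in "ACGTN")


def one_hot_encode(sequence: str) -> np.ndarray:
    """Encode a sequence over {A,C,G,T,N} as an L x 4 matrix.

    Channel order is A, C, G, T; N encodes as an all-zero row.
    """
    raw = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    bad = set(raw.tolist()) - _VALID_BYTES
    if bad:
        raise ValueError(f"invalid symbols in sequence: {sorted(chr(b) for b in bad)}")
    return _ENCODE_LUT[raw]


def encode_batch(sequences: Sequence[str]) -> np.ndarray:
    """Stack one-hot encodings into a (batch, L, 4) tensor."""
    return np.stack([one_hot_encode(s) for s in sequences])


@dataclass(frozen=True)
class ModelSpec:
    """Declarative architecture description.

    ``n_filters`` applies to the shallow/deep families (64 or 256);
    ``dilation_rates`` only to deep_cnn. ``input_length`` must match the
    labeling dialect (200 for bin-only, 1000 for 1 kb context; deepsea is
    fixed at 1000).
    """

    family: str
    n_filters: int = 64
    input_length: int = 200
    dilation_rates: tuple[int, ...] = (2, 4, 8, 16, 32)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in MODEL_FAMILIES:
            raise ValueError(f"unknown model family {self.family!r}")
        if self.family == "deep_cnn" and len(self.dilation_rates) != 5:
            raise ValueError("deep_cnn takes exactly 5 dilation rates")
        if self.input_length <= 0:
            raise ValueError("input_length must be positive")


class ClassifierModel:
    """A built classifier: spec + trainable state + probability predictions."""

    def __init__(self, spec: ModelSpec, net: Sequential):
        self.spec = spec
        self.net = net

    def predict(self, sequences: Sequence[str] | np.ndarray,
                batch_size: int = 256) -> np.ndarray:
        """Probabilities in [0, 1], deterministic given fixed parameters."""
        if isinstance(sequences, np.ndarray):
            x = sequences
        else:
            x = encode_batch(sequences)
        return self.net.predict_proba(x, batch_size=batch_size)

    def clone_architecture(self, seed: Optional[int] = None) -> "ClassifierModel":
        """Fresh randomly initialized model with the same architecture."""
        spec = self.spec if seed is None else ModelSpec(
            family=self.spec.family, n_filters=self.spec.n_filters,
            input_length=self.spec.input_length,
            dilation_rates=self.spec.dilation_rates, seed=seed,
        )
        return build_model(spec)


def build_model(spec: ModelSpec) -> ClassifierModel:
    """Instantiate the architecture named by ``spec`` with seeded weights."""
    rng = np.random.default_rng(spec.seed)
    f = spec.n_filters
    if spec.family == "shallow_cnn":
        layers = [
            Conv1D(4, f, 24, rng), ReLU(), GlobalMaxPool(), Dropout(0.2),
            Dense(f, 10, rng), ReLU(), Dropout(0.2), Dense(10, 1, rng),
        ]
    elif spec.family == "deep_cnn":
        layers = [Conv1D(4, f, 24, rng), ReLU()]
        for rate in spec.dilation_rates:
            layers.append(Residual([
                Conv1D(f, f, 3, rng, dilation=rate, padding="same"), ReLU(),
            ]))
        layers += [GlobalMaxPool(), Dropout(0.2), Dense(f, 10, rng), ReLU(),
                   Dropout(0.2), Dense(10, 1, rng)]
    elif spec.family == "deepbind":
        layers = [
            Conv1D(4, 16, 24, rng), ReLU(), GlobalMaxPool(),
            Dense(16, 32, rng), ReLU(), Dropout(0.5), Dense(32, 1, rng),
        ]
    else:  # deepsea
        L = spec.input_length
        l1 = L - 7
        l2 = l1 // 4 - 7
        l3 = l2 // 4 - 7
        if l1 < 4 or l2 < 4 or l3 < 1:
            raise ValueError(
                f"deepsea input_length {L} incompatible with two pool-by-4 stages"
            )
        layers = [
            Conv1D(4, 320, 8, rng), ReLU(), MaxPool1D(4, 4), Dropout(0.2),
            Conv1D(320, 480, 8, rng), ReLU(), MaxPool1D(4, 4), Dropout(0.2),
            Conv1D(480, 960, 8, rng), ReLU(), Dropout(0.5), Flatten(),
            Dense(960 * l3, 925, rng), ReLU(), Dense(925, 1, rng),
        ]
    return ClassifierModel(spec, Sequential(layers))


def count_parameters(model: ClassifierModel) -> int:
    """Total number of trainable scalars."""
    return model.net.n_parameters()
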