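"""Convolutional classifiers over pair images.

Three architectures share one training loop:

``tiny``
    two conv/pool blocks and a small dense head — the workhorse for
    desk-scale experiments on unresized encodings (e.g. 64x32);
``alexnet_like``
    five convolution layers followed by three dense layers with ReLU
    activations, a width-reduced re-expression of the classical eight-layer
    design for 224x224 inputs;
``inception_like``
    a convolutional stem plus two inception blocks (parallel 1x1 / 3x3 / 5x5 /
    pooled-projection branches concatenated on channels), global average
    pooling and a dense head.

Training is stochastic gradient descent with momentum 0.9 on 2-class
cross-entropy; the reference settings (learning rate 1e-4, 20 epochs,
mini-batches of 20) are the defaults.  A freshly initialized tiny network at
desk scale needs a larger step size to converge in 20 epochs;
:meth:`TrainConfig.desk_scale` pins that variant (learning rate 0.01).
Everything is driven by explicit seeds and runs bit-reproducibly.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from cdrscreen import _nn

ARCHITECTURES = ("tiny", "alexnet_like", "inception_like")


@dataclass(frozen=True)
class TrainConfig:
    architecture: str = "tiny"
    learning_rate: float = 1e-4
    momentum: float = 0.9
    max_epochs: int = 20
    batch_size: int = 20
    seed: int = 0
    input_shape: tuple[int, int] | None = None  # None: use images as given

    def __post_init__(self) -> None:
        if self.architecture not in ARCHITECTURES:
            raise ValueError(
                f"unknown architecture {self.architecture!r}; "
                f"choose from {ARCHITECTURES}"
            )
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size < 1 or self.max_epochs < 1:
            raise ValueError("batch_size and max_epochs must be >= 1")

    @classmethod
    def desk_scale(cls, seed: int = 0, max_epochs: int = 20, **kw) -> "TrainConfig":
        """Tiny-architecture settings for small unresized encodings."""
        return cls(architecture="tiny", learning_rate=0.01, seed=seed,
                   max_epochs=max_epochs, **kw)


@dataclass
class CNNModel:
    """An (un)trained network plus the metadata needed to rebuild it."""

    architecture: str
    input_shape: tuple[int, int]
    channels: int
    init_seed: int
    net: _nn.Network

    @property
    def n_parameters(self) -> int:
        return self.net.n_parameters()


@dataclass
class TrainedModel:
    model: CNNModel
    config: TrainConfig
    history: list[dict] = field(default_factory=list)  # per-epoch loss/accuracy


@dataclass
class PredictionSet:
    """Per-pair probabilities with hard labels at the 0.5 threshold."""

    compound_ids: list[str]
    disease_ids: list[str]
    probabilities: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if p.size and (p.min() < 0.0 or p.max() > 1.0):
            raise ValueError("probabilities must lie in [0, 1]")
        self.probabilities = p

    @property
    def labels(self) -> np.ndarray:
        """Predicted class: positive iff probability strictly exceeds 0.5."""
        return (self.probabilities > 0.5).astype(int)

    def __len__(self) -> int:
        return len(self.probabilities)


def _inception_block(cin: int, widths: tuple[int, tuple[int, int], tuple[int, int], int],
                     rng: np.random.Generator) -> _nn.Branches:
    b1, (b3r, b3), (b5r, b5), bp = widths
    return _nn.Branches([
        [_nn.Conv2D(cin, b1, 1, rng), _nn.ReLU()],
        [_nn.Conv2D(cin, b3r, 1, rng), _nn.ReLU(),
         _nn.Conv2D(b3r, b3, 3, rng), _nn.ReLU()],
        [_nn.Conv2D(cin, b5r, 1, rng), _nn.ReLU(),
         _nn.Conv2D(b5r, b5, 5, rng), _nn.ReLU()],
        [_nn.MaxPool2D(3, stride=1, pad=1),
         _nn.Conv2D(cin, bp, 1, rng), _nn.ReLU()],
    ])


def build_network(
    architecture: str,
    input_shape: tuple[int, int],
    channels: int = 1,
    seed: int = 0,
) -> CNNModel:
    """Construct an untrained network for ``channels x H x W`` inputs.

    Dense layer widths are inferred by tracing a dummy input through the
    convolutional stack; an input too small for the receptive field raises
    with the minimum workable size.
    """
    if architecture not in ARCHITECTURES:
        raise ValueError(f"unknown architecture {architecture!r}")
    h, w = input_shape
    rng = np.random.default_rng(seed)
    layers: list[_nn.Layer] = []
    x = np.zeros((1, channels, h, w), dtype=_nn.F32)

    def add(layer: _nn.Layer) -> None:
        nonlocal x
        x = layer.forward(x)
        layers.append(layer)

    if architecture == "tiny":
        add(_nn.Conv2D(channels, 8, 3, rng))
        add(_nn.ReLU())
        add(_nn.MaxPool2D(2))
        add(_nn.Conv2D(8, 16, 3, rng))
        add(_nn.ReLU())
        add(_nn.MaxPool2D(2))
        add(_nn.Flatten())
        add(_nn.Dense(x.shape[1], 64, rng))
        add(_nn.ReLU())
        add(_nn.Dense(64, 2, rng))
    elif architecture == "alexnet_like":
        add(_nn.Conv2D(channels, 32, 11, rng, stride=4, pad=2))
        add(_nn.ReLU())
        add(_nn.MaxPool2D(3, stride=2))
        add(_nn.Conv2D(32, 64, 5, rng, pad=2))
        add(_nn.ReLU())
        add(_nn.MaxPool2D(3, stride=2))
        add(_nn.Conv2D(64, 96, 3, rng))
        add(_nn.ReLU())
        add(_nn.Conv2D(96, 96, 3, rng))
        add(_nn.ReLU())
        add(_nn.Conv2D(96, 64, 3, rng))
        add(_nn.ReLU())
        add(_nn.MaxPool2D(3, stride=2))
        add(_nn.Flatten())
        add(_nn.Dense(x.shape[1], 256, rng))
        add(_nn.ReLU())
        add(_nn.Dense(256, 128, rng))
        add(_nn.ReLU())
        add(_nn.Dense(128, 2, rng))
    else:  # inception_like
        add(_nn.Conv2D(channels, 16, 3, rng))
        add(_nn.ReLU())
        add(_nn.MaxPool2D(2))
        add(_inception_block(16, (8, (8, 16), (4, 8), 8), rng))   # -> 40 ch
        add(_nn.MaxPool2D(2))
        add(_inception_block(40, (16, (12, 24), (6, 12), 12), rng))  # -> 64 ch
        add(_nn.GlobalAvgPool())
        add(_nn.Dense(64, 2, rng))

    return CNNModel(
        architecture=architecture,
        input_shape=(h, w),
        channels=channels,
        init_seed=seed,
        net=_nn.Network(layers),
    )


def _prepare_images(images: np.ndarray, model: CNNModel) -> np.ndarray:
    """Coerce (N,H,W) or (N,C,H,W) image stacks to the model's input tensor."""
    x = np.asarray(images, dtype=_nn.F32)
    if x.ndim == 3:
        x = x[:, None, :, :]
    if x.ndim != 4:
        raise ValueError(f"expected (N,H,W) or (N,C,H,W) images, got {x.shape}")
    if x.shape[1] == 1 and model.channels == 3:
        x = np.repeat(x, 3, axis=1)  # grayscale replicated for RGB-shaped nets
    if x.shape[1] != model.channels or x.shape[2:] != model.input_shape:
        raise ValueError(
            f"image stack {x.shape[1:]} does not match model input "
            f"({model.channels}, {model.input_shape[0]}, {model.input_shape[1]})"
        )
    return x


def train(
    model: CNNModel,
    images: np.ndarray,
    labels: Sequence[int],
    config: TrainConfig,
) -> TrainedModel:
    """Fit with SGD(momentum) on 2-class cross-entropy; reproducible per seed.

    ``images`` are floats on [0, 1] (pixels / 255).  The per-epoch mean loss
    and training accuracy are recorded in the returned history.
    """
    x = _prepare_images(images, model)
    y = np.asarray(labels, dtype=int)
    if y.shape[0] != x.shape[0]:
        raise ValueError("images and labels differ in length")
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    rng = np.random.default_rng(config.seed)
    opt = _nn.SGDMomentum(model.net, lr=config.learning_rate,
                          momentum=config.momentum)
    n = x.shape[0]
    history: list[dict] = []
    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        losses, correct = [], 0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            logits = model.net.forward(x[idx])
            loss, grad = _nn.cross_entropy(logits, y[idx])
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}; reduce learning_rate"
                )
            model.net.backward(grad)
            opt.step()
            losses.append(loss * len(idx))
            correct += int((logits.argmax(axis=1) == y[idx]).sum())
        history.append(
            {"epoch": epoch, "loss": sum(losses) / n, "accuracy": correct / n}
        )
    return TrainedModel(model=model, config=config, history=history)


def predict(
    trained: TrainedModel | CNNModel,
    images: np.ndarray,
    compound_ids: Sequence[str] | None = None,
    disease_ids: Sequence[str] | None = None,
    batch_size: int = 256,
) -> PredictionSet:
    """Per-pair probability of a positive relationship (softmax class 1)."""
    model = trained.model if isinstance(trained, TrainedModel) else trained
    x = _prepare_images(images, model)
    probs = np.empty(x.shape[0], dtype=float)
    for start in range(0, x.shape[0], batch_size):
        logits = model.net.forward(x[start:start + batch_size])
        probs[start:start + len(logits)] = _nn.softmax(logits)[:, 1]
    n = len(probs)
    cids = list(compound_ids) if compound_ids is not None else [str(i) for i in range(n)]
    dids = list(disease_ids) if disease_ids is not None else [""] * n
    if len(cids) != n or len(dids) != n:
        raise ValueError("id lists must match the number of images")
    return PredictionSet(compound_ids=cids, disease_ids=dids, probabilities=probs)


def save_model(trained: TrainedModel, path: str | Path) -> None:
    """Checkpoint: npz of parameter arrays plus a JSON sidecar of metadata."""
    path = Path(path)
    arrays = trained.model.net.state_arrays()
    np.savez(path.with_suffix(".npz"), *arrays)
    sidecar = {
        "architecture": trained.model.architecture,
        "input_shape": list(trained.model.input_shape),
        "channels": trained.model.channels,
        "init_seed": trained.model.init_seed,
        "config": {**asdict(trained.config),
                   "input_shape": list(trained.config.input_shape)
                   if trained.config.input_shape else None},
        "history": trained.history,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_model(path: str | Path) -> TrainedModel:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    model = build_network(
        sidecar["architecture"],
        tuple(sidecar["input_shape"]),
        channels=sidecar["channels"],
        seed=sidecar["init_seed"],
    )
    with np.load(path.with_suffix(".npz")) as data:
        arrays = [data[k] for k in data.files]
    model.net.load_state_arrays(arrays)
    cfg = sidecar["config"]
    if cfg.get("input_shape"):
        cfg["input_shape"] = tuple(cfg["input_shape"])
    config = TrainConfig(**cfg)
    return TrainedModel(model=model, config=config, history=sidecar["history"])
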