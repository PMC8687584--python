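"""The nine window-classifier architectures: {CNN, LSTM, GRU} x {OH, PSSM, WE}.

All models score a 61-residue window for one methylation state and emit a
single sigmoid probability.  The CNN body is two 1-D convolution sublayers
(256 kernels of length 9, then 32 kernels of length 7), each followed by
max-pooling of size 2, then a 128-unit fully connected layer; with the default
61 x 21 One-Hot input the per-layer sizes are

    61x21 -> conv 53x256 -> pool 26x256 -> conv 20x32 -> pool 10x32 -> 128 -> 1.

The recurrent bodies are seven stacked LSTM (or GRU) sublayers of 32 hidden
units each, read out at the final (61st) timestep of the top sublayer.
Encodings: OH feeds the 21-channel indicator matrix directly; PSSM feeds a
20-channel profile matrix; WE inserts a learned linear 21 -> 5 map (no
activation) in front of the body.  Hidden activations are ReLU; dropout
(rates 0.5 and 0.7) follows the two pooling stages of the CNN body during
training.  One independent binary model is trained per modification type.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np

from . import nn
from .corpus import SequenceWindow, WINDOW_LENGTH
from .encode import EncodedWindow, ONE_HOT_ORDER, one_hot_batch

FAMILIES = ("CNN", "LSTM", "GRU")
ENCODINGS = ("OH", "PSSM", "WE")


class SpecError(ValueError):
    """Inconsistent architecture description."""


@dataclass(frozen=True)
class ModelSpec:
    """Architecture description; defaults give the full-size published shapes.

    ``conv1``/``conv2`` are (kernel count, kernel length) pairs.  ``dropout``
    holds the two CNN dropout rates (after pool1 and after pool2).  Reduced
    widths (fewer kernels, narrower FC) can be set for quick desk-scale runs
    without touching the layer structure.
    """

    family: str = "CNN"
    encoding: str = "OH"
    window_length: int = WINDOW_LENGTH
    conv1: tuple[int, int] = (256, 9)
    conv2: tuple[int, int] = (32, 7)
    pool_size: int = 2
    fc_width: int = 128
    rnn_layers: int = 7
    rnn_hidden: int = 32
    we_dim: int = 5
    dropout: tuple[float, float] = (0.5, 0.7)
    activation: str = "relu"

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise SpecError(f"family must be one of {FAMILIES}, got {self.family!r}")
        if self.encoding not in ENCODINGS:
            raise SpecError(f"encoding must be one of {ENCODINGS}, got {self.encoding!r}")
        if self.activation != "relu":
            raise SpecError(f"unsupported activation {self.activation!r}")

    @property
    def input_channels(self) -> int:
        """21 indicator channels for OH/WE input, 20 profile channels for PSSM."""
        return 20 if self.encoding == "PSSM" else len(ONE_HOT_ORDER)

    @property
    def name(self) -> str:
        return f"{self.family}_{self.encoding}"


def shape_trace(spec: ModelSpec) -> list[tuple[str, tuple[int, ...]]]:
    """Per-layer output shapes, computed by plain shape arithmetic.

    Convolution (stride 1, no padding) maps length L to L - k + 1; pooling of
    size p maps L to floor(L / p).  This trace is the contract the built
    networks must satisfy.
    """
    length = spec.window_length
    c = spec.input_channels
    trace: list[tuple[str, tuple[int, ...]]] = [("input", (length, c))]
    if spec.encoding == "WE":
        c = spec.we_dim
        trace.append(("we", (length, c)))
    if spec.family == "CNN":
        for i, (kernels, klen) in enumerate((spec.conv1, spec.conv2), start=1):
            length = length - klen + 1
            trace.append((f"conv{i}", (length, kernels)))
            length //= spec.pool_size
            trace.append((f"pool{i}", (length, kernels)))
            c = kernels
        trace.append(("fc", (spec.fc_width,)))
    else:
        for i in range(1, spec.rnn_layers + 1):
            trace.append((f"{spec.family.lower()}{i}", (length, spec.rnn_hidden)))
    trace.append(("out", (1,)))
    return trace


@dataclass
class TrainedModel:
    """A spec plus fitted (or freshly initialized) parameters.

    ``training_history`` records the per-epoch training loss of the last
    :func:`splitbench.train.train` call that produced this model.
    """

    spec: ModelSpec
    net: nn.Network
    seed: int
    training_history: list[float] = field(default_factory=list)

    def score(self, windows, batch_size: int = 1024) -> np.ndarray:
        return score(self, windows, batch_size=batch_size)

    def copy(self) -> "TrainedModel":
        clone = build_model(self.spec, self.seed)
        clone.net.set_state(self.net.get_state())
        clone.training_history = list(self.training_history)
        return clone

    def save(self, path: str | Path) -> None:
        """Write spec + seed + weights as a single .npz archive."""
        arrays = {
            f"layer{i}.{k}": v
            for i, layer in enumerate(self.net.layers)
            for k, v in layer.params.items()
        }
        meta = json.dumps({"spec": asdict(self.spec), "seed": self.seed,
                           "history": self.training_history})
        np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        with np.load(path) as archive:
            meta = json.loads(archive["__meta__"].tobytes().decode())
            spec_dict = meta["spec"]
            for key in ("conv1", "conv2", "dropout"):
                spec_dict[key] = tuple(spec_dict[key])
            model = build_model(ModelSpec(**spec_dict), meta["seed"])
            model.training_history = meta["history"]
            for i, layer in enumerate(model.net.layers):
                for k in layer.params:
                    layer.params[k][...] = archive[f"layer{i}.{k}"]
        return model


def build_model(spec: ModelSpec, seed: int, dtype=np.float32) -> TrainedModel:
    """Instantiate the network for ``spec`` with seeded Glorot initialization.

    The same spec and seed always produce bit-identical initial parameters.
    """
    rng = np.random.default_rng(seed)
    length = spec.window_length
    cin = spec.input_channels
    layers: list[nn.Layer] = []
    if spec.encoding == "WE":
        layers.append(nn.Dense(cin, spec.we_dim, rng, dtype=dtype))
        cin = spec.we_dim

    if spec.family == "CNN":
        c = cin
        for (kernels, klen), rate in zip((spec.conv1, spec.conv2), spec.dropout):
            layers += [
                nn.Conv1D(klen, c, kernels, rng, dtype=dtype),
                nn.ReLU(),
                nn.MaxPool1D(spec.pool_size),
                nn.Dropout(rate),
            ]
            length = (length - klen + 1) // spec.pool_size
            c = kernels
        layers += [
            nn.Flatten(),
            nn.Dense(length * c, spec.fc_width, rng, dtype=dtype),
            nn.ReLU(),
            nn.Dense(spec.fc_width, 1, rng, dtype=dtype),
        ]
    else:
        cell = nn.LSTM if spec.family == "LSTM" else nn.GRU
        c = cin
        for _ in range(spec.rnn_layers):
            layers.append(cell(c, spec.rnn_hidden, rng, dtype=dtype))
            c = spec.rnn_hidden
        layers += [nn.LastStep(), nn.Dense(spec.rnn_hidden, 1, rng, dtype=dtype)]

    model = TrainedModel(spec, nn.Network(layers), seed)
    _check_shapes(model)
    return model


def _check_shapes(model: TrainedModel) -> None:
    """Assert the built network reproduces its own shape trace."""
    x = np.zeros((1, model.spec.window_length, model.spec.input_channels),
                 dtype=np.float32)
    expected = dict(shape_trace(model.spec))
    probes = {"input": x.shape[1:]}
    for layer, name in zip(model.net.layers, _layer_names(model.spec)):
        x = layer.forward(x)
        if name is not None:
            probes[name] = x.shape[1:]
    probes["out"] = (1,)
    for name, shape in probes.items():
        if name in expected and tuple(shape) != tuple(expected[name]):
            raise SpecError(f"layer {name}: built shape {shape} != trace {expected[name]}")


def _layer_names(spec: ModelSpec) -> list[str | None]:
    """Trace label for each built layer (None for layers not in the trace)."""
    names: list[str | None] = []
    if spec.encoding == "WE":
        names.append("we")
    if spec.family == "CNN":
        for i in (1, 2):
            names += [f"conv{i}", None, f"pool{i}", None]
        names += [None, "fc", None, None]
    else:
        names += [f"{spec.family.lower()}{i}" for i in range(1, spec.rnn_layers + 1)]
        names += [None, None]
    return names


def encode_inputs(spec: ModelSpec, windows) -> np.ndarray:
    """Turn windows into the (N, 61, C) array the model consumes.

    Accepts an ndarray (passed through after a channel check), a list of
    :class:`EncodedWindow`, or sequences / :class:`SequenceWindow` objects
    (One-Hot encoded; valid for OH and WE models only).
    """
    if isinstance(windows, np.ndarray):
        x = windows
    elif len(windows) == 0:
        x = np.zeros((0, spec.window_length, spec.input_channels), dtype=np.float32)
    elif isinstance(windows[0], EncodedWindow):
        tag = windows[0].encoding_tag
        want = "PSSM" if spec.encoding == "PSSM" else "OH"
        if tag != want:
            raise SpecError(f"{spec.name} expects {want} input, got {tag}")
        x = np.stack([w.matrix for w in windows]).astype(np.float32)
    else:
        if spec.encoding == "PSSM":
            raise SpecError(
                f"{spec.name} needs PSSM-encoded input; raw sequences carry no profile"
            )
        seqs = [w.sequence if isinstance(w, SequenceWindow) else w for w in windows]
        x = one_hot_batch(seqs)
    if x.ndim != 3 or x.shape[1:] != (spec.window_length, spec.input_channels):
        raise SpecError(
            f"{spec.name} expects input of shape (N, {spec.window_length}, "
            f"{spec.input_channels}), got {x.shape}"
        )
    return x


def score(model: TrainedModel, windows, batch_size: int = 1024) -> np.ndarray:
    """Sigmoid scores in [0, 1], one per window, order-preserving."""
    x = encode_inputs(model.spec, windows)
    out = np.empty(len(x), dtype=np.float64)
    for i in range(0, len(x), batch_size):
        logits = model.net.forward(x[i:i + batch_size], train=False)
        out[i:i + len(logits)] = nn.sigmoid(np.asarray(logits, dtype=np.float64))
    return out


def all_specs(**overrides) -> list[ModelSpec]:
    """The nine family x encoding combinations (with optional field overrides)."""
    return [
        replace(ModelSpec(family=f, encoding=e), **overrides)
        for f in FAMILIES
        for e in ENCODINGS
    ]
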