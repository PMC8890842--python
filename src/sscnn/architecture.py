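"""Declarative CNN architecture: layer specs, shape/parameter accounting.

The default architecture is the small landmark-detection CNN:
three 3x3 "same" conv blocks (32/64/64 filters) with 2x2 max pooling,
batch normalization and dropout, a 128-unit dense layer, and a softmax
output over the three landmark classes (Z-line, pylorus, cecum).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import yaml

from . import nn

VALID_KINDS = {"input", "conv2d", "maxpool", "batchnorm", "dropout", "leaky_relu", "flatten", "dense"}


@dataclass
class LayerSpec:
    """One layer of the network, by kind plus kind-specific hyperparameters.

    conv2d: filters, kernel_side, padding ("same"), activation ("relu"|"linear")
    maxpool: pool_side; dropout: rate; dense: units, activation
    ("relu"|"softmax"|"linear"); leaky_relu: negative_slope.
    """

    kind: str
    hyper: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in VALID_KINDS:
            raise ValueError(f"unknown layer kind {self.kind!r}; valid: {sorted(VALID_KINDS)}")
        h = self.hyper
        if self.kind == "conv2d":
            if h.get("filters", 0) <= 0 or h.get("kernel_side", 0) <= 0:
                raise ValueError("conv2d needs positive filters and kernel_side")
        elif self.kind == "maxpool" and h.get("pool_side", 0) <= 0:
            raise ValueError("maxpool needs positive pool_side")
        elif self.kind == "dropout" and not 0.0 <= h.get("rate", -1.0) < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        elif self.kind == "dense" and h.get("units", 0) <= 0:
            raise ValueError("dense needs positive units")


@dataclass
class ModelSpec:
    """Ordered layer sequence starting with an input spec.

    ``shapes()`` and ``parameter_counts()`` reproduce the per-layer
    "Output shape" and "Parameters" accounting of standard framework
    model summaries.
    """

    layers: list[LayerSpec]

    def __post_init__(self) -> None:
        if not self.layers or self.layers[0].kind != "input":
            raise ValueError("first layer must be kind='input'")

    @property
    def input_shape(self) -> tuple[int, int, int]:
        h = self.layers[0].hyper
        return (h["side"], h["side"], h["channels"])

    @property
    def n_classes(self) -> int:
        last = self.layers[-1]
        if last.kind != "dense" or last.hyper.get("activation") != "softmax":
            raise ValueError("final layer must be dense with softmax activation")
        return last.hyper["units"]

    def shapes(self) -> list[tuple[int, ...]]:
        """Output shape of each layer (without the batch dimension)."""
        out: list[tuple[int, ...]] = []
        shape: tuple[int, ...] = self.input_shape
        for i, layer in enumerate(self.layers):
            k, h = layer.kind, layer.hyper
            if k == "input":
                pass
            elif k == "conv2d":
                if len(shape) != 3:
                    raise ValueError(f"layer {i} (conv2d) needs a spatial input, got shape {shape}")
                if h.get("padding", "same") != "same":
                    raise ValueError("only 'same' padding is supported")
                shape = (shape[0], shape[1], h["filters"])
            elif k == "maxpool":
                s = h["pool_side"]
                if shape[0] % s or shape[1] % s:
                    raise ValueError(f"layer {i} (maxpool) does not divide shape {shape}")
                shape = (shape[0] // s, shape[1] // s, shape[2])
            elif k in ("batchnorm", "dropout", "leaky_relu"):
                pass
            elif k == "flatten":
                shape = (int(np.prod(shape)),)
            elif k == "dense":
                if len(shape) != 1:
                    raise ValueError(f"layer {i} (dense) needs a flat input, got shape {shape}")
                shape = (h["units"],)
            out.append(shape)
        return out

    def parameter_counts(self) -> list[int]:
        """Per-layer parameter counts (batchnorm counts 4 per channel:
        gamma/beta plus running mean/variance, the total-parameters
        convention)."""
        counts: list[int] = []
        shapes = self.shapes()
        in_shape: tuple[int, ...] = self.input_shape
        for i, layer in enumerate(self.layers):
            k, h = layer.kind, layer.hyper
            if k == "conv2d":
                counts.append(h["filters"] * (h["kernel_side"] ** 2 * in_shape[2] + 1))
            elif k == "dense":
                counts.append(h["units"] * (in_shape[0] + 1))
            elif k == "batchnorm":
                counts.append(4 * in_shape[-1])
            else:
                counts.append(0)
            in_shape = shapes[i]
        return counts

    def total_parameters(self) -> int:
        return sum(self.parameter_counts())

    def summary(self) -> str:
        """Human-readable layer table (layer, output shape, parameters)."""
        names = {
            "input": "Input layer", "conv2d": "Conv2D", "maxpool": "MaxPooling2D",
            "batchnorm": "Batch-normalization", "dropout": "Dropout",
            "leaky_relu": "LeakyReLU", "flatten": "Flatten", "dense": "Dense",
        }
        lines = [f"{'Layer':<22}{'Output shape':<22}{'Parameters':>10}"]
        for layer, shape, count in zip(self.layers, self.shapes(), self.parameter_counts()):
            shp = "(None, " + ", ".join(str(s) for s in shape) + ")"
            lines.append(f"{names[layer.kind]:<22}{shp:<22}{count:>10}")
        lines.append(f"{'Total':<44}{self.total_parameters():>10}")
        return "\n".join(lines)

    # ---- serialization --------------------------------------------
    def to_yaml(self) -> str:
        return yaml.safe_dump([{"kind": l.kind, **l.hyper} for l in self.layers], sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "ModelSpec":
        rows = yaml.safe_load(text)
        return cls([LayerSpec(kind=r.pop("kind"), hyper=r) for r in rows])


def default_architecture(
    n_classes: int = 3,
    input_side: int = 32,
    dropout_rates: tuple[float, float, float] = (0.25, 0.25, 0.5),
    leaky_slope: float = 0.3,
) -> ModelSpec:
    """The landmark-detection CNN: conv(32)->pool->BN->drop ->
    conv(64, linear)->LeakyReLU->pool->BN->drop -> conv(64)->pool ->
    flatten->dense(128)->BN->drop -> dense(n_classes, softmax)."""
    L = LayerSpec
    return ModelSpec([
        L("input", {"side": input_side, "channels": 3}),
        L("conv2d", {"filters": 32, "kernel_side": 3, "padding": "same", "activation": "relu"}),
        L("maxpool", {"pool_side": 2}),
        L("batchnorm", {}),
        L("dropout", {"rate": dropout_rates[0]}),
        L("conv2d", {"filters": 64, "kernel_side": 3, "padding": "same", "activation": "linear"}),
        L("leaky_relu", {"negative_slope": leaky_slope}),
        L("maxpool", {"pool_side": 2}),
        L("batchnorm", {}),
        L("dropout", {"rate": dropout_rates[1]}),
        L("conv2d", {"filters": 64, "kernel_side": 3, "padding": "same", "activation": "relu"}),
        L("maxpool", {"pool_side": 2}),
        L("flatten", {}),
        L("dense", {"units": 128, "activation": "relu"}),
        L("batchnorm", {}),
        L("dropout", {"rate": dropout_rates[2]}),
        L("dense", {"units": n_classes, "activation": "softmax"}),
    ])


def count_parameters(spec: ModelSpec) -> tuple[list[int], int]:
    """Per-layer and total parameter counts for a spec."""
    counts = spec.parameter_counts()
    return counts, sum(counts)


def build_network(spec: ModelSpec, seed: int) -> nn.Network:
    """Instantiate a trainable network from a spec with seeded init.

    The built network's per-layer parameter counts equal
    ``spec.parameter_counts()`` (checked by tests, not re-checked here).
    """
    rng = np.random.default_rng(seed)
    layers: list[nn.layers.Layer] = []
    in_shape: tuple[int, ...] = spec.input_shape
    for layer_spec, out_shape in zip(spec.layers, spec.shapes()):
        k, h = layer_spec.kind, layer_spec.hyper
        if k == "conv2d":
            # the very first layer never needs an input gradient
            layers.append(
                nn.Conv2D(in_shape[2], h["filters"], h["kernel_side"], rng,
                          needs_input_grad=bool(layers))
            )
            act = h.get("activation", "relu")
            if act == "relu":
                layers.append(nn.ReLU())
            elif act != "linear":
                raise ValueError(f"unsupported conv activation {act!r}")
        elif k == "maxpool":
            layers.append(nn.MaxPool2D(h["pool_side"]))
        elif k == "batchnorm":
            layers.append(nn.BatchNorm(in_shape[-1]))
        elif k == "dropout":
            layers.append(nn.Dropout(h["rate"]))
        elif k == "leaky_relu":
            layers.append(nn.LeakyReLU(h.get("negative_slope", 0.3)))
        elif k == "flatten":
            layers.append(nn.Flatten())
        elif k == "dense":
            layers.append(nn.Dense(in_shape[0], h["units"], rng))
            act = h.get("activation", "linear")
            if act == "relu":
                layers.append(nn.ReLU())
            elif act not in ("linear", "softmax"):  # softmax lives in the head
                raise ValueError(f"unsupported dense activation {act!r}")
        in_shape = out_shape
    return nn.Network(layers, n_classes=spec.n_classes)
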