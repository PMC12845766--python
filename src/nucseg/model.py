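"""Declarative architecture of the lightweight asymmetric U-Net.

The network is a six-level U-shaped encoder–decoder for 128x128 RGB
inputs producing a two-channel (background / nucleus) per-pixel softmax.
Each block is two 3x3 same-padded convolutions with ReLU and a trailing
dropout. Encoder blocks 2–6 and the bottleneck open with a 2x2 max-pool;
decoder blocks open with a 2x2 stride-2 transposed convolution followed
by concatenation with the matching encoder block's final feature map.

What makes the channel schedule *asymmetric*: the encoder doubles
filters up to block 4 (8, 16, 32, 64), but blocks 5 and 6 collapse their
second convolution to 16 and 32 channels, and the decoder mirrors this
(blocks 6 and 5 end at 32 and 16 channels instead of the classical
mirror-image counts). This keeps the model an order of magnitude
smaller than a standard U-Net of the same depth.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

from nucseg.nn.network import AsymmetricUNet

#: Table-driven channel schedule (full-width defaults).
DOWN_CONV1 = (8, 16, 32, 64, 128, 256)
DOWN_CONV2 = (8, 16, 32, 64, 16, 32)
MIDDLE_CONV = (512, 64)
UP_CONV1 = (256, 128, 64, 32, 16, 8)   # execution order: upblock-6 .. upblock-1
UP_CONV2 = (32, 16, 64, 32, 16, 8)


class SpecError(ValueError):
    """A NetworkSpec that violates the architecture's invariants."""


@dataclass
class BlockSpec:
    name: str
    kind: str                     # down | middle | up | output
    conv1_filters: int
    conv2_filters: int
    pool_before: bool = False
    upsample_before: bool = False
    dropout_rate: float = 0.2
    activation: str = "relu"
    skip_partner: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("down", "middle", "up", "output"):
            raise SpecError(f"{self.name}: unknown kind {self.kind!r}")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise SpecError(f"{self.name}: dropout_rate must be in [0,1)")
        if self.kind == "up" and (not self.upsample_before or not self.skip_partner):
            raise SpecError(f"{self.name}: up blocks need upsample_before "
                            "and a skip_partner")


@dataclass
class NetworkSpec:
    blocks: list[BlockSpec]
    input_shape: tuple[int, int, int] = (128, 128, 3)
    output_classes: int = 2

    def validate(self) -> None:
        kinds = [b.kind for b in self.blocks]
        counts = {k: kinds.count(k) for k in ("down", "middle", "up", "output")}
        if counts != {"down": 6, "middle": 1, "up": 6, "output": 1}:
            raise SpecError(f"expected 6 down / 1 middle / 6 up / 1 output "
                            f"blocks, got {counts}")
        downs = [b for b in self.blocks if b.kind == "down"]
        if downs[0].pool_before or not all(b.pool_before for b in downs[1:]):
            bad = downs[0].name if downs[0].pool_before else \
                next(b.name for b in downs[1:] if not b.pool_before)
            raise SpecError(f"{bad}: pooling must precede down blocks 2-6 only")
        down_names = {b.name for b in downs}
        for b in self.blocks:
            if b.kind == "up" and b.skip_partner not in down_names:
                raise SpecError(f"{b.name}: skip partner "
                                f"{b.skip_partner!r} is not a down block")

    def down_blocks(self) -> list[BlockSpec]:
        return [b for b in self.blocks if b.kind == "down"]

    def middle_block(self) -> BlockSpec:
        return next(b for b in self.blocks if b.kind == "middle")

    def up_blocks(self) -> list[BlockSpec]:
        """Decoder blocks in execution order (deepest first)."""
        return [b for b in self.blocks if b.kind == "up"]

    def to_yaml(self, path) -> None:
        doc = {"input_shape": list(self.input_shape),
               "output_classes": self.output_classes,
               "blocks": [asdict(b) for b in self.blocks]}
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "NetworkSpec":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(blocks=[BlockSpec(**b) for b in doc["blocks"]],
                   input_shape=tuple(doc["input_shape"]),
                   output_classes=doc["output_classes"])


def default_spec(width_divisor: int = 1, dropout_rate: float = 0.2) -> NetworkSpec:
    """The canonical layer table.

    ``width_divisor`` divides every filter count (minimum 2), yielding a
    width-reduced network with the identical topology — handy for
    desk-scale experiments on synthetic data.
    """
    def w(f: int) -> int:
        return max(2, f // width_divisor) if width_divisor > 1 else f

    blocks: list[BlockSpec] = []
    for i in range(6):
        blocks.append(BlockSpec(
            name=f"downblock-{i + 1}", kind="down",
            conv1_filters=w(DOWN_CONV1[i]), conv2_filters=w(DOWN_CONV2[i]),
            pool_before=i > 0, dropout_rate=dropout_rate))
    blocks.append(BlockSpec(
        name="middleblock", kind="middle",
        conv1_filters=w(MIDDLE_CONV[0]), conv2_filters=w(MIDDLE_CONV[1]),
        pool_before=True, dropout_rate=dropout_rate))
    for j, i in enumerate(range(6, 0, -1)):
        blocks.append(BlockSpec(
            name=f"upblock-{i}", kind="up",
            conv1_filters=w(UP_CONV1[j]), conv2_filters=w(UP_CONV2[j]),
            upsample_before=True, skip_partner=f"downblock-{i}",
            dropout_rate=dropout_rate))
    blocks.append(BlockSpec(name="output", kind="output",
                            conv1_filters=2, conv2_filters=2,
                            dropout_rate=0.0, activation="softmax"))
    return NetworkSpec(blocks=blocks)


class ShapeTrace:
    """Analytic per-layer output shapes (no weights involved)."""

    def __init__(self, rows: list[tuple[str, int, int, int]]):
        self.rows = rows
        self._by_name = {r[0]: r for r in rows}

    def shape(self, name: str) -> tuple[int, int, int]:
        _, h, w, c = self._by_name[name]
        return h, w, c

    def channels(self, name: str) -> int:
        return self._by_name[name][3]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=["layer", "height", "width",
                                                "channels"])

    def __iter__(self) -> Iterable[tuple[str, int, int, int]]:
        return iter(self.rows)


def shape_trace(spec: NetworkSpec,
                input_shape: tuple[int, int, int] | None = None) -> ShapeTrace:
    """Trace every layer's output shape through the spec analytically."""
    spec.validate()
    h, w, c = input_shape or spec.input_shape
    rows: list[tuple[str, int, int, int]] = [("input", h, w, c)]
    skip_shapes: dict[str, tuple[int, int, int]] = {}

    for b in spec.down_blocks() + [spec.middle_block()]:
        if b.pool_before:
            if h < 2 or w < 2:
                raise SpecError(f"{b.name}: spatial size {h}x{w} too small to pool")
            h, w = h // 2, w // 2
        rows.append((f"{b.name}/conv1", h, w, b.conv1_filters))
        rows.append((f"{b.name}/conv2", h, w, b.conv2_filters))
        c = b.conv2_filters
        if b.kind == "down":
            skip_shapes[b.name] = (h, w, c)

    for b in spec.up_blocks():
        h, w = h * 2, w * 2
        rows.append((f"{b.name}/upconv", h, w, b.conv1_filters))
        sh, sw, sc = skip_shapes[b.skip_partner]
        if (sh, sw) != (h, w):
            raise SpecError(f"{b.name}: skip partner shape {sh}x{sw} does not "
                            f"match decoder {h}x{w}")
        rows.append((f"{b.name}/concat", h, w, b.conv1_filters + sc))
        rows.append((f"{b.name}/conv1", h, w, b.conv1_filters))
        rows.append((f"{b.name}/conv2", h, w, b.conv2_filters))
        c = b.conv2_filters

    rows.append(("output", h, w, spec.output_classes))
    return ShapeTrace(rows)


def build_network(spec: NetworkSpec, seed: int = 42) -> AsymmetricUNet:
    """Construct a trainable network from the spec with seeded init."""
    spec.validate()
    shape_trace(spec)  # raises if shapes are inconsistent
    return AsymmetricUNet(spec, seed=seed)


def count_parameters(model: AsymmetricUNet) -> tuple[int, dict[str, int]]:
    """Total trainable parameters and a per-block breakdown.

    Dropout and pooling layers contribute nothing; only convolution
    weights and biases are counted.
    """
    per_block: dict[str, int] = {}
    for name, arr in model.named_params().items():
        block = name.split("/")[0]
        per_block[block] = per_block.get(block, 0) + arr.size
    return sum(per_block.values()), per_block
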