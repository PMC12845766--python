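"""The trainable U-shaped network, assembled from a NetworkSpec.

Forward/backward are written out explicitly (no autodiff): the topology
is a fixed U with skip concatenations, so the reverse pass just mirrors
the forward pass, splitting each concatenation gradient back into its
decoder and encoder halves.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from nucseg.nn.layers import (Conv2D, ConvTranspose2x2, Dropout, MaxPool2x2,
                              softmax)


class AsymmetricUNet:
    """Encoder–decoder with skip connections and per-pixel softmax.

    The model is fully convolutional: although the canonical input is
    128x128, any spatial size divisible by 64 (six halvings) works.
    """

    def __init__(self, spec, seed: int = 42):
        self.spec = spec
        self.seed = seed
        ss = np.random.SeedSequence(seed)
        rngs = iter([np.random.default_rng(s) for s in ss.spawn(64)])

        c = spec.input_shape[2]
        self.down = []
        for b in spec.down_blocks():
            blk = {
                "name": b.name,
                "pool": MaxPool2x2() if b.pool_before else None,
                "conv1": Conv2D(c, b.conv1_filters, 3, next(rngs)),
                "conv2": Conv2D(b.conv1_filters, b.conv2_filters, 3, next(rngs)),
                "drop": Dropout(b.dropout_rate),
            }
            c = b.conv2_filters
            self.down.append(blk)

        mb = spec.middle_block()
        self.middle = {
            "name": mb.name,
            "pool": MaxPool2x2(),
            "conv1": Conv2D(c, mb.conv1_filters, 3, next(rngs)),
            "conv2": Conv2D(mb.conv1_filters, mb.conv2_filters, 3, next(rngs)),
            "drop": Dropout(mb.dropout_rate),
        }
        c = mb.conv2_filters

        skip_channels = {b.name: b.conv2_filters for b in spec.down_blocks()}
        self.up = []
        for b in spec.up_blocks():
            sc = skip_channels[b.skip_partner]
            blk = {
                "name": b.name,
                "skip": b.skip_partner,
                "tconv": ConvTranspose2x2(c, b.conv1_filters, next(rngs)),
                "conv1": Conv2D(b.conv1_filters + sc, b.conv1_filters, 3, next(rngs)),
                "conv2": Conv2D(b.conv1_filters, b.conv2_filters, 3, next(rngs)),
                "drop": Dropout(b.dropout_rate),
            }
            c = b.conv2_filters
            self.up.append(blk)

        self.out_conv = Conv2D(c, spec.output_classes, 1, next(rngs),
                               activation=None)
        self._training = False

    # -- bookkeeping -----------------------------------------------------

    def _blocks(self):
        for blk in self.down + [self.middle] + self.up:
            yield blk["name"], blk
        yield "output", {"conv": self.out_conv}

    def _layers(self):
        for bname, blk in self._blocks():
            for lname, layer in blk.items():
                if hasattr(layer, "params"):
                    yield f"{bname}/{lname}", layer

    def named_params(self) -> dict[str, np.ndarray]:
        return {f"{ln}/{pn}": arr for ln, layer in self._layers()
                for pn, arr in layer.params.items()}

    def named_grads(self) -> dict[str, np.ndarray]:
        return {f"{ln}/{pn}": arr for ln, layer in self._layers()
                for pn, arr in layer.grads.items()}

    def train_mode(self, on: bool = True, dropout_seed: int | None = None) -> None:
        """Toggle dropout; optionally reseed all dropout masks."""
        self._training = on
        drops = [blk["drop"] for _, blk in self._blocks() if "drop" in blk]
        if dropout_seed is not None:
            ss = np.random.SeedSequence(dropout_seed)
            for drop, s in zip(drops, ss.spawn(len(drops))):
                drop.rng = np.random.default_rng(s)
        for drop in drops:
            drop.training = on

    # -- forward / backward ----------------------------------------------

    def astype(self, dtype) -> "AsymmetricUNet":
        """Cast all parameters in place (float64 helps verification)."""
        for _, layer in self._layers():
            for k in layer.params:
                layer.params[k] = layer.params[k].astype(dtype)
        return self

    def forward_logits(self, x: np.ndarray) -> np.ndarray:
        """(B,H,W,3) in [0,1] -> (B,H,W,classes) logits.

        Computation runs in the parameters' dtype (float32 by default).
        """
        x = np.ascontiguousarray(x, dtype=self.out_conv.params["W"].dtype)
        self._skips = {}
        for blk in self.down:
            if blk["pool"] is not None:
                x = blk["pool"].forward(x)
            x = blk["conv1"].forward(x)
            x = blk["conv2"].forward(x)
            x = blk["drop"].forward(x)
            self._skips[blk["name"]] = x
        x = self.middle["pool"].forward(x)
        x = self.middle["conv1"].forward(x)
        x = self.middle["conv2"].forward(x)
        x = self.middle["drop"].forward(x)
        self._concat_split = {}
        for blk in self.up:
            x = blk["tconv"].forward(x)
            skip = self._skips[blk["skip"]]
            self._concat_split[blk["name"]] = x.shape[-1]
            x = np.concatenate([x, skip], axis=-1)
            x = blk["conv1"].forward(x)
            x = blk["conv2"].forward(x)
            x = blk["drop"].forward(x)
        return self.out_conv.forward(x)

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Per-pixel class probabilities (channels sum to 1)."""
        return softmax(self.forward_logits(x), axis=-1)

    def predict_proba(self, x: np.ndarray, batch_size: int = 16) -> np.ndarray:
        """Batched inference with dropout off."""
        was_training = self._training
        self.train_mode(False)
        outs = [self.forward(x[i:i + batch_size])
                for i in range(0, len(x), batch_size)]
        if was_training:
            self.train_mode(True)
        return np.concatenate(outs, axis=0)

    def backward(self, dlogits: np.ndarray) -> None:
        """Accumulate parameter gradients from d(loss)/d(logits)."""
        g = self.out_conv.backward(dlogits)
        dskips = {name: None for name in self._skips}
        for blk in reversed(self.up):
            g = blk["drop"].backward(g)
            g = blk["conv2"].backward(g)
            g = blk["conv1"].backward(g)
            nc = self._concat_split[blk["name"]]
            g, gskip = g[..., :nc], g[..., nc:]
            dskips[blk["skip"]] = gskip
            g = blk["tconv"].backward(g)
        g = self.middle["drop"].backward(g)
        g = self.middle["conv2"].backward(g)
        g = self.middle["conv1"].backward(g)
        g = self.middle["pool"].backward(g)
        for blk in reversed(self.down):
            extra = dskips[blk["name"]]
            if extra is not None:
                g = g + extra
            g = blk["drop"].backward(g)
            g = blk["conv2"].backward(g)
            g = blk["conv1"].backward(g)
            if blk["pool"] is not None:
                g = blk["pool"].backward(g)
        self._skips = {}

    # -- checkpointing ---------------------------------------------------

    def save_weights(self, path: str | Path) -> None:
        arrays = {k.replace("/", "__"): v for k, v in self.named_params().items()}
        np.savez(path, **arrays)

    def load_weights(self, path: str | Path) -> None:
        data = np.load(path)
        params = self.named_params()
        for key in params:
            params[key][...] = data[key.replace("/", "__")]
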