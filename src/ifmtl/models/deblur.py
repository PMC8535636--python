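"""Residual-dense de-blurring network.

Five stages: (1) shallow feature extraction by two 3x3 convolutions;
(2) a chain of residual dense blocks (RDB) — inside a block every conv
layer's output is concatenated onto the inputs of all subsequent layers,
the concatenation of the block input and all layer outputs is fused by a
1x1 conv, and the fusion is added back to the block input (local
residual); (3) global feature fusion — all block outputs concatenated and
fused by a 1x1 conv; (4) global residual learning — the fused features are
added to the shallow features; (5) a restoration head. Gaussian defocus
preserves resolution, so the default head is a plain conv
(``upscale_factor=1``); a pixel-shuffle head is available for genuine
super-resolution factors. By default the head predicts a correction that
is added onto the blurred input stains (``residual_output=True``), so the
identity restoration is the starting point and short schedules converge.

Training minimizes the mean squared error between the restored and sharp
stacks with Adam. Output is left unclamped during training (clean MSE
gradients) and clipped to [0, 1] at inference.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .. import nn
from ..case import ValidationError


class _PixelShuffle(nn.Module):
    """(N, H, W, C*f*f) -> (N, H*f, W*f, C); backward is the exact inverse."""

    def __init__(self, factor: int) -> None:
        self.factor = factor

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, cff = x.shape
        f = self.factor
        c = cff // (f * f)
        y = x.reshape(n, h, w, f, f, c).transpose(0, 1, 3, 2, 4, 5)
        return np.ascontiguousarray(y.reshape(n, h * f, w * f, c))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, hf, wf, c = grad.shape
        f = self.factor
        h, w = hf // f, wf // f
        g = grad.reshape(n, h, f, w, f, c).transpose(0, 1, 3, 2, 4, 5)
        return np.ascontiguousarray(g.reshape(n, h, w, c * f * f))


class _RDB(nn.Module):
    """One residual dense block."""

    def __init__(
        self, base: int, layers: int, growth: int, rng: np.random.Generator, name: str
    ) -> None:
        self.base = base
        self.growth = growth
        self.convs = [
            nn.Conv2d(base + j * growth, growth, 3, rng=rng, name=f"{name}.conv{j+1}")
            for j in range(layers)
        ]
        self.relus = [nn.ReLU() for _ in range(layers)]
        self.fusion = nn.Conv2d(
            base + layers * growth, base, 1, rng=rng, name=f"{name}.lff"
        )

    def forward(self, x0: np.ndarray) -> np.ndarray:
        feats = [x0]
        for conv, relu in zip(self.convs, self.relus):
            feats.append(relu.forward(conv.forward(np.concatenate(feats, axis=3))))
        out = self.fusion.forward(np.concatenate(feats, axis=3))
        self._widths = [f.shape[3] for f in feats]
        return out + x0  # local residual

    def backward(self, dout: np.ndarray) -> np.ndarray:
        widths = self._widths
        bounds = np.cumsum([0, *widths])
        dcat = self.fusion.backward(dout)
        grads = [
            np.ascontiguousarray(dcat[..., bounds[i] : bounds[i + 1]])
            for i in range(len(widths))
        ]
        for j in range(len(self.convs), 0, -1):
            din = self.convs[j - 1].backward(self.relus[j - 1].backward(grads[j]))
            for i in range(j):
                grads[i] = grads[i] + din[..., bounds[i] : bounds[i + 1]]
        return grads[0] + dout  # local residual path


class DeblurNetwork(TransformerMixin, BaseEstimator):
    """Residual-dense restoration network as a transformer estimator.

    ``fit(X, Y)`` takes paired blurred/sharp stacks of shape
    (N, in_channels, H, W) / (N, out_channels, H, W); ``transform(X)``
    returns restored stacks clipped to [0, 1]. ``in_channels=8`` is the
    guided configuration (7 stains + attention map); the output is always
    the 7 restored stain channels.
    """

    def __init__(
        self,
        n_blocks: int = 4,
        layers_per_block: int = 4,
        growth_rate: int = 16,
        base_channels: int = 32,
        in_channels: int = 7,
        out_channels: int = 7,
        guidance_channels: int = 0,
        upscale_factor: int = 1,
        residual_output: bool = True,
        epochs: int = 40,
        batch_size: int = 16,
        learning_rate: float = 2e-4,
        seed: int = 0,
    ) -> None:
        self.n_blocks = n_blocks
        self.layers_per_block = layers_per_block
        self.growth_rate = growth_rate
        self.base_channels = base_channels
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.guidance_channels = guidance_channels
        self.upscale_factor = upscale_factor
        self.residual_output = residual_output
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.seed = seed

    # -- construction -------------------------------------------------

    def _build(self) -> None:
        if self.n_blocks < 1:
            raise ValidationError(f"n_blocks must be >= 1, got {self.n_blocks}")
        if self.upscale_factor < 1:
            raise ValidationError(
                f"upscale_factor must be >= 1, got {self.upscale_factor}"
            )
        if self.residual_output and self.upscale_factor != 1:
            raise ValidationError(
                "residual_output requires upscale_factor == 1 (resolutions must match)"
            )
        if not 0 <= self.guidance_channels < self.in_channels:
            raise ValidationError(
                f"guidance_channels must be in [0, in_channels), got "
                f"{self.guidance_channels}"
            )
        rng = np.random.default_rng(self.seed)
        base = self.base_channels
        # widening init: draw the first conv for the primary channels only
        # (same RNG stream as the unguided net of identical seed/config) and
        # zero-init the guidance slice, so at initialization the guided net
        # computes exactly what the unguided net would — training then grows
        # the guidance weights only where the extra channel reduces the loss
        primary_in = self.in_channels - self.guidance_channels
        self._sfe1 = nn.Conv2d(primary_in, base, 3, rng=rng, name="sfe1")
        if self.guidance_channels:
            w = self._sfe1.W.value
            wz = np.concatenate(
                [w, np.zeros((3, 3, self.guidance_channels, base), w.dtype)], axis=2
            )
            self._sfe1.W = nn.Parameter(wz, name="sfe1.W")
            self._sfe1.in_channels = self.in_channels
        self._sfe2 = nn.Conv2d(base, base, 3, rng=rng, name="sfe2")
        self._blocks = [
            _RDB(base, self.layers_per_block, self.growth_rate, rng, f"rdb{i+1}")
            for i in range(self.n_blocks)
        ]
        self._gff = nn.Conv2d(base * self.n_blocks, base, 1, rng=rng, name="gff")
        f = self.upscale_factor
        # with a residual output the head starts at zero so that the
        # initial restoration is exactly the identity
        zi = self.residual_output
        if f == 1:
            self._head = nn.Conv2d(
                base, self.out_channels, 3, rng=rng, name="head", zero_init=zi
            )
            self._shuffle = None
        else:
            self._head = nn.Conv2d(
                base, self.out_channels * f * f, 3, rng=rng, name="head"
            )
            self._shuffle = _PixelShuffle(f)

    def _modules(self) -> list[nn.Module]:
        return [self._sfe1, self._sfe2, *self._blocks, self._gff, self._head]

    def parameters(self) -> list[nn.Parameter]:
        params: list[nn.Parameter] = []
        for m in self._modules():
            params.extend(m.parameters())
        return params

    # -- forward / backward -------------------------------------------

    def _forward(self, x: np.ndarray) -> np.ndarray:
        """Channels-last forward: (N, H, W, in_channels) -> (N, H, W, out)."""
        if x.shape[3] != self.in_channels:
            raise ValidationError(
                f"expected {self.in_channels} input channels, got {x.shape[3]}"
            )
        f0 = self._sfe2.forward(self._sfe1.forward(x))
        outs = []
        cur = f0
        for block in self._blocks:
            cur = block.forward(cur)
            outs.append(cur)
        fused = self._gff.forward(np.concatenate(outs, axis=3))
        fdf = fused + f0  # global residual
        out = self._head.forward(fdf)
        if self._shuffle is not None:
            out = self._shuffle.forward(out)
        if self.residual_output:
            # predict a correction on top of the (blurred) stain channels;
            # identity restoration is then the no-op starting point
            out = out + x[..., : self.out_channels]
        return out

    def _backward(self, dout: np.ndarray) -> None:
        if self._shuffle is not None:
            dout = self._shuffle.backward(dout)
        dfdf = self._head.backward(dout)
        base = self.base_channels
        dcat = self._gff.backward(dfdf)
        carry = np.zeros_like(dfdf)
        for i in range(self.n_blocks - 1, -1, -1):
            d = dcat[..., i * base : (i + 1) * base] + carry
            carry = self._blocks[i].backward(np.ascontiguousarray(d))
        df0 = carry + dfdf  # global residual path
        self._sfe1.backward(self._sfe2.backward(df0))

    # -- sklearn API ---------------------------------------------------

    def fit(
        self,
        X: np.ndarray,
        y: np.ndarray,
        X_val: np.ndarray | None = None,
        y_val: np.ndarray | None = None,
    ) -> "DeblurNetwork":
        """Train on paired (blurred, sharp) stacks by MSE + Adam."""
        X = np.asarray(X, dtype=np.float32)
        Y = np.asarray(y, dtype=np.float32)
        if X.shape[0] == 0:
            raise ValidationError("empty training pair list")
        if X.shape[0] != Y.shape[0]:
            raise ValidationError("blurred/sharp pair count mismatch")
        f = self.upscale_factor
        if Y.shape[2:] != (X.shape[2] * f, X.shape[3] * f):
            raise ValidationError(
                f"target spatial size {Y.shape[2:]} != input x factor "
                f"{(X.shape[2] * f, X.shape[3] * f)}"
            )
        self._build()
        Xn, Yn = nn.to_nhwc(X), nn.to_nhwc(Y)
        self.loss_history_ = []
        self.val_loss_history_ = []
        rng = np.random.default_rng(self.seed + 1)
        if self.epochs > 0:
            opt = nn.Adam(self.parameters(), lr=self.learning_rate)
            n = Xn.shape[0]
            for _ in range(self.epochs):
                perm = rng.permutation(n)
                total = 0.0
                for start in range(0, n, self.batch_size):
                    idx = perm[start : start + self.batch_size]
                    pred = self._forward(Xn[idx])
                    loss, grad = nn.mse_loss(pred, Yn[idx])
                    opt.zero_grad()
                    self._backward(grad)
                    opt.step()
                    total += loss * len(idx)
                self.loss_history_.append(total / n)
                if X_val is not None:
                    restored = self.transform(X_val)
                    self.val_loss_history_.append(
                        float(np.mean((restored - np.asarray(y_val, np.float32)) ** 2))
                    )
        self.n_parameters_ = sum(p.size for p in self.parameters())
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Restore stacks; output clipped to [0, 1]."""
        if not hasattr(self, "_sfe1"):
            raise ValidationError("de-blurring model is not fitted")
        X = np.asarray(X, dtype=np.float32)
        single = X.ndim == 3
        if single:
            X = X[None]
        out = []
        for start in range(0, X.shape[0], 64):
            restored = self._forward(nn.to_nhwc(X[start : start + 64]))
            out.append(np.clip(nn.to_nchw(restored), 0.0, 1.0))
        result = np.concatenate(out, axis=0)
        return result[0] if single else result

    def weight_checksum(self) -> float:
        return float(
            sum(
                np.float64(i + 1) * np.abs(p.value).sum()
                for i, p in enumerate(self.parameters())
            )
        )


def expected_parameter_count(
    n_blocks: int,
    layers_per_block: int,
    growth_rate: int,
    base_channels: int,
    in_channels: int = 7,
    out_channels: int = 7,
    upscale_factor: int = 1,
) -> int:
    """Closed-form parameter total from the dense-concatenation recurrence.

    Independent of the network classes: every 3x3 conv contributes
    ``9*c_in*c_out + c_out``, every 1x1 fusion ``c_in*c_out + c_out``, with
    layer j of a block seeing ``base + (j-1)*growth`` input channels.
    """
    b, g = base_channels, growth_rate
    total = 9 * in_channels * b + b  # sfe1
    total += 9 * b * b + b  # sfe2
    per_block = sum(9 * (b + j * g) * g + g for j in range(layers_per_block))
    per_block += (b + layers_per_block * g) * b + b  # 1x1 local fusion
    total += n_blocks * per_block
    total += (n_blocks * b) * b + b  # 1x1 global fusion
    head_out = out_channels * upscale_factor**2
    total += 9 * b * head_out + head_out
    return total
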