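"""Detail-preserving building blocks of the detector.

Three primitives live here:

* **space-to-depth** — a lossless downsampling that slices every
  ``scale x scale`` spatial block into channels, so no pixel is discarded
  the way a strided convolution discards them;
* **the non-strided ghost convolution block** — a cheap feature mixer
  producing half its outputs with a pointwise convolution and the other
  half with a light grouped 5x5 transform of that primary half.  Together
  with space-to-depth it forms the ADEConv downsampling unit that replaces
  every strided convolution in the detector backbone;
* **AAFS** — an attention gate that combines a squeeze-excite style
  channel branch with a channel-pooled spatial branch, mixes the result
  with the input via channel shuffle and a grouped convolution, and emits
  a sigmoid weight map used to rescale fused pyramid features.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import nn
from .nn import tensor as T


# ---------------------------------------------------------------------------
# configs

@dataclass
class ADEConvConfig:
    """Shape parameters of one ADEConv downsampling unit.

    ``cheap_groups=None`` means depthwise (groups = out_channels//2), the
    ghost-convolution convention.
    """

    in_channels: int
    out_channels: int
    scale: int = 2
    cheap_kernel: int = 5
    cheap_groups: int | None = None

    def __post_init__(self):
        if self.out_channels % 2:
            raise ValueError(
                f"out_channels must be even (ghost split), got {self.out_channels}")
        if self.scale < 1:
            raise ValueError("scale must be positive")
        if self.cheap_kernel % 2 == 0:
            raise ValueError("cheap_kernel must be odd")
        if self.cheap_groups is None:
            self.cheap_groups = self.out_channels // 2


@dataclass
class AAFSConfig:
    """Shape parameters of one AAFS gate on a C-channel feature map."""

    channels: int
    reduction: int = 4
    gate_kernel: int = 7
    gate_groups: int = 2
    shuffle_groups: int = 2
    spatial_out_channels: int = 1

    def __post_init__(self):
        if self.channels % self.reduction:
            raise ValueError(
                f"channels={self.channels} not divisible by reduction={self.reduction}")
        if (2 * self.channels) % self.shuffle_groups:
            raise ValueError("2*channels must divide by shuffle_groups")
        if self.gate_kernel % 2 == 0:
            raise ValueError("gate_kernel must be odd")


# ---------------------------------------------------------------------------
# space-to-depth

def space_to_depth(x, scale: int = 2):
    """Rearrange scale x scale spatial blocks into channels.

    The output channel order is the concatenation of the slices
    ``f[h,w] = x[..., h::scale, w::scale]`` taken row-major over (h, w):
    f00, f01, ..., f(s-1)(s-1).  A pure permutation: every input value
    appears exactly once in the output.
    """
    n, c, h, w = x.shape
    if h % scale:
        raise ValueError(
            f"height {h} not divisible by space-to-depth scale {scale}")
    if w % scale:
        raise ValueError(
            f"width {w} not divisible by space-to-depth scale {scale}")
    if T.is_probe(x):
        return T.ShapeProbe((n, scale * scale * c, h // scale, w // scale))
    slices = [x[:, :, i::scale, j::scale]
              for i in range(scale) for j in range(scale)]
    return T.concat(slices, axis=1)


def space_to_depth_inverse(x, scale: int = 2):
    """Exact inverse of :func:`space_to_depth` (bit-exact round trip)."""
    n, c4, hh, ww = x.shape
    if c4 % (scale * scale):
        raise ValueError(f"channels {c4} not divisible by scale^2")
    c = c4 // (scale * scale)
    # (N, s*s*C, H', W') -> (N, s, s, C, H', W') -> interleave
    y = T.reshape(x, (n, scale, scale, c, hh, ww))
    y = T.transpose(y, (0, 3, 4, 1, 5, 2))  # N, C, H', s, W', s
    return T.reshape(y, (n, c, hh * scale, ww * scale))


def channel_shuffle(x, groups: int):
    """Reindex channels by reshape-(g, C/g)-transpose-flatten; values untouched."""
    n, c, h, w = x.shape
    if c % groups:
        raise ValueError(f"channels {c} not divisible by groups {groups}")
    if groups == 1:
        return x
    y = T.reshape(x, (n, groups, c // groups, h, w))
    y = T.transpose(y, (0, 2, 1, 3, 4))
    return T.reshape(y, (n, c, h, w))


# ---------------------------------------------------------------------------
# ghost block & ADEConv

class GhostBlock(nn.Module):
    """Non-strided ghost convolution: 1x1 primary to C2/2 channels, then a
    grouped ``cheap_kernel`` transform of that primary output; the two
    halves are concatenated (cheap half first) to give C2 channels.  The
    primary output is computed once and reused by both halves."""

    def __init__(self, cfg: ADEConvConfig):
        super().__init__()
        self.cfg = cfg
        half = cfg.out_channels // 2
        cin = cfg.scale ** 2 * cfg.in_channels
        self.primary = nn.ConvBNAct(cin, half, kernel=1)
        self.cheap = nn.ConvBNAct(half, half, kernel=cfg.cheap_kernel,
                                  groups=cfg.cheap_groups)

    def forward(self, x):
        y = self.primary(x)
        return T.concat([self.cheap(y), y], axis=1)


class ADEConv(nn.Module):
    """Detail-preserving downsampling: space-to-depth followed by the
    non-strided ghost block.  (N, C1, H, W) -> (N, C2, H/s, W/s) with no
    stride-2 convolution anywhere inside."""

    def __init__(self, cfg: ADEConvConfig):
        super().__init__()
        self.cfg = cfg
        self.ghost = GhostBlock(cfg)

    def forward(self, x):
        return self.ghost(space_to_depth(x, self.cfg.scale))


# ---------------------------------------------------------------------------
# AAFS

class AAFS(nn.Module):
    """Attention-guided adaptive feature selection gate.

    ``forward`` returns the gated feature ``W * x`` where the weight map

        W = sigmoid( GC_k( shuffle( concat[x, W_c + W_s] ) ) )

    combines a channel branch W_c (spatial global-average pool ->
    1x1 reduce by r -> ReLU -> 1x1 expand; shape (N, C, 1, 1)) and a
    spatial branch W_s (channel mean & max -> k_s x k_s convolution;
    shape (N, 1, H, W) by default), broadcast-added.  The grouped gate
    convolution maps 2C -> C so W has the shape of x, every element in
    (0, 1).  The three weight-producing convolutions carry bias and no
    batch norm, so a zero-initialized gate yields exactly W = 0.5.
    """

    def __init__(self, cfg: AAFSConfig):
        super().__init__()
        self.cfg = cfg
        c, r = cfg.channels, cfg.reduction
        self.fc_reduce = nn.Conv2d(c, c // r, kernel=1)
        self.fc_expand = nn.Conv2d(c // r, c, kernel=1)
        self.spatial_conv = nn.Conv2d(2, cfg.spatial_out_channels,
                                      kernel=cfg.gate_kernel)
        self.gate_conv = nn.Conv2d(2 * c, c, kernel=cfg.gate_kernel,
                                   groups=cfg.gate_groups)
        # neutral start: a zeroed gate emits W = 0.5 everywhere, so stacked
        # gates begin as uniform half-scalings instead of random masks
        self.gate_conv.weight.data[...] = 0.0
        self.gate_conv.bias.data[...] = 0.0

    def channel_weights(self, x):
        """W_c: squeeze-excite channel descriptor, shape (N, C, 1, 1)."""
        pooled = T.tmean(x, axis=(2, 3), keepdims=True)
        return self.fc_expand(T.relu(self.fc_reduce(pooled)))

    def spatial_weights(self, x):
        """W_s: convolution over the [channel-mean, channel-max] pair."""
        mean = T.tmean(x, axis=1, keepdims=True)
        mx = T.tmax(x, axis=1, keepdims=True)
        return self.spatial_conv(T.concat([mean, mx], axis=1))

    def gate(self, x):
        """The sigmoid fusion-weight map W, same shape as x."""
        wc = self.channel_weights(x)
        ws = self.spatial_weights(x)
        fused = T.add(wc, ws)  # broadcast (N,C,1,1)+(N,1,H,W) -> (N,C,H,W)
        if not T.is_probe(x):
            assert fused.shape == x.shape, (fused.shape, x.shape)
        z = T.concat([x, fused], axis=1)
        z = channel_shuffle(z, self.cfg.shuffle_groups)
        return T.sigmoid(self.gate_conv(z))

    def forward(self, x):
        return T.mul(self.gate(x), x)


def zero_init_gate(aafs: AAFS) -> None:
    """Zero the gate convolution so W == 0.5 everywhere (test/diagnostic aid)."""
    aafs.gate_conv.weight.data[...] = 0.0
    aafs.gate_conv.bias.data[...] = 0.0
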