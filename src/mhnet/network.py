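"""The MHNet registration architecture.

A fully convolutional encoder-decoder that maps the channel-concatenated
reference/moving pair (2, X, Y, Z) to a dense displacement field
(3, X, Y, Z), with two additions over the plain U-Net shape:

* a multiscale Inception stem — parallel 3D conv branches with kernels
  1/3/5/7 (channel-concatenated), each large-kernel branch preceded by a
  1x1x1 bottleneck that cuts its parameter count;
* a hierarchical forecast structure — the three coarsest decoder maps are
  trilinearly upsampled to full resolution (factors 8, 4, 2), convolved to
  3-channel intermediate fields (phi_low / phi_mid / phi_high), and fused
  with the end-of-decoder field by a 1x1x1 conv into phi_final.

Four stride-2 encoder levels reduce the grid to 1/16 of the input, so all
spatial dimensions must be divisible by 16.  Every feature conv is followed
by a LeakyReLU; field-producing convs are linear and zero-initialized so an
untrained network is exactly the identity transform.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

from .autodiff import Tensor, concat, conv3d, leaky_relu, upsample3
from .volumes import DisplacementField, Volume

__all__ = [
    "NetworkConfig",
    "ForecastFields",
    "Conv3dLayer",
    "InceptionBlock",
    "MHNet",
    "build_network",
    "forward",
    "count_inception_params",
]


@dataclass
class NetworkConfig:
    """Architecture hyperparameters (the source description leaves the
    channel widths open; these defaults are VoxelMorph-scale)."""

    enc_channels: tuple = (16, 32, 32, 32)
    dec_channels: tuple = (32, 32, 32, 16)
    inception_branch_out: int = 4
    inception_kernels: tuple = (1, 3, 5, 7)
    bottleneck_channels: int = 1
    use_bottleneck: bool = True
    leaky_slope: float = 0.2
    use_inception: bool = True
    use_hierarchical: bool = True

    def __post_init__(self):
        self.enc_channels = tuple(int(c) for c in self.enc_channels)
        self.dec_channels = tuple(int(c) for c in self.dec_channels)
        self.inception_kernels = tuple(int(k) for k in self.inception_kernels)
        if len(self.enc_channels) != 4 or len(self.dec_channels) != 4:
            raise ValueError("enc_channels and dec_channels must list 4 levels")
        if any(c < 1 for c in self.enc_channels + self.dec_channels):
            raise ValueError("channel counts must be positive")
        if any(k < 1 or k % 2 == 0 for k in self.inception_kernels):
            raise ValueError("inception kernels must be odd and positive")
        if self.inception_branch_out < 1 or self.bottleneck_channels < 1:
            raise ValueError("channel counts must be positive")
        if not (0.0 < self.leaky_slope < 1.0):
            raise ValueError("leaky_slope must lie in (0, 1)")

    @property
    def stem_out_channels(self) -> int:
        return self.inception_branch_out * len(self.inception_kernels)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        return cls(**d)


@dataclass
class ForecastFields:
    """The intermediate, end and fused displacement predictions."""

    phi_low: object
    phi_mid: object
    phi_high: object
    phi_end: object
    phi_final: object


def count_inception_params(
    cfg: NetworkConfig | None = None,
    with_bottleneck: bool = True,
    in_channels: int = 2,
) -> int:
    """Bias-free parameter count of the Inception stem.

    Each branch with cubic kernel k holds C_in * k^3 * C_out weights; with
    the bottleneck, a k > 1 branch instead holds C_in * C_in' (the 1x1x1
    reduction) plus C_in' * k^3 * C_out.  The 1x1x1 branch never carries a
    bottleneck (it is already the cheapest reduction).
    """
    cfg = cfg or NetworkConfig()
    c_out = cfg.inception_branch_out
    c_b = cfg.bottleneck_channels
    total = 0
    for k in cfg.inception_kernels:
        if k == 1 or not with_bottleneck:
            total += in_channels * k**3 * c_out
        else:
            total += in_channels * c_b + c_b * k**3 * c_out
    return int(total)


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

class Conv3dLayer:
    """A 3D conv with learnable weight/bias and 'same' padding."""

    def __init__(self, c_in, c_out, k, stride=1, rng=None, init="he",
                 slope=0.2, bias=True, dtype=np.float32):
        shape = (c_out, c_in, k, k, k)
        if isinstance(init, np.ndarray):
            w = init
        elif init == "he":
            fan_in = c_in * k**3
            gain = np.sqrt(2.0 / (1.0 + slope**2))
            w = rng.normal(0.0, gain / np.sqrt(fan_in), size=shape)
        elif init == "zeros":
            w = np.zeros(shape)
        else:
            raise ValueError(f"unknown init {init!r}")
        self.stride = stride
        self.weight = Tensor(np.asarray(w, dtype=dtype), requires_grad=True)
        self.bias = (
            Tensor(np.zeros(c_out, dtype=dtype), requires_grad=True) if bias else None
        )

    def __call__(self, x):
        return conv3d(x, self.weight, self.bias, stride=self.stride)

    def parameters(self):
        return [self.weight] + ([self.bias] if self.bias is not None else [])

    def n_weights(self, include_bias=False):
        n = self.weight.data.size
        if include_bias and self.bias is not None:
            n += self.bias.data.size
        return int(n)


class InceptionBlock:
    """Parallel multiscale conv branches, channel-concatenated.

    Branch kernels come from ``cfg.inception_kernels``; every branch with
    kernel > 1 is preceded by a 1x1x1 bottleneck when ``cfg.use_bottleneck``
    is set.  Spatial shape is preserved by 'same' padding.
    """

    def __init__(self, in_channels, cfg: NetworkConfig, rng, dtype=np.float32):
        self.slope = cfg.leaky_slope
        self.branches = []
        for k in cfg.inception_kernels:
            convs = []
            c = in_channels
            if k > 1 and cfg.use_bottleneck:
                convs.append(
                    Conv3dLayer(c, cfg.bottleneck_channels, 1, rng=rng,
                                slope=self.slope, dtype=dtype)
                )
                c = cfg.bottleneck_channels
            convs.append(
                Conv3dLayer(c, cfg.inception_branch_out, k, rng=rng,
                            slope=self.slope, dtype=dtype)
            )
            self.branches.append(convs)

    def __call__(self, x):
        outs = []
        for convs in self.branches:
            h = x
            for conv in convs:
                h = leaky_relu(conv(h), self.slope)
            outs.append(h)
        return concat(outs, axis=0)

    def parameters(self):
        return [p for convs in self.branches for c in convs for p in c.parameters()]

    def param_count(self, include_bias=False) -> int:
        return sum(
            c.n_weights(include_bias) for convs in self.branches for c in convs
        )


def _fusion_init(n_fields: int, dtype) -> np.ndarray:
    """1x1x1 kernel that averages the d-th component of every input field."""
    w = np.zeros((3, 3 * n_fields, 1, 1, 1), dtype=dtype)
    for i in range(n_fields):
        for d in range(3):
            w[d, 3 * i + d, 0, 0, 0] = 1.0 / n_fields
    return w


class MHNet:
    """The full registration network; see the module docstring."""

    def __init__(self, cfg: NetworkConfig | None = None, seed: int = 0,
                 dtype=np.float32):
        self.cfg = cfg = cfg or NetworkConfig()
        self.dtype = dtype
        rng = np.random.default_rng(seed)
        slope = cfg.leaky_slope
        stem_out = cfg.stem_out_channels
        if cfg.use_inception:
            self.stem = InceptionBlock(2, cfg, rng, dtype=dtype)
        else:
            # ablation: a single plain 3x3x3 conv with matching channels
            self.stem = Conv3dLayer(2, stem_out, 3, rng=rng, slope=slope,
                                    dtype=dtype)

        self.enc = []
        c = stem_out
        for ch in cfg.enc_channels:
            down = Conv3dLayer(c, ch, 3, stride=2, rng=rng, slope=slope, dtype=dtype)
            keep = Conv3dLayer(ch, ch, 3, stride=1, rng=rng, slope=slope, dtype=dtype)
            self.enc.append((down, keep))
            c = ch

        skip_channels = [cfg.enc_channels[2], cfg.enc_channels[1],
                         cfg.enc_channels[0], stem_out]
        self.dec = []
        c = cfg.enc_channels[3]
        for ch, skip in zip(cfg.dec_channels, skip_channels):
            self.dec.append(
                Conv3dLayer(c + skip, ch, 3, rng=rng, slope=slope, dtype=dtype)
            )
            c = ch

        self.end_head = Conv3dLayer(cfg.dec_channels[3], 3, 3, init="zeros",
                                    dtype=dtype)
        if cfg.use_hierarchical:
            self.heads = [
                Conv3dLayer(cfg.dec_channels[i], 3, 3, init="zeros", dtype=dtype)
                for i in range(3)
            ]
            self.fusion = Conv3dLayer(12, 3, 1, init=_fusion_init(4, dtype),
                                      dtype=dtype)
        else:
            self.heads = []
            self.fusion = None

    # -- parameter access ---------------------------------------------------
    def parameters(self):
        params = list(self.stem.parameters())
        for down, keep in self.enc:
            params += down.parameters() + keep.parameters()
        for conv in self.dec:
            params += conv.parameters()
        params += self.end_head.parameters()
        for h in self.heads:
            params += h.parameters()
        if self.fusion is not None:
            params += self.fusion.parameters()
        return params

    def state_arrays(self):
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays):
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError("checkpoint parameter count mismatch")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError("checkpoint parameter shape mismatch")
            p.data = np.asarray(a, dtype=self.dtype)

    # -- forward ------------------------------------------------------------
    def _check_input(self, shape):
        if any(s % 16 != 0 for s in shape):
            raise ValueError(
                f"input spatial shape {tuple(shape)} must be divisible by 16 "
                "(four stride-2 encoder levels)"
            )

    def forward_graph(self, x: Tensor) -> ForecastFields:
        """Run the network on a (2, X, Y, Z) tensor; fields are tensors."""
        if x.shape[0] != 2:
            raise ValueError(f"expected 2 input channels, got {x.shape[0]}")
        self._check_input(x.shape[1:])
        slope = self.cfg.leaky_slope

        s = self.stem(x)
        if not self.cfg.use_inception:
            s = leaky_relu(s, slope)
        skips = [s]
        h = s
        for down, keep in self.enc:
            h = leaky_relu(down(h), slope)
            h = leaky_relu(keep(h), slope)
            skips.append(h)

        dec_maps = []
        h = skips[4]
        for i, conv in enumerate(self.dec):
            h = upsample3(h, 2)
            h = concat([h, skips[3 - i]], axis=0)
            h = leaky_relu(conv(h), slope)
            dec_maps.append(h)

        phi_end = self.end_head(dec_maps[3])
        if self.cfg.use_hierarchical:
            phi_low = self.heads[0](upsample3(dec_maps[0], 8))
            phi_mid = self.heads[1](upsample3(dec_maps[1], 4))
            phi_high = self.heads[2](upsample3(dec_maps[2], 2))
            phi_final = self.fusion(
                concat([phi_low, phi_mid, phi_high, phi_end], axis=0)
            )
        else:
            phi_low = phi_mid = phi_high = phi_end
            phi_final = phi_end
        return ForecastFields(phi_low, phi_mid, phi_high, phi_end, phi_final)

    def predict_field(self, f_data: np.ndarray, m_data: np.ndarray) -> np.ndarray:
        """Deterministic forward pass returning phi_final as an array."""
        x = Tensor(np.stack([f_data, m_data]).astype(self.dtype))
        return self.forward_graph(x).phi_final.data


def build_network(cfg: NetworkConfig | None = None, seed: int = 0,
                  dtype=np.float32) -> MHNet:
    return MHNet(cfg, seed=seed, dtype=dtype)


def forward(net: MHNet, f: Volume, m: Volume) -> ForecastFields:
    """Forward pass on Volumes, returning DisplacementFields."""
    if f.shape != m.shape:
        raise ValueError(f"shape mismatch: {f.shape} vs {m.shape}")
    x = Tensor(np.stack([f.data, m.data]).astype(net.dtype))
    fields = net.forward_graph(x)
    to_field = lambda t: DisplacementField(t.data.astype(np.float32))
    return ForecastFields(
        to_field(fields.phi_low),
        to_field(fields.phi_mid),
        to_field(fields.phi_high),
        to_field(fields.phi_end),
        to_field(fields.phi_final),
    )
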