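"""Dual ResUNet: two bridged residual U-Nets for foreground-ISV segmentation.

The architecture couples two encoder--decoder sub-networks. Each sub-network
is a U-Net whose convolutional blocks are full pre-activation residual units
(BN -> ReLU -> 3x3 conv, twice, added to an identity path). Downsampling is
2x2 max pooling with stride 2; each encoder unit doubles the feature
channels. Upsampling is a 2x2 stride-2 transposed convolution that halves
the channels, followed by BN and ReLU. Encoder-to-decoder skips within a
sub-network are element-wise additions. The two sub-networks are *bridged*:
every decoder level of the first network is concatenated channel-wise into
the same-resolution encoder level of the second network (a 1x1 convolution
restores the expected channel count, so the second network's units are
unchanged by bridging). A final 1x1 convolution and an element-wise sigmoid
produce two per-pixel probability maps, one for the ISV class and one for
the non-ISV class.

Variants differ in the total number of residual units (10 / 14 / 18, split
equally across the two sub-networks and symmetrically across encoder and
decoder), in using plain double-convolution units instead of residual ones
(``dual_unet_14``), or in dropping the second network (``single_resunet``).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import nn
from .nn import Tensor

__all__ = [
    "NetworkConfig",
    "Network",
    "UnitInfo",
    "build_residual_unit",
    "build_network",
    "forward",
    "predict_mask",
    "fuse_feature_maps",
    "param_count",
    "save_checkpoint",
    "load_checkpoint",
    "VARIANTS",
]

# variant -> (units per sub-net encoder side, number of sub-nets, residual?)
# total units = n_nets * (2 * depth + 1): encoder levels + bottleneck + decoder
VARIANTS = {
    "dual_resunet_10": {"depth": 2, "n_nets": 2, "residual": True},
    "dual_resunet_14": {"depth": 3, "n_nets": 2, "residual": True},
    "dual_resunet_18": {"depth": 4, "n_nets": 2, "residual": True},
    "dual_unet_14": {"depth": 3, "n_nets": 2, "residual": False},
    "single_resunet": {"depth": 3, "n_nets": 1, "residual": True},
}


@dataclass
class NetworkConfig:
    variant: str = "dual_resunet_14"
    base_channels: int = 32
    in_channels: int = 1
    out_channels: int = 2

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; "
                             f"choose from {sorted(VARIANTS)}")
        if self.base_channels < 1:
            raise ValueError("base_channels must be >= 1")

    @property
    def depth(self) -> int:
        return VARIANTS[self.variant]["depth"]

    @property
    def unit_count(self) -> int:
        v = VARIANTS[self.variant]
        return v["n_nets"] * (2 * v["depth"] + 1)


@dataclass(frozen=True)
class UnitInfo:
    """Descriptor of one convolutional unit in the built graph."""
    net: int          # 1 or 2
    stage: str        # "encoder" | "bottleneck" | "decoder"
    level: int        # resolution level (0 = full resolution)
    in_ch: int
    out_ch: int


class ResidualUnit(nn.Module):
    """Full pre-activation residual unit.

    Computes ``x + F(x)`` with ``F = BN -> ReLU -> 3x3 conv -> BN -> ReLU ->
    3x3 conv`` (zero padding keeps the spatial size). When the channel count
    changes, a 1x1 convolution projects the identity path.
    """

    def __init__(self, in_ch: int, out_ch: int):
        super().__init__()
        self.bn1 = nn.BatchNorm2d(in_ch)
        self.conv1 = nn.Conv2d(in_ch, out_ch, 3, padding=1)
        self.bn2 = nn.BatchNorm2d(out_ch)
        self.conv2 = nn.Conv2d(out_ch, out_ch, 3, padding=1)
        self.proj = nn.Conv2d(in_ch, out_ch, 1) if in_ch != out_ch else None

    def __call__(self, x: Tensor) -> Tensor:
        h = self.conv1(nn.relu(self.bn1(x)))
        h = self.conv2(nn.relu(self.bn2(h)))
        identity = self.proj(x) if self.proj is not None else x
        return identity + h


class PlainUnit(nn.Module):
    """Original-flavour U-Net block: (3x3 conv -> BN -> ReLU) twice."""

    def __init__(self, in_ch: int, out_ch: int):
        super().__init__()
        self.conv1 = nn.Conv2d(in_ch, out_ch, 3, padding=1)
        self.bn1 = nn.BatchNorm2d(out_ch)
        self.conv2 = nn.Conv2d(out_ch, out_ch, 3, padding=1)
        self.bn2 = nn.BatchNorm2d(out_ch)

    def __call__(self, x: Tensor) -> Tensor:
        h = nn.relu(self.bn1(self.conv1(x)))
        return nn.relu(self.bn2(self.conv2(h)))


def build_residual_unit(in_ch: int, out_ch: int) -> ResidualUnit:
    """Stand-alone constructor for a full pre-activation residual unit."""
    if in_ch < 1 or out_ch < 1:
        raise ValueError("channel counts must be >= 1")
    return ResidualUnit(in_ch, out_ch)


class Upsample(nn.Module):
    """2x2 stride-2 transposed convolution halving channels, then BN + ReLU."""

    def __init__(self, in_ch: int, out_ch: int):
        super().__init__()
        self.deconv = nn.ConvTranspose2d(in_ch, out_ch)
        self.bn = nn.BatchNorm2d(out_ch)

    def __call__(self, x: Tensor) -> Tensor:
        return nn.relu(self.bn(self.deconv(x)))


class _SubNet(nn.Module):
    """One residual U-Net; optionally accepts bridged features per level."""

    def __init__(self, cfg: NetworkConfig, net_index: int, bridged: bool,
                 registry: list[UnitInfo]):
        super().__init__()
        d = cfg.depth
        c = cfg.base_channels
        unit_cls = ResidualUnit if VARIANTS[cfg.variant]["residual"] else PlainUnit
        self.depth = d
        self.bridged = bridged

        enc_in = [cfg.in_channels] + [c * 2 ** (i - 1) for i in range(1, d)]
        enc_out = [c * 2 ** i for i in range(d)]
        for i in range(d):
            setattr(self, f"enc{i}", unit_cls(enc_in[i], enc_out[i]))
            registry.append(UnitInfo(net_index, "encoder", i, enc_in[i], enc_out[i]))
            if bridged:
                # concat of the incoming feature with net 1's decoder output
                # at this level (c * 2**i channels), projected back
                setattr(self, f"bridge{i}",
                        nn.Conv2d(enc_in[i] + c * 2 ** i, enc_in[i], 1))
        self.bottleneck = unit_cls(c * 2 ** (d - 1), c * 2 ** d)
        registry.append(UnitInfo(net_index, "bottleneck", d,
                                 c * 2 ** (d - 1), c * 2 ** d))
        for i in reversed(range(d)):
            setattr(self, f"up{i}", Upsample(c * 2 ** (i + 1), c * 2 ** i))
            setattr(self, f"dec{i}", unit_cls(c * 2 ** i, c * 2 ** i))
            registry.append(UnitInfo(net_index, "decoder", i,
                                     c * 2 ** i, c * 2 ** i))

    def __call__(self, x: Tensor, bridge_feats: list[Tensor] | None = None):
        d = self.depth
        skips = []
        h = x
        for i in range(d):
            if self.bridged:
                h = getattr(self, f"bridge{i}")(nn.concat([h, bridge_feats[i]], axis=1))
            h = getattr(self, f"enc{i}")(h)
            skips.append(h)
            h = nn.maxpool2x2(h)
        h = self.bottleneck(h)
        dec_feats: list[Tensor | None] = [None] * d
        for i in reversed(range(d)):
            h = getattr(self, f"up{i}")(h)
            h = h + skips[i]
            h = getattr(self, f"dec{i}")(h)
            dec_feats[i] = h
        return h, dec_feats


class Network(nn.Module):
    """The built computation graph holding all trainable weights."""

    def __init__(self, config: NetworkConfig):
        super().__init__()
        self.config = config
        self.unit_registry: list[UnitInfo] = []
        n_nets = VARIANTS[config.variant]["n_nets"]
        self.net1 = _SubNet(config, 1, bridged=False, registry=self.unit_registry)
        if n_nets == 2:
            self.net2 = _SubNet(config, 2, bridged=True, registry=self.unit_registry)
        else:
            self.net2 = None
        self.head = nn.Conv2d(config.base_channels, config.out_channels, 1)

    def _check_input(self, x: np.ndarray):
        d = self.config.depth
        if x.ndim != 4:
            raise ValueError("input must be (N, C, H, W)")
        if x.shape[1] != self.config.in_channels:
            raise ValueError(f"expected {self.config.in_channels} input "
                             f"channel(s), got {x.shape[1]}")
        h, w = x.shape[2:]
        if h % 2 ** d or w % 2 ** d:
            raise ValueError(f"input spatial size {h}x{w} must be divisible "
                             f"by 2^depth = {2 ** d}")

    def __call__(self, x) -> Tensor:
        data = x.data if isinstance(x, Tensor) else np.asarray(x, dtype=np.float64)
        self._check_input(data)
        t = x if isinstance(x, Tensor) else Tensor(data)
        h1, dec_feats = self.net1(t)
        if self.net2 is not None:
            h2, _ = self.net2(t, bridge_feats=dec_feats)
        else:
            h2 = h1
        return nn.sigmoid(self.head(h2))


def build_network(config: NetworkConfig) -> Network:
    net = Network(config)
    assert len(net.unit_registry) == config.unit_count
    return net


def forward(network: Network, batch: np.ndarray) -> np.ndarray:
    """Run a batch through the network, returning probability maps
    (N, out_channels, H, W) as a plain array. Channel 0 is the ISV class."""
    return network(batch).data


def predict_mask(prob_maps: np.ndarray) -> np.ndarray:
    """Decision rule over the two sigmoid maps: a pixel is ISV iff the ISV
    probability strictly exceeds the non-ISV probability (ties -> non-ISV)."""
    return (prob_maps[..., 0, :, :] > prob_maps[..., 1, :, :]).astype(np.uint8)


def param_count(network: Network) -> int:
    return sum(p.data.size for p in network.parameters())


# ---------------------------------------------------------------------------
# Optional multi-level fusion head
# ---------------------------------------------------------------------------

def bilinear_resize(arr: np.ndarray, out_shape: tuple[int, int]) -> np.ndarray:
    """Bilinear resampling of the trailing two axes, aligning the corner
    pixels of the input and output grids."""
    h, w = arr.shape[-2:]
    oh, ow = out_shape
    rows = np.linspace(0, h - 1, oh) if oh > 1 else np.zeros(1)
    cols = np.linspace(0, w - 1, ow) if ow > 1 else np.zeros(1)
    r0 = np.clip(np.floor(rows).astype(int), 0, max(h - 2, 0))
    c0 = np.clip(np.floor(cols).astype(int), 0, max(w - 2, 0))
    fr = (rows - r0)[:, None]
    fc = (cols - c0)[None, :]
    if h == 1:
        top = bot = arr[..., 0, :]
    else:
        top, bot = arr[..., r0, :], arr[..., r0 + 1, :]
    def _cols(a):
        if w == 1:
            return a[..., 0][..., None] * np.ones(ow)
        return a[..., c0] * (1 - fc) + a[..., c0 + 1] * fc
    return _cols(top) * (1 - fr) + _cols(bot) * fr


def fuse_feature_maps(feature_maps: list[np.ndarray],
                      fusion_weights: list[float],
                      out_shape: tuple[int, int] | None = None) -> np.ndarray:
    """Weighted linear combination of multi-resolution response maps.

    Each map is bilinearly upsampled to ``out_shape`` (default: the largest
    map's shape) and the maps are summed with the given per-level scalar
    weights, yielding an auxiliary full-resolution prediction map.
    """
    if not feature_maps:
        raise ValueError("feature_maps must be non-empty")
    if len(fusion_weights) != len(feature_maps):
        raise ValueError("one fusion weight per feature map is required")
    if out_shape is None:
        out_shape = max((fm.shape[-2:] for fm in feature_maps),
                        key=lambda s: s[0] * s[1])
    fused = np.zeros(feature_maps[0].shape[:-2] + tuple(out_shape))
    for fm, wj in zip(feature_maps, fusion_weights):
        fused += wj * bilinear_resize(np.asarray(fm, dtype=np.float64), out_shape)
    return fused


# ---------------------------------------------------------------------------
# Checkpoint I/O
# ---------------------------------------------------------------------------

def save_checkpoint(network: Network, path) -> None:
    """Serialize weights, normalization statistics and config to one file."""
    state = network.state_dict()
    cfg = yaml.safe_dump({
        "variant": network.config.variant,
        "base_channels": network.config.base_channels,
        "in_channels": network.config.in_channels,
        "out_channels": network.config.out_channels,
    })
    np.savez(path, __config__=np.frombuffer(cfg.encode(), dtype=np.uint8),
             **state)


def load_checkpoint(path) -> Network:
    with np.load(path) as data:
        cfg_dict = yaml.safe_load(bytes(data["__config__"]).decode())
        state = {k: data[k] for k in data.files if k != "__config__"}
    net = build_network(NetworkConfig(**cfg_dict))
    net.load_state_dict(state)
    return net
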