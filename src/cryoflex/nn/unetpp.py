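"""3D UNet++ (L3) voxel networks.

The regression network maps C x 40^3 density boxes to the 10^3 central
subbox of RMSF values; the occupancy classifier maps 1 x 40^3 density to
two-channel per-voxel occupancy probabilities on the full 40^3 box; the
two-stage composition feeds frozen occupancy probabilities into a
two-channel regression network.

Topology (L3 = three down-samplings): nodes ``X[i][j]`` live at resolution
level ``i`` (40, 20, 10, 5 voxels) with ``base * 2^i`` channels.  Each nested
node receives the channel concatenation of all same-level predecessors and
the upsampled node one level below, per the dense-skip UNet++ wiring:

    X00 ── X01 ── X02 ── X03 ──> head
      \\   /  \\   /  \\  /
       X10 ─── X11 ─── X12
         \\    /  \\    /
          X20 ──── X21
            \\     /
             X30

The regression head is two 1-kernel (pointwise) convolutions; because they
are pointwise, the center crop is applied before the head with an identical
result to head-then-crop, at a fraction of the cost.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .layers import Conv3d, ConvBlock, Module

__all__ = [
    "NetworkConfig",
    "UNetPPBackbone",
    "RMSFRegressor",
    "OccClassifier",
    "Occ2RMSF",
    "build_rmsf_network",
    "build_occ_network",
    "compose_occ2rmsf",
    "center_crop",
    "save_checkpoint",
    "load_checkpoint",
]

#: Input channel count per model variant.
VARIANT_CHANNELS = {"cryo": 1, "pdb": 1, "pdb01": 2, "dual": 2,
                    "occ": 1, "occ2rmsf": 1}

BOX_EDGE = 40
SUBBOX_EDGE = 10


@dataclass
class NetworkConfig:
    """Hyperparameters of the voxel networks.

    ``in_channels`` follows the variant (cryo/pdb = 1, pdb01/dual = 2);
    ``base_channels`` doubles at each of the 3 down-sampling levels.
    """

    variant: str = "dual"
    in_channels: int | None = None
    base_channels: int = 16
    convs_per_block: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.variant not in VARIANT_CHANNELS:
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.in_channels is None:
            self.in_channels = VARIANT_CHANNELS[self.variant]
        if self.base_channels < 2:
            raise ValueError("base_channels must be >= 2")


def center_crop(field: Tensor | np.ndarray, edge: int = SUBBOX_EDGE):
    """Center crop of the trailing 3 spatial axes (40 -> indices 15..24)."""
    if isinstance(field, Tensor):
        return ag.center_crop(field, edge)
    t = ag.center_crop(Tensor(field), edge)
    return t.data


class UNetPPBackbone(Module):
    """Dense-nested encoder-decoder; forward returns the X03 feature map."""

    def __init__(self, in_channels: int, base: int, rng: np.random.Generator,
                 n_convs: int = 1):
        super().__init__()
        b = base
        ch = [b, 2 * b, 4 * b, 8 * b]
        mk = lambda cin, cout: ConvBlock(cin, cout, rng, n_convs)
        self.nodes = {
            "x00": mk(in_channels, ch[0]),
            "x10": mk(ch[0], ch[1]),
            "x20": mk(ch[1], ch[2]),
            "x30": mk(ch[2], ch[3]),
            "x01": mk(ch[0] + ch[1], ch[0]),
            "x11": mk(ch[1] + ch[2], ch[1]),
            "x21": mk(ch[2] + ch[3], ch[2]),
            "x02": mk(2 * ch[0] + ch[1], ch[0]),
            "x12": mk(2 * ch[1] + ch[2], ch[1]),
            "x03": mk(3 * ch[0] + ch[1], ch[0]),
        }
        self.out_channels = ch[0]

    def __call__(self, x: Tensor) -> Tensor:
        n = self.nodes
        x00 = n["x00"](x)
        x10 = n["x10"](ag.max_pool3d(x00))
        x20 = n["x20"](ag.max_pool3d(x10))
        x30 = n["x30"](ag.max_pool3d(x20))
        x01 = n["x01"](ag.concat([x00, ag.upsample_trilinear(x10)]))
        x11 = n["x11"](ag.concat([x10, ag.upsample_trilinear(x20)]))
        x21 = n["x21"](ag.concat([x20, ag.upsample_trilinear(x30)]))
        x02 = n["x02"](ag.concat([x00, x01, ag.upsample_trilinear(x11)]))
        x12 = n["x12"](ag.concat([x10, x11, ag.upsample_trilinear(x21)]))
        x03 = n["x03"](ag.concat([x00, x01, x02, ag.upsample_trilinear(x12)]))
        return x03

    def n_params(self) -> int:
        return sum(blk.n_params() for blk in self.nodes.values())

    def forward_center(self, x: Tensor) -> Tensor:
        """X03 features on the central 10^3 subbox only.

        Exploits the box geometry (pad 15 around a 10-voxel subbox): each
        nested node is evaluated by *valid* convolution on exactly the
        interior region the central output depends on.  In eval mode the
        result equals ``center_crop(self(x), 10)`` (up to float32 summation
        order); in training mode batch-norm statistics are taken over these
        interior regions instead of the whole 40^3 box.  Cuts work by an
        order of magnitude.
        """
        if len(self.nodes["x00"].layers) != 2:
            # regional schedule below assumes one conv per block
            return ag.center_crop(self(x), SUBBOX_EDGE)
        n = self.nodes
        crop = ag.crop_region
        # encoder column: computed in full (cheap, few input channels)
        x00 = n["x00"](x)                      # level 0, full 40
        x10 = n["x10"](ag.max_pool3d(x00))     # level 1, full 20
        x20 = n["x20"](ag.max_pool3d(x10))     # level 2, full 10
        x30 = n["x30"](ag.max_pool3d(x20))     # level 3, full 5
        # nested nodes: valid convs on receptive-field windows (region noted
        # in each level's own voxel coordinates, half-open)
        up30 = ag.upsample_region(x30, 5, 0, 1, 8)           # level2 [1,9)
        x21 = n["x21"](ag.concat([crop(x20, 1, 9), up30]), pad=0)    # [2,8)
        up10 = ag.upsample_region(x10, 20, 0, 12, 16)        # level0 [12,28)
        x01 = n["x01"](ag.concat([crop(x00, 12, 28), up10]), pad=0)  # [13,27)
        up20 = ag.upsample_region(x20, 10, 0, 4, 12)         # level1 [4,16)
        x11 = n["x11"](ag.concat([crop(x10, 4, 16), up20]), pad=0)   # [5,15)
        up11 = ag.upsample_region(x11, 20, 5, 13, 14)        # level0 [13,27)
        x02 = n["x02"](ag.concat([crop(x00, 13, 27), x01, up11]), pad=0)  # [14,26)
        up21 = ag.upsample_region(x21, 10, 2, 5, 10)         # level1 [5,15)
        x12 = n["x12"](ag.concat([crop(x10, 5, 15), x11, up21]), pad=0)   # [6,14)
        up12 = ag.upsample_region(x12, 20, 6, 14, 12)        # level0 [14,26)
        x03 = n["x03"](ag.concat([crop(x00, 14, 26), crop(x01, 1, 13),
                                  x02, up12]), pad=0)        # [15,25)
        return x03


class RMSFRegressor(Module):
    """C x 40^3 densities -> 10^3 RMSF subbox."""

    def __init__(self, config: NetworkConfig):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.backbone = UNetPPBackbone(config.in_channels, config.base_channels,
                                       rng, config.convs_per_block)
        b = self.backbone.out_channels
        self.head1 = Conv3d(b, b, 1, rng)
        self.head2 = Conv3d(b, 1, 1, rng)

    def __call__(self, x: Tensor | np.ndarray) -> Tensor:
        if not isinstance(x, Tensor):
            x = Tensor(x)
        self._check_input(x)
        feat = self.backbone.forward_center(x)  # X03 on the central 10^3
        return self.head2(ag.relu(self.head1(feat)))  # pointwise head commutes

    def _check_input(self, x: Tensor) -> None:
        if x.data.ndim != 5 or x.data.shape[-3:] != (BOX_EDGE,) * 3:
            raise ValueError(f"expected (B, C, 40, 40, 40) input, got {x.data.shape}")
        if x.data.shape[1] != self.config.in_channels:
            raise ValueError(
                f"variant {self.config.variant!r} expects "
                f"{self.config.in_channels} channels, got {x.data.shape[1]}")

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Inference: (B, C, 40^3) -> (B, 10^3), eval mode, no graph."""
        was_training = self.training
        self.eval()
        with ag.no_grad():
            out = self(np.asarray(x, np.float32)).data[:, 0]
        if was_training:
            self.train()
        return out

    def n_params(self) -> int:
        return self.backbone.n_params() + self.head1.n_params() + self.head2.n_params()


class OccClassifier(Module):
    """1 x 40^3 density -> per-voxel two-class occupancy probabilities (2 x 40^3).

    Channel 0 is the unoccupied-background probability, channel 1 the
    structure-occupied probability; they sum to 1 at every voxel.
    """

    #: Nominal occupied-voxel rate and training class weights used to match
    #: the head's initial output to the weighted class prior (the standard
    #: prior-bias initialization for sparse detection; it removes the early
    #: epochs a zero-initialized head spends rediscovering the base rate).
    NOMINAL_PRIOR = 0.01
    CLASS_WEIGHTS = (0.05, 0.95)

    def __init__(self, config: NetworkConfig):
        super().__init__()
        if config.in_channels != 1:
            raise ValueError("occupancy classifier takes a single input channel")
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.backbone = UNetPPBackbone(1, config.base_channels, rng,
                                       config.convs_per_block)
        self.head = Conv3d(self.backbone.out_channels, 2, 1, rng)
        w0, w1 = self.CLASS_WEIGHTS
        pi = self.NOMINAL_PRIOR
        p1 = w1 * pi / (w1 * pi + w0 * (1 - pi))  # weighted effective prior
        self.head.bias.data = np.array([0.0, np.log(p1 / (1 - p1))],
                                       dtype=np.float32)
        self.trained = False

    def __call__(self, x: Tensor | np.ndarray) -> Tensor:
        if not isinstance(x, Tensor):
            x = Tensor(x)
        if x.data.ndim != 5 or x.data.shape[1] != 1:
            raise ValueError(f"expected (B, 1, 40, 40, 40) input, got {x.data.shape}")
        if x.data.shape[-3:] != (BOX_EDGE,) * 3:
            raise ValueError(f"expected 40^3 spatial input, got {x.data.shape}")
        return ag.softmax_channels(self.head(self.backbone(x)))

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        was_training = self.training
        self.eval()
        with ag.no_grad():
            out = self(np.asarray(x, np.float32)).data
        if was_training:
            self.train()
        return out

    def n_params(self) -> int:
        return self.backbone.n_params() + self.head.n_params()


class Occ2RMSF(Module):
    """Two-stage model: frozen occupancy classifier -> 2-channel RMSF net."""

    def __init__(self, occ: OccClassifier, config: NetworkConfig):
        super().__init__()
        if not occ.trained:
            raise RuntimeError("occupancy classifier must be trained before composing")
        self.occ = occ.freeze()
        self.occ.eval()
        self.config = config
        self.rmsf = RMSFRegressor(NetworkConfig(
            variant="dual", in_channels=2, base_channels=config.base_channels,
            convs_per_block=config.convs_per_block, seed=config.seed))

    def __call__(self, x: Tensor | np.ndarray) -> Tensor:
        if not isinstance(x, Tensor):
            x = Tensor(x)
        with ag.no_grad():
            probs = self.occ(x)
        return self.rmsf(Tensor(probs.data))

    def parameters(self):
        # stage-2 training updates only the regression network
        return self.rmsf.parameters()

    def predict(self, x: np.ndarray) -> np.ndarray:
        was_training = self.training
        self.eval()
        with ag.no_grad():
            out = self(np.asarray(x, np.float32)).data[:, 0]
        if was_training:
            self.train()
        return out

    def train(self):
        super().train()
        self.occ.eval()  # frozen stage stays in inference mode
        return self


def build_rmsf_network(config: NetworkConfig) -> RMSFRegressor:
    """Regression network for variants cryo / pdb / pdb01 / dual."""
    if config.variant not in ("cryo", "pdb", "pdb01", "dual"):
        raise ValueError(f"not a regression variant: {config.variant!r}")
    expected = VARIANT_CHANNELS[config.variant]
    if config.in_channels != expected:
        raise ValueError(f"variant {config.variant!r} requires "
                         f"{expected} input channels")
    return RMSFRegressor(config)


def build_occ_network(config: NetworkConfig) -> OccClassifier:
    return OccClassifier(config)


def compose_occ2rmsf(occ: OccClassifier, config: NetworkConfig) -> Occ2RMSF:
    return Occ2RMSF(occ, config)


def _encode_json(obj) -> np.ndarray:
    return np.frombuffer(json.dumps(obj).encode(), dtype=np.uint8).copy()


def save_checkpoint(model: Module, path) -> None:
    """Save weights + embedded config as an npz archive."""
    state = model.named_state()
    state["__config__"] = _encode_json(asdict(model.config))
    if isinstance(model, Occ2RMSF):
        state["__occ_config__"] = _encode_json(asdict(model.occ.config))
    np.savez(path, **state)


def load_checkpoint(path, kind: str = "rmsf"):
    """Rebuild a network from a checkpoint; kind in {rmsf, occ, occ2rmsf}."""
    with np.load(path) as data:
        state = {k: data[k] for k in data.files}
    config = NetworkConfig(**json.loads(bytes(state.pop("__config__")).decode()))
    if kind == "occ":
        model: Module = OccClassifier(config)
        model.trained = True
    elif kind == "occ2rmsf":
        occ_config = NetworkConfig(
            **json.loads(bytes(state.pop("__occ_config__")).decode()))
        occ = OccClassifier(occ_config)
        occ.trained = True
        model = Occ2RMSF(occ, config)
    else:
        model = build_rmsf_network(config)
    model.load_state(state)
    return model
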