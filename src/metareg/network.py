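"""Encoder-decoder registration network predicting a dense displacement
field summed over multiple resolutions.

The architecture is a compact 3D U-Net-style stand-in for the
LocalNet family: an encoder of strided (pooled) conv blocks, a decoder
with skip connections, and a 3-channel displacement head at every
decoder resolution.  Coarse heads are trilinearly upsampled to full
resolution and summed, so the predicted field is a sum of per-scale
fields.  Heads are zero-initialized, making the initial prediction the
identity transform.

Inputs are stacked channel-first: source image, masked target image and
(by default) the binary acquisition mask as a third channel, which
disambiguates "zero intensity" from "not acquired".

Weights live in a plain ordered name->array mapping supporting the
elementwise linear combinations required by the Reptile meta-update, and
round-trip bit-exactly through ``.npz`` checkpoints.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from . import _autodiff as ad
from .core_spatial import DisplacementField, Volume

__all__ = [
    "NetworkConfig",
    "NetworkWeights",
    "RegistrationNetwork",
    "init_weights",
    "weights_axpy",
    "weights_mean",
    "save_weights",
    "load_weights",
]

NetworkWeights = dict  # ordered name -> np.ndarray


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture hyper-parameters.

    ``levels`` is the number of 2x down/upsampling stages; grids must be
    divisible by 2**levels.  ``base_channels`` doubles at each stage.
    """

    levels: int = 2
    base_channels: int = 4
    in_channels: int = 3
    kernel: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.levels < 1:
            raise ValueError("levels must be >= 1")
        if self.base_channels < 1:
            raise ValueError("base_channels must be >= 1")
        if self.in_channels not in (2, 3):
            raise ValueError("in_channels must be 2 or 3")

    def check_grid(self, grid_shape: tuple[int, int, int]) -> None:
        div = 2 ** self.levels
        if any(n % div for n in grid_shape):
            raise ValueError(
                f"grid {grid_shape} not divisible by 2^levels = {div}")


def _channels(cfg: NetworkConfig) -> list[int]:
    return [cfg.base_channels * 2 ** i for i in range(cfg.levels + 1)]


def init_weights(cfg: NetworkConfig) -> NetworkWeights:
    """He-initialized conv stacks; displacement heads start at zero so the
    untrained network predicts the identity transform."""
    rng = np.random.default_rng(cfg.seed)
    k = cfg.kernel
    ch = _channels(cfg)
    w: NetworkWeights = {}

    def conv(name: str, cin: int, cout: int, zero: bool = False) -> None:
        fan_in = cin * k ** 3
        if zero:
            w[name + "_w"] = np.zeros((cout, cin, k, k, k))
        else:
            w[name + "_w"] = rng.normal(0.0, np.sqrt(2.0 / fan_in), (cout, cin, k, k, k))
        w[name + "_b"] = np.zeros(cout)

    cin = cfg.in_channels
    for i, c in enumerate(ch):
        conv(f"enc{i}", cin, c)
        cin = c
    for i in range(cfg.levels - 1, -1, -1):
        conv(f"dec{i}", ch[i + 1] + ch[i], ch[i])
    for i in range(cfg.levels + 1):
        conv(f"head{i}", ch[i], 3, zero=True)
    return w


# ---------------------------------------------------------------------------
# weight-space algebra (what the Reptile update needs)
# ---------------------------------------------------------------------------

def weights_axpy(w1: NetworkWeights, w2: NetworkWeights, c: float) -> NetworkWeights:
    """Elementwise w1 + c * (w2 - w1)."""
    if list(w1) != list(w2):
        raise ValueError("weight collections have different parameter names")
    out = {}
    for name, a in w1.items():
        b = w2[name]
        if a.shape != b.shape:
            raise ValueError(f"shape mismatch for {name}: {a.shape} vs {b.shape}")
        out[name] = a + c * (b - a)
    return out


def weights_mean(ws: list[NetworkWeights]) -> NetworkWeights:
    if not ws:
        raise ValueError("need at least one weight collection")
    return {name: np.mean([w[name] for w in ws], axis=0) for name in ws[0]}


def save_weights(w: NetworkWeights, cfg: NetworkConfig, path) -> None:
    meta = json.dumps({"levels": cfg.levels, "base_channels": cfg.base_channels,
                       "in_channels": cfg.in_channels, "kernel": cfg.kernel,
                       "seed": cfg.seed})
    np.savez(path, __config__=np.frombuffer(meta.encode(), dtype=np.uint8), **w)


def load_weights(path) -> tuple[NetworkWeights, NetworkConfig]:
    data = np.load(path)
    meta = json.loads(bytes(data["__config__"]).decode())
    cfg = NetworkConfig(**meta)
    w = {k: data[k] for k in data.files if k != "__config__"}
    # restore canonical parameter ordering
    ref = init_weights(cfg)
    return {name: w[name] for name in ref}, cfg


# ---------------------------------------------------------------------------
# forward pass
# ---------------------------------------------------------------------------

class RegistrationNetwork:
    """Stateless forward-pass wrapper around a config."""

    def __init__(self, cfg: NetworkConfig):
        self.cfg = cfg

    def init_weights(self) -> NetworkWeights:
        return init_weights(self.cfg)

    def forward_t(self, params: dict[str, ad.Tensor], x: np.ndarray) -> ad.Tensor:
        """Build the graph from input (C,D,H,W) to the (3,D,H,W) field."""
        cfg = self.cfg
        self.cfg.check_grid(x.shape[1:])
        ch = _channels(cfg)

        def conv(name: str, t: ad.Tensor) -> ad.Tensor:
            return ad.conv3d(t, params[name + "_w"], params[name + "_b"])

        feats = []
        t = ad.constant(x)
        for i in range(cfg.levels + 1):
            if i > 0:
                t = ad.avg_pool2(t)
            t = ad.leaky_relu(conv(f"enc{i}", t))
            feats.append(t)
        heads = [conv(f"head{cfg.levels}", feats[-1])]
        t = feats[-1]
        for i in range(cfg.levels - 1, -1, -1):
            t = ad.leaky_relu(conv(f"dec{i}", ad.concat_channels([ad.upsample2(t), feats[i]])))
            heads.append(conv(f"head{i}", t))
        # sum per-resolution fields at full resolution
        total: ad.Tensor | None = None
        for level_from_top, head in enumerate(heads):
            ups = cfg.levels - level_from_top
            for _ in range(ups):
                head = ad.upsample2(head)
            total = head if total is None else total + head
        assert total.value.shape == (3, *x.shape[1:])
        return total

    @staticmethod
    def as_params(w: NetworkWeights) -> dict[str, ad.Tensor]:
        return {name: ad.parameter(a) for name, a in w.items()}

    def predict(self, w: NetworkWeights, x: np.ndarray) -> np.ndarray:
        params = {name: ad.constant(a) for name, a in w.items()}
        return self.forward_t(params, x).value

    def predict_ddf(self, w: NetworkWeights, source: Volume,
                    target_masked: Volume, mask: Volume | None = None
                    ) -> DisplacementField:
        """Predict the dense displacement field on the target grid."""
        if source.shape != target_masked.shape:
            raise ValueError(
                f"source grid {source.shape} != target grid {target_masked.shape}")
        x = stack_inputs(self.cfg, source, target_masked, mask)
        return DisplacementField(self.predict(w, x))


def stack_inputs(cfg: NetworkConfig, source: Volume, target_masked: Volume,
                 mask: Volume | None) -> np.ndarray:
    chans = [source.values, target_masked.values]
    if cfg.in_channels == 3:
        if mask is None:
            raise ValueError("config expects a mask channel but none was given")
        chans.append(mask.values)
    return np.stack(chans, axis=0)
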