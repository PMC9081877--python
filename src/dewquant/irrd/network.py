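"""The multi-convolutional edge detection network.

A residual backbone of K stages (stage k >= 2 halves the resolution).
Every residual block in every stage feeds a side branch: a 1x1
convolution to ``side_channel_width`` channels, summed over the blocks of
the stage, projected to one channel by a second 1x1 convolution and
bilinearly upsampled to input resolution.  The K per-stage side logit
maps are channel-concatenated and projected by a final 1x1 convolution to
the fused output.  All outputs pass through a sigmoid, giving per-pixel
edge probabilities.

Tapping every block (rather than only each stage's last) follows the idea
that thin droplet contours benefit from the features of every
convolutional layer.  The ``full`` preset mirrors a deep 5-stage residual
backbone; ``tiny`` and ``small`` are reduced presets for CPU-scale
training and testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import color as skcolor

from . import autograd as ag
from .autograd import Tensor

_PRESETS = {
    "tiny": {"stage_channels": (8, 16), "blocks_per_stage": (1, 1)},
    "small": {"stage_channels": (8, 16, 32), "blocks_per_stage": (2, 2, 2)},
    "full": {
        "stage_channels": (16, 32, 64, 128, 256),
        "blocks_per_stage": (2, 2, 2, 2, 2),
    },
}


@dataclass
class NetworkConfig:
    """Architecture hyperparameters.

    ``backbone_preset`` selects stage widths/depths unless
    ``stage_channels``/``blocks_per_stage`` are given explicitly.
    ``side_channel_width`` is the width of the per-block side taps
    (default 21).  ``n_stages`` is derived from the stage list.
    """

    backbone_preset: str = "tiny"
    stage_channels: tuple[int, ...] | None = None
    blocks_per_stage: tuple[int, ...] | None = None
    side_channel_width: int = 21
    in_channels: int = 1
    upsample_mode: str = "bilinear"

    def __post_init__(self) -> None:
        if self.stage_channels is None or self.blocks_per_stage is None:
            if self.backbone_preset not in _PRESETS:
                raise ValueError(
                    f"unknown preset {self.backbone_preset!r}; "
                    f"choose from {sorted(_PRESETS)}"
                )
            preset = _PRESETS[self.backbone_preset]
            self.stage_channels = self.stage_channels or preset["stage_channels"]
            self.blocks_per_stage = (
                self.blocks_per_stage or preset["blocks_per_stage"]
            )
        self.stage_channels = tuple(self.stage_channels)
        self.blocks_per_stage = tuple(self.blocks_per_stage)
        if len(self.stage_channels) != len(self.blocks_per_stage):
            raise ValueError("stage_channels and blocks_per_stage length mismatch")
        if self.n_stages < 2:
            raise ValueError("need at least 2 stages")
        if self.side_channel_width < 1:
            raise ValueError("side_channel_width must be >= 1")
        if any(c < 1 for c in self.stage_channels) or any(
            b < 1 for b in self.blocks_per_stage
        ):
            raise ValueError("stage widths and depths must be positive")
        if self.upsample_mode != "bilinear":
            raise ValueError("only bilinear upsampling is implemented")

    @property
    def n_stages(self) -> int:
        return len(self.stage_channels)


def _he(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    fan_in = int(np.prod(shape[1:]))
    return rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)


class IRRDNetwork:
    """Parameter container plus pure-function forward/backward."""

    def __init__(self, config: NetworkConfig, seed: int = 0):
        self.config = config
        self.params: dict[str, Tensor] = {}
        rng = np.random.default_rng(seed)
        c_in = config.in_channels
        for s, (c_out, n_blocks) in enumerate(
            zip(config.stage_channels, config.blocks_per_stage), start=1
        ):
            if s == 1:
                self._add(rng, f"s1_stem_w", (c_out, c_in, 3, 3))
                self._add(rng, f"s1_stem_b", (c_out,), zero=True)
                c_prev = c_out
            else:
                c_prev = config.stage_channels[s - 2]
            for b in range(n_blocks):
                stride_change = s > 1 and b == 0
                pfx = f"s{s}_b{b}"
                self._add(rng, f"{pfx}_conv1_w", (c_out, c_prev, 3, 3))
                self._add(rng, f"{pfx}_conv1_b", (c_out,), zero=True)
                self._add(rng, f"{pfx}_conv2_w", (c_out, c_out, 3, 3))
                self._add(rng, f"{pfx}_conv2_b", (c_out,), zero=True)
                if stride_change or c_prev != c_out:
                    self._add(rng, f"{pfx}_skip_w", (c_out, c_prev, 1, 1))
                    self._add(rng, f"{pfx}_skip_b", (c_out,), zero=True)
                self._add(
                    rng, f"{pfx}_side_w", (config.side_channel_width, c_out, 1, 1)
                )
                self._add(rng, f"{pfx}_side_b", (config.side_channel_width,), zero=True)
                c_prev = c_out
            self._add(rng, f"s{s}_score_w", (1, config.side_channel_width, 1, 1))
            self._add(rng, f"s{s}_score_b", (1,), zero=True)
        # fused projection starts as the mean of the side outputs
        k = config.n_stages
        self.params["fuse_w"] = Tensor(np.full((1, k, 1, 1), 1.0 / k), name="fuse_w")
        self.params["fuse_b"] = Tensor(np.zeros(1), name="fuse_b")

    def _add(self, rng, name: str, shape: tuple[int, ...], zero: bool = False) -> None:
        data = np.zeros(shape) if zero else _he(rng, shape)
        self.params[name] = Tensor(data, name=name)

    @property
    def n_parameters(self) -> int:
        return int(sum(t.data.size for t in self.params.values()))

    def _prepare(
        self, image: np.ndarray, mask: np.ndarray | None = None
    ) -> np.ndarray:
        image = np.asarray(image)
        if image.ndim == 3 and image.shape[2] == 3:
            image = skcolor.rgb2gray(image)  # rgb2gray rescales uint8 to [0,1]
        elif image.ndim != 2:
            raise ValueError(f"expected gray or RGB image, got shape {image.shape}")
        image = image.astype(np.float64)
        if image.max() > 1.5:  # 8-bit input
            image = image / 255.0
        # per-image standardisation: raw gray input is all-positive with a
        # background-dominated mean, which conditions first-layer gradients
        # poorly and can stall training in a flat-output saddle.  With an
        # analysis mask, statistics come from retained pixels only and
        # excluded pixels are set to the (zero) mean, so the mask boundary
        # does not become an artificial step edge
        if mask is not None:
            if mask.shape != image.shape:
                raise ValueError(
                    f"mask shape {mask.shape} != image shape {image.shape}"
                )
            sel = np.asarray(mask) > 0
            mu = image[sel].mean() if sel.any() else 0.0
            std = image[sel].std() if sel.any() else 1.0
            image = image - mu
            if std > 1e-8:
                image = image / std
            image[~sel] = 0.0
        else:
            image = image - image.mean()
            std = image.std()
            if std > 1e-8:
                image = image / std
        if self.config.in_channels != 1:
            raise ValueError("only single-channel input is supported")
        return image[None]  # (1, H, W)

    def forward_graph(
        self, image: np.ndarray, mask: np.ndarray | None = None
    ) -> tuple[list[Tensor], Tensor]:
        """Forward pass returning LOGIT tensors (K side maps, fused map)."""
        p = self.params
        cfg = self.config
        x_arr = self._prepare(image, mask)
        hw = x_arr.shape[1:]
        x = Tensor(x_arr, name="input")
        side_logits: list[Tensor] = []
        for s in range(1, cfg.n_stages + 1):
            n_blocks = cfg.blocks_per_stage[s - 1]
            if s == 1:
                x = ag.relu(ag.conv2d(x, p["s1_stem_w"], p["s1_stem_b"]))
            taps: Tensor | None = None
            for b in range(n_blocks):
                pfx = f"s{s}_b{b}"
                stride = 2 if (s > 1 and b == 0) else 1
                y = ag.relu(ag.conv2d(x, p[f"{pfx}_conv1_w"], p[f"{pfx}_conv1_b"], stride))
                y = ag.conv2d(y, p[f"{pfx}_conv2_w"], p[f"{pfx}_conv2_b"])
                if f"{pfx}_skip_w" in p:
                    skip = ag.conv2d(x, p[f"{pfx}_skip_w"], p[f"{pfx}_skip_b"], stride)
                else:
                    skip = x
                x = ag.relu(ag.add(y, skip))
                tap = ag.conv2d(x, p[f"{pfx}_side_w"], p[f"{pfx}_side_b"])
                taps = tap if taps is None else ag.add(taps, tap)
            score = ag.conv2d(taps, p[f"s{s}_score_w"], p[f"s{s}_score_b"])
            side_logits.append(ag.upsample_bilinear(score, hw))
        fused = ag.conv2d(
            ag.concat_channels(side_logits), p["fuse_w"], p["fuse_b"]
        )
        return side_logits, fused

    def forward(
        self, image: np.ndarray, mask: np.ndarray | None = None
    ) -> tuple[list[np.ndarray], np.ndarray]:
        """Edge probability maps: (K side maps, fused map), each (H, W) in [0, 1]."""
        side_logits, fused = self.forward_graph(image, mask)
        side = [ag.sigmoid(t.data[0]) for t in side_logits]
        return side, ag.sigmoid(fused.data[0])


def build_network(config: NetworkConfig | None = None, seed: int = 0) -> IRRDNetwork:
    """Construct a network with deterministic He-style initialisation."""
    return IRRDNetwork(config or NetworkConfig(), seed=seed)


def detect_edges_irrd(
    net: IRRDNetwork, image: np.ndarray, analysis_mask: np.ndarray | None = None
) -> np.ndarray:
    """Fused edge probability map, zeroed outside the analysis mask.

    The mask also conditions the input normalisation (statistics from
    retained pixels; excluded pixels held at the mean), so the mask
    boundary cannot masquerade as a contour.
    """
    _, fused = net.forward(image, analysis_mask)
    if analysis_mask is not None:
        fused = fused * (np.asarray(analysis_mask) > 0)
    return fused
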