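"""SGD training loop and checkpointing for the edge network.

The objective is the whole-image loss summed over the K side maps and
the fused map.  For optimisation the gradient is normalised by
(K + 1) times the image's count of certain-edge pixels, so the update
magnitude at the default learning rate of 0.01 tracks the amount of
contour in the image rather than the frame area: small desk-scale
frames and full-resolution photographs with proportional contours
receive comparable steps per contour pixel.  The loss values reported
in the trace are per-pixel means (total / (|I| * (K + 1))), which is
also the quantity training is judged by.  Plain SGD with momentum 0.9,
batch size 1, 30 epochs by default.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .loss import LossConfig, balance_weights, loss_gradients_wrt_logits
from .network import IRRDNetwork, NetworkConfig
from . import autograd as ag

CHECKPOINT_VERSION = 1


@dataclass
class TrainConfig:
    lr: float = 0.01
    epochs: int = 30
    batch_size: int = 1
    momentum: float = 0.9
    weight_decay: float = 0.0
    checkpoint_every: int = 1000  # steps between saved weight snapshots
    shuffle: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size != 1:
            raise ValueError("only batch_size=1 is supported (and works best)")
        if self.lr < 0 or self.epochs < 0:
            raise ValueError("lr and epochs must be non-negative")


class DivergenceError(RuntimeError):
    """Raised when the training loss becomes non-finite."""


def evaluate_loss(
    net: IRRDNetwork,
    dataset: list[tuple[np.ndarray, np.ndarray, np.ndarray]],
    weights: list[tuple[float, float]],
    eta: float,
) -> float:
    """Mean per-pixel image loss over the dataset, without updates."""
    losses = []
    for (image, consensus, _label), (alpha_w, beta_w) in zip(dataset, weights):
        side_logits, fused = net.forward_graph(image)
        outputs = [*side_logits, fused]
        norm = consensus.size * len(outputs)
        loss, _ = loss_gradients_wrt_logits(
            [t.data[0] for t in outputs], consensus, alpha_w, beta_w, eta,
            normalize=norm,
        )
        losses.append(loss)
    return float(np.mean(losses))


def train(
    net: IRRDNetwork,
    dataset: list[tuple[np.ndarray, np.ndarray, np.ndarray]],
    cfg: TrainConfig | None = None,
    loss_cfg: LossConfig | None = None,
    checkpoint_dir: str | Path | None = None,
) -> tuple[IRRDNetwork, list[float]]:
    """Train in place; returns the network and the per-epoch loss trace.

    ``dataset`` holds (image, consensus_edges, droplet_label_map) triples.
    The loss trace holds the mean per-pixel loss of the freshly
    initialised network (entry 0, evaluated before any update) followed
    by one mean per epoch.  Deterministic for a fixed
    (net, dataset, cfg.seed) in single-threaded numpy.
    """
    cfg = cfg or TrainConfig()
    loss_cfg = loss_cfg or LossConfig()
    rng = np.random.default_rng(cfg.seed)
    velocity = {k: np.zeros_like(t.data) for k, t in net.params.items()}
    balances = [balance_weights(cons, lab, loss_cfg) for _img, cons, lab in dataset]
    weights = [(alpha_w, beta_w) for alpha_w, beta_w, _bal in balances]
    n_pos = [max(bal.n_pos, 1) for _a, _b, bal in balances]
    trace: list[float] = [evaluate_loss(net, dataset, weights, loss_cfg.eta)]
    step = 0
    for epoch in range(cfg.epochs):
        order = np.arange(len(dataset))
        if cfg.shuffle:
            rng.shuffle(order)
        epoch_losses = []
        for idx in order:
            image, consensus, _label = dataset[idx]
            alpha_w, beta_w = weights[idx]
            side_logits, fused = net.forward_graph(image)
            outputs = [*side_logits, fused]
            # gradients per certain-edge pixel; reported loss per pixel
            total, grads = loss_gradients_wrt_logits(
                [t.data[0] for t in outputs],
                consensus,
                alpha_w,
                beta_w,
                loss_cfg.eta,
                normalize=len(outputs) * n_pos[idx],
            )
            mean_loss = total * n_pos[idx] / consensus.size
            if not np.isfinite(mean_loss):
                raise DivergenceError(
                    f"non-finite loss at epoch {epoch}, image {idx}: {mean_loss}"
                )
            epoch_losses.append(mean_loss)
            ag.zero_grads(net.params.values())
            ag.backward(outputs, [g[None] for g in grads])
            for name, tensor in net.params.items():
                g = tensor.grad if tensor.grad is not None else 0.0
                if cfg.weight_decay:
                    g = g + cfg.weight_decay * tensor.data
                velocity[name] = cfg.momentum * velocity[name] + g
                tensor.data -= cfg.lr * velocity[name]
            step += 1
            if checkpoint_dir is not None and step % cfg.checkpoint_every == 0:
                save_checkpoint(
                    Path(checkpoint_dir) / f"step_{step:06d}.npz",
                    net,
                    {"epoch": epoch, "step": step, "loss": mean_loss},
                )
        trace.append(float(np.mean(epoch_losses)))
    if checkpoint_dir is not None:
        save_checkpoint(
            Path(checkpoint_dir) / "final.npz",
            net,
            {"epoch": cfg.epochs, "step": step,
             "loss": trace[-1] if trace else None},
        )
    return net, trace


def save_checkpoint(
    path: str | Path, net: IRRDNetwork, metadata: dict | None = None
) -> None:
    """Self-describing .npz archive: version + config + params + metadata."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    header = {
        "checkpoint_version": CHECKPOINT_VERSION,
        "config": asdict(net.config),
        "metadata": metadata or {},
    }
    arrays = {f"param/{k}": t.data for k, t in net.params.items()}
    np.savez(path, __header__=np.frombuffer(
        json.dumps(header).encode(), dtype=np.uint8
    ), **arrays)


def load_checkpoint(path: str | Path) -> IRRDNetwork:
    with np.load(path) as archive:
        header = json.loads(bytes(archive["__header__"]).decode())
        if header.get("checkpoint_version") != CHECKPOINT_VERSION:
            raise ValueError(
                f"unsupported checkpoint version in {path}: "
                f"{header.get('checkpoint_version')}"
            )
        cfg_dict = header["config"]
        cfg_dict["stage_channels"] = tuple(cfg_dict["stage_channels"])
        cfg_dict["blocks_per_stage"] = tuple(cfg_dict["blocks_per_stage"])
        config = NetworkConfig(**cfg_dict)
        net = IRRDNetwork(config, seed=0)
        for key in archive.files:
            if key.startswith("param/"):
                name = key[len("param/") :]
                net.params[name].data = archive[key].astype(np.float64)
    return net
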