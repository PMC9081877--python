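"""Contour-search loss with consensus labels and area weighting.

Ground truth is a consensus edge probability map y (fraction of
annotators marking each pixel).  Pixels with y = 0 are certain non-edges,
pixels with y >= eta are certain edges, and "controversial" pixels with
0 < y < eta are excluded from the loss entirely.  The two certain classes
are cross-entropy weighted by class-balance factors scaled by the area
ratio R = |S+| / (|S+| + |S-|), where |S+| is the area of the largest dew
region and |S-| the total dew area -- the contour-search term that ties
the edge loss to the droplet areas it should enclose:

    alpha_w = lambda * n_pos / (n_pos + n_neg) * R     (non-edge weight)
    beta_w  =          n_neg / (n_pos + n_neg) * R     (edge weight)

The per-pixel loss is then

    l = -alpha_w * log(1 - p)   if y = 0
    l = 0                       if 0 < y < eta
    l = -beta_w  * log(p)       if y >= eta

and the image loss sums l over all pixels of each of the K side maps plus
the fused map.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import measure

EPS = 1e-7


@dataclass
class LossConfig:
    """eta: consensus threshold in (0, 1]; lam: non-edge weight multiplier."""

    eta: float = 0.5
    lam: float = 1.1

    def __post_init__(self) -> None:
        if not 0.0 < self.eta <= 1.0:
            raise ValueError(f"eta must be in (0, 1], got {self.eta}")
        if self.lam <= 0:
            raise ValueError(f"lambda must be positive, got {self.lam}")


@dataclass
class AreaBalance:
    """Certain-pixel counts and dew-area terms entering the loss weights.

    ``s_bar`` (mean area of the non-largest regions) is diagnostic only;
    it does not enter the weights.
    """

    n_pos: int
    n_neg: int
    s_plus: int
    s_minus: int
    n_total: int
    s_bar: float = 0.0


def balance_weights(
    consensus: np.ndarray,
    label_map: np.ndarray,
    cfg: LossConfig | None = None,
) -> tuple[float, float, AreaBalance]:
    """Compute (alpha_w, beta_w, AreaBalance) for one image.

    Raises if the consensus map contains no certain pixel at all.  When
    the label map holds no dew region the area ratio degenerates to 0/0
    and falls back to 0.5, reducing the loss to plain class-balanced
    cross-entropy.
    """
    cfg = cfg or LossConfig()
    cons = np.asarray(consensus, dtype=np.float64)
    lab = np.asarray(label_map)
    if cons.shape != lab.shape:
        raise ValueError("consensus and label map must share a shape")
    n_pos = int((cons >= cfg.eta).sum())
    n_neg = int((cons == 0.0).sum())
    if n_pos + n_neg == 0:
        raise ValueError("no certain labels: every pixel is controversial")
    if lab.max() > 0 and np.issubdtype(lab.dtype, np.integer):
        labelled = lab
    else:
        labelled = measure.label(lab > 0, connectivity=2)
    counts = np.bincount(np.asarray(labelled).ravel())[1:]
    counts = counts[counts > 0]
    s_plus = int(counts.max()) if counts.size else 0
    s_minus = int(counts.sum()) if counts.size else 0
    ratio = s_plus / (s_plus + s_minus) if s_minus > 0 else 0.5
    others = counts[counts < counts.max()] if counts.size > 1 else np.array([])
    balance = AreaBalance(
        n_pos=n_pos,
        n_neg=n_neg,
        s_plus=s_plus,
        s_minus=s_minus,
        n_total=int(cons.size),
        s_bar=float(others.mean()) if others.size else 0.0,
    )
    frac_pos = n_pos / (n_pos + n_neg)
    alpha_w = cfg.lam * frac_pos * ratio
    beta_w = (1.0 - frac_pos) * ratio
    return alpha_w, beta_w, balance


def pointwise_loss(
    p: np.ndarray | float,
    y: np.ndarray | float,
    alpha_w: float,
    beta_w: float,
    eta: float = 0.5,
) -> np.ndarray | float:
    """Per-pixel contour-search loss (vectorised); always >= 0.

    Predictions are clamped to [EPS, 1 - EPS] before the logarithms.
    """
    p_arr = np.clip(np.asarray(p, dtype=np.float64), EPS, 1.0 - EPS)
    y_arr = np.asarray(y, dtype=np.float64)
    neg = y_arr == 0.0
    pos = y_arr >= eta
    out = np.zeros(np.broadcast(p_arr, y_arr).shape)
    out = np.where(neg, -alpha_w * np.log1p(-p_arr), out)
    out = np.where(pos, -beta_w * np.log(p_arr), out)
    if np.isscalar(p) and np.isscalar(y):
        return float(out)
    return out


@dataclass
class ImageLoss:
    total: float
    per_pixel_mean: float
    per_map: list[float]


def image_loss(
    side_maps: list[np.ndarray],
    fused: np.ndarray,
    consensus: np.ndarray,
    label_map: np.ndarray,
    cfg: LossConfig | None = None,
) -> ImageLoss:
    """Whole-image loss: pointwise loss summed over the K side maps + fused.

    ``per_pixel_mean`` divides the total by |I| * (K + 1).
    """
    cfg = cfg or LossConfig()
    alpha_w, beta_w, _ = balance_weights(consensus, label_map, cfg)
    per_map = []
    for prob in [*side_maps, fused]:
        per_map.append(
            float(pointwise_loss(prob, consensus, alpha_w, beta_w, cfg.eta).sum())
        )
    total = float(sum(per_map))
    n = consensus.size * (len(side_maps) + 1)
    return ImageLoss(total=total, per_pixel_mean=total / n, per_map=per_map)


def loss_gradients_wrt_logits(
    logit_maps: list[np.ndarray],
    consensus: np.ndarray,
    alpha_w: float,
    beta_w: float,
    eta: float,
    normalize: float = 1.0,
) -> tuple[float, list[np.ndarray]]:
    """Total loss and d(loss)/d(logit) for each map, in closed form.

    For p = sigmoid(z): d l / d z is alpha_w * p on certain non-edges,
    -beta_w * (1 - p) on certain edges, and exactly 0 on controversial
    pixels.  ``normalize`` divides both loss and gradients (used to train
    on the per-pixel mean).
    """
    from .autograd import sigmoid

    cons = np.asarray(consensus, dtype=np.float64)
    neg = cons == 0.0
    pos = cons >= eta
    total = 0.0
    grads = []
    for z in logit_maps:
        p = sigmoid(np.asarray(z, dtype=np.float64))
        pc = np.clip(p, EPS, 1.0 - EPS)
        total += float(
            -(alpha_w * np.log1p(-pc) * neg).sum() - (beta_w * np.log(pc) * pos).sum()
        )
        g = np.zeros_like(p)
        g[neg] = alpha_w * p[neg]
        g[pos] = -beta_w * (1.0 - p[pos])
        grads.append(g / normalize)
    return total / normalize, grads
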