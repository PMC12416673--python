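"""Edge-weighted IoU + BCE training objective.

The composite loss is L = λ₁·L_IoU^w + λ₂·L_BCE^w with λ₁ = λ₂ = 0.5.  The
per-pixel weights emphasise vessel boundaries: around every pixel a 31×31
neighbourhood mean of the ground-truth mask is taken, and the weight is
1 + γ·|local mean − pixel label|.  Deep inside a vessel or far in the
background the local mean equals the label and the weight stays 1; at edges
the discrepancy (and hence the weight) is maximal.

Both loss terms accept either plain numpy arrays (returning floats) or
autograd tensors from :mod:`hardvessel.nn` (returning differentiable
scalars); predictions S live in [0,1] and are clamped away from {0,1}
before logarithms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter

from .nn import Tensor

__all__ = [
    "EdgeWeightMap",
    "LossConfig",
    "edge_weight_map",
    "weighted_iou_loss",
    "weighted_bce_loss",
    "total_loss",
]


@dataclass
class EdgeWeightMap:
    weights: np.ndarray
    window: int
    gamma: float


@dataclass
class LossConfig:
    lambda1: float = 0.5
    lambda2: float = 0.5
    gamma: float = 5.0
    window: int = 31
    epsilon: float = 1e-7
    border: str = "valid"  # "valid": mean over in-bounds pixels; "zero": zero-pad

    def validate(self) -> "LossConfig":
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ValueError("lambda weights must be >= 0")
        if self.window % 2 == 0:
            raise ValueError("window must be odd")
        if self.border not in ("valid", "zero"):
            raise ValueError("border must be 'valid' or 'zero'")
        return self


def edge_weight_map(G: np.ndarray, window: int = 31, gamma: float = 5.0,
                    border: str = "valid") -> EdgeWeightMap:
    """Per-pixel weights 1 + γ·|window-mean(G) − G|.

    ``border='valid'`` averages over in-bounds pixels only (weights stay
    exactly 1 on constant masks up to the image edge); ``'zero'`` treats
    out-of-bounds pixels as background.
    """
    if window % 2 == 0:
        raise ValueError(f"window must be odd, got {window}")
    G = np.asarray(G, dtype=np.float64)
    if not np.isin(G, (0.0, 1.0)).all():
        raise ValueError("ground-truth mask must be binary")
    # the window is spatial: leading batch/channel axes are not averaged over
    size = (1,) * (G.ndim - 2) + (window, window)
    sums = uniform_filter(G, size=size, mode="constant", cval=0.0)
    if border == "valid":
        counts = uniform_filter(np.ones_like(G), size=size,
                                mode="constant", cval=0.0)
        local_mean = sums / counts
    elif border == "zero":
        local_mean = sums
    else:
        raise ValueError("border must be 'valid' or 'zero'")
    weights = 1.0 + gamma * np.abs(local_mean - G)
    return EdgeWeightMap(weights=weights, window=window, gamma=gamma)


def _as_weights(W, like: np.ndarray) -> np.ndarray:
    if W is None:
        return np.ones_like(like, dtype=np.float64)
    if isinstance(W, EdgeWeightMap):
        W = W.weights
    return np.asarray(W, dtype=like.dtype if like.dtype.kind == "f" else np.float64)


def _check_shapes(s_shape, g_shape, w_shape):
    if s_shape != g_shape:
        raise ValueError(f"prediction shape {s_shape} != mask shape {g_shape}")
    if w_shape != g_shape:
        raise ValueError(f"weight shape {w_shape} != mask shape {g_shape}")


def weighted_iou_loss(S, G, W=None):
    """1 − Σ w·S·G / Σ w·(S + G − S·G) (soft IoU; w ≡ 1 is the plain form)."""
    if isinstance(S, Tensor):
        g = Tensor(np.asarray(G, dtype=S.data.dtype))
        w = Tensor(_as_weights(W, S.data))
        _check_shapes(S.data.shape, g.data.shape, w.data.shape)
        inter = (w * S * g).sum()
        union = (w * (S + g - S * g)).sum()
        return 1.0 - inter / union
    S = np.asarray(S, dtype=np.float64)
    G = np.asarray(G, dtype=np.float64)
    w = _as_weights(W, S)
    _check_shapes(S.shape, G.shape, w.shape)
    inter = float((w * S * G).sum())
    union = float((w * (S + G - S * G)).sum())
    return 1.0 - inter / union


def weighted_bce_loss(S, G, W=None, epsilon: float = 1e-7):
    """Weight-normalised binary cross-entropy, Σ w·bce / Σ w."""
    if isinstance(S, Tensor):
        g = Tensor(np.asarray(G, dtype=S.data.dtype))
        w = Tensor(_as_weights(W, S.data))
        _check_shapes(S.data.shape, g.data.shape, w.data.shape)
        s = S.clamp(epsilon, 1.0 - epsilon)
        bce = -(g * s.log()) - ((1.0 - g) * (1.0 - s).log())
        return (w * bce).sum() / w.sum()
    S = np.asarray(S, dtype=np.float64)
    G = np.asarray(G, dtype=np.float64)
    w = _as_weights(W, S)
    _check_shapes(S.shape, G.shape, w.shape)
    s = np.clip(S, epsilon, 1.0 - epsilon)
    bce = -(G * np.log(s)) - ((1.0 - G) * np.log(1.0 - s))
    return float((w * bce).sum() / w.sum())


def total_loss(S, G, config: LossConfig | None = None):
    """λ₁·L_IoU^w + λ₂·L_BCE^w with the edge-weight map computed once from G.

    ``S`` may be a single map or a list of maps (deep supervision), in which
    case the same weighted loss is applied to each and summed.  Returns
    ``(loss, breakdown)`` where the breakdown reports the two terms as
    floats.
    """
    config = (config or LossConfig()).validate()
    maps = S if isinstance(S, (list, tuple)) else [S]
    W = edge_weight_map(np.asarray(G, dtype=np.float64), config.window,
                        config.gamma, config.border)
    total = None
    breakdown = {"iou": 0.0, "bce": 0.0}
    for s in maps:
        iou = weighted_iou_loss(s, G, W)
        bce = weighted_bce_loss(s, G, W, config.epsilon)
        term = config.lambda1 * iou + config.lambda2 * bce
        total = term if total is None else total + term
        breakdown["iou"] += iou.item() if isinstance(iou, Tensor) else iou
        breakdown["bce"] += bce.item() if isinstance(bce, Tensor) else bce
    return total, breakdown
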