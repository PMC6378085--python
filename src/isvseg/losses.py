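"""Segmentation objective: weighted cross-entropy, a contour-aware term and
a shape-constraint term.

All loss functions accept the network's two-channel probability maps
(channel 0 = ISV, channel 1 = non-ISV), shaped ``(2, H, W)`` or
``(N, 2, H, W)``, either as plain arrays or as autodiff tensors, and return
a scalar :class:`~isvseg.nn.Tensor` so gradients can flow back to the
network. Probabilities are clamped to ``[eps, 1 - eps]`` before any
logarithm, which keeps every term finite and non-negative.

The contour-aware term concentrates the cross-entropy on two thin pixel
bands around the ground-truth boundary: the *inner* band (object pixels
within ``band_width`` of the background, written I-) and the *outer* band
(background pixels within ``band_width`` of the object, I+). The default
reading is class-balanced cross-entropy restricted to the band: the
positive-class sum over the inner band carries weight ``|I+| / |I|`` and the
negative-class sum over the outer band carries ``|I-| / |I|`` (each side
weighted by the opposite band's share, so neither side of a thick vessel
dominates). ``swap_band_weights`` transposes the pairing and
``mode='emphasis'`` instead applies the band indicator as an additive
emphasis weight over full-image cross-entropy; both alternatives are one
flag away because the two readings are equally defensible.

The shape-constraint term penalizes, at every pixel, the negative
log-probability assigned to the correct class, averaged over pixels. It is
minimized by the ground truth and decreases monotonically as the prediction
moves from an uninformative 0.5 map toward the ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .nn import Tensor, clamp, log

__all__ = [
    "ContourBands",
    "LossBreakdown",
    "compute_contour_bands",
    "stack_bands",
    "weighted_cross_entropy",
    "contour_aware_loss",
    "shape_constraint_loss",
    "total_objective",
    "DEFAULT_EPS",
    "DEFAULT_BAND_WIDTH",
    "DEFAULT_WEIGHT_DECAY",
    "LOSS_ARMS",
]

DEFAULT_EPS = 1e-7
DEFAULT_BAND_WIDTH = 2
#: L2 penalty applied through the optimizer, never added to reported losses.
DEFAULT_WEIGHT_DECAY = 5e-4
#: Ablation arms: plain weighted cross-entropy, contour term alone, shape
#: term alone, and the full contour + shape objective.
LOSS_ARMS = ("wce", "c", "s", "s+c")

_STRUCT = np.ones((3, 3), dtype=bool)  # 8-connected neighbourhood


@dataclass
class ContourBands:
    """Inner/outer contour pixel bands of a ground-truth mask.

    ``inner`` marks object pixels within the band width of a background
    pixel; ``outer`` marks background pixels within the band width of an
    object pixel. ``mu`` is the indicator of the full band (inner | outer)
    and ``total`` its pixel count |I| = |I-| + |I+|. ``empty`` flags masks
    without a boundary (all-zero or all-one), on which contour-aware losses
    fall back to plain weighted cross-entropy.
    """

    inner: np.ndarray
    outer: np.ndarray
    mu: np.ndarray
    total: int

    @property
    def n_inner(self) -> int:
        return int(self.inner.sum())

    @property
    def n_outer(self) -> int:
        return int(self.outer.sum())

    @property
    def empty(self) -> bool:
        return self.total == 0


def compute_contour_bands(mask: np.ndarray, band_width: int = DEFAULT_BAND_WIDTH
                          ) -> ContourBands:
    """Extract the inner and outer contour bands of a binary mask.

    The inner band is the erosion residue (object minus the object eroded by
    ``band_width`` 8-connected steps, with the image border treated as
    object so a mask touching the border gains no artificial contour); the
    outer band is the dilation residue.
    """
    if band_width < 1:
        raise ValueError("band_width must be >= 1")
    m = np.asarray(mask).astype(bool)
    if m.ndim != 2:
        raise ValueError("mask must be a single 2-D binary map")
    eroded = ndimage.binary_erosion(m, _STRUCT, iterations=band_width,
                                    border_value=1)
    dilated = ndimage.binary_dilation(m, _STRUCT, iterations=band_width,
                                      border_value=0)
    inner = m & ~eroded
    outer = ~m & dilated
    mu = (inner | outer).astype(np.uint8)
    return ContourBands(inner=inner, outer=outer, mu=mu,
                        total=int(inner.sum() + outer.sum()))


def stack_bands(bands: list[ContourBands]) -> ContourBands:
    """Stack per-image bands along a new leading axis for batched losses."""
    return ContourBands(
        inner=np.stack([b.inner for b in bands]),
        outer=np.stack([b.outer for b in bands]),
        mu=np.stack([b.mu for b in bands]),
        total=sum(b.total for b in bands),
    )


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _as_tensor(pred) -> Tensor:
    return pred if isinstance(pred, Tensor) else Tensor(np.asarray(pred, float))


def _split_channels(pred: Tensor) -> tuple[Tensor, Tensor]:
    """Split (..., 2, H, W) probability maps into the ISV and non-ISV maps."""
    data = pred.data
    axis = data.ndim - 3
    if data.shape[axis] != 2:
        raise ValueError("expected two-channel probability maps (..., 2, H, W)")

    def pick(i):
        idx = (slice(None),) * axis + (i,)

        def backward(g):
            if pred.requires_grad:
                full = np.zeros_like(data)
                full[idx] = g
                pred._accumulate(full)

        return Tensor._make(data[idx], (pred,), backward)

    return pick(0), pick(1)


def _check_shapes(y: Tensor, target: np.ndarray):
    if y.data.shape != np.asarray(target).shape:
        raise ValueError(f"prediction spatial shape {y.data.shape} does not "
                         f"match target shape {np.asarray(target).shape}")


# ---------------------------------------------------------------------------
# loss terms
# ---------------------------------------------------------------------------

def weighted_cross_entropy(pred, target: np.ndarray, pos_weight: float = 1.0,
                           eps: float = DEFAULT_EPS) -> Tensor:
    """Pixel-mean weighted binary cross-entropy on the ISV channel:
    ``-(w * t * log y + (1 - t) * log(1 - y))``."""
    pred = _as_tensor(pred)
    y, _ = _split_channels(pred)
    t = np.asarray(target, dtype=np.float64)
    _check_shapes(y, t)
    y = clamp(y, eps, 1.0 - eps)
    return (-1.0 * ((pos_weight * t) * log(y) + (1.0 - t) * log(1.0 - y))).mean()


def contour_aware_loss(pred, target: np.ndarray, bands: ContourBands,
                       mode: str = "band", swap_band_weights: bool = False,
                       pos_weight: float = 1.0,
                       eps: float = DEFAULT_EPS) -> Tensor:
    """Contour-aware cross-entropy over the boundary bands of the target.

    Falls back to :func:`weighted_cross_entropy` when the bands are empty
    (boundary-free mask). See the module docstring for the two modes.
    """
    if mode not in ("band", "emphasis"):
        raise ValueError("mode must be 'band' or 'emphasis'")
    if bands.empty:
        return weighted_cross_entropy(pred, target, pos_weight, eps)
    pred = _as_tensor(pred)
    y, _ = _split_channels(pred)
    t = np.asarray(target, dtype=np.float64)
    _check_shapes(y, t)
    if bands.inner.shape != t.shape:
        raise ValueError("bands shape does not match target; use stack_bands "
                         "for batched targets")
    y = clamp(y, eps, 1.0 - eps)
    total = bands.total
    w_pos = bands.n_outer / total
    w_neg = bands.n_inner / total
    if swap_band_weights:
        w_pos, w_neg = w_neg, w_pos
    if mode == "band":
        inner = bands.inner.astype(np.float64)
        outer = bands.outer.astype(np.float64)
        pos = (inner * log(y)).sum()
        neg = (outer * log(1.0 - y)).sum()
        return (-(w_pos) * pos + -(w_neg) * neg) / total
    # emphasis: band indicator as additive weight over full-image CE
    w = 1.0 + bands.mu.astype(np.float64)
    return (-1.0 * (w * ((pos_weight * t) * log(y) + (1.0 - t) * log(1.0 - y)))).mean()


def shape_constraint_loss(pred, target: np.ndarray,
                          eps: float = DEFAULT_EPS) -> Tensor:
    """Per-pixel negative log-score of the correct class, averaged.

    The two sigmoid maps are normalized into per-pixel class scores
    ``(y_isv, y_non) / (y_isv + y_non)`` and the penalty at pixel *i* is
    ``-log`` of the correct class's score. Normalization is essential with
    two independent sigmoids: without it the term has a trivial minimum at
    "both channels everywhere 1", which carries no shape information. The
    normalized term vanishes at the ground truth, equals ``log 2`` per pixel
    for a uniform 0.5 prediction, and decreases strictly as the prediction
    moves toward the ground truth.
    """
    pred = _as_tensor(pred)
    y_isv, y_non = _split_channels(pred)
    t = np.asarray(target, dtype=np.float64)
    _check_shapes(y_isv, t)
    y_isv = clamp(y_isv, eps, 1.0 - eps)
    y_non = clamp(y_non, eps, 1.0 - eps)
    correct = t * y_isv + (1.0 - t) * y_non
    return (log(y_isv + y_non) - log(correct)).mean()


@dataclass
class LossBreakdown:
    """Scalar values of every term plus the autodiff node of the selected
    objective (``tensor``); weight decay is an optimizer-side L2 penalty and
    is never included in these values."""

    L: float
    L_wce: float
    L_c: float
    L_s: float
    contour_fallback: bool
    tensor: Tensor


def total_objective(pred, target: np.ndarray, bands: ContourBands,
                    terms: str = "s+c", pos_weight: float = 1.0,
                    mode: str = "band", swap_band_weights: bool = False,
                    eps: float = DEFAULT_EPS) -> LossBreakdown:
    """Combined objective for one batch.

    ``terms`` selects the ablation arm: ``"wce"`` (plain weighted
    cross-entropy), ``"c"`` (contour term), ``"s"`` (shape term) or
    ``"s+c"`` (contour + shape, the full objective).
    """
    if terms not in LOSS_ARMS:
        raise ValueError(f"terms must be one of {LOSS_ARMS}")
    pred = _as_tensor(pred)
    l_wce = weighted_cross_entropy(pred, target, pos_weight, eps)
    l_c = contour_aware_loss(pred, target, bands, mode, swap_band_weights,
                             pos_weight, eps)
    l_s = shape_constraint_loss(pred, target, eps)
    selected = {"wce": l_wce, "c": l_c, "s": l_s, "s+c": l_c + l_s}[terms]
    return LossBreakdown(
        L=selected.item(),
        L_wce=l_wce.item(),
        L_c=l_c.item(),
        L_s=l_s.item(),
        contour_fallback=bands.empty,
        tensor=selected,
    )
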