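"""Patch pipeline: adaptive ISV-pair cropping, zero-padding to square,
mirror/flip augmentation (x4), resizing and fold splitting.

Full frames are cut into one patch per ISV pair. Connected foreground
components are sorted by centroid column and grouped into consecutive pairs
(in a 2-D projection the two vessels of a pair are horizontal neighbours);
a trailing unpaired component gets its own crop. Crops aim at a height
between ``min_h`` and ``max_h`` pixels (clipped to the frame), are padded
with zeros to a square, expanded fourfold by the mirror/flip group
{identity, horizontal mirror, vertical flip, both}, and resized to the
training side (128 px by default) — images bilinearly, masks by nearest
neighbour followed by re-binarization.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from skimage.transform import resize as _sk_resize

__all__ = [
    "PatchRecord",
    "FoldSplit",
    "crop_isv_regions",
    "pad_to_square",
    "augment_mirror_flip",
    "resize_patch",
    "split_folds",
    "build_patches",
    "patches_to_arrays",
    "AUG_TAGS",
]

AUG_TAGS = ("orig", "mirror", "flip", "mirror+flip")
DEFAULT_PATCH_SIDE = 128
_CROP_PAD = 6  # loose pixels around a pair's bounding box


@dataclass
class PatchRecord:
    image: np.ndarray   # (h, w) float in [0, 1]
    mask: np.ndarray    # (h, w) uint8 {0, 1}
    source_id: int | str = 0
    crop_box: tuple[int, int, int, int] = (0, 0, 0, 0)  # r0, c0, r1, c1
    aug_tag: str = "orig"

    def __post_init__(self):
        if self.image.shape != self.mask.shape:
            raise ValueError("image and mask patches must be congruent")


@dataclass
class FoldSplit:
    fold: int
    train: list
    test: list
    validation: list


def _clamped_span(lo: int, hi: int, target: int, limit: int) -> tuple[int, int]:
    """Grow [lo, hi) symmetrically to ``target`` length within [0, limit)."""
    length = hi - lo
    if length >= target:
        return lo, hi
    grow = target - length
    lo = lo - grow // 2
    hi = hi + (grow - grow // 2)
    if lo < 0:
        hi = min(hi - lo, limit)
        lo = 0
    if hi > limit:
        lo = max(lo - (hi - limit), 0)
        hi = limit
    return lo, hi


def crop_isv_regions(image: np.ndarray, mask: np.ndarray,
                     min_h: int = 120, max_h: int = 160,
                     source_id=0, label_mask: np.ndarray | None = None
                     ) -> list[PatchRecord]:
    """Cut one crop per ISV pair out of a full frame.

    ``mask`` is the vessel annotation used to locate pairs (both vessels of
    each pair). Each crop's mask keeps only its own pair's pixels, so the
    crop is an exact per-pair ground truth. When ``label_mask`` is given
    (e.g. the foreground-only annotation while ``mask`` holds all vessels),
    the crop geometry still comes from ``mask`` but the stored patch mask is
    the cropped ``label_mask``. An empty mask yields an empty list.
    """
    mask = (np.asarray(mask) > 0).astype(np.uint8)
    labels, n_comp = ndimage.label(mask, structure=np.ones((3, 3)))
    if n_comp == 0:
        return []
    centroids = ndimage.center_of_mass(mask, labels, range(1, n_comp + 1))
    order = sorted(range(n_comp), key=lambda i: centroids[i][1])
    groups = [order[i:i + 2] for i in range(0, n_comp, 2)]

    h, w = mask.shape
    records = []
    for gi, group in enumerate(groups):
        sel = np.isin(labels, [g + 1 for g in group])
        rows = np.flatnonzero(sel.any(axis=1))
        cols = np.flatnonzero(sel.any(axis=0))
        r0, r1 = rows[0], rows[-1] + 1
        c0, c1 = cols[0], cols[-1] + 1
        target_h = int(np.clip(max(r1 - r0 + 2 * _CROP_PAD, min_h), min_h, max_h))
        target_h = max(target_h, r1 - r0)  # never cut the pair itself
        r0, r1 = _clamped_span(r0, r1, min(target_h, h), h)
        c0, c1 = _clamped_span(c0, c1, min(c1 - c0 + 2 * _CROP_PAD, w), w)
        if label_mask is not None:
            patch_mask = (np.asarray(label_mask)[r0:r1, c0:c1] > 0).astype(np.uint8)
        else:
            patch_mask = sel[r0:r1, c0:c1].astype(np.uint8)
        records.append(PatchRecord(
            image=np.asarray(image, dtype=np.float64)[r0:r1, c0:c1].copy(),
            mask=patch_mask,
            source_id=source_id,
            crop_box=(int(r0), int(c0), int(r1), int(c1)),
        ))
    return records


def pad_to_square(patch: PatchRecord) -> PatchRecord:
    """Zero-pad to side = max(h, w) with the original content centered."""
    h, w = patch.image.shape
    side = max(h, w)
    if h == w:
        return patch
    top = (side - h) // 2
    left = (side - w) // 2
    pad = ((top, side - h - top), (left, side - w - left))
    return replace(patch,
                   image=np.pad(patch.image, pad),
                   mask=np.pad(patch.mask, pad))


def augment_mirror_flip(patch: PatchRecord) -> list[PatchRecord]:
    """The four-element mirror/flip group of a square patch: the original,
    its horizontal mirror, its vertical flip, and both combined."""
    ops = {
        "orig": lambda a: a.copy(),
        "mirror": np.fliplr,
        "flip": np.flipud,
        "mirror+flip": lambda a: np.flipud(np.fliplr(a)),
    }
    return [replace(patch, image=np.ascontiguousarray(op(patch.image)),
                    mask=np.ascontiguousarray(op(patch.mask)), aug_tag=tag)
            for tag, op in ops.items()]


def resize_patch(patch: PatchRecord, side: int = DEFAULT_PATCH_SIDE) -> PatchRecord:
    """Resize a square patch: bilinear for the image, nearest neighbour then
    re-binarization for the mask (masks stay exactly {0, 1})."""
    h, w = patch.image.shape
    if h != w:
        raise ValueError("resize_patch expects a square patch; pad first")
    if h == side:
        return patch
    img = _sk_resize(patch.image, (side, side), order=1, mode="edge",
                     anti_aliasing=False, preserve_range=True)
    msk = _sk_resize(patch.mask.astype(np.float64), (side, side), order=0,
                     mode="edge", anti_aliasing=False, preserve_range=True)
    return replace(patch, image=img, mask=(msk > 0.5).astype(np.uint8))


def split_folds(ids, ratios: tuple[float, float, float] = (0.6, 0.2, 0.2),
                n_folds: int = 5, seed: int = 0) -> list[FoldSplit]:
    """Five (by default) independent seeded 60/20/20 re-splits.

    Each fold shuffles the ids with its own derived seed and cuts them into
    train/test/validation; within every fold the three sets are disjoint and
    cover all ids.
    """
    ids = list(ids)
    if len(ids) < n_folds:
        raise ValueError(f"need at least {n_folds} ids, got {len(ids)}")
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("ratios must sum to 1")
    folds = []
    for f in range(n_folds):
        rng = np.random.default_rng(seed + f)
        perm = [ids[i] for i in rng.permutation(len(ids))]
        n = len(ids)
        n_train = int(round(ratios[0] * n))
        n_test = int(round(ratios[1] * n))
        folds.append(FoldSplit(fold=f,
                               train=perm[:n_train],
                               test=perm[n_train:n_train + n_test],
                               validation=perm[n_train + n_test:]))
    return folds


# ---------------------------------------------------------------------------
# Convenience composition
# ---------------------------------------------------------------------------

def build_patches(image: np.ndarray, mask: np.ndarray, side: int = DEFAULT_PATCH_SIDE,
                  min_h: int = 120, max_h: int = 160, augment: bool = True,
                  source_id=0, label_mask: np.ndarray | None = None
                  ) -> list[PatchRecord]:
    """Full pipeline for one frame: crop -> pad -> (augment) -> resize."""
    out = []
    for rec in crop_isv_regions(image, mask, min_h, max_h, source_id, label_mask):
        rec = pad_to_square(rec)
        variants = augment_mirror_flip(rec) if augment else [rec]
        out.extend(resize_patch(v, side) for v in variants)
    return out


def patches_to_arrays(patches: list[PatchRecord]) -> tuple[np.ndarray, np.ndarray]:
    """Stack patch records into network-ready arrays: images (N, 1, S, S)
    and masks (N, S, S)."""
    if not patches:
        raise ValueError("no patches")
    imgs = np.stack([p.image for p in patches])[:, None, :, :]
    masks = np.stack([p.mask for p in patches]).astype(np.float64)
    return imgs, masks
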