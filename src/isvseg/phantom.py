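"""Synthetic fluorescent-vessel phantoms with exact ground-truth masks.

Real zebrafish-trunk fluorescence projections show a ladder-like vasculature:
two horizontal rails — the dorsal aorta (DA) near the bottom and the dorsal
longitudinal anastomotic vessel (DLAV) near the top — connected by pairs of
near-vertical intersegmental vessels (ISVs). In the 2-D projection of the
confocal stack the two ISVs of a pair overlap: the vessel nearer the
objective (foreground) keeps its full shape while its contralateral partner
(background) appears as a dimmer, partly occluded copy. Fluorescence dose is
uneven along a vessel, and abnormal morphologies occur: short (arrested)
vessels, irregular branches, and adhesions bridging neighbouring vessels.

The generator emulates exactly this structure. Vessels are thick polylines
(a stroke of a given width around a jittered centerline); masks are
rasterized without anti-aliasing so the ground truth is exact, while the
rendered image may use a soft 1-pixel edge. Brightness along a vessel is a
per-vessel gain modulated by a low-frequency sinusoid whose amplitude is the
``intensity_unevenness`` knob; additive Gaussian noise is clipped to [0, 1].
Background vessels are drawn first so foreground strokes occlude them. The
foreground mask covers only the ISVs (the segmentation target); the rails
are image context only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = [
    "VesselSpec",
    "PhantomConfig",
    "PhantomSample",
    "generate_phantom",
    "generate_dataset",
    "rasterize_spec",
    "save_sample",
    "save_dataset",
    "load_image",
    "load_mask",
    "save_image",
    "save_mask",
    "MIN_PAIR_SPACING",
    "MIN_HEIGHT",
]

MIN_PAIR_SPACING = 20  # pixels of horizontal room per ISV pair
MIN_HEIGHT = 48        # smallest frame tall enough for two rails + vessels
_MARGIN = 10

ABNORMAL_KINDS = ("short", "branching", "adhesion")


@dataclass
class VesselSpec:
    """One vessel stroke: an ordered centerline with width and brightness."""

    kind: str                     # normal | short | branching | adhesion | background | rail
    centerline: np.ndarray        # (K, 2) float pixel coordinates (row, col)
    width: float                  # stroke width in pixels, > 0
    intensity_profile: np.ndarray  # (K,) brightness in [0, 1] at each point

    def __post_init__(self):
        self.centerline = np.asarray(self.centerline, dtype=np.float64)
        self.intensity_profile = np.asarray(self.intensity_profile, dtype=np.float64)
        if self.centerline.ndim != 2 or self.centerline.shape[0] < 2:
            raise ValueError("centerline needs at least 2 points")
        if self.width <= 0:
            raise ValueError("width must be positive")
        if self.intensity_profile.shape[0] != self.centerline.shape[0]:
            raise ValueError("one intensity value per centerline point required")
        if ((self.intensity_profile < 0) | (self.intensity_profile > 1)).any():
            raise ValueError("intensity values must lie in [0, 1]")


@dataclass
class PhantomConfig:
    """Knobs of the phantom world; defaults describe a typical 48-hpf frame."""

    image_size: tuple[int, int] = (160, 256)   # (height, width)
    n_isv_pairs: int = 4
    p_abnormal: float = 0.2
    background_vessel_prob: float = 0.7
    intensity_unevenness: float = 0.3
    noise_sigma: float = 0.02
    seed: int = 0
    vessel_width: float = 3.0
    antialias: bool = True

    def __post_init__(self):
        h, w = self.image_size
        if h < 1 or w < 1:
            raise ValueError("image_size must be positive")
        for name in ("p_abnormal", "background_vessel_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.intensity_unevenness < 0 or self.noise_sigma < 0:
            raise ValueError("intensity_unevenness and noise_sigma must be >= 0")
        if self.n_isv_pairs < 0:
            raise ValueError("n_isv_pairs must be >= 0")


@dataclass
class PhantomSample:
    """One synthetic frame: image plus exact foreground/background masks.

    The masks may overlap where a foreground ISV occludes its background
    partner; each stays the exact rasterization of its own vessel specs.
    """

    image: np.ndarray    # (H, W) float in [0, 1]
    fg_mask: np.ndarray  # (H, W) uint8 {0, 1}: foreground ISVs only
    bg_mask: np.ndarray  # (H, W) uint8 {0, 1}: background vessels
    fg_specs: list[VesselSpec] = field(default_factory=list)
    bg_specs: list[VesselSpec] = field(default_factory=list)
    rail_specs: list[VesselSpec] = field(default_factory=list)
    kinds: list[str] = field(default_factory=list)  # per ISV pair


# ---------------------------------------------------------------------------
# Rasterization
# ---------------------------------------------------------------------------

def rasterize_spec(spec: VesselSpec, shape: tuple[int, int],
                   antialias: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Rasterize one vessel stroke.

    Returns ``(alpha, intensity)``: coverage in [0, 1] (binary when
    ``antialias`` is off) and the interpolated brightness where covered.
    A pixel is inside the stroke when its center lies within ``width / 2``
    of the centerline polyline.
    """
    h, w = shape
    alpha = np.zeros(shape)
    intensity = np.zeros(shape)
    half = spec.width / 2.0
    pts = spec.centerline
    bright = spec.intensity_profile
    for k in range(len(pts) - 1):
        p0, p1 = pts[k], pts[k + 1]
        b0, b1 = bright[k], bright[k + 1]
        r_lo = max(int(np.floor(min(p0[0], p1[0]) - half - 1)), 0)
        r_hi = min(int(np.ceil(max(p0[0], p1[0]) + half + 1)) + 1, h)
        c_lo = max(int(np.floor(min(p0[1], p1[1]) - half - 1)), 0)
        c_hi = min(int(np.ceil(max(p0[1], p1[1]) + half + 1)) + 1, w)
        if r_lo >= r_hi or c_lo >= c_hi:
            continue
        rr, cc = np.meshgrid(np.arange(r_lo, r_hi), np.arange(c_lo, c_hi),
                             indexing="ij")
        d = p1 - p0
        L2 = float(d @ d)
        vr = rr - p0[0]
        vc = cc - p0[1]
        t = np.clip((vr * d[0] + vc * d[1]) / L2, 0.0, 1.0) if L2 > 0 else 0.0
        dist = np.hypot(vr - t * d[0], vc - t * d[1])
        if antialias:
            a = np.clip(half + 0.5 - dist, 0.0, 1.0)
        else:
            a = (dist <= half).astype(np.float64)
        seg_int = (b0 + (b1 - b0) * t) * (a > 0)
        sub_a = alpha[r_lo:r_hi, c_lo:c_hi]
        sub_i = intensity[r_lo:r_hi, c_lo:c_hi]
        np.maximum(sub_a, a, out=sub_a)
        np.maximum(sub_i, seg_int, out=sub_i)
    return alpha, intensity


def _paint(image: np.ndarray, spec: VesselSpec, antialias: bool) -> None:
    """Painter's-algorithm composite: the stroke occludes what is below."""
    alpha, intensity = rasterize_spec(spec, image.shape, antialias=antialias)
    np.copyto(image, alpha * intensity + (1.0 - alpha) * image)


# ---------------------------------------------------------------------------
# Vessel synthesis
# ---------------------------------------------------------------------------

def _modulated_profile(rng, n_pts: int, gain: float, unevenness: float) -> np.ndarray:
    s = np.linspace(0.0, 1.0, n_pts)
    freq = rng.uniform(0.8, 2.0)
    phase = rng.uniform(0.0, 2.0 * np.pi)
    prof = gain * (1.0 + unevenness * np.sin(2.0 * np.pi * freq * s + phase))
    return np.clip(prof, 0.05, 1.0)


def _isv_centerline(rng, x: float, y_top: float, y_bot: float,
                    n_pts: int = 9, wobble: float = 1.5) -> np.ndarray:
    ys = np.linspace(y_bot, y_top, n_pts)
    drift = rng.uniform(-2.0, 2.0)
    xs = x + np.linspace(0.0, drift, n_pts) + rng.normal(0.0, wobble / 3.0, n_pts)
    xs[0] = x
    return np.column_stack([ys, xs])


def _make_pair(rng, cfg: PhantomConfig, x: float, y_top: float, y_bot: float,
               x_next: float | None) -> tuple[list[VesselSpec], list[VesselSpec], str]:
    """Build the foreground ISV (possibly abnormal) and its optional
    background partner at anchor column ``x``."""
    kind = "normal"
    if rng.random() < cfg.p_abnormal:
        kind = ABNORMAL_KINDS[rng.integers(len(ABNORMAL_KINDS))]
    fg_gain = rng.uniform(0.65, 1.0)
    width = cfg.vessel_width * rng.uniform(0.85, 1.2)

    fg: list[VesselSpec] = []
    cl = _isv_centerline(rng, x, y_top, y_bot)
    if kind == "short":
        stop = rng.uniform(0.35, 0.65)
        n_keep = max(int(np.ceil(stop * len(cl))), 2)
        cl = cl[:n_keep]
    prof = _modulated_profile(rng, len(cl), fg_gain, cfg.intensity_unevenness)
    fg.append(VesselSpec(kind, cl, width, prof))

    if kind == "branching":
        k0 = len(cl) // 2
        n_br = len(cl) - k0
        branch = cl[k0:].copy()
        branch[:, 1] += np.linspace(0.0, rng.uniform(8.0, 16.0) * rng.choice([-1, 1]),
                                    n_br)
        bprof = _modulated_profile(rng, n_br, fg_gain * rng.uniform(0.8, 1.0),
                                   cfg.intensity_unevenness)
        fg.append(VesselSpec("branching", branch, width * 0.8, bprof))
    elif kind == "adhesion":
        # a thick pillar bridging toward the neighbouring vessel position
        y_mid = (y_top + y_bot) / 2.0 + rng.uniform(-8.0, 8.0)
        reach = (x_next - x) if x_next is not None else rng.uniform(10.0, 16.0)
        bridge = np.array([[y_mid, x], [y_mid + rng.uniform(-3, 3), x + reach]])
        bprof = np.full(2, min(fg_gain, 1.0))
        fg.append(VesselSpec("adhesion", bridge, width * 1.6, bprof))

    bg: list[VesselSpec] = []
    if rng.random() < cfg.background_vessel_prob:
        off = rng.uniform(3.0, 8.0) * rng.choice([-1, 1])
        bcl = _isv_centerline(rng, x + off, y_top, y_bot)
        bgain = fg_gain * rng.uniform(0.5, 1.0)
        bprof = _modulated_profile(rng, len(bcl), bgain, cfg.intensity_unevenness)
        bg.append(VesselSpec("background", bcl, width * rng.uniform(0.8, 1.1), bprof))
    return fg, bg, kind


def generate_phantom(config: PhantomConfig) -> PhantomSample:
    """Generate one phantom frame; deterministic given ``config.seed``."""
    h, w = config.image_size
    n = config.n_isv_pairs
    if h < MIN_HEIGHT:
        raise ValueError(f"image height {h} too small; minimum is {MIN_HEIGHT}")
    min_w = 2 * _MARGIN + max(n, 1) * MIN_PAIR_SPACING
    if n >= 1 and w < min_w:
        raise ValueError(
            f"image width {w} too small to place {n} ISV pair(s); "
            f"minimum width is {min_w} ({MIN_PAIR_SPACING} px per pair "
            f"plus {_MARGIN} px margins)")

    rng = np.random.default_rng(config.seed)
    y_top = 0.15 * h
    y_bot = 0.85 * h

    # rails: DLAV (top) and DA (bottom), gently wavy, context only
    rail_specs = []
    for y0 in (y_top, y_bot):
        xs = np.linspace(-2.0, w + 1.0, 12)
        ys = y0 + rng.normal(0.0, 0.6, len(xs))
        gain = rng.uniform(0.7, 1.0)
        prof = _modulated_profile(rng, len(xs), gain, config.intensity_unevenness / 2)
        rail_specs.append(VesselSpec("rail", np.column_stack([ys, xs]),
                                     config.vessel_width * 1.2, prof))

    # anchor columns for the pairs
    fg_specs: list[VesselSpec] = []
    bg_specs: list[VesselSpec] = []
    kinds: list[str] = []
    if n >= 1:
        spacing = (w - 2.0 * _MARGIN) / n
        anchors = [_MARGIN + spacing * (i + 0.5) + rng.uniform(-0.1, 0.1) * spacing
                   for i in range(n)]
        for i, x in enumerate(anchors):
            x_next = anchors[i + 1] if i + 1 < n else None
            fg, bg, kind = _make_pair(rng, config, x, y_top, y_bot, x_next)
            fg_specs.extend(fg)
            bg_specs.extend(bg)
            kinds.append(kind)

    image = np.zeros((h, w))
    for spec in bg_specs:
        _paint(image, spec, config.antialias)
    for spec in rail_specs:
        _paint(image, spec, config.antialias)
    for spec in fg_specs:
        _paint(image, spec, config.antialias)

    if config.noise_sigma > 0:
        image = image + rng.normal(0.0, config.noise_sigma, image.shape)
    image = np.clip(image, 0.0, 1.0)

    fg_mask = np.zeros((h, w), dtype=np.uint8)
    for spec in fg_specs:
        alpha, _ = rasterize_spec(spec, (h, w), antialias=False)
        fg_mask |= alpha.astype(np.uint8)
    bg_mask = np.zeros((h, w), dtype=np.uint8)
    for spec in bg_specs:
        alpha, _ = rasterize_spec(spec, (h, w), antialias=False)
        bg_mask |= alpha.astype(np.uint8)

    return PhantomSample(image=image, fg_mask=fg_mask, bg_mask=bg_mask,
                         fg_specs=fg_specs, bg_specs=bg_specs,
                         rail_specs=rail_specs, kinds=kinds)


def generate_dataset(n: int, config: PhantomConfig
                     ) -> tuple[list[PhantomSample], list[dict]]:
    """Generate ``n`` phantoms with per-sample seeds ``config.seed + i``.

    Returns the samples and a manifest listing each sample's seed and the
    abnormality kind of every ISV pair.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    samples, manifest = [], []
    for i in range(n):
        cfg_i = PhantomConfig(**{**config.__dict__, "seed": config.seed + i})
        sample = generate_phantom(cfg_i)
        samples.append(sample)
        manifest.append({"index": i, "seed": cfg_i.seed, "kinds": sample.kinds})
    return samples, manifest


# ---------------------------------------------------------------------------
# File I/O (8-bit grayscale PNG images, {0, 255} PNG masks, JSON manifest)
# ---------------------------------------------------------------------------

def save_image(image: np.ndarray, path) -> None:
    arr = np.clip(np.asarray(image) * 255.0, 0, 255).round().astype(np.uint8)
    Image.fromarray(arr, mode="L").save(path)


def save_mask(mask: np.ndarray, path) -> None:
    Image.fromarray((np.asarray(mask) > 0).astype(np.uint8) * 255, mode="L").save(path)


def load_image(path) -> np.ndarray:
    """Read a grayscale or RGB image (PNG/TIFF), collapsed to one channel
    and scaled to [0, 1]."""
    arr = np.asarray(Image.open(path), dtype=np.float64)
    if arr.ndim == 3:
        arr = arr[..., :3].mean(axis=-1)
    return arr / 255.0


def load_mask(path) -> np.ndarray:
    arr = np.asarray(Image.open(path))
    if arr.ndim == 3:
        arr = arr[..., :3].max(axis=-1)
    return (arr > 127).astype(np.uint8)


def save_sample(sample: PhantomSample, out_dir, stem: str) -> dict:
    """Write one sample; returned paths are relative to ``out_dir`` so a
    dataset directory stays relocatable."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    names = {
        "image": f"{stem}_image.png",
        "fg_mask": f"{stem}_fg.png",
        "bg_mask": f"{stem}_bg.png",
    }
    save_image(sample.image, out_dir / names["image"])
    save_mask(sample.fg_mask, out_dir / names["fg_mask"])
    save_mask(sample.bg_mask, out_dir / names["bg_mask"])
    return names


def save_dataset(n: int, config: PhantomConfig, out_dir) -> list[dict]:
    """Generate and write a dataset plus its ``manifest.json``."""
    samples, manifest = generate_dataset(n, config)
    out_dir = Path(out_dir)
    for sample, record in zip(samples, manifest):
        record.update(save_sample(sample, out_dir, f"sample{record['index']:04d}"))
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
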