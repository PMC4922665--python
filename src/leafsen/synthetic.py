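"""Seeded generator of synthetic plant scenes with exact ground truth.

Scenes emulate top-view/side-view phenotyping images: a cluster of
elongated, gently curved green leaves fanning out from a basal point on a
dark homogeneous background, optionally behind a blue support frame, with
senescent (yellow/brown) regions planted at a controlled area fraction.
Every scene carries its own plant mask, per-pixel color-category map and
realized senescent fraction, so segmentation, classification and the full
restoration pipeline can be validated without real imagery.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import categories as cat
from .io import save_image, save_mask

__all__ = [
    "DEFAULT_PALETTE",
    "SyntheticSceneSpec",
    "SyntheticTruth",
    "generate_scene",
    "generate_series",
    "write_truth",
]

# Representative RGB colors in [0,1]. Chosen so the five classes are
# linearly separable in HSV under the default classification thresholds
# even with per-pixel jitter.
DEFAULT_PALETTE: dict[str, tuple[float, float, float]] = {
    "dark_green": (0.10, 0.35, 0.08),
    "light_green": (0.35, 0.60, 0.15),
    "light_yellow": (0.75, 0.70, 0.15),
    "brown": (0.45, 0.30, 0.10),
    "background": (0.12, 0.12, 0.14),
    "frame_blue": (0.15, 0.25, 0.65),
}

_DAY_SEED_MULT = 1_000_003  # stable per-day seed derivation, see _day_seed
_DAY_SEED_STEP = 7_919


def _day_seed(base_seed: int, day: int) -> int:
    return (int(base_seed) * _DAY_SEED_MULT + _DAY_SEED_STEP * int(day)) % (2**31)


@dataclass
class SyntheticSceneSpec:
    """Parameters of one synthetic plant scene.

    Leaf geometry ranges are in pixels; ``curvature`` is the lateral
    deflection of the leaf midline at half length. ``senescent_fraction``
    is the target fraction of plant pixels in {light_yellow, brown}.
    """

    image_size: tuple[int, int] = (256, 256)
    leaf_count: int = 7
    leaf_length: tuple[float, float] = (70.0, 120.0)
    leaf_width: tuple[float, float] = (7.0, 13.0)
    curvature: tuple[float, float] = (5.0, 30.0)
    palette: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_PALETTE)
    )
    senescent_fraction: float = 0.0
    senescence_placement: str = "bottom"  # "bottom" | "uniform"
    include_frame: bool = False
    color_jitter: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.senescent_fraction <= 1.0:
            raise ValueError("senescent_fraction must be in [0, 1]")
        if self.leaf_count < 1:
            raise ValueError("leaf_count must be >= 1")
        if self.senescence_placement not in ("bottom", "uniform"):
            raise ValueError("senescence_placement must be 'bottom' or 'uniform'")
        colors = [tuple(self.palette[k]) for k in sorted(self.palette)]
        if len(set(colors)) != len(colors):
            raise ValueError("palette colors must be pairwise distinct")

    @classmethod
    def from_yaml(cls, path) -> "SyntheticSceneSpec":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        for key in ("image_size", "leaf_length", "leaf_width", "curvature"):
            if key in doc:
                doc[key] = tuple(doc[key])
        if "palette" in doc:
            doc["palette"] = {k: tuple(v) for k, v in doc["palette"].items()}
        return cls(**doc)


@dataclass
class SyntheticTruth:
    """A rendered scene plus its exact ground truth."""

    clean_image: np.ndarray  # (H, W, 3) float in [0, 1]
    plant_mask: np.ndarray  # (H, W) bool
    category_map: np.ndarray  # (H, W) uint8, labels from leafsen.categories
    realized_senescent_fraction: float
    frame_mask: np.ndarray | None = None  # (H, W) bool, support-frame pixels


def _sample_geometry(rng: np.random.Generator, spec: SyntheticSceneSpec) -> list[dict]:
    """Leaf skeleton parameters, independent of growth scale and color."""
    leaves = []
    for _ in range(spec.leaf_count):
        leaves.append(
            {
                "angle": rng.uniform(-1.15, 1.15),  # radians from vertical
                "length": rng.uniform(*spec.leaf_length),
                "width": rng.uniform(*spec.leaf_width),
                "curve": rng.uniform(*spec.curvature) * rng.choice([-1.0, 1.0]),
                "shade": rng.random(),  # < 0.5 -> dark green leaf
            }
        )
    return leaves


def _stamp_disk(canvas: np.ndarray, r: float, c: float, radius: float) -> None:
    H, W = canvas.shape
    r0, r1 = max(0, int(r - radius) - 1), min(H, int(r + radius) + 2)
    c0, c1 = max(0, int(c - radius) - 1), min(W, int(c + radius) + 2)
    if r0 >= r1 or c0 >= c1:
        return
    rr, cc = np.ogrid[r0:r1, c0:c1]
    canvas[r0:r1, c0:c1] |= (rr - r) ** 2 + (cc - c) ** 2 <= radius**2


def _render_leaves(
    spec: SyntheticSceneSpec, leaves: list[dict], scale: float
) -> tuple[np.ndarray, list[tuple[float, float]]]:
    """Rasterize leaves; returns (leaf_id map with -1 background, tips).

    Where leaves overlap the earlier-drawn leaf keeps the pixel, so each
    plant pixel belongs to exactly one leaf.
    """
    H, W = spec.image_size
    base_r, base_c = H * 0.92, W * 0.5
    leaf_id = np.full((H, W), -1, dtype=np.int16)
    tips: list[tuple[float, float]] = []
    for i, leaf in enumerate(leaves):
        length = leaf["length"] * scale
        width = max(1.5, leaf["width"] * scale)
        tip_r = base_r - length * np.cos(leaf["angle"])
        tip_c = base_c + length * np.sin(leaf["angle"])
        # quadratic Bezier: control point offset laterally at mid-length
        perp = np.array([np.sin(leaf["angle"]), np.cos(leaf["angle"])])
        mid = np.array([(base_r + tip_r) / 2, (base_c + tip_c) / 2])
        ctrl = mid + leaf["curve"] * scale * perp
        n_steps = max(8, int(length))
        t = np.linspace(0.0, 1.0, n_steps)
        pts_r = (1 - t) ** 2 * base_r + 2 * (1 - t) * t * ctrl[0] + t**2 * tip_r
        pts_c = (1 - t) ** 2 * base_c + 2 * (1 - t) * t * ctrl[1] + t**2 * tip_c
        single = np.zeros((H, W), dtype=bool)
        for ti, pr, pc in zip(t, pts_r, pts_c):
            radius = (width / 2.0) * (1.0 - 0.65 * ti)  # taper toward the tip
            _stamp_disk(single, pr, pc, radius)
        leaf_id[single & (leaf_id < 0)] = i
        tips.append((float(pts_r[-1]), float(pts_c[-1])))
    return leaf_id, tips


def _frame_mask(spec: SyntheticSceneSpec) -> np.ndarray:
    H, W = spec.image_size
    m = np.zeros((H, W), dtype=bool)
    bar = max(3, W // 64)
    for cfrac in (0.10, 0.90):
        c0 = int(W * cfrac) - bar // 2
        m[:, max(0, c0) : min(W, c0 + bar)] = True
    r0 = int(H * 0.30) - bar // 2
    m[max(0, r0) : min(H, r0 + bar), :] = True
    return m


def _select_senescent(
    spec: SyntheticSceneSpec,
    leaf_id: np.ndarray,
    tips: list[tuple[float, float]],
    fraction: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Pick senescent plant pixels leaf-wise; returns (senescent, brown).

    Senescence is assigned whole leaves at a time — the way it develops
    and is scored on real plants — in bottom-up order ("bottom" placement:
    leaves with the lowest pixels first) or in a seeded random order
    ("uniform"). The leaf that crosses the target fraction senesces
    partially, from its tip backwards (tips yellow first). Within the
    senescent set the most advanced 40% of pixels are brown, the rest
    light yellow.
    """
    plant = leaf_id >= 0
    sen = np.zeros(plant.shape, dtype=bool)
    brown = np.zeros(plant.shape, dtype=bool)
    n_plant = int(plant.sum())
    k = int(round(fraction * n_plant))
    if k == 0:
        return sen, brown
    present = [i for i in range(len(tips)) if (leaf_id == i).any()]
    if spec.senescence_placement == "bottom":
        # lowest leaves first (largest mean row index)
        mean_row = {
            i: float(np.nonzero(leaf_id == i)[0].mean()) for i in present
        }
        order = sorted(present, key=lambda i: (-mean_row[i], i))
    else:
        order = [present[j] for j in rng.permutation(len(present))]
    # concatenate pixel indices leaf by leaf, tip-first within each leaf
    ranked: list[np.ndarray] = []
    for i in order:
        rr, cc = np.nonzero(leaf_id == i)
        d2 = (rr - tips[i][0]) ** 2 + (cc - tips[i][1]) ** 2
        idx = np.argsort(d2, kind="stable")
        ranked.append(rr[idx] * plant.shape[1] + cc[idx])
    flat = np.concatenate(ranked)
    sen.ravel()[flat[:k]] = True
    k_brown = int(round(0.4 * k))
    brown.ravel()[flat[:k_brown]] = True
    return sen, brown


def _colorize(
    spec: SyntheticSceneSpec,
    category_map: np.ndarray,
    frame: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    H, W = category_map.shape
    img = np.empty((H, W, 3))
    pal = spec.palette
    img[:] = pal["background"]
    bg_jitter = rng.uniform(-0.02, 0.02, size=(H, W, 3))
    img *= 1.0 + bg_jitter
    if frame.any():
        fj = 1.0 + rng.uniform(-0.03, 0.03, size=(int(frame.sum()), 3))
        img[frame] = np.asarray(pal["frame_blue"]) * fj
    for code, name in cat.CATEGORY_NAMES.items():
        if code == cat.BACKGROUND:
            continue
        sel = category_map == code
        n = int(sel.sum())
        if n == 0:
            continue
        jit = 1.0 + rng.uniform(-spec.color_jitter, spec.color_jitter, size=(n, 3))
        img[sel] = np.asarray(pal[name]) * jit
    return np.clip(img, 0.0, 1.0)


def _render(
    spec: SyntheticSceneSpec,
    leaves: list[dict],
    scale: float,
    fraction: float,
    rng: np.random.Generator,
) -> SyntheticTruth:
    leaf_id, tips = _render_leaves(spec, leaves, scale)
    plant = leaf_id >= 0
    if not plant.any():
        raise RuntimeError("synthetic geometry produced an empty plant")
    frame = _frame_mask(spec) if spec.include_frame else np.zeros_like(plant)
    frame &= ~plant  # plant occludes the frame
    sen, brown = _select_senescent(spec, leaf_id, tips, fraction, rng)
    dark = np.zeros_like(plant)
    for i, leaf in enumerate(leaves):
        if leaf["shade"] < 0.5:
            dark |= leaf_id == i
    category = np.full(plant.shape, cat.BACKGROUND, dtype=np.uint8)
    category[plant & dark] = cat.DARK_GREEN
    category[plant & ~dark] = cat.LIGHT_GREEN
    category[sen] = cat.LIGHT_YELLOW
    category[brown] = cat.BROWN
    img = _colorize(spec, category, frame, rng)
    realized = float(sen.sum() / plant.sum())
    return SyntheticTruth(
        clean_image=img,
        plant_mask=plant,
        category_map=category,
        realized_senescent_fraction=realized,
        frame_mask=frame,
    )


def generate_scene(spec: SyntheticSceneSpec) -> SyntheticTruth:
    """Render one scene deterministically from ``spec.seed``.

    The realized senescent fraction equals the target up to pixel-count
    rounding; with ``senescence_placement="bottom"`` the senescent area is
    concentrated in the lower part of the plant, emulating the usual
    bottom-up progression of stress-induced senescence.
    """
    rng = np.random.default_rng(spec.seed)
    leaves = _sample_geometry(rng, spec)
    return _render(spec, leaves, 1.0, spec.senescent_fraction, rng)


def generate_series(
    spec: SyntheticSceneSpec,
    days: int,
    onset_day: int,
    growth_rate: float,
    senescence_rate: float,
) -> list[SyntheticTruth]:
    """Render a daily time series with growth and post-onset senescence.

    The plant's projected area grows by ``growth_rate`` (relative area per
    day, linear ramp); the senescent fraction is 0 strictly before
    ``onset_day`` and ``senescence_rate * (day - onset_day + 1)`` from
    onset on, capped at 1. Leaf skeletons are fixed across days (sampled
    from ``spec.seed``); per-day color jitter uses a seed derived as
    ``(seed * 1000003 + 7919 * day) mod 2^31``.
    """
    if not 0 <= onset_day < days:
        raise ValueError(f"onset_day must be in [0, days), got {onset_day} of {days}")
    if growth_rate < 0 or senescence_rate < 0:
        raise ValueError("rates must be >= 0")
    geom_rng = np.random.default_rng(spec.seed)
    leaves = _sample_geometry(geom_rng, spec)
    out = []
    for day in range(days):
        scale = float(np.sqrt(1.0 + growth_rate * day))  # area ~ 1 + rate*day
        if day < onset_day:
            frac = 0.0
        else:
            frac = min(1.0, senescence_rate * (day - onset_day + 1))
        rng = np.random.default_rng(_day_seed(spec.seed, day))
        out.append(_render(spec, leaves, scale, frac, rng))
    return out


def write_truth(truth: SyntheticTruth, outdir, stem: str = "scene") -> None:
    """Write image/mask/category PNGs plus a JSON sidecar of the truth."""
    os.makedirs(outdir, exist_ok=True)
    save_image(truth.clean_image, os.path.join(outdir, f"{stem}_image.png"))
    save_mask(truth.plant_mask, os.path.join(outdir, f"{stem}_mask.png"))
    # category map stored as raw label values in a grayscale PNG
    import imageio.v3 as iio

    iio.imwrite(
        os.path.join(outdir, f"{stem}_categories.png"),
        truth.category_map.astype(np.uint8),
        extension=".png",
    )
    sidecar = {
        "realized_senescent_fraction": truth.realized_senescent_fraction,
        "plant_area_px": int(truth.plant_mask.sum()),
        "category_counts": {
            name: int((truth.category_map == code).sum())
            for code, name in cat.CATEGORY_NAMES.items()
        },
    }
    with open(os.path.join(outdir, f"{stem}_truth.json"), "w") as fh:
        json.dump(sidecar, fh, indent=2)
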