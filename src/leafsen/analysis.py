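"""Per-image senescence quantification.

Pipeline: segment the plant from the background, split its vertical extent
into three equal-height zones (top/mid/bottom), classify every plant pixel
into one of four color categories — dark green, light green, light yellow,
brown — and report per-zone and overall category counts. Any yellow or
brown plant area counts as senescent; leaves fallen below the plant's
reference span belong to the bottom zone. Bluish restoration artifacts are
excluded from all plant categories, so ringing introduced by the linear
correction does not inflate the senescence estimate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy import ndimage
from skimage.color import rgb2hsv
from skimage.morphology import remove_small_holes, remove_small_objects

from . import categories as cat
from .io import as_image, as_mask
from .synthetic import DEFAULT_PALETTE

__all__ = [
    "ColorClassConfig",
    "ZoneMap",
    "SenescenceReport",
    "segment_plant",
    "partition_zones",
    "classify_colors",
    "senescence_report",
    "analyze_image",
]

ZONE_NAMES = ("top", "mid", "bottom")

# (hue_lo_deg, hue_hi_deg, sat_lo, sat_hi, val_lo, val_hi); half-open on
# hue and value so adjacent categories cannot overlap. The 0.40 saturation
# floor is the plant-tissue/background divide: healthy and senescent
# tissue colors are strongly saturated while blur-transition halos and
# soil/pot grays are not.
_DEFAULT_RANGES: dict[str, tuple[float, float, float, float, float, float]] = {
    "dark_green": (75.0, 165.0, 0.40, 1.0, 0.0, 0.45),
    "light_green": (75.0, 165.0, 0.40, 1.0, 0.45, 1.0001),
    "light_yellow": (40.0, 75.0, 0.40, 1.0, 0.0, 1.0001),
    "brown": (10.0, 40.0, 0.40, 1.0, 0.0, 0.6),
}


def _rgb_to_hsv_one(rgb) -> tuple[float, float, float]:
    h, s, v = rgb2hsv(np.asarray(rgb, dtype=np.float64).reshape(1, 1, 3))[0, 0]
    return (float(h) * 360.0, float(s), float(v))


@dataclass
class ColorClassConfig:
    """HSV decision rules for the four plant color categories.

    ``ranges`` maps category name to (hue_lo, hue_hi, sat_lo, sat_hi,
    val_lo, val_hi) with hue in degrees; ranges must be pairwise disjoint.
    Pixels inside the plant mask matching no range fall back to the
    nearest category centroid (circular hue metric). ``ringing_hue``
    bounds the bluish artifact band excluded from all plant categories,
    and ``frame_hue`` the blue support-frame band (both -> background).
    """

    ranges: dict[str, tuple[float, float, float, float, float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_RANGES)
    )
    centroids: dict[str, tuple[float, float, float]] | None = None
    ringing_hue: tuple[float, float] = (180.0, 280.0)
    min_saturation: float = 0.40
    min_small_object: int = 10
    max_hole: int = 5

    def __post_init__(self) -> None:
        unknown = set(self.ranges) - set(cat.CATEGORY_CODES)
        if unknown:
            raise ValueError(f"unknown categories in config: {sorted(unknown)}")
        names = sorted(self.ranges)
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                if self._overlap(self.ranges[a], self.ranges[b]):
                    raise ValueError(f"configured ranges overlap: {a} vs {b}")
        if self.centroids is None:
            self.centroids = {
                name: tuple(_rgb_to_hsv_one(DEFAULT_PALETTE[name]))
                for name in self.ranges
            }

    @staticmethod
    def _overlap(r1, r2) -> bool:
        for lo in (0, 2, 4):
            if r1[lo] >= r2[lo + 1] or r2[lo] >= r1[lo + 1]:
                return False
        return True

    def to_yaml(self, path) -> None:
        doc = {
            "ranges": {k: [float(x) for x in v] for k, v in self.ranges.items()},
            "centroids": {
                k: [float(x) for x in v] for k, v in (self.centroids or {}).items()
            },
            "ringing_hue": list(self.ringing_hue),
            "min_saturation": self.min_saturation,
            "min_small_object": self.min_small_object,
            "max_hole": self.max_hole,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh)

    @classmethod
    def from_yaml(cls, path) -> "ColorClassConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        kwargs = {}
        if "ranges" in doc:
            kwargs["ranges"] = {k: tuple(v) for k, v in doc["ranges"].items()}
        if "centroids" in doc:
            kwargs["centroids"] = {k: tuple(v) for k, v in doc["centroids"].items()}
        for key in ("ringing_hue", "min_saturation", "min_small_object", "max_hole"):
            if key in doc:
                kwargs[key] = tuple(doc[key]) if key == "ringing_hue" else doc[key]
        return cls(**kwargs)


def _hsv(img: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    hsv = rgb2hsv(img)
    return hsv[:, :, 0] * 360.0, hsv[:, :, 1], hsv[:, :, 2]


def _range_members(hue, sat, val, rng) -> np.ndarray:
    h0, h1, s0, s1, v0, v1 = rng
    return (
        (hue >= h0) & (hue < h1) & (sat >= s0) & (sat <= s1) & (val >= v0) & (val < v1)
    )


def segment_plant(img: np.ndarray, config: ColorClassConfig | None = None) -> np.ndarray:
    """Foreground segmentation by plant-color membership.

    A pixel is plant if its HSV color falls in any of the four category
    ranges and outside the bluish frame/ringing band; small speckles are
    removed and small holes filled. An empty mask is a valid result.
    """
    config = config or ColorClassConfig()
    a = as_image(img)
    hue, sat, val = _hsv(a)
    plant = np.zeros(a.shape[:2], dtype=bool)
    for rng in config.ranges.values():
        plant |= _range_members(hue, sat, val, rng)
    blue = (hue >= config.ringing_hue[0]) & (hue < config.ringing_hue[1])
    plant &= ~blue
    plant &= sat >= config.min_saturation
    # remove components smaller than min_small_object px, fill holes <= max_hole px
    plant = remove_small_objects(plant, max_size=config.min_small_object - 1)
    plant = remove_small_holes(plant, max_size=config.max_hole)
    return plant


@dataclass
class ZoneMap:
    """Top/mid/bottom zone assignment of plant pixels.

    ``zone`` is -1 off the plant, else 0 (top), 1 (mid), 2 (bottom).
    ``boundaries`` are the last rows of the top and mid bands. Plant
    pixels below the reference span (fallen leaves) are bottom; above it,
    top.
    """

    zone: np.ndarray  # (H, W) int8
    boundaries: tuple[int, int]
    reference_span: tuple[int, int]


def partition_zones(
    mask: np.ndarray, reference_span: tuple[int, int] | None = None
) -> ZoneMap:
    """Split the plant's vertical span into three equal-height zones.

    The span defaults to the bounding rows of the largest connected
    component; a fixed ``reference_span`` (first_row, last_row) may be
    supplied for cross-day comparability.
    """
    m = as_mask(mask)
    if not m.any():
        raise ValueError("cannot partition an empty plant mask")
    if reference_span is None:
        labels, n = ndimage.label(m)
        largest = np.argmax(np.bincount(labels.ravel())[1:]) + 1
        rows = np.nonzero((labels == largest).any(axis=1))[0]
        r0, r1 = int(rows.min()), int(rows.max())
    else:
        r0, r1 = int(reference_span[0]), int(reference_span[1])
        if r0 > r1:
            raise ValueError("reference span must satisfy first <= last")
    span = r1 - r0 + 1
    row_idx = np.arange(m.shape[0])
    zone_of_row = np.clip(np.floor(3.0 * (row_idx - r0) / span).astype(int), 0, 2)
    zone = np.where(m, zone_of_row[:, None], -1).astype(np.int8)
    b1 = r0 + int(np.ceil(span / 3.0)) - 1
    b2 = r0 + int(np.ceil(2.0 * span / 3.0)) - 1
    return ZoneMap(zone=zone, boundaries=(b1, b2), reference_span=(r0, r1))


def classify_colors(
    img: np.ndarray, mask: np.ndarray, config: ColorClassConfig | None = None
) -> np.ndarray:
    """Assign each plant pixel to a color category.

    Membership is by HSV range; mask pixels matching no range are assigned
    the nearest category centroid with hue treated circularly, except
    bluish ringing-band pixels which go to background.
    """
    config = config or ColorClassConfig()
    a = as_image(img)
    m = as_mask(mask, like=a)
    hue, sat, val = _hsv(a)
    out = np.full(a.shape[:2], cat.BACKGROUND, dtype=np.uint8)
    assigned = np.zeros(a.shape[:2], dtype=bool)
    for name, rng in config.ranges.items():
        sel = m & ~assigned & _range_members(hue, sat, val, rng)
        out[sel] = cat.CATEGORY_CODES[name]
        assigned |= sel
    rest = m & ~assigned
    # saturated blue = ringing artifact or frame -> background; desaturated
    # blue-hued pixels (e.g. filled mask holes) still get a plant label
    ringing = (
        (hue >= config.ringing_hue[0]) & (hue < config.ringing_hue[1]) & (sat >= 0.25)
    )
    rest &= ~ringing
    if rest.any():
        names = list(config.centroids)
        cen = np.array([config.centroids[n] for n in names])  # (K, 3) h-deg, s, v
        hr, sr, vr = hue[rest], sat[rest], val[rest]
        dh = np.abs(hr[:, None] - cen[None, :, 0])
        dh = np.minimum(dh, 360.0 - dh) / 180.0
        d2 = dh**2 + (sr[:, None] - cen[None, :, 1]) ** 2 + (vr[:, None] - cen[None, :, 2]) ** 2
        codes = np.array([cat.CATEGORY_CODES[n] for n in names], dtype=np.uint8)
        out[rest] = codes[np.argmin(d2, axis=1)]
    return out


@dataclass
class SenescenceReport:
    """Per-zone and overall category pixel accounting for one image."""

    zone_counts: dict[str, dict[str, int]]  # zone name -> category name -> px
    overall_counts: dict[str, int]
    zone_senescent_pct: dict[str, float]
    overall_senescent_pct: float
    plant_area: int
    zone_boundaries: tuple[int, int]

    def to_dict(self) -> dict:
        return {
            "plant_area_px": self.plant_area,
            "overall_senescent_pct": self.overall_senescent_pct,
            "zone_senescent_pct": self.zone_senescent_pct,
            "overall_counts": self.overall_counts,
            "zone_counts": self.zone_counts,
            "zone_boundaries": list(self.zone_boundaries),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def csv_row(self) -> dict:
        return {
            "area_px": self.plant_area,
            "pct_overall": self.overall_senescent_pct,
            "pct_top": self.zone_senescent_pct["top"],
            "pct_mid": self.zone_senescent_pct["mid"],
            "pct_bottom": self.zone_senescent_pct["bottom"],
        }


def senescence_report(categories: np.ndarray, zones: ZoneMap) -> SenescenceReport:
    """Exact integer accounting of category pixels per zone and overall.

    The senescent percentage is 100 * (light_yellow + brown) / plant
    pixels in scope; the overall percentage is by construction the
    area-weighted mean of the zone percentages.
    """
    cmap = np.asarray(categories)
    if cmap.shape != zones.zone.shape:
        raise ValueError(
            f"category map shape {cmap.shape} != zone map shape {zones.zone.shape}"
        )
    plant = cmap != cat.BACKGROUND
    zone_counts: dict[str, dict[str, int]] = {}
    zone_pct: dict[str, float] = {}
    plant_names = [cat.CATEGORY_NAMES[c] for c in cat.PLANT_CATEGORIES]
    for zi, zname in enumerate(ZONE_NAMES):
        sel = plant & (zones.zone == zi)
        counts = {
            name: int((cmap[sel] == cat.CATEGORY_CODES[name]).sum())
            for name in plant_names
        }
        zone_counts[zname] = counts
        total = sum(counts.values())
        senescent = counts["light_yellow"] + counts["brown"]
        zone_pct[zname] = 100.0 * senescent / total if total else 0.0
    overall = {
        name: sum(zone_counts[z][name] for z in ZONE_NAMES) for name in plant_names
    }
    area = sum(overall.values())
    sen = overall["light_yellow"] + overall["brown"]
    return SenescenceReport(
        zone_counts=zone_counts,
        overall_counts=overall,
        zone_senescent_pct=zone_pct,
        overall_senescent_pct=100.0 * sen / area if area else 0.0,
        plant_area=area,
        zone_boundaries=zones.boundaries,
    )


def analyze_image(
    img: np.ndarray,
    config: ColorClassConfig | None = None,
    correction=None,
    reference_span: tuple[int, int] | None = None,
) -> SenescenceReport:
    """Full per-image pipeline: (restore ->) segment -> zone -> classify -> report.

    ``correction`` may be a fitted CorrectionMatrix; when given, the image
    is restored before analysis. An image with no detectable plant yields
    an all-zero report.
    """
    config = config or ColorClassConfig()
    a = as_image(img)
    if correction is not None:
        from .restore import apply_correction

        a = apply_correction(a, correction)
    mask = segment_plant(a, config)
    if not mask.any():
        empty = {z: {cat.CATEGORY_NAMES[c]: 0 for c in cat.PLANT_CATEGORIES} for z in ZONE_NAMES}
        return SenescenceReport(
            zone_counts=empty,
            overall_counts={cat.CATEGORY_NAMES[c]: 0 for c in cat.PLANT_CATEGORIES},
            zone_senescent_pct={z: 0.0 for z in ZONE_NAMES},
            overall_senescent_pct=0.0,
            plant_area=0,
            zone_boundaries=(-1, -1),
        )
    zones = partition_zones(mask, reference_span=reference_span)
    cats = classify_colors(a, mask, config)
    return senescence_report(cats, zones)
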