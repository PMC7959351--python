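"""Gray-zone / nongray-zone segmentation of treated-pot images.

Soil directly reached by hydrogen peroxide is decolorized to near-neutral
gray (R ≈ G ≈ B), while untreated soil stays brown (R > G > B). The split is
therefore a chroma threshold: a pixel's grayness is 1 − chroma/255, and
non-green pixels above the threshold (with plausible brightness) seed the
gray zone. A majority filter removes speckle, and green (weed) pixels inherit
the zone of the non-green soil around them, since a weed physically stands on
one zone's soil. The procedure replaces an interactive background-removal
step with a deterministic, parameterized one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .quantify import RGBCode

__all__ = [
    "GRAY_ZONE",
    "NONGRAY_ZONE",
    "BACKGROUND",
    "GREEN",
    "ZoneMask",
    "DegenerateSegmentationError",
    "grayness_score",
    "segment_zones",
    "apply_mask",
]

# zone codes stored in ZoneMask.zone
BACKGROUND = 0
GRAY_ZONE = 1
NONGRAY_ZONE = 2
GREEN = 3  # only used in the 4-label membership view

ALPHA_THRESHOLD = 128


class DegenerateSegmentationError(ValueError):
    """Raised when no non-green pixels exist to define the zones."""


@dataclass(frozen=True)
class ZoneMask:
    """Per-pixel zone labelling of one image.

    ``zone`` holds GRAY_ZONE / NONGRAY_ZONE / BACKGROUND for every pixel
    (green pixels already carry the zone they were assigned to);
    ``green`` marks which unmasked pixels passed the green rule.
    ``membership`` gives the 4-label view where green pixels show as GREEN.
    """

    zone: np.ndarray  # (H, W) uint8
    green: np.ndarray  # (H, W) bool

    @property
    def width(self) -> int:
        return self.zone.shape[1]

    @property
    def height(self) -> int:
        return self.zone.shape[0]

    @property
    def membership(self) -> np.ndarray:
        m = self.zone.copy()
        m[self.green] = GREEN
        return m

    def zone_fraction(self, label: int) -> float:
        unmasked = self.zone != BACKGROUND
        if not unmasked.any():
            return 0.0
        return float((self.zone == label).sum() / unmasked.sum())


def grayness_score(code: RGBCode | np.ndarray) -> float | np.ndarray:
    """1 − chroma/255: 1.0 for perfect gray (R=G=B), 0.0 for a pure hue."""
    arr = np.asarray(code, dtype=np.float64)
    mx = arr[..., :3].max(axis=-1)
    mn = arr[..., :3].min(axis=-1)
    score = 1.0 - (mx - mn) / 255.0
    return float(score) if score.ndim == 0 else score


def _rgba(image: np.ndarray) -> np.ndarray:
    arr = np.asarray(image)
    if arr.ndim != 3 or arr.shape[2] not in (3, 4):
        raise ValueError("expected an (H, W, 3|4) RGB(A) array")
    if arr.shape[2] == 3:
        alpha = np.full(arr.shape[:2] + (1,), 255, dtype=np.uint8)
        arr = np.concatenate([arr, alpha], axis=2)
    return arr


def _box_count(mask: np.ndarray, radius: int) -> np.ndarray:
    """Count of True cells in the (2r+1)² square window around each pixel."""
    size = 2 * radius + 1
    return ndimage.uniform_filter(
        mask.astype(np.float64), size=size, mode="constant", cval=0.0
    ) * (size * size)


def segment_zones(
    image: np.ndarray,
    gray_threshold: float = 0.85,
    brightness_range: tuple[float, float] = (60.0, 220.0),
    smoothing_radius: int = 3,
) -> ZoneMask:
    """Label every pixel of a pot image GRAY_ZONE, NONGRAY_ZONE or BACKGROUND.

    Non-green pixels whose grayness_score is at least ``gray_threshold`` and
    whose mean brightness lies inside ``brightness_range`` seed the gray zone;
    other non-green pixels are nongray. A majority vote in the
    (2*smoothing_radius+1)² window removes isolated speckle (ties go to
    nongray). Green pixels take the majority zone of non-green pixels in the
    same window, falling back to the nearest non-green pixel's zone when the
    window contains none. Deterministic for fixed inputs.
    """
    if not 0.0 <= gray_threshold <= 1.0:
        raise ValueError("gray_threshold must lie in [0, 1]")
    arr = _rgba(image)
    unmasked = arr[..., 3] >= ALPHA_THRESHOLD
    rgb = arr[..., :3].astype(np.float64)
    r, g, b = rgb[..., 0], rgb[..., 1], rgb[..., 2]

    green = (g > r) & (g > b) & unmasked
    soil = unmasked & ~green
    if not soil.any():
        raise DegenerateSegmentationError(
            "every unmasked pixel is green; no soil to segment"
        )

    grayness = grayness_score(rgb)
    brightness = rgb.mean(axis=-1)
    lo, hi = brightness_range
    seed = soil & (grayness >= gray_threshold) & (brightness >= lo) & (brightness <= hi)
    nongray = soil & ~seed

    # majority smoothing over non-green pixels only
    n_gray = _box_count(seed, smoothing_radius)
    n_nongray = _box_count(nongray, smoothing_radius)
    gray_final = soil & (n_gray > n_nongray)

    zone = np.full(arr.shape[:2], BACKGROUND, dtype=np.uint8)
    zone[soil] = NONGRAY_ZONE
    zone[gray_final] = GRAY_ZONE

    if green.any():
        has_neighbor = (n_gray + n_nongray) > 0
        green_zone = np.where(n_gray > n_nongray, GRAY_ZONE, NONGRAY_ZONE)
        # fallback: nearest non-green pixel's (smoothed) zone
        if not has_neighbor[green].all():
            _, (iy, ix) = ndimage.distance_transform_edt(~soil, return_indices=True)
            nearest = zone[iy, ix]
            far = green & ~has_neighbor
            zone[far] = nearest[far]
            near = green & has_neighbor
            zone[near] = green_zone[near]
        else:
            zone[green] = green_zone[green]

    return ZoneMask(zone=zone, green=green)


def apply_mask(image: np.ndarray, mask: ZoneMask, zone: int) -> np.ndarray:
    """Return a copy of the image with everything outside ``zone`` made
    transparent (alpha = 0); colors inside the zone are untouched."""
    arr = _rgba(image)
    if arr.shape[:2] != mask.zone.shape:
        raise ValueError("mask dimensions do not match image")
    out = arr.copy()
    out[mask.zone != zone, 3] = 0
    return out
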