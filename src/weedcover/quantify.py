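"""Color quantization, pixel histograms, and green-cover proportion.

The measurement chain mirrors a palette-reducing web image analyzer: each
image is reduced to a small set of quantized RGB codes with per-code pixel
counts, "weed green" codes are selected by the rule ``G > R and G > B``
(strict; gray pixels with R = G = B are never green), and the green-area
proportion of an image is the green pixel count divided by the unmasked
pixel count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from PIL import Image

__all__ = [
    "RGBCode",
    "PixelHistogram",
    "GreenSelection",
    "EmptyImageError",
    "load_image",
    "quantize_colors",
    "is_green",
    "select_green_codes",
    "green_proportion",
    "histogram_to_frame",
    "write_histograms_csv",
    "read_histograms_csv",
    "write_histograms_xlsx",
]

RGBCode = tuple[int, int, int]

#: alpha values below this mark a pixel as removed background
ALPHA_THRESHOLD = 128


class EmptyImageError(ValueError):
    """Raised when an image has no unmasked pixels to histogram."""


def format_code(code: RGBCode) -> str:
    """Render a code in the conventional ``R-G-B`` text form (e.g. ``0-43-0``)."""
    return f"{code[0]}-{code[1]}-{code[2]}"


def parse_code(text: str) -> RGBCode:
    r, g, b = (int(x) for x in text.strip().split("-"))
    for v in (r, g, b):
        if not 0 <= v <= 255:
            raise ValueError(f"channel out of range in code {text!r}")
    return (r, g, b)


@dataclass(frozen=True)
class PixelHistogram:
    """Per-image map from quantized RGB code to pixel count.

    ``total_pixels`` counts only unmasked pixels (alpha >= 128 when an alpha
    channel is present); ``masked_pixels`` counts the removed background.
    """

    counts: Mapping[RGBCode, int]
    total_pixels: int
    masked_pixels: int = 0
    label: str | None = None

    def __post_init__(self) -> None:
        if self.total_pixels <= 0:
            raise EmptyImageError("histogram has no unmasked pixels")
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("negative pixel count")
        if sum(self.counts.values()) != self.total_pixels:
            raise ValueError("counts do not sum to total_pixels")


@dataclass(frozen=True)
class GreenSelection:
    """How 'weed green' codes are picked from histograms.

    ``top_k`` keeps the most abundant qualifying codes (summed across all
    supplied histograms); ``"all"`` keeps every code passing the rule.
    ``require_shared_across_groups`` additionally demands a nonzero count in
    every group, mirroring the practice of keeping only codes that appear in
    both control and treatment images.
    """

    top_k: int | str = 6
    require_shared_across_groups: bool = False

    def __post_init__(self) -> None:
        if self.top_k != "all" and (not isinstance(self.top_k, int) or self.top_k < 1):
            raise ValueError("top_k must be a positive integer or 'all'")


def load_image(path: str | Path) -> np.ndarray:
    """Read PNG/GIF/JPEG into an RGBA uint8 array (H, W, 4)."""
    with Image.open(path) as im:
        return np.asarray(im.convert("RGBA"), dtype=np.uint8)


def _as_rgba(image: np.ndarray | Image.Image) -> np.ndarray:
    if isinstance(image, Image.Image):
        return np.asarray(image.convert("RGBA"), dtype=np.uint8)
    arr = np.asarray(image)
    if arr.ndim != 3 or arr.shape[2] not in (3, 4):
        raise ValueError("expected an (H, W, 3|4) RGB(A) array")
    if arr.shape[2] == 3:
        alpha = np.full(arr.shape[:2] + (1,), 255, dtype=np.uint8)
        arr = np.concatenate([arr, alpha], axis=2)
    return arr.astype(np.uint8, copy=False)


def quantize_channel(values: np.ndarray, levels: int) -> np.ndarray:
    """Map 0..255 channel values to the nearest of ``levels`` evenly spaced
    values including both endpoints, rounding half up."""
    if levels < 2:
        raise ValueError("levels_per_channel must be >= 2")
    step = 255.0 / (levels - 1)
    idx = np.floor(values.astype(np.float64) / step + 0.5)
    return np.floor(idx * step + 0.5).astype(np.uint8)


def quantize_colors(
    image: np.ndarray | Image.Image,
    levels_per_channel: int = 6,
    label: str | None = None,
) -> PixelHistogram:
    """Quantize an image's colors and tally pixels per quantized RGB code.

    ``levels_per_channel=256`` is the identity (raw color histogram).
    Alpha-masked pixels (alpha < 128) are excluded from the counts and from
    ``total_pixels``.
    """
    arr = _as_rgba(image)
    unmasked = arr[..., 3] >= ALPHA_THRESHOLD
    n_masked = int((~unmasked).sum())
    rgb = arr[unmasked][:, :3]
    if rgb.shape[0] == 0:
        raise EmptyImageError("image has zero unmasked pixels")
    q = quantize_channel(rgb, levels_per_channel)
    packed = (
        q[:, 0].astype(np.int64) << 16
        | q[:, 1].astype(np.int64) << 8
        | q[:, 2].astype(np.int64)
    )
    codes, counts = np.unique(packed, return_counts=True)
    table = {
        (int(c >> 16 & 255), int(c >> 8 & 255), int(c & 255)): int(n)
        for c, n in zip(codes, counts)
    }
    return PixelHistogram(
        counts=table,
        total_pixels=int(rgb.shape[0]),
        masked_pixels=n_masked,
        label=label,
    )


def is_green(code: RGBCode) -> bool:
    """Weed-green rule: G strictly exceeds both R and B."""
    r, g, b = code
    return g > r and g > b


def select_green_codes(
    histograms: Sequence[PixelHistogram] | Mapping[str, Sequence[PixelHistogram]],
    selection: GreenSelection = GreenSelection(),
) -> set[RGBCode]:
    """Pick the green codes used to score every image.

    Codes passing :func:`is_green` are ranked by pixel count summed across all
    histograms and truncated to ``selection.top_k`` (ties broken by (r, g, b)
    order). With ``require_shared_across_groups`` and a mapping input, a code
    must occur in at least one histogram of every group. If fewer qualifying
    codes exist than requested, all of them are returned with a warning.
    """
    if isinstance(histograms, Mapping):
        groups = {k: list(v) for k, v in histograms.items()}
        flat = [h for hs in groups.values() for h in hs]
    else:
        groups = None
        flat = list(histograms)
    if not flat:
        raise ValueError("at least one histogram is required")

    totals: dict[RGBCode, int] = {}
    for h in flat:
        for code, n in h.counts.items():
            if n > 0 and is_green(code):
                totals[code] = totals.get(code, 0) + n

    if selection.require_shared_across_groups and groups is not None:
        shared = set(totals)
        for hs in groups.values():
            present = {c for h in hs for c, n in h.counts.items() if n > 0}
            shared &= present
        totals = {c: n for c, n in totals.items() if c in shared}

    ranked = sorted(totals.items(), key=lambda kv: (-kv[1], kv[0]))
    if selection.top_k == "all":
        return {c for c, _ in ranked}
    k = int(selection.top_k)
    if len(ranked) < k:
        warnings.warn(
            f"only {len(ranked)} green codes available, fewer than top_k={k}",
            stacklevel=2,
        )
    return {c for c, _ in ranked[:k]}


def green_proportion(
    histogram: PixelHistogram, green_codes: Iterable[RGBCode]
) -> float:
    """Fraction of unmasked pixels carrying a selected green code.

    For a zone-masked image the denominator is that zone's unmasked pixel
    count, so each segmented zone is scored per image like any other image.
    """
    codes = set(green_codes)
    green = sum(n for c, n in histogram.counts.items() if c in codes)
    return green / histogram.total_pixels


# ---------------------------------------------------------------------------
# tabular I/O


def histogram_to_frame(hist: PixelHistogram) -> pd.DataFrame:
    rows = sorted(hist.counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return pd.DataFrame(
        {
            "code": [format_code(c) for c, _ in rows],
            "r": [c[0] for c, _ in rows],
            "g": [c[1] for c, _ in rows],
            "b": [c[2] for c, _ in rows],
            "count": [n for _, n in rows],
        }
    )


def write_histograms_csv(histograms: Sequence[PixelHistogram], path: str | Path) -> None:
    """Write histograms as one long CSV (label,code,r,g,b,count)."""
    frames = []
    for i, h in enumerate(histograms):
        f = histogram_to_frame(h)
        f.insert(0, "label", h.label if h.label is not None else f"image_{i}")
        frames.append(f)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_histograms_csv(path: str | Path) -> list[PixelHistogram]:
    df = pd.read_csv(path)
    out = []
    for label, sub in df.groupby("label", sort=False):
        counts = {
            (int(r), int(g), int(b)): int(n)
            for r, g, b, n in zip(sub["r"], sub["g"], sub["b"], sub["count"])
        }
        out.append(
            PixelHistogram(
                counts=counts, total_pixels=sum(counts.values()), label=str(label)
            )
        )
    return out


def write_histograms_xlsx(
    histograms: Sequence[PixelHistogram], path: str | Path
) -> None:
    """Write one worksheet per image in the supplementary-workbook layout:
    columns Color, R, G, B, Pixels, sorted by descending pixel count."""
    with pd.ExcelWriter(path, engine="openpyxl") as xl:
        for i, h in enumerate(histograms):
            f = histogram_to_frame(h).rename(
                columns={"code": "Color", "r": "R", "g": "G", "b": "B", "count": "Pixels"}
            )
            name = (h.label if h.label is not None else f"image_{i}")[:31]
            f.to_excel(xl, sheet_name=name, index=False)
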