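"""Synthetic pot-experiment generator with known ground truth.

Emulates the study conditions of a small pesticide-efficacy bioassay: pots of
ryegrass photographed on days 1, 2, 4 and 5 after a hydrogen-peroxide (HP)
injection at the pot center, with 4 control and 4 treated pots. The HP
bleaches a roughly disc-shaped zone of soil gray (the directly affected zone
P1); the rest of a treated pot is the nongray zone P0.

Observed green proportions follow a beta distribution whose mean is logistic
in day with group-specific intercepts and slopes, and whose precision varies
with day on the log scale. Rendered images additionally carry a day-constant
background-noise floor: a fixed fraction of non-weed pixels is recolored with
weed-green codes, so day-zero images measure a nonzero apparent green cover
even though no weeds have grown — the artifact the baseline adjustment in
:mod:`weedcover.efficacy` exists to remove.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .quantify import RGBCode, is_green

__all__ = [
    "TruthParams",
    "StudyDesign",
    "Palette",
    "Disc",
    "PotImage",
    "default_truth",
    "default_palette",
    "simulate_proportions",
    "render_pot_image",
    "simulate_image_series",
]

GROUPS = ("C", "P0", "P1")


@dataclass(frozen=True)
class TruthParams:
    """Ground-truth coefficients of the generative beta-regression model.

    Mean model (logit scale): eta = alpha0 + alpha1*[P0] + alpha2*[P1]
    + (beta0 + beta1*[P0] + beta2*[P1]) * day.
    Precision model (log scale): phi(day) = exp(gamma0 + gamma1 * day).
    ``baseline_noise`` is the day-constant fraction of non-weed pixels that
    the image layer recolors green (apparent day-zero cover).
    """

    alpha0: float
    alpha1: float = 0.0
    alpha2: float = 0.0
    beta0: float = 0.5
    beta1: float = 0.0
    beta2: float = 0.0
    gamma0: float = 4.0
    gamma1: float = 0.0
    baseline_noise: float = 0.0

    def __post_init__(self) -> None:
        vals = [
            self.alpha0, self.alpha1, self.alpha2,
            self.beta0, self.beta1, self.beta2,
            self.gamma0, self.gamma1, self.baseline_noise,
        ]
        if not all(np.isfinite(vals)):
            raise ValueError("TruthParams must be finite")
        if not (self.beta0 > 0 and self.beta0 + self.beta1 > 0 and self.beta0 + self.beta2 > 0):
            raise ValueError(
                "growth slopes must satisfy beta0 > 0, beta0+beta1 > 0, beta0+beta2 > 0"
            )
        if not 0.0 <= self.baseline_noise < 1.0:
            raise ValueError("baseline_noise must lie in [0, 1)")

    def eta(self, day: float, group: str) -> float:
        p0 = 1.0 if group == "P0" else 0.0
        p1 = 1.0 if group == "P1" else 0.0
        return (
            self.alpha0 + self.alpha1 * p0 + self.alpha2 * p1
            + (self.beta0 + self.beta1 * p0 + self.beta2 * p1) * day
        )

    def mu(self, day: float, group: str) -> float:
        return float(expit(self.eta(day, group)))

    def phi(self, day: float) -> float:
        return float(np.exp(self.gamma0 + self.gamma1 * day))


@dataclass(frozen=True)
class StudyDesign:
    """Replication layout. Defaults reproduce the bioassay: 4 pots per group
    photographed 1, 2, 4 and 5 days after treatment."""

    pots_per_group: int = 4
    days: tuple[float, ...] = (1.0, 2.0, 4.0, 5.0)
    groups: tuple[str, ...] = GROUPS

    def __post_init__(self) -> None:
        if self.pots_per_group < 1:
            raise ValueError("pots_per_group must be >= 1")
        if len(self.days) == 0 or len(self.groups) == 0:
            raise ValueError("design needs at least one day and one group")
        if any(d < 0 for d in self.days):
            raise ValueError("days must be nonnegative")
        if any(b <= a for a, b in zip(self.days, self.days[1:])):
            raise ValueError("days must be strictly increasing")
        if any(g not in GROUPS for g in self.groups):
            raise ValueError(f"groups must be a subset of {GROUPS}")


@dataclass(frozen=True)
class Disc:
    """Disc-shaped treated zone: HP injected at the pot center bleaches a
    roughly circular gray patch."""

    cx: float
    cy: float
    radius: float

    def mask(self, width: int, height: int) -> np.ndarray:
        yy, xx = np.mgrid[0:height, 0:width]
        return (xx - self.cx) ** 2 + (yy - self.cy) ** 2 <= self.radius**2


def _weighted(codes: Sequence[tuple[RGBCode, float]]) -> tuple[np.ndarray, np.ndarray]:
    arr = np.array([c for c, _ in codes], dtype=np.uint8)
    w = np.array([w for _, w in codes], dtype=float)
    return arr, w / w.sum()


@dataclass(frozen=True)
class Palette:
    """Render palette. Weed codes default to the six characteristic weed-green
    codes (all satisfying G > R and G > B); soil codes are browns (R > G > B)
    and gray codes are neutral (R = G = B), so neither passes the green rule
    and the two soils are separable by chroma."""

    weed_codes: tuple[tuple[RGBCode, float], ...]
    soil_codes: tuple[tuple[RGBCode, float], ...]
    gray_codes: tuple[tuple[RGBCode, float], ...]

    def __post_init__(self) -> None:
        for code, _ in self.weed_codes:
            if not is_green(code):
                raise ValueError(f"weed code {code} fails the green rule")
        for code, _ in self.soil_codes + self.gray_codes:
            if is_green(code):
                raise ValueError(f"non-weed code {code} passes the green rule")


def default_palette() -> Palette:
    return Palette(
        weed_codes=(
            ((0, 43, 0), 1.0),
            ((51, 85, 51), 1.0),
            ((102, 128, 102), 1.0),
            ((153, 170, 102), 1.0),
            ((102, 128, 51), 1.0),
            ((51, 85, 0), 1.0),
        ),
        soil_codes=(
            ((153, 102, 51), 2.0),
            ((130, 90, 55), 1.5),
            ((110, 75, 45), 1.0),
            ((90, 60, 35), 0.5),
        ),
        gray_codes=(
            ((150, 150, 150), 2.0),
            ((165, 165, 165), 1.5),
            ((135, 135, 135), 1.0),
            ((120, 120, 120), 0.5),
        ),
    )


def default_truth() -> TruthParams:
    """Defaults chosen to emulate the study qualitatively: near-zero true weed
    cover at day 0, control growing to ~0.45 true cover by day 5, nongray zone
    tracking the control, gray-zone growth strongly suppressed, ~0.1 apparent
    day-zero cover from background noise, and pot-to-pot scatter wide enough
    that 4 pots/group leave visible uncertainty."""
    return TruthParams(
        alpha0=-4.6,
        alpha1=0.0,
        alpha2=0.0,
        beta0=0.87,
        beta1=0.02,
        beta2=-0.72,
        gamma0=4.5,
        gamma1=-0.15,
        baseline_noise=0.10,
    )


def _check_phi(truth: TruthParams, design: StudyDesign) -> None:
    for d in design.days:
        phi = truth.phi(d)
        if not np.isfinite(phi) or phi <= 2.0:
            raise ValueError(
                f"precision phi={phi:.3g} at day {d} must be finite and > 2 "
                "so both beta shape parameters stay bounded away from 0"
            )


def _pot_rng(seed: int, group: str, pot: int, stream: int) -> np.random.Generator:
    """Per-pot substream: spawn_key = (stream, group index, pot index).

    Adding pots or days never perturbs the draws of existing pots.
    """
    gi = GROUPS.index(group)
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream, gi, pot)))


def simulate_proportions(
    truth: TruthParams, design: StudyDesign, seed: int
) -> pd.DataFrame:
    """Draw one observed green proportion per (pot, day) from the generative
    beta model: y ~ Beta(mu*phi, (1-mu)*phi) with mu = logit^-1(eta(day, group))
    and phi = exp(gamma0 + gamma1*day).

    Returns a table with columns pot_id, group, day, proportion; identical
    seeds give identical tables.
    """
    _check_phi(truth, design)
    records = []
    for group in design.groups:
        for pot in range(design.pots_per_group):
            rng = _pot_rng(seed, group, pot, stream=0)
            for day in design.days:
                mu = truth.mu(day, group)
                phi = truth.phi(day)
                if not (np.isfinite(mu) and np.isfinite(phi) and 0 < mu < 1):
                    raise ValueError(f"non-finite or boundary mu/phi at day {day}")
                y = rng.beta(mu * phi, (1.0 - mu) * phi)
                y = min(max(y, 1e-12), 1.0 - 1e-12)
                records.append((f"{group}_{pot + 1}", group, float(day), float(y)))
    return pd.DataFrame(records, columns=["pot_id", "group", "day", "proportion"])


def _scatter_green(
    rng: np.random.Generator, region_idx: np.ndarray, green_prop: float
) -> np.ndarray:
    """Pick exactly round(green_prop * region size) pixel indices."""
    n = int(np.floor(green_prop * region_idx.size + 0.5))
    return rng.choice(region_idx, size=n, replace=False)


def render_pot_image(
    width: int,
    height: int,
    green_prop: float,
    gray_zone: Disc | None = None,
    palette: Palette | None = None,
    seed: int = 0,
    gray_zone_green_prop: float | None = None,
) -> np.ndarray:
    """Render an RGBA pot image with an exactly controlled green fraction.

    Non-green pixels take soil codes, or gray codes inside ``gray_zone``.
    Green (weed-code) pixels are scattered uniformly; the realized green
    fraction equals ``green_prop`` to within 1 pixel / total. When
    ``gray_zone_green_prop`` is given, the disc interior gets that green
    fraction instead (each region exact to within 1 pixel / region size).
    """
    if not 0.0 <= green_prop < 1.0:
        raise ValueError("green_prop must lie in [0, 1)")
    if gray_zone_green_prop is not None and not 0.0 <= gray_zone_green_prop < 1.0:
        raise ValueError("gray_zone_green_prop must lie in [0, 1)")
    if palette is None:
        palette = default_palette()
    rng = np.random.default_rng(seed)

    img = np.empty((height, width, 4), dtype=np.uint8)
    img[..., 3] = 255
    npix = width * height

    if gray_zone is not None:
        if not (
            0 <= gray_zone.cx - gray_zone.radius
            and gray_zone.cx + gray_zone.radius < width
            and 0 <= gray_zone.cy - gray_zone.radius
            and gray_zone.cy + gray_zone.radius < height
        ):
            raise ValueError("gray zone disc must lie inside image bounds")
        disc = gray_zone.mask(width, height).ravel()
    else:
        disc = np.zeros(npix, dtype=bool)

    soil_arr, soil_w = _weighted(palette.soil_codes)
    gray_arr, gray_w = _weighted(palette.gray_codes)
    weed_arr, weed_w = _weighted(palette.weed_codes)

    flat = img.reshape(npix, 4)
    out_idx = np.flatnonzero(~disc)
    in_idx = np.flatnonzero(disc)
    flat[out_idx, :3] = soil_arr[rng.choice(len(soil_arr), size=out_idx.size, p=soil_w)]
    if in_idx.size:
        flat[in_idx, :3] = gray_arr[rng.choice(len(gray_arr), size=in_idx.size, p=gray_w)]

    if gray_zone_green_prop is None:
        green_idx = _scatter_green(rng, np.arange(npix), green_prop)
    else:
        green_idx = np.concatenate(
            [
                _scatter_green(rng, out_idx, green_prop),
                _scatter_green(rng, in_idx, gray_zone_green_prop)
                if in_idx.size
                else np.array([], dtype=np.int64),
            ]
        )
    if green_idx.size:
        flat[green_idx, :3] = weed_arr[
            rng.choice(len(weed_arr), size=green_idx.size, p=weed_w)
        ]
    return img


@dataclass(frozen=True)
class PotImage:
    """A rendered pot photograph plus its generating ground truth."""

    image: np.ndarray
    pot_id: str
    day: float
    kind: str  # "control" or "treated"
    disc: Disc | None
    true_green: dict[str, float]  # realized target green fraction per zone


def mix_noise(p: float, baseline_noise: float) -> float:
    """Apparent green fraction after recoloring a ``baseline_noise`` share of
    non-weed pixels green: p + (1 - p) * noise."""
    return p + (1.0 - p) * baseline_noise


def simulate_image_series(
    truth: TruthParams,
    design: StudyDesign,
    image_size: tuple[int, int] = (160, 160),
    palette: Palette | None = None,
    seed: int = 0,
    disc_radius_frac: float = 0.30,
) -> list[PotImage]:
    """Render the full study's photographs with known per-zone green cover.

    Control pots are uniform soil; treated pots carry a central gray disc
    whose interior follows the P1 growth model while the exterior follows P0.
    Apparent green mixes the simulated weed proportion with
    ``truth.baseline_noise`` at the pixel layer.
    """
    if palette is None:
        palette = default_palette()
    props = simulate_proportions(truth, design, seed)
    lut = {
        (r.group, r.pot_id, r.day): r.proportion for r in props.itertuples()
    }
    w, h = image_size
    disc = Disc(cx=(w - 1) / 2.0, cy=(h - 1) / 2.0, radius=disc_radius_frac * min(w, h))

    out: list[PotImage] = []
    has_treated = "P0" in design.groups or "P1" in design.groups
    for pot in range(design.pots_per_group):
        for di, day in enumerate(design.days):
            if "C" in design.groups:
                g = mix_noise(lut[("C", f"C_{pot + 1}", day)], truth.baseline_noise)
                rng = _pot_rng(seed, "C", pot, stream=1)
                img = render_pot_image(
                    w, h, g, gray_zone=None, palette=palette,
                    seed=int(rng.integers(2**31)) + di,
                )
                out.append(
                    PotImage(img, f"C_{pot + 1}", float(day), "control", None, {"C": g})
                )
            if has_treated:
                p0 = lut.get(("P0", f"P0_{pot + 1}", day), 0.0)
                p1 = lut.get(("P1", f"P1_{pot + 1}", day), 0.0)
                g0 = mix_noise(p0, truth.baseline_noise)
                g1 = mix_noise(p1, truth.baseline_noise)
                rng = _pot_rng(seed, "P0", pot, stream=1)
                img = render_pot_image(
                    w, h, g0, gray_zone=disc, palette=palette,
                    seed=int(rng.integers(2**31)) + di,
                    gray_zone_green_prop=g1,
                )
                out.append(
                    PotImage(
                        img, f"T_{pot + 1}", float(day), "treated", disc,
                        {"P0": g0, "P1": g1},
                    )
                )
    return out
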