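"""Background-adjusted green cover and posterior efficacy ratios.

Apparent green cover at day zero is nonzero (lighting, sensor and human
noise), so raw modelled proportions overstate how much green is weed. The
adjusted proportion removes the baseline:

    theta(d) = [mu(d) - mu(0)] / [1 - mu(0)]

i.e. the share of the initially non-green area that has turned green by day
d. Under the admissible (positive-growth) parameter region theta(d) lies in
[0, 1) and increases with d. Treatment effects are reported as per-draw
posterior ratios theta_group(d) / theta_C(d), summarized by the posterior
mean and an equal-tailed credible interval; values below 1 mean the group
grows less green cover than the control.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .betareg import BetaRegParams, PosteriorDraws, mean_mu

__all__ = [
    "EfficacySummary",
    "adjusted_theta",
    "theta_closed_form",
    "efficacy_ratio_draws",
    "summarize",
    "unadjusted_ratio",
    "plugin_curve",
    "posterior_mean_curve",
]


@dataclass(frozen=True)
class EfficacySummary:
    """Posterior point estimate and credible interval of one estimand."""

    estimand: str
    posterior_mean: float
    ci_low: float
    ci_high: float
    ci_level: float
    n_draws: int
    flagged_draws: int = 0

    def __post_init__(self) -> None:
        if not self.ci_low <= self.ci_high:
            raise ValueError("ci_low must not exceed ci_high")
        if not 0.0 < self.ci_level < 1.0:
            raise ValueError("ci_level must lie in (0, 1)")


def _mu0_mu_d(params, day, group):
    mu_d = mean_mu(params, day, group)
    mu_0 = mean_mu(params, 0.0, group)
    return np.asarray(mu_0, dtype=float), np.asarray(mu_d, dtype=float)


def adjusted_theta(
    params: BetaRegParams, day: float, group: str
) -> float:
    """theta(d) = [mu(d) - mu(0)] / [1 - mu(0)], the generic definition.

    0 at day 0 for every group; approaches mu(d) when the baseline mu(0) is
    negligible. Requires mu(0) < 1.
    """
    if day < 0:
        raise ValueError("day must be nonnegative")
    mu0, mud = _mu0_mu_d(params, day, group)
    if np.any(mu0 >= 1.0):
        raise ValueError("mu(0) = 1: baseline leaves no room for growth")
    theta = (mud - mu0) / (1.0 - mu0)
    return float(theta)


def theta_closed_form(params: BetaRegParams, day: float, group: str) -> float:
    """Closed-form theta: (e^{a+b d} - e^{a}) / (1 + e^{a+b d}) with the
    group's own intercept a and slope b. Algebraically identical to
    :func:`adjusted_theta`; kept separate as an independent route."""
    if group == "C":
        a = params.alpha0
        b = params.beta0
    elif group in ("P0", "T"):
        a = params.alpha0 + params.alpha1
        b = params.beta0 + params.beta1
    elif group == "P1":
        a = params.alpha0 + params.alpha2
        b = params.beta0 + params.beta2
    else:
        raise ValueError(f"unknown group {group!r}")
    return float((np.exp(a + b * day) - np.exp(a)) / (1.0 + np.exp(a + b * day)))


def efficacy_ratio_draws(
    draws: PosteriorDraws,
    day: float,
    numerator_group: str,
    denominator_group: str,
) -> tuple[np.ndarray, int]:
    """Per-draw ratio theta_num(day) / theta_den(day).

    Returns (ratios over valid draws, count of flagged draws whose
    denominator theta was <= 0 — impossible for admissible draws with a
    positive denominator-group slope, but guarded anyway).
    """
    if day <= 0:
        raise ValueError("day must be positive: theta(0) = 0 for every group")
    p = draws.param_arrays()

    def theta_vec(group: str) -> np.ndarray:
        a = p["alpha0"].copy()
        b = p["beta0"].copy()
        if group in ("P0", "T"):
            a = a + p["alpha1"]
            b = b + p["beta1"]
        elif group == "P1":
            a = a + p["alpha2"]
            b = b + p["beta2"]
        elif group != "C":
            raise ValueError(f"unknown group {group!r}")
        if np.any(np.isnan(a + b)):
            raise ValueError(f"group {group!r} was not part of the fitted model")
        ea = np.exp(a)
        ead = np.exp(a + b * day)
        return (ead - ea) / (1.0 + ead)

    num = theta_vec(numerator_group)
    den = theta_vec(denominator_group)
    flagged = int(np.sum(den <= 0))
    if flagged == len(den):
        raise ValueError("every draw has nonpositive denominator theta")
    ok = den > 0
    return num[ok] / den[ok], flagged


def summarize(
    values: np.ndarray, ci_level: float = 0.95, estimand: str = "", method: str = "eti"
) -> EfficacySummary:
    """Posterior mean plus a credible interval of the draws.

    ``method="eti"`` (default) is the equal-tailed percentile interval using
    the linear-interpolation quantile definition; ``method="hdi"`` gives the
    highest-density interval instead.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("no draws to summarize")
    if not 0.0 < ci_level < 1.0:
        raise ValueError("ci_level must lie in (0, 1)")
    if method == "eti":
        tail = (1.0 - ci_level) / 2.0
        lo, hi = np.quantile(arr, [tail, 1.0 - tail], method="linear")
    elif method == "hdi":
        import arviz as az

        lo, hi = az.hdi(arr, hdi_prob=ci_level)
    else:
        raise ValueError("method must be 'eti' or 'hdi'")
    return EfficacySummary(
        estimand=estimand,
        posterior_mean=float(arr.mean()),
        ci_low=float(lo),
        ci_high=float(hi),
        ci_level=ci_level,
        n_draws=int(arr.size),
    )


def unadjusted_ratio(
    params: BetaRegParams, day: float, numerator_group: str, denominator_group: str
) -> float:
    """Raw modelled-cover ratio mu_num(day) / mu_den(day), no baseline
    adjustment — the pre-segmentation comparison of a whole treated pot
    (group "T") against the control."""
    num = mean_mu(params, day, numerator_group)
    den = mean_mu(params, day, denominator_group)
    return float(num / den)


def plugin_curve(
    params: BetaRegParams, days: np.ndarray, group: str, adjusted: bool = True
) -> np.ndarray:
    """Growth curve at one coefficient vector (e.g. posterior means)."""
    f = adjusted_theta if adjusted else (lambda p, d, g: mean_mu(p, d, g))
    return np.array([f(params, float(d), group) for d in np.asarray(days, float)])


def posterior_mean_curve(
    draws: PosteriorDraws, days: np.ndarray, group: str, adjusted: bool = True
) -> np.ndarray:
    """Pointwise posterior mean of the (adjusted) growth curve across draws."""
    out = np.zeros(len(days))
    params = draws.to_params()
    for p in params:
        out += plugin_curve(p, days, group, adjusted=adjusted)
    return out / len(params)
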