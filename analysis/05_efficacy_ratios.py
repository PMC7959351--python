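#!/usr/bin/env python
"""Report the day-5 efficacy estimands and contrast the adjusted and
unadjusted views of the treatment effect.

The adjusted ratios theta_P1(5)/theta_C(5) and theta_P0(5)/theta_C(5) are
posterior summaries over the constrained draws; the unadjusted whole-pot
ratio mu_T(5)/mu_C(5) comes from the two-group ML fit. Writes
results/efficacy.csv and a growth-curve figure to scratch/figures/.
"""

import json
import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

import numpy as np
import pandas as pd

from weedcover import betareg as br
from weedcover import efficacy as eff


def main() -> None:
    out = ROOT / "results"
    df = pd.read_csv(ROOT / "scratch" / "draws.csv")
    names = tuple(df.columns)
    draws = br.PosteriorDraws(
        draws=df.to_numpy()[None], names=names, groups=("C", "P0", "P1"),
        n_chains=1, n_warmup=0, seed=0,
    )

    rows = []
    for grp in ("P1", "P0"):
        ratios, flagged = eff.efficacy_ratio_draws(draws, 5.0, grp, "C")
        s = eff.summarize(ratios, estimand=f"theta_{grp}(5)/theta_C(5)")
        rows.append((s.estimand, 5.0, s.posterior_mean, s.ci_low, s.ci_high,
                     s.ci_level, s.n_draws, flagged))
        verdict = "CI entirely below 1" if s.ci_high < 1 else "CI contains 1"
        print(f"{s.estimand}: posterior mean {s.posterior_mean:.2f}, "
              f"95% CI ({s.ci_low:.4f}, {s.ci_high:.2f}) -> {verdict}")

    ml_whole = json.loads((out / "ml_fits.json").read_text())["whole_pot"]
    p = br.BetaRegParams(**ml_whole)
    unadj = eff.unadjusted_ratio(p, 5.0, "T", "C")
    print(f"unadjusted whole-pot ratio mu_T(5)/mu_C(5): {unadj:.2f} "
          "(no segmentation, no baseline adjustment)")
    rows.append(("mu_T(5)/mu_C(5) unadjusted", 5.0, unadj,
                 np.nan, np.nan, np.nan, 0, 0))

    pd.DataFrame(rows, columns=["estimand", "day", "posterior_mean", "ci_low",
                                "ci_high", "ci_level", "n_draws",
                                "flagged_draws"]).to_csv(
        out / "efficacy.csv", index=False
    )

    # Growth-curve figure: raw mu (left) vs baseline-adjusted theta (right)
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    days = np.linspace(0, 5, 51)
    fig, axes = plt.subplots(1, 2, figsize=(9, 3.6), sharex=True)
    colors = {"C": "tab:blue", "P0": "tab:orange", "P1": "tab:green"}
    for grp in ("C", "P0", "P1"):
        for ax, adjusted in zip(axes, (False, True)):
            curve = eff.posterior_mean_curve(draws, days, grp, adjusted=adjusted)
            ax.plot(days, curve, label=grp, color=colors[grp])
    axes[0].set_title("unadjusted $\\mu(d)$")
    axes[1].set_title("adjusted $\\theta(d)$")
    for ax in axes:
        ax.set_xlabel("days after treatment")
        ax.legend()
    axes[0].set_ylabel("green proportion")
    fig_dir = ROOT / "scratch" / "figures"
    fig_dir.mkdir(parents=True, exist_ok=True)
    fig.tight_layout()
    fig.savefig(fig_dir / "growth_curves.png", dpi=120)
    print(f"figure -> {fig_dir.relative_to(ROOT)}/growth_curves.png")


if __name__ == "__main__":
    main()
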