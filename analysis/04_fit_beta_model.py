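#!/usr/bin/env python
"""Fit the beta regressions to the measured green proportions.

Two fits on the zone-level table (C / P0 / P1): an unconstrained maximum-
likelihood fit, and the constrained Bayesian fit whose slopes are restricted
to nonnegative growth. A third, two-group ML fit on the whole-pot table
gives the pre-segmentation comparison.

Writes results/draws.csv, results/convergence.json, results/ml_fits.json.
"""

import json
import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

import pandas as pd

from weedcover import betareg as br

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1


def main() -> None:
    out = ROOT / "results"
    zones = pd.read_csv(out / "observations_zones.csv")
    whole = pd.read_csv(out / "observations_whole_pot.csv")

    ml_zone, rep_zone = br.fit_ml(zones)
    print("zone-level ML estimates (logit mean model + log precision model):")
    for k, v in zip(br.ALL_COEF, ml_zone.as_array()):
        se = rep_zone.std_errors.get(k, float("nan"))
        print(f"  {k:7s} = {v:8.4f}  (SE {se:.4f})")

    draws = br.sample_posterior(
        zones, n_chains=4, n_iter=3000, n_warmup=1500, seed=SEED
    )
    print(
        f"constrained posterior: {draws.n_draws} draws, "
        f"accept {draws.accept_rate:.2f}, max split-Rhat "
        f"{max(draws.rhat.values()):.3f}, min bulk ESS {min(draws.ess.values()):.0f}"
    )
    scratch = ROOT / "scratch"
    scratch.mkdir(exist_ok=True)
    draws.to_frame().to_csv(scratch / "draws.csv", index=False)
    (out / "convergence.json").write_text(
        json.dumps({"rhat": draws.rhat, "ess": draws.ess,
                    "accept_rate": draws.accept_rate}, indent=2)
    )

    ml_whole, rep_whole = br.fit_ml(whole)
    (out / "ml_fits.json").write_text(
        json.dumps(
            {
                "zones": {k: v for k, v in zip(br.ALL_COEF, ml_zone.as_array())},
                "zones_se": rep_zone.std_errors,
                "whole_pot": {k: v for k, v in zip(br.ALL_COEF, ml_whole.as_array())},
                "whole_pot_se": rep_whole.std_errors,
            },
            indent=2,
            default=float,
        )
    )
    print("wrote scratch/draws.csv, results/convergence.json, results/ml_fits.json")


if __name__ == "__main__":
    main()
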