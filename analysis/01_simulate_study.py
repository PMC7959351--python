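#!/usr/bin/env python
"""Render the synthetic pot study: 4 control + 4 treated pots photographed
1, 2, 4 and 5 days after treatment, with known per-zone green cover and a
10% day-zero background-noise floor.

Writes the photographs + sidecar to scratch/study_images/ (binary, rebuilt
on demand) and the ground-truth observation table to results/.
"""

import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

from weedcover import pipeline as pl
from weedcover import synthetic as sy

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1


def main() -> None:
    truth = sy.default_truth()
    design = sy.StudyDesign()
    print(f"truth: {truth}")
    print(f"design: {design.pots_per_group} pots/group, days {list(design.days)}")

    obs = sy.simulate_proportions(truth, design, SEED)
    out = ROOT / "results"
    out.mkdir(exist_ok=True)
    obs.to_csv(out / "true_proportions.csv", index=False)
    print(f"wrote {len(obs)} ground-truth proportions -> results/true_proportions.csv")

    series = sy.simulate_image_series(truth, design, image_size=(128, 128), seed=SEED)
    img_dir = ROOT / "scratch" / "study_images"
    pl.save_images(series, img_dir)
    print(f"rendered {len(series)} photographs -> {img_dir.relative_to(ROOT)}")
    day5 = [p for p in series if p.day == 5.0 and p.kind == "treated"][0]
    print(
        "example treated pot at day 5: apparent green "
        f"P0={day5.true_green['P0']:.3f}, P1={day5.true_green['P1']:.3f}"
    )


if __name__ == "__main__":
    main()
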