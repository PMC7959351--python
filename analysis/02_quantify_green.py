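#!/usr/bin/env python
"""Quantize the study photographs into RGB-code histograms, select the six
most abundant shared green codes, and measure whole-pot green proportions
(the pre-segmentation view: each treated pot is one unit, group "T").

Reads scratch/study_images/; writes results/histograms.csv,
results/green_codes.txt and results/observations_whole_pot.csv.
"""

import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

import pandas as pd

from weedcover import quantify as q


def main() -> None:
    img_dir = ROOT / "scratch" / "study_images"
    side = pd.read_csv(img_dir / "sidecar.csv")
    entries = []
    for row in side.itertuples():
        img = q.load_image(img_dir / row.filename)
        label = f"{row.pot_id}_{row.group}_d{row.day:g}"
        entries.append((row, q.quantize_colors(img, 256, label=label)))

    by_group = {}
    for row, h in entries:
        by_group.setdefault(row.group, []).append(h)
    codes = q.select_green_codes(
        by_group, q.GreenSelection(top_k=6, require_shared_across_groups=True)
    )
    code_txt = sorted(q.format_code(c) for c in codes)
    print(f"six most abundant shared green codes: {code_txt}")

    out = ROOT / "results"
    q.write_histograms_csv([h for _, h in entries], out / "histograms.csv")
    (out / "green_codes.txt").write_text("\n".join(code_txt) + "\n")

    obs = pd.DataFrame(
        [
            (f"{r.group}_{r.pot_id}", r.group, r.day, q.green_proportion(h, codes))
            for r, h in entries
        ],
        columns=["pot_id", "group", "day", "proportion"],
    )
    obs.to_csv(out / "observations_whole_pot.csv", index=False)
    day_means = obs.groupby(["group", "day"])["proportion"].mean().unstack()
    print("mean green proportion per group and day (whole pots):")
    print(day_means.round(3).to_string())


if __name__ == "__main__":
    main()
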