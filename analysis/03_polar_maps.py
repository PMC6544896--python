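"""Polar maps of the fitted visibility functions.

For each condition, express every gamut colour as (hue angle, RT
deficit from the hardest colour) and render the polar scatter with
100 ms contours; the hardest colour sits at the centre.  Reads the
predictions written by 02_fit_visibility.py; figures go to
scratch/figures/, a binned hue x deficit table to results/.
"""

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

ROOT = Path(__file__).resolve().parents[1]
PIPE = ROOT / "scratch" / "pipeline"
FIGS = ROOT / "scratch" / "figures"
RESULTS = ROOT / "results"


def main() -> None:
    FIGS.mkdir(parents=True, exist_ok=True)
    binned_rows = []
    cond_dirs = sorted(p for p in PIPE.iterdir() if (p / "polar.csv").exists())
    if not cond_dirs:
        raise SystemExit("run analysis/02_fit_visibility.py first")
    fig, axes = plt.subplots(
        2, 2, subplot_kw={"projection": "polar"}, figsize=(11, 10)
    )
    for ax, cond in zip(axes.ravel(), cond_dirs):
        polar = pd.read_csv(cond / "polar.csv")
        chromatic = polar[~polar["achromatic"]]
        colours = chromatic[["r", "g", "b"]].to_numpy() / 255.0
        ax.scatter(
            np.deg2rad(chromatic["hue_deg"]),
            chromatic["delta_rt_ms"],
            c=colours, s=4, linewidths=0,
        )
        max_delta = polar["delta_rt_ms"].max()
        ax.set_rgrids(np.arange(100, max_delta + 100, 100), labels=[])
        ax.set_title(cond.name.replace("_", " "), pad=18)
        # hue x 100 ms-deficit occupancy, for the compact results table
        hue_bin = (polar["hue_deg"] // 30).astype(int) % 12
        delta_bin = (polar["delta_rt_ms"] // 100).astype(int)
        counts = (
            polar.assign(hue_bin=hue_bin, delta_bin=delta_bin)
            .groupby(["hue_bin", "delta_bin"])
            .size()
            .reset_index(name="n_colours")
        )
        counts.insert(0, "condition", cond.name.replace("_", ":"))
        binned_rows.append(counts)
    fig.suptitle("RT deficit from the hardest colour (contours: 100 ms)")
    fig.savefig(FIGS / "polar_maps.png", dpi=150, bbox_inches="tight")
    out = pd.concat(binned_rows)
    out.to_csv(RESULTS / "polar_binned.csv", index=False)
    print(f"wrote {FIGS / 'polar_maps.png'}")
    print(
        "hue occupancy per 100 ms deficit band (30-degree bins):"
        f" {len(out)} rows -> results/polar_binned.csv"
    )


if __name__ == "__main__":
    main()
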