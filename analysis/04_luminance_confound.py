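"""Luminance-confound check between chromatic conditions.

The dichromat stimuli are protan projections of the trichromat scenes;
if the projection changed mean luminance, slower dichromat detection
could be an artefact of adaptation to the mid-grey interstimulus
screen rather than of colour.  Following the design of the original
check: per background image, compare the difference between its mean
Rec. 709 luminance and the mid-grey reference across the two
renderings with a pooled two-sample t-test (32 images per location,
so df = 62).
"""

import json
from pathlib import Path

from camopt.colour import simulate_protanope_image
from camopt.scene import generate_background
from camopt.stats import luminance_ttest

SEED = 7
N_IMAGES = 32
SIZE = (960, 540)

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    report = {}
    for env in ("forest", "desert"):
        tri = [
            generate_background(env, SEED + i, size=SIZE).background
            for i in range(N_IMAGES)
        ]
        di = [simulate_protanope_image(im) for im in tri]
        res = luminance_ttest(tri, di)
        report[env] = {"t": res.t, "df": res.df, "p": res.p_value}
        print(f"{env}: t({res.df}) = {res.t:.4f}, p = {res.p_value:.4f}")
    (RESULTS / "luminance_ttest.json").write_text(json.dumps(report, indent=2))
    ok = all(r["p"] > 0.05 for r in report.values())
    print(
        "no significant luminance difference between renderings"
        if ok
        else "WARNING: luminance differs between renderings"
    )


if __name__ == "__main__":
    main()
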