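"""Gamut-wide prediction, extreme-colour search and polar summaries.

An ensemble is evaluated over every colour of a gamut at a fixed
occlusion (the study's mean, 37.5%); the hardest- and easiest-to-see
colours are the argmax/argmin of the ensemble point estimate, and the
polar summary expresses every colour as (hue angle, RT deficit from
the hardest colour), the layout used to visualise the fitted
visibility function.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .colour import ColourTriplet, Gamut, hue_angles, protan_map, rgb_to_codes
from .model import VisibilityEnsemble, predict_members

__all__ = [
    "GamutPrediction",
    "GamutExtremes",
    "predict_gamut",
    "find_extremes",
    "polar_summary",
    "subgrid_gamut",
    "dichromat_subgrid",
    "PREDICTION_OCCLUSION",
]

PREDICTION_OCCLUSION = 0.375  # mean experimental occlusion level


@dataclass
class GamutPrediction:
    """Per-colour point estimate and bootstrap s.e. over one gamut.

    ``table`` has columns r, g, b, rt_ms, se_ms; ``member_mean_rt`` is
    each bootstrap member's mean predicted RT over the whole gamut
    (the sampling unit for between-condition permutation tests).
    """

    table: pd.DataFrame
    condition: tuple[str, str]
    occlusion: float
    gamut_label: str
    member_mean_rt: np.ndarray = field(default_factory=lambda: np.empty(0))
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.table)


@dataclass(frozen=True)
class GamutExtremes:
    hardest: ColourTriplet
    hardest_rt: float
    easiest: ColourTriplet
    easiest_rt: float
    condition: tuple[str, str]


def subgrid_gamut(step: int | None = None, points: int | None = None) -> Gamut:
    """Regular lattice over the RGB cube for desk-scale evaluation.

    Pass ``points`` for an n-per-axis grid including both endpoints
    (e.g. 17 -> 17^3 colours) or ``step`` for an explicit stride.
    """
    if points is not None:
        axis = np.linspace(0, 255, points).round().astype(np.uint8)
    elif step is not None:
        axis = np.arange(0, 256, step, dtype=np.uint8)
    else:
        raise ValueError("give either step or points")
    rr, gg, bb = np.meshgrid(axis, axis, axis, indexing="ij")
    rgb = np.stack([rr.ravel(), gg.ravel(), bb.ravel()], axis=-1)
    codes = np.sort(
        (rgb[:, 0].astype(np.uint32) << 16)
        | (rgb[:, 1].astype(np.uint32) << 8)
        | rgb[:, 2]
    )
    return Gamut(codes=codes, label="trichromat", metadata={"subgrid": len(axis)})


def dichromat_subgrid(points: int) -> Gamut:
    """Desk-scale dichromat gamut: the protan projection of a trichromat
    subgrid, deduplicated."""
    tri = subgrid_gamut(points=points)
    proj = protan_map(tri.rgb)
    codes = np.unique(rgb_to_codes(proj))
    return Gamut(codes=codes, label="dichromat", metadata={"subgrid": points})


def predict_gamut(
    ensemble: VisibilityEnsemble,
    gamut: Gamut,
    occlusion: float = PREDICTION_OCCLUSION,
    batch: int = 1 << 14,
) -> GamutPrediction:
    """Stream the whole gamut through the ensemble at fixed occlusion.

    The dichromat ensemble must be evaluated on the dichromat gamut
    (its training inputs are protan-projected, so the full RGB cube
    would be out of distribution); trichromat ensembles evaluate
    trichromat gamuts or subgrids thereof.
    """
    chromacy = ensemble.condition[1]
    if chromacy and chromacy != gamut.label:
        raise ValueError(
            f"{chromacy} ensemble cannot evaluate a {gamut.label} gamut"
        )
    rgb = gamut.rgb
    n = rgb.shape[0]
    point = np.empty(n)
    se = np.empty(n)
    member_sum = np.zeros(ensemble.n_boot)
    for start in range(0, n, batch):
        chunk = rgb[start : start + batch]
        member = predict_members(ensemble, chunk, occlusion)
        point[start : start + batch] = member.mean(axis=0)
        if ensemble.n_boot > 1:
            se[start : start + batch] = member.std(axis=0, ddof=1) / np.sqrt(
                ensemble.n_boot
            )
        else:
            se[start : start + batch] = 0.0
        member_sum += member.sum(axis=1)
    table = pd.DataFrame(
        {
            "r": rgb[:, 0].astype(int),
            "g": rgb[:, 1].astype(int),
            "b": rgb[:, 2].astype(int),
            "rt_ms": point,
            "se_ms": se,
        }
    )
    return GamutPrediction(
        table=table,
        condition=ensemble.condition,
        occlusion=occlusion,
        gamut_label=gamut.label,
        member_mean_rt=member_sum / n,
        metadata=dict(gamut.metadata, n_boot=ensemble.n_boot),
    )


def _extreme_row(table: pd.DataFrame, maximise: bool) -> pd.Series:
    col = table["rt_ms"]
    target = col.max() if maximise else col.min()
    cand = table[col == target]
    # ties: lowest s.e. first, then lexicographic colour order
    cand = cand.sort_values(["se_ms", "r", "g", "b"], kind="mergesort")
    return cand.iloc[0]


def find_extremes(pred: GamutPrediction) -> GamutExtremes:
    """Hardest (argmax RT) and easiest (argmin RT) colours of a prediction."""
    if len(pred) == 0:
        raise ValueError("empty gamut prediction")
    hard = _extreme_row(pred.table, maximise=True)
    easy = _extreme_row(pred.table, maximise=False)
    return GamutExtremes(
        hardest=ColourTriplet(int(hard["r"]), int(hard["g"]), int(hard["b"])),
        hardest_rt=float(hard["rt_ms"]),
        easiest=ColourTriplet(int(easy["r"]), int(easy["g"]), int(easy["b"])),
        easiest_rt=float(easy["rt_ms"]),
        condition=pred.condition,
    )


def polar_summary(
    pred: GamutPrediction,
    extremes: GamutExtremes,
    contour_ms: float = 100.0,
    achromatic_spoke_deg: float = 0.0,
) -> pd.DataFrame:
    """Hue angle vs RT deficit from the hardest colour, per gamut member.

    The hardest colour sits at the centre (deficit 0); each contour of
    the corresponding polar plot is ``contour_ms`` of extra predicted
    reaction time.  Achromatic colours, whose hue is undefined, are
    assigned to a designated spoke and flagged.
    """
    rgb = pred.table[["r", "g", "b"]].to_numpy(dtype=np.uint8)
    hues = hue_angles(rgb)
    achromatic = np.isnan(hues)
    delta = extremes.hardest_rt - pred.table["rt_ms"].to_numpy()
    if delta.min() < -1e-9:
        raise ValueError("extremes do not belong to this prediction")
    out = pd.DataFrame(
        {
            "r": pred.table["r"],
            "g": pred.table["g"],
            "b": pred.table["b"],
            "hue_deg": np.where(achromatic, achromatic_spoke_deg, hues),
            "achromatic": achromatic,
            "delta_rt_ms": np.maximum(delta, 0.0),
        }
    )
    out.attrs["contour_ms"] = contour_ms
    return out
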