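"""Synthetic observer: trial tables with the structure the analysis assumes.

The human search data are modelled as lognormal reaction times whose
median varies smoothly with the chromatic contrast between the target
and the background.  The generator is the package's stand-in for human
participants: a ground-truth visibility function (so recovery can be
measured exactly), participant-level offsets, multiplicative noise, and
censoring at the 10 s response deadline.

Model for the log reaction time of participant *p* on a trial with
colour *c* and occlusion *o* in environment *e*:

    mu = mu0 + beta * o + delta_p - alpha * sat(contrast(c', e))

where ``c'`` is ``c`` for a trichromat observer and the protanope
projection of ``c`` for the simulated dichromat (so colours that are
metamers after projection are exactly equally detectable), ``contrast``
is the Euclidean distance in linear RGB to the nearest background
centroid, and ``sat(x) = x / (x + k)`` saturates the salience response.
Observed RT is ``exp(mu + sigma * z)``, censored at the deadline.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .colour import (
    ColourTriplet,
    Gamut,
    _decode_lut,
    codes_to_rgb,
    protan_map,
)

__all__ = [
    "ObserverGroundTruth",
    "SimulationConfig",
    "true_log_rt",
    "true_log_rt_batch",
    "sample_trial_colours",
    "generate_dataset",
    "TRIAL_COLUMNS",
]

TRIAL_COLUMNS = [
    "participant_id",
    "environment",
    "chromacy",
    "r",
    "g",
    "b",
    "occlusion",
    "rt_ms",
    "success",
]

_DEFAULT_CENTROIDS: dict[str, tuple[tuple[int, int, int], ...]] = {
    # forest: a dark green/khaki; desert: two beige shades (bimodal)
    "forest": ((70, 80, 40),),
    "desert": ((150, 125, 95), (200, 175, 140)),
}


@dataclass(frozen=True)
class ObserverGroundTruth:
    """Parameters of the synthetic visibility function.

    ``mu0`` is the baseline log RT (log-ms) of a zero-contrast,
    zero-occlusion trial for the average participant; ``beta`` the
    log-RT cost per unit occlusion; ``alpha`` the salience gain
    (log-RT drop at full saturated contrast); ``k`` the contrast at
    which salience reaches half its ceiling (linear-RGB distance);
    ``sigma`` the trial-to-trial lognormal noise s.d. in log units.
    """

    centroids: Mapping[str, tuple[tuple[int, int, int], ...]] = field(
        default_factory=lambda: dict(_DEFAULT_CENTROIDS)
    )
    mu0: float = float(np.log(2800.0))
    beta: float = 0.8
    alpha: float = 1.5
    k: float = 0.25
    sigma: float = 0.30
    participant_sd: float = 0.1
    n_participants: int = 10
    censor_ms: float = 10_000.0
    participant_seed: int = 2019
    transfer: str = "gamma22"

    @property
    def participant_offsets(self) -> np.ndarray:
        """delta_p, drawn once per participant; index 0 = participant 1."""
        rng = np.random.default_rng(self.participant_seed)
        return rng.normal(0.0, self.participant_sd, self.n_participants)

    def with_(self, **kwargs) -> "ObserverGroundTruth":
        return replace(self, **kwargs)

    def optimum_colour(self, environment: str) -> ColourTriplet:
        """The hardest-to-see colour: the (first) background centroid."""
        return ColourTriplet(*self.centroids[environment][0])


def _representation(rgb: np.ndarray, chromacy: str, gt: ObserverGroundTruth) -> np.ndarray:
    """Observer colour representation: linear RGB, protan-projected for
    the dichromat condition."""
    rgb = np.asarray(rgb, dtype=np.uint8)
    if chromacy == "dichromat":
        rgb = protan_map(rgb)
    elif chromacy != "trichromat":
        raise ValueError(f"unknown chromacy {chromacy!r}")
    return _decode_lut(gt.transfer)[rgb]


def _contrast(rgb: np.ndarray, environment: str, chromacy: str, gt: ObserverGroundTruth) -> np.ndarray:
    """Distance in the observer representation to the nearest centroid."""
    if environment not in gt.centroids:
        raise ValueError(f"unknown environment {environment!r}")
    rep = _representation(rgb, chromacy, gt)
    cents = np.asarray(gt.centroids[environment], dtype=np.uint8)
    cent_rep = _representation(cents, chromacy, gt)
    d = np.linalg.norm(rep[..., None, :] - cent_rep[None, ...], axis=-1)
    return d.min(axis=-1)


def true_log_rt_batch(
    rgb: np.ndarray,
    occlusion: np.ndarray | float,
    participant: np.ndarray | int,
    environment: str,
    chromacy: str,
    gt: ObserverGroundTruth,
) -> np.ndarray:
    """Vectorised ground-truth mean log RT (log-ms) for ``(n, 3)`` colours.

    ``participant`` is 1-based; pass 0 for the average participant
    (zero offset).
    """
    c = _contrast(rgb, environment, chromacy, gt)
    sat = c / (c + gt.k)
    part = np.asarray(participant)
    offsets = np.concatenate([[0.0], gt.participant_offsets])
    delta = offsets[part]
    return gt.mu0 + gt.beta * np.asarray(occlusion) + delta - gt.alpha * sat


def true_log_rt(
    colour: ColourTriplet,
    occlusion: float,
    participant: int,
    environment: str,
    chromacy: str,
    gt: ObserverGroundTruth,
) -> float:
    """Scalar ground-truth mean log RT for one trial configuration."""
    colour = ColourTriplet(*colour).validate()
    out = true_log_rt_batch(
        np.asarray(colour, dtype=np.uint8)[None, :],
        occlusion,
        participant,
        environment,
        chromacy,
        gt,
    )
    return float(out[0])


def sample_trial_colours(n: int, gamut: Gamut, seed: int) -> np.ndarray:
    """``n`` distinct colours, uniform without replacement from the gamut.

    Returns an ``(n, 3)`` uint8 array; reproducible by seed.
    """
    if n > len(gamut):
        raise ValueError(f"cannot draw {n} distinct colours from a gamut of {len(gamut)}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(gamut), size=n, replace=False)
    return codes_to_rgb(gamut.codes[idx])


@dataclass(frozen=True)
class SimulationConfig:
    """Study design: 2 environments x 2 chromatic conditions,
    500 trials x 10 participants per condition, occlusion U[0.25, 0.50],
    10 s response deadline."""

    environments: tuple[str, ...] = ("forest", "desert")
    chromacies: tuple[str, ...] = ("trichromat", "dichromat")
    n_participants: int = 10
    n_trials: int = 500
    occlusion_range: tuple[float, float] = (0.25, 0.50)

    def validate(self) -> "SimulationConfig":
        if self.n_participants < 1 or self.n_trials < 1:
            raise ValueError("participant and trial counts must be positive")
        lo, hi = self.occlusion_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("occlusion_range must lie within [0, 1]")
        return self


def generate_dataset(
    config: SimulationConfig,
    gt: ObserverGroundTruth,
    seed: int,
    gamut: Gamut | None = None,
) -> pd.DataFrame:
    """Simulate the full trial table.

    One condition = environment x chromacy; each contributes
    ``n_trials * n_participants`` records.  Colours are drawn uniformly
    without replacement from the 24-bit gamut per participant; in the
    dichromat condition the *displayed* colour recorded in the table is
    the protanope projection of the drawn colour, mirroring how the
    dichromat stimuli are constructed from trichromat scenes.  Trials
    whose latent RT exceeds the deadline are recorded as failures with
    no reaction time.  Pure function of ``(config, gt, seed)``.
    """
    config = config.validate()
    if gt.n_participants != config.n_participants:
        gt = gt.with_(n_participants=config.n_participants)
    if gamut is None:
        from .colour import enumerate_trichromat_gamut

        gamut = enumerate_trichromat_gamut()
    ss = np.random.SeedSequence(seed)
    frames = []
    lo, hi = config.occlusion_range
    for ei, env in enumerate(config.environments):
        for ci, chrom in enumerate(config.chromacies):
            cond_ss = np.random.SeedSequence([seed, ei, ci])
            rng = np.random.default_rng(cond_ss)
            for p in range(1, config.n_participants + 1):
                colour_seed = int(rng.integers(2**31))
                drawn = sample_trial_colours(config.n_trials, gamut, colour_seed)
                displayed = protan_map(drawn) if chrom == "dichromat" else drawn
                occ = rng.uniform(lo, hi, config.n_trials)
                mu = true_log_rt_batch(drawn, occ, p, env, chrom, gt)
                z = rng.standard_normal(config.n_trials)
                rt = np.exp(mu + gt.sigma * z)
                success = rt <= gt.censor_ms
                frames.append(
                    pd.DataFrame(
                        {
                            "participant_id": p,
                            "environment": env,
                            "chromacy": chrom,
                            "r": displayed[:, 0].astype(int),
                            "g": displayed[:, 1].astype(int),
                            "b": displayed[:, 2].astype(int),
                            "occlusion": occ,
                            "rt_ms": np.where(success, rt, np.nan),
                            "success": success,
                        }
                    )
                )
    df = pd.concat(frames, ignore_index=True)
    return df
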