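"""End-to-end orchestration: simulate -> train -> predict -> test.

One config drives the whole pipeline; every stage's randomness flows
from named seeds derived from the config's master seed, artefacts are
written under one output directory per condition, and a manifest
records the config, the seeds and the row counts so any numeric output
can be regenerated.  A simulated analogue of the validation experiment
(fresh participants restricted to the selected colour categories)
closes the loop against the generator's ground truth.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .gamut import (
    GamutExtremes,
    GamutPrediction,
    PREDICTION_OCCLUSION,
    dichromat_subgrid,
    find_extremes,
    polar_summary,
    predict_gamut,
    subgrid_gamut,
)
from .model import train_ensemble, select_block_count
from .nnet import TrainingConfig
from .observer import (
    ObserverGroundTruth,
    SimulationConfig,
    generate_dataset,
    true_log_rt_batch,
)
from .stats import compare_conditions, geometric_mean, permutation_test

__all__ = [
    "PipelineConfig",
    "ValidationSpec",
    "run_pipeline",
    "select_validation_colours",
    "simulated_validation",
    "InfeasibleCategoryError",
]

log = logging.getLogger("camopt")


class InfeasibleCategoryError(RuntimeError):
    """A validation category has fewer eligible colours than requested."""


@dataclass(frozen=True)
class ValidationSpec:
    """Validation design: 25 colours per category, each within a 25 ms
    margin of the category's target RT; the intermediate target is the
    midpoint of the two extremes."""

    n_per_category: int = 25
    margin_ms: float = 25.0
    categories: tuple[str, ...] = ("easiest", "intermediate", "hardest")


@dataclass(frozen=True)
class PipelineConfig:
    """Everything a full run needs; round-trips through YAML unchanged."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    seed: int = 0
    n_boot: int = 10
    n_blocks: int | None = None  # None -> select from block_candidates
    block_candidates: tuple[int, ...] = (2, 4, 6)
    gamut_points: int = 33  # per-axis lattice for desk-scale prediction
    full_gamut: bool = False  # evaluate all 16.7M colours (slow)
    occlusion_eval: float = PREDICTION_OCCLUSION
    n_resamples: int = 10_000
    training: TrainingConfig = field(default_factory=TrainingConfig)
    observer: ObserverGroundTruth = field(default_factory=ObserverGroundTruth)
    out_dir: str = "out"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["observer"]["centroids"] = {
            k: [list(c) for c in v] for k, v in self.observer.centroids.items()
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sim = d.pop("simulation", {})
        if isinstance(sim, dict):
            for key in ("environments", "chromacies"):
                if key in sim:
                    sim[key] = tuple(sim[key])
            if "occlusion_range" in sim:
                sim["occlusion_range"] = tuple(sim["occlusion_range"])
            sim = SimulationConfig(**sim)
        train = d.pop("training", {})
        if isinstance(train, dict):
            train = TrainingConfig(**train)
        obs = d.pop("observer", {})
        if isinstance(obs, dict):
            obs = dict(obs)
            if "centroids" in obs:
                obs["centroids"] = {
                    k: tuple(tuple(int(x) for x in c) for c in v)
                    for k, v in obs["centroids"].items()
                }
            obs = ObserverGroundTruth(**obs)
        if "block_candidates" in d:
            d["block_candidates"] = tuple(d["block_candidates"])
        return cls(simulation=sim, training=train, observer=obs, **d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _condition_name(env: str, chromacy: str) -> str:
    return f"{env}:{chromacy}"


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis and write artefacts under ``config.out_dir``.

    Stages: simulate trial tables; per condition select the residual
    block count (unless fixed) and train the bootstrap ensemble; predict
    over the condition's gamut at the evaluation occlusion; locate the
    extreme colours; build polar summaries; run the permutation-test
    family.  Returns a report bundle with every intermediate object and
    writes a manifest with seeds and row counts.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = config.simulation
    manifest: dict = {"config": config.to_dict(), "conditions": {}}
    stage = "simulate"
    try:
        trials = generate_dataset(sim, config.observer, seed=config.seed)
        conditions = [
            (env, ch) for env in sim.environments for ch in sim.chromacies
        ]
        if config.full_gamut:
            from .colour import enumerate_trichromat_gamut, enumerate_dichromat_gamut

            tri_gamut = enumerate_trichromat_gamut()
            di_gamut = enumerate_dichromat_gamut()
        else:
            tri_gamut = subgrid_gamut(points=config.gamut_points)
            di_gamut = dichromat_subgrid(config.gamut_points)

        preds: dict[str, GamutPrediction] = {}
        ensembles = {}
        extremes: dict[str, GamutExtremes] = {}
        for env, chromacy in conditions:
            name = _condition_name(env, chromacy)
            stage = f"train:{name}"
            cond_dir = out / name.replace(":", "_")
            cond_dir.mkdir(exist_ok=True)
            cond = trials[
                (trials["environment"] == env) & (trials["chromacy"] == chromacy)
            ].reset_index(drop=True)
            cond.to_csv(cond_dir / "trials.csv", index=False)
            cond_seed = int(
                np.random.SeedSequence([config.seed, hash_name(name)]).generate_state(1)[0]
                & 0x7FFFFFFF
            )
            if config.n_blocks is None:
                n_blocks, table = select_block_count(
                    cond,
                    candidates=config.block_candidates,
                    seed=cond_seed,
                    n_participants=sim.n_participants,
                    condition=(env, chromacy),
                    config=config.training,
                )
                table.to_csv(cond_dir / "block_selection.csv", index=False)
                log.info("%s: selected %d residual blocks\n%s", name, n_blocks, table)
            else:
                n_blocks = config.n_blocks
            ens = train_ensemble(
                cond,
                n_boot=config.n_boot,
                base_seed=cond_seed + 1,
                n_blocks=n_blocks,
                n_participants=sim.n_participants,
                condition=(env, chromacy),
                config=config.training,
            )
            ensembles[name] = ens
            stage = f"predict:{name}"
            gamut = di_gamut if chromacy == "dichromat" else tri_gamut
            pred = predict_gamut(ens, gamut, occlusion=config.occlusion_eval)
            preds[name] = pred
            pred.table.to_csv(cond_dir / "pred.csv", index=False)
            ext = find_extremes(pred)
            extremes[name] = ext
            (cond_dir / "extremes.json").write_text(
                json.dumps(
                    {
                        "hardest": list(ext.hardest),
                        "hardest_rt_ms": ext.hardest_rt,
                        "easiest": list(ext.easiest),
                        "easiest_rt_ms": ext.easiest_rt,
                    },
                    indent=2,
                )
            )
            polar = polar_summary(pred, ext)
            polar.to_csv(cond_dir / "polar.csv", index=False)
            manifest["conditions"][name] = {
                "n_trials": int(len(cond)),
                "n_success": int(cond["success"].sum()),
                "n_blocks": n_blocks,
                "n_boot": ens.n_boot,
                "gamut_size": len(pred),
                "gamut_scale": "full" if config.full_gamut else f"subgrid {config.gamut_points}^3",
                "seed": cond_seed,
                "validation_mse": [m.validation_mse for m in ens.models],
            }
        stage = "stats"
        stats_table = compare_conditions(
            preds,
            ensembles,
            n_resamples=config.n_resamples,
            seed=config.seed + 1,
        )
        stats_table.to_csv(out / "stats.csv", index=False)
        manifest["seed"] = config.seed
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    except Exception:
        (out / "manifest.json").write_text(
            json.dumps(dict(manifest, failed_stage=stage), indent=2)
        )
        log.exception("pipeline failed at stage %s", stage)
        raise
    return {
        "trials": trials,
        "ensembles": ensembles,
        "predictions": preds,
        "extremes": extremes,
        "stats": stats_table,
        "manifest": manifest,
    }


def hash_name(name: str) -> int:
    """Stable small integer tag for a condition name."""
    return int.from_bytes(name.encode()[:8].ljust(8, b"\0"), "big") % (2**31)


def select_validation_colours(
    pred: GamutPrediction,
    extremes: GamutExtremes,
    spec: ValidationSpec = ValidationSpec(),
    seed: int = 0,
) -> dict[str, pd.DataFrame]:
    """Choose colours whose predicted RT sits within the margin of each
    category's target RT (easiest, midpoint, hardest).

    Colours are sampled uniformly among the eligible ones; raises
    :class:`InfeasibleCategoryError` (reporting the shortfall) when a
    category has fewer than the requested number of eligible colours.
    """
    targets = {
        "easiest": extremes.easiest_rt,
        "intermediate": 0.5 * (extremes.easiest_rt + extremes.hardest_rt),
        "hardest": extremes.hardest_rt,
    }
    rng = np.random.default_rng(seed)
    out: dict[str, pd.DataFrame] = {}
    for cat in spec.categories:
        target = targets[cat]
        eligible = pred.table[
            (pred.table["rt_ms"] - target).abs() <= spec.margin_ms
        ]
        if len(eligible) < spec.n_per_category:
            raise InfeasibleCategoryError(
                f"category {cat!r}: {len(eligible)} eligible colours, "
                f"need {spec.n_per_category} (target {target:.0f} ms "
                f"± {spec.margin_ms} ms)"
            )
        idx = rng.choice(len(eligible), spec.n_per_category, replace=False)
        out[cat] = eligible.iloc[np.sort(idx)].reset_index(drop=True)
    return out


def simulated_validation(
    gt: ObserverGroundTruth,
    colour_sets: dict[str, pd.DataFrame],
    environment: str,
    chromacy: str,
    seed: int = 0,
    n_participants: int = 4,
    n_reps: int = 20,
    occlusion: float = PREDICTION_OCCLUSION,
    n_resamples: int = 10_000,
) -> dict:
    """Fresh simulated participants search only the selected colours.

    Reports each category's geometric-mean RT, whether the ordering
    easiest < intermediate < hardest holds, and permutation p-values
    for adjacent category contrasts.

    Note the displayed colours in ``colour_sets`` are already in the
    observer's gamut (for a dichromat condition they are protan
    projections), so the ground truth is evaluated on them directly.
    """
    gt = gt.with_(n_participants=n_participants, participant_seed=seed + 977)
    rng = np.random.default_rng(seed)
    samples: dict[str, np.ndarray] = {}
    means: dict[str, float] = {}
    for cat, table in colour_sets.items():
        rgb = table[["r", "g", "b"]].to_numpy(dtype=np.uint8)
        rts = []
        for p in range(1, n_participants + 1):
            idx = rng.integers(len(rgb), size=n_reps)
            occ = np.full(n_reps, occlusion)
            mu = true_log_rt_batch(rgb[idx], occ, p, environment, chromacy, gt)
            rt = np.exp(mu + gt.sigma * rng.standard_normal(n_reps))
            rts.append(np.minimum(rt, gt.censor_ms))
        samples[cat] = np.concatenate(rts)
        means[cat] = geometric_mean(samples[cat])
    ordering = means.get("easiest", 0) < means.get("intermediate", 0) < means.get(
        "hardest", 0
    )
    contrasts = {}
    cats = list(colour_sets)
    for a, b in zip(cats, cats[1:]):
        res = permutation_test(
            np.log(samples[b]), np.log(samples[a]),
            n_resamples=n_resamples, seed=int(rng.integers(2**31)),
        )
        contrasts[f"{b} - {a}"] = {"observed_log": res.observed, "p": res.p_value}
    return {
        "geometric_mean_rt_ms": means,
        "ordering_holds": bool(ordering),
        "contrasts": contrasts,
        "n_per_category": {k: int(v.size) for k, v in samples.items()},
    }
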