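"""Bootstrap-ensemble regression of reaction times over colour space.

Each environment x chromacy condition gets its own ensemble: every
member is a residual MLP trained on a with-replacement resample of the
condition's successful trials, with a random 90/10 train/validation
split and early stopping.  Averaging the members smooths the fitted
visibility function; their spread estimates its standard error.  The
regression target is log RT, so reported point predictions are
geometric means.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .nnet import ResidualMLP, TrainingConfig

__all__ = [
    "VisibilityModel",
    "VisibilityEnsemble",
    "encode",
    "encode_frame",
    "train_model",
    "select_block_count",
    "train_ensemble",
    "predict",
    "predict_members",
]

BLOCK_CANDIDATES = (2, 4, 6)
DEFAULT_N_BOOT = 100


def encode(
    colour, occlusion: float, participant_id: int, n_participants: int
) -> np.ndarray:
    """Feature vector: 3 colour channels scaled to [0,1], occlusion,
    participant one-hot (1-based IDs)."""
    if not (1 <= participant_id <= n_participants):
        raise ValueError(
            f"participant {participant_id} outside 1..{n_participants}"
        )
    vec = np.zeros(4 + n_participants)
    vec[0:3] = np.asarray(tuple(colour), dtype=float) / 255.0
    vec[3] = occlusion
    vec[4 + participant_id - 1] = 1.0
    return vec


def encode_frame(trials: pd.DataFrame, n_participants: int) -> np.ndarray:
    """Vectorised encoding of a trial table into an (n, 4+P) design matrix."""
    pid = trials["participant_id"].to_numpy()
    if pid.min() < 1 or pid.max() > n_participants:
        raise ValueError("participant id outside the configured range")
    n = len(trials)
    X = np.zeros((n, 4 + n_participants))
    X[:, 0] = trials["r"].to_numpy() / 255.0
    X[:, 1] = trials["g"].to_numpy() / 255.0
    X[:, 2] = trials["b"].to_numpy() / 255.0
    X[:, 3] = trials["occlusion"].to_numpy()
    X[np.arange(n), 4 + pid - 1] = 1.0
    return X


@dataclass
class VisibilityModel:
    """A single trained regressor for one condition."""

    net: ResidualMLP
    n_blocks: int
    n_participants: int
    condition: tuple[str, str]  # (environment, chromacy)
    validation_mse: float  # log-RT units, squared
    history: dict = field(default_factory=dict)

    def predict_log_rt(self, X: np.ndarray) -> np.ndarray:
        return self.net.predict(X)


@dataclass
class VisibilityEnsemble:
    """Bootstrap ensemble of :class:`VisibilityModel` for one condition."""

    models: list[VisibilityModel]
    condition: tuple[str, str]
    n_participants: int
    member_seeds: list[int] = field(default_factory=list)

    @property
    def n_boot(self) -> int:
        return len(self.models)


def train_model(
    trials: pd.DataFrame,
    n_blocks: int,
    split_seed: int,
    init_seed: int,
    n_participants: int = 10,
    condition: tuple[str, str] = ("", ""),
    config: TrainingConfig | None = None,
) -> VisibilityModel:
    """Fit one residual MLP on the successful trials of one condition.

    Loss is mean squared error on log RT with the standard 90/10 random
    split and early stopping; requires at least 100 successful trials.
    """
    ok = trials[trials["success"].astype(bool)]
    if len(ok) < 100:
        raise ValueError(f"need >= 100 successful trials, got {len(ok)}")
    X = encode_frame(ok, n_participants)
    y = np.log(ok["rt_ms"].to_numpy(dtype=float))
    net = ResidualMLP(X.shape[1], n_blocks, init_seed=init_seed, config=config)
    net.fit(X, y, split_seed=split_seed)
    # the net standardises its target internally; report the loss in
    # log-RT units so it is comparable across runs
    return VisibilityModel(
        net=net,
        n_blocks=n_blocks,
        n_participants=n_participants,
        condition=condition,
        validation_mse=float(net.best_val_mse * net.y_std**2),
        history=dict(net.history),
    )


def select_block_count(
    trials: pd.DataFrame,
    candidates: tuple[int, ...] = BLOCK_CANDIDATES,
    seed: int = 0,
    n_participants: int = 10,
    condition: tuple[str, str] = ("", ""),
    config: TrainingConfig | None = None,
) -> tuple[int, pd.DataFrame]:
    """Pick the residual-block count with the lowest validation loss.

    All candidates share the same split/init seeds so the comparison is
    paired.  Ties break to the smallest block count.  Returns the winner
    and the full comparison table.
    """
    if not candidates:
        raise ValueError("no block-count candidates given")
    rows = []
    for nb in sorted(candidates):
        m = train_model(
            trials,
            nb,
            split_seed=seed,
            init_seed=seed + 1,
            n_participants=n_participants,
            condition=condition,
            config=config,
        )
        rows.append({"n_blocks": nb, "validation_mse": m.validation_mse})
    table = pd.DataFrame(rows)
    best = int(table.loc[table["validation_mse"].idxmin(), "n_blocks"])
    return best, table


def train_ensemble(
    trials: pd.DataFrame,
    n_boot: int = DEFAULT_N_BOOT,
    base_seed: int = 0,
    n_blocks: int = 4,
    n_participants: int = 10,
    condition: tuple[str, str] = ("", ""),
    config: TrainingConfig | None = None,
) -> VisibilityEnsemble:
    """Train ``n_boot`` members, each on a with-replacement resample of
    the trial table (same size), with member-specific seeds."""
    if n_boot < 2:
        raise ValueError("an ensemble needs at least 2 members")
    ss = np.random.SeedSequence(base_seed)
    member_seeds = [int(s.generate_state(1)[0] & 0x7FFFFFFF) for s in ss.spawn(n_boot)]
    models = []
    for seed in member_seeds:
        rng = np.random.default_rng(seed)
        resampled = trials.iloc[rng.integers(len(trials), size=len(trials))]
        models.append(
            train_model(
                resampled.reset_index(drop=True),
                n_blocks,
                split_seed=seed + 1,
                init_seed=seed + 2,
                n_participants=n_participants,
                condition=condition,
                config=config,
            )
        )
    return VisibilityEnsemble(
        models=models,
        condition=condition,
        n_participants=n_participants,
        member_seeds=member_seeds,
    )


def _participant_design(
    colours: np.ndarray, occlusion: float, n_participants: int
) -> np.ndarray:
    """Design matrix enumerating every participant for every colour:
    shape (P * n, 4 + P), participant-major."""
    colours = np.atleast_2d(np.asarray(colours, dtype=float))
    n = colours.shape[0]
    P = n_participants
    X = np.zeros((P * n, 4 + P))
    X[:, 0:3] = np.tile(colours / 255.0, (P, 1))
    X[:, 3] = occlusion
    rows = np.arange(P * n)
    X[rows, 4 + rows // n] = 1.0
    return X


def predict_members(
    ensemble: VisibilityEnsemble,
    colours: np.ndarray,
    occlusion: float,
    participant_weights: np.ndarray | None = None,
) -> np.ndarray:
    """Per-member geometric-mean RT predictions, shape (n_boot, n_colours).

    Each member's prediction marginalises over participants: exp of the
    weighted mean of its per-participant log-RT outputs (uniform weights
    by default, i.e. the population geometric mean).
    """
    P = ensemble.n_participants
    if participant_weights is None:
        w = np.full(P, 1.0 / P)
    else:
        w = np.asarray(participant_weights, dtype=float)
        if w.shape != (P,) or w.min() < 0 or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("participant_weights must be a probability vector")
    colours = np.atleast_2d(np.asarray(colours))
    n = colours.shape[0]
    X = _participant_design(colours, occlusion, P)
    out = np.empty((ensemble.n_boot, n))
    for mi, model in enumerate(ensemble.models):
        log_rt = model.predict_log_rt(X).reshape(P, n)
        out[mi] = np.exp(w @ log_rt)
    return out


def predict(
    model_or_ensemble,
    colours: np.ndarray,
    occlusion: float,
    participant_weights: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Point-estimate RT and bootstrap s.e. for each colour.

    For an ensemble the point estimate is the mean over member
    predictions and the s.e. their standard deviation divided by
    sqrt(n_boot); a single model returns zero s.e.
    """
    if isinstance(model_or_ensemble, VisibilityModel):
        ens = VisibilityEnsemble(
            models=[model_or_ensemble],
            condition=model_or_ensemble.condition,
            n_participants=model_or_ensemble.n_participants,
        )
        member = predict_members(ens, colours, occlusion, participant_weights)
        return member[0], np.zeros_like(member[0])
    member = predict_members(
        model_or_ensemble, colours, occlusion, participant_weights
    )
    point = member.mean(axis=0)
    if member.shape[0] > 1:
        se = member.std(axis=0, ddof=1) / np.sqrt(member.shape[0])
    else:
        se = np.zeros_like(point)
    return point, se
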