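"""Inferential machinery: permutation tests, FDR, geometric means,
and the luminance-confound t-test.

Condition comparisons use random two-sample permutation tests on the
difference of means with add-one smoothing, 100,000 resamples by
default, and Benjamini-Hochberg adjustment across each family of
contrasts.  The default sampling unit for between-condition contrasts
is the per-bootstrap-member mean predicted RT.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .colour import _decode_lut

__all__ = [
    "PermutationResult",
    "TTestResult",
    "permutation_test",
    "fdr_adjust",
    "geometric_mean",
    "mean_luminance",
    "luminance_ttest",
    "compare_conditions",
    "N_RESAMPLES",
]

N_RESAMPLES = 100_000

# Rec. 709 luma weights, applied to linearised channels
_LUMA = np.array([0.2126, 0.7152, 0.0722])


@dataclass(frozen=True)
class PermutationResult:
    observed: float  # mean(a) - mean(b)
    p_value: float
    n_resamples: int
    seed: int


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p_value: float


def permutation_test(
    a: np.ndarray,
    b: np.ndarray,
    n_resamples: int = N_RESAMPLES,
    seed: int = 0,
) -> PermutationResult:
    """Two-sample random permutation test on the difference of means.

    The null is built by re-labelling the pooled values; the two-sided
    p-value is ``(1 + #{|T*| >= |T|}) / (n_resamples + 1)``, which is
    strictly positive and at least ``1/(n_resamples+1)``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    observed = a.mean() - b.mean()
    # sorting the pool and drawing the smaller group make |T*| identical
    # under exchange of a and b with the same seed, so the two-sided p
    # is exactly symmetric
    pooled = np.sort(np.concatenate([a, b]))
    k = min(a.size, b.size)
    rng = np.random.default_rng(seed)
    count = 0
    # chunked so memory stays bounded for large n_resamples
    chunk = max(1, min(n_resamples, 10_000_000 // max(pooled.size, 1)))
    done = 0
    tot = pooled.sum()
    while done < n_resamples:
        m = min(chunk, n_resamples - done)
        idx = np.argsort(rng.random((m, pooled.size)), axis=1)[:, :k]
        sum_k = pooled[idx].sum(axis=1)
        stat = sum_k / k - (tot - sum_k) / (pooled.size - k)
        count += int((np.abs(stat) >= abs(observed) - 1e-12).sum())
        done += m
    p = (1 + count) / (n_resamples + 1)
    return PermutationResult(
        observed=float(observed), p_value=float(p), n_resamples=n_resamples, seed=seed
    )


def fdr_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1,
    order-preserving, each adjusted >= raw)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def geometric_mean(values) -> float:
    """exp of the mean of logs; defined for positive values only."""
    v = np.asarray(values, dtype=float)
    if v.size == 0 or np.any(v <= 0):
        raise ValueError("geometric mean requires positive values")
    return float(sps.gmean(v))


def mean_luminance(image: np.ndarray, transfer: str = "gamma22") -> float:
    """Mean Rec. 709 luminance of an 8-bit RGB raster, computed on
    linearised channels; in [0, 1]."""
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[-1] != 3:
        raise ValueError("expected an (H, W, 3) RGB raster")
    lin = _decode_lut(transfer)[img]
    return float((lin @ _LUMA).mean())


def luminance_ttest(
    images_a,
    images_b,
    reference_luminance: float | None = None,
) -> TTestResult:
    """Pooled two-sample t-test on per-image luminance differences from a
    reference (the mid-grey interstimulus screen by default).

    Each group supplies one mean-luminance-minus-reference value per
    image; df = n1 + n2 - 2.
    """
    if len(images_a) < 2 or len(images_b) < 2:
        raise ValueError("need at least 2 images per group")
    if reference_luminance is None:
        reference_luminance = mean_luminance(
            np.full((1, 1, 3), 128, dtype=np.uint8)
        )
    da = np.array([mean_luminance(im) - reference_luminance for im in images_a])
    db = np.array([mean_luminance(im) - reference_luminance for im in images_b])
    df = da.size + db.size - 2
    if da.var(ddof=1) == 0 and db.var(ddof=1) == 0 and da.mean() == db.mean():
        return TTestResult(t=0.0, df=df, p_value=1.0)  # degenerate: no spread
    res = sps.ttest_ind(da, db, equal_var=True)
    return TTestResult(t=float(res.statistic), df=df, p_value=float(res.pvalue))


def compare_conditions(
    preds: dict,
    ensembles: dict | None = None,
    n_resamples: int = N_RESAMPLES,
    seed: int = 0,
    occlusion: float | None = None,
) -> pd.DataFrame:
    """Family of condition contrasts with FDR adjustment.

    ``preds`` maps condition name (e.g. ``"forest:dichromat"``) to a
    :class:`~camopt.gamut.GamutPrediction`.  Two contrast families are
    built automatically:

    * between chromacies within each environment, on per-member mean
      predicted RT over the evaluated gamut (dichromat minus trichromat);
    * hardest vs easiest colour within each condition, on per-member
      RT predictions at the two extreme colours (requires ``ensembles``).

    Returns a tidy table with raw and FDR-adjusted p-values; the
    permutation unit and seeds are recorded in the columns.
    """
    from .gamut import find_extremes
    from .model import predict_members

    rows = []
    envs = sorted({k.split(":")[0] for k in preds})
    rng = np.random.default_rng(seed)
    for env in envs:
        di, tri = f"{env}:dichromat", f"{env}:trichromat"
        if di in preds and tri in preds:
            s = int(rng.integers(2**31))
            res = permutation_test(
                preds[di].member_mean_rt,
                preds[tri].member_mean_rt,
                n_resamples=n_resamples,
                seed=s,
            )
            rows.append(
                {
                    "contrast": f"{env}: dichromat - trichromat",
                    "unit": "member mean RT",
                    "observed_ms": res.observed,
                    "p_raw": res.p_value,
                    "n_resamples": n_resamples,
                    "seed": s,
                }
            )
    if ensembles is not None:
        for name, pred in sorted(preds.items()):
            if name not in ensembles:
                continue
            ext = find_extremes(pred)
            occ = pred.occlusion if occlusion is None else occlusion
            member = predict_members(
                ensembles[name],
                np.array([tuple(ext.hardest), tuple(ext.easiest)], dtype=np.uint8),
                occ,
            )
            s = int(rng.integers(2**31))
            res = permutation_test(
                member[:, 0], member[:, 1], n_resamples=n_resamples, seed=s
            )
            rows.append(
                {
                    "contrast": f"{name}: hardest - easiest",
                    "unit": "member RT at colour",
                    "observed_ms": res.observed,
                    "p_raw": res.p_value,
                    "n_resamples": n_resamples,
                    "seed": s,
                }
            )
    if not rows:
        raise ValueError("comparison plan produced no contrasts")
    table = pd.DataFrame(rows)
    table["p_fdr"] = fdr_adjust(table["p_raw"].to_numpy())
    return table
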