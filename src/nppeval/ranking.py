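"""Biome-weighted Earth-mover's-distance ranking of a model ensemble.

For each (model, observation algorithm, assessment, driver), the
distributions of significant MLR coefficients are compared biome by
biome with the first Wasserstein distance after a k=3 interquartile-range
fence removes extreme outliers; biome distances are averaged with areal
proportions as weights.  Per model, the three driver distances give an
EMD mean and standard deviation, each Z-scored across the ensemble; the
two Z-scores are averaged with equal weight and models are ranked by the
combined score, smallest (most observation-like) first.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import xarray as xr
from scipy import stats

from .errors import ValidationError
from .grid import BiomeMask
from .synthetic import DRIVERS

__all__ = [
    "iqr_fence",
    "emd_1d",
    "biome_weighted_emd",
    "zscore",
    "rank_models",
    "delta_npp_by_rank",
]

log = logging.getLogger(__name__)


def iqr_fence(values: np.ndarray, k: float = 3.0) -> np.ndarray:
    """Retain values inside [Q1 − k·IQR, Q3 + k·IQR].

    Quartiles use linear interpolation between order statistics (the
    numpy default), the convention fixed for reproducibility.  Samples
    of fewer than 4 values are returned unfiltered (logged) since the
    quartiles are not meaningful.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 4:
        log.debug("iqr_fence: %d values, returned unfiltered", v.size)
        return v
    q1, q3 = np.percentile(v, [25.0, 75.0])
    iqr = q3 - q1
    return v[(v >= q1 - k * iqr) & (v <= q3 + k * iqr)]


def emd_1d(u: np.ndarray, v: np.ndarray) -> float:
    """First Wasserstein distance between two empirical samples,
    ∫|U − V| over the real line (U, V the empirical CDFs)."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.size == 0 or v.size == 0:
        raise ValidationError("both samples must be non-empty")
    return float(stats.wasserstein_distance(u, v))


def biome_weighted_emd(
    model_maps: xr.Dataset,
    obs_maps: xr.Dataset,
    biomes: BiomeMask,
    k_fence: float = 3.0,
) -> dict[str, float]:
    """Per-driver EMD between model and observation coefficient samples,
    fenced and computed per biome, then averaged with areal-proportion
    weights.

    Only cells whose significance mask is set contribute.  Biomes where
    either side has no significant sample are dropped and the remaining
    weights renormalised (logged).  Raises when no biome overlaps.
    """
    out: dict[str, float] = {}
    for d in DRIVERS:
        m = model_maps[f"beta_{d}"].where(model_maps[f"sig_{d}"]).values
        o = obs_maps[f"beta_{d}"].where(obs_maps[f"sig_{d}"]).values
        dists, weights = [], []
        dropped = []
        for b in biomes.biome_ids:
            cells = biomes.labels == b
            mv = m[cells]
            ov = o[cells]
            mv = mv[np.isfinite(mv)]
            ov = ov[np.isfinite(ov)]
            if mv.size == 0 or ov.size == 0:
                dropped.append(b)
                continue
            dists.append(emd_1d(iqr_fence(mv, k_fence), iqr_fence(ov, k_fence)))
            weights.append(biomes.proportions[b])
        if not dists:
            raise ValidationError(f"no biome with data on both sides for driver {d!r}")
        if dropped:
            log.info("biome_weighted_emd[%s]: dropped biomes %s, weights renormalised", d, dropped)
        w = np.asarray(weights) / np.sum(weights)
        out[d] = float(np.dot(w, dists))
    return out


def zscore(x: float, ensemble: np.ndarray, ddof: int = 1) -> float:
    """Standard score of ``x`` within an ensemble, (x − μ)/σ.

    σ is the sample standard deviation (ddof=1) by default; a degenerate
    ensemble (σ = 0) yields z = 0 by convention.
    """
    e = np.asarray(ensemble, dtype=float)
    if e.size < 2:
        raise ValidationError("ensemble must have at least two members")
    sigma = e.std(ddof=ddof)
    if sigma == 0:
        return 0.0
    return float((x - e.mean()) / sigma)


def rank_models(
    emd_table: pd.DataFrame,
    delta_npps: dict[str, float] | None = None,
    ddof: int = 1,
) -> pd.DataFrame:
    """Rank ensemble members per (algorithm, assessment) by combined Z-score.

    ``emd_table`` needs columns [model, algorithm, assessment, driver,
    emd] and must be complete over models × the three drivers within
    each (algorithm, assessment) group; a model missing a driver EMD is
    excluded from that group (logged).  Per model the EMD mean and
    standard deviation across drivers are each Z-scored across the
    ensemble; their equal-weight average is the combined score, ranked
    ascending.  Ties break by lower EMD mean, then model id.  Prescribed
    ``delta_npps`` (Pg C per year, keyed by model) are carried through.
    """
    required = {"model", "algorithm", "assessment", "driver", "emd"}
    if not required <= set(emd_table.columns):
        raise ValidationError(f"emd_table must have columns {sorted(required)}")
    records = []
    for (alg, assess), grp in emd_table.groupby(["algorithm", "assessment"]):
        per_model = {}
        for model, mg in grp.groupby("model"):
            have = set(mg["driver"])
            if not set(DRIVERS) <= have:
                log.warning("rank_models: %s missing drivers %s in (%s, %s); excluded",
                            model, set(DRIVERS) - have, alg, assess)
                continue
            vals = mg.set_index("driver")["emd"].reindex(list(DRIVERS)).to_numpy()
            per_model[model] = (float(vals.mean()), float(vals.std(ddof=ddof)))
        if len(per_model) < 2:
            raise ValidationError(f"fewer than two rankable models in ({alg}, {assess})")
        models = sorted(per_model)
        means = np.array([per_model[m][0] for m in models])
        stds = np.array([per_model[m][1] for m in models])
        # spreads below numerical precision of the EMD magnitudes are zero;
        # otherwise rounding noise gets amplified into full-size Z-scores
        snap = 1e-12 * max(float(np.abs(means).max()), 1e-300)
        stds[np.abs(stds) < snap] = 0.0
        for m, mu, sd in zip(models, means, stds):
            z_mean = zscore(mu, means, ddof=ddof)
            z_std = zscore(sd, stds, ddof=ddof)
            records.append(
                {
                    "algorithm": alg,
                    "assessment": assess,
                    "model": m,
                    "emd_mean": mu,
                    "emd_std": sd,
                    "z_mean": z_mean,
                    "z_std": z_std,
                    "combined_z": 0.5 * (z_mean + z_std),
                    "delta_npp": (delta_npps or {}).get(m, np.nan),
                }
            )
    df = pd.DataFrame.from_records(records)
    df = df.sort_values(
        ["algorithm", "assessment", "combined_z", "emd_mean", "model"],
        kind="mergesort",
    ).reset_index(drop=True)
    df["rank"] = df.groupby(["algorithm", "assessment"]).cumcount() + 1
    return df


def delta_npp_by_rank(rankings: pd.DataFrame) -> pd.DataFrame:
    """Mean ± std of ΔNPP at each rank position across assessments.

    The std is NaN (no error bar) when the same model occupies a rank in
    every assessment of an algorithm.
    """
    rows = []
    for (alg, rank), grp in rankings.groupby(["algorithm", "rank"]):
        vals = grp["delta_npp"].to_numpy(dtype=float)
        unique_models = grp["model"].nunique()
        rows.append(
            {
                "algorithm": alg,
                "rank": rank,
                "delta_npp_mean": float(np.nanmean(vals)),
                "delta_npp_std": (
                    float(np.nanstd(vals, ddof=1)) if unique_models > 1 else np.nan
                ),
                "n_models": unique_models,
            }
        )
    return pd.DataFrame(rows)
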