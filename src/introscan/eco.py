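"""Clinality and seasonality tests for a focal SNP across wild samples.

A pooled sample's allele frequency is modelled as a binomial draw with
denominator equal to its (rounded) effective coverage, so pools of different
depth contribute proportionally to their information content. The seasonal
test compares a null GLM (year and locality factors) with a model that adds
one standardized lagged environmental summary, reporting the 1-df likelihood
ratio p and, optionally, the rank of the observed statistic among
within-locality permutations of the environmental values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "DegenerateFitError",
    "SeasonalFit",
    "lag_summary",
    "clinal_test",
    "seasonal_glm",
    "permutation_rank",
    "colocalize",
]

LAG_DAYS = (15, 30, 45, 60, 75, 90)
LAG_STATISTICS = ("mean", "sd", "max", "min")


class DegenerateFitError(RuntimeError):
    """The environmental term is inestimable (constant or separated fit)."""


@dataclass
class SeasonalFit:
    beta_seasonal: float
    beta_se: float
    lrt_stat: float
    p_value: float
    lag_days: int | None = None
    statistic: str | None = None
    permutation_proportion: float | None = None
    n_samples: int = 0


def lag_summary(
    env: pd.Series, collection_date, lag_days: int, statistic: str = "mean"
) -> float:
    """Summary of a daily environmental series over a pre-collection window.

    The window is the ``lag_days`` consecutive days ending on (and including)
    the collection date. ``sd`` is the sample standard deviation. Raises if
    any day in the window is missing from the series.
    """
    if statistic not in LAG_STATISTICS:
        raise ValueError(f"statistic must be one of {LAG_STATISTICS}")
    if lag_days < 1:
        raise ValueError("lag_days must be >= 1")
    date = pd.Timestamp(collection_date)
    wanted = pd.date_range(end=date, periods=lag_days, freq="D")
    env = env.copy()
    env.index = pd.DatetimeIndex(env.index)
    missing = wanted.difference(env.index)
    if len(missing):
        raise ValueError(
            f"environmental series missing {len(missing)} day(s) in the "
            f"{lag_days}-day window ending {date.date()}"
        )
    vals = env.loc[wanted].to_numpy(dtype=float)
    if statistic == "mean":
        return float(np.mean(vals))
    if statistic == "sd":
        return float(np.std(vals, ddof=1))
    if statistic == "max":
        return float(np.max(vals))
    return float(np.min(vals))


def clinal_test(frequencies: np.ndarray, latitudes: np.ndarray) -> tuple[float, float]:
    """Pearson correlation of allele frequency with latitude (r, two-sided p)."""
    frequencies = np.asarray(frequencies, dtype=float)
    latitudes = np.asarray(latitudes, dtype=float)
    if frequencies.size < 3:
        raise ValueError("clinal test needs >= 3 samples")
    if np.std(frequencies) == 0 or np.std(latitudes) == 0:
        raise ValueError("zero-variance input")
    r, p = stats.pearsonr(frequencies, latitudes)
    return float(r), float(p)


def _build_design(samples: pd.DataFrame, env: np.ndarray | None) -> np.ndarray:
    """Intercept + year dummies + locality dummies (+ standardized env)."""
    parts = [np.ones((len(samples), 1))]
    years = pd.Categorical(pd.DatetimeIndex(samples["date"]).year)
    if len(years.categories) > 1:
        parts.append(pd.get_dummies(years, drop_first=True).to_numpy(dtype=float))
    locs = pd.Categorical(samples["locality"])
    if len(locs.categories) > 1:
        parts.append(pd.get_dummies(locs, drop_first=True).to_numpy(dtype=float))
    if env is not None:
        parts.append(env.reshape(-1, 1))
    return np.hstack(parts)


def _glm_endog(samples: pd.DataFrame) -> np.ndarray:
    """Binomial successes/failures from frequency and effective coverage.

    Fractional counts are rounded half-to-even, the natural rounding for a
    non-integer effective sample size.
    """
    ne = np.round(samples["n_e"].to_numpy(dtype=float)).astype(int)
    if np.any(ne < 1):
        raise ValueError("every sample needs effective coverage >= 1")
    succ = np.round(samples["freq"].to_numpy(dtype=float) * ne).astype(int)
    return np.column_stack([succ, ne - succ])


def seasonal_glm(
    samples: pd.DataFrame,
    env_values: np.ndarray | None = None,
    env_column: str | None = "env",
    lag_days: int | None = None,
    statistic: str | None = None,
) -> SeasonalFit:
    """Binomial GLM test for an environmental effect on allele frequency.

    ``samples`` needs columns ``freq``, ``n_e``, ``locality``, ``date``, and
    the environmental summary (``env_column`` or explicit ``env_values``).
    The null model holds year and locality factors; the full model adds the
    z-scored environmental summary. Returns the environmental coefficient
    (per SD of the summary) and the 1-df likelihood-ratio p.
    """
    required = {"freq", "n_e", "locality", "date"}
    if not required.issubset(samples.columns):
        raise ValueError(f"samples needs columns {sorted(required)}")
    env = (
        np.asarray(env_values, dtype=float)
        if env_values is not None
        else samples[env_column].to_numpy(dtype=float)
    )
    if env.shape[0] != len(samples):
        raise ValueError("environmental values must align with samples")
    sd = env.std()
    if sd == 0 or not np.isfinite(sd):
        raise DegenerateFitError("environmental summary is constant; term inestimable")
    z = (env - env.mean()) / sd

    endog = _glm_endog(samples)
    x_null = _build_design(samples, None)
    x_full = _build_design(samples, z)
    try:
        fit_null = sm.GLM(endog, x_null, family=sm.families.Binomial()).fit()
        fit_full = sm.GLM(endog, x_full, family=sm.families.Binomial()).fit()
    except Exception as exc:  # perfect separation, singular design, ...
        raise DegenerateFitError(f"GLM fit failed: {exc}") from exc
    beta = float(fit_full.params[-1])
    se = float(fit_full.bse[-1])
    if not (np.isfinite(beta) and np.isfinite(se)):
        raise DegenerateFitError("non-finite environmental coefficient")
    lrt = 2.0 * (fit_full.llf - fit_null.llf)
    lrt = max(lrt, 0.0)
    p = float(stats.chi2.sf(lrt, df=1))
    return SeasonalFit(
        beta_seasonal=beta,
        beta_se=se,
        lrt_stat=float(lrt),
        p_value=p,
        lag_days=lag_days,
        statistic=statistic,
        n_samples=len(samples),
    )


def permutation_rank(
    samples: pd.DataFrame,
    env_values: np.ndarray | None = None,
    env_column: str | None = "env",
    n_perm: int = 100,
    seed: int | np.random.Generator | None = None,
) -> tuple[float, SeasonalFit]:
    """Proportion of permutations beaten by the observed seasonal LRT.

    Environmental values are shuffled across samples within each locality
    (preserving the year/locality factor structure); the reported proportion
    counts permuted LRT statistics strictly below the observed one, so ties
    do not count as beaten. Reported on a ``1/n_perm`` grid.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    env = (
        np.asarray(env_values, dtype=float)
        if env_values is not None
        else samples[env_column].to_numpy(dtype=float)
    )
    observed = seasonal_glm(samples, env_values=env)
    localities = samples["locality"].to_numpy()
    beaten = 0
    for _ in range(n_perm):
        perm = env.copy()
        for loc in pd.unique(localities):
            idx = np.nonzero(localities == loc)[0]
            perm[idx] = perm[idx[rng.permutation(len(idx))]]
        try:
            fit = seasonal_glm(samples, env_values=perm)
            if fit.lrt_stat < observed.lrt_stat:
                beaten += 1
        except DegenerateFitError:
            beaten += 1  # an inestimable permutation carries no evidence
    prop = beaten / n_perm
    observed.permutation_proportion = prop
    return prop, observed


def colocalize(
    scan_sites: pd.DataFrame,
    clinal_sites: pd.DataFrame | None = None,
    seasonal_sites: pd.DataFrame | None = None,
    clinal_q_threshold: float = 0.05,
    seasonal_p_threshold: float = 0.004,
) -> pd.DataFrame:
    """Intersect scan hits with external clinal and seasonal SNP sets.

    All tables are keyed by (arm, pos), 1-based. External sets are filtered
    strictly below their thresholds (q < 0.05 for clinal, p < 0.004 for
    seasonal) before joining; the result flags membership per set and the
    triple intersection. Duplicate keys within one set are an error.
    """
    def _check(df: pd.DataFrame, name: str) -> pd.DataFrame:
        if not {"arm", "pos"}.issubset(df.columns):
            raise ValueError(f"{name} set needs 'arm' and 'pos' columns")
        if df.duplicated(subset=["arm", "pos"]).any():
            raise ValueError(f"duplicate site keys in {name} set")
        return df

    out = _check(scan_sites, "scan").copy()
    if clinal_sites is not None:
        cl = _check(clinal_sites, "clinal")
        cl = cl[cl["q"] < clinal_q_threshold]
        keys = set(zip(cl["arm"], cl["pos"]))
        out["in_clinal"] = [t in keys for t in zip(out["arm"], out["pos"])]
    else:
        out["in_clinal"] = False
    if seasonal_sites is not None:
        se = _check(seasonal_sites, "seasonal")
        se = se[se["p"] < seasonal_p_threshold]
        keys = set(zip(se["arm"], se["pos"]))
        out["in_seasonal"] = [t in keys for t in zip(out["arm"], out["pos"])]
    else:
        out["in_seasonal"] = False
    out["triple"] = out["in_clinal"] & out["in_seasonal"]
    return out
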