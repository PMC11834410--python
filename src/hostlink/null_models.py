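"""Richness-matched resampling nulls for phylogenetic / functional diversity.

The question these nulls answer: is the focal environment's mean diversity
statistic (Faith PD, or an externally supplied functional-richness scalar)
higher or lower than expected for communities of comparable richness?  The
procedure:

1. collapse worm samples to per-apple units (mean Chao1 and mean statistic),
   so worms from one apple contribute a single unit;
2. take the focal environment's Chao1 range ``[min, max]``;
3. pool *all* units — both environments — whose Chao1 falls in that range;
4. repeatedly draw ``n_focal`` units without replacement from the pool and
   record the mean statistic;
5. report a two-sided empirical p-value with the add-one rule,
   ``p = 2 * min(tail_le, tail_ge)`` capped at 1.

An alternative pool restricted to the non-focal environment is available via
``pool="other"``; the default ``"both"`` follows the procedure literally.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InfeasibleError, InvalidArgumentError

logger = logging.getLogger(__name__)

CHAO1_MATCH_DECIMALS = 6  # exact matching absorbs float noise at 1e-6


@dataclass
class NullTestResult:
    focal_env: str
    statistic: str
    observed_mean: float
    null_draws: np.ndarray
    p_two_sided: float
    n_draws: int
    chao1_range: tuple[float, float]
    n_focal_units: int
    pool_size: int
    seed: int


@dataclass
class MatchedComparisonResult:
    n_pairs: int
    worm_values: np.ndarray
    apple_values: np.ndarray
    median_difference: float
    wilcoxon_p: float
    seed: int


def collapse_worms_to_units(
    profiles: pd.DataFrame, metadata: pd.DataFrame, statistic: str = "faith_pd"
) -> pd.DataFrame:
    """One analysis unit per apple sample and per apple's worm cohort.

    Worm samples from one apple are averaged (arithmetic mean of Chao1 and of
    the statistic); apple samples pass through unchanged.  Returns a frame
    with columns ``environment``, ``chao1`` and the statistic.
    """
    needed = {"chao1", statistic}
    missing = needed.difference(profiles.columns)
    if missing:
        raise InvalidArgumentError(f"profiles missing columns: {sorted(missing)}")
    meta = metadata.loc[profiles.index]
    rows = []
    apples = meta.index[meta["environment"] == "apple"]
    for sample in apples:
        rows.append(
            dict(unit_id=sample, environment="apple",
                 chao1=profiles.at[sample, "chao1"],
                 **{statistic: profiles.at[sample, statistic]})
        )
    worms = meta[meta["environment"] == "worm"]
    if worms["apple_id"].isna().any():
        bad = worms.index[worms["apple_id"].isna()].tolist()
        raise InvalidArgumentError(f"worm samples lacking apple_id: {bad}")
    for apple_id, group in worms.groupby("apple_id"):
        sub = profiles.loc[group.index]
        rows.append(
            dict(unit_id=f"worms[{apple_id}]", environment="worm",
                 chao1=float(sub["chao1"].mean()),
                 **{statistic: float(sub[statistic].mean())})
        )
    return pd.DataFrame(rows).set_index("unit_id")


def empirical_two_sided_p(observed: float, draws: np.ndarray) -> float:
    """Doubled one-sided add-one empirical p, capped at 1."""
    draws = np.asarray(draws, dtype=float)
    n = len(draws)
    lower = (1.0 + np.sum(draws <= observed)) / (1.0 + n)
    upper = (1.0 + np.sum(draws >= observed)) / (1.0 + n)
    return float(min(1.0, 2.0 * min(lower, upper)))


def richness_matched_null(
    units: pd.DataFrame,
    focal_env: str,
    statistic: str = "faith_pd",
    n_draws: int = 5000,
    seed: int = 0,
    pool: str = "both",
) -> NullTestResult:
    """Chao1-range-matched resampling null for the focal environment's mean
    statistic.  See the module docstring for the full procedure."""
    if statistic not in units.columns:
        raise InvalidArgumentError(f"units lack statistic column {statistic!r}")
    if units[statistic].isna().any():
        bad = units.index[units[statistic].isna()].tolist()
        raise InvalidArgumentError(f"units missing {statistic!r} values: {bad}")
    focal = units[units["environment"] == focal_env]
    if len(focal) < 2:
        raise InfeasibleError(
            f"need >= 2 focal units for environment {focal_env!r}, got {len(focal)}"
        )
    lo, hi = float(focal["chao1"].min()), float(focal["chao1"].max())
    eligible = units[(units["chao1"] >= lo) & (units["chao1"] <= hi)]
    if pool == "other":
        eligible = eligible[eligible["environment"] != focal_env]
    elif pool != "both":
        raise InvalidArgumentError("pool must be 'both' or 'other'")
    n_focal = len(focal)
    if len(eligible) < n_focal:
        raise InfeasibleError(
            f"eligible pool ({len(eligible)} units) smaller than focal count "
            f"({n_focal})"
        )
    rng = np.random.default_rng(seed)
    values = eligible[statistic].to_numpy(dtype=float)
    draws = np.empty(n_draws)
    for i in range(n_draws):
        draws[i] = values[rng.choice(len(values), size=n_focal, replace=False)].mean()
    observed = float(focal[statistic].mean())
    return NullTestResult(
        focal_env=focal_env,
        statistic=statistic,
        observed_mean=observed,
        null_draws=draws,
        p_two_sided=empirical_two_sided_p(observed, draws),
        n_draws=n_draws,
        chao1_range=(lo, hi),
        n_focal_units=n_focal,
        pool_size=len(eligible),
        seed=seed,
    )


def functional_richness_null(
    units: pd.DataFrame,
    focal_env: str,
    statistic: str = "functional_richness",
    n_draws: int = 5000,
    seed: int = 0,
    pool: str = "both",
) -> NullTestResult:
    """Identical machinery applied to an externally supplied per-unit scalar
    (e.g. EC or MetaCyc pathway richness from an annotation step)."""
    if statistic not in units.columns or units[statistic].isna().any():
        missing = (
            list(units.index)
            if statistic not in units.columns
            else units.index[units[statistic].isna()].tolist()
        )
        raise InvalidArgumentError(
            f"functional richness {statistic!r} missing for units: {missing}"
        )
    return richness_matched_null(
        units, focal_env, statistic=statistic, n_draws=n_draws, seed=seed, pool=pool
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment, input order preserved."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise InvalidArgumentError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


def matched_richness_comparison(
    profiles: pd.DataFrame,
    metadata: pd.DataFrame,
    statistic: str = "faith_pd",
    seed: int = 0,
) -> MatchedComparisonResult:
    """Pair worm and apple samples with exactly equal Chao1 (rounded to
    1e-6) and run a paired Wilcoxon on the statistic.

    Ties (several candidates at one Chao1 value) are resolved by a seeded
    random draw; with zero exact matches an empty result is returned with a
    warning.
    """
    meta = metadata.loc[profiles.index]
    rng = np.random.default_rng(seed)
    chao = profiles["chao1"].round(CHAO1_MATCH_DECIMALS)
    worm_ids = meta.index[meta["environment"] == "worm"]
    apple_ids = meta.index[meta["environment"] == "apple"]
    worm_vals, apple_vals = [], []
    shared = sorted(set(chao.loc[worm_ids]) & set(chao.loc[apple_ids]))
    for value in shared:
        worms = list(worm_ids[chao.loc[worm_ids] == value])
        apples = list(apple_ids[chao.loc[apple_ids] == value])
        n_pairs = min(len(worms), len(apples))
        worms = list(rng.choice(worms, size=n_pairs, replace=False))
        apples = list(rng.choice(apples, size=n_pairs, replace=False))
        worm_vals.extend(profiles.loc[worms, statistic])
        apple_vals.extend(profiles.loc[apples, statistic])
    worm_vals = np.asarray(worm_vals, dtype=float)
    apple_vals = np.asarray(apple_vals, dtype=float)
    if worm_vals.size == 0:
        logger.warning("no exactly matching Chao1 values; empty comparison")
        return MatchedComparisonResult(0, worm_vals, apple_vals,
                                       float("nan"), float("nan"), seed)
    diff = worm_vals - apple_vals
    if np.allclose(diff, 0.0):
        p = 1.0  # all ties carry no evidence either way
    else:
        p = float(stats.wilcoxon(worm_vals, apple_vals, zero_method="wilcox",
                                 alternative="two-sided").pvalue)
    return MatchedComparisonResult(
        n_pairs=int(worm_vals.size),
        worm_values=worm_vals,
        apple_values=apple_vals,
        median_difference=float(np.median(diff)),
        wilcoxon_p=p,
        seed=seed,
    )
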