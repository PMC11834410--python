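"""Bidirectional source–sink inference between host and substrate communities.

Two complementary approaches, each with a paired directionality test:

* **EM mixture source tracking** — a single-sink multinomial-mixture
  expectation–maximization tracker in the style of microbial source trackers:
  the sink's counts are modelled as a mixture of fixed source profiles plus
  one free "unknown" source whose profile is re-estimated each M-step.  The
  mixing proportions live on the simplex and the log-likelihood is
  non-decreasing over iterations (asserted).
* **Penalized-regression cross-prediction** — worm and apple samples are
  repeatedly paired one-to-one (one random worm per apple), and every
  target-side taxon's relative abundance is predicted from all predictor-side
  taxa with an L1-penalized linear model (penalty chosen by k-fold CV at the
  minimum CV error).  Per-taxon RMSE and R² are averaged over the random
  pairings; directions are compared with a paired Wilcoxon signed-rank over
  per-taxon aggregates.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import Lasso, LassoCV
from sklearn.model_selection import KFold, cross_val_predict

from .community_metrics import filter_min_occurrence
from .errors import InfeasibleError, InvalidArgumentError

logger = logging.getLogger(__name__)

_PSEUDO = 1e-8  # source-profile pseudocount: no taxon has exactly zero rate


@dataclass
class SourceContribution:
    sink_id: str
    contributions: dict[str, float]  # source id -> proportion, plus "unknown"
    log_likelihood: list[float]
    n_iterations: int
    converged: bool

    def __post_init__(self) -> None:
        total = sum(self.contributions.values())
        if abs(total - 1.0) > 1e-8:
            raise InvalidArgumentError("contributions must sum to 1")


@dataclass
class CrossPredictionResult:
    direction: str  # "worm->apple" or "apple->worm"
    per_taxon: pd.DataFrame  # index taxon; columns mean_rmse, mean_r2, n_pairings
    n_pairings: int
    seed: int
    mode: str = "cv"


@dataclass
class DirectionalityTest:
    statistic: float  # Wilcoxon W
    p: float
    favored: str
    metric: str = ""


def em_source_track(
    sink_counts,
    source_profiles: pd.DataFrame,
    tol: float = 1e-6,
    max_iter: int = 1000,
    sink_id: str = "sink",
    alpha_unknown_init: float = 0.01,
) -> SourceContribution:
    """Estimate mixing proportions of candidate sources (plus "unknown")
    composing a sink community.

    ``sink_counts`` is a count vector over taxa; ``source_profiles`` a
    (source x taxon) matrix of relative abundances (rows are renormalized
    after a 1e-8 pseudocount).  The unknown source starts uniform and its
    profile is re-estimated each M-step from the counts assigned to it, so
    it absorbs the mass the fixed sources cannot explain.

    Two numerical safeguards keep the free unknown identifiable: it starts
    with a near-zero share (``alpha_unknown_init``) because a mixture the
    sources already explain is likelihood-equivalent for any unknown share
    (EM stays near the initialization on that flat ridge), and the stopping
    rule is *relative* — improvement below ``tol * max(1, |loglik|)`` —
    so iterations end once only per-taxon sampling noise is left to fit.
    """
    x = np.asarray(sink_counts, dtype=float)
    if x.sum() < 1:
        raise InvalidArgumentError("sink depth must be >= 1")
    gamma = source_profiles.to_numpy(dtype=float)
    if gamma.ndim != 2 or gamma.shape[0] < 1 or gamma.shape[1] != x.size:
        raise InvalidArgumentError("source profiles must be (n_sources, n_taxa)")
    K, J = gamma.shape
    gamma = gamma + _PSEUDO
    gamma /= gamma.sum(axis=1, keepdims=True)
    gamma_u = np.full(J, 1.0 / J)
    alpha = np.concatenate(
        [np.full(K, (1.0 - alpha_unknown_init) / K), [alpha_unknown_init]]
    )

    loglik: list[float] = []
    converged = False
    for it in range(1, max_iter + 1):
        rates = alpha[:K, None] * gamma  # (K, J)
        mix = rates.sum(axis=0) + alpha[K] * gamma_u
        ll = float(np.sum(x[x > 0] * np.log(mix[x > 0])))
        if loglik:
            assert ll >= loglik[-1] - 1e-8, "EM log-likelihood decreased"
            if ll - loglik[-1] < tol * max(1.0, abs(ll)):
                loglik.append(ll)
                converged = True
                break
        loglik.append(ll)
        # E-step: expected counts per (source, taxon)
        with np.errstate(invalid="ignore", divide="ignore"):
            resp = np.vstack([rates, alpha[K] * gamma_u]) / mix
        resp[:, mix == 0] = 0.0
        m = resp * x  # (K+1, J)
        # M-step
        total = m.sum()
        alpha = m.sum(axis=1) / total
        mu = m[K]
        if mu.sum() > 0:
            gamma_u = mu / mu.sum()
    if not converged:
        logger.warning("EM did not converge in %d iterations", max_iter)
    contributions = {
        str(name): float(a) for name, a in zip(source_profiles.index, alpha[:K])
    }
    contributions["unknown"] = float(alpha[K])
    return SourceContribution(
        sink_id=sink_id,
        contributions=contributions,
        log_likelihood=loglik,
        n_iterations=len(loglik),
        converged=converged,
    )


def _relative(table: pd.DataFrame) -> pd.DataFrame:
    values = table.to_numpy(dtype=float)
    totals = values.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    return pd.DataFrame(values / totals, index=table.index, columns=table.columns)


def directionality_em(
    counts: pd.DataFrame,
    metadata: pd.DataFrame,
    min_count: int = 3,
    min_frac: float = 0.10,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> tuple[pd.DataFrame, DirectionalityTest]:
    """Per-apple paired EM contributions and their Wilcoxon comparison.

    For every apple with worms: (a) the apple is the sink and all its worms
    are simultaneous sources — their contributions are summed; (b) each worm
    is a sink with the apple as sole source — apple contributions are
    averaged over the apple's worms.  A paired two-sided Wilcoxon
    signed-rank across apples compares (a) worm->apple against
    (b) apple->worm.
    """
    counts = filter_min_occurrence(counts, min_count=min_count, min_frac=min_frac)
    if counts.shape[1] == 0:
        raise InfeasibleError("occurrence filter removed every taxon")
    meta = metadata.loc[counts.index.intersection(metadata.index)]
    worms = meta[meta["environment"] == "worm"]
    rows = []
    for apple_id, group in worms.groupby("apple_id"):
        if apple_id not in counts.index:
            continue
        worm_ids = [w for w in group.index if w in counts.index]
        if not worm_ids:
            continue
        apple_vec = counts.loc[apple_id].to_numpy(dtype=float)
        worm_profiles = _relative(counts.loc[worm_ids])
        res_a = em_source_track(apple_vec, worm_profiles, tol=tol,
                                max_iter=max_iter, sink_id=str(apple_id))
        worm_to_apple = 1.0 - res_a.contributions["unknown"]
        apple_profile = _relative(counts.loc[[apple_id]])
        apple_contribs = []
        for w in worm_ids:
            res_b = em_source_track(counts.loc[w].to_numpy(dtype=float),
                                    apple_profile, tol=tol, max_iter=max_iter,
                                    sink_id=w)
            apple_contribs.append(res_b.contributions[str(apple_id)])
        rows.append(dict(apple_id=str(apple_id), n_worms=len(worm_ids),
                         worm_to_apple=worm_to_apple,
                         apple_to_worm=float(np.mean(apple_contribs))))
    if len(rows) < 3:
        raise InfeasibleError(f"only {len(rows)} apples with worms; need >= 3")
    table = pd.DataFrame(rows).set_index("apple_id")
    test = _paired_directionality(
        table["worm_to_apple"].to_numpy(), table["apple_to_worm"].to_numpy(),
        "worm->apple", "apple->worm", metric="em_contribution",
    )
    return table, test


def _paired_directionality(a, b, name_a, name_b, metric="") -> DirectionalityTest:
    diff = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    if np.allclose(diff, 0.0):
        return DirectionalityTest(statistic=0.0, p=1.0, favored="tie", metric=metric)
    res = stats.wilcoxon(diff, zero_method="wilcox", alternative="two-sided",
                         method="exact" if len(diff) <= 25 else "approx")
    favored = name_a if np.median(diff) > 0 else name_b
    return DirectionalityTest(statistic=float(res.statistic),
                              p=float(res.pvalue), favored=favored, metric=metric)


def random_pair_assignment(
    metadata: pd.DataFrame, n_pairings: int = 100, seed: int = 0
) -> list[dict[str, str]]:
    """``n_pairings`` maps, each choosing one worm uniformly at random for
    every apple that has at least one worm."""
    worms = metadata[metadata["environment"] == "worm"]
    by_apple: dict[str, list[str]] = {}
    for sample, apple_id in worms["apple_id"].items():
        by_apple.setdefault(str(apple_id), []).append(sample)
    if not by_apple:
        raise InfeasibleError("no apples with worms")
    for worm_list in by_apple.values():
        worm_list.sort()
    apples = sorted(by_apple)
    rng = np.random.default_rng(seed)
    maps = []
    for _ in range(n_pairings):
        maps.append(
            {a: by_apple[a][int(rng.integers(len(by_apple[a])))] for a in apples}
        )
    return maps


def lasso_cross_predict(
    counts: pd.DataFrame,
    pairing_maps: list[dict[str, str]],
    direction: str,
    cv: int = 5,
    seed: int = 0,
    mode: str = "cv",
    n_alphas: int = 30,
) -> CrossPredictionResult:
    """Cross-predict taxon relative abundances between paired worm and apple
    samples under repeated random pairings.

    For each pairing map and each target-side taxon with non-zero variance,
    an L1-penalized fit of the target on all predictor-side taxa is scored:
    with ``mode="cv"`` RMSE and R² are computed on held-out k-fold
    predictions (R² may be negative); ``mode="in_sample"`` scores the fit on
    the training data.  Per-taxon values are averaged over the pairing maps.
    ``counts`` should already be occurrence-filtered.
    """
    if direction not in ("worm->apple", "apple->worm"):
        raise InvalidArgumentError("direction must be 'worm->apple' or 'apple->worm'")
    rel = _relative(counts)
    sums: dict[str, np.ndarray] = {}
    counts_per_taxon: dict[str, int] = {}
    rng = np.random.default_rng(seed)
    for pairing in pairing_maps:
        apples = sorted(pairing)
        worm_ids = [pairing[a] for a in apples]
        A = rel.loc[apples].to_numpy()
        W = rel.loc[worm_ids].to_numpy()
        X, Y = (W, A) if direction == "worm->apple" else (A, W)
        n = len(apples)
        k = min(cv, n)
        if k < cv:
            logger.warning("only %d pairs; reducing CV folds to %d", n, k)
        if k < 2:
            raise InfeasibleError("need >= 2 pairs for cross-validated scoring")
        folds = KFold(n_splits=k, shuffle=True,
                      random_state=int(rng.integers(2**31 - 1)))
        for j, taxon in enumerate(counts.columns):
            y = Y[:, j]
            if np.ptp(y) == 0:  # zero variance in this map: skip
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                sel = LassoCV(cv=folds, alphas=n_alphas, max_iter=5000)
                sel.fit(X, y)
                model = Lasso(alpha=sel.alpha_, max_iter=5000)
                if mode == "cv":
                    pred = cross_val_predict(model, X, y, cv=folds)
                elif mode == "in_sample":
                    pred = model.fit(X, y).predict(X)
                else:
                    raise InvalidArgumentError("mode must be 'cv' or 'in_sample'")
            rmse = float(np.sqrt(np.mean((y - pred) ** 2)))
            sst = float(np.sum((y - y.mean()) ** 2))
            r2 = 1.0 - float(np.sum((y - pred) ** 2)) / sst
            acc = sums.setdefault(taxon, np.zeros(2))
            acc += (rmse, r2)
            counts_per_taxon[taxon] = counts_per_taxon.get(taxon, 0) + 1
    per_taxon = pd.DataFrame(
        {
            taxon: dict(
                mean_rmse=acc[0] / counts_per_taxon[taxon],
                mean_r2=acc[1] / counts_per_taxon[taxon],
                n_pairings=counts_per_taxon[taxon],
            )
            for taxon, acc in sums.items()
        }
    ).T
    return CrossPredictionResult(
        direction=direction,
        per_taxon=per_taxon,
        n_pairings=len(pairing_maps),
        seed=seed,
        mode=mode,
    )


def directionality_regression(
    result_a: CrossPredictionResult, result_b: CrossPredictionResult
) -> dict[str, DirectionalityTest]:
    """Paired two-sided Wilcoxon over shared taxa, separately for per-taxon
    mean RMSE (lower is better) and mean R² (higher is better)."""
    shared = result_a.per_taxon.index.intersection(result_b.per_taxon.index)
    if len(shared) < 5:
        raise InfeasibleError(f"only {len(shared)} shared taxa; need >= 5")
    out = {}
    rmse_a = result_a.per_taxon.loc[shared, "mean_rmse"].to_numpy()
    rmse_b = result_b.per_taxon.loc[shared, "mean_rmse"].to_numpy()
    test = _paired_directionality(rmse_b, rmse_a, result_a.direction,
                                  result_b.direction, metric="mean_rmse")
    out["mean_rmse"] = test
    r2_a = result_a.per_taxon.loc[shared, "mean_r2"].to_numpy()
    r2_b = result_b.per_taxon.loc[shared, "mean_r2"].to_numpy()
    out["mean_r2"] = _paired_directionality(
        r2_a, r2_b, result_a.direction, result_b.direction, metric="mean_r2"
    )
    return out
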