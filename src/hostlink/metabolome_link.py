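"""Metabolome normalization, PCA, the ASV–metabolite mixed-model network and
penalized-regression prediction between the ASV and metabolite layers.

Normalization is order-exact: per-sample ratio to the internal standard,
natural log, then per-metabolite z-scaling.  The association network fits,
for every (ASV, metabolite) pair and direction, a linear mixed model with a
random intercept per sampling time point
(``metabolite ~ ASV + pH + (1|timepoint)`` and the reverse); the fixed-effect
slope p-value comes from a likelihood-ratio test (ML fits), and edges are
kept after Benjamini–Hochberg adjustment within each direction.

Prediction quality of the lasso cross-layer models is reported as relative
RMSE = held-out RMSE / span of the observed target (span = max - min).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import Lasso, LassoCV
from sklearn.model_selection import KFold, cross_val_predict

from .errors import InvalidArgumentError
from .io_formats import MetaboliteTable
from .null_models import bh_adjust

logger = logging.getLogger(__name__)


@dataclass
class NormalizedMetabolome:
    values: pd.DataFrame  # sample x metabolite, z-scaled log ratios
    ratio_normalized: bool = True
    log_transformed: bool = True
    scaled: bool = True
    excluded: list[str] = field(default_factory=list)  # zero-variance columns


@dataclass
class AssociationEdge:
    asv_id: str
    metabolite_id: str
    direction: str  # "metabolite~asv" or "asv~metabolite"
    coefficient: float
    p: float
    p_adjusted: float

    @property
    def sign(self) -> int:
        return int(np.sign(self.coefficient))


def normalize_metabolome(raw: MetaboliteTable) -> NormalizedMetabolome:
    """Ratio to the internal standard, natural log, per-metabolite z-scaling.

    Non-positive ratios become missing (with a warning); metabolite columns
    with zero variance after the log step are excluded from scaling and
    listed in ``excluded``.  The standard's own column is dropped.
    """
    std = raw.values[raw.internal_standard_id]
    table = raw.values.drop(columns=[raw.internal_standard_id])
    ratio = table.div(std, axis=0)
    n_bad = int((ratio <= 0).to_numpy().sum())
    if n_bad:
        logger.warning("%d non-positive ratios set to missing before log", n_bad)
    logged = pd.DataFrame(
        np.where(ratio > 0, np.log(ratio.where(ratio > 0)), np.nan),
        index=ratio.index, columns=ratio.columns,
    )
    excluded = [
        c for c in logged.columns if logged[c].std(ddof=1) == 0 or logged[c].count() < 2
    ]
    if excluded:
        logger.warning("excluding zero-variance metabolites from scaling: %s",
                       excluded)
    kept = logged.drop(columns=excluded)
    scaled = (kept - kept.mean()) / kept.std(ddof=1)
    return NormalizedMetabolome(values=scaled, excluded=excluded)


def pca_metabolome(normalized: NormalizedMetabolome, n_top: int = 10):
    """Centered PCA via SVD on complete rows.

    Returns ``(scores, loadings, explained_variance_fractions)``; the sign of
    each component is fixed so its largest-|loading| entry is positive, and
    ``loadings`` carries only the top ``n_top`` metabolites per component
    (others are NaN) mirroring biplot annotation practice.
    """
    values = normalized.values.dropna(axis=0, how="any")
    dropped = len(normalized.values) - len(values)
    if dropped:
        logger.info("PCA dropped %d rows with missing values", dropped)
    X = values.to_numpy(dtype=float)
    X = X - X.mean(axis=0, keepdims=True)
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    for k in range(Vt.shape[0]):  # deterministic sign convention
        pivot = np.argmax(np.abs(Vt[k]))
        if Vt[k, pivot] < 0:
            Vt[k] *= -1.0
            U[:, k] *= -1.0
    explained = S**2 / np.sum(S**2) if S.size else S
    comp_ids = [f"PC{i + 1}" for i in range(len(S))]
    scores = pd.DataFrame(U * S, index=values.index, columns=comp_ids)
    loadings = pd.DataFrame(Vt.T, index=values.columns, columns=comp_ids)
    if n_top is not None and n_top < loadings.shape[0]:
        masked = loadings.copy()
        for c in comp_ids:
            keep = loadings[c].abs().nlargest(n_top).index
            masked.loc[~masked.index.isin(keep), c] = np.nan
        loadings = masked
    return scores, loadings, pd.Series(explained, index=comp_ids)


# ---------------------------------------------------------------------------
# mixed models

def _mixed_lrt(y, x, covariates: pd.DataFrame, groups) -> tuple[float, float]:
    """Random-intercept mixed model LRT for the focal fixed effect.

    Fits ``y ~ x + covariates + (1|groups)`` and the same model without
    ``x``, both by maximum likelihood; returns (slope, p) from the 1-df
    chi-square likelihood-ratio test.
    """
    exog_full = sm.add_constant(pd.concat([x, covariates], axis=1))
    exog_red = sm.add_constant(covariates) if covariates.shape[1] else None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        full = sm.MixedLM(y, exog_full, groups=groups).fit(reml=False)
        if exog_red is not None:
            red = sm.MixedLM(y, exog_red, groups=groups).fit(reml=False)
        else:
            ones = pd.DataFrame({"const": np.ones(len(y))}, index=y.index)
            red = sm.MixedLM(y, ones, groups=groups).fit(reml=False)
    lr = 2.0 * (full.llf - red.llf)
    p = float(stats.chi2.sf(max(lr, 0.0), df=1))
    slope = float(full.params[x.columns[0] if hasattr(x, "columns") else x.name])
    return slope, p


def asv_metabolite_network(
    clr_asvs: pd.DataFrame,
    metabolome: NormalizedMetabolome,
    ph: pd.Series,
    timepoint: pd.Series,
    directions: tuple[str, ...] = ("metabolite~asv", "asv~metabolite"),
    alpha: float = 0.05,
    dashed_alpha: float | None = None,
) -> list[AssociationEdge]:
    """Mixed-model association network between CLR ASV abundances and
    normalized metabolite levels.

    For every (ASV, metabolite) pair and each requested direction a linear
    mixed model with pH as covariate and a random intercept per sampling
    time point is fitted; p-values are BH-adjusted within each direction and
    edges retained at adjusted p < ``alpha`` (plus, optionally, "dashed"
    edges at raw p < ``dashed_alpha``).  Non-converging pairs are dropped
    from the BH family with a warning.
    """
    samples = clr_asvs.index.intersection(metabolome.values.index)
    samples = samples[~metabolome.values.loc[samples].isna().any(axis=1)]
    if len(samples) < 8:
        raise InvalidArgumentError(f"only {len(samples)} usable samples")
    clr = clr_asvs.loc[samples]
    metab = metabolome.values.loc[samples]
    cov = pd.DataFrame({"pH": ph.loc[samples].astype(float)})
    groups = timepoint.loc[samples].astype(int)

    edges: list[AssociationEdge] = []
    for direction in directions:
        records = []
        for asv in clr.columns:
            for metabolite in metab.columns:
                if direction == "metabolite~asv":
                    y = metab[metabolite]
                    x = clr[[asv]]
                elif direction == "asv~metabolite":
                    y = clr[asv]
                    x = metab[[metabolite]]
                else:
                    raise InvalidArgumentError(f"unknown direction {direction!r}")
                try:
                    slope, p = _mixed_lrt(y, x, cov, groups)
                except Exception as exc:  # singular fits and the like
                    logger.warning("model failed for (%s, %s): %s",
                                   asv, metabolite, exc)
                    continue
                if not np.isfinite(p):
                    logger.warning("non-finite p for (%s, %s); dropped",
                                   asv, metabolite)
                    continue
                records.append((asv, metabolite, slope, p))
        if not records:
            continue
        adjusted = bh_adjust([r[3] for r in records])
        for (asv, metabolite, slope, p), p_adj in zip(records, adjusted):
            keep = p_adj < alpha or (dashed_alpha is not None and p < dashed_alpha)
            if keep:
                edges.append(AssociationEdge(
                    asv_id=asv, metabolite_id=metabolite, direction=direction,
                    coefficient=slope, p=p, p_adjusted=float(p_adj),
                ))
    return edges


def edges_to_frame(edges: list[AssociationEdge]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(asv_id=e.asv_id, metabolite_id=e.metabolite_id,
                 direction=e.direction, coefficient=e.coefficient,
                 sign=e.sign, p=e.p, p_adjusted=e.p_adjusted)
            for e in edges
        ]
    )


# ---------------------------------------------------------------------------
# penalized cross-layer prediction

def relative_rmse(rmse: float, span: float) -> float:
    """Prediction RMSE expressed relative to the observed target span
    (max - min)."""
    if span <= 0:
        raise InvalidArgumentError("span must be positive")
    return rmse / span


def _lasso_predict_targets(
    X: pd.DataFrame, Y: pd.DataFrame, cv: int, seed: int, n_alphas: int = 30
) -> pd.DataFrame:
    rows = {}
    rng = np.random.default_rng(seed)
    Xv = X.to_numpy(dtype=float)
    for target in Y.columns:
        y = Y[target].to_numpy(dtype=float)
        mask = np.isfinite(y)
        if mask.sum() < max(cv, 3):
            logger.warning("target %s skipped: too few observations", target)
            continue
        yv, Xm = y[mask], Xv[mask]
        span = float(np.ptp(yv))
        if span == 0:
            logger.warning("target %s skipped: zero span", target)
            continue
        k = min(cv, mask.sum())
        folds = KFold(n_splits=k, shuffle=True,
                      random_state=int(rng.integers(2**31 - 1)))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            sel = LassoCV(cv=folds, alphas=n_alphas, max_iter=5000)
            sel.fit(Xm, yv)
            pred = cross_val_predict(Lasso(alpha=sel.alpha_, max_iter=5000),
                                     Xm, yv, cv=folds)
        rmse = float(np.sqrt(np.mean((yv - pred) ** 2)))
        rows[target] = dict(rmse=rmse, span=span,
                            relative_rmse=relative_rmse(rmse, span))
    result = pd.DataFrame(rows).T
    return result


def _aggregate(per_target: pd.DataFrame) -> dict[str, float]:
    # mean relative RMSE is the mean of per-target ratios; the ratio of the
    # mean RMSE to the mean span is reported alongside, not assumed equal
    return dict(
        mean_relative_rmse=float(per_target["relative_rmse"].mean()),
        mean_rmse=float(per_target["rmse"].mean()),
        mean_span=float(per_target["span"].mean()),
        n_targets=int(len(per_target)),
    )


def predict_metabolites_from_asvs(
    clr_asvs: pd.DataFrame,
    metabolome: NormalizedMetabolome,
    cv: int = 5,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Lasso prediction of every metabolite from the CLR ASV matrix; returns
    (per-target table with rmse/span/relative_rmse, aggregate summary)."""
    samples = clr_asvs.index.intersection(metabolome.values.index)
    per_target = _lasso_predict_targets(
        clr_asvs.loc[samples], metabolome.values.loc[samples], cv=cv, seed=seed
    )
    return per_target, _aggregate(per_target)


def predict_asvs_from_metabolites(
    clr_asvs: pd.DataFrame,
    metabolome: NormalizedMetabolome,
    cv: int = 5,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Reverse direction: predict every CLR ASV from the metabolite matrix."""
    samples = clr_asvs.index.intersection(metabolome.values.index)
    complete = metabolome.values.loc[samples].dropna(axis=0, how="any")
    per_target = _lasso_predict_targets(
        complete, clr_asvs.loc[complete.index], cv=cv, seed=seed
    )
    return per_target, _aggregate(per_target)


# ---------------------------------------------------------------------------
# presence covariate models

def presence_covariate_models(
    metadata: pd.DataFrame,
    metabolome: NormalizedMetabolome | None = None,
    weather_covariates: tuple[str, ...] = ("t_max", "precipitation"),
) -> dict:
    """Worm-presence models on apple samples.

    (a) ``log(pH) ~ presence + (1|timepoint)``;
    (b) per-timepoint count of presence-yes apples ~ weather covariate, with
        a random intercept per batch when several batches exist (plain OLS
        otherwise);
    (c) ``metabolite ~ presence + pH + (1|timepoint)`` per metabolite with
        BH adjustment over metabolites.
    """
    apples = metadata[metadata["environment"] == "apple"].copy()
    presence = apples["worm_presence"].map({"yes": 1.0, "no": 0.0})
    usable = presence.notna() & apples["pH"].notna()
    apples = apples[usable]
    presence = presence[usable]
    if presence.nunique() < 2:
        raise InvalidArgumentError("need both presence levels among apples")

    report: dict = {}
    log_ph = np.log(apples["pH"].astype(float))
    if log_ph.std() == 0:
        report["ph_model"] = dict(estimable=False, reason="constant pH")
    else:
        slope, p = _mixed_lrt(
            log_ph, presence.to_frame("presence"),
            pd.DataFrame(index=apples.index), apples["timepoint"].astype(int),
        )
        report["ph_model"] = dict(estimable=True, coefficient=slope, p=p)

    weather = {}
    per_tp = apples.assign(presence=presence).groupby(["batch", "timepoint"]).agg(
        n_positive=("presence", "sum"),
        **{c: (c, "first") for c in weather_covariates if c in apples.columns},
    ).reset_index()
    for covariate in weather_covariates:
        if covariate not in per_tp.columns or per_tp[covariate].isna().all():
            continue
        sub = per_tp.dropna(subset=[covariate])
        if sub["batch"].nunique() > 1:
            slope, p = _mixed_lrt(
                sub["n_positive"].astype(float),
                sub[[covariate]].astype(float),
                pd.DataFrame(index=sub.index),
                sub["batch"],
            )
        else:  # single batch: random intercept unidentifiable, use OLS
            ols = sm.OLS(sub["n_positive"].astype(float),
                         sm.add_constant(sub[[covariate]].astype(float))).fit()
            slope = float(ols.params[covariate])
            p = float(ols.pvalues[covariate])
        weather[covariate] = dict(coefficient=slope, p=p)
    report["weather_models"] = weather

    if metabolome is not None:
        shared = apples.index.intersection(metabolome.values.index)
        rows = []
        for metabolite in metabolome.values.columns:
            y = metabolome.values.loc[shared, metabolite].dropna()
            idx = y.index
            if presence.loc[idx].nunique() < 2 or len(idx) < 8:
                continue
            try:
                slope, p = _mixed_lrt(
                    y, presence.loc[idx].to_frame("presence"),
                    apples.loc[idx, ["pH"]].astype(float),
                    apples.loc[idx, "timepoint"].astype(int),
                )
            except Exception as exc:
                logger.warning("presence model failed for %s: %s", metabolite, exc)
                continue
            rows.append(dict(metabolite=metabolite, coefficient=slope, p=p))
        frame = pd.DataFrame(rows)
        if len(frame):
            frame["p_adjusted"] = bh_adjust(frame["p"])
        report["metabolite_models"] = frame
    return report
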