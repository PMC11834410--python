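"""Alpha diversity, compositional transforms, phylogenetic metrics and
taxon-level summaries (filters, core taxa, indicator scores).

Conventions (echoed into output metadata by the pipeline):

* Chao1 is the bias-corrected estimator
  ``S_obs + F1*(F1-1) / (2*(F2+1))`` and is therefore defined even when the
  sample has no doubletons.
* Shannon uses the natural log; Simpson is the Gini–Simpson index
  ``1 - sum(p_i^2)``.
* The CLR transform adds a pseudocount (default 1) to every count before
  taking logs; the Aitchison distance is the Euclidean distance between CLR
  rows.
* Faith PD and unweighted UniFrac are root-inclusive (the path from each
  observed leaf to the root counts).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import skbio
from scipy.spatial.distance import pdist, squareform

from ._tree import BranchIndex
from .errors import InvalidArgumentError

logger = logging.getLogger(__name__)


@dataclass
class DistanceMatrix:
    """Symmetric sample-by-sample distance matrix with a metric tag."""

    ids: list[str]
    values: np.ndarray
    metric: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise InvalidArgumentError("distance matrix shape does not match ids")
        if not np.allclose(self.values, self.values.T, atol=1e-9):
            raise InvalidArgumentError("distance matrix is not symmetric")
        if np.any(self.values < -1e-12):
            raise InvalidArgumentError("distance matrix has negative entries")

    def between(self, a: str, b: str) -> float:
        i, j = self.ids.index(a), self.ids.index(b)
        return float(self.values[i, j])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def subset(self, ids: list[str]) -> "DistanceMatrix":
        idx = [self.ids.index(s) for s in ids]
        return DistanceMatrix(list(ids), self.values[np.ix_(idx, idx)], self.metric)


# ---------------------------------------------------------------------------
# taxon filters

def filter_asvs(
    table: pd.DataFrame,
    min_prevalence: int = 5,
    min_total: int = 10,
    min_single: int = 5,
) -> pd.DataFrame:
    """Keep taxa present in >= ``min_prevalence`` samples, with total
    abundance >= ``min_total`` and a count >= ``min_single`` in at least one
    sample.  All three thresholds are inclusive; samples are untouched."""
    values = table.to_numpy()
    keep = (
        ((values > 0).sum(axis=0) >= min_prevalence)
        & (values.sum(axis=0) >= min_total)
        & (values.max(axis=0, initial=0) >= min_single)
    )
    if not keep.any():
        logger.warning("filter_asvs removed every taxon")
    return table.loc[:, table.columns[keep]]


def filter_min_occurrence(
    table: pd.DataFrame, min_count: int = 3, min_frac: float = 0.10
) -> pd.DataFrame:
    """Keep taxa with count >= ``min_count`` in at least
    ``ceil(min_frac * n_samples)`` samples (the source-tracking input filter)."""
    if table.shape[1] == 0 or table.shape[0] == 0:
        return table
    need = math.ceil(min_frac * table.shape[0])
    keep = (table.to_numpy() >= min_count).sum(axis=0) >= need
    if not keep.any():
        logger.warning("filter_min_occurrence removed every taxon")
    return table.loc[:, table.columns[keep]]


# ---------------------------------------------------------------------------
# alpha diversity

def _as_counts(counts) -> np.ndarray:
    arr = np.asarray(counts, dtype=float)
    if np.any(arr < 0):
        raise InvalidArgumentError("counts must be non-negative")
    return arr


def chao1(counts) -> float:
    """Bias-corrected Chao1 richness estimate; NaN for an all-zero sample."""
    arr = _as_counts(counts)
    if arr.sum() == 0:
        logger.warning("chao1 undefined for an all-zero sample")
        return float("nan")
    s_obs = float((arr > 0).sum())
    f1 = float((arr == 1).sum())
    f2 = float((arr == 2).sum())
    return s_obs + f1 * (f1 - 1.0) / (2.0 * (f2 + 1.0))


def shannon(counts) -> float:
    """Shannon entropy (natural log) of the sample's relative abundances."""
    arr = _as_counts(counts)
    total = arr.sum()
    if total == 0:
        return float("nan")
    p = arr[arr > 0] / total
    return float(-(p * np.log(p)).sum())


def simpson(counts) -> float:
    """Gini–Simpson index ``1 - sum(p_i^2)``; 0 for a single-taxon sample."""
    arr = _as_counts(counts)
    total = arr.sum()
    if total == 0:
        return float("nan")
    p = arr / total
    return float(1.0 - (p**2).sum())


def faith_pd(observed_taxa, tree: skbio.TreeNode) -> float:
    """Root-inclusive Faith PD of a set of observed taxa.

    The value is the summed branch length of the minimal subtree connecting
    the observed leaves *and* the root.
    """
    taxa = list(observed_taxa)
    index = BranchIndex(tree, taxa)
    presence = np.ones((1, len(taxa)), dtype=bool)
    return float(index.faith_pd(presence)[0])


def diversity_profile(table: pd.DataFrame, tree: skbio.TreeNode | None = None) -> pd.DataFrame:
    """Per-sample alpha-diversity profile.

    Returns a DataFrame indexed by sample id with columns
    ``observed_richness``, ``chao1``, ``shannon``, ``simpson`` and, when a
    tree is supplied, ``faith_pd``.
    """
    values = table.to_numpy(dtype=float)
    profile = pd.DataFrame(index=table.index)
    profile["observed_richness"] = (values > 0).sum(axis=1)
    profile["chao1"] = [chao1(row) for row in values]
    profile["shannon"] = [shannon(row) for row in values]
    profile["simpson"] = [simpson(row) for row in values]
    if tree is not None:
        index = BranchIndex(tree, list(table.columns))
        profile["faith_pd"] = index.faith_pd(values > 0)
    return profile


# ---------------------------------------------------------------------------
# compositional transforms and distances

def clr_transform(table: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """Centered log-ratio transform per sample; output rows have mean 0."""
    values = table.to_numpy(dtype=float)
    if pseudocount < 0:
        raise InvalidArgumentError("pseudocount must be non-negative")
    if pseudocount == 0 and np.any(values == 0):
        raise InvalidArgumentError(
            "pseudocount 0 requires strictly positive counts"
        )
    logs = np.log(values + pseudocount)
    clr = logs - logs.mean(axis=1, keepdims=True)
    return pd.DataFrame(clr, index=table.index, columns=table.columns)


def aitchison_distance_matrix(
    table: pd.DataFrame, pseudocount: float = 1.0
) -> DistanceMatrix:
    """Euclidean distance between CLR-transformed samples."""
    if table.shape[0] < 2:
        raise InvalidArgumentError("need at least 2 samples for a distance matrix")
    clr = clr_transform(table, pseudocount=pseudocount).to_numpy()
    dist = squareform(pdist(clr, metric="euclidean"))
    return DistanceMatrix(list(table.index), dist, "aitchison")


def unweighted_unifrac_matrix(table: pd.DataFrame, tree: skbio.TreeNode) -> DistanceMatrix:
    """Unweighted UniFrac: unique branch length over union branch length."""
    if table.shape[0] < 2:
        raise InvalidArgumentError("need at least 2 samples for a distance matrix")
    index = BranchIndex(tree, list(table.columns))
    dist = index.unweighted_unifrac(table.to_numpy() > 0)
    return DistanceMatrix(list(table.index), dist, "unifrac_unweighted")


# ---------------------------------------------------------------------------
# core and indicator taxa

def core_asvs(table: pd.DataFrame, group_samples, threshold: float = 0.80) -> list[str]:
    """Taxa present (count > 0) in at least ``threshold`` of the group's
    samples (inclusive boundary)."""
    group = list(group_samples)
    if not group:
        raise InvalidArgumentError("core_asvs requires a non-empty group")
    sub = table.loc[group]
    frac = (sub.to_numpy() > 0).mean(axis=0)
    return [t for t, f in zip(table.columns, frac) if f >= threshold]


@dataclass
class IndicatorScore:
    taxon_id: str
    group: str
    A: float  # specificity: share of the taxon's mean abundance in this group
    B: float  # fidelity: fraction of the group's samples containing the taxon
    stat: float  # sqrt(A * B)
    permutation_p: float


def _indval_stats(values: np.ndarray, labels: np.ndarray, groups: np.ndarray):
    """Per-taxon A, B and IndVal statistic for every group.

    Returns arrays of shape (n_groups, n_taxa).
    """
    means = np.stack([values[labels == g].mean(axis=0) for g in groups])
    denom = means.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        A = np.where(denom > 0, means / denom, 0.0)
    B = np.stack([(values[labels == g] > 0).mean(axis=0) for g in groups])
    return A, B, np.sqrt(A * B)


def indicator_scores(
    table: pd.DataFrame,
    group_labels,
    n_perm: int | str = 999,
    seed: int = 0,
) -> list[IndicatorScore]:
    """IndVal-style indicator analysis.

    For every taxon the best group (largest ``sqrt(A*B)``) is reported with a
    label-permutation p-value using the add-one rule
    ``p = (1 + #{perm stat >= observed}) / (1 + n_perm)``.  With
    ``n_perm="exhaustive"`` every distinct relabelling is enumerated instead
    of sampled (feasible for small designs only).
    """
    labels = np.asarray(list(group_labels))
    if len(labels) != table.shape[0]:
        raise InvalidArgumentError("one group label per sample required")
    groups = np.unique(labels)
    if len(groups) < 2:
        raise InvalidArgumentError("indicator analysis needs at least 2 groups")

    values = table.to_numpy(dtype=float)
    A, B, stat = _indval_stats(values, labels, groups)
    best = stat.argmax(axis=0)
    obs = stat.max(axis=0)

    if n_perm == "exhaustive":
        from itertools import permutations

        perms = sorted({tuple(p) for p in permutations(labels)})
        n_used = len(perms)
    else:
        rng = np.random.default_rng(seed)
        perms = (rng.permutation(labels) for _ in range(n_perm))
        n_used = n_perm
    exceed = np.zeros(table.shape[1])
    for perm in perms:
        _, _, pstat = _indval_stats(values, np.asarray(perm), groups)
        exceed += pstat.max(axis=0) >= obs - 1e-12
    pvals = (1.0 + exceed) / (1.0 + n_used)

    return [
        IndicatorScore(
            taxon_id=str(t),
            group=str(groups[best[j]]),
            A=float(A[best[j], j]),
            B=float(B[best[j], j]),
            stat=float(obs[j]),
            permutation_p=float(pvals[j]),
        )
        for j, t in enumerate(table.columns)
    ]
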