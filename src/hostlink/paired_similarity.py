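"""Repeated random-pairing test: are worms from the same apple more similar
than worms from different apples?

Each iteration builds disjoint triples (focal worm, same-apple partner,
different-apple worm) so that a paired Wilcoxon signed-rank on
(within-apple distance, between-apple distance) is well-defined, with every
worm used at most once per iteration.  The iteration is repeated (default
100 times) and the median p-value reported.  An unpaired Mann–Whitney mode
is provided behind a flag for the alternative one-distance-per-worm reading
of the design.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .community_metrics import DistanceMatrix
from .errors import InfeasibleError

logger = logging.getLogger(__name__)


@dataclass
class PairingTriple:
    focal: str
    same_apple: str
    different_apple: str
    d_same: float
    d_diff: float


@dataclass
class RepeatedPairingResult:
    p_values: np.ndarray
    median_p: float
    n_iter: int
    metric: str
    mode: str
    seed: int
    n_triples: list[int] = field(default_factory=list)


def _worms_by_apple(metadata: pd.DataFrame) -> dict[str, list[str]]:
    worms = metadata[metadata["environment"] == "worm"]
    groups: dict[str, list[str]] = {}
    for sample, apple_id in worms["apple_id"].items():
        groups.setdefault(str(apple_id), []).append(sample)
    return groups


def build_random_pairing(
    metadata: pd.DataFrame, rng: np.random.Generator
) -> list[tuple[str, str, str]]:
    """One iteration's disjoint (focal, same-apple, different-apple) triples.

    Worms are visited in random order; a worm becomes focal if an unused
    same-apple partner and an unused worm from another apple exist, and all
    three are then marked used.
    """
    by_apple = _worms_by_apple(metadata)
    apple_of = {w: a for a, ws in by_apple.items() for w in ws}
    worms = sorted(apple_of)
    if not any(len(ws) >= 2 for ws in by_apple.values()) or len(by_apple) < 2:
        raise InfeasibleError(
            "pairing requires an apple with >= 2 worms and a worm on another apple"
        )
    order = list(rng.permutation(worms))
    used: set[str] = set()
    triples = []
    for focal in order:
        if focal in used:
            continue
        same_pool = [w for w in by_apple[apple_of[focal]]
                     if w != focal and w not in used]
        diff_pool = [w for w in worms
                     if apple_of[w] != apple_of[focal] and w not in used]
        if not same_pool or not diff_pool:
            continue
        same = same_pool[int(rng.integers(len(same_pool)))]
        diff = diff_pool[int(rng.integers(len(diff_pool)))]
        used.update((focal, same, diff))
        triples.append((focal, same, diff))
    return triples


def repeated_pairing_test(
    distance: DistanceMatrix,
    metadata: pd.DataFrame,
    n_iter: int = 100,
    seed: int = 0,
    min_triples: int = 3,
    mode: str = "paired",
) -> RepeatedPairingResult:
    """Repeat the random pairing ``n_iter`` times; per iteration run a
    two-sided paired Wilcoxon signed-rank on (d_same, d_diff); report all
    per-iteration p-values and their median.

    ``mode="unpaired"`` instead assigns each focal worm a single distance
    (same- or between-apple) and runs a Mann–Whitney U test.
    """
    rng = np.random.default_rng(seed)
    ids = {s: i for i, s in enumerate(distance.ids)}
    p_values, n_triples = [], []
    for _ in range(n_iter):
        triples = build_random_pairing(metadata, rng)
        assert len({w for t in triples for w in t}) == 3 * len(triples), \
            "a worm appears twice within one iteration"
        if len(triples) < min_triples:
            logger.warning("iteration skipped: only %d triples", len(triples))
            continue
        d_same = np.array([distance.values[ids[f], ids[s]] for f, s, _ in triples])
        d_diff = np.array([distance.values[ids[f], ids[d]] for f, _, d in triples])
        if mode == "paired":
            if np.allclose(d_same, d_diff):
                p = 1.0  # all ties: no evidence
            else:
                p = float(
                    stats.wilcoxon(
                        d_same, d_diff, zero_method="wilcox",
                        alternative="two-sided", correction=True,
                        method="exact" if len(triples) <= 25 else "approx",
                    ).pvalue
                )
        elif mode == "unpaired":
            p = float(stats.mannwhitneyu(d_same, d_diff,
                                         alternative="two-sided").pvalue)
        else:
            raise ValueError("mode must be 'paired' or 'unpaired'")
        p_values.append(p)
        n_triples.append(len(triples))
    if not p_values:
        raise InfeasibleError("every pairing iteration was skipped")
    p_values = np.asarray(p_values)
    return RepeatedPairingResult(
        p_values=p_values,
        median_p=float(np.median(p_values)),
        n_iter=n_iter,
        metric=distance.metric,
        mode=mode,
        seed=seed,
        n_triples=n_triples,
    )
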