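"""Calibration and recovery experiments exercising the whole toolkit on
synthetic data with known ground truth.

Each function generates data with :mod:`hostlink.synthetic_data`, runs one of
the package's analyses, and returns a summary statistic (rejection rate,
recovery error, direction-agreement count ...).  They are used by the test
suite and the reproduction script alike.

Problem sizes are deliberately desk-scale (tens of taxa, a few thousand
reads) so that whole calibration curves — hundreds of simulated datasets —
run in minutes; docs/methods.md discusses what these scales do and do not
demonstrate.

Where an experiment needs chao1-comparable worm and apple units (the
richness-matched null), worm and apple sequencing depths are matched; the
default generator's depth asymmetry would otherwise leave the matching pool
empty.
"""

from __future__ import annotations


import numpy as np
import pandas as pd

from . import community_metrics as cm
from . import metabolome_link as ml
from . import null_models as nm
from . import paired_similarity as ps
from . import source_sink as ss
from . import synthetic_data as sd

# Conditions for the richness-matched-null calibration: equal depths so worm
# and apple Chao1 ranges overlap, no shedding, near-certain worm presence.
NULL_CALIBRATION_CONFIG = dict(
    n_taxa=40,
    n_timepoints=2,
    apples_per_timepoint=5,
    worms_per_apple_range=(1, 2),
    sequencing_depth_substrate=3000,
    sequencing_depth_host=3000,
    shedding_lambda=0.0,
    drift_sd=0.2,
    apple_sd=1.0,
    presence_intercept=3.0,
    presence_ph_coeff=0.0,
    n_metabolites=2,
)

# Conditions for the pairing test: several worms per apple, apples
# compositionally distinct (power) or identical (type-I null, apple_sd=0).
PAIRING_CONFIG = dict(
    n_taxa=40,
    n_timepoints=2,
    apples_per_timepoint=5,
    worms_per_apple_range=(2, 4),
    sequencing_depth_substrate=3000,
    sequencing_depth_host=1000,
    shedding_lambda=0.0,
    clade_filter_strength=1.0,
    host_richness_fraction=0.8,
    drift_sd=0.2,
    presence_intercept=3.0,
    presence_ph_coeff=0.0,
    n_metabolites=2,
)

# Conditions for the directionality experiments: proportional clade filtering
# only (full support, equal depths), so the apple-as-source EM run is not
# degraded by support mismatch and the zero-shedding baseline is
# direction-neutral; the shedding knob is then the dominant asymmetry.
DIRECTIONALITY_CONFIG = dict(
    n_taxa=80,
    n_timepoints=4,
    apples_per_timepoint=5,
    worms_per_apple_range=(2, 3),
    sequencing_depth_substrate=2500,
    sequencing_depth_host=2500,
    clade_filter_strength=1.0,
    host_richness_fraction=1.0,
    drift_sd=0.3,
    presence_intercept=2.0,
    presence_ph_coeff=0.0,
    n_metabolites=2,
)


def _sub_seed(seed: int, *idx: int) -> int:
    return int(np.random.default_rng([seed, *idx]).integers(2**31 - 1))


def null_model_p_values(
    n_datasets: int,
    clade_filter_strength: float,
    host_richness_fraction: float,
    seed: int,
    n_draws: int = 400,
) -> np.ndarray:
    """Two-sided richness-matched-null p-values for the worm PD deficit over
    independently simulated datasets."""
    out = []
    for i in range(n_datasets):
        cfg = sd.SyntheticConfig(
            **NULL_CALIBRATION_CONFIG,
            clade_filter_strength=clade_filter_strength,
            host_richness_fraction=host_richness_fraction,
            seed=_sub_seed(seed, 1, i),
        )
        ds = sd.generate_dataset(cfg)
        profiles = cm.diversity_profile(ds.counts, ds.tree)
        units = nm.collapse_worms_to_units(profiles, ds.metadata)
        res = nm.richness_matched_null(
            units, "worm", n_draws=n_draws, seed=_sub_seed(seed, 2, i)
        )
        out.append(res.p_two_sided)
    return np.asarray(out)


def pairing_median_p_values(
    n_datasets: int, null: bool, seed: int, n_iter: int = 100
) -> np.ndarray:
    """Median repeated-pairing p per dataset; ``null=True`` draws all apples
    from a common pool (no apple-specific composition)."""
    out = []
    params = dict(PAIRING_CONFIG)
    if null:
        params["apple_sd"] = 0.0  # worms effectively share one source pool
    for i in range(n_datasets):
        ds = sd.generate_dataset(
            sd.SyntheticConfig(**params, seed=_sub_seed(seed, 3, i))
        )
        worm_ids = [s for s in ds.counts.index
                    if ds.metadata.at[s, "environment"] == "worm"]
        dist = cm.aitchison_distance_matrix(ds.counts.loc[worm_ids])
        res = ps.repeated_pairing_test(
            dist, ds.metadata.loc[worm_ids], n_iter=n_iter,
            seed=_sub_seed(seed, 4, i),
        )
        out.append(res.median_p)
    return np.asarray(out)


def em_mixture_recovery(
    n_replicates: int = 20,
    depth: int = 100_000,
    n_sources: int = 3,
    n_taxa: int = 60,
    seed: int = 0,
) -> float:
    """Mean L1 error of recovered mixing proportions for sinks drawn from
    known mixtures of mostly-disjoint sources."""
    rng = np.random.default_rng(seed)
    errors = []
    for _ in range(n_replicates):
        # sources concentrated on disjoint thirds with small shared leakage
        gamma = np.full((n_sources, n_taxa), 0.01 / n_taxa)
        block = n_taxa // n_sources
        for k in range(n_sources):
            sl = slice(k * block, (k + 1) * block)
            gamma[k, sl] += rng.dirichlet(np.ones(block)) * 0.99
        gamma /= gamma.sum(axis=1, keepdims=True)
        alpha = rng.dirichlet(np.ones(n_sources))
        sink = rng.multinomial(depth, alpha @ gamma)
        profiles = pd.DataFrame(gamma, index=[f"S{k}" for k in range(n_sources)])
        res = ss.em_source_track(sink, profiles)
        est = np.array([res.contributions[f"S{k}"] for k in range(n_sources)])
        errors.append(np.abs(est - alpha).sum())
    return float(np.mean(errors))


def directionality_agreement(
    shedding_lambda: float,
    n_seeds: int,
    seed: int,
    n_pairings: int = 8,
    max_target_taxa: int = 25,
    alpha: float = 0.05,
) -> dict[str, int]:
    """Count seeds in which each method significantly favors worm->apple."""
    em_hits = lasso_hits = 0
    for i in range(n_seeds):
        ds = sd.generate_dataset(
            sd.SyntheticConfig(
                **DIRECTIONALITY_CONFIG,
                shedding_lambda=shedding_lambda,
                seed=_sub_seed(seed, 5, i),
            )
        )
        occ = cm.filter_min_occurrence(ds.counts)
        _, em_test = ss.directionality_em(occ, ds.metadata)
        if em_test.favored == "worm->apple" and em_test.p < alpha:
            em_hits += 1
        maps = ss.random_pair_assignment(
            ds.metadata, n_pairings=n_pairings, seed=_sub_seed(seed, 6, i)
        )
        if occ.shape[1] > max_target_taxa:
            occ_l = occ[list(occ.sum().nlargest(max_target_taxa).index)]
        else:
            occ_l = occ
        results = {
            d: ss.lasso_cross_predict(occ_l, maps, d, cv=4, n_alphas=20,
                                      seed=_sub_seed(seed, 7, i))
            for d in ("worm->apple", "apple->worm")
        }
        tests = ss.directionality_regression(
            results["worm->apple"], results["apple->worm"]
        )
        t = tests["mean_rmse"]
        if t.favored == "worm->apple" and t.p < alpha:
            lasso_hits += 1
    return {"em": em_hits, "lasso": lasso_hits, "n_seeds": n_seeds}


def _network_dataset(n_samples, n_asvs, n_metabolites, seed, planted=None):
    """Independent CLR-like ASV matrix and metabolite matrix with a genuine
    per-timepoint random intercept; ``planted=(asv, metabolite, slope, noise_sd)``
    adds one real association."""
    rng = np.random.default_rng(seed)
    timepoint = pd.Series(
        np.repeat(np.arange(1, n_samples // 6 + 2), 6)[:n_samples],
        index=[f"S{i}" for i in range(n_samples)],
    )
    tp_effect = {t: rng.normal(0, 0.5) for t in timepoint.unique()}
    clr = pd.DataFrame(
        rng.normal(0, 1, (n_samples, n_asvs)),
        index=timepoint.index,
        columns=[f"ASV{j + 1}" for j in range(n_asvs)],
    )
    metab = pd.DataFrame(
        rng.normal(0, 1, (n_samples, n_metabolites)),
        index=timepoint.index,
        columns=[f"M{j + 1}" for j in range(n_metabolites)],
    )
    shift = timepoint.map(tp_effect)
    metab = metab.add(shift, axis=0)
    ph = pd.Series(rng.uniform(3, 5, n_samples), index=timepoint.index)
    if planted is not None:
        asv, metabolite, slope, noise_sd = planted
        metab[metabolite] = (
            slope * clr[asv] + shift + rng.normal(0, noise_sd, n_samples)
        )
    return clr, metab, ph, timepoint


def network_planted_edge(seed: int, n_samples: int = 60) -> dict:
    """Plant one metabolite = 2 x CLR(ASV) + noise(0.01) association among
    independent pairs; return the planted edge's adjusted p and sign."""
    clr, metab, ph, timepoint = _network_dataset(
        n_samples, n_asvs=5, n_metabolites=8, seed=seed,
        planted=("ASV1", "M1", 2.0, 0.01),
    )
    edges = ml.asv_metabolite_network(
        clr, ml.NormalizedMetabolome(values=metab), ph, timepoint,
        directions=("metabolite~asv",), alpha=0.05,
    )
    hit = [e for e in edges if e.asv_id == "ASV1" and e.metabolite_id == "M1"]
    return {
        "recovered": bool(hit),
        "p_adjusted": hit[0].p_adjusted if hit else float("nan"),
        "sign": hit[0].sign if hit else 0,
        "n_edges": len(edges),
    }


def network_false_edge_rate(seed: int, n_samples: int = 60,
                            n_asvs: int = 10, n_metabolites: int = 20) -> float:
    """Fraction of fully independent (ASV, metabolite) pairs reported as
    edges at BH 0.05."""
    clr, metab, ph, timepoint = _network_dataset(
        n_samples, n_asvs=n_asvs, n_metabolites=n_metabolites, seed=seed
    )
    edges = ml.asv_metabolite_network(
        clr, ml.NormalizedMetabolome(values=metab), ph, timepoint,
        directions=("metabolite~asv",), alpha=0.05,
    )
    return len(edges) / (n_asvs * n_metabolites)


def metabolite_prediction_error(seed: int) -> dict[str, float]:
    """Lasso cross-layer prediction on generator data with coupled
    metabolites (noise SD 0.1); returns the aggregate summary."""
    cfg = sd.SyntheticConfig(
        n_taxa=40,
        n_timepoints=5,
        apples_per_timepoint=6,
        worms_per_apple_range=(1, 2),
        sequencing_depth_substrate=4000,
        sequencing_depth_host=1000,
        n_metabolites=12,
        metabolite_sparsity=0.08,
        metabolite_noise_sd=0.1,
        presence_intercept=0.0,
        seed=seed,
    )
    ds = sd.generate_dataset(cfg)
    apples = [s for s in ds.counts.index
              if ds.metadata.at[s, "environment"] == "apple"]
    clr = cm.clr_transform(ds.counts.loc[apples])
    norm = ml.normalize_metabolome(ds.metabolites)
    _, agg = ml.predict_metabolites_from_asvs(clr, norm, seed=seed)
    return agg


def relative_rmse_worked_example(
    mean_rmse: float = 0.99, mean_span: float = 4.5
) -> float:
    """Aggregate relative RMSE implied by a mean prediction RMSE and a mean
    target span (the published worked example: 0.99 / 4.5 ~ 0.22)."""
    return ml.relative_rmse(mean_rmse, mean_span)
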