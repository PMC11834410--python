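"""End-to-end orchestration: simulate or ingest, filter, diversity, nulls,
pairing test, source–sink inference, metabolome linkage.

A run is driven by a YAML/dict config with explicit per-stage seeds derived
from one master seed, so re-running a config reproduces every stochastic
result exactly.  Stage failures are isolated: dependents are skipped and the
cause recorded in the machine-readable report.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, io_formats
from . import community_metrics as cm
from . import metabolome_link as ml
from . import null_models as nm
from . import paired_similarity as ps
from . import source_sink as ss
from . import synthetic_data as sd
from .errors import InvalidArgumentError

logger = logging.getLogger(__name__)

_TOP_KEYS = {"seed", "output_dir", "simulation", "inputs", "stages"}
_STAGE_KEYS = {
    "filter": {"min_prevalence", "min_total", "min_single"},
    "diversity": {"metrics", "pseudocount"},
    "null_models": {"n_draws", "statistic", "pool"},
    "pairing": {"n_iter", "metric", "mode"},
    "source_sink": {"n_pairings", "run_em", "run_lasso", "max_target_taxa", "cv"},
    "metabolome": {"network", "max_asvs", "max_metabolites", "predict",
                   "presence_models", "alpha"},
}
_STAGE_SEED_OFFSET = {
    "simulate": 1, "null_models": 2, "pairing": 3, "source_sink": 4,
    "metabolome": 5,
}

# paper-gap conventions echoed into every report
_CONVENTIONS = {
    "chao1": "bias-corrected (defined at F2=0)",
    "simpson": "Gini-Simpson (1 - sum p^2)",
    "clr_pseudocount": 1,
    "unifrac_faith_pd": "root-inclusive",
    "permutation_p": "add-one rule",
    "null_p": "doubled one-sided add-one tails, capped at 1",
    "wilcoxon": "zeros dropped; exact for n<=25 else normal approximation",
}


def _stage_seed(master: int, stage: str) -> int:
    return int((int(master) * 1009 + _STAGE_SEED_OFFSET.get(stage, 0)) % (2**31 - 1))


def validate_config(config: dict) -> dict:
    unknown = set(config) - _TOP_KEYS
    if unknown:
        raise InvalidArgumentError(f"unknown config keys: {sorted(unknown)}")
    if "seed" not in config:
        raise InvalidArgumentError("config must set an explicit master seed")
    if ("simulation" in config) == ("inputs" in config):
        raise InvalidArgumentError(
            "config must give exactly one of 'simulation' or 'inputs'"
        )
    stages = config.get("stages", {})
    for stage, params in stages.items():
        if stage not in _STAGE_KEYS:
            raise InvalidArgumentError(f"unknown stage {stage!r}")
        bad = set(params or {}) - _STAGE_KEYS[stage]
        if bad:
            raise InvalidArgumentError(f"unknown keys in stage {stage!r}: {sorted(bad)}")
    if "simulation" in config:
        valid = {f.name for f in fields(sd.SyntheticConfig)}
        bad = set(config["simulation"]) - valid
        if bad:
            raise InvalidArgumentError(f"unknown simulation keys: {sorted(bad)}")
    metrics = stages.get("diversity", {}).get("metrics", ["aitchison"])
    if "unifrac" in metrics and "inputs" in config and not config["inputs"].get("tree"):
        raise InvalidArgumentError("UniFrac requested but no tree provided")
    return config


def load_config(path) -> dict:
    with open(path) as fh:
        return validate_config(yaml.safe_load(fh))


def _load_inputs(inputs: dict):
    counts = io_formats.read_count_table(inputs["counts"])
    metadata = io_formats.read_metadata(inputs["metadata"])
    tree = io_formats.read_newick(inputs["tree"]) if inputs.get("tree") else None
    metabolites = None
    if inputs.get("metabolites"):
        metabolites = io_formats.read_metabolite_table(
            inputs["metabolites"],
            inputs.get("internal_standard_id", sd.INTERNAL_STANDARD_ID),
        )
    return counts, metadata, tree, metabolites


def run_pipeline(config: dict | str | Path) -> dict:
    """Execute all configured stages in dependency order; return the report."""
    if not isinstance(config, dict):
        config = load_config(config)
    else:
        config = validate_config(config)
    master = int(config["seed"])
    out_dir = Path(config.get("output_dir", "hostlink_out"))
    out_dir.mkdir(parents=True, exist_ok=True)
    stages = config.get("stages", {})
    report: dict = {
        "version": __version__,
        "seed": master,
        "conventions": _CONVENTIONS,
        "stages": {},
    }
    t_start = time.time()

    def record(stage, status, t0, **payload):
        report["stages"][stage] = {
            "status": status,
            "seconds": round(time.time() - t0, 3),
            **payload,
        }

    # --- data -------------------------------------------------------------
    t0 = time.time()
    tree = metabolites = None
    try:
        if "simulation" in config:
            sim_cfg = sd.SyntheticConfig(
                **{"seed": _stage_seed(master, "simulate"), **config["simulation"]}
            )
            dataset = sd.generate_dataset(sim_cfg)
            dataset.write(out_dir / "data")
            counts, metadata = dataset.counts, dataset.metadata
            tree, metabolites = dataset.tree, dataset.metabolites
            record("data", "ok", t0, source="simulation",
                   params=asdict(sim_cfg), n_samples=int(counts.shape[0]),
                   n_taxa=int(counts.shape[1]))
        else:
            counts, metadata, tree, metabolites = _load_inputs(config["inputs"])
            record("data", "ok", t0, source="inputs",
                   n_samples=int(counts.shape[0]), n_taxa=int(counts.shape[1]))
    except Exception as exc:
        record("data", "failed", t0, error=str(exc))
        report["wall_clock_seconds"] = round(time.time() - t_start, 3)
        _write_report(report, out_dir)
        return report

    findings = io_formats.validate_dataset(counts, metadata, tree, metabolites)
    report["validation_findings"] = list(findings)

    # --- filter -----------------------------------------------------------
    t0 = time.time()
    fparams = stages.get("filter", {})
    filtered = cm.filter_asvs(counts, **fparams)
    record("filter", "ok", t0, params=fparams,
           n_taxa_before=int(counts.shape[1]), n_taxa_after=int(filtered.shape[1]))

    # --- diversity ---------------------------------------------------------
    t0 = time.time()
    dparams = stages.get("diversity", {})
    metrics = dparams.get("metrics", ["aitchison"])
    profiles = distance = None
    try:
        profiles = cm.diversity_profile(filtered, tree)
        profiles.to_csv(out_dir / "diversity_profile.tsv", sep="\t")
        pseudo = dparams.get("pseudocount", 1)
        distance = cm.aitchison_distance_matrix(filtered, pseudocount=pseudo)
        payload = {"metrics": metrics}
        if "unifrac" in metrics:
            if tree is None:
                raise InvalidArgumentError("UniFrac requested but no tree available")
            unifrac = cm.unweighted_unifrac_matrix(filtered, tree)
            unifrac.to_dataframe().to_csv(out_dir / "unifrac.tsv", sep="\t")
            payload["unifrac_written"] = True
        distance.to_dataframe().to_csv(out_dir / "aitchison.tsv", sep="\t")
        record("diversity", "ok", t0, **payload)
    except Exception as exc:
        record("diversity", "failed", t0, error=str(exc))

    # --- richness-matched nulls --------------------------------------------
    t0 = time.time()
    nparams = stages.get("null_models", {})
    if profiles is None or tree is None:
        record("null_models", "skipped", t0,
               reason="diversity stage unavailable or no tree")
    else:
        try:
            statistic = nparams.get("statistic", "faith_pd")
            units = nm.collapse_worms_to_units(profiles, metadata,
                                               statistic=statistic)
            results = {}
            for env in ("worm", "apple"):
                res = nm.richness_matched_null(
                    units, env, statistic=statistic,
                    n_draws=nparams.get("n_draws", 5000),
                    seed=_stage_seed(master, "null_models"),
                    pool=nparams.get("pool", "both"),
                )
                results[env] = res
            adj = nm.bh_adjust([results[e].p_two_sided for e in ("worm", "apple")])
            record("null_models", "ok", t0, statistic=statistic, results={
                env: dict(observed_mean=results[env].observed_mean,
                          null_mean=float(np.mean(results[env].null_draws)),
                          p=results[env].p_two_sided,
                          p_adjusted=float(a),
                          chao1_range=list(results[env].chao1_range),
                          n_units=results[env].n_focal_units)
                for env, a in zip(("worm", "apple"), adj)
            })
        except Exception as exc:
            record("null_models", "failed", t0, error=str(exc))

    # --- repeated pairing test ---------------------------------------------
    t0 = time.time()
    pparams = stages.get("pairing", {})
    if distance is None:
        record("pairing", "skipped", t0, reason="distance matrix unavailable")
    else:
        try:
            worm_ids = [s for s in filtered.index
                        if metadata.at[s, "environment"] == "worm"]
            dist = distance
            if pparams.get("metric", "aitchison") == "unifrac":
                dist = cm.unweighted_unifrac_matrix(filtered, tree)
            dist = dist.subset(worm_ids)
            result = ps.repeated_pairing_test(
                dist, metadata.loc[worm_ids],
                n_iter=pparams.get("n_iter", 100),
                seed=_stage_seed(master, "pairing"),
                mode=pparams.get("mode", "paired"),
            )
            pd.DataFrame({"p": result.p_values}).to_csv(
                out_dir / "pairing_p_values.tsv", sep="\t", index=False)
            record("pairing", "ok", t0, metric=result.metric,
                   median_p=result.median_p, n_iterations=len(result.p_values))
        except Exception as exc:
            record("pairing", "failed", t0, error=str(exc))

    # --- source-sink --------------------------------------------------------
    t0 = time.time()
    sparams = stages.get("source_sink", {})
    try:
        payload = {}
        occ = cm.filter_min_occurrence(filtered)
        if sparams.get("run_em", True):
            table, test = ss.directionality_em(occ, metadata)
            table.to_csv(out_dir / "em_contributions.tsv", sep="\t")
            payload["em"] = dict(W=test.statistic, p=test.p, favored=test.favored,
                                 n_apples=int(len(table)))
        if sparams.get("run_lasso", True):
            seed = _stage_seed(master, "source_sink")
            maps = ss.random_pair_assignment(
                metadata, n_pairings=sparams.get("n_pairings", 100), seed=seed)
            occ_l = occ
            max_t = sparams.get("max_target_taxa")
            if max_t and occ.shape[1] > max_t:
                top = occ.sum().nlargest(max_t).index
                occ_l = occ[list(top)]
            results = {}
            for direction in ("worm->apple", "apple->worm"):
                results[direction] = ss.lasso_cross_predict(
                    occ_l, maps, direction, cv=sparams.get("cv", 5), seed=seed)
            tests = ss.directionality_regression(results["worm->apple"],
                                                 results["apple->worm"])
            payload["lasso"] = {
                metric: dict(W=t.statistic, p=t.p, favored=t.favored)
                for metric, t in tests.items()
            }
        record("source_sink", "ok", t0, **payload)
    except Exception as exc:
        record("source_sink", "failed", t0, error=str(exc))

    # --- metabolome ---------------------------------------------------------
    t0 = time.time()
    mparams = stages.get("metabolome", {})
    if metabolites is None:
        record("metabolome", "skipped", t0, reason="no metabolite table")
    else:
        try:
            seed = _stage_seed(master, "metabolome")
            normalized = ml.normalize_metabolome(metabolites)
            apple_ids = [s for s in filtered.index
                         if metadata.at[s, "environment"] == "apple"
                         and s in normalized.values.index]
            occ = cm.filter_min_occurrence(filtered.loc[apple_ids])
            clr = cm.clr_transform(occ)
            payload = {}
            scores, loadings, explained = ml.pca_metabolome(normalized)
            payload["pca_explained_pc1"] = float(explained.iloc[0])
            if mparams.get("network", True):
                max_a = mparams.get("max_asvs", 15)
                max_m = mparams.get("max_metabolites", 15)
                sub_clr = clr[list(occ.sum().nlargest(max_a).index)]
                sub_met = ml.NormalizedMetabolome(
                    values=normalized.values[
                        list(normalized.values.columns[:max_m])],
                    excluded=normalized.excluded)
                edges = ml.asv_metabolite_network(
                    sub_clr, sub_met,
                    ph=metadata["pH"], timepoint=metadata["timepoint"],
                    alpha=mparams.get("alpha", 0.05))
                ml.edges_to_frame(edges).to_csv(out_dir / "network_edges.tsv",
                                                sep="\t", index=False)
                payload["network_edges"] = len(edges)
            if mparams.get("predict", True):
                _, agg = ml.predict_metabolites_from_asvs(clr, normalized,
                                                          seed=seed)
                payload["metabolite_prediction"] = agg
            if mparams.get("presence_models", True):
                try:
                    rep = ml.presence_covariate_models(metadata, normalized)
                except InvalidArgumentError as exc:
                    payload["presence_models"] = f"not estimable: {exc}"
                else:
                    payload["ph_model"] = rep.get("ph_model")
                    metab_models = rep.get("metabolite_models")
                    if metab_models is not None and len(metab_models):
                        payload["n_presence_metabolites_bh05"] = int(
                            (metab_models["p_adjusted"] < 0.05).sum())
            record("metabolome", "ok", t0, **payload)
        except Exception as exc:
            record("metabolome", "failed", t0, error=str(exc))

    report["wall_clock_seconds"] = round(time.time() - t_start, 3)
    _write_report(report, out_dir)
    return report


def _write_report(report: dict, out_dir: Path) -> None:
    path = Path(out_dir) / "report.json"
    path.write_text(json.dumps(report, indent=2, default=_json_default))


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


DEMO_CONFIG: dict = {
    "seed": 7,
    "output_dir": "hostlink_demo",
    "simulation": {
        "n_taxa": 200,
        "n_timepoints": 8,
        "apples_per_timepoint": 5,
        "worms_per_apple_range": (0, 6),
    },
    "stages": {
        "filter": {},
        "diversity": {"metrics": ["aitchison", "unifrac"]},
        "null_models": {"n_draws": 5000},
        "pairing": {"n_iter": 100},
        "source_sink": {"n_pairings": 25, "max_target_taxa": 40},
        "metabolome": {"max_asvs": 10, "max_metabolites": 10},
    },
}
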