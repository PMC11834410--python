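"""Generator for paired substrate (apple) and host (worm) microbiome data.

The generator emulates the sampling design of a field survey in which rotting
apples on a compost heap are sampled weekly, each apple's bacterial community
is sequenced, and the nematodes found on it are sequenced individually.  It
produces, from a single seeded configuration:

* a random phylogeny over the taxon pool,
* substrate communities that drift over time (shared Gaussian random walk on
  log abundances) and differ between apples (apple-specific offsets),
* host (worm) communities sampled from their apple with two host-side
  mechanisms — a log-scale selection bonus for "host-competent" clades and a
  dispersal-limitation support restriction to a random fraction of the
  apple's taxa,
* an optional host-to-substrate shedding feedback that convexly mixes the
  mean worm community back into the apple's composition (the ground-truth
  mechanism behind worm-to-apple directionality).  Worms colonize the
  substrate before it is measured, so the reported apple sample reflects the
  shedding of the worms collected with it, and the mixed state carries over
  into the next time point's drift,
* per-apple pH (uniform 3–5, drifting upward with time), weather covariates,
  and worm presence drawn from a logistic model on pH,
* a metabolite layer linearly coupled (on the log scale) to the CLR-transformed
  substrate abundances, with a constant internal-standard column.

Every stochastic choice is driven by named sub-streams of the configured
seed, so identical configurations yield byte-identical outputs, and the
substrate stream is consumed identically whether or not worms are simulated
(the zero-shedding run is exactly the no-worm run).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import skbio
from scipy.special import expit, softmax

from . import io_formats
from .community_metrics import clr_transform
from .errors import DegenerateInputError, InvalidArgumentError

PH_CENTER = 4.0  # logistic model operates on pH - PH_CENTER
INTERNAL_STANDARD_ID = "IS"
INTERNAL_STANDARD_LEVEL = 100.0


@dataclass
class SyntheticConfig:
    """All knobs of the generator; defaults are the package's study conditions.

    Depth defaults (substrate 50,000 vs host 5,000) reflect the order-of-
    magnitude biomass asymmetry between an apple piece and a single worm.
    """

    n_taxa: int = 200
    n_timepoints: int = 8
    apples_per_timepoint: int = 5
    worms_per_apple_range: tuple[int, int] = (0, 6)
    sequencing_depth_substrate: int = 50_000
    sequencing_depth_host: int = 5_000
    shedding_lambda: float = 0.5
    clade_filter_strength: float = 3.0
    host_richness_fraction: float = 0.4
    drift_sd: float = 0.3
    apple_sd: float = 1.0
    competent_fraction: float = 0.25
    n_metabolites: int = 40
    metabolite_sparsity: float = 0.02
    metabolite_noise_sd: float = 0.1
    presence_ph_coeff: float = 2.0
    presence_intercept: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_taxa": self.n_taxa,
            "n_timepoints": self.n_timepoints,
            "apples_per_timepoint": self.apples_per_timepoint,
            "sequencing_depth_substrate": self.sequencing_depth_substrate,
            "sequencing_depth_host": self.sequencing_depth_host,
            "n_metabolites": self.n_metabolites,
        }
        for name, value in counts.items():
            if int(value) != value or value < 1:
                raise InvalidArgumentError(f"{name} must be an integer >= 1")
        lo, hi = self.worms_per_apple_range
        if lo > hi or lo < 0:
            raise InvalidArgumentError("worms_per_apple_range must satisfy 0 <= min <= max")
        if not 0.0 <= self.shedding_lambda <= 1.0:
            raise InvalidArgumentError("shedding_lambda must be in [0, 1]")
        if not 0.0 < self.host_richness_fraction <= 1.0:
            raise InvalidArgumentError("host_richness_fraction must be in (0, 1]")
        if not 0.0 <= self.metabolite_sparsity <= 1.0:
            raise InvalidArgumentError("metabolite_sparsity must be in [0, 1]")
        for name in ("clade_filter_strength", "drift_sd", "apple_sd",
                     "metabolite_noise_sd"):
            if getattr(self, name) < 0:
                raise InvalidArgumentError(f"{name} must be non-negative")
        if not 0.0 < self.competent_fraction <= 1.0:
            raise InvalidArgumentError("competent_fraction must be in (0, 1]")


@dataclass
class GroundTruth:
    """Record of every latent parameter a recovery test may read."""

    shedding_lambda: float
    host_competent_clades: list[list[str]]  # each clade as its leaf-name list
    metabolite_coefficients: pd.DataFrame  # metabolite x taxon
    presence_logit_params: dict
    seed: int

    @property
    def competent_taxa(self) -> set[str]:
        return {t for clade in self.host_competent_clades for t in clade}

    def to_json(self, path) -> None:
        payload = {
            "shedding_lambda": self.shedding_lambda,
            "host_competent_clades": self.host_competent_clades,
            "metabolite_coefficients": {
                "index": list(self.metabolite_coefficients.index),
                "columns": list(self.metabolite_coefficients.columns),
                "values": self.metabolite_coefficients.to_numpy().tolist(),
            },
            "presence_logit_params": self.presence_logit_params,
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        coeffs = payload["metabolite_coefficients"]
        return cls(
            shedding_lambda=payload["shedding_lambda"],
            host_competent_clades=payload["host_competent_clades"],
            metabolite_coefficients=pd.DataFrame(
                np.asarray(coeffs["values"]),
                index=coeffs["index"],
                columns=coeffs["columns"],
            ),
            presence_logit_params=payload["presence_logit_params"],
            seed=payload["seed"],
        )


@dataclass
class SimulatedDataset:
    counts: pd.DataFrame  # worm + apple samples x taxa
    metadata: pd.DataFrame
    tree: skbio.TreeNode
    metabolites: io_formats.MetaboliteTable
    truth: GroundTruth
    config: SyntheticConfig
    substrate_latent: np.ndarray = field(repr=False, default=None)  # (A, T, J)

    def samples(self, environment: str) -> pd.DataFrame:
        ids = self.metadata.index[self.metadata["environment"] == environment]
        return self.counts.loc[[s for s in self.counts.index if s in set(ids)]]

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        io_formats.write_count_table(self.counts, out / "counts.tsv")
        io_formats.write_metadata(self.metadata, out / "metadata.tsv")
        io_formats.write_metabolite_table(self.metabolites, out / "metabolites.tsv")
        io_formats.write_newick(self.tree, out / "tree.nwk")
        self.truth.to_json(out / "truth.json")


# ---------------------------------------------------------------------------
# phylogeny

def generate_phylogeny(n_taxa: int, seed: int) -> skbio.TreeNode:
    """Rooted binary tree by sequential random leaf attachment (Yule-like).

    Branch lengths are i.i.d. exponential with mean 1; leaves are labelled
    ``ASV1..ASVn``.  Deterministic given the seed.
    """
    if n_taxa < 2:
        raise InvalidArgumentError("a phylogeny needs at least 2 taxa")
    rng = np.random.default_rng(seed)
    leaves = [skbio.TreeNode(name="ASV1"), skbio.TreeNode(name="ASV2")]
    root = skbio.TreeNode(children=list(leaves))
    for i in range(3, n_taxa + 1):
        target = leaves[int(rng.integers(len(leaves)))]
        parent = target.parent
        parent.remove(target)
        new_leaf = skbio.TreeNode(name=f"ASV{i}")
        parent.append(skbio.TreeNode(children=[target, new_leaf]))
        leaves.append(new_leaf)
    for node in root.postorder(include_self=False):
        node.length = float(rng.exponential(1.0))
    return root


def host_competent_clades(
    tree: skbio.TreeNode, fraction: float = 0.25
) -> list[list[str]]:
    """Choose the smallest disjoint subtrees jointly covering ~``fraction``
    of the taxa; keeps the host-selection effect phylogenetically clustered."""
    n_taxa = len(list(tree.tips()))
    target = fraction * n_taxa
    internals = [
        node for node in tree.postorder(include_self=False) if not node.is_tip()
    ]
    internals.sort(key=lambda n: (len(list(n.tips())), min(t.name for t in n.tips())))
    chosen: list[list[str]] = []
    covered: set[str] = set()
    for node in internals:
        names = sorted(t.name for t in node.tips())
        if covered.intersection(names):
            continue
        chosen.append(names)
        covered.update(names)
        if len(covered) >= target:
            break
    return chosen


# ---------------------------------------------------------------------------
# substrate and host communities

def _softmax_rows(z: np.ndarray) -> np.ndarray:
    return softmax(z, axis=-1)


def apply_shedding_feedback(
    substrate_latent: np.ndarray, host_counts: np.ndarray, shedding_lambda: float
) -> np.ndarray:
    """Mix the mean host community into one apple's drifted latent state.

    ``substrate_latent`` is the apple's (already drifted) log-abundance
    vector; ``host_counts`` the (n_worms, n_taxa) counts of its worms.  The
    next-step substrate relative abundances become
    ``lambda * mean(host rel.) + (1 - lambda) * softmax(latent)``.
    """
    if not 0.0 <= shedding_lambda <= 1.0:
        raise InvalidArgumentError("shedding_lambda must be in [0, 1]")
    if shedding_lambda == 0.0 or len(host_counts) == 0:
        return substrate_latent
    host_counts = np.atleast_2d(np.asarray(host_counts, dtype=float))
    host_rel = host_counts / host_counts.sum(axis=1, keepdims=True)
    mixed = (
        shedding_lambda * host_rel.mean(axis=0)
        + (1.0 - shedding_lambda) * _softmax_rows(substrate_latent)
    )
    # taxa absent from both terms get probability ~0 (floor avoids log(0))
    return np.log(np.clip(mixed, 1e-300, None))


def _sample_one_worm(
    substrate_counts: np.ndarray,
    competent_mask: np.ndarray,
    config: SyntheticConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    total = substrate_counts.sum()
    if total == 0:
        raise DegenerateInputError("substrate sample has all-zero counts")
    rel = substrate_counts / total
    weights = rel * np.exp(config.clade_filter_strength * competent_mask)
    present = np.flatnonzero(substrate_counts > 0)
    k = int(np.ceil(config.host_richness_fraction * len(present)))
    w_present = weights[present]
    support = rng.choice(present, size=k, replace=False, p=w_present / w_present.sum())
    p = np.zeros_like(weights)
    p[support] = weights[support]
    p /= p.sum()
    return rng.multinomial(config.sequencing_depth_host, p)


def sample_host_communities(
    substrate_counts: pd.DataFrame,
    tree: skbio.TreeNode,
    config: SyntheticConfig,
    competent_taxa: set[str] | None = None,
    seed: int | None = None,
    worms_per_sample: int | None = None,
) -> pd.DataFrame:
    """Draw host (worm) communities from each substrate sample.

    Sampling weights are the substrate relative abundances boosted by
    ``exp(clade_filter_strength)`` on host-competent taxa; each worm's
    support is restricted to ``ceil(host_richness_fraction * richness)``
    taxa drawn (without replacement) by those weights.
    """
    if competent_taxa is None:
        competent_taxa = {
            t for clade in host_competent_clades(tree, config.competent_fraction)
            for t in clade
        }
    rng = np.random.default_rng(config.seed if seed is None else seed)
    competent_mask = np.array(
        [t in competent_taxa for t in substrate_counts.columns], dtype=float
    )
    lo, hi = config.worms_per_apple_range
    rows, ids, = [], []
    for sample_id, row in substrate_counts.iterrows():
        n_worms = (
            worms_per_sample
            if worms_per_sample is not None
            else int(rng.integers(max(lo, 1), hi + 1))
        )
        for k in range(1, n_worms + 1):
            rows.append(_sample_one_worm(row.to_numpy(dtype=float),
                                         competent_mask, config, rng))
            ids.append(f"W.{sample_id}.{k}")
    return pd.DataFrame(
        np.asarray(rows, dtype=np.int64), index=ids, columns=substrate_counts.columns
    )


def _simulate_communities(config: SyntheticConfig, tree, competent_taxa, with_worms):
    """Shared time loop for the substrate series with or without worms.

    The substrate stream is consumed identically in both modes, so a
    zero-shedding run with worms reproduces the no-worm substrate exactly.
    """
    J = config.n_taxa
    A = config.apples_per_timepoint
    T = config.n_timepoints
    taxa = [f"ASV{i}" for i in range(1, J + 1)]
    rng_sub = np.random.default_rng([config.seed, 101])
    rng_host = np.random.default_rng([config.seed, 202])
    rng_env = np.random.default_rng([config.seed, 303])
    competent_mask = np.array([t in competent_taxa for t in taxa], dtype=float)

    pool = rng_sub.normal(0.0, 1.0, J)
    z = pool + rng_sub.normal(0.0, config.apple_sd, (A, J))
    latent = np.empty((A, T, J))
    apple_rows, apple_meta, worm_rows, worm_meta = [], [], [], []

    for t in range(1, T + 1):
        if t > 1:
            z = z + rng_sub.normal(0.0, config.drift_sd, J)  # shared walk step
            z = z + rng_sub.normal(0.0, config.drift_sd, (A, J))  # apple noise
        t_max = 18.0 - 0.8 * (t - 1) + rng_env.normal(0.0, 1.5)
        precip = rng_env.gamma(2.0, 2.0)
        for a in range(A):
            apple_id = f"A{a + 1}.T{t}"
            ph = rng_env.uniform(3.0, 5.0) + 0.08 * (t - 1)
            logit = config.presence_intercept + config.presence_ph_coeff * (
                ph - PH_CENTER
            )
            presence = bool(rng_env.random() < expit(logit))
            if with_worms and presence:
                # worms colonized the substrate before it is measured: they
                # sample the pre-shedding bacterial population (a virtual
                # draw from the host stream, 10x the sequencing depth so the
                # population is effectively exhaustive and the neutral limit
                # stays exchangeable), then shedding updates the state the
                # reported apple sample is taken from
                pre_counts = rng_host.multinomial(
                    10 * config.sequencing_depth_substrate, _softmax_rows(z[a])
                )
                lo, hi = config.worms_per_apple_range
                n_worms = int(rng_host.integers(max(lo, 1), hi + 1))
                worms_here = []
                for k in range(1, n_worms + 1):
                    w = _sample_one_worm(
                        pre_counts.astype(float), competent_mask, config, rng_host
                    )
                    worms_here.append(w)
                    worm_rows.append(w)
                    worm_meta.append(
                        dict(sample_id=f"W{a + 1}.T{t}.{k}", environment="worm",
                             apple_id=apple_id, timepoint=t, batch="B1",
                             pH=np.nan, worm_presence="",
                             t_max=round(t_max, 2), precipitation=round(precip, 2))
                    )
                z[a] = apply_shedding_feedback(
                    z[a], np.asarray(worms_here), config.shedding_lambda
                )
            counts = rng_sub.multinomial(
                config.sequencing_depth_substrate, _softmax_rows(z[a])
            )
            apple_rows.append(counts)
            apple_meta.append(
                dict(sample_id=apple_id, environment="apple", apple_id=apple_id,
                     timepoint=t, batch="B1", pH=round(ph, 3),
                     worm_presence="yes" if presence else "no",
                     t_max=round(t_max, 2), precipitation=round(precip, 2))
            )
        latent[:, t - 1, :] = z

    apple_counts = pd.DataFrame(
        np.asarray(apple_rows, dtype=np.int64),
        index=[m["sample_id"] for m in apple_meta],
        columns=taxa,
    )
    worm_counts = pd.DataFrame(
        np.asarray(worm_rows, dtype=np.int64).reshape(len(worm_rows), J),
        index=[m["sample_id"] for m in worm_meta],
        columns=taxa,
    )
    metadata = pd.DataFrame(apple_meta + worm_meta).set_index("sample_id")
    return apple_counts, worm_counts, metadata, latent


def generate_substrate_series(
    config: SyntheticConfig, tree: skbio.TreeNode | None = None
) -> tuple[pd.DataFrame, np.ndarray]:
    """Substrate-only simulation: (counts, latent log-abundances (A, T, J)).

    Apple lineages persist across time points; each (lineage, time point)
    pair is observed once as its own apple sample.
    """
    apple_counts, _, _, latent = _simulate_communities(
        config, tree, competent_taxa=set(), with_worms=False
    )
    return apple_counts, latent


def generate_metabolome(
    substrate_counts: pd.DataFrame,
    truth: GroundTruth,
    config: SyntheticConfig,
    seed: int | None = None,
) -> io_formats.MetaboliteTable:
    """Metabolite layer: each metabolite is ``exp(eta)`` with
    ``eta = sparse linear form of CLR substrate abundances + noise``; the
    ratio-to-standard log recovers ``eta`` exactly.  A constant
    internal-standard column is appended."""
    rng = np.random.default_rng(
        [config.seed if seed is None else seed, 404, 1]
    )
    C = truth.metabolite_coefficients.loc[:, substrate_counts.columns].to_numpy()
    clr = clr_transform(substrate_counts, pseudocount=1.0).to_numpy()
    eta = clr @ C.T + rng.normal(
        0.0, config.metabolite_noise_sd, (substrate_counts.shape[0], C.shape[0])
    )
    values = pd.DataFrame(
        np.exp(eta),
        index=substrate_counts.index,
        columns=list(truth.metabolite_coefficients.index),
    )
    values[INTERNAL_STANDARD_ID] = INTERNAL_STANDARD_LEVEL
    return io_formats.MetaboliteTable(
        values=values, internal_standard_id=INTERNAL_STANDARD_ID
    )


def _draw_metabolite_coefficients(config: SyntheticConfig) -> pd.DataFrame:
    rng = np.random.default_rng([config.seed, 404, 0])
    taxa = [f"ASV{i}" for i in range(1, config.n_taxa + 1)]
    metabolites = [f"M{i}" for i in range(1, config.n_metabolites + 1)]
    C = np.zeros((config.n_metabolites, config.n_taxa))
    n_nz = int(round(config.metabolite_sparsity * config.n_taxa))
    for m in range(config.n_metabolites):
        if n_nz > 0:
            cols = rng.choice(config.n_taxa, size=n_nz, replace=False)
            C[m, cols] = rng.normal(0.0, 1.0, n_nz)
    return pd.DataFrame(C, index=metabolites, columns=taxa)


def generate_presence_labels(
    metadata: pd.DataFrame,
    metabolites: io_formats.MetaboliteTable | None,
    truth: GroundTruth,
    seed: int = 0,
) -> pd.DataFrame:
    """Redraw worm-presence labels for apple samples from the logistic model
    ``presence ~ logistic(intercept + ph_coeff * (pH - 4) + sum(c_m * log-signal))``.

    Metabolite terms are taken from ``truth.presence_logit_params`` (key
    ``metabolite_coeffs``, a ``{metabolite_id: coefficient}`` mapping); the
    signal is the log ratio to the internal standard.
    """
    params = truth.presence_logit_params
    rng = np.random.default_rng(seed)
    out = metadata.copy()
    apples = out.index[out["environment"] == "apple"]
    logit = np.full(len(apples), float(params.get("intercept", 0.0)))
    ph = out.loc[apples, "pH"].to_numpy(dtype=float)
    logit = logit + float(params.get("ph_coeff", 0.0)) * (ph - PH_CENTER)
    metab_coeffs = params.get("metabolite_coeffs", {}) or {}
    if metab_coeffs:
        if metabolites is None:
            raise InvalidArgumentError(
                "presence model has metabolite terms but no metabolite table given"
            )
        std = metabolites.values[metabolites.internal_standard_id]
        for metab_id, coeff in metab_coeffs.items():
            signal = np.log(
                metabolites.values.loc[apples, metab_id].to_numpy(dtype=float)
                / std.loc[apples].to_numpy(dtype=float)
            )
            logit = logit + float(coeff) * signal
    draws = rng.random(len(apples)) < expit(logit)
    out.loc[apples, "worm_presence"] = np.where(draws, "yes", "no")
    return out


def generate_dataset(config: SyntheticConfig) -> SimulatedDataset:
    """Run the full generator and return data plus its ground-truth record."""
    tree = generate_phylogeny(config.n_taxa, seed=config.seed)
    clades = host_competent_clades(tree, config.competent_fraction)
    competent = {t for clade in clades for t in clade}
    truth = GroundTruth(
        shedding_lambda=config.shedding_lambda,
        host_competent_clades=clades,
        metabolite_coefficients=_draw_metabolite_coefficients(config),
        presence_logit_params={
            "intercept": config.presence_intercept,
            "ph_coeff": config.presence_ph_coeff,
            "metabolite_coeffs": {},
        },
        seed=config.seed,
    )
    apple_counts, worm_counts, metadata, latent = _simulate_communities(
        config, tree, competent, with_worms=True
    )
    counts = pd.concat([apple_counts, worm_counts])
    metabolites = generate_metabolome(apple_counts, truth, config)
    return SimulatedDataset(
        counts=counts,
        metadata=metadata,
        tree=tree,
        metabolites=metabolites,
        truth=truth,
        config=config,
        substrate_latent=latent,
    )
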