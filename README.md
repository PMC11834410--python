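# hostlink

Statistical toolkit for linking host-associated microbiomes to the
microbiomes and metabolomes of their substrate, built around the model
system of *Caenorhabditis* nematodes living on rotting apples. Individual
worms and the apple pieces they were isolated from are sequenced (16S
ASV count tables); the package answers the questions that require bespoke
machinery rather than off-the-shelf tests:

* **Is the host community less phylogenetically diverse than expected for
  its richness?** A resampling null: collapse each apple's worms to one
  unit (mean Chao1, mean Faith PD), pool all units whose Chao1 falls in the
  focal group's range, and compare the observed mean PD with the
  distribution of means of repeated random draws — a two-sided empirical
  p-value with the add-one rule.
* **Are worms from the same apple more similar than worms from different
  apples?** A repeated random-pairing design: per iteration, disjoint
  triples (focal, same-apple partner, different-apple worm) feed a paired
  Wilcoxon on (d_same, d_diff); 100 iterations are summarized by the median
  p-value.
* **Who influences whom?** Two readouts of source–sink directionality:
  a single-sink multinomial-mixture EM source tracker (fixed source
  profiles γ_k plus one re-estimated "unknown"; sink ~ Multinomial(Σ α_k γ_k))
  run both ways per apple, and lasso cross-prediction of taxon abundances
  between randomly paired worm/apple samples (per-taxon CV RMSE and R²,
  paired Wilcoxon between directions).
* **Which bacteria track which metabolites?** Mixed-model association
  networks (`metabolite ~ ASV + pH + (1|time point)` and the reverse, LRT
  p-values, BH adjustment) plus lasso prediction across layers summarized
  by relative RMSE = RMSE / span(target).

Everything runs on a seeded synthetic-data generator that emulates the
study design (weekly apple sampling, per-apple worm cohorts, host-side
clade filtering and dispersal limitation, host→substrate shedding feedback,
a CLR-coupled metabolite layer) and records its ground truth, so each
analysis is validated by calibration and parameter recovery. See
`docs/methods.md` for the models and their assumptions.

## Worked example

```python
import numpy as np
from hostlink import synthetic_data as sd, community_metrics as cm
from hostlink import null_models as nm, paired_similarity as ps, source_sink as ss

cfg = sd.SyntheticConfig(
    n_taxa=60, n_timepoints=4, apples_per_timepoint=5,
    worms_per_apple_range=(1, 3), sequencing_depth_substrate=3000,
    sequencing_depth_host=3000, shedding_lambda=0.7,
    clade_filter_strength=1.0, host_richness_fraction=1.0,
    n_metabolites=10, presence_intercept=2.0, presence_ph_coeff=0.0, seed=42)
ds = sd.generate_dataset(cfg)

prof = cm.diversity_profile(ds.counts, ds.tree)
units = nm.collapse_worms_to_units(prof, ds.metadata)
res = nm.richness_matched_null(units, "worm", n_draws=2000, seed=1)

worms = [s for s in ds.counts.index if ds.metadata.at[s, "environment"] == "worm"]
dist = cm.aitchison_distance_matrix(ds.counts.loc[worms])
pair = ps.repeated_pairing_test(dist, ds.metadata.loc[worms], n_iter=100, seed=2)

occ = cm.filter_min_occurrence(ds.counts)
contrib, test = ss.directionality_em(occ, ds.metadata)
```

printing the three results gives:

```
worm PD: observed mean 104.47, null mean 105.55, p = 0.0660
pairing test: median p = 0.001953 over 100 iterations
EM: median worm->apple 0.838, apple->worm 0.708, Wilcoxon p = 7.629e-05, favored: worm->apple
```

Read: in this simulated world the worms' phylogenetic diversity is slightly
but not significantly below the richness-matched expectation (mild clade
filtering, p = 0.066); worms from the same apple are clearly more similar
than worms from different apples (median p ≈ 0.002 over 100 random
pairings); and with strong shedding feedback (λ = 0.7) the worm communities
explain their apple's community better than the reverse (summed worm
contribution 0.84 vs apple contribution 0.71, paired Wilcoxon p < 1e-4) —
the source-tracking readout recovers the direction of the feedback built
into the generator.

## Command line

```bash
hostlink simulate --seed 3 --out data/            # synthetic dataset + ground truth
hostlink diversity --counts data/counts.tsv --tree data/tree.nwk --out profile.tsv
hostlink distance  --counts data/counts.tsv --metric aitchison --out dist.tsv
hostlink nulltest  --units units.tsv --focal worm --draws 5000 --seed 7 --out null.json
hostlink pairtest  --distance dist.tsv --metadata data/metadata.tsv --out pair.json
hostlink sourcesink em --counts data/counts.tsv --metadata data/metadata.tsv --out em.json
hostlink metabolome --counts data/counts.tsv --metabolites data/metabolites.tsv \
                    --metadata data/metadata.tsv --out metab/
hostlink run --config run.yaml                    # full pipeline, JSON report
```

All tabular artifacts are plain TSV, trees are Newick, reports and ground
truth are JSON; every stage's seed derives from one master seed and reruns
reproduce all stochastic results exactly.

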