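import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from hostlink import community_metrics as cm
from hostlink import io_formats
from hostlink.errors import InvalidArgumentError

counts_arrays = st.lists(
    st.integers(min_value=0, max_value=200), min_size=1, max_size=30
).filter(lambda xs: sum(xs) > 0)


class TestAlphaDiversity:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ([5, 3, 2, 2, 4], 5.0),  # no singletons: estimate = observed
            ([1, 1, 2, 3, 5], 5.5),  # S=5, F1=2, F2=1 -> 5 + 2*1/4
            ([1, 1, 1], 6.0),  # S=3, F1=3, F2=0 -> 3 + 3*2/2
        ],
    )
    def test_chao1_bias_corrected_formula(self, counts, expected):
        assert cm.chao1(counts) == pytest.approx(expected, abs=1e-9)

    def test_chao1_all_zero_is_missing(self):
        assert math.isnan(cm.chao1([0, 0, 0]))

    @pytest.mark.parametrize(
        "counts,expected_shannon,expected_simpson",
        [
            ([1, 1, 1, 1], math.log(4), 0.75),
            ([7, 0, 0], 0.0, 0.0),
            ([1, 2, 3], 1.0114042647073518, 1 - (1 / 36 + 4 / 36 + 9 / 36)),
        ],
    )
    def test_shannon_and_simpson(self, counts, expected_shannon, expected_simpson):
        assert cm.shannon(counts) == pytest.approx(expected_shannon, abs=1e-9)
        assert cm.simpson(counts) == pytest.approx(expected_simpson, abs=1e-9)

    @settings(deadline=None, max_examples=60)
    @given(counts_arrays)
    def test_estimator_bounds(self, counts):
        richness = sum(c > 0 for c in counts)
        if richness == 0:
            return
        assert cm.chao1(counts) >= richness - 1e-12
        assert cm.shannon(counts) <= math.log(max(richness, 1)) + 1e-12
        assert cm.simpson(counts) < 1.0


class TestClrAndAitchison:
    def test_constant_row_maps_to_zero(self):
        table = pd.DataFrame([[5, 5, 5]], index=["S"], columns=list("ABC"))
        out = cm.clr_transform(table, pseudocount=0)
        assert np.allclose(out.to_numpy(), 0.0)

    def test_scale_invariance_without_zeros(self):
        row = pd.DataFrame([[2, 3, 7]], index=["S"], columns=list("ABC"))
        scaled = row * 10
        a = cm.clr_transform(row, pseudocount=0)
        b = cm.clr_transform(scaled, pseudocount=0)
        assert np.allclose(a.to_numpy(), b.to_numpy(), atol=1e-12)

    def test_closed_form_two_part_row(self):
        table = pd.DataFrame([[1, 3]], index=["S"], columns=list("AB"))
        out = cm.clr_transform(table, pseudocount=0).to_numpy()[0]
        assert out == pytest.approx([-math.log(3) / 2, math.log(3) / 2], abs=1e-12)

    def test_rows_center_to_zero(self, tiny_dataset):
        out = cm.clr_transform(tiny_dataset.counts)
        assert np.abs(out.mean(axis=1)).max() < 1e-9

    def test_zero_pseudocount_with_zeros_rejected(self, toy_counts):
        with pytest.raises(InvalidArgumentError):
            cm.clr_transform(toy_counts, pseudocount=0)

    def test_aitchison_closed_form(self):
        table = pd.DataFrame([[1, 3], [3, 1]], index=["S1", "S2"],
                             columns=list("AB"))
        dist = cm.aitchison_distance_matrix(table, pseudocount=0)
        expected = math.log(3) * math.sqrt(2)  # 2*ln(sqrt 3)*sqrt 2
        assert dist.between("S1", "S2") == pytest.approx(expected, abs=1e-9)

    def test_matrix_properties_on_fixture(self, tiny_dataset):
        dist = cm.aitchison_distance_matrix(tiny_dataset.counts.iloc[:50])
        assert np.allclose(dist.values, dist.values.T, atol=1e-9)
        assert np.allclose(np.diag(dist.values), 0.0)
        assert (dist.values >= -1e-12).all()


class TestPhylogeneticMetrics:
    def test_faith_pd_star_tree(self):
        tree = io_formats.read_newick("(A:1,B:1,C:1,D:1);")
        assert cm.faith_pd(["A", "B", "C"], tree) == pytest.approx(3.0)

    def test_faith_pd_path_enumeration(self, toy_tree):
        assert cm.faith_pd(["A", "C"], toy_tree) == pytest.approx(4.0, abs=1e-9)

    def test_faith_pd_all_leaves_is_total_length(self, toy_tree):
        assert cm.faith_pd(["A", "B", "C"], toy_tree) == pytest.approx(5.0)

    def test_faith_pd_unknown_taxon_named(self, toy_tree):
        with pytest.raises(InvalidArgumentError, match="ZZZ"):
            cm.faith_pd(["A", "ZZZ"], toy_tree)

    def test_faith_pd_monotone_in_taxa(self, tiny_dataset):
        taxa = list(tiny_dataset.counts.columns)
        pd1 = cm.faith_pd(taxa[:5], tiny_dataset.tree)
        pd2 = cm.faith_pd(taxa[:6], tiny_dataset.tree)
        assert pd2 >= pd1 - 1e-12

    def test_unifrac_hand_partition(self, toy_tree):
        table = pd.DataFrame(
            [[1, 1, 0], [1, 0, 1]], index=["S1", "S2"], columns=list("ABC")
        )
        dist = cm.unweighted_unifrac_matrix(table, toy_tree)
        # shared: A(1) + internal(1); unique: B(1) + C(2) -> 3/5
        assert dist.between("S1", "S2") == pytest.approx(0.6, abs=1e-9)

    def test_unifrac_limits(self, toy_tree):
        star = io_formats.read_newick("(A:1,B:1,C:1);")
        same = pd.DataFrame([[1, 1, 0], [1, 1, 0]], index=["S1", "S2"],
                            columns=list("ABC"))
        assert cm.unweighted_unifrac_matrix(same, toy_tree).between("S1", "S2") == 0
        disjoint = pd.DataFrame([[1, 0, 0], [0, 1, 0]], index=["S1", "S2"],
                                columns=list("ABC"))
        assert cm.unweighted_unifrac_matrix(disjoint, star).between(
            "S1", "S2") == pytest.approx(1.0)

    def test_against_skbio_reference(self, tiny_dataset):
        """Independent oracle: scikit-bio's implementations on a subsample."""
        import skbio.diversity

        counts = tiny_dataset.counts.iloc[:8]
        taxa = list(counts.columns)
        ours = cm.diversity_profile(counts, tiny_dataset.tree)["faith_pd"]
        for sample in counts.index:
            ref = skbio.diversity.alpha.faith_pd(
                counts.loc[sample].to_numpy(), taxa=taxa, tree=tiny_dataset.tree
            )
            assert ours[sample] == pytest.approx(ref, abs=1e-9)
        ref_uf = skbio.diversity.beta_diversity(
            "unweighted_unifrac", counts.to_numpy(), ids=list(counts.index),
            taxa=taxa, tree=tiny_dataset.tree,
        )
        ours_uf = cm.unweighted_unifrac_matrix(counts, tiny_dataset.tree)
        assert np.allclose(ours_uf.values, ref_uf.data, atol=1e-9)


class TestFilters:
    def test_boundary_taxon_retained(self):
        # in exactly 5 samples, total exactly 10, max exactly 5
        col = [5, 2, 1, 1, 1, 0]
        table = pd.DataFrame({"keep": col, "drop": [100, 100, 0, 0, 0, 0]},
                             index=[f"S{i}" for i in range(6)])
        out = cm.filter_asvs(table)
        assert list(out.columns) == ["keep"]

    def test_brute_force_agreement(self):
        rng = np.random.default_rng(8)
        table = pd.DataFrame(rng.integers(0, 8, (6, 8)),
                             index=[f"S{i}" for i in range(6)],
                             columns=[f"T{j}" for j in range(8)])
        out = cm.filter_asvs(table, min_prevalence=2, min_total=6, min_single=3)
        expected = [
            c for c in table.columns
            if (table[c] > 0).sum() >= 2 and table[c].sum() >= 6
            and table[c].max() >= 3
        ]
        assert list(out.columns) == expected

    def test_min_occurrence_ceiling_rule(self):
        # 20 samples: ceil(0.1 * 20) = 2 -> count 3 in 2 samples retained
        col = [3, 3] + [0] * 18
        table = pd.DataFrame({"keep": col, "drop": [2] * 20},
                             index=[f"S{i}" for i in range(20)])
        out = cm.filter_min_occurrence(table)
        assert list(out.columns) == ["keep"]

    def test_empty_table_passes_through(self):
        empty = pd.DataFrame(index=["S1"], columns=[], dtype=int)
        assert cm.filter_min_occurrence(empty).shape[1] == 0


class TestCoreAndIndicators:
    def test_core_inclusive_boundary(self):
        presence = [1] * 8 + [0] * 2
        table = pd.DataFrame({"core": presence, "rare": [1] + [0] * 9},
                             index=[f"S{i}" for i in range(10)])
        core = cm.core_asvs(table, table.index, threshold=0.8)
        assert core == ["core"]
        assert cm.core_asvs(table.assign(core=[1] * 7 + [0] * 3),
                            table.index)[0:] == []

    def test_random_fixture_matches_brute_force(self):
        rng = np.random.default_rng(12)
        table = pd.DataFrame(rng.integers(0, 3, (15, 10)),
                             index=[f"S{i}" for i in range(15)],
                             columns=[f"T{j}" for j in range(10)])
        group = list(table.index[:9])
        expected = [
            c for c in table.columns
            if (table.loc[group, c] > 0).mean() >= 0.8
        ]
        assert cm.core_asvs(table, group, 0.8) == expected

    def test_perfect_indicator(self):
        table = pd.DataFrame(
            {"ind": [4, 5, 6, 0, 0, 0], "flat": [1, 1, 1, 1, 1, 1]},
            index=[f"S{i}" for i in range(6)],
        )
        labels = ["g1"] * 3 + ["g2"] * 3
        scores = {s.taxon_id: s for s in cm.indicator_scores(table, labels,
                                                             n_perm=99, seed=0)}
        ind = scores["ind"]
        assert ind.group == "g1"
        assert ind.A == pytest.approx(1.0) and ind.B == pytest.approx(1.0)
        assert ind.stat == pytest.approx(1.0)

    def test_exhaustive_permutation_matches_independent_oracle(self):
        from itertools import permutations

        rng = np.random.default_rng(5)
        table = pd.DataFrame(rng.integers(0, 6, (6, 4)),
                             index=[f"S{i}" for i in range(6)],
                             columns=list("WXYZ"))
        labels = np.array(["a", "a", "a", "b", "b", "b"])
        scores = cm.indicator_scores(table, labels, n_perm="exhaustive")

        def stat_for(col, labs):
            best = 0.0
            for g in ("a", "b"):
                sub = table[col][np.asarray(labs) == g]
                other = table[col][np.asarray(labs) != g]
                denom = sub.mean() + other.mean()
                A = sub.mean() / denom if denom > 0 else 0.0
                B = (sub > 0).mean()
                best = max(best, math.sqrt(A * B))
            return best

        perms = sorted({tuple(p) for p in permutations(labels)})
        for score in scores:
            obs = stat_for(score.taxon_id, labels)
            hits = sum(
                stat_for(score.taxon_id, p) >= obs - 1e-12 for p in perms
            )
            assert score.permutation_p == pytest.approx(
                (1 + hits) / (1 + len(perms))
            )

    def test_single_group_rejected(self, toy_counts):
        with pytest.raises(InvalidArgumentError):
            cm.indicator_scores(toy_counts, ["g"] * 3)
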