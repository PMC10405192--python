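import numpy as np
import pytest
from skbio.diversity import beta_diversity
from skbio.stats.ordination import pcoa as skbio_pcoa

from ansbr.data_model import ASVTable, DistanceMatrix, Taxonomy
from ansbr.errors import DomainError, InsufficientDataError, ValidationError
from ansbr.microbiome import (
    alpha_diversity,
    core_microbiome,
    pcoa,
    rarefy,
    relative_abundance,
    shannon_index,
    unifrac_distance_matrix,
    unweighted_unifrac,
)
from conftest import brute_force_unifrac, random_tree, tree_from_newick


class TestRarefy:
    def test_sample_at_depth_is_unchanged(self):
        table = ASVTable(["s1"], ["A", "B"], np.array([[60, 40]]))
        out = rarefy(table, depth=100, seed=0)
        assert (out.counts == [[60, 40]]).all()

    def test_single_asv_sample_keeps_one_asv(self):
        table = ASVTable(["s1"], ["A"], np.array([[10**6]]))
        out = rarefy(table, depth=50_000, seed=0)
        assert out.counts.tolist() == [[50_000]]

    def test_totals_exactly_equal_depth_and_never_exceed_originals(self):
        rng = np.random.default_rng(5)
        counts = rng.integers(0, 500, size=(6, 30))
        counts[:, 0] += 200  # ensure all totals comfortably above depth
        table = ASVTable([f"s{i}" for i in range(6)], [f"a{j}" for j in range(30)], counts)
        out = rarefy(table, depth=1000, seed=1)
        assert (out.sample_totals() == 1000).all()
        assert (out.counts <= counts).all()

    def test_shallow_samples_dropped_with_warning(self, caplog):
        table = ASVTable(["deep", "shallow"], ["A", "B"], np.array([[900, 300], [5, 5]]))
        with caplog.at_level("WARNING"):
            out = rarefy(table, depth=100, seed=0)
        assert out.sample_ids == ["deep"]
        assert any("shallow" in m for m in caplog.messages)

    def test_deterministic_under_seed(self):
        table = ASVTable(["s1"], ["A", "B", "C"], np.array([[500, 300, 200]]))
        a = rarefy(table, depth=100, seed=7).counts
        b = rarefy(table, depth=100, seed=7).counts
        assert (a == b).all()

    def test_mean_matches_hypergeometric_expectation(self):
        # (900, 100) rarefied to 100: E[ASV1] = 90, hypergeometric SD ~ 2.85
        table = ASVTable(["s1"], ["A", "B"], np.array([[900, 100]]))
        draws = np.array(
            [rarefy(table, depth=100, seed=s).counts[0, 0] for s in range(1000)]
        )
        sd = np.sqrt(100 * 0.9 * 0.1 * (1000 - 100) / (1000 - 1))
        se_mean = sd / np.sqrt(1000)
        assert abs(draws.mean() - 90.0) < 3 * se_mean

    def test_nonpositive_depth_rejected(self):
        table = ASVTable(["s1"], ["A"], np.array([[10]]))
        with pytest.raises(DomainError):
            rarefy(table, depth=0)


class TestAlphaDiversity:
    def test_single_asv_sample(self):
        table = ASVTable(["s1"], ["A", "B"], np.array([[50, 0]]))
        res = alpha_diversity(table)
        assert res.per_sample.loc["s1", "observed_asvs"] == 1
        assert res.per_sample.loc["s1", "shannon"] == 0.0

    def test_uniform_distribution_attains_ln_s(self):
        table = ASVTable(["s1"], list("ABCD"), np.array([[25, 25, 25, 25]]))
        res = alpha_diversity(table)
        assert res.per_sample.loc["s1", "shannon"] == pytest.approx(np.log(4))

    def test_two_even_asvs_give_ln_2(self):
        table = ASVTable(["s1"], list("ABC"), np.array([[50, 50, 0]]))
        res = alpha_diversity(table)
        assert res.per_sample.loc["s1", "observed_asvs"] == 2
        assert res.per_sample.loc["s1", "shannon"] == pytest.approx(np.log(2))

    def test_uniform_is_the_maximum_and_zeros_are_ignored(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            counts = rng.integers(1, 100, size=8).astype(float)
            assert shannon_index(counts) <= np.log(8) + 1e-12
            assert shannon_index(np.append(counts, 0.0)) == pytest.approx(
                shannon_index(counts)
            )

    def test_all_zero_sample_rejected(self):
        table = ASVTable(["s1"], ["A"], np.array([[0]]))
        with pytest.raises(DomainError):
            alpha_diversity(table)

    def test_configurable_log_base(self):
        assert shannon_index(np.array([1, 1]), base=2) == pytest.approx(1.0)


class TestRelativeAbundance:
    def _taxonomy(self):
        return Taxonomy(
            {
                "A": {"phylum": "Firmicutes", "genus": "Clostridium"},
                "B": {"phylum": "Firmicutes", "genus": "Romboutsia"},
                "C": {"phylum": "Bacteroidota", "genus": "Proteiniphilum"},
                "D": {"phylum": "Firmicutes", "genus": None},
            }
        )

    def test_single_phylum_table_is_100_percent(self):
        table = ASVTable(["s1"], ["A", "B"], np.array([[30, 70]]))
        out = relative_abundance(table, self._taxonomy(), "phylum")
        assert out.loc["Firmicutes", "s1"] == pytest.approx(100.0)

    def test_simple_percentages(self):
        table = ASVTable(["s1"], ["A", "C"], np.array([[75, 25]]))
        out = relative_abundance(table, self._taxonomy(), "phylum")
        assert out.loc["Firmicutes", "s1"] == pytest.approx(75.0)
        assert out.loc["Bacteroidota", "s1"] == pytest.approx(25.0)

    def test_unassigned_rank_pools_separately(self):
        table = ASVTable(["s1"], ["A", "B", "C", "D"], np.array([[50, 30, 20, 0]]))
        out = relative_abundance(table, self._taxonomy(), "genus")
        assert out.loc["Clostridium", "s1"] == pytest.approx(50.0)
        assert out.loc["Unassigned", "s1"] == pytest.approx(0.0)
        assert out["s1"].sum() == pytest.approx(100.0)

    def test_empty_sample_names_the_sample(self):
        table = ASVTable(["good", "empty"], ["A"], np.array([[5], [0]]))
        with pytest.raises(ValidationError, match="empty"):
            relative_abundance(table, self._taxonomy(), "phylum")


class TestUnweightedUnifrac:
    def test_identical_sets_have_zero_distance(self, four_leaf_tree):
        assert unweighted_unifrac(four_leaf_tree, {"A", "C"}, {"A", "C"}) == 0.0

    def test_disjoint_singletons_on_star_tree(self):
        tree = tree_from_newick("(A:1,B:1);")
        assert unweighted_unifrac(tree, {"A"}, {"B"}) == pytest.approx(1.0)

    def test_quartet_hand_computed_value(self, four_leaf_tree):
        # observed branches: A, B, C, (A,B)-edge, (C,D)-edge -> total length 5.
        # Unique: leaf B (sample 1 only), leaf C and the (C,D) edge (sample 2
        # only); the (A,B) edge subtends A, which both samples share.
        assert unweighted_unifrac(four_leaf_tree, {"A", "B"}, {"A", "C"}) == pytest.approx(3 / 5)

    def test_missing_taxon_named_in_error(self, four_leaf_tree):
        with pytest.raises(ValidationError, match="Zzz"):
            unweighted_unifrac(four_leaf_tree, {"A"}, {"Zzz"})

    def test_matches_brute_force_oracle_on_random_trees(self):
        rng = np.random.default_rng(11)
        for _ in range(30):
            n = int(rng.integers(3, 12))
            tree = random_tree(rng, n)
            leaves = [f"L{i}" for i in range(n)]
            a = set(rng.choice(leaves, size=rng.integers(1, n), replace=False))
            b = set(rng.choice(leaves, size=rng.integers(1, n), replace=False))
            assert unweighted_unifrac(tree, a, b) == pytest.approx(
                brute_force_unifrac(tree, a, b), abs=1e-12
            )

    def test_distance_matrix_matches_scikit_bio(self):
        rng = np.random.default_rng(23)
        tree = random_tree(rng, 10)
        counts = rng.integers(0, 5, size=(6, 10))
        counts[:, 0] = 1  # no empty samples
        table = ASVTable([f"s{i}" for i in range(6)], [f"L{i}" for i in range(10)], counts)
        ours = unifrac_distance_matrix(tree, table)
        theirs = beta_diversity(
            "unweighted_unifrac", table.counts, ids=table.sample_ids,
            taxa=table.asv_ids, tree=tree,
        )
        assert np.abs(ours.data - theirs.data).max() < 1e-12

    def test_metric_axioms_on_random_triples(self):
        rng = np.random.default_rng(17)
        for _ in range(15):
            tree = random_tree(rng, 8)
            leaves = [f"L{i}" for i in range(8)]
            sets = [
                set(rng.choice(leaves, size=rng.integers(1, 8), replace=False))
                for _ in range(3)
            ]
            d = lambda x, y: unweighted_unifrac(tree, x, y)
            for s in sets:
                assert d(s, s) == 0.0
            d01, d02, d12 = d(sets[0], sets[1]), d(sets[0], sets[2]), d(sets[1], sets[2])
            for val in (d01, d02, d12):
                assert 0.0 <= val <= 1.0
            assert d01 <= d02 + d12 + 1e-12
            assert d(sets[1], sets[0]) == pytest.approx(d01, abs=1e-15)


class TestPcoa:
    def test_three_equidistant_samples_embed_exactly(self):
        dm = DistanceMatrix(("a", "b", "c"), 1.0 - np.eye(3))
        res = pcoa(dm, n_axes=2)
        coords = res.coordinates
        for i in range(3):
            for j in range(i + 1, 3):
                assert np.linalg.norm(coords[i] - coords[j]) == pytest.approx(1.0, abs=1e-9)

    def test_identical_samples_coincide(self):
        data = np.array([[0, 0, 1.0], [0, 0, 1.0], [1.0, 1.0, 0]])
        res = pcoa(DistanceMatrix(("a", "b", "c"), data), n_axes=2)
        assert np.allclose(res.coordinates[0], res.coordinates[1], atol=1e-9)

    def test_zero_matrix_gives_zero_coordinates(self):
        res = pcoa(DistanceMatrix(("a", "b"), np.zeros((2, 2))), n_axes=2)
        assert np.allclose(res.coordinates, 0.0)

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValidationError):
            DistanceMatrix(("a", "b"), np.array([[0, 1.0], [2.0, 0]]))

    def test_euclidean_configuration_reproduced_to_1e9(self):
        rng = np.random.default_rng(9)
        pts = rng.normal(size=(7, 3))
        D = np.linalg.norm(pts[:, None] - pts[None], axis=-1)
        dm = DistanceMatrix(tuple(f"s{i}" for i in range(7)), D)
        res = pcoa(dm, n_axes=7)
        embedded = np.linalg.norm(
            res.coordinates[:, None] - res.coordinates[None], axis=-1
        )
        assert np.abs(embedded - D).max() < 1e-9

    def test_axis_ordering_matches_scikit_bio_proportions(self):
        rng = np.random.default_rng(31)
        pts = rng.normal(size=(6, 4))
        D = np.linalg.norm(pts[:, None] - pts[None], axis=-1)
        ours = pcoa(DistanceMatrix(tuple(f"s{i}" for i in range(6)), D), n_axes=3)
        theirs = skbio_pcoa(D, number_of_dimensions=3)
        assert np.allclose(
            ours.explained, theirs.proportion_explained.to_numpy()[:3], atol=1e-9
        )


class TestCoreMicrobiome:
    def _table(self, presence):
        presence = np.asarray(presence, dtype=int)
        n, p = presence.shape
        return ASVTable(
            [f"s{i}" for i in range(n)], [f"a{j}" for j in range(p)], presence * 7
        )

    def test_everywhere_present_asv_is_core_with_fraction_one(self):
        table = self._table(np.ones((12, 3)))
        res = core_microbiome(table, n_resamples=200, seed=1)
        assert res.prevalence_fraction["a0"] == 1.0
        assert res.core_asv_ids == {"a0", "a1", "a2"}

    def test_absent_everywhere_asv_has_fraction_zero(self):
        presence = np.ones((12, 2))
        presence[:, 1] = 0
        res = core_microbiome(self._table(presence), n_resamples=200, seed=1)
        assert res.prevalence_fraction["a1"] == 0.0
        assert "a1" not in res.core_asv_ids

    def test_absent_in_one_of_twelve_matches_exact_bootstrap_probability(self):
        presence = np.ones((12, 2))
        presence[0, 1] = 0
        res = core_microbiome(self._table(presence), n_resamples=10_000, seed=3)
        exact = (11 / 12) ** 12  # resample must avoid the one missing sample
        se = np.sqrt(exact * (1 - exact) / 10_000)
        assert abs(res.prevalence_fraction["a1"] - exact) < 3 * se
        assert "a1" not in res.core_asv_ids

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(0)
        table = self._table(rng.random((10, 20)) > 0.3)
        a = core_microbiome(table, n_resamples=500, seed=9)
        b = core_microbiome(table, n_resamples=500, seed=9)
        assert a.prevalence_fraction == b.prevalence_fraction

    def test_parameter_validation(self):
        table = self._table(np.ones((3, 2)))
        with pytest.raises(DomainError):
            core_microbiome(table, n_resamples=0)
        with pytest.raises(DomainError):
            core_microbiome(table, threshold=1.5)
        with pytest.raises(InsufficientDataError):
            core_microbiome(self._table(np.ones((1, 2))))
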