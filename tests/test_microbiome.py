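"""Contaminant removal phases, rarefaction, diversity, and their oracles."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from uroscent import (
    SimulationDesign,
    TaxaTable,
    bray_curtis,
    differential_abundance,
    pcoa,
    phase1_negative_control_filter,
    phase2_indicator_correlation,
    phase3_genus_blacklist,
    profile_separation,
    rarefy,
    remove_contaminants,
    simulate_taxa_table,
    unweighted_unifrac,
)
from uroscent.config import ValidationError
from uroscent.microbiome import DistanceMatrix


def make_table(counts, species=None, n_neg=0, labels=None):
    counts = np.asarray(counts)
    n_sp, n_s = counts.shape
    species = species or [f"Genus{i} sp{i}" for i in range(n_sp)]
    n_true = n_s - n_neg
    if labels is None:
        labels = ["cancer"] * (n_true // 2) + ["control"] * (n_true - n_true // 2)
    sample_ids = [f"s{i}" for i in range(n_true)] + [
        f"NEG_b{i}" for i in range(n_neg)
    ]
    return TaxaTable(
        species_ids=species,
        sample_ids=sample_ids,
        counts=counts,
        is_negative_control=np.array([False] * n_true + [True] * n_neg),
        labels=np.array(list(labels) + [None] * n_neg, dtype=object),
    )


class TestPhase1:
    def test_control_dominant_species_flagged(self):
        counts = np.array(
            [
                [10, 12, 3000, 3000],  # 30%-ish of controls, trace in samples
                [5000, 6000, 5, 4],
            ]
        )
        t = make_table(counts, n_neg=2)
        flagged, ev = phase1_negative_control_filter(t)
        assert t.species_ids[0] in flagged
        assert t.species_ids[1] not in flagged
        assert ev[t.species_ids[0]]["control_abundance_ratio"] > 1

    def test_species_absent_from_controls_never_flagged(self):
        counts = np.array([[100, 100, 0, 0], [50, 60, 900, 800]])
        t = make_table(counts, n_neg=2)
        flagged, _ = phase1_negative_control_filter(t)
        assert t.species_ids[0] not in flagged

    def test_no_controls_skips_with_warning(self):
        t = make_table(np.array([[1, 2], [3, 4]]))
        with pytest.warns(UserWarning, match="skipped"):
            flagged, _ = phase1_negative_control_filter(t)
        assert flagged == set()

    def test_generator_truth_recovered_across_seeds(self):
        """All planted contaminants flagged, <= 5% innocent species."""
        for seed in range(20):
            t, truth = simulate_taxa_table(SimulationDesign(seed=seed))
            planted = set(truth["contaminant_species"]) | set(
                truth["indicator_species"]
            )
            flagged, _ = phase1_negative_control_filter(t)
            assert planted <= flagged
            innocents = len(flagged - planted)
            assert innocents <= 0.05 * (t.n_species - len(planted))


class TestPhase2:
    def test_rank_identical_species_flagged(self):
        ind = [10, 20, 30, 40, 50, 60]
        sp = [1, 2, 3, 4, 5, 6]  # same rank order -> rho = 1
        other = [6, 5, 4, 3, 2, 1]
        counts = np.array([ind, sp, other])
        t = make_table(counts)
        flagged, ev = phase2_indicator_correlation(t, [t.species_ids[0]])
        assert t.species_ids[1] in flagged
        assert ev[t.species_ids[1]]["max_spearman"] == pytest.approx(1.0)

    def test_cutoff_is_strict(self):
        """rho exactly 0.3 is not flagged; rho 0.5 is (strict > 0.30).

        Columns are padded to equal totals so relative abundances preserve
        the planted rank structure exactly.
        """
        ind = np.array([10, 20, 30, 40, 50])
        at03 = np.array([20, 40, 10, 50, 30])  # Spearman 0.3 against ind
        at05 = np.array([10, 40, 20, 50, 30])  # Spearman 0.5 against ind
        assert spearmanr(ind, at03).statistic == pytest.approx(0.3)
        assert spearmanr(ind, at05).statistic == pytest.approx(0.5)
        stack = np.vstack([ind, at03, at05])
        filler = 300 - stack.sum(axis=0)
        t = make_table(
            np.vstack([stack, filler]),
            species=["Ind i", "Low l", "High h", "Fill f"],
            labels=["cancer", "cancer", "control", "control", "control"],
        )
        flagged, ev = phase2_indicator_correlation(t, ["Ind i"], cutoff=0.30)
        assert ev["Low l"]["max_spearman"] == pytest.approx(0.3)
        assert "Low l" not in flagged
        assert "High h" in flagged

    def test_constant_species_not_flagged(self):
        # equal column totals; second species constant in relative abundance
        ind = np.array([10, 20, 30, 40])
        const = np.array([20, 20, 20, 20])
        filler = 100 - ind - const
        t = make_table(
            np.vstack([ind, const, filler]),
            species=["Ind i", "Const c", "Fill f"],
            labels=["cancer", "cancer", "control", "control"],
        )
        flagged, _ = phase2_indicator_correlation(t, ["Ind i"], cutoff=-1.1)
        assert "Const c" not in flagged

    def test_matches_independent_spearman_oracle(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 500, size=(6, 6))
        counts[0] += 100
        t = make_table(counts)
        ind = [t.species_ids[0], t.species_ids[1]]
        flagged, ev = phase2_indicator_correlation(t, ind, cutoff=-1.1)
        rel = t.relative_abundances()
        for i in range(2, 6):
            sp = t.species_ids[i]
            expect = max(
                spearmanr(rel[i], rel[0]).statistic,
                spearmanr(rel[i], rel[1]).statistic,
            )
            assert ev[sp]["max_spearman"] == pytest.approx(expect)

    def test_missing_indicator_rejected(self):
        t = make_table(np.ones((2, 4), dtype=int))
        with pytest.raises(ValidationError, match="absent"):
            phase2_indicator_correlation(t, ["Nope nope"])


class TestPhase3:
    def test_blacklisted_genus_flagged(self):
        t = make_table(
            np.ones((2, 4), dtype=int),
            species=["Ralstonia pickettii", "Lactobacillus iners"],
        )
        flagged, ev = phase3_genus_blacklist(t, ["Ralstonia"])
        assert flagged == {"Ralstonia pickettii"}
        assert ev["Ralstonia pickettii"]["blacklist_genus"] == "Ralstonia"

    def test_empty_blacklist(self):
        t = make_table(np.ones((2, 4), dtype=int))
        assert phase3_genus_blacklist(t, [])[0] == set()

    def test_matches_string_oracle_on_mixed_table(self):
        t, _ = simulate_taxa_table(SimulationDesign(seed=3))
        genera = ("Ralstonia", "Sphingomonas", "Dolosigranulum")
        flagged, _ = phase3_genus_blacklist(t, genera)
        oracle = {s for s in t.species_ids if s.split()[0] in genera}
        assert flagged == oracle

    def test_union_is_order_independent(self):
        t, truth = simulate_taxa_table(SimulationDesign(seed=5))
        ind = truth["indicator_species"]
        _, rep = remove_contaminants(t, ind)
        manual = (
            phase1_negative_control_filter(t)[0]
            | phase2_indicator_correlation(t, ind)[0]
            | phase3_genus_blacklist(t)[0]
        )
        assert rep.removed == manual
        # removal drops species only, never samples
        clean, _ = remove_contaminants(t, ind)
        assert clean.sample_ids == t.sample_ids


class TestRarefy:
    def test_exact_column_sums_and_dropping(self):
        counts = np.array([[2000, 500, 100], [700, 400, 100]])
        t = make_table(counts, labels=["cancer", "cancer", "control"])
        rare, dropped = rarefy(t, depth=900, seed=0)
        assert dropped == ["s2"]  # total 200 < 900
        assert (rare.counts.sum(axis=0) == 900).all()
        assert np.issubdtype(rare.counts.dtype, np.integer)

    def test_sample_at_exact_depth_retained(self):
        counts = np.array([[900, 1000], [0, 200]])
        t = make_table(counts, labels=["cancer", "control"])
        rare, dropped = rarefy(t, depth=900, seed=1)
        assert dropped == []
        np.testing.assert_array_equal(rare.counts[:, 0], [900, 0])

    def test_all_below_depth_is_an_error(self):
        t = make_table(np.array([[1, 2], [3, 4]]))
        with pytest.raises(ValidationError):
            rarefy(t, depth=1000)

    def test_hypergeometric_expectation(self):
        """Mean rarefied count approximates depth * proportion."""
        counts = np.array([[600], [300], [100]])
        t = make_table(counts, labels=["cancer"])
        draws = np.zeros(3)
        n_rep = 400
        for s in range(n_rep):
            rare, _ = rarefy(t, depth=100, seed=s)
            draws += rare.counts[:, 0]
        mean = draws / n_rep
        expected = 100 * counts[:, 0] / 1000
        # hypergeometric variance for each species
        var = 100 * (counts[:, 0] / 1000) * (1 - counts[:, 0] / 1000) * (900 / 999)
        se = np.sqrt(var / n_rep)
        assert (np.abs(mean - expected) <= 3 * se).all()


class TestBrayCurtis:
    def test_identical_and_disjoint_columns(self):
        counts = np.array([[5, 5, 0], [3, 3, 0], [0, 0, 7]])
        t = make_table(counts, labels=["cancer", "cancer", "control"])
        d = bray_curtis(t).matrix
        assert d[0, 1] == pytest.approx(0.0)
        assert d[0, 2] == pytest.approx(1.0)

    def test_hand_value(self):
        """(2,0) vs (1,1): 1 - 2*min_sum/total = 1 - 2/4 = 0.5."""
        counts = np.array([[2, 1], [0, 1]])
        t = make_table(counts, labels=["cancer", "control"])
        assert bray_curtis(t).matrix[0, 1] == pytest.approx(0.5)

    def test_symmetry_and_identity_on_simulated_tables(self):
        t, _ = simulate_taxa_table(SimulationDesign(seed=8))
        rare, _ = rarefy(t.select_samples(t.true_sample_mask), 2700, seed=0)
        d = bray_curtis(rare).matrix
        np.testing.assert_allclose(d, d.T)
        assert np.all(np.diag(d) == 0)
        assert d.max() <= 1.0 + 1e-12


def brute_force_unifrac(tree_branches, tips_a, tips_b):
    """Oracle: walk every branch; unique/union branch length by tip sets."""
    unique = union = 0.0
    for length, subtended in tree_branches:
        in_a = bool(subtended & tips_a)
        in_b = bool(subtended & tips_b)
        if in_a or in_b:
            union += length
            if in_a != in_b:
                unique += length
    return unique / union if union else 0.0


class TestUniFrac:
    def two_tip_table(self):
        counts = np.array([[4, 0], [0, 9]])
        return make_table(
            counts, species=["A a", "B b"], labels=["cancer", "control"]
        )

    def test_distinct_single_tips_distance_one(self):
        t = self.two_tip_table()
        d = unweighted_unifrac(t, "('A a':1,'B b':1);")
        assert d.matrix[0, 1] == pytest.approx(1.0)

    def test_identical_presence_sets_distance_zero(self):
        counts = np.array([[4, 2], [1, 9]])
        t = make_table(
            counts, species=["A a", "B b"], labels=["cancer", "control"]
        )
        d = unweighted_unifrac(t, "('A a':1,'B b':1);")
        assert d.matrix[0, 1] == pytest.approx(0.0)

    def test_missing_tip_listed(self):
        t = self.two_tip_table()
        with pytest.raises(ValidationError, match="B b"):
            unweighted_unifrac(t, "('A a':1,'C c':1);")

    def test_four_tip_tree_matches_branch_walk_oracle(self):
        # tree: ((A:1,B:2):0.5,(C:1,D:3):0.25);
        newick = "(('A a':1,'B b':2):0.5,('C c':1,'D d':3):0.25);"
        counts = np.array(
            [
                [5, 0, 2],
                [3, 0, 0],
                [0, 2, 2],
                [0, 4, 0],
            ]
        )
        t = make_table(
            counts,
            species=["A a", "B b", "C c", "D d"],
            labels=["cancer", "cancer", "control"],
        )
        d = unweighted_unifrac(t, newick).matrix
        branches = [
            (1.0, {"A a"}),
            (2.0, {"B b"}),
            (0.5, {"A a", "B b"}),
            (1.0, {"C c"}),
            (3.0, {"D d"}),
            (0.25, {"C c", "D d"}),
        ]
        present = [
            {sp for sp, c in zip(t.species_ids, counts[:, j]) if c > 0}
            for j in range(3)
        ]
        for i in range(3):
            for j in range(3):
                expect = brute_force_unifrac(branches, present[i], present[j])
                assert d[i, j] == pytest.approx(expect), (i, j)


class TestPcoa:
    def test_all_zero_matrix(self):
        dm = DistanceMatrix(["a", "b", "c"], np.zeros((3, 3)))
        res = pcoa(dm)
        assert res.coordinates.shape[1] == 0

    def test_three_equidistant_points(self):
        dm = DistanceMatrix(
            ["a", "b", "c"], np.ones((3, 3)) - np.eye(3)
        )
        res = pcoa(dm)
        pos = res.eigenvalues[res.eigenvalues > 1e-10]
        assert pos.size == 2
        assert pos[0] == pytest.approx(pos[1])
        coords = res.coordinates
        for i in range(3):
            for j in range(i + 1, 3):
                assert np.linalg.norm(coords[i] - coords[j]) == pytest.approx(1.0)

    def test_recovers_planted_euclidean_configuration(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(12, 2))
        D = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        res = pcoa(DistanceMatrix([f"s{i}" for i in range(12)], D))
        coords = res.coordinates[:, :2]
        # Procrustes: optimal rotation/reflection after centering
        A = pts - pts.mean(0)
        B = coords - coords.mean(0)
        U, _, Vt = np.linalg.svd(B.T @ A)
        aligned = B @ (U @ Vt)
        assert np.abs(aligned - A).max() < 1e-8

    def test_agrees_with_reference_implementation(self):
        """Eigenvalues match scikit-bio's PCoA on a random distance matrix."""
        import skbio

        t, _ = simulate_taxa_table(SimulationDesign(n_case=5, n_control=7, seed=9))
        sub = t.select_samples(t.true_sample_mask)
        dm = bray_curtis(sub)
        ours = pcoa(dm)
        ref = skbio.stats.ordination.pcoa(
            skbio.DistanceMatrix(dm.matrix, ids=dm.sample_ids)
        )
        n_pos = ours.coordinates.shape[1]
        np.testing.assert_allclose(
            ours.eigenvalues[:n_pos], ref.eigvals.values[:n_pos], atol=1e-10
        )


class TestDifferentialAbundance:
    def test_cancer_only_species(self):
        rng = np.random.default_rng(5)
        counts = rng.integers(50, 200, size=(4, 8))
        counts[0, 4:] = 0  # species 0 only in the 4 cancer samples
        t = make_table(counts, labels=["cancer"] * 4 + ["control"] * 4)
        da = differential_abundance(t)
        row = da[da.species == t.species_ids[0]].iloc[0]
        assert row.p_value < 0.05
        assert row.mean_percent_control == 0.0
        assert row.prevalence_control == 0.0

    def test_identical_groups_give_p_one(self):
        counts = np.tile(np.array([[10], [30]]), (1, 8))
        t = make_table(counts, labels=["cancer"] * 4 + ["control"] * 4)
        da = differential_abundance(t)
        assert (da.p_value == 1.0).all()

    def test_u_statistic_matches_pair_counting(self):
        rng = np.random.default_rng(6)
        counts = rng.integers(0, 50, size=(3, 10))
        counts[0] += 1  # keep species present
        t = make_table(counts, labels=["cancer"] * 5 + ["control"] * 5)
        da = differential_abundance(t)
        rel = t.relative_abundances()
        y = np.array([lab == "cancer" for lab in t.labels])
        for _, row in da.iterrows():
            i = t.species_ids.index(row.species)
            u = sum(
                1.0 if a > b else 0.5 if a == b else 0.0
                for a in rel[i, y]
                for b in rel[i, ~y]
            )
            assert row.U == pytest.approx(u)


class TestWholeProfile:
    def test_no_global_separation_but_planted_da_species(self):
        """Whole-profile clustering fails to separate cohorts, yet planted
        differential species reach significance."""
        t, truth = simulate_taxa_table(SimulationDesign(seed=2))
        clean, _ = remove_contaminants(t, truth["indicator_species"])
        rare, _ = rarefy(clean, 2700, seed=0)
        sep = profile_separation(rare)
        assert abs(sep["silhouette_vs_labels"]) < 0.15
        da = differential_abundance(rare)
        sig = set(da[da.p_value < 0.05].species)
        assert len(set(truth["differential_species"]) & sig) >= 1
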