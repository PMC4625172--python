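"""Ancestral similarity estimators and multi-way ancestry distances."""

import itertools

import numpy as np
import pytest

from admixvar import (
    LocalAncestryPanel,
    Locus,
    global_ancestry,
    kosman_distance,
    locus_mean_ancestry,
    similarity,
    similarity_centered,
    similarity_gcta,
    similarity_ibs,
    smouse_distance,
)
from admixvar.errors import SimilarityError


def panel_from_matrix(dosages):
    """Panel with one synthetic chromosome and the given (N, M) dosages."""
    dosages = np.asarray(dosages)
    N, M = dosages.shape
    return LocalAncestryPanel(
        individual_ids=[f"i{j}" for j in range(M)],
        loci=[Locus("1", 100 * (i + 1), f"l{i}") for i in range(N)],
        dosages=dosages,
    )


class TestAncestrySummaries:
    def test_all_reference_dosages_give_unit_ancestry(self):
        p = panel_from_matrix(np.full((3, 4), 2))
        assert np.allclose(global_ancestry(p), 1.0)

    def test_individual_mean_over_three_loci(self):
        p = panel_from_matrix(np.array([[0, 2], [1, 2], [2, 2]]))
        assert np.isclose(global_ancestry(p)[0], 0.5)  # (0+1+2)/6

    def test_locus_means(self):
        p = panel_from_matrix(np.array([[2, 2], [0, 1]]))
        assert np.allclose(locus_mean_ancestry(p), [1.0, 0.25])

    def test_mean_exchange_identity(self, small_panel):
        assert np.isclose(
            global_ancestry(small_panel).mean(), locus_mean_ancestry(small_panel).mean()
        )


class TestIBS:
    def test_single_locus_values(self):
        # dosage pairs (2,0) -> 0; (1,2) -> 0.5; identical -> 1
        p = panel_from_matrix(np.array([[2, 0, 1]]))
        A = similarity_ibs(p).values
        assert A[0, 1] == 0.0
        assert A[0, 2] == 0.5 and A[1, 2] == 0.5
        assert np.allclose(np.diag(A), 1.0)

    def test_single_locus_entries_restricted(self, small_panel):
        A = similarity_ibs(small_panel, ("locus", small_panel.loci[5].locus_id))
        assert set(np.unique(A.values)) <= {0.0, 0.5, 1.0}

    def test_multi_locus_average(self):
        # locus 1: (2,0) -> 0; locus 2: (1,1) -> 1; mean 0.5
        p = panel_from_matrix(np.array([[2, 0], [1, 1]]))
        assert np.isclose(similarity_ibs(p).values[0, 1], 0.5)

    def test_entries_in_unit_interval(self, small_panel):
        A = similarity_ibs(small_panel).values
        assert A.min() >= 0.0 and A.max() <= 1.0


class TestCenteredScaled:
    def test_printed_formula_single_locus(self):
        # p=0.5 panel: dosages (2, 0, 1, 1)
        p = panel_from_matrix(np.array([[2, 0, 1, 1]]))
        A = similarity_gcta(p).values
        assert np.isclose(A[0, 1], (2 - 1) * (0 - 1) / 0.5)  # -2
        assert np.isclose(A[0, 0], 1 + (4 - 2 * 2 + 0.5) / 0.5)  # 2
        assert np.isclose(A[2, 2], 1 + (1 - 2 + 0.5) / 0.5)  # 0

    def test_fixed_ancestry_loci_excluded(self):
        d = np.array([[2, 0, 1, 1], [2, 2, 2, 2]])
        A = similarity_gcta(panel_from_matrix(d))
        assert A.n_loci_used == 1

    def test_all_loci_fixed_errors(self):
        with pytest.raises(SimilarityError):
            similarity_gcta(panel_from_matrix(np.full((2, 3), 2)))

    def test_off_diagonal_sum_identity(self, small_panel):
        """Centering kills each locus's row sum, so the total off-diagonal
        sum equals minus the sum of scaled squared deviations."""
        A = similarity_gcta(small_panel)
        D = small_panel.dosages.astype(float)
        p = D.mean(axis=1) / 2
        keep = (p > 0) & (p < 1)
        D, p = D[keep], p[keep]
        w = 2 * p * (1 - p)
        C = D - 2 * p[:, None]
        expected = -np.sum(C**2 / w[:, None]) / keep.sum()
        off_sum = A.values.sum() - np.sum(np.diag(A.values))
        assert np.isclose(off_sum, expected, atol=1e-8)


class TestCentered:
    def test_single_locus_value(self):
        p = panel_from_matrix(np.array([[2, 0, 1, 1]]))
        assert np.isclose(similarity_centered(p).values[0, 1], -1.0)

    def test_row_sums_vanish(self, small_panel):
        A = similarity_centered(small_panel)
        M = A.n_individuals
        assert np.abs(A.values.sum(axis=1)).max() < 1e-8 * M

    def test_uniform_dosage_panel_gives_zero_matrix(self):
        p = panel_from_matrix(np.array([[1, 1, 1], [2, 2, 2]]))
        assert np.allclose(similarity_centered(p).values, 0.0)

    def test_monomorphic_locus_contributes_nothing(self):
        base = np.array([[2, 0, 1, 1]])
        with_fixed = np.vstack([base, np.full((1, 4), 2)])
        A1 = similarity_centered(panel_from_matrix(base)).values
        A2 = similarity_centered(panel_from_matrix(with_fixed)).values
        assert np.allclose(A2, A1 / 2)  # same numerators over twice the loci

    def test_half_frequency_panel_relates_centered_and_scaled(self):
        """When every p_i = 0.5 the scale 2p(1-p) = 0.5, so centered equals
        half the scaled off-diagonals exactly."""
        rng = np.random.default_rng(0)
        d = rng.integers(0, 3, size=(6, 4))
        d = np.hstack([d, 2 - d])  # mirrored individuals force p_i = 0.5
        p = panel_from_matrix(d)
        assert np.allclose(d.mean(axis=1) / 2, 0.5)
        Ac = similarity_centered(p).values
        As = similarity_gcta(p).values
        off = ~np.eye(Ac.shape[0], dtype=bool)
        assert np.allclose(Ac[off], 0.5 * As[off])


class TestEstimatorProperties:
    @pytest.mark.parametrize("estimator", ["ibs", "centered_scaled", "centered"])
    def test_symmetry_and_permutation_equivariance(self, small_panel, estimator):
        A = similarity(small_panel, estimator).values
        assert np.abs(A - A.T).max() < 1e-12
        rng = np.random.default_rng(1)
        perm = rng.permutation(small_panel.n_individuals)
        Ap = similarity(small_panel.subset_individuals(perm), estimator).values
        assert np.allclose(Ap, A[np.ix_(perm, perm)], atol=1e-10)

    @pytest.mark.parametrize("estimator", ["ibs", "centered_scaled", "centered"])
    def test_chromosome_subset_uses_only_its_loci(self, small_panel, estimator):
        chrom = small_panel.chromosomes[0]
        A = similarity(small_panel, estimator, ("chromosome", chrom))
        assert A.n_loci_used <= len(small_panel.chromosome_indices(chrom))
        assert A.locus_subset == f"chromosome:{chrom}"

    def test_empty_subset_rejected(self, small_panel):
        with pytest.raises(SimilarityError):
            similarity(small_panel, "centered", np.array([], dtype=int))


KOSMAN_TABLE = {
    ("AA", "AB"): 1, ("AA", "AC"): 1, ("AA", "BB"): 2, ("AA", "BC"): 2, ("AA", "CC"): 2,
    ("AB", "AC"): 1, ("AB", "BB"): 1, ("AB", "BC"): 1, ("AB", "CC"): 2,
    ("AC", "BB"): 2, ("AC", "BC"): 1, ("AC", "CC"): 1,
    ("BB", "BC"): 1, ("BB", "CC"): 2, ("BC", "CC"): 1,
}

SMOUSE_VALUES = {
    ("AA", "AB"): 1, ("AA", "AC"): 1, ("AA", "BB"): 4, ("AA", "BC"): 3, ("AA", "CC"): 4,
    ("AB", "AC"): 1, ("AB", "BB"): 1, ("AB", "BC"): 1, ("AB", "CC"): 3,
    ("AC", "BB"): 3, ("AC", "BC"): 1, ("AC", "CC"): 1,
    ("BB", "BC"): 1, ("BB", "CC"): 4, ("BC", "CC"): 1,
}


class TestAncestryDistances:
    @pytest.mark.parametrize("pair,expected", sorted(KOSMAN_TABLE.items()))
    def test_hamming_distance_table(self, pair, expected):
        assert kosman_distance(*pair) == expected

    @pytest.mark.parametrize("g", ["AA", "AB", "AC", "BB", "BC", "CC"])
    def test_self_distance_zero(self, g):
        assert kosman_distance(g, g) == 0
        assert smouse_distance(g, g) == 0

    @pytest.mark.parametrize("pair,expected", sorted(SMOUSE_VALUES.items()))
    def test_triangle_embedding_distances(self, pair, expected):
        assert np.isclose(smouse_distance(*pair), expected)

    def test_order_insensitive(self):
        for g1, g2 in itertools.combinations(["AA", "AB", "BC"], 2):
            assert kosman_distance(g1, g2) == kosman_distance(g2[::-1], g1[::-1])
            assert smouse_distance(g1, g2) == smouse_distance(g2, g1)

    def test_alphabet_mismatch_rejected(self):
        with pytest.raises(ValueError):
            kosman_distance("AD", "AA")
        with pytest.raises(ValueError):
            smouse_distance("AA", "AB", alphabet=("A", "B"))
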