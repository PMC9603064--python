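import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gxetools.errors import InvalidInputError
from gxetools.expression import TwoWayMeans
from gxetools.gge import (
    GgeResult,
    distance_from_center,
    gge_decompose,
    ideal_point_ranking,
    mean_vs_stability,
    ranking_table,
    tissue_relationships,
    which_won_where,
)

from oracles import gge_variance_shares_oracle


def means_of(matrix, genes=None, tissues=None):
    matrix = np.asarray(matrix, dtype=float)
    g, e = matrix.shape
    return TwoWayMeans(
        genes=genes or [f"g{i}" for i in range(g)],
        tissues=tissues or [f"e{j}" for j in range(e)],
        means=matrix, replicates=1, temperature="T",
    )


def random_result(seed, g=4, e=10):
    rng = np.random.default_rng(seed)
    return gge_decompose(means_of(rng.normal(size=(g, e))))


class TestDecompose:
    def test_columns_equal_up_to_offsets_give_zero(self):
        base = np.array([1.0, -0.5, 0.25, -0.75])
        matrix = np.stack([base + c for c in (0.0, 2.0, -1.0, 5.0)], axis=1)
        res = gge_decompose(means_of(matrix))
        # centering removes the column offsets AND the shared gene profile?
        # no: the shared profile is genotype signal and must survive
        assert res.singular_values[0] > 0
        assert res.singular_values[1] == pytest.approx(0.0, abs=1e-12)

    def test_constant_matrix_degenerates_to_zero_scores(self):
        res = gge_decompose(means_of(np.full((3, 4), 2.5)))
        assert np.allclose(res.singular_values, 0.0)
        assert np.allclose(res.gene_scores, 0.0)

    def test_rank_one_pc1_explains_everything(self):
        u = np.array([3.0, -1.0, -1.0, -1.0])
        v = np.array([1.0, 2.0, -1.5, 0.5, -2.0])
        res = gge_decompose(means_of(np.outer(u, v)))
        assert res.variance_explained[0] == pytest.approx(100.0)

    @pytest.mark.parametrize("seed", range(6))
    def test_variance_shares_match_eigendecomposition_oracle(self, seed):
        rng = np.random.default_rng(seed)
        matrix = rng.normal(size=(4, 10))
        res = gge_decompose(means_of(matrix))
        shares = gge_variance_shares_oracle(matrix)
        assert np.allclose(res.variance_explained / 100.0, shares[:3], atol=1e-10)

    @pytest.mark.parametrize("seed", range(6))
    def test_reconstruction_from_all_axes(self, seed):
        rng = np.random.default_rng(seed)
        matrix = rng.normal(size=(4, 6))
        res = gge_decompose(means_of(matrix))
        rec = res.gene_scores @ res.tissue_scores.T
        assert np.allclose(rec, res.centered, atol=1e-10)

    def test_gene_scores_sum_to_zero_per_axis(self):
        res = random_result(3)
        assert np.allclose(res.gene_scores.sum(axis=0), 0.0, atol=1e-10)

    @pytest.mark.parametrize("partition", ["genotype-focused", "environment-focused"])
    def test_inner_products_independent_of_partition(self, partition):
        rng = np.random.default_rng(8)
        matrix = rng.normal(size=(4, 10))
        sym = gge_decompose(means_of(matrix), partition="symmetric")
        other = gge_decompose(means_of(matrix), partition=partition)
        assert np.allclose(sym.gene_scores @ sym.tissue_scores.T,
                           other.gene_scores @ other.tissue_scores.T, atol=1e-10)

    def test_unknown_partition_rejected(self):
        with pytest.raises(InvalidInputError):
            gge_decompose(means_of(np.zeros((3, 3))), partition="banana")


class TestDistance:
    def test_origin(self):
        assert distance_from_center((0.0, 0.0, 0.0)) == 0.0

    def test_euclidean_norm(self):
        assert distance_from_center((3.0, 4.0, 12.0)) == pytest.approx(13.0)

    def test_wrong_arity_rejected(self):
        with pytest.raises(InvalidInputError):
            distance_from_center((1.0, 2.0))


class TestTissueRelationships:
    def test_identical_and_orthogonal_vectors(self):
        gene_scores = np.zeros((3, 3))
        tissue_scores = np.array([
            [1.0, 0.0, 0.0],
            [2.0, 0.0, 0.0],   # same direction as first
            [0.0, 1.0, 0.0],   # orthogonal to both
        ])
        res = GgeResult(genes=["a", "b", "c"], tissues=["x", "y", "z"],
                        gene_scores=gene_scores, tissue_scores=tissue_scores)
        rel = tissue_relationships(res)
        assert rel.angle_deg.loc["x", "y"] == pytest.approx(0.0, abs=1e-9)
        assert rel.cosine.loc["x", "y"] == pytest.approx(1.0)
        assert rel.angle_deg.loc["x", "z"] == pytest.approx(90.0)
        assert rel.vector_length["y"] == pytest.approx(2.0)

    def test_cosine_grid_symmetric_unit_diagonal(self):
        rel = tissue_relationships(random_result(5))
        c = rel.cosine.to_numpy()
        assert np.allclose(c, c.T, atol=1e-12)
        assert np.allclose(np.diag(c), 1.0)

    def test_zero_length_vector_flagged_not_raised(self):
        tissue_scores = np.array([[0.0, 0.0, 1.0], [1.0, 1.0, 0.0]])
        res = GgeResult(genes=["a", "b"], tissues=["x", "y"],
                        gene_scores=np.zeros((2, 3)), tissue_scores=tissue_scores)
        rel = tissue_relationships(res)
        assert rel.degenerate == ["x"]
        assert np.isnan(rel.angle_deg.loc["x", "y"])


class TestWhichWonWhere:
    def test_rank_one_single_occupied_sector(self):
        u = np.array([3.0, 1.0, -1.0, -3.0])
        v = np.abs(np.random.default_rng(0).normal(size=6)) + 0.1  # one direction
        res = gge_decompose(means_of(np.outer(u, v)))
        sa = which_won_where(res)
        assert sa.degenerate  # collinear gene scores on one axis
        winners = set(sa.tissue_winner.values())
        assert winners == {"g0"}  # largest PC1 score wins everywhere

    @pytest.mark.parametrize("seed", range(5))
    def test_winner_is_argmax_of_centered_means_on_rank2_data(self, seed):
        """On exact rank-2 data the planar biplot is lossless: the sector
        winner must equal the per-tissue argmax of centered cell means."""
        rng = np.random.default_rng(seed)
        u = rng.normal(size=(4, 2))
        v = rng.normal(size=(10, 2))
        matrix = u @ v.T  # rank 2, then add column offsets
        matrix += rng.normal(size=(1, 10))
        res = gge_decompose(means_of(matrix))
        sa = which_won_where(res)
        centered = matrix - matrix.mean(axis=0, keepdims=True)
        for j, tissue in enumerate(res.tissues):
            expected = res.genes[int(np.argmax(centered[:, j]))]
            assert sa.tissue_winner[tissue] == expected

    def test_every_tissue_in_exactly_one_sector(self):
        sa = which_won_where(random_result(9))
        assigned = [t for members in sa.sectors.values() for t in members]
        assert sorted(assigned) == sorted(sa.tissue_winner.keys())
        for winner in sa.sectors:
            assert winner in sa.hull


class TestMeanStability:
    def test_symmetric_two_gene_case(self):
        gene_scores = np.array([[1.0, 1.0, 0.0], [-1.0, -1.0, 0.0], [0.0, 0.0, 0.0]])
        tissue_scores = np.array([[1.0, 0.0, 0.0], [1.0, 0.2, 0.0]])
        res = GgeResult(genes=["a", "b", "c"], tissues=["x", "y"],
                        gene_scores=gene_scores, tissue_scores=tissue_scores)
        ms = mean_vs_stability(res)
        assert ms.mean_projection["a"] == pytest.approx(-ms.mean_projection["b"])
        assert ms.instability["a"] == pytest.approx(ms.instability["b"])

    @pytest.mark.parametrize("seed", range(5))
    def test_trigonometric_recomputation(self, seed):
        res = random_result(seed)
        ms = mean_vs_stability(res)
        axis = res.tissue_scores[:, :2].mean(axis=0)
        theta = np.arctan2(axis[1], axis[0])
        for gene, (x, y) in zip(res.genes, res.gene_scores[:, :2]):
            r = np.hypot(x, y)
            phi = np.arctan2(y, x)
            assert ms.mean_projection[gene] == pytest.approx(
                r * np.cos(phi - theta), abs=1e-10)
            assert ms.instability[gene] == pytest.approx(
                abs(r * np.sin(phi - theta)), abs=1e-10)

    def test_zero_mean_tissue_vector_rejected(self):
        tissue_scores = np.array([[1.0, 0.0, 0.0], [-1.0, 0.0, 0.0]])
        res = GgeResult(genes=["a", "b"], tissues=["x", "y"],
                        gene_scores=np.zeros((2, 3)), tissue_scores=tissue_scores)
        with pytest.raises(InvalidInputError):
            mean_vs_stability(res)


def rotate_result(res, theta):
    c, s = np.cos(theta), np.sin(theta)
    rot = np.array([[c, -s], [s, c]])
    gene = res.gene_scores.copy()
    tissue = res.tissue_scores.copy()
    gene[:, :2] = gene[:, :2] @ rot.T
    tissue[:, :2] = tissue[:, :2] @ rot.T
    return GgeResult(genes=res.genes, tissues=res.tissues,
                     gene_scores=gene, tissue_scores=tissue)


class TestIdealPoint:
    def test_gene_at_ideal_point_ranked_first_with_zero_distance(self):
        tissue_scores = np.array([[2.0, 0.0, 0.0], [1.0, 0.0, 0.0]])
        gene_scores = np.array([[3.0, 0.0, 0.0], [1.0, 1.0, 0.0], [-4.0, -1.0, 0.0]])
        res = GgeResult(genes=["best", "mid", "worst"], tissues=["x", "y"],
                        gene_scores=gene_scores, tissue_scores=tissue_scores)
        ip = ideal_point_ranking(res)
        assert ip.ranking[0] == "best"
        assert ip.distance["best"] == pytest.approx(0.0, abs=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(seed=st.integers(0, 1000), theta=st.floats(-np.pi, np.pi))
    def test_ranking_invariant_under_rotation(self, seed, theta):
        res = random_result(seed)
        assert (ideal_point_ranking(res).ranking
                == ideal_point_ranking(rotate_result(res, theta)).ranking)

    @pytest.mark.parametrize("flip_axis", [0, 1])
    def test_rankings_invariant_under_axis_sign_flip(self, flip_axis):
        res = random_result(12)
        flipped_gene = res.gene_scores.copy()
        flipped_tissue = res.tissue_scores.copy()
        flipped_gene[:, flip_axis] *= -1
        flipped_tissue[:, flip_axis] *= -1
        flipped = GgeResult(genes=res.genes, tissues=res.tissues,
                            gene_scores=flipped_gene, tissue_scores=flipped_tissue)
        assert mean_vs_stability(res).ranking_high == \
            mean_vs_stability(flipped).ranking_high
        assert mean_vs_stability(res).ranking_stable == \
            mean_vs_stability(flipped).ranking_stable
        assert ideal_point_ranking(res).ranking == ideal_point_ranking(flipped).ranking


class TestRankingTable:
    def test_each_ordering_is_a_permutation(self):
        results = {"14": random_result(1), "20": random_result(2)}
        table = ranking_table(results)
        for (temp, crit), grp in table.groupby(["temperature", "criterion"]):
            assert sorted(grp["gene"]) == sorted(results[temp].genes)
            assert sorted(grp["rank"]) == [1, 2, 3, 4]
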