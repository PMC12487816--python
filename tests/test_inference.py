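import math

import numpy as np
import pandas as pd
import pytest

from recalde import inference
from oracle_utils import (
    oracle_infer_matrix,
    ols_normal_equations,
    spearman_formula,
)


def matrix(rows, genes=None, tissues=None):
    genes = genes or [f"g{i+1}" for i in range(len(rows))]
    tissues = tissues or [f"t{j+1}" for j in range(len(rows[0]))]
    return pd.DataFrame(rows, index=genes, columns=tissues, dtype=float)


class TestPseudocount:
    def test_min_positive_added(self):
        e = matrix([[0.0, 2.0], [5.0, 1.0]])
        out = inference.apply_pseudocount(e)
        np.testing.assert_array_equal(out.to_numpy(), [[1.0, 3.0], [6.0, 2.0]])

    def test_fractional_minimum(self):
        e = matrix([[0.5, 2.0], [5.0, 1.0]])
        assert inference.apply_pseudocount(e).iat[0, 0] == 1.0

    def test_missing_cells_stay_missing(self):
        e = matrix([[np.nan, 2.0], [5.0, 1.0]])
        out = inference.apply_pseudocount(e)
        assert pd.isna(out.iat[0, 0]) and out.iat[0, 1] == 3.0

    def test_all_zero_matrix_errors(self):
        with pytest.raises(ValueError):
            inference.apply_pseudocount(matrix([[0.0, 0.0]]))


class TestExpressionVarianceFit:
    def test_collinear_points_recovered_exactly(self):
        v = {"g1": 0.01, "g2": 0.04, "g3": 0.16}
        e = {g: math.exp(2 + 0.5 * math.log(val)) for g, val in v.items()}
        fit = inference.fit_expression_variance_model(e, v, "t")
        assert fit.beta0 == pytest.approx(2.0, abs=1e-12)
        assert fit.beta1 == pytest.approx(0.5, abs=1e-12)

    def test_constant_expression_gives_zero_slope(self):
        v = {"g1": 0.01, "g2": 0.04, "g3": 0.16}
        e = {g: 7.0 for g in v}
        fit = inference.fit_expression_variance_model(e, v, "t")
        assert fit.beta1 == pytest.approx(0.0, abs=1e-12)
        assert fit.beta0 == pytest.approx(math.log(7.0), abs=1e-12)

    def test_noisy_fit_matches_normal_equations(self):
        rng = np.random.default_rng(4)
        log_v = rng.normal(-4, 1, size=50)
        log_e = 2.0 - 0.5 * log_v + rng.normal(0, 0.3, size=50)
        genes = [f"g{i}" for i in range(50)]
        fit = inference.fit_expression_variance_model(
            dict(zip(genes, np.exp(log_e))), dict(zip(genes, np.exp(log_v))), "t"
        )
        b0, b1 = ols_normal_equations(log_v, log_e)
        assert fit.beta0 == pytest.approx(b0, abs=1e-10)
        assert fit.beta1 == pytest.approx(b1, abs=1e-10)

    def test_too_few_shared_genes_errors(self):
        with pytest.raises(ValueError):
            inference.fit_expression_variance_model({"g1": 1.0}, {"g1": 0.01}, "t")


class TestMeanExpressionAdjustment:
    def make_fits(self, tissues, beta1):
        return {t: inference.TissueFit(t, 0.0, beta1, 10) for t in tissues}

    @pytest.mark.parametrize(
        "e_row,beta1,v,expected",
        [
            # expression at the cross-tissue mean: no change
            ([10.0, 10.0], 0.5, 0.02, 0.02),
            # mean/E = 4, beta1 = 0.5 -> factor 2
            ([4.0, 28.0], 0.5, 0.02, 0.04),
            # mean/E = 2, beta1 = -1 -> factor 0.5
            ([5.0, 15.0], -1.0, 0.02, 0.01),
        ],
    )
    def test_adjustment_factor(self, e_row, beta1, v, expected):
        vmat = matrix([[v, np.nan]])
        emat = matrix([e_row])
        fits = self.make_fits(vmat.columns, beta1)
        out = inference.adjust_to_mean_expression(vmat, emat, fits)
        assert out.iat[0, 0] == pytest.approx(expected, abs=1e-14)

    def test_inverse_composition_is_identity(self):
        rng = np.random.default_rng(8)
        vmat = matrix(np.exp(rng.normal(-4, 1, size=(5, 3))))
        emat = matrix(np.exp(rng.normal(2, 1, size=(5, 3))))
        fits = self.make_fits(vmat.columns, -0.7)
        e_bar = inference.apply_pseudocount(emat)
        v_hat = inference.adjust_to_mean_expression(vmat, e_bar, fits)
        for g in vmat.index:
            for t in vmat.columns:
                back = inference.readjust_to_tissue_expression(
                    v_hat.at[g, t], g, t, e_bar, fits
                )
                assert back == pytest.approx(vmat.at[g, t], abs=1e-12)


class TestTissueSimilarity:
    def test_identical_and_reversed_columns(self):
        col = [0.01, 0.02, 0.05, 0.04]
        # 1/x is a strictly decreasing transform: exact rank reversal
        sim = inference.tissue_similarity(matrix([[a, a, 1.0 / a] for a in col]))
        assert sim.at["t1", "t2"] == pytest.approx(1.0)
        assert sim.at["t1", "t3"] == pytest.approx(-1.0)
        assert np.allclose(np.diag(sim.to_numpy()), 1.0)

    def test_matches_rank_pearson_oracle(self):
        rng = np.random.default_rng(9)
        v = matrix(np.exp(rng.normal(-4, 1, size=(10, 2))))
        sim = inference.tissue_similarity(v)
        expected = spearman_formula(v["t1"], v["t2"])
        assert sim.at["t1", "t2"] == pytest.approx(expected, abs=1e-12)

    def test_insufficient_overlap_is_missing(self):
        v = matrix([[0.01, np.nan], [0.02, np.nan], [0.03, 0.01], [0.04, 0.02]])
        sim = inference.tissue_similarity(v)
        assert pd.isna(sim.at["t1", "t2"])


class TestNeighborSelection:
    def make_sim(self, target, rhos):
        tissues = [target] + list(rhos)
        sim = pd.DataFrame(1.0, index=tissues, columns=tissues)
        for t, r in rhos.items():
            sim.at[target, t] = sim.at[t, target] = r
        return sim

    def test_fewer_than_k_returns_all(self):
        v = matrix([[0.01, 0.02, 0.03, np.nan, np.nan]], tissues=list("abcde"))
        sim = self.make_sim("a", {"b": 0.9, "c": 0.8, "d": 0.7, "e": 0.6})
        assert inference.select_similar_tissues("g1", "a", v, sim, k=5) == ["b", "c"]

    def test_tie_broken_lexicographically(self):
        v = matrix([[0.01, 0.02, 0.03]], tissues=["t", "z", "y"])
        sim = self.make_sim("t", {"z": 0.5, "y": 0.5})
        assert inference.select_similar_tissues("g1", "t", v, sim, k=1) == ["y"]

    def test_top_k_matches_exhaustive_sort(self):
        rng = np.random.default_rng(12)
        tissues = ["t"] + [f"s{i}" for i in range(7)]
        rhos = {f"s{i}": float(r) for i, r in enumerate(rng.uniform(0.1, 0.9, 7))}
        v = matrix([np.full(8, 0.01)], tissues=tissues)
        sim = self.make_sim("t", rhos)
        expected = [s for s, _ in sorted(rhos.items(), key=lambda sr: (-sr[1], sr[0]))][:5]
        assert inference.select_similar_tissues("g1", "t", v, sim, k=5) == expected

    def test_negative_similarity_never_used(self):
        v = matrix([[0.01, 0.02, 0.03]], tissues=["t", "u", "w"])
        sim = self.make_sim("t", {"u": -0.9, "w": 0.2})
        assert inference.select_similar_tissues("g1", "t", v, sim) == ["w"]


class TestWeightedMean:
    @pytest.mark.parametrize(
        "rhos,vals,expected",
        [
            ({"s1": 0.5}, {"s1": 0.03}, 0.03),
            ({"s1": 0.5, "s2": 0.5}, {"s1": 0.01, "s2": 0.03}, 0.02),
            ({"s1": 0.8, "s2": 0.2}, {"s1": 0.01, "s2": 0.06}, 0.02),
        ],
    )
    def test_weighted_mean(self, rhos, vals, expected):
        tissues = ["t"] + list(rhos)
        sim = pd.DataFrame(1.0, index=tissues, columns=tissues)
        for s, r in rhos.items():
            sim.at["t", s] = r
        v_hat = matrix([[np.nan] + [vals[s] for s in rhos]], tissues=tissues)
        got = inference.infer_weighted_mean("g1", "t", list(rhos), v_hat, sim)
        assert got == pytest.approx(expected, abs=1e-15)

    def test_mean_within_neighbor_hull(self):
        rng = np.random.default_rng(13)
        tissues = ["t"] + [f"s{i}" for i in range(5)]
        sim = pd.DataFrame(1.0, index=tissues, columns=tissues)
        vals = {}
        for s in tissues[1:]:
            sim.at["t", s] = rng.uniform(0.1, 1.0)
            vals[s] = float(np.exp(rng.normal(-4, 1)))
        v_hat = matrix([[np.nan] + [vals[s] for s in tissues[1:]]], tissues=tissues)
        got = inference.infer_weighted_mean("g1", "t", tissues[1:], v_hat, sim)
        assert min(vals.values()) <= got <= max(vals.values())


class TestInferAll:
    def test_uniform_gene_is_reproduced_identically(self):
        # identical V everywhere and uniform expression: weighted mean of
        # equal values with identity adjustments returns the same value
        v = matrix(np.full((5, 4), np.nan))
        for g in range(5):
            for t in range(4):
                v.iat[g, t] = [0.01, 0.02, 0.05, 0.03, 0.08][g]
        v.iat[0, 3] = np.nan
        e = matrix(np.full((5, 4), 10.0))
        e.iloc[:, 0] *= 1.5  # keep log(V) non-constant per tissue fitable
        result = inference.infer_all(v, e)
        assert result.v_tilde.iat[0, 3] == pytest.approx(0.01, rel=1e-12)
        assert result.v_hi.iat[0, 3] == pytest.approx(0.01, rel=1e-12)

    def test_measured_values_take_precedence(self, tiny_matrices):
        vg, tpm = tiny_matrices
        result = inference.infer_all(vg, tpm)
        present = vg.notna()
        assert result.v_hi[present].equals(vg[present])

    def test_constant_expression_gene_gets_weighted_raw_mean(self):
        rng = np.random.default_rng(21)
        n_g, n_t = 30, 5
        base = rng.normal(-4, 1, size=(n_g, 1))  # shared gene effect -> positive similarity
        v = matrix(np.exp(base + rng.normal(0, 0.3, size=(n_g, n_t))))
        e = matrix(np.exp(rng.normal(2, 0.5, size=(n_g, n_t))))
        e.iloc[0] = 20.0  # constant across tissues: Eq-adjustments are identities
        v.iat[0, 0] = np.nan
        result = inference.infer_all(v, e)
        target = result.v_tilde.columns[0]
        neighbors = result.neighbor_sets[(v.index[0], target)]
        rho = np.array([result.similarity.at[target, s] for s in neighbors])
        raw = np.array([v.at[v.index[0], s] for s in neighbors])
        expected = (rho * raw).sum() / rho.sum()
        assert result.v_tilde.iat[0, 0] == pytest.approx(expected, rel=1e-12)

    def test_matches_per_cell_oracle(self, small_truth):
        """Full pipeline equals an independent straight-line per-cell
        re-computation on a 200-gene x 6-tissue instance."""
        v, e = small_truth.vg_observed, small_truth.expression
        result = inference.infer_all(v, e)
        expected = oracle_infer_matrix(v, e, k=5)
        got = {
            (g, t): result.v_tilde.at[g, t]
            for g in v.index
            for t in v.columns
            if pd.notna(result.v_tilde.at[g, t])
        }
        assert set(got) == set(expected)
        for cell, val in expected.items():
            assert got[cell] == pytest.approx(val, abs=1e-10, rel=1e-10), cell

    def test_deterministic(self, tiny_matrices):
        vg, tpm = tiny_matrices
        a = inference.infer_all(vg, tpm)
        b = inference.infer_all(vg, tpm)
        assert a.v_hi.equals(b.v_hi) and a.v_tilde.equals(b.v_tilde)


class TestHarmonicMean:
    def test_arithmetic_examples(self):
        v = matrix([[0.01, 0.02], [0.03, 0.03]])
        w_equal = matrix([[1.0, 1.0], [1.0, 1.0]])
        out = inference.weighted_harmonic_mean_vg(v, w_equal)
        assert out["g1"] == pytest.approx(2 / 150, abs=1e-15)
        assert out["g2"] == pytest.approx(0.03, abs=1e-15)
        w_31 = matrix([[3.0, 1.0], [1.0, 1.0]])
        out31 = inference.weighted_harmonic_mean_vg(v, w_31)
        assert out31["g1"] == pytest.approx(4 / 350, abs=1e-15)

    def test_bounded_by_min_and_max(self, default_truth):
        mean_vg = inference.weighted_harmonic_mean_vg(
            default_truth.vg_true, default_truth.expression
        )
        lo = default_truth.vg_true.min(axis=1)
        hi = default_truth.vg_true.max(axis=1)
        assert (mean_vg >= lo[mean_vg.index] - 1e-15).all()
        assert (mean_vg <= hi[mean_vg.index] + 1e-15).all()

    def test_gene_with_all_zero_weights_omitted(self):
        v = matrix([[0.01, 0.02], [0.03, 0.03]])
        w = matrix([[0.0, 0.0], [1.0, 1.0]])
        out = inference.weighted_harmonic_mean_vg(v, w)
        assert list(out.index) == ["g2"]


class TestLowestTissue:
    def test_minimum_tie_and_single(self):
        v = matrix([[0.01, 0.02], [0.01, 0.01], [np.nan, 0.05]])
        assert inference.lowest_vg_tissue(v, "g1") == "t1"
        assert inference.lowest_vg_tissue(v, "g2") == "t1"  # lexicographic tie
        assert inference.lowest_vg_tissue(v, "g3") == "t2"

    def test_fully_missing_gene_errors(self):
        v = matrix([[np.nan, np.nan]])
        with pytest.raises(ValueError):
            inference.lowest_vg_tissue(v, "g1")


class TestRecovery:
    def test_inference_beats_nearest_tissue_copy(self, default_truth):
        """Held-out cells are recovered well, and better than copying the
        most similar tissue's raw value."""
        result = inference.evaluate_recovery(
            default_truth.vg_true,
            default_truth.vg_observed,
            default_truth.expression,
            holdout_fraction=0.2,
            seed=1,
        )
        assert result.spearman_inferred >= 0.7
        assert result.spearman_inferred > result.spearman_baseline
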