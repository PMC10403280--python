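import numpy as np
import pandas as pd
import pytest

from coevoscreen.coupling_analysis import (
    auto_alpha,
    covariance_index_map,
    empirical_covariance,
    glasso_objective,
    graphical_lasso,
    mutual_information,
    pair_frequencies,
    pdb_pair_distances,
    position_coupling_scores,
    project_l1_ball,
    structure_comparison,
)
from oracles import (
    diagonal_glasso_closed_form,
    frankwolfe_glasso,
    suboptimality_certificate,
)


def freq_table(rows):
    return pd.DataFrame(rows, columns=["seq_a", "seq_b", "count"])


class TestPairFrequencies:
    def test_raw_ratios_without_pseudocount(self):
        fr = pair_frequencies(freq_table([("FL", "V", 3), ("LL", "V", 1)]))
        np.testing.assert_allclose(fr.single[0], [0.75, 0.25])  # F, L at A1
        np.testing.assert_allclose(fr.single[1], [1.0])  # L at A2
        np.testing.assert_allclose(fr.pairwise[(0, 1)].ravel(), [0.75, 0.25])

    def test_tables_sum_to_one_and_marginals_consistent(self):
        fr = pair_frequencies(
            freq_table([("FLI", "VF", 3), ("LLI", "VF", 2), ("ILF", "FV", 7)])
        )
        for f in fr.single:
            assert f.sum() == pytest.approx(1.0)
        for (i, j), fij in fr.pairwise.items():
            assert fij.sum() == pytest.approx(1.0)
            np.testing.assert_allclose(fij.sum(axis=1), fr.single[i], atol=1e-9)
            np.testing.assert_allclose(fij.sum(axis=0), fr.single[j], atol=1e-9)

    def test_count_vs_unique_weighting_divergence(self):
        rows = [("FF", "V", 99), ("FL", "V", 1), ("LF", "V", 1), ("LL", "V", 1)]
        count_w = pair_frequencies(freq_table(rows), weighting="count")
        unique_w = pair_frequencies(freq_table(rows), weighting="unique")
        assert count_w.single[0][0] == pytest.approx(100 / 102)
        assert unique_w.single[0][0] == pytest.approx(0.5)

    def test_pseudocount_mixing_keeps_marginal_consistency(self):
        fr = pair_frequencies(freq_table([("FL", "V", 3)]), pseudocount=0.5)
        for (i, j), fij in fr.pairwise.items():
            assert fij.sum() == pytest.approx(1.0)
            np.testing.assert_allclose(fij.sum(axis=1), fr.single[i], atol=1e-9)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            pair_frequencies(freq_table([]))


class TestMutualInformation:
    def test_independent_positions_zero(self):
        # joint factorizes: counts proportional to product of marginals
        rows = [("FF", "V", 6), ("FL", "V", 2), ("LF", "V", 3), ("LL", "V", 1)]
        mi = mutual_information(pair_frequencies(freq_table(rows)))
        assert mi[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_perfect_correlation_ln2(self):
        rows = [("FF", "V", 1), ("LL", "V", 1)]
        mi = mutual_information(pair_frequencies(freq_table(rows)))
        assert mi[0, 1] == pytest.approx(np.log(2))

    def test_symmetric_and_nonnegative(self):
        rows = [("FLI", "VF", 3), ("LLI", "FV", 2), ("ILF", "FV", 7),
                ("FLF", "VV", 1)]
        mi = mutual_information(pair_frequencies(freq_table(rows)))
        np.testing.assert_allclose(mi, mi.T)
        assert (mi >= 0).all()


class TestEmpiricalCovariance:
    def test_entry_arithmetic(self):
        # f(F_1)=f(F_2)=0.5, joint f(F_1,F_2)=0.5 -> covariance 0.25
        rows = [("FF", "V", 1), ("LL", "V", 1)]
        fr = pair_frequencies(freq_table(rows))
        s = empirical_covariance(fr)
        imap = covariance_index_map(fr)
        i = imap.index((0, "F"))
        j = imap.index((1, "F"))
        assert s[i, j] == pytest.approx(0.25)

    def test_independent_positions_zero_interblock(self):
        rows = [("FF", "V", 6), ("FL", "V", 2), ("LF", "V", 3), ("LL", "V", 1)]
        fr = pair_frequencies(freq_table(rows))
        s = empirical_covariance(fr)
        np.testing.assert_allclose(s[:2, 2:4], 0.0, atol=1e-12)

    def test_symmetric_with_simplex_diagonal_blocks(self):
        rows = [("FLI", "VF", 3), ("LLI", "FV", 2), ("ILF", "FV", 7)]
        fr = pair_frequencies(freq_table(rows))
        s = empirical_covariance(fr)
        np.testing.assert_allclose(s, s.T, atol=1e-12)
        # each diagonal block has row sums zero (one-hot simplex)
        q0 = len(fr.alphabets[0])
        np.testing.assert_allclose(s[:q0, :q0].sum(axis=1), 0.0, atol=1e-12)


class TestL1Projection:
    def test_inside_ball_unchanged(self):
        m = np.array([[0.1, -0.2], [-0.2, 0.3]])
        np.testing.assert_array_equal(project_l1_ball(m, 1.0), m)

    def test_projection_hits_budget_and_shrinks(self):
        rng = np.random.default_rng(0)
        m = rng.normal(size=(5, 5))
        out = project_l1_ball(m, 2.0)
        assert np.abs(out).sum() == pytest.approx(2.0, rel=1e-9)
        assert (np.sign(out) * np.sign(m) >= 0).all()


class TestGraphicalLasso:
    def test_1d_closed_form(self):
        # min(1/S, alpha): budget inactive
        theta = graphical_lasso(np.array([[2.0]]), alpha=1.0, ridge=0.0)
        assert theta[0, 0] == pytest.approx(0.5, abs=1e-6)
        # budget active
        theta = graphical_lasso(np.array([[0.25]]), alpha=1.0, ridge=0.0)
        assert theta[0, 0] == pytest.approx(1.0, abs=1e-6)

    def test_identity_covariance_splits_budget(self):
        theta = graphical_lasso(np.eye(2), alpha=1.0, ridge=0.0)
        np.testing.assert_allclose(theta, 0.5 * np.eye(2), atol=1e-6)
        assert glasso_objective(theta, np.eye(2)) == pytest.approx(
            2 * (np.log(0.5) - 0.5), abs=1e-5
        )

    def test_diagonal_covariance_matches_waterfilling(self):
        rng = np.random.default_rng(1)
        s_diag = rng.uniform(0.2, 3.0, size=6)
        expected = diagonal_glasso_closed_form(s_diag, alpha=4.0)
        theta = graphical_lasso(np.diag(s_diag), alpha=4.0, ridge=0.0, tol=1e-10)
        np.testing.assert_allclose(np.diag(theta), expected, atol=1e-5)
        off = theta - np.diag(np.diag(theta))
        np.testing.assert_allclose(off, 0.0, atol=1e-6)

    def test_feasibility_on_random_instances(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            d = rng.integers(3, 10)
            a = rng.normal(size=(d, d + 3))
            s = a @ a.T / (d + 3)
            alpha = float(rng.uniform(0.5, 5.0))
            theta = graphical_lasso(s, alpha=alpha, ridge=1e-3)
            assert np.abs(theta).sum() <= alpha * (1 + 1e-6)
            assert np.linalg.eigvalsh(theta).min() >= -1e-6
            np.testing.assert_allclose(theta, theta.T, atol=1e-10)

    def test_objective_matches_frankwolfe_reference(self):
        rng = np.random.default_rng(3)
        for _ in range(3):
            d = rng.integers(3, 8)
            a = rng.normal(size=(d, 2 * d))
            s = a @ a.T / (2 * d)
            alpha = float(rng.uniform(1.0, 4.0))
            theta = graphical_lasso(s, alpha=alpha, ridge=0.0, tol=1e-10)
            # duality-gap certificate: within 1e-4 of the true optimum
            assert suboptimality_certificate(theta, s, alpha) < 1e-4
            # and the independent Frank-Wolfe solver agrees within its own
            # certified gap
            ref, gap = frankwolfe_glasso(s, alpha, gap_tol=1e-7)
            assert abs(glasso_objective(theta, s) - glasso_objective(ref, s)) < (
                1e-4 + gap
            )

    def test_asymmetric_input_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            graphical_lasso(np.array([[1.0, 0.5], [0.0, 1.0]]))


class TestPositionScores:
    def make_result(self):
        rows = [("FF", "FF", 5), ("FL", "FL", 4), ("LF", "LF", 6), ("LL", "LL", 3)]
        fr = pair_frequencies(freq_table(rows))
        return fr, empirical_covariance(fr)

    def test_minmax_normalization_bounds(self):
        fr, s = self.make_result()
        theta = graphical_lasso(s, alpha=auto_alpha(s), ridge=1e-3)
        scores = position_coupling_scores(theta, covariance_index_map(fr), fr.len_A)
        vals = scores.to_numpy()
        if vals.max() > vals.min():
            assert vals.max() == pytest.approx(1.0)
            assert vals.min() == pytest.approx(0.0)

    def test_zero_theta_gives_zero_scores(self):
        fr, s = self.make_result()
        d = s.shape[0]
        scores = position_coupling_scores(
            np.zeros((d, d)), covariance_index_map(fr), fr.len_A
        )
        np.testing.assert_array_equal(scores.to_numpy(), 0.0)

    def test_labels_follow_chain_positions(self):
        fr, s = self.make_result()
        scores = position_coupling_scores(np.eye(s.shape[0]),
                                          covariance_index_map(fr), fr.len_A)
        assert list(scores.index) == ["A1", "A2"]
        assert list(scores.columns) == ["B1", "B2"]


class TestStructureComparison:
    def test_perfectly_linear_r2_one(self):
        scores = pd.DataFrame([[0.1, 0.2], [0.3, 0.4]],
                              index=["A1", "A2"], columns=["B1", "B2"])
        distances = {("A1", "B1"): 1.0, ("A1", "B2"): 2.0,
                     ("A2", "B1"): 3.0, ("A2", "B2"): 4.0}
        out = structure_comparison(scores, distances)
        assert out.r_squared == pytest.approx(1.0)

    def test_four_points_match_closed_form(self):
        scores = pd.DataFrame([[0.0, 0.9], [0.2, 0.5]],
                              index=["A1", "A2"], columns=["B1", "B2"])
        distances = {("A1", "B1"): 4.0, ("A1", "B2"): 6.0,
                     ("A2", "B1"): 9.0, ("A2", "B2"): 5.0}
        out = structure_comparison(scores, distances)
        x = np.array([4.0, 6.0, 9.0, 5.0])
        y = np.array([0.0, 0.9, 0.2, 0.5])
        r = np.corrcoef(x, y)[0, 1]
        assert out.r_squared == pytest.approx(r**2, rel=1e-12)

    def test_fewer_than_three_pairs_rejected(self):
        scores = pd.DataFrame([[0.1]], index=["A1"], columns=["B1"])
        with pytest.raises(ValueError, match=">= 3"):
            structure_comparison(scores, {("A1", "B1"): 1.0})

    def test_constant_vector_flagged_not_zero(self):
        scores = pd.DataFrame([[0.5, 0.5], [0.5, 0.5]],
                              index=["A1", "A2"], columns=["B1", "B2"])
        distances = {("A1", "B1"): 1.0, ("A1", "B2"): 2.0,
                     ("A2", "B1"): 3.0, ("A2", "B2"): 4.0}
        out = structure_comparison(scores, distances)
        assert out.r_squared is None
        assert "undefined" in out.note


SYNTHETIC_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.500   0.000   0.000  1.00  0.00           C
ATOM      3  CB  ALA A   1       2.000   1.400   0.000  1.00  0.00           C
ATOM      4  N   GLY A   2       5.000   0.000   0.000  1.00  0.00           N
ATOM      5  CA  GLY A   2       6.500   0.000   0.000  1.00  0.00           C
ATOM      6  N   VAL B   1       0.000   3.000   0.000  1.00  0.00           N
ATOM      7  CA  VAL B   1       1.500   3.000   0.000  1.00  0.00           C
END
"""


class TestPdbDistances:
    def test_minimum_heavy_atom_distance(self, tmp_path):
        # synthetic two-chain structure with hand-set coordinates
        path = tmp_path / "synthetic.pdb"
        path.write_text(SYNTHETIC_PDB)
        out = pdb_pair_distances(str(path), "A", "B", [1, 2], [1])
        # residue A1 CB (2.0, 1.4) to B1 CA (1.5, 3.0): sqrt(0.25 + 2.56)
        assert out[("A1", "B1")] == pytest.approx(np.hypot(0.5, 1.6), abs=1e-6)
        assert out[("A2", "B1")] == pytest.approx(np.hypot(3.5, 3.0), abs=1e-6)
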