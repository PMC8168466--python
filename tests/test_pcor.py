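import numpy as np
import pandas as pd
import pytest
from scipy import special

from com6ar import (ExpressionMatrix, InsufficientDfError,
                    UndefinedCorrelationError, pcor_first_order,
                    pcor_residual, pcor_screen, pcor_test, pearson_matrix,
                    sd_filter)
from conftest import make_matrix


# ---------------------------------------------------------------------------
# independent oracles (normal equations + textbook formulas; separate from
# the library's lstsq/vectorized path)
# ---------------------------------------------------------------------------

def pearson_oracle(a, b):
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    da, db = a - a.mean(), b - b.mean()
    return float((da * db).sum()
                 / np.sqrt((da * da).sum() * (db * db).sum()))


def pcor_oracle(x, y, D):
    """Explicit normal-equations regression of x and y on D + intercept,
    then textbook Pearson on the residuals."""
    n = len(x)
    A = np.column_stack([np.ones(n)] + [np.asarray(r, float) for r in D])
    def resid(v):
        beta = np.linalg.solve(A.T @ A, A.T @ np.asarray(v, float))
        return np.asarray(v, float) - A @ beta
    return pearson_oracle(resid(x), resid(y))


def t_two_sided_oracle(t, df):
    return float(special.betainc(df / 2.0, 0.5, df / (df + t * t)))


# ---------------------------------------------------------------------------
# pcor_residual
# ---------------------------------------------------------------------------

class TestPcorResidual:
    def test_identity_without_controls(self):
        x = [1.0, 3.0, 2.0, 5.0, 4.0]
        assert pcor_residual(x, x, None) == pytest.approx(1.0, abs=1e-12)

    def test_fully_explained_by_control_raises(self):
        z = np.arange(6.0)
        with pytest.raises(UndefinedCorrelationError):
            pcor_residual(2 * z + 1, -3 * z + 4, z[None, :])

    def test_insufficient_df(self):
        x = np.arange(5.0)
        D = np.ones((3, 5)) * np.arange(5.0)
        with pytest.raises(InsufficientDfError):
            pcor_residual(x, x + 1, D)

    @pytest.mark.parametrize("seed", range(100))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(8, 31))
        k = int(rng.integers(0, min(6, n - 3)))
        x = rng.standard_normal(n)
        y = rng.standard_normal(n)
        D = rng.standard_normal((k, n))
        assert pcor_residual(x, y, D) == pytest.approx(
            pcor_oracle(x, y, D), abs=1e-10)

    @pytest.mark.parametrize("seed", range(100))
    def test_single_control_matches_first_order_formula(self, seed):
        rng = np.random.default_rng(1000 + seed)
        n = int(rng.integers(6, 30))
        x, y, z = rng.standard_normal((3, n))
        expected = pcor_first_order(pearson_oracle(x, y),
                                    pearson_oracle(x, z),
                                    pearson_oracle(y, z))
        assert pcor_residual(x, y, z[None, :]) == pytest.approx(
            expected, abs=1e-10)

    @pytest.mark.parametrize("seed", range(20))
    def test_affine_invariance_and_symmetry(self, seed):
        rng = np.random.default_rng(3000 + seed)
        n = 15
        x, y = rng.standard_normal((2, n))
        D = rng.standard_normal((2, n))
        base = pcor_residual(x, y, D)
        scaled = pcor_residual(3.5 * x - 2.0, 0.25 * y + 7.0,
                               np.vstack([10 * D[0] + 1, -0.5 * D[1]]))
        assert scaled == pytest.approx(base, abs=1e-10)
        assert pcor_residual(y, x, D) == pytest.approx(base, abs=1e-12)


# ---------------------------------------------------------------------------
# pcor_first_order
# ---------------------------------------------------------------------------

class TestPcorFirstOrder:
    def test_no_confounding_reduces_to_plain(self):
        assert pcor_first_order(0.5, 0.0, 0.0) == 0.5

    def test_fully_mediated_is_zero(self):
        assert pcor_first_order(0.25, 0.5, 0.5) == pytest.approx(0.0)

    def test_hand_arithmetic(self):
        # (0.8 - 0.25) / sqrt(0.75 * 0.75) = 0.7333...
        assert pcor_first_order(0.8, 0.5, 0.5) == pytest.approx(
            0.55 / 0.75, abs=1e-12)

    def test_unit_control_correlation_raises(self):
        with pytest.raises(ZeroDivisionError):
            pcor_first_order(0.5, 1.0, 0.2)

    def test_out_of_range_input_raises(self):
        with pytest.raises(ValueError):
            pcor_first_order(1.5, 0.0, 0.0)


# ---------------------------------------------------------------------------
# pcor_test
# ---------------------------------------------------------------------------

class TestPcorTest:
    def test_null_rho(self):
        t, df, p = pcor_test(0.0, 20, 3)
        assert t == 0.0 and df == 15 and p == 1.0

    def test_hand_arithmetic_and_tail_oracle(self):
        t, df, p = pcor_test(0.5, 20, 1)
        t_expected = 0.5 * np.sqrt(17) / np.sqrt(0.75)
        assert t == pytest.approx(t_expected, abs=1e-12)
        assert df == 17
        assert p == pytest.approx(t_two_sided_oracle(t_expected, 17),
                                  rel=1e-10)

    def test_sign_symmetry(self):
        t_pos, _, p_pos = pcor_test(0.5, 20, 1)
        t_neg, _, p_neg = pcor_test(-0.5, 20, 1)
        assert t_neg == -t_pos and p_neg == p_pos

    def test_perfect_correlation_raises(self):
        with pytest.raises(ValueError, match="infinite"):
            pcor_test(1.0, 20, 1)

    def test_insufficient_df_raises(self):
        with pytest.raises(InsufficientDfError):
            pcor_test(0.3, 4, 2)


# ---------------------------------------------------------------------------
# sd_filter
# ---------------------------------------------------------------------------

class TestSdFilter:
    def test_constant_gene_removed(self):
        em = make_matrix([[1.0, 1.0, 1.0], [0.0, 1.0, 2.0]])
        assert sd_filter(em).gene_ids == ["G2"]

    def test_threshold_is_inclusive(self):
        em = make_matrix([[0.1, -0.1, 0.0], [5.0, 0.0, -5.0]])
        s = float(em.data.loc["G1"].std(ddof=1))  # sample SD of gene 1
        kept = sd_filter(em, threshold=s)
        assert kept.gene_ids == ["G2"]  # SD == threshold -> removed

    def test_variable_gene_retained(self):
        em = make_matrix([[0.0, 0.2, 0.4, 0.2]])
        assert sd_filter(em, threshold=0.1).gene_ids == ["G1"]

    def test_all_filtered_gives_empty_matrix(self):
        em = make_matrix([[1.0, 1.0, 1.0]])
        assert sd_filter(em).n_genes == 0


# ---------------------------------------------------------------------------
# pcor_screen / pearson_matrix
# ---------------------------------------------------------------------------

class TestPcorScreen:
    def make_em(self, seed=0, n=30, genes=6):
        rng = np.random.default_rng(seed)
        return make_matrix(rng.standard_normal((genes, n)),
                           genes=[f"G{i}" for i in range(genes)])

    def test_missing_symbols_listed(self):
        em = self.make_em()
        with pytest.raises(KeyError, match="NOPE1.*NOPE2"):
            pcor_screen(em, ["G0", "NOPE1"], ["NOPE2"])

    def test_empty_candidate_set(self):
        em = self.make_em(genes=3)
        assert pcor_screen(em, ["G0"], ["G1", "G2"]) == []

    def test_no_controls_reduces_to_plain_pearson(self):
        em = self.make_em(seed=5)
        res = pcor_screen(em, ["G0"], [])
        for r in res:
            expected = pearson_oracle(em.data.loc[r.gene],
                                      em.data.loc["G0"])
            assert r.rho == pytest.approx(expected, abs=1e-10)
            assert r.k == 0 and r.df == em.n_samples - 2

    def test_vectorized_path_matches_scalar_path(self):
        em = self.make_em(seed=8, genes=7)
        regs, ctls = ["G0", "G1"], ["G2", "G3"]
        res = pcor_screen(em, regs, ctls)
        D = em.data.loc[ctls].to_numpy()
        assert len(res) == 6  # 3 candidates x 2 regulators
        for r in res:
            rho = pcor_residual(em.data.loc[r.gene].to_numpy(),
                                em.data.loc[r.regulator].to_numpy(), D)
            t, df, p = pcor_test(rho, em.n_samples, len(ctls))
            assert r.rho == pytest.approx(rho, abs=1e-12)
            assert r.t_stat == pytest.approx(t, abs=1e-10)
            assert (r.df, r.n, r.k) == (df, em.n_samples, len(ctls))
            assert r.p == pytest.approx(p, rel=1e-10)

    def test_bh_option_fills_p_adj(self):
        em = self.make_em(seed=2)
        res = pcor_screen(em, ["G0"], ["G1"], adjust="bh")
        assert all(r.p_adj is not None and r.p_adj >= r.p - 1e-15
                   for r in res)

    def test_duplicate_of_control_raises(self):
        em = self.make_em(seed=3, genes=4)
        em.data.loc["G3"] = 2.0 * em.data.loc["G1"] + 1.0
        with pytest.raises(UndefinedCorrelationError, match="G3"):
            pcor_screen(em, ["G0"], ["G1"])


class TestPearsonMatrix:
    def test_unit_diagonal_and_antisymmetric_pair(self):
        em = make_matrix([[1.0, 2.0, 3.0, 1.0, 0.0],
                          [-1.0, -2.0, -3.0, -1.0, 0.0]])
        m = pearson_matrix(em)
        assert m.loc["G1", "G1"] == 1.0
        assert m.loc["G1", "G2"] == pytest.approx(-1.0)
        pd.testing.assert_frame_equal(m, m.T)

    def test_matches_textbook_oracle_entrywise(self, rng):
        em = make_matrix(rng.standard_normal((3, 5)))
        m = pearson_matrix(em)
        for a in em.gene_ids:
            for b in em.gene_ids:
                assert m.loc[a, b] == pytest.approx(
                    pearson_oracle(em.data.loc[a], em.data.loc[b]),
                    abs=1e-12)

    def test_zero_variance_regulator_named(self):
        em = make_matrix([[1.0, 1.0, 1.0], [0.0, 1.0, 2.0]])
        with pytest.raises(ValueError, match="G1"):
            pearson_matrix(em)
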