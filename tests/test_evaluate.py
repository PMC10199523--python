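"""ssGBLUP machinery: relationship matrices, MME, scenarios, rankings."""

import numpy as np
import pandas as pd
import pytest

from radseq_gs.evaluate import (
    VarianceComponents,
    build_A,
    build_A_inverse,
    build_G,
    build_Hinv,
    derive_esc,
    evaluate_trait,
    heterozygote_call_probability,
    rank_comparison,
    solve_mme,
)
from radseq_gs.qc import GenotypeMatrix


def ped_frame(rows):
    return pd.DataFrame(rows, columns=["id", "sire", "dam", "generation", "sex"])


TRIO = ped_frame(
    [(1, 0, 0, 0, "M"), (2, 0, 0, 0, "F"), (3, 1, 2, 1, "F"), (4, 1, 2, 1, "M")]
)


class TestDeriveEsc:
    @pytest.mark.parametrize(
        "L,a,b,expected", [(100, 0, 0, 0), (0, 0, 0, 100), (60, 20, 15, 75)]
    )
    def test_formula(self, L, a, b, expected):
        assert derive_esc(L, a, b) == expected


class TestHeterozygoteCallProbability:
    def test_two_reads_same_allele_probability_half(self):
        assert heterozygote_call_probability(2) == pytest.approx(0.5)

    def test_one_read_never_shows_both(self):
        assert heterozygote_call_probability(1) == 0.0

    def test_matches_monte_carlo(self, rng):
        n = 10
        draws = rng.integers(0, 2, size=(1_000_000, n))
        both = ((draws.min(axis=1) == 0) & (draws.max(axis=1) == 1)).mean()
        p = heterozygote_call_probability(n)
        se = np.sqrt(p * (1 - p) / 1_000_000)
        assert abs(both - p) < 3 * se + 1e-12

    def test_zero_reads_rejected(self):
        with pytest.raises(ValueError):
            heterozygote_call_probability(0)


class TestRelationshipMatrices:
    def test_unrelated_founders_identity(self):
        ped = ped_frame([(1, 0, 0, 0, "M"), (2, 0, 0, 0, "F")])
        assert np.array_equal(build_A(ped), np.eye(2))

    def test_trio_tabular_values(self):
        A = build_A(TRIO)
        assert A[2, 0] == 0.5  # offspring-sire
        assert A[2, 2] == 1.0  # non-inbred offspring
        assert A[2, 3] == 0.5  # full sibs

    def test_henderson_inverse_matches_direct(self):
        # three generations incl. inbred mating (sib x sib offspring)
        ped = ped_frame(
            [
                (1, 0, 0, 0, "M"),
                (2, 0, 0, 0, "F"),
                (3, 1, 2, 1, "M"),
                (4, 1, 2, 1, "F"),
                (5, 3, 4, 2, "M"),
            ]
        )
        np.testing.assert_allclose(
            build_A_inverse(ped, "henderson"), build_A_inverse(ped, "direct"),
            atol=1e-10,
        )

    def test_offspring_listed_before_parent_rejected(self):
        ped = ped_frame([(3, 1, 2, 1, "F"), (1, 0, 0, 0, "M"), (2, 0, 0, 0, "F")])
        with pytest.raises(ValueError):
            build_A(ped)

    def test_G_toy_matches_hand_product(self):
        codes = np.array([[0, 1, 2, 0], [1, 1, 0, 2], [2, 0, 1, 1]], dtype=float)
        p = codes.mean(axis=0) / 2
        M = codes - 2 * p
        expected = M @ M.T / (2 * np.sum(p * (1 - p)))
        np.testing.assert_allclose(build_G(codes), expected)

    def test_G_centering_gives_zero_row_for_mean_individual(self):
        p = np.array([0.25, 0.5])
        codes = np.array([[2 * 0.25, 2 * 0.5], [1, 2]])
        G = build_G(codes, p)
        np.testing.assert_allclose(G[0], 0.0, atol=1e-12)

    def test_G_duplicate_individuals_identical_rows(self):
        codes = np.array([[0, 1, 2], [0, 1, 2], [2, 1, 0]], dtype=float)
        G = build_G(codes)
        np.testing.assert_allclose(G[0], G[1])
        assert G[0, 0] == pytest.approx(G[0, 1])

    def test_G_monomorphic_only_rejected(self):
        with pytest.raises(ValueError, match="monomorphic"):
            build_G(np.array([[2.0, 0.0], [2.0, 0.0]]))

    def test_Hinv_reduces_to_Ainv_when_G_equals_A22(self):
        A = build_A(TRIO)
        Ainv = np.linalg.inv(A)
        gidx = np.array([2, 3])
        A22 = A[np.ix_(gidx, gidx)]
        H1 = build_Hinv(Ainv, A22, A22, gidx, blend=0.05)
        np.testing.assert_allclose(H1, Ainv, atol=1e-10)
        # blend=1 discards any G entirely
        G = np.array([[1.3, 0.2], [0.2, 0.9]])
        H2 = build_Hinv(Ainv, A22, G, gidx, blend=1.0)
        np.testing.assert_allclose(H2, Ainv, atol=1e-10)

    def test_Hinv_matches_bruteforce_H_on_small_system(self):
        ped = ped_frame(
            [
                (1, 0, 0, 0, "M"),
                (2, 0, 0, 0, "F"),
                (3, 1, 2, 1, "M"),
                (4, 1, 2, 1, "F"),
                (5, 3, 4, 2, "M"),
            ]
        )
        A = build_A(ped)
        rng = np.random.default_rng(0)
        codes = rng.integers(0, 3, size=(2, 20)).astype(float)
        gidx = np.array([3, 4])
        A22 = A[np.ix_(gidx, gidx)]
        G = build_G(codes)
        Gb = 0.95 * G + 0.05 * A22
        # assemble H directly: standard block formula
        n = len(ped)
        ng = list(gidx)
        nn = [i for i in range(n) if i not in ng]
        A11 = A[np.ix_(nn, nn)]
        A12 = A[np.ix_(nn, ng)]
        A22i = np.linalg.inv(A22)
        H = np.zeros_like(A)
        H11 = A11 + A12 @ A22i @ (Gb - A22) @ A22i @ A12.T
        H12 = A12 @ A22i @ Gb
        H[np.ix_(nn, nn)] = H11
        H[np.ix_(nn, ng)] = H12
        H[np.ix_(ng, nn)] = H12.T
        H[np.ix_(ng, ng)] = Gb
        Hinv = build_Hinv(np.linalg.inv(A), A22, G, gidx, blend=0.05)
        np.testing.assert_allclose(Hinv, np.linalg.inv(H), atol=1e-8)


def gls_pedigree_blup(y, X, Z, A, s2u, s2e):
    """Independent BLUP oracle via the variance-matrix (GLS) route."""
    V = Z @ A @ Z.T * s2u + np.eye(len(y)) * s2e
    Vi = np.linalg.inv(V)
    b = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
    u = s2u * A @ Z.T @ Vi @ (y - X @ b)
    return b, u


class TestSolveMme:
    def make_system(self, n=12, seed=3):
        rng = np.random.default_rng(seed)
        rows = [(i, 0, 0, 0, "M") for i in range(1, 5)]
        for i in range(5, n + 1):
            rows.append((i, 1 + (i % 2), 3 + (i % 2), 1, "F"))
        ped = ped_frame(rows)
        A = build_A(ped)
        y = rng.normal(size=n)
        X = np.column_stack([np.ones(n), rng.integers(0, 2, size=n)]).astype(float)
        Z = np.eye(n)
        return ped, A, y, X, Z

    def test_matches_gls_pedigree_blup_oracle(self):
        ped, A, y, X, Z = self.make_system()
        s2u, s2e = 0.4, 0.6
        b_o, u_o = gls_pedigree_blup(y, X, Z, A, s2u, s2e)
        b, u = solve_mme(y, X, Z, np.linalg.inv(A), s2e / s2u)
        np.testing.assert_allclose(u, u_o, atol=1e-8)
        np.testing.assert_allclose(b, b_o, atol=1e-8)

    def test_infinite_shrinkage_drives_gebv_to_zero(self):
        ped, A, y, X, Z = self.make_system()
        _, u = solve_mme(y, X, Z, np.linalg.inv(A), 1e10)
        assert np.abs(u).max() < 1e-6

    def test_single_animal_scalar_solution(self):
        y = np.array([3.0])
        X = np.ones((1, 1))
        Z = np.eye(1)
        b, u = solve_mme(y, X, Z, np.eye(1), 2.0)
        assert b[0] == pytest.approx(3.0)
        assert u[0] == pytest.approx(0.0)

    def test_rank_deficient_fixed_block_constrained(self):
        ped, A, y, X, Z = self.make_system()
        X2 = np.column_stack([X, X[:, 0] + X[:, 1]])  # dependent column
        with pytest.warns(UserWarning, match="rank-deficient"):
            b, u = solve_mme(y, X2, Z, np.linalg.inv(A), 1.0)
        _, u_ref = solve_mme(y, X, Z, np.linalg.inv(A), 1.0)
        np.testing.assert_allclose(u, u_ref, atol=1e-8)

    def test_gebv_invariant_to_phenotype_shift(self):
        ped, A, y, X, Z = self.make_system()
        _, u1 = solve_mme(y, X, Z, np.linalg.inv(A), 1.5)
        _, u2 = solve_mme(y + 100.0, X, Z, np.linalg.inv(A), 1.5)
        np.testing.assert_allclose(u1, u2, atol=1e-8)


class TestScenarioReduction:
    def test_ssgblup_equals_pedigree_blup_when_G_is_A22(self, sim_small):
        """With the blended G forced to A22 the H matrix collapses to A."""
        ped = sim_small.pedigree.head(40).copy()
        phen = sim_small.phenotypes
        phen = phen[
            (phen["trait"] == "EW") & (phen["individual"].isin(ped["id"]))
        ]
        phen_all = sim_small.phenotypes[
            sim_small.phenotypes["individual"].isin(ped["id"])
        ]
        vc = VarianceComponents(0.5, 0.5)
        A = build_A(ped)
        gebv_ped = evaluate_trait(ped, phen_all, "EW", vc, genotyped=None, A=A)
        gidx_ids = list(ped["id"].iloc[20:40])
        row_of = {i: k for k, i in enumerate(ped["id"])}
        gidx = np.array([row_of[i] for i in gidx_ids])
        A22 = A[np.ix_(gidx, gidx)]

        class FakeGm:
            individuals = gidx_ids
            n_individuals = len(gidx_ids)
            codes = None

        import radseq_gs.evaluate as ev

        Hinv = ev.build_Hinv(np.linalg.inv(A), A22, A22, gidx, blend=0.05)
        y, X, Z = ev._design(ped, phen[phen["individual"].isin(ped["id"])])
        _, u_h = ev.solve_mme(y, X, Z, Hinv, vc.lam)
        y2, X2, Z2 = ev._design(ped, phen)
        _, u_a = ev.solve_mme(y2, X2, Z2, np.linalg.inv(A), vc.lam)
        np.testing.assert_allclose(u_h, u_a, atol=1e-8)


class TestRankComparison:
    def make_gebv(self, n=20, seed=0):
        rng = np.random.default_rng(seed)
        ids = list(range(1, n + 1))
        vals = rng.normal(size=n)
        ped = ped_frame(
            [(i, 0, 0, 0, "M") for i in ids]
            + [(100 + j, 1 + (j % 3), 2, 1, "F") for j in range(36)]
        )
        return pd.Series(vals, index=ids), ped

    def test_identical_inputs_perfect_agreement(self):
        a, ped = self.make_gebv()
        rc = rank_comparison(a, a.copy(), ped, K=10, min_offspring=10)
        assert rc.spearman_topK == pytest.approx(1.0)
        assert rc.spearman_breeders == pytest.approx(1.0)
        assert rc.n_retained_in_topK == 10
        assert rc.pearson_relative_accuracy == pytest.approx(1.0)

    def test_negated_gebv_gives_minus_one(self):
        a, ped = self.make_gebv()
        rc = rank_comparison(a, -a, ped, K=10, min_offspring=10)
        assert rc.spearman_topK == pytest.approx(-1.0)
        assert rc.spearman_breeders == pytest.approx(-1.0)

    def test_single_swap_matches_rank_formula(self):
        ids = list(range(1, 7))
        a = pd.Series([6.0, 5.0, 4.0, 3.0, 2.0, 1.0], index=ids)
        b = a.copy()
        b.iloc[0], b.iloc[1] = b.iloc[1], b.iloc[0]
        ped = ped_frame([(i, 0, 0, 0, "M") for i in ids])
        rc = rank_comparison(a, b, ped, K=6, min_offspring=10)
        d2 = np.array([1, 1, 0, 0, 0, 0])  # squared rank differences
        expected = 1 - 6 * d2.sum() / (6 * (36 - 1))
        assert rc.spearman_topK == pytest.approx(expected)

    def test_oversized_K_rejected(self):
        a, ped = self.make_gebv()
        with pytest.raises(ValueError, match="exceeds"):
            rank_comparison(a, a, ped, K=999)

    def test_bootstrap_standard_errors_seeded(self):
        a, ped = self.make_gebv(n=40, seed=2)
        rng = np.random.default_rng(5)
        b = a + rng.normal(scale=0.5, size=len(a))
        r1 = rank_comparison(a, b, ped, K=20, n_bootstrap=200, seed=9)
        r2 = rank_comparison(a, b, ped, K=20, n_bootstrap=200, seed=9)
        assert r1.se_topK == r2.se_topK
        assert r1.se_topK > 0
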