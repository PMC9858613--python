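import numpy as np
import pytest

from cimap.association import (
    ContingencyTable,
    chi_square_effect,
    ci_test,
    conditional_mutual_information,
    crosstab,
    g_test,
    mutual_information,
    permutation_test,
)
from cimap.cohort import summarise
from cimap.errors import DegenerateTableError, EmptyTableError, SchemaError
from cimap.network import simulate_cohort

from conftest import chain_network, make_binary_cohort
from oracles import entropy_bits_oracle, g_oracle, mi_bits_oracle


def _table(counts, row="x", col="y"):
    counts = np.asarray(counts)
    return ContingencyTable(
        counts,
        row,
        col,
        tuple(str(i) for i in range(counts.shape[0])),
        tuple(str(j) for j in range(counts.shape[1])),
    )


class TestCrosstab:
    def test_exact_counts_on_enumerated_records(self):
        cohort = make_binary_cohort({"x": [0, 0, 1, 1], "y": [0, 1, 1, 1]})
        table = crosstab(cohort, "x", "y")
        assert table.counts.tolist() == [[1, 1], [0, 2]]
        assert table.N == 4

    def test_missing_records_excluded_and_counted(self):
        cohort = make_binary_cohort({"x": [0, None, 1], "y": [1, 1, None]})
        table = crosstab(cohort, "x", "y")
        assert table.N == 1
        assert table.n_excluded == 2

    def test_same_variable_rejected(self):
        cohort = make_binary_cohort({"x": [0, 1]})
        with pytest.raises(SchemaError):
            crosstab(cohort, "x", "x")

    def test_all_missing_is_empty_table_error(self):
        cohort = make_binary_cohort({"x": [None, None], "y": [0, 1]})
        with pytest.raises(EmptyTableError):
            crosstab(cohort, "x", "y")

    def test_table1_sex_by_previous_attendance(self, table1):
        table = crosstab(table1, "sex", "previous_attendance")
        # rows: female, male; cols: no, yes
        assert table.counts.tolist() == [[115, 45], [68, 12]]

    def test_csv_roundtrip(self, tmp_path):
        table = _table([[5, 2], [1, 9]])
        path = tmp_path / "t.csv"
        table.to_csv(path)
        back = ContingencyTable.from_csv(path)
        assert back.counts.tolist() == table.counts.tolist()


class TestMutualInformation:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            ([[50, 50], [50, 50]], 0.0),
            ([[60, 0], [0, 60]], 1.0),
            ([[40, 10], [10, 40]], 0.2780719051126377),
        ],
    )
    def test_reference_values(self, counts, expected):
        assert mutual_information(_table(counts)) == pytest.approx(expected, abs=1e-12)

    def test_empty_table_rejected(self):
        with pytest.raises(EmptyTableError):
            mutual_information(_table([[0, 0], [0, 0]]))

    def test_symmetry_and_entropy_bound_on_random_tables(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            shape = rng.integers(2, 5, size=2)
            counts = rng.poisson(5.0, size=shape) + 1
            mi_xy = mutual_information(_table(counts))
            mi_yx = mutual_information(_table(counts.T))
            assert mi_xy == pytest.approx(mi_yx, abs=1e-13)
            n = counts.sum()
            hx = entropy_bits_oracle(counts.sum(axis=1) / n)
            hy = entropy_bits_oracle(counts.sum(axis=0) / n)
            assert mi_xy <= min(hx, hy) + 1e-12


class TestConditionalMI:
    def test_copy_of_x_given_unrelated_z_equals_marginal_entropy(self):
        rng = np.random.default_rng(0)
        x = rng.integers(0, 2, 4000)
        z = rng.integers(0, 2, 4000)
        cohort = make_binary_cohort({"x": x, "y": x, "z": z})
        cmi = conditional_mutual_information(cohort, "x", "y", ["z"])
        hx = entropy_bits_oracle([np.mean(x == 0), np.mean(x == 1)])
        # CMI of a perfect copy equals H(X) up to stratification noise
        assert cmi == pytest.approx(hx, abs=5e-4)
        assert conditional_mutual_information(cohort, "x", "y", []) == pytest.approx(
            mutual_information(crosstab(cohort, "x", "y")), abs=1e-14
        )

    def test_conditioning_on_x_itself_annihilates_association(self):
        cohort = make_binary_cohort({"x": [0, 0, 1, 1] * 10, "y": [0, 0, 1, 1] * 10})
        assert conditional_mutual_information(cohort, "x", "y", ["x"]) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_chain_conditional_test_detects_independence(self):
        """CMI(x, y | z) on an x->z->y chain: rejection stays near alpha.

        The rejection rate of a calibrated alpha=0.05 test fluctuates around
        0.05 (binomial sd ~0.015 at 200 seeds), so the check is a 3-sigma
        band rather than a hard 5% cap; the CMI itself must vanish.
        """
        net = chain_network(flip=0.1)
        rejections = 0
        cmis = []
        n_seeds = 200
        for seed in range(n_seeds):
            cohort = simulate_cohort(net, 10_000, seed)
            res = ci_test(cohort, "x", "y", given=["z"], seed=seed)
            cmis.append(res.mi)
            if res.p <= 0.05:
                rejections += 1
        assert rejections / n_seeds <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / n_seeds)
        assert np.mean(cmis) < 0.002  # bits; marginal MI(x, y) here is ~0.3


class TestGTest:
    def test_independent_product_table(self):
        res = g_test(_table([[40, 60], [20, 30]]))
        assert res.g == pytest.approx(0.0, abs=1e-9)
        assert res.p == pytest.approx(1.0, abs=1e-9)

    def test_reference_table_matches_direct_summation(self):
        counts = [[40, 10], [10, 40]]
        res = g_test(_table(counts))
        assert res.g == pytest.approx(g_oracle(counts), rel=1e-12)
        assert res.g == pytest.approx(38.55, abs=0.01)
        assert res.df == 1
        assert res.p < 0.001

    def test_g_mi_identity(self):
        counts = [[13, 5, 9], [2, 17, 4]]
        res = g_test(_table(counts))
        n = np.sum(counts)
        assert res.g == pytest.approx(2 * n * np.log(2) * res.mi, rel=1e-12)

    def test_df_for_2x3(self):
        assert g_test(_table([[10, 5, 6], [3, 8, 9]])).df == 2

    def test_degenerate_when_no_usable_df(self):
        with pytest.raises(DegenerateTableError):
            g_test(_table([[10, 0], [5, 0]]))


class TestPermutation:
    def test_perfect_association_gives_minimum_p(self):
        cohort = make_binary_cohort({"x": [0, 1] * 30, "y": [0, 1] * 30})
        res = permutation_test(cohort, "x", "y", n_perm=999, seed=5)
        assert res.p == pytest.approx(1 / 1000, abs=1e-12)

    def test_fixed_seed_reproducible(self):
        rng = np.random.default_rng(3)
        cohort = make_binary_cohort(
            {"x": rng.integers(0, 2, 100), "y": rng.integers(0, 2, 100)}
        )
        a = permutation_test(cohort, "x", "y", n_perm=499, seed=9)
        b = permutation_test(cohort, "x", "y", n_perm=499, seed=9)
        assert a.p == b.p

    def test_type_one_error_calibrated_under_independence(self):
        rejections = 0
        reps = 500
        for seed in range(reps):
            rng = np.random.default_rng(seed)
            cohort = make_binary_cohort(
                {"x": rng.integers(0, 2, 200), "y": rng.integers(0, 2, 200)}
            )
            res = permutation_test(cohort, "x", "y", n_perm=199, seed=seed)
            if res.p <= 0.05:
                rejections += 1
        assert 0.03 <= rejections / reps <= 0.07

    def test_agrees_with_g_test_on_dense_tables(self):
        """Permutation and asymptotic p-values coincide on dense 2x2 tables.

        The permutation null is discrete and the >=-convention puts the
        whole observed atom (up to ~0.07 wide at n=500, largest near p=1)
        into the tail, so the permutation p sits systematically at or
        just above the continuous chi-square tail: agreement is one-sided
        conservative within one atom, not symmetric.
        """
        rng = np.random.default_rng(12)
        diffs = []
        for seed in range(20):
            x = rng.integers(0, 2, 500)
            y = rng.integers(0, 2, 500)
            cohort = make_binary_cohort({"x": x, "y": y})
            p_perm = permutation_test(cohort, "x", "y", n_perm=9999, seed=seed).p
            p_g = g_test(crosstab(cohort, "x", "y")).p
            diffs.append(p_perm - p_g)
            assert p_perm >= p_g - 0.01  # MC noise only on the low side
            assert p_perm - p_g <= 0.08  # at most one null atom
        assert np.mean(diffs) <= 0.03


class TestChiSquareEffect:
    def test_diagonal_table_has_unit_phi(self):
        res = chi_square_effect(_table([[60, 0], [0, 60]]))
        assert res.phi == pytest.approx(1.0, abs=1e-12)
        assert res.cramers_v == pytest.approx(1.0, abs=1e-12)

    def test_product_table_has_zero_effect(self):
        res = chi_square_effect(_table([[40, 60], [20, 30]]))
        assert res.chi2 == pytest.approx(0.0, abs=1e-9)
        assert res.phi == pytest.approx(0.0, abs=1e-6)

    def test_sex_by_attendance_against_textbook_oracle(self):
        from oracles import chi2_oracle, phi_oracle

        counts = [[45, 115], [12, 68]]
        res = chi_square_effect(_table(counts))
        assert res.chi2 == pytest.approx(chi2_oracle(counts), rel=1e-12)
        assert res.phi == pytest.approx(phi_oracle(counts), rel=1e-12)
        assert res.df == 1

    def test_zero_margin_names_degenerate_level(self):
        with pytest.raises(DegenerateTableError, match="1"):
            chi_square_effect(_table([[10, 0], [5, 0]]))

    def test_phi_equals_cramers_v_on_2x2(self):
        res = chi_square_effect(_table([[30, 12], [7, 25]]))
        assert res.phi == pytest.approx(res.cramers_v, abs=1e-15)
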