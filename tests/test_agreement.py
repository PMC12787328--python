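"""Agreement statistics: kappa, Spearman/phi, table reconstruction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from statsmodels.stats.inter_rater import cohens_kappa as sm_kappa

from frailsense.agreement import (
    ContingencyTable2x2,
    agreement_report,
    cohens_kappa,
    cohens_kappa_confusion,
    crosstab,
    expected_agreement_hypergeometric,
    phi,
    reconstruct_table,
    spearman_rho,
    stratified_agreement,
    table_to_binary_vectors,
)
from frailsense.errors import DegenerateTableError


class TestCrosstab:
    def test_identity_pairs(self):
        t = crosstab([1, 0], [1, 0])
        assert (t.a, t.b, t.c, t.d) == (1, 0, 0, 1)

    def test_enumerated_cells(self):
        t = crosstab([1, 1, 0], [0, 1, 0])
        assert (t.a, t.b, t.c, t.d) == (1, 1, 0, 1)

    def test_missing_pairs_dropped(self):
        t = crosstab([1, None, 0, 1], [1, 1, None, 0])
        assert t.n == 2 and (t.a, t.b, t.c, t.d) == (1, 1, 0, 0)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            crosstab([1], [1, 0])


class TestCohensKappa:
    def test_perfect_agreement(self):
        assert cohens_kappa(ContingencyTable2x2(6, 0, 0, 15)).kappa == pytest.approx(1.0)

    def test_slowness_table_hand_computed(self):
        # p_o = 15/21, p_e = 207/441 -> kappa = 54/117... = 0.462
        res = cohens_kappa(ContingencyTable2x2(6, 0, 6, 9))
        assert res.kappa == pytest.approx(0.462, abs=1e-3)
        assert res.p == pytest.approx(0.012, abs=2e-3)

    def test_male_stratum_table(self):
        res = cohens_kappa(ContingencyTable2x2(1, 1, 0, 9))
        assert res.kappa == pytest.approx(0.621, abs=1e-3)
        assert res.p == pytest.approx(0.026, abs=2e-3)

    def test_transpose_invariance(self):
        t = ContingencyTable2x2(5, 2, 7, 9)
        assert cohens_kappa(t).kappa == pytest.approx(
            cohens_kappa(t.transpose()).kappa, abs=1e-12
        )

    def test_degenerate_marginals_signalled(self):
        with pytest.raises(DegenerateTableError):
            cohens_kappa(ContingencyTable2x2(0, 0, 0, 10))

    def test_zero_when_observed_equals_expected(self):
        # independence: a/n = row*col marginal product
        res = cohens_kappa(ContingencyTable2x2(1, 1, 4, 4))
        assert res.kappa == pytest.approx(0.0, abs=1e-12)

    def test_matches_statsmodels(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            cells = rng.integers(1, 12, size=4)
            t = ContingencyTable2x2(*cells)
            ours = cohens_kappa(t).kappa
            theirs = sm_kappa(t.as_matrix(), return_results=False)
            assert ours == pytest.approx(float(theirs), abs=1e-10)

    def test_kappa_one_iff_no_disagreement(self):
        assert cohens_kappa(ContingencyTable2x2(3, 0, 0, 7)).kappa == 1.0
        assert cohens_kappa(ContingencyTable2x2(3, 1, 0, 7)).kappa < 1.0

    def test_exhaustive_small_n_vs_hypergeometric_chance(self):
        # chance agreement from the closed-form marginal product must
        # equal the brute-force expectation over all same-margin tables
        for n in range(2, 13):
            for a in range(n + 1):
                for b in range(n - a + 1):
                    for c in range(n - a - b + 1):
                        t = ContingencyTable2x2(a, b, c, n - a - b - c)
                        try:
                            res = cohens_kappa(t)
                        except DegenerateTableError:
                            continue
                        p_e = expected_agreement_hypergeometric(t)
                        p_o = (t.a + t.d) / t.n
                        brute = (p_o - p_e) / (1 - p_e)
                        assert res.kappa == pytest.approx(brute, abs=1e-9)


class TestSpearmanAndPhi:
    def test_monotone_pairing_is_one(self):
        r = spearman_rho([1, 2, 3, 4], [10, 20, 30, 40])
        assert r.rho == pytest.approx(1.0) and r.p == 0.0

    def test_df_is_n_minus_2(self):
        assert spearman_rho(list(range(21)), list(range(21))).df == 19

    @pytest.mark.parametrize(
        "table,expected",
        [
            (ContingencyTable2x2(6, 0, 6, 9), 0.548),
            (ContingencyTable2x2(1, 4, 2, 14), 0.091),
            (ContingencyTable2x2(3, 0, 2, 16), 0.730),
        ],
    )
    def test_binary_spearman_matches_reported_phi(self, table, expected):
        x, y = table_to_binary_vectors(table)
        assert spearman_rho(x, y).rho == pytest.approx(expected, abs=1e-3)
        assert phi(table) == pytest.approx(expected, abs=1e-3)

    def test_phi_extremes(self):
        assert phi(ContingencyTable2x2(1, 0, 0, 1)) == pytest.approx(1.0)
        assert phi(ContingencyTable2x2(0, 1, 1, 0)) == pytest.approx(-1.0)

    def test_phi_zero_margin_signalled(self):
        with pytest.raises(DegenerateTableError):
            phi(ContingencyTable2x2(2, 0, 3, 0))

    def test_zero_variance_signalled(self):
        with pytest.raises(DegenerateTableError):
            spearman_rho([1, 1, 1, 1], [0, 1, 0, 1])

    def test_matches_scipy_with_ties(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            x = rng.integers(0, 4, size=15).astype(float)
            y = (x + rng.normal(0, 1.2, size=15)).round()
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            ours = spearman_rho(x, y)
            ref = stats.spearmanr(x, y)
            assert ours.rho == pytest.approx(float(ref.statistic), abs=1e-12)
            assert ours.p == pytest.approx(float(ref.pvalue), abs=1e-9)

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(
        a=st.integers(0, 20), b=st.integers(0, 20),
        c=st.integers(0, 20), d=st.integers(0, 20),
    )
    def test_binary_spearman_equals_phi(self, a, b, c, d):
        if a + b + c + d < 3:
            return
        table = ContingencyTable2x2(a, b, c, d)
        try:
            expected = phi(table)
        except DegenerateTableError:
            return
        x, y = table_to_binary_vectors(table)
        assert spearman_rho(x, y).rho == pytest.approx(expected, abs=1e-12)


class TestReconstruction:
    @pytest.mark.parametrize(
        "m1,m2,kappa,cells",
        [
            ((6, 15), (12, 9), 0.462, (6, 0, 6, 9)),
            ((5, 16), (3, 18), 0.087, (1, 4, 2, 14)),
            ((3, 18), (5, 16), 0.696, (3, 0, 2, 16)),
        ],
    )
    def test_recovers_unique_table(self, m1, m2, kappa, cells):
        t = reconstruct_table(m1, m2, kappa)
        assert (t.a, t.b, t.c, t.d) == cells
        assert cohens_kappa(t).kappa == pytest.approx(kappa, abs=0.005)

    def test_infeasible_margins(self):
        with pytest.raises(ValueError):
            reconstruct_table((5, 5), (3, 18), 0.5)

    def test_no_match_within_tolerance(self):
        with pytest.raises(ValueError, match="deviates"):
            reconstruct_table((6, 15), (12, 9), 0.99)


class TestStratifiedAgreement:
    def test_per_stratum_reports(self):
        # stratum A: the male-stratum table (1,1,0,9); stratum B: perfect
        l1 = [1, 1, 0, 0, 0, 0, 0, 0, 0, 0, 0] + [1, 0, 0, 0]
        l2 = [1, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0] + [1, 0, 0, 0]
        strata = ["A"] * 11 + ["B"] * 4
        reps = stratified_agreement(l1, l2, strata)
        assert reps["A"].kappa == pytest.approx(0.621, abs=1e-3)
        assert reps["B"].kappa == pytest.approx(1.0)

    def test_degenerate_stratum_flagged(self):
        reps = stratified_agreement([0, 0, 0], [0, 0, 0], ["A"] * 3)
        assert reps["A"].degenerate and reps["A"].kappa is None

    def test_identical_strata_identical_reports(self):
        l1, l2 = [1, 0, 1, 0], [1, 0, 0, 0]
        reps = stratified_agreement(l1 * 2, l2 * 2, ["A"] * 4 + ["B"] * 4)
        assert reps["A"] == reps["B"]


def test_agreement_report_end_to_end():
    l1 = [1] * 6 + [0] * 15
    l2 = [1] * 6 + [1] * 6 + [0] * 9
    rep = agreement_report(l1, l2)
    assert rep.kappa == pytest.approx(0.462, abs=1e-3)
    assert rep.rho == pytest.approx(0.548, abs=1e-3)
    assert rep.rho_df == 19 and rep.n == 21
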