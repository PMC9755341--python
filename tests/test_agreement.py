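import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from hmquant import agreement
from hmquant.errors import DegenerateInputError, DegenerateTableError, ValidationError


# ---------------------------------------------------------------------------
# Independent oracles (direct summation / hand formulas)
# ---------------------------------------------------------------------------

def oracle_icc(matrix, form):
    """Variance components by explicit per-cell summation."""
    m = [list(map(float, row)) for row in matrix]
    n, k = len(m), len(m[0])
    grand = sum(sum(row) for row in m) / (n * k)
    row_means = [sum(row) / k for row in m]
    col_means = [sum(m[i][j] for i in range(n)) / n for j in range(k)]
    ssr = k * sum((rm - grand) ** 2 for rm in row_means)
    ssc = n * sum((cm - grand) ** 2 for cm in col_means)
    sse = sum(
        (m[i][j] - row_means[i] - col_means[j] + grand) ** 2
        for i in range(n) for j in range(k)
    )
    msr, msc, mse = ssr / (n - 1), ssc / (k - 1), sse / ((n - 1) * (k - 1))
    if form == "icc2":
        return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    if form == "icc3":
        return (msr - mse) / (msr + (k - 1) * mse)
    raise ValueError(form)


def oracle_fleiss(matrix):
    rows = [list(r) for r in matrix]
    n, k = len(rows), len(rows[0])
    cats = sorted({v for r in rows for v in r})
    p_sum = 0.0
    totals = {c: 0 for c in cats}
    for r in rows:
        agree = 0
        for c in cats:
            nij = r.count(c)
            totals[c] += nij
            agree += nij * (nij - 1)
        p_sum += agree / (k * (k - 1))
    p_bar = p_sum / n
    p_e = sum((totals[c] / (n * k)) ** 2 for c in cats)
    return (p_bar - p_e) / (1 - p_e)


def oracle_cohen(table):
    t = [list(map(float, r)) for r in table]
    n = sum(sum(r) for r in t)
    p_o = sum(t[i][i] for i in range(len(t))) / n
    p_e = sum(
        sum(t[i]) * sum(t[j][i] for j in range(len(t))) for i in range(len(t))
    ) / n**2
    return (p_o - p_e) / (1 - p_e)


def oracle_ranks(v):
    """Average ranks computed by explicit comparison counting."""
    out = []
    for x in v:
        less = sum(1 for y in v if y < x)
        equal = sum(1 for y in v if y == x)
        out.append(less + (equal + 1) / 2.0)
    return out


def oracle_chi2(table):
    t = [list(map(float, r)) for r in table]
    n = sum(sum(r) for r in t)
    rows = [sum(r) for r in t]
    cols = [sum(t[i][j] for i in range(2)) for j in range(2)]
    stat = 0.0
    for i in range(2):
        for j in range(2):
            e = rows[i] * cols[j] / n
            stat += (t[i][j] - e) ** 2 / e
    return stat


# ---------------------------------------------------------------------------
# ICC
# ---------------------------------------------------------------------------

FIXTURE_6x3 = np.array(
    [[1, 2, 3], [2, 3, 4], [3, 4, 5], [4, 5, 6], [5, 6, 7], [6, 7, 8]], dtype=float
)


class TestICC:
    def test_identical_columns_give_one(self):
        m = np.tile(np.arange(1.0, 7.0)[:, None], (1, 3))
        res = agreement.icc(m)
        assert res.estimate == 1.0
        assert res.ci_low == res.ci_high == 1.0

    def test_fixture_matches_brute_force_oracle(self):
        for form in ("icc2", "icc3"):
            mine = agreement.icc(FIXTURE_6x3, form).estimate
            assert mine == pytest.approx(oracle_icc(FIXTURE_6x3, form), abs=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_random_matrices_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        m = rng.normal(size=(10, 4)) + rng.normal(size=(10, 1)) * 1.5
        for form in ("icc2", "icc3"):
            assert agreement.icc(m, form).estimate == pytest.approx(
                oracle_icc(m, form), abs=1e-10
            )

    def test_column_offset_lowers_absolute_agreement_only(self):
        rng = np.random.default_rng(3)
        m = rng.normal(size=(12, 3)) + rng.normal(size=(12, 1)) * 2
        shifted = m.copy()
        shifted[:, 0] += 1.5
        assert agreement.icc(shifted, "icc2").estimate < agreement.icc(m, "icc2").estimate
        assert agreement.icc(shifted, "icc3").estimate == pytest.approx(
            agreement.icc(m, "icc3").estimate, abs=1e-10
        )
        # the same ordering holds under the oracle
        assert oracle_icc(shifted, "icc2") < oracle_icc(m, "icc2")

    def test_matches_pingouin_estimates_and_cis(self):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(0)
        m = rng.normal(size=(12, 4)) + rng.normal(size=(12, 1)) * 2 + np.array([0, 0.3, 0.6, 0.1])
        df = pd.DataFrame(
            {"s": np.repeat(range(12), 4), "r": list(range(4)) * 12, "v": m.ravel()}
        )
        pg = pingouin.intraclass_corr(df, targets="s", raters="r", ratings="v")
        for form, label in (("icc1", "ICC(1,1)"), ("icc2", "ICC(A,1)"), ("icc3", "ICC(C,1)")):
            row = pg[pg.Type == label].iloc[0]
            mine = agreement.icc(m, form)
            assert mine.estimate == pytest.approx(row.ICC, abs=1e-10)
            assert mine.ci_low == pytest.approx(row.CI95[0], abs=5e-3)
            assert mine.ci_high == pytest.approx(row.CI95[1], abs=5e-3)

    def test_zero_variance_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            agreement.icc(np.full((5, 3), 2.0))

    def test_ci_brackets_estimate(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            m = rng.normal(size=(8, 3)) + rng.normal(size=(8, 1))
            res = agreement.icc(m)
            assert res.ci_low <= res.estimate <= res.ci_high

    def test_shape_validation(self):
        with pytest.raises(ValidationError):
            agreement.icc(np.ones((1, 3)))
        with pytest.raises(ValidationError):
            agreement.icc(np.ones(5))


# ---------------------------------------------------------------------------
# Fleiss kappa
# ---------------------------------------------------------------------------

class TestFleissKappa:
    def test_total_agreement_gives_one(self):
        m = np.array([[0, 0, 0], [1, 1, 1], [0, 0, 0], [1, 1, 1]])
        res = agreement.fleiss_kappa(m, ci_method="none")
        assert res.estimate == pytest.approx(1.0, abs=1e-12)

    def test_hand_evaluated_example(self):
        # per-subject pathological counts (3,2,1,0) over 3 raters:
        # P_bar = (1 + 1/3 + 1/3 + 1)/4 = 2/3, P_e = 0.5, kappa = 1/3
        m = np.array([[1, 1, 1], [1, 1, 0], [1, 0, 0], [0, 0, 0]])
        res = agreement.fleiss_kappa(m, ci_method="none")
        assert res.estimate == pytest.approx(1.0 / 3.0, abs=1e-12)
        assert res.estimate == pytest.approx(oracle_fleiss(m.tolist()), abs=1e-12)

    def test_independent_random_ratings_near_zero(self):
        rng = np.random.default_rng(42)
        m = rng.integers(0, 2, size=(2000, 3))
        res = agreement.fleiss_kappa(m, ci_method="none")
        assert abs(res.estimate) < 0.05

    @pytest.mark.parametrize("seed", range(5))
    def test_random_tables_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        m = rng.integers(0, 2, size=(15, 4))
        if len(np.unique(m)) < 2:
            return
        res = agreement.fleiss_kappa(m, ci_method="none")
        assert res.estimate == pytest.approx(oracle_fleiss(m.tolist()), abs=1e-10)

    def test_single_category_is_degenerate(self):
        res = agreement.fleiss_kappa(np.ones((6, 3), dtype=int))
        assert res.degenerate

    def test_bootstrap_ci_brackets_estimate(self):
        rng = np.random.default_rng(0)
        m = rng.integers(0, 2, size=(30, 3))
        res = agreement.fleiss_kappa(m, n_boot=500, seed=1)
        assert res.ci_low <= res.estimate <= res.ci_high

    def test_bootstrap_is_seeded(self):
        rng = np.random.default_rng(0)
        m = rng.integers(0, 2, size=(30, 3))
        a = agreement.fleiss_kappa(m, n_boot=200, seed=7)
        b = agreement.fleiss_kappa(m, n_boot=200, seed=7)
        assert a == b

    def test_two_raters_equals_cohen_on_homogeneous_marginals(self):
        # both raters use each category equally often -> pooled and
        # per-rater chance agreement coincide
        a = np.array([0, 0, 1, 1, 0, 1])
        b = np.array([0, 1, 0, 1, 1, 0])
        fl = agreement.fleiss_kappa(np.column_stack([a, b]), ci_method="none")
        co = agreement.cohens_kappa(a, b)
        assert fl.estimate == pytest.approx(co.estimate, abs=1e-12)

    def test_two_raters_general_case_computes(self):
        rng = np.random.default_rng(5)
        m = rng.integers(0, 2, size=(20, 2))
        res = agreement.fleiss_kappa(m, ci_method="none")
        assert -1.0 <= res.estimate <= 1.0

    def test_bootstrap_coverage_of_known_kappa(self):
        """Percentile-bootstrap coverage at the nominal 95% level stays in
        [90%, 99%] for a latent-class rating process with known kappa."""
        n, p, q = 80, 0.5, 0.9
        p_o = q * q + (1 - q) * (1 - q)
        marg = p * q + (1 - p) * (1 - q)
        p_e = marg**2 + (1 - marg) ** 2
        kappa_true = (p_o - p_e) / (1 - p_e)
        rng = np.random.default_rng(1234)
        covered = 0
        n_rep = 500
        for _ in range(n_rep):
            latent = rng.random(n) < p
            ratings = ((rng.random((n, 3)) < q) == latent[:, None]).astype(int)
            res = agreement.fleiss_kappa(ratings, n_boot=1000, seed=int(rng.integers(2**31)))
            if res.degenerate:
                continue
            covered += res.ci_low <= kappa_true <= res.ci_high
        assert 0.90 <= covered / n_rep <= 0.99


# ---------------------------------------------------------------------------
# Cohen kappa
# ---------------------------------------------------------------------------

class TestCohenKappa:
    def test_identical_columns_give_one(self):
        a = np.array([0, 1, 0, 1, 1])
        assert agreement.cohens_kappa(a, a).estimate == pytest.approx(1.0)

    def test_cross_table_example(self):
        # [[20,5],[10,15]]: p_o = 0.7, p_e = 0.5, kappa = 0.4
        res = agreement.cohens_kappa_from_table([[20, 5], [10, 15]])
        assert res.estimate == pytest.approx(0.4, abs=1e-12)
        assert res.estimate == pytest.approx(oracle_cohen([[20, 5], [10, 15]]), abs=1e-12)

    def test_perfect_disagreement(self):
        res = agreement.cohens_kappa_from_table([[0, 10], [10, 0]])
        assert res.estimate == pytest.approx(-1.0, abs=1e-12)

    def test_degenerate_when_chance_agreement_is_one(self):
        res = agreement.cohens_kappa(np.zeros(10, dtype=int), np.zeros(10, dtype=int))
        assert res.degenerate

    def test_column_length_validation(self):
        with pytest.raises(ValidationError):
            agreement.cohens_kappa([0, 1], [0, 1, 1])

    @pytest.mark.parametrize("seed", range(5))
    def test_random_columns_match_oracle_table(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.integers(0, 2, 40)
        b = rng.integers(0, 2, 40)
        table = [[int(((a == i) & (b == j)).sum()) for j in (0, 1)] for i in (0, 1)]
        assert agreement.cohens_kappa(a, b).estimate == pytest.approx(
            oracle_cohen(table), abs=1e-10
        )


# ---------------------------------------------------------------------------
# Spearman
# ---------------------------------------------------------------------------

class TestSpearman:
    def test_monotone_gives_one(self):
        x = np.arange(1.0, 11.0)
        res = agreement.spearman_rho(x, x**3)
        assert res.rho == 1.0 and res.p == 0.0

    def test_antitone_gives_minus_one(self):
        x = np.arange(1.0, 11.0)
        assert agreement.spearman_rho(x, -x).rho == -1.0

    def test_tied_fixture_matches_rank_oracle(self):
        x = [1, 2, 2, 4]
        y = [1, 3, 2, 4]
        rx, ry = oracle_ranks(x), oracle_ranks(y)
        expected = np.corrcoef(rx, ry)[0, 1]
        assert agreement.spearman_rho(x, y).rho == pytest.approx(expected, abs=1e-12)

    def test_matches_scipy(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=25)
        y = x + rng.normal(size=25)
        res = agreement.spearman_rho(x, y)
        ref = sps.spearmanr(x, y)
        assert res.rho == pytest.approx(ref.statistic, abs=1e-12)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_constant_input_is_flagged(self):
        res = agreement.spearman_rho([1, 1, 1, 1], [1, 2, 3, 4])
        assert res.undefined

    def test_length_validation(self):
        with pytest.raises(ValidationError):
            agreement.spearman_rho([1, 2], [1, 2])


# ---------------------------------------------------------------------------
# Chi-square / McNemar
# ---------------------------------------------------------------------------

class TestChiSquare:
    def test_balanced_table_is_zero(self):
        res = agreement.chi_square_2x2([[10, 10], [10, 10]])
        assert res.statistic == 0.0 and res.p == 1.0

    def test_pathological_proportion_example(self):
        # 32/35 vs 26/35 pathological; expected counts (29,6,29,6)
        table = [[32, 3], [26, 9]]
        res = agreement.chi_square_2x2(table)
        assert res.statistic == pytest.approx(oracle_chi2(table), abs=1e-10)
        assert res.statistic == pytest.approx(3.6207, abs=1e-3)

    def test_swap_symmetry(self):
        t = np.array([[12, 5], [7, 16]])
        a = agreement.chi_square_2x2(t)
        b = agreement.chi_square_2x2(t[::-1, ::-1])
        assert a.statistic == pytest.approx(b.statistic, abs=1e-12)

    def test_matches_scipy_without_correction(self):
        t = [[18, 7], [11, 14]]
        res = agreement.chi_square_2x2(t)
        ref = sps.chi2_contingency(t, correction=False)
        assert res.statistic == pytest.approx(ref.statistic, abs=1e-10)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_yates_flag(self):
        t = [[18, 7], [11, 14]]
        ref = sps.chi2_contingency(t, correction=True)
        res = agreement.chi_square_2x2(t, correction=True)
        assert res.statistic == pytest.approx(ref.statistic, abs=1e-10)

    def test_zero_margin_is_degenerate(self):
        with pytest.raises(DegenerateTableError):
            agreement.chi_square_2x2([[0, 0], [5, 10]])

    def test_mcnemar_basic(self):
        res = agreement.mcnemar([[20, 5], [10, 15]], correction=False)
        assert res.statistic == pytest.approx((5 - 10) ** 2 / 15.0, abs=1e-12)
        with pytest.raises(DegenerateTableError):
            agreement.mcnemar([[20, 0], [0, 15]])


# ---------------------------------------------------------------------------
# Interpretive bands
# ---------------------------------------------------------------------------

class TestInterpret:
    @pytest.mark.parametrize(
        "kind,value,label",
        [
            ("fleiss", 0.45, "moderate"),
            ("fleiss", 0.78, "good"),
            ("fleiss", 0.10, "poor"),
            ("fleiss", 0.95, "very good"),
            ("cohen", 0.90, "perfect"),
            ("cohen", 0.29, "fair"),
            ("cohen", 0.69, "substantial"),
            ("cohen", 0.54, "moderate"),
            ("cohen", 0.005, "poor"),
            ("icc", 0.94, "excellent"),
            ("icc", 0.85, "good"),
            ("icc", 0.60, "moderate"),
            ("icc", 0.40, "poor"),
        ],
    )
    def test_band_labels(self, kind, value, label):
        assert agreement.interpret(kind, value) == label

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValidationError):
            agreement.interpret("pearson", 0.5)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            agreement.interpret("icc", 1.5)


# ---------------------------------------------------------------------------
# Properties
# ---------------------------------------------------------------------------

@settings(max_examples=60, deadline=None)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_kappa_and_icc_bounded(seed):
    rng = np.random.default_rng(seed)
    n, k = int(rng.integers(3, 15)), int(rng.integers(2, 5))
    cats = rng.integers(0, 2, size=(n, k))
    fl = agreement.fleiss_kappa(cats, ci_method="none")
    if not fl.degenerate:
        assert -1.0 - 1e-9 <= fl.estimate <= 1.0 + 1e-9
    co = agreement.cohens_kappa(cats[:, 0], cats[:, 1])
    if not co.degenerate:
        assert -1.0 - 1e-9 <= co.estimate <= 1.0 + 1e-9
    cont = rng.normal(size=(n, k))
    try:
        res = agreement.icc(cont)
        assert -1.0 <= res.estimate <= 1.0
    except DegenerateInputError:
        pass


def test_subject_permutation_invariance():
    rng = np.random.default_rng(17)
    cont = rng.normal(size=(20, 3)) + rng.normal(size=(20, 1))
    cats = rng.integers(0, 2, size=(20, 3))
    perm = rng.permutation(20)
    assert agreement.icc(cont).estimate == pytest.approx(
        agreement.icc(cont[perm]).estimate, abs=1e-12
    )
    assert agreement.fleiss_kappa(cats, ci_method="none").estimate == pytest.approx(
        agreement.fleiss_kappa(cats[perm], ci_method="none").estimate, abs=1e-12
    )
    assert agreement.cohens_kappa(cats[:, 0], cats[:, 1]).estimate == pytest.approx(
        agreement.cohens_kappa(cats[perm, 0], cats[perm, 1]).estimate, abs=1e-12
    )
    x, y = rng.normal(size=20), rng.normal(size=20)
    assert agreement.spearman_rho(x, y).rho == pytest.approx(
        agreement.spearman_rho(x[perm], y[perm]).rho, abs=1e-12
    )
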