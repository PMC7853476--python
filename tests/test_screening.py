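"""Correlation screen: PCC/DCC estimators, BY-FDR, relevance, norm tables."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import gawkit as gk
from gawkit.battery import PARAMETER_COLUMNS
from gawkit.errors import DegenerateSignalError, GawkitError
from gawkit.screening import (
    by_fdr,
    dcc_permutation_p,
    distance_correlation,
    mukaka_category,
    norm_table,
    pearson,
    relevance_screen,
    run_screen,
)


def brute_force_dcor(x, y):
    """Independent explicit-loop double-centering estimator (O(n^2) memory-free)."""
    n = len(x)
    a = np.empty((n, n))
    b = np.empty((n, n))
    for j in range(n):
        for k in range(n):
            a[j, k] = abs(x[j] - x[k])
            b[j, k] = abs(y[j] - y[k])
    for m in (a, b):
        row = m.mean(axis=1)
        col = m.mean(axis=0)
        grand = m.mean()
        for j in range(n):
            for k in range(n):
                m[j, k] = m[j, k] - row[j] - col[k] + grand
    dcov2 = (a * b).mean()
    dvx = (a * a).mean()
    dvy = (b * b).mean()
    if dvx * dvy <= 0:
        return 0.0
    return float(np.sqrt(max(dcov2, 0.0) / np.sqrt(dvx * dvy)))


class TestPearson:
    def test_identity_and_inversion(self):
        x = np.array([1.0, 2, 3, 5, 8])
        assert pearson(x, x)[0] == pytest.approx(1.0)
        assert pearson(x, -x)[0] == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        r, p = pearson([1, 2, 3, 4], [1, 3, 2, 4])
        assert r == pytest.approx(0.8)
        assert 0 < p < 1

    def test_constant_input_rejected(self):
        with pytest.raises(DegenerateSignalError):
            pearson([1, 1, 1, 1], [1, 2, 3, 4])

    def test_pairwise_complete_deletion(self):
        x = np.array([1.0, 2, np.nan, 4, 5])
        y = np.array([2.0, 4, 6, np.nan, 10])
        r, _ = pearson(x, y)
        assert r == pytest.approx(1.0)  # remaining pairs are collinear


class TestDistanceCorrelation:
    def test_identity(self):
        x = np.arange(1, 21, dtype=float)
        assert distance_correlation(x, x) == pytest.approx(1.0, abs=1e-12)

    def test_affine_invariance(self):
        x = np.array([0.3, 1.2, -0.7, 2.2, 0.05, -1.4])
        assert distance_correlation(x, 3 * x + 2) == pytest.approx(1.0, abs=1e-12)
        y = np.array([1.0, 0.2, 0.6, -0.9, 2.0, 0.4])
        assert distance_correlation(x, y) == pytest.approx(
            distance_correlation(-2 * x + 1, y), abs=1e-12)

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        x, y = rng.standard_normal(25), rng.standard_normal(25)
        assert distance_correlation(x, y) == pytest.approx(
            distance_correlation(y, x), abs=1e-14)

    def test_quadratic_dependence_matches_oracle(self):
        x = np.array([1.0, 2, 3, 4, 5])
        assert distance_correlation(x, x**2) == pytest.approx(
            brute_force_dcor(x, x**2), abs=1e-12)

    def test_oracle_equivalence_on_random_instances(self):
        rng = np.random.default_rng(99)
        for _ in range(50):
            n = int(rng.integers(5, 31))
            x = rng.standard_normal(n)
            y = rng.standard_normal(n) + 0.5 * x
            assert distance_correlation(x, y) == pytest.approx(
                brute_force_dcor(x, y), abs=1e-10)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-1e3, 1e3), min_size=5, max_size=25, unique=True))
    def test_range_property(self, xs):
        x = np.asarray(xs)
        rng = np.random.default_rng(0)
        y = rng.standard_normal(len(x))
        d = distance_correlation(x, y)
        assert 0.0 <= d <= 1.0 + 1e-12


class TestPermutationP:
    def test_identity_attains_lower_bound(self):
        x = np.arange(30.0)
        assert dcc_permutation_p(x, x, n_perm=500, seed=1) == pytest.approx(1 / 501)

    def test_seeded_determinism(self):
        rng = np.random.default_rng(2)
        x, y = rng.standard_normal(30), rng.standard_normal(30)
        p1 = dcc_permutation_p(x, y, n_perm=300, seed=5)
        p2 = dcc_permutation_p(x, y, n_perm=300, seed=5)
        assert p1 == p2

    def test_null_p_values_approximately_uniform(self):
        """Under independence the permutation p-value is uniform on (0,1]:
        a KS test over 150 seeded replicates must not reject at alpha=0.01."""
        from scipy.stats import kstest

        rng = np.random.default_rng(3)
        pvals = []
        for _ in range(150):
            x = rng.standard_normal(30)
            y = rng.standard_normal(30)
            pvals.append(dcc_permutation_p(x, y, n_perm=200,
                                           seed=int(rng.integers(2**31))))
        assert kstest(pvals, "uniform").pvalue > 0.01


class TestByFdr:
    def test_hand_computed_example(self):
        adj, rej = by_fdr([0.01, 0.02, 0.04])
        # m=3, c(3)=1.8333: [0.055, 0.055, 0.0733] to 3 s.f.
        assert adj == pytest.approx([0.055, 0.055, 0.0733], rel=1e-3)
        assert not rej.any()

    def test_degenerate_inputs(self):
        adj, _ = by_fdr([1.0, 1.0, 1.0])
        assert (adj == 1.0).all()
        adj, _ = by_fdr([0.03])
        assert adj == pytest.approx([0.03])  # c(1) = 1

    def test_rejects_invalid_pvalues(self):
        with pytest.raises(ValueError):
            by_fdr([0.1, 1.2])

    def test_more_conservative_than_bh_and_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(8)
        p = rng.uniform(size=200)
        adj, rej = by_fdr(p)
        sm_by = multipletests(p, alpha=0.05, method="fdr_by")
        sm_bh = multipletests(p, alpha=0.05, method="fdr_bh")
        np.testing.assert_allclose(adj, sm_by[1], atol=1e-12)
        np.testing.assert_array_equal(rej, sm_by[0])
        assert (adj >= sm_bh[1] - 1e-12).all()


class TestRelevance:
    @pytest.mark.parametrize(
        "coef,p_adj,relevant,category",
        [
            (0.95, 0.001, True, "very high"),
            (0.29, 0.0001, False, "negligible"),
            (0.40, 0.2, False, "low"),
            (-0.55, 0.01, True, "moderate"),
        ],
    )
    def test_relevance_rule_and_bins(self, coef, p_adj, relevant, category):
        df = pd.DataFrame({"pcc": [coef], "pcc_p_adj": [p_adj],
                           "dcc": [abs(coef)], "dcc_p_adj": [p_adj]})
        out = relevance_screen(df)
        assert bool(out["relevant_pcc"][0]) is relevant
        assert out["category"][0] == category
        assert mukaka_category(coef) == category


class TestRunScreen:
    def test_shared_f0_pair_relevant_in_both_genders(self, small_cohort_params):
        screens = run_screen(small_cohort_params, n_perm=200, seed=3)
        for gender in ("female", "male"):
            df = screens[gender]
            assert len(df) == 490
            row = df[(df.gaw_param == "gaw_F0_Mean_Hz")
                     & (df.acoustic_param == "ac_F0_Mean_Hz")].iloc[0]
            assert row.pcc >= 0.9
            assert row.relevant_pcc
            # DCC magnitude matches, and its permutation p sits at the floor;
            # with 200 permutations the floor (1/201) cannot survive a BY
            # correction over 490 tests, so only the coefficient is asserted
            assert row.dcc >= 0.9
            assert row.dcc_p_raw == pytest.approx(1 / 201)
            assert row.category == "very high"

    def test_subject_order_invariance(self, small_cohort_params):
        shuffled = small_cohort_params.sample(frac=1.0, random_state=4).reset_index(drop=True)
        a = run_screen(small_cohort_params, n_perm=200, seed=1, compute_dcc=False)
        b = run_screen(shuffled, n_perm=200, seed=1, compute_dcc=False)
        np.testing.assert_allclose(a["female"]["pcc"], b["female"]["pcc"], atol=1e-12)

    def test_adjusted_never_below_raw(self, small_cohort_params):
        df = run_screen(small_cohort_params, n_perm=200, seed=2)["female"]
        assert (df["pcc_p_adj"] >= df["pcc_p_raw"] - 1e-12).all()
        assert (df["dcc_p_adj"] >= df["dcc_p_raw"] - 1e-12).all()

    def test_too_few_subjects_names_gender(self, small_cohort_params):
        females_only = small_cohort_params[
            small_cohort_params.group.isin(["NF", "FDF"])]
        with pytest.raises(GawkitError, match="male"):
            run_screen(females_only, n_perm=200)

    def test_null_columns_rarely_flagged(self):
        """Independent columns: BY-corrected screen keeps false relevant
        pairs to a small fraction (light, single-replicate check)."""
        rng = np.random.default_rng(12)
        df = pd.DataFrame(rng.standard_normal((90, 49)), columns=list(PARAMETER_COLUMNS))
        df.insert(0, "group", ["NF"] * 45 + ["NM"] * 45)
        df.insert(0, "subject_id", [f"s{i}" for i in range(90)])
        sc = run_screen(df, n_perm=200, seed=5)
        for gender in ("female", "male"):
            assert sc[gender]["relevant_pcc"].sum() <= 490 * 0.05


class TestNormTable:
    def test_moment_definitions_on_known_samples(self):
        from scipy.stats import kurtosis, skew

        cols = {c: np.zeros(5) for c in PARAMETER_COLUMNS}
        cols["gaw_F0_Mean_Hz"] = np.array([-2.0, -1, 0, 1, 2])  # symmetric
        df = pd.DataFrame(cols)
        df.insert(0, "group", "NF")
        df.insert(0, "subject_id", [f"s{i}" for i in range(5)])
        nt = norm_table(df, groups=("NF",))
        row = nt[nt.parameter == "gaw_F0_Mean_Hz"].iloc[0]
        assert row["skewness"] == pytest.approx(0.0, abs=1e-12)
        assert row["median"] == 0.0 and row["min"] == -2 and row["max"] == 2
        assert row["kurtosis"] == pytest.approx(kurtosis([-2, -1, 0, 1, 2]))
        assert row["skewness"] == pytest.approx(skew([-2, -1, 0, 1, 2]))

    def test_constant_column_higher_moments_missing(self):
        cols = {c: np.ones(4) for c in PARAMETER_COLUMNS}
        df = pd.DataFrame(cols)
        df.insert(0, "group", "FDM")
        df.insert(0, "subject_id", [f"s{i}" for i in range(4)])
        nt = norm_table(df, groups=("FDM",))
        row = nt.iloc[0]
        assert row["std"] == 0.0
        assert np.isnan(row["skewness"]) and np.isnan(row["kurtosis"])

    def test_empty_group_rows_have_zero_n(self, small_cohort_params):
        nt = norm_table(small_cohort_params[small_cohort_params.group != "FDM"])
        fdm = nt[nt.group == "FDM"]
        assert (fdm["n"] == 0).all()
        assert fdm["mean"].isna().all()

    def test_large_normal_sample_kurtosis_near_zero(self):
        rng = np.random.default_rng(44)
        cols = {c: np.zeros(10000) for c in PARAMETER_COLUMNS}
        cols["ac_CPP_dB"] = rng.standard_normal(10000)
        df = pd.DataFrame(cols)
        df.insert(0, "group", "NF")
        df.insert(0, "subject_id", [f"s{i}" for i in range(10000)])
        nt = norm_table(df, groups=("NF",))
        row = nt[nt.parameter == "ac_CPP_dB"].iloc[0]
        assert row["kurtosis"] == pytest.approx(0.0, abs=0.1)

    def test_min_le_median_le_max_invariant(self, small_cohort_params):
        nt = norm_table(small_cohort_params)
        ok = nt.dropna(subset=["min", "median", "max"])
        assert (ok["min"] <= ok["median"]).all()
        assert (ok["median"] <= ok["max"]).all()
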