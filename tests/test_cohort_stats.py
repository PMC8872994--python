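"""Kruskal-Wallis, Dunn's post hoc, repeated-measures correlation, diagnostics."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from mifquant import (
    CohortSimParams,
    RepeatedMeasuresCorrelation,
    bootstrap_rmcorr,
    distribution_diagnostics,
    dunn_posthoc,
    kruskal_wallis,
    rmcorr,
    run_longitudinal_report,
    simulate_cohort,
)
from mifquant.cohort_stats import sidak_adjust
from mifquant.exceptions import (
    InsufficientDataError,
    InvalidInputError,
    SchemaError,
    UndefinedCorrelationError,
)


# ---------------------------------------------------------------------------
# Kruskal-Wallis
# ---------------------------------------------------------------------------


class TestKruskalWallis:
    def test_worked_three_group_example(self):
        # ranks are 1..9, rank sums (6, 15, 24):
        # H = 12/(9*10) * (36 + 225 + 576)/3 - 3*10 = 7.2
        values = [1, 2, 3, 4, 5, 6, 7, 8, 9]
        groups = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        res = kruskal_wallis(values, groups)
        assert res.H == pytest.approx(7.2, abs=1e-12)
        assert res.df == 2

    def test_identical_groups_give_zero_H_unit_p(self):
        res = kruskal_wallis([5, 5, 5, 5, 5, 5], ["a", "a", "b", "b", "c", "c"])
        assert res.H == 0.0
        assert res.p == 1.0

    def test_chi_square_p_close_to_exact_permutation_for_small_n(self):
        # exhaustive two-group permutation distribution, N = 8
        values = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0])
        groups = np.array(["a"] * 4 + ["b"] * 4)
        obs = kruskal_wallis(values, groups)
        hs = []
        for comb in itertools.combinations(range(8), 4):
            g = np.array(["b"] * 8)
            g[list(comb)] = "a"
            hs.append(kruskal_wallis(values, g).H)
        p_perm = np.mean(np.asarray(hs) >= obs.H - 1e-12)
        assert abs(obs.p - p_perm) < 0.01

    def test_empty_group_is_invalid(self):
        with pytest.raises(InvalidInputError):
            kruskal_wallis([1.0, 2.0, np.nan], ["a", "a", "b"])


# ---------------------------------------------------------------------------
# Dunn's post hoc
# ---------------------------------------------------------------------------


def _dunn_z_oracle(values, groups):
    """Independent direct computation of Dunn z from pooled rank means."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    ranks = sps.rankdata(values)
    labels = list(pd.unique(groups))
    n = len(values)
    _, t = np.unique(values, return_counts=True)
    ties = np.sum(t**3 - t)
    out = {}
    for ga, gb in itertools.combinations(labels, 2):
        ra, rb = ranks[groups == ga].mean(), ranks[groups == gb].mean()
        na, nb = (groups == ga).sum(), (groups == gb).sum()
        se = np.sqrt((n * (n + 1) / 12 - ties / (12 * (n - 1))) * (1 / na + 1 / nb))
        out[(ga, gb)] = (ra - rb) / se
    return out


class TestDunnPosthoc:
    def test_z_matches_independent_rank_mean_computation(self):
        rng = np.random.default_rng(4)
        values = np.round(rng.normal(size=30), 1)  # rounding creates ties
        groups = np.repeat(["a", "b", "c"], 10)
        res = dunn_posthoc(values, groups)
        oracle = _dunn_z_oracle(values, groups)
        for _, row in res.pairs.iterrows():
            assert row["z"] == pytest.approx(oracle[(row["group_a"], row["group_b"])],
                                             abs=1e-10)

    def test_sidak_with_single_pair_is_identity(self):
        res = dunn_posthoc([1, 2, 3, 7, 8, 9], ["a"] * 3 + ["b"] * 3, adjust="sidak")
        assert len(res.pairs) == 1
        assert res.pairs.loc[0, "p_adj"] == pytest.approx(res.pairs.loc[0, "p_raw"])

    def test_zero_raw_p_stays_zero_under_both_adjustments(self):
        assert sidak_adjust(np.array([0.0]), m=3)[0] == 0.0
        assert sps.false_discovery_control(np.array([0.0, 0.5]), method="bh")[0] == 0.0

    @pytest.mark.parametrize("adjust", ["sidak", "bh"])
    def test_adjusted_p_dominates_raw_and_preserves_order(self, adjust):
        rng = np.random.default_rng(8)
        values = np.concatenate([rng.normal(mu, 1, 10) for mu in (0, 0.5, 1.0, 1.5)])
        groups = np.repeat(list("abcd"), 10)
        res = dunn_posthoc(values, groups, adjust=adjust)
        assert (res.pairs["p_adj"] >= res.pairs["p_raw"] - 1e-15).all()
        order_raw = res.pairs.sort_values("p_raw").index
        adj_sorted = res.pairs.loc[order_raw, "p_adj"].to_numpy()
        assert (np.diff(adj_sorted) >= -1e-12).all()


# ---------------------------------------------------------------------------
# Repeated-measures correlation
# ---------------------------------------------------------------------------


def _rmcorr_ancova_oracle(table, x, y):
    """Brute-force ANCOVA via explicit least squares on the dummy design."""
    subjects = pd.unique(table["subject_id"])
    dummies = (table["subject_id"].to_numpy()[:, None] == subjects[None, :]).astype(float)
    X_full = np.column_stack([dummies, table[x].to_numpy()])
    yv = table[y].to_numpy()
    beta, *_ = np.linalg.lstsq(X_full, yv, rcond=None)
    resid_full = yv - X_full @ beta
    beta0, *_ = np.linalg.lstsq(dummies, yv, rcond=None)
    resid_reduced = yv - dummies @ beta0
    ss_err = resid_full @ resid_full
    ss_x = resid_reduced @ resid_reduced - ss_err
    r = np.sign(beta[-1]) * np.sqrt(ss_x / (ss_x + ss_err))
    df = len(yv) - len(subjects) - 1
    t = r * np.sqrt(df) / np.sqrt(1 - r**2)
    p = 2 * sps.t.sf(abs(t), df)
    return r, df, p


def _fixture_table(seed=0, n_subj=8, noise=1.0):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_subj):
        c = rng.normal(0, 5)
        for t in range(3):
            x = rng.normal(t, 1)
            rows.append({"subject_id": f"s{i}", "x": x,
                         "y": 0.7 * x + c + noise * rng.normal()})
    return pd.DataFrame(rows)


class TestRmcorr:
    def test_perfect_within_subject_line_gives_plus_one(self):
        t = _fixture_table(noise=0.0)
        t["y"] = t["x"] + t.groupby("subject_id")["x"].transform("size")  # x + c_i
        res = rmcorr(t, "x", "y")
        assert res.r == pytest.approx(1.0)
        assert res.pvalue == 0.0

    def test_sign_symmetry_gives_minus_one(self):
        t = _fixture_table(noise=0.0)
        t["y"] = -t["x"] + 3.0
        res = rmcorr(t, "x", "y")
        assert res.r == pytest.approx(-1.0)

    def test_matches_normal_equations_ancova_oracle(self):
        t = _fixture_table(seed=3)
        res = rmcorr(t, "x", "y")
        r0, df0, p0 = _rmcorr_ancova_oracle(t, "x", "y")
        assert res.r == pytest.approx(r0, abs=1e-10)
        assert res.df == df0
        assert res.pvalue == pytest.approx(p0, abs=1e-10)

    def test_matches_pingouin_cross_check(self):
        pingouin = pytest.importorskip("pingouin")
        t = _fixture_table(seed=5)
        res = rmcorr(t, "x", "y")
        pg = pingouin.rm_corr(data=t, x="x", y="y", subject="subject_id")
        assert res.r == pytest.approx(float(pg["r"].iloc[0]), abs=1e-8)
        assert res.df == int(pg["dof"].iloc[0])
        assert res.pvalue == pytest.approx(float(pg["pval"].iloc[0]), rel=1e-6)

    def test_invariant_to_subject_specific_offsets(self):
        t = _fixture_table(seed=9)
        res0 = rmcorr(t, "x", "y")
        shifted = t.copy()
        offs = {s: k * 11.0 for k, s in enumerate(pd.unique(t["subject_id"]))}
        shifted["x"] = shifted["x"] + shifted["subject_id"].map(offs)
        shifted["y"] = shifted["y"] - 3 * shifted["subject_id"].map(offs)
        res1 = rmcorr(shifted, "x", "y")
        assert res1.r == pytest.approx(res0.r, abs=1e-12)

    def test_equals_pearson_when_intercepts_identical(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=30)
        y = 0.5 * x + rng.normal(size=30)
        t = pd.DataFrame({"subject_id": np.repeat([f"s{i}" for i in range(10)], 3),
                          "x": x, "y": y})
        # centering within subject, then Pearson on the centered data
        xc = x - t.groupby("subject_id")["x"].transform("mean")
        yc = y - t.groupby("subject_id")["y"].transform("mean")
        r_pearson = np.corrcoef(xc, yc)[0, 1]
        assert rmcorr(t, "x", "y").r == pytest.approx(r_pearson, abs=1e-10)

    def test_zero_within_subject_x_variance_is_undefined(self):
        t = pd.DataFrame({"subject_id": list("aabb"), "x": [1.0, 1.0, 2.0, 2.0],
                          "y": [0.0, 1.0, 2.0, 3.0]})
        with pytest.raises(UndefinedCorrelationError):
            rmcorr(t, "x", "y")

    def test_insufficient_df_raises(self):
        t = pd.DataFrame({"subject_id": list("ab"), "x": [1.0, 2.0], "y": [1.0, 2.0]})
        with pytest.raises(InsufficientDataError):
            rmcorr(t, "x", "y")

    def test_summary_mentions_estimate(self):
        res = rmcorr(_fixture_table(), "x", "y")
        text = res.summary()
        assert f"{res.r:.4f}" in text and "df" in text


class TestBootstrapRmcorr:
    def test_degenerate_line_gives_width_zero_ci(self):
        t = _fixture_table(noise=0.0)
        t["y"] = t["x"] + t.groupby("subject_id").ngroup() * 4.0
        res = bootstrap_rmcorr(t, "x", "y", n_boot=200, seed=1)
        assert res.ci_low == pytest.approx(1.0)
        assert res.ci_high == pytest.approx(1.0)

    def test_same_seed_gives_identical_ci(self):
        t = _fixture_table(seed=7)
        a = bootstrap_rmcorr(t, "x", "y", n_boot=300, seed=42)
        b = bootstrap_rmcorr(t, "x", "y", n_boot=300, seed=42)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)
        np.testing.assert_array_equal(a.boot_r, b.boot_r)

    def test_ci_is_ordered_and_brackets_reasonably(self):
        t = _fixture_table(seed=11, n_subj=20)
        res = bootstrap_rmcorr(t, "x", "y", n_boot=500, seed=3)
        assert res.ci_low <= res.ci_high
        assert res.ci_low < res.r < res.ci_high


# ---------------------------------------------------------------------------
# Distribution diagnostics
# ---------------------------------------------------------------------------


class TestDistributionDiagnostics:
    def test_equal_variance_groups_rarely_flagged(self):
        # type-I behaviour of the variance tests on identically drawn groups
        flags = 0
        n_rep = 100
        for rep in range(n_rep):
            rng = np.random.default_rng(rep)
            vals = rng.normal(size=200)
            groups = np.repeat(["a", "b"], 100)
            d = distribution_diagnostics(vals, groups)
            ps = [d.bartlett[1], d.levene[1], d.fligner[1]]
            if min(ps) <= 0.01:
                flags += 1
        assert flags <= 5

    def test_tenfold_variance_difference_is_detected(self):
        rng = np.random.default_rng(0)
        vals = np.concatenate([rng.normal(0, 1, 50), rng.normal(0, np.sqrt(10), 50)])
        groups = np.repeat(["a", "b"], 50)
        d = distribution_diagnostics(vals, groups)
        assert d.bartlett[1] < 0.01

    def test_normal_data_qq_close_to_identity(self):
        rng = np.random.default_rng(1)
        d = distribution_diagnostics(rng.normal(size=500))
        # sample quantiles track theoretical quantiles in the bulk
        bulk = np.abs(d.qq_theoretical) < 2
        assert np.abs(d.qq_sample[bulk] - d.qq_theoretical[bulk]).max() < 0.4

    def test_lognormal_data_flagged_boxcox_suitable(self):
        rng = np.random.default_rng(3)
        d = distribution_diagnostics(rng.lognormal(0, 0.8, 300))
        assert d.shapiro_p < 0.05  # raw values clearly non-normal
        assert d.boxcox_suitable

    def test_small_groups_mark_variance_tests_not_computable(self):
        d = distribution_diagnostics([1.0, 2.0, 3.0, 4.0], ["a", "a", "b", "b"])
        assert d.bartlett is None
        assert d.shapiro_p is not None


# ---------------------------------------------------------------------------
# Longitudinal report
# ---------------------------------------------------------------------------


class TestLongitudinalReport:
    def test_default_cohort_flags_programmed_declines(self):
        table, _ = simulate_cohort(CohortSimParams(), seed=13)
        report = run_longitudinal_report(table, pairs=[("cd8", "weight")], n_boot=0)
        kw = report.kruskal.set_index("variable")
        assert kw.loc["crp", "p"] < 0.05
        assert kw.loc["il6", "p"] < 0.05
        dunn = report.dunn
        crp_b12 = dunn[(dunn["variable"] == "crp") & (dunn["group_a"] == 0)
                       & (dunn["group_b"] == 12)]
        assert bool(crp_b12["significant"].iloc[0])
        assert report.rmcorr.loc[0, "r"] < 0

    def test_empty_pairs_gives_kw_dunn_only(self):
        table, _ = simulate_cohort(CohortSimParams(), seed=1)
        report = run_longitudinal_report(table, pairs=[])
        assert report.rmcorr is None
        assert not report.kruskal.empty

    def test_missing_columns_listed_in_schema_error(self):
        table, _ = simulate_cohort(CohortSimParams(), seed=1)
        with pytest.raises(SchemaError) as err:
            run_longitudinal_report(table.drop(columns=["subject_id"]),
                                    pairs=[("nope", "weight")])
        assert "subject_id" in str(err.value) and "nope" in str(err.value)

    def test_report_round_trips_to_csv(self, tmp_path):
        table, _ = simulate_cohort(CohortSimParams(), seed=1)
        report = run_longitudinal_report(table, pairs=[("crp", "weight")], n_boot=50, seed=0)
        report.to_csv(tmp_path)
        assert (tmp_path / "medians_by_timepoint.csv").exists()
        assert (tmp_path / "rmcorr_pairs.csv").exists()
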