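"""Dosage regression, region-wise BH correction and stratified scans."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from oameqtl.discovery import (
    CohortData,
    SampleRecord,
    bh_adjust,
    dosage_regression,
    group_methylation_comparison,
    run_strata,
    scan_locus,
    variance_explained,
)
from oameqtl.regions import build_window, select_probes
from oameqtl.simulate import LocusSim, SimConfig, simulate_cohort

from conftest import make_cohort


def ols_oracle(x, y):
    """Closed-form normal equations, independent of the implementation."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = x.size
    sxx = ((x - x.mean()) ** 2).sum()
    sxy = ((x - x.mean()) * (y - y.mean())).sum()
    syy = ((y - y.mean()) ** 2).sum()
    slope = sxy / sxx
    intercept = y.mean() - slope * x.mean()
    rss = syy - slope * sxy
    se = np.sqrt(rss / ((n - 2) * sxx))
    t = slope / se
    p = 2 * stats.t.sf(abs(t), n - 2)
    return slope, intercept, p, sxy**2 / (sxx * syy)


class TestDosageRegression:
    def test_matches_closed_form_oracle(self):
        dosage = [0, 1, 2, 0, 1, 2]
        beta = [0.20, 0.31, 0.39, 0.21, 0.29, 0.41]
        res = dosage_regression(beta, dosage)
        slope, intercept, p, r2 = ols_oracle(dosage, beta)
        assert res.status == "ok" and res.n_used == 6
        assert res.slope == pytest.approx(slope)
        assert res.intercept == pytest.approx(intercept)
        assert res.p_raw == pytest.approx(p)
        assert res.r_squared == pytest.approx(r2)

    def test_matches_scipy_linregress_on_random_data(self, rng):
        for _ in range(20):
            d = rng.binomial(2, 0.4, 25).astype(float)
            if np.unique(d).size < 2:
                continue
            b = rng.uniform(0, 1, 25)
            res = dosage_regression(b, d)
            ref = stats.linregress(d, b)
            assert res.slope == pytest.approx(ref.slope)
            assert res.p_raw == pytest.approx(ref.pvalue)
            assert res.r_squared == pytest.approx(ref.rvalue**2)

    def test_constant_beta_gives_zero_slope(self):
        res = dosage_regression([0.5] * 6, [0, 1, 2, 0, 1, 2])
        assert res.slope == 0.0
        assert res.p_raw == 1.0

    def test_p_value_agrees_with_permutation_oracle(self, rng):
        d = np.array([0, 0, 0, 1, 1, 1, 2, 2, 2], float)
        b = np.array([0.31, 0.28, 0.35, 0.30, 0.26, 0.22, 0.20, 0.24, 0.25])
        res = dosage_regression(b, d)
        n_perm = 20_000
        obs = abs(ols_oracle(d, b)[0])
        count = 0
        for _ in range(n_perm):
            count += abs(ols_oracle(d, rng.permutation(b))[0]) >= obs - 1e-12
        p_perm = count / n_perm
        # permutation p and t-test p agree within Monte-Carlo error
        mc = 4 * np.sqrt(p_perm * (1 - p_perm) / n_perm) + 0.01
        assert abs(res.p_raw - p_perm) < mc

    def test_monomorphic_and_insufficient_flags(self):
        assert dosage_regression([0.1, 0.2, 0.3], [1, 1, 1]).status == \
            "monomorphic"
        assert dosage_regression([0.1, 0.2], [0, 1]).status == "insufficient"
        # flagged outcomes carry NaN statistics, not exceptions
        res = dosage_regression([0.1, 0.2, 0.3], [2, 2, 2])
        assert np.isnan(res.slope) and np.isnan(res.p_raw)

    def test_pairwise_deletion_of_missing_values(self):
        d = [0, 1, 2, np.nan, 1, 2]
        b = [0.2, 0.3, np.nan, 0.5, 0.35, 0.42]
        res = dosage_regression(b, d)
        ref = stats.linregress([0, 1, 1, 2], [0.2, 0.3, 0.35, 0.42])
        assert res.n_used == 4
        assert res.slope == pytest.approx(ref.slope)


def bh_oracle(pvals, m):
    """Hand-applied step-up: adj_(i) = min_{j>=i} m p_(j)/j, capped at 1."""
    order = np.argsort(pvals, kind="stable")
    k = len(pvals)
    adj = [None] * k
    best = 1.0
    for i in range(k - 1, -1, -1):
        best = min(best, m * pvals[order[i]] / (i + 1))
        adj[order[i]] = best
    return np.array(adj)


class TestBhAdjust:
    def test_hand_example(self):
        assert bh_adjust([0.01, 0.02, 0.03]).tolist() == pytest.approx(
            [0.03, 0.03, 0.03]
        )

    def test_identity_at_single_test(self):
        assert bh_adjust([0.04], m=1).tolist() == [0.04]

    def test_all_ones_stay_one(self):
        assert bh_adjust([1.0, 1.0, 1.0]).tolist() == [1.0, 1.0, 1.0]

    def test_empty_input(self):
        assert bh_adjust([]).size == 0

    @given(
        st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=40),
        st.integers(0, 10),
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_oracle_and_statsmodels(self, pvals, extra):
        m = len(pvals) + extra
        got = bh_adjust(pvals, m=m)
        assert np.allclose(got, bh_oracle(pvals, m))
        assert np.all(got >= np.asarray(pvals) - 1e-12)
        assert np.all(got <= 1.0)
        # untested region probes behave exactly like p = 1 entries
        from statsmodels.stats.multitest import multipletests

        padded = list(pvals) + [1.0] * extra
        ref = multipletests(padded, method="fdr_bh")[1][: len(pvals)]
        assert np.allclose(got, ref)

    def test_region_denominator_smaller_than_tests_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.1, 0.2], m=1)


def _planted_setup(seed, effect=-0.5, maf=0.35, n_probes=40):
    cfg = SimConfig(
        loci=(LocusSim("locusA", maf, n_probes,
                       planted={n_probes // 2: effect}),),
    )
    return simulate_cohort(cfg, seed)


class TestScanLocus:
    def test_only_planted_probe_significant(self):
        cohort, loci, manifest, truth = _planted_setup(seed=11)
        probes = select_probes(manifest, build_window(loci[0]))
        scan = scan_locus(cohort, loci[0], probes, "all")
        assert scan.status == "ok"
        sig = scan.results.loc[scan.results["significant"]]
        assert truth.planted_probes()[0] in set(sig["probe_id"])
        # false positives beyond the planted probe are rare at FDR 5%
        assert len(sig) <= 3

    def test_direction_reported_versus_risk_allele(self):
        cohort, loci, manifest, truth = _planted_setup(seed=12)
        probes = select_probes(manifest, build_window(loci[0]))
        scan = scan_locus(cohort, loci[0], probes, "all")
        planted = scan.results.set_index("probe_id").loc[
            truth.planted_probes()[0]
        ]
        assert planted["direction_vs_risk"] == "lower"
        assert planted["p_adj"] >= planted["p_raw"]

    def test_empty_stratum_flagged_not_raised(self):
        cohort, loci, manifest, _ = _planted_setup(seed=13)
        # simulated cohort here has no NOF samples in config? It does;
        # restrict to a stratum with no members instead: drop all males
        cohort.samples["sex"] = "female"
        scan = scan_locus(cohort, loci[0],
                          select_probes(manifest, build_window(loci[0])),
                          "males")
        assert scan.status == "empty_stratum"
        assert scan.results.empty

    def test_bh_denominator_is_full_region_probe_count(self):
        cohort, loci, manifest, _ = _planted_setup(seed=14)
        probes = select_probes(manifest, build_window(loci[0]))
        # knock one probe down to 2 usable samples: untestable, but it must
        # still count toward m
        victim = probes[0].probe_id
        cohort.betas.loc[cohort.betas.index[2:], victim] = np.nan
        scan = scan_locus(cohort, loci[0], probes, "all")
        row = scan.results.set_index("probe_id")
        assert row.loc[victim, "status"] == "insufficient"
        tested = scan.results["p_raw"].notna()
        ref = bh_oracle(
            scan.results.loc[tested, "p_raw"].to_numpy(), len(probes)
        )
        assert np.allclose(scan.results.loc[tested, "p_adj"], ref)


class TestRunStrata:
    def test_knee_specific_effect_strongest_in_knee_pass(self):
        cfg = SimConfig(
            n_oa_knee=50, n_oa_hip=25, n_nof=24,
            loci=(LocusSim("locusA", 0.4, 10, planted={5: 0.0}),),
        )
        cohort, loci, manifest, truth = simulate_cohort(cfg, 21)
        probe = f"cg_locusA_0005"
        # plant the effect in knees only, by hand
        knee = (cohort.samples["joint"] == "knee").to_numpy()
        d = cohort.dosages.iloc[:, 0].to_numpy()
        cohort.betas[probe] = np.clip(
            0.5 - 0.08 * d * knee
            + np.random.default_rng(5).normal(0, 0.02, len(d)),
            0.01, 0.99,
        )
        results, flags = run_strata(cohort, loci, manifest,
                                    passes=("all", "OA_knee", "OA_hip"))
        by_pass = results.set_index(["stratum", "probe_id"])
        p_knee = by_pass.loc[("OA_knee", probe), "p_raw"]
        p_hip = by_pass.loc[("OA_hip", probe), "p_raw"]
        assert by_pass.loc[("OA_knee", probe), "significant"]
        assert p_knee < p_hip

    def test_deterministic_rerun(self, small_config):
        a = simulate_cohort(small_config, 99)
        b = simulate_cohort(small_config, 99)
        ra, _ = run_strata(a[0], a[1], a[2])
        rb, _ = run_strata(b[0], b[1], b[2])
        pd.testing.assert_frame_equal(ra, rb)

    def test_each_pass_reports_every_locus(self, small_config):
        cohort, loci, manifest, _ = simulate_cohort(small_config, 7)
        results, flags = run_strata(cohort, loci, manifest)
        assert set(flags["stratum"]) == {
            "all", "OA", "NOF", "OA_knee", "OA_hip", "males", "females"
        }
        assert len(flags) == len(loci) * 7


class TestGroupComparison:
    def test_identical_distributions_h_zero(self):
        cohort = make_cohort(n=24, seed=3)
        beta = pd.Series(0.4, index=cohort.samples.index)
        out = group_methylation_comparison(beta, cohort.samples)
        assert out["H"] == 0.0 and out["p"] == 1.0

    def test_shifted_nof_group_detected(self, rng):
        cfg = SimConfig(n_oa_knee=63, n_oa_hip=17, n_nof=19,
                        loci=(LocusSim("locusA", 0.3, 5,
                                       nof_offsets={0: -0.6}),))
        cohort, *_ = simulate_cohort(cfg, 31)
        out = group_methylation_comparison(
            cohort.betas["cg_locusA_0000"], cohort.samples
        )
        assert out["means"]["NOF"] == min(out["means"].values())
        assert out["p"] < 0.05

    def test_two_groups_agree_with_rank_sum(self, rng):
        cohort = make_cohort(n=30, seed=8)
        cohort.samples.loc[cohort.samples["joint"] == "hip", "joint"] = \
            "knee"  # leaves OA_knee and NOF only
        beta = pd.Series(rng.uniform(0, 1, 30), index=cohort.samples.index)
        out = group_methylation_comparison(beta, cohort.samples)
        g1 = beta[cohort.samples["status"] == "OA"]
        g2 = beta[cohort.samples["status"] == "NOF"]
        ref = stats.mannwhitneyu(g1, g2, method="asymptotic",
                                 use_continuity=False)
        assert out["p"] == pytest.approx(ref.pvalue, rel=1e-9)


class TestVarianceExplained:
    def test_exactly_linear_beta_is_100(self):
        d = [0, 1, 2, 0, 1, 2]
        assert variance_explained([0.1 + 0.2 * x for x in d], d) == \
            pytest.approx(100.0)

    def test_constant_beta_is_0(self):
        assert variance_explained([0.5] * 6, [0, 1, 2, 0, 1, 2]) == 0.0

    def test_equals_squared_pearson(self, rng):
        d = rng.binomial(2, 0.4, 40).astype(float)
        b = rng.uniform(0, 1, 40)
        r = stats.pearsonr(d, b)[0]
        assert variance_explained(b, d) == pytest.approx(100 * r * r)


class TestRiskReExpression:
    def test_sign_flips_iff_risk_is_major(self, rng):
        d = rng.binomial(2, 0.4, 50).astype(float)
        b = 0.3 + 0.1 * d + rng.normal(0, 0.02, 50)
        slope_minor = dosage_regression(b, d).slope
        slope_risk_major = dosage_regression(b, 2 - d).slope
        assert slope_risk_major == pytest.approx(-slope_minor)


class TestSampleRecord:
    def test_nof_with_knee_joint_rejected(self):
        with pytest.raises(ValueError, match="free of OA"):
            SampleRecord("s1", "NOF", "knee", "male")

    def test_bad_category_rejected(self):
        with pytest.raises(ValueError):
            SampleRecord("s1", "OA", "hand", "male")


class TestCohortValidation:
    def test_beta_out_of_range_rejected_with_coordinates(self):
        cohort = make_cohort()
        betas = cohort.betas.copy()
        betas.iloc[2, 1] = 1.2
        with pytest.raises(ValueError, match="cg00001"):
            CohortData(cohort.samples, cohort.dosages, betas)

    def test_fractional_dosage_rejected(self):
        cohort = make_cohort()
        dosages = cohort.dosages.copy()
        dosages.iloc[0, 0] = 0.5
        with pytest.raises(ValueError, match="rsTEST"):
            CohortData(cohort.samples, dosages, cohort.betas)
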