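import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dcisime import (
    RaterSimSpec,
    bh_fdr,
    bin_tils,
    cluster_densities,
    contrast_suite,
    icc,
    perm_kruskal_wallis,
    perm_rank_test,
    simulate_rater_scores,
    spearman,
)
from oracles import (
    bh_qvalues_bruteforce,
    complete_linkage_heights,
    exact_perm_p_two_sided,
    kruskal_h_bruteforce,
    spearman_bruteforce,
)


class TestPermRankTest:
    def test_identical_constant_groups_p1(self):
        res = perm_rank_test([2.0, 2.0, 2.0], [2.0, 2.0, 2.0])
        assert res.p_nominal == 1.0

    def test_exact_separated_groups(self):
        res = perm_rank_test([1, 2, 3], [4, 5, 6], mode="exact")
        assert res.p_nominal == pytest.approx(0.1)
        assert res.method.startswith("exact")

    def test_exact_matches_bruteforce_random_fixtures(self, rng):
        for _ in range(30):
            na, nb = int(rng.integers(2, 6)), int(rng.integers(2, 6))
            a = rng.integers(0, 8, na).astype(float)
            b = rng.integers(0, 8, nb).astype(float)
            res = perm_rank_test(a, b, mode="exact")
            assert res.p_nominal == pytest.approx(exact_perm_p_two_sided(a, b), rel=1e-9)

    def test_monte_carlo_close_to_exact(self, rng):
        a = rng.normal(0, 1, 5)
        b = rng.normal(0.8, 1, 5)
        exact = perm_rank_test(a, b, mode="exact").p_nominal
        n_perm = 100_000
        mc = perm_rank_test(a, b, mode="mc", n_perm=n_perm, seed=1).p_nominal
        se = np.sqrt(exact * (1 - exact) / n_perm)
        assert abs(mc - exact) < 3 * se + 2 / n_perm

    def test_deterministic_given_seed(self, rng):
        a, b = rng.normal(0, 1, 30), rng.normal(0, 1, 30)
        r1 = perm_rank_test(a, b, seed=5, n_perm=2000)
        r2 = perm_rank_test(a, b, seed=5, n_perm=2000)
        assert r1.p_nominal == r2.p_nominal

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            perm_rank_test([], [1.0])

    def test_nonfinite_dropped_and_logged(self):
        res = perm_rank_test([1, 2, np.nan, 3], [4, np.inf, 5, 6], mode="exact")
        assert res.n_per_group == (3, 3)
        assert "dropped 2" in res.notes

    def test_validity_under_null(self, rng):
        # P(p <= alpha) <= alpha + MC tolerance for a valid permutation p
        n_rep = 400
        for alpha in (0.01, 0.05, 0.1):
            hits = 0
            for _ in range(n_rep):
                a = rng.normal(0, 1, 8)
                b = rng.normal(0, 1, 8)
                if perm_rank_test(a, b, n_perm=400, seed=int(rng.integers(1 << 31))).p_nominal <= alpha:
                    hits += 1
            se = np.sqrt(alpha * (1 - alpha) / n_rep)
            assert hits / n_rep <= alpha + 3 * se + 0.01


class TestPermKruskalWallis:
    def test_three_identical_groups_p1(self):
        with pytest.warns(UserWarning, match="tied"):
            res = perm_kruskal_wallis([[1.0, 1.0], [1.0, 1.0], [1.0, 1.0]])
        assert res.p_nominal == 1.0

    def test_h_statistic_matches_bruteforce(self, rng):
        groups = [rng.integers(0, 10, 6).astype(float) for _ in range(3)]
        res = perm_kruskal_wallis(groups, n_perm=100, seed=0)
        assert res.statistic == pytest.approx(kruskal_h_bruteforce([list(g) for g in groups]), rel=1e-9)

    def test_two_group_agrees_with_mann_whitney(self, rng):
        a = rng.normal(0, 1, 12)
        b = rng.normal(0.7, 1, 12)
        p_kw = perm_kruskal_wallis([a, b], n_perm=20_000, seed=3).p_nominal
        p_mw = perm_rank_test(a, b, n_perm=20_000, seed=4, mode="mc").p_nominal
        se = np.sqrt(p_mw * (1 - p_mw) / 20_000)
        assert abs(p_kw - p_mw) < 4 * se + 1e-3

    def test_power_increases_with_shift(self, rng):
        rejections = []
        for shift in (0.0, 1.0, 2.5):
            hits = 0
            for rep in range(60):
                g1 = rng.normal(0, 1, 10)
                g2 = rng.normal(shift, 1, 10)
                g3 = rng.normal(-shift, 1, 10)
                p = perm_kruskal_wallis([g1, g2, g3], n_perm=300,
                                        seed=int(rng.integers(1 << 31))).p_nominal
                hits += p < 0.05
            rejections.append(hits / 60)
        assert rejections[0] < rejections[1] < rejections[2]

    def test_fewer_than_two_groups_rejected(self):
        with pytest.raises(ValueError):
            perm_kruskal_wallis([[1.0, 2.0]])


class TestBHFDR:
    def test_single_p(self):
        assert bh_fdr([0.03])[0] == pytest.approx(0.03)

    def test_hand_applied_stepup(self):
        q = bh_fdr([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_matches_bruteforce_random_vectors(self, rng):
        for _ in range(100):
            p = rng.random(int(rng.integers(1, 40)))
            np.testing.assert_allclose(bh_fdr(p), bh_qvalues_bruteforce(p), rtol=1e-9)

    def test_nan_passthrough(self):
        q = bh_fdr([0.01, np.nan, 0.5])
        assert np.isnan(q[1])
        np.testing.assert_allclose(q[[0, 2]], bh_qvalues_bruteforce([0.01, 0.5]), rtol=1e-9)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([1.2])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    @settings(max_examples=100)
    def test_stepup_property(self, p):
        q = bh_fdr(p)
        order = np.argsort(p, kind="stable")
        assert (np.diff(np.asarray(q)[order]) >= -1e-12).all()
        assert ((q >= np.asarray(p) - 1e-12) | np.isnan(q)).all()

    def test_fdr_control_simulation(self, rng):
        # independent nulls + strong alternatives: empirical FDR <= 0.05 + tol
        fdrs = []
        for _ in range(200):
            p_null = rng.random(40)
            p_alt = rng.random(10) * 1e-4
            p = np.concatenate([p_null, p_alt])
            q = bh_fdr(p)
            rejected = q < 0.05
            if rejected.any():
                fdrs.append(rejected[:40].sum() / rejected.sum())
        assert np.mean(fdrs) <= 0.05 + 0.02


class TestSpearman:
    def test_monotone_pairs(self):
        x = [1, 2, 3, 4, 5]
        assert spearman(x, [2, 4, 9, 16, 30])[0] == pytest.approx(1.0)
        assert spearman(x, [30, 16, 9, 4, 2])[0] == pytest.approx(-1.0)

    def test_matches_bruteforce(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 30))
            x = rng.integers(0, 10, n).astype(float)
            y = rng.integers(0, 10, n).astype(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            rho, _ = spearman(x, y)
            assert rho == pytest.approx(spearman_bruteforce(x, y), abs=1e-12)

    def test_constant_vector_missing(self):
        rho, p = spearman([1, 1, 1], [1, 2, 3])
        assert np.isnan(rho) and np.isnan(p)

    def test_short_input_rejected(self):
        with pytest.raises(ValueError):
            spearman([1, 2], [3, 4])


class TestBinTils:
    @pytest.mark.parametrize("pct,expected", [
        (0.0, "<1%"), (0.5, "<1%"), (1.0, "1-49%"), (7.5, "1-49%"),
        (49.99, "1-49%"), (50.0, ">=50%"), (100.0, ">=50%"),
    ])
    def test_bins(self, pct, expected):
        assert bin_tils(pct) == expected

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            bin_tils(101.0)
        with pytest.raises(ValueError):
            bin_tils(-0.1)


class TestICC:
    def test_identical_raters_icc1(self):
        m = np.tile(np.arange(10.0)[:, None], (1, 3))
        res = icc(m, unit="mean-of-k")
        assert res.estimate == pytest.approx(1.0)

    def test_worked_fixture_closed_form(self):
        # classic Shrout & Fleiss 6x4 judge matrix, checked against the
        # published estimates (ICC(2,1)=0.29, ICC(3,1)=0.71, ICC(2,4)=0.62)
        m = np.array([
            [9, 2, 5, 8],
            [6, 1, 3, 2],
            [8, 4, 6, 8],
            [7, 1, 2, 6],
            [10, 5, 6, 9],
            [6, 2, 4, 7],
        ], dtype=float)
        assert icc(m, form="absolute", unit="single").estimate == pytest.approx(0.29, abs=0.005)
        assert icc(m, form="consistency", unit="single").estimate == pytest.approx(0.71, abs=0.005)
        assert icc(m, form="absolute", unit="mean-of-k").estimate == pytest.approx(0.62, abs=0.005)

    def test_matches_pingouin_oracle(self, rng):
        pingouin = pytest.importorskip("pingouin")
        m = rng.normal(0, 1, (12, 3)) + rng.normal(0, 1, (12, 1))
        df = pd.DataFrame(m, columns=["r1", "r2", "r3"]).reset_index(names="subject")
        long = df.melt(id_vars="subject", var_name="rater", value_name="score")
        png = pingouin.intraclass_corr(long, targets="subject", raters="rater",
                                       ratings="score")
        png = png.set_index("Type")["ICC"]
        assert icc(m, form="absolute", unit="single").estimate == pytest.approx(png["ICC(A,1)"], abs=1e-6)
        assert icc(m, form="consistency", unit="single").estimate == pytest.approx(png["ICC(C,1)"], abs=1e-6)
        assert icc(m, form="absolute", unit="mean-of-k").estimate == pytest.approx(png["ICC(A,k)"], abs=1e-6)
        assert icc(m, form="consistency", unit="mean-of-k").estimate == pytest.approx(png["ICC(C,k)"], abs=1e-6)

    def test_recovery_single_unit(self):
        spec = RaterSimSpec(n_subjects=500, n_raters=3, true_icc=0.89, seed=8)
        est = icc(simulate_rater_scores(spec), unit="single").estimate
        assert abs(est - 0.89) < 0.05

    def test_recovery_mean_of_k_unit(self):
        spec = RaterSimSpec(n_subjects=500, n_raters=3, true_icc=0.89,
                            unit="mean-of-k", seed=8)
        est = icc(simulate_rater_scores(spec), unit="mean-of-k").estimate
        assert abs(est - 0.89) < 0.05

    def test_null_icc_near_zero(self):
        spec = RaterSimSpec(n_subjects=500, n_raters=3, true_icc=0.0,
                            subject_sd=0.0, rater_sd=0.0, error_sd=1.0, seed=3)
        est = icc(simulate_rater_scores(spec), unit="single").estimate
        assert est <= 0.1

    def test_shift_invariance(self, rng):
        m = rng.normal(5, 2, (20, 3))
        a = icc(m).estimate
        b = icc(m + 100.0).estimate
        assert a == pytest.approx(b, abs=1e-10)

    def test_mean_of_k_geq_single(self, rng):
        m = rng.normal(0, 1, (15, 3)) + rng.normal(0, 1, (15, 1))
        single = icc(m, unit="single").estimate
        meank = icc(m, unit="mean-of-k").estimate
        assert meank >= single - 1e-12

    def test_missing_rows_complete_case(self, rng):
        m = rng.normal(0, 1, (20, 3)) + rng.normal(0, 2, (20, 1))
        m_miss = m.copy()
        m_miss[3, 1] = np.nan
        complete = np.delete(m, 3, axis=0)
        assert icc(m_miss).estimate == pytest.approx(icc(complete).estimate, abs=1e-12)

    def test_ci_brackets_estimate(self, rng):
        m = rng.normal(0, 1, (30, 3)) + rng.normal(0, 1.5, (30, 1))
        for form in ("absolute", "consistency"):
            for unit in ("single", "mean-of-k"):
                res = icc(m, form=form, unit=unit)
                assert res.ci_low <= res.estimate <= res.ci_high

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            icc(np.ones((1, 3)))


class TestClustering:
    def test_identical_profiles_merge_height_zero(self):
        m = np.array([[1.0, 2.0], [1.0, 2.0], [5.0, 9.0]])
        res = cluster_densities(m)
        assert res.linkage_matrix[0, 2] == pytest.approx(0.0)

    def test_heights_match_bruteforce(self, rng):
        for _ in range(20):
            m = rng.uniform(0, 100, (int(rng.integers(3, 8)), 4))
            res = cluster_densities(m)
            expected = complete_linkage_heights(np.log1p(m))
            np.testing.assert_allclose(sorted(res.linkage_matrix[:, 2]), expected, rtol=1e-9)

    def test_row_permutation_invariance(self, rng):
        m = rng.uniform(0, 50, (6, 5))
        perm = rng.permutation(6)
        a = cluster_densities(m)
        b = cluster_densities(m[perm])
        np.testing.assert_allclose(sorted(a.linkage_matrix[:, 2]),
                                   sorted(b.linkage_matrix[:, 2]), rtol=1e-9)

    def test_newick_well_formed(self):
        m = np.array([[1.0, 2.0], [1.1, 2.1], [9.0, 0.5], [8.5, 0.2]])
        res = cluster_densities(m, row_ids=["a", "b", "c", "d"])
        nw = res.newick()
        assert nw.endswith(";") and nw.count("(") == 3
        for name in "abcd":
            assert name in nw

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            cluster_densities(np.ones((1, 3)))


class TestContrastSuite:
    def _features(self, rng, n_case=8, n_control=8, effect=1.0):
        rows = []
        md_rows = []
        for i in range(n_case + n_control):
            outcome = "case" if i < n_case else "control"
            pid = f"p{i}"
            md_rows.append({
                "patient_id": pid, "outcome": outcome, "grade": int(rng.integers(1, 4)),
                "er": rng.choice(["negative", "positive"]),
                "her2": rng.choice(["negative", "positive"]),
                "fibrosis": rng.choice(["absent", "present"]),
                "comedonecrosis": rng.choice(["absent", "present"]),
                "ki67_category": rng.choice(["<14%", ">=14%"]),
            })
            for feat in ("lymphocytes_stroma", "t_reg_stroma"):
                val = rng.lognormal(5, 0.5)
                if outcome == "case" and feat == "t_reg_stroma":
                    val *= effect
                rows.append({"patient_id": pid, "family": "stromal_densities",
                             "feature_id": feat, "value": val})
        return pd.DataFrame(rows), pd.DataFrame(md_rows)

    def test_runs_all_contrasts(self, rng):
        features, md = self._features(rng)
        res = contrast_suite(features, md, n_perm=200, seed=1)
        assert set(res["feature_id"]) == {"lymphocytes_stroma", "t_reg_stroma"}
        assert "case_vs_control" in set(res["contrast"])
        assert "grade" in set(res["contrast"])
        cc = res[res["contrast"] == "case_vs_control"]
        assert cc["q_bh"].notna().all()
        other = res[res["contrast"] != "case_vs_control"]
        assert other["q_bh"].isna().all()
        assert other["notes"].str.contains("no-mtc").all()

    def test_injected_effect_found(self, rng):
        features, md = self._features(rng, n_case=15, n_control=15, effect=6.0)
        res = contrast_suite(features, md, n_perm=2000, seed=2)
        cc = res[res["contrast"] == "case_vs_control"].set_index("feature_id")
        assert cc.loc["t_reg_stroma", "p_nominal"] < 0.05

    def test_stratum_filter(self, rng):
        features, md = self._features(rng, n_case=12, n_control=12)
        res = contrast_suite(features, md, n_perm=100, seed=3,
                             stratum_query="er == 'positive'")
        n_expected = (md["er"] == "positive").sum()
        cc = res[res["contrast"] == "case_vs_control"].iloc[0]
        assert sum(cc["n_per_group"]) == n_expected

    def test_empty_group_marked_not_computable(self, rng):
        features, md = self._features(rng)
        md["er"] = "positive"  # no negatives anywhere
        res = contrast_suite(features, md, n_perm=100, seed=4)
        er = res[res["contrast"].str.startswith("er:")]
        assert er["notes"].str.contains("not-computable").all()
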