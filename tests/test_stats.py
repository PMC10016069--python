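"""Cohort statistics: reliability, heritability, regression, FDR."""

import numpy as np
import pandas as pd
import pytest

from ficmap.morphometry import compute_morphometry
from ficmap.parcellation import RestrictionMask
from ficmap.stats import (
    DEFAULT_THRESHOLDS,
    SweepResult,
    compare_groups,
    falconer,
    fdr_bh,
    heritability,
    pair_correlation,
    probability_map,
    regress_behavior,
    reliability,
    select_threshold,
    sibling_pairs,
    skewness,
    sweep_thresholds,
    tukey_filter,
)
from ficmap.synthetic import CohortSpec, make_cohort, make_sweep_cohort


class TestSweep:
    def test_grid_has_41_thresholds(self):
        assert DEFAULT_THRESHOLDS.size == 41
        assert DEFAULT_THRESHOLDS[0] == 0.0 and DEFAULT_THRESHOLDS[-1] == 1.0
        assert np.allclose(np.diff(DEFAULT_THRESHOLDS), 0.025)

    def test_planted_optimum_recovered(self):
        co = make_sweep_cohort(n_subjects=40, seed=12)
        morph = compute_morphometry(co.surfaces)
        sweep = sweep_thresholds(
            co.maps, co.surfaces.triangles,
            RestrictionMask("atlas", co.restriction_indices), morph,
        )
        assert abs(select_threshold(sweep) - co.optimum) <= 0.025 + 1e-9

    def test_saturated_thresholds_undefined(self):
        co = make_sweep_cohort(n_subjects=10, seed=3)
        morph = compute_morphometry(co.surfaces)
        sweep = sweep_thresholds(
            co.maps, co.surfaces.triangles,
            RestrictionMask("atlas", co.restriction_indices), morph,
        )
        # empty parcels at t=0 and saturated parcels at t=1: both undefined
        assert np.isnan(sweep.skewness[0])
        assert np.isnan(sweep.skewness[-1])

    def test_too_few_subjects_rejected(self):
        co = make_sweep_cohort(n_subjects=2, seed=0)
        morph = compute_morphometry(co.surfaces)
        with pytest.raises(ValueError, match="3 subjects"):
            sweep_thresholds(
                co.maps, co.surfaces.triangles,
                RestrictionMask("atlas", co.restriction_indices), morph,
            )


class TestSelectThreshold:
    def test_unique_minimum(self):
        sweep = SweepResult(
            thresholds=np.array([0.1, 0.2, 0.3]),
            volumes=np.zeros((3, 3)),
            skewness=np.array([0.5, -0.1, 0.4]),
        )
        assert select_threshold(sweep) == 0.2

    def test_tie_takes_lower(self):
        sweep = SweepResult(
            thresholds=np.array([0.1, 0.2, 0.3]),
            volumes=np.zeros((3, 3)),
            skewness=np.array([0.4, -0.2, 0.2]),
        )
        assert select_threshold(sweep) == 0.2  # |-0.2| ties |0.2|, lower wins

    def test_all_undefined_rejected(self):
        sweep = SweepResult(
            thresholds=np.array([0.1]), volumes=np.zeros((3, 1)),
            skewness=np.array([np.nan]),
        )
        with pytest.raises(ValueError):
            select_threshold(sweep)


class TestSkewness:
    def test_symmetric_sample(self):
        assert skewness(np.array([-2, -1.0, 0, 1, 2])) == pytest.approx(0.0)

    def test_constant_undefined(self):
        assert np.isnan(skewness(np.full(10, 3.0)))

    def test_matches_adjusted_fisher_pearson(self, rng):
        from scipy.stats import skew

        x = rng.lognormal(size=100)
        assert skewness(x) == pytest.approx(skew(x, bias=False), abs=1e-12)


class TestReliability:
    def test_perfect_retest(self, rng):
        x = rng.normal(size=50)
        res = reliability(x, x)
        assert res.icc == pytest.approx(1.0)
        assert res.cov == pytest.approx(0.0)

    def test_no_between_subject_variance(self, rng):
        noise = rng.normal(0, 1.0, (50, 2))
        res = reliability(5.0 + noise[:, 0], 5.0 - noise[:, 0])
        assert res.icc < 0

    def test_simulated_variance_ratio(self):
        """MS_between = 3 MS_within -> ICC = (3-1)/(3+1) = 0.5."""
        rng = np.random.default_rng(77)
        n = 500
        subject = rng.normal(0, 1.0, n)          # between-component var 1
        test = subject + rng.normal(0, 1.0, n)   # within var 1 -> MSB ~ 3 MSW
        retest = subject + rng.normal(0, 1.0, n)
        res = reliability(test, retest)
        assert res.icc == pytest.approx(0.5, abs=0.05)

    def test_equals_classical_icc1_oracle(self, rng):
        """Stated formula == one-way random-effects ICC(1) (pingouin)."""
        import pingouin as pg

        x = rng.normal(size=(40, 2)) + rng.normal(size=(40, 1))
        res = reliability(x[:, 0], x[:, 1])
        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(40), 2),
                "session": np.tile([0, 1], 40),
                "y": x.ravel(),
            }
        )
        icc1 = pg.intraclass_corr(
            long, targets="subject", raters="session", ratings="y"
        )
        oracle = icc1.loc[icc1["Type"] == "ICC(1,1)", "ICC"].iloc[0]
        assert res.icc == pytest.approx(oracle, abs=1e-10)


class TestPairCorrelation:
    def test_identical_twins(self, rng):
        v = rng.normal(size=20)
        assert pair_correlation(np.column_stack([v, v])) == pytest.approx(1.0)

    def test_order_invariance(self, rng):
        pairs = rng.normal(size=(30, 2)) + rng.normal(size=(30, 1))
        flipped = pairs.copy()
        swap = rng.random(30) > 0.5
        flipped[swap] = flipped[swap][:, ::-1]
        assert pair_correlation(pairs) == pytest.approx(
            pair_correlation(flipped), abs=1e-12
        )

    def test_independent_pairs_near_zero(self):
        rng = np.random.default_rng(123)
        pairs = rng.normal(size=(2000, 2))
        assert abs(pair_correlation(pairs)) < 0.05


class TestFalconer:
    def test_volume_worked_example(self):
        assert falconer(0.61, 0.35) == pytest.approx(0.52, abs=1e-12)

    def test_area_worked_example(self):
        assert falconer(0.60, 0.39) == pytest.approx(0.42, abs=1e-12)

    def test_equal_correlations_zero(self):
        assert falconer(0.4, 0.4) == 0.0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            falconer(1.5, 0.2)


class TestHeritability:
    def test_ace_recovery(self):
        """Falconer recovers a2 (c2 cancels) within 3 Monte-Carlo SEs."""
        spec = CohortSpec(
            n_mz_pairs=2000, n_dz_pairs=2000, a2=0.5, c2=0.2, e2=0.3, seed=21
        )
        cohort, _ = make_cohort(spec)
        res = heritability(cohort)
        se_mz = (1 - 0.7**2) / np.sqrt(2000)
        se_dz = (1 - 0.45**2) / np.sqrt(2000)
        se = 2 * np.sqrt(se_mz**2 + se_dz**2)
        assert abs(res.h2b - 0.5) < 3 * se

    def test_sibling_pairing_by_parents(self):
        cohort = pd.DataFrame(
            {
                "subject_id": ["a", "b", "c", "d", "e"],
                "mother_id": ["m1", "m1", "m2", "m2", "m3"],
                "father_id": ["f1", "f1", "f2", "f2", "f3"],
                "group": ["MZ", "MZ", "DZ", "DZ", "SINGLE"],
                "value": [1.0, 2.0, 3.0, 4.0, 5.0],
            }
        )
        pairs = sibling_pairs(cohort)
        assert pairs["MZ"].tolist() == [[1.0, 2.0]]
        assert pairs["DZ"].tolist() == [[3.0, 4.0]]
        assert "SINGLE" not in pairs

    def test_multimember_sibship_all_pairs(self):
        cohort = pd.DataFrame(
            {
                "subject_id": list("abc"),
                "mother_id": ["m"] * 3,
                "father_id": ["f"] * 3,
                "group": ["NT"] * 3,
                "value": [1.0, 2.0, 3.0],
            }
        )
        pairs = sibling_pairs(cohort)
        assert len(pairs["NT"]) == 3  # C(3,2)


class TestCompareGroups:
    def test_identical_groups(self, rng):
        x = rng.normal(size=30)
        res = compare_groups(x, x.copy(), paired=True)
        assert res.t == 0.0

    def test_constant_paired_difference(self, rng):
        x = rng.normal(size=30)
        res = compare_groups(x + 1.0, x, paired=True)
        assert res.p == 0.0 and res.t > 0 and not res.defined

    def test_power_near_analytic(self):
        """Rejection rate for a 0.5 SD shift, n=200/group, alpha=0.05."""
        from scipy.stats import norm

        rng = np.random.default_rng(55)
        n, shift, alpha, reps = 200, 0.5, 0.05, 400
        rejections = 0
        for _ in range(reps):
            a = rng.normal(0, 1, n)
            b = rng.normal(shift, 1, n)
            if compare_groups(a, b).p < alpha:
                rejections += 1
        power = norm.cdf(shift / np.sqrt(2 / n) - norm.ppf(1 - alpha / 2))
        se = np.sqrt(power * (1 - power) / reps)
        assert abs(rejections / reps - power) < 4 * se


class TestTukeyFilter:
    def test_constant_data_all_retained(self):
        assert tukey_filter(np.full(10, 2.0)).all()

    def test_gross_outlier_removed(self):
        values = np.r_[np.arange(1.0, 21.0), 1000.0]
        mask = tukey_filter(values)
        # direct fence computation
        q1, q3 = np.percentile(values, [25, 75])
        lo, hi = q1 - 1.5 * (q3 - q1), q3 + 1.5 * (q3 - q1)
        assert np.array_equal(mask, (values >= lo) & (values <= hi))
        assert not mask[-1] and mask[:-1].all()

    def test_inliers_identity(self, rng):
        values = rng.uniform(0, 1, 50)
        q1, q3 = np.percentile(values, [25, 75])
        assert tukey_filter(values).all() or not (
            (values >= q1 - 1.5 * (q3 - q1)) & (values <= q3 + 1.5 * (q3 - q1))
        ).all()


class TestRegression:
    def test_outcome_equals_predictor(self, rng):
        x = rng.normal(size=100)
        table = pd.DataFrame({"y": x, "x": x})
        res = regress_behavior(table, "y", "x")
        assert res.std_beta == pytest.approx(1.0, abs=1e-10)
        assert res.r2 == pytest.approx(1.0, abs=1e-10)

    def test_std_beta_equals_pearson_r(self, rng):
        x = rng.normal(size=200)
        y = 0.4 * x + rng.normal(size=200)
        table = pd.DataFrame({"y": y, "x": x})
        res = regress_behavior(table, "y", "x", tukey=False)
        r = np.corrcoef(x, y)[0, 1]
        assert res.std_beta == pytest.approx(r, abs=1e-10)

    def test_generative_recovery(self):
        rng = np.random.default_rng(9)
        n, beta = 1000, 0.3
        x = rng.normal(size=n)
        y = beta * x + np.sqrt(1 - beta**2) * rng.normal(size=n)
        table = pd.DataFrame({"y": y, "x": x})
        res = regress_behavior(table, "y", "x")
        assert abs(res.std_beta - beta) < 3 * res.se

    def test_null_delta_bic_negative(self):
        """BIC's ln(n) penalty dominates the expected null fit gain."""
        rng = np.random.default_rng(31)
        n, reps = 1000, 200
        negative = 0
        for _ in range(reps):
            table = pd.DataFrame(
                {"y": rng.normal(size=n), "x": rng.normal(size=n)}
            )
            if regress_behavior(table, "y", "x", tukey=False).delta_bic < 0:
                negative += 1
        assert negative / reps >= 0.95

    def test_covariates_and_sex_coding(self, rng):
        n = 200
        x = rng.normal(size=n)
        sex = rng.choice(["F", "M"], n)
        age = rng.uniform(20, 40, n)
        y = 0.5 * x + 0.3 * (sex == "M") + 0.01 * age + rng.normal(size=n)
        table = pd.DataFrame({"y": y, "x": x, "sex": sex, "age": age})
        res = regress_behavior(table, "y", "x", covariates=("sex", "age"))
        assert abs(res.std_beta - 0.5 / y.std()) < 5 * res.se

    def test_collinear_rejected(self, rng):
        x = rng.normal(size=50)
        table = pd.DataFrame({"y": rng.normal(size=50), "x": x, "x2": x})
        with pytest.raises(ValueError, match="collinear"):
            regress_behavior(table, "y", "x", covariates=("x2",), tukey=False)


class TestFdrBh:
    def test_single_p(self):
        q, reject = fdr_bh(np.array([0.01]))
        assert q[0] == pytest.approx(0.01)
        assert reject[0]

    def test_all_equal_at_boundary(self):
        p = np.full(20, 0.04)
        q, reject = fdr_bh(p, q=0.05)
        assert reject.all()  # 0.04 <= (m/m) * 0.05

    def test_matches_brute_force_step_up(self, rng):
        """Rejections equal the max-k step-up definition, 100 instances."""
        for _ in range(100):
            m = rng.integers(1, 60)
            p = rng.uniform(size=m)
            _, reject = fdr_bh(p, q=0.05)
            order = np.argsort(p)
            ps = p[order]
            ks = np.flatnonzero(ps <= (np.arange(1, m + 1) / m) * 0.05)
            expected = np.zeros(m, dtype=bool)
            if ks.size:
                expected[order[: ks.max() + 1]] = True
            assert np.array_equal(reject, expected)

    def test_q_monotone_and_geq_p(self, rng):
        p = rng.uniform(size=50)
        q, _ = fdr_bh(p)
        assert np.all(q >= p - 1e-15)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)


class TestProbabilityMap:
    def test_identical_parcels_binary(self):
        m = np.array([True, False, True])
        out = probability_map([m, m, m])
        assert set(out.tolist()) <= {0.0, 1.0}

    def test_half_inclusion(self):
        a = np.array([True, False])
        b = np.array([False, False])
        out = probability_map([a, b])
        assert out[0] == 0.5 and out[1] == 0.0

    def test_topology_mismatch_rejected(self):
        with pytest.raises(ValueError, match="topologies differ"):
            probability_map([np.zeros(3, bool), np.zeros(4, bool)])
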