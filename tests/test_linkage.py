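"""Haseman-Elston regression, Pearson linkage p-values, adjusted models,
the allele-sharing LRT and the cohort summary."""

import math

import numpy as np
import pytest
from scipy import stats

from edsp import linkage as lk
from edsp.models import (
    EdspError,
    IBDPosterior,
    PhenotypeError,
    SibPairRecord,
)
from edsp.oracles import normal_equations_fit, sharing_lrt_closed_form

from conftest import make_sib


class TestSquaredDifference:
    def test_group_mean_profile(self):
        pair = SibPairRecord("F1", make_sib(iid="S1", sbp=143, dbp=89),
                             make_sib(iid="S2", sbp=108, dbp=66))
        assert lk.squared_trait_difference(pair, "sbp") == 1225

    def test_degenerate_and_order_invariance(self):
        a = SibPairRecord("F1", make_sib(iid="S1", sbp=120, dbp=70),
                          make_sib(iid="S2", sbp=130, dbp=90))
        b = SibPairRecord("F1", a.sib2, a.sib1)
        assert lk.squared_trait_difference(a, "sbp") == \
            lk.squared_trait_difference(b, "sbp") == 100
        same = SibPairRecord("F2", make_sib(iid="S1", sbp=120, dbp=80),
                             make_sib(iid="S2", sbp=120, dbp=80))
        assert lk.squared_trait_difference(same, "pp") == 0

    def test_missing_phenotype_excluded(self):
        pair = SibPairRecord("F1", make_sib(iid="S1"),
                             make_sib(iid="S2", sbp=120, dbp=80))
        with pytest.raises(PhenotypeError):
            lk.squared_trait_difference(pair, "sbp")


class TestPearson:
    @pytest.mark.parametrize("r, expected", [
        (-0.51, 0.011),
        (-0.44, 0.031),
        (-0.42, 0.041),   # t transform at n=24
        (-0.46, 0.024),
    ])
    def test_printed_p_values_at_n24(self, r, expected):
        assert round(lk.pearson_p_from_r(r, 24), 3) == expected

    def test_zero_correlation_p_one(self):
        assert lk.pearson_p_from_r(0.0, 24) == pytest.approx(1.0)

    def test_constant_variable_rejected(self):
        with pytest.raises(lk.UndefinedCorrelationError):
            lk.pearson_linkage_test([1, 2, 3, 4], [1, 1, 1, 1])

    def test_matches_scipy_pearsonr(self, rng):
        x = rng.normal(size=30)
        y = 0.3 * x + rng.normal(size=30)
        r, p = lk.pearson_linkage_test(y, x)
        ref = stats.pearsonr(x, y)
        assert r == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)


class TestHasemanElston:
    def test_hand_ols_three_points(self):
        he = lk.haseman_elston([4, 2, 0], [0, 1, 2])
        assert he.slope == pytest.approx(-2.0)
        assert he.intercept == pytest.approx(4.0)
        assert he.pearson_r == pytest.approx(-1.0)

    def test_constant_y_is_undefined_correlation(self):
        with pytest.raises(lk.UndefinedCorrelationError):
            lk.haseman_elston([3, 3, 3, 3], [0, 1, 2, 1])

    def test_slope_and_r_share_sign_and_p_consistency(self, rng):
        for _ in range(10):
            x = rng.integers(0, 3, 24).astype(float)
            y = rng.gamma(2.0, 100.0, 24) - 20.0 * x
            he = lk.haseman_elston(y, x)
            assert np.sign(he.slope) == np.sign(he.pearson_r)
            # two-sided p = 2 * min(one-sided, 1 - one-sided)
            assert he.p_two_sided == pytest.approx(
                2 * min(he.p_one_sided, 1 - he.p_one_sided))

    def test_pihat_rescaling_leaves_inference_unchanged(self, rng):
        x = rng.integers(0, 3, 24).astype(float)  # expected shared
        y = rng.gamma(2.0, 100.0, 24)
        full = lk.haseman_elston(y, x)
        half = lk.haseman_elston(y, x / 2.0)  # pihat scale
        assert half.slope == pytest.approx(2 * full.slope)
        assert half.p_one_sided == pytest.approx(full.p_one_sided)
        assert half.pearson_r == pytest.approx(full.pearson_r)


class TestAdjustedRegression:
    def test_single_standardized_predictor_beta_is_r(self, rng):
        x = rng.normal(size=40)
        y = 2.0 * x + rng.normal(size=40)
        res = lk.adjusted_regression(y, {"x": x})
        r = np.corrcoef(x, y)[0, 1]
        assert res.beta("x") == pytest.approx(r)

    def test_recovers_generating_betas(self, rng):
        """y = 2 x1 - x2 + noise recovered within 0.05 of the
        normal-equations oracle and the generating standardized betas."""
        n = 50
        x1 = rng.normal(size=n)
        x2 = rng.normal(size=n)
        y = 2.0 * x1 - x2 + rng.normal(0, 0.1, n)
        res = lk.adjusted_regression(y, {"x1": x1, "x2": x2})

        def z(v):
            return (v - v.mean()) / v.std(ddof=1)

        oracle = normal_equations_fit(np.column_stack([z(x1), z(x2)]), z(y))
        assert res.beta("x1") == pytest.approx(oracle[1], abs=1e-9)
        assert res.beta("x2") == pytest.approx(oracle[2], abs=1e-9)
        gen_beta1 = 2.0 * x1.std(ddof=1) / y.std(ddof=1)
        gen_beta2 = -1.0 * x2.std(ddof=1) / y.std(ddof=1)
        assert abs(res.beta("x1") - gen_beta1) < 0.05
        assert abs(res.beta("x2") - gen_beta2) < 0.05
        assert res.adjusted_r2 <= 1.0

    def test_constant_covariate_is_collinearity_error(self, rng):
        y = rng.normal(size=20)
        with pytest.raises(EdspError, match="constant"):
            lk.adjusted_regression(y, {"x": rng.normal(size=20),
                                       "c": np.ones(20)})

    def test_duplicated_covariate_is_collinearity_error(self, rng):
        y = rng.normal(size=20)
        x = rng.normal(size=20)
        with pytest.raises(EdspError, match="collinear"):
            lk.adjusted_regression(y, {"x": x, "x2": 2 * x + 1})


class TestSharingLRT:
    def test_null_sharing_gives_zero_statistic(self):
        prior_post = [IBDPosterior(0.25, 0.5, 0.25)] * 12
        res = lk.sharing_lrt(prior_post, n_perm=99, seed=1)
        assert res.lr_stat == pytest.approx(0.0, abs=1e-9)
        assert res.p_perm > 0.9

    def test_all_ibd0_closed_form(self):
        posts = [IBDPosterior(1.0, 0.0, 0.0)] * 10
        res = lk.sharing_lrt(posts, n_perm=99, seed=2)
        assert res.lr_stat == pytest.approx(20 * math.log(4), abs=1e-9)
        assert res.z_hat[0] == pytest.approx(1.0, abs=1e-6)
        assert res.p_perm < 0.05

    def test_matches_closed_form_on_informative_mixtures(self):
        # 6 IBD-0, 3 IBD-1, 1 IBD-2 fully informative pairs
        posts = ([IBDPosterior(1, 0, 0)] * 6 + [IBDPosterior(0, 1, 0)] * 3
                 + [IBDPosterior(0, 0, 1)])
        res = lk.sharing_lrt(posts, n_perm=99, seed=3)
        assert res.lr_stat == pytest.approx(
            sharing_lrt_closed_form((6, 3, 1)), abs=1e-7)

    def test_deficit_direction_constrains_simplex(self):
        posts = [IBDPosterior(0, 0, 1)] * 10  # excess sharing
        res = lk.sharing_lrt(posts, direction="deficit", n_perm=99, seed=4)
        assert res.z_hat[0] >= 0.25 - 1e-9
        assert res.z_hat[2] <= 0.25 + 1e-9
        any_dir = lk.sharing_lrt(posts, direction="any", n_perm=99, seed=4)
        assert any_dir.lr_stat > res.lr_stat

    def test_permutation_p_uniform_under_null(self):
        """Fully informative pairs drawn from the prior: permutation
        p-values should be uniform (KS test over replicates)."""
        rng = np.random.default_rng(55)
        basis = [IBDPosterior(1, 0, 0), IBDPosterior(0, 1, 0),
                 IBDPosterior(0, 0, 1)]
        pvals = []
        for i in range(500):
            ks = rng.choice(3, size=24, p=[0.25, 0.5, 0.25])
            posts = [basis[k] for k in ks]
            pvals.append(lk.sharing_lrt(posts, n_perm=199, seed=i).p_perm)
        ks_stat = stats.kstest(pvals, "uniform").statistic
        # discreteness of the permutation p inflates KS slightly
        assert ks_stat < 0.1

    def test_needs_two_informative_pairs(self):
        with pytest.raises(EdspError):
            lk.sharing_lrt([IBDPosterior(1, 0, 0), None], n_perm=9, seed=0)


class TestCohortSummary:
    def _pairs(self, rng, n=40):
        pairs = []
        for i in range(n):
            hi = make_sib(family=f"F{i}", iid="S1",
                          sbp=143 + rng.normal(0, 7),
                          dbp=89 + rng.normal(0, 5),
                          age=40.0 + rng.normal(0, 5))
            lo = make_sib(family=f"F{i}", iid="S2",
                          sbp=108 + rng.normal(0, 5),
                          dbp=66 + rng.normal(0, 5),
                          age=39.0 + rng.normal(0, 5))
            pairs.append(SibPairRecord(f"F{i}", hi, lo))
        return pairs

    def test_group_means_recovered(self, rng):
        table = lk.cohort_summary(self._pairs(rng)).set_index("variable")
        sbp = table.loc["Systolic blood pressure (mmHg)"]
        assert sbp["affected_mean"] == pytest.approx(143, abs=3 * 7 / 6.3)
        assert sbp["unaffected_mean"] == pytest.approx(108, abs=3 * 5 / 6.3)
        assert sbp["p_welch"] < 1e-6
        pp = table.loc["Pulse pressure (mmHg)"]
        assert pp["all_mean"] == pytest.approx((54 + 42) / 2, abs=4)

    def test_single_pair_has_missing_sd(self):
        pair = SibPairRecord("F1", make_sib(iid="S1", sbp=143, dbp=89),
                             make_sib(iid="S2", sbp=108, dbp=66))
        table = lk.cohort_summary([pair]).set_index("variable")
        assert math.isnan(
            table.loc["Systolic blood pressure (mmHg)", "affected_sd"])

    def test_extra_variables_join(self, rng):
        import pandas as pd

        pairs = self._pairs(rng, n=10)
        rows = []
        for p in pairs:
            for s in (p.sib1, p.sib2):
                rows.append({"family_id": s.family_id,
                             "individual_id": s.individual_id,
                             "weight": 70.0 + rng.normal(0, 10)})
        extra = pd.DataFrame(rows).set_index(
            ["family_id", "individual_id"])
        table = lk.cohort_summary(pairs, extra=extra).set_index("variable")
        assert table.loc["Weight (kg)", "all_mean"] == pytest.approx(
            70.0, abs=10)
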