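import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import genassoc_meta as gm
from oracles import cochran_q_oracle, dl_oracle, fixed_pool_oracle, i2_oracle


def est(y, se, sid="s", model=gm.GeneticModel.ALLELE, **cov):
    return gm.EffectEstimate(log_or=y, se=se, study_id=sid, model=model,
                             covariates=cov)


def pair():
    return [est(0.0, 0.2, "a"), est(1.0, 0.2, "b")]


class TestCochranQ:
    def test_hand_computed_two_studies(self):
        # w = 25 each, weighted mean 0.5, q = 25*0.25 + 25*0.25 = 12.5
        q, df, p = gm.cochran_q(pair())
        assert q == pytest.approx(12.5)
        assert df == 1

    def test_single_study_zero(self):
        q, df, p = gm.cochran_q([est(0.3, 0.1)])
        assert (q, df, p) == (0.0, 0, 1.0)

    def test_identical_estimates_zero(self):
        q, _, _ = gm.cochran_q([est(0.4, 0.15, f"s{i}") for i in range(5)])
        assert q == pytest.approx(0.0, abs=1e-12)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            gm.cochran_q([])


class TestISquared:
    @pytest.mark.parametrize("q,df,expected", [
        (12.5, 1, 92.0),
        (3.0, 5, 0.0),   # truncation at zero
        (0.0, 0, 0.0),   # convention
    ])
    def test_values(self, q, df, expected):
        assert gm.i_squared(q, df) == pytest.approx(expected)


class TestPoolFixed:
    def test_single_study_identity(self):
        r = gm.pool_fixed([est(0.3, 0.1)])
        assert r.pooled_log_or == pytest.approx(0.3)
        assert r.ci95 == pytest.approx(
            (math.exp(0.3 - 1.959964 * 0.1), math.exp(0.3 + 1.959964 * 0.1)))

    def test_equal_weights_average(self):
        r = gm.pool_fixed(pair())
        assert r.pooled_log_or == pytest.approx(0.5)

    def test_null_effect_p_one(self):
        r = gm.pool_fixed([est(0.0, 0.2)])
        assert r.z == 0.0 and r.p_z == pytest.approx(1.0)

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ValueError):
            gm.pool_fixed([est(0.1, 0.0)])


class TestPoolRandomDL:
    def test_hand_computed_dl(self):
        # q = 12.5, denominator 50 - 1250/50 = 25, tau2 = 11.5/25 = 0.46
        r = gm.pool_random_dl(pair())
        assert r.tau2 == pytest.approx(0.46)
        assert r.pooled_log_or == pytest.approx(0.5)
        assert r.i2 == pytest.approx(92.0)

    def test_homogeneous_degenerates_to_fixed(self):
        ests = [est(0.2, 0.3, "a"), est(0.2, 0.25, "b"), est(0.2, 0.2, "c")]
        fe, re = gm.pool_fixed(ests), gm.pool_random_dl(ests)
        assert re.tau2 == 0.0
        assert re.pooled_log_or == fe.pooled_log_or
        assert re.pooled_se == fe.pooled_se
        assert re.weights == fe.weights

    def test_single_study(self):
        r = gm.pool_random_dl([est(0.3, 0.1)])
        assert r.tau2 == 0.0 and r.pooled_log_or == pytest.approx(0.3)
        assert r.i2 == 0.0 and r.p_q == 1.0

    def test_weights_normalized(self, allele_estimates):
        r = gm.pool_random_dl(allele_estimates)
        assert sum(r.weights.values()) == pytest.approx(1.0)


class TestClassifyHeterogeneity:
    @pytest.mark.parametrize("i2,p_q,band,sig", [
        (79.0, 1e-5, "strong", True),
        (0.0, 0.47, "none_or_little", False),
        (50.0, 0.2, "moderate", False),   # boundary -> moderate
        (25.0, 0.05, "moderate", True),
        (24.9, 0.5, "none_or_little", False),
    ])
    def test_bands(self, i2, p_q, band, sig, allele_estimates):
        base = gm.pool_random_dl(allele_estimates)
        from dataclasses import replace
        v = gm.classify_heterogeneity(replace(base, i2=i2, p_q=p_q))
        assert (v.band, v.significant) == (band, sig)


class TestAgainstOracles:
    def test_dl_matches_textbook_oracle_on_random_instances(self, rng):
        for _ in range(400):
            k = int(rng.integers(1, 9))
            y = rng.normal(0, 1, k)
            se = rng.uniform(0.05, 1.0, k)
            ests = [est(yi, si, f"s{i}") for i, (yi, si) in enumerate(zip(y, se))]
            mine = gm.pool_random_dl(ests)
            mu, var, tau2 = dl_oracle(list(y), list(se ** 2))
            assert mine.pooled_log_or == pytest.approx(mu, rel=1e-10, abs=1e-12)
            assert mine.pooled_se ** 2 == pytest.approx(var, rel=1e-10)
            assert mine.tau2 == pytest.approx(tau2, rel=1e-10, abs=1e-12)
            assert mine.q == pytest.approx(cochran_q_oracle(list(y), list(se ** 2)),
                                           rel=1e-10, abs=1e-12)

    def test_dl_matches_statsmodels(self, rng):
        from statsmodels.stats.meta_analysis import combine_effects
        for _ in range(25):
            k = int(rng.integers(2, 12))
            y = rng.normal(0.2, 0.8, k)
            se = rng.uniform(0.05, 1.0, k)
            ests = [est(yi, si, f"s{i}") for i, (yi, si) in enumerate(zip(y, se))]
            mine = gm.pool_random_dl(ests)
            ref = combine_effects(y, se ** 2, method_re="dl")
            # statsmodels reports the untruncated moment estimate; the DL
            # convention truncates at zero
            assert mine.tau2 == pytest.approx(max(0.0, ref.tau2),
                                              rel=1e-8, abs=1e-12)
            if ref.tau2 > 0:
                assert mine.pooled_log_or == pytest.approx(
                    ref.mean_effect_re, rel=1e-8, abs=1e-12)
            else:
                assert mine.pooled_log_or == pytest.approx(
                    ref.mean_effect_fe, rel=1e-8, abs=1e-12)


class TestProperties:
    @given(st.lists(st.tuples(st.floats(-2, 2), st.floats(0.05, 1.5)),
                    min_size=1, max_size=10),
           st.floats(-3, 3))
    def test_shift_equivariance(self, pairs, c):
        ests = [est(y, se, f"s{i}") for i, (y, se) in enumerate(pairs)]
        shifted = [est(y + c, se, f"s{i}") for i, (y, se) in enumerate(pairs)]
        r1, r2 = gm.pool_random_dl(ests), gm.pool_random_dl(shifted)
        assert r2.pooled_log_or == pytest.approx(r1.pooled_log_or + c,
                                                 rel=1e-9, abs=1e-9)
        assert r2.q == pytest.approx(r1.q, rel=1e-9, abs=1e-9)
        assert r2.i2 == pytest.approx(r1.i2, rel=1e-9, abs=1e-9)
        assert r2.tau2 == pytest.approx(r1.tau2, rel=1e-9, abs=1e-9)

    @given(st.lists(st.tuples(st.floats(-2, 2), st.floats(0.05, 1.5)),
                    min_size=2, max_size=10))
    def test_re_variance_at_least_fe(self, pairs):
        ests = [est(y, se, f"s{i}") for i, (y, se) in enumerate(pairs)]
        fe, re = gm.pool_fixed(ests), gm.pool_random_dl(ests)
        assert re.pooled_se >= fe.pooled_se - 1e-15
        if re.tau2 == 0.0:
            assert re.pooled_se == fe.pooled_se

    def test_weight_monotonic_in_precision(self):
        ests = [est(0.1, 0.4, "a"), est(0.2, 0.3, "b"), est(0.3, 0.2, "c")]
        w_before = gm.pool_fixed(ests).weights["b"]
        ests[1] = est(0.2, 0.2, "b")
        w_after = gm.pool_fixed(ests).weights["b"]
        assert w_after > w_before


def test_summary_mentions_key_quantities(allele_estimates):
    text = gm.MetaAnalysis.from_estimates(allele_estimates).fit().summary()
    for token in ("pooled OR", "95% CI", "Cochran Q", "tau2", "I2"):
        assert token in text


def test_from_dataframe_matches_from_estimates(allele_estimates):
    import pandas as pd
    df = pd.DataFrame({"study_id": [e.study_id for e in allele_estimates],
                       "log_or": [e.log_or for e in allele_estimates],
                       "se": [e.se for e in allele_estimates]})
    a = gm.MetaAnalysis.from_dataframe(df).fit()
    b = gm.MetaAnalysis.from_estimates(allele_estimates).fit()
    assert a.pooled_log_or == b.pooled_log_or and a.tau2 == b.tau2
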