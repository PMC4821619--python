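"""Inverse-variance pooling: hand-computed oracles, library cross-checks,
and algebraic invariants."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from statsmodels.stats.meta_analysis import combine_effects

import robmeta as rm
from robmeta.pooling import EmptySetError, ZeroWidthCIError, cochran_q

Z = 1.959964


def make_effect(estimate, lo, hi, study_id="s", **over):
    kwargs = dict(
        study_id=study_id, design="cohort", measure="RR", outcome="o",
        exposure="x", estimate=estimate, ci_low=lo, ci_high=hi,
    )
    kwargs.update(over)
    return rm.StudyEffect(**kwargs)


def brute_force_pool(log_effects, tau2=0.0):
    """Independent direct-summation weighted mean (oracle for small k)."""
    num = den = 0.0
    for e in log_effects:
        w = 1.0 / (e.se**2 + tau2)
        num += w * e.y
        den += w
    return num / den


class TestToLogEffect:
    @pytest.mark.parametrize(
        "estimate,lo,hi,exp_y,exp_se",
        [
            # (ln U - ln L) / (2 * 1.959964), hand-computed
            (1.06, 0.96, 1.18, 0.058269, 0.052638),
            (1.00, 0.67, 1.49, 0.0, 0.203895),
        ],
    )
    def test_back_calculation(self, estimate, lo, hi, exp_y, exp_se):
        le = rm.to_log_effect(make_effect(estimate, lo, hi))
        assert le.y == pytest.approx(exp_y, abs=1e-5)
        assert le.se == pytest.approx(exp_se, abs=1e-5)

    def test_symmetric_interval_limit(self):
        # estimate 1.00 with a shrinking symmetric CI: y = 0, se -> 0+
        for eps in (1e-3, 1e-6):
            le = rm.to_log_effect(make_effect(1.0, 1.0 - eps, 1.0 + eps))
            assert le.y == 0.0
            assert 0 < le.se < eps

    def test_zero_width_ci_rejected(self):
        e = make_effect(1.0, 1.01, 1.01)  # equal bounds pass rounding slack
        with pytest.raises(ZeroWidthCIError):
            rm.to_log_effect(e)

    def test_ci_level_respected(self):
        e90 = make_effect(1.2, 1.0, 1.44, ci_level=0.90)
        le = rm.to_log_effect(e90)
        z90 = 1.6448536
        assert le.se == pytest.approx(
            (math.log(1.44) - math.log(1.0)) / (2 * z90), rel=1e-6
        )


class TestFixedEffectPool:
    def test_two_study_hand_computation(self):
        effects = [rm.LogEffect("a", 0.0, 0.1), rm.LogEffect("b", 0.2, 0.1)]
        res = rm.fixed_effect_pool(effects)
        assert res.pooled_log == pytest.approx(0.1, abs=1e-12)
        assert res.Q == pytest.approx(2.0, abs=1e-12)
        assert res.tau2 == 0.0
        assert res.se_pooled == pytest.approx((200.0) ** -0.5, rel=1e-12)

    def test_single_study_reproduces_input(self):
        e = make_effect(1.21, 0.95, 1.54)
        res = rm.fixed_effect_pool([rm.to_log_effect(e)])
        assert res.k == 1 and res.df == 0
        assert res.estimate == pytest.approx(1.21, rel=1e-12)
        # the printed CI is slightly asymmetric around the estimate on the
        # log scale; the reconstruction matches to printed-rounding precision
        assert res.ci_low == pytest.approx(0.95, abs=0.01)
        assert res.ci_high == pytest.approx(1.54, abs=0.01)
        assert res.display() == "1.21 (0.95-1.54)"
        assert res.tau2 == 0.0 and res.i2 == 0.0

    def test_identical_studies_q_zero(self):
        effects = [rm.LogEffect(f"s{i}", 0.3, 0.2) for i in range(5)]
        res = rm.fixed_effect_pool(effects)
        assert res.Q == pytest.approx(0.0, abs=1e-12)
        assert res.i2 == 0.0

    def test_empty_input(self):
        with pytest.raises(EmptySetError):
            rm.fixed_effect_pool([])


class TestDLTau2:
    def test_hand_computation(self):
        effects = [rm.LogEffect("a", 0.0, 0.1), rm.LogEffect("b", 0.4, 0.1)]
        # Q = 8, tau2 = (8-1)/(200 - 100) = 0.07
        assert cochran_q(effects) == pytest.approx(8.0, abs=1e-12)
        assert rm.dl_tau2(effects) == pytest.approx(0.07, abs=1e-12)

    def test_homogeneous_truncates_to_zero(self):
        effects = [rm.LogEffect(f"s{i}", 0.1, 0.2) for i in range(4)]
        assert rm.dl_tau2(effects) == 0.0

    def test_single_study_warns_and_returns_zero(self):
        with pytest.warns(UserWarning):
            assert rm.dl_tau2([rm.LogEffect("a", 0.1, 0.1)]) == 0.0

    def test_tzd_mortality_homogeneous(self, tzd):
        mort = tzd.select(outcome="mortality")
        logs = [rm.to_log_effect(e) for e in mort]
        assert rm.dl_tau2(logs) == 0.0  # consistent with I2 = 0%


class TestISquared:
    @pytest.mark.parametrize(
        "Q,df,expected", [(10.0, 5, 50.0), (3.0, 5, 0.0), (0.0, 0, 0.0), (4.0, 4, 0.0)]
    )
    def test_closed_form(self, Q, df, expected):
        assert rm.i_squared(Q, df) == pytest.approx(expected)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            rm.i_squared(1.0, -1)
        with pytest.raises(ValueError):
            rm.i_squared(-1.0, 2)


class TestRandomEffectsPool:
    def test_reduces_to_fixed_when_homogeneous(self):
        effects = [rm.LogEffect(f"s{i}", 0.1, 0.2) for i in range(4)]
        re = rm.random_effects_pool(effects)
        fe = rm.fixed_effect_pool(effects)
        assert re.tau2 == 0.0
        assert re.pooled_log == pytest.approx(fe.pooled_log, abs=1e-15)
        assert re.se_pooled == pytest.approx(fe.se_pooled, abs=1e-15)

    def test_weights_normalized(self, tzd_mi):
        res = rm.pool_effect_set(tzd_mi)
        assert sum(res.weights.values()) == pytest.approx(1.0, abs=1e-9)
        assert all(0 <= w <= 1 for w in res.weights.values())

    def test_statsmodels_cross_check(self, tzd_mi, ibuprofen):
        """The DL synthesis agrees with statsmodels' combine_effects."""
        for es in (tzd_mi, ibuprofen):
            logs = [rm.to_log_effect(e) for e in es]
            res = rm.random_effects_pool(logs)
            sm = combine_effects(
                np.array([e.y for e in logs]),
                np.array([e.se**2 for e in logs]),
                method_re="chi2",  # DerSimonian-Laird moment estimator
            )
            assert res.tau2 == pytest.approx(sm.tau2, rel=1e-10)
            assert res.pooled_log == pytest.approx(sm.mean_effect_re, rel=1e-10)
            assert res.Q == pytest.approx(sm.q, rel=1e-10)

    @given(
        st.lists(
            st.tuples(
                st.floats(-1.0, 1.0, allow_nan=False),
                st.floats(0.05, 0.5, allow_nan=False),
            ),
            min_size=1,
            max_size=4,
        )
    )
    def test_brute_force_oracle_small_k(self, ys):
        """For k <= 4 the pooled log equals a direct-summation weighted mean."""
        effects = [rm.LogEffect(f"s{i}", y, se) for i, (y, se) in enumerate(ys)]
        res = rm.random_effects_pool(effects)
        assert res.pooled_log == pytest.approx(
            brute_force_pool(effects, res.tau2), abs=1e-12
        )

    @given(
        st.lists(
            st.tuples(
                st.floats(0.5, 2.0, allow_nan=False),
                st.floats(1.05, 3.0, allow_nan=False),
            ),
            min_size=2,
            max_size=6,
        ),
        st.floats(0.2, 5.0, allow_nan=False),
    )
    def test_scale_equivariance(self, rows, c):
        """Multiplying all estimates and CIs by c shifts the pooled log by
        ln c and leaves SE, Q, tau2 and I2 unchanged."""
        effects = [
            make_effect(est, est / width, est * width, study_id=f"s{i}")
            for i, (est, width) in enumerate(rows)
        ]
        scaled = [
            make_effect(e.estimate * c, e.ci_low * c, e.ci_high * c, study_id=e.study_id)
            for e in effects
        ]
        r1 = rm.random_effects_pool([rm.to_log_effect(e) for e in effects])
        r2 = rm.random_effects_pool([rm.to_log_effect(e) for e in scaled])
        assert r2.pooled_log - r1.pooled_log == pytest.approx(math.log(c), abs=1e-9)
        assert r2.se_pooled == pytest.approx(r1.se_pooled, rel=1e-9)
        assert r2.Q == pytest.approx(r1.Q, abs=1e-8)
        assert r2.tau2 == pytest.approx(r1.tau2, abs=1e-10)
        assert r2.i2 == pytest.approx(r1.i2, abs=1e-6)

    @given(order=st.permutations(range(15)))
    def test_permutation_invariance(self, tzd_mi, order):
        logs = [rm.to_log_effect(e) for e in tzd_mi]
        base = rm.random_effects_pool(logs)
        perm = rm.random_effects_pool([logs[i] for i in order])
        assert perm.pooled_log == pytest.approx(base.pooled_log, abs=1e-12)
        assert perm.se_pooled == pytest.approx(base.se_pooled, abs=1e-12)
        assert perm.Q == pytest.approx(base.Q, abs=1e-9)
        assert perm.weights == pytest.approx(base.weights, abs=1e-12)


class TestSubgroups:
    def test_overall_k_is_sum_of_strata(self, tzd_mi):
        sub = rm.pool_by_subgroup(tzd_mi)
        assert sub.overall.k == sum(r.k for r in sub.per_group.values()) == 15

    def test_missing_stratum_omitted(self, cox2):
        meloxicam = cox2.select(exposure="meloxicam")
        sub = rm.pool_by_subgroup(meloxicam)
        assert set(sub.per_group) == {"case_control"}

    def test_single_stratum_overall_equals_stratum(self, cox2):
        meloxicam = cox2.select(exposure="meloxicam")
        sub = rm.pool_by_subgroup(meloxicam)
        only = sub.per_group["case_control"]
        assert sub.overall.pooled_log == pytest.approx(only.pooled_log, abs=1e-15)
        assert sub.overall.se_pooled == pytest.approx(only.se_pooled, abs=1e-15)

    def test_design_strata_match_printed_mi_rows(self, tzd_mi):
        sub = rm.pool_by_subgroup(tzd_mi)
        assert sub.per_group["cohort"].display() == "1.16 (1.05-1.28)"
        assert sub.per_group["case_control"].display() == "1.15 (1.04-1.27)"
        assert sub.overall.display() == "1.16 (1.07-1.24)"
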