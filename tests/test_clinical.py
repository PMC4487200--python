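"""Clinical layer: LOCF, responder calls, exact tests, mixed model."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from sscexpr import clinical as cs
from sscexpr import simulate


def _records(trajectories, arm="abatacept", duration=3.0):
    rows = []
    for pid, traj in trajectories.items():
        for day, val in traj.items():
            rows.append({"patient_id": pid, "arm": arm, "visit_day": day,
                         "mrss": val, "disease_duration": duration})
    return pd.DataFrame(rows)


class TestLocf:
    def test_complete_record_unchanged(self):
        traj = {d: 20 for d in cs.VISIT_DAYS}
        out = cs.apply_locf(_records({"p1": traj}))
        assert not out["locf"].any()
        assert (out["mrss"] == 20).all()

    def test_missing_tail_filled_and_flagged(self):
        traj = {d: v for d, v in zip(cs.VISIT_DAYS[:5], [30, 28, 26, 24, 22])}
        out = cs.apply_locf(_records({"p1": traj}))
        tail = out[out["visit_day"].isin(cs.VISIT_DAYS[5:])]
        assert (tail["mrss"] == 22).all()
        assert tail["locf"].all()

    def test_withdrawal_after_week16_uses_day113_value(self):
        # dropout pattern: observed through the day-113 (week 16) visit
        traj = {d: v for d, v in zip(cs.VISIT_DAYS[:6], [33, 33, 32, 32, 31, 31])}
        out = cs.apply_locf(_records({"p1": traj}, arm="placebo"))
        final = out.loc[out["visit_day"] == 169, "mrss"].iloc[0]
        assert final == 31

    def test_missing_baseline_errors(self):
        traj = {cs.VISIT_DAYS[1]: 20}
        with pytest.raises(ValueError, match="baseline"):
            cs.apply_locf(_records({"p1": traj}))


class TestImprover:
    @pytest.mark.parametrize("baseline,final,expected", [
        (30, 21, True),    # exactly 30% decrease: boundary inclusive
        (22, 22, False),   # no change
        (30, 20, True),
        (30, 22, False),
    ])
    def test_threshold(self, baseline, final, expected):
        traj = {cs.VISIT_DAYS[0]: baseline, cs.VISIT_DAYS[-1]: final}
        out = cs.classify_improver(cs.apply_locf(_records({"p1": traj})))
        assert bool(out.loc["p1", "improver"]) is expected

    def test_trial_proportions(self):
        # 5 of 7 treated and 1 of 3 placebo improvers
        records = []
        for i in range(7):
            final = 14 if i < 5 else 28
            records.append(_records({f"a{i}": {1: 30, 169: final}}, arm="abatacept"))
        for i in range(3):
            final = 14 if i < 1 else 28
            records.append(_records({f"p{i}": {1: 30, 169: final}}, arm="placebo"))
        clin = cs.apply_locf(pd.concat(records, ignore_index=True))
        calls = cs.classify_improver(clin)
        by_arm = calls.groupby("arm")["improver"].agg(["sum", "count"])
        assert by_arm.loc["abatacept", "sum"] == 5 and by_arm.loc["abatacept", "count"] == 7
        assert by_arm.loc["placebo", "sum"] == 1 and by_arm.loc["placebo", "count"] == 3

    @given(st.integers(1, 51), st.integers(0, 51), st.integers(2, 5))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_scale_invariance(self, baseline, final, factor):
        traj1 = {cs.VISIT_DAYS[0]: baseline, cs.VISIT_DAYS[-1]: final}
        traj2 = {k: v * factor for k, v in traj1.items()}
        c1 = cs.classify_improver(cs.apply_locf(_records({"p": traj1})))
        c2 = cs.classify_improver(cs.apply_locf(_records({"p": traj2})))
        assert bool(c1.loc["p", "improver"]) == bool(c2.loc["p", "improver"])

    def test_zero_baseline_errors(self):
        traj = {cs.VISIT_DAYS[0]: 0, cs.VISIT_DAYS[-1]: 0}
        with pytest.raises(ValueError, match="baseline mRSS 0"):
            cs.classify_improver(cs.apply_locf(_records({"p1": traj})))


class TestSummaryT:
    def test_identical_summaries(self):
        out = cs.summary_two_sample_t(5, 2, 5, 5, 2, 5)
        assert out["t"] == 0.0 and out["p"] == 1.0

    def test_table1_disease_duration(self):
        out = cs.summary_two_sample_t(2.4, 1.6, 7, 8.8, 3.8, 3)
        assert round(out["p"], 3) == 0.004

    def test_hand_toy_matches_t_cdf(self):
        out = cs.summary_two_sample_t(0, 1, 5, 1, 1, 5)
        assert out["t"] == pytest.approx(-1.5811, abs=1e-4)
        assert out["df"] == 8
        assert out["p"] == pytest.approx(2 * stats.t.sf(1.58113883, 8), rel=1e-6)

    def test_welch_differs_with_unequal_variances(self):
        pooled = cs.summary_two_sample_t(0, 1, 10, 1, 5, 4, pooled=True)
        welch = cs.summary_two_sample_t(0, 1, 10, 1, 5, 4, pooled=False)
        assert welch["df"] < pooled["df"]
        assert welch["p"] != pooled["p"]

    def test_degenerate_zero_sds(self):
        out = cs.summary_two_sample_t(1, 0, 3, 1, 0, 3)
        assert out["degenerate"] and out["p"] == 1.0


def brute_fisher_two_sided(a, b, c, d):
    """Enumeration oracle: probability-mass two-sided rule."""
    r1, c1, N = a + b, a + c, a + b + c + d
    def logp(x):
        return (math.lgamma(r1 + 1) - math.lgamma(x + 1) - math.lgamma(r1 - x + 1)
                + math.lgamma(N - r1 + 1) - math.lgamma(c1 - x + 1)
                - math.lgamma(N - r1 - c1 + x + 1)
                - (math.lgamma(N + 1) - math.lgamma(c1 + 1) - math.lgamma(N - c1 + 1)))
    lo, hi = max(0, r1 + c1 - N), min(r1, c1)
    p_obs = math.exp(logp(a))
    return sum(math.exp(logp(x)) for x in range(lo, hi + 1)
               if math.exp(logp(x)) <= p_obs * (1 + 1e-7))


class TestFisher:
    def test_improver_table(self):
        assert cs.fisher_exact_2x2(5, 2, 1, 2)["p"] == pytest.approx(0.5, abs=1e-12)

    def test_symmetric_table(self):
        assert cs.fisher_exact_2x2(3, 3, 3, 3)["p"] == pytest.approx(1.0)

    def test_diagonal_table_enumeration(self):
        # margins (3,3)/(3,3): 4 tables, the two extreme ones have mass 1/20
        assert cs.fisher_exact_2x2(3, 0, 0, 3)["p"] == pytest.approx(0.1)

    def test_matches_scipy(self):
        for table in [(5, 2, 1, 2), (8, 1, 2, 7), (0, 5, 5, 0), (4, 4, 4, 4)]:
            ours = cs.fisher_exact_2x2(*table)["p"]
            ref = stats.fisher_exact([[table[0], table[1]], [table[2], table[3]]])[1]
            assert ours == pytest.approx(ref, rel=1e-9)

    def test_zero_margin_convention(self):
        out = cs.fisher_exact_2x2(0, 0, 3, 4)
        assert out["p"] == 1.0 and out["degenerate"]

    def test_exhaustive_oracle_margins_up_to_six(self):
        # every table with margins <= 6 against the enumeration oracle
        for a, b, c, d in itertools.product(range(7), repeat=4):
            if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
                continue
            if a + b > 6 or c + d > 6 or a + c > 6 or b + d > 6:
                continue
            assert cs.fisher_exact_2x2(a, b, c, d)["p"] == pytest.approx(
                brute_fisher_two_sided(a, b, c, d), rel=1e-7), (a, b, c, d)


def brute_wilcoxon_two_sided(diffs):
    """Full 2^n sign-assignment enumeration oracle."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = len(d)
    ranks = stats.rankdata(np.abs(d))
    total = ranks.sum()
    w_obs = ranks[d > 0].sum()
    dev = abs(w_obs - total / 2)
    count = 0
    for signs in itertools.product([0, 1], repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if abs(w - total / 2) >= dev - 1e-9:
            count += 1
    return count / 2**n


class TestWilcoxon:
    def test_examples(self):
        assert cs.wilcoxon_signed_rank([-1, -2, -3])["p"] == pytest.approx(0.25)
        assert cs.wilcoxon_signed_rank([1, -1])["p"] == pytest.approx(1.0)
        out = cs.wilcoxon_signed_rank([-1, -2, -3, -4, -5, -6, -7])
        assert out["p"] == pytest.approx(2 / 128)

    def test_zeros_dropped(self):
        out = cs.wilcoxon_signed_rank([0, 0, -1, -2, -3])
        assert out["n"] == 3
        assert out["p"] == pytest.approx(0.25)

    def test_all_zero_errors(self):
        with pytest.raises(ValueError, match="no information"):
            cs.wilcoxon_signed_rank([0, 0, 0])

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(21)
        for n in range(2, 11):
            for _ in range(3):
                diffs = rng.integers(-5, 6, size=n)
                if not np.any(diffs != 0):
                    continue
                ours = cs.wilcoxon_signed_rank(diffs)["p"]
                assert ours == pytest.approx(brute_wilcoxon_two_sided(diffs)), diffs

    def test_normal_approximation_large_n(self):
        rng = np.random.default_rng(4)
        diffs = rng.normal(-0.8, 1.0, size=40)
        out = cs.wilcoxon_signed_rank(diffs)
        ref = stats.wilcoxon(diffs, correction=True, mode="approx")
        assert out["p"] == pytest.approx(ref.pvalue, rel=0.05)


class TestCohortSummary:
    def test_pooled_mean_age(self):
        assert cs.pooled_mean([39.8, 48.6], [7, 3]) == pytest.approx(42.44)

    def test_pooled_proportion(self):
        assert cs.pooled_proportion([5, 3], [7, 3]) == pytest.approx(0.8)

    def test_single_patient_summary_equals_record(self):
        df = pd.DataFrame([{"arm": "abatacept", "age": 40.0, "female": True}])
        out = cs.cohort_summary(df, numeric=["age"], categorical=["female"])
        age = out[(out["variable"] == "age") & (out["arm"] == "pooled")].iloc[0]
        assert age["mean"] == 40.0
        fem = out[(out["variable"] == "female") & (out["arm"] == "pooled")].iloc[0]
        assert fem["percent"] == 100.0


class TestMixedModel:
    def _cohort(self, seed, **kwargs):
        params = dict(n_genes=10, n_signature_genes=3,
                      n_abatacept=10, n_placebo=10, n_healthy=0,
                      mrss_drug_visit_trend=0.0)
        params.update(kwargs)
        cfg = simulate.SimulationConfig(seed=seed, **params)
        return simulate.generate_trial_cohort(cfg)["clinical"]

    def test_zero_variance_collapses_to_ols(self):
        import statsmodels.api as sm
        clin = self._cohort(1, mrss_intercept_sd=0.0, mrss_residual_sd=4.0)
        fit = cs.fit_mrss_mixed_model(clin)
        df = clin.copy()
        visit_index = {d: i for i, d in enumerate(sorted(df["visit_day"].unique()))}
        X = np.column_stack([
            np.ones(len(df)),
            df["disease_duration"],
            (df["arm"] == "abatacept").astype(float),
            df["visit_day"].map(visit_index).astype(float),
        ])
        ols = sm.OLS(df["mrss"].to_numpy(dtype=float), X).fit()
        for i, name in enumerate(["intercept", "disease_duration", "drug", "visit"]):
            assert fit["coefficients"][name]["estimate"] == pytest.approx(
                ols.params[i], abs=0.35)

    def test_recovers_generating_effects(self):
        clin = self._cohort(7, n_abatacept=25, n_placebo=25)
        fit = cs.fit_mrss_mixed_model(clin)
        drug = fit["coefficients"]["drug"]
        assert drug["ci_low"] <= -9.8 <= drug["ci_high"]
        assert fit["random_intercept_var"] > 0

    def test_shifted_trajectory_toy_variance_decomposition(self):
        # per-arm pairs of identical declining trajectories offset by +-c,
        # with the offset pattern (+c,-c,+c,-c) orthogonal to the
        # between-patient design (intercept, duration (2,4,4,2), drug
        # (1,1,0,0)).  Closed form: the between-patient residual sum of
        # squares is 4c^2 on 4-3=1 df, so with negligible residual noise
        # the REML random-intercept variance is 4c^2 and the fixed
        # effects match the unshifted data (visit slope -1, drug 0).
        c = 4.0
        rng = np.random.default_rng(0)
        rows = []
        base = np.array([30, 29, 28, 27, 26, 25, 24, 23], dtype=float)
        layout = [("p1", +c, "abatacept", 2.0), ("p2", -c, "abatacept", 4.0),
                  ("p3", +c, "placebo", 4.0), ("p4", -c, "placebo", 2.0)]
        for pid, offset, arm, dur in layout:
            noise = rng.normal(0, 0.05, size=len(base))
            for day, val in zip(cs.VISIT_DAYS, base + offset + noise):
                rows.append({"patient_id": pid, "arm": arm, "visit_day": day,
                             "mrss": val, "disease_duration": dur})
        fit = cs.fit_mrss_mixed_model(pd.DataFrame(rows))
        assert fit["coefficients"]["visit"]["estimate"] == pytest.approx(-1.0, abs=0.05)
        assert fit["coefficients"]["drug"]["estimate"] == pytest.approx(0.0, abs=0.2)
        assert fit["random_intercept_var"] == pytest.approx(4 * c**2, rel=0.1)

    def test_visit_affine_recoding_rescales_coefficient(self):
        clin = self._cohort(9)
        fit1 = cs.fit_mrss_mixed_model(clin)
        # recode visit day so the visit index doubles: insert phantom
        # spacing by remapping days to twice their rank
        days = sorted(clin["visit_day"].unique())
        remap = {d: 2 * i for i, d in enumerate(days)}
        clin2 = clin.copy()
        clin2["visit_day"] = clin2["visit_day"].map(remap)
        fit2 = cs.fit_mrss_mixed_model(clin2)
        # index is rank-based, so the fit is unchanged
        assert fit2["coefficients"]["visit"]["estimate"] == pytest.approx(
            fit1["coefficients"]["visit"]["estimate"], rel=1e-6)

    def test_interaction_term_estimated(self):
        cfg = simulate.SimulationConfig(
            seed=13, n_genes=10, n_signature_genes=3,
            n_abatacept=15, n_placebo=15, n_healthy=0,
            mrss_drug_visit_trend=-0.9)
        clin = simulate.generate_trial_cohort(cfg)["clinical"]
        fit = cs.fit_mrss_mixed_model(clin, interaction=True)
        est = fit["coefficients"]["visit_x_drug"]["estimate"]
        assert est == pytest.approx(-0.9, abs=0.5)

    def test_too_few_patients_errors(self):
        clin = self._cohort(1)
        solo = clin[clin["patient_id"].isin(["A01", "P01"])]
        with pytest.raises(ValueError, match="2 patients per arm"):
            cs.fit_mrss_mixed_model(solo)
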