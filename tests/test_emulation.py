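"""Emulation protocol: eligibility, propensity, matching, follow-up, Cox."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from trialgen.balance import compute_smd
from trialgen.emulation import (
    CoxResult,
    EligibilityRule,
    TrialProtocol,
    apply_eligibility,
    build_followup,
    covariate_matrix,
    estimate_agreement,
    estimate_propensity,
    fit_cox,
    kaplan_meier,
    match_nearest_neighbor,
    stage_cohorts,
)
from trialgen.synthetic import Cohort

from conftest import confounded_config, randomized_config
from trialgen.synthetic import generate_cohort


def toy_cohort(individuals: pd.DataFrame, purchases: pd.DataFrame | None = None,
               traits=("t2d",), registry_end=1000, package_days=100.0) -> Cohort:
    if purchases is None:
        purchases = pd.DataFrame(columns=["individual_id", "day", "n_packages", "drug"])
    return Cohort(individuals, purchases, tuple(traits), registry_end, package_days)


def make_individuals(n, arm, flag_t2d=None, flag_day=None, init_day=None):
    return pd.DataFrame(
        {
            "individual_id": np.arange(n),
            "arm": arm,
            "initiation_day": init_day if init_day is not None else [100.0] * n,
            "event_day": [np.nan] * n,
            "death_day": [np.nan] * n,
            "censor_day": [1000.0] * n,
            "flag_t2d": flag_t2d if flag_t2d is not None else [0] * n,
            "flag_t2d_day": flag_day if flag_day is not None else [np.nan] * n,
        }
    )


class TestEligibility:
    def test_empty_rule_list_is_identity_on_initiators(self):
        ind = make_individuals(4, ["target_drug", "comparator", "target_drug", "noninitiator"])
        cohort = toy_cohort(ind)
        eligible, attrition = apply_eligibility(cohort, TrialProtocol())
        assert len(eligible.individuals) == 3
        assert attrition["n_after"].iloc[-1] == 3

    def test_flag_rule_retains_exactly_the_flagged(self):
        # 10 initiators, 6 with a T2D onset before initiation → 6 retained
        flags = [1, 1, 1, 1, 1, 1, 0, 0, 0, 1]
        days = [50.0] * 6 + [np.nan] * 3 + [200.0]  # last onset is after initiation
        ind = make_individuals(10, ["target_drug"] * 5 + ["comparator"] * 5,
                               flag_t2d=flags, flag_day=days)
        cohort = toy_cohort(ind)
        proto = TrialProtocol(eligibility_rules=[EligibilityRule("t2d", require=True)])
        eligible, attrition = apply_eligibility(cohort, proto)
        assert set(eligible.individuals["individual_id"]) == set(range(6))
        assert attrition.iloc[-1]["n_removed"] == 4

    def test_lookback_window_excludes_stale_onsets(self):
        ind = make_individuals(2, ["target_drug", "comparator"],
                               flag_t2d=[1, 1], flag_day=[10.0, 95.0])
        cohort = toy_cohort(ind)
        proto = TrialProtocol(
            eligibility_rules=[EligibilityRule("t2d", require=True, lookback_days=30)]
        )
        eligible, _ = apply_eligibility(cohort, proto)
        assert list(eligible.individuals["individual_id"]) == [1]

    def test_attrition_counts_consistent_with_set_intersection(self, confounded_cohort):
        proto = TrialProtocol(
            eligibility_rules=[
                EligibilityRule("t2d", require=True),
                EligibilityRule("ckd", require=False),
            ]
        )
        eligible, attrition = apply_eligibility(confounded_cohort, proto)
        # brute-force re-derivation
        frame = confounded_cohort.individuals
        init = frame["arm"].isin(["target_drug", "comparator"])
        has_t2d = (frame["flag_t2d"] == 1) & (frame["flag_t2d_day"] <= frame["initiation_day"])
        no_ckd = ~((frame["flag_ckd"] == 1) & (frame["flag_ckd_day"] <= frame["initiation_day"]))
        expected = frame[init & has_t2d & no_ckd]
        assert set(eligible.individuals["individual_id"]) == set(expected["individual_id"])
        assert attrition["n_after"].iloc[-1] == len(expected)
        assert (attrition["n_before"] - attrition["n_removed"] == attrition["n_after"]).all()

    def test_unknown_covariate_raises(self):
        cohort = toy_cohort(make_individuals(2, ["target_drug", "comparator"]))
        proto = TrialProtocol(eligibility_rules=[EligibilityRule("nonexistent")])
        with pytest.raises(KeyError, match="nonexistent"):
            apply_eligibility(cohort, proto)


class TestPropensity:
    def test_covariate_independent_of_arm_gives_flat_ps(self):
        rng = np.random.default_rng(1)
        n = 2_000
        ind = make_individuals(
            n, rng.choice(["target_drug", "comparator"], size=n, p=[0.3, 0.7]),
            flag_t2d=rng.integers(0, 2, size=n), flag_day=[10.0] * n,
        )
        ps = estimate_propensity(toy_cohort(ind), ["t2d"])
        assert np.allclose(ps, 0.3, atol=0.05)

    def test_perfect_predictor_raises_separation_error(self):
        ind = make_individuals(
            40, ["target_drug"] * 20 + ["comparator"] * 20,
            flag_t2d=[1] * 20 + [0] * 20, flag_day=[10.0] * 40,
        )
        with pytest.raises(ValueError, match="separation.*t2d"):
            estimate_propensity(toy_cohort(ind), ["t2d"])

    def test_matches_independent_likelihood_maximizer(self):
        rng = np.random.default_rng(2)
        n = 400
        x1 = rng.integers(0, 2, size=n).astype(float)
        x2 = rng.normal(size=n)
        lin = -0.4 + 0.8 * x1 + 0.5 * x2
        arm = np.where(rng.random(n) < 1 / (1 + np.exp(-lin)), "target_drug", "comparator")
        ind = make_individuals(n, arm, flag_t2d=x1.astype(int), flag_day=[10.0] * n)
        ind["severity"] = x2
        ps = estimate_propensity(toy_cohort(ind), ["t2d", "severity"])

        treated = (arm == "target_drug").astype(float)
        design = np.column_stack([np.ones(n), x1, x2])

        def nll(beta):
            eta = design @ beta
            return np.sum(np.log1p(np.exp(eta)) - treated * eta)

        res = optimize.minimize(nll, np.zeros(3), method="BFGS")
        oracle_ps = 1 / (1 + np.exp(-design @ res.x))
        np.testing.assert_allclose(ps, oracle_ps, atol=1e-6)


class TestMatching:
    def _cohort_with_ps(self, treated_ps, comparator_ps):
        n_t, n_c = len(treated_ps), len(comparator_ps)
        ind = make_individuals(n_t + n_c, ["target_drug"] * n_t + ["comparator"] * n_c)
        return toy_cohort(ind), np.array(list(treated_ps) + list(comparator_ps))

    def test_identical_ps_matches_everyone(self):
        cohort, ps = self._cohort_with_ps([0.4, 0.4, 0.4], [0.4, 0.4, 0.4, 0.4])
        matched, stats = match_nearest_neighbor(cohort, ps, caliper=0.1, seed=0)
        assert stats.n_matched_pairs == 3
        assert stats.fraction_treated_discarded == 0.0
        assert (matched.individuals["arm"] == "target_drug").sum() == 3

    def test_caliper_excludes_distant_pairs(self):
        cohort, ps = self._cohort_with_ps([0.9], [0.5])
        matched, stats = match_nearest_neighbor(cohort, ps, caliper=0.1, seed=0)
        assert stats.n_matched_pairs == 0
        assert matched.individuals.empty
        assert stats.fraction_treated_discarded == 1.0

    def test_greedy_pairing_equals_brute_force_for_any_order(self):
        treated_ps = [0.30, 0.50, 0.70]
        comp_ps = [0.28, 0.52, 0.71, 0.90]
        cohort, ps = self._cohort_with_ps(treated_ps, comp_ps)
        matched, stats = match_nearest_neighbor(cohort, ps, caliper=0.1, seed=3)

        # brute force: greedy without replacement under every processing order
        def greedy(order):
            avail = set(range(len(comp_ps)))
            pairs = {}
            for t in order:
                best, bestd = None, np.inf
                for c in sorted(avail):
                    d = abs(treated_ps[t] - comp_ps[c])
                    if d < bestd - 1e-15:
                        best, bestd = c, d
                if best is not None and bestd <= 0.1:
                    avail.remove(best)
                    pairs[t] = best
            return pairs

        results = {frozenset(greedy(o).items()) for o in itertools.permutations(range(3))}
        # distances are well separated: every order yields the same pairing
        assert len(results) == 1
        expected = dict(results.pop())
        got = {
            row.treated_id: row.comparator_id - 3
            for row in stats.pairs.itertuples()
        }
        assert got == expected

    def test_empty_arm_raises(self):
        ind = make_individuals(2, ["target_drug", "target_drug"])
        with pytest.raises(ValueError, match="nonempty"):
            match_nearest_neighbor(toy_cohort(ind), np.array([0.5, 0.5]), 0.1, seed=0)

    def test_matching_shrinks_covariate_smd(self, confounded_cohort):
        # matching may not worsen balance on any PS covariate beyond noise
        proto = TrialProtocol(
            comparator_type="noninitiator",
            covariates_for_ps=["t2d", "bmi", "hba1c", "chd", "ldl", "sbp"],
            caliper=0.1,
        )
        staged = stage_cohorts(confounded_cohort, proto, seed=5)
        before = covariate_matrix(staged.eligible_cohort, proto.covariates_for_ps)
        after = covariate_matrix(staged.matched_cohort, proto.covariates_for_ps)
        t_before = (staged.eligible_cohort.individuals["arm"] == "target_drug").to_numpy()
        t_after = (staged.matched_cohort.individuals["arm"] == "target_drug").to_numpy()
        for cov in proto.covariates_for_ps:
            smd_b = abs(compute_smd(before[cov][t_before], before[cov][~t_before]).smd)
            smd_a = abs(compute_smd(after[cov][t_after], after[cov][~t_after]).smd)
            assert smd_a <= smd_b + 0.02


class TestFollowup:
    def _one_person(self, event_day, purchases, arm="target_drug", registry_end=1000):
        ind = make_individuals(1, [arm])
        ind["initiation_day"] = [purchases[0][0]]
        ind["event_day"] = [event_day]
        pur = pd.DataFrame(
            [(0, d, n, arm) for d, n in purchases],
            columns=["individual_id", "day", "n_packages", "drug"],
        )
        return toy_cohort(ind, pur, registry_end=registry_end)

    def test_event_before_supply_ends(self):
        cohort = self._one_person(event_day=50.0, purchases=[(0.0, 1)])
        rec = build_followup(cohort)
        assert rec.iloc[0]["time_days"] == 50.0
        assert rec.iloc[0]["event"]

    def test_discontinuation_censors_before_event(self):
        # 1 package of 100 days, event at day 150 → censored at day 100
        cohort = self._one_person(event_day=150.0, purchases=[(0.0, 1)])
        rec = build_followup(cohort)
        assert rec.iloc[0]["time_days"] == 100.0
        assert not rec.iloc[0]["event"]

    def test_registry_end_is_administrative_censoring(self):
        cohort = self._one_person(event_day=np.nan, purchases=[(0.0, 1)], registry_end=30)
        rec = build_followup(cohort)
        assert rec.iloc[0]["time_days"] == 30.0
        assert not rec.iloc[0]["event"]

    def test_supply_accumulates_over_purchases(self):
        # two packages bought on days 0 and 100 → supply to day 200
        cohort = self._one_person(event_day=np.nan, purchases=[(0.0, 1), (100.0, 1)])
        rec = build_followup(cohort)
        assert rec.iloc[0]["time_days"] == 200.0

    def test_switch_to_opposing_drug_terminates(self):
        ind = make_individuals(1, ["target_drug"])
        ind["initiation_day"] = [0.0]
        pur = pd.DataFrame(
            [(0, 0.0, 5, "target_drug"), (0, 60.0, 1, "comparator")],
            columns=["individual_id", "day", "n_packages", "drug"],
        )
        rec = build_followup(toy_cohort(ind, pur))
        assert rec.iloc[0]["time_days"] == 60.0
        assert not rec.iloc[0]["event"]

    def test_individual_without_purchase_excluded(self, caplog):
        ind = make_individuals(1, ["target_drug"])
        rec = build_followup(toy_cohort(ind))
        assert rec.empty


class TestCox:
    def test_null_effect_on_identical_distributions(self):
        rng = np.random.default_rng(7)
        n = 4_000
        t = rng.exponential(300.0, size=n)
        records = pd.DataFrame(
            {"treated": np.repeat([1, 0], n // 2), "time_days": t,
             "event": np.ones(n, dtype=bool)}
        )
        res = fit_cox(records)
        assert res.ci_low < 1.0 < res.ci_high
        assert abs(res.log_hr) < 0.1

    def test_grid_search_oracle_small_dataset(self):
        # 6 observations, distinct event times → exact partial likelihood
        records = pd.DataFrame(
            {
                "treated": [1, 1, 1, 0, 0, 0],
                "time_days": [3.0, 5.0, 9.0, 4.0, 7.0, 11.0],
                "event": [True, True, False, True, True, True],
            }
        )
        res = fit_cox(records)

        x = records["treated"].to_numpy(dtype=float)
        times = records["time_days"].to_numpy()
        events = records["event"].to_numpy()

        def log_pl(beta):
            ll = 0.0
            for i in np.flatnonzero(events):
                risk = times >= times[i]
                ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[risk])))
            return ll

        grid = np.arange(-3.0, 3.0, 1e-4)
        oracle_beta = grid[np.argmax([log_pl(b) for b in grid])]
        assert abs(res.log_hr - oracle_beta) < 1e-3
        assert abs(log_pl(res.log_hr) - log_pl(oracle_beta)) < 1e-4

    def test_zero_events_raises(self):
        records = pd.DataFrame(
            {"treated": [1, 0], "time_days": [10.0, 20.0], "event": [False, False]}
        )
        with pytest.raises(ValueError, match="events"):
            fit_cox(records)

    def test_hr_log_hr_consistency_enforced(self):
        with pytest.raises(ValueError):
            CoxResult(hr=2.0, ci_low=1.0, ci_high=4.0, log_hr=0.0,
                      se=0.3, p=0.05, n=10, n_events=5)


class TestAgreement:
    def test_emulation_inside_rct_interval(self):
        # a nonsignificant emulated HR can still agree with the RCT estimate
        res = CoxResult(hr=0.88, ci_low=0.57, ci_high=1.36, log_hr=np.log(0.88),
                        se=0.22, p=0.3, n=1000, n_events=80)
        assert estimate_agreement(res, (0.79, 0.66, 0.96))

    def test_boundary_is_closed(self):
        res = CoxResult(hr=0.96, ci_low=0.8, ci_high=1.2, log_hr=np.log(0.96),
                        se=0.1, p=0.5, n=100, n_events=20)
        assert estimate_agreement(res, (0.79, 0.66, 0.96))

    def test_outside_interval(self):
        res = CoxResult(hr=1.20, ci_low=1.0, ci_high=1.4, log_hr=np.log(1.2),
                        se=0.1, p=0.05, n=100, n_events=20)
        assert not estimate_agreement(res, (0.79, 0.66, 0.96))

    def test_malformed_interval_raises(self):
        res = CoxResult(hr=1.0, ci_low=0.9, ci_high=1.1, log_hr=0.0,
                        se=0.1, p=1.0, n=10, n_events=5)
        with pytest.raises(ValueError, match="malformed"):
            estimate_agreement(res, (0.8, 0.96, 0.66))

    def test_symmetry_under_arm_relabeling(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            hr = float(np.exp(rng.normal(0, 0.5)))
            lo, hi = np.sort(np.exp(rng.normal(0, 0.5, size=2)))
            res = CoxResult(hr=hr, ci_low=hr * 0.8, ci_high=hr * 1.25,
                            log_hr=np.log(hr), se=0.1, p=0.5, n=10, n_events=5)
            flipped = CoxResult(hr=1 / hr, ci_low=1 / (hr * 1.25), ci_high=1 / (hr * 0.8),
                                log_hr=-np.log(hr), se=0.1, p=0.5, n=10, n_events=5)
            assert estimate_agreement(res, (1.0, lo, hi)) == \
                estimate_agreement(flipped, (1.0, 1 / hi, 1 / lo))


class TestKaplanMeier:
    def test_no_events_flat_at_one(self):
        records = pd.DataFrame(
            {"treated": [0, 0, 0], "time_days": [5.0, 8.0, 9.0],
             "event": [False, False, False]}
        )
        curves = kaplan_meier(records)
        assert np.allclose(curves[0]["survival"], 1.0)

    def test_textbook_no_censoring(self):
        records = pd.DataFrame(
            {"treated": [0, 0, 0], "time_days": [1.0, 2.0, 3.0],
             "event": [True, True, True]}
        )
        curve = kaplan_meier(records)[0].set_index("time_days")["survival"]
        np.testing.assert_allclose(curve.loc[[1.0, 2.0, 3.0]], [2 / 3, 1 / 3, 0.0])

    def test_mixed_censoring_matches_hand_product_limit(self):
        # events at 2 (n=6 at risk) and 5 (n=3 at risk); censored at 3, 4
        records = pd.DataFrame(
            {
                "treated": [0] * 6,
                "time_days": [2.0, 2.0, 3.0, 4.0, 5.0, 6.0],
                "event": [True, True, False, False, True, False],
            }
        )
        curve = kaplan_meier(records)[0].set_index("time_days")["survival"]
        np.testing.assert_allclose(curve.loc[2.0], 4 / 6)
        np.testing.assert_allclose(curve.loc[5.0], (4 / 6) * (1 / 2))

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            kaplan_meier(pd.DataFrame(columns=["treated", "time_days", "event"]))


class TestStagedCohorts:
    def test_nesting_and_equal_arms(self, confounded_cohort):
        proto = TrialProtocol(
            comparator_type="noninitiator",
            eligibility_rules=[EligibilityRule("t2d", require=True)],
            covariates_for_ps=["bmi", "hba1c", "chd", "ldl", "sbp"],
            caliper=0.1,
        )
        staged = stage_cohorts(confounded_cohort, proto, seed=13)
        staged.check_nesting()  # raises on violation
        counts = staged.matched["_treated"].value_counts()
        assert counts.iloc[0] == counts.iloc[1]

    def test_randomized_cohort_matched_vs_unmatched_hr_agree(self):
        cohort = generate_cohort(randomized_config(n=30_000, seed=17,
                                                   true_treatment_log_hr=np.log(0.8)))
        proto = TrialProtocol(comparator_type="active",
                              covariates_for_ps=["t2d", "bmi", "chd"], caliper=0.1)
        staged = stage_cohorts(cohort, proto, seed=17)
        rec_matched = build_followup(staged.matched_cohort)
        rec_all = build_followup(staged.eligible_cohort)
        hr_m = fit_cox(rec_matched)
        hr_u = fit_cox(rec_all)
        assert abs(hr_m.log_hr - hr_u.log_hr) < 2.5 * np.hypot(hr_m.se, hr_u.se)
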