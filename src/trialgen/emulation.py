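"""Target-trial emulation: eligibility, matching, follow-up and Cox analysis.

The emulation protocol mirrors standard registry-based replication practice:
new users of the target drug are compared with an active comparator (or with
noninitiators for placebo-controlled designs), eligibility criteria are
evaluated at drug initiation with optional look-back windows, arms are
1:1 propensity-score nearest-neighbor matched within a caliper, follow-up is
on-treatment (censored at discontinuation, switch, death or the end of
registry coverage), and the hazard ratio comes from a Cox proportional-
hazards model with Efron tie handling.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError

from ._rng import child_rng
from .synthetic import Cohort

__all__ = [
    "EligibilityRule",
    "TrialProtocol",
    "StagedCohorts",
    "CoxResult",
    "apply_eligibility",
    "estimate_propensity",
    "choose_caliper",
    "match_nearest_neighbor",
    "build_followup",
    "fit_cox",
    "estimate_agreement",
    "kaplan_meier",
    "stage_cohorts",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EligibilityRule:
    """One inclusion/exclusion predicate evaluated at drug initiation.

    ``require=True`` keeps individuals whose ``covariate`` flag has an onset
    on or before their initiation day (and, when ``lookback_days`` is set,
    within that many days before initiation); ``require=False`` keeps those
    without such an onset.
    """

    covariate: str
    require: bool = True
    lookback_days: float | None = None

    @property
    def label(self) -> str:
        verb = "has" if self.require else "no"
        window = f" within {self.lookback_days:g}d" if self.lookback_days else ""
        return f"{verb} {self.covariate}{window}"


@dataclass
class TrialProtocol:
    """Declarative emulation protocol for one trial."""

    name: str = "trial"
    comparator_type: str = "active"  # "active" or "noninitiator"
    eligibility_rules: list[EligibilityRule] = field(default_factory=list)
    covariates_for_ps: list[str] = field(default_factory=list)
    caliper: float | None = 0.1  # None → choose by PS-overlap rule
    rct_reference: tuple[float, float, float] | None = None  # (hr, lo, hi)

    def validate(self) -> None:
        if self.caliper is not None and self.caliper <= 0:
            raise ValueError("caliper must be positive")
        if self.comparator_type not in ("active", "noninitiator"):
            raise ValueError("comparator_type must be 'active' or 'noninitiator'")

    @classmethod
    def from_yaml(cls, path) -> "TrialProtocol":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "TrialProtocol":
        rules = [EligibilityRule(**r) for r in raw.get("eligibility_rules", [])]
        ref = raw.get("rct_reference")
        return cls(
            name=raw.get("name", "trial"),
            comparator_type=raw.get("comparator_type", "active"),
            eligibility_rules=rules,
            covariates_for_ps=list(raw.get("covariates_for_ps", [])),
            caliper=raw.get("caliper", 0.1),
            rct_reference=tuple(ref) if ref else None,
        )

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "comparator_type": self.comparator_type,
            "eligibility_rules": [
                {"covariate": r.covariate, "require": r.require,
                 "lookback_days": r.lookback_days}
                for r in self.eligibility_rules
            ],
            "covariates_for_ps": list(self.covariates_for_ps),
            "caliper": self.caliper,
            "rct_reference": list(self.rct_reference) if self.rct_reference else None,
        }


# ---------------------------------------------------------------------------
# eligibility
# ---------------------------------------------------------------------------

def _rule_mask(frame: pd.DataFrame, rule: EligibilityRule) -> np.ndarray:
    flag_col = f"flag_{rule.covariate}"
    day_col = f"flag_{rule.covariate}_day"
    if flag_col not in frame.columns or day_col not in frame.columns:
        raise KeyError(f"eligibility rule references unknown covariate {rule.covariate!r}")
    init = frame["initiation_day"].to_numpy(dtype=float)
    onset = frame[day_col].to_numpy(dtype=float)
    present = (frame[flag_col].to_numpy() == 1) & (onset <= init)
    if rule.lookback_days is not None:
        present &= init - onset <= rule.lookback_days
    return present if rule.require else ~present


def apply_eligibility(cohort: Cohort, protocol: TrialProtocol) -> tuple[Cohort, pd.DataFrame]:
    """Restrict to target/comparator initiators passing every rule in order.

    Returns the restricted cohort and an attrition log with one row per rule
    (counts before, removed, after), mirroring a cohort-formation flowchart.
    """
    frame = cohort.individuals
    mask = frame["arm"].isin(["target_drug", "comparator"]).to_numpy()
    attrition = [{"rule": "initiator of target or comparator",
                  "n_before": len(frame), "n_removed": int((~mask).sum()),
                  "n_after": int(mask.sum())}]
    for rule in protocol.eligibility_rules:
        keep = _rule_mask(frame, rule)
        before = int(mask.sum())
        mask &= keep
        after = int(mask.sum())
        attrition.append({"rule": rule.label, "n_before": before,
                          "n_removed": before - after, "n_after": after})
    eligible = cohort.subset(frame.loc[mask, "individual_id"])
    return eligible, pd.DataFrame(attrition)


# ---------------------------------------------------------------------------
# propensity score and matching
# ---------------------------------------------------------------------------

def covariate_matrix(cohort: Cohort, covariates: list[str]) -> pd.DataFrame:
    """Design matrix for the PS model, evaluated at initiation.

    A name matching a diagnosis flag becomes the 0/1 indicator "onset on or
    before initiation"; any other name must be a numeric column of the
    individuals table (e.g. a PGS) and is used as-is.
    """
    frame = cohort.individuals
    init = frame["initiation_day"].to_numpy(dtype=float)
    out = {}
    for cov in covariates:
        flag_col, day_col = f"flag_{cov}", f"flag_{cov}_day"
        if flag_col in frame.columns:
            onset = frame[day_col].to_numpy(dtype=float)
            out[cov] = ((frame[flag_col].to_numpy() == 1) & (onset <= init)).astype(float)
        elif cov in frame.columns:
            out[cov] = frame[cov].to_numpy(dtype=float)
        else:
            raise KeyError(f"PS covariate {cov!r} not found in cohort")
    return pd.DataFrame(out, index=frame.index)


def estimate_propensity(cohort: Cohort, covariates: list[str]) -> np.ndarray:
    """Fitted P(target drug | covariates) from a main-effects logistic model."""
    import statsmodels.api as sm

    if not covariates:
        raise ValueError("covariate list for the PS model is empty")
    frame = cohort.individuals
    treated = (frame["arm"] == "target_drug").to_numpy(dtype=float)
    if treated.sum() == 0 or treated.sum() == len(treated):
        raise ValueError("both arms must be nonempty to fit a propensity model")
    design = covariate_matrix(cohort, covariates)

    # constant columns (e.g. a flag required by eligibility) carry no
    # information for the PS model; drop them rather than fail on singularity
    constant = [c for c in design.columns if design[c].nunique() <= 1]
    if constant:
        logger.warning("dropping constant PS covariates: %s", constant)
        design = design.drop(columns=constant)
        if design.shape[1] == 0:
            raise ValueError(f"all PS covariates are constant: {covariates}")

    # flag covariates that perfectly predict the arm (complete separation)
    separating = []
    for cov in design.columns:
        x = design[cov].to_numpy()
        if len(np.unique(x)) <= 2:
            for level in np.unique(x):
                sel = x == level
                if sel.any() and len(np.unique(treated[sel])) == 1 and sel.sum() < len(x):
                    other = ~sel
                    if other.any() and len(np.unique(treated[other])) == 1 \
                            and treated[sel][0] != treated[other][0]:
                        separating.append(cov)
    if separating:
        raise ValueError(f"perfect separation by covariates: {sorted(set(separating))}")

    exog = sm.add_constant(design, has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(treated, exog).fit(disp=0, maxiter=200)
        except Exception as exc:  # singular design, separation missed above
            raise ValueError(f"propensity model failed for covariates {covariates}: {exc}")
    if not fit.mle_retvals.get("converged", True):
        raise ValueError(f"propensity model did not converge (covariates {covariates})")
    ps = np.asarray(fit.predict(exog))
    return np.clip(ps, 1e-12, 1.0 - 1e-12)


def choose_caliper(ps: np.ndarray, treated: np.ndarray, bins: int = 50) -> float:
    """0.1 by default, tightened to 0.01 when the arm-wise PS densities
    nearly coincide (histogram overlap coefficient > 0.98)."""
    edges = np.linspace(0.0, 1.0, bins + 1)
    h1, _ = np.histogram(ps[treated.astype(bool)], bins=edges, density=False)
    h0, _ = np.histogram(ps[~treated.astype(bool)], bins=edges, density=False)
    p1 = h1 / max(h1.sum(), 1)
    p0 = h0 / max(h0.sum(), 1)
    overlap = float(np.minimum(p1, p0).sum())
    return 0.01 if overlap > 0.98 else 0.1


@dataclass
class MatchResult:
    pairs: pd.DataFrame  # treated_id, comparator_id, ps_treated, ps_comparator
    matched_ids: np.ndarray
    n_treated: int
    n_matched_pairs: int

    @property
    def fraction_treated_discarded(self) -> float:
        return 1.0 - self.n_matched_pairs / self.n_treated if self.n_treated else 0.0


def match_nearest_neighbor(
    cohort: Cohort, ps: np.ndarray, caliper: float, seed: int = 0
) -> tuple[Cohort, MatchResult]:
    """Greedy 1:1 nearest-neighbor PS matching without replacement.

    Treated individuals are processed in a seeded random order; each is
    paired with the closest-PS unmatched comparator within ``caliper``
    (distance ties broken by lowest comparator id). Unmatched treated are
    dropped, so the output arms are equal-sized.
    """
    if caliper <= 0:
        raise ValueError("caliper must be positive")
    frame = cohort.individuals
    ps = np.asarray(ps, dtype=float)
    if len(ps) != len(frame):
        raise ValueError("ps vector length must match the cohort")
    t_idx = np.flatnonzero((frame["arm"] == "target_drug").to_numpy())
    c_idx = np.flatnonzero((frame["arm"] != "target_drug").to_numpy())
    if t_idx.size == 0 or c_idx.size == 0:
        raise ValueError("both arms must be nonempty for matching")

    rng = child_rng(seed, "matching")
    order = rng.permutation(t_idx.size)
    # comparators sorted by (ps, id) so the lowest id wins distance ties
    c_ids = frame["individual_id"].to_numpy()[c_idx]
    c_order = np.lexsort((c_ids, ps[c_idx]))
    c_sorted = c_idx[c_order]
    c_ps = ps[c_sorted]
    available = np.ones(c_sorted.size, dtype=bool)

    rows = []
    for oi in order:
        ti = t_idx[oi]
        dist = np.abs(c_ps - ps[ti])
        dist[~available] = np.inf
        j = int(np.argmin(dist))  # argmin takes first occurrence → lowest id on ties
        if not np.isfinite(dist[j]) or dist[j] > caliper:
            continue
        available[j] = False
        rows.append(
            {
                "treated_id": int(frame["individual_id"].iloc[ti]),
                "comparator_id": int(frame["individual_id"].iloc[c_sorted[j]]),
                "ps_treated": float(ps[ti]),
                "ps_comparator": float(c_ps[j]),
            }
        )
    pairs = pd.DataFrame(rows, columns=["treated_id", "comparator_id", "ps_treated", "ps_comparator"])
    matched_ids = np.concatenate([pairs["treated_id"].to_numpy(), pairs["comparator_id"].to_numpy()]) \
        if len(pairs) else np.array([], dtype=int)
    result = MatchResult(
        pairs=pairs, matched_ids=matched_ids,
        n_treated=int(t_idx.size), n_matched_pairs=len(pairs),
    )
    return cohort.subset(matched_ids), result


# ---------------------------------------------------------------------------
# staged cohorts
# ---------------------------------------------------------------------------

@dataclass
class StagedCohorts:
    """The three comparison stages of one emulation.

    ``plain``: the design-reflecting observational contrast on the full
    cohort (target initiators versus noninitiators of the target drug for
    placebo-controlled designs, versus active-comparator initiators
    otherwise). ``eligible``: after eligibility and comparator restriction.
    ``matched``: after 1:1 PS matching. Each stage's table carries a
    ``_treated`` 0/1 column; treated ids are nested across stages.
    """

    plain: pd.DataFrame
    eligible: pd.DataFrame
    matched: pd.DataFrame
    eligible_cohort: Cohort
    matched_cohort: Cohort
    attrition: pd.DataFrame
    match_result: MatchResult
    propensity: np.ndarray
    caliper: float

    def as_dict(self) -> dict[str, pd.DataFrame]:
        return {"plain": self.plain, "eligible": self.eligible, "matched": self.matched}

    def check_nesting(self) -> None:
        def treated_ids(df: pd.DataFrame) -> set:
            return set(df.loc[df["_treated"] == 1, "individual_id"])

        ids_m, ids_e, ids_p = map(treated_ids, (self.matched, self.eligible, self.plain))
        if not (ids_m <= ids_e <= ids_p):
            raise AssertionError("stage nesting violated: matched ⊆ eligible ⊆ plain")
        arms = self.matched["_treated"].value_counts()
        if len(arms) == 2 and arms.iloc[0] != arms.iloc[1]:
            raise AssertionError("matched stage arms are not equal-sized")


def _with_treated(frame: pd.DataFrame, treated_mask: np.ndarray) -> pd.DataFrame:
    out = frame.copy()
    out["_treated"] = treated_mask.astype(int)
    return out


def stage_cohorts(cohort: Cohort, protocol: TrialProtocol, seed: int = 0) -> StagedCohorts:
    """Run eligibility, PS estimation and matching; return all three stages."""
    protocol.validate()
    frame = cohort.individuals
    is_target = (frame["arm"] == "target_drug").to_numpy()
    if protocol.comparator_type == "noninitiator":
        plain = _with_treated(frame, is_target)  # control: everyone else
    else:
        sel = frame["arm"].isin(["target_drug", "comparator"]).to_numpy()
        plain = _with_treated(frame[sel], is_target[sel])

    eligible_cohort, attrition = apply_eligibility(cohort, protocol)
    el_frame = eligible_cohort.individuals
    eligible = _with_treated(el_frame, (el_frame["arm"] == "target_drug").to_numpy())

    ps = estimate_propensity(eligible_cohort, protocol.covariates_for_ps)
    caliper = protocol.caliper
    if caliper is None:
        caliper = choose_caliper(ps, eligible["_treated"].to_numpy())
    matched_cohort, match_result = match_nearest_neighbor(eligible_cohort, ps, caliper, seed)
    m_frame = matched_cohort.individuals
    matched = _with_treated(m_frame, (m_frame["arm"] == "target_drug").to_numpy())

    staged = StagedCohorts(
        plain=plain, eligible=eligible, matched=matched,
        eligible_cohort=eligible_cohort, matched_cohort=matched_cohort,
        attrition=attrition, match_result=match_result,
        propensity=ps, caliper=caliper,
    )
    staged.check_nesting()
    return staged


# ---------------------------------------------------------------------------
# follow-up construction
# ---------------------------------------------------------------------------

def build_followup(
    matched: Cohort,
    pgs_columns: list[str] | None = None,
) -> pd.DataFrame:
    """On-treatment survival records for matched initiators.

    Follow-up starts at the first purchase and ends at the earliest of the
    outcome event, death, discontinuation, switch to the opposing drug or the
    end of registry coverage. Discontinuation is when the purchased supply
    runs out: first purchase day + total packages × days of supply per
    package. The event flag is set only when the outcome is the earliest
    terminator. Individuals without purchases, or whose follow-up would be
    nonpositive, are excluded with a logged warning.
    """
    frame = matched.individuals.set_index("individual_id")
    purch = matched.purchases
    by_individual = {iid: grp for iid, grp in purch.groupby("individual_id")}
    rows = []
    excluded = []
    for iid, row in frame.iterrows():
        own = by_individual.get(iid)
        if own is None or own.empty:
            excluded.append((iid, "no purchases"))
            continue
        own_drug = row["arm"]
        own_purch = own[own["drug"] == own_drug]
        if own_purch.empty:
            excluded.append((iid, "no purchases of assigned drug"))
            continue
        first = float(own_purch["day"].min())
        last_supply = first + float(own_purch["n_packages"].sum()) * matched.package_days
        switch = own[(own["drug"] != own_drug) & (own["day"] > first)]
        switch_day = float(switch["day"].min()) if not switch.empty else np.inf
        event_day = row["event_day"] if np.isfinite(row.get("event_day", np.nan)) else np.inf
        death_day = row["death_day"] if np.isfinite(row.get("death_day", np.nan)) else np.inf
        end = min(event_day, death_day, last_supply, switch_day, float(matched.registry_end))
        time = end - first
        if time <= 0:
            excluded.append((iid, "nonpositive follow-up"))
            continue
        rec = {
            "individual_id": iid,
            "treated": 1 if row["arm"] == "target_drug" else 0,
            "time_days": time,
            "event": bool(event_day == end),
        }
        if pgs_columns:
            for col in pgs_columns:
                rec[col] = row[col]
        rows.append(rec)
    if excluded:
        logger.warning("excluded %d individuals from follow-up: %s",
                       len(excluded), excluded[:5])
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Cox model, agreement, Kaplan-Meier
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CoxResult:
    """Hazard ratio for one model term with Wald 95% CI."""

    hr: float
    ci_low: float
    ci_high: float
    log_hr: float
    se: float
    p: float
    n: int
    n_events: int
    term: str = "treated"

    def __post_init__(self) -> None:
        if not np.isclose(np.exp(self.log_hr), self.hr, rtol=1e-9):
            raise ValueError("hr and log_hr are inconsistent")


def fit_cox(
    records: pd.DataFrame,
    covariates: list[str] | None = None,
    term: str = "treated",
    duration_col: str = "time_days",
    event_col: str = "event",
) -> CoxResult:
    """Cox partial-likelihood fit (Efron ties) returning the HR for ``term``.

    ``covariates`` defaults to ``[term]``; extra names are adjustment terms.
    """
    covariates = covariates or [term]
    if records.empty:
        raise ValueError("no survival records")
    n_events = int(records[event_col].sum())
    if n_events == 0:
        raise ValueError("no events in the data; the Cox model is not estimable")
    df = records[[duration_col, event_col] + covariates].astype(float)
    constant = [c for c in covariates if df[c].nunique() <= 1]
    if term in constant:
        raise ValueError(f"model term {term!r} is constant; the Cox model is degenerate")
    if constant:
        logger.warning("dropping constant Cox covariates: %s", constant)
        df = df.drop(columns=constant)
    fitter = CoxPHFitter()
    try:
        fitter.fit(df, duration_col=duration_col, event_col=event_col)
    except ConvergenceError as exc:
        raise ValueError(f"Cox model failed to converge: {exc}")
    s = fitter.summary.loc[term]
    return CoxResult(
        hr=float(np.exp(s["coef"])),
        ci_low=float(np.exp(s["coef lower 95%"])),
        ci_high=float(np.exp(s["coef upper 95%"])),
        log_hr=float(s["coef"]),
        se=float(s["se(coef)"]),
        p=float(s["p"]),
        n=len(df),
        n_events=n_events,
        term=term,
    )


def estimate_agreement(emulation: CoxResult, rct_reference: tuple[float, float, float]) -> bool:
    """True iff the emulated HR falls inside the RCT's 95% CI (closed interval)."""
    _, lo, hi = rct_reference
    if lo > hi:
        raise ValueError(f"malformed RCT confidence interval: ({lo}, {hi})")
    return bool(lo <= emulation.hr <= hi)


def kaplan_meier(records: pd.DataFrame) -> dict[int, pd.DataFrame]:
    """Product-limit survival curve with Greenwood 95% CI, one per arm."""
    if records.empty:
        raise ValueError("no survival records")
    out = {}
    for arm, grp in records.groupby("treated"):
        km = KaplanMeierFitter()
        km.fit(grp["time_days"], grp["event"])
        curve = km.survival_function_.copy()
        curve.columns = ["survival"]
        ci = km.confidence_interval_
        curve["ci_low"] = ci.iloc[:, 0].to_numpy()
        curve["ci_high"] = ci.iloc[:, 1].to_numpy()
        out[int(arm)] = curve.reset_index().rename(columns={"timeline": "time_days"})
    return out
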