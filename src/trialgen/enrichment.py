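"""PGS prognostic and predictive enrichment within emulated trial cohorts.

Prognostic enrichment asks whether the outcome PGS predicts the primary
outcome *inside* the emulated trial cohort (Cox model with the treatment as
an adjustment term) and how that association compares with the full
population (follow-up from birth, age as the timescale). Eligibility
criteria can restrict the trial to high-risk individuals, where a PGS may
lose discriminative value, so trial-cohort and population HRs need not
agree.

If the PGS does stratify event risk, selecting the top quantile of genetic
risk raises the event rate and shrinks the sample size needed for the same
expected number of events — the equal-events operationalization of "same
statistical power". A Schoenfeld log-rank power calculation is available as
an alternative.

Predictive enrichment (treatment effect varying with PGS) is tested via the
Wald p-value of the treatment × PGS interaction term.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .emulation import CoxResult, fit_cox
from .synthetic import Cohort

__all__ = [
    "EnrichmentResult",
    "prognostic_association",
    "population_association",
    "event_rates",
    "enrichment_sample_size",
    "predictive_interaction",
    "evaluate_enrichment",
]


def prognostic_association(records: pd.DataFrame, pgs_col: str) -> CoxResult:
    """HR per 1 sd of PGS within the matched cohort, treatment-adjusted.

    Fits h(t|T, PGS) = h0(t)·exp(β1·T + β2·PGS) on on-treatment follow-up
    records and returns the PGS term (β2).
    """
    return fit_cox(records, covariates=["treated", pgs_col], term=pgs_col)


def population_association(cohort: Cohort, pgs_col: str) -> CoxResult:
    """HR per 1 sd of PGS in the full cohort, follow-up from birth.

    Survival time runs from day 0 until the event, death or the end of
    registry coverage, whichever comes first (age as the timescale; no
    left truncation by default).
    """
    frame = cohort.individuals
    event_day = frame["event_day"].to_numpy(dtype=float)
    death_day = frame["death_day"].to_numpy(dtype=float)
    end = float(cohort.registry_end)
    stop = np.nanmin(
        np.column_stack([
            np.where(np.isnan(event_day), np.inf, event_day),
            np.where(np.isnan(death_day), np.inf, death_day),
            np.full(len(frame), end),
        ]),
        axis=1,
    )
    records = pd.DataFrame(
        {
            "time_days": stop,
            "event": np.isfinite(event_day) & (event_day <= stop),
            pgs_col: frame[pgs_col].to_numpy(dtype=float),
        }
    )
    records = records[records["time_days"] > 0]
    return fit_cox(records, covariates=[pgs_col], term=pgs_col)


def event_rates(
    records: pd.DataFrame, pgs_values: np.ndarray, threshold: float
) -> tuple[float, float]:
    """(events per person overall, events per person in the top-PGS stratum).

    ``threshold`` is the PGS cut defining the enriched stratum — typically
    the top-quantile boundary of the *full-population* PGS distribution, not
    the trial cohort's own.
    """
    events = records["event"].to_numpy(dtype=bool)
    top = np.asarray(pgs_values, dtype=float) >= threshold
    if top.sum() == 0:
        raise ValueError("no individuals above the PGS threshold")
    return float(events.mean()), float(events[top].mean())


def enrichment_sample_size(
    event_rate_all: float,
    event_rate_topq: float,
    n_original: int,
    method: str = "equal_events",
    hr: float | None = None,
    alpha: float = 0.05,
    power: float = 0.8,
) -> tuple[float, float]:
    """Sample size needed at the enriched event rate for the same power.

    ``equal_events`` (default): n_required = n_original · rate_all /
    rate_topq, i.e. the enriched cohort needs only as many participants as
    produce the original expected number of events. ``schoenfeld``: events
    needed d = 4·(z_{1−α/2} + z_power)² / log(hr)² for a 1:1 log-rank test;
    n_required = d / rate_topq, and n_original is recomputed as d / rate_all
    so the reported reduction is internally consistent.

    Returns ``(n_required, pct_reduction)`` with
    pct_reduction = 100·(1 − n_required / n_original).
    """
    if not (0.0 < event_rate_all <= 1.0):
        raise ValueError("event_rate_all must be in (0, 1]")
    if not (0.0 < event_rate_topq <= 1.0):
        raise ValueError("event_rate_topq must be in (0, 1]")
    if n_original <= 0:
        raise ValueError("n_original must be positive")
    if event_rate_topq < event_rate_all:
        import warnings

        warnings.warn(
            "top-quantile event rate is below the overall rate; "
            "PGS enrichment would increase the required sample size",
            stacklevel=2,
        )
    if method == "equal_events":
        n_required = n_original * event_rate_all / event_rate_topq
    elif method == "schoenfeld":
        if hr is None or hr <= 0 or hr == 1.0:
            raise ValueError("schoenfeld method needs a hazard ratio != 1")
        z = stats.norm.ppf(1.0 - alpha / 2.0) + stats.norm.ppf(power)
        d_needed = 4.0 * z * z / np.log(hr) ** 2
        n_required = d_needed / event_rate_topq
        n_original = d_needed / event_rate_all
    else:
        raise ValueError(f"unknown method {method!r}")
    pct_reduction = 100.0 * (1.0 - n_required / n_original)
    return float(n_required), float(pct_reduction)


def predictive_interaction(records: pd.DataFrame, pgs_col: str) -> float:
    """Wald p-value of the treatment × PGS product term in the Cox model."""
    df = records.copy()
    pgs = df[pgs_col].to_numpy(dtype=float)
    if np.ptp(pgs) == 0:
        raise ValueError("PGS is constant; the interaction model is degenerate")
    df["_interaction"] = df["treated"].to_numpy(dtype=float) * pgs
    res = fit_cox(df, covariates=["treated", pgs_col, "_interaction"], term="_interaction")
    return res.p


@dataclass
class EnrichmentResult:
    """Joint prognostic/predictive enrichment evaluation for one trial."""

    hr_trial: CoxResult
    hr_population: CoxResult
    event_rate_all: float
    event_rate_topq: float
    q: float
    n_original: int
    n_required: float
    pct_reduction: float
    interaction_p: float

    def to_dict(self) -> dict:
        return {
            "hr_trial": self.hr_trial.hr,
            "hr_trial_ci": [self.hr_trial.ci_low, self.hr_trial.ci_high],
            "hr_population": self.hr_population.hr,
            "hr_population_ci": [self.hr_population.ci_low, self.hr_population.ci_high],
            "event_rate_all": self.event_rate_all,
            "event_rate_topq": self.event_rate_topq,
            "q": self.q,
            "n_original": self.n_original,
            "n_required": self.n_required,
            "pct_reduction": self.pct_reduction,
            "interaction_p": self.interaction_p,
        }


def evaluate_enrichment(
    full_cohort: Cohort,
    matched_records: pd.DataFrame,
    pgs_col: str,
    q: float = 0.25,
    method: str = "equal_events",
) -> EnrichmentResult:
    """End-to-end enrichment evaluation for one outcome PGS.

    ``matched_records`` must carry the PGS column (pass ``pgs_columns`` to
    :func:`trialgen.emulation.build_followup`). The top-``q`` cut uses the
    full-population PGS distribution.
    """
    if not 0.0 < q < 1.0:
        raise ValueError("q must be in (0, 1)")
    hr_trial = prognostic_association(matched_records, pgs_col)
    hr_population = population_association(full_cohort, pgs_col)
    threshold = float(np.quantile(full_cohort.individuals[pgs_col], 1.0 - q))
    rate_all, rate_top = event_rates(
        matched_records, matched_records[pgs_col].to_numpy(), threshold
    )
    n_required, pct = enrichment_sample_size(
        rate_all, rate_top, len(matched_records), method=method,
        hr=hr_trial.hr if method == "schoenfeld" else None,
    )
    interaction_p = predictive_interaction(matched_records, pgs_col)
    return EnrichmentResult(
        hr_trial=hr_trial,
        hr_population=hr_population,
        event_rate_all=rate_all,
        event_rate_topq=rate_top,
        q=q,
        n_original=len(matched_records),
        n_required=n_required,
        pct_reduction=pct,
        interaction_p=interaction_p,
    )
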