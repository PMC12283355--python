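"""Polygenic-score balance diagnostics across trial-emulation stages.

The central diagnostic: if the emulation design progressively removes
confounding (plain observational comparison → eligibility plus an active
comparator → propensity-score matching), the standardized mean difference
(SMD) of each PGS between the trial arms should shrink stage by stage,
because the PGS proxy genetically determined patient characteristics that
drive prescription choice.

SMD is the between-arm mean difference divided by the pooled standard
deviation; |SMD| < 0.1 is the conventional balance threshold. Significance
of the mean difference is assessed with a two-sided Welch t-test against a
Bonferroni-corrected threshold (alpha divided by the number of scores
tested).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SMDResult",
    "BalanceReport",
    "compute_smd",
    "bonferroni_threshold",
    "balance_trajectory",
]

STAGES = ("plain", "eligible", "matched")


@dataclass(frozen=True)
class SMDResult:
    smd: float
    ci_low: float
    ci_high: float
    p_value: float


def compute_smd(values_arm1: np.ndarray, values_arm0: np.ndarray) -> SMDResult:
    """SMD with large-sample 95% CI and a Welch t-test p-value.

    smd = (mean₁ − mean₀) / pooled sd, with the standard large-sample SMD
    variance var(d) = (n₁+n₀)/(n₁·n₀) + d²/(2·(n₁+n₀)).
    """
    a1 = np.asarray(values_arm1, dtype=float)
    a0 = np.asarray(values_arm0, dtype=float)
    n1, n0 = a1.size, a0.size
    if n1 < 2 or n0 < 2:
        raise ValueError("each arm needs at least 2 observations")
    v1, v0 = a1.var(ddof=1), a0.var(ddof=1)
    pooled = np.sqrt(((n1 - 1) * v1 + (n0 - 1) * v0) / (n1 + n0 - 2))
    if pooled == 0.0:
        raise ValueError("zero pooled variance: SMD undefined")
    d = (a1.mean() - a0.mean()) / pooled
    var_d = (n1 + n0) / (n1 * n0) + d * d / (2.0 * (n1 + n0))
    half = 1.96 * np.sqrt(var_d)
    if v1 == 0.0 and v0 == 0.0:
        p = 1.0  # unreachable given pooled > 0; defensive
    else:
        p = float(stats.ttest_ind(a1, a0, equal_var=False).pvalue)
    return SMDResult(smd=float(d), ci_low=float(d - half), ci_high=float(d + half), p_value=p)


def bonferroni_threshold(n_tests: int, alpha: float = 0.05) -> float:
    """Family-wise significance threshold alpha / n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be at least 1")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    return alpha / n_tests


@dataclass
class BalanceReport:
    """Per-(trait, stage) SMD records plus stage-level summaries."""

    records: pd.DataFrame  # trait, stage, smd, ci_low, ci_high, p, significant
    threshold: float

    def mean_abs_smd(self) -> pd.Series:
        """Mean |SMD| per stage, in stage order."""
        out = self.records.assign(abs_smd=self.records["smd"].abs())
        means = out.groupby("stage", sort=False)["abs_smd"].mean()
        order = [s for s in STAGES if s in means.index]
        return means.reindex(order + [s for s in means.index if s not in order])

    @property
    def monotone_decreasing(self) -> bool:
        """True when mean |SMD| strictly decreases across present stages."""
        m = self.mean_abs_smd().to_numpy()
        return bool(np.all(np.diff(m) < 0)) if m.size > 1 else True

    def to_tsv(self, path) -> None:
        self.records.to_csv(path, sep="\t", index=False)


def _arm_values(frame: pd.DataFrame, column: str) -> tuple[np.ndarray, np.ndarray]:
    treated = frame.loc[frame["_treated"] == 1, column].to_numpy()
    control = frame.loc[frame["_treated"] == 0, column].to_numpy()
    return treated, control


def balance_trajectory(
    staged: dict[str, pd.DataFrame],
    pgs_names: list[str],
    alpha: float = 0.05,
) -> BalanceReport:
    """SMD of every PGS at every emulation stage.

    ``staged`` maps stage name → individuals table containing a ``_treated``
    0/1 column and one ``pgs_<name>`` column per score (as produced by
    :func:`trialgen.emulation.stage_cohorts`). Stages are processed in
    canonical order (plain, eligible, matched) when present; any other keys
    follow in input order.
    """
    if not staged:
        raise ValueError("no stages supplied")
    if not pgs_names:
        raise ValueError("pgs_names is empty")
    threshold = bonferroni_threshold(len(pgs_names), alpha)
    order = [s for s in STAGES if s in staged] + [s for s in staged if s not in STAGES]
    rows = []
    for stage in order:
        frame = staged[stage]
        if "_treated" not in frame.columns:
            raise ValueError(f"stage {stage!r} lacks the _treated indicator")
        for trait in pgs_names:
            col = f"pgs_{trait}" if f"pgs_{trait}" in frame.columns else trait
            if col not in frame.columns:
                raise KeyError(f"stage {stage!r} lacks PGS column for {trait!r}")
            res = compute_smd(*_arm_values(frame, col))
            rows.append(
                {
                    "trait": trait,
                    "stage": stage,
                    "smd": res.smd,
                    "ci_low": res.ci_low,
                    "ci_high": res.ci_high,
                    "p": res.p_value,
                    "significant": res.p_value < threshold,
                }
            )
    return BalanceReport(records=pd.DataFrame(rows), threshold=threshold)
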