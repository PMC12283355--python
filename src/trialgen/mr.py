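"""Two-sample Mendelian randomization as a confounder detector.

A trait confounds a drug-versus-outcome comparison when it causally affects
both the decision to prescribe the drug and the trial outcome. Genetic
variants associated with the trait can serve as instrumental variables for
both questions: MR of the trait on treatment initiation (step 1), MR of the
trait on the outcome (step 2), and the conjunction of the two significance
calls flags the trait as a putative confounder (step 3).

Instrument selection follows the standard summary-statistics workflow:
keep genome-wide-significant exposure variants (p < 5×10⁻⁸), greedily clump
by LD (r² < 0.001 within a 10,000-kb window, keeping the smallest exposure
p-value), and drop variants independently associated with the outcome.
Estimation uses the fixed-effect inverse-variance-weighted (IVW) estimator;
a multiplicative random-effects variant is available via a flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BlockLD",
    "InstrumentSet",
    "MRResult",
    "ConfounderVerdict",
    "harmonize",
    "select_instruments",
    "ivw_estimate",
    "classify_confounder",
    "direct_effect_adjustment",
]


class BlockLD:
    """LD lookup for block-structured panels.

    ``blocks`` maps variant_id → block label; two variants have
    r² = ``within_block_r2`` when they share a block (on the same chromosome)
    and 0 otherwise. Matches the block-exchangeable structure of the
    synthetic genotype generator.
    """

    def __init__(self, blocks: dict[str, int] | pd.Series, within_block_r2: float):
        self.blocks = dict(blocks)
        self.within_block_r2 = float(within_block_r2)

    def r2(self, variant_a: str, variant_b: str) -> float:
        if variant_a == variant_b:
            return 1.0
        ba = self.blocks.get(variant_a)
        bb = self.blocks.get(variant_b)
        if ba is None or bb is None or ba != bb:
            return 0.0
        return self.within_block_r2


@dataclass
class InstrumentSet:
    """Harmonized instruments with per-variant provenance flags.

    ``table`` columns: variant_id, chromosome, position_bp, beta_exposure,
    se_exposure, p_exposure, beta_outcome, se_outcome, p_outcome, plus
    boolean flags passed_p_threshold, survived_clumping,
    not_outcome_associated, retained.
    """

    table: pd.DataFrame

    @property
    def retained(self) -> pd.DataFrame:
        return self.table[self.table["retained"]]

    @property
    def n_instruments(self) -> int:
        return int(self.table["retained"].sum())


def harmonize(exposure: pd.DataFrame, outcome: pd.DataFrame) -> pd.DataFrame:
    """Join two summary-statistic tables on variant id with allele alignment.

    When the outcome sample's effect allele equals the exposure sample's
    other allele (and vice versa), the outcome beta sign is flipped. Variants
    whose allele pairs cannot be reconciled are dropped, with ids recorded in
    the result's ``attrs['unharmonizable']``.
    """
    merged = exposure.merge(
        outcome, on="variant_id", suffixes=("_exposure", "_outcome"), how="inner"
    )
    same = (
        (merged["effect_allele_exposure"] == merged["effect_allele_outcome"])
        & (merged["other_allele_exposure"] == merged["other_allele_outcome"])
    )
    flipped = (
        (merged["effect_allele_exposure"] == merged["other_allele_outcome"])
        & (merged["other_allele_exposure"] == merged["effect_allele_outcome"])
    )
    bad = ~(same | flipped)
    dropped = merged.loc[bad, "variant_id"].tolist()
    merged = merged[~bad].copy()
    merged.loc[flipped[~bad], "beta_outcome"] = -merged.loc[flipped[~bad], "beta_outcome"]
    out = pd.DataFrame(
        {
            "variant_id": merged["variant_id"],
            "chromosome": merged["chromosome_exposure"],
            "position_bp": merged["position_bp_exposure"],
            "beta_exposure": merged["beta_exposure"],
            "se_exposure": merged["se_exposure"],
            "p_exposure": merged["p_exposure"],
            "beta_outcome": merged["beta_outcome"],
            "se_outcome": merged["se_outcome"],
            "p_outcome": merged["p_outcome"],
        }
    ).reset_index(drop=True)
    out.attrs["unharmonizable"] = dropped
    return out


def _greedy_clump(
    candidates: pd.DataFrame, ld: BlockLD | None, clump_r2: float, window_kb: float
) -> set[str]:
    """Ids surviving greedy clumping by ascending exposure p-value.

    Iteratively keep the most significant remaining variant and drop every
    variant within ``window_kb`` (center-to-center, same chromosome) whose LD
    r² with it is ≥ ``clump_r2``. Deterministic: p-value ties break by
    (chromosome, position, variant_id).
    """
    ordered = candidates.sort_values(
        ["p_exposure", "chromosome", "position_bp", "variant_id"]
    ).reset_index(drop=True)
    kept: list[tuple[str, int, int]] = []
    for row in ordered.itertuples(index=False):
        clumped = False
        for kid, kchrom, kpos in kept:
            if kchrom != row.chromosome:
                continue
            if abs(int(row.position_bp) - kpos) > window_kb * 1_000:
                continue
            r2 = 1.0 if ld is None and kid == row.variant_id else (
                ld.r2(kid, row.variant_id) if ld is not None else 0.0
            )
            if r2 >= clump_r2:
                clumped = True
                break
        if not clumped:
            kept.append((row.variant_id, int(row.chromosome), int(row.position_bp)))
    return {k[0] for k in kept}


def select_instruments(
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    ld: BlockLD | None = None,
    p_thresh: float = 5e-8,
    clump_r2: float = 0.001,
    window_kb: float = 10_000,
    outcome_p_thresh: float = 5e-8,
) -> InstrumentSet:
    """Threshold → clump → exclude outcome-associated variants, in that order."""
    joint = harmonize(exposure, outcome)
    joint["passed_p_threshold"] = joint["p_exposure"] < p_thresh
    candidates = joint[joint["passed_p_threshold"]]
    surviving = _greedy_clump(candidates, ld, clump_r2, window_kb) if len(candidates) else set()
    joint["survived_clumping"] = joint["variant_id"].isin(surviving)
    joint["not_outcome_associated"] = joint["p_outcome"] >= outcome_p_thresh
    joint["retained"] = (
        joint["passed_p_threshold"]
        & joint["survived_clumping"]
        & joint["not_outcome_associated"]
    )
    if not joint["retained"].any():
        raise ValueError("no valid instruments survive selection")
    return InstrumentSet(table=joint)


@dataclass(frozen=True)
class MRResult:
    """IVW causal-effect estimate on the log-odds / per-sd scale."""

    beta: float
    se: float
    p: float
    n_instruments: int
    method: str = "ivw_fixed"
    exposure_scale: str = "per_sd"

    @property
    def or_estimate(self) -> float:
        return float(np.exp(self.beta))

    @property
    def ci(self) -> tuple[float, float]:
        return (
            float(np.exp(self.beta - 1.96 * self.se)),
            float(np.exp(self.beta + 1.96 * self.se)),
        )


def ivw_estimate(
    iv: InstrumentSet | pd.DataFrame,
    random_effects: bool = False,
    exposure_scale: str = "per_sd",
) -> MRResult:
    """Inverse-variance-weighted estimate over the retained instruments.

    beta = Σ_j (β_Xj·β_Yj / se²_Yj) / Σ_j (β²_Xj / se²_Yj), fixed-effect
    se = 1/√(Σ_j β²_Xj / se²_Yj). With ``random_effects`` the se is inflated
    by the multiplicative overdispersion factor max(1, √(Q/(J−1))). A single
    instrument degenerates to the Wald ratio with first-order delta-method
    se, flagged in ``method``.
    """
    table = iv.retained if isinstance(iv, InstrumentSet) else iv
    bx = table["beta_exposure"].to_numpy(dtype=float)
    by = table["beta_outcome"].to_numpy(dtype=float)
    sy = table["se_outcome"].to_numpy(dtype=float)
    if bx.size == 0:
        raise ValueError("empty instrument set")
    if np.any(sy <= 0):
        raise ValueError("outcome standard errors must be positive")
    if bx.size == 1:
        beta = float(by[0] / bx[0])
        se = float(abs(sy[0] / bx[0]))
        method = "wald_ratio"
    else:
        w = bx * bx / (sy * sy)
        beta = float(np.sum(bx * by / (sy * sy)) / np.sum(w))
        se = float(1.0 / np.sqrt(np.sum(w)))
        method = "ivw_fixed"
        if random_effects:
            q = float(np.sum(((by - beta * bx) / sy) ** 2))
            phi = max(1.0, np.sqrt(q / (bx.size - 1)))
            se *= phi
            method = "ivw_mre"
    p = float(2.0 * stats.norm.sf(abs(beta / se)))
    return MRResult(beta=beta, se=se, p=p, n_instruments=int(bx.size),
                    method=method, exposure_scale=exposure_scale)


@dataclass(frozen=True)
class ConfounderVerdict:
    """Three-step conjunction verdict for one candidate trait."""

    trait: str
    significant_on_treatment: bool
    significant_on_outcome: bool
    verdict: str  # putative_confounder | exposure_only | outcome_only | neither
    alpha: float


def classify_confounder(
    mr_treatment: MRResult,
    mr_outcome: MRResult,
    trait: str = "",
    alpha: float = 0.05,
) -> ConfounderVerdict:
    """Conjunction rule: a trait significant (strictly, p < alpha) in the MR
    on treatment *and* the MR on outcome is a putative confounder."""
    if mr_treatment is None or mr_outcome is None:
        raise ValueError("both MR results are required")
    sig_t = mr_treatment.p < alpha
    sig_o = mr_outcome.p < alpha
    verdict = {
        (True, True): "putative_confounder",
        (True, False): "exposure_only",
        (False, True): "outcome_only",
        (False, False): "neither",
    }[(sig_t, sig_o)]
    return ConfounderVerdict(
        trait=trait,
        significant_on_treatment=bool(sig_t),
        significant_on_outcome=bool(sig_o),
        verdict=verdict,
        alpha=alpha,
    )


def direct_effect_adjustment(
    total_cx: MRResult,
    effect_cy: MRResult,
    effect_yx: float,
    se_yx: float,
    alpha: float = 0.05,
) -> MRResult:
    """Direct confounder→treatment effect after removing the outcome-mediated
    path: direct = total_CX − β_CY·β_YX, with delta-method se assuming the
    three estimates are independent.

    A confounder whose effect on treatment runs entirely through the outcome
    (C→Y→X: the physician prescribes because of the patient's outcome risk)
    is not a confounder; only the direct remainder counts.
    """
    if effect_cy is None:
        raise ValueError("mediator-path estimate (C→Y) is required")
    direct = total_cx.beta - effect_cy.beta * effect_yx
    var = (
        total_cx.se**2
        + (effect_yx * effect_cy.se) ** 2
        + (effect_cy.beta * se_yx) ** 2
    )
    se = float(np.sqrt(var))
    p = float(2.0 * stats.norm.sf(abs(direct / se))) if se > 0 else 0.0
    return MRResult(
        beta=float(direct), se=se, p=p,
        n_instruments=total_cx.n_instruments,
        method="direct_effect", exposure_scale=total_cx.exposure_scale,
    )
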