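"""Synthetic biobank cohorts and GWAS summary statistics with known ground truth.

Real registry-linked biobank data of the kind used for drug-target trial
emulation are access-restricted, so every downstream stage of this package is
exercised on synthetic cohorts whose generative process is fully known: the
true treatment hazard ratio, the confounding structure (which latent traits
drive prescription and the outcome), and the fraction of each confounder's
variance captured by its polygenic score (PGS) are all configuration inputs.

The cohort generator emulates the essential structure of a national-registry
biobank: per-individual standardized PGS for a panel of cardiometabolic
traits, latent trait values correlated with those PGS at a controllable r²,
binary diagnosis flags with onset dates, drug initiation driven by the latent
traits (confounding by indication), package-level purchase records, and
proportional-hazards event times.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from ._rng import child_rng

__all__ = [
    "DEFAULT_TRAITS",
    "DEFAULT_R2_CYCLE",
    "GenotypeBlockSpec",
    "CohortConfig",
    "Cohort",
    "generate_genotypes",
    "score_pgs",
    "standardize",
    "generate_cohort",
    "generate_summary_stats",
    "validate_summary_stats",
]

#: Cardiometabolic trait panel mirroring the kind of PGS panel used to audit
#: covariate balance in emulated cardiometabolic trials (20 traits).
DEFAULT_TRAITS = (
    "t2d", "hba1c", "bmi", "chd", "stroke",
    "ldl", "hdl", "triglycerides", "sbp", "dbp",
    "crp", "egfr", "alt", "ast", "smoking",
    "education", "af", "heart_failure", "ckd", "insomnia",
)

#: Default PGS→trait r² values cycled across traits; spans the realistic
#: range for polygenic predictors of complex traits (r² between 0.01 and 0.5).
DEFAULT_R2_CYCLE = (0.01, 0.05, 0.1, 0.2, 0.3, 0.5)

DAYS_PER_YEAR = 365.25


# ---------------------------------------------------------------------------
# genotypes and PGS scoring
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenotypeBlockSpec:
    """Block-exchangeable LD structure for synthetic dosages.

    Variants are grouped into consecutive blocks of ``block_size``; dosage
    correlation is ``within_block_r`` inside a block and zero across blocks.
    Minor-allele frequencies are drawn per block from ``maf_range``.
    """

    n_variants: int
    block_size: int = 1
    within_block_r: float = 0.0
    maf_range: tuple[float, float] = (0.05, 0.5)

    def __post_init__(self) -> None:
        if self.n_variants < 1 or self.block_size < 1:
            raise ValueError("n_variants and block_size must be positive")
        if not 0.0 <= self.within_block_r < 1.0:
            raise ValueError("within_block_r must be in [0, 1)")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < low <= high <= 0.5")

    def block_of(self, j: int) -> int:
        return j // self.block_size


def _latent_rho_for_binary_r(target_r: float, maf: float) -> float:
    """Latent Gaussian correlation giving allele-indicator correlation target_r.

    Alleles are thresholded Gaussians (allele = 1 iff latent < Φ⁻¹(maf)); the
    indicator correlation is the tetrachoric transform of the latent one, so
    the latent correlation is found by root-finding.
    """
    if target_r == 0.0:
        return 0.0
    z = stats.norm.ppf(maf)

    def gap(rho: float) -> float:
        joint = stats.multivariate_normal.cdf(
            [z, z], mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]]
        )
        return (joint - maf**2) / (maf * (1.0 - maf)) - target_r

    return optimize.brentq(gap, 0.0, 0.999999, xtol=1e-10)


def generate_genotypes(
    n_individuals: int, spec: GenotypeBlockSpec, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate biallelic dosages (0/1/2) with block LD.

    Returns ``(dosages, variants)`` where ``dosages`` is an
    individuals × variants DataFrame with variant-id columns and ``variants``
    records id, chromosome, position, alleles, maf and block index.
    Column means are ≈ 2·maf; pairwise dosage correlation is ≈
    ``within_block_r`` within a block and ≈ 0 across blocks.
    """
    if n_individuals < 1:
        raise ValueError("n_individuals must be positive")
    rng = child_rng(seed, "genotypes")
    m = spec.n_variants
    n_blocks = -(-m // spec.block_size)
    block_maf = rng.uniform(*spec.maf_range, size=n_blocks)

    dosage = np.empty((n_individuals, m), dtype=np.int8)
    for b in range(n_blocks):
        j0, j1 = b * spec.block_size, min((b + 1) * spec.block_size, m)
        width = j1 - j0
        maf = block_maf[b]
        rho = _latent_rho_for_binary_r(spec.within_block_r, maf) if width > 1 else 0.0
        z_thr = stats.norm.ppf(maf)
        alleles = np.zeros((n_individuals, width), dtype=np.int8)
        for _hap in range(2):
            shared = rng.standard_normal((n_individuals, 1))
            noise = rng.standard_normal((n_individuals, width))
            latent = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * noise
            alleles += (latent < z_thr).astype(np.int8)
        dosage[:, j0:j1] = alleles

    variant_ids = [f"rs{j + 1}" for j in range(m)]
    variants = pd.DataFrame(
        {
            "variant_id": variant_ids,
            "chromosome": 1 + (np.arange(m) * 22) // m,
            "position_bp": 1 + np.arange(m) * 50_000,
            "effect_allele": "A",
            "other_allele": "G",
            "maf": np.repeat(block_maf, spec.block_size)[:m],
            "block": np.arange(m) // spec.block_size,
        }
    )
    dosages = pd.DataFrame(dosage, columns=variant_ids)
    return dosages, variants


def standardize(x: np.ndarray | pd.Series) -> np.ndarray:
    """Center to mean 0 and scale to sd 1 (population sd, ddof=0)."""
    arr = np.asarray(x, dtype=float)
    sd = arr.std(ddof=0)
    if sd == 0.0 or not np.isfinite(sd):
        raise ValueError("cannot standardize a zero-variance vector")
    return (arr - arr.mean()) / sd


def score_pgs(
    dosages: pd.DataFrame,
    weights: pd.DataFrame,
    variants: pd.DataFrame | None = None,
) -> np.ndarray:
    """Compute a standardized PGS from per-variant weights.

    ``weights`` needs columns ``variant_id``, ``effect_allele``, ``weight``.
    The raw score is Σ_j weight_j × dosage_j after allele reconciliation:
    when a weight's effect allele is the dosage-counted variant's *other*
    allele, the weight sign is flipped (the constant offset 2·w is absorbed
    by standardization). Scores are standardized over all scored individuals.
    """
    missing = [v for v in weights["variant_id"] if v not in dosages.columns]
    if missing:
        raise KeyError(f"weight variants absent from dosages: {missing}")

    w = weights.set_index("variant_id")["weight"].astype(float).copy()
    if variants is not None and "effect_allele" in weights.columns:
        meta = variants.set_index("variant_id")
        for vid, eff in weights.set_index("variant_id")["effect_allele"].items():
            if vid not in meta.index:
                continue
            if eff == meta.at[vid, "other_allele"]:
                w.at[vid] = -w.at[vid]
            elif eff != meta.at[vid, "effect_allele"]:
                raise ValueError(f"allele mismatch for {vid}: {eff!r} matches neither allele")

    raw = dosages[list(w.index)].to_numpy(dtype=float) @ w.to_numpy()
    return standardize(raw)


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

@dataclass
class CohortConfig:
    """Parameters of the synthetic biobank cohort generator.

    The generative model is deliberately minimal while still producing
    confounding by indication with a known true treatment effect:

    * ``PGS_k`` standard normal, standardized exactly in the full cohort;
    * latent trait ``C_k = √(r²_k)·PGS_k + √(1−r²_k)·ε`` so that
      cor(PGS_k, C_k)² = r²_k;
    * drug initiation and target-vs-comparator choice follow logistic models
      in the latent traits (``initiation_log_odds``, ``prescription_log_odds``);
    * event times are exponential with hazard
      ``baseline_hazard × exp(Σ confounder_log_hr_k·C_k)`` from day 0,
      multiplied by ``exp(true_treatment_log_hr)`` from initiation onward for
      target-drug initiators;
    * purchases of one package occur every ``package_days`` until random
      discontinuation (per-refill probability), the event, death or the end
      of registry coverage.

    Dates are integer days from an epoch; ``registry_end`` is a hard
    administrative censoring date.
    """

    n_individuals: int = 10_000
    trait_names: tuple[str, ...] = DEFAULT_TRAITS
    pgs_confounder_r2: dict[str, float] | None = None
    initiation_log_odds: dict[str, float] = field(default_factory=dict)
    prescription_log_odds: dict[str, float] = field(default_factory=dict)
    initiation_intercept: float = -1.5
    prescription_intercept: float = 0.0
    true_treatment_log_hr: float = 0.0
    baseline_hazard: float = 0.02  # events per person-year
    confounder_log_hr: dict[str, float] = field(default_factory=dict)
    death_hazard: float = 0.005  # per person-year, independent of traits
    registry_end: int = 3_650
    initiation_window: tuple[int, int] = (0, 1_825)
    package_days: float = 90.0
    discontinuation_prob: float = 0.08
    flag_quantile: float = 0.75
    seed: int = 0

    @property
    def n_traits(self) -> int:
        return len(self.trait_names)

    def r2_vector(self) -> np.ndarray:
        if self.pgs_confounder_r2 is None:
            cycle = DEFAULT_R2_CYCLE
            return np.array([cycle[i % len(cycle)] for i in range(self.n_traits)])
        return np.array([self.pgs_confounder_r2.get(t, 0.1) for t in self.trait_names])

    def validate(self) -> None:
        if self.n_individuals < 2:
            raise ValueError("n_individuals must be at least 2")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be positive")
        if self.package_days <= 0:
            raise ValueError("package_days must be positive")
        r2 = self.r2_vector()
        if np.any((r2 < 0) | (r2 > 1)):
            raise ValueError("pgs_confounder_r2 values must lie in [0, 1]")
        if not 0 <= self.initiation_window[0] <= self.initiation_window[1] <= self.registry_end:
            raise ValueError("initiation_window must lie within [0, registry_end]")
        if not 0.0 <= self.discontinuation_prob < 1.0:
            raise ValueError("discontinuation_prob must be in [0, 1)")


@dataclass
class Cohort:
    """A synthetic biobank cohort.

    ``individuals`` has one row per person: ``individual_id``, ``arm``
    (``target_drug`` / ``comparator`` / ``noninitiator``), ``initiation_day``,
    ``event_day`` / ``death_day`` (NaN when absent or beyond registry
    coverage), per-trait standardized PGS (``pgs_<trait>``), latent trait
    values (``conf_<trait>``), and binary diagnosis flags with onset days
    (``flag_<trait>``, ``flag_<trait>_day``). ``purchases`` has one row per
    package purchase: ``individual_id``, ``day``, ``n_packages``, ``drug``.
    """

    individuals: pd.DataFrame
    purchases: pd.DataFrame
    trait_names: tuple[str, ...]
    registry_end: int
    package_days: float = 90.0

    @property
    def pgs_columns(self) -> list[str]:
        return [f"pgs_{t}" for t in self.trait_names]

    def subset(self, ids: pd.Index | np.ndarray | list) -> "Cohort":
        mask = self.individuals["individual_id"].isin(ids)
        return Cohort(
            self.individuals.loc[mask].reset_index(drop=True),
            self.purchases[self.purchases["individual_id"].isin(ids)].reset_index(drop=True),
            self.trait_names,
            self.registry_end,
            self.package_days,
        )


def _logistic_prob(intercept: float, log_odds: dict[str, float],
                   conf: pd.DataFrame, traits: tuple[str, ...]) -> np.ndarray:
    lin = np.full(len(conf), float(intercept))
    for t, lo in log_odds.items():
        if t not in traits:
            raise KeyError(f"log-odds refers to unknown trait {t!r}")
        lin += lo * conf[f"conf_{t}"].to_numpy()
    return 1.0 / (1.0 + np.exp(-lin))


def generate_cohort(config: CohortConfig) -> Cohort:
    """Draw a full synthetic cohort under ``config`` (see class docstring)."""
    config.validate()
    n = config.n_individuals
    traits = config.trait_names
    r2 = config.r2_vector()

    rng_pgs = child_rng(config.seed, "cohort", "pgs")
    rng_conf = child_rng(config.seed, "cohort", "confounders")
    rng_arm = child_rng(config.seed, "cohort", "arms")
    rng_time = child_rng(config.seed, "cohort", "times")
    rng_flag = child_rng(config.seed, "cohort", "flags")
    rng_purch = child_rng(config.seed, "cohort", "purchases")

    data: dict[str, np.ndarray] = {"individual_id": np.arange(n)}
    for k, t in enumerate(traits):
        pgs = standardize(rng_pgs.standard_normal(n))
        noise = rng_conf.standard_normal(n)
        data[f"pgs_{t}"] = pgs
        data[f"conf_{t}"] = np.sqrt(r2[k]) * pgs + np.sqrt(1.0 - r2[k]) * noise
    ind = pd.DataFrame(data)

    # treatment assignment: initiation, then drug choice (indication-driven)
    p_init = _logistic_prob(config.initiation_intercept, config.initiation_log_odds, ind, traits)
    initiator = rng_arm.random(n) < p_init
    p_target = _logistic_prob(config.prescription_intercept, config.prescription_log_odds, ind, traits)
    target = initiator & (rng_arm.random(n) < p_target)
    arm = np.where(~initiator, "noninitiator", np.where(target, "target_drug", "comparator"))
    ind["arm"] = arm

    lo, hi = config.initiation_window
    init_day = rng_arm.integers(lo, hi + 1, size=n).astype(float)
    init_day[~initiator] = np.nan
    ind["initiation_day"] = init_day

    # proportional-hazards event times (piecewise-constant hazard around
    # initiation for target-drug users; memorylessness keeps this exact)
    log_h = np.full(n, np.log(config.baseline_hazard / DAYS_PER_YEAR))
    for t, b in config.confounder_log_hr.items():
        if t not in traits:
            raise KeyError(f"confounder_log_hr refers to unknown trait {t!r}")
        log_h = log_h + b * ind[f"conf_{t}"].to_numpy()
    haz0 = np.exp(log_h)
    t_pre = rng_time.exponential(1.0, size=n) / haz0
    event_t = t_pre.copy()
    on_drug = target & (t_pre > init_day)
    if np.any(on_drug):
        haz1 = haz0[on_drug] * np.exp(config.true_treatment_log_hr)
        event_t[on_drug] = init_day[on_drug] + rng_time.exponential(1.0, size=on_drug.sum()) / haz1
    death_t = rng_time.exponential(1.0, size=n) / (config.death_hazard / DAYS_PER_YEAR)

    end = float(config.registry_end)
    event_day = np.where((event_t <= np.minimum(death_t, end)), event_t, np.nan)
    death_day = np.where((death_t < event_t) & (death_t <= end), death_t, np.nan)
    ind["event_day"] = event_day
    ind["death_day"] = death_day
    ind["censor_day"] = end

    # diagnosis flags: trait above its cohort quantile. For initiators the
    # onset precedes initiation (the indication is on record when the
    # prescribing decision is made — the confounding-by-indication premise);
    # for noninitiators onset is uniform over the registry period.
    onset_cap = np.where(initiator, np.maximum(init_day, 1.0), float(config.registry_end))
    for t in traits:
        c = ind[f"conf_{t}"].to_numpy()
        flagged = c > np.quantile(c, config.flag_quantile)
        onset = np.floor(rng_flag.random(n) * onset_cap)
        onset[~flagged] = np.nan
        ind[f"flag_{t}"] = flagged.astype(int)
        ind[f"flag_{t}_day"] = onset

    # purchase records: one package every package_days until stop
    rows: list[tuple[int, float, int, str]] = []
    init_ids = np.flatnonzero(initiator)
    stop_day = np.nanmin(
        np.column_stack([np.where(np.isnan(event_day), np.inf, event_day),
                         np.where(np.isnan(death_day), np.inf, death_day),
                         np.full(n, end)]),
        axis=1,
    )
    for i in init_ids:
        drug = "target_drug" if target[i] else "comparator"
        day = init_day[i]
        while True:
            rows.append((int(i), float(day), 1, drug))
            day += config.package_days
            if day > stop_day[i] or rng_purch.random() < config.discontinuation_prob:
                break
    purchases = pd.DataFrame(rows, columns=["individual_id", "day", "n_packages", "drug"])

    return Cohort(ind, purchases, traits, config.registry_end, config.package_days)


# ---------------------------------------------------------------------------
# GWAS summary statistics
# ---------------------------------------------------------------------------

SUMMARY_STAT_COLUMNS = [
    "variant_id", "chromosome", "position_bp", "effect_allele", "other_allele",
    "eaf", "beta", "se", "p", "n_sample",
]


def validate_summary_stats(df: pd.DataFrame) -> None:
    missing = [c for c in SUMMARY_STAT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"summary statistics missing columns: {missing}")
    if (df["se"] <= 0).any():
        raise ValueError("all standard errors must be positive")
    p_check = 2.0 * stats.norm.sf(np.abs(df["beta"] / df["se"]))
    if not np.allclose(df["p"], p_check, rtol=1e-6, atol=1e-300):
        raise ValueError("p column inconsistent with beta/se under normal approximation")


def generate_summary_stats(
    true_exposure_effects: np.ndarray,
    theta: float,
    pleiotropy_sd: float,
    n_exposure: int,
    n_outcome: int,
    seed: int,
    variants: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-sample GWAS summary statistics with a known causal effect θ.

    Per variant j the outcome-sample effect is
    ``β_Yj = θ·β_Xj + α_j + noise`` with pleiotropic intercepts
    ``α_j ~ N(0, pleiotropy_sd²)``. Standard errors follow the usual
    1/√(2·n·eaf·(1−eaf)) scaling for standardized phenotypes, estimation
    noise is added at those standard errors, and p-values come from the
    normal approximation.
    """
    if pleiotropy_sd < 0:
        raise ValueError("pleiotropy_sd must be nonnegative")
    if n_exposure < 2 or n_outcome < 2:
        raise ValueError("sample sizes must be at least 2")
    beta_true = np.asarray(true_exposure_effects, dtype=float)
    m = beta_true.size
    rng = child_rng(seed, "sumstats")

    if variants is None:
        variants = pd.DataFrame(
            {
                "variant_id": [f"rs{j + 1}" for j in range(m)],
                "chromosome": 1 + (np.arange(m) * 22) // m,
                "position_bp": 1 + np.arange(m) * 1_000_000,
                "effect_allele": "A",
                "other_allele": "G",
                "maf": rng.uniform(0.05, 0.5, size=m),
            }
        )
    eaf = variants["maf"].to_numpy()

    def one_sample(true_beta: np.ndarray, n: int) -> pd.DataFrame:
        se = 1.0 / np.sqrt(2.0 * n * eaf * (1.0 - eaf))
        beta_hat = true_beta + rng.standard_normal(m) * se
        p = 2.0 * stats.norm.sf(np.abs(beta_hat / se))
        return pd.DataFrame(
            {
                "variant_id": variants["variant_id"].to_numpy(),
                "chromosome": variants["chromosome"].to_numpy(),
                "position_bp": variants["position_bp"].to_numpy(),
                "effect_allele": variants["effect_allele"].to_numpy(),
                "other_allele": variants["other_allele"].to_numpy(),
                "eaf": eaf,
                "beta": beta_hat,
                "se": se,
                "p": np.clip(p, 1e-300, 1.0),
                "n_sample": n,
            }
        )

    alpha = rng.standard_normal(m) * pleiotropy_sd
    exposure = one_sample(beta_true, n_exposure)
    outcome = one_sample(theta * beta_true + alpha, n_outcome)
    return exposure, outcome
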