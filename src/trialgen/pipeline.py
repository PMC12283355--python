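"""End-to-end orchestration: cohort → emulation → balance → proxy-sim → MR → enrichment.

A single YAML configuration drives the whole run; stages communicate only
through files written under the output directory, and a JSON manifest
records every artifact with a checksum so identical configurations and
seeds produce identical runs.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .balance import balance_trajectory
from .emulation import TrialProtocol, build_followup, estimate_agreement, fit_cox, stage_cohorts
from .enrichment import evaluate_enrichment
from .io import write_cohort, write_summary_stats
from .mr import classify_confounder, ivw_estimate, select_instruments
from .proxysim import default_grid_model1, grid_to_frame, run_grid
from .synthetic import CohortConfig, generate_cohort, generate_summary_stats
from ._rng import child_rng

__all__ = ["RunConfig", "run_pipeline"]


class ConfigError(ValueError):
    """Invalid run configuration (exit code 2 in the CLI)."""


@dataclass
class RunConfig:
    """Validated pipeline configuration; see ``RunConfig.from_yaml``."""

    seed: int = 0
    cohort: CohortConfig = field(default_factory=CohortConfig)
    protocol: TrialProtocol = field(default_factory=TrialProtocol)
    balance: dict = field(default_factory=lambda: {"alpha": 0.05})
    proxy_sim: dict | None = None
    mr: dict | None = None
    enrichment: dict | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        try:
            seed = int(raw.get("seed", 0))
            cohort_raw = dict(raw.get("cohort", {}))
            if "trait_names" in cohort_raw:
                cohort_raw["trait_names"] = tuple(cohort_raw["trait_names"])
            if "initiation_window" in cohort_raw:
                cohort_raw["initiation_window"] = tuple(cohort_raw["initiation_window"])
            cohort_raw.setdefault("seed", seed)
            cohort = CohortConfig(**cohort_raw)
            cohort.validate()
            protocol = TrialProtocol.from_dict(raw.get("protocol", {}))
            protocol.validate()
        except (TypeError, ValueError, KeyError) as exc:
            raise ConfigError(str(exc)) from exc
        return cls(
            seed=seed,
            cohort=cohort,
            protocol=protocol,
            balance=dict(raw.get("balance", {"alpha": 0.05})),
            proxy_sim=raw.get("proxy_sim"),
            mr=raw.get("mr"),
            enrichment=raw.get("enrichment"),
        )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(
    config: RunConfig, out_dir: str | Path, overwrite: bool = False
) -> dict:
    """Execute every configured stage in dependency order.

    Returns (and writes as ``manifest.json``) a manifest listing per-stage
    artifacts with SHA-256 checksums, record counts and wall times. Stages
    whose configuration block is omitted are skipped and noted. Refuses to
    write into a directory that already holds a manifest unless
    ``overwrite`` is set.
    """
    out = Path(out_dir)
    manifest_path = out / "manifest.json"
    if manifest_path.exists() and not overwrite:
        raise ConfigError(f"{out} already contains a manifest; pass overwrite=True")
    out.mkdir(parents=True, exist_ok=True)

    manifest: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages": {},
        "artifacts": {},
    }

    def record_stage(name: str, t0: float, n_records: int, paths: list[Path],
                     extra: dict | None = None) -> None:
        manifest["stages"][name] = {
            "status": "completed",
            "n_records": int(n_records),
            "wall_seconds": round(time.time() - t0, 3),
            **(extra or {}),
        }
        for p in paths:
            manifest["artifacts"][str(p.relative_to(out))] = _sha256(p)

    # --- stage 1: synthetic cohort -------------------------------------
    t0 = time.time()
    cohort = generate_cohort(config.cohort)
    cohort_paths = write_cohort(cohort, out / "cohort")
    record_stage("simulate_cohort", t0, len(cohort.individuals), cohort_paths)

    # --- stage 2: emulation --------------------------------------------
    t0 = time.time()
    staged = stage_cohorts(cohort, config.protocol, seed=config.seed)
    attrition_path = out / "attrition.tsv"
    staged.attrition.to_csv(attrition_path, sep="\t", index=False)
    records = build_followup(staged.matched_cohort, pgs_columns=cohort.pgs_columns)
    cox = fit_cox(records)
    emulation_result = {
        "hr": cox.hr, "ci_low": cox.ci_low, "ci_high": cox.ci_high,
        "p": cox.p, "n": cox.n, "n_events": cox.n_events,
        "caliper": staged.caliper,
        "fraction_treated_discarded": staged.match_result.fraction_treated_discarded,
    }
    if config.protocol.rct_reference is not None:
        emulation_result["estimate_agreement"] = estimate_agreement(
            cox, config.protocol.rct_reference
        )
    emulation_path = out / "emulation.json"
    emulation_path.write_text(json.dumps(emulation_result, indent=2))
    record_stage("emulate", t0, len(records), [attrition_path, emulation_path])

    # --- stage 3: PGS balance trajectory --------------------------------
    t0 = time.time()
    report = balance_trajectory(
        staged.as_dict(), list(cohort.trait_names),
        alpha=float(config.balance.get("alpha", 0.05)),
    )
    balance_path = out / "balance.tsv"
    report.to_tsv(balance_path)
    record_stage(
        "balance", t0, len(report.records), [balance_path],
        extra={"mean_abs_smd": {k: float(v) for k, v in report.mean_abs_smd().items()},
               "monotone_decreasing": report.monotone_decreasing},
    )

    # --- stage 4: confounder-proxy simulation ---------------------------
    if config.proxy_sim is not None:
        t0 = time.time()
        ps = config.proxy_sim
        conditions = default_grid_model1(
            r2_values=tuple(ps.get("r2_values", (0.01, 0.05, 0.1, 0.2, 0.3, 0.5))),
            conf_fracs=tuple(ps.get("conf_fracs", (0.1, 0.2, 0.3, 0.5))),
            n=int(ps.get("n", 100_000)),
            iterations=int(ps.get("iterations", 100)),
            seed=config.seed,
        )
        grid_frame = grid_to_frame(run_grid(conditions))
        proxy_path = out / "proxy_bias.tsv"
        grid_frame.to_csv(proxy_path, sep="\t", index=False)
        record_stage("proxy_sim", t0, len(grid_frame), [proxy_path])
    else:
        manifest["stages"]["proxy_sim"] = {"status": "skipped"}

    # --- stage 5: MR confounder scan ------------------------------------
    if config.mr is not None:
        t0 = time.time()
        mr_cfg = config.mr
        m = int(mr_cfg.get("n_variants_per_trait", 50))
        n_gwas = int(mr_cfg.get("n_gwas", 200_000))
        effect_sd = float(mr_cfg.get("effect_sd", 0.02))
        pleio = float(mr_cfg.get("pleiotropy_sd", 0.0))
        alpha = float(mr_cfg.get("alpha", 0.05))
        rows = []
        for k, trait in enumerate(cohort.trait_names):
            rng = child_rng(config.seed, "mr_scan", trait)
            effects = rng.normal(0.0, effect_sd, size=m) + effect_sd
            theta_x = config.cohort.prescription_log_odds.get(trait, 0.0)
            theta_y = config.cohort.confounder_log_hr.get(trait, 0.0)
            expo_t, out_t = generate_summary_stats(
                effects, theta_x, pleio, n_gwas, n_gwas,
                seed=int(child_rng(config.seed, "mr", trait, "x").integers(2**31)),
            )
            expo_y, out_y = generate_summary_stats(
                effects, theta_y, pleio, n_gwas, n_gwas,
                seed=int(child_rng(config.seed, "mr", trait, "y").integers(2**31)),
            )
            try:
                iv_t = select_instruments(expo_t, out_t)
                iv_y = select_instruments(expo_y, out_y)
            except ValueError:
                rows.append({"trait": trait, "verdict": "no_instruments"})
                continue
            mr_t = ivw_estimate(iv_t)
            mr_y = ivw_estimate(iv_y)
            verdict = classify_confounder(mr_t, mr_y, trait=trait, alpha=alpha)
            rows.append(
                {
                    "trait": trait,
                    "beta_treatment": mr_t.beta, "p_treatment": mr_t.p,
                    "beta_outcome": mr_y.beta, "p_outcome": mr_y.p,
                    "n_instruments": mr_t.n_instruments,
                    "true_theta_treatment": theta_x, "true_theta_outcome": theta_y,
                    "verdict": verdict.verdict,
                }
            )
        mr_frame = pd.DataFrame(rows)
        mr_path = out / "mr_confounders.tsv"
        mr_frame.to_csv(mr_path, sep="\t", index=False)
        record_stage("mr_scan", t0, len(mr_frame), [mr_path])
    else:
        manifest["stages"]["mr_scan"] = {"status": "skipped"}

    # --- stage 6: enrichment ---------------------------------------------
    if config.enrichment is not None:
        t0 = time.time()
        enr_cfg = config.enrichment
        outcome_trait = enr_cfg.get("outcome_trait", cohort.trait_names[0])
        pgs_col = f"pgs_{outcome_trait}"
        result = evaluate_enrichment(
            cohort, records, pgs_col,
            q=float(enr_cfg.get("q", 0.25)),
            method=enr_cfg.get("method", "equal_events"),
        )
        enr_path = out / "enrichment.json"
        enr_path.write_text(json.dumps(result.to_dict(), indent=2))
        record_stage("enrich", t0, 1, [enr_path])
    else:
        manifest["stages"]["enrich"] = {"status": "skipped"}

    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
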