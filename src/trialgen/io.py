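"""Plain-text serialization for cohorts, weights and summary statistics.

Everything round-trips through tab-separated tables so pipeline stages
communicate only via files: cohorts as a TSV pair (individuals, purchases)
with a sidecar JSON schema, PGS weights as three-column TSV tolerating a
PGS-Catalog-style ``#`` header, and GWAS summary statistics as TSV with the
canonical column set (gzip-transparent via the file extension).
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .synthetic import SUMMARY_STAT_COLUMNS, Cohort, validate_summary_stats

__all__ = [
    "write_cohort",
    "read_cohort",
    "read_weights",
    "write_summary_stats",
    "read_summary_stats",
]


def write_cohort(cohort: Cohort, prefix: str | Path) -> list[Path]:
    """Write ``<prefix>.individuals.tsv``, ``<prefix>.purchases.tsv`` and a
    sidecar ``<prefix>.schema.json``; returns the paths written."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    ind_path = prefix.with_suffix(".individuals.tsv")
    pur_path = prefix.with_suffix(".purchases.tsv")
    schema_path = prefix.with_suffix(".schema.json")
    cohort.individuals.to_csv(ind_path, sep="\t", index=False)
    cohort.purchases.to_csv(pur_path, sep="\t", index=False)
    schema = {
        "trait_names": list(cohort.trait_names),
        "registry_end": cohort.registry_end,
        "package_days": cohort.package_days,
        "individual_columns": list(cohort.individuals.columns),
        "purchase_columns": list(cohort.purchases.columns),
    }
    schema_path.write_text(json.dumps(schema, indent=2))
    return [ind_path, pur_path, schema_path]


def read_cohort(prefix: str | Path) -> Cohort:
    prefix = Path(prefix)
    schema = json.loads(prefix.with_suffix(".schema.json").read_text())
    individuals = pd.read_csv(prefix.with_suffix(".individuals.tsv"), sep="\t")
    purchases = pd.read_csv(prefix.with_suffix(".purchases.tsv"), sep="\t")
    return Cohort(
        individuals=individuals,
        purchases=purchases,
        trait_names=tuple(schema["trait_names"]),
        registry_end=int(schema["registry_end"]),
        package_days=float(schema["package_days"]),
    )


def read_weights(path: str | Path) -> pd.DataFrame:
    """Read a PGS weight table (variant_id, effect_allele, weight).

    Lines starting with ``#`` (PGS-Catalog-style metadata headers) are
    skipped; common alternative column names are normalized.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    rename = {
        "rsID": "variant_id", "rsid": "variant_id", "ID": "variant_id",
        "effect_weight": "weight", "beta": "weight",
        "A1": "effect_allele",
    }
    df = df.rename(columns={k: v for k, v in rename.items() if k in df.columns})
    required = {"variant_id", "effect_allele", "weight"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"weight file lacks columns: {sorted(missing)}")
    return df[["variant_id", "effect_allele", "weight"]]


def write_summary_stats(df: pd.DataFrame, path: str | Path) -> Path:
    """Write summary statistics as TSV (``.gz`` extension compresses)."""
    validate_summary_stats(df)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df[SUMMARY_STAT_COLUMNS].to_csv(path, sep="\t", index=False)
    return path


def read_summary_stats(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    validate_summary_stats(df)
    return df
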