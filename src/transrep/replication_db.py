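"""Data model, TSV I/O and curation rules for discovery/replication records.

Three tab-separated tables describe a replicability database:

* ``studies``      - one row per GWAS (ancestry, sample sizes, imputation).
* ``associations`` - one row per discovered disease-associated SNP, with
  the discovery odds ratio referenced to the risk allele.
* ``attempts``     - one row per replication attempt of a discovered SNP
  in a later study, with the OR referenced to the discovery risk allele.

Curation follows conservative genome-wide significance rules: the
discovery p-value must beat 5e-7 (5e-8 when the study used imputed
SNPs), SNPs in the MHC region are excluded, sex-specific-only
associations are excluded, and within genomic regions (SNPs chained at
< 200 kb on the same chromosome) only the SNP with the lowest p-value
is retained.

Missing values are encoded as "." in all TSVs.  Coordinates are
1-based inclusive (VCF convention).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ValidationError",
    "TableSet",
    "OrientedOR",
    "STUDY_COLUMNS",
    "ASSOCIATION_COLUMNS",
    "ATTEMPT_COLUMNS",
    "ANCESTRIES",
    "read_table",
    "write_table",
    "load_tables",
    "apply_discovery_filters",
    "reference_risk_allele",
    "select_attempts",
]

NA = "."

ANCESTRIES = ("European", "EastAsian", "African")

STUDY_COLUMNS = {
    "study_id": str,
    "disease": str,
    "ancestry": str,
    "year": int,
    "n_gwas_stage": int,
    "n_replication_stage": int,
    "uses_imputation": bool,
    "genomic_control_lambda": float,  # optional metadata
}

ASSOCIATION_COLUMNS = {
    "snp_id": str,
    "chrom": str,
    "pos_bp": int,
    "disease": str,
    "discovery_study_id": str,
    "risk_allele": str,
    "other_allele": str,
    "or_discovery": float,
    "log_or": float,
    "p_discovery": float,
    "maf_discovery_pop": float,
    "sex_specific": bool,
    "region_id": str,
}

ATTEMPT_COLUMNS = {
    "snp_id": str,
    "replication_study_id": str,
    "ancestry": str,
    "or_replication": float,
    "p_replication": float,
    "n_cases": int,
    "n_controls": int,
    "raf_replication_pop": float,
    "allele_shift_flag": bool,
    "power": float,      # optional, filled by power_calc
    "success": bool,     # derived: same risk allele AND p < alpha
}

_OPTIONAL = {"genomic_control_lambda", "power", "region_id", "success"}


class ValidationError(ValueError):
    """A table failed schema or referential-integrity validation."""


@dataclass
class TableSet:
    """A validated trio of replicability tables."""

    studies: pd.DataFrame
    associations: pd.DataFrame
    attempts: pd.DataFrame


@dataclass(frozen=True)
class OrientedOR:
    """An odds ratio re-referenced to the discovery risk allele."""

    or_value: float
    log_or: float
    shift: bool
    direction_same: bool | None  # None when OR == 1 (direction undefined)


# ---------------------------------------------------------------------------
# TSV I/O


def _coerce_column(raw: pd.Series, dtype, table: str, column: str) -> pd.Series:
    """Strictly convert a string column; never silently coerce bad cells."""
    is_na = raw.isna() | (raw.astype(str).str.strip() == NA)
    if dtype is str:
        out = raw.where(~is_na, other=pd.NA)
        return out
    if dtype is bool:
        mapping = {"true": True, "false": False, "1": True, "0": False,
                   "y": True, "n": False}
        lowered = raw.astype(str).str.strip().str.lower()
        bad = ~is_na & ~lowered.isin(mapping)
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValidationError(
                f"{table}.{column}: unparseable boolean {raw.iloc[row]!r} "
                f"at row {row}"
            )
        return lowered.map(mapping).where(~is_na, other=pd.NA).astype("boolean")
    numeric = pd.to_numeric(raw.where(~is_na), errors="coerce")
    bad = ~is_na & numeric.isna()
    if bad.any():
        row = int(np.flatnonzero(bad)[0])
        raise ValidationError(
            f"{table}.{column}: unparseable value {raw.iloc[row]!r} at row "
            f"{row} (decimal commas are not accepted)"
        )
    if dtype is int:
        frac = numeric.dropna() % 1
        if (frac != 0).any():
            raise ValidationError(f"{table}.{column}: non-integer value present")
        return numeric.astype("Int64")
    return numeric.astype(float)


def read_table(path, schema: dict, name: str) -> pd.DataFrame:
    """Read one TSV against a schema; extra columns are kept as strings."""
    raw = pd.read_csv(path, sep="\t", dtype=str, comment="#",
                      keep_default_na=False, na_values=[""])
    missing = [c for c in schema if c not in raw.columns and c not in _OPTIONAL]
    if missing:
        raise ValidationError(f"{name}: missing required columns {missing}")
    out = pd.DataFrame(index=raw.index)
    for column, dtype in schema.items():
        if column not in raw.columns:
            continue
        out[column] = _coerce_column(raw[column], dtype, name, column)
    for column in raw.columns:
        if column not in schema:
            out[column] = raw[column].replace(NA, pd.NA)
    return out


def write_table(frame: pd.DataFrame, path, header_comment: str | None = None):
    """Write a TSV with '.' for missing and stable float formatting."""
    with open(path, "w", encoding="utf-8") as handle:
        if header_comment:
            for line in header_comment.splitlines():
                handle.write(f"# {line}\n")
        frame.to_csv(handle, sep="\t", index=False, na_rep=NA,
                     float_format="%.10g")


def load_tables(studies_path, associations_path, attempts_path) -> TableSet:
    """Load and validate the three tables, checking referential integrity."""
    studies = read_table(studies_path, STUDY_COLUMNS, "studies")
    associations = read_table(associations_path, ASSOCIATION_COLUMNS,
                              "associations")
    attempts = read_table(attempts_path, ATTEMPT_COLUMNS, "attempts")

    bad_anc = set(studies["ancestry"].dropna()) - set(ANCESTRIES)
    if bad_anc:
        raise ValidationError(f"studies: unknown ancestry labels {sorted(bad_anc)}")

    known_snps = set(associations["snp_id"])
    dangling = sorted(set(attempts["snp_id"]) - known_snps)
    if dangling:
        raise ValidationError(
            f"attempts: snp_id not present in associations: {dangling}"
        )
    known_studies = set(studies["study_id"])
    dangling = sorted(set(associations["discovery_study_id"]) - known_studies)
    if dangling:
        raise ValidationError(
            f"associations: unknown discovery_study_id: {dangling}"
        )
    dangling = sorted(set(attempts["replication_study_id"]) - known_studies)
    if dangling:
        raise ValidationError(
            f"attempts: unknown replication_study_id: {dangling}"
        )
    bad_or = associations["or_discovery"] <= 0
    if bad_or.any():
        row = int(np.flatnonzero(bad_or)[0])
        raise ValidationError(f"associations: non-positive OR at row {row}")
    logger.info(
        "loaded %d studies, %d associations, %d attempts",
        len(studies), len(associations), len(attempts),
    )
    return TableSet(studies, associations, attempts)


# ---------------------------------------------------------------------------
# Curation filters


def _cluster_regions(pos: np.ndarray, max_gap: int) -> np.ndarray:
    """Single-linkage chaining of sorted positions at < max_gap bp.

    Returns a cluster label per (sorted) position: adjacent positions
    closer than ``max_gap`` join the same cluster, transitively.
    """
    if len(pos) == 0:
        return np.array([], dtype=int)
    breaks = np.diff(pos) >= max_gap  # strict "< max_gap" chains
    return np.concatenate([[0], np.cumsum(breaks)])


def apply_discovery_filters(
    associations: pd.DataFrame,
    studies: pd.DataFrame,
    *,
    p_genotyped: float = 5e-7,
    p_imputed: float = 5e-8,
    prune_bp: int = 200_000,
    mhc_chrom: str = "6",
    mhc_start: int = 25_000_000,
    mhc_end: int = 35_000_000,
):
    """Apply the discovery-inclusion rules; return (kept, exclusion_log).

    Per disease: drop sex-specific-only associations; drop SNPs whose
    discovery p-value misses the study-appropriate genome-wide
    threshold (``p_imputed`` when the discovery study used imputation,
    ``p_genotyped`` otherwise); drop SNPs in the MHC window; then chain
    the survivors into regions at < ``prune_bp`` on the same chromosome
    and keep the SNP with the lowest p-value per region (ties broken by
    smaller position).  ``region_id`` is assigned to the kept rows.

    The exclusion log has columns (snp_id, reason).
    """
    assoc = associations.copy()
    uses_imp = studies.set_index("study_id")["uses_imputation"]
    unknown = set(assoc["discovery_study_id"]) - set(uses_imp.index)
    if unknown:
        raise ValidationError(f"unknown discovery studies: {sorted(unknown)}")
    imputed = assoc["discovery_study_id"].map(uses_imp).astype(bool)
    threshold = np.where(imputed, p_imputed, p_genotyped)

    reasons = {}

    sex = assoc["sex_specific"].fillna(False).astype(bool)
    for snp in assoc.loc[sex, "snp_id"]:
        reasons.setdefault(snp, "sex_specific")
    keep = ~sex

    above = assoc["p_discovery"].to_numpy(dtype=float) >= threshold
    for snp in assoc.loc[keep & above, "snp_id"]:
        reasons.setdefault(snp, "p_above_threshold")
    keep &= ~above

    in_mhc = (
        (assoc["chrom"].astype(str) == str(mhc_chrom))
        & (assoc["pos_bp"] >= mhc_start)
        & (assoc["pos_bp"] <= mhc_end)
    )
    for snp in assoc.loc[keep & in_mhc, "snp_id"]:
        reasons.setdefault(snp, "mhc_region")
    keep &= ~in_mhc

    kept = assoc.loc[keep].copy()
    best_index, region_ids = [], {}
    for (disease, chrom), group in kept.groupby(["disease", "chrom"], sort=True):
        group = group.sort_values(["pos_bp", "snp_id"], kind="stable")
        labels = _cluster_regions(group["pos_bp"].to_numpy(dtype=np.int64),
                                  prune_bp)
        group = group.assign(_cluster=labels)
        for label, cluster in group.groupby("_cluster", sort=True):
            best = cluster.sort_values(
                ["p_discovery", "pos_bp", "snp_id"], kind="stable"
            ).iloc[0]
            best_index.append(best.name)
            region_ids[best.name] = f"{disease}|chr{chrom}|r{label}"
            for snp in cluster["snp_id"]:
                if snp != best["snp_id"]:
                    reasons.setdefault(snp, "not_min_p_in_region")
    result = kept.loc[sorted(best_index)].copy()
    result["region_id"] = result.index.map(region_ids)
    exclusions = pd.DataFrame(
        sorted(reasons.items()), columns=["snp_id", "reason"]
    )
    logger.info("discovery filters kept %d of %d associations",
                len(result), len(assoc))
    return result, exclusions


# ---------------------------------------------------------------------------
# Allele referencing


def reference_risk_allele(or_reported: float, reported_allele: str,
                          discovery_risk_allele: str) -> OrientedOR:
    """Re-reference a reported OR to the discovery risk allele.

    When the reporting allele is not the discovery risk allele the OR is
    inverted (an OR of 2 for one allele is an OR of 0.5 for the other)
    and the shift flag is set.  ``direction_same`` is True when the
    oriented OR exceeds 1 (the discovery risk allele also increases risk
    here), None when OR == 1 exactly.
    """
    if or_reported <= 0:
        raise ValueError("odds ratio must be positive")
    shift = reported_allele != discovery_risk_allele
    oriented = 1.0 / or_reported if shift else float(or_reported)
    log_or = float(np.log(oriented))
    direction = None if oriented == 1.0 else (log_or > 0)
    return OrientedOR(oriented, log_or, shift, direction)


# ---------------------------------------------------------------------------
# Attempt selection


def select_attempts(attempts: pd.DataFrame, mode: str = "all",
                    associations: pd.DataFrame | None = None) -> pd.DataFrame:
    """Deterministically select a subset of replication attempts.

    Modes: ``all`` (identity), ``largest_per_snp`` (largest total sample
    size per SNP), ``most_powered_per_snp``, ``most_powered_per_region``
    (requires ``associations`` with region_id).  Ties are broken by
    larger total sample size, then lexicographic replication_study_id.
    """
    if mode == "all":
        return attempts.copy()
    work = attempts.copy()
    work["_n_total"] = (
        work["n_cases"].astype(float) + work["n_controls"].astype(float)
    )
    if mode == "largest_per_snp":
        key, score = "snp_id", "_n_total"
    elif mode == "most_powered_per_snp":
        _require_power(work)
        key, score = "snp_id", "power"
    elif mode == "most_powered_per_region":
        _require_power(work)
        if associations is None or "region_id" not in associations.columns:
            raise ValueError(
                "most_powered_per_region requires associations with region_id"
            )
        regions = associations.set_index("snp_id")["region_id"]
        work["_region"] = work["snp_id"].map(regions)
        key, score = "_region", "power"
    else:
        raise ValueError(f"unknown selection mode: {mode!r}")
    ordered = work.sort_values(
        [score, "_n_total", "replication_study_id"],
        ascending=[False, False, True],
        kind="stable",
    )
    chosen = ordered.drop_duplicates(subset=key, keep="first")
    chosen = chosen.sort_index()
    return chosen.drop(columns=[c for c in ("_n_total", "_region")
                                if c in chosen.columns])


def _require_power(frame: pd.DataFrame) -> None:
    if "power" not in frame.columns or frame["power"].isna().any():
        raise ValueError("power column must be filled for most_powered modes")
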