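"""End-to-end orchestration: MATH -> neoantigens -> escape -> cohort statistics.

``run_pipeline`` takes assembled patient profiles plus a per-patient
strong-binder count source and produces the per-stage tables as DataFrames;
``write_report`` persists them as tab-delimited files next to a manifest
(config echo, seed, versions, input checksums) that suffices to reproduce
the run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .cohort_stats import (
    chi_square_2x2,
    cox_ph,
    kendall_tau_b,
    km_logrank,
    median_split,
    spearman_rho,
)
from .errors import DomainError, InsufficientDataError
from .escape import escape_for_cohort, stratify_by_escape
from .heterogeneity import (
    DEFAULT_ITH_CUTOFF,
    DEFAULT_MIN_VARIANTS,
    MAD_CONSTANT,
    math_for_patient,
)
from .io_variants import PatientProfile
from .neoepitope import DEFAULT_PEPTIDE_LENGTHS, DEFAULT_STRONG_RANK, DEFAULT_WEAK_RANK

log = logging.getLogger("mmith")


@dataclass(frozen=True)
class AnalysisConfig:
    """Every fixed constant of the analysis, overridable without code edits."""

    ith_cutoff: float = DEFAULT_ITH_CUTOFF
    mad_constant: float = MAD_CONSTANT
    min_variants: int = DEFAULT_MIN_VARIANTS
    strong_rank: float = DEFAULT_STRONG_RANK
    weak_rank: float = DEFAULT_WEAK_RANK
    peptide_lengths: tuple[int, ...] = DEFAULT_PEPTIDE_LENGTHS
    nal_definition: str = "strong_snv"        # or "strong_all"
    standard_method: str = "cohort_median"    # or "fixed"
    standard_fixed: Optional[tuple[float, float]] = None
    cluster_filter: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.strong_rank >= self.weak_rank:
            raise DomainError("strong_rank must be below weak_rank")
        if not set(self.peptide_lengths) <= set(range(8, 12)):
            raise DomainError("peptide lengths must lie in 8..11")
        if self.ith_cutoff <= 0:
            raise DomainError("ith_cutoff must be positive")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "peptide_lengths" in raw:
            raw["peptide_lengths"] = tuple(raw["peptide_lengths"])
        if "standard_fixed" in raw and raw["standard_fixed"] is not None:
            raw["standard_fixed"] = tuple(raw["standard_fixed"])
        return cls(**raw)


def math_table(profiles: Sequence[PatientProfile], config: AnalysisConfig) -> pd.DataFrame:
    """Stage 1: per-patient MATH scores and ITH classes."""
    rows, dropped = [], 0
    for p in profiles:
        try:
            r = math_for_patient(
                p.patient_id,
                p.variants,
                min_variants=config.min_variants,
                cutoff=config.ith_cutoff,
                cluster_filter=config.cluster_filter,
            )
        except InsufficientDataError as exc:
            dropped += 1
            log.warning("math: skipping %s (%s)", p.patient_id, exc)
            continue
        rows.append(
            {
                "patient_id": r.patient_id,
                "n": r.n_variants_used,
                "median_vaf": r.median_vaf,
                "scaled_mad": r.scaled_mad,
                "math": r.math,
                "ith_class": r.ith_class.value,
            }
        )
    log.info("math: %d patients scored, %d dropped", len(rows), dropped)
    return pd.DataFrame(rows)


def escape_table(
    math_df: pd.DataFrame,
    nal_by_patient: Mapping[str, int],
    config: AnalysisConfig,
) -> pd.DataFrame:
    """Stage 3: escape indices against the shared standard, plus the median split."""
    cohort = [
        (row.patient_id, int(nal_by_patient[row.patient_id]), row.scaled_mad, row.median_vaf)
        for row in math_df.itertuples()
        if row.patient_id in nal_by_patient
    ]
    results = escape_for_cohort(
        cohort, method=config.standard_method, fixed=config.standard_fixed
    )
    low, high = stratify_by_escape(results)
    low_ids = {r.patient_id for r in low}
    return pd.DataFrame(
        [
            {
                "patient_id": r.patient_id,
                "nal": r.nal,
                "mad_over_median": r.mad_over_median,
                "patient_density": r.patient_density,
                "standard_density": r.standard_density,
                "escape_index": r.escape_index,
                "escape_group": "low" if r.patient_id in low_ids else "high",
            }
            for r in results
        ]
    )


def stats_tables(
    profiles: Sequence[PatientProfile],
    math_df: pd.DataFrame,
    escape_df: pd.DataFrame,
) -> dict[str, pd.DataFrame]:
    """Stage 4: correlations, remission contingency, log-rank and Cox fits."""
    by_id = {p.patient_id: p for p in profiles}
    merged = math_df.merge(escape_df, on="patient_id")
    out: dict[str, pd.DataFrame] = {}

    # MATH vs NAL rank correlations
    corr_rows = []
    for name, fn in (("kendall_tau_b", kendall_tau_b), ("spearman_rho", spearman_rho)):
        r = fn(merged["math"], merged["nal"])
        corr_rows.append(
            {"analysis": f"math_vs_nal_{name}", "statistic": r.statistic,
             "effect": r.effect, "p_value": r.p_value, "n": r.n}
        )
    out["correlations"] = pd.DataFrame(corr_rows)

    # remission rate by NAL split (more-loss = below-median NAL)
    low_nal, high_nal = median_split(dict(zip(merged["patient_id"], merged["nal"])))
    def resp_counts(ids):
        good = sum(1 for i in ids if by_id[i].best_response == ">=VGPR")
        return [good, len(ids) - good]
    table = [resp_counts(low_nal), resp_counts(high_nal)]
    chi = chi_square_2x2(table)
    out["remission"] = pd.DataFrame(
        [{
            "more_loss_vgpr": table[0][0], "more_loss_lt_vgpr": table[0][1],
            "less_loss_vgpr": table[1][0], "less_loss_lt_vgpr": table[1][1],
            "chi2": chi.statistic, "p_value": chi.p_value,
            "more_loss_rate": chi.extra["proportions"][0],
            "less_loss_rate": chi.extra["proportions"][1],
        }]
    )

    # log-rank by escape group
    groups = {
        g: [
            (by_id[r.patient_id].pfs_months, by_id[r.patient_id].pfs_event)
            for r in merged.itertuples()
            if r.escape_group == g
        ]
        for g in ("low", "high")
    }
    surv_rows = []
    if all(len(g) > 0 for g in groups.values()):
        lr, _ = km_logrank(groups)
        surv_rows.append(
            {"analysis": "logrank_escape_groups", "statistic": lr.statistic,
             "p_value": lr.p_value, "n": lr.n}
        )

    # multivariate Cox with the study's covariate panel
    cov = pd.DataFrame(
        {
            "math": merged["math"].to_numpy(),
            "nal": merged["nal"].to_numpy(),
            "age": [by_id[i].age for i in merged["patient_id"]],
            "male": [1.0 if by_id[i].gender and by_id[i].gender.value == "male" else 0.0
                     for i in merged["patient_id"]],
            "ecog": [float(by_id[i].ecog or 0) for i in merged["patient_id"]],
            "fish_high_risk": [1.0 if by_id[i].fish_high_risk else 0.0
                               for i in merged["patient_id"]],
            "iss": [{"I": 1.0, "II": 2.0, "III": 3.0}.get(by_id[i].iss_stage, 2.0)
                    for i in merged["patient_id"]],
            "hyperdiploid": [1.0 if by_id[i].hyperdiploid else 0.0
                             for i in merged["patient_id"]],
        }
    )
    times = [by_id[i].pfs_months for i in merged["patient_id"]]
    events = [bool(by_id[i].pfs_event) for i in merged["patient_id"]]
    cox_rows = []
    try:
        fit = cox_ph(cov, times, events)
        for ce in fit.covariates:
            cox_rows.append(
                {"covariate": ce.name, "hazard_ratio": ce.hazard_ratio,
                 "ci95_low": ce.ci95_low, "ci95_high": ce.ci95_high,
                 "p_value": ce.p_value, "converged": fit.converged}
            )
    except DomainError as exc:
        log.warning("cox: %s", exc)
    out["survival"] = pd.DataFrame(surv_rows)
    out["cox"] = pd.DataFrame(cox_rows)
    return out


def run_pipeline(
    profiles: Sequence[PatientProfile],
    nal_by_patient: Mapping[str, int],
    config: AnalysisConfig = AnalysisConfig(),
) -> dict[str, pd.DataFrame]:
    """Run math -> escape -> stats over assembled profiles.

    *nal_by_patient* carries each patient's strong-binding neoantigen
    count, produced either by the neoepitope stage or by the synthetic
    generator's ground truth.
    """
    math_df = math_table(profiles, config)
    if math_df.empty:
        raise DomainError("no patient had enough variants for MATH")
    esc_df = escape_table(math_df, nal_by_patient, config)
    tables = {"math": math_df, "escape": esc_df}
    tables.update(stats_tables(profiles, math_df, esc_df))
    return tables


def _checksum(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()[:16]


def write_report(
    tables: Mapping[str, pd.DataFrame],
    out_dir: str | Path,
    config: AnalysisConfig,
    inputs: Sequence[str | Path] = (),
) -> Path:
    """Write stage tables as TSV plus a reproducibility manifest; returns out_dir."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, df in tables.items():
        df.to_csv(out / f"{name}.tsv", sep="\t", index=False)
    manifest = {
        "package_version": __version__,
        "python": platform.python_version(),
        "config": dataclasses.asdict(config),
        "inputs": {str(p): _checksum(Path(p)) for p in inputs if Path(p).exists()},
        "tables": sorted(tables),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=list)
    return out
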