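"""The immune-escape index: neoantigen shortfall per unit VAF-dispersion.

A patient's strong-binding neoantigen density is their strong-binder load
(NAL) divided by the width of their VAF distribution, measured as
MAD/median (= MATH/100). The escape index is the cohort-standard density
minus the patient's own:

    escape = sNAL / (sMAD/sMedian) - NAL / (MAD/median)

Tumors that are very heterogeneous yet present few strong binders fall far
below the standard density and get a large positive index — interpreted as
strong immune escape. The absolute standard density for myeloma is not yet
established, so the default standard is the cohort's own medians and only
relative values are meaningful.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .errors import DomainError


@dataclass(frozen=True)
class EscapeIndexResult:
    patient_id: str
    nal: int
    mad_over_median: float
    patient_density: float
    s_nal: float
    s_mad_over_median: float
    standard_density: float
    escape_index: float


def neoantigen_density(nal: int, scaled_mad: float, median_vaf: float) -> float:
    """Strong-binder count per unit of relative VAF dispersion (MAD/median)."""
    if scaled_mad <= 0:
        raise DomainError("zero VAF dispersion: neoantigen density undefined")
    if median_vaf <= 0:
        raise DomainError("median VAF must be positive")
    if nal < 0:
        raise DomainError("NAL cannot be negative")
    return nal / (scaled_mad / median_vaf)


def cohort_standard(
    cohort: Sequence[tuple[int, float, float]],
    method: str = "cohort_median",
    fixed: Optional[tuple[float, float]] = None,
) -> tuple[float, float]:
    """Pick the standard (sNAL, sMAD/sMedian) pair.

    ``cohort_median`` (default): medians of the cohort's NALs and
    dispersion ratios. ``fixed``: pass user-supplied constants through —
    the hook for an externally established standard density.
    """
    if method == "fixed":
        if fixed is None:
            raise DomainError("method='fixed' requires the (s_nal, s_ratio) pair")
        return float(fixed[0]), float(fixed[1])
    if method != "cohort_median":
        raise DomainError(f"unknown standard method {method!r}")
    if not cohort:
        raise DomainError("cohort_standard needs a non-empty cohort")
    nals = [c[0] for c in cohort]
    ratios = [c[1] / c[2] for c in cohort]
    if any(r <= 0 for r in ratios):
        raise DomainError("non-positive dispersion ratio in cohort")
    return float(np.median(nals)), float(np.median(ratios))


def escape_index(patient_density: float, standard_density: float) -> float:
    """Standard minus patient density; larger = more neoantigen loss per unit ITH."""
    if not (np.isfinite(patient_density) and np.isfinite(standard_density)):
        raise DomainError("densities must be finite")
    return standard_density - patient_density


def escape_for_cohort(
    cohort: Sequence[tuple[str, int, float, float]],
    method: str = "cohort_median",
    fixed: Optional[tuple[float, float]] = None,
) -> list[EscapeIndexResult]:
    """Compute per-patient escape indices against one shared standard.

    *cohort* rows are (patient_id, nal, scaled_mad, median_vaf).
    """
    s_nal, s_ratio = cohort_standard([(n, m, md) for _, n, m, md in cohort], method, fixed)
    if s_ratio <= 0:
        raise DomainError("standard dispersion ratio must be positive")
    standard_density = s_nal / s_ratio
    out = []
    for pid, nal, smad, med in cohort:
        dens = neoantigen_density(nal, smad, med)
        out.append(
            EscapeIndexResult(
                patient_id=pid,
                nal=nal,
                mad_over_median=smad / med,
                patient_density=dens,
                s_nal=s_nal,
                s_mad_over_median=s_ratio,
                standard_density=standard_density,
                escape_index=escape_index(dens, standard_density),
            )
        )
    return out


def stratify_by_escape(
    results: Sequence[EscapeIndexResult],
) -> tuple[list[EscapeIndexResult], list[EscapeIndexResult]]:
    """Median-split into (low-escape, high-escape); ties at the median go low."""
    if len(results) < 2:
        raise DomainError("stratification needs at least two patients")
    med = float(np.median([r.escape_index for r in results]))
    low = [r for r in results if r.escape_index <= med]
    high = [r for r in results if r.escape_index > med]
    if not high:
        warnings.warn("all escape indices equal: high-escape group is empty")
    return low, high
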