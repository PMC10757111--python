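"""MATH scoring of VAF distributions, high-ITH classification, and TMB.

The mutant-allele tumor heterogeneity (MATH) score summarizes intratumor
heterogeneity from a single sample as the percentage ratio of the scaled
median absolute deviation to the median of the somatic variant allele
fractions:

    MATH = 100 * MAD / median,   MAD = 1.4826 * median(|VAF_i - median(VAF)|)

The 1.4826 factor makes the MAD a consistent estimator of the standard
deviation under normality, so for VAFs ~ N(mu, sigma) the score tends to
100*sigma/mu. Tumors whose subclones sit at well-separated cancer-cell
fractions produce a wide VAF spread and hence a high MATH; a score above
40 (strict) classifies the sample as high-ITH, the threshold at which
myeloma samples stand out among tumor types despite a modest mutation
burden.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Optional, Sequence

import numpy as np

from .errors import DomainError, InsufficientDataError
from .io_variants import NON_SILENT, SomaticVariant, VariantClass

MAD_CONSTANT = 1.4826
DEFAULT_ITH_CUTOFF = 40.0
DEFAULT_MIN_VARIANTS = 5
DEFAULT_EXOME_MB = 38.0
#: default depth / VAF floor applied when scoring a patient's calls
DEFAULT_MIN_DEPTH = 14
DEFAULT_MIN_VAF = 0.05


class ITHClass(str, Enum):
    HIGH = "high"
    LOW = "low"


@dataclass(frozen=True)
class MATHResult:
    patient_id: str
    n_variants_used: int
    median_vaf: float
    scaled_mad: float
    math: float
    ith_class: ITHClass


@dataclass(frozen=True)
class TMBResult:
    patient_id: str
    n_counted_variants: int
    exome_megabases: float
    tmb_per_mb: float


def scaled_mad(values: Sequence[float], constant: float = MAD_CONSTANT) -> float:
    """Median absolute deviation scaled so it estimates sigma under normality."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise DomainError("scaled_mad of an empty sample is undefined")
    if not np.all(np.isfinite(arr)):
        raise DomainError("scaled_mad requires finite values")
    med = np.median(arr)
    return float(constant * np.median(np.abs(arr - med)))


def math_score(
    vafs: Sequence[float],
    patient_id: str = "",
    min_variants: int = DEFAULT_MIN_VARIANTS,
    cutoff: float = DEFAULT_ITH_CUTOFF,
    mad_constant: float = MAD_CONSTANT,
) -> MATHResult:
    """Compute MATH = 100 * scaled MAD / median over a VAF sample."""
    arr = np.asarray(vafs, dtype=float)
    if arr.size < min_variants:
        raise InsufficientDataError(
            f"MATH needs >= {min_variants} VAFs, got {arr.size}", n=int(arr.size)
        )
    if np.any(arr <= 0) or np.any(arr > 1):
        raise DomainError("VAFs must lie in (0, 1]")
    med = float(np.median(arr))
    if med == 0:
        raise DomainError("median VAF of 0: MATH undefined")
    smad = scaled_mad(arr, mad_constant)
    score = 100.0 * smad / med
    return MATHResult(
        patient_id=patient_id,
        n_variants_used=int(arr.size),
        median_vaf=med,
        scaled_mad=smad,
        math=score,
        ith_class=classify_ith(score, cutoff),
    )


def classify_ith(math: float, cutoff: float = DEFAULT_ITH_CUTOFF) -> ITHClass:
    """High ITH iff the score strictly exceeds the cutoff; ties go low."""
    if math < 0:
        raise DomainError("MATH score cannot be negative")
    return ITHClass.HIGH if math > cutoff else ITHClass.LOW


def vaf_cluster_filter(
    vafs: Sequence[float],
    enabled: bool = False,
    min_cluster_fraction: float = 0.05,
    max_components: int = 6,
    seed: int = 0,
) -> list[float]:
    """Optionally drop VAFs in minor mixture components before scoring.

    When enabled, fits 1-D Gaussian mixtures with 1..max_components
    components, picks the BIC-best fit, assigns each VAF to its maximum-
    responsibility component and discards components carrying fewer than
    ``min_cluster_fraction`` of the variants. Never returns an empty list:
    if everything would be dropped the input is returned unchanged. Off by
    default — the plain formula is the reproducible baseline.
    """
    vals = [float(v) for v in vafs]
    if not vals:
        raise DomainError("vaf_cluster_filter needs a non-empty sample")
    if not enabled or len(vals) < 4:
        return vals

    from sklearn.mixture import GaussianMixture

    X = np.asarray(vals, dtype=float).reshape(-1, 1)
    best = None
    best_bic = np.inf
    for k in range(1, min(max_components, len(vals)) + 1):
        gm = GaussianMixture(n_components=k, random_state=seed, n_init=2)
        gm.fit(X)
        bic = gm.bic(X)
        if bic < best_bic - 1e-9:
            best_bic, best = bic, gm
    labels = best.predict(X)
    counts = np.bincount(labels, minlength=best.n_components)
    keep_components = {
        c for c in range(best.n_components) if counts[c] / len(vals) >= min_cluster_fraction
    }
    kept = [v for v, lab in zip(vals, labels) if lab in keep_components]
    return kept if kept else vals


def filter_variants_for_math(
    variants: Iterable[SomaticVariant],
    counted_classes: frozenset[VariantClass] = NON_SILENT,
    min_depth: Optional[int] = DEFAULT_MIN_DEPTH,
    min_vaf: float = DEFAULT_MIN_VAF,
) -> list[float]:
    """Default pre-MATH filter: non-silent calls with adequate depth and VAF.

    Every threshold is a parameter so the unfiltered behaviour is one call
    away (`counted_classes=frozenset(VariantClass), min_depth=None, min_vaf=0`).
    """
    vafs = []
    for v in variants:
        if v.vaf is None or v.vaf <= 0:
            continue
        if counted_classes is not None and v.variant_class not in counted_classes:
            continue
        if min_depth is not None and (v.depth is None or v.depth < min_depth):
            continue
        if v.vaf < min_vaf:
            continue
        vafs.append(v.vaf)
    return vafs


def math_for_patient(
    patient_id: str,
    variants: Iterable[SomaticVariant],
    min_variants: int = DEFAULT_MIN_VARIANTS,
    cutoff: float = DEFAULT_ITH_CUTOFF,
    cluster_filter: bool = False,
    min_cluster_fraction: float = 0.05,
    **filter_kwargs,
) -> MATHResult:
    """Filter a patient's calls and score them; the standard entry point."""
    vafs = filter_variants_for_math(variants, **filter_kwargs)
    if cluster_filter and vafs:
        vafs = vaf_cluster_filter(vafs, enabled=True, min_cluster_fraction=min_cluster_fraction)
    return math_score(vafs, patient_id=patient_id, min_variants=min_variants, cutoff=cutoff)


def tmb(
    variants: Iterable[SomaticVariant],
    patient_id: str = "",
    exome_megabases: float = DEFAULT_EXOME_MB,
    counted_classes: frozenset[VariantClass] = NON_SILENT,
) -> TMBResult:
    """Tumor mutation burden: counted somatic calls per megabase of exome."""
    if exome_megabases <= 0:
        raise DomainError("exome_megabases must be positive")
    n = sum(1 for v in variants if v.variant_class in counted_classes)
    return TMBResult(
        patient_id=patient_id,
        n_counted_variants=n,
        exome_megabases=exome_megabases,
        tmb_per_mb=n / exome_megabases,
    )
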