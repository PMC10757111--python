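"""Synthetic myeloma cohorts with the dependence structure the analysis assumes.

Each patient gets a subclonal architecture (a truncal clone plus 0-4
subclones at lower cancer-cell fractions), somatic variants whose read
counts are binomial draws at Poisson depth — so the VAF spread, and hence
the MATH score, emerges from the architecture rather than being stamped on
— and clinical covariates. On top of that, three couplings are imposed in
reduced form, because the study reports correlations, not mechanisms:

* strong-binding neoantigen load (NAL) is negatively coupled to the
  realized MATH score at a target Kendall tau via a Gaussian copula over
  the cohort's MATH ranks, with a negative-binomial marginal;
* CD8/NK lymphocyte fractions are positively coupled to NAL the same way
  (CD19 negatively; CD3/CD4 uncoupled);
* progression-free survival is exponential proportional-hazards in
  (MATH, NAL), with uniform independent censoring, and the probability of
  a >=VGPR best response is logistic in NAL.

Every generator is a pure function of (spec, seed). Ground truth (latent
architecture, drawn NAL, linear predictors) is returned alongside the
profiles so recovery tests can compare estimates to the values actually
simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError
from .heterogeneity import math_for_patient
from .io_variants import (
    DiseaseStage,
    Gender,
    LightChain,
    PatientProfile,
    SomaticVariant,
    VariantClass,
    infer_variant_type,
)
from .neoepitope import EffectKind, ProteinEffect

_BASES = "ACGT"
_AA = "ACDEFGHIKLMNPQRSTVWY"

# variant functional-class frequencies, loosely exome-like
_CLASS_PROBS = [
    (VariantClass.MISSENSE, 0.58),
    (VariantClass.SILENT, 0.16),
    (VariantClass.NONSENSE, 0.05),
    (VariantClass.FRAMESHIFT_INS, 0.03),
    (VariantClass.FRAMESHIFT_DEL, 0.04),
    (VariantClass.INFRAME_INS, 0.02),
    (VariantClass.INFRAME_DEL, 0.02),
    (VariantClass.SPLICE, 0.05),
    (VariantClass.OTHER, 0.05),
]

_HLA_POOL = [
    "HLA-A*01:01", "HLA-A*02:01", "HLA-A*03:01", "HLA-A*11:01", "HLA-A*24:02",
    "HLA-B*07:02", "HLA-B*08:01", "HLA-B*35:01", "HLA-B*40:01", "HLA-B*51:01",
    "HLA-C*03:04", "HLA-C*04:01", "HLA-C*06:02", "HLA-C*07:01", "HLA-C*07:02",
]


@dataclass(frozen=True)
class CohortSpec:
    """Generation parameters; defaults emulate the 49-patient NDMM study cohort."""

    n_patients: int = 49
    subclones_per_patient: tuple[int, int] = (3, 7)
    ccf_range: tuple[float, float] = (0.12, 0.6)
    truncal_weight_range: tuple[float, float] = (0.2, 0.5)
    purity_range: tuple[float, float] = (0.65, 0.95)
    mean_depth: float = 120.0
    mutations_per_patient: tuple[int, int] = (20, 70)
    target_tau: float = -0.25
    nal_mean: float = 42.0
    nal_dispersion: float = 6.0
    beta_math: float = float(np.log(1.022))   # log-hazard per MATH unit
    beta_nal: float = float(np.log(0.982))    # log-hazard per strong binder
    median_pfs_months: float = 25.0
    censor_rate: float = 0.5
    immune_coupling: float = 0.26             # target tau, NAL vs CD8/NK
    response_intercept: float = 0.1
    response_slope: float = 0.05              # logit >=VGPR per strong binder
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 1:
            raise DomainError("n_patients must be >= 1")
        for name in ("subclones_per_patient", "ccf_range", "purity_range",
                     "mutations_per_patient", "truncal_weight_range"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise DomainError(f"{name} range must be non-degenerate, got ({lo}, {hi})")
        if not 0.0 <= self.censor_rate < 1.0:
            raise DomainError("censor_rate must lie in [0, 1)")
        if not -1.0 < self.target_tau < 1.0:
            raise DomainError("target_tau must lie in (-1, 1)")


def _rng(spec_seed: int, *stream) -> np.random.Generator:
    return np.random.default_rng([int(spec_seed), *map(int, stream)])


def simulate_vafs(
    subclone_ccfs: Sequence[float],
    subclone_weights: Sequence[float],
    purity: float,
    mean_depth: float,
    n_mutations: int,
    seed: int | np.random.Generator,
    patient_id: str = "SIM",
) -> list[SomaticVariant]:
    """Draw somatic variants from a subclonal architecture.

    Each mutation joins a subclone by weight; its expected VAF under the
    diploid heterozygous model is purity*ccf/2, read counts are
    alt ~ Binomial(depth, purity*ccf/2) at depth ~ Poisson(mean_depth)
    truncated at 10.
    """
    ccfs = np.asarray(subclone_ccfs, dtype=float)
    w = np.asarray(subclone_weights, dtype=float)
    if np.any(ccfs <= 0) or np.any(ccfs > 1):
        raise DomainError("subclone CCFs must lie in (0, 1]")
    if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
        raise DomainError("subclone weights must be non-negative and sum to 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    classes, class_p = zip(*_CLASS_PROBS)
    out: list[SomaticVariant] = []
    for i in range(n_mutations):
        clone = rng.choice(len(ccfs), p=w)
        depth = 0
        while depth < 10:
            depth = int(rng.poisson(mean_depth))
        p_alt = purity * ccfs[clone] / 2.0
        alt = int(rng.binomial(depth, p_alt))
        vclass = classes[rng.choice(len(classes), p=class_p)]
        if vclass in (VariantClass.FRAMESHIFT_INS, VariantClass.INFRAME_INS):
            ref = _BASES[rng.integers(4)]
            alt_allele = ref + "".join(_BASES[j] for j in rng.integers(0, 4, size=3))
        elif vclass in (VariantClass.FRAMESHIFT_DEL, VariantClass.INFRAME_DEL):
            alt_allele = _BASES[rng.integers(4)]
            ref = alt_allele + "".join(_BASES[j] for j in rng.integers(0, 4, size=3))
        else:
            ref = _BASES[rng.integers(4)]
            alt_allele = _BASES[(int(_BASES.index(ref)) + 1 + int(rng.integers(3))) % 4]
        out.append(
            SomaticVariant(
                patient_id=patient_id,
                chrom=str(int(rng.integers(1, 23))),
                pos=int(rng.integers(1, 250_000_000)),
                ref=ref,
                alt=alt_allele,
                gene=f"GENE{int(rng.integers(1, 20000)):05d}",
                variant_class=vclass,
                variant_type=infer_variant_type(ref, alt_allele),
                alt_count=alt,
                depth=depth,
                vaf=alt / depth,
            )
        )
    return out


def simulate_patient(
    spec: CohortSpec, patient_index: int
) -> tuple[PatientProfile, dict]:
    """One patient's architecture, variants and demographics (pre-coupling).

    NAL, immune fractions, survival and response are attached at cohort
    level by :func:`simulate_cohort`, because the MATH-NAL coupling is
    calibrated on cohort ranks.
    """
    rng = _rng(spec.seed, 1, patient_index)
    pid = f"SIM{patient_index:03d}"
    k = int(rng.integers(spec.subclones_per_patient[0], spec.subclones_per_patient[1] + 1))
    ccfs = np.concatenate([[1.0], rng.uniform(*spec.ccf_range, size=k - 1)])
    # truncal clone holds a bounded share; the rest is split among subclones,
    # which is what pushes the VAF spread (and MATH) into the study's range
    if k == 1:
        weights = np.array([1.0])
    else:
        w0 = float(rng.uniform(*spec.truncal_weight_range))
        weights = np.concatenate([[w0], rng.dirichlet(np.ones(k - 1)) * (1.0 - w0)])
    purity = float(rng.uniform(*spec.purity_range))
    n_mut = int(rng.integers(spec.mutations_per_patient[0], spec.mutations_per_patient[1] + 1))
    variants = simulate_vafs(ccfs, weights, purity, spec.mean_depth, n_mut, rng, pid)

    profile = PatientProfile(
        patient_id=pid,
        disease_stage=DiseaseStage.NDMM,
        iss_stage=("I", "II", "III")[int(rng.choice(3, p=[0.3, 0.35, 0.35]))],
        variants=variants,
        hla_alleles=list(rng.choice(_HLA_POOL, size=6, replace=False)),
        age=float(np.clip(rng.normal(60, 9), 35, 85)),
        gender=Gender.MALE if rng.random() < 0.55 else Gender.FEMALE,
        ecog=int(rng.choice(4, p=[0.4, 0.35, 0.2, 0.05])),
        fish_high_risk=bool(rng.random() < 0.22),
        hyperdiploid=bool(rng.random() < 0.5),
        light_chain=LightChain.KAPPA if rng.random() < 0.6 else LightChain.LAMBDA,
        hla_loh=False,
    )
    latent = {
        "patient_id": pid,
        "n_subclones": k,
        "purity": purity,
        "n_mutations": n_mut,
        "ccf_spread": float(ccfs.max() - ccfs.min()),
    }
    return profile, latent


def _copula_counts(
    anchor: np.ndarray,
    tau: float,
    marginal_ppf,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw values rank-coupled to *anchor* at Kendall tau via a Gaussian copula.

    For a bivariate normal copula, Kendall's tau relates to the latent
    Pearson correlation by rho = sin(pi*tau/2); discreteness of the target
    marginal attenuates the realized tau slightly through ties.
    """
    n = anchor.size
    ranks = stats.rankdata(anchor, method="average")
    u = stats.norm.ppf((ranks - 0.5) / n)
    rho = np.sin(np.pi * tau / 2.0)
    z = rho * u + np.sqrt(1.0 - rho**2) * rng.standard_normal(n)
    return marginal_ppf(stats.norm.cdf(z))


def simulate_cohort(spec: CohortSpec) -> tuple[list[PatientProfile], pd.DataFrame]:
    """Generate the full cohort plus its ground-truth table.

    The truth table records realized MATH, the drawn NAL, the survival
    linear predictor and the latent architecture per patient, so recovery
    tests compare estimates against what was actually simulated.
    """
    profiles, latents = [], []
    for i in range(spec.n_patients):
        p, lat = simulate_patient(spec, i)
        profiles.append(p)
        latents.append(lat)

    math_scores = np.array(
        [math_for_patient(p.patient_id, p.variants).math for p in profiles]
    )

    # --- NAL negatively coupled to MATH (Gaussian copula, NB marginal)
    rng = _rng(spec.seed, 2)
    size = spec.nal_dispersion
    p_nb = size / (size + spec.nal_mean)
    nal = _copula_counts(
        math_scores,
        spec.target_tau,
        lambda q: stats.nbinom.ppf(np.clip(q, 1e-12, 1 - 1e-12), size, p_nb),
        rng,
    ).astype(int)

    # --- immune fractions coupled to NAL
    rng_imm = _rng(spec.seed, 3)
    def gauss_ppf(mu, sd):
        return lambda q: stats.norm.ppf(np.clip(q, 1e-9, 1 - 1e-9), mu, sd)

    cd8 = np.clip(_copula_counts(nal, spec.immune_coupling, gauss_ppf(24, 6), rng_imm), 1, 60)
    nk = np.clip(_copula_counts(nal, spec.immune_coupling, gauss_ppf(15, 5), rng_imm), 0.5, 45)
    cd19 = np.clip(_copula_counts(nal, -0.30, gauss_ppf(10, 4), rng_imm), 0.2, 35)
    cd3 = np.clip(rng_imm.normal(68, 8, spec.n_patients), 30, 90)
    cd4 = np.clip(rng_imm.normal(35, 7, spec.n_patients), 5, 60)

    # --- proportional-hazards PFS and censoring
    rng_surv = _rng(spec.seed, 4)
    lp = spec.beta_math * (math_scores - np.median(math_scores)) + spec.beta_nal * (
        nal - np.median(nal)
    )
    lam0 = np.log(2.0) / spec.median_pfs_months
    t_event = rng_surv.exponential(1.0 / (lam0 * np.exp(lp)))
    censored = rng_surv.random(spec.n_patients) < spec.censor_rate
    t_obs = np.where(censored, rng_surv.uniform(0, 1, spec.n_patients) * t_event, t_event)

    # --- best response logistic in NAL
    rng_resp = _rng(spec.seed, 5)
    p_vgpr = 1.0 / (
        1.0 + np.exp(-(spec.response_intercept + spec.response_slope * (nal - np.median(nal))))
    )
    good = rng_resp.random(spec.n_patients) < p_vgpr

    for i, p in enumerate(profiles):
        p.pfs_months = float(t_obs[i])
        p.pfs_event = bool(~censored[i])
        p.best_response = ">=VGPR" if good[i] else "<VGPR"
        p.lymphocyte_fractions = {
            "CD3": float(cd3[i]),
            "CD4": float(cd4[i]),
            "CD8": float(cd8[i]),
            "CD19": float(cd19[i]),
            "NK": float(nk[i]),
        }

    truth = pd.DataFrame(latents)
    truth["true_math"] = math_scores
    truth["nal"] = nal
    truth["linear_predictor"] = lp
    truth["pfs_months"] = t_obs
    truth["pfs_event"] = ~censored
    truth["p_vgpr"] = p_vgpr
    truth["beta_math"] = spec.beta_math
    truth["beta_nal"] = spec.beta_nal
    return profiles, truth


def synthetic_peptidome(
    n_variants: int,
    protein_length_range: tuple[int, int] = (30, 200),
    seed: int = 0,
    frameshift_fraction: float = 0.2,
) -> tuple[dict[str, str], list[ProteinEffect]]:
    """Random proteins plus matched coding effects for tiling tests.

    Proteins are uniform over the 20-letter alphabet; each variant gets a
    missense (interior position, guaranteed residue change) or a frameshift
    with a random novel tail. Deterministic and byte-stable for a given seed.
    """
    lo, hi = protein_length_range
    if lo < 8:
        raise DomainError("proteins must be at least 8 residues for tiling")
    rng = np.random.default_rng(seed)
    proteins: dict[str, str] = {}
    effects: list[ProteinEffect] = []
    for i in range(n_variants):
        pid = f"PROT{i:04d}"
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(_AA[j] for j in rng.integers(0, 20, size=length))
        proteins[pid] = seq
        pos = int(rng.integers(1, length + 1))
        if rng.random() < frameshift_fraction:
            tail = "".join(_AA[j] for j in rng.integers(0, 20, size=int(rng.integers(5, 16))))
            eff = ProteinEffect(f"var{i:04d}", pid, pos, EffectKind.FRAMESHIFT, tail + "*")
        else:
            wt_res = seq[pos - 1]
            alt = _AA[(int(_AA.index(wt_res)) + 1 + int(rng.integers(19))) % 20]
            eff = ProteinEffect(f"var{i:04d}", pid, pos, EffectKind.MISSENSE, alt)
        effects.append(eff)
    return proteins, effects


def write_peptidome_fasta(proteins: dict[str, str], path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    records = [SeqRecord(Seq(s), id=pid, description="synthetic") for pid, s in proteins.items()]
    SeqIO.write(records, str(path), "fasta")


def write_effects_table(effects: Sequence[ProteinEffect], path) -> None:
    df = pd.DataFrame(
        [
            {
                "variant_id": e.variant_id,
                "protein_id": e.protein_id,
                "protein_pos": e.protein_pos,
                "effect": e.kind.value,
                "payload": e.payload,
            }
            for e in effects
        ]
    )
    df.to_csv(path, sep="\t", index=False)
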