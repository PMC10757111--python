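"""Neoantigen candidate enumeration and MHC-I binder classification.

From each protein-altering somatic variant, all mutant windows of 8, 9 and
10 residues that overlap the altered region are tiled out of the mutant
protein; proteins shorter than 8 residues yield nothing. Each candidate
peptide is scored against the patient's HLA class-I alleles with a
percentile-rank predictor and keeps its best (lowest) rank. A peptide is a
strong binder at rank <= 0.5 and a weak binder at rank <= 2 (both
thresholds configurable); the per-patient count of unique strong-binding
SNV-derived peptides is the strong-binding neoantigen load (NAL) that the
downstream escape analysis consumes.

The percentile-rank predictor is pluggable: either an adapter over a
netMHCpan-style output table, or a built-in surrogate that maps a hash of
(peptide, allele, seed) to a Uniform(0,100) rank — a deterministic stand-in
that exercises every counting and classification path without an external
neural network (its ranks carry no biochemistry).

A candidate's immunogenicity can additionally be summarized by the
recognition potential A*R, where A = Kd(wild-type)/Kd(mutant) is the
binding-amplitude gain of the mutant peptide and R is a logistic function
of the best gapless BLOSUM62 alignment score against a reference set of
pathogen epitopes (the probability a TCR clone recognizes the peptide).
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Optional, Protocol, Sequence

from .errors import DomainError
from .io_variants import BindingRecord, normalize_hla

DEFAULT_STRONG_RANK = 0.5
DEFAULT_WEAK_RANK = 2.0
DEFAULT_PEPTIDE_LENGTHS = (8, 9, 10)
#: logistic parameters of the TCR-recognition similarity term
DEFAULT_SIMILARITY_MIDPOINT = 26.0
DEFAULT_SIMILARITY_SLOPE = 4.87
#: amplitude assigned to frameshift-novel peptides that have no wild-type partner
DEFAULT_NOVEL_AMPLITUDE = 1.0


class BinderClass(str, Enum):
    STRONG = "strong"
    WEAK = "weak"
    NON = "non"


class MutationType(str, Enum):
    SNV = "SNV"
    INDEL = "indel"


class EffectKind(str, Enum):
    MISSENSE = "missense"
    NONSENSE = "nonsense"
    FRAMESHIFT = "frameshift"
    INFRAME_INS = "inframe_ins"
    INFRAME_DEL = "inframe_del"


@dataclass(frozen=True)
class ProteinEffect:
    """Annotation-supplied coding consequence of one variant.

    ``protein_pos`` is 1-based. ``payload`` is the alternate residue for a
    missense, the novel translated tail (stop-stripped or '*'-terminated)
    for a frameshift, the inserted residues for an in-frame insertion, and
    the deletion length (as decimal string) for an in-frame deletion.
    """

    variant_id: str
    protein_id: str
    protein_pos: int
    kind: EffectKind
    payload: str = ""

    @property
    def mutation_type(self) -> MutationType:
        if self.kind in (EffectKind.MISSENSE, EffectKind.NONSENSE):
            return MutationType.SNV
        return MutationType.INDEL


@dataclass(frozen=True)
class PeptideCandidate:
    patient_id: str
    variant_id: str
    mutant_peptide: str
    wt_peptide: Optional[str]
    mutation_type: MutationType
    allele: Optional[str] = None
    rank_percent: Optional[float] = None
    kd_mut_nm: Optional[float] = None
    kd_wt_nm: Optional[float] = None
    binder_class: Optional[BinderClass] = None


@dataclass(frozen=True)
class NeoantigenSummary:
    patient_id: str
    total_snv: int = 0
    strong_snv: int = 0
    weak_snv: int = 0
    total_indel: int = 0
    strong_indel: int = 0
    weak_indel: int = 0
    nal: int = 0


@dataclass(frozen=True)
class RecognitionScore:
    amplitude_a: float
    similarity_r: float
    potential: float


# ---------------------------------------------------------------------------
# mutant protein construction

def mutant_protein(wt_protein: str, effect: ProteinEffect) -> tuple[str, Optional[tuple[int, int]]]:
    """Apply a coding effect to a protein; return (mutant, changed interval).

    The interval is 1-based inclusive in *mutant* coordinates and covers the
    residues a tiling window must overlap to be novel; ``None`` means no
    novel residues (e.g. a pure truncation).
    """
    n = len(wt_protein)
    p = effect.protein_pos
    if p < 1 or p > n:
        raise DomainError(
            f"{effect.variant_id}: protein position {p} outside 1..{n} of {effect.protein_id}"
        )
    if effect.kind is EffectKind.MISSENSE:
        alt = effect.payload
        if len(alt) != 1:
            raise DomainError(f"{effect.variant_id}: missense payload must be one residue")
        mut = wt_protein[: p - 1] + alt + wt_protein[p:]
        return mut, (p, p)
    if effect.kind is EffectKind.NONSENSE:
        return wt_protein[: p - 1], None
    if effect.kind is EffectKind.FRAMESHIFT:
        tail = effect.payload.split("*")[0]
        mut = wt_protein[: p - 1] + tail
        if not tail:
            return mut, None
        return mut, (p, p - 1 + len(tail))
    if effect.kind is EffectKind.INFRAME_INS:
        ins = effect.payload
        if not ins:
            raise DomainError(f"{effect.variant_id}: empty insertion payload")
        # residues inserted after position p
        mut = wt_protein[:p] + ins + wt_protein[p:]
        return mut, (p + 1, p + len(ins))
    if effect.kind is EffectKind.INFRAME_DEL:
        length = int(effect.payload)
        if length < 1 or p - 1 + length > n:
            raise DomainError(f"{effect.variant_id}: deletion exceeds protein bounds")
        mut = wt_protein[: p - 1] + wt_protein[p - 1 + length :]
        if not mut:
            return mut, None
        # windows spanning the new junction between p-1 and p are novel
        lo = max(1, p - 1)
        hi = min(len(mut), p)
        return mut, (lo, hi)
    raise DomainError(f"unknown effect kind {effect.kind!r}")


def tile_mutant_peptides(
    wt_protein: str,
    mut_protein: str,
    changed_interval: Optional[tuple[int, int]],
    lengths: Sequence[int] = DEFAULT_PEPTIDE_LENGTHS,
    positional_wt: bool = True,
) -> list[tuple[str, Optional[str]]]:
    """Tile all mutant windows overlapping the changed interval.

    Returns (mutant_peptide, wt_peptide) pairs; duplicates by mutant peptide
    string are collapsed. ``positional_wt`` pairs each window with the
    same-coordinate wild-type window (valid for substitutions); when False
    (indels / frameshifts, where coordinates shift) wt_peptide is ``None``
    and mutant windows that occur verbatim anywhere in the wild-type protein
    are discarded as non-novel.
    """
    if changed_interval is None or not mut_protein:
        return []
    lo, hi = changed_interval
    nm = len(mut_protein)
    seen: dict[str, Optional[str]] = {}
    for L in lengths:
        if nm < L:
            continue
        start_min = max(1, lo - L + 1)
        start_max = min(hi, nm - L + 1)
        for s in range(start_min, start_max + 1):
            pep = mut_protein[s - 1 : s - 1 + L]
            if positional_wt:
                wt = wt_protein[s - 1 : s - 1 + L]
                if pep == wt or len(wt) != L:
                    continue
            else:
                wt = None
                if pep in wt_protein:
                    continue
            if pep not in seen:
                seen[pep] = wt
    return list(seen.items())


def candidates_for_effect(
    patient_id: str,
    wt_protein: str,
    effect: ProteinEffect,
    lengths: Sequence[int] = DEFAULT_PEPTIDE_LENGTHS,
) -> list[PeptideCandidate]:
    """Mutant-protein construction + tiling for one annotated variant."""
    if len(wt_protein) < min(lengths):
        return []
    mut, interval = mutant_protein(wt_protein, effect)
    positional = effect.kind is EffectKind.MISSENSE
    tiles = tile_mutant_peptides(wt_protein, mut, interval, lengths, positional_wt=positional)
    return [
        PeptideCandidate(
            patient_id=patient_id,
            variant_id=effect.variant_id,
            mutant_peptide=pep,
            wt_peptide=wt,
            mutation_type=effect.mutation_type,
        )
        for pep, wt in tiles
    ]


# ---------------------------------------------------------------------------
# binder classification and rank assignment

def classify_binder(
    rank_percent: float,
    strong_cut: float = DEFAULT_STRONG_RANK,
    weak_cut: float = DEFAULT_WEAK_RANK,
) -> BinderClass:
    """Strong at rank <= strong_cut, weak at rank <= weak_cut, else non."""
    if rank_percent < 0:
        raise DomainError("rank_percent must be >= 0")
    if strong_cut >= weak_cut:
        raise DomainError("strong_cut must be below weak_cut")
    if rank_percent <= strong_cut:
        return BinderClass.STRONG
    if rank_percent <= weak_cut:
        return BinderClass.WEAK
    return BinderClass.NON


class RankPredictor(Protocol):
    def __call__(self, peptide: str, allele: str) -> tuple[float, Optional[float]]:
        """Return (rank_percent, kd_nm or None) for a peptide-allele pair."""


class SurrogatePredictor:
    """Deterministic hash-based percentile-rank generator.

    Maps SHA-256(peptide|allele|seed) to Uniform(0,100); bit-identical
    across runs and platforms. A monotone pseudo-affinity (5 nM at rank 0,
    50,000 nM at rank 100) is attached so amplitude arithmetic can be
    exercised. Carries no binding biochemistry whatsoever.
    """

    def __init__(self, seed: int = 0):
        self.seed = int(seed)

    def __call__(self, peptide: str, allele: str) -> tuple[float, Optional[float]]:
        digest = hashlib.sha256(
            f"{peptide}|{allele}|{self.seed}".encode("ascii")
        ).digest()
        u = int.from_bytes(digest[:8], "big") / 2**64
        rank = 100.0 * u
        kd = 5.0 * 10000.0 ** (rank / 100.0)
        return rank, kd


class TablePredictor:
    """Adapter over a netMHCpan-style binding table joined on peptide x allele."""

    def __init__(self, records: Iterable[BindingRecord]):
        self._table: dict[tuple[str, str], BindingRecord] = {}
        for r in records:
            key = (r.peptide, r.allele)
            prev = self._table.get(key)
            if prev is None or r.rank_percent < prev.rank_percent:
                self._table[key] = r
        self.unresolved: list[tuple[str, str]] = []

    def __call__(self, peptide: str, allele: str) -> tuple[float, Optional[float]]:
        rec = self._table.get((peptide, allele))
        if rec is None:
            self.unresolved.append((peptide, allele))
            return math.inf, None
        return rec.rank_percent, rec.kd_nm


def assign_ranks(
    candidates: Sequence[PeptideCandidate],
    alleles: Sequence[str],
    predictor: RankPredictor,
    strong_cut: float = DEFAULT_STRONG_RANK,
    weak_cut: float = DEFAULT_WEAK_RANK,
) -> list[PeptideCandidate]:
    """Score every candidate against each allele; keep the best (lowest) rank.

    Pairs missing from a table predictor come back with infinite rank and
    are listed in the predictor's ``unresolved`` report rather than dropped.
    """
    if not alleles:
        raise DomainError("assign_ranks needs at least one HLA allele")
    normed = [normalize_hla(a) for a in alleles]
    out = []
    for c in candidates:
        best_rank, best_allele, best_kd = math.inf, None, None
        for a in normed:
            rank, kd = predictor(c.mutant_peptide, a)
            if rank < best_rank:
                best_rank, best_allele, best_kd = rank, a, kd
        kd_wt = None
        if c.wt_peptide is not None and best_allele is not None:
            _, kd_wt = predictor(c.wt_peptide, best_allele)
        out.append(
            replace(
                c,
                allele=best_allele,
                rank_percent=best_rank,
                kd_mut_nm=best_kd,
                kd_wt_nm=kd_wt,
                binder_class=(
                    classify_binder(best_rank, strong_cut, weak_cut)
                    if math.isfinite(best_rank)
                    else BinderClass.NON
                ),
            )
        )
    return out


def summarize_neoantigens(
    candidates: Sequence[PeptideCandidate],
    patient_id: Optional[str] = None,
    nal_definition: str = "strong_snv",
) -> NeoantigenSummary:
    """Count unique mutant peptides per binder class, split SNV vs indel.

    The neoantigen unit is the unique mutant peptide per patient at its
    best rank across alleles; a peptide reachable from several alleles or
    variants counts once. ``nal`` is the strong SNV count by default, or
    strong SNV + indel under ``nal_definition="strong_all"``.
    """
    pids = {c.patient_id for c in candidates}
    if patient_id is None:
        if len(pids) > 1:
            raise DomainError(f"candidates span several patients: {sorted(pids)}")
        patient_id = next(iter(pids)) if pids else ""
    elif pids - {patient_id}:
        raise DomainError(f"candidates span several patients: {sorted(pids)}")

    best: dict[str, PeptideCandidate] = {}
    for c in candidates:
        if c.binder_class is None:
            raise DomainError("summarize_neoantigens requires ranked candidates")
        prev = best.get(c.mutant_peptide)
        if prev is None or (c.rank_percent or math.inf) < (prev.rank_percent or math.inf):
            best[c.mutant_peptide] = c

    counts = {MutationType.SNV: [0, 0, 0], MutationType.INDEL: [0, 0, 0]}  # total, strong, weak
    for c in best.values():
        bucket = counts[c.mutation_type]
        bucket[0] += 1
        if c.binder_class is BinderClass.STRONG:
            bucket[1] += 1
        elif c.binder_class is BinderClass.WEAK:
            bucket[2] += 1
    snv, indel = counts[MutationType.SNV], counts[MutationType.INDEL]
    nal = snv[1] if nal_definition == "strong_snv" else snv[1] + indel[1]
    return NeoantigenSummary(
        patient_id=patient_id,
        total_snv=snv[0],
        strong_snv=snv[1],
        weak_snv=snv[2],
        total_indel=indel[0],
        strong_indel=indel[1],
        weak_indel=indel[2],
        nal=nal,
    )


# ---------------------------------------------------------------------------
# recognition potential

def amplitude_a(kd_wt_nm: float, kd_mut_nm: float) -> float:
    """Binding-amplitude gain Kd(WT)/Kd(mutant); > 1 means the mutant binds tighter."""
    if kd_wt_nm <= 0 or kd_mut_nm <= 0:
        raise DomainError("dissociation constants must be positive")
    return kd_wt_nm / kd_mut_nm


_BLOSUM62 = None


def _blosum62():
    global _BLOSUM62
    if _BLOSUM62 is None:
        from Bio.Align import substitution_matrices

        _BLOSUM62 = substitution_matrices.load("BLOSUM62")
    return _BLOSUM62


def gapless_local_score(a: str, b: str, matrix=None) -> float:
    """Best gapless local alignment score between two sequences.

    Equivalent to Smith-Waterman with infinite gap penalties: the maximum,
    over all diagonal offsets, of the best-scoring contiguous run of
    aligned positions.
    """
    m = matrix if matrix is not None else _blosum62()
    best = 0.0
    for offset in range(-(len(b) - 1), len(a)):
        run = 0.0
        for i in range(len(a)):
            j = i - offset
            if 0 <= j < len(b):
                run = max(0.0, run) + float(m[a[i], b[j]])
                best = max(best, run)
    return best


def similarity_r(
    mut_peptide: str,
    epitope_reference: Sequence[str],
    midpoint_a: float = DEFAULT_SIMILARITY_MIDPOINT,
    slope_k: float = DEFAULT_SIMILARITY_SLOPE,
    matrix=None,
) -> float:
    """TCR-recognition probability: logistic in the best reference-epitope score.

    R = 1 / (1 + exp(-slope_k * (s* - midpoint_a))) where s* is the best
    gapless BLOSUM62 score of the peptide against the reference set.
    """
    if not epitope_reference:
        raise DomainError("similarity_r needs a non-empty epitope reference set")
    s_star = max(gapless_local_score(mut_peptide, e, matrix) for e in epitope_reference)
    z = slope_k * (s_star - midpoint_a)
    # guard exp overflow for very dissimilar peptides
    if z < -700:
        return 0.0
    return 1.0 / (1.0 + math.exp(-z))


def recognition_potential(a: float, r: float) -> RecognitionScore:
    """Combine amplitude and recognition probability into A*R."""
    if a < 0:
        raise DomainError("amplitude must be >= 0")
    if not 0.0 <= r <= 1.0:
        raise DomainError("similarity must lie in [0,1]")
    return RecognitionScore(amplitude_a=a, similarity_r=r, potential=a * r)
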