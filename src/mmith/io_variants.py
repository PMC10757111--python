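"""Readers and writers for somatic-variant, binding-prediction and clinical tables.

Somatic calls arrive as MAF, a simple tab-delimited dialect, or VCF with
tumor read counts; coordinates are stored 1-based inclusive (MAF
convention) and VCF positions are already 1-based so no shift is applied.
The readers are deliberately lossless: silent and splice calls are kept and
any filtering (functional class, depth, VAF) happens downstream where it is
a visible parameter rather than a parsing side effect.
"""

from __future__ import annotations

import csv
import math
import re
import warnings
from dataclasses import dataclass, field, fields
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional

from .errors import FormatError, ValidationError


class VariantClass(str, Enum):
    MISSENSE = "missense"
    NONSENSE = "nonsense"
    FRAMESHIFT_INS = "frameshift_ins"
    FRAMESHIFT_DEL = "frameshift_del"
    INFRAME_INS = "inframe_ins"
    INFRAME_DEL = "inframe_del"
    SILENT = "silent"
    SPLICE = "splice"
    OTHER = "other"


class VariantType(str, Enum):
    SNV = "SNV"
    INS = "INS"
    DEL = "DEL"


#: non-silent functional classes counted by default for MATH / TMB / neoantigens
NON_SILENT = frozenset(
    {
        VariantClass.MISSENSE,
        VariantClass.NONSENSE,
        VariantClass.FRAMESHIFT_INS,
        VariantClass.FRAMESHIFT_DEL,
        VariantClass.INFRAME_INS,
        VariantClass.INFRAME_DEL,
        VariantClass.SPLICE,
    }
)

# MAF Variant_Classification -> internal class
_MAF_CLASS_MAP = {
    "missense_mutation": VariantClass.MISSENSE,
    "nonsense_mutation": VariantClass.NONSENSE,
    "frame_shift_ins": VariantClass.FRAMESHIFT_INS,
    "frame_shift_del": VariantClass.FRAMESHIFT_DEL,
    "in_frame_ins": VariantClass.INFRAME_INS,
    "in_frame_del": VariantClass.INFRAME_DEL,
    "silent": VariantClass.SILENT,
    "splice_site": VariantClass.SPLICE,
    "splice_region": VariantClass.SPLICE,
}


@dataclass(frozen=True)
class SomaticVariant:
    """One somatic call: the atom of the MATH and neoantigen analyses."""

    patient_id: str
    chrom: str
    pos: int  # 1-based inclusive
    ref: str
    alt: str
    gene: str
    variant_class: VariantClass
    variant_type: VariantType
    alt_count: Optional[int] = None
    depth: Optional[int] = None
    vaf: Optional[float] = None

    def __post_init__(self):
        if self.depth is not None and self.depth <= 0:
            raise ValidationError(f"depth must be positive, got {self.depth}")
        if self.alt_count is not None and self.alt_count < 0:
            raise ValidationError(f"alt_count must be non-negative, got {self.alt_count}")
        if (
            self.alt_count is not None
            and self.depth is not None
            and self.alt_count > self.depth
        ):
            raise ValidationError(
                f"alt_count {self.alt_count} exceeds depth {self.depth}"
            )
        if self.vaf is not None and not (0.0 <= self.vaf <= 1.0):
            raise ValidationError(f"vaf must lie in [0,1], got {self.vaf}")


def infer_variant_type(ref: str, alt: str) -> VariantType:
    """SNV iff both alleles are single bases; longer alt = INS, longer ref = DEL."""
    ref = ref.strip("-") or ""
    alt = alt.strip("-") or ""
    if len(ref) == 1 and len(alt) == 1:
        return VariantType.SNV
    if len(alt) > len(ref):
        return VariantType.INS
    return VariantType.DEL


_HLA_RE = re.compile(r"^(?:HLA-?)?([ABC])\*?(\d{2,3}):?(\d{2,3})$")


def normalize_hla(allele: str) -> str:
    """Canonicalize a class-I allele name to ``HLA-A*02:01`` form.

    netMHCpan dialects write ``HLA-A02:01``, ``HLA-A*02:01`` or ``A0201``;
    all are accepted.
    """
    s = allele.strip().replace(" ", "")
    m = _HLA_RE.match(s)
    if m is None:
        # four+four digit compact form, e.g. A0201
        m2 = re.match(r"^(?:HLA-?)?([ABC])\*?(\d{2})(\d{2})$", s)
        if m2 is None:
            raise ValidationError(f"unrecognized HLA class-I allele: {allele!r}")
        locus, g, p = m2.groups()
    else:
        locus, g, p = m.groups()
    return f"HLA-{locus}*{int(g):02d}:{int(p):02d}"


class Gender(str, Enum):
    MALE = "male"
    FEMALE = "female"


class DiseaseStage(str, Enum):
    MGUS = "MGUS"
    NDMM = "NDMM"
    RRMM = "RRMM"


class LightChain(str, Enum):
    KAPPA = "kappa"
    LAMBDA = "lambda"
    NONE = "none"


LYMPHOCYTE_SUBSETS = ("CD3", "CD4", "CD8", "CD19", "NK")


@dataclass
class PatientProfile:
    """Everything the pipeline knows about one patient."""

    patient_id: str
    disease_stage: Optional[DiseaseStage] = None
    iss_stage: Optional[str] = None  # "I" | "II" | "III"
    variants: list[SomaticVariant] = field(default_factory=list)
    hla_alleles: list[str] = field(default_factory=list)
    age: Optional[float] = None
    gender: Optional[Gender] = None
    ecog: Optional[int] = None
    fish_high_risk: Optional[bool] = None
    hyperdiploid: Optional[bool] = None
    light_chain: Optional[LightChain] = None
    pfs_months: Optional[float] = None
    pfs_event: Optional[bool] = None
    best_response: Optional[str] = None  # ">=VGPR" | "<VGPR"
    lymphocyte_fractions: dict[str, float] = field(default_factory=dict)
    hla_loh: Optional[bool] = None

    def __post_init__(self):
        if self.pfs_months is not None and self.pfs_months < 0:
            raise ValidationError("pfs_months must be non-negative")
        self.hla_alleles = [normalize_hla(a) for a in self.hla_alleles]
        for v in self.variants:
            if v.patient_id != self.patient_id:
                raise ValidationError(
                    f"variant patient_id {v.patient_id!r} does not match {self.patient_id!r}"
                )


@dataclass(frozen=True)
class BindingRecord:
    """One peptide x allele MHC-I binding prediction (percentile rank)."""

    peptide: str
    allele: str
    rank_percent: float
    kd_nm: Optional[float] = None

    def __post_init__(self):
        if not re.fullmatch(r"[ACDEFGHIKLMNPQRSTVWY]+", self.peptide):
            raise ValidationError(f"peptide has non-canonical residues: {self.peptide!r}")
        if not math.isfinite(self.rank_percent) or self.rank_percent < 0:
            raise ValidationError(f"rank_percent must be finite and >= 0")


# ---------------------------------------------------------------------------
# variant tables

SIMPLE_TSV_COLUMNS = [
    "patient_id",
    "chrom",
    "pos",
    "ref",
    "alt",
    "gene",
    "variant_class",
    "alt_count",
    "depth",
    "vaf",
]

_MAF_REQUIRED = [
    "Hugo_Symbol",
    "Chromosome",
    "Start_Position",
    "Reference_Allele",
    "Tumor_Seq_Allele2",
    "Variant_Classification",
    "t_alt_count",
    "t_depth",
]


@dataclass
class ParseReport:
    n_rows: int = 0
    n_parsed: int = 0
    n_skipped: int = 0
    skipped_reasons: list[str] = field(default_factory=list)


def _finish_variant(
    patient_id, chrom, pos, ref, alt, gene, vclass, alt_count, depth, vaf_col
) -> SomaticVariant:
    vaf = vaf_col
    if alt_count is not None and depth is not None:
        vaf_counts = alt_count / depth
        if vaf is None:
            vaf = vaf_counts
        elif abs(vaf - vaf_counts) > 1e-6:
            # explicit VAF wins; upstream rounding is common
            warnings.warn(
                f"VAF column ({vaf}) inconsistent with counts ({vaf_counts:.6f}) "
                f"at {chrom}:{pos}; keeping VAF column",
                stacklevel=3,
            )
    return SomaticVariant(
        patient_id=patient_id,
        chrom=str(chrom),
        pos=int(pos),
        ref=ref,
        alt=alt,
        gene=gene,
        variant_class=vclass,
        variant_type=infer_variant_type(ref, alt),
        alt_count=alt_count,
        depth=depth,
        vaf=vaf,
    )


def _parse_class(raw: str) -> VariantClass:
    key = raw.strip().lower()
    try:
        return VariantClass(key)
    except ValueError:
        return _MAF_CLASS_MAP.get(key, VariantClass.OTHER)


def read_variant_table(
    path: str | Path,
    dialect: str = "simple_tsv",
    patient_id: str | None = None,
    report: ParseReport | None = None,
) -> list[SomaticVariant]:
    """Read somatic calls from ``simple_tsv``, ``maf`` or ``vcf``.

    Rows with depth 0 or unparseable alleles are skipped and tallied in
    *report*; an empty table returns an empty list. For VCF input,
    *patient_id* names the profile the calls belong to (defaults to the
    tumor sample name) and counts are taken from the tumor sample's AD/DP.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if report is None:
        report = ParseReport()
    if dialect == "vcf":
        return _read_vcf(path, patient_id, report)
    if dialect not in ("simple_tsv", "maf"):
        raise FormatError(f"unknown dialect {dialect!r}")

    with open(path, newline="") as fh:
        rows = list(csv.DictReader(fh, delimiter="\t"))
    if not rows:
        return []
    header = rows[0].keys()
    required = _MAF_REQUIRED if dialect == "maf" else SIMPLE_TSV_COLUMNS[:9]
    for col in required:
        if col not in header:
            raise FormatError(f"missing required column {col!r} for dialect {dialect!r}")

    out: list[SomaticVariant] = []
    for row in rows:
        report.n_rows += 1
        try:
            if dialect == "maf":
                pid = patient_id or row.get("Tumor_Sample_Barcode", "unknown")
                v = _finish_variant(
                    pid,
                    row["Chromosome"],
                    row["Start_Position"],
                    row["Reference_Allele"].strip().upper(),
                    row["Tumor_Seq_Allele2"].strip().upper(),
                    row["Hugo_Symbol"],
                    _parse_class(row["Variant_Classification"]),
                    int(row["t_alt_count"]),
                    int(row["t_depth"]),
                    None,
                )
            else:
                vaf_raw = row.get("vaf", "")
                alt_raw = row.get("alt_count", "")
                depth_raw = row.get("depth", "")
                v = _finish_variant(
                    row["patient_id"],
                    row["chrom"],
                    row["pos"],
                    row["ref"].strip().upper(),
                    row["alt"].strip().upper(),
                    row["gene"],
                    _parse_class(row["variant_class"]),
                    int(alt_raw) if alt_raw not in ("", None) else None,
                    int(depth_raw) if depth_raw not in ("", None) else None,
                    float(vaf_raw) if vaf_raw not in ("", None) else None,
                )
            if not re.fullmatch(r"[ACGT]+", v.ref) or not re.fullmatch(r"[ACGT]+", v.alt):
                raise ValidationError(f"unparseable alleles {v.ref!r}>{v.alt!r}")
        except (ValidationError, ValueError, ZeroDivisionError) as exc:
            report.n_skipped += 1
            report.skipped_reasons.append(str(exc))
            continue
        report.n_parsed += 1
        out.append(v)
    return out


def _read_vcf(path: Path, patient_id: str | None, report: ParseReport) -> list[SomaticVariant]:
    import pysam

    out: list[SomaticVariant] = []
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        if not samples:
            raise FormatError("VCF has no sample columns; tumor AD/DP required")
        tumor = samples[-1]  # convention: tumor sample last
        pid = patient_id or tumor
        for rec in vf:
            report.n_rows += 1
            try:
                if rec.alts is None or len(rec.alts) != 1:
                    raise ValidationError("multi-allelic or alt-less record")
                sample = rec.samples[tumor]
                ad = sample.get("AD")
                depth = sample.get("DP")
                alt_count = int(ad[1]) if ad is not None and len(ad) > 1 else None
                depth = int(depth) if depth is not None else (
                    int(sum(ad)) if ad is not None else None
                )
                gene = rec.info.get("GENE", "unknown")
                vclass = _parse_class(str(rec.info.get("VCLASS", "other")))
                v = _finish_variant(
                    pid, rec.chrom, rec.pos, rec.ref, rec.alts[0], gene,
                    vclass, alt_count, depth, None,
                )
            except (ValidationError, ValueError, TypeError) as exc:
                report.n_skipped += 1
                report.skipped_reasons.append(str(exc))
                continue
            report.n_parsed += 1
            out.append(v)
    return out


def write_variant_table(variants: Iterable[SomaticVariant], path: str | Path) -> None:
    """Write calls in the simple_tsv dialect (round-trips bit-exactly)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(SIMPLE_TSV_COLUMNS)
        for v in variants:
            w.writerow(
                [
                    v.patient_id,
                    v.chrom,
                    v.pos,
                    v.ref,
                    v.alt,
                    v.gene,
                    v.variant_class.value,
                    "" if v.alt_count is None else v.alt_count,
                    "" if v.depth is None else v.depth,
                    "" if v.vaf is None else repr(v.vaf),
                ]
            )


# ---------------------------------------------------------------------------
# binding tables (netMHCpan-style)

_RANK_COLS = ("%Rank_EL", "%Rank", "Rank_EL", "Rank", "rank_percent", "rank")
_PEPTIDE_COLS = ("Peptide", "peptide")
_ALLELE_COLS = ("MHC", "HLA", "allele", "Allele")
_AFF_COLS = ("Aff(nM)", "Affinity(nM)", "kd_nm")


def read_binding_table(path: str | Path) -> list[BindingRecord]:
    """Parse a netMHCpan-style whitespace/tab table of peptide ranks.

    Comment lines (``#``) and separator lines are tolerated; allele names
    are normalized on read.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    records: list[BindingRecord] = []
    header: list[str] | None = None
    idx: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or set(line) <= {"-", " "}:
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if header is None:
                header = parts
                for want, candidates in (
                    ("rank", _RANK_COLS),
                    ("peptide", _PEPTIDE_COLS),
                    ("allele", _ALLELE_COLS),
                ):
                    for c in candidates:
                        if c in header:
                            idx[want] = header.index(c)
                            break
                if "rank" not in idx:
                    raise FormatError(
                        f"no recognizable %Rank column in header {header!r}"
                    )
                if "peptide" not in idx or "allele" not in idx:
                    raise FormatError("binding table needs peptide and allele columns")
                for c in _AFF_COLS:
                    if c in header:
                        idx["kd"] = header.index(c)
                        break
                continue
            kd = float(parts[idx["kd"]]) if "kd" in idx else None
            records.append(
                BindingRecord(
                    peptide=parts[idx["peptide"]],
                    allele=normalize_hla(parts[idx["allele"]]),
                    rank_percent=float(parts[idx["rank"]]),
                    kd_nm=kd,
                )
            )
    if header is None:
        raise FormatError(f"{path}: empty binding table (no header)")
    return records


# ---------------------------------------------------------------------------
# clinical tables

_TRUTHY = {"1", "true", "yes", "y"}
_FALSY = {"0", "false", "no", "n"}


def _parse_bool(raw: str, col: str) -> bool:
    s = raw.strip().lower()
    if s in _TRUTHY:
        return True
    if s in _FALSY:
        return False
    raise ValidationError(f"column {col!r}: cannot interpret {raw!r} as boolean")


def read_clinical_table(path: str | Path) -> list[PatientProfile]:
    """Read the clinical CSV into partial profiles (no variants attached).

    Categorical fields are validated eagerly; a bad category raises a
    ``ValidationError`` naming the column and value. Missing optional
    fields stay unset.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    with open(path, newline="") as fh:
        rows = list(csv.DictReader(fh))
    if rows and "patient_id" not in rows[0]:
        raise FormatError("clinical table lacks a patient_id column")

    profiles: list[PatientProfile] = []
    seen: set[str] = set()
    for row in rows:
        pid = row["patient_id"].strip()
        if pid in seen:
            raise FormatError(f"duplicate patient_id {pid!r}")
        seen.add(pid)
        p = PatientProfile(patient_id=pid)

        def get(col):
            raw = row.get(col)
            return raw.strip() if raw is not None and raw.strip() != "" else None

        if (v := get("disease_stage")) is not None:
            try:
                p.disease_stage = DiseaseStage(v)
            except ValueError:
                raise ValidationError(f"column 'disease_stage': unknown value {v!r}")
        if (v := get("iss")) or (v := get("iss_stage")):
            if v not in ("I", "II", "III"):
                raise ValidationError(f"column 'iss': unknown value {v!r}")
            p.iss_stage = v
        if (v := get("gender")) is not None:
            try:
                p.gender = Gender(v.lower())
            except ValueError:
                raise ValidationError(f"column 'gender': unknown value {v!r}")
        if (v := get("light_chain")) is not None:
            try:
                p.light_chain = LightChain(v.lower())
            except ValueError:
                raise ValidationError(f"column 'light_chain': unknown value {v!r}")
        if (v := get("age")) is not None:
            p.age = float(v)
        if (v := get("ecog")) is not None:
            p.ecog = int(v)
            if not 0 <= p.ecog <= 4:
                raise ValidationError(f"column 'ecog': out of range {v!r}")
        for col, attr in (
            ("fish_high_risk", "fish_high_risk"),
            ("hyperdiploid", "hyperdiploid"),
            ("hla_loh", "hla_loh"),
        ):
            if (v := get(col)) is not None:
                setattr(p, attr, _parse_bool(v, col))
        if (v := get("pfs")) or (v := get("pfs_months")):
            p.pfs_months = float(v)
        if (v := get("event")) or (v := get("pfs_event")):
            p.pfs_event = _parse_bool(v, "pfs_event")
        if (v := get("best_response")) is not None:
            if v not in (">=VGPR", "<VGPR"):
                raise ValidationError(f"column 'best_response': unknown value {v!r}")
            p.best_response = v
        if (v := get("hla_alleles")) is not None:
            p.hla_alleles = [normalize_hla(a) for a in v.split(";") if a.strip()]
        for subset in LYMPHOCYTE_SUBSETS:
            if (v := get(subset)) is not None:
                p.lymphocyte_fractions[subset] = float(v)
        profiles.append(p)
    return profiles
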