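import numpy as np
import pytest

from mmith.io_variants import (
    SomaticVariant,
    VariantClass,
    VariantType,
    infer_variant_type,
)


def make_variant(
    patient_id="P1",
    chrom="1",
    pos=1000,
    ref="G",
    alt="A",
    gene="KRAS",
    variant_class=VariantClass.MISSENSE,
    alt_count=30,
    depth=100,
    vaf=None,
):
    return SomaticVariant(
        patient_id=patient_id,
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        gene=gene,
        variant_class=variant_class,
        variant_type=infer_variant_type(ref, alt),
        alt_count=alt_count,
        depth=depth,
        vaf=vaf if vaf is not None else (alt_count / depth if depth else None),
    )


@pytest.fixture
def simple_tsv(tmp_path):
    """5-row variant table with one depth=0 row that must be skipped."""
    rows = [
        "patient_id\tchrom\tpos\tref\talt\tgene\tvariant_class\talt_count\tdepth\tvaf",
        "P1\t1\t100\tG\tA\tKRAS\tmissense\t30\t100\t",
        "P1\t2\t200\tC\tT\tTP53\tnonsense\t12\t60\t",
        "P1\t3\t300\tG\tGTT\tNRAS\tframeshift_ins\t20\t80\t",
        "P1\t4\t400\tA\tG\tBRAF\tsilent\t5\t0\t",  # depth 0 -> skipped
        "P1\t5\t500\tT\tC\tDIS3\tmissense\t40\t90\t",
    ]
    path = tmp_path / "variants.tsv"
    path.write_text("\n".join(rows) + "\n")
    return path


@pytest.fixture
def clinical_csv(tmp_path):
    header = (
        "patient_id,disease_stage,iss,age,gender,ecog,fish_high_risk,"
        "hyperdiploid,light_chain,pfs,event,best_response,CD8,NK"
    )
    rows = [header]
    for i in range(7):
        rows.append(
            f"P{i},NDMM,III,6{i},male,1,0,1,kappa,16.7,1,>=VGPR,2{i},1{i}"
        )
    path = tmp_path / "clinical.csv"
    path.write_text("\n".join(rows) + "\n")
    return path


@pytest.fixture
def binding_table(tmp_path):
    lines = [
        "# netMHCpan-style output",
        "Peptide\tMHC\t%Rank_EL",
        "KLDETFFYV\tHLA-A02:01\t0.12",
        "ACDEFGHIK\tHLA-B*07:02\t1.5",
        "SIINFEKLM\tHLA-A02:01\t12.0",
    ]
    path = tmp_path / "binding.tsv"
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20231115)
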