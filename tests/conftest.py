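"""Shared builders for variant fixtures.

All fixtures are generated in memory or in tmp_path; nothing binary is read
from the repository.
"""

from __future__ import annotations

import pytest

from pgxburden.variant_ingest import (
    ANALYSIS_POPULATIONS,
    GLOBAL,
    OTH,
    AlleleCounts,
    TranscriptAnnotation,
    VariantRecord,
)

# chromosomes genotyped per stratum in the default test cohort
DEFAULT_AN = {pop: 1000 for pop in ANALYSIS_POPULATIONS} | {OTH: 100}


def ann(
    gene: str = "GENE1",
    consequence: str = "missense_variant",
    sift: str = "absent",
    polyphen: str = "absent",
    lof: str = "absent",
    transcript: str = "TR1",
    allele: str = "",
) -> TranscriptAnnotation:
    return TranscriptAnnotation(
        transcript_id=transcript,
        consequence=consequence,
        gene=gene,
        sift_category=sift,
        polyphen_category=polyphen,
        lof_flag=lof,
        allele=allele,
    )


def make_record(
    pos: int = 100,
    ref: str = "C",
    alt: str = "T",
    chrom: str = "1",
    ac: dict[str, int] | int = 1,
    an: dict[str, int] | None = None,
    annotations: list[TranscriptAnnotation] | None = None,
    global_an: int | None = None,
) -> VariantRecord:
    """Bi-allelic record with consistent GLOBAL = sum-of-strata counts.

    ``ac`` may be a single count assigned to AFR, or a per-stratum map.
    """
    an_map = dict(DEFAULT_AN if an is None else an)
    if isinstance(ac, int):
        ac_map = {pop: 0 for pop in an_map}
        ac_map["AFR"] = ac
    else:
        ac_map = {pop: ac.get(pop, 0) for pop in an_map}
    counts = {pop: AlleleCounts(ac=ac_map[pop], an=an_map[pop]) for pop in an_map}
    counts[GLOBAL] = AlleleCounts(
        ac=sum(ac_map.values()),
        an=sum(an_map.values()) if global_an is None else global_an,
    )
    if annotations is None:
        annotations = [ann()]
    return VariantRecord(
        chrom=chrom, pos=pos, ref=ref, alt=alt, counts=counts, annotations=annotations
    )


@pytest.fixture
def damaging_annotation() -> TranscriptAnnotation:
    return ann(sift="deleterious", polyphen="probably_damaging")


@pytest.fixture
def lof_annotation() -> TranscriptAnnotation:
    return ann(consequence="stop_gained", lof="HC")
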