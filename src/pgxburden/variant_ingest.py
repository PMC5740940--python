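"""Reading annotated variant files and computing per-population allele frequencies.

Input is a VCF 4.x file carrying aggregate allele counts per population
(``AC_<POP>``/``AN_<POP>`` INFO keys, plus cohort-wide ``AC``/``AN``) and a
pipe-delimited per-transcript annotation key whose field order is declared in
the header line, as in VEP's CSQ. Multi-allelic records are decomposed into
bi-allelic :class:`VariantRecord` objects; indel alleles are normalized to
their minimal representation (shared suffix stripped, then shared prefix).

Coordinates are 1-based throughout, as in the VCF standard.
"""

from __future__ import annotations

import dataclasses
import logging
from collections.abc import Iterable, Iterator, Mapping, Sequence
from pathlib import Path

from cyvcf2 import VCF

logger = logging.getLogger(__name__)

#: The six geographic strata that enter every comparison.
ANALYSIS_POPULATIONS: tuple[str, ...] = ("AFR", "SAS", "EAS", "FIN", "NFE", "AMR")

#: Full-cohort pseudo-population (taken from the file's own AC/AN fields).
GLOBAL = "GLOBAL"

#: Residual stratum: parsed if present, but never enters scoring.
OTH = "OTH"

ALL_POPULATIONS: tuple[str, ...] = ANALYSIS_POPULATIONS + (OTH, GLOBAL)

SIFT_CATEGORIES = frozenset({"deleterious", "tolerated", "absent"})
POLYPHEN_CATEGORIES = frozenset(
    {"probably_damaging", "possibly_damaging", "benign", "absent"}
)
LOF_FLAGS = frozenset({"HC", "LC", "absent"})


class IngestError(ValueError):
    """A variant record violates the input contract."""


class FrequencyUndefinedError(IngestError):
    """Allele frequency requested where no chromosome was genotyped (AN = 0)."""


@dataclasses.dataclass(frozen=True, slots=True)
class AlleleCounts:
    """Aggregate allele count (AC) and allele number (AN) for one stratum."""

    ac: int
    an: int

    def __post_init__(self) -> None:
        if self.ac < 0 or self.an < 0:
            raise IngestError(f"negative allele counts: AC={self.ac}, AN={self.an}")
        if self.ac > self.an:
            raise IngestError(f"AC={self.ac} exceeds AN={self.an}")


def allele_frequency(counts: AlleleCounts) -> float:
    """AF = AC / AN.

    Raises
    ------
    FrequencyUndefinedError
        If ``an == 0``; callers must treat the variant as unobserved in that
        stratum rather than assigning it a frequency.
    """
    if counts.an == 0:
        raise FrequencyUndefinedError("AN = 0: allele frequency undefined")
    return counts.ac / counts.an


def variant_key(chrom: str, pos: int, ref: str, alt: str) -> str:
    """Canonical identifier ``chrom:pos:ref:alt``; injective over distinct tuples."""
    chrom, ref, alt = str(chrom), str(ref), str(alt)
    if not chrom or not ref or not alt:
        raise IngestError("variant key fields must be nonempty")
    if pos < 1:
        raise IngestError(f"position must be >= 1, got {pos}")
    return f"{chrom}:{pos}:{ref}:{alt}"


def _normalize_category(value: str | None, vocab: frozenset[str]) -> str:
    """Map empty/None to 'absent' and strip VEP-style '(score)' suffixes."""
    if not value:
        return "absent"
    value = value.split("(", 1)[0].strip()
    if not value:
        return "absent"
    if value not in vocab:
        raise IngestError(f"unknown category {value!r}; expected one of {sorted(vocab)}")
    return value


@dataclasses.dataclass(frozen=True, slots=True)
class TranscriptAnnotation:
    """Functional annotation of one alt allele on one transcript."""

    transcript_id: str
    consequence: str
    gene: str
    sift_category: str = "absent"
    polyphen_category: str = "absent"
    lof_flag: str = "absent"
    allele: str = ""

    def __post_init__(self) -> None:
        if not self.gene:
            raise IngestError("annotation gene symbol must be nonempty")
        object.__setattr__(
            self, "sift_category", _normalize_category(self.sift_category, SIFT_CATEGORIES)
        )
        object.__setattr__(
            self,
            "polyphen_category",
            _normalize_category(self.polyphen_category, POLYPHEN_CATEGORIES),
        )
        object.__setattr__(self, "lof_flag", _normalize_category(self.lof_flag, LOF_FLAGS))

    @property
    def consequences(self) -> tuple[str, ...]:
        """VEP joins multiple consequence terms with '&'."""
        return tuple(self.consequence.split("&"))


@dataclasses.dataclass(slots=True)
class VariantRecord:
    """One bi-allelic variant with per-population counts and annotations."""

    chrom: str
    pos: int
    ref: str
    alt: str
    counts: dict[str, AlleleCounts]
    annotations: list[TranscriptAnnotation] = dataclasses.field(default_factory=list)
    cadd_scaled: float | None = None
    evmutation_score: float | None = None

    @property
    def key(self) -> str:
        return variant_key(self.chrom, self.pos, self.ref, self.alt)

    def af(self, population: str = GLOBAL) -> float | None:
        """Allele frequency in a stratum, or None where AN = 0 / stratum absent."""
        counts = self.counts.get(population)
        if counts is None or counts.an == 0:
            return None
        return allele_frequency(counts)

    @property
    def genes(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for ann in self.annotations:
            seen.setdefault(ann.gene)
        return tuple(seen)


@dataclasses.dataclass(slots=True)
class RawVariant:
    """A possibly multi-allelic record as parsed from disk, before decomposition.

    ``ac`` maps population → per-alt allele counts (one entry per alt allele,
    VCF ``Number=A`` semantics); ``an`` maps population → the shared allele
    number for the locus.
    """

    chrom: str
    pos: int
    ref: str
    alts: list[str]
    ac: dict[str, tuple[int, ...]]
    an: dict[str, int]
    annotations: list[TranscriptAnnotation] = dataclasses.field(default_factory=list)


def trim_allele(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Minimal representation: strip the shared suffix, then the shared prefix.

    Prefix trimming advances ``pos``; at least one base is kept on each allele.
    """
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def _annotation_matches(ann: TranscriptAnnotation, ref: str, alt: str) -> bool:
    # VEP reports the trimmed alt for indels ('-' for pure deletions); accept
    # the exact alt string and both common indel spellings.
    if ann.allele == alt:
        return True
    if len(ref) > 1 or len(alt) > 1:
        if len(alt) > 1 and ann.allele == alt[1:]:
            return True
        if alt == ref[0] and ann.allele == "-":
            return True
    return False


def split_multiallelic(raw: RawVariant) -> list[VariantRecord]:
    """Decompose a raw record into one bi-allelic :class:`VariantRecord` per alt.

    Each child inherits the shared AN of its population and the AC entry for
    its own alt allele. Annotations are assigned by allele-string matching;
    for single-alt records unmatched annotations are assigned to the only
    child (the common case for files that omit the CSQ Allele field).
    """
    if not raw.alts:
        raise IngestError(f"record {raw.chrom}:{raw.pos} has no alt allele")
    n_alt = len(raw.alts)
    for pop, acs in raw.ac.items():
        if len(acs) != n_alt:
            raise IngestError(
                f"record {raw.chrom}:{raw.pos}: population {pop} has "
                f"{len(acs)} AC values for {n_alt} alt alleles"
            )
    records = []
    for i, alt in enumerate(raw.alts):
        counts = {}
        for pop, an in raw.an.items():
            acs = raw.ac.get(pop)
            if acs is None:
                raise IngestError(
                    f"record {raw.chrom}:{raw.pos}: missing AC for population {pop}"
                )
            counts[pop] = AlleleCounts(ac=acs[i], an=an)
        anns = [a for a in raw.annotations if _annotation_matches(a, raw.ref, alt)]
        if not anns and n_alt == 1:
            anns = list(raw.annotations)
        pos, ref, alt_trim = trim_allele(raw.pos, raw.ref, alt)
        records.append(
            VariantRecord(chrom=raw.chrom, pos=pos, ref=ref, alt=alt_trim,
                          counts=counts, annotations=anns)
        )
    return records


# ---------------------------------------------------------------------------
# VCF parsing
# ---------------------------------------------------------------------------

CSQ_FIELDS_DEFAULT = ("Allele", "Gene", "Feature", "Consequence", "SIFT", "PolyPhen", "LoF")


def _csq_format(vcf: VCF, info_key: str) -> list[str]:
    header = vcf.get_header_type(info_key)
    desc = header.get("Description", "")
    if "Format:" in desc:
        fmt = desc.split("Format:", 1)[1].strip().strip('"').strip()
        return fmt.split("|")
    logger.warning("no Format declaration for %s; assuming default field order", info_key)
    return list(CSQ_FIELDS_DEFAULT)


def _parse_annotations(csq_value: str, fields: Sequence[str]) -> list[TranscriptAnnotation]:
    idx = {name: i for i, name in enumerate(fields)}

    def get(parts: list[str], name: str) -> str:
        i = idx.get(name)
        return parts[i] if i is not None and i < len(parts) else ""

    annotations = []
    for entry in csq_value.split(","):
        parts = entry.split("|")
        gene = get(parts, "Gene") or get(parts, "SYMBOL")
        if not gene:
            continue
        annotations.append(
            TranscriptAnnotation(
                transcript_id=get(parts, "Feature"),
                consequence=get(parts, "Consequence"),
                gene=gene,
                sift_category=get(parts, "SIFT"),
                polyphen_category=get(parts, "PolyPhen"),
                lof_flag=get(parts, "LoF"),
                allele=get(parts, "Allele"),
            )
        )
    return annotations


def _as_tuple(value) -> tuple[int, ...]:
    if value is None:
        raise KeyError("missing AC")
    if isinstance(value, (tuple, list)):
        return tuple(int(v) for v in value)
    # scalar: length checked against n_alt by split_multiallelic
    return (int(value),)


def read_vcf(
    path: str | Path,
    annotation_key: str = "CSQ",
    populations: Sequence[str] = ANALYSIS_POPULATIONS + (OTH,),
    cadd_scores: Mapping[str, float] | None = None,
    evmutation_scores: Mapping[str, float] | None = None,
) -> Iterator[VariantRecord]:
    """Stream bi-allelic records from an annotated population VCF.

    Multi-allelic lines are split; records whose per-alt AC is missing are
    rejected with a diagnostic (logged and skipped). Optional score maps keyed
    by :func:`variant_key` attach CADD / EVmutation scores after splitting and
    normalization.
    """
    vcf = VCF(str(path))
    fields = _csq_format(vcf, annotation_key)
    for rec in vcf:
        alts = list(rec.ALT)
        n_alt = len(alts)
        an: dict[str, int] = {}
        ac: dict[str, tuple[int, ...]] = {}
        try:
            an[GLOBAL] = int(rec.INFO["AN"])
            ac[GLOBAL] = _as_tuple(rec.INFO["AC"])
            for pop in populations:
                an_val = rec.INFO.get(f"AN_{pop}")
                ac_val = rec.INFO.get(f"AC_{pop}")
                if an_val is None and ac_val is None:
                    continue  # stratum absent from this file
                an[pop] = int(an_val) if an_val is not None else 0
                ac[pop] = _as_tuple(ac_val)
        except KeyError as exc:
            logger.warning("rejecting %s:%s: %s", rec.CHROM, rec.POS, exc)
            continue
        csq = rec.INFO.get(annotation_key)
        annotations = _parse_annotations(csq, fields) if csq else []
        raw = RawVariant(chrom=rec.CHROM, pos=rec.POS, ref=rec.REF, alts=alts,
                         ac=ac, an=an, annotations=annotations)
        try:
            children = split_multiallelic(raw)
        except IngestError as exc:
            logger.warning("rejecting %s:%s: %s", rec.CHROM, rec.POS, exc)
            continue
        for child in children:
            if cadd_scores is not None:
                child.cadd_scaled = cadd_scores.get(child.key)
            if evmutation_scores is not None:
                child.evmutation_score = evmutation_scores.get(child.key)
            yield child


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------

_VCF_HEADER_TEMPLATE = """\
##fileformat=VCFv4.2
{contigs}##INFO=<ID=AC,Number=A,Type=Integer,Description="Alternate allele count, full cohort">
##INFO=<ID=AN,Number=1,Type=Integer,Description="Allele number, full cohort">
{pop_info}##INFO=<ID=CSQ,Number=.,Type=String,Description="Consequence annotations. Format: {fmt}">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def write_vcf(records: Iterable[VariantRecord], path: str | Path) -> None:
    """Write bi-allelic records in the same dialect :func:`read_vcf` consumes."""
    records = list(records)
    pops = [p for p in (*ANALYSIS_POPULATIONS, OTH)
            if any(p in r.counts for r in records)]
    contigs = "".join(
        f"##contig=<ID={c}>\n" for c in dict.fromkeys(r.chrom for r in records)
    )
    pop_info = "".join(
        f'##INFO=<ID=AC_{p},Number=A,Type=Integer,Description="Alternate allele count, {p}">\n'
        f'##INFO=<ID=AN_{p},Number=1,Type=Integer,Description="Allele number, {p}">\n'
        for p in pops
    )
    fmt = "|".join(CSQ_FIELDS_DEFAULT)
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER_TEMPLATE.format(contigs=contigs, pop_info=pop_info, fmt=fmt))
        for rec in records:
            fh.write(format_vcf_line(rec, pops) + "\n")


def format_vcf_line(rec: VariantRecord, pops: Sequence[str]) -> str:
    info = [f"AC={rec.counts[GLOBAL].ac}", f"AN={rec.counts[GLOBAL].an}"]
    for p in pops:
        if p in rec.counts:
            info.append(f"AC_{p}={rec.counts[p].ac}")
            info.append(f"AN_{p}={rec.counts[p].an}")
    if rec.annotations:
        entries = ",".join(
            "|".join(
                [a.allele or rec.alt, a.gene, a.transcript_id, a.consequence,
                 "" if a.sift_category == "absent" else a.sift_category,
                 "" if a.polyphen_category == "absent" else a.polyphen_category,
                 "" if a.lof_flag == "absent" else a.lof_flag]
            )
            for a in rec.annotations
        )
        info.append(f"CSQ={entries}")
    return "\t".join(
        [rec.chrom, str(rec.pos), ".", rec.ref, rec.alt, ".", ".", ";".join(info)]
    )


def load_score_table(path: str | Path) -> dict[str, float]:
    """Read a two-column TSV ``variant_key<TAB>score`` (header optional)."""
    scores: dict[str, float] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, value = line.split("\t")[:2]
            if key == "variant_key":
                continue
            scores[key] = float(value)
    return scores


def write_variant_table(records: Iterable[VariantRecord], path: str | Path) -> None:
    """Tab-separated table: one row per bi-allelic variant per population with AF."""
    with open(path, "w") as fh:
        fh.write("variant_key\tgene\tpopulation\tac\tan\taf\n")
        for rec in records:
            genes = ",".join(rec.genes) or "."
            for pop in (GLOBAL, *ANALYSIS_POPULATIONS, OTH):
                counts = rec.counts.get(pop)
                if counts is None:
                    continue
                af = "" if counts.an == 0 else f"{counts.ac / counts.an:.10g}"
                fh.write(f"{rec.key}\t{genes}\t{pop}\t{counts.ac}\t{counts.an}\t{af}\n")
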