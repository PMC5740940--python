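"""Core burden statistics: CAP, DRP and their decompositions.

CAP(g) = 1 − ∏_{a∈A_g} (1 − AF(a))² is the probability that a diploid
individual carries at least one alternate allele among a gene's functional
variants, assuming Hardy–Weinberg independence of the two alleles at a locus
and independence across loci. DRP(D) extends the product over all
pharmacological target genes G of a drug.

Products are accumulated in log space via ``log1p`` so that thousands of very
rare alleles do not underflow. All loci are treated as diploid, including sex
chromosomes (the aggregate AN fields of the source data absorb ploidy); a
warning is emitted for X/Y.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from collections.abc import Iterable, Mapping, Sequence

import pandas as pd

from pgxburden.functional_classes import (
    FUNCTIONAL_CLASSES,
    ClassifyConfig,
    DEFAULT_CLASSIFY,
    FunctionalClass,
    classify,
)
from pgxburden.variant_ingest import (
    ANALYSIS_POPULATIONS,
    GLOBAL,
    AlleleCounts,
    VariantRecord,
)

logger = logging.getLogger(__name__)

RARE_AF_THRESHOLD = 0.001  # AF < 0.1% is "rare"


def cap(afs: Iterable[float]) -> float:
    """Carrier probability 1 − ∏ (1 − AF)²; empty input → 0.0.

    Accumulated as ``1 − exp(2 Σ log1p(−AF))`` for numerical stability.
    """
    log_hom_ref = 0.0
    for af in afs:
        if not 0.0 <= af <= 1.0:
            raise ValueError(f"allele frequency {af} outside [0, 1]")
        if af == 1.0:
            return 1.0
        log_hom_ref += math.log1p(-af)
    return -math.expm1(2.0 * log_hom_ref) + 0.0  # normalize -0.0


@dataclasses.dataclass(frozen=True, slots=True)
class GeneVariant:
    """One functional variant as seen by the scoring layer."""

    key: str
    functional_class: FunctionalClass
    counts: Mapping[str, AlleleCounts]

    def af(self, population: str) -> float | None:
        c = self.counts.get(population)
        if c is None or c.an == 0:
            return None
        return c.ac / c.an


@dataclasses.dataclass(slots=True)
class GeneVariantTable:
    """Per-gene collection of functional variants with per-population counts."""

    gene: str
    variants: list[GeneVariant] = dataclasses.field(default_factory=list)
    protein_length: int | None = None

    def __post_init__(self) -> None:
        keys = [v.key for v in self.variants]
        if len(keys) != len(set(keys)):
            raise ValueError(f"duplicate variant keys in gene {self.gene}")
        if self.protein_length is not None and self.protein_length <= 0:
            raise ValueError("protein_length must be positive")

    def afs(
        self,
        population: str = GLOBAL,
        classes: Sequence[FunctionalClass] = FUNCTIONAL_CLASSES,
    ) -> list[float]:
        """AFs of variants in the given classes; undefined AFs contribute nothing."""
        out = []
        for v in self.variants:
            if v.functional_class not in classes:
                continue
            af = v.af(population)
            if af is not None:
                out.append(af)
        return out


def cap_gene(table: GeneVariantTable, population: str = GLOBAL) -> float:
    """CAP over all functional variants of a gene in one population."""
    return cap(table.afs(population))


def cap_lof(table: GeneVariantTable, population: str = GLOBAL) -> float:
    """CAP restricted to the loss-of-function subset."""
    return cap(table.afs(population, classes=(FunctionalClass.LOF,)))


def drp(
    target_tables: Mapping[str, GeneVariantTable],
    population: str = GLOBAL,
    classes: Sequence[FunctionalClass] = FUNCTIONAL_CLASSES,
    deduplicate_across_genes: bool = False,
) -> float:
    """DRP = 1 − ∏_g ∏_{a∈A_g} (1 − AF(a))² over a drug's target genes.

    Follows the formula literally: a variant annotated to two target genes of
    the same drug contributes once per gene, unless
    ``deduplicate_across_genes`` collapses the union by variant key.
    """
    if not target_tables:
        raise ValueError("drug has no target genes; unscorable")
    log_hom_ref = 0.0
    seen: set[str] = set()
    for gene in sorted(target_tables):
        table = target_tables[gene]
        for v in table.variants:
            if v.functional_class not in classes:
                continue
            if deduplicate_across_genes:
                if v.key in seen:
                    continue
                seen.add(v.key)
            af = v.af(population)
            if af is None:
                continue
            if af == 1.0:
                return 1.0
            log_hom_ref += math.log1p(-af)
    return -math.expm1(2.0 * log_hom_ref) + 0.0  # normalize -0.0


def rare_contribution(
    table: GeneVariantTable,
    population: str = GLOBAL,
    rare_threshold: float = RARE_AF_THRESHOLD,
) -> tuple[float, float]:
    """(CAP over rare variants, CAP over common variants).

    Rare means AF < threshold; boundary AF == threshold counts as common.
    Satisfies 1 − (1 − cap_rare)(1 − cap_common) = CAP(all).
    """
    if not 0 < rare_threshold < 1:
        raise ValueError("rare_threshold must be in (0, 1)")
    afs = table.afs(population)
    return (
        cap([af for af in afs if af < rare_threshold]),
        cap([af for af in afs if af >= rare_threshold]),
    )


def rare_common_fraction(
    table: GeneVariantTable,
    population: str = GLOBAL,
    threshold: float = RARE_AF_THRESHOLD,
) -> tuple[float, float]:
    """Fractions of a gene's functional variants that are rare / common, by count."""
    afs = table.afs(population)
    if not afs:
        raise ValueError(f"gene {table.gene} has no scorable variants in {population}")
    n_rare = sum(1 for af in afs if af < threshold)
    return n_rare / len(afs), (len(afs) - n_rare) / len(afs)


def variants_per_residue(table: GeneVariantTable) -> float | None:
    """Functional variants per protein residue; None when length unknown."""
    if table.protein_length is None:
        return None
    n = sum(1 for v in table.variants if v.functional_class in FUNCTIONAL_CLASSES)
    return n / table.protein_length


@dataclasses.dataclass(frozen=True, slots=True)
class RiskResult:
    """A CAP/DRP value for one (gene-or-drug, population) pair."""

    subject: str
    population: str
    score: float
    variant_basis: str  # functional | lof_only | rare_only | common_only
    n_variants: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"score {self.score} outside [0, 1]")
        if self.n_variants < 0:
            raise ValueError("n_variants must be >= 0")


def gene_risk(table: GeneVariantTable, population: str = GLOBAL) -> RiskResult:
    afs = table.afs(population)
    return RiskResult(
        subject=table.gene,
        population=population,
        score=cap(afs),
        variant_basis="functional",
        n_variants=len(afs),
    )


# ---------------------------------------------------------------------------
# Table construction and report frames
# ---------------------------------------------------------------------------

def build_gene_tables(
    records: Iterable[VariantRecord],
    genes: Iterable[str] | None = None,
    classify_config: ClassifyConfig = DEFAULT_CLASSIFY,
    protein_lengths: Mapping[str, int] | None = None,
) -> dict[str, GeneVariantTable]:
    """Group classified variants by annotated gene.

    A variant annotated to several genes enters each gene's table. When
    ``genes`` is given, tables are restricted to (and created for every
    member of) that panel.
    """
    panel = set(genes) if genes is not None else None
    tables: dict[str, GeneVariantTable] = {}
    lengths = protein_lengths or {}
    if panel is not None:
        for g in panel:
            tables[g] = GeneVariantTable(gene=g, protein_length=lengths.get(g))
    for rec in records:
        fclass = classify(rec, classify_config)
        if rec.chrom in ("X", "Y", "chrX", "chrY"):
            logger.warning("%s: sex chromosome treated as diploid", rec.key)
        for gene in rec.genes:
            if panel is not None and gene not in panel:
                continue
            table = tables.setdefault(
                gene, GeneVariantTable(gene=gene, protein_length=lengths.get(gene))
            )
            if any(v.key == rec.key for v in table.variants):
                continue
            table.variants.append(
                GeneVariant(key=rec.key, functional_class=fclass, counts=dict(rec.counts))
            )
    return tables


def gene_scores_frame(
    tables: Mapping[str, GeneVariantTable],
    populations: Sequence[str] = (GLOBAL, *ANALYSIS_POPULATIONS),
    rare_threshold: float = RARE_AF_THRESHOLD,
) -> pd.DataFrame:
    """gene × population CAP table (columns: gene, population, cap, cap_lof,
    cap_rare, cap_common, n_variants, variants_per_residue)."""
    rows = []
    for gene in sorted(tables):
        table = tables[gene]
        vpr = variants_per_residue(table)
        for pop in populations:
            cap_rare, cap_common = rare_contribution(table, pop, rare_threshold)
            rows.append(
                {
                    "gene": gene,
                    "population": pop,
                    "cap": cap_gene(table, pop),
                    "cap_lof": cap_lof(table, pop),
                    "cap_rare": cap_rare,
                    "cap_common": cap_common,
                    "n_variants": len(table.afs(pop)),
                    "variants_per_residue": vpr,
                }
            )
    return pd.DataFrame(rows)


def drug_scores_frame(
    targets: Mapping[str, frozenset[str]],
    tables: Mapping[str, GeneVariantTable],
    populations: Sequence[str] = (GLOBAL, *ANALYSIS_POPULATIONS),
) -> pd.DataFrame:
    """drug × population DRP table (columns: drug_id, population, drp, drp_lof,
    n_targets). Target genes without a variant table contribute an empty table."""
    rows = []
    for drug_id in sorted(targets):
        genes = targets[drug_id]
        if not genes:
            continue
        drug_tables = {
            g: tables.get(g, GeneVariantTable(gene=g)) for g in genes
        }
        for pop in populations:
            rows.append(
                {
                    "drug_id": drug_id,
                    "population": pop,
                    "drp": drp(drug_tables, pop),
                    "drp_lof": drp(drug_tables, pop, classes=(FunctionalClass.LOF,)),
                    "n_targets": len(genes),
                }
            )
    return pd.DataFrame(rows)
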