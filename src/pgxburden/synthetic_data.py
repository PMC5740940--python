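"""Synthetic multi-population cohorts, drug catalogs, and predictor scores.

Every generator is deterministic given the spec's master seed; sub-generators
are derived by seed-sequence spawning (fixed child order), so individual
pieces are reproducible in isolation.

The ground-truth table computes analytic CAP/DRP by a plain floating-point
product — deliberately *not* the log-space accumulation used by
:mod:`pgxburden.risk_scores` — so pipeline-vs-truth comparisons cross two
independent code paths.

Allele counts are drawn binomially from the true per-population frequencies
over the cohort's finite chromosome pool; the emitted GLOBAL AC/AN are the
sums over all strata including the residual OTH stratum, as in the source
data model.
"""

from __future__ import annotations

import dataclasses
import math
from collections.abc import Iterable, Mapping, Sequence
from pathlib import Path

import numpy as np
import pandas as pd

from pgxburden.drug_gene_catalog import DrugGeneRelation
from pgxburden.variant_ingest import (
    ANALYSIS_POPULATIONS,
    GLOBAL,
    OTH,
    AlleleCounts,
    TranscriptAnnotation,
    VariantRecord,
)

#: Published stratum sizes of the 60,706-exome reference cohort (individuals).
EXAC_POPULATION_SIZES: dict[str, int] = {
    "AFR": 5203,
    "SAS": 8256,
    "EAS": 4327,
    "FIN": 3307,
    "NFE": 33370,
    "AMR": 5789,
    "OTH": 545,
}

_LOF_CONSEQUENCES = ("stop_gained", "splice_donor_variant",
                     "splice_acceptor_variant", "frameshift_variant")
_BASES = ("A", "C", "G", "T")


@dataclasses.dataclass(slots=True)
class CohortSpec:
    """Parameters of a synthetic cohort.

    ``class_proportions`` is (lof, damaging, other) and must sum to 1.
    ``rare_fraction`` controls the site-frequency mixture: rare true AFs are
    drawn log-uniformly over [1/(2N_total), rare_threshold), common ones over
    [rare_threshold, 0.5]. ``an_thinning`` is the probability that a
    population's AN at a site is thinned below the full chromosome pool
    (exercises the locus-coverage filter). ``synonymous_fraction``,
    ``duplicate_fraction`` and ``multiallelic_fraction`` inject records that
    exercise the corresponding pipeline stages.
    """

    population_sizes: dict[str, int] = dataclasses.field(
        default_factory=lambda: dict(EXAC_POPULATION_SIZES)
    )
    n_genes: int = 20
    mean_variants_per_gene: float = 15.0
    rare_fraction: float = 0.975
    rare_threshold: float = 0.001
    class_proportions: tuple[float, float, float] = (0.10, 0.45, 0.45)
    population_af_sigma: float = 0.6
    synonymous_fraction: float = 0.0
    duplicate_fraction: float = 0.0
    multiallelic_fraction: float = 0.0
    an_thinning: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n <= 0 for n in self.population_sizes.values()):
            raise ValueError("population sizes must be positive")
        if abs(sum(self.class_proportions) - 1.0) > 1e-9:
            raise ValueError("class proportions must sum to 1")
        if self.n_genes < 1 or self.mean_variants_per_gene <= 0:
            raise ValueError("need at least one gene and positive variant rate")
        if not 0.0 <= self.rare_fraction <= 1.0:
            raise ValueError("rare_fraction must be in [0, 1]")

    @property
    def n_total(self) -> int:
        return sum(self.population_sizes.values())

    def scaled(self, factor: float) -> "CohortSpec":
        """Copy with population sizes divided by ``factor`` (min 1)."""
        sizes = {p: max(1, round(n / factor)) for p, n in self.population_sizes.items()}
        return dataclasses.replace(self, population_sizes=sizes)


def _plain_cap(afs: Iterable[float]) -> float:
    """Oracle form of the carrier probability: direct product, no log tricks."""
    product = 1.0
    for af in afs:
        product *= (1.0 - af) ** 2
    return 1.0 - product


@dataclasses.dataclass(slots=True)
class TruthTable:
    """Ground truth for a synthetic cohort.

    ``variants`` has one row per emitted bi-allelic variant: gene, true
    class, true per-population AF, and the emitted AC/AN per stratum.
    """

    variants: pd.DataFrame
    protein_lengths: dict[str, int]
    populations: tuple[str, ...]

    def emitted_af(self, row: pd.Series, population: str) -> float | None:
        an = row[f"an_{population}"]
        if an == 0:
            return None
        return row[f"ac_{population}"] / an

    def _gene_afs(
        self,
        gene: str,
        population: str,
        classes: Sequence[str],
        source: str,
        max_global_af: float | None = None,
    ) -> list[float]:
        sub = self.variants[
            (self.variants.gene == gene) & (self.variants.true_class.isin(classes))
        ]
        afs = []
        for _, row in sub.iterrows():
            if max_global_af is not None:
                global_af = self.emitted_af(row, GLOBAL)
                if global_af is None or global_af > max_global_af:
                    continue
            if source == "emitted":
                af = self.emitted_af(row, population)
            else:
                af = row[f"true_af_{population}"]
            if af is not None:
                afs.append(af)
        return afs

    def analytic_cap(
        self,
        gene: str,
        population: str = GLOBAL,
        classes: Sequence[str] = ("LOF", "DAMAGING"),
        source: str = "emitted",
        max_global_af: float | None = None,
    ) -> float:
        """CAP from the truth table (``source``: 'emitted' AC/AN or 'true' AFs).

        ``max_global_af`` mirrors the pipeline's functional-AF cap: variants
        whose emitted GLOBAL AF exceeds it are excluded.
        """
        return _plain_cap(
            self._gene_afs(gene, population, classes, source, max_global_af)
        )

    def analytic_drp(
        self,
        target_genes: Iterable[str],
        population: str = GLOBAL,
        classes: Sequence[str] = ("LOF", "DAMAGING"),
        source: str = "emitted",
        max_global_af: float | None = None,
    ) -> float:
        afs: list[float] = []
        for gene in target_genes:
            afs.extend(
                self._gene_afs(gene, population, classes, source, max_global_af)
            )
        return _plain_cap(afs)

    def to_tsv(self, path: str | Path) -> None:
        self.variants.to_csv(path, sep="\t", index=False)


@dataclasses.dataclass(slots=True)
class SyntheticCohort:
    spec: CohortSpec
    records: list[VariantRecord]          # bi-allelic, post-split view
    vcf_lines: list[str]                  # raw emitted lines (may be multi-allelic)
    truth: TruthTable

    def write_vcf(self, path: str | Path) -> None:
        pops = [p for p in (*ANALYSIS_POPULATIONS, OTH)
                if p in self.spec.population_sizes]
        contigs = "".join(
            f"##contig=<ID={c}>\n"
            for c in dict.fromkeys(r.chrom for r in self.records)
        )
        pop_info = "".join(
            f'##INFO=<ID=AC_{p},Number=A,Type=Integer,Description="Alternate allele count, {p}">\n'
            f'##INFO=<ID=AN_{p},Number=1,Type=Integer,Description="Allele number, {p}">\n'
            for p in pops
        )
        header = (
            "##fileformat=VCFv4.2\n"
            + contigs
            + '##INFO=<ID=AC,Number=A,Type=Integer,Description="Alternate allele count, full cohort">\n'
            + '##INFO=<ID=AN,Number=1,Type=Integer,Description="Allele number, full cohort">\n'
            + pop_info
            + '##INFO=<ID=CSQ,Number=.,Type=String,Description="Consequence annotations. '
            + 'Format: Allele|Gene|Feature|Consequence|SIFT|PolyPhen|LoF">\n'
            + "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            fh.writelines(line + "\n" for line in self.vcf_lines)


def _draw_true_af(rng: np.random.Generator, spec: CohortSpec) -> float:
    if rng.random() < spec.rare_fraction:
        # singleton resolution, but never above the rare band itself (tiny
        # scaled-down cohorts can have 1/(2N) above the threshold)
        hi = spec.rare_threshold
        lo = min(1.0 / (2 * spec.n_total), hi / 10)
    else:
        lo, hi = spec.rare_threshold, 0.5
    return math.exp(rng.uniform(math.log(lo), math.log(hi)))


def _annotation_for_class(
    rng: np.random.Generator, true_class: str, gene: str, transcript: str, allele: str
) -> TranscriptAnnotation:
    if true_class == "LOF":
        return TranscriptAnnotation(
            transcript_id=transcript, gene=gene, allele=allele,
            consequence=str(rng.choice(_LOF_CONSEQUENCES)), lof_flag="HC",
        )
    if true_class == "DAMAGING":
        return TranscriptAnnotation(
            transcript_id=transcript, gene=gene, allele=allele,
            consequence="missense_variant", sift_category="deleterious",
            polyphen_category=str(
                rng.choice(("probably_damaging", "possibly_damaging"))
            ),
        )
    if true_class == "SYNONYMOUS":
        return TranscriptAnnotation(
            transcript_id=transcript, gene=gene, allele=allele,
            consequence="synonymous_variant",
        )
    # OTHER: benign missense; some carry a low-confidence LoF flag, which must
    # not count as loss of function.
    return TranscriptAnnotation(
        transcript_id=transcript, gene=gene, allele=allele,
        consequence="missense_variant", sift_category="tolerated",
        polyphen_category="benign",
        lof_flag="LC" if rng.random() < 0.2 else "absent",
    )


def simulate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Generate an annotated variant file plus its ground truth.

    For each variant and stratum, AC is drawn binomially over the stratum's
    genotyped chromosomes at the true per-stratum AF; GLOBAL counts are the
    sums over all strata (including OTH). Deterministic given ``spec.seed``.
    """
    ss = np.random.SeedSequence(spec.seed)
    rng_af, rng_counts, rng_ann, rng_struct = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )
    pops = [p for p in (*ANALYSIS_POPULATIONS, OTH) if p in spec.population_sizes]
    class_labels = ("LOF", "DAMAGING", "OTHER")

    protein_lengths = {
        f"GENE{i:04d}": int(rng_struct.integers(100, 1000))
        for i in range(1, spec.n_genes + 1)
    }

    rows = []
    records: list[VariantRecord] = []
    vcf_lines: list[str] = []
    pos = 0
    for gene_idx, gene in enumerate(sorted(protein_lengths), start=1):
        transcript = f"TR{gene_idx:04d}"
        n_variants = max(1, int(rng_struct.poisson(spec.mean_variants_per_gene)))
        n_syn = int(rng_struct.binomial(n_variants, spec.synonymous_fraction)) \
            if spec.synonymous_fraction else 0
        site = 0
        while site < n_variants + n_syn:
            pos += int(rng_struct.integers(2, 30))
            ref = _BASES[pos % 4]
            # group two alts on one line occasionally, to exercise splitting
            group = 2 if (
                spec.multiallelic_fraction
                and site + 1 < n_variants + n_syn
                and rng_struct.random() < spec.multiallelic_fraction
            ) else 1
            alts = [str(a) for a in rng_struct.choice(
                [b for b in _BASES if b != ref], size=group, replace=False
            )]
            an_by_pop: dict[str, int] = {}
            for p in pops:
                full = 2 * spec.population_sizes[p]
                if spec.an_thinning and rng_counts.random() < spec.an_thinning:
                    an_by_pop[p] = int(rng_counts.integers(0, full))
                else:
                    an_by_pop[p] = full
            per_alt = []
            for alt in alts:
                if site >= n_variants:
                    true_class = "SYNONYMOUS"
                else:
                    true_class = str(rng_ann.choice(class_labels,
                                                    p=spec.class_proportions))
                true_af_global = _draw_true_af(rng_af, spec)
                true_afs = {}
                acs = {}
                for p in pops:
                    af_p = min(
                        0.95,
                        true_af_global
                        * math.exp(rng_af.normal(0.0, spec.population_af_sigma)),
                    )
                    true_afs[p] = af_p
                    acs[p] = int(rng_counts.binomial(an_by_pop[p], af_p))
                per_alt.append((alt, true_class, true_af_global, true_afs, acs))
                site += 1
            # multi-allelic sanity: total alt count cannot exceed AN
            for p in pops:
                total = sum(item[4][p] for item in per_alt)
                if total > an_by_pop[p]:
                    scale = an_by_pop[p] / total
                    for item in per_alt:
                        item[4][p] = int(item[4][p] * scale)
            an_global = sum(an_by_pop.values())
            info = [
                "AC=" + ",".join(str(sum(item[4].values())) for item in per_alt),
                f"AN={an_global}",
            ]
            for p in pops:
                info.append("AC_" + p + "=" + ",".join(str(item[4][p]) for item in per_alt))
                info.append(f"AN_{p}={an_by_pop[p]}")
            csq_entries = []
            for alt, true_class, _, _, _ in per_alt:
                ann = _annotation_for_class(rng_ann, true_class, gene, transcript, alt)
                csq_entries.append(
                    "|".join([
                        ann.allele, ann.gene, ann.transcript_id, ann.consequence,
                        "" if ann.sift_category == "absent" else ann.sift_category,
                        "" if ann.polyphen_category == "absent" else ann.polyphen_category,
                        "" if ann.lof_flag == "absent" else ann.lof_flag,
                    ])
                )
            info.append("CSQ=" + ",".join(csq_entries))
            line = "\t".join(
                ["1", str(pos), ".", ref, ",".join(alts), ".", ".", ";".join(info)]
            )
            vcf_lines.append(line)
            if spec.duplicate_fraction and rng_struct.random() < spec.duplicate_fraction:
                vcf_lines.append(line)

            for (alt, true_class, true_af_global, true_afs, acs), csq in zip(
                per_alt, csq_entries
            ):
                counts = {
                    p: AlleleCounts(ac=acs[p], an=an_by_pop[p]) for p in pops
                }
                counts[GLOBAL] = AlleleCounts(
                    ac=sum(acs.values()), an=an_global
                )
                parts = csq.split("|")
                record = VariantRecord(
                    chrom="1", pos=pos, ref=ref, alt=alt, counts=counts,
                    annotations=[TranscriptAnnotation(
                        transcript_id=parts[2], gene=parts[1],
                        consequence=parts[3], sift_category=parts[4],
                        polyphen_category=parts[5], lof_flag=parts[6],
                        allele=parts[0],
                    )],
                )
                records.append(record)
                row: dict[str, object] = {
                    "variant_key": record.key,
                    "gene": gene,
                    "true_class": true_class,
                    "true_af_GLOBAL": true_af_global,
                    "ac_GLOBAL": counts[GLOBAL].ac,
                    "an_GLOBAL": counts[GLOBAL].an,
                }
                for p in pops:
                    row[f"true_af_{p}"] = true_afs[p]
                    row[f"ac_{p}"] = acs[p]
                    row[f"an_{p}"] = an_by_pop[p]
                rows.append(row)

    truth = TruthTable(
        variants=pd.DataFrame(rows),
        protein_lengths=protein_lengths,
        populations=tuple(pops),
    )
    return SyntheticCohort(spec=spec, records=records, vcf_lines=vcf_lines, truth=truth)


# ---------------------------------------------------------------------------
# Drug catalogs
# ---------------------------------------------------------------------------

def simulate_catalog(
    n_drugs: int,
    genes: Sequence[str],
    seed: int = 0,
    targets_range: tuple[int, int] = (1, 10),
    oncology_fraction: float = 0.15,
    non_action_fraction: float = 0.2,
    non_target_fraction: float = 0.1,
) -> tuple[list[DrugGeneRelation], dict[str, frozenset[str]]]:
    """Random drug→gene relation rows plus the expected post-filter targets.

    A ``non_action_fraction`` of rows carry ``pharmacological_action`` of
    unknown/no and a ``non_target_fraction`` are non-target relations; both
    kinds must be removed by catalog extraction. Returns (relations,
    expected_targets) where the expectation covers drugs with >= 1 surviving
    target.
    """
    if n_drugs < 1:
        raise ValueError("need at least one drug")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xCA7)))
    relations: list[DrugGeneRelation] = []
    expected: dict[str, set[str]] = {}
    for i in range(1, n_drugs + 1):
        drug_id = f"DRUG{i:04d}"
        name = f"drug-{i:04d}"
        oncology = rng.random() < oncology_fraction
        atc = (f"L01X{rng.integers(10, 99)}",) if oncology \
            else (f"{rng.choice(('A', 'C', 'J', 'N'))}0{rng.integers(1, 9)}AB{rng.integers(10, 99)}",)
        n_targets = int(rng.integers(targets_range[0], targets_range[1] + 1))
        chosen = rng.choice(len(genes), size=min(n_targets, len(genes)), replace=False)
        for gi in chosen:
            gene = genes[int(gi)]
            roll = rng.random()
            if roll < non_action_fraction:
                action = str(rng.choice(("unknown", "no")))
                is_target = True
            elif roll < non_action_fraction + non_target_fraction:
                action = "yes"
                is_target = False
            else:
                action = "yes"
                is_target = True
                expected.setdefault(drug_id, set()).add(gene)
            relations.append(
                DrugGeneRelation(
                    drug_id=drug_id, drug_name=name, gene=gene,
                    is_target=is_target, pharmacological_action=action,
                    action_type="inhibitor", atc_codes=atc, approved=True,
                )
            )
    return relations, {d: frozenset(g) for d, g in expected.items()}


def write_relations_tsv(relations: Iterable[DrugGeneRelation], path: str | Path) -> None:
    cols = ["drug_id", "drug_name", "gene", "is_target", "pharmacological_action",
            "action_type", "atc_codes", "approved"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for r in relations:
            fh.write("\t".join([
                r.drug_id, r.drug_name, r.gene,
                "true" if r.is_target else "false",
                r.pharmacological_action, r.action_type,
                ";".join(r.atc_codes),
                "true" if r.approved else "false",
            ]) + "\n")


# ---------------------------------------------------------------------------
# Monte-Carlo oracle
# ---------------------------------------------------------------------------

def simulate_individuals(
    afs: Sequence[float],
    n_individuals: int,
    seed: int | np.random.Generator = 0,
    chunk: int = 100_000,
) -> float:
    """Fraction of simulated diploid individuals carrying >= 1 alternate allele.

    Two alleles per locus per individual are drawn independently at the given
    frequencies (Hardy–Weinberg); loci are independent. This is the
    Monte-Carlo oracle for CAP/DRP.
    """
    if n_individuals < 1:
        raise ValueError("need at least one individual")
    afs_arr = np.asarray(afs, dtype=float)
    if afs_arr.size and (afs_arr.min() < 0 or afs_arr.max() > 1):
        raise ValueError("allele frequencies must be in [0, 1]")
    if afs_arr.size == 0:
        return 0.0
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    carriers = 0
    remaining = n_individuals
    while remaining > 0:
        n = min(chunk, remaining)
        draws = rng.binomial(2, afs_arr, size=(n, afs_arr.size))
        carriers += int((draws > 0).any(axis=1).sum())
        remaining -= n
    return carriers / n_individuals


def simulate_scores(
    variant_keys: Sequence[str],
    damaging_truth: Mapping[str, bool],
    seed: int = 0,
    flip_probability: float = 0.1,
    coverage: float = 1.0,
) -> tuple[dict[str, float], dict[str, float]]:
    """Emit CADD-scaled and effect-score maps consistent (up to flips) with a
    damaging/benign truth assignment; for exercising concordance reporting."""
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0x5C0)))
    cadd: dict[str, float] = {}
    evm: dict[str, float] = {}
    for key in variant_keys:
        if rng.random() >= coverage:
            continue
        positive = damaging_truth.get(key, False)
        if rng.random() < flip_probability:
            positive = not positive
        if positive:
            cadd[key] = float(20.0 + rng.uniform(0.5, 20.0))
            evm[key] = float(-rng.uniform(0.5, 10.0))
        else:
            # a reference-negative needs only one predictor to disagree
            if rng.random() < 0.5:
                cadd[key] = float(rng.uniform(0.0, 20.0))
                evm[key] = float(rng.normal(0.0, 3.0))
            else:
                cadd[key] = float(20.0 + rng.uniform(0.5, 20.0))
                evm[key] = float(rng.uniform(0.1, 5.0))
    return cadd, evm


def write_score_tsv(scores: Mapping[str, float], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("variant_key\tscore\n")
        for key in sorted(scores):
            fh.write(f"{key}\t{scores[key]:.6g}\n")
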