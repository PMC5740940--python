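"""Loss-of-function / consensus-damaging classification and predictor concordance.

A variant is loss-of-function (LOF) when any transcript carries a
high-confidence LoF flag; it is consensus-damaging (DAMAGING) when any
transcript is called deleterious by SIFT *and* possibly/probably damaging by
PolyPhen. LOF takes precedence. "Functional" = LOF ∪ DAMAGING.

Concordance against independent predictors uses CADD scaled > 20 combined
with an effect-score call from a mutation-effect model; the effect-score
cutoff (score < 0, deleterious relative to wild type) is this package's
default, configurable — no published threshold exists for it.
"""

from __future__ import annotations

import dataclasses
import enum
from collections.abc import Iterable, Mapping, Set

from pgxburden.variant_ingest import VariantRecord


class FunctionalClass(enum.Enum):
    LOF = "LOF"
    DAMAGING = "DAMAGING"
    OTHER = "OTHER"

    def __str__(self) -> str:  # TSV-friendly
        return self.value


FUNCTIONAL_CLASSES = (FunctionalClass.LOF, FunctionalClass.DAMAGING)

DAMAGING_POLYPHEN = frozenset({"possibly_damaging", "probably_damaging"})


@dataclasses.dataclass(slots=True)
class ClassifyConfig:
    """``lof_flags``: which LoF confidence flags count (default high-confidence
    only). ``transcript_policy``: 'any' (worst-consequence, default) or
    'canonical' restricted to transcript ids in ``canonical_transcripts``."""

    lof_flags: tuple[str, ...] = ("HC",)
    transcript_policy: str = "any"
    canonical_transcripts: frozenset[str] = frozenset()

    def relevant_annotations(self, record: VariantRecord):
        if self.transcript_policy == "canonical":
            return [a for a in record.annotations
                    if a.transcript_id in self.canonical_transcripts]
        return record.annotations


DEFAULT_CLASSIFY = ClassifyConfig()


def is_lof(record: VariantRecord, config: ClassifyConfig = DEFAULT_CLASSIFY) -> bool:
    """True iff any (relevant) transcript annotation carries a counted LoF flag."""
    return any(a.lof_flag in config.lof_flags
               for a in config.relevant_annotations(record))


def is_damaging_consensus(
    record: VariantRecord, config: ClassifyConfig = DEFAULT_CLASSIFY
) -> bool:
    """True iff some transcript is SIFT-deleterious AND PolyPhen-damaging.

    Missing predictions ('absent') never satisfy the consensus.
    """
    return any(
        a.sift_category == "deleterious" and a.polyphen_category in DAMAGING_POLYPHEN
        for a in config.relevant_annotations(record)
    )


def classify(
    record: VariantRecord, config: ClassifyConfig = DEFAULT_CLASSIFY
) -> FunctionalClass:
    """LOF if any high-confidence LoF transcript; else DAMAGING on consensus;
    else OTHER. Every record gets exactly one label."""
    if is_lof(record, config):
        return FunctionalClass.LOF
    if is_damaging_consensus(record, config):
        return FunctionalClass.DAMAGING
    return FunctionalClass.OTHER


def is_functional(
    record: VariantRecord, config: ClassifyConfig = DEFAULT_CLASSIFY
) -> bool:
    return classify(record, config) in FUNCTIONAL_CLASSES


def functional_subset(
    records: Iterable[VariantRecord], config: ClassifyConfig = DEFAULT_CLASSIFY
) -> list[VariantRecord]:
    return [r for r in records if is_functional(r, config)]


# ---------------------------------------------------------------------------
# Concordance with independent predictors
# ---------------------------------------------------------------------------

@dataclasses.dataclass(slots=True)
class ConcordanceReport:
    """2x2 agreement of the consensus call against an independent reference.

    ``sensitivity`` / ``specificity`` are None when the corresponding
    denominator is empty (undefined, never reported as a number).
    """

    sensitivity: float | None
    specificity: float | None
    n_consensus_damaging: int
    n_reference_damaging: int
    n_compared: int
    true_positive: int
    false_positive: int
    true_negative: int
    false_negative: int


def concordance(
    consensus_set: Set[str],
    all_nonsyn_set: Iterable[str],
    cadd_scores: Mapping[str, float],
    evm_scores: Mapping[str, float],
    cadd_threshold: float = 20.0,
    evm_threshold: float = 0.0,
) -> ConcordanceReport:
    """Sensitivity/specificity of the SIFT+PolyPhen consensus against
    (CADD scaled > threshold) AND (effect score < evm_threshold).

    Variants lacking either reference score are dropped from the comparison.
    CADD comparison is strict (> 20).
    """
    tp = fp = tn = fn = 0
    n_consensus = n_reference = n_compared = 0
    for key in all_nonsyn_set:
        cadd = cadd_scores.get(key)
        evm = evm_scores.get(key)
        if cadd is None or evm is None:
            continue
        n_compared += 1
        reference_positive = cadd > cadd_threshold and evm < evm_threshold
        consensus_positive = key in consensus_set
        n_consensus += consensus_positive
        n_reference += reference_positive
        if reference_positive:
            if consensus_positive:
                tp += 1
            else:
                fn += 1
        else:
            if consensus_positive:
                fp += 1
            else:
                tn += 1
    sensitivity = tp / (tp + fn) if (tp + fn) > 0 else None
    specificity = tn / (tn + fp) if (tn + fp) > 0 else None
    return ConcordanceReport(
        sensitivity=sensitivity,
        specificity=specificity,
        n_consensus_damaging=n_consensus,
        n_reference_damaging=n_reference,
        n_compared=n_compared,
        true_positive=tp,
        false_positive=fp,
        true_negative=tn,
        false_negative=fn,
    )
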