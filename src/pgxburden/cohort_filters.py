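"""Variant-level exclusion cascade applied before any scoring.

Stages, in the canonical order: locus-coverage filter → synonymous exclusion
→ deduplication → allele-frequency cap on the functional subset. The first
three stages commute (checked as a test property); the AF cap applies only
after functional classification and is therefore exposed separately.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from collections.abc import Iterable, Sequence
from pathlib import Path

import yaml

from pgxburden.variant_ingest import (
    ANALYSIS_POPULATIONS,
    GLOBAL,
    VariantRecord,
)

logger = logging.getLogger(__name__)

#: Half of the chromosomes of the 60,706-exome reference cohort.
DEFAULT_MIN_GLOBAL_AN = 60706


@dataclasses.dataclass(slots=True)
class FilterConfig:
    """Thresholds for the exclusion cascade.

    ``observation_field`` selects whether "observed at least once in every
    geographic population" requires the locus to be genotyped there
    (``"AN"``, default) or the alternate allele to be carried there
    (``"AC"``). Requiring AC >= 1 everywhere would remove nearly all rare
    variants, so AN is the default.
    """

    min_global_an: int = DEFAULT_MIN_GLOBAL_AN
    require_all_populations_observed: bool = True
    observation_field: str = "AN"
    exclude_synonymous: bool = True
    max_functional_af: float = 0.5

    def __post_init__(self) -> None:
        if self.min_global_an < 0:
            raise ValueError("min_global_an must be >= 0")
        if not 0 < self.max_functional_af <= 1:
            raise ValueError("max_functional_af must be in (0, 1]")
        if self.observation_field not in ("AN", "AC"):
            raise ValueError("observation_field must be 'AN' or 'AC'")

    @classmethod
    def for_cohort_size(cls, n_individuals: int, **kwargs) -> "FilterConfig":
        """Coverage threshold of ceil(0.5 * 2N) chromosomes for a cohort of N."""
        return cls(min_global_an=math.ceil(0.5 * 2 * n_individuals), **kwargs)

    @classmethod
    def from_file(cls, path: str | Path) -> "FilterConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) if str(path).endswith((".yaml", ".yml")) \
                else json.load(fh)
        return cls(**(data or {}))


@dataclasses.dataclass(slots=True)
class StageReport:
    stage: str
    n_in: int
    n_out: int

    @property
    def n_removed(self) -> int:
        return self.n_in - self.n_out


@dataclasses.dataclass(slots=True)
class CascadeReport:
    """Per-stage funnel counts; stages sum to input − output."""

    stages: list[StageReport] = dataclasses.field(default_factory=list)
    removed_keys: dict[str, list[str]] = dataclasses.field(default_factory=dict)

    def add(self, stage: str, before: Sequence, after: Sequence) -> None:
        self.stages.append(StageReport(stage, len(before), len(after)))
        kept = {id(v) for v in after}
        self.removed_keys[stage] = [v.key for v in before if id(v) not in kept]

    def as_dict(self) -> dict:
        return {s.stage: {"in": s.n_in, "out": s.n_out, "removed": s.n_removed}
                for s in self.stages}


def filter_locus_coverage(
    variants: Iterable[VariantRecord], config: FilterConfig
) -> list[VariantRecord]:
    """Keep variants genotyped at >= ``min_global_an`` chromosomes overall and
    observed in all six analysis populations.

    A variant missing a population's counts is treated as unobserved there
    (fails the filter) and logged.
    """
    kept = []
    for v in variants:
        global_counts = v.counts.get(GLOBAL)
        if global_counts is None or global_counts.an < config.min_global_an:
            continue
        if config.require_all_populations_observed:
            ok = True
            for pop in ANALYSIS_POPULATIONS:
                counts = v.counts.get(pop)
                if counts is None:
                    logger.debug("%s: missing %s counts, treated as AN=0", v.key, pop)
                    ok = False
                    break
                observed = counts.an if config.observation_field == "AN" else counts.ac
                if observed < 1:
                    ok = False
                    break
            if not ok:
                continue
        kept.append(v)
    return kept


def _is_synonymous_only(v: VariantRecord) -> bool:
    if not v.annotations:
        logger.debug("%s: no annotations, removed as non-coding/unknown", v.key)
        return True
    return all(
        all(c == "synonymous_variant" for c in ann.consequences)
        for ann in v.annotations
    )


def exclude_synonymous(variants: Iterable[VariantRecord]) -> list[VariantRecord]:
    """Drop variants whose every transcript consequence is synonymous.

    A variant with at least one non-synonymous transcript consequence
    survives; variants with no annotations at all are dropped (no evidence of
    a coding effect).
    """
    return [v for v in variants if not _is_synonymous_only(v)]


def deduplicate(variants: Iterable[VariantRecord]) -> list[VariantRecord]:
    """Keep the first occurrence per canonical variant key. Idempotent."""
    seen: set[str] = set()
    kept = []
    for v in variants:
        if v.key in seen:
            continue
        seen.add(v.key)
        kept.append(v)
    return kept


def cap_functional_af(
    variants: Iterable[VariantRecord], max_functional_af: float = 0.5
) -> list[VariantRecord]:
    """Drop (functional) variants with GLOBAL AF strictly above the cap.

    Applies to the functional subset only — callers pass classified
    functional variants. Boundary AF == cap is retained. Variants with
    undefined GLOBAL AF are dropped (cannot be scored).
    """
    kept = []
    for v in variants:
        af = v.af(GLOBAL)
        if af is None:
            logger.debug("%s: undefined GLOBAL AF, removed", v.key)
            continue
        if af > max_functional_af:
            continue
        kept.append(v)
    return kept


def apply_cascade(
    variants: Sequence[VariantRecord], config: FilterConfig
) -> tuple[list[VariantRecord], CascadeReport]:
    """Coverage → synonymous → dedup; returns survivors plus funnel counts.

    The functional-AF cap is not part of this cascade because it requires
    functional classification first; see :func:`cap_functional_af`.
    """
    report = CascadeReport()
    current = list(variants)
    after = filter_locus_coverage(current, config)
    report.add("locus_coverage", current, after)
    current = after
    if config.exclude_synonymous:
        after = exclude_synonymous(current)
        report.add("synonymous", current, after)
        current = after
    after = deduplicate(current)
    report.add("deduplicate", current, after)
    for s in report.stages:
        logger.info("filter %s: %d -> %d (removed %d)", s.stage, s.n_in, s.n_out, s.n_removed)
    return after, report
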