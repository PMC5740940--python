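"""Cross-population comparison of CAP/DRP scores.

Risk differences are absolute, |p2 − p1|; comparisons run over the six
analysis populations only (the residual stratum never enters). Threshold
comparisons are strict (score > threshold).
"""

from __future__ import annotations

import dataclasses
import logging
import math
from collections.abc import Mapping, Sequence

import pandas as pd

from pgxburden.risk_scores import GeneVariantTable
from pgxburden.variant_ingest import ANALYSIS_POPULATIONS

logger = logging.getLogger(__name__)


def risk_difference(p1: float, p2: float) -> float:
    """Absolute risk difference |p2 − p1| between two probabilities."""
    for p in (p1, p2):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"probability {p} outside [0, 1]")
    return abs(p2 - p1)


@dataclasses.dataclass(slots=True)
class RdMatrix:
    """Symmetric pairwise risk-difference matrix for one gene or drug."""

    subject: str
    entries: dict[tuple[str, str], float]

    def max_entry(self) -> float:
        return max(self.entries.values(), default=0.0)


def rd_matrix(
    subject: str,
    scores: Mapping[str, float],
    populations: Sequence[str] = ANALYSIS_POPULATIONS,
) -> RdMatrix:
    entries: dict[tuple[str, str], float] = {}
    for p in populations:
        for q in populations:
            entries[(p, q)] = risk_difference(scores[p], scores[q])
    return RdMatrix(subject=subject, entries=entries)


def max_rd(scores: Mapping[str, float]) -> float:
    """Highest minus lowest population score.

    Equals the maximum entry of the pairwise matrix.
    """
    values = [scores[p] for p in scores]
    if len(values) < 2:
        raise ValueError("max_rd needs at least two population scores")
    return max(values) - min(values)


def mean_pairwise_rd(
    scores: Mapping[str, float],
    populations: Sequence[str] = ANALYSIS_POPULATIONS,
) -> dict[str, float]:
    """For each population, the mean absolute difference to the other five.

    Used to rank which population sits at above/below-average risk.
    """
    missing = [p for p in populations if p not in scores]
    if missing:
        raise KeyError(f"missing population scores: {missing}")
    out = {}
    for p in populations:
        others = [q for q in populations if q != p]
        out[p] = sum(abs(scores[p] - scores[q]) for q in others) / len(others)
    return out


def population_unique_fraction(
    tables: Mapping[str, GeneVariantTable],
    populations: Sequence[str] = ANALYSIS_POPULATIONS,
) -> tuple[dict[str, float], float | None, float | None]:
    """Per-gene fraction of functional variants seen in exactly one population,
    plus mean and (population) SD across genes.

    A variant is population-unique iff its alternate allele count is positive
    in exactly one of the six analysis populations. Genes with zero functional
    variants are excluded from the mean/SD.
    """
    fractions: dict[str, float] = {}
    for gene in sorted(tables):
        table = tables[gene]
        n_total = 0
        n_unique = 0
        for v in table.variants:
            n_total += 1
            observed_in = sum(
                1
                for p in populations
                if (c := v.counts.get(p)) is not None and c.ac > 0
            )
            if observed_in == 1:
                n_unique += 1
        if n_total == 0:
            logger.debug("gene %s has no functional variants; excluded", gene)
            continue
        fractions[gene] = n_unique / n_total
    if not fractions:
        return fractions, None, None
    values = list(fractions.values())
    mean = sum(values) / len(values)
    sd = math.sqrt(sum((v - mean) ** 2 for v in values) / len(values))
    return fractions, mean, sd


@dataclasses.dataclass(slots=True)
class ThresholdSummary:
    threshold: float
    per_population: dict[str, int]
    shared: int  # subjects above threshold in all six populations


def threshold_summary(
    scores: Mapping[str, Mapping[str, float]],
    threshold: float = 0.01,
    populations: Sequence[str] = ANALYSIS_POPULATIONS,
) -> ThresholdSummary:
    """Count subjects with score strictly above the threshold, per population
    and in all populations simultaneously.

    ``scores`` maps subject → population → score.
    """
    per_pop = {p: 0 for p in populations}
    shared = 0
    for subject_scores in scores.values():
        above = [p for p in populations if subject_scores.get(p, 0.0) > threshold]
        for p in above:
            per_pop[p] += 1
        if len(above) == len(populations):
            shared += 1
    return ThresholdSummary(threshold=threshold, per_population=per_pop, shared=shared)


# ---------------------------------------------------------------------------
# Report frames
# ---------------------------------------------------------------------------

def rd_frame(scores_by_subject: Mapping[str, Mapping[str, float]]) -> pd.DataFrame:
    """Long-format pairwise RD table (subject, pop1, pop2, rd); upper triangle."""
    rows = []
    for subject in sorted(scores_by_subject):
        scores = scores_by_subject[subject]
        if any(p not in scores for p in ANALYSIS_POPULATIONS):
            logger.info("subject %s missing a population score; skipped", subject)
            continue
        for i, p in enumerate(ANALYSIS_POPULATIONS):
            for q in ANALYSIS_POPULATIONS[i + 1:]:
                rows.append(
                    {"subject": subject, "pop1": p, "pop2": q,
                     "rd": risk_difference(scores[p], scores[q])}
                )
    return pd.DataFrame(rows)


def summary_frame(scores_by_subject: Mapping[str, Mapping[str, float]]) -> pd.DataFrame:
    """Per subject: max RD and population-specific mean RD with an
    above/below-average sign per population."""
    rows = []
    for subject in sorted(scores_by_subject):
        scores = scores_by_subject[subject]
        if any(p not in scores for p in ANALYSIS_POPULATIONS):
            continue
        pop_scores = {p: scores[p] for p in ANALYSIS_POPULATIONS}
        means = mean_pairwise_rd(pop_scores)
        overall_mean = sum(pop_scores.values()) / len(pop_scores)
        row: dict[str, object] = {"subject": subject, "max_rd": max_rd(pop_scores)}
        for p in ANALYSIS_POPULATIONS:
            row[f"mean_rd_{p}"] = means[p]
            row[f"sign_{p}"] = "above" if pop_scores[p] > overall_mean else "below"
        rows.append(row)
    return pd.DataFrame(rows)
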