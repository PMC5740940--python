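"""Drug→target mapping and gene panels from relation tables and curated lists.

The canonical input is a simplified relation TSV (columns ``drug_id``,
``drug_name``, ``gene``, ``is_target``, ``pharmacological_action``,
``action_type``, ``atc_codes``, ``approved``); licensing prevents shipping a
vendor database, and the pipeline must run on synthetic catalogs. Hand-curated
exclusions (specific drug–gene pairs or whole drugs) come from a config file
rather than being hard-coded.
"""

from __future__ import annotations

import dataclasses
import logging
from collections.abc import Iterable, Mapping, Sequence
from pathlib import Path

logger = logging.getLogger(__name__)

_BOOL = {"true": True, "1": True, "yes": True, "false": False, "0": False, "no": False}


@dataclasses.dataclass(frozen=True, slots=True)
class DrugGeneRelation:
    """One drug–gene row of the relation table."""

    drug_id: str
    drug_name: str
    gene: str
    is_target: bool
    pharmacological_action: str  # yes | no | unknown
    action_type: str = ""
    atc_codes: tuple[str, ...] = ()
    approved: bool = True

    def __post_init__(self) -> None:
        if not self.drug_id or not self.gene:
            raise ValueError("drug_id and gene must be nonempty")
        if self.pharmacological_action not in ("yes", "no", "unknown"):
            raise ValueError(
                f"pharmacological_action must be yes/no/unknown, "
                f"got {self.pharmacological_action!r}"
            )


@dataclasses.dataclass(slots=True)
class DrugTargetCatalog:
    """Drug → pharmacological target genes, plus gene panels and drug lists."""

    targets: dict[str, frozenset[str]] = dataclasses.field(default_factory=dict)
    drug_names: dict[str, str] = dataclasses.field(default_factory=dict)
    atc_codes: dict[str, tuple[str, ...]] = dataclasses.field(default_factory=dict)
    approved: dict[str, bool] = dataclasses.field(default_factory=dict)
    panels: dict[str, frozenset[str]] = dataclasses.field(default_factory=dict)
    drug_lists: dict[str, frozenset[str]] = dataclasses.field(default_factory=dict)
    synonyms: dict[str, str] = dataclasses.field(default_factory=dict)

    @property
    def all_target_genes(self) -> frozenset[str]:
        out: set[str] = set()
        for genes in self.targets.values():
            out |= genes
        return frozenset(out)

    def gene_panel(self, *names: str) -> frozenset[str]:
        """Union of named panels; 'targets' expands to every target gene."""
        out: set[str] = set()
        for name in names:
            if name == "targets":
                out |= self.all_target_genes
            else:
                out |= self.panels[name]
        return frozenset(out)


def read_relations_tsv(path: str | Path) -> list[DrugGeneRelation]:
    relations = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        required = {"drug_id", "drug_name", "gene", "is_target", "pharmacological_action"}
        missing = required - idx.keys()
        if missing:
            raise ValueError(f"relation table missing columns: {sorted(missing)}")
        for line in fh:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")

            def col(name: str, default: str = "") -> str:
                i = idx.get(name)
                return parts[i] if i is not None and i < len(parts) else default

            atc = tuple(c for c in col("atc_codes").split(";") if c)
            relations.append(
                DrugGeneRelation(
                    drug_id=col("drug_id"),
                    drug_name=col("drug_name"),
                    gene=col("gene"),
                    is_target=_BOOL[col("is_target", "false").lower()],
                    pharmacological_action=col("pharmacological_action", "unknown"),
                    action_type=col("action_type"),
                    atc_codes=atc,
                    approved=_BOOL[col("approved", "true").lower()],
                )
            )
    return relations


def extract_targets(
    relations: Iterable[DrugGeneRelation],
    excluded_pairs: Iterable[tuple[str, str]] = (),
    excluded_drugs: Iterable[str] = (),
) -> DrugTargetCatalog:
    """Keep (drug, gene) pairs that are targets with established
    pharmacological action, minus curated exclusions.

    Drugs left with zero surviving targets are excluded from scoring and
    logged. Deterministic and idempotent.
    """
    excluded_pairs = set(excluded_pairs)
    excluded_drugs = set(excluded_drugs)
    catalog = DrugTargetCatalog()
    targets: dict[str, set[str]] = {}
    seen_drugs: set[str] = set()
    for rel in relations:
        seen_drugs.add(rel.drug_id)
        catalog.drug_names.setdefault(rel.drug_id, rel.drug_name)
        if rel.atc_codes and rel.drug_id not in catalog.atc_codes:
            catalog.atc_codes[rel.drug_id] = rel.atc_codes
        catalog.approved.setdefault(rel.drug_id, rel.approved)
        if rel.drug_id in excluded_drugs:
            continue
        if not rel.is_target or rel.pharmacological_action != "yes":
            continue
        if (rel.drug_id, rel.gene) in excluded_pairs:
            continue
        targets.setdefault(rel.drug_id, set()).add(rel.gene)
    for drug_id in sorted(seen_drugs - targets.keys()):
        logger.info("drug %s has no pharmacological targets; excluded from scoring",
                    drug_id)
    catalog.targets = {d: frozenset(g) for d, g in targets.items()}
    return catalog


def tag_oncology(catalog: DrugTargetCatalog, atc_prefix: str = "L01") -> frozenset[str]:
    """Drugs with at least one ATC code under the antineoplastic prefix."""
    return frozenset(
        drug_id
        for drug_id, codes in catalog.atc_codes.items()
        if drug_id in catalog.targets and any(c.startswith(atc_prefix) for c in codes)
    )


def map_drug_list(
    names: Sequence[str],
    catalog: DrugTargetCatalog,
    synonyms: Mapping[str, str] | None = None,
) -> tuple[frozenset[str], tuple[str, ...]]:
    """Map free-text drug names to catalog ids; unmapped names are returned,
    never silently dropped.

    Matching is case-insensitive and exact against primary names and the
    supplied synonym table (name → drug_id).
    """
    by_name = {name.lower(): drug_id for drug_id, name in catalog.drug_names.items()}
    syn = {k.lower(): v for k, v in (synonyms or catalog.synonyms or {}).items()}
    mapped: set[str] = set()
    unmapped: list[str] = []
    for name in names:
        drug_id = by_name.get(name.lower()) or syn.get(name.lower())
        if drug_id is None:
            unmapped.append(name)
        else:
            mapped.add(drug_id)
    return frozenset(mapped), tuple(unmapped)


def load_gene_panel(path: str | Path) -> frozenset[str]:
    """Newline-delimited gene symbols; blank lines and '#' comments ignored."""
    with open(path) as fh:
        return frozenset(
            line.strip() for line in fh if line.strip() and not line.startswith("#")
        )


def load_drug_names(path: str | Path) -> list[str]:
    """Newline-delimited drug names, order preserved."""
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip() and not line.startswith("#")]
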