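import math

import numpy as np
import pytest

from pgxburden.cohort_filters import deduplicate
from pgxburden.drug_gene_catalog import extract_targets
from pgxburden.synthetic_data import (
    EXAC_POPULATION_SIZES,
    CohortSpec,
    simulate_catalog,
    simulate_cohort,
    simulate_individuals,
    simulate_scores,
)
from pgxburden.variant_ingest import GLOBAL, read_vcf


def small_spec(**kwargs):
    defaults = dict(n_genes=5, mean_variants_per_gene=8.0, seed=42)
    defaults.update(kwargs)
    return CohortSpec(**defaults).scaled(100)


class TestCohortSpec:
    def test_default_population_sizes(self):
        spec = CohortSpec()
        assert spec.population_sizes == EXAC_POPULATION_SIZES
        assert spec.n_total == 60_797

    def test_invalid_proportions_rejected(self):
        with pytest.raises(ValueError):
            CohortSpec(class_proportions=(0.5, 0.5, 0.5))

    def test_scaled_keeps_strata(self):
        spec = CohortSpec().scaled(10)
        assert spec.population_sizes["NFE"] == 3337
        assert set(spec.population_sizes) == set(EXAC_POPULATION_SIZES)


class TestSimulateCohort:
    def test_deterministic_given_seed(self, tmp_path):
        a = simulate_cohort(small_spec())
        b = simulate_cohort(small_spec())
        pa, pb = tmp_path / "a.vcf", tmp_path / "b.vcf"
        a.write_vcf(pa)
        b.write_vcf(pb)
        assert pa.read_bytes() == pb.read_bytes()

    def test_different_seed_differs(self):
        a = simulate_cohort(small_spec(seed=1))
        b = simulate_cohort(small_spec(seed=2))
        assert a.vcf_lines != b.vcf_lines

    def test_binomial_sampling_recovers_af(self):
        # one common variant, large stratum: empirical AF within 3 binomial SE
        spec = CohortSpec(
            n_genes=1, mean_variants_per_gene=60.0, rare_fraction=0.0,
            population_af_sigma=0.0, seed=7,
        )
        cohort = simulate_cohort(spec)
        frame = cohort.truth.variants
        n_checked = 0
        for _, row in frame.iterrows():
            af, an, ac = row["true_af_NFE"], row["an_NFE"], row["ac_NFE"]
            se = math.sqrt(af * (1 - af) / an)
            assert abs(ac / an - af) <= 4 * se  # 4 SE to keep flake rate ~1e-3
            n_checked += 1
        assert n_checked >= 30

    def test_pure_rare_spectrum(self):
        spec = small_spec(rare_fraction=1.0, population_af_sigma=0.0)
        cohort = simulate_cohort(spec)
        for _, row in cohort.truth.variants.iterrows():
            assert row["true_af_GLOBAL"] < 0.001

    def test_global_counts_are_stratum_sums(self):
        cohort = simulate_cohort(small_spec())
        pops = [p for p in cohort.truth.populations]
        for _, row in cohort.truth.variants.iterrows():
            assert row["ac_GLOBAL"] == sum(row[f"ac_{p}"] for p in pops)
            assert row["an_GLOBAL"] == sum(row[f"an_{p}"] for p in pops)

    def test_emitted_vcf_round_trips(self, tmp_path):
        cohort = simulate_cohort(small_spec(multiallelic_fraction=0.2))
        path = tmp_path / "cohort.vcf"
        cohort.write_vcf(path)
        back = deduplicate(list(read_vcf(path)))
        by_key = {r.key: r for r in back}
        assert set(by_key) == set(cohort.truth.variants.variant_key)
        for rec in cohort.records:
            assert by_key[rec.key].counts == rec.counts

    def test_class_proportions_reflected_in_annotations(self):
        spec = CohortSpec(n_genes=10, mean_variants_per_gene=30.0,
                          class_proportions=(1.0, 0.0, 0.0), seed=3).scaled(100)
        cohort = simulate_cohort(spec)
        assert (cohort.truth.variants.true_class == "LOF").all()

    def test_an_thinning_reduces_allele_numbers(self):
        thin = simulate_cohort(small_spec(an_thinning=0.5))
        full = simulate_cohort(small_spec(an_thinning=0.0))
        full_an = 2 * thin.spec.population_sizes["AFR"]
        assert (full.truth.variants["an_AFR"] == full_an).all()
        assert (thin.truth.variants["an_AFR"] < full_an).any()


class TestAnalyticTruth:
    def test_analytic_cap_matches_plain_product(self):
        cohort = simulate_cohort(small_spec())
        frame = cohort.truth.variants
        gene = frame.gene.iloc[0]
        sub = frame[(frame.gene == gene) & frame.true_class.isin(["LOF", "DAMAGING"])]
        product = 1.0
        for _, row in sub.iterrows():
            if row["an_GLOBAL"] > 0:
                product *= (1 - row["ac_GLOBAL"] / row["an_GLOBAL"]) ** 2
        assert cohort.truth.analytic_cap(gene) == pytest.approx(1 - product, abs=1e-15)

    def test_lof_subset(self):
        cohort = simulate_cohort(small_spec())
        gene = cohort.truth.variants.gene.iloc[0]
        full = cohort.truth.analytic_cap(gene)
        lof_only = cohort.truth.analytic_cap(gene, classes=("LOF",))
        assert lof_only <= full + 1e-15


class TestSimulateCatalog:
    def test_all_yes_relations_all_kept(self):
        relations, expected = simulate_catalog(
            10, [f"G{i}" for i in range(30)], seed=5,
            non_action_fraction=0.0, non_target_fraction=0.0,
        )
        catalog = extract_targets(relations)
        assert catalog.targets == expected
        for rel in relations:
            assert rel.drug_id in catalog.targets

    def test_filtered_relations_dropped(self):
        relations, expected = simulate_catalog(
            20, [f"G{i}" for i in range(30)], seed=6,
            non_action_fraction=0.5, non_target_fraction=0.0,
        )
        catalog = extract_targets(relations)
        assert catalog.targets == expected
        n_yes_targets = {}
        for rel in relations:
            if rel.is_target and rel.pharmacological_action == "yes":
                n_yes_targets.setdefault(rel.drug_id, set()).add(rel.gene)
        assert {d: frozenset(g) for d, g in n_yes_targets.items()} == catalog.targets

    def test_target_range_respected(self):
        relations, _ = simulate_catalog(
            50, [f"G{i}" for i in range(40)], seed=7, targets_range=(1, 10)
        )
        per_drug: dict[str, set[str]] = {}
        for rel in relations:
            per_drug.setdefault(rel.drug_id, set()).add(rel.gene)
        assert all(1 <= len(g) <= 10 for g in per_drug.values())


class TestSimulateIndividuals:
    def test_fixed_allele_everyone_carries(self):
        assert simulate_individuals([1.0], 1000, seed=1) == 1.0

    def test_no_variants_no_carriers(self):
        assert simulate_individuals([], 1000, seed=1) == 0.0

    def test_matches_closed_form(self):
        n = 10**6
        observed = simulate_individuals([0.1, 0.2], n, seed=123)
        expected = 0.4816
        se = math.sqrt(expected * (1 - expected) / n)
        assert abs(observed - expected) <= 3 * se

    def test_invalid_af_rejected(self):
        with pytest.raises(ValueError):
            simulate_individuals([1.5], 10)


class TestSimulateScores:
    def test_zero_flip_perfect_concordance(self):
        keys = [f"1:{i}:C:T" for i in range(200)]
        truth = {k: i % 2 == 0 for i, k in enumerate(keys)}
        cadd, evm = simulate_scores(keys, truth, seed=1, flip_probability=0.0)
        for k in keys:
            reference_positive = cadd[k] > 20 and evm[k] < 0
            assert reference_positive == truth[k]
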