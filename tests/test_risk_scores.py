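import math
import random

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pgxburden.functional_classes import FunctionalClass
from pgxburden.risk_scores import (
    GeneVariant,
    GeneVariantTable,
    cap,
    cap_gene,
    cap_lof,
    drp,
    rare_common_fraction,
    rare_contribution,
    variants_per_residue,
)
from pgxburden.synthetic_data import simulate_individuals
from pgxburden.variant_ingest import GLOBAL, AlleleCounts

afs_strategy = st.lists(st.floats(0.0, 1.0, allow_nan=False), max_size=30)


def table_from_afs(afs, classes=None, gene="G1", protein_length=None, an=10**6):
    """Gene table whose GLOBAL AFs are (approximately, via counts) the given AFs."""
    variants = []
    for i, af in enumerate(afs):
        fclass = classes[i] if classes else FunctionalClass.DAMAGING
        variants.append(
            GeneVariant(
                key=f"1:{i + 1}:C:T",
                functional_class=fclass,
                counts={GLOBAL: AlleleCounts(ac=round(af * an), an=an)},
            )
        )
    return GeneVariantTable(gene=gene, variants=variants,
                            protein_length=protein_length)


class TestCap:
    def test_empty_product(self):
        assert cap([]) == 0.0

    def test_single_half(self):
        assert cap([0.5]) == pytest.approx(0.75, abs=1e-15)

    def test_two_variants(self):
        assert cap([0.1, 0.2]) == pytest.approx(0.4816, abs=1e-12)

    def test_fixation_gives_one(self):
        assert cap([0.001, 1.0, 0.002]) == 1.0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            cap([1.1])
        with pytest.raises(ValueError):
            cap([-0.1])

    def test_monte_carlo_oracle(self):
        n = 10**6
        observed = simulate_individuals([0.1, 0.2], n, seed=7)
        expected = 0.4816
        se = math.sqrt(expected * (1 - expected) / n)
        assert abs(observed - expected) <= 3 * se

    @given(afs=afs_strategy)
    @settings(max_examples=100)
    def test_in_unit_interval(self, afs):
        assert 0.0 <= cap(afs) <= 1.0

    @given(afs=st.lists(st.floats(0.0, 0.999), min_size=1, max_size=20),
           extra=st.floats(0.0, 0.999))
    @settings(max_examples=100)
    def test_monotone_in_added_variant(self, afs, extra):
        assert cap(afs + [extra]) >= cap(afs) - 1e-15

    @given(afs=st.lists(st.floats(0.0, 0.5), min_size=1, max_size=10),
           idx=st.integers(0, 9), bump=st.floats(0.0, 0.4))
    @settings(max_examples=100)
    def test_monotone_in_each_af(self, afs, idx, bump):
        idx %= len(afs)
        bumped = list(afs)
        bumped[idx] = min(1.0, bumped[idx] + bump)
        assert cap(bumped) >= cap(afs) - 1e-15

    def test_log_space_stability(self):
        afs = [1e-6] * 10**4
        expected = 1.0 - math.exp(2 * sum(math.log1p(-a) for a in afs))
        got = cap(afs)
        assert got > 0.0
        assert abs(got - expected) / expected < 1e-9
        # agrees with the closed form 1 - (1-p)^(2n)
        closed = -math.expm1(2 * 10**4 * math.log1p(-1e-6))
        assert got == pytest.approx(closed, rel=1e-9)


class TestCapLof:
    def test_no_lof_variants(self):
        table = table_from_afs([0.1, 0.2])
        assert cap_lof(table) == 0.0

    def test_all_lof_equals_full_cap(self):
        table = table_from_afs([0.1, 0.2], classes=[FunctionalClass.LOF] * 2)
        assert cap_lof(table) == cap_gene(table)

    def test_mixed_equals_subset_oracle(self):
        rng = random.Random(9)
        afs = [rng.uniform(0, 0.3) for _ in range(20)]
        classes = [rng.choice([FunctionalClass.LOF, FunctionalClass.DAMAGING])
                   for _ in range(20)]
        table = table_from_afs(afs, classes=classes)
        lof_afs = table.afs(GLOBAL, classes=(FunctionalClass.LOF,))
        brute = 1.0
        for af in lof_afs:
            brute *= (1 - af) ** 2
        assert cap_lof(table) == pytest.approx(1 - brute, abs=1e-12)


class TestDrp:
    def test_single_gene_equals_cap(self):
        table = table_from_afs([0.1, 0.2])
        assert drp({"G1": table}) == pytest.approx(cap_gene(table), abs=1e-15)

    def test_two_genes_combination(self):
        g1 = table_from_afs([0.5], gene="G1")        # CAP 0.75? no: 1-0.25=0.75
        g2 = table_from_afs([], gene="G2")
        assert drp({"G1": g1, "G2": g2}) == pytest.approx(cap_gene(g1), abs=1e-15)

    def test_cap_composition(self):
        # CAPs 0.2 and 0.5 -> 1 - 0.8*0.5 = 0.6
        af1 = 1 - math.sqrt(0.8)   # single-variant AF giving CAP 0.2
        af2 = 1 - math.sqrt(0.5)
        g1 = table_from_afs([af1], gene="G1", an=10**9)
        g2 = table_from_afs([af2], gene="G2", an=10**9)
        assert drp({"G1": g1, "G2": g2}) == pytest.approx(0.6, abs=1e-6)

    def test_empty_gene_set_rejected(self):
        with pytest.raises(ValueError):
            drp({})

    def test_double_product_equals_cap_product_form(self):
        rng = random.Random(10)
        tables = {}
        for g in range(5):
            afs = [rng.uniform(0, 0.2) for _ in range(rng.randint(0, 15))]
            tables[f"G{g}"] = table_from_afs(afs, gene=f"G{g}", an=10**8)
        via_caps = 1.0
        for t in tables.values():
            via_caps *= 1 - cap_gene(t)
        assert drp(tables) == pytest.approx(1 - via_caps, abs=1e-12)

    def test_shared_variant_counted_per_gene_by_default(self):
        shared = GeneVariant(key="1:5:C:T", functional_class=FunctionalClass.DAMAGING,
                             counts={GLOBAL: AlleleCounts(ac=10, an=100)})
        t1 = GeneVariantTable(gene="G1", variants=[shared])
        t2 = GeneVariantTable(gene="G2", variants=[shared])
        literal = drp({"G1": t1, "G2": t2})
        deduped = drp({"G1": t1, "G2": t2}, deduplicate_across_genes=True)
        assert literal == pytest.approx(1 - (1 - 0.1) ** 4, abs=1e-12)
        assert deduped == pytest.approx(1 - (1 - 0.1) ** 2, abs=1e-12)

    def test_monte_carlo_multi_gene(self):
        rng = random.Random(11)
        tables = {}
        all_afs = []
        for g in range(3):
            afs = [rng.uniform(0.01, 0.2) for _ in range(4)]
            all_afs.extend(afs)
            tables[f"G{g}"] = table_from_afs(afs, gene=f"G{g}", an=10**8)
        n = 200_000
        observed = simulate_individuals(all_afs, n, seed=12)
        expected = drp(tables)
        se = math.sqrt(expected * (1 - expected) / n)
        assert abs(observed - expected) <= 3 * se


class TestRareDecomposition:
    def test_all_rare_no_common_cap(self):
        table = table_from_afs([1e-4, 5e-4], an=10**6)
        cap_rare, cap_common = rare_contribution(table)
        assert cap_common == 0.0
        assert cap_rare > 0.0

    def test_boundary_af_is_common(self):
        table = table_from_afs([0.001], an=10**6)
        cap_rare, cap_common = rare_contribution(table)
        assert cap_rare == 0.0
        assert cap_common > 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_partition_identity(self, seed):
        rng = random.Random(seed)
        afs = [10 ** rng.uniform(-6, -0.5) for _ in range(30)]
        table = table_from_afs(afs, an=10**9)
        cap_rare, cap_common = rare_contribution(table)
        combined = 1 - (1 - cap_rare) * (1 - cap_common)
        assert combined == pytest.approx(cap_gene(table), abs=1e-12)


class TestRareCommonFraction:
    def test_even_split(self):
        table = table_from_afs([0.0005, 0.002], an=10**6)
        assert rare_common_fraction(table) == (0.5, 0.5)

    def test_all_rare(self):
        table = table_from_afs([1e-5, 2e-5], an=10**6)
        assert rare_common_fraction(table) == (1.0, 0.0)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            rare_common_fraction(table_from_afs([]))

    def test_matches_brute_force_counting(self):
        rng = random.Random(13)
        afs = [10 ** rng.uniform(-6, -1) for _ in range(40)]
        table = table_from_afs(afs, an=10**9)
        frac_rare, frac_common = rare_common_fraction(table)
        emitted = table.afs(GLOBAL)
        n_rare = sum(1 for a in emitted if a < 0.001)
        assert frac_rare == pytest.approx(n_rare / len(emitted))
        assert frac_rare + frac_common == pytest.approx(1.0)


class TestVariantsPerResidue:
    def test_direct_ratio(self):
        table = table_from_afs([0.01] * 36, protein_length=100)
        assert variants_per_residue(table) == pytest.approx(0.36)

    def test_zero_variants(self):
        table = table_from_afs([], protein_length=100)
        assert variants_per_residue(table) == 0.0

    def test_missing_length_unavailable(self):
        table = table_from_afs([0.01])
        assert variants_per_residue(table) is None

    def test_hand_computed_fixture(self):
        table = table_from_afs(
            [0.1, 0.2, 0.3],
            classes=[FunctionalClass.LOF, FunctionalClass.DAMAGING,
                     FunctionalClass.OTHER],
            protein_length=10,
        )
        # OTHER variants do not count as functional
        assert variants_per_residue(table) == pytest.approx(0.2)


class TestGeneVariantTable:
    def test_duplicate_keys_rejected(self):
        v = GeneVariant(key="1:1:C:T", functional_class=FunctionalClass.LOF,
                        counts={GLOBAL: AlleleCounts(ac=1, an=10)})
        with pytest.raises(ValueError):
            GeneVariantTable(gene="G", variants=[v, v])

    def test_undefined_af_contributes_nothing(self):
        v = GeneVariant(key="1:1:C:T", functional_class=FunctionalClass.DAMAGING,
                        counts={GLOBAL: AlleleCounts(ac=0, an=0)})
        table = GeneVariantTable(gene="G", variants=[v])
        assert table.afs(GLOBAL) == []
        assert cap_gene(table) == 0.0
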