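"""Region/effect vocabulary, tally matrices, and the published derived-row
arithmetic."""

import random
from collections import Counter

import pytest

from varsieve.annotate_classify import (
    EXONIC_REGIONS,
    GENES_ROW,
    INTRAGENIC_REGIONS,
    INTRAGENIC_ROW,
    NONSYNONYMOUS_EFFECTS,
    TOTAL_ROW,
    EffectClass,
    RegionClass,
    distinct_gene_count,
    effect_of,
    nonsynonymous_subset,
    parse_effect,
    parse_region,
    region_of,
    tally_effects,
    tally_regions,
)
from varsieve.cohort_sets import REPORTED_CLASSES, MembershipClass
from varsieve.io_formats import AnnotationRecord
from varsieve.variant_core import VariantType, normalize, variant_type


class TestRegionVocabulary:
    @pytest.mark.parametrize(
        "text, expected",
        [
            ("exonic", RegionClass.EXONIC),
            ("UTR5", RegionClass.UTR5),
            ("5'UTR", RegionClass.UTR5),
            ("ncRNA_exonic;splicing", RegionClass.NCRNA_EXONIC_SPLICING),
            ("ncRNA exonic; splicing", RegionClass.NCRNA_EXONIC_SPLICING),
            ("Exonic; Splicing", RegionClass.EXONIC_SPLICING),
            ("Upstream; Downstream", RegionClass.UPSTREAM_DOWNSTREAM),
            ("NA", RegionClass.NA),
        ],
    )
    def test_dialect_mapping(self, text, expected):
        assert parse_region(text) is expected

    def test_every_level_round_trips(self):
        for level in RegionClass:
            assert parse_region(level.value) is level

    def test_unrecognized_region_raises_not_na(self):
        with pytest.raises(ValueError, match="unrecognized region"):
            parse_region("exomic")


class TestEffectVocabulary:
    @pytest.mark.parametrize(
        "text, expected",
        [
            ("missense SNV", EffectClass.MISSENSE),
            ("frameshift deletion", EffectClass.FRAMESHIFT_DELETION),
            ("Non-frameshift insertion", EffectClass.NONFRAMESHIFT_INSERTION),
            ("stop gain", EffectClass.STOPGAIN),
            ("nonsense", EffectClass.STOPGAIN),  # prose and table name one level
            ("stopgain", EffectClass.STOPGAIN),
        ],
    )
    def test_dialect_mapping(self, text, expected):
        assert parse_effect(text) is expected

    def test_unrecognized_effect_raises(self):
        with pytest.raises(ValueError, match="unrecognized effect"):
            parse_effect("misssense")


def make_records(rng, n=200):
    """Random annotated records plus a membership map, for oracle checks."""
    regions = list(RegionClass)
    classes = list(MembershipClass)
    records, membership = [], {}
    for i in range(n):
        if rng.random() < 0.3:
            key = normalize("2", 1000 + i, "A", "AT" if rng.random() < 0.5 else "ATG")
        else:
            key = normalize("2", 1000 + i, "A", "G")
        region = rng.choice(regions)
        effect = None
        if region in EXONIC_REGIONS:
            if variant_type(key) is VariantType.SNP:
                effect = rng.choice(
                    [EffectClass.MISSENSE, EffectClass.SYNONYMOUS,
                     EffectClass.UNKNOWN, EffectClass.STOPGAIN]
                )
            else:
                effect = rng.choice(
                    [EffectClass.FRAMESHIFT_INSERTION, EffectClass.NONFRAMESHIFT_INSERTION,
                     EffectClass.UNKNOWN]
                )
        genes = (
            []
            if region in (RegionClass.INTERGENIC, RegionClass.NA)
            else [f"G{rng.randint(1, 40)}"]
        )
        records.append(
            AnnotationRecord(key=key, genes=genes, region=region, effect=effect)
        )
        membership[key] = rng.choice(classes)
    return records, membership


class TestTallies:
    def test_empty_input_gives_zero_matrices(self):
        matrices = tally_regions([], {})
        for vtype in (VariantType.SNP, VariantType.INDEL):
            assert (matrices[vtype].to_numpy() == 0).all()

    def test_region_tally_matches_group_by_oracle(self):
        rng = random.Random(0)
        for trial in range(10):
            records, membership = make_records(rng)
            matrices = tally_regions(records, membership)
            oracle = Counter()
            for rec in records:
                cls = membership[rec.key]
                if cls is MembershipClass.EXCLUDED:
                    continue
                oracle[(variant_type(rec.key), rec.region, cls)] += 1
            for (vtype, region, cls), n in oracle.items():
                assert matrices[vtype].loc[region.value, cls.value] == n
            # partition: total row equals the number of tallied records
            for vtype in (VariantType.SNP, VariantType.INDEL):
                expected_total = sum(
                    n for (vt, _, _), n in oracle.items() if vt is vtype
                )
                assert matrices[vtype].loc[TOTAL_ROW].sum() == expected_total

    def test_effect_tally_matches_group_by_oracle(self):
        rng = random.Random(1)
        records, membership = make_records(rng)
        matrices = tally_effects(records, membership)
        oracle = Counter()
        for rec in records:
            cls = membership[rec.key]
            if cls is MembershipClass.EXCLUDED or rec.region not in EXONIC_REGIONS:
                continue
            oracle[(variant_type(rec.key), rec.effect, cls)] += 1
        for (vtype, effect, cls), n in oracle.items():
            assert matrices[vtype].loc[effect.value, cls.value] == n

    def test_excluded_and_unclassified_records_are_omitted(self):
        key1 = normalize("1", 10, "A", "G")
        key2 = normalize("1", 20, "A", "G")
        records = [
            AnnotationRecord(key=key1, genes=["A"], region=RegionClass.EXONIC,
                             effect=EffectClass.MISSENSE),
            AnnotationRecord(key=key2, genes=["B"], region=RegionClass.EXONIC,
                             effect=EffectClass.MISSENSE),
        ]
        membership = {key1: MembershipClass.EXCLUDED}  # key2 unclassified
        matrices = tally_regions(records, membership)
        assert matrices[VariantType.SNP].loc[TOTAL_ROW].sum() == 0


class TestPublishedDerivedRows:
    """Printed-table arithmetic: Intragenic and Total identities."""

    def test_intragenic_rows_equal_component_sums(self, fixtures):
        member_rows = [rc.value for rc in RegionClass if rc in INTRAGENIC_REGIONS]
        for vtype, matrix in fixtures["region_counts"].items():
            for col in matrix.columns:
                assert matrix.loc[INTRAGENIC_ROW, col] == matrix[col][member_rows].sum(), (
                    vtype, col,
                )

    def test_total_rows_equal_region_sums(self, fixtures):
        top_rows = [rc.value for rc in RegionClass]
        for vtype, matrix in fixtures["region_counts"].items():
            for col in matrix.columns:
                assert matrix.loc[TOTAL_ROW, col] == matrix[col][top_rows].sum()

    def test_intragenic_example_cell(self, fixtures):
        snp = fixtures["region_counts"][VariantType.SNP]
        assert snp.loc[INTRAGENIC_ROW, "Saliva;Blood"] == 73 + 67 + 5 + 12 == 157

    def test_effect_table_lesion_specific_snp_column(self, fixtures):
        snp = fixtures["effect_counts"][VariantType.SNP]
        col = snp["Lesion-Specific"]
        assert col["missense"] == 9
        assert col["synonymous"] == 5
        assert col["unknown"] == 4
        assert col[TOTAL_ROW] == 18

    def test_effect_totals_match_cell_sums_where_printed_consistently(self, fixtures):
        """All printed effect columns are internally consistent except the
        known one-off in the SNP common-group column (printed total 1866 vs
        cell sum 1867), which the tally code would report as 1867."""
        effect_rows = [ec.value for ec in EffectClass]
        for vtype, matrix in fixtures["effect_counts"].items():
            for col in matrix.columns:
                cell_sum = matrix[col][effect_rows].sum()
                printed = matrix.loc[TOTAL_ROW, col]
                if vtype is VariantType.SNP and col == "Saliva;Blood;Lesion":
                    assert (printed, cell_sum) == (1866, 1867)
                else:
                    assert printed == cell_sum, (vtype, col)


class TestNonsynonymousSubset:
    def test_missense_kept_synonymous_dropped(self):
        key1 = normalize("1", 10, "A", "G")
        key2 = normalize("1", 20, "A", "G")
        records = [
            AnnotationRecord(key=key1, genes=["A"], region=RegionClass.EXONIC,
                             effect=EffectClass.MISSENSE),
            AnnotationRecord(key=key2, genes=["B"], region=RegionClass.EXONIC,
                             effect=EffectClass.SYNONYMOUS),
        ]
        kept = nonsynonymous_subset(records)
        assert [r.key for r in kept] == [key1]

    def test_no_record_lost_from_effect_partition(self):
        rng = random.Random(2)
        records, _ = make_records(rng)
        effect_bearing = [r for r in records if r.effect is not None]
        non_syn = nonsynonymous_subset(effect_bearing)
        synonymous = [r for r in effect_bearing if r.effect is EffectClass.SYNONYMOUS]
        frameshifty = [
            r for r in effect_bearing
            if r.effect not in NONSYNONYMOUS_EFFECTS and r.effect is not EffectClass.SYNONYMOUS
        ]
        assert len(non_syn) + len(synonymous) + len(frameshifty) == len(effect_bearing)

    def test_published_snp_subset_size(self, fixtures):
        snp = fixtures["effect_counts"][VariantType.SNP]
        kept_rows = ["missense", "stopgain", "unknown"]
        assert snp.loc[kept_rows].sum().sum() == 1020


class TestDistinctGenes:
    def test_empty_is_zero(self):
        assert distinct_gene_count([]) == 0

    def test_published_rare_snp_rows_cover_four_genes(self, fixtures):
        rare = fixtures["rare_annotations"]
        snp_records = [r for r in rare.values() if variant_type(r.key) is VariantType.SNP]
        assert distinct_gene_count(snp_records) == 4

    def test_matches_set_union_oracle_with_semicolon_lists(self):
        rng = random.Random(8)
        records = []
        oracle = set()
        for i in range(60):
            genes = [f"G{rng.randint(1, 15)}" for _ in range(rng.randint(1, 3))]
            oracle.update(genes)
            records.append(
                AnnotationRecord(
                    key=normalize("1", 100 + i, "A", "G"),
                    genes=genes,
                    region=RegionClass.EXONIC,
                    effect=EffectClass.MISSENSE,
                )
            )
        assert distinct_gene_count(records) == len(oracle)


def test_region_of_and_effect_of_accept_records_and_strings():
    rec = AnnotationRecord(
        key=normalize("1", 10, "A", "G"),
        genes=["X"],
        region=RegionClass.SPLICING,
        effect=EffectClass.UNKNOWN,
    )
    assert region_of(rec) is RegionClass.SPLICING
    assert effect_of(rec) is EffectClass.UNKNOWN
    assert region_of("splicing") is RegionClass.SPLICING
    assert effect_of("unknown") is EffectClass.UNKNOWN
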