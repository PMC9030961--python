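"""Region and exonic-effect classification plus the summary tally matrices.

Annotations arrive from an upstream functional annotator (ANNOVAR-style
``Func`` / ``ExonicFunc`` columns); this module maps those strings onto a
fixed vocabulary, tallies variants per region-or-effect × membership class,
and appends the derived rows the study's summary tables print:

* ``Intragenic`` — the sum of the seven genic region rows (exonic,
  exonic;splicing, splicing, intronic, UTR5, UTR3, UTR5;UTR3);
* ``Total variants`` — the sum of all disjoint top-level region rows;
* ``(Total Genes)`` — the number of distinct gene symbols touched.

"Nonsense" (prose) and "stopgain" (table vocabulary) are the same level.
Effects labelled "unknown" by the annotator are counted as *nonsynonymous*
alongside missense and stop-gain — the convention this pipeline follows for
its nonsynonymous subset — while synonymous changes are excluded.
"""

from __future__ import annotations

import enum
from typing import TYPE_CHECKING, Iterable, Mapping

import pandas as pd

from .cohort_sets import REPORTED_CLASSES, MembershipClass
from .variant_core import VariantKey, VariantType, variant_type

if TYPE_CHECKING:  # pragma: no cover
    from .io_formats import AnnotationRecord

__all__ = [
    "RegionClass",
    "EffectClass",
    "INTRAGENIC_REGIONS",
    "EXONIC_REGIONS",
    "NONSYNONYMOUS_EFFECTS",
    "region_of",
    "effect_of",
    "parse_region",
    "parse_effect",
    "tally_regions",
    "tally_effects",
    "nonsynonymous_subset",
    "distinct_gene_count",
    "split_genes",
]


class RegionClass(enum.Enum):
    """Genomic region of a variant, in the upstream annotator's vocabulary."""

    EXONIC = "exonic"
    EXONIC_SPLICING = "exonic;splicing"
    SPLICING = "splicing"
    INTRONIC = "intronic"
    UTR5 = "UTR5"
    UTR3 = "UTR3"
    UTR5_UTR3 = "UTR5;UTR3"
    INTERGENIC = "intergenic"
    UPSTREAM = "upstream"
    DOWNSTREAM = "downstream"
    UPSTREAM_DOWNSTREAM = "upstream;downstream"
    NCRNA_EXONIC = "ncRNA_exonic"
    NCRNA_SPLICING = "ncRNA_splicing"
    NCRNA_INTRONIC = "ncRNA_intronic"
    NCRNA_EXONIC_SPLICING = "ncRNA_exonic;splicing"
    NA = "NA"


#: Regions whose sum forms the derived "Intragenic" row.
INTRAGENIC_REGIONS: frozenset[RegionClass] = frozenset(
    {
        RegionClass.EXONIC,
        RegionClass.EXONIC_SPLICING,
        RegionClass.SPLICING,
        RegionClass.INTRONIC,
        RegionClass.UTR5,
        RegionClass.UTR3,
        RegionClass.UTR5_UTR3,
    }
)

#: Regions admitted to the exonic-effect table (exonic and splice-touching).
EXONIC_REGIONS: frozenset[RegionClass] = frozenset(
    {RegionClass.EXONIC, RegionClass.EXONIC_SPLICING, RegionClass.SPLICING}
)


class EffectClass(enum.Enum):
    MISSENSE = "missense"
    SYNONYMOUS = "synonymous"
    STOPGAIN = "stopgain"
    UNKNOWN = "unknown"
    FRAMESHIFT_INSERTION = "frameshift_insertion"
    FRAMESHIFT_DELETION = "frameshift_deletion"
    NONFRAMESHIFT_INSERTION = "nonframeshift_insertion"
    NONFRAMESHIFT_DELETION = "nonframeshift_deletion"


#: Effects the pipeline counts as nonsynonymous for SNVs: missense,
#: stop-gain, and annotator-"unknown" changes; synonymous is excluded.
NONSYNONYMOUS_EFFECTS: frozenset[EffectClass] = frozenset(
    {EffectClass.MISSENSE, EffectClass.STOPGAIN, EffectClass.UNKNOWN}
)


def _normalize_token(text: str) -> str:
    # collapse the cosmetic variation seen in published tables:
    # "Exonic; Splicing", "ncRNA exonic", curly apostrophes in "5'UTR"
    t = text.strip().replace("’", "'")
    t = ";".join(part.strip() for part in t.split(";"))
    return t


_REGION_ALIASES: dict[str, RegionClass] = {}
for _rc in RegionClass:
    _REGION_ALIASES[_rc.value.lower()] = _rc
for _alias, _rc in {
    "5'utr": RegionClass.UTR5,
    "3'utr": RegionClass.UTR3,
    "5'utr;3'utr": RegionClass.UTR5_UTR3,
    "ncrna exonic": RegionClass.NCRNA_EXONIC,
    "ncrna splicing": RegionClass.NCRNA_SPLICING,
    "ncrna intronic": RegionClass.NCRNA_INTRONIC,
    "ncrna exonic;splicing": RegionClass.NCRNA_EXONIC_SPLICING,
}.items():
    _REGION_ALIASES[_alias] = _rc


def parse_region(text: str) -> RegionClass:
    """Map an annotator region string to a :class:`RegionClass`.

    Unrecognized strings raise — a typo in an input table must never be
    silently folded into ``NA``.
    """
    token = _normalize_token(text).lower()
    try:
        return _REGION_ALIASES[token]
    except KeyError:
        raise ValueError(
            f"unrecognized region annotation {text!r}; known values: "
            f"{sorted(rc.value for rc in RegionClass)}"
        ) from None


_EFFECT_ALIASES: dict[str, EffectClass] = {
    "missense": EffectClass.MISSENSE,
    "missense snv": EffectClass.MISSENSE,
    "nonsynonymous snv": EffectClass.MISSENSE,
    "synonymous": EffectClass.SYNONYMOUS,
    "synonymous snv": EffectClass.SYNONYMOUS,
    "stopgain": EffectClass.STOPGAIN,
    "stop gain": EffectClass.STOPGAIN,
    "stopgain snv": EffectClass.STOPGAIN,
    "nonsense": EffectClass.STOPGAIN,
    "unknown": EffectClass.UNKNOWN,
    "frameshift insertion": EffectClass.FRAMESHIFT_INSERTION,
    "frameshift_insertion": EffectClass.FRAMESHIFT_INSERTION,
    "frameshift deletion": EffectClass.FRAMESHIFT_DELETION,
    "frameshift_deletion": EffectClass.FRAMESHIFT_DELETION,
    "nonframeshift insertion": EffectClass.NONFRAMESHIFT_INSERTION,
    "nonframeshift_insertion": EffectClass.NONFRAMESHIFT_INSERTION,
    "non-frameshift insertion": EffectClass.NONFRAMESHIFT_INSERTION,
    "nonframeshift deletion": EffectClass.NONFRAMESHIFT_DELETION,
    "nonframeshift_deletion": EffectClass.NONFRAMESHIFT_DELETION,
    "non-frameshift deletion": EffectClass.NONFRAMESHIFT_DELETION,
}


def parse_effect(text: str) -> EffectClass:
    """Map an annotator exonic-effect string to an :class:`EffectClass`."""
    token = _normalize_token(text).lower()
    try:
        return _EFFECT_ALIASES[token]
    except KeyError:
        raise ValueError(
            f"unrecognized effect annotation {text!r}; known values include "
            f"{sorted(set(_EFFECT_ALIASES))}"
        ) from None


def region_of(record: "AnnotationRecord | str") -> RegionClass:
    """Region class of an annotation record (or a raw region string)."""
    if isinstance(record, str):
        return parse_region(record)
    region = record.region
    return region if isinstance(region, RegionClass) else parse_region(region)


def effect_of(record: "AnnotationRecord | str") -> EffectClass | None:
    """Effect class of an annotation record, or None when not annotated."""
    if isinstance(record, str):
        return parse_effect(record)
    effect = record.effect
    if effect is None:
        return None
    return effect if isinstance(effect, EffectClass) else parse_effect(effect)


def split_genes(genes: str | Iterable[str]) -> list[str]:
    """Split a ``;``-joined gene field into individual symbols."""
    if isinstance(genes, str):
        genes = genes.split(";")
    return [g.strip() for g in genes if g and g.strip() and g.strip() != "."]


def distinct_gene_count(records: Iterable["AnnotationRecord"]) -> int:
    """Number of distinct gene symbols across records (``;`` lists split)."""
    symbols: set[str] = set()
    for rec in records:
        symbols.update(split_genes(rec.genes))
    return len(symbols)


_REGION_ROW_ORDER: tuple[RegionClass, ...] = (
    RegionClass.EXONIC,
    RegionClass.INTRONIC,
    RegionClass.EXONIC_SPLICING,
    RegionClass.SPLICING,
    RegionClass.UTR5,
    RegionClass.UTR3,
    RegionClass.UTR5_UTR3,
    RegionClass.INTERGENIC,
    RegionClass.UPSTREAM_DOWNSTREAM,
    RegionClass.UPSTREAM,
    RegionClass.DOWNSTREAM,
    RegionClass.NCRNA_EXONIC,
    RegionClass.NCRNA_SPLICING,
    RegionClass.NCRNA_INTRONIC,
    RegionClass.NCRNA_EXONIC_SPLICING,
    RegionClass.NA,
)

_EFFECT_ROW_ORDER: tuple[EffectClass, ...] = (
    EffectClass.MISSENSE,
    EffectClass.SYNONYMOUS,
    EffectClass.UNKNOWN,
    EffectClass.STOPGAIN,
    EffectClass.NONFRAMESHIFT_INSERTION,
    EffectClass.NONFRAMESHIFT_DELETION,
    EffectClass.FRAMESHIFT_INSERTION,
    EffectClass.FRAMESHIFT_DELETION,
)

INTRAGENIC_ROW = "Intragenic"
TOTAL_ROW = "Total variants"
GENES_ROW = "(Total Genes)"


def _empty_matrix(row_labels: list[str]) -> pd.DataFrame:
    cols = [cls.value for cls in REPORTED_CLASSES]
    return pd.DataFrame(0, index=pd.Index(row_labels, name="row"), columns=cols)


def add_region_derived_rows(matrix: pd.DataFrame) -> pd.DataFrame:
    """Append (or recompute) Intragenic and Total rows of a region matrix."""
    base = matrix.loc[[rc.value for rc in _REGION_ROW_ORDER]]
    out = base.copy()
    intragenic = base.loc[[rc.value for rc in _REGION_ROW_ORDER if rc in INTRAGENIC_REGIONS]].sum()
    total = base.sum()
    out.loc[INTRAGENIC_ROW] = intragenic
    out.loc[TOTAL_ROW] = total
    return out


def _select(
    records: Iterable["AnnotationRecord"],
    membership: Mapping[VariantKey, MembershipClass],
) -> list[tuple["AnnotationRecord", MembershipClass, VariantType]]:
    picked = []
    for rec in records:
        cls = membership.get(rec.key)
        if cls is None or cls is MembershipClass.EXCLUDED:
            continue
        vtype = variant_type(rec.key)
        if vtype is VariantType.OTHER:
            continue  # MNVs are outside the SNP/InDel partition
        picked.append((rec, cls, vtype))
    return picked


def tally_regions(
    records: Iterable["AnnotationRecord"],
    membership: Mapping[VariantKey, MembershipClass],
) -> dict[VariantType, pd.DataFrame]:
    """Region × membership-class count matrices, one per variant type.

    Records whose key is unclassified or EXCLUDED are omitted, as are MNVs.
    Derived Intragenic / Total-variants / (Total Genes) rows are appended.
    """
    picked = _select(records, membership)
    out: dict[VariantType, pd.DataFrame] = {}
    for vtype in (VariantType.SNP, VariantType.INDEL):
        matrix = _empty_matrix([rc.value for rc in _REGION_ROW_ORDER])
        per_cell_records: dict[str, list] = {c: [] for c in matrix.columns}
        for rec, cls, vt in picked:
            if vt is not vtype:
                continue
            matrix.loc[region_of(rec).value, cls.value] += 1
            per_cell_records[cls.value].append(rec)
        matrix = add_region_derived_rows(matrix)
        matrix.loc[GENES_ROW] = [
            distinct_gene_count(per_cell_records[c]) for c in matrix.columns
        ]
        out[vtype] = matrix
    return out


def tally_effects(
    records: Iterable["AnnotationRecord"],
    membership: Mapping[VariantKey, MembershipClass],
) -> dict[VariantType, pd.DataFrame]:
    """Exonic-effect × membership-class count matrices, one per variant type.

    Restricted to records in exonic / exonic;splicing / splicing regions.
    Records there without an effect annotation are an input defect and raise.
    """
    picked = [
        (rec, cls, vt)
        for rec, cls, vt in _select(records, membership)
        if region_of(rec) in EXONIC_REGIONS
    ]
    out: dict[VariantType, pd.DataFrame] = {}
    for vtype in (VariantType.SNP, VariantType.INDEL):
        matrix = _empty_matrix([ec.value for ec in _EFFECT_ROW_ORDER])
        per_cell_records: dict[str, list] = {c: [] for c in matrix.columns}
        for rec, cls, vt in picked:
            if vt is not vtype:
                continue
            effect = effect_of(rec)
            if effect is None:
                raise ValueError(
                    f"exonic record {rec.key} has no effect annotation"
                )
            matrix.loc[effect.value, cls.value] += 1
            per_cell_records[cls.value].append(rec)
        matrix.loc[TOTAL_ROW] = matrix.loc[[ec.value for ec in _EFFECT_ROW_ORDER]].sum()
        matrix.loc[GENES_ROW] = [
            distinct_gene_count(per_cell_records[c]) for c in matrix.columns
        ]
        out[vtype] = matrix
    return out


def nonsynonymous_subset(
    records: Iterable["AnnotationRecord"],
) -> list["AnnotationRecord"]:
    """Records with a nonsynonymous effect (missense, stop-gain, unknown).

    Synonymous records and records without an effect annotation are dropped.
    """
    return [rec for rec in records if effect_of(rec) in NONSYNONYMOUS_EFFECTS]
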