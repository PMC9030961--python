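"""Readers and writers for every file format the pipeline touches.

* VCF 4.x per-patient callsets (read through pysam; multi-allelic records
  are split, keys normalized, non-PASS records dropped);
* flat variant-set files (TSV with chrom/pos/ref/alt columns, or a VCF) for
  the population-control and external saliva cohorts;
* per-variant annotation tables in the upstream annotator's dialect, where
  missing values are printed ``./.`` or ``.`` and predictor columns may hold
  ``score, letter`` pairs — only the numeric score is trusted; the letter is
  recomputed downstream so the classifier stays testable against published
  letters;
* GMT gene-set files for enrichment;
* TSV output with deterministic column and row order.

Genotype columns are ignored throughout: cohort sharing is presence-based.
"""

from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import pysam

from .annotate_classify import EffectClass, RegionClass, parse_effect, parse_region
from .cohort_sets import PatientCallset, Tissue
from .variant_core import VariantKey, normalize

__all__ = [
    "AnnotationRecord",
    "read_vcf",
    "write_vcf",
    "read_variant_set",
    "write_variant_set",
    "read_annotations",
    "write_annotations",
    "ANNOTATION_COLUMNS",
    "read_gmt",
    "write_gmt",
    "write_table",
]

_MISSING_TOKENS = {"", ".", "./.", "NA", "na"}


@dataclass
class AnnotationRecord:
    """Functional annotation of one variant key.

    Frequencies are alternate-allele population frequencies in [0, 1];
    predictor scores are in [0, 1].  ``None`` means the source printed a
    missing marker.  ``genes`` holds the already-split symbol list.
    """

    key: VariantKey
    genes: list[str]
    region: RegionClass
    effect: EffectClass | None = None
    hgvs_c: str | None = None
    hgvs_p: str | None = None
    dbsnp_id: str | None = None
    af_1000g: float | None = None
    af_esp: float | None = None
    af_exac: float | None = None
    sift_score: float | None = None
    pp2_hvar: float | None = None
    pp2_hdiv: float | None = None

    def __post_init__(self) -> None:
        for name in ("af_1000g", "af_esp", "af_exac", "sift_score", "pp2_hvar", "pp2_hdiv"):
            value = getattr(self, name)
            if value is not None and not 0.0 <= value <= 1.0:
                raise ValueError(f"{name}={value} outside [0, 1] for {self.key}")
        if self.region not in (
            RegionClass.INTERGENIC,
            RegionClass.NA,
        ) and not self.genes:
            raise ValueError(f"genic record {self.key} has no gene symbol")


# ---------------------------------------------------------------------------
# VCF

def read_vcf(path: str | Path, sample_label: str, tissue: Tissue | str) -> PatientCallset:
    """Read one patient/tissue callset from a VCF 4.x file.

    Multi-allelic records contribute one key per ALT allele; keys are
    normalized and deduplicated.  Records whose FILTER is anything other
    than PASS or missing are excluded, as are symbolic/spanning alleles
    (``<DEL>``, ``*``) which carry no sequence to compare.
    """
    path = Path(path)
    keys: set[VariantKey] = set()
    try:
        vcf = pysam.VariantFile(str(path))
    except (ValueError, OSError) as exc:
        raise ValueError(f"cannot parse VCF {path}: {exc}") from exc
    with vcf:
        for i, rec in enumerate(vcf, start=1):
            filters = list(rec.filter.keys())
            if filters and filters != ["PASS"]:
                continue
            if rec.alts is None:
                continue
            for alt in rec.alts:
                if not alt or alt in ("*", ".") or alt.startswith("<"):
                    continue
                try:
                    keys.add(normalize(rec.chrom, rec.pos, rec.ref, alt))
                except ValueError as exc:
                    raise ValueError(
                        f"{path} record {i} ({rec.chrom}:{rec.pos}): {exc}"
                    ) from exc
    if not keys:
        warnings.warn(f"VCF {path} yielded an empty callset", stacklevel=2)
    return PatientCallset(patient_id=sample_label, tissue=Tissue(tissue), keys=frozenset(keys))


def write_vcf(keys: Iterable[VariantKey], path: str | Path, sample_label: str = "SAMPLE") -> None:
    """Write a sites-level VCF 4.2 file for a set of keys (sorted order).

    One trivially-genotyped sample column is emitted so the file exercises
    the same code path as caller-produced VCFs; genotypes carry no meaning
    in this presence-based pipeline.
    """
    keys = sorted(set(keys))
    seen: list[str] = []
    for k in keys:
        if k.chrom not in seen:
            seen.append(k.chrom)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in seen:
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample_label}\n")
        for k in keys:
            fh.write(f"{k.chrom}\t{k.pos}\t.\t{k.ref}\t{k.alt}\t.\tPASS\t.\tGT\t0/1\n")


# ---------------------------------------------------------------------------
# Flat variant sets (control / saliva)

def read_variant_set(path: str | Path) -> frozenset[VariantKey]:
    """Read a flat variant list: TSV with chrom/pos/ref/alt columns, or VCF."""
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline()
    if first.startswith("##fileformat=VCF") or path.suffix.lower() == ".vcf":
        return frozenset(read_vcf(path, sample_label=path.stem, tissue=Tissue.BLOOD).keys)
    frame = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    frame.columns = [c.strip().lower() for c in frame.columns]
    required = {"chrom", "pos", "ref", "alt"}
    if not required <= set(frame.columns):
        raise ValueError(
            f"variant-set file {path} must have columns {sorted(required)}; "
            f"found {list(frame.columns)}"
        )
    keys = set()
    for row in frame.itertuples(index=False):
        keys.add(normalize(row.chrom, int(row.pos), row.ref, row.alt))
    return frozenset(keys)


def write_variant_set(keys: Iterable[VariantKey], path: str | Path) -> None:
    frame = pd.DataFrame(
        [(k.chrom, k.pos, k.ref, k.alt) for k in sorted(set(keys))],
        columns=["chrom", "pos", "ref", "alt"],
    )
    frame.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Annotation tables

#: Documented header of the annotation TSV dialect.
ANNOTATION_COLUMNS: tuple[str, ...] = (
    "chrom",
    "pos",
    "ref",
    "alt",
    "gene",
    "region",
    "effect",
    "hgvs_c",
    "hgvs_p",
    "dbsnp_id",
    "af_1000g",
    "af_esp",
    "af_exac",
    "sift",
    "pp2_hvar",
    "pp2_hdiv",
)


def _parse_optional_str(token: str) -> str | None:
    token = token.strip()
    return None if token in _MISSING_TOKENS else token


def _parse_score(token: str, column: str, where: str) -> float | None:
    """Parse ``0.032`` or ``0.032, D`` style cells; letters are discarded."""
    token = token.strip()
    if token in _MISSING_TOKENS:
        return None
    numeric = token.split(",")[0].strip()
    try:
        value = float(numeric)
    except ValueError:
        raise ValueError(f"{where}: cannot parse {column} value {token!r}") from None
    if math.isnan(value):
        return None
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{where}: {column} value {value} outside [0, 1]")
    return value


def read_annotations(path: str | Path) -> dict[VariantKey, AnnotationRecord]:
    """Read a per-variant annotation TSV into a key → record mapping.

    The header must contain :data:`ANNOTATION_COLUMNS` (extra columns are
    ignored).  ``./.`` and ``.`` denote missing values.  Predictor cells may
    be ``score, letter`` pairs; only the score survives.  A frequency outside
    [0, 1] or a duplicate normalized key is an error.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    frame.columns = [c.strip().lower() for c in frame.columns]
    missing_cols = set(ANNOTATION_COLUMNS) - set(frame.columns)
    if missing_cols:
        raise ValueError(
            f"annotation table {path} lacks columns {sorted(missing_cols)}; "
            f"found {list(frame.columns)}"
        )
    records: dict[VariantKey, AnnotationRecord] = {}
    for i, row in enumerate(frame.itertuples(index=False), start=2):
        where = f"{path}:{i}"
        key = normalize(row.chrom, int(row.pos), row.ref, row.alt)
        if key in records:
            raise ValueError(f"{where}: duplicate variant key {key}")
        effect_token = _parse_optional_str(row.effect)
        records[key] = AnnotationRecord(
            key=key,
            genes=[g for g in (row.gene or "").replace("*", "").split(";") if g.strip() and g.strip() != "."],
            region=parse_region(row.region),
            effect=parse_effect(effect_token) if effect_token else None,
            hgvs_c=_parse_optional_str(row.hgvs_c),
            hgvs_p=_parse_optional_str(row.hgvs_p),
            dbsnp_id=_parse_optional_str(row.dbsnp_id),
            af_1000g=_parse_score(row.af_1000g, "af_1000g", where),
            af_esp=_parse_score(row.af_esp, "af_esp", where),
            af_exac=_parse_score(row.af_exac, "af_exac", where),
            sift_score=_parse_score(row.sift, "sift", where),
            pp2_hvar=_parse_score(row.pp2_hvar, "pp2_hvar", where),
            pp2_hdiv=_parse_score(row.pp2_hdiv, "pp2_hdiv", where),
        )
    return records


def _fmt(value) -> str:
    if value is None:
        return "."
    if isinstance(value, float):
        return repr(value)  # shortest representation that round-trips exactly
    return str(value)


def write_annotations(
    records: Mapping[VariantKey, AnnotationRecord] | Iterable[AnnotationRecord],
    path: str | Path,
) -> None:
    """Write records back to the annotation TSV dialect (sorted by key)."""
    if isinstance(records, Mapping):
        records = records.values()
    rows = []
    for rec in sorted(records, key=lambda r: r.key):
        rows.append(
            {
                "chrom": rec.key.chrom,
                "pos": rec.key.pos,
                "ref": rec.key.ref,
                "alt": rec.key.alt,
                "gene": ";".join(rec.genes) if rec.genes else ".",
                "region": rec.region.value,
                "effect": rec.effect.value if rec.effect else ".",
                "hgvs_c": _fmt(rec.hgvs_c),
                "hgvs_p": _fmt(rec.hgvs_p),
                "dbsnp_id": _fmt(rec.dbsnp_id),
                "af_1000g": _fmt(rec.af_1000g),
                "af_esp": _fmt(rec.af_esp),
                "af_exac": _fmt(rec.af_exac),
                "sift": _fmt(rec.sift_score),
                "pp2_hvar": _fmt(rec.pp2_hvar),
                "pp2_hdiv": _fmt(rec.pp2_hdiv),
            }
        )
    pd.DataFrame(rows, columns=list(ANNOTATION_COLUMNS)).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GMT gene sets

def read_gmt(path: str | Path) -> dict[str, frozenset[str]]:
    """Read a GMT file: one term per line, tab-separated
    ``term<TAB>description<TAB>gene1<TAB>gene2…``.

    Duplicate genes within a term are deduplicated; a term without genes is
    rejected; a duplicate term name is an error.
    """
    path = Path(path)
    sets: dict[str, frozenset[str]] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs term, description and >= 1 gene"
                )
            term = parts[0].strip()
            genes = frozenset(g.strip() for g in parts[2:] if g.strip())
            if not genes:
                raise ValueError(f"{path}:{lineno}: term {term!r} has no genes")
            if term in sets:
                raise ValueError(f"{path}:{lineno}: duplicate term {term!r}")
            sets[term] = genes
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for term in sorted(sets):
            genes = sorted(set(sets[term]))
            if not genes:
                raise ValueError(f"term {term!r} has no genes")
            fh.write("\t".join([term, "na", *genes]) + "\n")


# ---------------------------------------------------------------------------
# Generic tables

def write_table(table: pd.DataFrame, path: str | Path, index_label: str | None = "row") -> None:
    """Write a DataFrame as TSV with deterministic layout ("." for missing)."""
    table.to_csv(path, sep="\t", na_rep=".", index_label=index_label, quoting=csv.QUOTE_NONE)
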