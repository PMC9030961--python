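"""Deterministic synthetic cohorts with known ground truth, plus packaged
fixtures of the published summary tables.

The study's raw exome data are not deposited, so validation rests on two
surfaces:

1. :func:`generate_cohort` builds a complete, seeded input bundle —
   per-patient blood/lesion VCFs, a population-control set, an external
   saliva-cohort set, and an annotation table — with every non-noise variant
   recorded in a truth manifest (its membership class, variant type, rarity
   flag and, for planted rare variants, the consensus class its predictor
   scores were drawn to realize).  Running the pipeline on the bundle must
   recover the manifest exactly.

2. :func:`table_fixtures` loads verbatim transcriptions of the published
   count tables and the 31-row rare-candidate table, so the printed-table
   arithmetic is reproducible without any sequencing data.

Planted structure mirrors the study design: core variants shared by every
patient in both tissues and present in saliva; blood+saliva and
lesion+saliva groups; lesion-specific variants in every lesion only;
control-overlap variants that the subtraction step must remove; and
patient-private noise in exactly one callset each, which the cohort-wide
intersection must discard (guaranteed for cohorts of at least two patients).

Coordinates are drawn without replacement on chromosomes 21 and 22 — a small
space that still exercises normalization and cross-chromosome sorting.
Predictor scores for planted consensus classes are drawn from the interior
of each class-defining score region (e.g. concordant: SIFT in [0, 0.045),
both PolyPhen-2 in [0.96, 1]) so classification is never decided at a bin
boundary.  One seeded generator drives everything; no global random state.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .annotate_classify import EffectClass, RegionClass
from .cohort_sets import CohortCallset, MembershipClass, PatientCallset, Tissue
from .io_formats import (
    AnnotationRecord,
    write_annotations,
    write_variant_set,
    write_vcf,
)
from .prioritize import ConsensusClass
from .variant_core import VariantKey, VariantType, normalize, variant_type

__all__ = [
    "SyntheticCohortConfig",
    "ManifestEntry",
    "SyntheticBundle",
    "generate_cohort",
    "table_fixtures",
]

_BASES = np.array(list("ACGT"))
_CHROMS = ("21", "22")
_POSITION_SPACE = 2_000_000  # per chromosome

_DEFAULT_RARE: dict[ConsensusClass, int] = {
    ConsensusClass.CONCORDANT_DELETERIOUS: 2,
    ConsensusClass.DISCORDANT: 2,
    ConsensusClass.NOT_DAMAGING: 3,
    ConsensusClass.UNSCORED: 2,
}


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """Planted composition of a synthetic cohort.

    Defaults emulate the study's shape — ten patients with paired
    blood/lesion callsets — at a desk-scale variant count: tens of shared
    variants per Venn class, per-patient private noise, a control-overlap
    block for the subtraction step, and roughly one indel per four variants
    (the shared-variant SNP:InDel ratio seen in exome cohorts of this kind).
    """

    n_patients: int = 10
    n_core_sbl: int = 60
    n_sb: int = 12
    n_sl: int = 8
    n_lesion_specific: int = 30
    n_private_per_patient: int = 15
    n_control_overlap: int = 10
    indel_fraction: float = 0.25
    n_rare_planted: Mapping[ConsensusClass, int] = field(
        default_factory=lambda: dict(_DEFAULT_RARE)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.n_patients,
            self.n_core_sbl,
            self.n_sb,
            self.n_sl,
            self.n_lesion_specific,
            self.n_private_per_patient,
            self.n_control_overlap,
        )
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if any(c < 0 for c in counts):
            raise ValueError("all planted counts must be >= 0")
        if not 0.0 <= self.indel_fraction <= 1.0:
            raise ValueError("indel_fraction must lie in [0, 1]")
        if any(v < 0 for v in self.n_rare_planted.values()):
            raise ValueError("rare-planted counts must be >= 0")


@dataclass(frozen=True)
class ManifestEntry:
    """Ground truth for one planted variant."""

    membership: MembershipClass | None  # None for control-overlap variants
    vtype: VariantType
    rare: bool
    consensus: ConsensusClass | None  # None when rarity was not planted


@dataclass
class SyntheticBundle:
    """In-memory synthetic inputs plus their truth manifest."""

    config: SyntheticCohortConfig
    cohort: CohortCallset
    control: frozenset[VariantKey]
    saliva: frozenset[VariantKey]
    annotations: dict[VariantKey, AnnotationRecord]
    manifest: dict[VariantKey, ManifestEntry]

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write the bundle to disk in the formats the pipeline reads.

        Returns a name → path map; ``cohort_map.tsv`` lists every patient
        VCF with its tissue, the layout the classify stage consumes.
        """
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        map_rows = []
        for pid in self.cohort.patients:
            for tissue, callsets in (("blood", self.cohort.blood), ("lesion", self.cohort.lesion)):
                vcf_path = outdir / f"{pid}_{tissue}.vcf"
                write_vcf(callsets[pid].keys, vcf_path, sample_label=pid)
                map_rows.append({"patient_id": pid, "tissue": tissue, "path": vcf_path.name})
        pd.DataFrame(map_rows).to_csv(outdir / "cohort_map.tsv", sep="\t", index=False)
        paths["cohort_map"] = outdir / "cohort_map.tsv"
        write_variant_set(self.control, outdir / "control.tsv")
        paths["control"] = outdir / "control.tsv"
        write_variant_set(self.saliva, outdir / "saliva.tsv")
        paths["saliva"] = outdir / "saliva.tsv"
        write_annotations(self.annotations, outdir / "annotations.tsv")
        paths["annotations"] = outdir / "annotations.tsv"
        manifest_rows = [
            {
                "key": str(key),
                "membership": entry.membership.value if entry.membership else ".",
                "variant_type": entry.vtype.value,
                "rare": int(entry.rare),
                "consensus": entry.consensus.value if entry.consensus else ".",
            }
            for key, entry in sorted(self.manifest.items())
        ]
        pd.DataFrame(manifest_rows).to_csv(outdir / "manifest.tsv", sep="\t", index=False)
        paths["manifest"] = outdir / "manifest.tsv"
        return paths


def _draw_sites(rng: np.random.Generator, count: int) -> list[tuple[str, int]]:
    if count > len(_CHROMS) * _POSITION_SPACE:
        raise ValueError(
            f"config requires {count} distinct sites but the synthetic "
            f"coordinate space holds only {len(_CHROMS) * _POSITION_SPACE}"
        )
    sites: set[tuple[str, int]] = set()
    while len(sites) < count:
        need = count - len(sites)
        chroms = rng.choice(len(_CHROMS), size=need * 2)
        positions = rng.integers(1, _POSITION_SPACE + 1, size=need * 2)
        for c, p in zip(chroms, positions):
            sites.add((_CHROMS[c], int(p)))
            if len(sites) == count:
                break
    ordered = sorted(sites)
    rng.shuffle(ordered)
    return ordered


def _draw_variant(rng: np.random.Generator, site: tuple[str, int], is_indel: bool) -> VariantKey:
    chrom, pos = site
    if not is_indel:
        ref, alt = rng.choice(_BASES, size=2, replace=False)
        return normalize(chrom, pos, str(ref), str(alt))
    anchor = str(rng.choice(_BASES))
    length = int(rng.integers(1, 5))
    tail = [str(b) for b in rng.choice(_BASES, size=length)]
    others = [b for b in "ACGT" if b != anchor]
    tail[-1] = str(rng.choice(others))  # keep the pair suffix-minimal
    long_allele = anchor + "".join(tail)
    if rng.random() < 0.5:
        return normalize(chrom, pos, long_allele, anchor)  # deletion
    return normalize(chrom, pos, anchor, long_allele)  # insertion


def _draw_scores(
    rng: np.random.Generator, consensus: ConsensusClass
) -> tuple[float | None, float | None, float | None]:
    """(sift, pp2_hvar, pp2_hdiv) drawn inside the class-defining regions."""
    u = rng.uniform
    if consensus is ConsensusClass.CONCORDANT_DELETERIOUS:
        return u(0.0, 0.045), u(0.96, 1.0), u(0.96, 1.0)
    if consensus is ConsensusClass.DISCORDANT:
        if rng.random() < 0.5:  # SIFT-only support
            return u(0.0, 0.045), u(0.0, 0.4), u(0.0, 0.4)
        return u(0.1, 1.0), u(0.96, 1.0), u(0.96, 1.0)  # PolyPhen-only
    if consensus is ConsensusClass.NOT_DAMAGING:
        return u(0.1, 1.0), u(0.0, 0.4), u(0.0, 0.4)
    return None, None, None


_NONCODING_REGIONS = (
    RegionClass.INTRONIC,
    RegionClass.UTR5,
    RegionClass.UTR3,
    RegionClass.INTERGENIC,
    RegionClass.UPSTREAM,
    RegionClass.DOWNSTREAM,
    RegionClass.NCRNA_EXONIC,
    RegionClass.NCRNA_INTRONIC,
)


def _annotate(
    rng: np.random.Generator,
    key: VariantKey,
    gene: str,
    rare: bool,
    consensus: ConsensusClass | None,
) -> AnnotationRecord:
    vtype = variant_type(key)
    if rare:
        region = RegionClass.EXONIC
        if vtype is VariantType.SNP:
            effect = (
                EffectClass.UNKNOWN
                if consensus is ConsensusClass.UNSCORED
                else EffectClass.MISSENSE
            )
        else:
            shift = abs(len(key.ref) - len(key.alt)) % 3 != 0
            inserting = len(key.alt) > len(key.ref)
            effect = {
                (True, True): EffectClass.FRAMESHIFT_INSERTION,
                (True, False): EffectClass.FRAMESHIFT_DELETION,
                (False, True): EffectClass.NONFRAMESHIFT_INSERTION,
                (False, False): EffectClass.NONFRAMESHIFT_DELETION,
            }[(shift, inserting)]
        sift, hvar, hdiv = _draw_scores(rng, consensus)
        # each database either lacks the variant or reports it as very rare
        afs = [None if rng.random() < 0.5 else float(rng.uniform(0.0, 0.009)) for _ in range(3)]
    else:
        region = (
            RegionClass.EXONIC
            if rng.random() < 0.35
            else _NONCODING_REGIONS[int(rng.integers(len(_NONCODING_REGIONS)))]
        )
        if region is RegionClass.EXONIC:
            if vtype is VariantType.SNP:
                effect = (
                    EffectClass.MISSENSE,
                    EffectClass.SYNONYMOUS,
                    EffectClass.UNKNOWN,
                    EffectClass.STOPGAIN,
                )[int(rng.choice(4, p=[0.45, 0.45, 0.07, 0.03]))]
            else:
                shift = abs(len(key.ref) - len(key.alt)) % 3 != 0
                inserting = len(key.alt) > len(key.ref)
                effect = {
                    (True, True): EffectClass.FRAMESHIFT_INSERTION,
                    (True, False): EffectClass.FRAMESHIFT_DELETION,
                    (False, True): EffectClass.NONFRAMESHIFT_INSERTION,
                    (False, False): EffectClass.NONFRAMESHIFT_DELETION,
                }[(shift, inserting)]
        else:
            effect = None
        sift = hvar = hdiv = None
        # at least one database sees the variant at a common frequency
        afs = [float(rng.uniform(0.02, 0.5))] + [
            None if rng.random() < 0.3 else float(rng.uniform(0.0, 0.5)) for _ in range(2)
        ]
        rng.shuffle(afs)
        if all(a is None or a < 0.01 for a in afs):  # pragma: no cover - defensive
            afs[0] = 0.05
    genes = [] if region in (RegionClass.INTERGENIC, RegionClass.NA) else [gene]
    return AnnotationRecord(
        key=key,
        genes=genes,
        region=region,
        effect=effect,
        dbsnp_id=None,
        af_1000g=afs[0],
        af_esp=afs[1],
        af_exac=afs[2],
        sift_score=sift,
        pp2_hvar=hvar,
        pp2_hdiv=hdiv,
    )


def generate_cohort(config: SyntheticCohortConfig) -> SyntheticBundle:
    """Generate the full synthetic input bundle for one seeded config.

    Fully reproducible: the same config (including seed) yields identical
    keys, annotations and files; different seeds yield different key sets.
    """
    rng = np.random.default_rng(config.seed)
    pool_counts = {
        MembershipClass.SALIVA_BLOOD_LESION: config.n_core_sbl,
        MembershipClass.SALIVA_BLOOD: config.n_sb,
        MembershipClass.SALIVA_LESION: config.n_sl,
        MembershipClass.LESION_SPECIFIC: config.n_lesion_specific,
    }
    n_noise = config.n_patients * config.n_private_per_patient
    total = sum(pool_counts.values()) + config.n_control_overlap + n_noise
    sites = _draw_sites(rng, total)
    cursor = 0

    def take(count: int, is_indel_flags: list[bool]) -> list[VariantKey]:
        nonlocal cursor
        out = []
        for flag in is_indel_flags:
            out.append(_draw_variant(rng, sites[cursor], flag))
            cursor += 1
        return out

    def indel_flags(count: int) -> list[bool]:
        return [bool(r < config.indel_fraction) for r in rng.random(count)]

    pools: dict[MembershipClass, list[VariantKey]] = {}
    for cls, count in pool_counts.items():
        pools[cls] = take(count, indel_flags(count))
    control_overlap = take(config.n_control_overlap, indel_flags(config.n_control_overlap))
    noise = take(n_noise, indel_flags(n_noise))

    # --- choose which planted variants realize each consensus class
    rare_assignment: dict[VariantKey, ConsensusClass] = {}
    snp_pool = [k for cls in pools for k in pools[cls] if variant_type(k) is VariantType.SNP]
    indel_pool = [k for cls in pools for k in pools[cls] if variant_type(k) is VariantType.INDEL]
    rng.shuffle(snp_pool)
    rng.shuffle(indel_pool)
    scored_classes = (
        ConsensusClass.CONCORDANT_DELETERIOUS,
        ConsensusClass.DISCORDANT,
        ConsensusClass.NOT_DAMAGING,
    )
    need_scored = sum(int(config.n_rare_planted.get(c, 0)) for c in scored_classes)
    if need_scored > len(snp_pool):
        raise ValueError(
            f"config plants {need_scored} scored rare variants but only "
            f"{len(snp_pool)} SNPs exist across the membership pools"
        )
    for cls in scored_classes:
        for _ in range(int(config.n_rare_planted.get(cls, 0))):
            rare_assignment[snp_pool.pop()] = cls
    for _ in range(int(config.n_rare_planted.get(ConsensusClass.UNSCORED, 0))):
        if indel_pool:
            rare_assignment[indel_pool.pop()] = ConsensusClass.UNSCORED
        elif snp_pool:
            rare_assignment[snp_pool.pop()] = ConsensusClass.UNSCORED
        else:
            raise ValueError("no planted variants left to realize UNSCORED rarity")

    # --- assemble per-patient callsets
    sbl = set(pools[MembershipClass.SALIVA_BLOOD_LESION])
    sb = set(pools[MembershipClass.SALIVA_BLOOD])
    sl = set(pools[MembershipClass.SALIVA_LESION])
    ls = set(pools[MembershipClass.LESION_SPECIFIC])
    overlap = set(control_overlap)
    patients = [f"P{i + 1:02d}" for i in range(config.n_patients)]
    blood_base = sbl | sb | overlap
    lesion_base = sbl | sl | ls | overlap
    blood_keys = {p: set(blood_base) for p in patients}
    lesion_keys = {p: set(lesion_base) for p in patients}
    for i, key in enumerate(noise):
        patient = patients[i // max(config.n_private_per_patient, 1)]
        if rng.random() < 0.5:
            blood_keys[patient].add(key)
        else:
            lesion_keys[patient].add(key)
    cohort = CohortCallset(
        blood={p: PatientCallset(p, Tissue.BLOOD, frozenset(blood_keys[p])) for p in patients},
        lesion={p: PatientCallset(p, Tissue.LESION, frozenset(lesion_keys[p])) for p in patients},
    )
    saliva = frozenset(sbl | sb | sl | overlap)
    control = frozenset(overlap)

    # --- annotations + manifest for every non-noise variant
    n_genes = max(4, total // 3)
    annotations: dict[VariantKey, AnnotationRecord] = {}
    manifest: dict[VariantKey, ManifestEntry] = {}
    for cls in pool_counts:
        for key in pools[cls]:
            gene = f"GENE{int(rng.integers(n_genes)) + 1:04d}"
            consensus = rare_assignment.get(key)
            rare = consensus is not None
            annotations[key] = _annotate(rng, key, gene, rare, consensus)
            manifest[key] = ManifestEntry(
                membership=cls, vtype=variant_type(key), rare=rare, consensus=consensus
            )
    for key in control_overlap:
        gene = f"GENE{int(rng.integers(n_genes)) + 1:04d}"
        annotations[key] = _annotate(rng, key, gene, rare=False, consensus=None)
        manifest[key] = ManifestEntry(
            membership=None, vtype=variant_type(key), rare=False, consensus=None
        )
    return SyntheticBundle(
        config=config,
        cohort=cohort,
        control=control,
        saliva=saliva,
        annotations=annotations,
        manifest=manifest,
    )


# ---------------------------------------------------------------------------
# Published-table fixtures

def _fixture_path(name: str):
    return importlib.resources.files("varsieve.data").joinpath(name)


def _load_count_fixture(name: str) -> dict[VariantType, pd.DataFrame]:
    with importlib.resources.as_file(_fixture_path(name)) as path:
        frame = pd.read_csv(path, sep="\t", index_col="row", keep_default_na=False)
    out: dict[VariantType, pd.DataFrame] = {}
    for vtype in (VariantType.SNP, VariantType.INDEL):
        prefix = f"{vtype.value}|"
        cols = [c for c in frame.columns if c.startswith(prefix)]
        sub = frame[cols].copy()
        sub.columns = [c[len(prefix):] for c in cols]
        out[vtype] = sub.astype(int)
    return out


def table_fixtures() -> dict[str, object]:
    """Load the packaged transcriptions of the published summary tables.

    Returns a mapping with:

    * ``"region_counts"`` — region × membership matrices per variant type
      (the variant-candidate count table, including its printed derived
      rows);
    * ``"effect_counts"`` — exonic-effect × membership matrices per variant
      type;
    * ``"rare_annotations"`` — the 31-row rare-candidate table parsed into
      key → :class:`AnnotationRecord` through the standard reader.
    """
    from .io_formats import read_annotations

    with importlib.resources.as_file(
        _fixture_path("table4_rare_annotations.tsv")
    ) as path:
        rare = read_annotations(path)
    return {
        "region_counts": _load_count_fixture("table2_region_counts.tsv"),
        "effect_counts": _load_count_fixture("table3_effect_counts.tsv"),
        "rare_annotations": rare,
    }
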