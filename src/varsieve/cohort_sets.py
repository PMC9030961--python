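"""Cohort-wide shared-variant collection, control subtraction, and
membership classification.

The pipeline's central comparison takes four variant sets:

* the intersection of all patients' *blood* callsets (germline candidates),
* the intersection of all patients' *lesion* callsets (somatic candidates),
* an external disease-cohort *saliva* variant set, and
* a population *control* set (KOVA-like) subtracted from both cohort
  intersections before any classification.

Each variant surviving subtraction is assigned one Venn membership class
from its (blood, lesion, saliva) presence pattern:

==========  ==========  ==========  =======================
in blood    in lesion   in saliva   class
==========  ==========  ==========  =======================
yes         yes         yes         SALIVA_BLOOD_LESION
yes         no          yes         SALIVA_BLOOD
no          yes         yes         SALIVA_LESION
no          yes         no          LESION_SPECIFIC
yes         no          no          EXCLUDED
yes         yes         no          EXCLUDED
==========  ==========  ==========  =======================

Saliva-only variants are never emitted (the saliva set is external evidence,
not part of this cohort).  Blood-supported variants without saliva support
are retained with class EXCLUDED so that reports can show them; the study's
summary tables drop them.

Sharing is presence-based on normalized site+allele keys and genotype-blind:
the comparison is between variant *lists*, never genotypes.
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass, field

from .variant_core import VariantKey, VariantType, variant_type

__all__ = [
    "Tissue",
    "MembershipClass",
    "REPORTED_CLASSES",
    "PatientCallset",
    "CohortCallset",
    "shared_across_patients",
    "subtract_control",
    "classify_membership",
    "venn_counts",
]


class Tissue(enum.Enum):
    BLOOD = "blood"
    LESION = "lesion"


class MembershipClass(enum.Enum):
    """Venn category of a variant across saliva / blood / lesion evidence."""

    SALIVA_BLOOD = "Saliva;Blood"
    SALIVA_LESION = "Saliva;Lesion"
    SALIVA_BLOOD_LESION = "Saliva;Blood;Lesion"
    LESION_SPECIFIC = "Lesion-Specific"
    EXCLUDED = "Excluded"


#: The four classes the study's summary tables report, in column order.
REPORTED_CLASSES: tuple[MembershipClass, ...] = (
    MembershipClass.SALIVA_BLOOD,
    MembershipClass.SALIVA_LESION,
    MembershipClass.SALIVA_BLOOD_LESION,
    MembershipClass.LESION_SPECIFIC,
)


@dataclass
class PatientCallset:
    """One patient's variant keys for one tissue."""

    patient_id: str
    tissue: Tissue
    keys: frozenset[VariantKey] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not isinstance(self.tissue, Tissue):
            self.tissue = Tissue(self.tissue)
        self.keys = frozenset(self.keys)


@dataclass
class CohortCallset:
    """Paired blood/lesion callsets for every patient in the cohort."""

    blood: dict[str, PatientCallset]
    lesion: dict[str, PatientCallset]

    def __post_init__(self) -> None:
        if not self.blood:
            raise ValueError("cohort must contain at least one patient")
        if set(self.blood) != set(self.lesion):
            missing = set(self.blood) ^ set(self.lesion)
            raise ValueError(
                f"blood and lesion callsets cover different patients: {sorted(missing)}"
            )

    @property
    def patients(self) -> list[str]:
        return sorted(self.blood)

    @classmethod
    def from_callsets(cls, callsets: list[PatientCallset]) -> "CohortCallset":
        blood = {c.patient_id: c for c in callsets if c.tissue is Tissue.BLOOD}
        lesion = {c.patient_id: c for c in callsets if c.tissue is Tissue.LESION}
        return cls(blood=blood, lesion=lesion)


def shared_across_patients(
    cohort: CohortCallset, tissue: Tissue
) -> frozenset[VariantKey]:
    """Variants present in *every* patient's callset for the given tissue.

    This is the study's strict cohort filter: a variant is a candidate only
    when all patients carry it, so any single empty callset yields an empty
    result.
    """
    if not isinstance(tissue, Tissue):
        tissue = Tissue(tissue)
    per_patient = cohort.blood if tissue is Tissue.BLOOD else cohort.lesion
    sets = [c.keys for c in per_patient.values()]
    return frozenset(frozenset.intersection(*sets))


def subtract_control(
    shared: frozenset[VariantKey], control: frozenset[VariantKey]
) -> frozenset[VariantKey]:
    """Remove population-control variants (e.g. common Korean variants)."""
    return frozenset(shared) - frozenset(control)


def classify_membership(
    blood_shared: frozenset[VariantKey],
    lesion_shared: frozenset[VariantKey],
    saliva: frozenset[VariantKey],
) -> dict[VariantKey, MembershipClass]:
    """Assign every cohort-supported variant its Venn membership class.

    ``blood_shared`` and ``lesion_shared`` must already be control-subtracted.
    Every key in their union receives exactly one class; saliva-only keys are
    not emitted.
    """
    out: dict[VariantKey, MembershipClass] = {}
    for key in frozenset(blood_shared) | frozenset(lesion_shared):
        in_blood = key in blood_shared
        in_lesion = key in lesion_shared
        in_saliva = key in saliva
        if in_saliva:
            if in_blood and in_lesion:
                out[key] = MembershipClass.SALIVA_BLOOD_LESION
            elif in_blood:
                out[key] = MembershipClass.SALIVA_BLOOD
            else:
                out[key] = MembershipClass.SALIVA_LESION
        else:
            if in_lesion and not in_blood:
                out[key] = MembershipClass.LESION_SPECIFIC
            else:
                out[key] = MembershipClass.EXCLUDED
    return out


def venn_counts(
    classified: dict[VariantKey, MembershipClass],
    type_filter: VariantType | None = None,
) -> dict[MembershipClass, int]:
    """Count classified variants per membership class.

    With a ``type_filter`` only variants of that type are counted; counts
    always sum to the number of classified keys of the selected type.
    """
    counts: Counter[MembershipClass] = Counter()
    for key, cls in classified.items():
        if type_filter is not None and variant_type(key) is not type_filter:
            continue
        counts[cls] += 1
    return {cls: counts.get(cls, 0) for cls in MembershipClass}
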