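"""Rare-variant filtering and SIFT / PolyPhen-2 consensus classification.

A variant is *rare* when each of its three population allele frequencies
(1000 Genomes phase 3, NHLBI ESP, ExAC) is either missing or strictly below
the threshold (default 0.01).  Missing counts as rare: a variant absent from
all three databases is exactly the kind of private variant the filter is
meant to keep.

Predictor letters are recomputed from numeric scores using the tools'
published bins:

* SIFT: deleterious (D) iff score < 0.05, else tolerated (T);
* PolyPhen-2 HDIV: probably damaging (D) at >= 0.957, possibly damaging (P)
  at >= 0.453, else benign (B);
* PolyPhen-2 HVAR: D at >= 0.909, P at >= 0.447, else B.

The consensus class combines two support flags — SIFT says deleterious, and
*both* PolyPhen-2 models say at least possibly damaging:

* both flags            → CONCORDANT_DELETERIOUS
* exactly one flag      → DISCORDANT
* neither (all scored)  → NOT_DAMAGING
* any score missing     → UNSCORED

Requiring both PolyPhen-2 models for the damaging flag matters: a variant
called benign by HVAR but possibly damaging by HDIV contributes no PolyPhen
support, so SIFT-tolerated variants of that kind stay NOT_DAMAGING rather
than leaking into the discordant bin.

Frequencies are used as reported (alternate-allele frequencies), not folded
to the minor allele; every frequency below 0.01 is unchanged by folding, so
the distinction cannot affect which variants pass the rarity filter.
"""

from __future__ import annotations

import enum
from typing import Iterable, Mapping

import pandas as pd

from .cohort_sets import MembershipClass
from .io_formats import AnnotationRecord
from .variant_core import VariantKey, variant_type

__all__ = [
    "SIFT_DELETERIOUS_CUTOFF",
    "MAF_THRESHOLD",
    "PolyphenModel",
    "ConsensusClass",
    "is_rare",
    "sift_call",
    "polyphen_call",
    "consensus_class",
    "prioritize_candidates",
]

SIFT_DELETERIOUS_CUTOFF = 0.05
MAF_THRESHOLD = 0.01

_PP2_BINS = {
    "HDIV": (0.957, 0.453),  # (probably-damaging floor, possibly-damaging floor)
    "HVAR": (0.909, 0.447),
}


class PolyphenModel(enum.Enum):
    HDIV = "HDIV"
    HVAR = "HVAR"


class ConsensusClass(enum.Enum):
    CONCORDANT_DELETERIOUS = "concordant_deleterious"
    DISCORDANT = "discordant"
    NOT_DAMAGING = "not_damaging"
    UNSCORED = "unscored"


#: Report ordering: strongest evidence first.
_CONSENSUS_RANK = {
    ConsensusClass.CONCORDANT_DELETERIOUS: 0,
    ConsensusClass.DISCORDANT: 1,
    ConsensusClass.NOT_DAMAGING: 2,
    ConsensusClass.UNSCORED: 3,
}


def is_rare(record: AnnotationRecord, threshold: float = MAF_THRESHOLD) -> bool:
    """True iff every population frequency is missing or strictly below
    ``threshold``."""
    for af in (record.af_1000g, record.af_esp, record.af_exac):
        if af is not None and af >= threshold:
            return False
    return True


def sift_call(score: float) -> str:
    """SIFT letter: 'D' (deleterious) iff score < 0.05, else 'T'."""
    if not 0.0 <= score <= 1.0:
        raise ValueError(f"SIFT score {score} outside [0, 1]")
    return "D" if score < SIFT_DELETERIOUS_CUTOFF else "T"


def polyphen_call(score: float, model: PolyphenModel | str) -> str:
    """PolyPhen-2 letter for the given trained model: 'B', 'P' or 'D'."""
    if not 0.0 <= score <= 1.0:
        raise ValueError(f"PolyPhen-2 score {score} outside [0, 1]")
    model = PolyphenModel(model) if not isinstance(model, PolyphenModel) else model
    d_floor, p_floor = _PP2_BINS[model.value]
    if score >= d_floor:
        return "D"
    if score >= p_floor:
        return "P"
    return "B"


def consensus_class(record: AnnotationRecord) -> ConsensusClass:
    """Combine SIFT and both PolyPhen-2 models into one consensus class."""
    scores = (record.sift_score, record.pp2_hvar, record.pp2_hdiv)
    if any(s is None for s in scores):
        return ConsensusClass.UNSCORED
    flag_sift = sift_call(record.sift_score) == "D"
    flag_pp = (
        polyphen_call(record.pp2_hvar, PolyphenModel.HVAR) in ("P", "D")
        and polyphen_call(record.pp2_hdiv, PolyphenModel.HDIV) in ("P", "D")
    )
    if flag_sift and flag_pp:
        return ConsensusClass.CONCORDANT_DELETERIOUS
    if flag_sift or flag_pp:
        return ConsensusClass.DISCORDANT
    return ConsensusClass.NOT_DAMAGING


def prioritize_candidates(
    records: Mapping[VariantKey, AnnotationRecord] | Iterable[AnnotationRecord],
    membership: Mapping[VariantKey, MembershipClass] | None = None,
    threshold: float = MAF_THRESHOLD,
) -> pd.DataFrame:
    """Build the ordered rare-candidate table.

    Keeps rare records only, annotates variant type, membership class (when
    a classification mapping is supplied), recomputed predictor letters and
    the consensus class, and orders rows by consensus strength then key.
    Scoreless records (typically InDels, which SIFT/PolyPhen-2 do not score)
    appear as UNSCORED rather than being dropped.
    """
    if isinstance(records, Mapping):
        records = records.values()
    rows = []
    for rec in records:
        if not is_rare(rec, threshold=threshold):
            continue
        consensus = consensus_class(rec)
        cls = membership.get(rec.key) if membership is not None else None
        rows.append(
            {
                "key": str(rec.key),
                "variant_type": variant_type(rec.key).value,
                "gene": ";".join(rec.genes) if rec.genes else ".",
                "effect": rec.effect.value if rec.effect else ".",
                "hgvs_c": rec.hgvs_c or ".",
                "hgvs_p": rec.hgvs_p or ".",
                "dbsnp_id": rec.dbsnp_id or ".",
                "af_1000g": rec.af_1000g,
                "af_esp": rec.af_esp,
                "af_exac": rec.af_exac,
                "sift_score": rec.sift_score,
                "sift_call": sift_call(rec.sift_score) if rec.sift_score is not None else ".",
                "pp2_hvar": rec.pp2_hvar,
                "pp2_hvar_call": (
                    polyphen_call(rec.pp2_hvar, PolyphenModel.HVAR)
                    if rec.pp2_hvar is not None
                    else "."
                ),
                "pp2_hdiv": rec.pp2_hdiv,
                "pp2_hdiv_call": (
                    polyphen_call(rec.pp2_hdiv, PolyphenModel.HDIV)
                    if rec.pp2_hdiv is not None
                    else "."
                ),
                "consensus_class": consensus.value,
                "membership_class": cls.value if cls is not None else ".",
                "_sort": (_CONSENSUS_RANK[consensus], rec.key),
            }
        )
    rows.sort(key=lambda r: r["_sort"])
    for row in rows:
        del row["_sort"]
    return pd.DataFrame(rows, columns=list(_CANDIDATE_COLUMNS))


_CANDIDATE_COLUMNS = (
    "key",
    "variant_type",
    "gene",
    "effect",
    "hgvs_c",
    "hgvs_p",
    "dbsnp_id",
    "af_1000g",
    "af_esp",
    "af_exac",
    "sift_score",
    "sift_call",
    "pp2_hvar",
    "pp2_hvar_call",
    "pp2_hdiv",
    "pp2_hdiv_call",
    "consensus_class",
    "membership_class",
)
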