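"""Variant identity, normalization, and type classification.

Every downstream stage (cohort set algebra, control subtraction, annotation
joining) compares variants by a normalized ``(chrom, pos, ref, alt)`` key, so
this module defines the single canonical representation used everywhere:

* chromosome names are GRCh37-style without a ``chr`` prefix (``1``–``22``,
  ``X``, ``Y``, ``MT``);
* alleles are upper-case strings over {A, C, G, T};
* the ref/alt pair is minimal — a shared trailing suffix is trimmed, then a
  shared leading prefix is trimmed down to the single mandatory anchor base
  for length-changing variants (the VCF convention for indels).

Full left-alignment against a reference genome is deliberately *not*
performed: no reference FASTA is assumed by the pipeline, so two descriptions
of the same indel that differ by placement inside a repeat are distinct keys.
This is a documented limitation, not an oversight.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from functools import total_ordering

__all__ = [
    "CHROMOSOMES",
    "VariantKey",
    "VariantType",
    "normalize",
    "variant_type",
]

#: Accepted chromosome labels in canonical sort order.
CHROMOSOMES: tuple[str, ...] = tuple(str(i) for i in range(1, 23)) + ("X", "Y", "MT")

_CHROM_RANK: dict[str, int] = {name: i for i, name in enumerate(CHROMOSOMES)}

_ALLELE_ALPHABET = frozenset("ACGT")


class VariantType(enum.Enum):
    """Coarse variant class used by the count tables.

    SNP: single-base substitution.  INDEL: ref and alt lengths differ.
    OTHER: equal-length multi-base substitution (MNV); carried through set
    algebra but excluded from the SNP/InDel tallies.
    """

    SNP = "SNP"
    INDEL = "INDEL"
    OTHER = "OTHER"


@total_ordering
@dataclass(frozen=True)
class VariantKey:
    """Normalized site+allele identity of a variant.

    Instances are only constructed through :func:`normalize`, which enforces
    the minimal-representation invariant; constructing one directly with
    non-minimal alleles is a programming error.

    Sorting follows (chromosome rank 1..22, X, Y, MT; position; ref; alt).
    """

    chrom: str
    pos: int
    ref: str
    alt: str

    def _sort_key(self) -> tuple[int, int, str, str]:
        return (_CHROM_RANK[self.chrom], self.pos, self.ref, self.alt)

    def __lt__(self, other: "VariantKey") -> bool:
        if not isinstance(other, VariantKey):
            return NotImplemented
        return self._sort_key() < other._sort_key()

    def __str__(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"

    @classmethod
    def from_string(cls, text: str) -> "VariantKey":
        """Parse the ``chrom:pos:ref:alt`` serialization used in TSV outputs."""
        parts = text.strip().split(":")
        if len(parts) != 4:
            raise ValueError(f"expected chrom:pos:ref:alt, got {text!r}")
        chrom, pos, ref, alt = parts
        return normalize(chrom, int(pos), ref, alt)


def _canonical_chrom(chrom: str) -> str:
    name = chrom.strip()
    if name.lower().startswith("chr"):
        name = name[3:]
    name = name.upper()
    if name == "M":
        name = "MT"
    if name not in _CHROM_RANK:
        raise ValueError(
            f"unrecognized chromosome {chrom!r}: expected 1-22, X, Y or MT "
            "(with or without a 'chr' prefix)"
        )
    return name


def _check_allele(allele: str, which: str) -> str:
    allele = allele.strip().upper()
    if not allele:
        raise ValueError(f"{which} allele is empty")
    bad = set(allele) - _ALLELE_ALPHABET
    if bad:
        raise ValueError(
            f"{which} allele {allele!r} contains non-ACGT characters: {sorted(bad)}"
        )
    return allele


def normalize(chrom: str, pos: int, ref: str, alt: str) -> VariantKey:
    """Build the canonical :class:`VariantKey` for a raw variant description.

    Trims a shared trailing suffix, then a shared leading prefix — keeping one
    anchor base when ref and alt lengths differ — and adjusts ``pos`` for any
    leading bases removed.  Idempotent: normalizing a normalized key is a
    no-op.

    Raises
    ------
    ValueError
        If the chromosome name is unrecognized, an allele contains non-ACGT
        characters, ``pos`` < 1, or ref equals alt after trimming (i.e. the
        record does not describe a variant).
    """
    chrom = _canonical_chrom(chrom)
    if pos < 1:
        raise ValueError(f"position must be >= 1, got {pos}")
    ref = _check_allele(ref, "ref")
    alt = _check_allele(alt, "alt")
    if ref == alt:
        raise ValueError(f"ref == alt ({ref!r}): not a variant")

    # Trim shared suffix, always leaving at least one base per allele.
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]

    # Trim shared prefix.  The >1 guards stop the loop exactly when the next
    # trim would empty an allele, which for length-changing variants leaves
    # the single VCF-style anchor base in place.
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1

    if ref == alt:  # pragma: no cover - caught above; defensive
        raise ValueError(f"ref == alt after trimming at {chrom}:{pos}")
    return VariantKey(chrom=chrom, pos=pos, ref=ref, alt=alt)


def variant_type(key: VariantKey) -> VariantType:
    """Classify a normalized key as SNP, INDEL or OTHER (MNV)."""
    if len(key.ref) == 1 and len(key.alt) == 1:
        return VariantType.SNP
    if len(key.ref) != len(key.alt):
        return VariantType.INDEL
    return VariantType.OTHER
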