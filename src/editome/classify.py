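"""The 12 reference-strand mismatch classes and their biological reading.

An RNA:DNA difference observed on the reference (+) strand belongs to one
of 12 ordered ref->alt classes. Whether it is a deamination signature
depends on the strand of the gene it falls in: adenosine-to-inosine (ADAR)
editing reads as A>G on a '+' gene and as T>C on a '-' gene; cytidine-to-
uridine (APOBEC) editing reads as C>T on '+' and G>A on '-'.
"""

from __future__ import annotations

from enum import Enum

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

A_TO_I = "A-to-I"
C_TO_U = "C-to-U"
OTHER = "other"

EDITING_CLASSES = (A_TO_I, C_TO_U, OTHER)


class RddType(str, Enum):
    """Reference-strand mismatch classes, in fixed display order."""

    AC = "A>C"
    AG = "A>G"
    AT = "A>T"
    CA = "C>A"
    CG = "C>G"
    CT = "C>T"
    GA = "G>A"
    GC = "G>C"
    GT = "G>T"
    TA = "T>A"
    TC = "T>C"
    TG = "T>G"

    @property
    def ref(self) -> str:
        return self.value[0]

    @property
    def alt(self) -> str:
        return self.value[2]


RDD_TYPES: tuple[RddType, ...] = tuple(RddType)


def classify_mismatch(ref_base: str, alt_base: str) -> RddType:
    """Map an observed ref/alt pair to its mismatch class."""
    ref_base, alt_base = ref_base.upper(), alt_base.upper()
    if ref_base not in COMPLEMENT or alt_base not in COMPLEMENT:
        raise ValueError(f"bases must be A/C/G/T, got {ref_base!r}>{alt_base!r}")
    if ref_base == alt_base:
        raise ValueError(f"ref and alt are both {ref_base!r}: not a mismatch")
    return RddType(f"{ref_base}>{alt_base}")


def complement_type(rdd_type: RddType) -> RddType:
    """Mismatch class as it would read on the opposite strand."""
    return RddType(f"{COMPLEMENT[rdd_type.ref]}>{COMPLEMENT[rdd_type.alt]}")


def resolve_editing_class(rdd_type: RddType, gene_strand: str) -> str:
    """Resolve a mismatch class to A-to-I, C-to-U or "other".

    ``gene_strand`` is '+', '-' or 'unknown'. With unknown strand the
    mismatch is read on '+': A>G and C>T still classify, while T>C and
    G>A (signatures only on a '-' gene) stay "other" — callers should
    treat unknown-strand assignments as low-confidence.
    """
    if gene_strand not in ("+", "-", "unknown"):
        raise ValueError(f"gene_strand must be +/-/unknown, got {gene_strand!r}")
    if gene_strand == "-":
        rdd_type = complement_type(rdd_type)
    if rdd_type is RddType.AG:
        return A_TO_I
    if rdd_type is RddType.CT:
        return C_TO_U
    return OTHER
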