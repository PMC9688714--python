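"""Genomic-feature annotation of called sites.

Sites are assigned to one of eight feature classes. When a position is
covered by intervals of several classes (e.g. one gene's exon inside
another gene's intron) a fixed precedence decides:

    exonic > 5'UTR > 3'UTR > ncRNA-exonic > intronic
           > ncRNA-intronic > upstream/downstream

A position covered by nothing is intergenic and carries no gene. Ties
within the winning class go to the lexicographically smallest gene id so
annotation is deterministic.
"""

from __future__ import annotations

import pandas as pd
from intervaltree import IntervalTree

from .classify import resolve_editing_class, classify_mismatch

EXONIC = "exonic"
UTR5 = "5'UTR"
UTR3 = "3'UTR"
NC_EXONIC = "ncRNA-exonic"
INTRONIC = "intronic"
NC_INTRONIC = "ncRNA-intronic"
FLANK = "upstream/downstream"
INTERGENIC = "intergenic"

#: genic feature classes in precedence order (highest first)
FEATURE_PRECEDENCE = (EXONIC, UTR5, UTR3, NC_EXONIC, INTRONIC, NC_INTRONIC, FLANK)
#: all feature classes, for summaries
FEATURE_CLASSES = FEATURE_PRECEDENCE + (INTERGENIC,)

_RANK = {f: i for i, f in enumerate(FEATURE_PRECEDENCE)}


class GenomeAnnotation:
    """Interval index over a feature table for point queries."""

    def __init__(self, intervals: pd.DataFrame):
        bad = intervals[intervals.start > intervals.end]
        if len(bad):
            raise ValueError(f"{len(bad)} intervals with start > end")
        unknown = set(intervals.feature) - set(FEATURE_PRECEDENCE)
        if unknown:
            raise ValueError(f"unknown feature classes: {sorted(unknown)}")
        self.intervals = intervals.reset_index(drop=True)
        self._trees: dict[str, IntervalTree] = {}
        for row in self.intervals.itertuples():
            tree = self._trees.setdefault(row.chrom, IntervalTree())
            # interval tree is half-open; intervals here are 1-based inclusive
            tree.addi(row.start, row.end + 1, (row.feature, row.gene, row.strand))

    def annotate_position(self, chrom: str, pos: int) -> tuple[str, str, str]:
        """Return ``(feature, gene, gene_strand)`` for a 1-based position."""
        tree = self._trees.get(chrom)
        hits = tree[pos] if tree is not None else ()
        if not hits:
            return INTERGENIC, "", "unknown"
        best = min(hits, key=lambda iv: (_RANK[iv.data[0]], iv.data[1]))
        return best.data

    def genes(self) -> list[str]:
        return sorted(set(self.intervals.gene))


def annotate_region(chrom: str, pos: int,
                    annotation: GenomeAnnotation | pd.DataFrame
                    ) -> tuple[str, str, str]:
    """Annotate a single 1-based position; convenience wrapper."""
    if isinstance(annotation, pd.DataFrame):
        annotation = GenomeAnnotation(annotation)
    return annotation.annotate_position(chrom, pos)


def annotate_calls(calls: pd.DataFrame,
                   annotation: GenomeAnnotation | pd.DataFrame) -> pd.DataFrame:
    """Attach mismatch type, editing class and feature to called sites.

    ``calls`` needs columns chrom, pos, ref, alt. Adds rdd_type,
    editing_class, feature, gene, gene_strand and a low_confidence_strand
    flag for sites whose class was read without gene-strand information.
    """
    if isinstance(annotation, pd.DataFrame):
        annotation = GenomeAnnotation(annotation)
    out = calls.copy()
    feats, genes, strands, types, classes, lowconf = [], [], [], [], [], []
    for row in out.itertuples():
        feature, gene, strand = annotation.annotate_position(row.chrom, row.pos)
        rdd = classify_mismatch(row.ref, row.alt)
        feats.append(feature)
        genes.append(gene)
        strands.append(strand)
        types.append(rdd.value)
        classes.append(resolve_editing_class(rdd, strand))
        lowconf.append(strand == "unknown")
    out["rdd_type"] = types
    out["feature"] = feats
    out["gene"] = genes
    out["gene_strand"] = strands
    out["editing_class"] = classes
    out["low_confidence_strand"] = lowconf
    return out
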