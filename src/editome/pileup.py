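"""Quality-filtered per-site pileups from coordinate-sorted alignments.

Base-level filters are applied while tallying: minimum base quality,
exclusion of bases within ``end_trim`` of either read end (random-hexamer
priming inflates mismatches there), and exclusion of multimapping reads
(mapping quality at or below the configured floor, 0 by default).
End-trimming at pileup time is equivalent to FASTQ trimming for mismatch
counting and keeps the pipeline alignment-native.
"""

from __future__ import annotations

import os
from collections import defaultdict

import numpy as np
import pandas as pd
import pysam
from pyfaidx import Fasta

from .config import FilterConfig

PILEUP_COLUMNS = ["chrom", "pos", "ref", "A", "C", "G", "T", "depth"]
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


def build_pileup(sam_path: str | os.PathLike,
                 reference: str | os.PathLike | Fasta,
                 config: FilterConfig | None = None) -> pd.DataFrame:
    """Tally quality-passing bases per covered reference position.

    Returns a DataFrame with one row per position of non-zero surviving
    depth: chrom, pos (1-based), ref, per-base counts A/C/G/T and depth.
    Positions whose reference base is not A/C/G/T are dropped.
    """
    config = config or FilterConfig()
    fasta = reference if isinstance(reference, Fasta) else Fasta(str(reference))

    counts: dict[tuple[str, int], np.ndarray] = defaultdict(
        lambda: np.zeros(4, dtype=np.int64))
    with pysam.AlignmentFile(str(sam_path), "r") as sam:
        for read in sam:
            if read.is_unmapped or read.query_sequence is None:
                continue
            if (config.exclude_multimapped
                    and read.mapping_quality <= config.max_multimap_mapq):
                continue
            chrom = read.reference_name
            if chrom not in fasta:
                raise ValueError(
                    f"alignment on contig {chrom!r} absent from the reference")
            seq = read.query_sequence
            quals = read.query_qualities
            qlen = len(seq)
            lo, hi = config.end_trim, qlen - config.end_trim
            for qpos, rpos in read.get_aligned_pairs(matches_only=True):
                if qpos < lo or qpos >= hi:
                    continue
                if quals is not None and quals[qpos] < config.min_base_quality:
                    continue
                idx = _BASE_INDEX.get(seq[qpos].upper())
                if idx is not None:
                    counts[(chrom, rpos)][idx] += 1

    rows = []
    for (chrom, rpos) in sorted(counts):
        c = counts[(chrom, rpos)]
        depth = int(c.sum())
        if depth == 0:
            continue
        ref = str(fasta[chrom][rpos]).upper()
        if ref not in _BASE_INDEX:
            continue
        rows.append((chrom, rpos + 1, ref, int(c[0]), int(c[1]),
                     int(c[2]), int(c[3]), depth))
    return pd.DataFrame(rows, columns=PILEUP_COLUMNS)
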