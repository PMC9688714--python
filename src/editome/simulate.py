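"""Desk-scale simulator of an RNA-editing RNA-seq experiment.

Produces a small annotated genome, plants A-to-I and C-to-U editing events
at known per-site frequencies plus SNP positions, and emits pre-aligned
reads (SAM) with base qualities, a multimapping fraction (MAPQ 0) and
substitution errors elevated near read ends, mimicking random-hexamer
priming bias. Every planted site is recorded in a truth table so recovery
can be scored exactly.

Reads are emitted as simple full-match alignments: splicing, indels and
soft-clips are deliberately out of scope — mismatch calling downstream of
alignment is the object under test.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from . import io as eio
from .annotate import (GenomeAnnotation, EXONIC, UTR5, UTR3, NC_EXONIC,
                       INTRONIC, NC_INTRONIC, FLANK)
from .classify import A_TO_I, C_TO_U, COMPLEMENT
from .config import SimConfig, ConfigError

BASES = np.frombuffer(b"ACGT", dtype="S1")
_BASE_INDEX = {b: i for i, b in enumerate("ACGT")}

TRUTH_COLUMNS = ["chrom", "pos", "ref_base", "alt_base", "editing_class",
                 "gene_strand", "planted_frequency", "feature"]

#: reference base an editing class requires, by gene strand
_REQUIRED_REF = {(A_TO_I, "+"): "A", (A_TO_I, "-"): "T",
                 (C_TO_U, "+"): "C", (C_TO_U, "-"): "G"}
_ALT_BASE = {(A_TO_I, "+"): "G", (A_TO_I, "-"): "C",
             (C_TO_U, "+"): "T", (C_TO_U, "-"): "A"}


def _rng(config: SimConfig, stage: int) -> np.random.Generator:
    # stage-keyed child streams: planting does not perturb read noise etc.
    return np.random.default_rng([stage, config.seed])


def simulate_reference(config: SimConfig) -> tuple[str, pd.DataFrame]:
    """Generate the genome sequence and its feature annotation.

    Transcripts are laid out left to right with equal intergenic gaps.
    For a '-'-strand transcript the genomic order of its segments is
    reversed, so its 3'UTR is the 5'-most interval in genome coordinates.
    """
    rng = _rng(config, 0)
    total_span = sum(lay.span for lay in config.layouts)
    n = len(config.layouts)
    # gaps: one before each transcript and one after the last
    gap = (config.genome_length - total_span) // (n + 1) if n else 0
    if n and (total_span + (n + 1) > config.genome_length or gap < 1):
        raise ConfigError(
            f"transcript layout spans {total_span} bases which does not fit "
            f"in a {config.genome_length} base genome with gaps")

    seq = rng.choice(BASES, size=config.genome_length)
    rows = []
    cursor = gap + 1  # 1-based start of next transcript
    for i, lay in enumerate(config.layouts):
        gene = f"gene{i + 1:02d}"
        if lay.kind == "coding":
            segs = [(UTR5, lay.utr5)]
            for j, ex in enumerate(lay.exons):
                segs.append((EXONIC, ex))
                if j < len(lay.introns):
                    segs.append((INTRONIC, lay.introns[j]))
            segs.append((UTR3, lay.utr3))
        else:
            segs = []
            for j, ex in enumerate(lay.exons):
                segs.append((NC_EXONIC, ex))
                if j < len(lay.introns):
                    segs.append((NC_INTRONIC, lay.introns[j]))
        if lay.strand == "-":
            segs = segs[::-1]
        start = cursor
        for feature, length in segs:
            rows.append((config.chrom, cursor, cursor + length - 1,
                         feature, gene, lay.strand))
            cursor += length
        end = cursor - 1
        # merged upstream/downstream windows, clipped to the genome
        up = (max(1, start - config.flank_window), start - 1)
        down = (end + 1, min(config.genome_length, end + config.flank_window))
        for lo, hi in (up, down):
            if lo <= hi:
                rows.append((config.chrom, lo, hi, FLANK, gene, lay.strand))
        cursor += gap
    annotation = pd.DataFrame(rows, columns=eio.ANNOTATION_COLUMNS)
    return seq.tobytes().decode(), annotation


def plant_sites(config: SimConfig, reference: str, annotation: pd.DataFrame
                ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Choose editing and SNP positions; returns (truth_table, snp_table).

    Editing sites are planted inside annotated gene features (including
    flank windows) on bases compatible with their class and the gene
    strand, using the same precedence lookup the annotator applies, so
    truth feature labels round-trip exactly. SNP positions are disjoint
    from editing sites.
    """
    rng = _rng(config, 1)
    index = GenomeAnnotation(annotation)
    genic = annotation[annotation.feature != FLANK]
    candidate_pos = sorted({p for row in genic.itertuples()
                            for p in range(row.start, row.end + 1)})

    taken: set[int] = set()
    truth_rows = []
    for editing_class in (A_TO_I, C_TO_U):
        n_sites = config.n_edit_sites.get(editing_class, 0)
        eligible = []
        for pos in candidate_pos:
            if pos in taken:
                continue
            feature, gene, strand = index.annotate_position(config.chrom, pos)
            if strand not in "+-":
                continue
            if reference[pos - 1] == _REQUIRED_REF[(editing_class, strand)]:
                eligible.append((pos, feature, strand))
        if len(eligible) < n_sites:
            raise ConfigError(
                f"only {len(eligible)} eligible reference bases for "
                f"{n_sites} requested {editing_class} sites")
        picks = rng.choice(len(eligible), size=n_sites, replace=False)
        freqs = rng.uniform(*config.edit_freq_range, size=n_sites)
        for k, idx in enumerate(sorted(picks)):
            pos, feature, strand = eligible[idx]
            taken.add(pos)
            truth_rows.append((config.chrom, pos, reference[pos - 1],
                               _ALT_BASE[(editing_class, strand)],
                               editing_class, strand, float(freqs[k]), feature))
    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    truth = truth.sort_values("pos", kind="stable").reset_index(drop=True)

    free = [p for p in range(1, len(reference) + 1) if p not in taken]
    if len(free) < config.n_snp_sites:
        raise ConfigError("genome too small for requested SNP count")
    snp_pos = np.sort(rng.choice(free, size=config.n_snp_sites, replace=False))
    snp_rows = []
    for pos in snp_pos:
        ref = reference[pos - 1]
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        genotype = "hom" if rng.random() < config.snp_hom_fraction else "het"
        snp_rows.append((config.chrom, int(pos), ref, alt, genotype))
    snps = pd.DataFrame(snp_rows,
                        columns=["chrom", "pos", "ref", "alt", "genotype"])
    return truth, snps


def _sam_header(config: SimConfig) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict({
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": config.chrom, "LN": config.genome_length}],
    })


def simulate_alignments(config: SimConfig, reference: str,
                        truth: pd.DataFrame, snps: pd.DataFrame | None,
                        sam_path: str | os.PathLike,
                        replicate: int = 0) -> int:
    """Write simulated aligned reads as coordinate-sorted SAM.

    At a planted site each overlapping read carries the alt base with
    probability equal to the planted frequency (independent draws). Het
    SNPs show the alt in ~50% of reads, hom SNPs in all. A
    ``multimap_fraction`` of reads gets mapping quality 0 (and tag ZM:i:1);
    the rest MAPQ 60. Substitution errors occur at ``error_rate``, boosted
    ``end_error_boost``-fold within ``end_error_window`` bases of either
    read end. Returns the number of reads written.
    """
    rng = np.random.default_rng([2, replicate, config.seed])
    L, rl = config.genome_length, config.read_length
    if rl > L:
        raise ConfigError("read_length exceeds genome length")
    n_reads = int(round(config.mean_depth * L / rl)) if rl else 0

    ref_arr = np.frombuffer(reference.encode(), dtype="S1")
    starts = np.sort(rng.integers(0, L - rl + 1, size=n_reads))  # 0-based
    is_multi = rng.random(n_reads) < config.multimap_fraction
    is_reverse = rng.random(n_reads) < 0.5

    # per-base error probability profile along the read
    err_profile = np.full(rl, config.error_rate)
    w = min(config.end_error_window, rl)
    err_profile[:w] *= config.end_error_boost
    err_profile[rl - w:] *= config.end_error_boost
    np.clip(err_profile, 0.0, 1.0, out=err_profile)

    variant_pos: dict[int, tuple[str, float]] = {}
    for row in truth.itertuples():
        variant_pos[row.pos - 1] = (row.alt_base, row.planted_frequency)
    if snps is not None:
        for row in snps.itertuples():
            frac = 1.0 if row.genotype == "hom" else 0.5
            variant_pos[row.pos - 1] = (row.alt, frac)

    with pysam.AlignmentFile(str(sam_path), "w", header=_sam_header(config)) as out:
        for i in range(n_reads):
            s = int(starts[i])
            seq = ref_arr[s:s + rl].copy()
            for off in range(rl):
                hit = variant_pos.get(s + off)
                if hit is not None and rng.random() < hit[1]:
                    seq[off] = hit[0].encode()
            err_mask = rng.random(rl) < err_profile
            for off in np.nonzero(err_mask)[0]:
                cur = seq[off].decode()
                others = [b for b in "ACGT" if b != cur]
                seq[off] = rng.choice(others).encode()
            low = rng.random(rl) < config.low_quality_fraction
            quals = np.where(low, rng.integers(10, 25, size=rl),
                             rng.integers(30, 41, size=rl)).astype(np.uint8)

            read = pysam.AlignedSegment(header=out.header)
            read.query_name = f"read{i:07d}"
            read.reference_id = 0
            read.reference_start = s
            read.mapping_quality = 0 if is_multi[i] else 60
            read.cigarstring = f"{rl}M"
            read.query_sequence = seq.tobytes().decode()
            read.query_qualities = quals.tolist()
            read.flag = 16 if is_reverse[i] else 0
            if is_multi[i]:
                read.set_tag("ZM", 1, value_type="i")
            out.write(read)
    return n_reads


def simulate_dataset(config: SimConfig, outdir: str | os.PathLike
                     ) -> dict[str, str]:
    """Run the full simulation and write all artifacts into ``outdir``.

    Writes reference.fasta, features.bed, features.gff3, reads.sam,
    snp_mask.vcf and truth.tsv; returns a name -> path mapping.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    reference, annotation = simulate_reference(config)
    truth, snps = plant_sites(config, reference, annotation)

    paths = {name: str(outdir / fname) for name, fname in [
        ("reference", "reference.fasta"), ("bed", "features.bed"),
        ("gff3", "features.gff3"), ("sam", "reads.sam"),
        ("snp_mask", "snp_mask.vcf"), ("truth", "truth.tsv")]}
    eio.write_fasta(paths["reference"], {config.chrom: reference})
    eio.write_bed(paths["bed"], annotation)
    eio.write_gff3(paths["gff3"], annotation)
    eio.write_vcf(paths["snp_mask"], snps,
                  {config.chrom: config.genome_length})
    eio.write_tsv(paths["truth"], truth)
    simulate_alignments(config, reference, truth, snps, paths["sam"])
    # optional biological replicates: same truth, independent read noise
    for rep in range(1, config.n_replicates):
        rep_path = str(outdir / f"reads_rep{rep + 1}.sam")
        paths[f"sam_rep{rep + 1}"] = rep_path
        simulate_alignments(config, reference, truth, snps, rep_path,
                            replicate=rep)
    return paths
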