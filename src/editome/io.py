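"""Readers and writers for the file formats the pipeline touches.

Coordinate conventions: site tables, truth tables and VCF are 1-based
inclusive; BED is 0-based half-open and converted on read/write. Annotation
is held in memory as a pandas DataFrame with columns
``chrom, start, end, feature, gene, strand`` (1-based inclusive).
"""

from __future__ import annotations

import os

import pandas as pd
import pysam
from pyfaidx import Fasta

ANNOTATION_COLUMNS = ["chrom", "start", "end", "feature", "gene", "strand"]

_GFF3_TYPES = {
    "5'UTR": "five_prime_UTR",
    "3'UTR": "three_prime_UTR",
    "exonic": "CDS",
    "intronic": "intron",
    "ncRNA-exonic": "noncoding_exon",
    "ncRNA-intronic": "noncoding_intron",
    "upstream/downstream": "flank",
}
_GFF3_TYPES_INV = {v: k for k, v in _GFF3_TYPES.items()}


def write_fasta(path: str | os.PathLike, sequences: dict[str, str],
                width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_fasta(path: str | os.PathLike) -> Fasta:
    """Open an indexed FASTA (builds the .fai on first use)."""
    return Fasta(str(path))


def write_bed(path: str | os.PathLike, annotation: pd.DataFrame) -> None:
    """Write annotation intervals as BED6 (name = ``feature|gene``)."""
    with open(path, "w") as fh:
        for row in annotation.itertuples():
            fh.write(f"{row.chrom}\t{row.start - 1}\t{row.end}\t"
                     f"{row.feature}|{row.gene}\t0\t{row.strand}\n")


def read_bed(path: str | os.PathLike) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            chrom, start0, end = parts[0], int(parts[1]), int(parts[2])
            if start0 >= end:
                raise ValueError(f"malformed BED interval: {line!r}")
            name = parts[3] if len(parts) > 3 else "region|"
            strand = parts[5] if len(parts) > 5 else "."
            feature, _, gene = name.partition("|")
            rows.append((chrom, start0 + 1, end, feature, gene, strand))
    return pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)


def write_gff3(path: str | os.PathLike, annotation: pd.DataFrame) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in annotation.itertuples():
            gtype = _GFF3_TYPES.get(row.feature, row.feature)
            attrs = f"gene_id={row.gene};feature_class={row.feature}"
            fh.write(f"{row.chrom}\teditome\t{gtype}\t{row.start}\t{row.end}"
                     f"\t.\t{row.strand}\t.\t{attrs}\n")


def read_gff3(path: str | os.PathLike) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            chrom, _, gtype, start, end, _, strand, _, attrs = line.split("\t")
            start, end = int(start), int(end)
            if start > end:
                raise ValueError(f"malformed GFF3 interval: {line!r}")
            fields = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
            feature = fields.get("feature_class", _GFF3_TYPES_INV.get(gtype, gtype))
            gene = fields.get("gene_id", "")
            rows.append((chrom, start, end, feature, gene, strand))
    return pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)


def read_annotation(path: str | os.PathLike) -> pd.DataFrame:
    """Load annotation from BED or GFF3, sniffing by extension."""
    p = str(path)
    if p.endswith((".gff", ".gff3")):
        df = read_gff3(p)
    else:
        df = read_bed(p)
    bad = df[df.start > df.end]
    if len(bad):
        raise ValueError(f"{len(bad)} annotation intervals with start > end")
    return df


def write_vcf(path: str | os.PathLike, records: pd.DataFrame,
              contigs: dict[str, int]) -> None:
    """Write a minimal VCF 4.2 with chrom/pos/ref/alt (+ optional GT info)."""
    header = pysam.VariantHeader()
    for name, length in contigs.items():
        header.contigs.add(name, length=length)
    header.info.add("GT", 1, "String", "Simulated genotype (het/hom)")
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for row in records.itertuples():
            rec = vcf.new_record(contig=row.chrom, start=row.pos - 1,
                                 stop=row.pos, alleles=(row.ref, row.alt))
            if hasattr(row, "genotype"):
                rec.info["GT"] = row.genotype
            vcf.write(rec)


def read_vcf_positions(path: str | os.PathLike,
                       known_contigs: set[str] | None = None
                       ) -> tuple[set[tuple[str, int]], list[str]]:
    """Read (chrom, pos) pairs from a VCF mask.

    Entries on contigs absent from ``known_contigs`` are skipped and
    reported back as warnings rather than failing the run.
    """
    positions: set[tuple[str, int]] = set()
    warnings: list[str] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            if known_contigs is not None and rec.chrom not in known_contigs:
                warnings.append(
                    f"SNP mask entry on unknown contig {rec.chrom!r} ignored")
                continue
            positions.add((rec.chrom, rec.pos))
    return positions, warnings


def write_tsv(path: str | os.PathLike, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
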