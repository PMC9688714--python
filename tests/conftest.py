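import numpy as np
import pandas as pd
import pysam
import pytest

from editome import SimConfig, simulate_dataset
from editome.config import TranscriptLayout


SMALL_SIM = dict(
    genome_length=20_000,
    n_transcripts=4,
    n_edit_sites={"A-to-I": 20, "C-to-U": 10},
    n_snp_sites=10,
    flank_window=500,
)


@pytest.fixture(scope="session")
def sim_paths(tmp_path_factory):
    """One simulated dataset shared across read-only tests."""
    cfg = SimConfig(seed=11, **SMALL_SIM)
    return simulate_dataset(cfg, tmp_path_factory.mktemp("sim")), cfg


@pytest.fixture(scope="session")
def sim_truth(sim_paths):
    paths, _ = sim_paths
    return pd.read_csv(paths["truth"], sep="\t")


def write_reference(path, seq, chrom="ref1"):
    with open(path, "w") as fh:
        fh.write(f">{chrom}\n{seq}\n")
    return str(path)


def write_sam(path, reads, chrom="ref1", length=500):
    """Write simple full-match reads.

    ``reads`` is a list of dicts with keys start (0-based), seq, and
    optionally qual (list of ints), mapq, name.
    """
    header = pysam.AlignmentHeader.from_dict({
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": chrom, "LN": length}],
    })
    reads = sorted(reads, key=lambda r: r["start"])
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for i, r in enumerate(reads):
            a = pysam.AlignedSegment(header=header)
            a.query_name = r.get("name", f"r{i}")
            a.reference_id = 0
            a.reference_start = r["start"]
            a.mapping_quality = r.get("mapq", 60)
            a.cigarstring = f"{len(r['seq'])}M"
            a.query_sequence = r["seq"]
            a.query_qualities = r.get("qual", [40] * len(r["seq"]))
            out.write(a)
    return str(path)


def tiny_layouts():
    return [
        TranscriptLayout(kind="coding", strand="+", utr5=50, utr3=80,
                         exons=(100, 100), introns=(120,)),
        TranscriptLayout(kind="ncRNA", strand="-", exons=(80, 80),
                         introns=(90,)),
    ]
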