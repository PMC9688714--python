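"""Configuration objects for the simulator, the RDD caller and the pipeline.

Defaults reproduce a stringent bulk RNA-seq editing-detection setup:
base quality >= 25, read depth >= 10, >= 3 reads supporting the variant,
editing frequency >= 0.1, and per-site significance at alpha = 0.05 with
BH-FDR control, excluding multimapping reads and known SNPs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence


class ConfigError(ValueError):
    """Raised when a configuration violates its invariants."""


@dataclass
class TranscriptLayout:
    """Segment lengths of one simulated transcript, 5'->3' in gene orientation.

    ``kind`` is "coding" (5'UTR / CDS exons / introns / 3'UTR) or "ncRNA"
    (non-coding exons and introns only).
    """

    kind: str = "coding"
    strand: str = "+"
    utr5: int = 150
    utr3: int = 400
    exons: Sequence[int] = (300, 300)
    introns: Sequence[int] = (500,)

    def __post_init__(self) -> None:
        if self.kind not in ("coding", "ncRNA"):
            raise ConfigError(f"unknown transcript kind {self.kind!r}")
        if self.strand not in "+-":
            raise ConfigError(f"strand must be '+' or '-', got {self.strand!r}")
        if len(self.introns) != len(self.exons) - 1:
            raise ConfigError("need exactly len(exons) - 1 introns")
        if any(x <= 0 for x in (*self.exons, *self.introns)):
            raise ConfigError("exon/intron lengths must be positive")
        if self.kind == "coding" and (self.utr5 <= 0 or self.utr3 <= 0):
            raise ConfigError("coding transcripts need positive UTR lengths")

    @property
    def span(self) -> int:
        body = sum(self.exons) + sum(self.introns)
        if self.kind == "coding":
            body += self.utr5 + self.utr3
        return body


def default_layouts(n_transcripts: int) -> list[TranscriptLayout]:
    """Alternate coding/ncRNA transcripts on alternating strands."""
    layouts = []
    for i in range(n_transcripts):
        strand = "+" if i % 2 == 0 else "-"
        if i % 3 == 2:
            layouts.append(
                TranscriptLayout(kind="ncRNA", strand=strand,
                                 exons=(250, 250), introns=(400,))
            )
        else:
            layouts.append(TranscriptLayout(kind="coding", strand=strand))
    return layouts


@dataclass
class SimConfig:
    """Conditions for one simulated library.

    The simulator emulates, at desk scale, a pooled microglia bulk RNA-seq
    library: planted A-to-I and C-to-U events at known frequencies, masked
    SNP positions, a multimapping read fraction, and substitution errors
    elevated near read ends (random-hexamer priming bias).
    """

    seed: int = 0
    chrom: str = "sim1"
    genome_length: int = 100_000
    n_transcripts: int = 6
    layouts: list[TranscriptLayout] | None = None
    flank_window: int = 1_000
    n_edit_sites: dict = field(default_factory=lambda: {"A-to-I": 30, "C-to-U": 15})
    edit_freq_range: tuple[float, float] = (0.2, 0.8)
    n_snp_sites: int = 20
    snp_hom_fraction: float = 0.0
    error_rate: float = 0.005
    end_error_boost: float = 3.0
    end_error_window: int = 6
    read_length: int = 75
    mean_depth: float = 50.0
    multimap_fraction: float = 0.1
    low_quality_fraction: float = 0.05
    n_replicates: int = 1

    def __post_init__(self) -> None:
        if self.layouts is None:
            self.layouts = default_layouts(self.n_transcripts)
        else:
            self.layouts = list(self.layouts)
            self.n_transcripts = len(self.layouts)
        counts = (self.genome_length, self.n_transcripts, self.flank_window,
                  self.n_snp_sites, self.read_length)
        if any(c < 0 for c in counts):
            raise ConfigError("counts and lengths must be non-negative")
        for cls, n in self.n_edit_sites.items():
            if cls not in ("A-to-I", "C-to-U"):
                raise ConfigError(f"unknown editing class {cls!r}")
            if n < 0:
                raise ConfigError("site counts must be non-negative")
        lo, hi = self.edit_freq_range
        if not (0 < lo <= hi <= 1):
            raise ConfigError("edit_freq_range must satisfy 0 < lo <= hi <= 1")
        for name in ("error_rate", "multimap_fraction", "low_quality_fraction",
                     "snp_hom_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.mean_depth < 0 or self.end_error_boost < 1:
            raise ConfigError("mean_depth >= 0 and end_error_boost >= 1 required")


@dataclass
class FilterConfig:
    """Thresholds and exclusions applied by the RDD caller."""

    min_base_quality: int = 25
    min_depth: int = 10
    min_alt_support: int = 3
    min_freq: float = 0.1
    alpha: float = 0.05
    error_rate: float = 0.01
    end_trim: int = 6
    exclude_multimapped: bool = True
    max_multimap_mapq: int = 0
    snp_mask_path: str = ""

    def __post_init__(self) -> None:
        if not self.min_depth >= self.min_alt_support >= 1:
            raise ConfigError("need min_depth >= min_alt_support >= 1")
        if not 0 < self.min_freq <= 1:
            raise ConfigError("min_freq must be in (0, 1]")
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must be in (0, 1)")
        if not 0 < self.error_rate < self.min_freq:
            raise ConfigError("error_rate must satisfy 0 < error_rate < min_freq")
        if self.end_trim < 0 or self.min_base_quality < 0:
            raise ConfigError("end_trim and min_base_quality must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)


def filter_config_from_dict(raw: dict | None) -> FilterConfig:
    """Build a FilterConfig from a (possibly partial) mapping.

    Unknown keys are rejected so typos in config files fail loudly.
    """
    raw = dict(raw or {})
    valid = set(FilterConfig.__dataclass_fields__)
    unknown = set(raw) - valid
    if unknown:
        raise ConfigError(f"unknown FilterConfig fields: {sorted(unknown)}")
    return FilterConfig(**raw)


def sim_config_from_dict(raw: dict | None) -> SimConfig:
    raw = dict(raw or {})
    if "layouts" in raw and raw["layouts"] is not None:
        raw["layouts"] = [
            TranscriptLayout(**lay) if isinstance(lay, dict) else lay
            for lay in raw["layouts"]
        ]
    if "edit_freq_range" in raw:
        raw["edit_freq_range"] = tuple(raw["edit_freq_range"])
    valid = set(SimConfig.__dataclass_fields__)
    unknown = set(raw) - valid
    if unknown:
        raise ConfigError(f"unknown SimConfig fields: {sorted(unknown)}")
    return SimConfig(**raw)
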