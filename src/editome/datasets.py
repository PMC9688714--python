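"""Published summary tables bundled for worked examples.

These are transcriptions of printed results tables — per-enzyme and
per-stage editome counts, the naive feature-percentage row, and the
per-position B2m 3'UTR clone-detection lists from the bench validation —
used by the worked-example checks and the acceptance script. Positions
listed as predicted but never detected are not individually printed in
the source; they appear here under synthetic ``*_nd*`` labels solely so
the predicted-position denominators are represented.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

NAIVE_ADAR_EVENTS = 775
NAIVE_APOBEC_EVENTS = 450
TOTAL_EVENTS = {"naive": 1225, "pre-clinical": 1134, "acute": 891}


def _load(name: str) -> pd.DataFrame:
    ref = resources.files("editome") / "data" / name
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def editome_counts() -> pd.DataFrame:
    """Per-condition event counts (per enzyme class where published)."""
    return _load("editome_counts.tsv")


def naive_feature_percentages() -> pd.DataFrame:
    """Genomic-feature percentage distribution of the naive editome."""
    return _load("editome_naive_features.tsv")


def b2m_clone_detections(tissue: str | None = None,
                         condition: str | None = None) -> pd.DataFrame:
    """Per-position, per-replicate B2m 3'UTR C-to-U clone detections.

    Columns: tissue (microglia/brain), condition (naive/acute), position,
    replicate, edited (clones carrying the edited base; 0/1 encodes
    detected-or-not per replicate), total (clones examined).
    """
    df = _load("b2m_clone_detections.tsv")
    if tissue is not None:
        df = df[df.tissue == tissue]
    if condition is not None:
        df = df[df.condition == condition]
    return df.reset_index(drop=True)
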