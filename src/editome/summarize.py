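"""Per-condition editome summaries and cross-condition comparisons."""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field, asdict

import pandas as pd

from .annotate import FEATURE_CLASSES
from .classify import RDD_TYPES, EDITING_CLASSES


@dataclass
class EditomeSummary:
    """Counts and percentages describing one condition's editome."""

    label: str
    n_total: int
    n_by_class: dict[str, int]
    n_by_feature: dict[str, int]
    pct_by_feature: dict[str, float]
    type_histogram: dict[str, int]

    def to_dict(self) -> dict:
        return asdict(self)

    def to_frame(self) -> pd.DataFrame:
        """Feature table mirroring a per-condition distribution ring."""
        return pd.DataFrame({
            "feature": list(self.n_by_feature),
            "n": list(self.n_by_feature.values()),
            "pct": [self.pct_by_feature[f] for f in self.n_by_feature],
        })


@dataclass
class EditomeComparison:
    """Reductions and feature shifts of a case editome vs a baseline."""

    baseline: str
    case: str
    reduction_total_pct: float | None
    reduction_total_pct_rounded: int | None
    reduction_by_class_pct: dict[str, float | None]
    feature_shift_points: dict[str, float]

    def to_dict(self) -> dict:
        return asdict(self)


def percent_reduction(n_base: int, n_case: int) -> float | None:
    """100 * (n_base - n_case) / n_base, or None when the base is empty."""
    if n_base == 0:
        return None
    return 100.0 * (n_base - n_case) / n_base


def summarize_editome(edits: pd.DataFrame, label: str) -> EditomeSummary:
    """Summarize annotated edits (one condition) into counts/percentages.

    ``edits`` needs columns editing_class, feature and rdd_type (as
    produced by :func:`editome.annotate.annotate_calls`). Percentages are
    rounded to 0.1; an empty input yields zero percentages with a warning.
    """
    n_total = int(len(edits))
    if n_total == 0:
        _warnings.warn(f"empty editome for condition {label!r}; "
                       "percentages reported as zero")
    by_class = {c: 0 for c in EDITING_CLASSES}
    by_feature = {f: 0 for f in FEATURE_CLASSES}
    histogram = {t.value: 0 for t in RDD_TYPES}
    if n_total:
        for cls, n in edits.editing_class.value_counts().items():
            by_class[cls] = int(n)
        for feat, n in edits.feature.value_counts().items():
            by_feature[feat] = int(n)
        for t, n in edits.rdd_type.value_counts().items():
            histogram[t] = int(n)
    pct = {f: round(100.0 * n / n_total, 1) if n_total else 0.0
           for f, n in by_feature.items()}
    return EditomeSummary(label=label, n_total=n_total, n_by_class=by_class,
                          n_by_feature=by_feature, pct_by_feature=pct,
                          type_histogram=histogram)


def compare_editomes(base: EditomeSummary, case: EditomeSummary
                     ) -> EditomeComparison:
    """Percent reductions (total and per class) and per-feature shifts.

    Reductions are reported both unrounded and rounded to the nearest
    integer; feature shifts are percentage points (case - base).
    """
    total = percent_reduction(base.n_total, case.n_total)
    by_class = {
        cls: percent_reduction(base.n_by_class.get(cls, 0),
                               case.n_by_class.get(cls, 0))
        for cls in EDITING_CLASSES}
    shifts = {
        f: round(case.pct_by_feature.get(f, 0.0)
                 - base.pct_by_feature.get(f, 0.0), 1)
        for f in FEATURE_CLASSES}
    return EditomeComparison(
        baseline=base.label, case=case.label,
        reduction_total_pct=total,
        reduction_total_pct_rounded=None if total is None else round(total),
        reduction_by_class_pct=by_class,
        feature_shift_points=shifts)


def summary_from_counts(label: str, n_by_class: dict[str, int],
                        n_by_feature: dict[str, int] | None = None
                        ) -> EditomeSummary:
    """Build a summary directly from per-class (and per-feature) counts.

    Used for worked examples on published count tables where per-site
    records are not available.
    """
    by_class = {c: int(n_by_class.get(c, 0)) for c in EDITING_CLASSES}
    n_total = sum(by_class.values())
    by_feature = {f: 0 for f in FEATURE_CLASSES}
    if n_by_feature:
        for f, n in n_by_feature.items():
            by_feature[f] = int(n)
    pct = {f: round(100.0 * n / n_total, 1) if n_total else 0.0
           for f, n in by_feature.items()}
    return EditomeSummary(label=label, n_total=n_total, n_by_class=by_class,
                          n_by_feature=by_feature, pct_by_feature=pct,
                          type_histogram={t.value: 0 for t in RDD_TYPES})
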