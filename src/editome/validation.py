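"""Validation-stage quantifications: clone counting, chromatogram peak
ratios, one-tailed unpaired t-tests, 2^-ddCt expression fold changes, and
EAE clinical-course statistics.

Two editing-frequency estimators are implemented, matching the two bench
readouts: the fraction of sequenced cDNA clones carrying the edited base
(clone counting), and the edited-peak fraction G/(A+G) from Sanger
chromatogram peak heights. Group comparisons use the Student pooled-
variance unpaired t-test (one-tailed for editing frequencies, two-tailed
for clinical statistics); Welch's correction is available via
``equal_var=False``.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats


# ---------------------------------------------------------------- editing

def clone_editing_frequency(edited: int | np.ndarray,
                            total: int | np.ndarray) -> np.ndarray:
    """Editing frequency as edited-clone fraction, per replicate."""
    edited = np.atleast_1d(np.asarray(edited, dtype=float))
    total = np.atleast_1d(np.asarray(total, dtype=float))
    if np.any(total < 1):
        raise ValueError("total clone count must be >= 1")
    if np.any((edited < 0) | (edited > total)):
        raise ValueError("need 0 <= edited <= total")
    return edited / total


def peak_editing_frequency(a_peak: float | np.ndarray,
                           g_peak: float | np.ndarray) -> np.ndarray:
    """Editing frequency from chromatogram peaks: edited/(ref + edited)."""
    a = np.atleast_1d(np.asarray(a_peak, dtype=float))
    g = np.atleast_1d(np.asarray(g_peak, dtype=float))
    if np.any((a < 0) | (g < 0)):
        raise ValueError("peak heights must be non-negative")
    if np.any(a + g == 0):
        raise ValueError("both peaks are zero at some site")
    return g / (a + g)


def detection_summary(clones: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Per-position replicate detection and the verified-position count.

    ``clones`` needs columns position, replicate, edited, total (one row
    per position x replicate). A position is *verified* when at least one
    replicate shows at least one edited clone. Returns a per-position
    table (replicates_detected, replicates_total, verified) and the number
    of verified positions.
    """
    rows = []
    for position, grp in clones.groupby("position", sort=True):
        detected = int((grp.edited >= 1).sum())
        rows.append((position, detected, int(len(grp)), detected >= 1))
    table = pd.DataFrame(rows, columns=[
        "position", "replicates_detected", "replicates_total", "verified"])
    return table, int(table.verified.sum())


@dataclass
class TTestResult:
    t: float
    df: float
    p: float
    degenerate: bool = False

    def to_dict(self) -> dict:
        return asdict(self)


def one_tailed_unpaired_t(baseline, case, direction: str = "greater",
                          equal_var: bool = True) -> TTestResult:
    """One-tailed unpaired t-test between two groups.

    ``direction="greater"`` tests case > baseline (the default, matching
    an expected editing increase in disease); ``"less"`` tests the
    opposite. With zero pooled variance the statistic is degenerate: equal
    means give p = 0.5, unequal means give p -> 0 or 1 by direction, and
    the result is flagged.
    """
    a = np.asarray(baseline, dtype=float)
    b = np.asarray(case, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    if direction not in ("greater", "less"):
        raise ValueError("direction must be 'greater' or 'less'")
    df = (a.size + b.size - 2 if equal_var
          else stats.ttest_ind(b, a, equal_var=False).df)
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        if np.mean(a) == np.mean(b):
            return TTestResult(t=0.0, df=float(df), p=0.5, degenerate=True)
        diff_sign = np.sign(np.mean(b) - np.mean(a))
        want = 1.0 if direction == "greater" else -1.0
        p = 0.0 if diff_sign == want else 1.0
        return TTestResult(t=float("inf") * diff_sign, df=float(df), p=p,
                           degenerate=True)
    res = stats.ttest_ind(b, a, equal_var=equal_var, alternative=direction)
    return TTestResult(t=float(res.statistic), df=float(res.df),
                       p=float(res.pvalue))


# ------------------------------------------------------------------ qPCR

def ddct_fold_change(case: pd.DataFrame, baseline: pd.DataFrame
                     ) -> tuple[float, list[str]]:
    """Relative expression fold change by the 2^-ddCt method.

    Each input needs columns Ct_target and Ct_reference (the reference
    gene, e.g. Gapdh). Per sample dCt = Ct_target - Ct_reference;
    ddCt = mean dCt(case) - mean dCt(baseline); fold = 2 ** -ddCt.
    Samples missing the reference Ct are dropped with a warning.
    """
    warnings = []

    def _dcts(df: pd.DataFrame, name: str) -> np.ndarray:
        missing = df.Ct_reference.isna() | df.Ct_target.isna()
        if missing.any():
            warnings.append(
                f"{int(missing.sum())} {name} sample(s) dropped: missing Ct")
        kept = df[~missing]
        if kept.empty:
            raise ValueError(f"no usable {name} samples")
        return (kept.Ct_target - kept.Ct_reference).to_numpy()

    ddct = float(np.mean(_dcts(case, "case")) - np.mean(_dcts(baseline, "baseline")))
    return float(2.0 ** (-ddct)), warnings


# -------------------------------------------------------------- clinical

@dataclass
class CourseStats:
    """Per-animal disease-course statistics on the 0-5 ordinal scale."""

    animal: str
    max_score: float
    auc: float
    day_onset: float | None  # first day with score >= onset threshold


@dataclass
class GroupClinicalStats:
    group: str
    n: int
    mms: float
    mms_se: float
    mauc: float
    mauc_se: float
    ddo: float | None
    ddo_se: float | None
    n_onset: int

    def to_dict(self) -> dict:
        return asdict(self)


def _course_stats(animal: str, days: np.ndarray, scores: np.ndarray,
                  onset_threshold: float) -> CourseStats:
    if days.size < 2:
        raise ValueError(f"animal {animal!r} has fewer than 2 scored days")
    if np.any(np.diff(days) <= 0):
        raise ValueError(f"animal {animal!r}: days must be strictly increasing")
    onset_idx = np.nonzero(scores >= onset_threshold)[0]
    onset = float(days[onset_idx[0]]) if onset_idx.size else None
    return CourseStats(animal=animal, max_score=float(scores.max()),
                       auc=float(np.trapezoid(scores, days)), day_onset=onset)


def clinical_course_stats(courses: pd.DataFrame, onset_threshold: float = 1.0
                          ) -> tuple[pd.DataFrame, list[GroupClinicalStats]]:
    """Per-animal and per-group clinical-course statistics.

    ``courses`` needs columns animal, group, day, score. Per animal:
    maximal score (MS), trapezoidal area under the score-day curve (AUC)
    over the observed window, and day of onset (DO; first day scoring at
    least ``onset_threshold``). Group statistics are means with standard
    errors: mMS, mAUC and dDO, the latter over onset animals only (the
    non-onset count is reported).
    """
    per_animal = []
    for (animal, group), grp in courses.groupby(["animal", "group"], sort=True):
        grp = grp.sort_values("day")
        cs = _course_stats(str(animal), grp.day.to_numpy(dtype=float),
                           grp.score.to_numpy(dtype=float), onset_threshold)
        per_animal.append((cs.animal, group, cs.max_score, cs.auc, cs.day_onset))
    table = pd.DataFrame(per_animal, columns=[
        "animal", "group", "max_score", "auc", "day_onset"])

    def _mean_se(x: np.ndarray) -> tuple[float, float]:
        se = float(np.std(x, ddof=1) / np.sqrt(x.size)) if x.size > 1 else 0.0
        return float(np.mean(x)), se

    groups = []
    for group, grp in table.groupby("group", sort=True):
        mms, mms_se = _mean_se(grp.max_score.to_numpy())
        mauc, mauc_se = _mean_se(grp.auc.to_numpy())
        onset = grp.day_onset.dropna().to_numpy(dtype=float)
        ddo, ddo_se = _mean_se(onset) if onset.size else (None, None)
        groups.append(GroupClinicalStats(
            group=str(group), n=int(len(grp)), mms=mms, mms_se=mms_se,
            mauc=mauc, mauc_se=mauc_se, ddo=ddo, ddo_se=ddo_se,
            n_onset=int(onset.size)))
    return table, groups


def compare_clinical_groups(table: pd.DataFrame, group_a: str, group_b: str,
                            metric: str = "max_score") -> TTestResult:
    """Two-tailed unpaired t-test of a per-animal clinical metric."""
    a = table.loc[table.group == group_a, metric].dropna().to_numpy(dtype=float)
    b = table.loc[table.group == group_b, metric].dropna().to_numpy(dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2 for the comparison")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        p = 1.0 if np.mean(a) == np.mean(b) else 0.0
        return TTestResult(t=0.0, df=float(a.size + b.size - 2), p=p,
                           degenerate=True)
    res = stats.ttest_ind(b, a, equal_var=True)
    return TTestResult(t=float(res.statistic), df=float(res.df),
                       p=float(res.pvalue))
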