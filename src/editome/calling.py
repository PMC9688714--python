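"""Per-site RDD statistics and threshold-based call filtering.

Each candidate site (any non-reference base observed after pileup
filtering) is scored with two one-sided tests against a sequencing-error
null with per-base error rate ``error_rate``:

* a binomial tail test, ``P(X >= alt_count)`` for
  ``X ~ Binomial(depth, error_rate)``;
* a Fisher's exact test on the 2x2 table of observed alt/ref counts
  against the expected error counts ``e = round(error_rate * depth)``
  vs ``depth - e`` (at minimal depth ``e`` may be 0, which makes this
  test weak — a documented property, not an error).

A site passes when every threshold predicate holds jointly: depth,
supporting reads, frequency, both raw p-values at alpha, BH-FDR q-value
at alpha, and absence from the SNP mask. The FDR correction is applied
to the per-site maximum of the two p-values over the *candidate* sites —
those surviving the depth/support/frequency thresholds and the SNP mask
— mirroring how variant-calling suites gate pre-filtered candidates with
their statistics; sequencing-noise positions below the hard thresholds
are not part of the tested family. All mismatch-bearing sites are
retained in the output with per-filter failure flags for audit
(non-candidates carry no q-value).
"""

from __future__ import annotations

import os
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import io as eio
from .config import FilterConfig

CALL_COLUMNS = ["chrom", "pos", "ref", "alt", "depth", "alt_count", "freq",
                "p_binomial", "p_fisher", "q_value", "passed", "flags"]

FILTER_NAMES = ("min_depth", "min_alt_support", "min_freq",
                "p_binomial", "p_fisher", "q_value", "snp_mask")


def binomial_site_test(alt_count: int, depth: int, error_rate: float) -> float:
    """One-sided binomial tail p-value, P(X >= alt_count | depth, error)."""
    if not 0 <= alt_count <= depth or depth < 1:
        raise ValueError("need 0 <= alt_count <= depth and depth >= 1")
    return float(stats.binom.sf(alt_count - 1, depth, error_rate))


def fisher_site_test(alt_count: int, depth: int, error_rate: float) -> float:
    """One-sided Fisher's exact p for alt enrichment over the error rate.

    Contingency table: ``[[alt, depth - alt], [e, depth - e]]`` with
    ``e = round(error_rate * depth)``; alternative = alt enriched in the
    observed row.
    """
    if not 0 <= alt_count <= depth or depth < 1:
        raise ValueError("need 0 <= alt_count <= depth and depth >= 1")
    e = int(round(error_rate * depth))
    table = [[alt_count, depth - alt_count], [e, depth - e]]
    return float(stats.fisher_exact(table, alternative="greater")[1])


def fdr_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in input order."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _pick_alt(row) -> tuple[str, int]:
    # most abundant non-reference base; ties break lexicographically (A<C<G<T)
    best_base, best_count = "", -1
    for base in "ACGT":
        if base == row.ref:
            continue
        count = getattr(row, base)
        if count > best_count:
            best_base, best_count = base, count
    return best_base, int(best_count)


def call_rdd_sites(pileup: pd.DataFrame,
                   snp_mask: Iterable[tuple[str, int]] | str | os.PathLike | None,
                   config: FilterConfig | None = None,
                   ) -> tuple[pd.DataFrame, list[str]]:
    """Score and filter candidate RDD sites from a pileup table.

    ``snp_mask`` may be a VCF path, an iterable of (chrom, pos) pairs, or
    None. Returns ``(calls, warnings)`` where ``calls`` holds every
    candidate site with its statistics, pass status and failure flags.
    """
    config = config or FilterConfig()
    warnings: list[str] = []
    if snp_mask is None and config.snp_mask_path:
        snp_mask = config.snp_mask_path
    if isinstance(snp_mask, (str, os.PathLike)):
        known = set(pileup.chrom.unique()) if len(pileup) else None
        mask, warnings = eio.read_vcf_positions(snp_mask, known)
    elif snp_mask is None:
        mask = set()
    else:
        mask = set(snp_mask)

    rows = []
    for row in pileup.itertuples():
        alt, alt_count = _pick_alt(row)
        if alt_count < 1:
            continue
        rows.append((row.chrom, row.pos, row.ref, alt, row.depth, alt_count))
    if not rows:
        calls = pd.DataFrame(columns=CALL_COLUMNS)
        calls["passed"] = calls["passed"].astype(bool)
        return calls, warnings

    calls = pd.DataFrame(
        rows, columns=["chrom", "pos", "ref", "alt", "depth", "alt_count"])
    calls["freq"] = calls.alt_count / calls.depth
    calls["p_binomial"] = stats.binom.sf(
        calls.alt_count - 1, calls.depth, config.error_rate)
    calls["p_fisher"] = [
        fisher_site_test(a, d, config.error_rate)
        for a, d in zip(calls.alt_count, calls.depth)]
    masked = pd.Series(
        [(c, p) in mask for c, p in zip(calls.chrom, calls.pos)],
        index=calls.index)
    # the FDR family: sites surviving the hard filters and the SNP mask
    candidate = ((calls.depth >= config.min_depth)
                 & (calls.alt_count >= config.min_alt_support)
                 & (calls.freq >= config.min_freq)
                 & ~masked)
    combined = np.maximum(calls.p_binomial, calls.p_fisher)
    calls["q_value"] = np.nan
    calls.loc[candidate, "q_value"] = fdr_adjust(combined[candidate])

    failures = {
        "min_depth": calls.depth < config.min_depth,
        "min_alt_support": calls.alt_count < config.min_alt_support,
        "min_freq": calls.freq < config.min_freq,
        "p_binomial": calls.p_binomial > config.alpha,
        "p_fisher": calls.p_fisher > config.alpha,
        "q_value": candidate & (calls.q_value > config.alpha),
        "snp_mask": masked,
    }
    flag_matrix = pd.DataFrame(failures)
    calls["passed"] = ~flag_matrix.any(axis=1)
    calls["flags"] = [
        ",".join(name for name in FILTER_NAMES if flag_matrix.at[i, name])
        for i in calls.index]
    return calls[CALL_COLUMNS], warnings


def attrition_counts(calls: pd.DataFrame) -> dict[str, int]:
    """Per-filter failure counts plus candidate/passing totals."""
    out = {"candidates": int(len(calls)), "passed": int(calls.passed.sum())}
    for name in FILTER_NAMES:
        out[f"fail_{name}"] = int(
            calls["flags"].str.split(",").apply(lambda fl: name in fl).sum()
        ) if len(calls) else 0
    return out


def write_calls_tsv(path: str | os.PathLike, calls: pd.DataFrame) -> None:
    eio.write_tsv(path, calls)


def write_calls_vcf(path: str | os.PathLike, calls: pd.DataFrame,
                    contigs: dict[str, int]) -> None:
    """Write passing calls as a minimal VCF."""
    passing = calls[calls.passed].rename(columns={})
    records = passing[["chrom", "pos", "ref", "alt"]]
    eio.write_vcf(path, records, contigs)
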