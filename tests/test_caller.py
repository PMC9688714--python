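"""RDD caller: pileup filters, exact-test oracles, BH-FDR, and the
threshold/exclusion logic of site calling."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from editome import (FilterConfig, build_pileup, binomial_site_test,
                     fisher_site_test, fdr_adjust, call_rdd_sites)
from editome.calling import attrition_counts

from conftest import write_reference, write_sam


# ------------------------------------------------------- enumeration oracles

def binomial_tail_oracle(alt, depth, p):
    """P(X >= alt) by exhaustive summation over the binomial pmf."""
    return sum(math.comb(depth, k) * p ** k * (1 - p) ** (depth - k)
               for k in range(alt, depth + 1))


def fisher_greater_oracle(a, b, c, d):
    """One-sided Fisher p for [[a,b],[c,d]] by hypergeometric enumeration."""
    n = a + b + c + d
    col1 = a + c
    row1 = a + b
    denom = math.comb(n, col1)
    lo, hi = max(0, col1 - (n - row1)), min(row1, col1)
    return sum(math.comb(row1, x) * math.comb(n - row1, col1 - x) / denom
               for x in range(a, hi + 1))


# ------------------------------------------------------------------- pileup

@pytest.fixture()
def ref200(tmp_path):
    rng = np.random.default_rng(42)
    seq = "".join(rng.choice(list("ACGT"), size=200))
    return write_reference(tmp_path / "ref.fa", seq), seq


def test_end_trimmed_read_covers_length_minus_two_trims(ref200, tmp_path):
    ref_path, seq = ref200
    sam = write_sam(tmp_path / "r.sam", [dict(start=10, seq=seq[10:85])])
    pileup = build_pileup(sam, ref_path, FilterConfig(end_trim=6))
    assert len(pileup) == 75 - 2 * 6
    assert pileup.pos.min() == 10 + 6 + 1 and pileup.pos.max() == 10 + 75 - 6


def test_base_below_quality_threshold_not_counted(ref200, tmp_path):
    ref_path, seq = ref200
    qual = [40] * 75
    qual[30] = 24  # boundary: Q24 < 25 is excluded
    sam = write_sam(tmp_path / "r.sam",
                    [dict(start=0, seq=seq[:75], qual=qual),
                     dict(start=0, seq=seq[:75])])
    pileup = build_pileup(sam, ref_path, FilterConfig())
    assert int(pileup.loc[pileup.pos == 31, "depth"].iloc[0]) == 1
    assert int(pileup.loc[pileup.pos == 32, "depth"].iloc[0]) == 2


def test_multimapping_reads_excluded_from_depth(ref200, tmp_path):
    ref_path, seq = ref200
    reads = [dict(start=0, seq=seq[:75], mapq=0) for _ in range(5)]
    reads += [dict(start=0, seq=seq[:75], mapq=60) for _ in range(5)]
    sam = write_sam(tmp_path / "r.sam", reads)
    pileup = build_pileup(sam, ref_path, FilterConfig())
    assert (pileup.depth == 5).all()
    keep_all = build_pileup(sam, ref_path,
                            FilterConfig(exclude_multimapped=False))
    assert (keep_all.depth == 10).all()


def test_unknown_contig_raises(ref200, tmp_path):
    ref_path, seq = ref200
    sam = write_sam(tmp_path / "r.sam", [dict(start=0, seq=seq[:75])],
                    chrom="chrMystery")
    with pytest.raises(ValueError, match="chrMystery"):
        build_pileup(sam, ref_path, FilterConfig())


# -------------------------------------------------------------- exact tests

@pytest.mark.parametrize("alt,depth,eps,expected", [
    (0, 10, 0.01, 1.0),
    (10, 10, 0.01, 1e-20),
    (3, 10, 0.01, 1.1385e-4),  # frozen from the enumeration oracle
])
def test_binomial_tail_reference_values(alt, depth, eps, expected):
    assert binomial_site_test(alt, depth, eps) == pytest.approx(expected,
                                                                rel=1e-3)


@pytest.mark.parametrize("table,expected", [
    ([[3, 7], [0, 10]], 0.10526315789),   # C(10,3)/C(20,3)
    ([[10, 0], [0, 10]], 1 / 184756),     # C(20,10)^-1
])
def test_fisher_reference_values(table, expected):
    (a, b), (c, d) = table
    depth = a + b
    # choose an error rate whose expected count reproduces row 2
    eps = c / depth if depth else 0.0
    assert fisher_site_test(a, depth, eps) == pytest.approx(expected,
                                                            rel=1e-9)
    assert fisher_greater_oracle(a, b, c, d) == pytest.approx(expected,
                                                              rel=1e-9)


def test_fisher_observed_equals_expected_is_not_enriched():
    # alt_count == e means no enrichment over the error model
    assert fisher_site_test(1, 100, 0.01) >= 0.5
    assert fisher_site_test(0, 10, 0.0) >= 0.5


@settings(max_examples=150, deadline=None, derandomize=True)
@given(depth=st.integers(1, 200), frac=st.floats(0, 1),
       eps=st.sampled_from([0.001, 0.005, 0.01, 0.05, 0.09]))
def test_exact_tests_match_enumeration_oracles(depth, frac, eps):
    alt = round(frac * depth)
    assert binomial_site_test(alt, depth, eps) == pytest.approx(
        binomial_tail_oracle(alt, depth, eps), abs=1e-10)
    e = int(round(eps * depth))
    assert fisher_site_test(alt, depth, eps) == pytest.approx(
        fisher_greater_oracle(alt, depth - alt, e, depth - e), abs=1e-10)


def test_invalid_counts_rejected():
    with pytest.raises(ValueError):
        binomial_site_test(5, 4, 0.01)
    with pytest.raises(ValueError):
        fisher_site_test(-1, 10, 0.01)


# ---------------------------------------------------------------------- BH

def test_bh_stepup_hand_computed_case():
    assert fdr_adjust([0.01, 0.02, 0.04]) == pytest.approx([0.03, 0.03, 0.04])


def test_bh_identity_and_fixed_points():
    assert fdr_adjust([0.37]) == pytest.approx([0.37])
    assert fdr_adjust([0.2, 0.2, 0.2]) == pytest.approx([0.2, 0.2, 0.2])
    assert fdr_adjust([]).size == 0


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
def test_bh_output_order_and_monotonicity(pvals):
    q = fdr_adjust(pvals)
    assert q.shape == (len(pvals),)
    assert np.all(q >= np.asarray(pvals) - 1e-12)  # BH never decreases p
    assert np.all(q <= 1.0 + 1e-12)
    order = np.argsort(pvals, kind="stable")
    assert np.all(np.diff(q[order]) >= -1e-12)  # q monotone in sorted p


# ----------------------------------------------------------------- calling

def _pileup_row(ref, counts, chrom="ref1", pos=100):
    a, c, g, t = counts
    return dict(chrom=chrom, pos=pos, ref=ref, A=a, C=c, G=g, T=t,
                depth=a + c + g + t)


def test_shallow_site_rejected_for_depth():
    pileup = pd.DataFrame([_pileup_row("A", (6, 0, 3, 0))])  # depth 9, alt 3
    calls, _ = call_rdd_sites(pileup, None, FilterConfig())
    row = calls.iloc[0]
    assert not row.passed and "min_depth" in row["flags"].split(",")


def test_low_support_low_freq_flags_both():
    pileup = pd.DataFrame([_pileup_row("A", (28, 0, 2, 0))])  # depth 30, alt 2
    calls, _ = call_rdd_sites(pileup, None, FilterConfig())
    flags = set(calls.iloc[0]["flags"].split(","))
    assert {"min_alt_support", "min_freq"} <= flags


def test_well_supported_site_accepted():
    pileup = pd.DataFrame([_pileup_row("A", (35, 0, 15, 0))])  # depth 50, 0.30
    calls, _ = call_rdd_sites(pileup, None, FilterConfig(error_rate=0.01))
    row = calls.iloc[0]
    assert row.passed and row["flags"] == ""
    assert row.freq == pytest.approx(0.30)
    assert row.p_binomial < 0.05 and row.p_fisher < 0.05 and row.q_value < 0.05


def test_alt_base_tie_breaks_lexicographically():
    pileup = pd.DataFrame([_pileup_row("A", (40, 5, 5, 0))])
    calls, _ = call_rdd_sites(pileup, None, FilterConfig())
    assert calls.iloc[0].alt == "C"


def test_masked_site_rejected_and_flagged():
    pileup = pd.DataFrame([_pileup_row("A", (35, 0, 15, 0))])
    calls, _ = call_rdd_sites(pileup, [("ref1", 100)], FilterConfig())
    row = calls.iloc[0]
    assert not row.passed and "snp_mask" in row["flags"]
    assert attrition_counts(calls)["fail_snp_mask"] == 1


def test_reference_only_sites_are_not_candidates():
    pileup = pd.DataFrame([_pileup_row("A", (50, 0, 0, 0))])
    calls, _ = call_rdd_sites(pileup, None, FilterConfig())
    assert calls.empty
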