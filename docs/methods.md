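# Methods

## Scope and model

The package detects RNA:DNA differences (RDDs) from aligned RNA-seq reads
and interprets them as enzymatic RNA editing. The underlying model is
deliberately simple and standard: at a genomic position with quality-
filtered depth `n`, the number of reads carrying a particular
non-reference base is `Binomial(n, f)` where `f` is the true editing
frequency at an edited site, or is governed by the residual sequencing
error rate ε at an unedited one. Calling a site therefore reduces to
rejecting the error null and clearing a set of hard thresholds designed
to remove the known failure modes of editome analysis: low-quality base
calls, read-end artefacts from random-hexamer priming, multimapping
reads, and genomic polymorphism masquerading as editing.

## Pileup filters

Filters are applied while tallying bases, not afterwards:

| parameter | default | unit | role |
|---|---|---|---|
| `min_base_quality` | 25 | phred | drop uncertain base calls |
| `end_trim` | 6 | bases | ignore both read ends (hexamer bias) |
| `exclude_multimapped` / `max_multimap_mapq` | true / 0 | — | drop reads with MAPQ ≤ floor |

End-trimming at pileup time is equivalent to FASTQ trimming for mismatch
counting and keeps the pipeline alignment-native; the trim is symmetric,
so read orientation is irrelevant. Positions with zero surviving depth
are omitted; positions whose reference base is not A/C/G/T are dropped.

## Per-site statistics and calling

Each site with at least one non-reference read is scored twice against
the error null with rate `error_rate` (default ε = 0.01, a conservative
ceiling for post-Q25 mismatch rates; configurable):

* one-sided binomial tail, `P(X ≥ alt_count)`, `X ~ Binomial(depth, ε)`;
* one-sided Fisher's exact test on `[[alt, depth−alt], [e, depth−e]]`
  with `e = round(ε·depth)`. When `e` rounds to 0 (depth below ~1/2ε)
  this test is weak — its p-value cannot fall below roughly
  `C(depth, alt)/C(2·depth, alt)` — which is documented behaviour, not a
  defect; the binomial test carries the statistical weight there.

A call requires *all* predicates jointly: `depth ≥ min_depth` (10),
`alt_count ≥ min_alt_support` (3), `freq ≥ min_freq` (0.1), both raw
p ≤ `alpha` (0.05), BH-FDR q ≤ `alpha`, and absence from the SNP mask.
Requiring both tests is the conservative intersection of two calling
routes; the FDR correction uses the per-site maximum of the two p-values,
which upper-bounds either test's p and keeps the combined decision
conservative.

The FDR family is the set of *candidate* sites — those that survive the
hard depth/support/frequency thresholds and the SNP mask. This mirrors
how variant-calling suites apply their statistics to pre-filtered
candidates. The alternative — correcting over every mismatch-bearing
position — makes the family overwhelmingly sequencing noise (thousands
of 1–2-read mismatch positions per 20 kb at ε ≈ 0.005) and, combined
with the Fisher floor above, pushes attainable q-values for genuinely
edited mid-frequency sites above any reasonable alpha. The trade-off is
that Benjamini–Hochberg on a threshold-dependent family does not
*formally* guarantee that raising a count threshold never admits a new
call (removing large-p candidates shrinks the family and can lower other
sites' q); in practice, across the simulated regimes the pass count is
monotone in every threshold, and the property suite checks this.

Alt-base ties (two non-reference bases with equal support) break
lexicographically A<C<G<T for determinism. Sites are recorded on the
reference strand; biological strand resolution happens at annotation.
All mismatch-bearing sites are retained in the output with per-filter
failure flags, so attrition is fully auditable; non-candidates carry no
q-value.

## Classification and annotation

The 12 reference-strand mismatch classes map to editing classes via the
annotated gene strand: A>G on `+` or T>C on `−` is A-to-I; C>T on `+` or
G>A on `−` is C-to-U; everything else is "other". Read strandedness is
not used — the feature vocabulary (UTRs, introns) presupposes gene-model
annotation anyway. Sites outside any gene are read on `+` and flagged
low-confidence: a T>C or G>A intergenic site stays "other" rather than
guessing a strand.

Feature precedence when intervals overlap: exonic > 5′UTR > 3′UTR >
ncRNA-exonic > intronic > ncRNA-intronic > upstream/downstream, ties
within a class to the smallest gene id; no overlap means intergenic. The
upstream/downstream flank is a single merged category with a 1 kb default
window. Per-condition summaries round feature percentages to 0.1, so a
summary row closes to 100 ± 0.2 by construction. Percent reductions
between conditions are reported unrounded and rounded to integers.

## Synthetic data

The simulator emulates the statistical structure of a pooled-microglia
bulk RNA-seq editing experiment at desk scale. Defaults: a 100 kb single-
contig genome; six transcripts alternating coding/non-coding and strand,
each contributing every feature class; 30 A-to-I and 15 C-to-U sites
(the ~2:1 class imbalance typical of mammalian editomes) with per-site
frequencies uniform on [0.2, 0.8]; 20 SNPs, heterozygous by default
(alt fraction 0.5) precisely so they pass the frequency filter and only
the mask can remove them; per-base substitution error 0.005, boosted
3× within 6 bases of read ends; 75 bp reads at mean depth 50; 10 %
multimapping reads (MAPQ 0). Base qualities are drawn around Q30–40 with
a 5 % low-quality (Q10–24) fraction to exercise the quality filter.
Planted sites are chosen through the same annotation lookup the caller
uses, so truth feature labels round-trip exactly. All outputs are
byte-deterministic given the seed, with independent RNG streams per stage
(genome, site planting, reads) so changing one stage's parameters leaves
the others' draws untouched.

What the simulator does *not* model — splicing, indels, soft-clips,
fragment-length and GC biases, quality-correlated errors, library
strandedness — bounds what passing tests show: they validate the calling
logic, filter semantics and statistics downstream of alignment, not
robustness to alignment artefacts on real libraries. Error bases receive
qualities from the same distribution as correct bases, so the Q25 filter
does not preferentially remove simulated errors; recovery results are in
that sense conservative about the quality filter's real-data benefit.

## Validation statistics

Editing frequency has two bench estimators, selected per input type:
clone counting (`edited/total` sequenced cDNA clones; used for B2m and
brain-tissue material) and chromatogram peak ratio (`G/(A+G)` peak
heights; used for microglia Mpeg1). A predicted position counts as
*verified* when at least one replicate shows at least one edited clone.
Group comparisons of frequencies use Student's pooled-variance unpaired
t-test, one-tailed (the direction of an expected disease increase),
`equal_var=False` switching to Welch. Zero-variance inputs return the
degenerate limits (p = 0.5 for equal means) with an explicit flag.

qRT-PCR fold changes use 2^−ΔΔCt with a reference gene (Gapdh role);
samples missing a Ct are dropped with a warning. Clinical courses on the
0–5 ordinal scale yield per-animal maximal score, trapezoidal AUC over
the observed window (no extrapolation; AUC is invariant to inserting
linearly interpolated days), and day of onset (first day scoring
≥ 1, the configurable "limp tail" threshold). Group values are means ±
standard error; animals never reaching onset are excluded from the onset
mean and counted separately. Published group-level clinical summaries are
not recomputable from per-animal data (not available) and are not
asserted anywhere.

## Problem sizes and numerical choices

The test suite and the acceptance script run the recovery experiment on
20 kb genomes, 30 planted sites, mean depth 50, five seeds — large enough
that sensitivity, false-positive and frequency-error estimates are stable
(≈150 sites, ≈13 000 reads per replicate) while the whole suite stays
fast on one CPU. Exact-test implementations are verified against
exhaustive enumeration oracles (binomial pmf summation; hypergeometric
tail summation) to 1e-10 absolute for depths ≤ 200. Frequency accuracy
is assessed as the mean absolute error against planted frequencies
(binomial sampling noise at effective depths near 40 makes a per-site
hard bound of 0.1 unattainable at ~2σ; the mean is the stable quantity).
Mismatch classification, BH adjustment and comparisons are deterministic;
every stochastic test is seeded or derandomised.

## Known limitations

* The caller takes one SAM per condition; pooling strategies and
  replicate-aware calling are out of scope (the simulator can emit
  replicate SAMs, but the caller treats each independently).
* No hyper-editing rescue: reads dense with edits still align here by
  construction, but on real data such reads are lost at mapping.
* Fisher's test is underpowered at depths below ~1/2ε (see above).
* Intergenic editing-class assignment is convention, flagged rather than
  resolved; repeat/Alu context and recoding consequences are not
  analysed.
* In-silico PCR (`editome.primers`) uses exact primer matches only — no
  mismatch tolerance or melting-temperature model.
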