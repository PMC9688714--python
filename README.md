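# editome

Detection and comparative analysis of RNA editing from aligned RNA-seq
reads, built around the editing biology of neuroinflammation models:
microglia editomes shift as experimental autoimmune encephalomyelitis
(EAE) progresses from the naïve state through pre-clinical to acute
disease, and those shifts are confirmed at the bench by clone counting,
Sanger chromatogram peak ratios, qRT-PCR and clinical scoring. This
package implements that entire analysis chain at desk scale, for
bioinformaticians who want a tested, reproducible re-implementation they
can run end-to-end on simulated data or point at their own alignments.

## What it computes

**RDD calling.** An RNA:DNA difference (RDD) is a transcript base that
differs from its genomic template — the observable signature of A-to-I
(ADAR) or C-to-U (APOBEC) editing. From a coordinate-sorted SAM, a
reference FASTA and a SNP mask (VCF), the caller builds a quality-filtered
pileup (base quality ≥ 25, `end_trim` bases ignored at both read ends to
suppress random-hexamer artefacts, multimapping reads excluded) and scores
every mismatch-bearing site against a sequencing-error null with rate ε:

* binomial tail test: `p_b = P(X ≥ k)`, `X ~ Binomial(n, ε)` for `k` alt
  reads at depth `n`;
* one-sided Fisher's exact test of `[[k, n−k], [e, n−e]]` with
  `e = round(ε·n)`.

A site is called when depth ≥ 10, alt support ≥ 3, frequency `k/n` ≥ 0.1,
both p-values ≤ 0.05, the Benjamini–Hochberg q-value (on `max(p_b, p_f)`
over the candidate sites) ≤ 0.05, and the position is not a known SNP.
Every threshold is configurable; all rejected sites are kept with
per-filter failure flags.

**Editome classification and comparison.** Passing calls are classified
into the 12 reference-strand mismatch types, resolved to A-to-I / C-to-U /
other using the annotated gene strand (A>G on `+` or T>C on `−` is
A-to-I; C>T on `+` or G>A on `−` is C-to-U), and assigned a genomic
feature (exonic > 5′UTR > 3′UTR > ncRNA-exonic > intronic >
ncRNA-intronic > upstream/downstream > intergenic, by precedence).
Per-condition summaries and baseline comparisons report per-class counts,
feature percentages, percent reductions and feature shifts.

**Validation statistics.** Editing frequency from clone counts
(`edited/total`) or chromatogram peaks (`G/(A+G)`), per-position
detection summaries, one-tailed pooled-variance unpaired t-tests, 2^−ΔΔCt
expression fold changes, and EAE clinical-course metrics (mean maximal
score, trapezoidal mean AUC, mean day of onset on the 0–5 scale).

**Simulator.** A miniature annotated genome with planted A-to-I / C-to-U
sites at known frequencies, het/hom SNPs, a multimapping read fraction
(MAPQ 0) and end-biased substitution errors, plus a ground-truth table —
so sensitivity, specificity and frequency accuracy are measurable exactly.

## Worked example

```python
import pandas as pd
from editome import (SimConfig, FilterConfig, simulate_dataset, build_pileup,
                     call_rdd_sites, GenomeAnnotation, annotate_calls,
                     summarize_editome)
from editome.io import read_annotation

cfg = SimConfig(seed=42, genome_length=20_000, n_transcripts=4,
                n_edit_sites={"A-to-I": 20, "C-to-U": 10}, n_snp_sites=10,
                flank_window=500)
paths = simulate_dataset(cfg, "demo")
filters = FilterConfig()  # Q>=25, depth>=10, support>=3, freq>=0.1, alpha=0.05
pileup = build_pileup(paths["sam"], paths["reference"], filters)
calls, _ = call_rdd_sites(pileup, paths["snp_mask"], filters)
passing = calls[calls.passed]

truth = pd.read_csv(paths["truth"], sep="\t")
ann = GenomeAnnotation(read_annotation(paths["bed"]))
summary = summarize_editome(annotate_calls(passing, ann), "synthetic")
```

Output:

```
covered positions: 19986, candidate sites: 3352, passing: 30
planted sites recovered: 30/30
events by class: {'A-to-I': 20, 'C-to-U': 10, 'other': 0}
top features: {'exonic': 30.0, 'intronic': 26.7, "3'UTR": 20.0}
```

All 30 planted sites are recovered, none of the ~3,300 error- or
SNP-driven candidate sites survives the filters, and the strand-resolved
class of every call matches what was planted.

The same flow is available from the shell:

```bash
editome simulate --outdir demo --seed 42
editome call --sam demo/reads.sam --ref demo/reference.fasta \
             --snp-mask demo/snp_mask.vcf --out demo/calls
editome run --config pipeline.yaml   # multi-condition + comparisons
```

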