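# Methods

This note documents the statistical procedures, defaults, numerical
choices and limitations of the mirflux pipeline, and what the synthetic
generator does and does not emulate.

## Study design assumed

Five somatic tissues (neurons `Neu`, intestine `Int`, body wall muscle
`BWM`, hypodermis `Hyp`, coelomocytes `Coel`) profiled by small-RNA
sequencing at two adult ages, day 1 (young) and day 8 (aged,
post-reproductive), with three biological replicates each; whole-organism
and extracellular-vesicle (EV) UMI libraries with the same age/replicate
layout; a boolean promoter-reporter transcription map per miRNA gene ×
tissue × age; and a matched, pre-normalised mRNA matrix. The tissue/age
vocabulary is configurable (`AnalysisConfig`); the five-tissue, two-age
default is the layout the generator emulates.

## Normalisation and detection

Mature miRNAs are treated as equal effective length, so TPM reduces to
`count × 1e6 / column sum`. Quantile normalisation acts on
log2(TPM + pseudocount): every column is mapped onto the mean of the
per-column sorted vectors. Ties receive the mean of the reference
quantiles they span, via average ranks with linear interpolation — a
deterministic, order-independent convention, and the transform is
idempotent.

Detection in read-count libraries is *strictly more than* the threshold
(default 5 reads). The group-level call applies the threshold to the mean
raw count over the group's replicates (`mean` rule); `any` and `all`
replicate-combining rules are available because the group semantics of a
read cut-off is a genuine design choice — the mean rule feeds the
group-level transcription/expression contrast, while per-replicate calls
(count > 5) drive the per-replicate trafficking flow table. UMI detection
is *at least* a summed 10 UMIs over the group's replicates (inclusive, as
"a minimum of" reads naturally).

Pseudocount 1 before log2 and in fold-change ratios; it is recorded in
the config and logs.

## Differential expression (Age-DEMIRs)

For each miRNA expressed in a tissue at either age, the pooled D1+D8
TPM values (plus pseudocount) are Box-Cox transformed with a single
maximum-likelihood λ — one monotone transform for both groups keeps them
comparable — followed by a two-sided pooled-variance Student *t*-test
(df = n1 + n8 − 2). λ is found by profiling the log-likelihood
`(λ−1)·Σlog x − n/2·log var(y)` on a grid over [−5, 5] (step 0.05) with
parabolic refinement of the maximum; the variance term is evaluated on
`exp(λ·log x)` and rescaled by λ² because forming `(x^λ−1)/λ` directly
collapses catastrophically for large x and very negative λ. The grid MLE
agrees with an unconstrained optimiser to ~1e-3 in λ. Degenerate cases:
a constant vector admits any λ and returns λ = 1 (y = x − 1); zero pooled
variance yields p = 1 for equal means and p → 0 (flagged) otherwise.

Two significance criteria coexist because the tissue-level and
compartment-level analyses differ: tissue mode uses p < 0.05 alone;
compartment mode (worm/EV relative abundance) also requires fold change
> 1.5 or < 1/1.5. Fold change is the D8/D1 ratio of untransformed group
means with pseudocount — the transform scale would make folds
λ-dependent and incomparable across miRNAs. Significance is deliberately
unadjusted for multiple testing (the per-tissue volcano convention); a
Benjamini–Hochberg FDR column is emitted for users who want it.

Measured behaviour (recomputed by `scripts/acceptance.py`): under the
null generator the p < 0.05 rate of this test is ≈ 0.067 at n = 3 + 3 —
slightly liberal, as expected when a power transform is fitted on six
points, but within the 0.05 ± 0.02 acceptance band.

## PITT classification and the trafficking network

Gene-level transcription calls are lifted to mature arms (both arms
inherit the gene's T). Matures absent from the transcription map are
excluded with a warning — promoters that cannot be assessed must not be
classified. PITT in (tissue, age) ⇔ E ∧ ¬T there; the global PITT set is
PITT anywhere.

The network at one age adds each miRNA to every (source, receiver) pair
of S × R — integral weights, no fractionation, because each directed flow
counts "miRNAs moving in this direction" and one receiver can take the
same miRNA from several sources. Receivers with no internal source are
fed from "Other", which only ever appears as a source node.

The permutation null redraws, per miRNA and permutation round, disjoint
uniform S′/R′ of the observed sizes ("Other" sources stay external; only
their receiver sets are redrawn). This preserves each miRNA's
source/receiver multiplicity and the total flow mass, which is exactly
what over/under-representation of a particular direction should be judged
against. A global edge-shuffle null would break per-miRNA degrees and is
not what a per-direction enrichment question asks. Per observed edge, the
null weight sample is Yeo-Johnson transformed (MLE λ per edge — the null
contains zeros, so the Box-Cox family is unavailable), the observed
weight transformed with the same λ, and z = (w′ − μ)/σ with two-sided
normal p; an add-one empirical rank p is emitted alongside as the
distribution-free check. Degenerate nulls (σ = 0) give z = NaN, p = 1,
flagged. z-scores are per *directed* edge. Calibration: on networks drawn
from the null itself, |z| > 1.96 on ≈ 4.8% of edges (200 permutations,
100 datasets).

## EV loading

Relative abundance divides each miRNA's replicate-mean UMI count by the
summed replicate means over the *detected* miRNAome of that
compartment-age (pooled-UMI mode is available; with equal replicate
counts the fractions coincide). The loading ratio is EV share / worm
share, per age; its D8/D1 ratio classifies secretion with strict
inequalities: promoted > 2, suppressed < ½, stable otherwise. A miRNA
missing the detected set on either side at either age is `undetermined`
with a reason code instead of an infinite ratio — only the jointly
detected miRNAome supports a ratio. Fractions are scale-invariant per
compartment-age and sum to 1 over the detected set by construction.

## Target inference and autonomy

Canonical seed sites only: 8mer, 7mer-m8, 7mer-A1, scanned via the seed
core (reverse complement of miRNA positions 2–7) and classified by the m8
extension and the A1 anchor; the strongest type wins at each core locus,
bare 6mer cores are not reported. No context scoring, conservation
branch lengths or 3′-supplementary pairing — sites act purely as a
filter, and an external site table in the same tidy format can be
substituted.

The anti-correlation axis is the tissue × age condition means (ten
conditions in the default design), not the thirty replicate samples: the
question is whether the *age- and tissue-level* profiles oppose each
other, and replicate-level correlation would mostly measure within-group
noise (a replicate-level mode exists). Pairs with r < −0.2 and ≥ 1 site
become target calls in every (tissue, age) where the miRNA is expressed
(group detection) and the gene exceeds the mRNA expression threshold
(default: mean > 0 on the pre-normalised scale). Autonomy is inherited
from the PITT table: non-autonomous exactly where the miRNA is PITT.
Enrichment uses a one-sided Fisher exact test per category label at each
of the three annotation levels, against the expressed-gene background by
default (the whole annotation is available behind a flag); raw p < 0.05
marks significance, with BH-FDR emitted.

## Synthetic data generator

The generator plants: a transcription map (1–3 source tissues per gene),
transport events (default 30% of miRNAs, 1–2 receiver tissues disjoint
from the sources, receiver abundance 20% of source level — transported
miRNAs ride at lower levels than at their source), age effects (default
30% of miRNAs changing 4-fold, up or down, wherever present), log-normal
EV sorting weights (σ = 1) with 30%/30% of miRNAs boosted/damped 3-fold
at D8, and anti-correlated target genes (20% of genes, coupling strength
2 log2-units per SD of the miRNA profile) whose UTRs carry one planted
8mer; all other UTRs are scrubbed of every seed core by rejection
mutation, so planted-truth FDR is measurable. Read counts are negative
binomial (α = 0.1, i.e. var = μ + 0.1μ²) around baseline expected counts
of ~300 (log-normal, σ = 1); UMI counts are multinomial draws of 200 000
molecules from the expected shares. `noiseless=True` rounds expectations
and floors present miRNAs above the detection cut-off, making recovery
exact by construction — that mode tests wiring, not power. All
randomness flows from one seed; identical seeds give byte-identical
datasets.

What it does *not* emulate: genomic sequence composition (UTRs are
uniform random), sequencing error and adapter artefacts, cross-tissue
contamination, isoform structure, batch effects, or correlated biological
replicates. Passing recovery tests therefore demonstrates that the
pipeline's logic and statistics behave as specified under the planted
model — not that real libraries are free of the artefacts the generator
omits.

## Problem sizes used by the test suite and reproduction script

Type-I calibration: 100 null datasets × 200 miRNAs (≈ 20 000 tests).
Permutation-z calibration: 100 null networks × 60 miRNAs at 200
permutations (≈ 2 400 edges). Parameter recovery: 20 seeded datasets at
generator defaults (60 miRNAs, 300 genes). Seed-site oracle equivalence:
exhaustive over all 4^10 ten-nt UTRs. These sizes keep Monte-Carlo error
well inside the acceptance bands while the whole suite runs in about a
minute.

## Known limitations

* The Box-Cox *t*-test at n = 3 + 3 is mildly liberal (measured ≈ 0.067
  at nominal 0.05) because λ is estimated from the same six values.
* The permutation z rests on the chosen degree-preserving null; other
  nulls answer different questions and would change z.
* The transcription map is boolean; graded promoter activity, and
  reporter false negatives, propagate directly into PITT calls.
* Detection thresholds are hard cut-offs; miRNAs hovering near 5 reads
  flicker between groups and replicates.
* Compartment DE uses the power-transformed *t*-test on relative
  abundance for consistency across compartments; a pooled-UMI
  two-proportion z-statistic would weight deep libraries differently.
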