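# Methods

This note documents the models, parameter choices and known limitations of
the ovatome pipeline, stage by stage.

## PCR-duplicate rule

Two reads are duplicates iff (a) their first 10 bases (0-based positions
0–9) are identical, case-insensitively, with `N` never matching — not even
another `N` — and (b) whole-read similarity is **strictly** greater than
0.90. For equal-length reads, similarity is positional identity (Hamming
matches / L), the natural reading for a fixed-length single-end library.
For unequal lengths (e.g. after adapter trimming) it falls back to global
alignment identity with match +1 and mismatch/gap 0, matches divided by the
alignment length. No reverse-complement check is made: the library is
single-end and orientation-fixed.

Clusters are the single-linkage closure of the pairwise relation, computed
inside exact 10-mer prefix buckets (prefix identity is a necessary
condition, so bucketing is lossless); the first-seen read of each cluster is
the kept representative. Consequently two reads in one cluster need not be
pairwise duplicates — they are linked through intermediates, which is what
single linkage means. The test suite checks the clustering against a
brute-force all-pairs oracle that applies the rule verbatim.

Dedup runs before adapter trimming, so the 90% similarity is evaluated on
full-length reads; this ordering is a package choice. Adapter and quality
criteria have no single standard; the defaults (3'-end match of an adapter
prefix with minimum overlap 5; removal below mean Phred 20) are documented,
configurable package defaults, not derived quantities.

## FPKM and threshold calls

`FPKM = c · 10⁹ / (L · N)` with annotated transcript length `L` (no
effective-length correction) and library size `N` defaulting to the sum of
counts in the provided table — whether "mapped fragments" should count only
the quantified gene set or all alignments is a convention; the package uses
the table sum and lets callers override both library sizes explicitly.

All thresholds are strict inequalities: expressed iff FPKM > 5; up-in-mutant
iff ratio > 2; up-in-wildtype iff ratio < 0.5. The comparison universe is
genes expressed in at least one condition. A zero denominator with an
expressed numerator counts as an infinite ratio (the limiting behaviour of
the rule), so such genes are called in the direction of the non-zero side.
With one library per condition there is no dispersion estimate and no
p-value; the calls are descriptive.

## Comparative GO enrichment

Only `is_a` edges are used; `relationship:` edges and obsolete terms are
dropped at parse time. Annotations are ancestor-closed by default (the
true-path rule: a gene annotated to a term is annotated to all its
ancestors); `--no-propagate` scores raw direct annotations instead, since it
is not universally agreed whether upstream annotation tools emit closed or
direct sets.

The score is the signed log-ratio of pseudo-count-regularized term
frequencies between the two condition-specific gene sets,
`score(t) = log₂(f_A(t)+ε) − log₂(f_B(t)+ε)` (computed as a difference of
logarithms so that swapping the sets negates the score exactly in floating
point). The logarithm base is pluggable; base 2 is the default and matches
the ±1.2 display band in scale. The pseudo-count ε defaults to 0.01 — a
fixed small constant that keeps terms absent from one set finite; it is
exposed as `--pseudo`. This functional form is a reconstruction: it is
consistent with frequency-based symbols, a signed band, and a red/blue
diverging rendering, but other regularized forms exist and the score
function is deliberately pluggable.

GO level is the shortest `is_a` path length from the namespace root
(root = 0), the cheapest well-defined reading of "level" on a DAG. The
display rule masks (node size 0, node retained) any term with level < 2 or
score strictly inside (−1.2, 1.2); the endpoints ±1.2 are displayed.
Displayed terms get node size = number of genes across both sets carrying
the term. Graphs are one per namespace, GraphML, importable by Cytoscape.

## Follicle morphometry

Stage boundaries are the midpoints of the nominal stage diameters
(I/II at 60 µm, II/III at 85 µm), half-open upward, so a follicle exactly at
a boundary belongs to the higher stage. Stage IV (ovulated) follicles do not
occur in sections and are not classified. Summaries report totals, per-stage
counts, follicles/mm² and the stage-III percentage; report rounding is
half-up at the precision used in section tables (two decimals for the
stage-III density, one elsewhere) with raw values always retained.

One documented discrepancy: from raw counts of 7 stage-III among 476
follicles the proportion is 1.47%, which rounds half-up to 1.5%; a published
rendering of the same raw numbers gives 1.4%, consistent with truncation or
with different underlying raw data. The package reports 1.5 and does not
attempt to match the truncated figure.

## ΔΔCt

ΔCt_s = mean Ct(target, s) − mean Ct(reference, s) over replicates;
ΔΔCt = ΔCt_test − ΔCt_calibrator; RQ = 2^(−ΔΔCt), i.e. amplification
efficiency is fixed at 2 per cycle (classic ΔΔCt, no standard-curve
correction). Replicate standard deviations propagate to a standard error on
ΔΔCt as the root-sum-square of the four mean-Ct standard errors. Fold
reports present RQ < 1 as its reciprocal with direction "lower", so every
fold is ≥ 1. No significance test is attached: with three replicates the
standard error is reported and interpretation is left to the caller.

## Synthetic data: what it emulates, and what it does not

All generators hang off one `SimulationConfig`; a single top-level seed fans
out to fixed per-generator substreams (`numpy` `SeedSequence` spawn keys),
so any stage can be regenerated independently and bit-identically.

**Reads.** 101-nt single-end reads (the sequencing mode of the study design
this emulates; where a library is ambiguously described as single- or
paired-end, single-end is the default here). Each unique molecule gets a
random read with a set-unique 10-mer prefix. A molecule becomes a
multi-read cluster with probability r² (r = `duplicate_rate`) and then
carries 1 + Poisson(1/r − 1) extra copies; this makes the expected fraction
of reads sitting in clusters of size ≥ 2 equal r. Duplicate copies keep the
prefix intact and mutate at most ⌈0.1·L⌉ − 1 positions, keeping identity
strictly above 0.90. Every multi-read cluster also contributes one
"near-miss" read violating exactly one condition: either one mutated prefix
base (identity 100/101) or an intact prefix with exactly ⌈0.1·L⌉ mutations
(identity ≤ 0.90). Mutation positions within a cluster are disjoint, which
guarantees the near-miss cannot link to any cluster member and the truth
partition equals what the rule itself produces. Not emulated: positional
error profiles, quality-score variation, adapter chemistry.

**Expression.** True FPKMs are log-normal (median 6, σ_log = 1.2) so the
FPKM > 5 call is exercised on both sides. Planted genes take a clearly
expressed low side (uniform 8–60 FPKM) times `planted_fold` on the high
side; all other genes share one true FPKM across conditions. Counts are
negative-binomial (gamma-Poisson, θ = 50) around the expected count implied
by FPKM, transcript length (uniform 500–3000 nt) and a 20-million-fragment
library — half the scale of a typical HiSeq run, chosen to keep desk runs
fast while preserving realistic counting noise at the threshold. RNA-seq
counts are overdispersed relative to Poisson, hence the two-parameter
family. Not emulated: biological replicate variance (the design has none),
GC/length bias, multi-mapping.

**GO world.** One namespace, `dag_depth` levels under a single root, each
term with one or two parents from the level above (acyclic by
construction). Planted terms are chosen among *leaf* terms at level ≥ 2:
below a leaf there is nothing to propagate, so the planted frequency margin
(0.30 in the favoured set vs 0.05 in the other, against a 0.03 background
annotation rate) survives ancestor closure intact, and
log₂(0.31/0.06) ≈ 2.37 clears the 1.2 display band at the default
pseudo-count. Planting an internal term instead would let background
annotations on its descendants dilute the margin. Not emulated: realistic GO
topology (multiple namespaces interleaved, term sizes spanning orders of
magnitude), annotation bias toward well-studied genes.

**Sections.** Diameters are normal around the nominal stage means 50/70/100
µm with a common coefficient of variation (default 0.05, at which
diameter-based staging recovers ≥ 99% of truth). If a configured CV makes
expected misclassification exceed 20%, the generator warns and proceeds —
overlapping stages are a property of real histology, not an error.

**Ct tables.** Reference gene at 20 cycles in both samples, targets at 24
in the calibrator and 24 + ΔΔCt in the test sample, three replicates with
Gaussian noise of 0.2 cycles (a typical technical-replicate spread). The
default planted ΔΔCt values correspond to a 1.5-fold deficit of a ceramide
synthase homolog, a ~1.4-fold deficit of a PKCβ homolog, and a 2.1-fold
excess of an MLH3 homolog in the test sample — the kind of effect sizes a
follow-up qPCR panel in this design reports. Recovered folds are synthetic
recoveries, not wet-lab measurements.

Passing tests on these fixtures show the *algorithms* implement their rules
exactly and recover planted signals at the stated noise; they do not show
that the thresholds are well calibrated for any particular real library —
threshold calling on single libraries is known to admit false calls near
the cutoffs, and the acceptance run reports the realized false-discovery
proportion (~0.07 at 4-fold planted changes) rather than hiding it.

## Problem sizes and numerical choices

Defaults are desk-scale: 200–400 unique reads per simulated library, 500
genes, 60 GO terms, 50-fixture recovery sweeps, 200-simulation ΔΔCt bias
checks. The full test suite runs in well under a minute; the acceptance
script in seconds. Half-up decimal rounding is used for report tables;
comparisons against thresholds are exact floating-point inequalities with
no tolerance, because the thresholds themselves are definitions, not
estimates. Degenerate inputs (empty sections, zero denominators) yield
flagged undefined values where a quantity is genuinely undefined and errors
only where an operation's precondition is violated.
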