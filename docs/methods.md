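# Methods

This note documents the models, conventions and design choices behind
`crossregulome`: what each stage computes, which knobs matter, what the
synthetic generator does and does not emulate, and the package's known
limitations.

## Coordinate and window conventions

All internal coordinates are 0-based half-open (BED convention); GTF
input is converted on read, and genes on chrM or on chromosomes absent
from the genome layout are dropped. The TSS is the first transcribed
base (start on +, end−1 on −); all windows are strand-aware:
promoter-proximal [TSS−30, TSS+300), gene body [TSS+300, gene end),
promoter ±1 kb around the TSS. Peak-to-gene distances always use the
peak **summit** (the canonical anchor of summit-bearing peak callers),
with equidistant ties broken deterministically by smaller TSS coordinate
then gene id. bedGraph is the signal interchange format (text,
bit-exactly testable); interval values are rebinned onto a fixed grid by
length-weighted mean, uncovered bins zero.

## Calibration and per-gene statistics

Spike-in calibration divides every sample by its foreign-genome read
count: factor_i = count_ref / count_i with the first untreated replicate
as reference; calibrated signal is raw × factor. All cross-condition
density comparisons use calibrated tracks; the pausing index is a
within-sample ratio and is scale-invariant.

The **activity filter** takes promoter-proximal density > 0 and gene-body
density > 0.04 reads/kb on the pooled untreated tracks. The quoted
background threshold is applied as a hard cutoff because the underlying
background-estimation procedure is not specified; the value is
configurable (`min_body_density`). The mRNA union list additionally
requires gene length ≥ 5 kb.

The **pausing index** is promoter-proximal density over gene-body
density. The defining sentence in the source methods is self-inverting
(its ratio is written body/promoter while the reported effect direction
requires promoter/body); the orientation here is fixed so that
pause release gives PI < 1 ratios for gene-body-gaining genes, matching
the reported ECDF shifts. Genes shorter than 5 kb, or with zero body
density, get NaN (excluded, never infinite).

The **transcription-rate proxy** is R = PRO body density / ChIP body
density with a pseudocount ε = 0.01 reads/kb on both (zero-handling is
otherwise undefined); lower R is slower elongation per bound polymerase.

Metagene profiles support scaled mode (100 equal gene-body bins, 3-kb
flanks in 50-bp bins) and TSS-centered mode; per-gene values are capped
at the gene's 95th percentile before averaging ("extreme 5% removal");
the exact semantics of the original plotting suite are unknown, so the
winsorization fraction is a documented, configurable approximation.

## Differential occupancy

Count-based tools with dispersion shrinkage (DESeq2/DiffBind) are
deliberately **not** re-implemented. The substitute is a conditional
binomial exact test on pooled raw counts with the conditions' effective
depths (inverse calibration factors) as null weights:
a | a+b ~ Bin(a+b, π₀), π₀ = w_t/(w_t+w_u); the two-sided p-value sums
the probabilities of all outcomes no more likely than the observed one.
This test is exactly enumerable (it is verified against rational
arithmetic to < 1e-12), has the same decision interface (log2FC + FDR),
and is anti-conservative only through ignored replicate overdispersion —
acceptable at the mild dispersions simulated here, and visible in the
null-calibration check. log2FC uses spike-scaled pooled counts with a
pseudocount of 1. FDR is Benjamini–Hochberg (the adjustment procedure is
not named in the source; BH is the field default). Genes with fewer than
five reads in every sample are dropped before testing.

Decision rules: the gene-body differential that defines the gene sets is
**FDR < 0.05 only** (`fc_thresh=1`), matching the described gene-level
analysis; the |FC| > 2 threshold is kept as the default for peak-style
differentials where it belongs. *genebody-up* = up in both ChIP and PRO;
*genebody-unaffected* = ns in both; *unchanged control* = ns in both with
|log2FC| < 0.1 in both — the 0.1 operationalizes "not at all affected",
which has no numeric rule in the source. The three sets are disjoint by
construction.

## Target inference and direction call

Peak→gene assignment is hierarchical: first loop mode (peak overlaps a
contact anchor by ≥ 1 bp and the partner anchor overlaps a promoter,
TSS ± 1 kb — "partner on the other side" is operationalized as promoter
overlap, since body-vs-promoter overlap is unspecified), then nearest
TSS within ±100 kb; otherwise unassigned. Regulatory potential uses the
classic BETA decay w(Δ) = e^−(0.5+4Δ), Δ = distance/100 kb clipped to
[0, 1] and Δ = 0 for looped peaks, multiplied by peak strength
normalized to the median strength (comparable across depths); a logistic
alternative w(Δ) = 1/(1+e^{10Δ−5}) and a strength-free mode are exposed
because the published description ("ranked according to the
corresponding peaks") does not pin the functional form.

The direction test compares score distributions (up-set vs unchanged,
down-set vs unchanged) with two-sided two-sample KS at α = 0.05, on the
universe of genes with at least one assigned peak. Restricting to
scored genes matches the "factor-associated genes" framing and keeps the
score distribution continuous — with a universe dominated by tied zero
scores the KS test is badly conservative and its permutation null is
uninterpretable. An empty comparison set is reported as not applicable.

## Mechanism classification

Strict precedence interference > looping > ncRNA > nearby > unexplained
(configurable; the source's sequential subgroup figure is not available,
so the order follows the reported left-to-right listing). ncRNA evidence
requires overlap with a supplied annotation track (tRNA/SINE/other
Pol III-type elements); expression-based ncRNA evidence is out of scope.
Percentages are reported at one decimal, collapsed to an integer when
within 0.1 of one — reproducing mixed-precision reporting such as
15.7 / 4.4 / 46.

## ChIP-MS differentials

DDA: PSM counts are normalized per condition to the bait subunit
(POLR2A), and the treated/untreated ratio is classified at < 0.8
(decreased) / > 1.2 (increased); proteins absent untreated are reported
as undefined rather than classified. DIA: abundance is log2 of the
summed top-3 unique-peptide intensities; fold change on mean linear
abundances at |FC| > 1.2. With n = 2 replicates a calibrated p-value is
unattainable, so the fold-change rule is primary and the rank-sum p
advisory — a documented divergence from the count-model-based
description of the original analysis. Contamination filtering drops
non-nuclear proteins and proteins whose IgG or Input signal reaches
(≥) the mean IP signal. A consensus call requires agreeing DDA and DIA
directions.

## The synthetic generator

`simulate_study` lays out 5 chromosomes × 16 Mb with 2000 non-overlapping
genes by default: 10% tRNA loci, 90% mRNA (10% of them below the 5-kb
union cutoff, 10% silent), gene lengths 5–20 kb. Of the active mRNA
genes, 12.5% (202 genes at the defaults) are planted *genebody-up*, each
with exactly one mechanism (20% interference, 15% looping, 10% ncRNA,
55% nearby). Planted genes get a private ±110-kb clearance in which only
their own evidence is placed — mechanisms are therefore mutually
exclusive by construction and classifier accuracy on the planted genes
is exactly 1 in expectation. Regulating peak offsets are lognormal
around 12 kb (regulating peaks concentrate near the TSS, as in the
distance-density profiles of affected genes); decoy peaks (600) and
background loops avoid the clearance zones.

Expected signal per gene: gene-body rate depth × rel_expr / body length
(depth = 100 reads/gene/sample; rel_expr lognormal with unit mean,
σ = 0.8), promoter rate PI × body rate with PI lognormal around 4.
Under depletion, planted genes multiply body rate by `effect_genebody`
(2.0) and PI by `effect_pausing` (0.5) — promoter signal stays flat
while the body doubles; their ChIP body rises by
`effect_genebody/effect_rate` (rate proxy multiplier 0.67, i.e.
elongation per bound polymerase slows); tRNA signal collapses to 10%.
Counts are negative-binomial (gamma–Poisson, dispersion 0.05; Poisson
available) per bin on a 50-bp grid, a weak 0.02 reads/kb background
covers the genome, and per-sample capture efficiencies (lognormal,
σ = 0.15) plus proportional spike-in counts (5% spike fraction) make the
true calibration factors recoverable. All randomness flows from one
seeded generator; per-sample streams are derived from the seed and the
(condition, replicate) key, so outputs are byte-identical for a fixed
config.

What the generator does **not** emulate: read-level artifacts (mappability,
PCR duplicates, fragment-size effects), correlated biological replicate
variation, overlapping mechanisms on one gene (a stress configuration
can be built by placing evidence manually), enhancer RNA expression, and
realistic genome architecture (gene clusters, repeat density). Passing
the recovery tests therefore demonstrates the pipeline's correctness and
calibration under its stated model, not performance on real libraries.

## Problem sizes and numerics

The packaged checks run the default study (2000 genes, 2×2 samples) over
10 seeds for recovery and 20 seeds for null calibration, plus a 200-draw
permutation calibration of the direction test — a few minutes on one
CPU; unit tests use a 120-gene reduction of the same design. Exact-test
agreement is checked against rational enumeration for all totals ≤ 30;
BH against a brute-force step-up oracle; the rank-sum exact path against
labeling enumeration. Degenerate inputs are defined, not guessed: zero
pooled counts → p = 1; all-tied rank-sum → p = 1; zero spike-in counts
and empty KS reference sets raise.

## Known limitations

- The exact ratio test pools replicates and cannot model replicate-level
  overdispersion; strong biological variability would inflate its FDR.
- Loop-mode assignment treats anchors symmetrically and requires
  promoter overlap; enhancer–enhancer contacts are invisible to it.
- The regulatory-potential functional form is adopted, not fitted.
- The ChIP-MS p-values at n = 2 are advisory; only the fold-change rule
  is calibrated by construction.
- Percentage display collapses near-integers; downstream consumers
  needing full precision should read `pct`, not `pct_display`.
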