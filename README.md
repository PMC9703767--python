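# crossregulome

Inference of cross-polymerase regulation from chromatin genomics data:
given one RNA polymerase's binding peaks (e.g. Pol III), chromatin loops,
and spike-in-calibrated nascent-transcription (PRO-Seq-like) and occupancy
(ChIP-Seq-like) tracks from an acute-depletion experiment, infer **which
Pol II genes the factor regulates, in which direction, through which
mechanism class, and with what effect on promoter-proximal pausing and
transcription rate**.

The package is aimed at computational genomicists analyzing degron-style
depletion studies (two conditions × replicates) and ships a synthetic-data
generator with planted ground truth, so the entire pipeline is testable
without any sequencing data.

## The analysis

For each annotated gene with strand-aware TSS, the untreated
nascent-transcription track defines the **active** gene universe
(promoter-proximal density > 0 and gene-body density > 0.04 reads/kb;
mRNA union list additionally requires length ≥ 5 kb). Per-gene statistics
are computed on strand-aware windows:

- **Pausing index**  PI = d(TSS−30, TSS+300) / d(TSS+300, TES), where
  d(·) is spike-calibrated read density — high PI means promoter-proximal
  pausing.
- **Transcription-rate proxy**  R = d_PRO(body) / d_ChIP(body) — nascent
  RNA per bound polymerase; lower R means slower elongation.

Differential gene-body occupancy between conditions uses pooled,
spike-offset counts with a conditional binomial exact test: for region
counts a (treated) and b (untreated), a | a+b ~ Bin(a+b, π₀) with π₀ set
by the conditions' effective depths; two-sided p is the total probability
of outcomes no more likely than the observed one, BH-adjusted. Genes up
in **both** ChIP and PRO gene bodies are *genebody-up*; ns in both are
*genebody-unaffected*; ns with |log2FC| < 0.1 in both form the
*unchanged control* set.

Peaks are assigned to genes hierarchically (loop anchors with ≥ 1 bp
overlap and a partner anchor over a promoter first, then nearest TSS
within ±100 kb), and each gene is scored by a BETA-style regulatory
potential S_g = Σ strength·e^−(0.5+4Δ) with Δ the TSS distance on a
100-kb scale (Δ = 0 for looped peaks). Two-sample Kolmogorov–Smirnov
tests of score distributions (up-set vs unchanged, down-set vs unchanged)
call the factor activating and/or repressive. Finally each regulated gene
is assigned one mechanism class by strict precedence:
**interference** (factor peak overlaps a Pol II peak on the gene) >
**looping** (loop-assigned peak) > **ncRNA** (peak on an annotated
Pol III-type ncRNA/SINE within the window) > **nearby** (any peak summit
within ±100 kb) > **unexplained**.

## Worked example

Simulate a study (800 genes, two conditions × two replicates, 5%
spike-in, planted gene-body effect 2.0) and run the pipeline:

```sh
cat > sim.yaml <<EOF
n_chroms: 3
chrom_length: 12000000
n_genes: 800
n_pol3_peaks: 250
seed: 5
EOF
crossregulome simulate --config sim.yaml --out bundle/
cat > run.yaml <<EOF
bundle: bundle/
out: run/
EOF
crossregulome run --config run.yaml
```

The run log prints each stage; `run/summary.json` contains (abridged):

```json
{
  "direction_call": "activating",
  "ks_up": {"D": 0.386, "p": 0.000261},
  "n_active": 645,
  "n_union": 571,
  "n_genebody_up": 79,
  "mechanisms": {"interference": {"count": 16}, "looping": {"count": 12},
                 "ncRNA": {"count": 8}, "nearby": {"count": 43}},
  "median_pi_ratio_genebody_up": 0.50,
  "median_rate_ratio_change_genebody_up": 0.67,
  "evaluation": {"sensitivity": 0.975, "precision": 1.0,
                 "mechanism_accuracy": 1.0}
}
```

Reading: 571 of 800 genes pass the active-mRNA filter; 79 genes gained
gene-body signal in both assays after depletion (79/81 planted genes
recovered, no false positives); their regulatory scores differ from the
unchanged genes' (KS p ≈ 3e-4, up-set only → the factor is called
activating); every recovered gene's mechanism matches the planted one;
and under depletion the genebody-up genes halve their pausing index and
drop their PRO/ChIP rate proxy to ~0.67 — pausing is released while
elongation per bound polymerase slows.

The same analyses are available programmatically
(`crossregulome.simulate_study`, `analyze_study`, …) and as per-stage
commands (`crossregulome quant/diff/beta/classify/chipms`). A ChIP-MS
module provides the matching interactome calls (bait-normalized PSM
ratios, top-3 DIA abundances, contamination filters).

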