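"""Peak-to-gene target inference and direction-of-regulation testing.

Peaks are assigned to active mRNA genes hierarchically: a peak overlapping
a chromatin-loop anchor (>=1 bp) whose partner anchor overlaps a gene
promoter (TSS ± 1 kb) is loop-assigned to that gene; otherwise the peak
goes to the nearest TSS within ±100 kb of its summit.  Genes are then
scored by a distance-decayed regulatory potential and the score
distributions of up- vs down-regulated gene sets are compared to the
unchanged set with two-sample Kolmogorov–Smirnov tests to call the factor
activating or repressive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from intervaltree import IntervalTree
from scipy import stats

__all__ = ["PeakGeneAssignment", "DirectionTestResult", "assign_peaks_to_genes",
           "regulatory_potential", "beta_direction_test",
           "direction_null_calibration"]

MAX_LINEAR_DIST = 100_000
PROMOTER_FLANK = 1_000


@dataclass(frozen=True)
class PeakGeneAssignment:
    peak_id: str
    gene_id: str
    mode: str            # {loop, nearest}
    distance: int        # |summit − TSS|
    loop_id: str = ""


@dataclass(frozen=True)
class DirectionTestResult:
    ks_up: tuple         # (D, p) or None if not applicable
    ks_down: tuple
    call: str            # {activating, repressive, both, none}


def assign_peaks_to_genes(peaks, loops, genes,
                          max_dist: int = MAX_LINEAR_DIST,
                          promoter_flank: int = PROMOTER_FLANK) -> list:
    """Hierarchical peak→gene assignment: loops first, linear proximity second.

    ``genes`` should already be restricted to the active mRNA universe.
    Loop mode yields one assignment per qualifying partner-promoter gene;
    peaks with no loop and no TSS within ``max_dist`` stay unassigned.
    """
    promoter_trees = {}
    for g in genes:
        s, e = g.tss - promoter_flank, g.tss + promoter_flank + 1
        promoter_trees.setdefault(g.chrom, IntervalTree()).addi(max(s, 0), e, g)

    anchor_trees = {}
    for loop in loops:
        tree = anchor_trees.setdefault(loop.chrom, IntervalTree())
        tree.addi(loop.start_a, loop.end_a, (loop, "a"))
        tree.addi(loop.start_b, loop.end_b, (loop, "b"))

    tss_sorted = {}
    for g in genes:
        tss_sorted.setdefault(g.chrom, []).append(g)
    for chrom in tss_sorted:
        tss_sorted[chrom].sort(key=lambda g: (g.tss, g.gene_id))
    tss_arrays = {c: np.array([g.tss for g in gs])
                  for c, gs in tss_sorted.items()}

    assignments = []
    for peak in peaks:
        loop_hits = []
        tree = anchor_trees.get(peak.chrom)
        if tree is not None:
            for hit in tree.overlap(peak.start, peak.end):
                loop, side = hit.data
                if side == "a":
                    ps, pe = loop.start_b, loop.end_b
                else:
                    ps, pe = loop.start_a, loop.end_a
                ptree = promoter_trees.get(loop.chrom)
                if ptree is None:
                    continue
                for ph in ptree.overlap(ps, pe):
                    loop_hits.append((loop, ph.data))
        if loop_hits:
            seen = set()
            for loop, gene in sorted(loop_hits,
                                     key=lambda t: (t[1].gene_id, t[0].name)):
                if gene.gene_id in seen:
                    continue
                seen.add(gene.gene_id)
                assignments.append(PeakGeneAssignment(
                    peak_id=peak.name, gene_id=gene.gene_id, mode="loop",
                    distance=abs(peak.summit - gene.tss), loop_id=loop.name))
            continue
        # linear proximity: nearest TSS within max_dist
        arr = tss_arrays.get(peak.chrom)
        if arr is None or arr.size == 0:
            continue
        i = int(np.searchsorted(arr, peak.summit))
        best = None
        for j in (i - 1, i, i + 1):
            if 0 <= j < arr.size:
                g = tss_sorted[peak.chrom][j]
                d = abs(peak.summit - g.tss)
                key = (d, g.tss, g.gene_id)
                if d <= max_dist and (best is None or key < best[0]):
                    best = (key, g)
        if best is not None:
            g = best[1]
            assignments.append(PeakGeneAssignment(
                peak_id=peak.name, gene_id=g.gene_id, mode="nearest",
                distance=abs(peak.summit - g.tss)))
    return assignments


def _weight_beta(delta: float) -> float:
    return math.exp(-(0.5 + 4.0 * delta))


def _weight_logistic(delta: float) -> float:
    return 1.0 / (1.0 + math.exp(10.0 * delta - 5.0))


_WEIGHTS = {"beta": _weight_beta, "logistic": _weight_logistic}


def regulatory_potential(assignments, peaks, weight: str = "beta",
                         use_strength: bool = True,
                         max_dist: int = MAX_LINEAR_DIST) -> dict:
    """Per-gene regulatory-potential scores S_g.

    S_g sums, over assigned peaks, a distance-decayed weight w(Δ) with
    Δ = distance / ``max_dist`` clipped to [0, 1] (Δ = 0 for loop-mode
    assignments), optionally multiplied by the peak strength normalized to
    the median peak strength.  Returns {gene_id: score}; genes without
    peaks are absent (score 0).
    """
    wfun = _WEIGHTS[weight]
    strengths = {p.name: p.strength for p in peaks}
    med = float(np.median([p.strength for p in peaks])) if peaks else 1.0
    if med <= 0:
        med = 1.0
    scores = {}
    for a in assignments:
        delta = 0.0 if a.mode == "loop" else min(a.distance / max_dist, 1.0)
        w = wfun(delta)
        if use_strength:
            w *= strengths.get(a.peak_id, 1.0) / med
        scores[a.gene_id] = scores.get(a.gene_id, 0.0) + w
    return scores


def _ks(sample, reference, method: str = "auto"):
    res = stats.ks_2samp(sample, reference, alternative="two-sided",
                         method=method)
    return float(res.statistic), float(res.pvalue)


def beta_direction_test(scores: dict, up_genes, down_genes, unchanged_genes,
                        alpha: float = 0.05, method: str = "auto",
                        restrict_to_scored: bool = True) -> DirectionTestResult:
    """KS comparison of regulatory scores: up/down sets vs unchanged.

    By default the comparison is restricted to genes with at least one
    assigned peak (the factor-associated genes), which keeps the score
    distributions continuous.  The call is activating/repressive if only
    the corresponding comparison is significant at ``alpha``, "both" or
    "none" otherwise; an empty set makes that comparison not applicable.
    """
    def pick(gene_set):
        if restrict_to_scored:
            return np.array([scores[g] for g in gene_set if g in scores])
        return np.array([scores.get(g, 0.0) for g in gene_set])

    ref = pick(unchanged_genes)
    if ref.size == 0:
        raise ValueError("unchanged reference set is empty")

    def compare(gene_set):
        vals = pick(gene_set)
        if vals.size == 0:
            return None
        return _ks(vals, ref, method=method)

    ks_up = compare(up_genes)
    ks_down = compare(down_genes)
    up_sig = ks_up is not None and ks_up[1] < alpha
    down_sig = ks_down is not None and ks_down[1] < alpha
    call = {(True, False): "activating", (False, True): "repressive",
            (True, True): "both", (False, False): "none"}[(up_sig, down_sig)]
    return DirectionTestResult(ks_up=ks_up, ks_down=ks_down, call=call)


def direction_null_calibration(scores: dict, n_up: int, n_unchanged: int,
                               n_perm: int, rng) -> np.ndarray:
    """KS p-values for random up/unchanged label permutations.

    Draws disjoint random up/unchanged sets from the scored universe
    ``n_perm`` times; under this permutation null the p-values should be
    uniform on (0, 1).
    """
    universe = np.array(sorted(scores))
    ps = np.empty(n_perm)
    for i in range(n_perm):
        pick = rng.choice(universe.size, size=n_up + n_unchanged, replace=False)
        up = [scores[universe[j]] for j in pick[:n_up]]
        ref = [scores[universe[j]] for j in pick[n_up:]]
        ps[i] = _ks(np.asarray(up), np.asarray(ref), method="asymp")[1]
    return ps
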