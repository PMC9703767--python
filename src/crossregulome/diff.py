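"""Replicated count-based differential occupancy/expression.

The decision interface mirrors the standard count-based tools (log2 fold
change + BH-adjusted p), but the p-value comes from a conditional binomial
exact test on pooled, scale-offset counts: given n = a + b total reads for
a region, a ~ Binomial(n, pi0) under the null, with pi0 set by the two
conditions' effective depths.  The two-sided p-value is the total
probability of outcomes no more likely than the observed one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .quant import gene_body_window, region_sum

__all__ = ["RegionCounts", "GeneSets", "build_count_matrix",
           "exact_ratio_test", "benjamini_hochberg", "differential_regions",
           "define_gene_sets", "rank_sum_test"]


@dataclass
class RegionCounts:
    """Integer count matrix over regions x samples with per-sample
    calibration factors and condition labels."""

    counts: pd.DataFrame          # index: region/gene ids; columns: samples
    conditions: dict              # sample -> condition label
    scale_factors: dict           # sample -> spike-in calibration factor

    def __post_init__(self):
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be nonnegative")
        missing = set(self.counts.columns) - set(self.conditions)
        if missing:
            raise ValueError(f"samples without condition label: {missing}")

    def samples_for(self, condition: str):
        return [s for s in self.counts.columns
                if self.conditions[s] == condition]


@dataclass(frozen=True)
class GeneSets:
    """The derived gene-set partition (pairwise disjoint)."""

    genebody_up: frozenset
    genebody_unaffected: frozenset
    unchanged_control: frozenset


def build_count_matrix(tracks_by_sample: dict, genes, conditions: dict,
                       scale_factors: dict, min_total: int = 5) -> RegionCounts:
    """Gene-body read counts per sample.

    ``tracks_by_sample[sample]`` is either a single track (unstranded data)
    or a ``(plus, minus)`` pair for strand-specific counting, in which case
    a gene is counted only on its own strand.  Counting uses the gene-body
    window (TSS+300 bp to the gene end).  Genes with fewer than
    ``min_total`` reads in every sample are dropped.
    """
    rows = {}
    kept_genes = []
    for g in genes:
        body = gene_body_window(g)
        if body is None:
            continue
        s, e = max(body[0], 0), body[1]
        vals = []
        for smp, tracks in tracks_by_sample.items():
            if isinstance(tracks, tuple):
                track = tracks[0] if g.strand == "+" else tracks[1]
            else:
                track = tracks
            vals.append(int(round(region_sum(track, g.chrom, s, e))))
        rows[g.gene_id] = vals
        kept_genes.append(g.gene_id)
    if not rows:
        raise ValueError("no countable regions on this layout")
    df = pd.DataFrame.from_dict(rows, orient="index",
                                columns=list(tracks_by_sample))
    keep = (df >= min_total).any(axis=1)
    return RegionCounts(counts=df.loc[keep], conditions=dict(conditions),
                        scale_factors=dict(scale_factors))


def exact_ratio_test(count_a: int, count_b: int,
                     scale_a: float = 1.0, scale_b: float = 1.0) -> float:
    """Two-sided conditional binomial exact test.

    ``scale_a``/``scale_b`` are null expected-count weights, proportional
    to effective sequencing depth (for spike-calibrated data, the inverse
    of the calibration factor).  With n = a + b, a ~ Binomial(n, pi0),
    pi0 = scale_a / (scale_a + scale_b); p is the sum of the probabilities
    of all outcomes no more likely than the observed one.
    """
    if count_a < 0 or count_b < 0:
        raise ValueError("counts must be nonnegative")
    if scale_a <= 0 or scale_b <= 0:
        raise ValueError("scales must be positive")
    n = count_a + count_b
    if n == 0:
        return 1.0
    pi0 = scale_a / (scale_a + scale_b)
    k = np.arange(n + 1)
    logpmf = stats.binom.logpmf(k, n, pi0)
    # include probability ties up to float round-off
    mask = logpmf <= logpmf[count_a] + 1e-9
    if mask.all():
        return 1.0
    return float(min(1.0, np.exp(logpmf[mask]).sum()))


def _exact_ratio_test_many(a: np.ndarray, b: np.ndarray,
                           scale_a: float, scale_b: float) -> np.ndarray:
    pi0 = scale_a / (scale_a + scale_b)
    out = np.empty(len(a))
    for i, (ai, bi) in enumerate(zip(a, b)):
        n = ai + bi
        if n == 0:
            out[i] = 1.0
            continue
        logpmf = stats.binom.logpmf(np.arange(n + 1), n, pi0)
        mask = logpmf <= logpmf[ai] + 1e-9
        out[i] = 1.0 if mask.all() else min(1.0, np.exp(logpmf[mask]).sum())
    return out


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must be in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def differential_regions(counts: RegionCounts, fc_thresh: float = 2.0,
                         fdr_thresh: float = 0.05,
                         treated: str = "depleted",
                         untreated: str = "untreated") -> pd.DataFrame:
    """Per-region differential table (treated vs untreated).

    log2FC is computed on spike-scaled pooled counts with a pseudocount of
    1; the p-value comes from the exact ratio test on pooled raw counts
    with depth weights 1/factor; FDR is BH.  ``status`` is up/down iff
    fdr < ``fdr_thresh`` and |fold change| > ``fc_thresh`` (pass
    ``fc_thresh=1`` for an FDR-only rule).
    """
    t_samples = counts.samples_for(treated)
    u_samples = counts.samples_for(untreated)
    if not t_samples or not u_samples:
        raise ValueError("both conditions must have at least one sample")
    sf = counts.scale_factors
    raw = counts.counts
    t_raw = raw[t_samples].to_numpy()
    u_raw = raw[u_samples].to_numpy()
    t_scaled = (t_raw * np.array([sf[s] for s in t_samples])).sum(axis=1)
    u_scaled = (u_raw * np.array([sf[s] for s in u_samples])).sum(axis=1)
    log2fc = np.log2((t_scaled + 1.0) / (u_scaled + 1.0))
    depth_t = sum(1.0 / sf[s] for s in t_samples)
    depth_u = sum(1.0 / sf[s] for s in u_samples)
    a = t_raw.sum(axis=1).astype(int)
    b = u_raw.sum(axis=1).astype(int)
    p = _exact_ratio_test_many(a, b, depth_t, depth_u)
    fdr = benjamini_hochberg(p)
    base_mean = (t_scaled + u_scaled) / (len(t_samples) + len(u_samples))
    sig = (fdr < fdr_thresh) & (np.abs(log2fc) > np.log2(fc_thresh))
    status = np.where(~sig, "ns", np.where(log2fc > 0, "up", "down"))
    return pd.DataFrame({
        "baseMean": base_mean, "log2FC": log2fc, "p_value": p,
        "fdr": fdr, "status": status,
    }, index=raw.index)


def define_gene_sets(diff_chip: pd.DataFrame, diff_pro: pd.DataFrame,
                     active_genes, unchanged_lfc: float = 0.1) -> GeneSets:
    """Partition the active-gene universe from the two assays' calls.

    genebody_up: up in BOTH ChIP and PRO.  genebody_unaffected: ns in both.
    unchanged_control: ns in both AND |log2FC| < ``unchanged_lfc`` in both
    (the "not at all affected" control set).  Genes significant in only one
    assay fall in none of the sets.
    """
    active = set(active_genes)
    shared = [g for g in diff_pro.index if g in set(diff_chip.index) and g in active]
    up, unaff, ctrl = set(), set(), set()
    for g in shared:
        c, p = diff_chip.loc[g], diff_pro.loc[g]
        if c["status"] == "up" and p["status"] == "up":
            up.add(g)
        elif c["status"] == "ns" and p["status"] == "ns":
            unaff.add(g)
            if abs(c["log2FC"]) < unchanged_lfc and abs(p["log2FC"]) < unchanged_lfc:
                ctrl.add(g)
    # the three reported sets are pairwise disjoint
    unaff -= ctrl
    return GeneSets(genebody_up=frozenset(up),
                    genebody_unaffected=frozenset(unaff),
                    unchanged_control=frozenset(ctrl))


def rank_sum_test(x, y, exact_max_n: int = 12):
    """Two-sided Mann–Whitney/Wilcoxon rank-sum test.

    Exact enumeration when n + m <= ``exact_max_n`` and there are no ties;
    otherwise the normal approximation with tie correction.  If every value
    is tied across both samples, p = 1.0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return float(x.size * y.size / 2.0), 1.0
    no_ties = len(np.unique(pooled)) == pooled.size
    method = "exact" if (pooled.size <= exact_max_n and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)
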