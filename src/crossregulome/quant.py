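"""Per-gene and per-region signal statistics.

Implements the quantities the analysis is built on: spike-in calibration
factors, read densities over strand-aware windows, the activity filter
(promoter density > 0 and gene-body density > 0.04 reads/kb), the
promoter-proximal pausing index, the PRO/ChIP transcription-rate proxy,
and metagene / feature-distance profiles.

Window conventions (transcript-relative, strand-aware):

* promoter-proximal: [TSS−30, TSS+300)
* gene body: [TSS+300, gene end)
* promoter ±1 kb / ±2 kb: symmetric around the TSS
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import GeneRecord, SignalTrack

__all__ = [
    "spike_in_scale_factors",
    "region_density",
    "promoter_proximal_window",
    "gene_body_window",
    "promoter_window",
    "classify_active_genes",
    "active_mrna_union",
    "pausing_index",
    "transcription_rate_ratio",
    "gene_quant_table",
    "metagene_profile",
    "feature_distance_profile",
]

PAUSE_UPSTREAM = 30      # bp upstream of the TSS in the pause window
PAUSE_DOWNSTREAM = 300   # bp downstream; also the gene-body start
ACTIVE_BODY_DENSITY = 0.04   # reads/kb floor for the activity call
UNION_MIN_LENGTH = 5_000     # bp; mRNA union-list length cutoff
RATE_EPS = 0.01              # reads/kb pseudocount in the rate proxy


def spike_in_scale_factors(spike_counts) -> dict:
    """Calibration factors relative to the first sample.

    ``factor_i = reference_count / spike_count_i``; scaled signal is
    raw x factor.  ``spike_counts`` is an ordered mapping or sequence of
    (sample, count) pairs.  Zero counts cannot be calibrated and raise.
    """
    items = list(spike_counts.items()) if hasattr(spike_counts, "items") \
        else list(spike_counts)
    if not items:
        raise ValueError("no spike-in counts supplied")
    for name, c in items:
        if c <= 0:
            raise ValueError(f"sample {name!r}: zero spike-in count, cannot calibrate")
    ref = items[0][1]
    return {name: ref / c for name, c in items}


def _oriented_window(gene: GeneRecord, rel_start: int, rel_end: int):
    """Genome-coordinate window for transcript positions [rel_start, rel_end)."""
    if gene.strand == "+":
        return gene.tss + rel_start, gene.tss + rel_end
    return gene.tss - rel_end + 1, gene.tss - rel_start + 1


def promoter_proximal_window(gene: GeneRecord):
    return _oriented_window(gene, -PAUSE_UPSTREAM, PAUSE_DOWNSTREAM)


def gene_body_window(gene: GeneRecord):
    """[TSS+300, gene end); empty (None) for genes shorter than 300 bp."""
    if gene.length <= PAUSE_DOWNSTREAM:
        return None
    return _oriented_window(gene, PAUSE_DOWNSTREAM, gene.length)


def promoter_window(gene: GeneRecord, flank: int = 1_000):
    return gene.tss - flank, gene.tss + flank + 1


def region_sum(track: SignalTrack, chrom: str, start: int, end: int) -> float:
    """Signal sum over [start, end) with fractional edge-bin weighting."""
    arr = track.data[chrom]
    bs = track.bin_size
    start = max(start, 0)
    end = min(end, len(arr) * bs)
    if end <= start:
        return 0.0
    b0, b1 = start // bs, (end - 1) // bs
    if b0 == b1:
        return float(arr[b0]) * (end - start) / bs
    total = float(arr[b0]) * ((b0 + 1) * bs - start) / bs
    total += float(arr[b1]) * (end - b1 * bs) / bs
    if b1 > b0 + 1:
        total += float(arr[b0 + 1:b1].sum())
    return total


def region_density(track: SignalTrack, chrom: str, start: int, end: int) -> float:
    """Signal density in reads/kb over [start, end)."""
    if end <= start:
        raise ValueError("region must have positive length")
    if chrom not in track.data:
        raise KeyError(f"region chromosome {chrom!r} not in track")
    n_bp = len(track.data[chrom]) * track.bin_size
    if start < 0 or end > n_bp:
        raise ValueError(f"region {chrom}:{start}-{end} off chromosome")
    return region_sum(track, chrom, start, end) * 1_000.0 / (end - start)


def _pro_track(gene: GeneRecord, pro_plus: SignalTrack, pro_minus: SignalTrack):
    return pro_plus if gene.strand == "+" else pro_minus


def _gene_densities(gene, pro_plus, pro_minus):
    track = _pro_track(gene, pro_plus, pro_minus)
    ps, pe = promoter_proximal_window(gene)
    prom = region_density(track, gene.chrom, max(ps, 0), pe)
    body = gene_body_window(gene)
    if body is None:
        return prom, 0.0
    bs_, be_ = body
    return prom, region_density(track, gene.chrom, max(bs_, 0), be_)


def classify_active_genes(pro_plus: SignalTrack, pro_minus: SignalTrack,
                          genes, min_body_density: float = ACTIVE_BODY_DENSITY):
    """Active gene set: promoter-proximal density > 0 AND gene-body density
    above ``min_body_density`` reads/kb (untreated tracks)."""
    active = set()
    for g in genes:
        prom, body = _gene_densities(g, pro_plus, pro_minus)
        if prom > 0 and body > min_body_density:
            active.add(g.gene_id)
    return active


def active_mrna_union(pro_plus: SignalTrack, pro_minus: SignalTrack, genes,
                      min_body_density: float = ACTIVE_BODY_DENSITY,
                      min_length: int = UNION_MIN_LENGTH):
    """The mRNA union list: active mRNA genes of at least ``min_length`` bp."""
    active = classify_active_genes(pro_plus, pro_minus, genes, min_body_density)
    return {g.gene_id for g in genes
            if g.gene_id in active and g.biotype == "mRNA"
            and g.length >= min_length}


def pausing_index(pro_plus: SignalTrack, pro_minus: SignalTrack,
                  gene: GeneRecord, min_length: int = UNION_MIN_LENGTH):
    """Promoter-proximal density over gene-body density.

    Defined only for genes of at least ``min_length`` bp with nonzero
    gene-body density; returns NaN otherwise (excluded, not infinite).
    """
    if gene.length < min_length:
        return float("nan")
    prom, body = _gene_densities(gene, pro_plus, pro_minus)
    if body <= 0:
        return float("nan")
    return prom / body


def transcription_rate_ratio(pro_plus: SignalTrack, pro_minus: SignalTrack,
                             chip: SignalTrack, gene: GeneRecord,
                             eps: float = RATE_EPS) -> float:
    """PRO/ChIP gene-body density ratio — the transcription-rate proxy.

    A pseudocount of ``eps`` reads/kb is added to both densities.
    """
    body = gene_body_window(gene)
    if body is None:
        return float("nan")
    s, e = max(body[0], 0), body[1]
    pro_d = region_density(_pro_track(gene, pro_plus, pro_minus),
                           gene.chrom, s, e)
    chip_d = region_density(chip, gene.chrom, s, e)
    return (pro_d + eps) / (chip_d + eps)


def gene_quant_table(pro_plus: SignalTrack, pro_minus: SignalTrack,
                     chip: SignalTrack, genes,
                     min_body_density: float = ACTIVE_BODY_DENSITY) -> pd.DataFrame:
    """Per-gene quantification table (densities, PI, rate proxy, activity)."""
    rows = []
    for g in genes:
        prom, body = _gene_densities(g, pro_plus, pro_minus)
        rows.append({
            "gene_id": g.gene_id,
            "biotype": g.biotype,
            "length": g.length,
            "promoter_density": prom,
            "genebody_density": body,
            "pausing_index": pausing_index(pro_plus, pro_minus, g),
            "rate_ratio": transcription_rate_ratio(pro_plus, pro_minus, chip, g),
            "active": prom > 0 and body > min_body_density,
        })
    return pd.DataFrame(rows).set_index("gene_id")


# ---------------------------------------------------------------------------
# Profiles


def _bin_means(track: SignalTrack, chrom: str, edges: np.ndarray) -> np.ndarray:
    """Mean track value over each [edges[i], edges[i+1]) window."""
    out = np.empty(len(edges) - 1)
    for i in range(len(edges) - 1):
        s, e = int(edges[i]), int(edges[i + 1])
        if e <= s:
            out[i] = 0.0
            continue
        out[i] = region_sum(track, chrom, s, e) / max(e - s, 1) * track.bin_size
    return out


def _winsorize_rows(mat: np.ndarray, frac: float) -> np.ndarray:
    """Cap each gene's values at its (1-frac) quantile (extreme-value removal)."""
    if frac <= 0:
        return mat
    caps = np.quantile(mat, 1.0 - frac, axis=1, keepdims=True)
    return np.minimum(mat, caps)


def metagene_profile(track: SignalTrack, genes, mode: str = "scaled",
                     flank: int = 3_000, bin: int = 50,
                     body_bins: int = 100, winsor: float = 0.05) -> np.ndarray:
    """Average signal profile over genes, strand-flipped for − genes.

    ``scaled`` mode: ``flank/bin`` upstream bins, ``body_bins`` equally
    sized gene-body bins, ``flank/bin`` downstream bins.  ``tss_centered``
    mode: ±flank around the TSS in ``bin``-bp bins.  The top ``winsor``
    fraction of each gene's values is capped before averaging.
    """
    genes = list(genes)
    if not genes:
        raise ValueError("genes must be nonempty")
    fb = flank // bin
    rows = []
    for g in genes:
        chrom_len = len(track.data[g.chrom]) * track.bin_size
        if mode == "scaled":
            body_edges = np.linspace(g.start, g.end, body_bins + 1)
            up = np.arange(g.start - flank, g.start + 1, bin, dtype=float)
            down = np.arange(g.end, g.end + flank + 1, bin, dtype=float)
            edges = np.concatenate([up[:-1], body_edges, down[1:]])
        elif mode == "tss_centered":
            edges = np.arange(g.tss - flank, g.tss + flank + 1, bin, dtype=float)
        else:
            raise ValueError(f"unknown mode {mode!r}")
        edges = np.clip(edges, 0, chrom_len)
        vals = _bin_means(track, g.chrom, edges)
        if g.strand == "-":
            vals = vals[::-1]
        rows.append(vals)
    mat = _winsorize_rows(np.vstack(rows), winsor)
    return mat.mean(axis=0)


def feature_distance_profile(genes, feature_positions,
                             half_window: int = 10_000,
                             bin: int = 50) -> np.ndarray:
    """Average count of feature anchors per gene in strand-oriented
    ``bin``-bp bins over TSS ± ``half_window``.

    ``feature_positions`` is a sequence of (chrom, position) anchors —
    typically peak summits or annotation TSSs.
    """
    genes = list(genes)
    if not genes:
        raise ValueError("genes must be nonempty")
    n_bins = 2 * half_window // bin
    by_chrom = {}
    for chrom, pos in feature_positions:
        by_chrom.setdefault(chrom, []).append(pos)
    by_chrom = {c: np.sort(np.asarray(p)) for c, p in by_chrom.items()}
    total = np.zeros(n_bins)
    for g in genes:
        pos = by_chrom.get(g.chrom)
        if pos is None:
            continue
        rel = pos - g.tss
        if g.strand == "-":
            rel = -rel
        idx = (rel + half_window) // bin
        ok = (idx >= 0) & (idx < n_bins) & (rel >= -half_window) & (rel < half_window)
        np.add.at(total, idx[ok].astype(int), 1)
    return total / len(genes)
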