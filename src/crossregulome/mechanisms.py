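"""Mechanistic classification of regulated genes.

Each gene is assigned to exactly one category by strict precedence:

1. ``interference`` — a Pol III peak overlaps a Pol II peak that itself
   overlaps the gene (body or ±1 kb promoter): the two polymerases share
   a template and can interfere directly.
2. ``looping`` — a Pol III peak is loop-assigned to the gene (3D contact).
3. ``ncRNA`` — a Pol III peak within the window overlaps an annotated
   Pol III-type ncRNA/SINE element.
4. ``nearby`` — any Pol III peak summit within the window of the TSS.
5. ``unexplained`` — none of the above.

The precedence order is configurable; categories always partition the
input universe.
"""

from __future__ import annotations

from dataclasses import dataclass

from intervaltree import IntervalTree

from .targets import assign_peaks_to_genes

__all__ = ["MechanismAssignment", "MechanismClassifier", "classify_mechanisms",
           "summarize_mechanisms", "format_percentage"]

DEFAULT_ORDER = ("interference", "looping", "ncRNA", "nearby")


@dataclass(frozen=True)
class MechanismAssignment:
    gene_id: str
    category: str
    evidence: tuple      # supporting peak/loop/ncRNA ids


class MechanismClassifier:
    """Precomputes interval indexes and loop assignments, then classifies
    genes one at a time."""

    def __init__(self, pol3_peaks, pol2_peaks, loops, ncrna_annotations,
                 genes, window: int = 100_000, order=DEFAULT_ORDER,
                 promoter_flank: int = 1_000):
        self.window = window
        self.order = tuple(order)
        self.promoter_flank = promoter_flank
        self.pol3_peaks = list(pol3_peaks)

        self._pol2_trees = {}
        for p in pol2_peaks:
            self._pol2_trees.setdefault(p.chrom, IntervalTree()).addi(
                p.start, p.end, p)
        self._ncrna_trees = {}
        for (chrom, s, e, name) in ncrna_annotations:
            self._ncrna_trees.setdefault(chrom, IntervalTree()).addi(s, e, name)
        self._pol3_trees = {}
        for p in self.pol3_peaks:
            self._pol3_trees.setdefault(p.chrom, IntervalTree()).addi(
                p.start, p.end, p)

        # loop-mode assignments over the same gene universe
        self._loop_assigned = {}
        for a in assign_peaks_to_genes(self.pol3_peaks, loops, list(genes),
                                       max_dist=window,
                                       promoter_flank=promoter_flank):
            if a.mode == "loop":
                self._loop_assigned.setdefault(a.gene_id, []).append(a)

    # --- individual category tests (each returns evidence ids or []) ------

    def _interference(self, gene):
        ptree = self._pol2_trees.get(gene.chrom)
        p3tree = self._pol3_trees.get(gene.chrom)
        if ptree is None or p3tree is None:
            return []
        gs = min(gene.start, gene.tss - self.promoter_flank)
        ge = max(gene.end, gene.tss + self.promoter_flank + 1)
        evidence = []
        for hit in ptree.overlap(gs, ge):
            pol2 = hit.data
            for h3 in p3tree.overlap(pol2.start, pol2.end):
                evidence.append((h3.data.name, pol2.name))
        return sorted({f"{a}|{b}" for a, b in evidence})

    def _looping(self, gene):
        hits = self._loop_assigned.get(gene.gene_id, [])
        return sorted({f"{a.peak_id}|{a.loop_id}" for a in hits})

    def _ncrna(self, gene):
        p3tree = self._pol3_trees.get(gene.chrom)
        ntree = self._ncrna_trees.get(gene.chrom)
        if p3tree is None or ntree is None:
            return []
        evidence = set()
        lo, hi = gene.tss - self.window, gene.tss + self.window + 1
        for hit in p3tree.overlap(lo, hi):
            peak = hit.data
            if not lo <= peak.summit < hi:
                continue
            for nh in ntree.overlap(peak.start, peak.end):
                evidence.add(f"{peak.name}|{nh.data}")
        return sorted(evidence)

    def _nearby(self, gene):
        p3tree = self._pol3_trees.get(gene.chrom)
        if p3tree is None:
            return []
        lo, hi = gene.tss - self.window, gene.tss + self.window + 1
        return sorted({hit.data.name for hit in p3tree.overlap(lo, hi)
                       if lo <= hit.data.summit < hi})

    _TESTS = {"interference": _interference, "looping": _looping,
              "ncRNA": _ncrna, "nearby": _nearby}

    def classify(self, gene) -> MechanismAssignment:
        for category in self.order:
            evidence = self._TESTS[category](self, gene)
            if evidence:
                return MechanismAssignment(gene.gene_id, category,
                                           tuple(evidence))
        return MechanismAssignment(gene.gene_id, "unexplained", ())


def classify_mechanisms(genes, pol3_peaks, pol2_peaks, loops,
                        ncrna_annotations, window: int = 100_000,
                        order=DEFAULT_ORDER,
                        loop_universe=None) -> list:
    """Classify each gene in ``genes``; ``loop_universe`` (default:
    ``genes``) is the gene universe used for loop-mode assignment."""
    genes = list(genes)
    clf = MechanismClassifier(
        pol3_peaks, pol2_peaks, loops, ncrna_annotations,
        genes if loop_universe is None else loop_universe,
        window=window, order=order)
    return [clf.classify(g) for g in genes]


def format_percentage(pct: float) -> str:
    """One decimal, collapsed to an integer when within 0.1 of one.

    Reproduces mixed-precision reporting such as 15.7 / 4.4 / 46.
    """
    nearest = round(pct)
    if abs(pct - nearest) < 0.1:
        return str(int(nearest))
    return f"{pct:.1f}"


def summarize_mechanisms(assignments, universe_size: int) -> dict:
    """Category counts and percentages over a gene universe.

    ``assignments`` may be MechanismAssignment objects or a
    {category: count} mapping.  Returns
    {category: {count, pct, pct_display}} with pct rounded to one decimal.
    """
    if universe_size <= 0:
        raise ValueError("universe_size must be positive")
    if isinstance(assignments, dict):
        counts = dict(assignments)
    else:
        counts = {}
        for a in assignments:
            counts[a.category] = counts.get(a.category, 0) + 1
    out = {}
    for category in list(DEFAULT_ORDER) + ["unexplained"]:
        c = counts.get(category, 0)
        pct = 100.0 * c / universe_size
        out[category] = {
            "count": c,
            "pct": round(pct, 1),
            "pct_display": format_percentage(pct),
        }
    for category in counts:
        if category not in out:
            pct = 100.0 * counts[category] / universe_size
            out[category] = {"count": counts[category], "pct": round(pct, 1),
                             "pct_display": format_percentage(pct)}
    return out
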