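"""Genomic interval data model and text-format readers/writers.

All coordinates are 0-based half-open (BED convention); GTF input is
converted on read.  This module is the single home for coordinate
conventions — everything downstream consumes these records.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

__all__ = [
    "GenomeLayout",
    "GeneRecord",
    "PeakRecord",
    "LoopRecord",
    "SignalTrack",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "read_gene_annotation",
    "write_genes_gtf",
    "read_peaks",
    "write_peaks",
    "read_loops",
    "write_loops",
    "read_signal_track",
    "write_bedgraph",
    "intersect_intervals",
    "nearest_tss_gene",
]

# chrM and its aliases are dropped on annotation read, as are scaffolds
# absent from the layout ("random" chromosomes).
_MITO_NAMES = {"chrM", "chrMT", "MT", "M"}


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosome names and lengths (bp)."""

    chrom_names: tuple
    chrom_lengths: tuple

    def __post_init__(self):
        if len(self.chrom_names) != len(set(self.chrom_names)):
            raise ValueError("chromosome names must be unique")
        if any(l <= 0 for l in self.chrom_lengths):
            raise ValueError("chromosome lengths must be > 0")
        if len(self.chrom_names) != len(self.chrom_lengths):
            raise ValueError("names and lengths differ in length")

    def length(self, chrom: str) -> int:
        try:
            return self.chrom_lengths[self.chrom_names.index(chrom)]
        except ValueError:
            raise KeyError(f"unknown chromosome {chrom!r}")

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chrom_names

    def items(self):
        return zip(self.chrom_names, self.chrom_lengths)


@dataclass(frozen=True)
class GeneRecord:
    """One annotated gene with strand-aware TSS/TES.

    ``tss`` is the first transcribed base (``start`` on +, ``end - 1`` on −);
    ``tes`` is the opposite end.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    biotype: str = "mRNA"  # {mRNA, tRNA, ncRNA, other}
    intronless: bool = False

    def __post_init__(self):
        if not self.start < self.end:
            raise ValueError(f"{self.gene_id}: start must be < end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be + or -")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tes(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class PeakRecord:
    """A binding peak with summit and signal strength."""

    chrom: str
    start: int
    end: int
    summit: int
    strength: float = 1.0
    name: str = "."
    factor: str = "."

    def __post_init__(self):
        if not (self.start <= self.summit < self.end):
            raise ValueError(f"peak {self.name}: summit outside interval")
        if self.strength < 0:
            raise ValueError(f"peak {self.name}: strength must be >= 0")


@dataclass(frozen=True)
class LoopRecord:
    """A pair of contact anchors on the same chromosome with a score."""

    chrom: str
    start_a: int
    end_a: int
    start_b: int
    end_b: int
    score: float = 1.0
    name: str = "."

    def __post_init__(self):
        if self.start_a >= self.end_a or self.start_b >= self.end_b:
            raise ValueError(f"loop {self.name}: anchors must be proper intervals")
        if self.score < 0:
            raise ValueError(f"loop {self.name}: score must be >= 0")

    @property
    def anchor_a(self):
        return (self.chrom, self.start_a, self.end_a)

    @property
    def anchor_b(self):
        return (self.chrom, self.start_b, self.end_b)


@dataclass
class SignalTrack:
    """Per-chromosome binned coverage.

    ``data[chrom]`` has ``ceil(chrom_length / bin_size)`` entries; values are
    read counts (or normalized signal) per bin.
    """

    bin_size: int
    data: dict
    strand: str = "."  # {+, -, .}
    normalization: str = "raw"  # {raw, spike_in, RPGC, RPKM}
    total_reads: float = 0.0
    spike_in_reads: float = 0.0

    def n_bins(self, chrom: str) -> int:
        return len(self.data[chrom])

    def scaled(self, factor: float, normalization: str = "spike_in") -> "SignalTrack":
        return SignalTrack(
            bin_size=self.bin_size,
            data={c: v * factor for c, v in self.data.items()},
            strand=self.strand,
            normalization=normalization,
            total_reads=self.total_reads * factor,
            spike_in_reads=self.spike_in_reads,
        )

    @classmethod
    def zeros(cls, layout: GenomeLayout, bin_size: int, strand: str = ".",
              dtype=np.float32) -> "SignalTrack":
        data = {
            c: np.zeros(math.ceil(l / bin_size), dtype=dtype)
            for c, l in layout.items()
        }
        return cls(bin_size=bin_size, data=data, strand=strand)


# ---------------------------------------------------------------------------
# chrom.sizes


def read_chrom_sizes(path) -> GenomeLayout:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"])
    return GenomeLayout(tuple(df["chrom"]), tuple(int(x) for x in df["length"]))


def write_chrom_sizes(layout: GenomeLayout, path) -> None:
    with open(path, "w") as fh:
        for name, length in layout.items():
            fh.write(f"{name}\t{length}\n")


# ---------------------------------------------------------------------------
# Gene annotation (GTF, Gencode dialect; or BED12)

_GTF_ATTR = re.compile(r'(\w+) "([^"]*)"')

_BIOTYPE_MAP = {
    "protein_coding": "mRNA",
    "mRNA": "mRNA",
    "tRNA": "tRNA",
    "Mt_tRNA": "tRNA",
}


def _map_biotype(raw: str) -> str:
    if raw in _BIOTYPE_MAP:
        return _BIOTYPE_MAP[raw]
    if "RNA" in raw:
        return "ncRNA"
    return "other"


def read_gene_annotation(path, layout: GenomeLayout) -> list:
    """Read gene records from GTF (``gene`` features only) or BED12.

    Genes on chrM or on chromosomes absent from ``layout`` are dropped.
    1-based closed GTF coordinates are converted to 0-based half-open.
    Malformed lines raise; records with unknown strand are skipped with a
    warning.
    """
    path = Path(path)
    if path.suffix.lower() in (".bed", ".bed12"):
        return _read_genes_bed12(path, layout)
    genes = []
    seen = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GTF columns, got {len(fields)}")
            chrom, _, feature, start, end, _, strand, _, attrs = fields[:9]
            if feature != "gene":
                continue
            if chrom in _MITO_NAMES or chrom not in layout:
                continue
            if strand not in ("+", "-"):
                warnings.warn(f"{path}:{lineno}: unknown strand {strand!r}; record skipped")
                continue
            try:
                start_i, end_i = int(start) - 1, int(end)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            attr = dict(_GTF_ATTR.findall(attrs))
            gene_id = attr.get("gene_id")
            if gene_id is None:
                raise ValueError(f"{path}:{lineno}: missing gene_id attribute")
            if gene_id in seen:
                raise ValueError(f"{path}:{lineno}: duplicate gene_id {gene_id!r}")
            seen.add(gene_id)
            raw_bt = attr.get("gene_biotype", attr.get("gene_type", "other"))
            genes.append(GeneRecord(
                gene_id=gene_id, chrom=chrom, start=start_i, end=end_i,
                strand=strand, biotype=_map_biotype(raw_bt),
                intronless=attr.get("intronless", "").lower() == "true",
            ))
    return genes


def _read_genes_bed12(path, layout: GenomeLayout) -> list:
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 6:
                raise ValueError(f"{path}:{lineno}: expected >=6 BED columns")
            chrom = f[0]
            if chrom in _MITO_NAMES or chrom not in layout:
                continue
            if f[5] not in ("+", "-"):
                warnings.warn(f"{path}:{lineno}: unknown strand {f[5]!r}; record skipped")
                continue
            intronless = len(f) >= 10 and int(f[9]) == 1
            genes.append(GeneRecord(
                gene_id=f[3], chrom=chrom, start=int(f[1]), end=int(f[2]),
                strand=f[5], biotype="mRNA", intronless=intronless,
            ))
    return genes


def write_genes_gtf(genes: Sequence[GeneRecord], path) -> None:
    genes = sorted(genes, key=lambda g: (g.chrom, g.start, g.gene_id))
    with open(path, "w") as fh:
        for g in genes:
            attrs = (
                f'gene_id "{g.gene_id}"; gene_biotype "{_gtf_biotype(g.biotype)}"; '
                f'intronless "{"true" if g.intronless else "false"}";'
            )
            fh.write(
                f"{g.chrom}\tcrossregulome\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\t{attrs}\n"
            )


def _gtf_biotype(biotype: str) -> str:
    return {"mRNA": "protein_coding"}.get(biotype, biotype)


# ---------------------------------------------------------------------------
# Peaks (BED3+; optional name, score, strand, summit offset)


def read_peaks(path, factor: str = ".") -> list:
    """Read peaks from BED.

    Column layout: chrom, start, end[, name, score, strand, summit-offset].
    Missing summit defaults to the interval midpoint; missing score to 1.0.
    Records with start >= end are rejected with a warning.
    """
    peaks = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 BED columns")
            chrom, start, end = f[0], int(f[1]), int(f[2])
            if start >= end:
                warnings.warn(f"{path}:{lineno}: start >= end; record rejected")
                continue
            name = f[3] if len(f) > 3 and f[3] else f"peak_{lineno}"
            strength = float(f[4]) if len(f) > 4 and f[4] not in (".", "") else 1.0
            if len(f) > 6 and f[6] not in (".", ""):
                summit = start + int(f[6])
            else:
                summit = (start + end) // 2
            peaks.append(PeakRecord(chrom=chrom, start=start, end=end,
                                    summit=summit, strength=strength,
                                    name=name, factor=factor))
    return peaks


def write_peaks(peaks: Sequence[PeakRecord], path) -> None:
    peaks = sorted(peaks, key=lambda p: (p.chrom, p.start, p.name))
    with open(path, "w") as fh:
        for p in peaks:
            fh.write(
                f"{p.chrom}\t{p.start}\t{p.end}\t{p.name}\t{p.strength:.12g}\t.\t"
                f"{p.summit - p.start}\n"
            )


# ---------------------------------------------------------------------------
# Loops (BEDPE)


def read_loops(path) -> list:
    """Read loops from BEDPE (>=6 columns; optional name, score).

    Trans-chromosomal pairs and malformed anchors are rejected with a
    warning; a missing score defaults to 1.0.
    """
    loops = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 6:
                raise ValueError(f"{path}:{lineno}: expected >=6 BEDPE columns")
            ca, sa, ea, cb, sb, eb = f[0], int(f[1]), int(f[2]), f[3], int(f[4]), int(f[5])
            if ca != cb:
                warnings.warn(f"{path}:{lineno}: trans-chromosomal pair rejected")
                continue
            if sa >= ea or sb >= eb:
                warnings.warn(f"{path}:{lineno}: degenerate anchor rejected")
                continue
            name = f[6] if len(f) > 6 and f[6] else f"loop_{lineno}"
            score = float(f[7]) if len(f) > 7 and f[7] not in (".", "") else 1.0
            loops.append(LoopRecord(chrom=ca, start_a=sa, end_a=ea,
                                    start_b=sb, end_b=eb, score=score, name=name))
    return loops


def write_loops(loops: Sequence[LoopRecord], path) -> None:
    loops = sorted(loops, key=lambda l: (l.chrom, l.start_a, l.start_b, l.name))
    with open(path, "w") as fh:
        for l in loops:
            fh.write(
                f"{l.chrom}\t{l.start_a}\t{l.end_a}\t{l.chrom}\t{l.start_b}\t"
                f"{l.end_b}\t{l.name}\t{l.score:.12g}\n"
            )


# ---------------------------------------------------------------------------
# bedGraph signal tracks


def read_signal_track(path, layout: GenomeLayout, bin_size: int,
                      strand: str = ".") -> SignalTrack:
    """Read a bedGraph onto a fixed grid of ``bin_size`` bins.

    Interval values are rebinned by length-weighted mean; uncovered bins are
    zero.  Negative values raise.
    """
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "value"],
                     comment="#", dtype={"chrom": str})
    if (df["value"] < 0).any():
        bad = df.index[df["value"] < 0][0] + 1
        raise ValueError(f"{path}: negative value at record {bad}")
    track = SignalTrack.zeros(layout, bin_size, strand=strand)
    for chrom, sub in df.groupby("chrom", sort=False):
        if chrom not in layout:
            continue
        n = track.n_bins(chrom)
        num = np.zeros(n)
        den = np.zeros(n)
        starts = sub["start"].to_numpy()
        ends = np.minimum(sub["end"].to_numpy(), layout.length(chrom))
        values = sub["value"].to_numpy(dtype=float)
        b0 = starts // bin_size
        b1 = (ends - 1) // bin_size
        single = b0 == b1
        if single.any():  # vectorized path: record within one bin
            ov = (ends[single] - starts[single]).astype(float)
            np.add.at(num, b0[single], values[single] * ov)
            np.add.at(den, b0[single], ov)
        for s, e, v in zip(starts[~single], ends[~single], values[~single]):
            for b in range(s // bin_size, (e - 1) // bin_size + 1):
                ov = min(e, (b + 1) * bin_size) - max(s, b * bin_size)
                num[b] += v * ov
                den[b] += ov
        covered = den > 0
        out = np.zeros(n, dtype=np.float32)
        out[covered] = (num[covered] / den[covered]).astype(np.float32)
        track.data[chrom] = out
    track.total_reads = float(sum(v.sum() for v in track.data.values()))
    return track


def write_bedgraph(track: SignalTrack, path) -> None:
    """Write nonzero bins as sorted bedGraph records (one per bin)."""
    bs = track.bin_size
    with open(path, "w") as fh:
        for chrom in track.data:
            values = track.data[chrom]
            nz = np.nonzero(values)[0]
            for b in nz:
                v = values[b]
                fh.write(f"{chrom}\t{b * bs}\t{(b + 1) * bs}\t{v:g}\n")


# ---------------------------------------------------------------------------
# Interval operations


def _as_interval(x):
    if hasattr(x, "chrom"):
        return (x.chrom, x.start, x.end)
    return (x[0], int(x[1]), int(x[2]))


def intersect_intervals(a: Iterable, b: Iterable, min_overlap: int = 1) -> list:
    """All (i, j) index pairs with overlap >= ``min_overlap`` bp.

    Inputs are sequences of (chrom, start, end) tuples or records with those
    attributes; intervals are 0-based half-open.
    """
    a = [_as_interval(x) for x in a]
    b = [_as_interval(x) for x in b]
    trees = {}
    for j, (chrom, s, e) in enumerate(b):
        trees.setdefault(chrom, IntervalTree()).addi(s, e, j)
    pairs = []
    for i, (chrom, s, e) in enumerate(a):
        tree = trees.get(chrom)
        if tree is None:
            continue
        for hit in tree.overlap(s, e):
            if min(e, hit.end) - max(s, hit.begin) >= min_overlap:
                pairs.append((i, hit.data))
    pairs.sort()
    return pairs


def nearest_tss_gene(peak: PeakRecord, genes: Sequence[GeneRecord],
                     max_dist: int = 100_000):
    """Nearest gene by |summit − TSS| within ``max_dist``, else None.

    Ties are broken by smaller TSS coordinate, then lexicographic gene_id.
    """
    best = None
    best_key = None
    for g in genes:
        if g.chrom != peak.chrom:
            continue
        d = abs(peak.summit - g.tss)
        if d > max_dist:
            continue
        key = (d, g.tss, g.gene_id)
        if best_key is None or key < best_key:
            best, best_key = g, key
    return best
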