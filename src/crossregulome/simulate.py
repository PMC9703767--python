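"""Synthetic two-condition polymerase-depletion study generator.

Builds a toy genome with non-overlapping genes, polymerase binding peaks,
chromatin loops, and replicated nascent-transcription / occupancy /
accessibility tracks, with a known fraction of active mRNA genes planted as
"genebody-up" responders to Pol III depletion.  Each planted gene is also
assigned one mechanistic route (interference, looping, ncRNA, or nearby)
and the corresponding evidence — an overlapping promoter peak, a loop to a
distal peak, a Pol III-type ncRNA element, or a bare nearby peak — is
placed inside a private ±110 kb clearance zone so the planted mechanisms
are mutually exclusive by construction.

Ground truth (labels, mechanisms, peak targets, per-sample scale factors)
is returned alongside the data so every downstream stage is testable
without any real sequencing data.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    GenomeLayout,
    GeneRecord,
    LoopRecord,
    PeakRecord,
    SignalTrack,
    write_bedgraph,
    write_chrom_sizes,
    write_genes_gtf,
    write_loops,
    write_peaks,
)

__all__ = ["SimConfig", "SimTruth", "SyntheticStudy", "SampleSignals",
           "simulate_study", "simulate_signal", "simulate_all_samples",
           "write_fixture_bundle", "load_fixture_bundle"]

CONDITIONS = ("untreated", "depleted")

# Clearance around each planted gene inside which only that gene's own
# mechanistic evidence may be placed; must exceed the 100-kb association
# window used downstream.
_CLEARANCE = 110_000


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters for the synthetic generator.

    Defaults encode the emulated study design: two conditions with two
    replicates, 5% spike-in, a gene-body effect of 2.0 and a pausing-index
    effect of 0.5 on planted genes, and a mean sequencing depth of 100
    gene-body reads per gene per sample.
    """

    n_chroms: int = 5
    chrom_length: int = 16_000_000
    n_genes: int = 2000
    gene_length_range: tuple = (5_000, 20_000)
    frac_short_mrna: float = 0.1      # mRNAs below the 5-kb union-list cutoff
    frac_tRNA: float = 0.1
    frac_intronless: float = 0.1
    frac_inactive: float = 0.1        # silent mRNA genes (background only)
    n_pol3_peaks: int = 600           # background/decoy Pol III peaks
    frac_loops: float = 0.2           # genes given a background loop
    planted_fraction: float = 0.125   # of active mRNA genes made genebody-up
    mech_proportions: tuple = (
        ("interference", 0.20), ("looping", 0.15),
        ("ncRNA", 0.10), ("nearby", 0.55),
    )
    effect_genebody: float = 2.0      # PRO gene-body multiplier under depletion
    effect_pausing: float = 0.5       # pausing-index multiplier under depletion
    effect_rate: float = 0.67         # PRO/ChIP rate-proxy multiplier (<1: slower)
    trna_depletion: float = 0.1       # tRNA signal multiplier under depletion
    spike_in_fraction: float = 0.05
    depth: float = 100.0              # mean gene-body reads per gene per sample
    background_density: float = 0.02  # reads/kb of untemplated background
    n_replicates: int = 2
    noise_model: str = "negative_binomial"  # or "poisson"
    dispersion: float = 0.05
    bin_size: int = 50
    seed: int = 0

    def __post_init__(self):
        for name in ("frac_short_mrna", "frac_tRNA", "frac_intronless",
                     "frac_inactive", "frac_loops", "planted_fraction",
                     "spike_in_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("effect_genebody", "effect_pausing", "effect_rate",
                     "depth"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.noise_model not in ("poisson", "negative_binomial"):
            raise ValueError(f"unknown noise_model {self.noise_model!r}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["gene_length_range"] = list(self.gene_length_range)
        d["mech_proportions"] = [list(x) for x in self.mech_proportions]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "gene_length_range" in d:
            d["gene_length_range"] = tuple(d["gene_length_range"])
        if "mech_proportions" in d:
            d["mech_proportions"] = tuple(
                (k, float(v)) for k, v in d["mech_proportions"])
        return cls(**d)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class SimTruth:
    """Ground truth for one simulated study."""

    labels: dict            # gene_id -> {genebody_up, unaffected, inactive}
    mechanism: dict         # gene_id -> category (planted genes only)
    peak_target: dict       # peak name -> gene_id (mechanistic peaks)
    scale_factors: dict     # sample -> true spike-in calibration factor
    efficiency: dict        # sample -> latent capture efficiency
    params: pd.DataFrame    # per-gene latent expression / pausing parameters

    @property
    def planted(self) -> list:
        return sorted(g for g, l in self.labels.items() if l == "genebody_up")


@dataclass
class SyntheticStudy:
    config: SimConfig
    layout: GenomeLayout
    genes: list
    pol3_peaks: list
    pol2_peaks: list
    loops: list
    ncrna: list             # (chrom, start, end, name) Pol III-type ncRNA/SINE
    truth: SimTruth


@dataclass
class SampleSignals:
    sample: str
    condition: str
    replicate: int
    pro_plus: SignalTrack
    pro_minus: SignalTrack
    chip: SignalTrack
    atac: SignalTrack
    spike_in_reads: int


def _largest_remainder(total: int, proportions) -> dict:
    raw = {k: total * p for k, p in proportions}
    counts = {k: int(math.floor(v)) for k, v in raw.items()}
    short = total - sum(counts.values())
    order = sorted(raw, key=lambda k: raw[k] - counts[k], reverse=True)
    for k in order[:short]:
        counts[k] += 1
    return counts


def sample_name(condition: str, replicate: int) -> str:
    return f"{condition}_r{replicate}"


def simulate_study(config: SimConfig) -> SyntheticStudy:
    """Lay out the genome, genes, peaks, loops and ground truth.

    Deterministic for a fixed config (including seed).  Raises if the genes
    plus clearance zones cannot be packed into the configured genome.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    layout = GenomeLayout(
        tuple(f"chr{i + 1}" for i in range(config.n_chroms)),
        tuple([config.chrom_length] * config.n_chroms),
    )

    # --- gene specs -------------------------------------------------------
    n_trna = int(round(config.frac_tRNA * config.n_genes))
    n_mrna = config.n_genes - n_trna
    lo, hi = config.gene_length_range
    is_short = rng.random(n_mrna) < config.frac_short_mrna
    mrna_len = np.where(is_short,
                        rng.integers(2_000, 4_500, n_mrna),
                        rng.integers(lo, hi, n_mrna))
    trna_len = rng.integers(90, 250, n_trna)
    intronless = rng.random(n_mrna) < config.frac_intronless

    n_inactive = int(round(config.frac_inactive * n_mrna))
    mrna_idx = rng.permutation(n_mrna)
    inactive_set = set(mrna_idx[:n_inactive])
    active_idx = [i for i in range(n_mrna) if i not in inactive_set]
    n_planted = int(round(config.planted_fraction * len(active_idx)))
    eligible = [i for i in active_idx if mrna_len[i] >= 5_000]
    if n_planted > len(eligible):
        raise ValueError("not enough >=5 kb active mRNA genes to plant effects")
    planted_idx = list(rng.choice(eligible, size=n_planted, replace=False))
    mech_counts = _largest_remainder(n_planted, config.mech_proportions)
    mech_of = {}
    cursor = 0
    for cat, cnt in mech_counts.items():
        for i in planted_idx[cursor:cursor + cnt]:
            mech_of[int(i)] = cat
        cursor += cnt

    # --- placement --------------------------------------------------------
    # Sequential packing with per-gene gaps; planted genes get a private
    # clearance on both sides so mechanism evidence cannot collide.
    specs = []  # (kind, local index, length)
    for i in range(n_mrna):
        specs.append(("mRNA", i, int(mrna_len[i])))
    for i in range(n_trna):
        specs.append(("tRNA", i, int(trna_len[i])))
    order = rng.permutation(len(specs))
    planted_set = set(int(i) for i in planted_idx)

    genes = []
    gene_meta = []  # dicts aligned with genes
    chrom_i = 0
    cur = 10_000
    for oi in order:
        kind, li, length = specs[oi]
        planted = kind == "mRNA" and li in planted_set
        gap = _CLEARANCE if planted else int(rng.integers(1_000, 5_000))
        placed = False
        while chrom_i < config.n_chroms:
            start = cur + gap
            trailing = _CLEARANCE if planted else 0
            if start + length + trailing <= config.chrom_length - 1_000:
                placed = True
                break
            chrom_i += 1
            cur = 10_000
        if not placed:
            raise ValueError(
                "infeasible packing: genome too small for the configured genes")
        chrom = layout.chrom_names[chrom_i]
        strand = "+" if rng.random() < 0.5 else "-"
        gid = f"g{li:05d}" if kind == "mRNA" else f"t{li:04d}"
        genes.append(GeneRecord(
            gene_id=gid, chrom=chrom, start=start, end=start + length,
            strand=strand, biotype="mRNA" if kind == "mRNA" else "tRNA",
            intronless=kind == "mRNA" and bool(intronless[li]),
        ))
        gene_meta.append({"kind": kind, "local": li, "planted": planted})
        cur = start + length + (_CLEARANCE if planted else 0)

    by_id = {g.gene_id: g for g in genes}

    # --- labels and latent expression parameters --------------------------
    labels = {}
    mechanism = {}
    rel_expr = {}
    pausing = {}
    for g, meta in zip(genes, gene_meta):
        if meta["kind"] == "tRNA":
            labels[g.gene_id] = "unaffected"
        elif meta["local"] in inactive_set:
            labels[g.gene_id] = "inactive"
        elif meta["planted"]:
            labels[g.gene_id] = "genebody_up"
            mechanism[g.gene_id] = mech_of[meta["local"]]
        else:
            labels[g.gene_id] = "unaffected"
        rel_expr[g.gene_id] = float(rng.lognormal(-0.32, 0.8))
        pausing[g.gene_id] = float(rng.lognormal(np.log(4.0), 0.5))

    params = pd.DataFrame({
        "gene_id": [g.gene_id for g in genes],
        "rel_expr": [rel_expr[g.gene_id] for g in genes],
        "pausing_index": [pausing[g.gene_id] for g in genes],
        "label": [labels[g.gene_id] for g in genes],
    }).set_index("gene_id")

    # --- Pol II promoter peaks at active mRNA genes -----------------------
    pol2_peaks = []
    for g in genes:
        if g.biotype != "mRNA" or labels[g.gene_id] == "inactive":
            continue
        s, e = max(0, g.tss - 250), g.tss + 250
        pol2_peaks.append(PeakRecord(
            chrom=g.chrom, start=s, end=e, summit=g.tss,
            strength=float(10 * rng.lognormal(0, 0.5)),
            name=f"p2_{g.gene_id}", factor="Pol II"))

    # --- Pol III peaks, loops, ncRNA elements -----------------------------
    pol3_peaks = []
    loops = []
    ncrna = []
    peak_target = {}

    def planted_offset():
        # regulating peaks concentrate near the TSS (distance-density
        # profiles of affected genes peak within ~10 kb)
        d = int(np.clip(rng.lognormal(np.log(12_000), 0.7), 2_000, 90_000))
        return d if rng.random() < 0.5 else -d

    for g in genes:
        mech = mechanism.get(g.gene_id)
        if mech is None:
            continue
        strength = float(20 * rng.lognormal(0, 0.5))
        if mech == "interference":
            pos = g.tss
            pol3_peaks.append(PeakRecord(
                chrom=g.chrom, start=max(0, pos - 150), end=pos + 150,
                summit=pos, strength=strength,
                name=f"p3_{g.gene_id}", factor="Pol III"))
        elif mech == "looping":
            pos = g.tss + planted_offset()
            pol3_peaks.append(PeakRecord(
                chrom=g.chrom, start=pos - 150, end=pos + 150, summit=pos,
                strength=strength, name=f"p3_{g.gene_id}", factor="Pol III"))
            loops.append(LoopRecord(
                chrom=g.chrom, start_a=pos - 1_000, end_a=pos + 1_000,
                start_b=g.tss - 500, end_b=g.tss + 500,
                score=float(rng.uniform(5, 50)), name=f"L_{g.gene_id}"))
        elif mech == "ncRNA":
            pos = g.tss + planted_offset()
            ncrna.append((g.chrom, pos - 150, pos + 150, f"sine_{g.gene_id}"))
            pol3_peaks.append(PeakRecord(
                chrom=g.chrom, start=pos - 100, end=pos + 100, summit=pos,
                strength=strength, name=f"p3_{g.gene_id}", factor="Pol III"))
        else:  # nearby
            pos = g.tss + planted_offset()
            pol3_peaks.append(PeakRecord(
                chrom=g.chrom, start=pos - 150, end=pos + 150, summit=pos,
                strength=strength, name=f"p3_{g.gene_id}", factor="Pol III"))
        peak_target[f"p3_{g.gene_id}"] = g.gene_id

    # tRNA genes are canonical Pol III sites and part of the ncRNA track.
    for g in genes:
        if g.biotype != "tRNA":
            continue
        mid = (g.start + g.end) // 2
        name = f"p3_{g.gene_id}"
        pol3_peaks.append(PeakRecord(
            chrom=g.chrom, start=max(0, g.start - 50), end=g.end + 50,
            summit=mid, strength=float(30 * rng.lognormal(0, 0.5)),
            name=name, factor="Pol III"))
        ncrna.append((g.chrom, g.start, g.end, g.gene_id))
        peak_target[name] = g.gene_id

    planted_tss = [(by_id[g].chrom, by_id[g].tss) for g in mechanism]

    def clear_of_planted(chrom, pos):
        return all(c != chrom or abs(pos - t) > _CLEARANCE
                   for c, t in planted_tss)

    n_decoy = 0
    attempts = 0
    while n_decoy < config.n_pol3_peaks and attempts < 50 * config.n_pol3_peaks:
        attempts += 1
        chrom = layout.chrom_names[int(rng.integers(config.n_chroms))]
        pos = int(rng.integers(5_000, config.chrom_length - 5_000))
        if not clear_of_planted(chrom, pos):
            continue
        pol3_peaks.append(PeakRecord(
            chrom=chrom, start=pos - 150, end=pos + 150, summit=pos,
            strength=float(5 * rng.lognormal(0, 0.5)),
            name=f"p3_decoy{n_decoy:04d}", factor="Pol III"))
        n_decoy += 1

    # Background loops at unplanted active genes with a clear distal anchor.
    candidates = [g for g in genes
                  if g.biotype == "mRNA" and labels[g.gene_id] == "unaffected"]
    n_bg_loops = int(round(config.frac_loops * len(candidates)))
    if n_bg_loops and candidates:
        chosen = rng.choice(len(candidates), size=min(n_bg_loops, len(candidates)),
                            replace=False)
        for ci in chosen:
            g = candidates[int(ci)]
            for _ in range(20):
                d = int(rng.integers(20_000, 200_000))
                pos = g.tss + (d if rng.random() < 0.5 else -d)
                if 2_000 < pos < config.chrom_length - 2_000 and \
                        clear_of_planted(g.chrom, pos):
                    loops.append(LoopRecord(
                        chrom=g.chrom, start_a=pos - 1_000, end_a=pos + 1_000,
                        start_b=g.tss - 500, end_b=g.tss + 500,
                        score=float(rng.uniform(1, 20)), name=f"Lbg_{g.gene_id}"))
                    break

    # --- per-sample capture efficiencies / true scale factors -------------
    efficiency = {}
    for condition in CONDITIONS:
        for rep in range(1, config.n_replicates + 1):
            efficiency[sample_name(condition, rep)] = float(rng.lognormal(0, 0.15))
    ref = sample_name("untreated", 1)
    scale_factors = {s: efficiency[ref] / e for s, e in efficiency.items()}

    truth = SimTruth(labels=labels, mechanism=mechanism,
                     peak_target=peak_target, scale_factors=scale_factors,
                     efficiency=efficiency, params=params)
    return SyntheticStudy(config=config, layout=layout, genes=genes,
                          pol3_peaks=pol3_peaks, pol2_peaks=pol2_peaks,
                          loops=loops, ncrna=ncrna, truth=truth)


# ---------------------------------------------------------------------------
# Signal simulation


def _add_interval(arr: np.ndarray, start: int, end: int, per_bp: float,
                  bin_size: int) -> None:
    """Add ``per_bp`` expected reads/bp over [start, end) with fractional
    edge-bin weighting."""
    if per_bp <= 0 or end <= start:
        return
    start = max(start, 0)
    end = min(end, len(arr) * bin_size)
    if end <= start:
        return
    b0, b1 = start // bin_size, (end - 1) // bin_size
    if b0 == b1:
        arr[b0] += per_bp * (end - start)
        return
    arr[b0] += per_bp * ((b0 + 1) * bin_size - start)
    arr[b1] += per_bp * (end - b1 * bin_size)
    if b1 > b0 + 1:
        arr[b0 + 1:b1] += per_bp * bin_size


def _oriented(gene: GeneRecord, rel_start: int, rel_end: int):
    """Genome interval for transcript-relative positions [rel_start, rel_end)."""
    if gene.strand == "+":
        return gene.tss + rel_start, gene.tss + rel_end
    return gene.tss - rel_end + 1, gene.tss - rel_start + 1


def simulate_signal(study: SyntheticStudy, condition: str,
                    replicate: int) -> SampleSignals:
    """Draw one sample's PRO (stranded), ChIP, and ATAC tracks plus its
    spike-in read count.

    Expected per-gene intensities follow the planted design: under
    depletion, genebody-up genes gain ``effect_genebody`` in the gene body
    and lose pausing (x ``effect_pausing``); their ChIP gene-body signal
    rises by ``effect_genebody / effect_rate`` so the PRO/ChIP rate proxy
    falls; tRNA genes lose ``1 - trna_depletion`` of their signal.
    """
    config = study.config
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    if not 1 <= replicate <= config.n_replicates:
        raise ValueError(f"replicate out of range: {replicate}")
    name = sample_name(condition, replicate)
    eff = study.truth.efficiency[name]
    depleted = condition == "depleted"
    bs = config.bin_size
    ss = np.random.SeedSequence(
        config.seed, spawn_key=(CONDITIONS.index(condition), replicate))
    rng = np.random.default_rng(ss)

    lam = {key: {c: np.zeros(math.ceil(l / bs)) for c, l in study.layout.items()}
           for key in ("pro_plus", "pro_minus", "chip", "atac")}

    bg = config.background_density / 1_000.0 * eff  # reads per bp
    for key in lam:
        for c in lam[key]:
            lam[key][c] += bg * bs

    for g in study.genes:
        p = study.truth.params.loc[g.gene_id]
        label = p["label"]
        pro = lam["pro_plus" if g.strand == "+" else "pro_minus"][g.chrom]
        if g.biotype == "tRNA":
            per_bp = 2.0 * config.depth * p["rel_expr"] / g.length
            if depleted:
                per_bp *= config.trna_depletion
            _add_interval(pro, g.start, g.end, per_bp * eff, bs)
            continue
        if label == "inactive":
            continue
        body_len = g.length - 300
        if body_len <= 0:
            continue
        body_per_bp = config.depth * p["rel_expr"] / body_len
        pi = p["pausing_index"]
        planted = label == "genebody_up"
        body_mult = config.effect_genebody if (depleted and planted) else 1.0
        pi_mult = config.effect_pausing if (depleted and planted) else 1.0
        prom_per_bp = pi * pi_mult * body_per_bp * body_mult
        bs_, be_ = _oriented(g, 300, g.length)
        ps_, pe_ = _oriented(g, -30, 300)
        _add_interval(pro, bs_, be_, body_per_bp * body_mult * eff, bs)
        _add_interval(pro, ps_, pe_, prom_per_bp * eff, bs)

        chip = lam["chip"][g.chrom]
        chip_body_mult = (config.effect_genebody / config.effect_rate
                          if (depleted and planted) else 1.0)
        chip_prom_mult = config.effect_pausing if (depleted and planted) else 1.0
        _add_interval(chip, bs_, be_, body_per_bp * chip_body_mult * eff, bs)
        _add_interval(chip, ps_, pe_, pi * body_per_bp * chip_prom_mult * eff, bs)

        atac = lam["atac"][g.chrom]
        atac_per_bp = 0.05 * config.depth * p["rel_expr"] / 1_000.0
        atac_mult = 0.7 if (depleted and planted) else 1.0
        _add_interval(atac, g.tss - 500, g.tss + 500, atac_per_bp * atac_mult * eff, bs)

    def draw(arrs: dict) -> dict:
        out = {}
        for c, a in arrs.items():
            counts = np.zeros(len(a), dtype=np.float32)
            nz = a > 0
            mean = a[nz]
            if config.noise_model == "negative_binomial":
                alpha = config.dispersion
                mean = rng.gamma(1.0 / alpha, alpha * mean)
            counts[nz] = rng.poisson(mean)
            out[c] = counts
        return out

    tracks = {}
    for key in ("pro_plus", "pro_minus", "chip", "atac"):
        data = draw(lam[key])
        strand = {"pro_plus": "+", "pro_minus": "-"}.get(key, ".")
        t = SignalTrack(bin_size=bs, data=data, strand=strand)
        t.total_reads = float(sum(v.sum() for v in data.values()))
        tracks[key] = t

    n_active = int((study.truth.params["label"] != "inactive").sum())
    spike_mean = (config.depth * n_active * config.spike_in_fraction
                  / (1.0 - config.spike_in_fraction)) * eff
    spike = int(rng.poisson(spike_mean))
    for t in tracks.values():
        t.spike_in_reads = spike

    return SampleSignals(sample=name, condition=condition, replicate=replicate,
                         spike_in_reads=spike, **tracks)


def simulate_all_samples(study: SyntheticStudy) -> list:
    return [simulate_signal(study, cond, rep)
            for cond in CONDITIONS
            for rep in range(1, study.config.n_replicates + 1)]


# ---------------------------------------------------------------------------
# Fixture bundles on disk


def write_fixture_bundle(study: SyntheticStudy, samples, outdir) -> dict:
    """Write the study as GTF/BED/BEDPE/bedGraph/TSV files plus a JSON
    manifest carrying the config and its hash.  Returns the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_chrom_sizes(study.layout, outdir / "genome.chrom.sizes")
    write_genes_gtf(study.genes, outdir / "genes.gtf")
    write_peaks(study.pol3_peaks, outdir / "pol3_peaks.bed")
    write_peaks(study.pol2_peaks, outdir / "pol2_peaks.bed")
    write_loops(study.loops, outdir / "loops.bedpe")
    with open(outdir / "ncrna.bed", "w") as fh:
        for chrom, s, e, name in sorted(study.ncrna):
            fh.write(f"{chrom}\t{s}\t{e}\t{name}\n")

    track_files = {}
    spike = {}
    for smp in samples:
        for key in ("pro_plus", "pro_minus", "chip", "atac"):
            fname = f"{smp.sample}.{key}.bedgraph"
            write_bedgraph(getattr(smp, key), outdir / fname)
            track_files.setdefault(smp.sample, {})[key] = fname
        spike[smp.sample] = smp.spike_in_reads
    pd.DataFrame({"sample": list(spike), "spike_in_reads": list(spike.values())}
                 ).to_csv(outdir / "spike_in_counts.tsv", sep="\t", index=False)

    truth = study.truth
    truth.params.assign(
        mechanism=[truth.mechanism.get(g, "") for g in truth.params.index]
    ).to_csv(outdir / "truth_genes.tsv", sep="\t")
    pd.DataFrame({
        "sample": list(truth.scale_factors),
        "true_scale_factor": list(truth.scale_factors.values()),
        "efficiency": [truth.efficiency[s] for s in truth.scale_factors],
    }).to_csv(outdir / "truth_samples.tsv", sep="\t", index=False)

    manifest = {
        "config": study.config.to_dict(),
        "config_hash": study.config.config_hash(),
        "seed": study.config.seed,
        "samples": {s: track_files[s] for s in sorted(track_files)},
        "bin_size": study.config.bin_size,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def load_fixture_bundle(bundle_dir):
    """Re-read a fixture bundle through the core readers.

    Returns (study, samples) with tracks rebinned on the manifest's grid.
    Truth tables are reloaded for evaluation use.
    """
    from .core import (read_chrom_sizes, read_gene_annotation, read_loops,
                       read_peaks, read_signal_track)

    bundle_dir = Path(bundle_dir)
    with open(bundle_dir / "manifest.json") as fh:
        manifest = json.load(fh)
    config = SimConfig.from_dict(manifest["config"])
    layout = read_chrom_sizes(bundle_dir / "genome.chrom.sizes")
    genes = read_gene_annotation(bundle_dir / "genes.gtf", layout)
    pol3 = read_peaks(bundle_dir / "pol3_peaks.bed", factor="Pol III")
    pol2 = read_peaks(bundle_dir / "pol2_peaks.bed", factor="Pol II")
    loops = read_loops(bundle_dir / "loops.bedpe")
    ncrna = []
    with open(bundle_dir / "ncrna.bed") as fh:
        for line in fh:
            f = line.split("\t")
            ncrna.append((f[0], int(f[1]), int(f[2]), f[3].strip()))

    spike_df = pd.read_csv(bundle_dir / "spike_in_counts.tsv", sep="\t")
    spike = dict(zip(spike_df["sample"], spike_df["spike_in_reads"]))
    params = pd.read_csv(bundle_dir / "truth_genes.tsv", sep="\t",
                         index_col="gene_id")
    mech = {g: m for g, m in params["mechanism"].fillna("").items() if m}
    labels = dict(params["label"])
    smp_df = pd.read_csv(bundle_dir / "truth_samples.tsv", sep="\t")
    truth = SimTruth(
        labels=labels, mechanism=mech, peak_target={},
        scale_factors=dict(zip(smp_df["sample"], smp_df["true_scale_factor"])),
        efficiency=dict(zip(smp_df["sample"], smp_df["efficiency"])),
        params=params.drop(columns=["mechanism"]),
    )
    study = SyntheticStudy(config=config, layout=layout, genes=genes,
                           pol3_peaks=pol3, pol2_peaks=pol2, loops=loops,
                           ncrna=ncrna, truth=truth)
    samples = []
    bs = manifest["bin_size"]
    for name, files in manifest["samples"].items():
        condition, rep = name.rsplit("_r", 1)
        tracks = {}
        for key, fname in files.items():
            strand = {"pro_plus": "+", "pro_minus": "-"}.get(key, ".")
            t = read_signal_track(bundle_dir / fname, layout, bs, strand=strand)
            t.spike_in_reads = spike[name]
            tracks[key] = t
        samples.append(SampleSignals(sample=name, condition=condition,
                                     replicate=int(rep),
                                     spike_in_reads=spike[name], **tracks))
    return study, samples
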