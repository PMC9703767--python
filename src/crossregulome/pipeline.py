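"""End-to-end study analysis: quant → differential → targets → mechanisms.

`analyze_study` runs the whole inference in memory on a simulated (or
loaded) study; `run_pipeline` is the file-based orchestrator behind the
command-line interface, reading a fixture bundle and writing tables, a
summary JSON and a log into a run directory.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diff as diffmod
from . import mechanisms as mechmod
from . import quant as quantmod
from . import targets as targetmod
from .core import SignalTrack
from .simulate import (SampleSignals, SimConfig, SyntheticStudy,
                       load_fixture_bundle, simulate_all_samples,
                       simulate_study)

__all__ = ["PipelineConfig", "StudyResult", "analyze_study", "run_pipeline",
           "pooled_condition_tracks"]

SCHEMA_VERSION = 1


@dataclass(frozen=True)
class PipelineConfig:
    """Run-level paths and thresholds (the numeric knobs of the analysis)."""

    bundle: str
    out: str
    fdr: float = 0.05
    fc_genes: float = 1.0        # gene-body rule is FDR-only by default
    fc_peaks: float = 2.0
    active_density: float = 0.04
    window: int = 100_000
    alpha: float = 0.05
    unchanged_lfc: float = 0.1
    min_total: int = 5
    seed: int = 0

    def __post_init__(self):
        for name in ("fdr", "fc_genes", "fc_peaks", "active_density",
                     "alpha", "unchanged_lfc"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


@dataclass
class StudyResult:
    scale_factors: dict
    active_genes: set
    union_genes: set
    diff_pro: pd.DataFrame
    diff_chip: pd.DataFrame
    gene_sets: diffmod.GeneSets
    down_both: frozenset
    assignments: list
    scores: dict
    direction: targetmod.DirectionTestResult
    mech_assignments: list
    mech_summary: dict
    gene_metrics: pd.DataFrame   # per-gene PI and rate-proxy, both conditions

    def summary(self) -> dict:
        def ks(t):
            return None if t is None else {"D": t[0], "p": t[1]}

        planted_cols = self.gene_metrics.loc[
            list(self.gene_sets.genebody_up)] if len(self.gene_sets.genebody_up) \
            else self.gene_metrics.iloc[:0]
        return {
            "schema_version": SCHEMA_VERSION,
            "n_active": len(self.active_genes),
            "n_union": len(self.union_genes),
            "n_genebody_up": len(self.gene_sets.genebody_up),
            "n_genebody_unaffected": len(self.gene_sets.genebody_unaffected),
            "n_unchanged_control": len(self.gene_sets.unchanged_control),
            "n_down_both": len(self.down_both),
            "direction_call": self.direction.call,
            "ks_up": ks(self.direction.ks_up),
            "ks_down": ks(self.direction.ks_down),
            "mechanisms": {
                c: {"count": v["count"], "pct": v["pct"]}
                for c, v in self.mech_summary.items()
            },
            "median_pi_ratio_genebody_up": _safe_median(
                planted_cols["pi_ratio"]) if len(planted_cols) else None,
            "median_rate_ratio_change_genebody_up": _safe_median(
                planted_cols["rate_ratio_change"]) if len(planted_cols) else None,
        }


def _safe_median(series) -> float:
    vals = np.asarray(series, dtype=float)
    vals = vals[np.isfinite(vals)]
    return float(np.median(vals)) if vals.size else float("nan")


def pooled_condition_tracks(samples, scale_factors: dict, condition: str) -> dict:
    """Spike-scaled, replicate-pooled tracks for one condition."""
    subset = [s for s in samples if s.condition == condition]
    if not subset:
        raise ValueError(f"no samples for condition {condition!r}")
    pooled = {}
    for key in ("pro_plus", "pro_minus", "chip", "atac"):
        tracks = [getattr(s, key).scaled(scale_factors[s.sample])
                  for s in subset]
        base = tracks[0]
        data = {c: sum(t.data[c] for t in tracks) for c in base.data}
        pooled[key] = SignalTrack(bin_size=base.bin_size, data=data,
                                  strand=base.strand,
                                  normalization="spike_in",
                                  total_reads=sum(t.total_reads for t in tracks))
    return pooled


def analyze_study(study: SyntheticStudy, samples,
                  config: PipelineConfig | None = None,
                  log: logging.Logger | None = None) -> StudyResult:
    """Run the full inference on an in-memory study."""
    cfg = config or PipelineConfig(bundle="", out="")
    log = log or logging.getLogger("crossregulome")

    spike = {s.sample: s.spike_in_reads for s in samples}
    # reference sample: first untreated replicate
    ordered = sorted(spike, key=lambda n: (not n.startswith("untreated"), n))
    factors = quantmod.spike_in_scale_factors({n: spike[n] for n in ordered})
    log.info("stage=calibration factors=%s",
             {k: round(v, 4) for k, v in factors.items()})

    untr = pooled_condition_tracks(samples, factors, "untreated")
    depl = pooled_condition_tracks(samples, factors, "depleted")

    genes = study.genes
    active = quantmod.classify_active_genes(
        untr["pro_plus"], untr["pro_minus"], genes,
        min_body_density=cfg.active_density)
    union = quantmod.active_mrna_union(
        untr["pro_plus"], untr["pro_minus"], genes,
        min_body_density=cfg.active_density)
    union_genes = [g for g in genes if g.gene_id in union]
    log.info("stage=activity n_active=%d n_union=%d", len(active), len(union))

    conditions = {s.sample: s.condition for s in samples}
    pro_tracks = {s.sample: (s.pro_plus, s.pro_minus) for s in samples}
    chip_tracks = {s.sample: s.chip for s in samples}
    counts_pro = diffmod.build_count_matrix(
        pro_tracks, union_genes, conditions, factors, min_total=cfg.min_total)
    counts_chip = diffmod.build_count_matrix(
        chip_tracks, union_genes, conditions, factors, min_total=cfg.min_total)
    diff_pro = diffmod.differential_regions(
        counts_pro, fc_thresh=cfg.fc_genes, fdr_thresh=cfg.fdr)
    diff_chip = diffmod.differential_regions(
        counts_chip, fc_thresh=cfg.fc_genes, fdr_thresh=cfg.fdr)
    gene_sets = diffmod.define_gene_sets(diff_chip, diff_pro, union,
                                         unchanged_lfc=cfg.unchanged_lfc)
    shared = diff_pro.index.intersection(diff_chip.index)
    down_both = frozenset(
        g for g in shared
        if diff_pro.at[g, "status"] == "down" and diff_chip.at[g, "status"] == "down")
    log.info("stage=differential up=%d unaffected=%d control=%d down=%d",
             len(gene_sets.genebody_up), len(gene_sets.genebody_unaffected),
             len(gene_sets.unchanged_control), len(down_both))

    assignments = targetmod.assign_peaks_to_genes(
        study.pol3_peaks, study.loops, union_genes, max_dist=cfg.window)
    scores = targetmod.regulatory_potential(assignments, study.pol3_peaks)
    # reference set must contain scored genes; fall back from the strict
    # unchanged-control set to the broader unaffected set if needed
    unchanged = gene_sets.unchanged_control
    if not any(g in scores for g in unchanged):
        unchanged = gene_sets.genebody_unaffected
    if any(g in scores for g in unchanged):
        direction = targetmod.beta_direction_test(
            scores, gene_sets.genebody_up, down_both, unchanged, alpha=cfg.alpha)
    else:
        direction = targetmod.DirectionTestResult(ks_up=None, ks_down=None,
                                                  call="none")
    log.info("stage=targets n_assigned=%d call=%s", len(assignments),
             direction.call)

    up_records = [g for g in union_genes if g.gene_id in gene_sets.genebody_up]
    mech_assignments = mechmod.classify_mechanisms(
        up_records, study.pol3_peaks, study.pol2_peaks, study.loops,
        study.ncrna, window=cfg.window, loop_universe=union_genes)
    mech_summary = mechmod.summarize_mechanisms(
        mech_assignments, max(len(up_records), 1))
    log.info("stage=mechanisms %s",
             {c: v["count"] for c, v in mech_summary.items()})

    gene_metrics = _condition_metrics(untr, depl, union_genes)

    return StudyResult(
        scale_factors=factors, active_genes=active, union_genes=union,
        diff_pro=diff_pro, diff_chip=diff_chip, gene_sets=gene_sets,
        down_both=down_both, assignments=assignments, scores=scores,
        direction=direction, mech_assignments=mech_assignments,
        mech_summary=mech_summary, gene_metrics=gene_metrics)


def _condition_metrics(untr: dict, depl: dict, genes) -> pd.DataFrame:
    """Per-gene pausing index and rate proxy in each condition and their
    depleted/untreated ratios."""
    rows = []
    for g in genes:
        pi_u = quantmod.pausing_index(untr["pro_plus"], untr["pro_minus"], g)
        pi_d = quantmod.pausing_index(depl["pro_plus"], depl["pro_minus"], g)
        r_u = quantmod.transcription_rate_ratio(
            untr["pro_plus"], untr["pro_minus"], untr["chip"], g)
        r_d = quantmod.transcription_rate_ratio(
            depl["pro_plus"], depl["pro_minus"], depl["chip"], g)
        rows.append({
            "gene_id": g.gene_id,
            "pi_untreated": pi_u, "pi_depleted": pi_d,
            "pi_ratio": pi_d / pi_u if pi_u and np.isfinite(pi_u) and pi_u > 0 else np.nan,
            "rate_untreated": r_u, "rate_depleted": r_d,
            "rate_ratio_change": r_d / r_u if r_u and np.isfinite(r_u) and r_u > 0 else np.nan,
        })
    return pd.DataFrame(rows).set_index("gene_id")


# ---------------------------------------------------------------------------
# Truth-based evaluation (synthetic studies)


def evaluate_against_truth(result: StudyResult, study: SyntheticStudy) -> dict:
    """Sensitivity/precision of genebody-up recovery and mechanism accuracy
    on the planted genes."""
    truth = study.truth
    planted = set(truth.planted)
    called = set(result.gene_sets.genebody_up)
    tp = len(planted & called)
    sensitivity = tp / len(planted) if planted else float("nan")
    precision = tp / len(called) if called else float("nan")

    by_id = {g.gene_id: g for g in study.genes}
    # loop evidence must cover the evaluated genes themselves, regardless
    # of whether they survived the activity filter
    loop_universe = [g for g in study.genes
                     if g.gene_id in result.union_genes or g.gene_id in planted]
    planted_records = [by_id[g] for g in sorted(planted)]
    mech = mechmod.classify_mechanisms(
        planted_records, study.pol3_peaks, study.pol2_peaks, study.loops,
        study.ncrna, loop_universe=loop_universe)
    correct = sum(1 for a in mech if truth.mechanism.get(a.gene_id) == a.category)
    accuracy = correct / len(mech) if mech else float("nan")
    return {"sensitivity": sensitivity, "precision": precision,
            "mechanism_accuracy": accuracy, "n_planted": len(planted),
            "n_called": len(called), "true_positives": tp}


# ---------------------------------------------------------------------------
# File-based runner


def run_pipeline(config: PipelineConfig) -> Path:
    """Run the pipeline from a fixture bundle on disk.

    Writes differential tables, assignments, mechanism calls, a summary
    JSON (stable schema) and a log into ``config.out``; returns the run
    directory.  Any stage failure is logged with the stage name and
    re-raised.
    """
    bundle = Path(config.bundle)
    for required in ("manifest.json", "genes.gtf", "loops.bedpe"):
        if not (bundle / required).exists():
            raise FileNotFoundError(f"missing input file: {bundle / required}")
    outdir = Path(config.out)
    outdir.mkdir(parents=True, exist_ok=True)

    log = logging.getLogger("crossregulome.run")
    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    t0 = time.time()
    log.info("stage=load bundle=%s config=%s", bundle,
             dataclasses.asdict(config))
    try:
        study, samples = load_fixture_bundle(bundle)
        result = analyze_study(study, samples, config, log=log)
    except Exception as exc:  # pragma: no cover - error path
        log.error("pipeline failed: %s", exc)
        handler.close()
        raise

    result.diff_pro.to_csv(outdir / "diff_pro.tsv", sep="\t")
    result.diff_chip.to_csv(outdir / "diff_chip.tsv", sep="\t")
    pd.DataFrame([dataclasses.asdict(a) for a in result.assignments]
                 ).to_csv(outdir / "assignments.tsv", sep="\t", index=False)
    pd.DataFrame(sorted(result.scores.items()),
                 columns=["gene_id", "score"]
                 ).to_csv(outdir / "regulatory_scores.tsv", sep="\t", index=False)
    pd.DataFrame([{"gene_id": a.gene_id, "category": a.category,
                   "evidence": ";".join(a.evidence)}
                  for a in result.mech_assignments]
                 ).to_csv(outdir / "mechanisms.tsv", sep="\t", index=False)
    result.gene_metrics.to_csv(outdir / "gene_metrics.tsv", sep="\t")
    summary = result.summary()
    if hasattr(study.truth, "labels") and study.truth.labels:
        summary["evaluation"] = evaluate_against_truth(result, study)
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    log.info("stage=done elapsed=%.1fs", time.time() - t0)
    handler.close()
    log.removeHandler(handler)
    return outdir
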