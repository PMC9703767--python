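"""Differential polymerase-interactome calls from ChIP-MS tables.

DDA route: per-condition PSM counts are normalized to the bait subunit
(POLR2A by default, since it is the immunoprecipitation target) and the
treated/untreated ratio is thresholded at 0.8 / 1.2.  DIA route: protein
abundance is log2 of the summed top-3 unique-peptide intensities, and the
fold change on mean abundances (linear scale) is thresholded at 1.2.  With
two replicates the fold-change rule is primary; the rank-sum p-value is
advisory only.  Contamination filtering removes non-nuclear proteins and
proteins whose IgG or Input signal reaches the IP signal.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .diff import rank_sum_test

__all__ = ["dda_differential", "dia_abundance", "dia_abundance_table",
           "filter_contaminants", "dia_differential", "consensus_calls"]


def dda_differential(table: pd.DataFrame, treated_col: str, untreated_col: str,
                     reference: str = "POLR2A",
                     low: float = 0.8, high: float = 1.2) -> pd.DataFrame:
    """Classify proteins by bait-normalized PSM ratio.

    ``table`` is indexed by protein id with per-condition PSM columns.
    ratio = (PSM_t / PSM_ref,t) / (PSM_u / PSM_ref,u); < ``low`` is
    decreased, > ``high`` increased, else unchanged.  Proteins absent in
    the untreated condition have an undefined ratio and are reported with
    call "undefined" rather than classified.
    """
    if reference not in table.index:
        raise ValueError(f"reference protein {reference!r} missing from table")
    ref_t = table.at[reference, treated_col]
    ref_u = table.at[reference, untreated_col]
    if ref_t <= 0 or ref_u <= 0:
        raise ValueError(f"{reference} PSM must be > 0 in both conditions")
    norm_t = table[treated_col] / ref_t
    norm_u = table[untreated_col] / ref_u
    ratio = np.where(norm_u > 0, norm_t / np.where(norm_u > 0, norm_u, 1.0),
                     np.nan)
    call = np.where(np.isnan(ratio), "undefined",
                    np.where(ratio < low, "decreased",
                             np.where(ratio > high, "increased", "unchanged")))
    return pd.DataFrame({"ratio": ratio, "call": call}, index=table.index)


def dia_abundance(peptide_intensities) -> float:
    """log2 of the sum of the 3 largest unique-peptide intensities
    (all of them if fewer than 3).  NaN when the total is zero."""
    vals = sorted((float(v) for v in peptide_intensities), reverse=True)
    top = sum(vals[:3])
    if top <= 0:
        return float("nan")
    return float(np.log2(top))


def dia_abundance_table(peptides: pd.DataFrame, sample_cols) -> pd.DataFrame:
    """Per-protein top-3 abundances from a long peptide table.

    ``peptides`` has a ``protein_id`` column and one intensity column per
    sample; returns protein x sample log2 top-3 abundances.
    """
    out = {}
    for col in sample_cols:
        out[col] = peptides.groupby("protein_id")[col].apply(
            lambda v: dia_abundance(v.to_numpy()))
    return pd.DataFrame(out)


def filter_contaminants(table: pd.DataFrame, sample_cols,
                        igg_col: str = "IgG", input_col: str = "Input",
                        localization_col: str = "localization") -> pd.DataFrame:
    """Drop non-nuclear proteins and IgG/Input-dominated proteins.

    A protein is removed when its IgG or Input signal is >= its mean IP
    signal across ``sample_cols``.
    """
    keep = pd.Series(True, index=table.index)
    if localization_col in table.columns:
        keep &= table[localization_col] == "nuclear"
    sample_mean = table[list(sample_cols)].mean(axis=1)
    if igg_col in table.columns:
        keep &= table[igg_col] < sample_mean
    if input_col in table.columns:
        keep &= table[input_col] < sample_mean
    return table.loc[keep]


def dia_differential(abundances: pd.DataFrame, treated_cols, untreated_cols,
                     fc_thresh: float = 1.2) -> pd.DataFrame:
    """Fold-change calls on DIA top-3 abundances.

    Fold change is computed on mean linear-scale abundances (2**log2
    values); |FC| > ``fc_thresh`` in either direction flags the protein.
    The rank-sum p across replicate abundances is reported as advisory.
    """
    treated_cols, untreated_cols = list(treated_cols), list(untreated_cols)
    for cols, label in ((treated_cols, "treated"), (untreated_cols, "untreated")):
        if not cols:
            raise ValueError(f"missing {label} replicate columns")
    lin_t = np.power(2.0, abundances[treated_cols])
    lin_u = np.power(2.0, abundances[untreated_cols])
    fc = lin_t.mean(axis=1) / lin_u.mean(axis=1)
    rows = []
    for pid in abundances.index:
        x = abundances.loc[pid, treated_cols].to_numpy(dtype=float)
        y = abundances.loc[pid, untreated_cols].to_numpy(dtype=float)
        if np.isnan(x).any() or np.isnan(y).any():
            rows.append(np.nan)
            continue
        rows.append(rank_sum_test(x, y)[1])
    sig = (fc > fc_thresh) | (fc < 1.0 / fc_thresh)
    call = np.where(~sig, "unchanged",
                    np.where(fc > 1, "increased", "decreased"))
    return pd.DataFrame({
        "fold_change": fc, "log2FC": np.log2(fc), "p_advisory": rows,
        "call": call,
    }, index=abundances.index)


def consensus_calls(dda: pd.DataFrame, dia: pd.DataFrame) -> pd.DataFrame:
    """Proteins called in the same direction by both DDA and DIA."""
    shared = dda.index.intersection(dia.index)
    agree = [p for p in shared
             if dda.at[p, "call"] == dia.at[p, "call"]
             and dda.at[p, "call"] in ("increased", "decreased")]
    return pd.DataFrame({
        "call": [dda.at[p, "call"] for p in agree],
        "dda_ratio": [dda.at[p, "ratio"] for p in agree],
        "dia_fold_change": [dia.at[p, "fold_change"] for p in agree],
    }, index=pd.Index(agree, name="protein_id"))
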