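"""Fold change, Student's t-test, variance-coverage threshold, target calls.

After normalization, a stabilized target shows a higher soluble
abundance in the treated channels.  Per protein the pipeline computes
the geometric-mean fold change (2 to the difference of mean log2
intensities — the scale the t-test lives on) and a classic
pooled-variance two-sided Student's t-test of treated vs control log2
intensities.  The linear-FC cutoff is chosen from the variance-coverage
curve: the smallest observed FC at which the empirical coverage of the
FC distribution reaches the requested fraction (88% by default).
Proteins with p < alpha and FC strictly above the cutoff are called
targets; only stabilization (FC above 1) is ever flagged, since ligand
binding raises thermal stability.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .quant import ProteinQuantTable


@dataclass(frozen=True)
class ThresholdSelection:
    """The variance-coverage curve and the FC cutoff read from it.

    ``curve`` columns: threshold (candidate FC), coverage (fraction of
    proteins with FC <= threshold), variance (sample variance of log2FC
    among those proteins, 0 when fewer than 2).
    """

    coverage_param: float
    fc_threshold: float
    curve: pd.DataFrame


def compute_group_stats(table: ProteinQuantTable) -> pd.DataFrame:
    """Per-protein fc, log2fc, t_stat, p_value (flags not yet set).

    Requires a normalized, strictly positive, missing-free table with at
    least two replicates per condition.  log2fc is the difference of
    group means on the log2 scale; the t-test is pooled-variance
    (classic Student), two-sided, on the same log2 values.  A protein
    with zero pooled variance and equal group means gets t = 0, p = 1.
    """
    design = table.design
    for cond in ("control", "treated"):
        if len(design.labels_for(cond)) < 2:
            raise ValueError(f"need >= 2 {cond} channels for a t-test")
    mat = table.abundance_matrix()
    if np.isnan(mat).any() or (mat <= 0).any():
        raise ValueError("group stats require strictly positive, missing-free abundances")

    log2 = np.log2(mat)
    ctrl_idx = [design.labels.index(l) for l in design.control_labels]
    trt_idx = [design.labels.index(l) for l in design.treated_labels]
    ctrl, trt = log2[:, ctrl_idx], log2[:, trt_idx]

    log2fc = trt.mean(axis=1) - ctrl.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # constant rows
        t_stat, p_value = stats.ttest_ind(trt, ctrl, axis=1, equal_var=True)
    # degenerate rows: zero pooled variance
    degenerate = ~np.isfinite(t_stat)
    equal_means = np.isclose(log2fc, 0.0)
    with np.errstate(invalid="ignore"):
        t_stat = np.where(degenerate & equal_means, 0.0, t_stat)
        p_value = np.where(degenerate & equal_means, 1.0, p_value)
        t_stat = np.where(degenerate & ~equal_means, np.sign(log2fc) * np.inf, t_stat)
        p_value = np.where(degenerate & ~equal_means, 0.0, p_value)

    return pd.DataFrame(
        {
            "accession": table.data["accession"].to_numpy(),
            "gene_symbol": table.data["gene_symbol"].to_numpy(),
            "fc": 2.0**log2fc,
            "log2fc": log2fc,
            "t_stat": t_stat,
            "p_value": p_value,
        }
    )


def variance_coverage_curve(fcs: np.ndarray | pd.Series) -> pd.DataFrame:
    """Coverage and cumulative log2FC variance at every observed FC value.

    Candidates are the sorted unique FCs.  coverage(t) = #{fc <= t}/n;
    variance(t) = sample variance (ddof=1) of log2(fc) over {fc <= t},
    zero with fewer than two members.  Coverage is non-decreasing in t
    by construction.
    """
    fcs = np.asarray(fcs, dtype=float)
    if fcs.size == 0:
        raise ValueError("need at least one fold change")
    if (fcs <= 0).any():
        raise ValueError("fold changes must be positive")
    order = np.sort(fcs)
    log2_sorted = np.log2(order)
    candidates, last_idx = np.unique(order, return_index=True)
    # index of the last element <= each candidate
    counts = np.searchsorted(order, candidates, side="right")
    coverage = counts / fcs.size
    variances = np.empty_like(candidates)
    csum = np.cumsum(log2_sorted)
    csum2 = np.cumsum(log2_sorted**2)
    for i, c in enumerate(counts):
        if c < 2:
            variances[i] = 0.0
        else:
            mean = csum[c - 1] / c
            variances[i] = max(0.0, (csum2[c - 1] - c * mean**2) / (c - 1))
    return pd.DataFrame({"threshold": candidates, "coverage": coverage, "variance": variances})


def select_fc_threshold(
    curve: pd.DataFrame,
    coverage_param: float = 0.88,
    round_to: float | None = None,
) -> float:
    """Smallest candidate FC whose coverage reaches ``coverage_param``.

    Equals the ceil(coverage_param * n)-th order statistic of the FC
    sample.  ``round_to`` optionally rounds the result to a grid (e.g.
    0.1) for reporting.
    """
    if not 0 < coverage_param <= 1:
        raise ValueError("coverage_param must be in (0, 1]")
    ok = curve.loc[curve["coverage"] >= coverage_param, "threshold"]
    if ok.empty:  # cannot happen: the largest candidate has coverage 1
        raise ValueError("no candidate reaches the requested coverage")
    t = float(ok.iloc[0])
    if round_to is not None:
        t = round(t / round_to) * round_to
    return t


def select_threshold_from_stats(
    stats_df: pd.DataFrame, coverage_param: float = 0.88, round_to: float | None = None
) -> ThresholdSelection:
    curve = variance_coverage_curve(stats_df["fc"].to_numpy())
    thr = select_fc_threshold(curve, coverage_param, round_to)
    return ThresholdSelection(coverage_param, thr, curve)


def call_targets(
    stats_df: pd.DataFrame,
    fc_threshold: float = 1.3,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Flag targets: p_value < alpha AND fc > fc_threshold, both strict.

    Returns the stats table with an ``is_target`` column plus the
    summary counts.  Destabilized proteins (FC < 1) are never flagged.
    """
    out = stats_df.copy()
    out["is_target"] = (out["p_value"] < alpha) & (out["fc"] > fc_threshold)
    summary = {"n_tested": int(len(out)), "n_targets": int(out["is_target"].sum())}
    return out, summary
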