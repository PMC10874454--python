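"""Integrator-gene screen on bulk RNA-seq count matrices.

An integrator gene changes expression at a rate proportional to the
signaling level, so its level reflects the time integral of signaling.
Candidates are found by combining two datasets: a time series after BMP
treatment (which classes genes into continuously decreasing, immediately
increasing, and delayed increasing) and a dose-response series at 5 h
(which selects genes whose immediate response is both proportional to
the SMAD4 level — correlation above 0.9 — and strong — slope above 0.1
when normalized to the gene's time-series maximum). Intersecting
immediate dose-responsive genes with the temporal classes, restricted to
transcription factors, yields the immediately-decreasing (SOX2-like) and
immediately-increasing (GATA3/TFAP2C-like) candidate integrators.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import linregress

logger = logging.getLogger(__name__)

__all__ = [
    "cpm",
    "filter_expressed",
    "cumulative_log2fc",
    "filter_dynamic",
    "max_normalize",
    "cluster_timecourses",
    "dose_response_screen",
    "integrator_candidates",
]

CLASS_LABELS = ("decreasing", "immediate_up", "delayed_up")


def cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts per million: each sample scaled to a library size of 1e6."""
    lib = counts.sum(axis=0)
    if (lib <= 0).any():
        raise ValueError("zero library size")
    return counts / lib * 1e6


def filter_expressed(cpm_matrix: pd.DataFrame, min_mean: float = 2.5) -> pd.Index:
    """Genes with mean CPM across all samples at or above ``min_mean``."""
    keep = cpm_matrix.index[cpm_matrix.mean(axis=1) >= min_mean]
    if len(keep) == 0:
        logger.warning("expression filter removed every gene")
    return keep


def cumulative_log2fc(cpm_matrix: pd.DataFrame, t0=None, pseudocount: float = 0.5) -> pd.Series:
    """Per-gene cumulative |log2 fold change| vs t=0 over all later samples."""
    cols = list(cpm_matrix.columns)
    if t0 is None:
        t0 = min(cols)
    ref = cpm_matrix[t0] + pseudocount
    stat = sum(
        (np.log2(cpm_matrix[c] + pseudocount) - np.log2(ref)).abs()
        for c in cols if c != t0
    )
    return stat.rename("cum_abs_log2fc")


def filter_dynamic(cpm_matrix: pd.DataFrame, sd_multiplier: float = 1.0,
                   threshold: float | None = None):
    """Genes with large cumulative expression change over the time series.

    The statistic is the cumulative |log2FC| relative to t=0
    (pseudocount 0.5). By default the threshold is mean + sd_multiplier
    standard deviations of that statistic across genes; an explicit
    ``threshold`` (e.g. 1.55) overrides the automatic rule. Returns
    (gene index, realized threshold).
    """
    if cpm_matrix.shape[1] < 3:
        raise ValueError("need at least 3 timepoints")
    stat = cumulative_log2fc(cpm_matrix)
    if threshold is None:
        threshold = float(stat.mean() + sd_multiplier * stat.std(ddof=0))
    return cpm_matrix.index[stat > threshold], threshold


def max_normalize(cpm_matrix: pd.DataFrame) -> pd.DataFrame:
    """Scale each gene's profile to its maximum over the time series."""
    return cpm_matrix.div(cpm_matrix.max(axis=1), axis=0)


def _label_profile(mean: np.ndarray, t: np.ndarray) -> str:
    """Kinetic labeling of a max-normalized mean profile.

    Decreasing: the profile falls overall. Rising clusters split by
    half-rise time: before a quarter of the time span = immediate, later
    = delayed.
    """
    if mean[-1] < mean[0]:
        return "decreasing"
    half = mean[0] + 0.5 * (mean.max() - mean[0])
    above = np.nonzero(mean >= half)[0]
    t_half = t[above[0]] if above.size else t[-1]
    quarter_span = t[0] + 0.25 * (t[-1] - t[0])
    return "immediate_up" if t_half <= quarter_span else "delayed_up"


def cluster_timecourses(filtered_cpm: pd.DataFrame, k: int = 3, seed: int = 0) -> pd.Series:
    """Ward/Euclidean clustering of max-normalized profiles into 3 classes.

    The dendrogram is cut at ``k`` clusters; each cluster is labeled from
    the kinetics of its mean profile (continuously decreasing /
    early-rising / late-rising).
    """
    if len(filtered_cpm) < 3:
        raise ValueError("need at least 3 genes to cluster")
    X = max_normalize(filtered_cpm).to_numpy(dtype=float)
    Z = linkage(X, method="ward", metric="euclidean")
    raw = fcluster(Z, t=k, criterion="maxclust")
    t = np.asarray(filtered_cpm.columns, dtype=float)
    labels = {c: _label_profile(X[raw == c].mean(axis=0), t) for c in np.unique(raw)}
    return pd.Series([labels[c] for c in raw], index=filtered_cpm.index, name="class")


def dose_response_screen(dose_cpm: pd.DataFrame, smad4_levels=None,
                         timeseries_max: pd.Series | None = None,
                         corr_min: float = 0.9, slope_min: float = 0.1) -> pd.DataFrame:
    """Genes responding proportionally and strongly to SMAD4 level at 5 h.

    Per gene, the Pearson correlation of expression with the SMAD4 level
    and the OLS slope normalized to the gene's time-series maximum (its
    own dose-series maximum if no time series is supplied). Keeps genes
    with |corr| > corr_min and |normalized slope| > slope_min; the slope
    sign distinguishes immediately-increasing from immediately-decreasing
    responders. Zero-variance genes are skipped.
    """
    levels = np.asarray(smad4_levels if smad4_levels is not None else dose_cpm.columns,
                        dtype=float)
    if len(levels) < 4:
        raise ValueError("need at least 4 dose levels")
    rows = []
    for gene, expr in dose_cpm.iterrows():
        y = expr.to_numpy(dtype=float)
        if np.std(y) == 0:
            continue
        fit = linregress(levels, y)
        norm = timeseries_max[gene] if timeseries_max is not None else y.max()
        if norm <= 0:
            continue
        rows.append((gene, fit.rvalue, fit.slope / norm))
    out = pd.DataFrame(rows, columns=["gene", "corr", "norm_slope"]).set_index("gene")
    out["hit"] = (out["corr"].abs() > corr_min) & (out["norm_slope"].abs() > slope_min)
    return out


def integrator_candidates(classes: pd.Series, screen: pd.DataFrame,
                          tf_flags: pd.Series) -> dict:
    """Intersect temporal classes with dose-screen hits, restricted to TFs.

    Immediately-decreasing candidates: decreasing class, negative-slope
    hit, TF. Immediately-increasing candidates: immediate_up class,
    positive-slope hit, TF.
    """
    hits = screen[screen["hit"]]
    down_hits = set(hits.index[hits["norm_slope"] < 0])
    up_hits = set(hits.index[hits["norm_slope"] > 0])
    tfs = set(tf_flags.index[tf_flags.astype(bool)])
    decreasing = set(classes.index[classes == "decreasing"])
    immediate = set(classes.index[classes == "immediate_up"])
    return {
        "immediate_down": sorted(decreasing & down_hits & tfs),
        "immediate_up": sorted(immediate & up_hits & tfs),
    }
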