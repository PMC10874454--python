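"""Fate calling from immunofluorescence marker intensities.

Cells stained for seven transcription factors (ISL1, GATA3, TFAP2C,
HAND1 marking amnion-like fate; SOX2, NANOG, OCT4 marking pluripotency)
are assigned a discrete fate by a two-component Gaussian mixture in
log-normalized 7-marker space, and a continuous fate score, the log
expression ratio log(ISL1/NANOG), which best separates the two fates.
Cells with score > 0 are amnion-like; the score is scale invariant, so
global illumination changes cancel.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

from .synthgen import DEFAULT_MARKERS

__all__ = [
    "marker_matrix",
    "normalize_markers",
    "cluster_fates",
    "separation_statistic",
    "rank_markers",
    "fate_score",
]


def marker_matrix(table: pd.DataFrame, markers=None) -> pd.DataFrame:
    """Extract raw marker intensity columns from a fate table."""
    if markers is None:
        markers = [m for m in DEFAULT_MARKERS if m in table.columns]
        if not markers:
            markers = [c for c in table.columns if table[c].dtype.kind in "fi"]
    return table[list(markers)]


def normalize_markers(raw: pd.DataFrame, pseudo: float = 0.0, method: str = "zscore") -> pd.DataFrame:
    """Natural-log transform then per-marker normalization.

    ``method='zscore'`` (default) standardizes each marker; ``'minmax'``
    rescales each to [0, 1]. A pseudo-offset guards zero intensities.
    Raw log values are what ratio scores use; this normalized form is for
    clustering and graph building.
    """
    arr = raw.to_numpy(dtype=float) + pseudo
    if (arr <= 0).any():
        raise ValueError("intensities must be positive (use a pseudo-offset for zeros)")
    logged = np.log(arr)
    if method == "zscore":
        sd = logged.std(axis=0)
        sd[sd == 0] = 1.0  # constant marker -> all-zero z-scores
        out = (logged - logged.mean(axis=0)) / sd
    elif method == "minmax":
        rng = logged.max(axis=0) - logged.min(axis=0)
        rng[rng == 0] = 1.0
        out = (logged - logged.min(axis=0)) / rng
    else:
        raise ValueError(f"unknown normalization method {method!r}")
    return pd.DataFrame(out, index=raw.index, columns=raw.columns)


def cluster_fates(table: pd.DataFrame, seed: int = 0, n_init: int = 5) -> pd.Series:
    """Two-component full-covariance GMM fate clustering.

    Fits the mixture to log-normalized 7-marker data; the component with
    the higher mean (normalized) ISL1 is labeled ``amnion``, the other
    ``pluripotent``, which fixes the label-swap ambiguity. Deterministic
    given the seed (k-means++ initialization with ``n_init`` restarts).
    """
    raw = marker_matrix(table)
    if len(raw) < 20:
        raise ValueError("need at least 20 cells to cluster fates")
    X = normalize_markers(raw).to_numpy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        gmm = GaussianMixture(n_components=2, covariance_type="full",
                              n_init=n_init, random_state=seed, reg_covar=1e-6)
        comp = gmm.fit_predict(X)
    isl1_col = list(raw.columns).index("ISL1")
    amnion_comp = int(np.argmax(gmm.means_[:, isl1_col]))
    labels = np.where(comp == amnion_comp, "amnion", "pluripotent")
    return pd.Series(labels, index=table.index, name="fate_label")


def separation_statistic(values, labels) -> float:
    """Cluster separation: |mean difference| over the sum of the SDs.

    Ranks markers by how well they separate the two fate clusters. A zero
    summed SD (both groups constant) gives +inf.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if len(groups) != 2:
        raise ValueError("separation statistic requires exactly two classes, both nonempty")
    a, b = (values[labels == g] for g in groups)
    denom = a.std() + b.std()
    if denom == 0:
        return float("inf")
    return float(abs(a.mean() - b.mean()) / denom)


def rank_markers(table: pd.DataFrame, labels) -> pd.Series:
    """Separation statistic of each marker's log intensity, descending."""
    raw = marker_matrix(table)
    sep = {m: separation_statistic(np.log(raw[m]), labels) for m in raw.columns}
    return pd.Series(sep, name="separation").sort_values(ascending=False)


def fate_score(table: pd.DataFrame, pair=("ISL1", "NANOG"), threshold: float = 0.0) -> pd.DataFrame:
    """Continuous fate score log(ISL1/NANOG) and its thresholded label.

    Computed as the difference of raw log intensities, so the score is
    invariant to global intensity scaling. Cells strictly above the
    threshold (default 0) are amnion-like; the boundary goes to
    pluripotent. An alternative pair such as ("ISL1", "SOX2") can be
    used when NANOG is perturbed (e.g. under TGF-beta receptor
    inhibition).
    """
    num, den = pair
    for m in pair:
        if m not in table.columns:
            raise ValueError(f"marker {m!r} missing from table")
    score = np.log(table[num].to_numpy(dtype=float)) - np.log(table[den].to_numpy(dtype=float))
    label = np.where(score > threshold, "amnion", "pluripotent")
    return pd.DataFrame({"fate_score": score, "fate_label": label}, index=table.index)
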