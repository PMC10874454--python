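"""Micropattern colony analyses.

Circular micropatterned colonies self-organize concentric fate rings
under BMP4; because the system is approximately rotationally symmetric,
cells are pooled into 30 bins of equal cell count by distance to the
colony edge, and every spatial statistic (kymograph rows, signaling
clusters, fate maps, dose-response curves) is computed per bin with the
median as the bin summary.

The module also hosts the level/duration threshold analysis: a logistic
fit to a differentiated-fraction curve defines the threshold of any
signaling feature as its 50% crossing, and the collapse test asks
whether conditions that differ in signaling level or duration share a
single threshold once mapped onto the integral axis — the signature of
integral-controlled differentiation, versus separate level and duration
thresholds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.special import expit

logger = logging.getLogger(__name__)

__all__ = [
    "RadialBinning",
    "radial_bin",
    "kymograph",
    "soft_kmeans",
    "cluster_radial_histories",
    "fate_map",
    "DoseResponseCurve",
    "threshold_from_dose_response",
    "collapse_test",
    "simulate_level_duration_conditions",
]


@dataclass
class RadialBinning:
    """Equal-count binning by distance to the colony edge (bin 0 = edge)."""

    bin_of: pd.Series  # cell_id -> bin index
    edges: np.ndarray  # per-bin (min, max) edge distance, shape (n_bins, 2)

    @property
    def n_bins(self) -> int:
        return len(self.edges)


def radial_bin(positions: pd.DataFrame, colony_radius: float, n_bins: int = 30) -> RadialBinning:
    """Assign each cell to one of ``n_bins`` equal-count edge-distance bins.

    ``positions`` needs either an ``edge_dist`` column or x/y (edge
    distance is then radius - distance to center). Bin 0 is the
    outermost. Counts are equal up to +-1. Degenerate geometries where
    many cells share one radius are flagged with a warning (quantile bins
    then carry duplicate boundaries).
    """
    if len(positions) < n_bins:
        raise ValueError("fewer cells than bins")
    if "edge_dist" in positions.columns:
        ed = positions["edge_dist"].to_numpy(dtype=float)
    else:
        r = np.hypot(positions["x"].to_numpy(dtype=float), positions["y"].to_numpy(dtype=float))
        ed = colony_radius - r
    if np.unique(ed).size < n_bins:
        logger.warning("degenerate radial geometry: %d distinct edge distances for %d bins",
                       np.unique(ed).size, n_bins)
    order = np.argsort(ed, kind="stable")
    splits = np.array_split(order, n_bins)
    bins = np.empty(len(ed), dtype=int)
    edges = np.empty((n_bins, 2))
    for k, idx in enumerate(splits):
        bins[idx] = k
        edges[k] = (ed[idx].min(), ed[idx].max()) if len(idx) else (np.nan, np.nan)
    return RadialBinning(bin_of=pd.Series(bins, index=positions.index, name="bin"), edges=edges)


def kymograph(histories: pd.DataFrame, binning: RadialBinning) -> pd.DataFrame:
    """Bins x timepoints matrix of per-bin median signaling.

    For replicate colonies, compute one kymograph per colony and average
    the matrices afterwards.
    """
    joined = histories.groupby(binning.bin_of).median()
    joined.index.name = "bin"
    return joined


def soft_kmeans(X: np.ndarray, k: int, m: float = 2.0, restarts: int = 10,
                seed: int = 0, max_iter: int = 300, tol: float = 1e-9):
    """Fuzzy c-means with fuzzifier ``m``; returns (memberships, centroids).

    Memberships sum to 1 per row. Restarts with different centroid
    initializations; the run with the lowest objective wins, so results
    are deterministic given the seed.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k == 1:
        return np.ones((n, 1)), X.mean(axis=0, keepdims=True)
    rng = np.random.default_rng(seed)
    best = None
    power = 2.0 / (m - 1.0)
    for _ in range(restarts):
        centroids = X[rng.choice(n, size=k, replace=False)]
        for _ in range(max_iter):
            d2 = ((X[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=-1)
            d2 = np.maximum(d2, 1e-300)
            u = 1.0 / (d2 ** (power / 2.0) * (1.0 / d2 ** (power / 2.0)).sum(axis=1, keepdims=True))
            um = u**m
            new_c = (um.T @ X) / um.sum(axis=0)[:, None]
            shift = np.abs(new_c - centroids).max()
            centroids = new_c
            if shift < tol:
                break
        d2 = np.maximum(((X[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=-1), 1e-300)
        obj = float((u**m * d2).sum())
        if best is None or obj < best[0]:
            best = (obj, u.copy(), centroids.copy())
    _, u, centroids = best
    # stable cluster order: by time of first centroid half-drop is overkill;
    # order by descending centroid mean so cluster 0 = highest signaling
    order = np.argsort(-centroids.mean(axis=1), kind="stable")
    return u[:, order], centroids[order]


def cluster_radial_histories(radial_histories: pd.DataFrame, k: int = 3, m: float = 2.0,
                             restarts: int = 10, seed: int = 0,
                             manual_overrides: dict | None = None):
    """Soft k-means clustering of radially averaged signaling histories.

    Rows are radial bins (e.g. a kymograph); returns the membership
    matrix and the dominant cluster per bin. ``manual_overrides`` maps a
    bin index to a cluster label and implements the manual reassignment
    used when a cluster (the "elbow") has no objectively correct
    assignment. If the hardened assignment leaves a cluster empty, or two
    centroids nearly coincide (duplicated cluster), a warning is logged.
    """
    X = radial_histories.to_numpy(dtype=float)
    if len(np.unique(X, axis=0)) < k:
        raise ValueError("need at least k distinct histories")
    u, centroids = soft_kmeans(X, k=k, m=m, restarts=restarts, seed=seed)
    dominant = u.argmax(axis=1)
    if manual_overrides:
        for b, c in manual_overrides.items():
            dominant[b] = c
    if len(np.unique(dominant)) < k:
        logger.warning("a cluster is empty after hardening")
    if k > 1:
        cd = np.sqrt(((centroids[:, None] - centroids[None, :]) ** 2).sum(-1))
        mind = cd[~np.eye(k, dtype=bool)].min()
        scale = np.sqrt(((X - X.mean(0)) ** 2).sum(-1)).mean()
        if scale > 0 and mind < 0.05 * scale:
            logger.warning("two cluster centroids nearly coincide (duplicated cluster)")
    memberships = pd.DataFrame(u, index=radial_histories.index,
                               columns=[f"cluster{c}" for c in range(u.shape[1])])
    return memberships, pd.Series(dominant, index=radial_histories.index, name="cluster")


def fate_map(fate_labels, binning: RadialBinning, replicates=None) -> pd.Series:
    """Dominant fate per radial bin, optionally averaged over colonies.

    ``replicates`` may give further (labels, binning) pairs; each colony
    is discretized to a per-bin modal fate first and bins then take the
    majority across colonies. Ties go to ``amnion``, the fate of the
    colony edge (documented tie-break).
    """

    def one(labels, b):
        lab = pd.Series(np.asarray(labels), index=b.bin_of.index)
        out = {}
        for k, sub in lab.groupby(b.bin_of):
            counts = sub.value_counts()
            top = counts[counts == counts.iloc[0]].index
            out[k] = "amnion" if "amnion" in top else top.sort_values()[0]
        return pd.Series(out, name="fate")

    maps = [one(fate_labels, binning)]
    for labels, b in replicates or []:
        maps.append(one(labels, b))
    stacked = pd.concat(maps, axis=1)
    result = {}
    for k, row in stacked.iterrows():
        counts = row.value_counts()
        top = counts[counts == counts.iloc[0]].index
        result[k] = "amnion" if "amnion" in top else top.sort_values()[0]
    return pd.Series(result, name="fate").sort_index()


# ---------------------------------------------------------------------------
# dose-response thresholds and the collapse test


@dataclass
class DoseResponseCurve:
    """Differentiated fraction versus one signaling feature.

    ``x`` are per-condition feature values (level, duration or integral),
    ``frac`` the differentiated fractions in [0, 1], ``sd`` optional
    replicate SDs. ``label`` names the experimental series (e.g. its
    signaling level), ``feature`` the axis.
    """

    x: np.ndarray
    frac: np.ndarray
    sd: np.ndarray | None = None
    label: str = ""
    feature: str = "integral"

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.frac = np.asarray(self.frac, dtype=float)
        if np.any((self.frac < 0) | (self.frac > 1)):
            raise ValueError("fractions must lie in [0, 1]")


def threshold_from_dose_response(curve: DoseResponseCurve):
    """Feature threshold at 50% differentiation from a logistic fit.

    Fits frac = logistic((x - x0)/w) by least squares and returns
    (x0, stderr) where the standard error comes from the fit covariance.
    Refuses to extrapolate: the observed fractions must straddle 50%.
    """
    x, f = curve.x, curve.frac
    if f.min() > 0.5 or f.max() < 0.5:
        raise ValueError("curve does not cross 50% differentiation; refusing to extrapolate")
    order = np.argsort(x)
    xs, fs = x[order], f[order]
    # two-point degenerate step: midpoint between the flanking feature values
    if len(xs) == 2:
        return 0.5 * (xs[0] + xs[1]), np.nan
    x0_init = float(np.interp(0.5, fs, xs)) if fs[0] < fs[-1] else float(np.interp(0.5, fs[::-1], xs[::-1]))
    w_init = max((xs[-1] - xs[0]) / 10.0, 1e-6)

    def model(x, x0, w):
        return expit((x - x0) / w)

    popt, pcov = curve_fit(model, xs, fs, p0=[x0_init, w_init], maxfev=20000)
    stderr = float(np.sqrt(pcov[0, 0])) if np.all(np.isfinite(pcov)) else np.nan
    return float(popt[0]), stderr


def collapse_test(curves: list[DoseResponseCurve]) -> dict:
    """Do conditions share one threshold on this feature axis?

    Fits a 50% threshold per curve and reports the per-condition
    thresholds and their coefficient of variation. A small CV (a few
    percent) on the integral axis, when the same conditions show large
    threshold shifts on the level or duration axis, is the signature of
    integral-controlled differentiation.
    """
    if len(curves) < 2:
        raise ValueError("collapse test needs at least 2 conditions")
    thresholds, labels = [], []
    for c in curves:
        thr, _ = threshold_from_dose_response(c)
        thresholds.append(thr)
        labels.append(c.label)
    thresholds = np.asarray(thresholds)
    cv = float(thresholds.std(ddof=0) / np.abs(thresholds.mean()))
    return {"thresholds": dict(zip(labels, thresholds)), "cv": cv,
            "feature": curves[0].feature}


def simulate_level_duration_conditions(levels, durations, n_cells: int = 200,
                                       rule: str = "integral",
                                       integral_threshold: float = 26.0,
                                       logistic_width: float = 1.0,
                                       level_threshold: float = 1.0,
                                       duration_threshold: float = 26.0,
                                       level_sd: float = 0.05, seed: int = 0):
    """Differentiated fractions for a grid of step signaling programs.

    Each condition holds signaling at a given level (baseline-subtracted
    N:C units) for a given duration then shuts down, so the per-cell
    integral is level x duration (cell-to-cell level spread
    ``level_sd``). Under ``rule='integral'`` cells differentiate with
    probability logistic((integral - integral_threshold)/width); under
    ``rule='level_duration'`` they differentiate when both the level and
    the duration exceed their separate thresholds (the classic
    morphogen-model alternative). Returns a DataFrame with one row per
    condition: level, duration, mean integral and differentiated
    fraction.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for lev in levels:
        for dur in durations:
            cell_levels = rng.normal(lev, level_sd, n_cells)
            sigma = cell_levels * dur
            if rule == "integral":
                p = expit((sigma - integral_threshold) / logistic_width)
            elif rule == "level_duration":
                p = (expit((cell_levels - level_threshold) / max(level_sd, 1e-6))
                     * expit((dur - duration_threshold) / 0.5))
            else:
                raise ValueError(f"unknown rule {rule!r}")
            diff = rng.random(n_cells) < p
            rows.append({"level": lev, "duration": dur, "integral": float(sigma.mean()),
                         "frac": float(diff.mean())})
    return pd.DataFrame(rows)
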