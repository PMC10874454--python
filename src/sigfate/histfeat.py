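"""Signaling-history feature extraction.

Converts raw nuclear/cytoplasmic intensity measurements into
nuclear:cytoplasmic (N:C) ratio signaling histories and reduces each
history to the four interpretable features of a descending sigmoid
response: the initial high plateau H, the final low plateau L, the
duration d (sigmoid midpoint time) and the baseline-subtracted time
integral of signaling. PCA of the history matrix provides the
complementary unbiased description; principal components are oriented so
their scores correlate nonnegatively with the integral.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from sklearn.decomposition import PCA

from .synthgen import sigmoid, sigmoid_integral

__all__ = [
    "nc_ratio",
    "SigmoidFit",
    "fit_sigmoid",
    "integral",
    "feature_table",
    "pca_histories",
    "feature_pc_correlation",
]

FEATURE_COLUMNS = ["H", "L", "d", "tau", "integral"]


def nc_ratio(nuclear, cytoplasmic, background=0.0, subtract_background=True):
    """Nuclear-to-cytoplasmic intensity ratio.

    Default is (nuc - bg) / (cyto - bg); with ``subtract_background=False``
    the plain nuc/cyto ratio is returned (appropriate when background
    subtraction is unreliable, e.g. dim reporters). A nonpositive
    denominator yields NaN rather than raising, so downstream code can
    treat the measurement as missing.
    """
    nuclear = np.asarray(nuclear, dtype=float)
    cytoplasmic = np.asarray(cytoplasmic, dtype=float)
    bg = background if subtract_background else 0.0
    denom = cytoplasmic - bg
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(denom > 0, (nuclear - bg) / denom, np.nan)
    return out if out.ndim else float(out)


@dataclass
class SigmoidFit:
    """Result of a least-squares descending-sigmoid fit to one history."""

    H: float
    L: float
    d: float
    tau: float
    rmse: float
    converged: bool = True

    def predict(self, t):
        return sigmoid(t, self.H, self.L, self.d, self.tau)

    def integral(self, t0, t1, baseline=0.0):
        """Closed-form integral of the fitted curve minus baseline."""
        return float(sigmoid_integral(self.H, self.L, self.d, self.tau, t0, t1, baseline))


def _default_init(y, t):
    q = max(1, len(t) // 4)
    H0 = float(np.mean(y[:q]))
    L0 = float(np.mean(y[-q:]))
    half = 0.5 * (H0 + L0)
    below = np.nonzero(y <= half)[0]
    d0 = float(t[below[0]]) if below.size else float(t[len(t) // 2])
    return H0, L0, d0, 2.0


def fit_sigmoid(history, time_grid, init: SigmoidFit | None = None) -> SigmoidFit:
    """Fit s(t) = L + (H-L)/(1+exp((t-d)/tau)) by least squares.

    Initial guesses default to data-driven values (H from the first
    quartile of timepoints, L from the last, d from the half-crossing,
    tau = 2 h). Degenerate histories with no discernible transition
    (fitted amplitude below twice the residual noise, or midpoint pushed
    outside the observation window) are flagged ``converged=False`` with
    d and tau set to NaN: the plateaus are still meaningful but the
    duration is unidentifiable.
    """
    y = np.asarray(history, dtype=float)
    t = np.asarray(time_grid, dtype=float)
    if y.shape != t.shape:
        raise ValueError("history and time_grid must have equal length")
    if len(t) < 8:
        raise ValueError("need at least 8 timepoints to fit a sigmoid")
    if init is None:
        x0 = _default_init(y, t)
    else:
        x0 = (init.H, init.L, init.d, init.tau)

    def resid(p):
        return sigmoid(t, p[0], p[1], p[2], p[3]) - y

    span = t[-1] - t[0]
    lo = [-np.inf, -np.inf, t[0] - span, 1e-3]
    hi = [np.inf, np.inf, t[-1] + span, span]
    x0 = np.clip(x0, lo, hi)
    sol = least_squares(resid, x0, bounds=(lo, hi), method="trf")
    H, L, d, tau = sol.x
    if L > H:  # descending convention
        H, L, d = L, H, d
    rmse = float(np.sqrt(np.mean(sol.fun**2)))
    ok = bool(sol.success)
    min_amp = max(2 * rmse, 1e-8 * max(1.0, abs(H)))
    if abs(H - L) <= min_amp or not (t[0] <= d <= t[-1]):
        return SigmoidFit(H=float(H), L=float(L), d=float("nan"), tau=float("nan"),
                          rmse=rmse, converged=False)
    return SigmoidFit(H=float(H), L=float(L), d=float(d), tau=float(tau),
                      rmse=rmse, converged=ok)


def integral(history, time_grid, baseline=0.0):
    """Trapezoid integral of (s(t) - baseline) over the observation window."""
    y = np.asarray(history, dtype=float)
    t = np.asarray(time_grid, dtype=float)
    if y.shape[-1] != t.shape[0]:
        raise ValueError("history and time_grid length mismatch")
    if np.any(np.diff(t) <= 0):
        raise ValueError("time_grid must be strictly increasing")
    return np.trapezoid(y - baseline, t, axis=-1)


def feature_table(histories: pd.DataFrame, baseline: float | str = "auto") -> pd.DataFrame:
    """Per-cell sigmoid features and integral for a history matrix.

    ``baseline='auto'`` estimates the pre-treatment N:C level as the
    population median of the fitted low plateau L (the unstimulated ratio
    the response returns to), so a zero-signal history integrates to ~0.
    Columns: H, L, d, tau, rmse, converged, integral.
    """
    t = np.asarray(histories.columns, dtype=float)
    fits = [fit_sigmoid(row, t) for row in histories.to_numpy()]
    out = pd.DataFrame(
        {
            "H": [f.H for f in fits],
            "L": [f.L for f in fits],
            "d": [f.d for f in fits],
            "tau": [f.tau for f in fits],
            "rmse": [f.rmse for f in fits],
            "converged": [f.converged for f in fits],
        },
        index=histories.index,
    )
    if baseline == "auto":
        baseline = float(np.nanmedian(out["L"]))
    out["integral"] = integral(histories.to_numpy(), t, baseline=baseline)
    out.attrs["baseline"] = baseline
    return out


def pca_histories(histories: pd.DataFrame, n_components: int = 3):
    """Column-mean-centered PCA of the history matrix.

    Returns ``(scores, components, variance_explained)``. Components are
    deterministic up to sign; the sign is fixed by orienting each
    component so its score correlates nonnegatively with the per-cell
    signaling integral (computed against the population-median final
    level, so the orientation is intrinsic to the data).
    """
    X = histories.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("histories contain missing values; impute or drop first")
    if X.shape[0] < n_components:
        raise ValueError("fewer cells than components")
    t = np.asarray(histories.columns, dtype=float)
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    components = pca.components_.copy()
    sigma = integral(X, t, baseline=float(np.median(X[:, -max(1, len(t) // 4):])))
    for k in range(n_components):
        if np.std(scores[:, k]) > 0 and np.corrcoef(scores[:, k], sigma)[0, 1] < 0:
            scores[:, k] *= -1
            components[k] *= -1
    cols = [f"pc{k + 1}" for k in range(n_components)]
    return (
        pd.DataFrame(scores, index=histories.index, columns=cols),
        pd.DataFrame(components, index=cols, columns=histories.columns),
        pca.explained_variance_ratio_,
    )


def feature_pc_correlation(features: pd.DataFrame, scores: pd.DataFrame,
                           feature_names=("H", "L", "d", "integral")) -> pd.DataFrame:
    """Pearson correlation of each sigmoid feature with each PC score.

    Zero-variance features (or features that are all-NaN after dropping
    failed fits) get NaN correlations. Rows with any missing feature are
    dropped pairwise.
    """
    if len(features) < 3:
        raise ValueError("need at least 3 cells")
    out = pd.DataFrame(index=list(feature_names), columns=scores.columns, dtype=float)
    for f in feature_names:
        x = features[f].to_numpy(dtype=float)
        for c in scores.columns:
            y = scores[c].to_numpy(dtype=float)
            m = np.isfinite(x) & np.isfinite(y)
            if m.sum() < 3 or np.std(x[m]) == 0 or np.std(y[m]) == 0:
                out.loc[f, c] = np.nan
            else:
                out.loc[f, c] = np.corrcoef(x[m], y[m])[0, 1]
    return out
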