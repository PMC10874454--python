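"""Synthetic data generators with known ground truth.

Every downstream stage of the pipeline (tracking, feature extraction,
denoising, fate calling, prediction, micropattern analysis, RNA screen)
is exercised on data produced here, so each generator records the truth
it planted. The default parameters describe the biological regime the
pipeline targets: nuclear:cytoplasmic SMAD4 ratios that start on a high
plateau (~2x baseline) and descend to a low plateau over ~42 h of
differentiation, with the transition time ("duration") varying between
cells around 26 h; cell fate set by a noisy threshold on the time
integral of signaling; seven fate markers (four amnion, three
pluripotency) with bimodal log-normal expression; 700 um diameter
micropatterned colonies with radially organized signaling classes;
sparse-labeling tracking movies at 10-min frame intervals with
divisions; and bulk RNA-seq counts in four temporal classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit

AMNION_MARKERS = ("ISL1", "GATA3", "TFAP2C", "HAND1")
PLURIPOTENCY_MARKERS = ("SOX2", "NANOG", "OCT4")
DEFAULT_MARKERS = AMNION_MARKERS + PLURIPOTENCY_MARKERS

__all__ = [
    "AMNION_MARKERS",
    "PLURIPOTENCY_MARKERS",
    "DEFAULT_MARKERS",
    "HistoryGenParams",
    "FateGenParams",
    "ColonyGenParams",
    "TrackingTruth",
    "sigmoid",
    "sigmoid_integral",
    "gen_histories",
    "gen_fates",
    "gen_colony",
    "gen_tracking_fixture",
    "gen_counts",
    "substream",
]


def substream(seed: int, key: str) -> np.random.Generator:
    """Deterministic per-component RNG derived from a master seed.

    A stable hash of ``key`` selects the child stream so each pipeline
    component is reproducible in isolation.
    """
    digest = sum(ord(c) * 257**i for i, c in enumerate(key)) % (2**31)
    return np.random.default_rng(np.random.SeedSequence([int(seed), digest]))


# ---------------------------------------------------------------------------
# signaling histories


def sigmoid(t, high, low, duration, tau):
    """Descending logistic: high plateau -> low plateau, midpoint at ``duration``."""
    t = np.asarray(t, dtype=float)
    return low + (high - low) * expit(-(t - duration) / tau)


def sigmoid_integral(high, low, duration, tau, t0, t1, baseline=0.0):
    """Closed-form integral of ``sigmoid(t) - baseline`` over [t0, t1].

    Uses the antiderivative of the logistic,
    int 1/(1+exp((t-d)/tau)) dt = t - tau*log(1+exp((t-d)/tau)),
    evaluated stably with logaddexp.
    """

    def anti(t):
        return t - tau * np.logaddexp(0.0, (t - duration) / tau)

    return (low - baseline) * (t1 - t0) + (high - low) * (anti(t1) - anti(t0))


@dataclass(frozen=True)
class HistoryGenParams:
    """Parameters of the sigmoid signaling-history generator.

    Ratio units are nuclear:cytoplasmic intensity ratio; times in hours.
    ``noise_autocorr`` is the lag-one AR coefficient of the measurement
    noise (0 = i.i.d. Gaussian, the default noise model).
    """

    n_cells: int = 500
    t_start: float = 0.0
    t_end: float = 42.0
    dt: float = 1.0 / 6.0  # 10-min imaging interval
    high_mean: float = 2.0
    high_sd: float = 0.1
    low_mean: float = 1.0
    low_sd: float = 0.05
    duration_mean: float = 26.0
    duration_sd: float = 6.0
    rate_tau: float = 2.0
    noise_sd: float = 0.1
    baseline: float = 1.0
    noise_autocorr: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_cells <= 0:
            raise ValueError("n_cells must be positive")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.t_end <= self.t_start:
            raise ValueError("t_end must exceed t_start")
        if min(self.high_sd, self.low_sd, self.duration_sd, self.noise_sd) < 0:
            raise ValueError("standard deviations must be nonnegative")
        if self.low_mean >= self.high_mean:
            raise ValueError("low_mean must be below high_mean")
        if self.rate_tau <= 0:
            raise ValueError("rate_tau must be positive")
        if not 0.0 <= self.noise_autocorr < 1.0:
            raise ValueError("noise_autocorr must be in [0, 1)")

    @property
    def time_grid(self) -> np.ndarray:
        n = int(round((self.t_end - self.t_start) / self.dt)) + 1
        return self.t_start + self.dt * np.arange(n)


def gen_histories(params: HistoryGenParams, rng: np.random.Generator | None = None):
    """Draw per-cell sigmoid histories plus measurement noise.

    Returns ``(histories, truth)``: a cells x timepoints DataFrame whose
    columns are the time grid in hours, and the generating parameters per
    cell (H, L, d, tau and the baseline-subtracted integral) computed in
    closed form.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    t = params.time_grid
    n = params.n_cells
    high = rng.normal(params.high_mean, params.high_sd, n)
    low = rng.normal(params.low_mean, params.low_sd, n)
    dur = rng.normal(params.duration_mean, params.duration_sd, n)
    clean = sigmoid(t[None, :], high[:, None], low[:, None], dur[:, None], params.rate_tau)
    noise = rng.normal(0.0, 1.0, clean.shape)
    if params.noise_autocorr > 0:
        rho = params.noise_autocorr
        for j in range(1, noise.shape[1]):
            noise[:, j] = rho * noise[:, j - 1] + np.sqrt(1 - rho**2) * noise[:, j]
    histories = clean + params.noise_sd * noise
    cells = pd.RangeIndex(n, name="cell_id")
    truth = pd.DataFrame(
        {
            "H": high,
            "L": low,
            "d": dur,
            "tau": params.rate_tau,
            "integral": sigmoid_integral(
                high, low, dur, params.rate_tau, t[0], t[-1], params.baseline
            ),
        },
        index=cells,
    )
    return pd.DataFrame(histories, index=cells, columns=t), truth


# ---------------------------------------------------------------------------
# fates and markers


@dataclass(frozen=True)
class FateGenParams:
    """Noisy integral-threshold fate rule plus bimodal log-normal markers.

    P(differentiate) = logistic((integral - threshold)/width). Amnion
    markers are drawn from the "on" log-intensity distribution in
    differentiated cells and "off" otherwise; pluripotency markers the
    reverse. The default on/off gap of 6 marker_sd makes every marker
    clearly bimodal.
    """

    integral_threshold: float = 26.0  # ratio*hours
    logistic_width: float = 2.0
    marker_names: tuple = DEFAULT_MARKERS
    on_mean: float = 6.8  # log-intensity units
    off_mean: float = 5.0
    marker_sd: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if self.logistic_width <= 0:
            raise ValueError("logistic_width must be positive")
        if "ISL1" not in self.marker_names or "NANOG" not in self.marker_names:
            raise ValueError("marker_names must include ISL1 and NANOG")


def gen_fates(features: pd.DataFrame, params: FateGenParams,
              rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Assign fates from the signaling integral and draw marker intensities.

    ``features`` must carry an ``integral`` column (one row per cell).
    Returns a table of raw marker intensities plus the planted
    ``true_fate`` label and differentiation probability ``p_diff``.
    """
    if "integral" not in features.columns:
        raise ValueError("features must contain an 'integral' column")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    sigma = np.asarray(features["integral"], dtype=float)
    p = expit((sigma - params.integral_threshold) / params.logistic_width)
    differentiated = rng.random(len(p)) < p
    out = pd.DataFrame(index=features.index)
    for name in params.marker_names:
        amnion_marker = name in AMNION_MARKERS
        on = differentiated if amnion_marker else ~differentiated
        mu = np.where(on, params.on_mean, params.off_mean)
        out[name] = np.exp(rng.normal(mu, params.marker_sd))
    out["p_diff"] = p
    out["true_fate"] = np.where(differentiated, "amnion", "pluripotent")
    return out


# ---------------------------------------------------------------------------
# micropattern colonies


def _default_class_histories():
    base = HistoryGenParams(n_cells=1)
    # edge: sustained signaling; middle: late shutdown (still above the
    # fate threshold); center: early shutdown — three decisive fate rings
    return (
        replace(base, duration_mean=38.0, duration_sd=2.0),
        replace(base, duration_mean=30.0, duration_sd=2.0),
        replace(base, duration_mean=12.0, duration_sd=2.0),
    )


@dataclass(frozen=True)
class ColonyGenParams:
    """Disc colony with radially organized signaling classes.

    ``class_boundaries`` are edge distances (um) splitting the colony into
    len(class_histories) annuli, ordered edge -> center. Default geometry
    is a 700 um diameter micropatterned colony.
    """

    radius: float = 350.0
    n_cells: int = 900
    class_boundaries: tuple = (110.0, 220.0)
    class_histories: tuple = field(default_factory=_default_class_histories)
    fate_params: FateGenParams = field(default_factory=FateGenParams)
    seed: int = 0

    def __post_init__(self):
        b = np.asarray(self.class_boundaries, dtype=float)
        if np.any(np.diff(b) <= 0) or np.any(b <= 0) or np.any(b >= self.radius):
            raise ValueError("class_boundaries must be strictly increasing within (0, radius)")
        if len(self.class_histories) != len(b) + 1:
            raise ValueError("need one HistoryGenParams per radial class")


def gen_colony(params: ColonyGenParams, rng: np.random.Generator | None = None):
    """Place cells uniformly in the disc and draw class-dependent histories.

    Returns ``(positions, histories, fates, truth)``; positions carries
    x, y, edge_dist and the planted radial class (0 = outermost).
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    n = params.n_cells
    r = params.radius * np.sqrt(rng.random(n))
    theta = rng.uniform(0, 2 * np.pi, n)
    edge_dist = params.radius - r
    cls = np.searchsorted(np.asarray(params.class_boundaries), edge_dist, side="right")
    cells = pd.RangeIndex(n, name="cell_id")
    positions = pd.DataFrame(
        {"x": r * np.cos(theta), "y": r * np.sin(theta),
         "edge_dist": edge_dist, "true_class": cls},
        index=cells,
    )
    grid = params.class_histories[0].time_grid
    histories = np.empty((n, grid.size))
    truth_parts = []
    for k, hp in enumerate(params.class_histories):
        idx = np.flatnonzero(cls == k)
        if idx.size == 0:
            continue
        h, tr = gen_histories(replace(hp, n_cells=idx.size), rng=rng)
        histories[idx] = h.to_numpy()
        tr.index = pd.Index(idx, name="cell_id")
        truth_parts.append(tr)
    truth = pd.concat(truth_parts).sort_index()
    fates = gen_fates(truth, params.fate_params, rng=rng)
    return positions, pd.DataFrame(histories, index=cells, columns=grid), fates, truth


# ---------------------------------------------------------------------------
# tracking fixtures


@dataclass
class TrackingTruth:
    """Planted lineage for a tracking fixture.

    ``assignment`` maps detection_id -> track_id; ``tracks`` has one row
    per track with its parent (NaN for founders); ``links`` is the set of
    true consecutive-frame detection pairs, including the two
    parent -> daughter links of each division.
    """

    assignment: pd.Series
    tracks: pd.DataFrame
    links: set

    @property
    def division_links(self) -> set:
        kids = self.tracks.dropna(subset=["parent"])
        det_by_track = {}
        for det, tr in self.assignment.items():
            det_by_track.setdefault(tr, []).append(det)
        out = set()
        for tr, parent in kids["parent"].items():
            parent_dets = det_by_track[int(parent)]
            child_first = min(det_by_track[tr])
            out.add((max(parent_dets), child_first))
        return out


def _enforce_separation(pos: np.ndarray, min_sep: float, rng, iters: int = 20) -> np.ndarray:
    """Push overlapping nuclei apart until all pairs are >= min_sep um."""
    if min_sep <= 0 or len(pos) < 2:
        return pos
    for _ in range(iters):
        d = np.sqrt(((pos[:, None] - pos[None, :]) ** 2).sum(-1))
        np.fill_diagonal(d, np.inf)
        ii, jj = np.nonzero(np.triu(d < min_sep))
        if ii.size == 0:
            break
        for i, j in zip(ii, jj):
            v = pos[j] - pos[i]
            norm = np.linalg.norm(v)
            if norm < 1e-9:
                v = rng.normal(0, 1, 2)
                norm = np.linalg.norm(v)
            push = 0.5 * (min_sep - min(norm, min_sep)) * v / norm
            pos[i] -= push
            pos[j] += push
    return pos


def gen_tracking_fixture(n_cells: int = 100, n_frames: int = 50, step_sd: float = 1.5,
                         division_prob: float = 0.002, label_fraction: float = 0.15,
                         seed: int = 0, field_spacing: float = 15.0,
                         division_offset: float = 6.0, min_separation: float = 8.0,
                         rng: np.random.Generator | None = None):
    """Random-walk nuclei with divisions, under sparse labeling.

    ``n_cells`` founders populate a square field at confluent density
    (one cell per ``field_spacing``^2 um^2); only a ``label_fraction``
    subset carries the nuclear label and yields detections. A dividing
    cell is detected as metaphase on its last frame, then two daughters
    appear displaced symmetrically by ``division_offset`` um. Frames are
    10 min apart; ``step_sd`` is the per-frame random-walk step (um).
    Nuclei have finite size: after each step, overlapping cells are
    pushed apart to at least ``min_separation`` um (set 0 to disable).

    Returns ``(detections, truth)`` with detections columns
    frame, detection_id, x, y, division_class.
    """
    if not 0 < label_fraction <= 1:
        raise ValueError("label_fraction must be in (0, 1]")
    if n_cells <= 0 or n_frames <= 0:
        raise ValueError("n_cells and n_frames must be positive")
    if step_sd < 0 or division_prob < 0:
        raise ValueError("step_sd and division_prob must be nonnegative")
    if rng is None:
        rng = np.random.default_rng(seed)
    side = field_spacing * np.sqrt(n_cells)
    n_labeled = max(1, int(round(n_cells * label_fraction)))
    labeled = set(range(n_labeled))  # founders are exchangeable

    pos = rng.uniform(0, side, (n_cells, 2))
    pos = _enforce_separation(pos, min_separation, rng)
    next_track = n_cells
    next_det = 0
    alive = {i: pos[i].copy() for i in range(n_cells)}
    track_parent = {i: np.nan for i in range(n_cells)}
    rows, assign = [], {}
    links = set()
    last_det = {}

    for frame in range(n_frames):
        divide = {}
        for tr in sorted(alive):
            divide[tr] = frame < n_frames - 1 and rng.random() < division_prob
        trs = sorted(alive)
        arr = np.stack([alive[tr] for tr in trs])
        if step_sd > 0:
            arr = arr + rng.normal(0, step_sd, arr.shape)
        arr = _enforce_separation(arr, min_separation, rng)
        for tr, p in zip(trs, arr):
            alive[tr] = p
        for tr in trs:
            if tr in labeled:
                det = next_det
                next_det += 1
                cls = "metaphase" if divide[tr] else "interphase"
                rows.append((frame, det, alive[tr][0], alive[tr][1], cls))
                assign[det] = tr
                if tr in last_det:
                    links.add((last_det[tr], det))
                last_det[tr] = det
        for tr in sorted(alive):
            if not divide[tr]:
                continue
            parent_pos = alive.pop(tr)
            parent_last = last_det.pop(tr, None)
            direction = rng.normal(0, 1, 2)
            direction /= np.linalg.norm(direction)
            for sgn in (1.0, -1.0):
                child = next_track
                next_track += 1
                alive[child] = parent_pos + sgn * division_offset * direction
                track_parent[child] = tr
                if tr in labeled:
                    labeled.add(child)
    # daughters placed mid-loop emit their first detection on the next frame;
    # record the parent->daughter link lazily via division_links in truth
    detections = pd.DataFrame(rows, columns=["frame", "detection_id", "x", "y", "division_class"])
    assignment = pd.Series(assign, name="track_id").rename_axis("detection_id")
    tracks = pd.DataFrame({"parent": pd.Series(track_parent)}).rename_axis("track_id")
    tracks = tracks.loc[sorted(set(assignment.values))]
    truth = TrackingTruth(assignment=assignment, tracks=tracks, links=links)
    truth.links = links | truth.division_links
    return detections, truth


# ---------------------------------------------------------------------------
# RNA-seq counts


_CLASS_NAMES = ("decreasing", "immediate_up", "delayed_up", "flat")


def _class_profile(cls, t, rng):
    """Multiplicative expression profile over time, value 1 at t=0."""
    t = np.asarray(t, dtype=float)
    if cls == "decreasing":
        # immediate transcriptional shutdown, e.g. SOX2-like direct targets
        tau = rng.uniform(4.0, 8.0)
        return np.exp(-t / tau)
    if cls == "immediate_up":
        amp = rng.uniform(4.0, 10.0)
        return 1.0 + amp * (1.0 - np.exp(-t / 3.0))
    if cls == "delayed_up":
        amp = rng.uniform(10.0, 20.0)
        onset = rng.uniform(10.0, 14.0)
        return 1.0 + amp * expit((t - onset) / 2.5)
    return np.ones_like(t)


def gen_counts(n_genes: int = 2000,
               class_fractions: dict | None = None,
               timepoints=(0.0, 1.0, 3.0, 5.0, 8.0, 12.0, 24.0, 42.0),
               dose_levels=(0.0, 0.2, 0.4, 0.6, 0.8, 1.0),
               library_size: int = 20_000_000,
               tf_fraction: float = 0.1,
               dispersion: float = 0.002,
               poisson: bool = True,
               seed: int = 0,
               rng: np.random.Generator | None = None):
    """Bulk RNA-seq counts in four planted temporal classes.

    The time series follows per-class templates (continuously decreasing,
    immediately increasing, delayed increasing, flat). The dose series is
    sampled at the 5 h timepoint with expression responding linearly to
    the stated SMAD4 level for immediate-response classes (decreasing and
    immediate_up) and not at all for delayed/flat genes. Counts are
    gamma-Poisson with the given dispersion; ``poisson=False`` with
    ``dispersion=0`` yields deterministic (rounded expected) counts for
    zero-noise tests. Returns ``(timecourse, dose, truth)`` where truth
    carries class and TF flag.
    """
    timepoints = tuple(float(t) for t in timepoints)
    if len(timepoints) == 0:
        raise ValueError("timepoints must be nonempty")
    if class_fractions is None:
        class_fractions = {"decreasing": 0.04, "immediate_up": 0.035, "delayed_up": 0.035}
    total = sum(class_fractions.get(c, 0.0) for c in _CLASS_NAMES[:3])
    if total > 1:
        raise ValueError("class fractions must sum to at most 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    counts_per_class = {c: int(round(n_genes * class_fractions.get(c, 0.0)))
                        for c in _CLASS_NAMES[:3]}
    classes = []
    for c in _CLASS_NAMES[:3]:
        classes += [c] * counts_per_class[c]
    classes += ["flat"] * (n_genes - len(classes))
    classes = np.array(classes)
    is_tf = rng.random(n_genes) < tf_fraction
    base = np.exp(rng.normal(np.log(50.0), 1.0, n_genes))  # baseline relative expression

    t = np.asarray(timepoints)
    profiles = np.vstack([_class_profile(c, t, rng) for c in classes])
    mean_ts = base[:, None] * profiles

    dose = np.asarray(dose_levels, dtype=float)
    i5 = int(np.argmin(np.abs(t - 5.0)))
    fc5 = profiles[:, i5]  # fold change at 5 h under full signaling
    responsive = np.isin(classes, ["decreasing", "immediate_up"])
    fc_dose = np.where(responsive[:, None], 1.0 + (fc5[:, None] - 1.0) * dose[None, :], 1.0)
    mean_dose = base[:, None] * fc_dose

    def draw(mean):
        frac = mean / mean.sum(axis=0, keepdims=True)
        mu = frac * library_size
        if dispersion > 0:
            shape = 1.0 / dispersion
            mu = rng.gamma(shape, mu / shape)
        return rng.poisson(mu) if poisson else np.round(mu).astype(np.int64)

    genes = pd.Index([f"g{i:05d}" for i in range(n_genes)], name="gene")
    timecourse = pd.DataFrame(draw(mean_ts), index=genes,
                              columns=pd.Index(t, name="time_h"))
    dose_df = pd.DataFrame(draw(mean_dose), index=genes,
                           columns=pd.Index(dose, name="smad4_level"))
    truth = pd.DataFrame({"class": classes, "is_tf": is_tf}, index=genes)
    return timecourse, dose_df, truth
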