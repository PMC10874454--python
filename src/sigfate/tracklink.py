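"""Division-aware single-cell tracking by linear assignment.

Frame-to-frame linking follows the classic linear-assignment-problem
(LAP) formulation: candidate links between consecutive frames cost their
squared displacement, links beyond ``max_disp`` are forbidden, and
alternative birth/death assignments cost 1.05x the 90th percentile of
all candidate link costs, so a detection is left unmatched rather than
forced into an implausibly long link. Divisions are handled in a second
pass: a detection labeled metaphase may link to two detections in the
next frame within ``division_radius``, producing two daughter tracks
with the parent recorded. A final utility matches the last live frame to
fixed-cell detections with the same assignment machinery, and
``track_metrics`` scores a tracking result against a known lineage.

Detections labeled ``junk`` are discarded before linking. All steps are
deterministic and invariant to the input row order (detections are
sorted by frame and id internally).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

logger = logging.getLogger(__name__)

_BIG = 1e12

__all__ = ["TrackSet", "link_frames", "resolve_divisions", "match_live_fixed", "track_metrics"]


@dataclass
class TrackSet:
    """Lineage-linked detections.

    ``detections`` carries a ``track_id`` column; ``parents`` maps a
    daughter track to its parent track; ``links`` is the set of linked
    detection-id pairs (earlier frame first), including parent->daughter
    links at divisions.
    """

    detections: pd.DataFrame
    parents: dict = field(default_factory=dict)
    links: set = field(default_factory=set)

    @property
    def n_tracks(self) -> int:
        return self.detections["track_id"].nunique()

    def lineage(self) -> pd.DataFrame:
        g = self.detections.groupby("track_id")["frame"]
        out = pd.DataFrame({"start": g.min(), "end": g.max(), "n": g.size()})
        out["parent"] = pd.Series(self.parents, dtype=float).reindex(out.index)
        return out


def _augmented_lap(cost: np.ndarray, alt: float):
    """Solve the LAP with birth/death alternatives at cost ``alt``.

    ``cost`` is n x m with forbidden links set to np.inf. Returns the
    list of (i, j) accepted links.
    """
    n, m = cost.shape
    C = np.full((n + m, m + n), _BIG)
    finite = np.isfinite(cost)
    tl = np.where(finite, cost, _BIG)
    C[:n, :m] = tl
    C[:n, m:] = np.where(np.eye(n, dtype=bool), alt, _BIG)  # deaths
    C[n:, :m] = np.where(np.eye(m, dtype=bool), alt, _BIG)  # births
    C[n:, m:] = np.where(finite.T, 0.0, _BIG)  # complements
    rows, cols = linear_sum_assignment(C)
    return [(i, j) for i, j in zip(rows, cols) if i < n and j < m and finite[i, j]]


def _clean(detections: pd.DataFrame) -> pd.DataFrame:
    d = detections.copy()
    if "division_class" in d.columns:
        d = d[d["division_class"] != "junk"]
    if d[["x", "y"]].to_numpy().dtype.kind not in "fi" or not np.isfinite(
            d[["x", "y"]].to_numpy(dtype=float)).all():
        raise ValueError("detection coordinates must be finite")
    if d.duplicated(["frame", "detection_id"]).any():
        raise ValueError("(frame, detection_id) must be unique")
    return d.sort_values(["frame", "detection_id"], kind="stable").reset_index(drop=True)


def link_frames(detections: pd.DataFrame, max_disp: float, max_gap: int = 1) -> TrackSet:
    """Frame-to-frame LAP linking with optional one-frame gap closing.

    ``max_disp`` (um) gates candidate links per frame step; during gap
    closing over g skipped frames the gate scales to ``max_disp * (g+1)``.
    The birth/death cost is 1.05x the 90th percentile of all candidate
    link costs across the movie (squared-displacement units).
    """
    if max_disp <= 0:
        raise ValueError("max_disp must be positive")
    d = _clean(detections)
    frames = np.arange(d["frame"].min(), d["frame"].max() + 1)
    by_frame = {f: d[d["frame"] == f] for f in frames}

    # first pass over candidate costs to set the birth/death alternative
    cand = []
    for f in frames[:-1]:
        a, b = by_frame[f], by_frame[f + 1]
        if len(a) == 0 or len(b) == 0:
            continue
        D2 = cdist(a[["x", "y"]], b[["x", "y"]], "sqeuclidean")
        cand.append(D2[D2 <= max_disp**2])
    alt = 1.05 * np.percentile(np.concatenate(cand), 90) if cand and len(np.concatenate(cand)) else max_disp**2
    alt = max(alt, 1e-12)

    track_of = {}  # detection_id -> track_id
    next_track = 0
    links = set()
    open_ends = {}  # track_id -> (frame, detection_id, x, y) of last detection
    for f in frames:
        b = by_frame[f]
        matched = set()
        if len(b):
            # candidate predecessors: tracks ending within max_gap frames
            ends = [(tr, *v) for tr, v in sorted(open_ends.items())
                    if 1 <= f - v[0] <= max_gap + 1]
            if ends:
                exy = np.array([[e[3], e[4]] for e in ends])
                bxy = b[["x", "y"]].to_numpy(dtype=float)
                D2 = cdist(exy, bxy, "sqeuclidean")
                gaps = np.array([f - e[1] for e in ends])
                gate = (max_disp * gaps) ** 2
                D2[D2 > gate[:, None]] = np.inf
                for i, j in _augmented_lap(D2, alt):
                    tr, _, det_prev = ends[i][0], ends[i][1], ends[i][2]
                    det = int(b.iloc[j]["detection_id"])
                    track_of[det] = tr
                    links.add((det_prev, det))
                    matched.add(j)
            for j in range(len(b)):
                if j not in matched:
                    det = int(b.iloc[j]["detection_id"])
                    track_of[det] = next_track
                    next_track += 1
            for j in range(len(b)):
                row = b.iloc[j]
                det = int(row["detection_id"])
                open_ends[track_of[det]] = (f, det, float(row["x"]), float(row["y"]))
        # tracks whose end fell out of the gap window stay closed implicitly

    d["track_id"] = d["detection_id"].map(track_of)
    return TrackSet(detections=d, parents={}, links=links)


def resolve_divisions(trackset: TrackSet, detections: pd.DataFrame | None = None,
                      division_radius: float = 10.0) -> TrackSet:
    """Open division hypotheses at metaphase detections.

    A metaphase-labeled detection at frame t may be the mother of two
    detections at t+1 within ``division_radius``: its already-linked
    successor (if any) plus detections that started new tracks at t+1.
    When two or more candidates exist, the best two by squared
    displacement become daughters: each daughter's suffix of detections
    is moved to a fresh track with the mother recorded as parent. With
    fewer than two candidates, one-to-one linking is kept unchanged (no
    spurious division). More than two candidates logs a warning and keeps
    the best two.
    """
    d = trackset.detections.copy()
    links = set(trackset.links)
    parents = dict(trackset.parents)
    if "division_class" not in d.columns:
        raise ValueError("detections must carry division_class labels")
    next_track = int(d["track_id"].max()) + 1
    det_row = d.set_index("detection_id")
    succ = {a: b for a, b in links}
    track_dets = {tr: list(sub.sort_values("frame")["detection_id"])
                  for tr, sub in d.groupby("track_id")}
    first_det = {tr: dets[0] for tr, dets in track_dets.items()}

    meta = d[d["division_class"] == "metaphase"].sort_values(["frame", "detection_id"])
    for _, mrow in meta.iterrows():
        mdet, mframe = int(mrow["detection_id"]), int(mrow["frame"])
        mxy = np.array([mrow["x"], mrow["y"]])
        cands = []
        linked = succ.get(mdet)
        if linked is not None and int(det_row.loc[linked, "frame"]) == mframe + 1:
            cands.append(linked)
        starts = d[(d["frame"] == mframe + 1)
                   & d["detection_id"].isin(pd.Index(first_det.values()))]
        for _, srow in starts.iterrows():
            sdet = int(srow["detection_id"])
            if sdet == linked:
                continue
            if np.hypot(srow["x"] - mxy[0], srow["y"] - mxy[1]) <= division_radius:
                cands.append(sdet)
        if len(cands) < 2:
            continue
        cost = {c: float(((det_row.loc[c, ["x", "y"]].to_numpy(dtype=float) - mxy) ** 2).sum())
                for c in cands}
        if len(cands) > 2:
            logger.warning("metaphase detection %d has %d daughter candidates; keeping best two",
                           mdet, len(cands))
        best = sorted(cands, key=lambda c: (cost[c], c))[:2]
        mtrack = int(det_row.loc[mdet, "track_id"])
        for c in best:
            ctrack = int(det_row.loc[c, "track_id"])
            chain = track_dets[ctrack]
            suffix = chain[chain.index(c):]
            new_tr = next_track
            next_track += 1
            d.loc[d["detection_id"].isin(suffix), "track_id"] = new_tr
            det_row.loc[suffix, "track_id"] = new_tr
            track_dets[ctrack] = chain[:chain.index(c)]
            track_dets[new_tr] = suffix
            first_det[new_tr] = suffix[0]
            if ctrack in parents and chain.index(c) == 0:
                parents.pop(ctrack, None)
            parents[new_tr] = mtrack
            links.add((mdet, c))
        # the mother track now ends at the metaphase detection
    return TrackSet(detections=d, parents=parents, links=links)


def match_live_fixed(live_last_frame: pd.DataFrame, fixed_detections: pd.DataFrame,
                     max_disp: float) -> pd.DataFrame:
    """One-to-one partial matching of live to fixed detections.

    Minimizes total squared displacement with the same birth/death
    alternative as tracking, so grossly displaced or missing cells stay
    unmatched. Returns one row per live detection with ``fixed_id``
    (NaN if unmatched) and the displacement.
    """
    if len(live_last_frame) == 0 or len(fixed_detections) == 0:
        raise ValueError("both detection tables must be nonempty")
    live = live_last_frame.sort_values("detection_id").reset_index(drop=True)
    fixed = fixed_detections.sort_values("detection_id").reset_index(drop=True)
    D2 = cdist(live[["x", "y"]], fixed[["x", "y"]], "sqeuclidean")
    D2g = D2.copy()
    D2g[D2g > max_disp**2] = np.inf
    finite = D2g[np.isfinite(D2g)]
    alt = 1.05 * np.percentile(finite, 90) if finite.size else max_disp**2
    alt = max(alt, 1e-12)
    pairs = dict(_augmented_lap(D2g, alt))
    out = live[["detection_id"]].copy().rename(columns={"detection_id": "live_id"})
    out["fixed_id"] = [int(fixed.iloc[pairs[i]]["detection_id"]) if i in pairs else np.nan
                       for i in range(len(live))]
    out["displacement"] = [np.sqrt(D2[i, pairs[i]]) if i in pairs else np.nan
                           for i in range(len(live))]
    return out


def track_metrics(trackset: TrackSet, truth) -> dict:
    """Score a tracking result against a planted lineage.

    * ``link_accuracy``: correct frame-to-frame links / true links;
    * ``division_recall``: divisions with both parent->daughter links
      recovered / true divisions;
    * ``track_purity``: detection-weighted max fraction of each predicted
      track's detections that share one true track.
    """
    pred_dets = set(trackset.detections["detection_id"])
    true_dets = set(truth.assignment.index)
    if pred_dets != true_dets:
        raise ValueError("trackset and truth cover different detections")
    true_links = truth.links
    correct = len(trackset.links & true_links)
    link_accuracy = correct / len(true_links) if true_links else 1.0

    div_links = truth.division_links
    mothers = {}
    for a, b in div_links:
        mothers.setdefault(a, set()).add((a, b))
    if mothers:
        recalled = sum(1 for pair in mothers.values() if pair <= trackset.links)
        division_recall = recalled / len(mothers)
    else:
        division_recall = 1.0

    assigned = trackset.detections.set_index("detection_id")["track_id"]
    df = pd.DataFrame({"pred": assigned, "true": truth.assignment})
    purity_num = sum(sub["true"].value_counts().iloc[0] for _, sub in df.groupby("pred"))
    track_purity = purity_num / len(df)
    out = {"link_accuracy": link_accuracy, "division_recall": division_recall,
           "track_purity": track_purity}
    assert all(0.0 <= v <= 1.0 for v in out.values())
    return out
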