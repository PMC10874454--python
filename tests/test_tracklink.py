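"""Division-aware LAP tracking against brute-force and planted lineages."""

import itertools

import numpy as np
import pandas as pd
import pytest

from sigfate import synthgen, tracklink


def make_detections(frames_xy, division_class="interphase"):
    """Build a detection table from {frame: [(x, y), ...]}."""
    rows = []
    det = 0
    for frame in sorted(frames_xy):
        for x, y in frames_xy[frame]:
            rows.append((frame, det, float(x), float(y), division_class))
            det += 1
    return pd.DataFrame(rows, columns=["frame", "detection_id", "x", "y", "division_class"])


def brute_force_links(a_xy, b_xy, max_disp, alt):
    """Exhaustive minimum-cost matching with birth/death alternatives.

    Enumerates every partial injective mapping from frame-t detections to
    frame-t+1 detections; unmatched detections cost ``alt`` each.
    """
    n, m = len(a_xy), len(b_xy)
    best_cost, best_links = np.inf, []
    for k in range(min(n, m) + 1):
        for rows in itertools.combinations(range(n), k):
            for cols in itertools.permutations(range(m), k):
                cost = 0.0
                ok = True
                for i, j in zip(rows, cols):
                    d2 = sum((np.array(a_xy[i]) - np.array(b_xy[j])) ** 2)
                    if d2 > max_disp**2:
                        ok = False
                        break
                    cost += d2
                if not ok:
                    continue
                cost += alt * (n - k) + alt * (m - k)
                if cost < best_cost - 1e-12:
                    best_cost, best_links = cost, list(zip(rows, cols))
    return best_cost, set(best_links)


class TestLinkFrames:
    def test_two_stationary_points_give_two_full_tracks(self):
        dets = make_detections({f: [(0, 0), (50, 50)] for f in range(10)})
        ts = tracklink.link_frames(dets, max_disp=5.0)
        assert ts.n_tracks == 2
        assert len(ts.links) == 18

    @pytest.mark.parametrize("n_points", [2, 3, 4])
    def test_assignment_matches_brute_force_oracle(self, n_points):
        rng = np.random.default_rng(n_points)
        for trial in range(20):
            a = [tuple(p) for p in rng.uniform(0, 30, (n_points, 2))]
            b = [tuple(p + rng.normal(0, 3, 2)) for p in a]
            dets = make_detections({0: a, 1: b})
            max_disp = 10.0
            ts = tracklink.link_frames(dets, max_disp=max_disp)
            # reconstruct the alternative cost exactly as link_frames does
            d2 = np.array([[sum((np.array(p) - np.array(q)) ** 2) for q in b] for p in a])
            finite = d2[d2 <= max_disp**2]
            alt = max(1.05 * np.percentile(finite, 90), 1e-12) if finite.size else max_disp**2
            cost_oracle, _ = brute_force_links(a, b, max_disp, alt)
            # detection ids: frame 0 -> 0..n-1, frame 1 -> n..2n-1
            got = sum(d2[i, j - n_points] for i, j in ts.links)
            total = got + alt * (2 * n_points - 2 * len(ts.links))
            # totals agree even when equivalent-cost pairings differ
            assert total == pytest.approx(cost_oracle, rel=1e-9)

    def test_jump_beyond_max_disp_starts_new_track(self):
        dets = make_detections({0: [(0, 0)], 1: [(100, 0)]})
        ts = tracklink.link_frames(dets, max_disp=10.0)
        assert ts.n_tracks == 2
        assert len(ts.links) == 0

    def test_swapping_points_resolved_by_global_cost(self):
        # two points approach and pass each other with small per-step motion
        frames = {f: [(f * 1.0, 0.0), (10.0 - f * 1.0, 0.5)] for f in range(11)}
        dets = make_detections(frames)
        ts = tracklink.link_frames(dets, max_disp=3.0)
        assert ts.n_tracks == 2
        per_track = ts.detections.groupby("track_id")["frame"].count()
        assert sorted(per_track) == [11, 11]

    def test_junk_detections_are_dropped(self):
        dets = make_detections({0: [(0, 0)], 1: [(0, 0)]})
        junk = make_detections({0: [(1, 1)]}, division_class="junk")
        junk["detection_id"] += 100
        ts = tracklink.link_frames(pd.concat([dets, junk]), max_disp=5.0)
        assert 100 not in set(ts.detections["detection_id"])

    def test_negative_max_disp_rejected(self):
        with pytest.raises(ValueError):
            tracklink.link_frames(make_detections({0: [(0, 0)]}), max_disp=-1.0)

    def test_order_permutation_invariance(self):
        rng = np.random.default_rng(7)
        dets, _ = synthgen.gen_tracking_fixture(n_cells=60, n_frames=10, seed=13)
        shuffled = dets.sample(frac=1.0, random_state=1)
        a = tracklink.link_frames(dets, max_disp=10.0)
        b = tracklink.link_frames(shuffled, max_disp=10.0)
        assert a.links == b.links

    def test_more_reach_never_fewer_links(self):
        dets, _ = synthgen.gen_tracking_fixture(n_cells=60, n_frames=10, seed=14)
        n_small = len(tracklink.link_frames(dets, max_disp=4.0).links)
        n_large = len(tracklink.link_frames(dets, max_disp=12.0).links)
        assert n_large >= n_small

    def test_no_two_detections_of_one_track_share_a_frame(self, tracking_fixture):
        dets, _ = tracking_fixture
        ts = tracklink.link_frames(dets, max_disp=10.0)
        dup = ts.detections.groupby(["track_id", "frame"]).size()
        assert (dup == 1).all()


class TestDivisions:
    def test_single_division_yields_one_parent_two_children(self):
        dets = make_detections({0: [(0, 0)], 2: [(6, 0), (-6, 0)]})
        dets.loc[dets["frame"] == 0, "division_class"] = "metaphase"
        dets["frame"] = dets["frame"].replace({2: 1})
        ts = tracklink.link_frames(dets, max_disp=8.0)
        ts = tracklink.resolve_divisions(ts, division_radius=8.0)
        lin = ts.lineage()
        children = lin.dropna(subset=["parent"])
        assert len(children) == 2
        assert children["parent"].nunique() == 1

    def test_metaphase_with_one_successor_keeps_single_link(self):
        dets = make_detections({0: [(0, 0)], 1: [(1, 0)]})
        dets.loc[dets["frame"] == 0, "division_class"] = "metaphase"
        ts = tracklink.link_frames(dets, max_disp=5.0)
        ts = tracklink.resolve_divisions(ts, division_radius=8.0)
        assert ts.n_tracks == 1
        assert ts.parents == {}

    def test_fixture_accuracy_meets_validated_regime(self, tracking_fixture):
        dets, truth = tracking_fixture
        ts = tracklink.link_frames(dets, max_disp=10.0)
        ts = tracklink.resolve_divisions(ts, division_radius=12.0)
        m = tracklink.track_metrics(ts, truth)
        assert m["link_accuracy"] >= 0.988
        assert m["division_recall"] >= 0.9

    def test_division_preserves_detection_count(self, tracking_fixture):
        dets, _ = tracking_fixture
        ts = tracklink.link_frames(dets, max_disp=10.0)
        n_before = len(ts.detections)
        ts = tracklink.resolve_divisions(ts, division_radius=12.0)
        assert len(ts.detections) == n_before


class TestLiveFixedMatching:
    def test_constant_shift_matches_perfectly(self):
        rng = np.random.default_rng(3)
        live = make_detections({0: [tuple(p) for p in rng.uniform(0, 100, (30, 2))]})
        fixed = live.copy()
        fixed["x"] += 2.0
        mapping = tracklink.match_live_fixed(live, fixed, max_disp=5.0)
        assert (mapping["fixed_id"] == mapping["live_id"]).all()

    def test_missing_fixed_cell_leaves_one_unmatched(self):
        live = make_detections({0: [(0, 0), (50, 0), (100, 0)]})
        fixed = live.iloc[[0, 2]].copy()
        mapping = tracklink.match_live_fixed(live, fixed, max_disp=5.0)
        assert mapping["fixed_id"].isna().sum() == 1
        assert mapping.loc[mapping["live_id"] == 1, "fixed_id"].isna().all()

    def test_jitter_and_dropout_matching_above_95pct(self):
        # density as in sparse labeling: ~35 um spacing
        rng = np.random.default_rng(4)
        n = 200
        pts = rng.uniform(0, 35 * np.sqrt(n), (n, 2))
        live = make_detections({0: [tuple(p) for p in pts]})
        keep = rng.random(n) > 0.10
        fixed_pts = pts[keep] + rng.normal(0, 3.0, (keep.sum(), 2))
        fixed = make_detections({0: [tuple(p) for p in fixed_pts]})
        fixed["detection_id"] = np.flatnonzero(keep)
        mapping = tracklink.match_live_fixed(live, fixed, max_disp=12.0)
        matched = mapping.dropna(subset=["fixed_id"])
        accuracy = (matched["fixed_id"] == matched["live_id"]).mean()
        assert accuracy > 0.95


class TestMetrics:
    def test_perfect_trackset_scores_ones(self, tracking_fixture):
        dets, truth = tracking_fixture
        perfect = tracklink.TrackSet(
            detections=dets.assign(track_id=truth.assignment.loc[dets["detection_id"]].to_numpy()),
            parents=truth.tracks["parent"].dropna().astype(int).to_dict(),
            links=set(truth.links),
        )
        m = tracklink.track_metrics(perfect, truth)
        assert m == {"link_accuracy": 1.0, "division_recall": 1.0, "track_purity": 1.0}

    def test_no_links_scores_zero_accuracy(self, tracking_fixture):
        dets, truth = tracking_fixture
        broken = tracklink.TrackSet(
            detections=dets.assign(track_id=np.arange(len(dets))), links=set())
        assert tracklink.track_metrics(broken, truth)["link_accuracy"] == 0.0

    def test_one_wrong_link_counted_exactly(self):
        dets = make_detections({f: [(0, 0), (50, 50)] for f in range(50)})
        ts = tracklink.link_frames(dets, max_disp=5.0)
        links = sorted(ts.links)
        truth = synthgen.TrackingTruth(
            assignment=ts.detections.set_index("detection_id")["track_id"],
            tracks=pd.DataFrame({"parent": [np.nan, np.nan]}, index=[0, 1]).rename_axis("track_id"),
            links=set(links[:-1]) | {(links[-1][0], -1)},  # one true link differs
        )
        m = tracklink.track_metrics(ts, truth)
        assert m["link_accuracy"] == pytest.approx((len(links) - 1) / len(links))

    def test_mismatched_detection_sets_error(self, tracking_fixture):
        dets, truth = tracking_fixture
        ts = tracklink.link_frames(dets.iloc[:-1], max_disp=10.0)
        with pytest.raises(ValueError):
            tracklink.track_metrics(ts, truth)
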