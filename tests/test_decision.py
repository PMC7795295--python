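"""Stream fusion, size estimation, classification and action policy."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from avistereo.decision import (
    ActionPolicy,
    DetectionMessage,
    Event,
    EventArchive,
    MatchedPair,
    SizeClassBoundaries,
    SizeEstimate,
    approx_area,
    classify_size,
    decide_action,
    estimate_size,
    match_objects,
    record_event,
    synchronize_streams,
)
from avistereo.scene import default_assembly
from avistereo.stereo import StereoRig

RIG = StereoRig()
ASM = default_assembly()


def msg(camera, xc, yc, t=0.0, o_s=100.0, p_w=20.0, p_h=8.0, module="m1"):
    return DetectionMessage(
        module_id=module, camera=camera, timestamp=t, o_s=o_s, p_w=p_w, p_h=p_h,
        centroid=(xc, yc),
    )


class TestSynchronizeStreams:
    def test_identical_timestamps_all_paired(self):
        up = [msg("upper", 100, 500, t) for t in (0.0, 1.0, 2.0)]
        lo = [msg("lower", 100, 480, t) for t in (0.0, 1.0, 2.0)]
        pairs = synchronize_streams(up, lo)
        assert len(pairs) == 3

    def test_offset_beyond_tolerance_gives_nothing(self):
        up = [msg("upper", 100, 500, 0.0)]
        lo = [msg("lower", 100, 480, 0.2)]
        assert synchronize_streams(up, lo, tolerance=0.05) == []

    def test_unsorted_stream_rejected(self):
        up = [msg("upper", 0, 0, 2.0), msg("upper", 0, 0, 1.0)]
        with pytest.raises(ValueError):
            synchronize_streams(up, [])

    def test_jittered_pairing_matches_nearest_assignment_oracle(self, rng):
        times = np.sort(rng.uniform(0, 5, 12))
        up = [msg("upper", 0, 0, t) for t in times]
        jit = np.sort(times + rng.uniform(-0.02, 0.02, len(times)))
        lo = [msg("lower", 0, 0, t) for t in jit]
        pairs = synchronize_streams(up, lo, tolerance=0.05)
        # oracle: greedy scan over the full offset matrix, no sorting tricks
        remaining = [(i, j) for i in range(len(times)) for j in range(len(jit))
                     if abs(times[i] - jit[j]) <= 0.05]
        chosen = []
        used_u, used_l = set(), set()
        while True:
            cands = [(abs(times[i] - jit[j]), i, j) for i, j in remaining
                     if i not in used_u and j not in used_l]
            if not cands:
                break
            _, i, j = min(cands)
            used_u.add(i)
            used_l.add(j)
            chosen.append((times[i], jit[j]))
        got = {(u[0].timestamp, l[0].timestamp) for u, l in pairs}
        assert got == set(chosen)


class TestMatchObjects:
    def test_single_obvious_pair(self):
        pairs = match_objects([msg("upper", 100, 100)], [msg("lower", 110, 90)])
        assert len(pairs) == 1
        assert pairs[0].center_distance == pytest.approx(math.sqrt(200))

    def test_two_clusters_matched_correctly(self):
        up = [msg("upper", 100, 100), msg("upper", 500, 400)]
        lo = [msg("lower", 110, 90), msg("lower", 505, 395)]
        pairs = match_objects(up, lo)
        assert {(p.upper.xc, p.lower.xc) for p in pairs} == {(100, 110), (500, 505)}

    def test_false_pair_filter_removes_large_offsets(self):
        assert match_objects([msg("upper", 100, 100)], [msg("lower", 300, 90)]) == []
        assert match_objects([msg("upper", 100, 100)], [msg("lower", 100, 300)]) == []

    def test_negative_disparity_removed(self):
        # lower camera centre above the upper's: physically impossible
        assert match_objects([msg("upper", 100, 100)], [msg("lower", 100, 120)]) == []

    def test_empty_inputs(self):
        assert match_objects([], [msg("lower", 0, 0)]) == []

    @given(
        n_up=st.integers(1, 4),
        n_lo=st.integers(1, 4),
        data=st.data(),
    )
    def test_greedy_matches_exhaustive_min_scan_oracle(self, n_up, n_lo, data):
        coords = st.tuples(st.floats(0, 1000), st.floats(0, 1000))
        # unique module ids keep equal-coordinate messages distinguishable
        up = [msg("upper", *data.draw(coords), module=f"u{i}") for i in range(n_up)]
        lo = [msg("lower", *data.draw(coords), module=f"l{j}") for j in range(n_lo)]
        got = match_objects(up, lo, max_center_offset=1e9, min_ydiff=-1e9)
        # oracle: repeatedly pick the globally smallest distance by brute
        # scan of the full matrix, removing the chosen row and column
        mat = {(i, j): math.hypot(u.xc - l.xc, u.yc - l.yc)
               for i, u in enumerate(up) for j, l in enumerate(lo)}
        expected = []
        while mat:
            (i, j), _ = min(mat.items(), key=lambda kv: (kv[1], kv[0]))
            expected.append((i, j))
            mat = {k: v for k, v in mat.items() if k[0] != i and k[1] != j}
        assert len(got) == min(n_up, n_lo)
        got_idx = {(up.index(p.upper), lo.index(p.lower)) for p in got}
        assert got_idx == set(expected)


class TestEstimateSize:
    def _pair(self, ydiff, p_w, p_h, o_s=150.0):
        u = msg("upper", 1200, 1600 + ydiff, p_w=p_w, p_h=p_h, o_s=o_s)
        l = msg("lower", 1200, 1600, p_w=p_w, p_h=p_h, o_s=o_s)
        return MatchedPair(upper=u, lower=l)

    def test_published_size_pairs_reproduced(self):
        assert approx_area(1.53, 0.51) == pytest.approx(0.39, abs=0.005)
        assert approx_area(0.84, 0.34) == pytest.approx(0.14, abs=0.005)

    def test_estimate_consistency(self):
        est = estimate_size(self._pair(18, 25, 9), RIG, ASM)
        assert est.distance_db == pytest.approx(148.68, abs=0.01)
        assert est.approx_area == pytest.approx(
            est.wingspan * est.body_height / 2.0, rel=1e-12
        )
        # 25 px at ~148.7 m with the C1/3mm assembly is a ~1.39 m wingspan
        assert est.wingspan == pytest.approx(25 * 148.68 / 2673.9, rel=1e-3)

    def test_zero_extent_gives_zero_sizes(self):
        est = estimate_size(self._pair(18, 0.0, 0.0, o_s=0.0), RIG, ASM)
        assert est.wingspan == est.body_height == est.contour_area == 0.0
        assert est.approx_area == 0.0

    def test_uncertainty_scales_with_extent(self):
        est = estimate_size(self._pair(18, 25, 9), RIG, ASM)
        assert est.wingspan_delta == pytest.approx(
            est.distance_db_delta * 25 / 2673.9, rel=1e-3
        )


class TestClassifySize:
    def _est(self, pw, ph, os_):
        return SizeEstimate(
            wingspan=pw, wingspan_delta=0.0, body_height=ph, body_height_delta=0.0,
            contour_area=os_, approx_area=approx_area(pw, ph),
            distance_db=100.0, distance_db_delta=1.0,
        )

    @pytest.mark.parametrize(
        "pw,ph,os_,expected",
        [
            (1.6, 0.6, 0.5, "large"),
            (1.0, 0.35, 0.2, "small"),
            (1.0, 0.45, 0.2, "medium"),  # height vote wins by the max rule
            (0.4, 0.1, 0.05, "uncategorized"),
            (1.51, 0.3, 0.05, "large"),  # single large vote dominates
        ],
    )
    def test_boundary_cases(self, pw, ph, os_, expected):
        assert classify_size(self._est(pw, ph, os_)) == expected

    @given(
        pw=st.floats(0.1, 2.5),
        ph=st.floats(0.05, 1.0),
        os_=st.floats(0.01, 1.0),
        dpw=st.floats(0.0, 1.0),
        dph=st.floats(0.0, 0.5),
        dos=st.floats(0.0, 0.5),
    )
    def test_monotone_in_every_parameter(self, pw, ph, os_, dpw, dph, dos):
        order = ["uncategorized", "small", "medium", "large"]
        a = order.index(classify_size(self._est(pw, ph, os_)))
        b = order.index(classify_size(self._est(pw + dpw, ph + dph, os_ + dos)))
        assert b >= a

    def test_bad_boundaries_rejected(self):
        with pytest.raises(ValueError):
            SizeClassBoundaries(wingspan=(1.0, 0.5, 2.0))


class TestDecideAction:
    def test_large_bird_inside_stop_zone(self):
        assert decide_action("large", 150.0) == {"strobe", "audio", "turbine_stop"}

    def test_small_bird_outside_all_zones(self):
        assert decide_action("small", 350.0) == frozenset()

    def test_boundary_is_inclusive(self):
        assert "strobe" in decide_action("medium", 300.0)
        assert "turbine_stop" in decide_action("large", 200.0)

    def test_stop_implies_deterrents(self):
        policy = ActionPolicy(strobe={}, audio={}, turbine_stop={"large": 200.0})
        assert decide_action("large", 100.0, policy) == {
            "strobe", "audio", "turbine_stop",
        }

    def test_uncategorized_triggers_nothing(self):
        assert decide_action("uncategorized", 50.0) == frozenset()


class TestEventArchive:
    def _event(self, t=0.0):
        return Event(
            timestamp=t, module_id="m1", size_class="large", d=150.0, h=90.0,
            d_b=170.0, delta_db=5.5, wingspan=1.6, body_height=0.55,
            contour_area=0.44, approx_area=0.44, actions=("audio", "strobe"),
        )

    def test_single_event_round_trip(self, tmp_path):
        archive = EventArchive(tmp_path / "arch")
        record_event(archive, self._event())
        (back,) = archive.read()
        assert back == self._event()

    def test_many_events_in_order(self, tmp_path):
        archive = EventArchive(tmp_path / "arch")
        for t in range(50):
            archive.append(self._event(float(t)))
        events = archive.read()
        assert len(events) == 50
        assert [e.timestamp for e in events] == [float(t) for t in range(50)]

    def test_jsonl_mirror_written(self, tmp_path):
        archive = EventArchive(tmp_path / "arch")
        archive.append(self._event())
        assert archive.jsonl_path.read_text().count("\n") == 1
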