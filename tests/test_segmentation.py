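"""Nucleus segmentation, bridge status, anaphase onset and RPA foci."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import abscission as ab
from abscission.actin import MidzoneROI
from abscission.exceptions import AmbiguousThresholdError, DataError
from abscission.segmentation import BridgeState, BridgeStatus
from conftest import segment_histone


def otsu_sweep_oracle(image):
    """Exhaustive threshold sweep maximizing between-class variance."""
    values = np.sort(np.unique(image.ravel()))
    best_t, best_v = None, -1.0
    flat = image.ravel().astype(float)
    for t in (values[:-1] + values[1:]) / 2.0:
        lo, hi = flat[flat <= t], flat[flat > t]
        if lo.size == 0 or hi.size == 0:
            continue
        w0, w1 = lo.size / flat.size, hi.size / flat.size
        v = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if v > best_v:
            best_v, best_t = v, t
    return best_t


class TestThreshold:
    def test_otsu_on_two_level_image_matches_sweep_oracle(self):
        rng = np.random.default_rng(0)
        image = np.full(100, 10.0)
        image[rng.choice(100, 10, replace=False)] = 100.0
        image = image.reshape(10, 10)
        mask = ab.threshold_positive(image, "otsu")
        oracle_mask = image > otsu_sweep_oracle(image)
        assert np.array_equal(mask, oracle_mask)
        assert mask.sum() == 10 and (image[mask] == 100.0).all()

    def test_fixed_zero_threshold_keeps_all_positive_pixels(self):
        image = np.ones((4, 4))
        assert ab.threshold_positive(image, 0.0).all()
        assert ab.threshold_positive(image, ("fixed", 0.0)).all()

    def test_otsu_on_constant_image_is_ambiguous(self):
        with pytest.raises(AmbiguousThresholdError):
            ab.threshold_positive(np.full((5, 5), 3.0), "otsu")

    def test_otsu_mask_invariant_under_constant_offset(self):
        rng = np.random.default_rng(1)
        image = np.where(rng.random((20, 20)) < 0.1, 100.0, 10.0)
        m1 = ab.threshold_positive(image, "otsu")
        m2 = ab.threshold_positive(image + 57.0, "otsu")
        assert np.array_equal(m1, m2)

    def test_suppress_background_zeroes_subthreshold_pixels(self):
        image = np.array([[1.0, 5.0], [9.0, 2.0]])
        mask = image > 4
        out = ab.suppress_background(image, mask)
        assert out.tolist() == [[0.0, 5.0], [9.0, 0.0]]


class TestLabelNuclei:
    def test_two_squares_have_analytic_centroids_and_area(self):
        mask = np.zeros((40, 40), dtype=bool)
        mask[5:10, 5:10] = True    # centre (7, 7)
        mask[20:25, 30:35] = True  # centre (22, 32)
        ns = ab.label_nuclei(mask, min_area_px=10)
        got = sorted((r.centroid, r.area_px) for r in ns.regions)
        assert got == [((7.0, 7.0), 25), ((22.0, 32.0), 25)]

    def test_component_touching_border_is_flagged(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[0:6, 4:10] = True
        ns = ab.label_nuclei(mask, min_area_px=10)
        assert ns.regions[0].touches_border

    def test_disk_major_axis_is_its_diameter(self):
        r = 12
        yy, xx = np.mgrid[0:64, 0:64]
        mask = (yy - 32) ** 2 + (xx - 32) ** 2 <= r**2
        ns = ab.label_nuclei(mask)
        assert ns.regions[0].major_axis_px == pytest.approx(2 * r, rel=0.05)

    def test_small_components_are_dropped(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[2, 2] = True
        assert ab.label_nuclei(mask, min_area_px=4).regions == []


class TestSelectTwoNuclei:
    def _set(self, n_interior, n_border=0):
        regions = [
            ab.NucleusRegion(i + 1, (5.0 + i, 5.0), 25, 5.0, touches_border=False)
            for i in range(n_interior)
        ]
        regions += [
            ab.NucleusRegion(10 + i, (0.0, 5.0), 25, 5.0, touches_border=True)
            for i in range(n_border)
        ]
        return ab.NucleusSet(0, regions)

    @pytest.mark.parametrize(
        "n_interior,n_border,kept",
        [(1, 0, False), (2, 0, True), (2, 1, True), (3, 0, False)],
    )
    def test_exactly_two_interior_nuclei_are_kept(self, n_interior, n_border, kept):
        result = ab.select_two_nuclei_frames([self._set(n_interior, n_border)])
        assert bool(result) is kept


def _two_nuclei_scene():
    """Two 7x7 nucleus squares plus label set and corridor ROI."""
    mask = np.zeros((40, 60), dtype=bool)
    mask[17:24, 5:12] = True
    mask[17:24, 48:55] = True
    ns = ab.label_nuclei(mask, min_area_px=10)
    a, b = ns.interior_regions()
    roi = MidzoneROI(center=(20.0, 30.0), axis_unit_vector=(0.0, 1.0), height_px=20.0, width_px=20.0)
    return mask, ns, roi


class TestDetectBridge:
    def test_thin_line_joining_nuclei_is_connected(self):
        mask, ns, roi = _two_nuclei_scene()
        bridge = mask.copy()
        bridge[20, 12:48] = True
        assert ab.detect_bridge(bridge, ns, roi).status is BridgeState.CONNECTED

    def test_isolated_blob_in_corridor_is_fragmented_hence_unresolved(self):
        mask, ns, roi = _two_nuclei_scene()
        blob = mask.copy()
        blob[19:21, 28:33] = True  # 10-px blob mid-corridor
        status = ab.detect_bridge(blob, ns, roi)
        assert status.status is BridgeState.FRAGMENTED
        assert status.status.unresolved

    def test_clean_corridor_is_resolved(self):
        mask, ns, roi = _two_nuclei_scene()
        assert ab.detect_bridge(mask, ns, roi).status is BridgeState.RESOLVED

    def test_requires_exactly_two_nuclei(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[5:12, 5:12] = True
        ns = ab.label_nuclei(mask, min_area_px=10)
        roi = MidzoneROI((10.0, 10.0), (0.0, 1.0), 5.0, 5.0)
        with pytest.raises(DataError):
            ab.detect_bridge(mask, ns, roi)

    def test_closed_loop_unresolved_until_truth_then_resolved(self, hela_scene):
        params, movie, truth = hela_scene
        sets = segment_histone(movie, params)
        thr = params.background_offset + params.bridge_peak / 2.0
        resolve_frame = truth.event_frames["t_bridge_resolve_min"]
        from abscission.actin import build_midzone_roi

        for ns in ab.select_two_nuclei_frames(sets):
            hist = movie.frame(ns.frame_index, "histone")
            a, b = ns.interior_regions()
            status = ab.detect_bridge(ab.threshold_positive(hist, thr), ns, build_midzone_roi(a, b))
            assert status.status.unresolved == (ns.frame_index < resolve_frame)


def resolution_scan_oracle(states, t_anaphase, interval):
    """Literal definition: first at/after-anaphase RESOLVED frame with no later relapse."""
    for i, (frame, s) in enumerate(states):
        t = frame * interval
        if t >= t_anaphase and s is BridgeState.RESOLVED:
            if all(s2 is BridgeState.RESOLVED for _, s2 in states[i:]):
                return t - t_anaphase
    return None


class TestBridgeResolutionTime:
    def _statuses(self, pattern):
        return [BridgeStatus(f, s, 0) for f, s in pattern]

    def test_resolved_from_frame_five_with_anaphase_at_two(self):
        pattern = [(f, BridgeState.CONNECTED if f < 5 else BridgeState.RESOLVED) for f in range(10)]
        t = ab.bridge_resolution_time(self._statuses(pattern), t_anaphase_min=4.0, frame_interval_min=2.0)
        assert t == 6.0  # (5 - 2) * 2

    def test_never_resolved_is_censored(self):
        pattern = [(f, BridgeState.CONNECTED) for f in range(6)]
        assert ab.bridge_resolution_time(self._statuses(pattern), 0.0, 2.0) is None

    def test_relapse_moves_resolution_to_later_frame(self):
        states = {5: BridgeState.RESOLVED, 6: BridgeState.CONNECTED}
        pattern = [(f, states.get(f, BridgeState.RESOLVED if f >= 7 else BridgeState.CONNECTED)) for f in range(10)]
        t = ab.bridge_resolution_time(self._statuses(pattern), 0.0, 2.0)
        assert t == 14.0  # frame 7

    def test_empty_input_is_an_error(self):
        with pytest.raises(DataError):
            ab.bridge_resolution_time([], 0.0, 2.0)

    def test_matches_scan_oracle_on_random_sequences(self):
        rng = np.random.default_rng(42)
        states = list(BridgeState)
        for _ in range(1000):
            n = rng.integers(1, 15)
            pattern = [(f, states[rng.integers(0, 3)]) for f in range(n)]
            t_ana = float(rng.integers(0, n) * 2)
            got = ab.bridge_resolution_time(self._statuses(pattern), t_ana, 2.0)
            assert got == resolution_scan_oracle(pattern, t_ana, 2.0)


class TestAnaphaseOnset:
    def test_step_trace_detected_at_the_jump(self):
        trace = [10.0] * 8 + [20.0] * 6
        assert ab.detect_anaphase_onset(trace) == 8

    def test_flat_noisy_trace_is_censored(self):
        rng = np.random.default_rng(3)
        trace = 10.0 * (1 + 0.05 * rng.uniform(-1, 1, 30))
        assert ab.detect_anaphase_onset(trace) is None

    def test_short_trace_is_an_error(self):
        with pytest.raises(DataError):
            ab.detect_anaphase_onset([10.0, 10.0, 10.0])

    def test_closed_loop_recovers_ground_truth_exactly(self, hela_scene, hela_nuclei):
        params, movie, truth = hela_scene
        trace = ab.major_axis_trace([ns.label_image > 0 for ns in hela_nuclei])
        assert ab.detect_anaphase_onset(trace) == truth.event_frames["t_anaphase_min"]


class TestRpaFoci:
    def _nucleus(self):
        mask = np.zeros((40, 40), dtype=int)
        mask[10:30, 10:30] = 1
        return mask

    def test_uniform_nuclear_intensity_has_no_foci(self):
        call = ab.detect_rpa_foci(np.full((40, 40), 50.0), self._nucleus())
        assert call.foci == []
        assert call.background_level == 50.0

    def test_bright_spot_at_five_times_background_is_one_focus_at_its_centre(self):
        image = np.full((40, 40), 50.0)
        yy, xx = np.mgrid[0:40, 0:40]
        image += 200.0 * np.exp(-((yy - 20) ** 2 + (xx - 21) ** 2) / (2 * 1.5**2))
        call = ab.detect_rpa_foci(image, self._nucleus(), k=3.0)
        assert len(call.foci) == 1
        cy, cx = call.foci[0]["centroid"]
        assert abs(cy - 20) <= 1 and abs(cx - 21) <= 1

    def test_identical_spot_outside_nucleus_mask_is_ignored(self):
        image = np.full((40, 40), 50.0)
        yy, xx = np.mgrid[0:40, 0:40]
        image += 200.0 * np.exp(-((yy - 4) ** 2 + (xx - 4) ** 2) / (2 * 1.5**2))
        call = ab.detect_rpa_foci(image, self._nucleus(), k=3.0)
        assert call.foci == []

    def test_empty_mask_is_an_error(self):
        with pytest.raises(DataError):
            ab.detect_rpa_foci(np.zeros((10, 10)), np.zeros((10, 10), dtype=int))

    def test_focus_count_non_increasing_in_k(self):
        rng = np.random.default_rng(6)
        image = 50.0 + rng.normal(0, 5.0, (40, 40))
        yy, xx = np.mgrid[0:40, 0:40]
        for cy, cx, amp in ((15, 15, 40.0), (24, 24, 80.0), (14, 26, 120.0)):
            image += amp * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * 1.5**2))
        counts = [len(ab.detect_rpa_foci(image, self._nucleus(), k=k).foci) for k in (1, 2, 4, 8, 16)]
        assert counts == sorted(counts, reverse=True)


@settings(max_examples=200, derandomize=True)
@given(
    st.lists(st.sampled_from(list(BridgeState)), min_size=1, max_size=12),
    st.integers(min_value=0, max_value=11),
)
def test_resolution_time_property_matches_oracle(states, ana_frame):
    pattern = list(enumerate(states))
    statuses = [BridgeStatus(f, s, 0) for f, s in pattern]
    got = ab.bridge_resolution_time(statuses, float(ana_frame), 1.0)
    assert got == resolution_scan_oracle(pattern, float(ana_frame), 1.0)
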