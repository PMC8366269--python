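"""Spiral geometry, marker projection, binning and the place-frequency map."""

import math

import numpy as np
import pytest

from presbycusis import (Marker, SegmentTrace, SpiralSimParams, assign_marker,
                         band_loss, bin_cytocochleogram, build_spiral_map,
                         gen_spiral, path_length, place_frequency_map,
                         project_point, step_loss)
from presbycusis.cochleogram import SpiralMap
import pandas as pd


def straight_trace(label, start, length, markers=(), spans=()):
    x0, y0 = start
    return SegmentTrace(label, [[x0, y0], [x0 + length, y0]], 1.0,
                        list(markers), list(spans))


class TestPathLength:
    def test_two_points(self):
        t = SegmentTrace("apical", [[0, 0], [100, 0]], 1.0)
        assert path_length(t) == pytest.approx(100.0)

    def test_unit_square(self):
        t = SegmentTrace("apical", [[0, 0], [1, 0], [1, 1], [0, 1], [0, 0]], 1.0)
        assert path_length(t) == pytest.approx(4.0)

    def test_scale_applied(self):
        t = SegmentTrace("apical", [[0, 0], [10, 0]], 2.5)
        assert path_length(t) == pytest.approx(25.0)

    def test_duplicate_points_collapsed(self):
        t = SegmentTrace("apical", [[0, 0], [0, 0], [3, 4]], 1.0)
        assert path_length(t) == pytest.approx(5.0)

    def test_synthetic_spiral_length_recovered(self):
        traces, truth = gen_spiral(SpiralSimParams(seed=3))
        total = sum(path_length(t) for t in traces)
        assert abs(total - 5330.0) / 5330.0 < 1e-3


class TestProjection:
    def test_marker_on_vertex(self):
        t = SegmentTrace("apical", [[0, 0], [10, 0], [10, 10]], 1.0)
        assert assign_marker(t, Marker("OHC", 10, 0)) == pytest.approx(10.0)

    def test_perpendicular_offset_projects_to_foot(self):
        t = SegmentTrace("apical", [[0, 0], [10, 0]], 1.0)
        assert assign_marker(t, Marker("OHC", 5, 5)) == pytest.approx(5.0)

    def test_midpoint_not_vertex_snap(self):
        # equidistant from the two vertices of a straight segment: the
        # projection lands at the midpoint, not at either vertex
        arc, dist = project_point(np.array([[0.0, 0.0], [10.0, 0.0]]), 5.0, 2.0)
        assert arc == pytest.approx(5.0)
        assert dist == pytest.approx(2.0)

    def test_orphan_excluded(self):
        t = SegmentTrace("apical", [[0, 0], [10, 0]], 1.0)
        with pytest.warns(UserWarning, match="excluded"):
            assert assign_marker(t, Marker("OHC", 5, 500)) is None

    def test_tie_breaks_toward_smaller_arc(self):
        # a point equidistant from two parallel passes of a U-shaped path
        path = np.array([[0, 0], [10, 0], [10, 4], [0, 4]], dtype=float)
        arc, _ = project_point(path, 5.0, 2.0)
        assert arc == pytest.approx(5.0)   # first (smaller-arc) branch wins

    def test_agrees_with_dense_resampling_oracle(self):
        """Segment projection matches brute-force nearest point on a densely
        resampled path within 1 µm at 5 µm resampling."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = rng.integers(3, 8)
            path = np.cumsum(rng.uniform(-30, 30, (n, 2)), axis=0)
            m = path.mean(axis=0) + rng.uniform(-20, 20, 2)
            arc, dist = project_point(path, m[0], m[1])
            # oracle: resample every segment at 5 µm steps, nearest sample
            seg = np.diff(path, axis=0)
            lens = np.linalg.norm(seg, axis=1)
            cum = np.concatenate([[0], np.cumsum(lens)])
            ss = np.arange(0, cum[-1], 5.0 / 10)  # finer than 5 µm for the bound
            pts = np.array([np.interp(ss, cum, path[:, i]) for i in (0, 1)]).T
            d = np.linalg.norm(pts - m, axis=1)
            # implementation is never farther than the best sampled point
            assert dist <= d.min() + 1e-9
            # and its arc position matches one of the near-optimal samples
            near = np.abs(d - d.min()) <= 0.05
            assert np.min(np.abs(ss[near] - arc)) <= 1.0


class TestSpiralMap:
    def _three(self, markers_mid=()):
        a = straight_trace("apical", (0, 0), 100)
        m = straight_trace("middle", (0, 10), 100, markers_mid)
        b = straight_trace("basal", (0, 20), 100)
        return a, m, b

    def test_apical_start_is_zero(self):
        a, m, b = self._three()
        a.markers.append(Marker("OHC", 0, 0))
        sm = build_spiral_map(a, m, b)
        assert sm.markers["position_pct"].iloc[0] == pytest.approx(0.0)

    def test_basal_end_is_hundred(self):
        a, m, b = self._three()
        b.markers.append(Marker("OHC", 100, 20))
        sm = build_spiral_map(a, m, b)
        assert sm.markers["position_pct"].iloc[0] == pytest.approx(100.0)

    def test_middle_start_is_one_third(self):
        a, m, b = self._three(markers_mid=[Marker("IHC", 0, 10)])
        sm = build_spiral_map(a, m, b)
        assert sm.markers["position_pct"].iloc[0] == pytest.approx(100 / 3, abs=1e-6)

    def test_inconsistent_scales_rejected(self):
        a, m, b = self._three()
        m.scale_um_per_px = 2.0
        with pytest.raises(ValueError, match="scale"):
            build_spiral_map(a, m, b)

    def test_rigid_motion_invariance(self):
        """Rotating and translating all coordinates leaves the cytocochleogram
        unchanged."""
        traces, _ = gen_spiral(SpiralSimParams(
            total_length_um=1500, loss_profile=step_loss(50, 0.4), seed=7))
        cyto0 = bin_cytocochleogram(build_spiral_map(*traces))
        th = 0.7
        R = np.array([[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]])
        shift = np.array([123.0, -45.0])
        moved = [SegmentTrace(t.label, t.path @ R.T + shift, t.scale_um_per_px,
                              [Marker(m.type, *(R @ [m.x, m.y] + shift))
                               for m in t.markers], t.invalid_spans_um)
                 for t in traces]
        cyto1 = bin_cytocochleogram(build_spiral_map(*moved))
        pd.testing.assert_frame_equal(cyto0.table, cyto1.table)

    def test_marker_order_invariance(self):
        traces, _ = gen_spiral(SpiralSimParams(
            total_length_um=1500, loss_profile=step_loss(50, 0.4), seed=8))
        cyto0 = bin_cytocochleogram(build_spiral_map(*traces))
        rng = np.random.default_rng(0)
        shuffled = [SegmentTrace(t.label, t.path, t.scale_um_per_px,
                                 [t.markers[i] for i in rng.permutation(len(t.markers))],
                                 t.invalid_spans_um)
                    for t in traces]
        cyto1 = bin_cytocochleogram(build_spiral_map(*shuffled))
        pd.testing.assert_frame_equal(cyto0.table, cyto1.table)


class TestBinning:
    def _spiral_map(self, markers, spans=()):
        rows = [(t, p, "apical") for t, p in markers]
        return SpiralMap(1000.0, pd.DataFrame(
            rows, columns=["type", "position_pct", "segment"]), list(spans))

    def test_loss_percentage(self):
        markers = [("OHC", 1.0)] * 38 + [("OHx", 2.0)] * 2
        cyto = bin_cytocochleogram(self._spiral_map(markers))
        row = cyto.loss("OHC").iloc[0]
        assert row["loss_pct"] == pytest.approx(5.0)
        assert row["n_present"] == 38 and row["n_missing"] == 2

    def test_empty_bin_excluded(self):
        cyto = bin_cytocochleogram(self._spiral_map([("OHC", 1.0)]))
        ohc = cyto.loss("OHC")
        assert not ohc.iloc[0]["excluded"]
        assert ohc.iloc[1]["excluded"] and math.isnan(ohc.iloc[1]["loss_pct"])

    def test_bin_inside_invalid_span_excluded(self):
        cyto = bin_cytocochleogram(self._spiral_map(
            [("OHC", 1.0)], spans=[(10.0, 20.0)]))
        ohc = cyto.loss("OHC")
        assert bool(ohc.iloc[2]["excluded"]) and bool(ohc.iloc[3]["excluded"])

    def test_position_100_in_last_bin(self):
        cyto = bin_cytocochleogram(self._spiral_map([("IHC", 100.0)]))
        assert cyto.loss("IHC").iloc[-1]["n_present"] == 1

    def test_counts_conserved(self):
        traces, truth = gen_spiral(SpiralSimParams(
            total_length_um=2000, loss_profile=step_loss(30, 0.5), seed=9))
        cyto = bin_cytocochleogram(build_spiral_map(*traces))
        for cls in ("OHC", "IHC"):
            t = cyto.loss(cls)
            total = (t["n_present"] + t["n_missing"]).sum()
            assert total == (truth.cells["cell_class"] == cls).sum()

    def test_step_profile_recovered(self):
        """A 0 -> 30% OHC loss step at 50% from apex is recovered bin by bin
        within 3 binomial standard errors."""
        traces, truth = gen_spiral(SpiralSimParams(
            loss_profile=step_loss(50.0, 0.3), seed=10))
        cyto = bin_cytocochleogram(build_spiral_map(*traces))
        ohc = cyto.loss("OHC")
        for _, row in ohc.iterrows():
            n = row["n_present"] + row["n_missing"]
            if n < 30:
                continue
            p_true = 0.0 if row["bin_end"] <= 50 else (
                0.3 if row["bin_start"] >= 50 else None)
            if p_true is None:
                continue
            se = math.sqrt(max(p_true * (1 - p_true), 0.25 / n) / n) * 100
            assert abs(row["loss_pct"] - p_true * 100) <= 3 * se + 1e-9


class TestPlaceFrequencyMap:
    def test_anchor_40pct_is_9khz(self):
        pm = place_frequency_map("anchored_9khz")
        assert pm.to_frequency(40.0) == pytest.approx(9.0)

    def test_apex_frequency_muller(self):
        pm = place_frequency_map("muller2005")
        assert pm.to_frequency(0.0) == pytest.approx(10 ** (56.5 / 82.5), rel=1e-12)

    @pytest.mark.parametrize("preset", ["muller2005", "anchored_9khz"])
    @pytest.mark.parametrize("f", [2.0, 8.0, 16.0, 45.2])
    def test_round_trip(self, preset, f):
        pm = place_frequency_map(preset)
        p = pm.to_place(f)
        if 0 <= p <= 100:
            assert pm.to_frequency(p) == pytest.approx(f, rel=1e-9)

    def test_monotone_toward_base(self):
        pm = place_frequency_map("anchored_9khz")
        f = pm.to_frequency(np.linspace(0, 100, 21))
        assert np.all(np.diff(f) > 0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            place_frequency_map("anchored_9khz").to_frequency(101.0)


class TestBandLoss:
    def _uniform_cyto(self, low, high, pm):
        rows = []
        for b in range(20):
            lo, hi = 5.0 * b, 5.0 * (b + 1)
            f = pm.to_frequency((lo + hi) / 2)
            loss = low if f <= 8.0 else high
            rows.append((lo, hi, "OHC", 90, int(round(90 * loss / (100 - loss)))
                         if loss < 100 else 90, loss, False))
        t = pd.DataFrame(rows, columns=["bin_start", "bin_end", "cell_class",
                                        "n_present", "n_missing", "loss_pct",
                                        "excluded"])
        from presbycusis.cochleogram import Cytocochleogram
        return Cytocochleogram(t, 5330.0)

    def test_uniform_loss_both_bands(self):
        pm = place_frequency_map("anchored_9khz")
        bl = band_loss(self._uniform_cyto(10.0, 10.0, pm), pm)
        assert bl.low_pct == pytest.approx(10.0)
        assert bl.high_pct == pytest.approx(10.0)

    def test_step_by_band(self):
        pm = place_frequency_map("anchored_9khz")
        bl = band_loss(self._uniform_cyto(0.0, 40.0, pm), pm)
        assert bl.low_pct == pytest.approx(0.0)
        assert bl.high_pct == pytest.approx(40.0)

    def test_empty_band_warns(self):
        pm = place_frequency_map("anchored_9khz")
        cyto = self._uniform_cyto(10.0, 20.0, pm)
        cyto.table.loc[cyto.table.index < 100, "excluded"] = True
        centers = (cyto.table["bin_start"] + cyto.table["bin_end"]) / 2
        cyto.table.loc[pm.to_frequency(centers.to_numpy()) <= 8.0, "excluded"] = True
        with pytest.warns(UserWarning, match="low band"):
            bl = band_loss(cyto, pm)
        assert math.isnan(bl.low_pct)
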