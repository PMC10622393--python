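"""Dual-threshold segmentation, Eq.-style NCAR arithmetic, and auto-thresholding."""


import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import ncarkit as nk
from conftest import brute_force_disk_count


def exhaustive_otsu3(counts):
    """Independent brute-force three-class Otsu: pure-Python scan of all pairs.

    Minimizes total within-class variance over boundaries [0..t1], [t1+1..t2],
    [t2+1..255] with all classes populated; ties to smallest (t1, t2).
    Uses exact integer prefix sums, so no floating-point tie ambiguity.
    """
    from fractions import Fraction

    w = [0] * 257
    s = [0] * 257
    q = [0] * 257
    for v in range(256):
        w[v + 1] = w[v] + counts[v]
        s[v + 1] = s[v] + v * counts[v]
        q[v + 1] = q[v] + v * v * counts[v]

    def within(a, b):  # class over levels [a, b]; None when empty
        cw = w[b + 1] - w[a]
        if cw == 0:
            return None
        cs = s[b + 1] - s[a]
        cq = q[b + 1] - q[a]
        return Fraction(cq) - Fraction(cs * cs, cw)

    best = (None, None)
    for t1 in range(0, 254):
        for t2 in range(t1 + 1, 255):
            parts = [within(0, t1), within(t1 + 1, t2), within(t2 + 1, 255)]
            if any(p is None for p in parts):
                continue
            total = sum(parts)
            if best[0] is None or total < best[0]:
                best = (total, (t1, t2))
    return best[1]


class TestThresholdPair:
    def test_light_colony_ordering_enforced(self):
        nk.ThresholdPair(60, 180)
        with pytest.raises(ValueError):
            nk.ThresholdPair(180, 60)

    def test_dark_colony_ordering_enforced(self):
        nk.ThresholdPair(180, 60, orientation=nk.DARK_COLONY)
        with pytest.raises(ValueError):
            nk.ThresholdPair(60, 180, orientation=nk.DARK_COLONY)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            nk.ThresholdPair(-1, 100)
        with pytest.raises(ValueError):
            nk.ThresholdPair(0, 300)


class TestSegmentPlate:
    def test_synthetic_disks_match_bruteforce_enumeration(self, small_plate_spec):
        img, _ = nk.render_plate(small_plate_spec, source_id="p1", day=9)
        area = nk.segment_plate(img, nk.ThresholdPair(60, 180))
        assert area.A_d == brute_force_disk_count(100, (50.0, 50.0), 40.0)
        assert area.A_c == brute_force_disk_count(100, (50.0, 50.0), 20.0)
        assert area.plate_id == "p1" and area.day == 9

    def test_saturated_image_full_coverage(self):
        img = nk.RedChannelImage(np.full((64, 64), 255, dtype=np.uint8))
        area = nk.segment_plate(img, nk.ThresholdPair(60, 180))
        assert area.A_c == area.A_d == 64 * 64

    def test_all_dark_image_raises_no_dish(self):
        img = nk.RedChannelImage(np.zeros((64, 64), dtype=np.uint8), source_id="dark1")
        with pytest.raises(nk.SegmentationError, match="no dish detected.*dark1"):
            nk.segment_plate(img, nk.ThresholdPair(60, 180))

    def test_dark_colony_orientation_mirrors_light(self, small_plate_spec):
        """Inverted plate segments identically under dark_colony thresholds."""
        img, _ = nk.render_plate(small_plate_spec)
        inverted = nk.RedChannelImage(255 - img.values)
        light = nk.segment_plate(img, nk.ThresholdPair(60, 180))
        dark = nk.segment_plate(
            inverted, nk.ThresholdPair(255 - 60, 255 - 180, orientation=nk.DARK_COLONY)
        )
        assert (dark.A_d, dark.A_c) == (light.A_d, light.A_c)

    def test_threshold_tie_is_inclusive_on_bright_side(self):
        img = nk.RedChannelImage(np.array([[60, 59], [180, 179]], dtype=np.uint8))
        area = nk.segment_plate(img, nk.ThresholdPair(60, 180))
        # 60, 179 and 180 clear t_dish=60 inclusively; only 180 clears t_colony=180
        assert (area.A_d, area.A_c) == (3, 1)


class TestGroupNCAR:
    def test_full_and_empty_coverage(self):
        full = nk.group_ncar([nk.AreaIndices(1000, 1000)], "g", 9)
        empty = nk.group_ncar([nk.AreaIndices(5000, 0)], "g", 9)
        assert full.eta == 100.0 and empty.eta == 0.0
        assert full.sd == 0.0  # single replicate

    def test_mean_of_replicate_ratios(self):
        plates = [nk.AreaIndices(4000, 1000), nk.AreaIndices(4000, 2000)]
        s = nk.group_ncar(plates, "g", 13)
        assert s.eta == pytest.approx(37.5)
        assert s.n == 2
        assert s.sd == pytest.approx(100 * np.std([0.25, 0.5], ddof=1))

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="no plates"):
            nk.group_ncar([], "g", 9)

    @given(st.lists(st.tuples(st.integers(1, 10000), st.floats(0, 1)), min_size=1, max_size=8))
    def test_eta_bounded_and_consistent_with_ratios(self, pairs):
        plates = [nk.AreaIndices(ad, int(ad * f)) for ad, f in pairs]
        s = nk.group_ncar(plates, "g", 9)
        assert 0.0 <= s.eta <= 100.0
        assert s.eta == pytest.approx(100 * np.mean(s.per_plate_ratios))

    def test_monotone_in_colony_radius(self, small_plate_spec):
        """Growing the colony inside a fixed dish never decreases eta."""
        from dataclasses import replace

        etas = []
        for r in [0.0, 5.0, 10.0, 20.0, 30.0, 40.0]:
            img, _ = nk.render_plate(replace(small_plate_spec, colony_radius=r))
            area = nk.segment_plate(img, nk.ThresholdPair(60, 180))
            etas.append(nk.group_ncar([area], "g", 9).eta)
        assert all(a <= b for a, b in zip(etas, etas[1:]))
        assert etas[0] == 0.0 and etas[-1] == 100.0


class TestAutoThresholds:
    def test_three_equal_spikes_bracket_the_modes(self):
        counts = np.zeros(256, dtype=int)
        counts[[10, 120, 240]] = 500
        thr = nk.auto_thresholds(nk.RedHistogram(counts))
        assert 10 < thr.t_dish <= 120
        assert 120 < thr.t_colony <= 240
        assert thr.orientation == nk.LIGHT_COLONY

    def test_single_level_histogram_rejected(self):
        counts = np.zeros(256, dtype=int)
        counts[100] = 900
        with pytest.raises(nk.ThresholdError, match="not trimodal-capable"):
            nk.auto_thresholds(nk.RedHistogram(counts))

    def test_two_level_histogram_rejected(self):
        counts = np.zeros(256, dtype=int)
        counts[[10, 200]] = 100
        with pytest.raises(nk.ThresholdError):
            nk.auto_thresholds(nk.RedHistogram(counts))

    def test_noiseless_plate_auto_thresholds_recover_exact_classes(self, small_plate_spec):
        img, truth = nk.render_plate(small_plate_spec)
        thr = nk.auto_thresholds(nk.red_histogram(img))
        area = nk.segment_plate(img, thr)
        assert (area.A_d, area.A_c) == (truth.A_d, truth.A_c)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_exhaustive_pure_python_scan(self, seed):
        """Vectorized search equals the independent brute-force Otsu oracle."""
        rng = np.random.default_rng(seed)
        counts = np.zeros(256, dtype=int)
        centers = rng.choice(np.arange(5, 250), size=3, replace=False)
        for c in centers:
            lo, hi = max(c - 4, 0), min(c + 5, 256)
            counts[lo:hi] += rng.integers(1, 200, hi - lo)
        thr = nk.auto_thresholds(nk.RedHistogram(counts))
        t1, t2 = exhaustive_otsu3(counts.tolist())
        assert (thr.t_dish, thr.t_colony) == (t1 + 1, t2 + 1)
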