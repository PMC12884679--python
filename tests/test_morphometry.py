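import math

import numpy as np
import pytest

from retinograph.labels import ARTERY, VEIN
from retinograph.morphometry import (
    Centreline,
    InsufficientVesselsError,
    avr,
    crae,
    crve,
    find_edge_pair,
    measure_branch,
    measure_calibres,
    select_branches,
    skeletonize,
    vessel_width,
)
from retinograph.synthetic import _stamp_capsules


def straight_mask(width, angle_deg, n=128, half_len=50.0):
    mask = np.zeros((n, n), dtype=bool)
    c = n / 2
    a = math.radians(angle_deg)
    p0 = np.array([c - half_len * math.sin(a), c - half_len * math.cos(a)])
    p1 = np.array([c + half_len * math.sin(a), c + half_len * math.cos(a)])
    _stamp_capsules(mask, np.array([p0, p1]), width / 2.0)
    return mask


class TestSkeletonize:
    def test_one_pixel_line_unchanged(self):
        mask = np.zeros((5, 9), dtype=bool)
        mask[2, 1:8] = True
        branches = skeletonize(mask)
        assert len(branches) == 1
        got = {tuple(p) for p in branches[0].pixels}
        assert got == {(2, c) for c in range(1, 8)}

    def test_horizontal_bar_thins_to_middle_row(self):
        mask = np.zeros((11, 24), dtype=bool)
        mask[3:8, 2:22] = True                # 5 rows tall, middle row = 5
        branches = skeletonize(mask)
        assert len(branches) == 1
        pix = branches[0].pixels
        middle = pix[(pix[:, 1] > 5) & (pix[:, 1] < 18)]
        assert np.all(middle[:, 0] == 5)

    def test_component_count_preserved(self):
        from scipy import ndimage

        rng = np.random.default_rng(0)
        mask = np.zeros((40, 40), dtype=bool)
        _stamp_capsules(mask, np.array([[8.0, 5.0], [8.0, 35.0]]), 2.0)
        _stamp_capsules(mask, np.array([[30.0, 5.0], [20.0, 35.0]]), 2.5)
        branches = skeletonize(mask)
        skel = np.zeros_like(mask)
        for b in branches:
            skel[b.pixels[:, 0], b.pixels[:, 1]] = True
        _, n_sk = ndimage.label(skel, structure=np.ones((3, 3)))
        _, n_mask = ndimage.label(mask, structure=np.ones((3, 3)))
        assert n_sk == n_mask

    def test_empty_mask(self):
        assert skeletonize(np.zeros((4, 4), dtype=bool)) == []


class TestFindEdgePair:
    def test_width5_bar_pixel_mode(self):
        mask = np.zeros((11, 21), dtype=bool)
        mask[3:8, :] = True                    # rows 3..7, centre row 5
        ea, eb = find_edge_pair(mask, (5, 10), theta=0.0, subpixel=False)
        rows = sorted([ea[0], eb[0]])
        assert rows == [3.0, 7.0]              # 2 above and 2 below
        assert ea[1] == eb[1] == 10.0

    def test_width1_line_degenerate(self):
        mask = np.zeros((5, 9), dtype=bool)
        mask[2] = True
        ea, eb = find_edge_pair(mask, (2, 4), theta=0.0, subpixel=False)
        assert ea == eb == (2.0, 4.0)

    def test_direction_swap_symmetry(self):
        mask = straight_mask(7, 0)
        ea, eb = find_edge_pair(mask, (64, 64), theta=0.0)
        eb2, ea2 = find_edge_pair(mask, (64, 64), theta=math.pi)
        assert ea == pytest.approx(ea2, abs=1e-9) or ea == pytest.approx(eb2, abs=1e-9)

    def test_centre_outside_mask(self):
        with pytest.raises(ValueError, match="not inside"):
            find_edge_pair(np.zeros((4, 4), dtype=bool), (1, 1), 0.0)


class TestVesselWidth:
    def test_pythagorean_triple(self):
        assert vessel_width((0, 0), (3, 4)) == 5.0

    def test_identical_points(self):
        assert vessel_width((2, 2), (2, 2)) == 0.0

    @pytest.mark.parametrize("angle", [0, 30, 45, 90])
    @pytest.mark.parametrize("wtrue", [3, 6, 10, 15])
    def test_straight_vessel_recovery(self, wtrue, angle):
        mask = straight_mask(wtrue, angle)
        branches = skeletonize(mask)
        branch = max(branches, key=lambda b: len(b.pixels))
        widths = [m.width for m in measure_branch(mask, branch)]
        assert abs(np.median(widths) - wtrue) <= 1.0

    def test_width6_within_one(self):
        mask = straight_mask(6, 0)
        branch = max(skeletonize(mask), key=lambda b: len(b.pixels))
        meas = measure_branch(mask, branch)
        close = sum(abs(m.width - 6) <= 1.0 for m in meas)
        assert close >= 0.9 * len(meas)


class TestSelectBranches:
    def test_order_statistic(self):
        rows = [(1, ARTERY, 8.0), (2, ARTERY, 6.0), (3, ARTERY, 5.0),
                (4, VEIN, 9.0), (5, VEIN, 7.0)]
        da1, da2, dv1, dv2 = select_branches(rows)
        assert (da1, da2) == (8.0, 6.0)
        assert (dv1, dv2) == (9.0, 7.0)

    def test_tie_both_selected(self):
        rows = [(1, ARTERY, 6.0), (2, ARTERY, 6.0),
                (3, VEIN, 7.0), (4, VEIN, 7.0)]
        da1, da2, _, _ = select_branches(rows)
        assert da1 == da2 == 6.0

    def test_permutation_invariance(self):
        rows = [(1, ARTERY, 8.0), (2, ARTERY, 6.0),
                (3, VEIN, 9.0), (4, VEIN, 7.0)]
        assert select_branches(rows) == select_branches(rows[::-1])

    def test_insufficient(self):
        with pytest.raises(InsufficientVesselsError):
            select_branches([(1, ARTERY, 5.0), (2, VEIN, 6.0), (3, VEIN, 4.0)])


class TestCalibreFormulas:
    def test_crae_paper_zero(self):
        assert crae(0, 0, mode="paper") == pytest.approx(-10.73)

    def test_crae_paper_worked(self):
        assert crae(100, 90, mode="paper") == pytest.approx(16190.27)

    def test_crae_paper_monotone_region(self):
        # d/dDa1 = 2 Da1 - 0.22 Da2 > 0 whenever Da1 > 0.11 Da2
        for da2 in (10.0, 50.0, 120.0):
            for da1 in (0.12 * da2, 0.5 * da2, 2 * da2):
                h = 1e-5
                deriv = (crae(da1 + h, da2) - crae(da1 - h, da2)) / (2 * h)
                assert deriv > 0

    def test_crve_paper_zero(self):
        assert crve(0, 0, mode="paper") == pytest.approx(450.02)

    def test_crve_paper_worked(self):
        assert crve(100, 90, mode="paper") == pytest.approx(25021.02)

    def test_crve_strictly_increasing(self):
        assert crve(11, 10) > crve(10, 10) > crve(10, 9)

    def test_canonical_forms(self):
        assert crae(150, 140, mode="canonical") == pytest.approx(
            math.sqrt(0.87 * 150**2 + 1.01 * 140**2 - 0.22 * 150 * 140 - 10.76))
        assert crve(200, 180, mode="canonical") == pytest.approx(
            math.sqrt(0.72 * 200**2 + 0.91 * 180**2 + 450.05))

    def test_canonical_negative_radicand(self):
        with pytest.raises(ValueError, match="radicand"):
            crae(0.5, 0.5, mode="canonical")

    def test_avr_basic(self):
        assert avr(1.0, 1.0) == 1.0
        assert avr(2.0, 3.0) == pytest.approx(2.0 / 3.0)

    def test_avr_domain_error(self):
        with pytest.raises(ValueError):
            avr(1.0, 0.0)

    def test_narrowing_arteries_decreases_avr_both_modes(self):
        for mode in ("paper", "canonical"):
            dv = (180.0, 170.0)
            prev = None
            for da in (160.0, 140.0, 120.0, 100.0):
                val = avr(crae(da, da - 5, mode=mode), crve(*dv, mode=mode))
                if prev is not None:
                    assert val < prev
                prev = val

    def test_scale_covariance_via_formula_algebra(self):
        d = (120.0, 110.0, 170.0, 160.0)
        for mode in ("paper", "canonical"):
            base = avr(crae(d[0], d[1], mode=mode), crve(d[2], d[3], mode=mode))
            doubled = avr(crae(2 * d[0], 2 * d[1], mode=mode),
                          crve(2 * d[2], 2 * d[3], mode=mode))
            expect = crae(2 * d[0], 2 * d[1], mode=mode) / \
                crve(2 * d[2], 2 * d[3], mode=mode)
            assert doubled == pytest.approx(expect)
            assert doubled != pytest.approx(base)


class TestMeasureCalibres:
    def test_recovers_root_widths_on_synthetic(self, sample128):
        s = sample128
        summary, rows = measure_calibres(
            s.vessel_mask, s.av_labels, s.disc_center, s.disc_radius,
            formula_mode="canonical", micron_per_pixel=s.spec.micron_per_pixel)
        assert summary.da1 == pytest.approx(s.spec.root_width_artery, abs=1.0)
        assert summary.dv1 == pytest.approx(s.spec.root_width_vein, abs=1.0)
        assert summary.avr == pytest.approx(s.true_avr, abs=0.12)

    def test_sorted_diameters(self, sample128):
        s = sample128
        summary, _ = measure_calibres(
            s.vessel_mask, s.av_labels, s.disc_center, s.disc_radius)
        assert summary.da1 >= summary.da2
        assert summary.dv1 >= summary.dv2
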