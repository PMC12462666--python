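"""Spot detection: point maxima, region foci, trajectories, midcell distance."""

import numpy as np
import pytest

from conftest import rectangle_cell, render_single_cell
from nucleotrack.foci import (
    detect_point_maxima,
    detect_region_foci,
    relative_midcell_distance,
    track_foci,
)
from nucleotrack.records import FocusRecord


def _img_for(cell, values):
    """Embed a small value array at the cell's bbox inside a zero frame."""
    r0, c0, r1, c1 = cell.bbox
    img = np.zeros((r1 + 5, c1 + 5))
    img[r0:r1, c0:c1] = values
    return img


class TestPointMaxima:
    def test_constant_cell_has_no_maxima(self):
        cell = rectangle_cell()
        img = _img_for(cell, np.full(cell.mask.shape, 3.0))
        assert detect_point_maxima(img, cell) == []

    def test_exhaustive_scan_oracle_agrees_exactly(self):
        """With smoothing and thresholds off, the detector must equal a
        brute-force 8-neighborhood scan on small random arrays."""
        rng = np.random.default_rng(10)
        cell = rectangle_cell(height=9, width=13)
        r0, c0, r1, c1 = cell.bbox
        for _ in range(25):
            vals = rng.random((r1 - r0, c1 - c0))
            img = _img_for(cell, vals)
            got = {
                (int(f.centroid[0]), int(f.centroid[1]))
                for f in detect_point_maxima(
                    img, cell, smoothing_sigma=0.0, prominence_frac=0.0,
                    min_separation_px=0,
                )
            }
            expected = set()
            for y in range(r0, r1):
                for x in range(c0, c1):
                    neigh = []
                    for dy in (-1, 0, 1):
                        for dx in (-1, 0, 1):
                            if dy == dx == 0:
                                continue
                            yy, xx = y + dy, x + dx
                            if r0 <= yy < r1 and c0 <= xx < c1:
                                neigh.append(img[yy, xx])
                    if all(img[y, x] > v for v in neigh):
                        expected.add((y, x))
            assert got == expected

    def test_shift_invariance_of_prominence_rule(self):
        rng = np.random.default_rng(11)
        cell = rectangle_cell()
        vals = rng.random(cell.mask.shape)
        img = _img_for(cell, vals)
        base = detect_point_maxima(img, cell)
        shifted = detect_point_maxima(img + 100.0, cell)
        assert [f.centroid for f in base] == [f.centroid for f in shifted]

    @pytest.mark.parametrize(
        "state,expected", [("midcell", 1), ("quarter", 2), ("periseptal", 2)]
    )
    def test_state_templates_yield_expected_maxima(
        self, single_cell_by_state, state, expected
    ):
        _, dna, cell, _ = single_cell_by_state[state]
        assert len(detect_point_maxima(dna, cell)) == expected

    def test_multifocal_template_yields_more_than_two_maxima(
        self, single_cell_by_state
    ):
        _, dna, cell, _ = single_cell_by_state["multifocal"]
        assert len(detect_point_maxima(dna, cell)) > 2

    def test_midcell_maximum_sits_at_blob_center(self, single_cell_by_state):
        _, dna, cell, geom = single_cell_by_state["midcell"]
        (focus,) = detect_point_maxima(dna, cell)
        assert np.hypot(
            focus.centroid[0] - geom.center_yx[0],
            focus.centroid[1] - geom.center_yx[1],
        ) <= 1.5


class TestRegionFoci:
    def test_flat_cell_has_no_regions(self):
        cell = rectangle_cell()
        img = _img_for(cell, np.full(cell.mask.shape, 2.0))
        assert detect_region_foci(img, cell) == []

    @pytest.mark.parametrize(
        "state,expected", [("quarter", 2), ("midcell", 1), ("periseptal", 1)]
    )
    def test_state_templates_yield_expected_regions(
        self, single_cell_by_state, state, expected
    ):
        _, dna, cell, _ = single_cell_by_state[state]
        assert len(detect_region_foci(dna, cell)) == expected

    def test_periseptal_region_contains_both_maxima(self, single_cell_by_state):
        """The merged septal region holds two point maxima: the signature
        separating periseptal from quarter compaction."""
        _, dna, cell, _ = single_cell_by_state["periseptal"]
        (region,) = detect_region_foci(dna, cell)
        maxima = detect_point_maxima(dna, cell)
        pix = {tuple(p) for p in region.region_pixels}
        assert len(maxima) == 2
        assert all(
            (int(round(m.centroid[0])), int(round(m.centroid[1]))) in pix
            for m in maxima
        )

    def test_region_pixels_stay_inside_cell_mask(self, single_cell_by_state):
        for state in ("quarter", "midcell", "periseptal"):
            _, dna, cell, _ = single_cell_by_state[state]
            for region in detect_region_foci(dna, cell):
                for y, x in region.region_pixels:
                    assert cell.contains(y, x)


def _focus(frame, y, x, focus_id=0):
    return FocusRecord(
        focus_id=focus_id, channel="recn", frame=frame, cell_id=0,
        kind="point_maximum", centroid=(float(y), float(x)), axial_s_um=0.0,
        peak_intensity=1.0,
    )


class TestTrackFoci:
    def test_static_focus_yields_one_full_trajectory(self):
        frames = [[_focus(f, 10.0, 10.0)] for f in range(20)]
        tracks = track_foci(frames, min_lifespan=5)
        assert len(tracks) == 1
        assert tracks[0].lifespan_frames == 20

    def test_four_frame_focus_discarded_by_lifespan_rule(self):
        frames = [[_focus(f, 10.0, 10.0)] for f in range(4)] + [[]] * 6
        assert track_foci(frames, min_lifespan=5) == []

    def test_two_distant_static_foci_never_swap(self):
        frames = [
            [_focus(f, 10.0, 10.0, 0), _focus(f, 10.0, 40.0, 1)]
            for f in range(12)
        ]
        tracks = track_foci(frames, min_lifespan=5, max_disp_px=5.0)
        assert len(tracks) == 2
        for t in tracks:
            xs = {round(f.centroid[1]) for f in t.foci}
            assert len(xs) == 1  # each trajectory stays at one position

    def test_jump_beyond_max_displacement_starts_new_trajectory(self):
        frames = [[_focus(f, 10.0, 10.0)] for f in range(6)]
        frames += [[_focus(f, 10.0, 30.0)] for f in range(6, 12)]
        tracks = track_foci(frames, min_lifespan=5, max_disp_px=5.0)
        assert len(tracks) == 2
        assert sorted(t.lifespan_frames for t in tracks) == [6, 6]


class TestRelativeMidcellDistance:
    def _cell_and_focus(self, s_um, length_um=4.0):
        cell = rectangle_cell(height=9, width=int(length_um / 0.1))
        # place the focus centroid on the axis at arc-length s_um
        frac = np.clip(s_um / cell.length_um, 0.0, 1.0)
        idx = int(round(frac * (len(cell.axis) - 1)))
        y, x = cell.axis[idx]
        focus = FocusRecord(
            focus_id=0, channel="dna", frame=0, cell_id=0,
            kind="point_maximum", centroid=(float(y), float(x)),
            axial_s_um=s_um, peak_intensity=1.0,
        )
        return cell, focus

    def test_midcell_focus_scores_zero(self):
        cell, focus = self._cell_and_focus(2.0, length_um=4.0)
        focus.axial_s_um = cell.length_um / 2
        assert relative_midcell_distance(focus, cell) == 0.0

    def test_pole_focus_scores_half(self):
        cell, focus = self._cell_and_focus(0.5)  # centroid safely in-mask
        focus.axial_s_um = 0.0  # axial position exactly at pole A
        assert relative_midcell_distance(focus, cell) == 0.5

    def test_worked_arithmetic_example(self):
        """L = 4 um, s = 3 um -> |3 - 2| / 4 = 0.25."""
        cell, focus = self._cell_and_focus(3.0, length_um=4.0)
        focus.axial_s_um = 3.0
        cell.length_um = 4.0
        assert relative_midcell_distance(focus, cell) == pytest.approx(0.25)

    def test_focus_outside_cell_rejected(self):
        cell, focus = self._cell_and_focus(2.0)
        focus.centroid = (0.0, 0.0)
        with pytest.raises(ValueError):
            relative_midcell_distance(focus, cell)
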