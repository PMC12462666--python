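"""Colocalization rule and replicate-level statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from nucleotrack.coloc import (
    coloc_fraction_timeseries,
    colocalize,
    foci_count_timeseries,
    midcell_proximity_contrast,
    welch_holm_sidak,
    welch_t,
)
from nucleotrack.records import FocusRecord


def _region(frame=0, y0=10, x0=10, h=5, w=5):
    yy, xx = np.mgrid[y0 : y0 + h, x0 : x0 + w]
    pix = np.column_stack([yy.ravel(), xx.ravel()])
    return FocusRecord(
        focus_id=0, channel="dna", frame=frame, cell_id=0, kind="region_focus",
        centroid=(y0 + h / 2, x0 + w / 2), axial_s_um=0.0, peak_intensity=1.0,
        region_pixels=pix, area_um2=h * w * 0.01,
    )


def _point(frame, y, x):
    return FocusRecord(
        focus_id=1, channel="recn", frame=frame, cell_id=0,
        kind="point_maximum", centroid=(float(y), float(x)), axial_s_um=0.0,
        peak_intensity=1.0,
    )


class TestColocalizeRule:
    def test_centroid_inside_region_margin_zero(self):
        assert colocalize(_point(0, 12, 12), [_region()], margin_px=0)

    def test_one_pixel_outside_needs_margin_one(self):
        query = _point(0, 10, 9)  # exactly 1 px left of the region
        assert not colocalize(query, [_region()], margin_px=0)
        assert colocalize(query, [_region()], margin_px=1)

    def test_two_pixels_outside_fails_margin_one(self):
        query = _point(0, 10, 8)
        assert not colocalize(query, [_region()], margin_px=1)
        assert colocalize(query, [_region()], margin_px=2)

    def test_diagonal_margin_uses_8_connectivity(self):
        query = _point(0, 9, 9)  # diagonal corner neighbour
        assert colocalize(query, [_region()], margin_px=1)

    def test_monotone_in_margin_on_random_scenes(self):
        rng = np.random.default_rng(14)
        for _ in range(30):
            regions = [
                _region(y0=int(rng.integers(5, 40)), x0=int(rng.integers(5, 40)),
                        h=int(rng.integers(2, 6)), w=int(rng.integers(2, 6)))
            ]
            q = _point(0, int(rng.integers(0, 50)), int(rng.integers(0, 50)))
            results = [
                colocalize(q, regions, margin_px=m, shape=(60, 60))
                for m in range(5)
            ]
            # once true, stays true for all larger margins
            assert results == sorted(results)

    def test_whole_cell_reference_saturates(self):
        big = _region(y0=0, x0=0, h=50, w=50)
        rng = np.random.default_rng(15)
        for _ in range(10):
            q = _point(0, int(rng.integers(0, 50)), int(rng.integers(0, 50)))
            assert colocalize(q, [big], margin_px=0, shape=(50, 50))

    def test_frame_mismatch_rejected(self):
        with pytest.raises(ValueError):
            colocalize(_point(1, 12, 12), [_region(frame=0)])


class TestFractionTimeseries:
    def test_fixture_fractions(self):
        records = pd.DataFrame(
            dict(
                replicate=["a"] * 10,
                frame=[0] * 10,
                colocalized=[True] * 3 + [False] * 7,
            )
        )
        out = coloc_fraction_timeseries(records)
        assert out.iloc[0]["fraction"] == pytest.approx(0.3)

    def test_all_colocalized_gives_one(self):
        records = pd.DataFrame(
            dict(replicate=["a", "a", "b"], frame=[0, 0, 0],
                 colocalized=[True, True, True])
        )
        assert coloc_fraction_timeseries(records).iloc[0]["fraction"] == 1.0

    def test_planted_rate_recovered_within_binomial_ci(self):
        rng = np.random.default_rng(16)
        p, n = 0.4, 4000
        records = pd.DataFrame(
            dict(replicate=["a"] * n, frame=[0] * n,
                 colocalized=rng.random(n) < p)
        )
        got = coloc_fraction_timeseries(records).iloc[0]["fraction"]
        assert abs(got - p) < 2.58 * np.sqrt(p * (1 - p) / n)


class TestProximityContrast:
    @staticmethod
    def _records(deltas, base=0.3, n_foci=50):
        rows = []
        for i, d in enumerate(deltas):
            for _ in range(n_foci):
                rows.append(dict(replicate=f"r{i}", colocalized=True,
                                 rel_midcell_distance=base + d))
                rows.append(dict(replicate=f"r{i}", colocalized=False,
                                 rel_midcell_distance=base))
        return pd.DataFrame(rows)

    def test_closed_form_t_statistic(self):
        deltas = (-0.02, -0.03, -0.04)
        res = midcell_proximity_contrast(self._records(deltas))
        d = np.array(deltas)
        t_expected = d.mean() / (d.std(ddof=1) / np.sqrt(3))
        assert res.mean == pytest.approx(-0.03)
        assert res.t == pytest.approx(t_expected, abs=1e-10)
        # cross-check p against an independent implementation
        assert res.p == pytest.approx(
            sps.ttest_1samp(d, 0.0).pvalue, abs=1e-12
        )

    def test_all_zero_deltas_degenerate_path(self):
        res = midcell_proximity_contrast(self._records((0.0, 0.0, 0.0)))
        assert res.t == 0.0
        assert res.p == 1.0

    def test_planted_shift_recovered_within_ci(self):
        rng = np.random.default_rng(17)
        delta = -0.05
        rows = []
        for rep in range(3):
            rows += [
                dict(replicate=f"r{rep}", colocalized=True,
                     rel_midcell_distance=v)
                for v in rng.normal(0.25 + delta, 0.05, 200)
            ]
            rows += [
                dict(replicate=f"r{rep}", colocalized=False,
                     rel_midcell_distance=v)
                for v in rng.normal(0.25, 0.05, 200)
            ]
        res = midcell_proximity_contrast(pd.DataFrame(rows))
        assert res.ci95[0] < delta < res.ci95[1]

    def test_replicate_with_empty_group_dropped(self):
        df = self._records((-0.02, -0.03, -0.04))
        df = pd.concat(
            [df, pd.DataFrame([dict(replicate="r9", colocalized=True,
                                    rel_midcell_distance=0.1)])]
        )
        res = midcell_proximity_contrast(df)
        assert res.dropped_replicates == ["r9"]

    def test_fewer_than_two_usable_replicates_rejected(self):
        with pytest.raises(ValueError):
            midcell_proximity_contrast(self._records((-0.02,)))


class TestWelchHolmSidak:
    def test_identical_groups_give_p_one(self):
        a = np.array([1.0, 2.0, 3.0])
        t, df, p = welch_t(a, a.copy())
        assert t == 0.0
        assert p == 1.0

    def test_formulas_match_independent_implementation(self):
        """t and Satterthwaite df agree with scipy's Welch test to 1e-10
        on 100 random small datasets."""
        rng = np.random.default_rng(18)
        for _ in range(100):
            a = rng.normal(0, 1 + rng.random(), rng.integers(3, 12))
            b = rng.normal(rng.random(), 1 + rng.random(), rng.integers(3, 12))
            t, df, p = welch_t(a, b)
            ref = sps.ttest_ind(a, b, equal_var=False)
            assert t == pytest.approx(ref.statistic, abs=1e-10)
            assert df == pytest.approx(ref.df, abs=1e-10)
            assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_holm_sidak_matches_stepdown_formula(self):
        """p_adj(i) = max_{j<=i} 1 - (1 - p_(j))^(m - j + 1), clipped at 1."""
        rng = np.random.default_rng(19)
        groups_a = [rng.normal(0, 1, 6) for _ in range(4)]
        groups_b = [rng.normal(mu, 1, 6) for mu in (0.1, 2.0, 1.0, 0.0)]
        out = welch_holm_sidak(groups_a, groups_b)
        p_raw = out["p_raw"].to_numpy()
        m = len(p_raw)
        order = np.argsort(p_raw)
        expected = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            adj = 1.0 - (1.0 - p_raw[idx]) ** (m - rank)
            running = max(running, adj)
            expected[idx] = min(1.0, running)
        assert np.allclose(out["p_adj"].to_numpy(), expected, atol=1e-12)
        # monotone in rank, never below raw
        assert (out["p_adj"] >= out["p_raw"] - 1e-15).all()

    def test_zero_variance_equal_means_p_one(self):
        out = welch_holm_sidak([np.array([2.0, 2.0])], [np.array([2.0, 2.0])])
        assert out.iloc[0]["p_raw"] == 1.0
        assert out.iloc[0]["p_adj"] == 1.0


class TestFociCountTimeseries:
    def test_fixture_mean(self):
        foci = pd.DataFrame(dict(replicate=["a"], frame=[0], n_foci=[6]))
        cells = pd.DataFrame(dict(replicate=["a"], frame=[0], n_cells=[3]))
        out = foci_count_timeseries(foci, cells)
        assert out.iloc[0]["mean_foci_per_cell"] == pytest.approx(2.0)

    def test_no_foci_gives_zero(self):
        foci = pd.DataFrame(dict(replicate=[], frame=[], n_foci=[]))
        cells = pd.DataFrame(dict(replicate=["a"], frame=[0], n_cells=[5]))
        out = foci_count_timeseries(foci, cells)
        assert out.iloc[0]["mean_foci_per_cell"] == 0.0

    def test_zero_cell_frames_flagged(self):
        foci = pd.DataFrame(dict(replicate=["a"], frame=[0], n_foci=[2]))
        cells = pd.DataFrame(dict(replicate=["a"], frame=[0], n_cells=[0]))
        out = foci_count_timeseries(foci, cells)
        assert out.iloc[0]["flagged_zero_cells"] == 1
        assert np.isnan(out.iloc[0]["mean_foci_per_cell"])
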