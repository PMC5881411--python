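import numpy as np
import pytest

import landfuse as lf
from landfuse.validation import Z95, format_report


def fused_map(grid, codes):
    return lf.CategoricalRaster(grid, np.asarray(codes, dtype=np.int64), 0, (1, 2, 3), "fused")


def record(i, lat, lon, cid):
    return lf.ValidationRecord(id=i, lat=lat, lon=lon, class_id=cid)


@pytest.fixture
def uniform_map():
    g = lf.GridSpec(10.0, 30.0, 55.0, 10, 10)
    codes = np.ones((10, 10), dtype=np.int64)
    codes[:, 4:7] = 2
    codes[:, 7:] = 3
    return fused_map(g, codes)


# -- allocate_sample ---------------------------------------------------------

class TestAllocateSample:
    def regions(self, grid, code=1):
        return lf.CategoricalRaster(
            grid, np.full(grid.shape, code, dtype=np.int64), 0, (code,), "regions"
        )

    def test_srs_within_stratum_is_distinct_and_reproducible(self, uniform_map):
        regions = self.regions(uniform_map.grid)
        s1 = lf.allocate_sample(uniform_map, regions, {(1, 1): 10}, seed=3)
        s2 = lf.allocate_sample(uniform_map, regions, {(1, 1): 10}, seed=3)
        assert len(s1) == 10
        assert s1[["row", "col"]].drop_duplicates().shape[0] == 10
        # every sampled cell is mapped arable
        assert (uniform_map.codes[s1.row, s1.col] == 1).all()
        assert s1.equals(s2)

    def test_zero_size_and_overdraw(self, uniform_map):
        regions = self.regions(uniform_map.grid)
        assert len(lf.allocate_sample(uniform_map, regions, {(1, 1): 0}, seed=1)) == 0
        with pytest.raises(ValueError, match="region=1"):
            lf.allocate_sample(uniform_map, regions, {(1, 2): 1000}, seed=1)

    def test_regional_totals_match_requests(self):
        # six regions, sizes as published for the regional validation campaign
        totals = {1: 1504, 2: 911, 3: 923, 4: 915, 5: 922, 6: 797}
        g = lf.GridSpec(10.0, 30.0, 55.0, 120, 120)
        rng = np.random.default_rng(0)
        fused = fused_map(g, rng.integers(1, 4, size=g.shape))
        region_codes = 1 + (np.arange(g.n_cols) * 6) // g.n_cols
        regions = lf.CategoricalRaster(
            g, np.broadcast_to(region_codes, g.shape).copy(), 0, tuple(range(1, 7)), "regions"
        )
        sizes = {}
        for reg, tot in totals.items():
            base = tot // 3
            sizes[(reg, 1)] = base
            sizes[(reg, 2)] = base
            sizes[(reg, 3)] = tot - 2 * base
        sample = lf.allocate_sample(fused, regions, sizes, seed=9)
        got = sample.groupby("region").size().to_dict()
        assert got == totals
        assert len(sample) == 5972


# -- build_confusion ---------------------------------------------------------

class TestBuildConfusion:
    def test_ambiguous_record_splits_half_and_half(self, uniform_map):
        lon, lat = uniform_map.grid.cell_center(0, 0)  # mapped arable
        conf = lf.build_confusion(uniform_map, [record(1, float(lat), float(lon), 12)])[0]
        assert conf.matrix[0, 0] == 0.5
        assert conf.matrix[0, 1] == 0.5
        assert conf.total_mass == 1.0

    def test_unambiguous_record_adds_one(self, uniform_map):
        lon, lat = uniform_map.grid.cell_center(0, 0)
        conf = lf.build_confusion(uniform_map, [record(1, float(lat), float(lon), 2)])[0]
        assert conf.matrix[0, 1] == 1.0
        assert conf.matrix.sum() == 1.0

    def test_conservation_of_mass_on_random_records(self, uniform_map):
        rng = np.random.default_rng(21)
        g = uniform_map.grid
        ids = np.array([1, 2, 3, 12, 13, 23])
        records = []
        for i in range(500):
            r, c = rng.integers(0, 10), rng.integers(0, 10)
            lon, lat = g.cell_center(int(r), int(c))
            records.append(record(i, float(lat), float(lon), int(rng.choice(ids))))
        conf = lf.build_confusion(uniform_map, records)[0]
        assert conf.total_mass == pytest.approx(500.0, abs=1e-9)
        assert conf.n_discarded == 0

    def test_records_on_nodata_are_discarded_with_tally(self):
        g = lf.GridSpec(10.0, 30.0, 55.0, 1, 2)
        fused = fused_map(g, [[1, 0]])
        lon0, lat0 = g.cell_center(0, 0)
        lon1, lat1 = g.cell_center(0, 1)
        conf = lf.build_confusion(
            fused,
            [record(1, float(lat0), float(lon0), 1), record(2, float(lat1), float(lon1), 1)],
        )[0]
        assert conf.total_mass == 1.0
        assert conf.n_discarded == 1

    def test_per_region_matrices(self, uniform_map):
        g = uniform_map.grid
        region_codes = np.ones(g.shape, dtype=np.int64)
        region_codes[:, 5:] = 2
        regions = lf.CategoricalRaster(g, region_codes, 0, (1, 2), "regions")
        lon_w, lat_w = g.cell_center(0, 0)
        lon_e, lat_e = g.cell_center(0, 9)
        out = lf.build_confusion(
            uniform_map,
            [record(1, float(lat_w), float(lon_w), 1), record(2, float(lat_e), float(lon_e), 3)],
            regions,
        )
        assert set(out) == {1, 2}
        assert out[1].total_mass == 1.0 and out[2].total_mass == 1.0


# -- accuracy_report / adjusted_areas ----------------------------------------

class TestOlofssonEstimators:
    def test_perfect_map(self):
        conf = lf.FractionalConfusion(np.diag([30.0, 10.0, 60.0]))
        rep = lf.accuracy_report(conf, np.array([0.3, 0.1, 0.6]))
        assert rep.overall == pytest.approx(100.0)
        np.testing.assert_allclose(rep.users, 100.0)
        np.testing.assert_allclose(rep.producers, 100.0)
        assert rep.overall_se == 0.0
        areas = lf.adjusted_areas(conf, np.array([0.3, 0.1, 0.6]), total_area=200.0)
        np.testing.assert_allclose(areas.adjusted_area, areas.mapped_area)
        np.testing.assert_allclose(areas.ci95, 0.0)

    def test_two_class_overall_accuracy_example(self):
        """W = (0.8, 0.2), 50 samples each, 45 and 40 correct -> OA = 88%."""
        m = np.array([[45.0, 5.0, 0.0], [10.0, 40.0, 0.0], [0.0, 0.0, 0.0]])
        rep = lf.accuracy_report(lf.FractionalConfusion(m), np.array([0.8, 0.2, 0.0]))
        assert rep.overall == pytest.approx(88.0, abs=1e-12)
        assert rep.users[0] == pytest.approx(90.0, abs=1e-12)
        assert rep.users[1] == pytest.approx(80.0, abs=1e-12)

    def test_two_class_adjusted_proportion_example(self):
        """W=(0.9,0.1), 100 samples each, n11=95, n21=20 -> p_.1 = 0.875."""
        m = np.array([[95.0, 5.0, 0.0], [20.0, 80.0, 0.0], [0.0, 0.0, 0.0]])
        areas = lf.adjusted_areas(lf.FractionalConfusion(m), np.array([0.9, 0.1, 0.0]), 1.0)
        assert areas.adjusted_area[0] == pytest.approx(0.875, abs=1e-12)
        # class absent from map and reference has zero area and zero CI
        assert areas.adjusted_area[2] == 0.0 and areas.ci95[2] == 0.0

    def test_cell_proportions_and_adjusted_areas_sum_to_totals(self):
        rng = np.random.default_rng(17)
        m = rng.uniform(0, 20, size=(3, 3)) + np.diag(rng.uniform(20, 50, 3))
        m += 0.5 * (rng.random((3, 3)) < 0.3)  # fractional cells
        W = rng.dirichlet(np.ones(3))
        conf = lf.FractionalConfusion(m)
        areas = lf.adjusted_areas(conf, W, total_area=123.0)
        assert areas.adjusted_area.sum() == pytest.approx(123.0, abs=1e-9)
        n_i = m.sum(axis=1)
        p = W[:, None] * m / n_i[:, None]
        assert p.sum() == pytest.approx(1.0, abs=1e-12)

    def test_random_reference_labels_drive_overall_to_one_third(self):
        rng = np.random.default_rng(31)
        n_per = 1000
        m = np.zeros((3, 3))
        for i in range(3):
            m[i] = np.bincount(rng.integers(0, 3, size=n_per), minlength=3)
        rep = lf.accuracy_report(lf.FractionalConfusion(m), np.full(3, 1 / 3))
        assert rep.overall == pytest.approx(100 / 3, abs=3.0)

    def test_integer_confusion_matches_hand_computed_reference(self):
        """Cross-check every estimator against an independent from-scratch
        computation of the stratified formulas on an integer matrix."""
        m = np.array([[97.0, 0.0, 3.0], [3.0, 279.0, 18.0], [2.0, 1.0, 97.0]])
        W = np.array([0.2, 0.6, 0.2])
        conf = lf.FractionalConfusion(m)
        rep = lf.accuracy_report(conf, W)
        areas = lf.adjusted_areas(conf, W, total_area=1.0)

        n_i = m.sum(axis=1)
        p = W[:, None] * m / n_i[:, None]
        oa = p.trace()
        users = np.diag(m) / n_i
        producers = np.diag(p) / p.sum(axis=0)
        assert rep.overall == pytest.approx(100 * oa, abs=1e-12)
        np.testing.assert_allclose(rep.users, 100 * users, atol=1e-12)
        np.testing.assert_allclose(rep.producers, 100 * producers, atol=1e-12)

        var_oa = np.sum(W**2 * users * (1 - users) / (n_i - 1))
        assert rep.overall_se == pytest.approx(100 * np.sqrt(var_oa), abs=1e-12)

        se_area = np.sqrt([
            np.sum(W**2 * (m[:, j] / n_i) * (1 - m[:, j] / n_i) / (n_i - 1))
            for j in range(3)
        ])
        np.testing.assert_allclose(areas.ci95, Z95 * se_area, atol=1e-12)

        # producer's SE, spelled out for one class
        j = 1
        Nj = p[:, j].sum()
        t1 = W[j] ** 2 * (1 - producers[j]) ** 2 * users[j] * (1 - users[j]) / (n_i[j] - 1)
        t2 = sum(
            W[i] ** 2 * (m[i, j] / n_i[i]) * (1 - m[i, j] / n_i[i]) / (n_i[i] - 1)
            for i in range(3) if i != j
        )
        se_pj = np.sqrt((t1 + producers[j] ** 2 * t2) / Nj**2)
        assert rep.producers_se[j] == pytest.approx(100 * se_pj, abs=1e-12)

    def test_zero_sample_mapped_class_reports_nan_users(self):
        m = np.array([[40.0, 5.0, 5.0], [5.0, 40.0, 5.0], [0.0, 0.0, 0.0]])
        rep = lf.accuracy_report(lf.FractionalConfusion(m), np.array([0.5, 0.5, 0.0]))
        assert np.isnan(rep.users[2])

    def test_bad_weights_rejected(self):
        conf = lf.FractionalConfusion(np.diag([10.0, 10.0, 10.0]))
        with pytest.raises(ValueError):
            lf.accuracy_report(conf, np.array([0.5, 0.5, 0.5]))

    def test_monte_carlo_ci_coverage(self):
        """95% CIs for the adjusted class area cover the true area in about
        95% of repeated stratified validation samples."""
        rng = np.random.default_rng(2024)
        W = np.array([0.35, 0.15, 0.50])
        # truth distribution within each mapped stratum (rows)
        Q = np.array([[0.85, 0.10, 0.05], [0.20, 0.70, 0.10], [0.05, 0.10, 0.85]])
        true_area = W @ Q  # true proportion of each reference class
        n_i = np.array([100, 100, 100])
        hits = np.zeros(3)
        n_rep = 1000
        for _ in range(n_rep):
            m = np.stack([rng.multinomial(n_i[i], Q[i]) for i in range(3)]).astype(float)
            est = lf.adjusted_areas(lf.FractionalConfusion(m), W, total_area=1.0)
            hits += np.abs(est.adjusted_area - true_area) <= est.ci95
        coverage = hits / n_rep
        assert (np.abs(coverage - 0.95) <= 0.03).all()


# -- change_summary ----------------------------------------------------------

class TestChangeSummary:
    def grid(self, n):
        return lf.GridSpec(10.0, 30.0, 55.0, 1, n)

    def test_identical_maps_have_no_change(self):
        g = self.grid(5)
        m = fused_map(g, [[1, 1, 2, 3, 1]])
        assert lf.change_summary(m, m, 1) == (0.0, 0.0)

    def test_loss_and_gain_fractions(self):
        g = self.grid(200)
        t1 = np.full((1, 200), 3, dtype=np.int64)
        t1[0, :100] = 1  # 100 class-1 cells at t1
        t2 = t1.copy()
        t2[0, :10] = 3  # lose 10
        t2[0, 150:180] = 1  # gain 30
        loss, gain = lf.change_summary(fused_map(g, t1), fused_map(g, t2), 1)
        assert loss == pytest.approx(10.0)
        assert gain == pytest.approx(30.0)

    def test_empty_class_at_t1_falls_back_to_map_area(self):
        g = self.grid(10)
        t1 = fused_map(g, [[3] * 10])
        t2c = np.full((1, 10), 3, dtype=np.int64)
        t2c[0, :2] = 1
        loss, gain = lf.change_summary(t1, fused_map(g, t2c), 1)
        assert loss == 0.0
        assert gain == pytest.approx(20.0)

    def test_grid_mismatch_raises(self):
        m1 = fused_map(self.grid(5), [[1] * 5])
        m2 = fused_map(self.grid(6), [[1] * 6])
        with pytest.raises(lf.AlignmentError):
            lf.change_summary(m1, m2, 1)


def test_format_report_mentions_every_class(uniform_map):
    conf = lf.FractionalConfusion(np.diag([10.0, 10.0, 10.0]))
    rep = lf.accuracy_report(conf, np.full(3, 1 / 3))
    text = format_report(rep)
    for name in ("arable", "abandoned", "other"):
        assert name in text
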