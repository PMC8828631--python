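"""Image measurement: exactness against brute-force pixel oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pgmorph as pg
from pgmorph.synthetic import MASK_PG_BASE


def brute_union_find_clusters(centers, radii, contact_gap, min_size):
    """Independent oracle: explicit union-find over all pairs."""
    n = len(radii)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            d = np.hypot(centers[i][0] - centers[j][0],
                         centers[i][1] - centers[j][1])
            if d <= radii[i] + radii[j] + contact_gap:
                parent[find(i)] = find(j)
    sizes = {}
    for i in range(n):
        sizes[find(i)] = sizes.get(find(i), 0) + 1
    return sum(1 for s in sizes.values() if s >= min_size)


class TestCalibrateScale:
    def test_bar_division(self):
        assert pg.calibrate_scale(200, 1000).nm_per_pixel == pytest.approx(5)
        assert pg.calibrate_scale(1, 1).nm_per_pixel == pytest.approx(1)

    @pytest.mark.parametrize("px,nm", [(0, 100), (100, 0), (-5, 100)])
    def test_non_positive_inputs_rejected(self, px, nm):
        with pytest.raises(ValueError):
            pg.calibrate_scale(px, nm)

    def test_absent_scale_restricts_downstream(self):
        scale = pg.ABSENT_SCALE
        assert not scale.known
        with pytest.raises(ValueError):
            pg.PixelScale(None, "metadata")


class TestSegmentScene:
    def _scene(self, seed=0, n=6):
        params = pg.PopulationParams(cluster_fraction=0.0)
        truth = pg.sample_population(params, 1, seed=seed,
                                     image_size=256)[0]
        return truth, pg.render_scene(truth, image_size=256, noise_sd=3.0,
                                      seed=seed)

    def test_mask_measurement_matches_brute_pixel_loops(self):
        _, (img, mask) = self._scene(seed=11)
        objects = pg.segment_scene(img, mask)
        pg_objects = [o for o in objects if o.role == "pg"]
        # oracle: explicit python loop per PG label
        for pid in np.unique(mask[mask >= MASK_PG_BASE]):
            total, count, rsum, csum = 0.0, 0, 0.0, 0.0
            for r in range(mask.shape[0]):
                for c in range(mask.shape[1]):
                    if mask[r, c] == pid:
                        total += float(img[r, c])
                        count += 1
                        rsum += r
                        csum += c
            match = [o for o in pg_objects
                     if o.pixel_area == count
                     and o.mean_grey == pytest.approx(total / count)
                     and o.centroid[0] == pytest.approx(rsum / count)]
            assert match, f"no measured object matches label {pid}"

    def test_rasterised_disk_area_near_continuous(self):
        truth = pg.SceneGroundTruth(
            center=(128.0, 128.0), semi_axes=(100.0, 110.0),
            starch_blobs=[], pg_disks=[(128.0, 128.0, 10.0)])
        img, mask = pg.render_scene(truth, image_size=256, noise_sd=0.0)
        area = [o for o in pg.segment_scene(img, mask)
                if o.role == "pg"][0].pixel_area
        assert area == pytest.approx(100 * np.pi, rel=0.05)

    def test_threshold_mode_recovers_objects_without_mask(self):
        truth = pg.SceneGroundTruth(
            center=(128.0, 128.0), semi_axes=(90.0, 110.0),
            starch_blobs=[(100.0, 100.0, 15.0, 20.0)],
            pg_disks=[(128.0, 160.0, 6.0), (150.0, 110.0, 4.0),
                      (90.0, 128.0, 8.0), (160.0, 160.0, 3.0)])
        img, _ = pg.render_scene(truth, image_size=256, noise_sd=3.0, seed=1)
        objects = pg.segment_scene(img)  # no mask: grey thresholds only
        roles = {o.role for o in objects}
        assert {"chloroplast", "vacuole_ref", "starch"} <= roles
        assert sum(o.role == "pg" for o in objects) == 4

    def test_uniform_image_has_no_chloroplast(self):
        flat = np.full((64, 64), 200, dtype=np.uint8)
        with pytest.raises(ValueError, match="no chloroplast"):
            pg.segment_scene(flat)


class TestMeasureChloroplast:
    def _objects(self, ca_px=40_000, vacuole=True):
        objs = [pg.ObjectMeasurement("chloroplast", ca_px, 120.0,
                                     (50.0, 50.0))]
        if vacuole:
            objs.append(pg.ObjectMeasurement("vacuole_ref", 5000, 200.0,
                                             (5.0, 5.0)))
        return objs

    def test_area_unit_conversion(self):
        rec = pg.measure_chloroplast(self._objects(),
                                     pg.PixelScale(5.0, "metadata"))
        assert rec.ca_um2 == pytest.approx(1.0)   # 40000 px * 25 nm^2

    def test_conversion_round_trips(self):
        rec = pg.measure_chloroplast(self._objects(ca_px=12_345),
                                     pg.PixelScale(7.3, "metadata"))
        back = rec.ca_um2 * 1e6 / 7.3 ** 2
        assert back == pytest.approx(12_345, rel=1e-12)

    def test_missing_vacuole_leaves_grey_null(self):
        rec = pg.measure_chloroplast(self._objects(vacuole=False),
                                     pg.PixelScale(5.0, "metadata"))
        assert rec.vacuole_grey is None

    def test_absent_scale_gives_scale_free_record(self):
        rec = pg.measure_chloroplast(self._objects(), pg.ABSENT_SCALE)
        assert rec.ca_um2 is None and rec.pg_areas_um2 is None
        assert rec.ca_px == 40_000   # pixel data kept

    def test_requires_exactly_one_chloroplast(self):
        objs = self._objects() + [pg.ObjectMeasurement(
            "chloroplast", 100, 120.0, (9.0, 9.0))]
        with pytest.raises(ValueError, match="exactly one chloroplast"):
            pg.measure_chloroplast(objs, pg.ABSENT_SCALE)

    def test_pg_lists_ordered_by_decreasing_area(self):
        objs = self._objects()
        for area, grey in [(10, 40.0), (90, 20.0), (50, 30.0)]:
            objs.append(pg.ObjectMeasurement("pg", area, grey, (9.0, 9.0)))
        rec = pg.measure_chloroplast(objs, pg.PixelScale(5.0, "metadata"))
        assert rec.pg_px == [90, 50, 10]
        assert rec.pg_greys == [20.0, 30.0, 40.0]

    def test_measured_diameter_within_two_pixels_of_truth(self, scale):
        for radius_px in (3.0, 5.0, 9.0, 15.0):
            truth = pg.SceneGroundTruth(
                center=(128.0, 128.0), semi_axes=(100.0, 110.0),
                starch_blobs=[],
                pg_disks=[(120.0, 120.0, radius_px)])
            img, mask = pg.render_scene(truth, image_size=256, noise_sd=0.0)
            rec = pg.measure_scene(img, mask, scale)
            diam = pg.diameter_from_area(rec.pg_areas_um2[0], units="um2")
            true_nm = 2 * radius_px * truth.nm_per_pixel
            assert abs(diam - true_nm) <= 2 * truth.nm_per_pixel


class TestCountClusters:
    def test_touching_pair_is_one_cluster(self):
        assert pg.count_clusters([(0, 0), (2, 0)], [1.0, 1.0],
                                 contact_gap=0.0, min_size=2) == 1

    def test_distant_disks_form_no_cluster(self):
        assert pg.count_clusters([(0, 0), (10, 0), (0, 10)], [1.0] * 3,
                                 contact_gap=0.0, min_size=2) == 0

    def test_chain_of_twelve_is_one_grape_like_cluster(self):
        centers = [(0.0, 2.0 * k) for k in range(12)]
        assert pg.count_clusters(centers, [1.0] * 12,
                                 contact_gap=0.0, min_size=2) == 1

    def test_strict_min_size_excludes_pairs(self):
        assert pg.count_clusters([(0, 0), (2, 0)], [1.0, 1.0],
                                 contact_gap=0.0, min_size=3) == 0

    def test_empty_input(self):
        assert pg.count_clusters(np.empty((0, 2)), [], contact_gap=0.0) == 0

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1), st.integers(2, 3))
    def test_matches_union_find_oracle(self, seed, min_size):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 50))
        centers = rng.uniform(0, 40, (n, 2))
        radii = rng.uniform(0.5, 4.0, n)
        gap = float(rng.uniform(0, 2))
        assert pg.count_clusters(centers, radii, contact_gap=gap,
                                 min_size=min_size) == \
            brute_union_find_clusters(centers.tolist(), radii.tolist(),
                                      gap, min_size)


class TestSelectChloroplasts:
    def _record(self, image_id, cid, ca_px=1000, visibility=1.0):
        return pg.ChloroplastRecord(
            image_id=image_id, chloroplast_id=cid, scale=pg.ABSENT_SCALE,
            ca_px=ca_px, starch_px=0, pg_px=[], pg_greys=[],
            vacuole_grey=None, visibility_fraction=visibility)

    def test_at_most_four_per_image_largest_first(self):
        records = [self._record("img1", i, ca_px=100 * (i + 1))
                   for i in range(6)]
        kept, log = pg.select_chloroplasts(records)
        assert len(kept) == 4
        assert {r.chloroplast_id for r in kept} == {2, 3, 4, 5}
        assert (log["reason"].str.contains("more than 4")).sum() == 2

    def test_visibility_boundary_inclusive_at_80pct(self):
        records = [self._record("img1", 0, visibility=0.79),
                   self._record("img1", 1, visibility=0.80)]
        kept, log = pg.select_chloroplasts(records)
        assert [r.chloroplast_id for r in kept] == [1]
        assert "visibility" in log.iloc[0]["reason"]

    def test_empty_input(self):
        kept, log = pg.select_chloroplasts([])
        assert kept == [] and len(log) == 0

    def test_tie_break_is_deterministic_by_id(self):
        records = [self._record("img1", cid, ca_px=500)
                   for cid in (5, 1, 3, 2, 4)]
        kept, _ = pg.select_chloroplasts(records, max_per_image=2)
        assert [r.chloroplast_id for r in kept] == [1, 2]


class TestTabularIO:
    def test_measurement_csv_round_trip(self, tmp_path, scale,
                                        pipeline_runner, two_arm_design):
        from pgmorph.cli import _frames_to_records

        study = pg.generate_study(two_arm_design(1.0, 1.0, 2),
                                  pg.PopulationParams(), seed=3,
                                  image_size=384)
        records = pipeline_runner(study, image_size=384)
        main, pgs = pg.write_measurements(records, tmp_path / "m.csv")
        import pandas as pd
        rebuilt = _frames_to_records(pd.read_csv(main), pd.read_csv(pgs))
        for orig, back in zip(records, rebuilt):
            assert back.ca_px == orig.ca_px
            assert back.pg_px == orig.pg_px
            assert back.pg_greys == pytest.approx(orig.pg_greys)
            assert back.n_clusters == orig.n_clusters
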