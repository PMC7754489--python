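"""Magnitude detrending, vessel identification, stripe geometry, censoring."""

import numpy as np
import pytest
from scipy import ndimage

from perfcensor import (
    MaskRaster,
    RunConfig,
    build_stripe_mask,
    censor,
    detrend_magnitude,
    ghost_fraction,
    identify_large_vessels,
    run_pipeline,
    synthesize,
)
from perfcensor.censoring import StripeMask, VesselCluster
from perfcensor.detection import PerforatorRecord
from perfcensor.exceptions import DegenerateInputError, ParameterError
from perfcensor.masking import CentralWMMask

from conftest import small_config, small_phantom_spec


def brute_force_stripe(clusters, shape, pe_axis):
    """Per-voxel offset enumeration oracle for stripe construction."""
    pe = 0 if pe_axis == "rows" else 1
    data = np.zeros(shape, dtype=bool)
    for cluster in clusters:
        for r, c in cluster.voxels:
            for d_ro in range(-cluster.dilate_px, cluster.dilate_px + 1):
                for d_pe in range(-cluster.extend_px, cluster.extend_px + 1):
                    pos = [r, c]
                    pos[pe] += d_pe
                    pos[1 - pe] += d_ro
                    if 0 <= pos[0] < shape[0] and 0 <= pos[1] < shape[1]:
                        data[pos[0], pos[1]] = True
    return data


def _record(i, row, col):
    return PerforatorRecord(
        id=i, row=row, col=col, cluster_id=i + 1, cluster_size=1,
        v_curve=np.full(4, -0.7), v_mean=-0.7, ci=(-0.75, -0.65),
    )


class TestDetrendMagnitude:
    def test_constant_image_maps_to_zero(self):
        np.testing.assert_allclose(detrend_magnitude(np.full((32, 32), 7.0), 7), 0.0)

    def test_bright_pixel_isolated(self, rng):
        img = np.full((32, 32), 100.0)
        img[16, 16] = 500.0
        out = detrend_magnitude(img, 7)
        assert out[16, 16] == pytest.approx(400.0)
        off = out.copy()
        off[16, 16] = 0
        assert np.abs(off).max() < 1e-12

    def test_even_window_uses_next_odd(self, rng):
        img = rng.normal(100, 5, size=(80, 80))
        np.testing.assert_array_equal(
            detrend_magnitude(img, 70),
            img - ndimage.median_filter(img, size=71, mode="reflect"),
        )

    def test_flattens_phantom_inhomogeneity(self):
        # full-size scene: the inhomogeneity field is smooth on scales well
        # above the 70-px window, which is the regime the detrend step assumes
        from perfcensor import PhantomSpec

        spec = PhantomSpec(
            n_big_vessels=0, n_perforators=0, noise_sd_magnitude=0.0,
            inhomogeneity_amplitude=0.2, seed=5,
        )
        series, truth = synthesize(spec)
        mean_mag = series.magnitude.mean(axis=2)
        interior = (
            ndimage.distance_transform_edt(truth.brain_mask.data) > 40
        )  # away from the brain edge taper
        pre_range = mean_mag[interior].max() - mean_mag[interior].min()
        out = detrend_magnitude(mean_mag, 70)
        assert np.abs(out[interior]).max() < 0.1 * pre_range

    def test_window_validation(self):
        with pytest.raises(ParameterError):
            detrend_magnitude(np.zeros((16, 16)), 2)
        with pytest.raises(ParameterError):
            detrend_magnitude(np.zeros((16, 16)), 30)


class TestIdentifyLargeVessels:
    def test_top_fraction_candidate_count(self, rng):
        # 1000 brain voxels with distinct intensities -> ceil(0.003*1000) = 3
        img = np.zeros((40, 40))
        brain = np.zeros((40, 40), dtype=np.uint8)
        flat = rng.permutation(1000).astype(float)
        brain.flat[:1000] = 1
        img.flat[:1000] = flat
        clusters = identify_large_vessels(
            img, MaskRaster(data=brain, kind="brain_slice"),
            top_fraction=0.003, min_cluster=1,
        )
        assert sum(c.size for c in clusters) == 3
        kept = {v for c in clusters for v in c.voxels}
        values = sorted(img[r, c] for r, c in kept)
        assert values == [997.0, 998.0, 999.0]

    def test_small_components_dropped(self):
        img = np.zeros((32, 32))
        brain = np.ones((32, 32), dtype=np.uint8)
        img[2, 2] = 50  # size 1
        img[10, 10:12] = 50  # size 2
        img[20, 20:23] = 50  # size 3
        clusters = identify_large_vessels(
            img, MaskRaster(data=brain, kind="brain_slice"),
            top_fraction=6 / 1024, min_cluster=3,
        )
        assert len(clusters) == 1
        assert clusters[0].voxels == frozenset({(20, 20), (20, 21), (20, 22)})

    def test_size_rule_at_cluster_threshold(self):
        # clusters of exactly 79 and 80 voxels: only the latter is "large"
        img = np.zeros((64, 64))
        brain = np.ones((64, 64), dtype=np.uint8)
        img[5:10, 5:21] = 100.0  # 5 x 16 = 80 voxels
        img[30:35, 30:46] = 100.0
        img[34, 45] = 0.0  # knock one voxel out: 79
        frac = 159 / (64 * 64)
        clusters = identify_large_vessels(
            img, MaskRaster(data=brain, kind="brain_slice"), top_fraction=frac
        )
        by_size = {c.size: c for c in clusters}
        assert set(by_size) == {80, 79}
        assert (by_size[80].dilate_px, by_size[80].extend_px) == (2, 200)
        assert (by_size[79].dilate_px, by_size[79].extend_px) == (1, 110)

    def test_threshold_ties_all_included(self):
        img = np.zeros((32, 32))
        brain = np.ones((32, 32), dtype=np.uint8)
        img[4, 4:10] = 42.0  # six tied voxels; ceil(0.003*1024) = 4 < 6
        clusters = identify_large_vessels(
            img, MaskRaster(data=brain, kind="brain_slice"), min_cluster=1
        )
        assert sum(c.size for c in clusters) == 6

    def test_phantom_vessels_recovered(self):
        spec = small_phantom_spec(seed=2, n_perforators=0, n_ghost_replicas=0)
        series, truth = synthesize(spec)
        detrended = detrend_magnitude(series.magnitude.mean(axis=2), 41)
        clusters = identify_large_vessels(detrended, truth.brain_mask)
        assert len(clusters) == len(truth.vessel_clusters)
        for found, planted in zip(
            sorted(clusters, key=lambda c: min(c.voxels)),
            sorted(truth.vessel_clusters, key=min),
        ):
            # recovered clusters may differ by edge voxels, not by location
            assert len(found.voxels & planted) / len(planted) > 0.8


class TestBuildStripeMask:
    def test_single_voxel_geometry(self):
        cluster = VesselCluster(
            voxels=frozenset({(128, 128)}), dilate_px=1, extend_px=110
        )
        stripes = build_stripe_mask([cluster], (256, 256), "rows")
        expected = np.zeros((256, 256), dtype=bool)
        expected[18:239, 127:130] = True  # rows 128 +/- 110, cols 128 +/- 1
        np.testing.assert_array_equal(stripes.data, expected)

    def test_empty_cluster_list(self):
        stripes = build_stripe_mask([], (64, 64), "rows")
        assert not stripes.data.any()

    def test_extension_clips_at_border(self):
        cluster = VesselCluster(voxels=frozenset({(5, 10)}), dilate_px=0, extend_px=500)
        stripes = build_stripe_mask([cluster], (64, 64), "rows")
        assert stripes.data[:, 10].all()
        assert stripes.data.sum() == 64  # full pe span, single readout line

    def test_pe_axis_cols_transposes_geometry(self):
        cluster = VesselCluster(voxels=frozenset({(20, 20)}), dilate_px=1, extend_px=10)
        by_rows = build_stripe_mask([cluster], (64, 64), "rows")
        by_cols = build_stripe_mask([cluster], (64, 64), "cols")
        np.testing.assert_array_equal(by_rows.data.T, by_cols.data)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(20):
            shape = (int(rng.integers(24, 64)), int(rng.integers(24, 64)))
            pe_axis = "rows" if rng.uniform() < 0.5 else "cols"
            clusters = []
            for _ in range(int(rng.integers(1, 5))):
                n_vox = int(rng.integers(1, 8))
                voxels = frozenset(
                    (int(rng.integers(shape[0])), int(rng.integers(shape[1])))
                    for _ in range(n_vox)
                )
                clusters.append(
                    VesselCluster(
                        voxels=voxels,
                        dilate_px=int(rng.integers(0, 4)),
                        extend_px=int(rng.integers(0, 30)),
                    )
                )
            ours = build_stripe_mask(clusters, shape, pe_axis)
            np.testing.assert_array_equal(
                ours.data, brute_force_stripe(clusters, shape, pe_axis)
            )

    def test_total_extend_mode_halves_growth(self):
        cluster = VesselCluster(voxels=frozenset({(32, 32)}), dilate_px=0, extend_px=20)
        per_side = build_stripe_mask([cluster], (64, 64), "rows", extend_mode="per_side")
        total = build_stripe_mask([cluster], (64, 64), "rows", extend_mode="total")
        assert per_side.data[:, 32].sum() == 41
        assert total.data[:, 32].sum() == 21


class TestCensor:
    def test_empty_stripes_include_all(self):
        stripes = StripeMask(data=np.zeros((64, 64), bool), clusters=(), pe_axis="rows")
        records = [_record(0, 10, 10), _record(1, 20, 20)]
        included, excluded = censor(records, stripes)
        assert [r.id for r in included] == [0, 1] and excluded == []

    def test_on_stripe_edge_pixel_excluded(self):
        data = np.zeros((64, 64), bool)
        data[:, 30:33] = True
        stripes = StripeMask(data=data, clusters=(), pe_axis="rows")
        records = [_record(0, 10, 30), _record(1, 10, 29)]  # edge vs 1 px off
        included, excluded = censor(records, stripes)
        assert [r.id for r in excluded] == [0]
        assert excluded[0].exclusion_reason == "ghost_stripe"
        assert [r.id for r in included] == [1]

    def test_partition_property(self, rng):
        data = rng.uniform(size=(64, 64)) < 0.3
        stripes = StripeMask(data=data, clusters=(), pe_axis="rows")
        records = [
            _record(i, int(rng.integers(64)), int(rng.integers(64))) for i in range(30)
        ]
        included, excluded = censor(records, stripes)
        assert len(included) + len(excluded) == len(records)
        assert {r.id for r in included} | {r.id for r in excluded} == set(range(30))
        assert {r.id for r in included} & {r.id for r in excluded} == set()
        # order preserved within each list
        assert [r.id for r in included] == sorted(r.id for r in included)
        assert [r.id for r in excluded] == sorted(r.id for r in excluded)


class TestGhostFraction:
    def test_bounds_and_direct_count(self):
        wm = CentralWMMask(data=np.ones((100, 100), bool), margin_px=0)
        empty = StripeMask(data=np.zeros((100, 100), bool), clusters=(), pe_axis="rows")
        assert ghost_fraction(wm, empty) == 0.0
        full = StripeMask(data=np.ones((100, 100), bool), clusters=(), pe_axis="rows")
        assert ghost_fraction(wm, full) == 100.0
        data = np.zeros((100, 100), bool)
        data[:, :30] = True  # 30 full pe-axis lines
        assert ghost_fraction(wm, StripeMask(data=data, clusters=(), pe_axis="rows")) == 30.0

    def test_empty_wm_rejected(self):
        wm = CentralWMMask(data=np.zeros((10, 10), bool), margin_px=0)
        stripes = StripeMask(data=np.zeros((10, 10), bool), clusters=(), pe_axis="rows")
        with pytest.raises(DegenerateInputError):
            ghost_fraction(wm, stripes)


class TestCensoringMonotonicity:
    def test_growing_stripes_never_add_inclusions(self, small_noisy_phantom):
        spec, series, truth = small_noisy_phantom
        base = small_config()
        n_included, gfrac = [], []
        for overrides in (
            dict(small_extend=40, big_extend=40, small_dilate=1, big_dilate=1),
            dict(small_extend=80, big_extend=80, small_dilate=2, big_dilate=2),
            dict(small_extend=128, big_extend=128, small_dilate=3, big_dilate=3,
                 vessel_top_fraction=0.006),
        ):
            import dataclasses

            cfg = dataclasses.replace(base, **overrides)
            result = run_pipeline(series, truth.wm_mask, truth.brain_mask, cfg)
            n_included.append(len(result.included))
            gfrac.append(result.ghost_fraction)
        assert n_included[0] >= n_included[1] >= n_included[2]
        assert gfrac[0] <= gfrac[1] <= gfrac[2]
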