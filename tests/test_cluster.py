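import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from scnwave import circstats, cluster, stack_io, synth
from conftest import roi_truth_labels


@pytest.fixture(scope="module")
def banded_result(banded_rois):
    rois, norm, gt = banded_rois
    return cluster.kmeans_timeseries(rois, k=5, seed=0, series=norm), rois, gt


class TestKMeansTimeseries:
    def test_planted_bands_recovered(self, banded_result):
        result, rois, gt = banded_result
        truth = roi_truth_labels(rois, gt)
        keep = truth >= 0
        assert adjusted_rand_score(truth[keep], result.labels[keep]) >= 0.9

    def test_seeded_determinism(self, banded_rois):
        rois, norm, _ = banded_rois
        a = cluster.kmeans_timeseries(rois, k=5, seed=11, series=norm)
        b = cluster.kmeans_timeseries(rois, k=5, seed=11, series=norm)
        assert np.array_equal(a.labels, b.labels)

    def test_stability_across_seeds(self, banded_rois):
        rois, norm, _ = banded_rois
        a = cluster.kmeans_timeseries(rois, k=5, seed=0, series=norm)
        b = cluster.kmeans_timeseries(rois, k=5, seed=123, series=norm)
        assert adjusted_rand_score(a.labels, b.labels) >= 0.9

    def test_sizes_partition_rois(self, banded_result):
        result, rois, _ = banded_result
        assert result.sizes.sum() == rois.n_roi
        assert (result.sizes >= 1).all()

    def test_com_inside_member_bounding_box(self, banded_result):
        result, _, _ = banded_result
        for c in range(result.k):
            members = result.roi_centers[result.labels == c]
            assert members[:, 0].min() <= result.com[c, 0] <= members[:, 0].max()
            assert members[:, 1].min() <= result.com[c, 1] <= members[:, 1].max()

    def test_fewer_rois_than_k_rejected(self, banded_rois):
        rois, norm, _ = banded_rois
        with pytest.raises(ValueError):
            cluster.kmeans_timeseries(rois, k=rois.n_roi + 1, series=norm)

    def test_identical_series_reduce_k_with_warning(self, banded_rois):
        rois, _, _ = banded_rois
        const = np.tile(np.sin(np.arange(rois.series.shape[1])), (rois.n_roi, 1))
        with pytest.warns(UserWarning, match="reducing k"):
            result = cluster.kmeans_timeseries(rois, k=5, seed=0, series=const)
        assert result.k == 1


class TestDerivedStatisticInvariance:
    def test_label_permutation_leaves_statistics_unchanged(self, banded_result):
        result, _, _ = banded_result
        perm = np.array([3, 0, 4, 1, 2])
        inv = np.argsort(perm)
        permuted = cluster.ClusterResult(
            k=result.k,
            labels=inv[result.labels],
            mean_series=result.mean_series[perm],
            fits=[result.fits[i] for i in perm],
            com=result.com[perm],
            inertia=result.inertia,
            seed=result.seed,
            roi_centers=result.roi_centers,
            roi_size=result.roi_size,
            frame_interval_h=result.frame_interval_h,
        )
        for res in (result, permuted):
            res.rhythmic_fits = [f for f in res.fits if f.is_rhythmic]
        stat = lambda r: (
            circstats.circular_variance(
                circstats.PhaseSample.from_hours([f.circ_phase_h for f in r.rhythmic_fits])
            ),
            circstats.period_dispersion(r.rhythmic_fits),
            cluster.wave_vector(r).angle_rad,
        )
        a, b = stat(result), stat(permuted)
        assert a[0] == pytest.approx(b[0], abs=1e-12)
        assert a[1] == pytest.approx(b[1], abs=1e-12)
        assert a[2] == pytest.approx(b[2], abs=1e-9)


class TestClusterPhaseMap:
    def test_phase_monotone_along_wave_axis(self, banded_result):
        result, rois, gt = banded_result
        phase_img, _ = cluster.cluster_phase_map(result, gt.tissue_mask.shape)
        cols = np.arange(phase_img.shape[1])
        col_mean = np.array(
            [
                phase_img[:, c][~np.isnan(phase_img[:, c])].mean()
                if np.any(~np.isnan(phase_img[:, c]))
                else np.nan
                for c in cols
            ]
        )
        valid = ~np.isnan(col_mean)
        # wave planted along +col: column-mean peak time increases
        assert np.polyfit(cols[valid], col_mean[valid], 1)[0] > 0

    def test_single_cluster_constant_map(self, banded_rois):
        rois, norm, _ = banded_rois
        res = cluster.kmeans_timeseries(rois, k=2, seed=0, series=norm)
        one = cluster.ClusterResult(
            k=1,
            labels=np.zeros(rois.n_roi, dtype=int),
            mean_series=res.mean_series[:1],
            fits=res.fits[:1],
            com=res.com[:1],
            inertia=0.0,
            seed=0,
            roi_centers=rois.roi_centers,
            roi_size=rois.roi_size,
            frame_interval_h=rois.frame_interval_h,
        )
        phase_img, _ = cluster.cluster_phase_map(one, (48, 48))
        vals = phase_img[~np.isnan(phase_img)]
        assert np.unique(vals).size == 1

    def test_shape_mismatch_rejected(self, banded_result):
        result, _, _ = banded_result
        with pytest.raises(ValueError):
            cluster.cluster_phase_map(result, (10, 10))


class TestWaveVector:
    def test_two_clusters_exact_line(self, banded_rois):
        rois, norm, _ = banded_rois
        res = cluster.kmeans_timeseries(rois, k=2, seed=0, series=norm)
        wv = cluster.wave_vector(res)
        assert wv.defined
        assert wv.r2 == pytest.approx(1.0, abs=1e-9)

    def test_planted_angle_zero_recovered(self, banded_result):
        result, _, gt = banded_result
        wv = cluster.wave_vector(result)
        assert wv.defined
        assert abs(wv.angle_deg - np.degrees(gt.wave_angle_rad)) <= 10.0

    def test_rotating_stack_rotates_angle(self, banded_stack):
        stack, gt, _ = banded_stack
        rot = stack_io.FrameStack(
            frames=np.rot90(stack.frames, k=-1, axes=(1, 2)).copy(),
            frame_interval_h=stack.frame_interval_h,
        )
        mask_rot = np.rot90(gt.tissue_mask, k=-1).copy()
        rois = stack_io.tile_rois(stack_io.moving_average_detrend(rot, 24.5), mask_rot)
        norm = stack_io.normalize_series(rois.series)
        res = cluster.kmeans_timeseries(rois, k=5, seed=0, series=norm.values)
        wv = cluster.wave_vector(res)
        expected = np.degrees(gt.wave_angle_rad) + 90.0  # clockwise image rotation
        diff = (wv.angle_deg - expected + 180.0) % 360.0 - 180.0
        assert abs(diff) <= 10.0

    def test_synchronous_tissue_flagged_or_weak(self):
        params = synth.SynthParams(
            grid_shape=(48, 48), n_frames=240, phase_span_h=0.0,
            noise_model="poisson", seed=9,
        )
        stack, gt = synth.generate_stack(params)
        rois = stack_io.tile_rois(stack_io.moving_average_detrend(stack, 24.5), gt.tissue_mask)
        norm = stack_io.normalize_series(rois.series)
        res = cluster.kmeans_timeseries(rois, k=5, seed=0, series=norm.values)
        phases = [f.abs_phase_h for f in res.fits if f.is_rhythmic]
        assert np.ptp(phases) < 1.0  # all clusters near-identical phase
        wv = cluster.wave_vector(res)
        assert (not wv.defined) or wv.r2 < 0.5

    def test_fewer_than_two_rhythmic_clusters_flagged(self, banded_result):
        result, _, _ = banded_result
        nr_fits = [
            type(f)(**{**f.__dict__, "is_rhythmic": False}) for f in result.fits
        ]
        crippled = cluster.ClusterResult(
            k=result.k, labels=result.labels, mean_series=result.mean_series,
            fits=nr_fits, com=result.com, inertia=result.inertia, seed=result.seed,
            roi_centers=result.roi_centers, roi_size=result.roi_size,
            frame_interval_h=result.frame_interval_h,
        )
        wv = cluster.wave_vector(crippled)
        assert not wv.defined
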