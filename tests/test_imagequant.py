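"""Fixed-image measurements: line-profile ratios, control normalisation,
cluster ratio, puncta, migration index, cluster length."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import pdist

from folliquant import imagequant as iq
from folliquant.errors import NoClusterError
from tests.conftest import CYTOPLASM_OFFSET, MEMBRANE_LINES


def flat_image(pmrlc=100.0, phalloidin=100.0, shape=(64, 64), pixel_size=0.2):
    return iq.FollicleImage(
        {"pmrlc": np.full(shape, float(pmrlc)), "phalloidin": np.full(shape, float(phalloidin))},
        pixel_size,
    )


class TestMembraneRatio:
    def test_uniform_channels_ratio_one(self):
        m = iq.measure_membrane_ratio(flat_image(), ((10, 5), (10, 55)))
        assert m.ratio == 1.0

    def test_constructed_peak_ratio(self):
        image = flat_image(pmrlc=100.0, phalloidin=150.0)
        image.channels["pmrlc"][:, 30:33] = 300.0  # 3 px plateau spans the smoother
        m = iq.measure_membrane_ratio(image, ((20, 5), (20, 55)))
        assert m.peak_pmrlc == pytest.approx(300.0, rel=1e-12)
        assert m.ratio == pytest.approx(2.0, rel=1e-12)

    @settings(derandomize=True, max_examples=20)
    @given(gain=st.floats(0.1, 20.0))
    def test_homogeneity_in_channel_gains(self, gain):
        image = flat_image(pmrlc=100.0, phalloidin=150.0)
        image.channels["pmrlc"][:, 30:33] = 300.0
        line = ((20, 5), (20, 55))
        base = iq.measure_membrane_ratio(image, line).ratio
        scaled_num = iq.FollicleImage(
            {"pmrlc": image.channels["pmrlc"] * gain, "phalloidin": image.channels["phalloidin"]},
            0.2,
        )
        both = iq.FollicleImage(
            {name: ch * gain for name, ch in image.channels.items()}, 0.2
        )
        assert iq.measure_membrane_ratio(scaled_num, line).ratio == pytest.approx(
            gain * base, rel=1e-9
        )
        assert iq.measure_membrane_ratio(both, line).ratio == pytest.approx(base, rel=1e-9)

    def test_line_shorter_than_smoother_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            iq.measure_membrane_ratio(flat_image(), ((10, 10), (10, 10)), smooth_window=5)

    def test_zero_normalisation_channel_rejected(self):
        image = flat_image(phalloidin=0.0)
        with pytest.raises(ValueError, match="undefined ratio"):
            iq.measure_membrane_ratio(image, ((10, 5), (10, 55)))


class TestFollicleScore:
    def test_mean_of_three_lines(self):
        image = flat_image(pmrlc=100.0, phalloidin=100.0)
        image.channels["pmrlc"][10, :] = 100.0  # keep flat; score is 1
        score = iq.follicle_membrane_score(
            image, [((5, 5), (5, 55)), ((20, 5), (20, 55)), ((40, 5), (40, 55))]
        )
        assert score == 1.0

    def test_wrong_line_count_rejected(self):
        with pytest.raises(ValueError, match="exactly 3"):
            iq.follicle_membrane_score(flat_image(), [((5, 5), (5, 55))])

    def test_synthetic_scene_score_near_truth(self, default_scene):
        image, truth = default_scene
        score = iq.follicle_membrane_score(image, MEMBRANE_LINES)
        assert score == pytest.approx(truth.membrane_ratio.iloc[0], rel=0.05)

    def test_noiseless_scene_score_exact(self, noiseless_scene):
        image, truth = noiseless_scene
        score = iq.follicle_membrane_score(image, MEMBRANE_LINES)
        assert score == pytest.approx(truth.membrane_ratio.iloc[0], rel=1e-9)


class TestControlNormalisation:
    def test_division_by_control_mean(self):
        np.testing.assert_allclose(iq.normalize_to_control([2, 4], [2, 2]), [1, 2])

    def test_control_normalised_to_unit_mean(self):
        control = np.array([1.4, 2.2, 1.8])
        assert iq.normalize_to_control(control, control).mean() == pytest.approx(1.0)
        # idempotent on an already-normalised control group
        once = iq.normalize_to_control(control, control)
        np.testing.assert_allclose(iq.normalize_to_control(once, once), once)

    def test_batchwise_normalisation_differs_from_pooled(self):
        batch1, ctrl1 = np.array([3.0, 5.0]), np.array([2.0, 2.0])
        batch2, ctrl2 = np.array([6.0, 10.0]), np.array([4.0, 4.0])
        per_batch = np.concatenate(
            [iq.normalize_to_control(batch1, ctrl1), iq.normalize_to_control(batch2, ctrl2)]
        )
        np.testing.assert_allclose(per_batch, [1.5, 2.5, 1.5, 2.5])
        pooled = iq.normalize_to_control(
            np.concatenate([batch1, batch2]), np.concatenate([ctrl1, ctrl2])
        )
        assert not np.allclose(per_batch, pooled)

    def test_nonpositive_control_rejected(self):
        with pytest.raises(ValueError):
            iq.normalize_to_control([1.0], [0.0, 0.0])


class TestClusterRatio:
    def test_uniform_image_ratio_one(self):
        image = flat_image(shape=(64, 64))
        mask = np.zeros((64, 64), bool)
        mask[10:20, 10:20] = True
        assert iq.cluster_pmrlc_ratio(image, mask, (30, 0)).ratio == 1.0

    def test_two_fold_cluster(self):
        image = flat_image(shape=(64, 64))
        mask = np.zeros((64, 64), bool)
        mask[10:20, 10:20] = True
        image.channels["pmrlc"][mask] = 200.0
        assert iq.cluster_pmrlc_ratio(image, mask, (30, 0)).ratio == pytest.approx(2.0)

    def test_synthetic_scene_ratio_near_truth(self, default_scene):
        image, truth = default_scene
        m = iq.cluster_pmrlc_ratio(image, cytoplasm_offset_px=CYTOPLASM_OFFSET)
        assert m.ratio == pytest.approx(truth.cluster_cytoplasm_ratio.iloc[0], rel=0.05)

    def test_noiseless_scene_ratio_exact(self, noiseless_scene):
        image, truth = noiseless_scene
        m = iq.cluster_pmrlc_ratio(image, cytoplasm_offset_px=CYTOPLASM_OFFSET)
        assert m.ratio == pytest.approx(truth.cluster_cytoplasm_ratio.iloc[0], rel=1e-9)

    def test_out_of_bounds_placement_rejected(self):
        image = flat_image(shape=(64, 64))
        mask = np.zeros((64, 64), bool)
        mask[10:20, 10:20] = True
        with pytest.raises(ValueError, match="invalid cytoplasm placement"):
            iq.cluster_pmrlc_ratio(image, mask, (60, 0))

    def test_membrane_overlap_rejected(self):
        membranes = np.zeros((64, 64), bool)
        membranes[40:45, :] = True
        image = iq.FollicleImage(
            {"pmrlc": np.full((64, 64), 100.0)}, 0.2, masks={"membranes": membranes}
        )
        mask = np.zeros((64, 64), bool)
        mask[10:20, 10:20] = True
        with pytest.raises(ValueError, match="membranes"):
            iq.cluster_pmrlc_ratio(image, mask, (30, 0))


class TestFixedPuncta:
    def test_blank_cluster_zero_count(self):
        image = flat_image(shape=(64, 64))
        mask = np.ones((64, 64), bool)
        count, lengths = iq.detect_fixed_puncta(image, mask)
        assert count == 0 and lengths.size == 0

    def test_two_bars_counted_with_feret_lengths(self):
        image = flat_image(pmrlc=10.0, shape=(64, 64), pixel_size=0.2)
        image.channels["pmrlc"][10, 10:13] = 200.0
        image.channels["pmrlc"][40, 30:33] = 200.0
        count, lengths = iq.detect_fixed_puncta(image, np.ones((64, 64), bool), min_area_px=3)
        assert count == 2
        # brute-force oracle: max pairwise distance of a 3 x 1 px bar
        oracle = pdist(np.array([[10, 10], [10, 11], [10, 12]])).max() * 0.2
        np.testing.assert_allclose(lengths, [oracle, oracle])
        assert oracle == pytest.approx(0.4)

    def test_rendered_spots_counted_exactly_without_noise(self):
        from folliquant.synthetic import TimelapseParams, simulate_timelapse

        p = TimelapseParams(n_frames=5, birth_rate_per_frame=2.0, photons_per_au=None, seed=4)
        movie, truth = simulate_timelapse(p)
        alive = ((truth.birth_frame <= 2) & (truth.birth_frame + truth.n_frames - 1 >= 2)).sum()
        image = iq.FollicleImage({"pmrlc": movie.frames[2]}, 0.2)
        count, _ = iq.detect_fixed_puncta(image, movie.cluster_mask)
        assert count == alive

    def test_empty_mask_rejected(self):
        with pytest.raises(NoClusterError):
            iq.detect_fixed_puncta(flat_image(), np.zeros((64, 64), bool))


class TestMigrationGeometry:
    @pytest.mark.parametrize(
        "border,follicle,expected,label",
        [
            (150.0, 150.0, 1.0, "on-time"),
            (117.0, 150.0, 0.78, "delayed"),
            (165.0, 150.0, 1.1, "accelerated"),
        ],
    )
    def test_index_value_and_band(self, border, follicle, expected, label):
        geom = iq.FollicleGeometry(border, follicle, 200.0)
        mi = iq.migration_index(geom)
        assert mi.value == pytest.approx(expected)
        assert mi.classification == label

    def test_scale_invariance(self):
        a = iq.migration_index(iq.FollicleGeometry(120.0, 150.0, 200.0))
        b = iq.migration_index(iq.FollicleGeometry(240.0, 300.0, 400.0))
        assert a.value == pytest.approx(b.value, rel=1e-12)

    def test_cluster_length(self):
        geom = iq.FollicleGeometry(150.0, 150.0, 200.0, cluster_front=100.0, cluster_rear=80.0)
        assert iq.cluster_length(geom) == 20.0
        degenerate = iq.FollicleGeometry(150.0, 150.0, 200.0, cluster_front=90.0, cluster_rear=90.0)
        assert iq.cluster_length(degenerate) == 0.0
        shifted = iq.FollicleGeometry(150.0, 150.0, 250.0, cluster_front=150.0, cluster_rear=130.0)
        assert iq.cluster_length(shifted) == 20.0

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            iq.FollicleGeometry(150.0, 250.0, 200.0)
        with pytest.raises(ValueError):
            iq.FollicleGeometry(150.0, 150.0, 200.0, cluster_front=80.0, cluster_rear=100.0)
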