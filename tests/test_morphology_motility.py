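"""Feature bank, pixel classification, mask cleanup, size and motility."""

import numpy as np
import pytest

from plasmogram import morphology_motility as mm
from plasmogram import phantom as ph

from conftest import flood_fill_oracle


def disk_mask(size, cx, cy, r):
    yy, xx = np.mgrid[0:size, 0:size]
    return (xx - cx) ** 2 + (yy - cy) ** 2 <= r**2


class TestFeatureBank:
    def test_default_bank_is_37_dimensional(self):
        cfg = mm.FeatureBankConfig()
        img = np.random.default_rng(0).random((48, 48))
        assert cfg.n_features == 37
        assert mm.compute_features(img, cfg).shape == (48, 48, 37)

    @pytest.mark.parametrize(
        "gauss, other, mode, expected",
        [
            ((0.3, 0.7, 1.0, 1.6, 3.5, 5.0, 10.0), (0.7, 1.0, 1.6, 3.5, 5.0, 10.0), "largest", 37),
            ((0.3, 0.7, 1.0, 1.6, 3.5, 5.0, 10.0), (0.7, 1.0, 1.6, 3.5, 5.0, 10.0), "both", 49),
            ((1.0, 2.0), (1.0,), "largest", 7),
            ((1.0,), (1.0, 2.0), "both", 15),
        ],
    )
    def test_feature_count_matches_closed_form(self, gauss, other, mode, expected):
        cfg = mm.FeatureBankConfig(gaussian_radii=gauss, other_radii=other, eigen_summary=mode)
        assert cfg.n_features == expected
        img = np.random.default_rng(1).random((64, 64))
        assert mm.compute_features(img, cfg).shape[-1] == expected

    def test_constant_image_has_zero_derivative_features(self):
        cfg = mm.FeatureBankConfig(gaussian_radii=(1.0,), other_radii=(1.0, 2.0))
        f = mm.compute_features(np.full((40, 40), 0.7), cfg)
        interior = f[10:-10, 10:-10]
        # planes 1..6: LoG x2, gradient magnitude x2, DoG x2
        assert np.abs(interior[..., 1:7]).max() < 1e-10

    def test_impulse_gaussian_matches_analytic_kernel_peak(self):
        img = np.zeros((65, 65))
        img[32, 32] = 1.0
        cfg = mm.FeatureBankConfig(gaussian_radii=(1.6,), other_radii=(1.0,))
        f = mm.compute_features(img, cfg)
        assert f[32, 32, 0] == pytest.approx(1.0 / (2 * np.pi * 1.6**2), rel=0.01)

    def test_non_positive_radius_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            mm.FeatureBankConfig(gaussian_radii=(0.0, 1.0))


@pytest.fixture(scope="module")
def trained_setup():
    """Small phantom, classifier trained on ground-truth labels."""
    cfg = ph.PhantomConfig(
        seed=21, duration_min=90.0, bf_image_size=96,
        radius_start_px=22.0, radius_end_px=26.0,
    )
    frames, truth = ph.render_brightfield_stack(cfg)
    labels = np.where(truth.masks, mm.TUMOROID_LABEL, mm.BACKGROUND_LABEL).astype(np.uint8)
    clf = mm.train_classifier(frames[:6], labels[:6], seed=0, max_samples_per_class=3000)
    return cfg, frames, truth, clf


class TestClassifier:
    def test_training_is_deterministic(self, trained_setup):
        cfg, frames, truth, clf = trained_setup
        labels = np.where(truth.masks, 1, 2).astype(np.uint8)
        clf2 = mm.train_classifier(frames[:6], labels[:6], seed=0, max_samples_per_class=3000)
        np.testing.assert_array_equal(
            mm.segment(frames[-1], clf), mm.segment(frames[-1], clf2)
        )

    def test_heldout_frame_segmented_accurately(self, trained_setup):
        _, frames, truth, clf = trained_setup
        mask = mm.segment(frames[-1], clf)
        assert (mask == truth.masks[-1]).mean() >= 0.99

    def test_single_class_labels_rejected(self, trained_setup):
        _, frames, _, _ = trained_setup
        labels = np.full(frames[:2].shape, 2, dtype=np.uint8)
        with pytest.raises(ValueError, match="both"):
            mm.train_classifier(frames[:2], labels, seed=0)

    def test_feature_config_mismatch_rejected(self, trained_setup):
        _, frames, _, clf = trained_setup
        other = mm.FeatureBankConfig(gaussian_radii=(1.0, 2.0), other_radii=(1.0,))
        with pytest.raises(ValueError, match="configuration"):
            mm.segment(frames[0], clf, config=other)


class TestPostprocess:
    def test_solid_disk_unchanged_and_idempotent(self):
        m = disk_mask(64, 32, 32, 20)
        out, valid = mm.postprocess_mask(m)
        assert valid and np.array_equal(out, m)
        out2, _ = mm.postprocess_mask(out)
        assert np.array_equal(out2, out)

    def test_speck_removed_hole_filled_matches_flood_fill_oracle(self):
        m = disk_mask(64, 30, 30, 20)
        m[28:33, 28:33] = False  # interior hole
        m[2:5, 58:61] = True  # separate speck
        out, valid = mm.postprocess_mask(m)
        assert valid
        assert not out[3, 59]  # speck gone
        assert out[30, 30]  # hole filled
        assert int(out.sum()) == flood_fill_oracle(m)

    def test_empty_mask_flagged_invalid(self):
        out, valid = mm.postprocess_mask(np.zeros((16, 16), dtype=bool))
        assert not valid and not out.any()


class TestMeasureTrack:
    def test_stationary_disk_has_zero_total_displacement(self):
        masks = np.stack([disk_mask(64, 32, 32, 12)] * 10)
        track = mm.measure_track(masks, pixel_size_um=0.73)
        assert track.total_displacement_um == 0.0

    def test_scripted_walk_displacement_arithmetic(self):
        # centroid stepping 3 px/frame for 10 steps at 0.73 µm/px -> 21.9 µm
        masks = np.stack([disk_mask(128, 20 + 3 * i, 40, 10) for i in range(11)])
        track = mm.measure_track(masks, pixel_size_um=0.73)
        assert track.total_displacement_um == pytest.approx(10 * 3 * 0.73, rel=1e-12)

    def test_disk_area_matches_pixel_count_and_analytic_area(self):
        m = disk_mask(128, 64, 64, 50)
        track = mm.measure_track(m[np.newaxis], pixel_size_um=1.0)
        assert track.areas_um2[0] == float(m.sum())  # exact pixel-count scaling
        assert track.areas_um2[0] == pytest.approx(np.pi * 50**2, rel=0.01)

    def test_invalid_frame_breaks_displacement_chain(self):
        frames = [disk_mask(64, 20, 32, 8), disk_mask(64, 24, 32, 8),
                  np.zeros((64, 64), dtype=bool), disk_mask(64, 40, 32, 8)]
        track = mm.measure_track(np.stack(frames), pixel_size_um=1.0)
        # only the 0->1 step counts; no step across the invalid frame
        assert track.total_displacement_um == pytest.approx(4.0)
        assert not track.valid[2]

    def test_total_displacement_invariant_under_global_translation(self):
        rng = np.random.default_rng(8)
        xs = 30 + np.cumsum(rng.integers(-2, 3, size=8))
        masks = np.stack([disk_mask(96, x, 48, 10) for x in xs])
        shifted = np.stack([np.roll(np.roll(m, 5, axis=0), 7, axis=1) for m in masks])
        a = mm.measure_track(masks, 0.73).total_displacement_um
        b = mm.measure_track(shifted, 0.73).total_displacement_um
        assert a == pytest.approx(b, abs=1e-9)

    def test_all_invalid_is_error(self):
        with pytest.raises(ValueError, match="empty track"):
            mm.measure_track(np.zeros((3, 8, 8), dtype=bool), 1.0)


def track_with_diameter(d_um, track_id=""):
    area = np.pi * (d_um / 2) ** 2
    n = 5
    return mm.TumoroidTrack(
        times_min=np.arange(n, dtype=float),
        areas_um2=np.full(n, area),
        centroids_um=np.zeros((n, 2)),
        valid=np.ones(n, dtype=bool),
        pixel_size_um=0.73,
        track_id=track_id,
        step_displacements_um=np.full(n, np.nan),
    )


class TestMotilityFilter:
    def test_effective_diameter_definition(self):
        assert mm.effective_diameter(np.pi * 75.0**2) == pytest.approx(150.0)

    def test_center_of_range_kept(self):
        assert mm.motility_filter([track_with_diameter(150.0)])

    def test_bounds_are_inclusive(self):
        assert not mm.motility_filter([track_with_diameter(129.0)])
        assert mm.motility_filter([track_with_diameter(130.0)])
        assert mm.motility_filter([track_with_diameter(170.0)])
        assert not mm.motility_filter([track_with_diameter(171.0)])

    def test_scripted_cohort_membership(self):
        cohort = [track_with_diameter(d, str(d)) for d in (100, 135, 150, 169, 180)]
        kept = mm.motility_filter(cohort)
        assert sorted(t.track_id for t in kept) == ["135", "150", "169"]

    def test_inverted_bounds_rejected(self):
        with pytest.raises(ValueError):
            mm.motility_filter([], 170.0, 130.0)
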