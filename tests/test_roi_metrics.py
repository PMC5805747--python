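"""ROI statistics, CNR, automatic ROI placement, and area quantification."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from darkfield_thorax.phantom import PneumothoraxSpec, induce_pneumothorax
from darkfield_thorax.roi_metrics import (
    ROI,
    auto_cnr_rois,
    cnr,
    projected_area,
    retro_band_params,
    roi_stats,
    rois_from_json,
    segment_inflated_lung,
)


def _roi_from_box(shape, r0, r1, c0, c1, label="lung"):
    mask = np.zeros(shape, bool)
    mask[r0:r1, c0:c1] = True
    return ROI(mask, label)


class TestROIStats:
    def test_constant_image(self):
        img = np.full((20, 20), 2.5)
        s = roi_stats(img, _roi_from_box(img.shape, 2, 10, 2, 10))
        assert (s.mean, s.sd) == (2.5, 0.0)
        assert s.n_pixels == 64

    def test_two_pixel_sample_sd(self):
        img = np.zeros((4, 4))
        img[0, 1] = 2.0
        mask = np.zeros((4, 4), bool)
        mask[0, 0] = mask[0, 1] = True
        s = roi_stats(img, ROI(mask, "lung"))
        assert s.mean == pytest.approx(1.0)
        assert s.sd == pytest.approx(np.sqrt(2.0))

    def test_matches_bruteforce_loop(self, rng):
        img = rng.uniform(0, 1, (30, 30))
        mask = rng.random((30, 30)) < 0.3
        s = roi_stats(img, ROI(mask, "lung"))
        vals = [img[r, c] for r in range(30) for c in range(30) if mask[r, c]]
        assert s.mean == pytest.approx(np.mean(vals))
        assert s.sd == pytest.approx(np.std(vals, ddof=1))
        assert s.n_pixels == len(vals)

    def test_empty_roi_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            ROI(np.zeros((5, 5), bool), "lung")


class TestCNR:
    def test_printed_formula_substitution(self, rng):
        """mu_L=3, mu_P=1, sigma_L=sigma_P=1 gives 2/sqrt(2)."""
        img = np.zeros((2, 400))
        img[0] = 3.0 + np.where(np.arange(400) % 2 == 0, 1.0, -1.0)
        img[1] = 1.0 + np.where(np.arange(400) % 2 == 0, 1.0, -1.0)
        roi_l = _roi_from_box(img.shape, 0, 1, 0, 400, "lung")
        roi_p = _roi_from_box(img.shape, 1, 2, 0, 400, "pneumothorax")
        sd = img[0].std(ddof=1)  # ~1 up to the ddof correction
        expected = 2.0 / np.sqrt(2.0 * sd**2)
        assert cnr(img, roi_l, roi_p) == pytest.approx(expected, rel=1e-12)

    def test_identical_regions_give_zero(self, rng):
        img = rng.uniform(0, 1, (20, 40))
        img[:, 20:] = img[:, :20]
        roi_l = _roi_from_box(img.shape, 0, 20, 0, 20)
        roi_p = _roi_from_box(img.shape, 0, 20, 20, 40, "pneumothorax")
        assert cnr(img, roi_l, roi_p) == pytest.approx(0.0, abs=1e-12)

    def test_symmetry(self, rng):
        img = rng.uniform(0, 1, (20, 40))
        roi_a = _roi_from_box(img.shape, 0, 20, 0, 18)
        roi_b = _roi_from_box(img.shape, 0, 20, 20, 40, "pneumothorax")
        assert cnr(img, roi_a, roi_b) == pytest.approx(cnr(img, roi_b, roi_a))

    def test_overlapping_rois_rejected(self, rng):
        img = rng.uniform(0, 1, (10, 10))
        roi_a = _roi_from_box(img.shape, 0, 5, 0, 6)
        roi_b = _roi_from_box(img.shape, 0, 5, 5, 10, "pneumothorax")
        with pytest.raises(ValueError, match="disjoint"):
            cnr(img, roi_a, roi_b)

    def test_zero_noise_rejected(self):
        img = np.zeros((4, 8))
        img[:, 4:] = 1.0
        with pytest.raises(ValueError, match="undefined"):
            cnr(
                img,
                _roi_from_box(img.shape, 0, 4, 0, 4),
                _roi_from_box(img.shape, 0, 4, 4, 8, "pneumothorax"),
            )

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(
        scale=st.floats(0.01, 100.0),
        offset=st.floats(-50.0, 50.0),
        flip=st.booleans(),
    )
    def test_affine_invariance(self, scale, offset, flip):
        """CNR is invariant under a*x + b for any a != 0."""
        rng = np.random.default_rng(99)
        img = rng.uniform(0.2, 1.0, (16, 32))
        roi_l = _roi_from_box(img.shape, 2, 14, 2, 14)
        roi_p = _roi_from_box(img.shape, 2, 14, 18, 30, "pneumothorax")
        a = -scale if flip else scale
        base = cnr(img, roi_l, roi_p)
        assert cnr(a * img + offset, roi_l, roi_p) == pytest.approx(
            base, rel=1e-9
        )


class TestAutoROIs:
    def test_rois_exclude_ribs_and_are_disjoint(self, smoke_phantom):
        pneu = induce_pneumothorax(
            smoke_phantom, PneumothoraxSpec(side="left", air_volume=400.0)
        )
        roi_l, roi_p = auto_cnr_rois(pneu, "left")
        assert not (roi_l.mask & roi_p.mask).any()
        assert not (roi_l.mask & pneu.masks["ribs"]).any()
        assert not (roi_l.mask & pneu.masks["heart"]).any()
        assert (roi_p.mask & pneu.masks["pleural_gas"]).sum() == roi_p.n_pixels
        assert (roi_l.mask & pneu.masks["left_lung"]).sum() == roi_l.n_pixels

    def test_missing_gas_band_rejected(self, smoke_phantom):
        with pytest.raises(ValueError, match="pleural gas"):
            auto_cnr_rois(smoke_phantom, "left")

    def test_manual_json_rois(self):
        spec = [{"label": "lung", "runs": [[0, 1, 4], [1, 0, 2]]}]
        (roi,) = rois_from_json(spec, (4, 6))
        assert roi.n_pixels == 5
        assert roi.mask[0, 1] and roi.mask[0, 3] and not roi.mask[0, 4]


class TestSegmentation:
    def test_noiseless_dice_against_truth(self, smoke_phantom, noiseless_pair):
        """Segmentation recovers the retro-diaphragmatic truth, Dice >= 0.95."""
        for side in ("left", "right"):
            mask = segment_inflated_lung(
                noiseless_pair.darkfield, side,
                retro_band_params(smoke_phantom, side),
            )
            truth = smoke_phantom.masks[f"retro_diaphragmatic_lung_{side}"]
            dice = 2.0 * (mask & truth).sum() / (mask.sum() + truth.sum())
            assert dice >= 0.95
            area = projected_area(mask, smoke_phantom.pixel_size)
            truth_area = smoke_phantom.truth[f"retro_diaphragmatic_lung_{side}"]
            assert area == pytest.approx(truth_area, rel=0.05)

    def test_affected_side_shrinks_after_induction(
        self, smoke_phantom, smoke_geometry, noiseless_settings, noiseless_pair
    ):
        from darkfield_thorax.interferometer import simulate_reference, simulate_scan
        from darkfield_thorax.retrieval import retrieve

        pneu = induce_pneumothorax(
            smoke_phantom,
            PneumothoraxSpec(side="right", location="dorsal",
                             collapse_fraction=0.25),
        )
        ref = simulate_reference(smoke_geometry, noiseless_settings)
        pair = retrieve(
            simulate_scan(pneu, smoke_geometry, noiseless_settings), ref
        )
        params = retro_band_params(smoke_phantom, "right")
        before = segment_inflated_lung(noiseless_pair.darkfield, "right", params)
        after = segment_inflated_lung(pair.darkfield, "right", params)
        assert after.sum() < before.sum()

    def test_no_scatter_yields_empty_mask(self, smoke_phantom):
        flat = np.ones(smoke_phantom.grid_shape)
        with pytest.warns(UserWarning, match="no inflated lung"):
            mask = segment_inflated_lung(
                flat, "left", retro_band_params(smoke_phantom, "left")
            )
        assert mask.sum() == 0


class TestProjectedArea:
    def test_pixel_count_scaling(self):
        mask = np.zeros((200, 200), bool)
        mask.flat[:10000] = True
        assert projected_area(mask, 0.036) == pytest.approx(12.96)

    def test_cohort_mean_area_pixel_count(self):
        """48457 px at 360 um is the 62.8 cm^2 mean affected baseline area."""
        mask = np.zeros((250, 250), bool)
        mask.flat[:48457] = True
        assert projected_area(mask, 0.036) == pytest.approx(62.8, abs=0.01)

    def test_empty_mask_and_bad_pixel_size(self):
        assert projected_area(np.zeros((5, 5), bool), 0.036) == 0.0
        with pytest.raises(ValueError):
            projected_area(np.ones((5, 5), bool), 0.0)
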