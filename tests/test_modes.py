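"""Patterning-mode calling: score field, pigment mask, classification."""
import numpy as np
import pytest

import petalign as pa
from petalign.errors import InputError
from petalign.frame import HomologousROI
from petalign.modes import pigment_mask, pigment_score


def _roi(gray_field, valid=None):
    """ROI with the given gray field (0..1) replicated over RGB."""
    g = np.clip(np.asarray(gray_field, float) * 255, 0, 255).astype(np.uint8)
    px = np.stack([g] * 3, axis=2)
    valid = np.ones(g.shape, bool) if valid is None else valid
    return HomologousROI(pixels=px, validity_mask=valid)


class TestPigmentScore:
    def test_uniform_roi_scores_zero(self):
        f = pigment_score(_roi(np.full((20, 20), 0.8)))
        assert np.allclose(f, 0.0)

    def test_dark_spot_scores_positive_exactly_there(self):
        g = np.full((20, 20), 0.8)
        g[5:8, 5:8] = 0.4
        f = pigment_score(_roi(g))
        assert (f[5:8, 5:8] > 0.3).all()
        outside = np.ones((20, 20), bool)
        outside[5:8, 5:8] = False
        assert np.abs(f[outside]).max() < 0.01

    def test_brightness_shift_invariance(self):
        g = np.full((20, 20), 0.7)
        g[4:9, 4:9] = 0.4
        f1 = pigment_score(_roi(g))
        f2 = pigment_score(_roi(g + 0.08))
        assert np.abs(f1 - f2).max() < 0.01

    def test_empty_mask_rejected(self):
        with pytest.raises(InputError):
            pigment_score(_roi(np.full((8, 8), 0.5), np.zeros((8, 8), bool)))


class TestPigmentMask:
    def test_uniform_field_has_no_pigment(self):
        mask, has = pigment_mask(np.zeros((30, 30)))
        assert not has and not mask.any()

    def test_two_level_field_masks_the_dark_fifth(self):
        # Otsu of a single positive level falls mid-way, below the level
        f = np.zeros((30, 30))
        f[:6, :] = 0.3  # exactly 20% of pixels
        mask, has = pigment_mask(f)
        assert has
        assert mask.sum() == 180 and mask[:6].all()

    def test_tiny_speck_below_min_fraction(self):
        f = np.zeros((40, 40))
        f[0, :3] = 0.3
        _, has = pigment_mask(f)
        assert not has


class TestClassifySpecimen:
    """Against generator ground truth, end-to-end calls are exercised in the
    cohort tests; here the per-family logic on constructed fields."""

    def test_shape_mismatch_rejected(self, frame):
        roi = _roi(np.full((10, 10), 0.5))
        with pytest.raises(InputError):
            pa.classify_specimen(roi, frame)

    def test_unpigmented_specimen_is_none_none(self, frame):
        g = np.full(frame.shape, 0.8)
        roi = _roi(g, frame.frame_mask())
        call = pa.classify_specimen(roi, frame)
        assert (call.variegated, call.gradient) == ("none", "none")

    def test_vein_corridor_pigment_called_vascular(self, frame):
        g = np.full(frame.shape, 0.8)
        corridor = frame.vein_corridor(4.0)
        g[corridor] = 0.5
        roi = _roi(g, frame.frame_mask())
        call = pa.classify_specimen(roi, frame)
        assert call.variegated == "vascular" and call.gradient == "none"
        assert call.vein_enrichment >= 1.5

    def test_offvein_blobs_called_random(self, frame):
        g = np.full(frame.shape, 0.8)
        rng = np.random.default_rng(0)
        corridor = frame.vein_corridor(12.0)
        fm = frame.frame_mask()
        ok = np.argwhere(fm & ~corridor)
        ok = ok[(ok[:, 0] > 20) & (ok[:, 0] < frame.height - 15)]
        for r, c in ok[rng.choice(len(ok), 15, replace=False)]:
            rr, cc = np.mgrid[r - 4 : r + 5, c - 4 : c + 5]
            keep = (rr >= 0) & (rr < frame.height) & (cc >= 0) & (cc < frame.width)
            g[rr[keep], cc[keep]] = 0.5
        roi = _roi(g, fm)
        call = pa.classify_specimen(roi, frame)
        assert call.variegated == "random" and call.gradient == "none"

    def test_proximal_shading_called_proximal(self, frame):
        g = np.full(frame.shape, 0.8)
        yy = np.arange(frame.height, dtype=float)[:, None]
        t = yy / (frame.height - 1)
        g = g - 0.3 * np.clip((t - 0.55) / 0.45, 0, 1)
        roi = _roi(np.broadcast_to(g, frame.shape), frame.frame_mask())
        call = pa.classify_specimen(roi, frame)
        assert call.gradient == "proximal" and call.variegated == "none"
        assert call.gradient_delta < -0.04

    def test_distal_shading_called_distal(self, frame):
        yy = np.arange(frame.height, dtype=float)[:, None]
        t = yy / (frame.height - 1)
        g = 0.8 - 0.3 * np.clip(1 - t / 0.45, 0, 1)
        roi = _roi(np.broadcast_to(g, frame.shape), frame.frame_mask())
        call = pa.classify_specimen(roi, frame)
        assert call.gradient == "distal"


class TestAggregate:
    def test_majority_wins(self):
        calls = [
            pa.ModeCall("none", "distal", gradient_delta=0.1),
            pa.ModeCall("none", "distal", gradient_delta=0.1),
            pa.ModeCall("none", "none"),
        ]
        assert pa.aggregate_species(calls).gradient == "distal"

    def test_tie_broken_by_support(self):
        calls = [
            pa.ModeCall("none", "distal", gradient_delta=0.10),
            pa.ModeCall("none", "proximal", gradient_delta=-0.02),
        ]
        assert pa.aggregate_species(calls).gradient == "distal"

    def test_all_none_stays_none(self):
        calls = [pa.ModeCall("none", "none")] * 3
        agg = pa.aggregate_species(calls)
        assert (agg.variegated, agg.gradient) == ("none", "none")

    def test_none_wins_at_half(self):
        calls = [
            pa.ModeCall("vascular", "none", vein_enrichment=3.0),
            pa.ModeCall("none", "none"),
        ]
        assert pa.aggregate_species(calls).variegated == "none"

    def test_empty_list_rejected(self):
        with pytest.raises(InputError):
            pa.aggregate_species([])

    def test_mutual_exclusivity_by_construction(self):
        with pytest.raises(InputError):
            pa.ModeCall("both", "distal")


class TestCohortRecovery:
    def test_specimen_calls_match_generator_truth(self, four_mode_results):
        cohort, _, _, calls = four_mode_results
        truth = cohort.manifest
        hits = [
            (c.variegated, c.gradient) == (tv, tg)
            for c, tv, tg in zip(calls, truth["variegated"], truth["gradient"])
        ]
        assert np.mean(hits) >= 0.95

    def test_species_aggregation_matches_truth(self, four_mode_results):
        cohort, _, _, calls = four_mode_results
        truth = cohort.manifest
        for sp in truth["species"].unique():
            idx = truth.index[truth["species"] == sp].tolist()
            agg = pa.aggregate_species([calls[i] for i in idx])
            assert agg.variegated == truth.loc[idx[0], "variegated"]
            assert agg.gradient == truth.loc[idx[0], "gradient"]

    def test_combined_random_and_proximal_modes(self):
        spec = pa.generate_specimen(
            pa.SpecimenParams(spot_amp=0.55, proximal_amp=0.55), seed=9
        )
        roi = pa.process_specimen(
            spec.fresh_image,
            spec.truth_annotation_hist,
            spec.control_points,
            hist_image=spec.hist_image,
        )
        call = pa.classify_specimen(roi, pa.build_frame())
        assert (call.variegated, call.gradient) == ("random", "proximal")
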